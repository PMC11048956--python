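"""Dataset construction: FASTA/GFF3 parsing, site derivation, windows,
negative mining, dedup, balance/split and one-hot encoding."""

from __future__ import annotations

import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import resplice.datasets as ds


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


# ---------------------------------------------------------------------------
# FASTA reading
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_uppercases_lowercase_input(self, tmp_path):
        recs = ds.read_fasta(write(tmp_path, "a.fa", ">chr1\nacgt\n"))
        assert len(recs) == 1
        assert recs[0].seq_id == "chr1"
        assert recs[0].sequence == "ACGT"

    def test_ambiguity_codes_become_n(self, tmp_path):
        recs = ds.read_fasta(write(tmp_path, "a.fa", ">c\nACGTRY\n"))
        assert recs[0].sequence == "ACGTNN"

    def test_empty_file_errors_naming_line(self, tmp_path):
        with pytest.raises(ds.FastaParseError, match="line 1"):
            ds.read_fasta(write(tmp_path, "a.fa", ""))

    def test_missing_header_errors_naming_line(self, tmp_path):
        with pytest.raises(ds.FastaParseError, match="line 1"):
            ds.read_fasta(write(tmp_path, "a.fa", "ACGT\n"))

    def test_simulator_fasta_round_trips(self, tiny_sim, tiny_sim_paths):
        recs = ds.read_fasta(tiny_sim_paths["fasta"])
        assert len(recs) == len(tiny_sim.genomes)
        for got, want in zip(recs, tiny_sim.genomes):
            assert got.seq_id == want.seq_id
            assert len(got) == len(want)
            assert got.sequence == want.sequence


# ---------------------------------------------------------------------------
# Splice-site derivation
# ---------------------------------------------------------------------------

GFF_HEADER = "##gff-version 3\n"


def toy_gff(tmp_path, body):
    return write(tmp_path, "t.gff3", GFF_HEADER + body)


def toy_genome(seq="A" * 40):
    return {"c": ds.GenomeSequence("c", seq)}


class TestDeriveSpliceSites:
    def test_intron_boundaries_from_exon_chain(self, tmp_path):
        # exons [1,10] and [21,30]: intron [11,20], donor at 11, acceptor at 19
        seq = "A" * 10 + "GT" + "A" * 6 + "AG" + "A" * 20
        gff = toy_gff(tmp_path, "\n".join([
            "c\tx\tmRNA\t1\t30\t.\t+\t.\tID=t1",
            "c\tx\texon\t1\t10\t.\t+\t.\tID=e1;Parent=t1",
            "c\tx\texon\t21\t30\t.\t+\t.\tID=e2;Parent=t1",
        ]) + "\n")
        sites = ds.derive_splice_sites(gff, {"c": ds.GenomeSequence("c", seq)})
        by_type = {s.site_type: s for s in sites}
        assert by_type["donor"].position == 11
        assert by_type["donor"].dinucleotide == "GT"
        assert by_type["donor"].canonical
        assert by_type["acceptor"].position == 19
        assert by_type["acceptor"].dinucleotide == "AG"

    def test_minus_strand_is_skipped(self, tmp_path):
        gff = toy_gff(tmp_path, "\n".join([
            "c\tx\tmRNA\t1\t30\t.\t-\t.\tID=t1",
            "c\tx\texon\t1\t10\t.\t-\t.\tID=e1;Parent=t1",
            "c\tx\texon\t21\t30\t.\t-\t.\tID=e2;Parent=t1",
        ]) + "\n")
        assert ds.derive_splice_sites(gff, toy_genome()) == []

    def test_noncanonical_site_kept_with_flag(self, tmp_path):
        seq = "A" * 10 + "GC" + "A" * 6 + "AG" + "A" * 20  # GC-AG intron
        gff = toy_gff(tmp_path, "\n".join([
            "c\tx\tmRNA\t1\t30\t.\t+\t.\tID=t1",
            "c\tx\texon\t1\t10\t.\t+\t.\tID=e1;Parent=t1",
            "c\tx\texon\t21\t30\t.\t+\t.\tID=e2;Parent=t1",
        ]) + "\n")
        donor = [s for s in ds.derive_splice_sites(
            gff, {"c": ds.GenomeSequence("c", seq)}) if s.site_type == "donor"][0]
        assert donor.dinucleotide == "GC"
        assert not donor.canonical

    def test_overlapping_isoforms_collapse_duplicates(self, tmp_path):
        seq = "A" * 10 + "GT" + "A" * 6 + "AG" + "A" * 20
        rows = []
        for t in ("t1", "t2"):
            rows += [
                f"c\tx\tmRNA\t1\t30\t.\t+\t.\tID={t}",
                f"c\tx\texon\t1\t10\t.\t+\t.\tID={t}e1;Parent={t}",
                f"c\tx\texon\t21\t30\t.\t+\t.\tID={t}e2;Parent={t}",
            ]
        gff = toy_gff(tmp_path, "\n".join(rows) + "\n")
        sites = ds.derive_splice_sites(gff, {"c": ds.GenomeSequence("c", seq)})
        assert len(sites) == 2  # one donor + one acceptor, not four

    def test_exon_outside_contig_errors(self, tmp_path):
        gff = toy_gff(tmp_path, "\n".join([
            "c\tx\tmRNA\t1\t99\t.\t+\t.\tID=t1",
            "c\tx\texon\t1\t10\t.\t+\t.\tID=e1;Parent=t1",
            "c\tx\texon\t90\t99\t.\t+\t.\tID=e2;Parent=t1",
        ]) + "\n")
        with pytest.raises(ds.DatasetError, match="outside"):
            ds.derive_splice_sites(gff, toy_genome("A" * 40))

    def test_simulator_gff_yields_planted_counts(self, tiny_sim, tiny_sim_paths):
        sites = ds.derive_splice_sites(tiny_sim_paths["gff"],
                                       {g.seq_id: g for g in tiny_sim.genomes})
        n_donor = sum(1 for s in sites if s.site_type == "donor")
        n_acc = sum(1 for s in sites if s.site_type == "acceptor")
        truth_donor = sum(1 for s in tiny_sim.truth.sites if s.site_type == "donor")
        assert n_donor == truth_donor
        assert n_acc == truth_donor  # one acceptor per planted intron


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

class TestExtractWindow:
    def test_small_flank_slice_arithmetic(self):
        g = ds.GenomeSequence("c", "AAAGTCCC")
        ex = ds.extract_window(g, 4, ds.WindowSpec(flank=2), site_type="donor")
        assert isinstance(ex, ds.WindowExample)
        assert ex.sequence == "AAGTCC"
        assert len(ex.sequence) == 6
        assert ex.sequence[2:4] == "GT"

    def test_out_of_bounds_rejected(self):
        g = ds.GenomeSequence("c", "A" * 10_000)
        res = ds.extract_window(g, 100, ds.WindowSpec(flank=200), site_type="donor")
        assert isinstance(res, ds.WindowRejection)
        assert "out of bounds" in res.reason

    def test_n_in_window_rejected(self):
        g = ds.GenomeSequence("c", "AANAGTCC")
        res = ds.extract_window(g, 5, ds.WindowSpec(flank=2), site_type="donor")
        assert isinstance(res, ds.WindowRejection)
        assert "N" in res.reason

    def test_default_flank_gives_402_with_site_at_201(self):
        seq = "C" * 200 + "GT" + "C" * 200
        g = ds.GenomeSequence("c", seq)
        ex = ds.extract_window(g, 201, site_type="donor")
        assert isinstance(ex, ds.WindowExample)
        assert len(ex.sequence) == 402
        assert ex.sequence[200:202] == "GT"  # 1-based positions 201-202


# ---------------------------------------------------------------------------
# Negative mining and sampling
# ---------------------------------------------------------------------------

class TestNegativeMining:
    def test_finds_dinucleotide_respecting_exclusion(self):
        seq = "CCGTCCGTCC"
        g = ds.GenomeSequence("c", seq)
        spec = ds.WindowSpec(flank=2)
        got = ds.mine_negative_candidates(g, "donor", set(), spec)
        assert got == [3, 7]
        assert ds.mine_negative_candidates(g, "donor", {3}, spec) == [7]

    def test_matches_brute_force_scan(self, tiny_sim):
        g = tiny_sim.genomes[0]
        spec = ds.WindowSpec(flank=5)
        got = ds.mine_negative_candidates(g, "acceptor", set(), spec)
        brute = [
            m.start() + 1
            for m in re.finditer("(?=AG)", g.sequence)
            if m.start() + 1 - spec.flank >= 1
            and m.start() + 1 + spec.flank + 1 <= len(g)
            and "N" not in g.sequence[m.start() - spec.flank : m.start() + spec.flank + 2]
        ]
        assert got == brute

    def test_sampling_is_seeded_and_exhaustive(self):
        cands = list(range(100, 110))
        assert sorted(ds.sample_negatives(cands, 10, seed=1)) == cands
        assert ds.sample_negatives(cands, 5, seed=7) == ds.sample_negatives(cands, 5, seed=7)
        assert ds.sample_negatives(cands, 0, seed=1) == []

    def test_shortfall_reported(self):
        with pytest.raises(ds.DatasetError, match="short by 2"):
            ds.sample_negatives([1, 2, 3], 5, seed=0)


# ---------------------------------------------------------------------------
# Dedup / balance / split
# ---------------------------------------------------------------------------

def mk(seq, label="site", pos=1):
    return ds.WindowExample(seq, label, "donor", "c", pos)


class TestDeduplicate:
    def test_keeps_first_of_identical_windows(self):
        a, b = mk("ACGT", pos=1), mk("ACGT", pos=99)
        out = ds.deduplicate([a, b])
        assert out == [a]

    def test_unique_input_unchanged(self):
        xs = [mk("ACGT"), mk("TTTT"), mk("GGGG")]
        assert ds.deduplicate(xs) == xs

    def test_counts_match_hash_multiset(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(60)]
        xs = [mk(s, pos=i) for i, s in enumerate(seqs)]
        assert len(ds.deduplicate(xs)) == len(set(seqs))


class TestBalanceAndSplit:
    def test_proportions_100_100(self):
        pos = [mk(f"P{i}", "site", i) for i in range(100)]
        neg = [mk(f"N{i}", "non_site", i) for i in range(100)]
        s = ds.balance_and_split(pos, neg, seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (120, 30, 50)

    def test_larger_class_subsampled(self):
        pos = [mk(f"P{i}", "site", i) for i in range(100)]
        neg = [mk(f"N{i}", "non_site", i) for i in range(150)]
        s = ds.balance_and_split(pos, neg, seed=0)
        assert s.n_examples == 200

    @pytest.mark.parametrize("seed", [0, 1, 17])
    @pytest.mark.parametrize("n_pos,n_neg", [(50, 50), (101, 73), (64, 200)])
    def test_partitions_disjoint_exhaustive_balanced(self, seed, n_pos, n_neg):
        pos = [mk(f"P{i}", "site", i) for i in range(n_pos)]
        neg = [mk(f"N{i}", "non_site", i) for i in range(n_neg)]
        s = ds.balance_and_split(pos, neg, seed=seed)
        n = min(n_pos, n_neg)
        all_seqs = [e.sequence for part in s for e in part]
        assert len(all_seqs) == len(set(all_seqs)) == 2 * n  # disjoint+exhaustive
        for part in s:
            n_site = sum(1 for e in part if e.label == "site")
            assert abs(n_site - (len(part) - n_site)) <= 1  # balanced +/-1

    def test_seed_reproducible(self):
        pos = [mk(f"P{i}", "site", i) for i in range(40)]
        neg = [mk(f"N{i}", "non_site", i) for i in range(40)]
        a = ds.balance_and_split(pos, neg, seed=5)
        b = ds.balance_and_split(pos, neg, seed=5)
        assert [e.sequence for e in a.train] == [e.sequence for e in b.train]

    def test_empty_class_errors(self):
        with pytest.raises(ds.DatasetError):
            ds.balance_and_split([], [mk("A", "non_site")], seed=0)


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

class TestEncoding:
    def test_base_vectors(self):
        X = ds.encode_sequences(["ATGC"])
        assert np.array_equal(X[0], np.eye(4))
        assert np.array_equal(ds.encode_sequences(["A"])[0][0], [1, 0, 0, 0])

    def test_label_vectors(self):
        _, y_site = ds.encode(mk("ACGT", "site"))
        _, y_non = ds.encode(mk("ACGT", "non_site"))
        assert y_site.tolist() == [1, 0]
        assert y_non.tolist() == [0, 1]

    def test_rejects_n(self):
        with pytest.raises(ds.DatasetError):
            ds.encode_sequences(["ACGN"])

    @given(st.text(alphabet="ACGT", min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_bijection(self, seq):
        assert ds.decode(ds.encode_sequences([seq])[0]) == seq

    def test_rows_one_hot(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 30))
        X = ds.encode_sequences([seq])[0]
        assert np.all(X.sum(axis=1) == 1)
        assert np.all((X == 0) | (X == 1))


# ---------------------------------------------------------------------------
# Pipeline and on-disk round trip
# ---------------------------------------------------------------------------

class TestPipeline:
    def test_positive_windows_carry_annotated_dinucleotide(self, tiny_sim, tiny_sim_paths):
        splits, manifest = ds.build_dataset(
            tiny_sim_paths["fasta"], tiny_sim_paths["gff"], "donor", seed=0
        )
        truth = {
            (s.seq_id, s.position): s.dinucleotide
            for s in tiny_sim.truth.sites if s.site_type == "donor"
        }
        for part in splits:
            for e in part:
                core = e.sequence[200:202]
                if e.label == "site":
                    assert core == truth[(e.seq_id, e.position)]
                else:
                    assert core == "GT"  # negatives obey the GT-AG rule

    def test_positive_count_accounts_rejections(self, tiny_sim, tiny_sim_paths):
        splits, manifest = ds.build_dataset(
            tiny_sim_paths["fasta"], tiny_sim_paths["gff"], "donor", seed=0
        )
        assert (
            manifest["n_positive_windows"] + manifest["n_rejected_windows"]
            == manifest["n_annotated_sites"]
        )

    def test_write_read_round_trip(self, tiny_splits, tmp_path):
        splits, manifest = tiny_splits
        ds.write_dataset(splits, manifest, tmp_path / "d")
        back, manifest2 = ds.read_dataset(tmp_path / "d")
        assert manifest2["n_examples"] == manifest["n_examples"]
        assert [e.sequence for e in back.train] == [e.sequence for e in splits.train]
        assert [e.label for e in back.test] == [e.label for e in splits.test]
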