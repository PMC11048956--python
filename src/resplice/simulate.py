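"""Seeded synthetic genome + GFF3 generator with planted splice-site
structure.

Emits forward-strand gene models whose introns carry the sequence features a
splice-site model is expected to learn:

* consensus donor context MAG|GTAAGT and acceptor context ...YAG|G sampled
  from configurable position-weight matrices (the GT / AG cores are fixed,
  except for a configurable fraction of GC-AG donors standing in for
  non-canonical sites);
* a polypyrimidine tract (default 12 nt, 85% pyrimidine) immediately
  upstream of the acceptor YAG;
* a CTNA branch-point motif planted 20-40 nt upstream of the acceptor;
* higher G+C in exons (default 0.55) than introns (default 0.35), with
  intergenic background in between.

Every planted site is recorded as ground truth, and the emitted GFF3
round-trips through :func:`resplice.datasets.derive_splice_sites` to exactly
the planted site set, which makes the whole pipeline testable without any
genome download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .datasets import (
    DatasetSplits,
    GenomeSequence,
    SpliceSiteRecord,
    WindowSpec,
    build_dataset,
)

__all__ = [
    "SimulatorConfig",
    "GroundTruth",
    "SimulatedGenome",
    "simulate_genome",
    "make_fixture",
]

#: PWM column order used by the simulator.
PWM_ORDER = "ACGT"
_PWM_INDEX = {b: i for i, b in enumerate(PWM_ORDER)}


class SimulationError(ValueError):
    pass


def _pwm(rows: list[dict[str, float]]) -> np.ndarray:
    out = np.zeros((len(rows), 4))
    for i, row in enumerate(rows):
        for b, p in row.items():
            out[i, _PWM_INDEX[b]] = p
    return out


def default_donor_pwm() -> np.ndarray:
    """Exon positions -3..-1 then intron +1..+6; consensus MAG|GTAAGT with
    the GT core (+1, +2) fixed.

    The planted consensus is deliberately dominant (0.80-0.95 at the
    informative positions): the fixture's job is a recoverable signal at a
    few thousand examples, which a natural-frequency motif only yields at
    real-genome sample sizes.
    """
    return _pwm([
        {"A": 0.49, "C": 0.49, "G": 0.01, "T": 0.01},   # -3  M
        {"A": 0.95, "C": 0.02, "G": 0.02, "T": 0.01},   # -2  A
        {"A": 0.02, "C": 0.02, "G": 0.95, "T": 0.01},   # -1  G
        {"G": 1.0},                                      # +1  G (core)
        {"T": 1.0},                                      # +2  T (core)
        {"A": 0.96, "C": 0.02, "G": 0.01, "T": 0.01},   # +3  A
        {"A": 0.92, "C": 0.03, "G": 0.03, "T": 0.02},   # +4  A
        {"A": 0.02, "C": 0.02, "G": 0.95, "T": 0.01},   # +5  G
        {"A": 0.04, "C": 0.04, "G": 0.02, "T": 0.90},   # +6  T
    ])


def default_acceptor_pwm() -> np.ndarray:
    """Intron positions -3..-1 then first exon base; consensus YAG|G.
    The AG core (-2, -1) is fixed."""
    return _pwm([
        {"A": 0.03, "C": 0.52, "G": 0.03, "T": 0.42},   # -3  Y
        {"A": 1.0},                                      # -2  A (core)
        {"G": 1.0},                                      # -1  G (core)
        {"A": 0.22, "C": 0.11, "G": 0.56, "T": 0.11},   # +1  G
    ])


def variant_donor_pwm() -> np.ndarray:
    """An alternative donor context (TTC|GTCGCG) sharing only the GT core
    with the default — for 'unrelated organism' experiments."""
    return _pwm([
        {"A": 0.02, "C": 0.02, "G": 0.02, "T": 0.94},   # -3  T
        {"A": 0.03, "C": 0.04, "G": 0.03, "T": 0.90},   # -2  T
        {"A": 0.03, "C": 0.91, "G": 0.03, "T": 0.03},   # -1  C
        {"G": 1.0},                                      # +1  G (core)
        {"T": 1.0},                                      # +2  T (core)
        {"A": 0.02, "C": 0.95, "G": 0.02, "T": 0.01},   # +3  C
        {"A": 0.05, "C": 0.06, "G": 0.85, "T": 0.04},   # +4  G
        {"A": 0.03, "C": 0.91, "G": 0.03, "T": 0.03},   # +5  C
        {"A": 0.07, "C": 0.06, "G": 0.80, "T": 0.07},   # +6  G
    ])


def variant_acceptor_pwm() -> np.ndarray:
    """Alternative acceptor context (GAG|T) sharing only the AG core."""
    return _pwm([
        {"A": 0.35, "C": 0.05, "G": 0.55, "T": 0.05},   # -3  R (not Y)
        {"A": 1.0},                                      # -2  A (core)
        {"G": 1.0},                                      # -1  G (core)
        {"A": 0.125, "C": 0.25, "G": 0.125, "T": 0.50},  # +1  T
    ])


@dataclass(frozen=True)
class SimulatorConfig:
    n_contigs: int = 2
    contig_length: int = 120_000
    n_genes: int = 40
    exons_per_gene: tuple[int, int] = (3, 5)       # inclusive range
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 200)
    # rice-like site density (~1 donor per 5 kb): windows around negative
    # GT/AG picks rarely contain a planted site
    intergenic_gap: tuple[int, int] = (2500, 5300)
    margin: int = 250                              # contig-end clearance
    donor_pwm: np.ndarray = field(default_factory=default_donor_pwm)
    acceptor_pwm: np.ndarray = field(default_factory=default_acceptor_pwm)
    fraction_noncanonical: float = 0.01            # GC-AG donors
    exon_gc: float = 0.55
    intron_gc: float = 0.35
    intergenic_gc: float = 0.45
    ppt_length: int = 12
    ppt_pyrimidine_fraction: float = 0.85
    branch_motif: str | None = "CTNA"
    branch_offset: tuple[int, int] = (20, 40)      # nt upstream of acceptor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exon_gc", "intron_gc", "intergenic_gc"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise SimulationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("contig_length", "ppt_length"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be positive")
        if not 0 <= self.fraction_noncanonical <= 1:
            raise SimulationError("fraction_noncanonical must lie in [0, 1]")
        for pwm_name in ("donor_pwm", "acceptor_pwm"):
            pwm = getattr(self, pwm_name)
            if not np.allclose(pwm.sum(axis=1), 1.0):
                raise SimulationError(f"{pwm_name} rows must sum to 1")
        # an intron must hold the donor context, branch motif, PPT and YAG
        min_intron = self.intron_length[0]
        need = 6 + 3 + self.ppt_length + 2
        if self.branch_motif:
            need += len(self.branch_motif) + self.branch_offset[0]
        if min_intron < need:
            raise SimulationError(
                f"minimum intron length {min_intron} cannot hold the planted "
                f"features (need >= {need})"
            )

    @classmethod
    def tiny(cls, seed: int = 0) -> "SimulatorConfig":
        """~200 planted introns -> ~400-example balanced dataset."""
        return cls(n_contigs=2, contig_length=190_000, n_genes=68, seed=seed)

    @classmethod
    def small(cls, seed: int = 0) -> "SimulatorConfig":
        """~2,000 planted introns -> ~4,000-example balanced dataset."""
        return cls(n_contigs=3, contig_length=1_150_000, n_genes=660, seed=seed)

    def with_variant_motifs(self) -> "SimulatorConfig":
        """An 'unrelated organism': different donor/acceptor context PWMs,
        no PPT enrichment, no branch motif, and flat G+C across exons,
        introns and intergenic background, so only the GT/AG cores are
        shared with the default organism."""
        return replace(
            self,
            donor_pwm=variant_donor_pwm(),
            acceptor_pwm=variant_acceptor_pwm(),
            ppt_pyrimidine_fraction=0.5,
            branch_motif=None,
            exon_gc=0.45,
            intron_gc=0.45,
            intergenic_gc=0.45,
        )


@dataclass
class GroundTruth:
    """Planted sites and gene structures, consistent with the emitted
    FASTA/GFF3 byte for byte."""

    sites: list[SpliceSiteRecord]
    genes: list[dict]  # {gene_id, seq_id, exons: [(start, end), ...]}

    def site_keys(self) -> set[tuple[str, str, int]]:
        return {(s.seq_id, s.site_type, s.position) for s in self.sites}

    def to_tsv(self) -> str:
        lines = ["seq_id\tsite_type\tposition\tdinucleotide\tcanonical\ttranscript_id"]
        for s in self.sites:
            lines.append(
                f"{s.seq_id}\t{s.site_type}\t{s.position}\t{s.dinucleotide}"
                f"\t{int(s.canonical)}\t{s.transcript_id}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class SimulatedGenome:
    genomes: list[GenomeSequence]
    gff_text: str
    truth: GroundTruth
    config: SimulatorConfig

    def fasta_text(self, width: int = 70) -> str:
        chunks = []
        for g in self.genomes:
            chunks.append(f">{g.seq_id}\n")
            for i in range(0, len(g.sequence), width):
                chunks.append(g.sequence[i : i + width] + "\n")
        return "".join(chunks)

    def write(self, prefix: str | Path) -> dict[str, Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": prefix.with_suffix(".fa"),
            "gff": prefix.with_suffix(".gff3"),
            "truth": Path(f"{prefix}.truth.tsv"),
        }
        paths["fasta"].write_text(self.fasta_text())
        paths["gff"].write_text(self.gff_text)
        paths["truth"].write_text(self.truth.to_tsv())
        return paths


def _background(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Random bases (as an integer array over PWM_ORDER) at a target G+C."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _sample_pwm(pwm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.choice(4, p=row) for row in pwm])


def _to_str(arr: np.ndarray) -> str:
    return "".join(PWM_ORDER[i] for i in arr)


def simulate_genome(config: SimulatorConfig = SimulatorConfig()) -> SimulatedGenome:
    """Generate FASTA + GFF3 + ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    d_pwm, a_pwm = config.donor_pwm, config.acceptor_pwm
    d_exonic = 3  # donor PWM positions inside the exon
    a_intronic = 3  # acceptor PWM positions inside the intron (YAG)

    contigs: list[np.ndarray] = [
        _background(config.contig_length, config.intergenic_gc, rng)
        for _ in range(config.n_contigs)
    ]
    contig_ids = [f"ctg{i + 1}" for i in range(config.n_contigs)]
    cursor = [config.margin] * config.n_contigs

    sites: list[SpliceSiteRecord] = []
    genes: list[dict] = []
    gff_lines = ["##gff-version 3"]
    for i, cid in enumerate(contig_ids):
        gff_lines.append(
            f"##sequence-region {cid} 1 {config.contig_length}"
        )

    placed = 0
    contig_idx = 0
    while placed < config.n_genes:
        # round-robin contigs; stop when nothing fits anywhere
        attempts = 0
        while attempts < config.n_contigs:
            ci = contig_idx % config.n_contigs
            contig_idx += 1
            n_exons = int(rng.integers(config.exons_per_gene[0],
                                       config.exons_per_gene[1] + 1))
            exon_lens = rng.integers(config.exon_length[0],
                                     config.exon_length[1] + 1, size=n_exons)
            intron_lens = rng.integers(config.intron_length[0],
                                       config.intron_length[1] + 1,
                                       size=n_exons - 1)
            gene_len = int(exon_lens.sum() + intron_lens.sum())
            start = cursor[ci]
            if start + gene_len + config.margin <= config.contig_length:
                break
            attempts += 1
        else:
            raise SimulationError(
                f"could not place gene {placed + 1}/{config.n_genes}: "
                "contigs exhausted (increase contig_length or n_contigs)"
            )

        ci = (contig_idx - 1) % config.n_contigs
        cid = contig_ids[ci]
        seq = contigs[ci]
        gene_id = f"g{placed + 1:04d}"
        tx_id = f"{gene_id}.t1"
        exons: list[tuple[int, int]] = []
        introns: list[tuple[int, int]] = []  # 0-based half-open
        pos = start  # 0-based running coordinate
        for e in range(n_exons):
            e_start, e_end = pos, pos + int(exon_lens[e])  # [e_start, e_end)
            seq[e_start:e_end] = _background(e_end - e_start, config.exon_gc, rng)
            exons.append((e_start + 1, e_end))  # 1-based inclusive
            pos = e_end
            if e < n_exons - 1:
                i_start, i_end = pos, pos + int(intron_lens[e])
                seq[i_start:i_end] = _background(i_end - i_start, config.intron_gc, rng)
                introns.append((i_start, i_end))
                pos = i_end

        # plant contexts after all backgrounds so nothing overwrites them
        for i_start, i_end in introns:
            # donor: exon tail + intron head from the donor PWM
            ctx = _sample_pwm(d_pwm, rng)
            noncanonical = rng.random() < config.fraction_noncanonical
            if noncanonical:
                ctx[d_exonic + 1] = _PWM_INDEX["C"]  # GT -> GC
            seq[i_start - d_exonic : i_start + (len(d_pwm) - d_exonic)] = ctx

            # acceptor: PPT, then YAG at the intron end, exon head base
            ppt_hi = i_end - a_intronic  # exclusive
            ppt_lo = ppt_hi - config.ppt_length
            pyr = rng.random(config.ppt_length) < config.ppt_pyrimidine_fraction
            ct = rng.choice([_PWM_INDEX["C"], _PWM_INDEX["T"]],
                            size=config.ppt_length)
            ag = rng.choice([_PWM_INDEX["A"], _PWM_INDEX["G"]],
                            size=config.ppt_length)
            seq[ppt_lo:ppt_hi] = np.where(pyr, ct, ag)
            actx = _sample_pwm(a_pwm, rng)
            seq[i_end - a_intronic : i_end - a_intronic + len(a_pwm)] = actx

            if config.branch_motif:
                offset = int(rng.integers(config.branch_offset[0],
                                          config.branch_offset[1] + 1))
                acc_pos0 = i_end - 2  # 0-based index of the A of AG
                # keep the motif clear of the donor context in short introns
                b_start = max(acc_pos0 - offset, i_start + 6)
                motif_arr = np.array([
                    int(rng.integers(4)) if c == "N" else _PWM_INDEX[c]
                    for c in config.branch_motif
                ])
                seq[b_start : b_start + len(motif_arr)] = motif_arr

            donor_pos = i_start + 1  # 1-based first intron base
            donor_dinuc = "GC" if noncanonical else "GT"
            sites.append(SpliceSiteRecord(
                seq_id=cid, site_type="donor", position=donor_pos,
                dinucleotide=donor_dinuc, canonical=not noncanonical,
                transcript_id=tx_id,
            ))
            acc_pos = i_end - 1  # 1-based first base of the terminal AG
            sites.append(SpliceSiteRecord(
                seq_id=cid, site_type="acceptor", position=acc_pos,
                dinucleotide="AG", canonical=True, transcript_id=tx_id,
            ))

        gene_start, gene_end = exons[0][0], exons[-1][1]
        gff_lines.append(
            f"{cid}\tresplice_sim\tgene\t{gene_start}\t{gene_end}\t.\t+\t.\t"
            f"ID={gene_id}"
        )
        gff_lines.append(
            f"{cid}\tresplice_sim\tmRNA\t{gene_start}\t{gene_end}\t.\t+\t.\t"
            f"ID={tx_id};Parent={gene_id}"
        )
        for j, (es, ee) in enumerate(exons, start=1):
            gff_lines.append(
                f"{cid}\tresplice_sim\texon\t{es}\t{ee}\t.\t+\t.\t"
                f"ID={tx_id}.exon{j};Parent={tx_id}"
            )
        genes.append({"gene_id": gene_id, "seq_id": cid, "exons": exons})
        gap = int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
        cursor[ci] = gene_end + gap
        placed += 1

    genomes = [
        GenomeSequence(seq_id=cid, sequence=_to_str(arr))
        for cid, arr in zip(contig_ids, contigs)
    ]
    return SimulatedGenome(
        genomes=genomes,
        gff_text="\n".join(gff_lines) + "\n",
        truth=GroundTruth(sites=sites, genes=genes),
        config=config,
    )


def make_fixture(
    scale: Literal["tiny", "small"] = "tiny",
    site_type: Literal["donor", "acceptor"] = "donor",
    seed: int = 0,
    config: SimulatorConfig | None = None,
    workdir: str | Path | None = None,
    flank: int = 200,
) -> tuple[DatasetSplits, dict]:
    """Run the full dataset pipeline on a simulated genome.

    ``tiny`` plants ~200 introns (≈400 balanced examples), ``small`` ~2,000
    (≈4,000 examples). Returns the splits and the pipeline manifest,
    augmented with the simulator configuration scale and seed.
    """
    import tempfile

    if config is None:
        config = (SimulatorConfig.tiny(seed) if scale == "tiny"
                  else SimulatorConfig.small(seed))
    sim = simulate_genome(config)

    def run(prefix: Path):
        paths = sim.write(prefix)
        return build_dataset(
            paths["fasta"], paths["gff"], site_type,
            spec=WindowSpec(flank=flank), seed=seed,
        )

    if workdir is not None:
        splits, manifest = run(Path(workdir) / "simulated")
    else:
        with tempfile.TemporaryDirectory() as tmp:
            splits, manifest = run(Path(tmp) / "simulated")
    manifest["simulator"] = {"scale": scale, "seed": seed,
                             "n_genes": config.n_genes,
                             "n_planted_sites": len(sim.truth.sites)}
    return splits, manifest
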