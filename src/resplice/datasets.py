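"""Dataset construction for splice-site classification.

Builds balanced donor/acceptor window datasets from a genome (FASTA) and its
annotation (GFF3, 1-based inclusive coordinates):

1. derive donor/acceptor splice sites from forward-strand multi-exon
   transcripts (canonical GT/AG and non-canonical sites alike);
2. cut a fixed window around each site — 200 nt of flank on either side of
   the site dinucleotide, 402 nt in total by default, so the dinucleotide
   sits at window positions 201-202 (1-based);
3. mine negative windows centred on GT/AG dinucleotides that are *not*
   annotated sites, so the classifier cannot win on the dinucleotide alone;
4. deduplicate exact window strings, balance the classes, and split
   60/15/25 into train/validation/test;
5. one-hot encode (A, T, G, C column order) for the network.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "SpliceSiteRecord",
    "WindowSpec",
    "WindowExample",
    "WindowRejection",
    "DatasetSplits",
    "read_fasta",
    "derive_splice_sites",
    "extract_window",
    "mine_negative_candidates",
    "sample_negatives",
    "deduplicate",
    "balance_and_split",
    "encode",
    "encode_sequences",
    "decode",
    "encode_splits",
    "build_dataset",
    "write_dataset",
    "read_dataset",
]

SiteType = Literal["donor", "acceptor"]

#: Canonical site dinucleotides: a donor opens an intron with GT, an
#: acceptor closes it with AG.
CANONICAL = {"donor": "GT", "acceptor": "AG"}

# One-hot column order. This is deliberately A,T,G,C (not alphabetical).
BASE_ORDER = "ATGC"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

LABEL_SITE = "site"
LABEL_NON_SITE = "non_site"

#: Label one-hot: splice site -> [1, 0], non-site -> [0, 1].
LABEL_VECTORS = {LABEL_SITE: (1, 0), LABEL_NON_SITE: (0, 1)}

_VALID = set("ACGT")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


class DatasetError(ValueError):
    """Raised for invalid dataset-construction requests."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: uppercase sequence over {A, C, G, T, N}."""

    seq_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """1-based single-base access."""
        return self.sequence[position - 1]

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice [start, end]."""
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class SpliceSiteRecord:
    """A donor or acceptor site on the forward strand.

    ``position`` is the 1-based coordinate of the FIRST base of the site
    dinucleotide: for a donor the first intron base (the G of GT), for an
    acceptor the penultimate intron base (the A of AG).
    """

    seq_id: str
    site_type: SiteType
    position: int
    dinucleotide: str
    canonical: bool
    transcript_id: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"site position must be >= 1, got {self.position}")
        if len(self.dinucleotide) != 2:
            raise ValueError("site dinucleotide must have length 2")
        expected = self.dinucleotide == CANONICAL[self.site_type]
        if self.canonical != expected:
            raise ValueError(
                f"canonical flag {self.canonical} inconsistent with "
                f"dinucleotide {self.dinucleotide!r} for {self.site_type}"
            )


@dataclass(frozen=True)
class WindowSpec:
    """Window geometry around the site dinucleotide.

    With the default flank of 200 nt the window is 402 nt long and the site
    dinucleotide occupies 1-based window positions 201-202.
    """

    flank: int = 200

    @property
    def window_length(self) -> int:
        return 2 * self.flank + 2

    @property
    def site_slice(self) -> tuple[int, int]:
        """1-based inclusive window positions of the site dinucleotide."""
        return (self.flank + 1, self.flank + 2)


@dataclass(frozen=True)
class WindowExample:
    """A window sequence with its label and provenance."""

    sequence: str
    label: str  # LABEL_SITE or LABEL_NON_SITE
    site_type: SiteType
    seq_id: str
    position: int


@dataclass(frozen=True)
class WindowRejection:
    """Why a requested window could not be extracted."""

    seq_id: str
    position: int
    reason: str


@dataclass
class DatasetSplits:
    """Disjoint, balanced train/validation/test partitions."""

    train: list[WindowExample]
    validation: list[WindowExample]
    test: list[WindowExample]
    proportions: tuple[float, float, float] = (0.60, 0.15, 0.25)
    seed: int = 0
    window_spec: WindowSpec = field(default_factory=WindowSpec)

    def __iter__(self):
        return iter((self.train, self.validation, self.test))

    @property
    def n_examples(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


# ---------------------------------------------------------------------------
# FASTA input
# ---------------------------------------------------------------------------

def _normalize(seq: str) -> str:
    """Uppercase and collapse every non-ACGT character (IUPAC ambiguity
    codes included) to N."""
    up = seq.upper()
    return "".join(c if c in _VALID else "N" for c in up)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into normalized :class:`GenomeSequence` records.

    Raises :class:`FastaParseError` naming the offending line for an empty
    file, a file that does not open with a header, or a header with an
    empty sequence.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    first_content = next(
        ((i, ln) for i, ln in enumerate(lines, 1) if ln.strip()), None
    )
    if first_content is None:
        raise FastaParseError(f"{path}: empty FASTA file (line 1)")
    if not first_content[1].lstrip().startswith(">"):
        raise FastaParseError(
            f"{path}: line {first_content[0]}: expected FASTA header "
            f"starting with '>', got {first_content[1].strip()[:30]!r}"
        )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalize(str(rec.seq))
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(GenomeSequence(seq_id=rec.id, sequence=seq))
    return records


def genome_map(genomes: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    return {g.seq_id: g for g in genomes}


# ---------------------------------------------------------------------------
# Splice-site derivation from GFF3
# ---------------------------------------------------------------------------

def derive_splice_sites(
    gff_path: str | Path,
    genome: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
) -> list[SpliceSiteRecord]:
    """Derive donor/acceptor sites from forward-strand exon chains.

    For every forward-strand transcript with >= 2 exons, each intron
    ``[prev_exon_end+1, next_exon_start-1]`` yields one donor at the intron
    start and one acceptor at ``intron_end - 1`` (the first base of the
    terminal AG). Minus-strand features are skipped; zero-length introns are
    skipped with a warning; duplicate ``(seq_id, site_type, position)``
    records (e.g. from overlapping transcript isoforms) are collapsed to the
    first occurrence. Non-canonical dinucleotides are retained with
    ``canonical=False``.
    """
    import gffutils

    if not isinstance(genome, Mapping):
        genome = genome_map(genome)

    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []  # annotation with no features yields no sites

    # group exons by parent transcript, preserving file order
    exons_by_parent: dict[str, list] = {}
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        for parent in exon.attributes.get("Parent", ["<orphan>"]):
            exons_by_parent.setdefault(parent, []).append(exon)

    seen: set[tuple[str, str, int]] = set()
    records: list[SpliceSiteRecord] = []
    for transcript_id, exons in exons_by_parent.items():
        if any(e.strand == "-" for e in exons):
            continue
        if len(exons) < 2:
            continue
        exons = sorted(exons, key=lambda e: e.start)
        contig = genome.get(exons[0].seqid)
        if contig is None:
            raise DatasetError(
                f"GFF3 references contig {exons[0].seqid!r} absent from the FASTA"
            )
        for e in exons:
            if e.start < 1 or e.end > len(contig):
                raise DatasetError(
                    f"exon {e.start}-{e.end} of {transcript_id} outside "
                    f"contig {contig.seq_id} bounds (length {len(contig)})"
                )
        for prev, nxt in zip(exons, exons[1:]):
            intron_start = prev.end + 1
            intron_end = nxt.start - 1
            if intron_end < intron_start + 1:
                warnings.warn(
                    f"skipping zero/one-length intron between exons of "
                    f"{transcript_id} at {contig.seq_id}:{intron_start}",
                    stacklevel=2,
                )
                continue
            for site_type, position in (
                ("donor", intron_start),
                ("acceptor", intron_end - 1),
            ):
                key = (contig.seq_id, site_type, position)
                if key in seen:
                    continue
                seen.add(key)
                dinuc = contig.slice(position, position + 1)
                records.append(
                    SpliceSiteRecord(
                        seq_id=contig.seq_id,
                        site_type=site_type,  # type: ignore[arg-type]
                        position=position,
                        dinucleotide=dinuc,
                        canonical=dinuc == CANONICAL[site_type],
                        transcript_id=transcript_id,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Window extraction and negative mining
# ---------------------------------------------------------------------------

def extract_window(
    genome: GenomeSequence,
    position: int,
    spec: WindowSpec = WindowSpec(),
    *,
    site_type: SiteType,
    label: str = LABEL_SITE,
) -> WindowExample | WindowRejection:
    """Cut the window around a site at 1-based ``position`` (first base of
    the dinucleotide): ``genome[position-flank ... position+flank+1]``,
    inclusive. Returns a :class:`WindowRejection` if the window overruns the
    contig or contains N."""
    start = position - spec.flank
    end = position + spec.flank + 1
    if start < 1 or end > len(genome):
        return WindowRejection(genome.seq_id, position, "window out of bounds")
    window = genome.slice(start, end)
    if "N" in window:
        return WindowRejection(genome.seq_id, position, "window contains N")
    return WindowExample(
        sequence=window,
        label=label,
        site_type=site_type,
        seq_id=genome.seq_id,
        position=position,
    )


def mine_negative_candidates(
    genome: GenomeSequence,
    site_type: SiteType,
    exclusion: set[int],
    spec: WindowSpec = WindowSpec(),
) -> list[int]:
    """All 1-based positions p on the forward strand where the canonical
    dinucleotide for ``site_type`` occurs, p is not an annotated true site,
    and a full N-free window exists around p."""
    dinuc = CANONICAL[site_type]
    seq = genome.sequence
    out = []
    # windows must fit, so only scan the feasible interior
    lo = spec.flank  # 0-based index of first feasible p
    hi = len(seq) - spec.flank - 2
    i = seq.find(dinuc, lo)
    while i != -1 and i <= hi:
        p = i + 1
        if p not in exclusion:
            window = seq[i - spec.flank : i + spec.flank + 2]
            if "N" not in window:
                out.append(p)
        i = seq.find(dinuc, i + 1)
    return out


def sample_negatives(candidates: Sequence[int], n: int, seed: int) -> list[int]:
    """Uniform sample of ``n`` candidate positions without replacement."""
    if n > len(candidates):
        raise DatasetError(
            f"requested {n} negatives but only {len(candidates)} candidates "
            f"available (short by {n - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in idx]


def deduplicate(examples: Iterable[WindowExample]) -> list[WindowExample]:
    """Keep the first occurrence of each exact window sequence."""
    seen: set[str] = set()
    out = []
    for ex in examples:
        if ex.sequence not in seen:
            seen.add(ex.sequence)
            out.append(ex)
    return out


def _split_counts(n: int, proportions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = int(round(n * proportions[0]))
    n_val = int(round(n * proportions[1]))
    return n_train, n_val, n - n_train - n_val


def balance_and_split(
    positives: Sequence[WindowExample],
    negatives: Sequence[WindowExample],
    proportions: tuple[float, float, float] = (0.60, 0.15, 0.25),
    seed: int = 0,
    window_spec: WindowSpec = WindowSpec(),
) -> DatasetSplits:
    """Balance the two classes and split 60/15/25, stratified by class.

    The larger class is randomly subsampled (seeded) to the size of the
    smaller one; each class is then shuffled and partitioned with identical
    per-class counts, so every partition is balanced within +/-1 example.
    """
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise DatasetError(f"proportions must sum to 1, got {proportions}")
    if not positives or not negatives:
        raise DatasetError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(len(positives), len(negatives))

    def subsample(cls: Sequence[WindowExample]) -> list[WindowExample]:
        if len(cls) == n:
            return list(cls)
        idx = rng.choice(len(cls), size=n, replace=False)
        return [cls[i] for i in sorted(idx)]

    pos, neg = subsample(positives), subsample(negatives)
    n_tr, n_va, n_te = _split_counts(n, proportions)
    parts: dict[str, list[WindowExample]] = {"train": [], "validation": [], "test": []}
    for cls in (pos, neg):
        order = rng.permutation(n)
        shuffled = [cls[i] for i in order]
        parts["train"] += shuffled[:n_tr]
        parts["validation"] += shuffled[n_tr : n_tr + n_va]
        parts["test"] += shuffled[n_tr + n_va :]
    # shuffle within each partition so classes are interleaved
    for name, ex in parts.items():
        order = rng.permutation(len(ex))
        parts[name] = [ex[i] for i in order]
    return DatasetSplits(
        train=parts["train"],
        validation=parts["validation"],
        test=parts["test"],
        proportions=proportions,
        seed=seed,
        window_spec=window_spec,
    )


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

def encode_sequences(sequences: Sequence[str]) -> np.ndarray:
    """One-hot encode equal-length ACGT strings to (n, L, 4) float32,
    column order (A, T, G, C)."""
    if not sequences:
        raise DatasetError("no sequences to encode")
    L = len(sequences[0])
    X = np.zeros((len(sequences), L, 4), dtype=np.float32)
    for i, s in enumerate(sequences):
        if len(s) != L:
            raise DatasetError("sequences must have equal length")
        for j, c in enumerate(s):
            k = _BASE_INDEX.get(c)
            if k is None:
                raise DatasetError(f"cannot one-hot encode character {c!r}")
            X[i, j, k] = 1.0
    return X


def encode(example: WindowExample) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode one example: (L, 4) matrix and 2-vector label."""
    matrix = encode_sequences([example.sequence])[0]
    label_vec = np.array(LABEL_VECTORS[example.label], dtype=np.float32)
    return matrix, label_vec


def decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode` for the sequence matrix."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise DatasetError("expected an (L, 4) one-hot matrix")
    if not np.all(matrix.sum(axis=1) == 1) or not np.all((matrix == 0) | (matrix == 1)):
        raise DatasetError("matrix rows must be exact one-hot vectors")
    return "".join(BASE_ORDER[k] for k in matrix.argmax(axis=1))


def encode_splits(splits: DatasetSplits) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Encode all three partitions: name -> (X (n,L,4), Y (n,2))."""
    out = {}
    for name, examples in zip(("train", "validation", "test"), splits):
        X = encode_sequences([e.sequence for e in examples])
        Y = np.array([LABEL_VECTORS[e.label] for e in examples], dtype=np.float32)
        out[name] = (X, Y)
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline and on-disk format
# ---------------------------------------------------------------------------

def build_dataset(
    fasta_path: str | Path,
    gff_path: str | Path,
    site_type: SiteType,
    spec: WindowSpec = WindowSpec(),
    proportions: tuple[float, float, float] = (0.60, 0.15, 0.25),
    seed: int = 0,
) -> tuple[DatasetSplits, dict]:
    """FASTA + GFF3 -> balanced, deduplicated, split window dataset.

    Returns the splits and a manifest dict (counts at every stage, seed,
    window spec) suitable for JSON serialization.
    """
    genomes = read_fasta(fasta_path)
    gmap = genome_map(genomes)
    sites = derive_splice_sites(gff_path, gmap)
    sites_of_type = [s for s in sites if s.site_type == site_type]

    positives: list[WindowExample] = []
    rejections: list[WindowRejection] = []
    for s in sites_of_type:
        res = extract_window(
            gmap[s.seq_id], s.position, spec, site_type=site_type, label=LABEL_SITE
        )
        (positives if isinstance(res, WindowExample) else rejections).append(res)  # type: ignore[arg-type]

    exclusion_by_contig: dict[str, set[int]] = {}
    for s in sites_of_type:
        exclusion_by_contig.setdefault(s.seq_id, set()).add(s.position)

    negatives: list[WindowExample] = []
    all_candidates: list[tuple[str, int]] = []
    for g in genomes:
        for p in mine_negative_candidates(
            g, site_type, exclusion_by_contig.get(g.seq_id, set()), spec
        ):
            all_candidates.append((g.seq_id, p))
    n_neg = min(len(positives), len(all_candidates))
    for i in np.random.default_rng(seed).choice(
        len(all_candidates), size=n_neg, replace=False
    ):
        seq_id, p = all_candidates[i]
        res = extract_window(
            gmap[seq_id], p, spec, site_type=site_type, label=LABEL_NON_SITE
        )
        assert isinstance(res, WindowExample)  # candidates are pre-validated
        negatives.append(res)

    positives = deduplicate(positives)
    negatives = deduplicate(negatives)
    splits = balance_and_split(positives, negatives, proportions, seed, spec)
    manifest = {
        "site_type": site_type,
        "flank": spec.flank,
        "window_length": spec.window_length,
        "seed": seed,
        "proportions": list(proportions),
        "n_annotated_sites": len(sites_of_type),
        "n_positive_windows": len(positives),
        "n_rejected_windows": len(rejections),
        "rejection_reasons": sorted({r.reason for r in rejections}),
        "n_negative_candidates": len(all_candidates),
        "n_examples": splits.n_examples,
        "split_sizes": {
            "train": len(splits.train),
            "validation": len(splits.validation),
            "test": len(splits.test),
        },
    }
    return splits, manifest


_TSV_HEADER = "seq_id\tposition\tsite_type\tlabel\tsplit\tsequence"


def write_dataset(splits: DatasetSplits, manifest: dict, prefix: str | Path) -> None:
    """Write ``<prefix>.tsv.gz`` (one row per example) and
    ``<prefix>.manifest.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with gzip.open(f"{prefix}.tsv.gz", "wt") as fh:
        fh.write(_TSV_HEADER + "\n")
        for split_name, examples in zip(("train", "validation", "test"), splits):
            for e in examples:
                fh.write(
                    f"{e.seq_id}\t{e.position}\t{e.site_type}\t{e.label}"
                    f"\t{split_name}\t{e.sequence}\n"
                )
    with open(f"{prefix}.manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def read_dataset(prefix: str | Path) -> tuple[DatasetSplits, dict]:
    """Read a dataset written by :func:`write_dataset`."""
    prefix = Path(prefix)
    with open(f"{prefix}.manifest.json") as fh:
        manifest = json.load(fh)
    parts: dict[str, list[WindowExample]] = {"train": [], "validation": [], "test": []}
    with gzip.open(f"{prefix}.tsv.gz", "rt") as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise DatasetError(f"unexpected dataset header: {header!r}")
        for line in fh:
            seq_id, pos, site_type, label, split_name, seq = line.rstrip("\n").split("\t")
            parts[split_name].append(
                WindowExample(seq, label, site_type, seq_id, int(pos))  # type: ignore[arg-type]
            )
    spec = WindowSpec(flank=manifest["flank"])
    return (
        DatasetSplits(
            train=parts["train"],
            validation=parts["validation"],
            test=parts["test"],
            proportions=tuple(manifest["proportions"]),  # type: ignore[arg-type]
            seed=manifest["seed"],
            window_spec=spec,
        ),
        manifest,
    )
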