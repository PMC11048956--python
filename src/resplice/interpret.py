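"""Model interpretation: contribution scores, motif tracks, Grad-CAM and
sequence-conservation profiles.

Contribution scores follow the reference-difference contract: per input
window the per-base, per-position scores sum (approximately) to
``f(x) - mean f(reference)``, where ``f`` is the pre-softmax splice-site
logit. They are computed by expected gradients — path-integrated gradients
(midpoint rule) averaged over a set of dinucleotide-shuffled references,
which preserves each window's mono- and dinucleotide composition while
destroying positional signal. Raw scores are put on a common scale by
per-sequence L1 normalization ("weighted" scores), from which position
importance profiles and base-set / IUPAC-motif tracks are derived.

Grad-CAM projects class-gradient-weighted activations of the final
convolutional layer back onto the window; conservation profiles give
per-position nucleotide frequencies and information content R = 2 - H bits,
the height scale of a sequence logo.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import BASE_ORDER, encode_sequences, decode

__all__ = [
    "AttributionMatrix",
    "CompletenessReport",
    "GradCamResult",
    "ConservationProfile",
    "dinucleotide_shuffle",
    "attribute",
    "normalize_weighted",
    "position_importance",
    "base_profiles",
    "motif_track",
    "grad_cam",
    "conservation",
    "cosine_similarity",
    "profile_to_tsv",
    "pwm_to_text",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class InterpretError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul-Erickson)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Random permutation of ``sequence`` preserving its exact dinucleotide
    counts (Altschul-Erickson Eulerian-walk shuffle)."""
    if len(sequence) < 3:
        return sequence
    chars = sorted(set(sequence))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for a, b in zip(sequence, sequence[1:]):
        edges[a].append(b)
    last = sequence[-1]

    # choose a random "last edge" per non-terminal vertex such that
    # following the last edges from every vertex reaches the terminal one
    while True:
        last_edge: dict[str, str] = {}
        ok = True
        for c in chars:
            if c == last:
                continue
            if not edges[c]:
                continue
            last_edge[c] = edges[c][rng.integers(len(edges[c]))]
        for c in last_edge:
            seen = {c}
            cur = c
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for c in chars:
        pool = list(edges[c])
        if c in last_edge:
            pool.remove(last_edge[c])
        order = rng.permutation(len(pool))
        pool = [pool[i] for i in order]
        if c in last_edge:
            pool.append(last_edge[c])
        shuffled[c] = pool

    # Eulerian walk consuming edges in the shuffled order
    out = [sequence[0]]
    counters = {c: 0 for c in chars}
    cur = sequence[0]
    for _ in range(len(sequence) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# Expected-gradients attribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompletenessReport:
    """Per-sequence relative residuals of the completeness identity
    ``sum(scores) == f(x) - mean f(reference)``."""

    residuals: np.ndarray  # relative, per sequence
    tolerance: float

    @property
    def ok(self) -> bool:
        return bool(np.all(self.residuals <= self.tolerance))

    def describe(self) -> str:
        worst = float(self.residuals.max()) if len(self.residuals) else 0.0
        status = "within" if self.ok else "BEYOND"
        return (
            f"completeness {status} tolerance {self.tolerance:.0%}: "
            f"max relative residual {worst:.4f} over {len(self.residuals)} sequences"
        )


@dataclass
class AttributionMatrix:
    """Raw and L1-normalized ("weighted") contribution scores for a set of
    windows, with the one-hot inputs they refer to."""

    raw: np.ndarray          # (n, L, 4)
    weighted: np.ndarray     # (n, L, 4), per-sequence sum of |scores| == 1
    sequences_onehot: np.ndarray  # (n, L, 4)
    f_x: np.ndarray          # (n,) model logit on each input
    f_ref_mean: np.ndarray   # (n,) mean logit over each input's references
    reference_description: str = ""

    def completeness(self, tolerance: float = 0.05) -> CompletenessReport:
        target = self.f_x - self.f_ref_mean
        total = self.raw.sum(axis=(1, 2))
        scale = np.maximum(np.abs(target), 1e-8)
        return CompletenessReport(
            residuals=np.abs(total - target) / scale, tolerance=tolerance
        )


def _model_logit(network, X: np.ndarray, class_index: int, batch: int) -> np.ndarray:
    return np.concatenate([
        network.logits(X[i : i + batch], training=False)[:, class_index]
        for i in range(0, len(X), batch)
    ])


def attribute(
    network,
    sequences: np.ndarray,
    references: np.ndarray | None = None,
    n_references: int = 100,
    n_steps: int = 64,
    seed: int = 0,
    target_class: int = 0,
    batch_size: int = 256,
    completeness_tolerance: float = 0.05,
) -> AttributionMatrix:
    """Expected-gradients contribution scores for one-hot windows.

    For every input ``x`` and reference ``r`` the integrated gradient
    ``(x - r) * mean_alpha grad f(r + alpha (x - r))`` is evaluated with an
    ``n_steps``-point midpoint rule and averaged over references; ``f`` is
    the pre-softmax logit of ``target_class`` (0 = splice site). References
    default to ``n_references`` dinucleotide shuffles of each input; an
    explicit ``(n_refs, L, 4)`` array (shared across inputs) may be passed
    instead. Scores satisfy the completeness identity up to the quadrature
    error; a violation beyond ``completeness_tolerance`` triggers a
    diagnostic warning (the report stays available on the result).
    """
    X = np.asarray(sequences, dtype=np.float64)
    if X.ndim != 3 or X.shape[2] != 4:
        raise InterpretError("sequences must be a (n, L, 4) one-hot array")
    n, L, _ = X.shape
    rng = np.random.default_rng(seed)
    alphas = (np.arange(n_steps) + 0.5) / n_steps

    raw = np.zeros_like(X, dtype=np.float64)
    f_ref_mean = np.zeros(n)
    if references is not None:
        references = np.asarray(references, dtype=np.float64)
        ref_desc = f"user-supplied ({references.shape[0]} references)"
    else:
        ref_desc = f"{n_references} dinucleotide shuffles per input"

    for i in range(n):
        if references is not None:
            refs = references
        else:
            s = decode(X[i].astype(np.float32))
            refs = encode_sequences(
                [dinucleotide_shuffle(s, rng) for _ in range(n_references)]
            ).astype(np.float64)
        n_refs = refs.shape[0]
        diff = X[i][None] - refs  # (n_refs, L, 4)
        # all (ref, alpha) interpolation points for this sequence
        points = (refs[:, None] + alphas[None, :, None, None] * diff[:, None]).reshape(
            n_refs * n_steps, L, 4
        )
        grads = np.concatenate([
            network.input_gradient(points[j : j + batch_size], class_index=target_class)
            for j in range(0, len(points), batch_size)
        ]).reshape(n_refs, n_steps, L, 4)
        raw[i] = (diff * grads.mean(axis=1)).mean(axis=0)
        f_ref_mean[i] = _model_logit(network, refs, target_class, batch_size).mean()

    f_x = _model_logit(network, X, target_class, batch_size)
    result = AttributionMatrix(
        raw=raw,
        weighted=normalize_weighted(raw),
        sequences_onehot=X,
        f_x=f_x,
        f_ref_mean=f_ref_mean,
        reference_description=ref_desc,
    )
    report = result.completeness(completeness_tolerance)
    if not report.ok:
        warnings.warn("attribution " + report.describe(), stacklevel=2)
    return result


def normalize_weighted(raw: np.ndarray) -> np.ndarray:
    """Per-sequence L1 normalization: each sequence's scores are divided by
    the sum of their absolute values, preserving signs, so sequences become
    comparable on a common scale. All-zero score matrices are left zero
    (with a warning)."""
    raw = np.asarray(raw, dtype=np.float64)
    sums = np.abs(raw).sum(axis=(1, 2), keepdims=True)
    zero = sums[:, 0, 0] == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} sequence(s) have all-zero contribution scores",
            stacklevel=2,
        )
    return np.divide(raw, np.where(sums == 0, 1.0, sums))


# ---------------------------------------------------------------------------
# Importance profiles and motif tracks
# ---------------------------------------------------------------------------

def _realized(weighted: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """(n, L) scores of the realized base at each position."""
    return (weighted * onehot).sum(axis=2)


def position_importance(weighted: np.ndarray, sequences_onehot: np.ndarray) -> np.ndarray:
    """Mean absolute weighted contribution of the realized base per position
    (length-L vector >= 0)."""
    if len(weighted) == 0:
        raise InterpretError("need at least one sequence")
    return np.abs(_realized(weighted, sequences_onehot)).mean(axis=0)


def base_profiles(weighted: np.ndarray, sequences_onehot: np.ndarray) -> np.ndarray:
    """(L, 4) per-base mean weighted scores: entry [p, b] averages the score
    of base b at position p over the sequences whose realized base there is
    b; NaN where the base never occurs. Column order (A, T, G, C)."""
    onehot = sequences_onehot.astype(bool)
    counts = onehot.sum(axis=0)  # (L, 4)
    sums = (weighted * onehot).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def motif_track(
    weighted: np.ndarray,
    sequences_onehot: np.ndarray,
    base_set: str | None = None,
    motif: str | None = None,
) -> np.ndarray:
    """Average weighted contribution per position, restricted to a base set
    or anchored on an IUPAC motif.

    Base-set mode (e.g. ``"GC"``): ``values[p]`` is the mean realized-base
    score at p over sequences whose realized base belongs to the set.
    Motif mode (e.g. ``"CTNA"``): occurrences are indexed by their first
    position; ``values[p]`` is the mean, over occurrences starting at p, of
    the summed realized-base scores across the motif. Positions with no
    occurrence are NaN.
    """
    if (base_set is None) == (motif is None):
        raise InterpretError("pass exactly one of base_set or motif")
    realized = _realized(weighted, sequences_onehot)
    n, L = realized.shape

    if base_set is not None:
        bad = set(base_set) - set("ACGT")
        if bad or not base_set:
            raise InterpretError(f"base_set must be a non-empty subset of ACGT, got {base_set!r}")
        cols = [_BASE_INDEX[b] for b in base_set]
        mask = sequences_onehot[:, :, cols].sum(axis=2) > 0  # (n, L)
        counts = mask.sum(axis=0)
        sums = (realized * mask).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    assert motif is not None
    motif = motif.upper()
    if not motif or any(c not in IUPAC for c in motif):
        raise InterpretError(f"invalid IUPAC motif {motif!r}")
    m = len(motif)
    # boolean (n, L) match of each motif character at each offset
    allowed = [
        sequences_onehot[:, :, [_BASE_INDEX[b] for b in IUPAC[c]]].sum(axis=2) > 0
        for c in motif
    ]
    values = np.full(L, np.nan)
    for p in range(L - m + 1):
        hit = np.ones(n, dtype=bool)
        for j in range(m):
            hit &= allowed[j][:, p + j]
        if hit.any():
            values[p] = realized[hit, p : p + m].sum(axis=1).mean()
    return values


# ---------------------------------------------------------------------------
# Grad-CAM
# ---------------------------------------------------------------------------

@dataclass
class GradCamResult:
    maps: np.ndarray  # (n, L) per-sequence min-max normalized heatmaps
    mean: np.ndarray  # (L,) dataset mean
    n_flat: int = 0   # sequences with an all-zero (flagged) map


def grad_cam(network, sequences: np.ndarray, target_class: int = 0,
             batch_size: int = 256) -> GradCamResult:
    """Grad-CAM over the final convolutional layer.

    Channel weights are the position-averaged gradients of the target-class
    logit w.r.t. the final conv feature maps; the ReLU of the weighted
    channel sum is linearly interpolated from the final-conv length (8 under
    the default spec) to the window length and min-max normalized per
    sequence. Zero-gradient maps are left zero and counted in ``n_flat``.
    """
    X = np.asarray(sequences, dtype=np.float32)
    n, L, _ = X.shape
    conv = network.final_conv
    maps = np.zeros((n, L))
    n_flat = 0
    conv.capture = True
    try:
        for i in range(0, n, batch_size):
            Xb = X[i : i + batch_size]
            out = network.logits(Xb, training=False)
            network.zero_grads()
            dlogits = np.zeros_like(out)
            dlogits[:, target_class] = 1.0
            network.backward(dlogits)
            A = conv.last_output          # (B, L_conv, C)
            dA = conv.grad_output         # (B, L_conv, C)
            w = dA.mean(axis=1)           # (B, C) channel weights
            cam = np.maximum((A * w[:, None, :]).sum(axis=2), 0.0)  # (B, L_conv)
            src = np.linspace(0, L - 1, cam.shape[1])
            for j in range(len(cam)):
                m = np.interp(np.arange(L), src, cam[j])
                lo, hi = m.min(), m.max()
                if hi > lo:
                    maps[i + j] = (m - lo) / (hi - lo)
                else:
                    n_flat += 1  # untrained/zero-gradient: flagged, left zero
    finally:
        conv.capture = False
    if n_flat:
        warnings.warn(f"{n_flat} Grad-CAM map(s) were flat and left zero", stacklevel=2)
    return GradCamResult(maps=maps, mean=maps.mean(axis=0), n_flat=n_flat)


# ---------------------------------------------------------------------------
# Conservation and profile comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConservationProfile:
    """Per-position nucleotide frequencies (columns A, T, G, C) and
    information content R = 2 - H bits (0 = uniform, 2 = invariant)."""

    frequencies: np.ndarray  # (L, 4), rows sum to 1
    information: np.ndarray  # (L,) in [0, 2]
    n_sequences: int


def conservation(sequences: Sequence[str] | np.ndarray,
                 small_sample_correction: bool = False) -> ConservationProfile:
    """Column frequencies and information content of equal-length ACGT
    sequences (strings or a one-hot array).

    ``small_sample_correction`` subtracts the standard sequence-logo
    correction e(n) = 3 / (2 n ln 2) from R (clipped at 0); off by default.
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 3:
        onehot = sequences.astype(float)
    else:
        seq_list = list(sequences)
        if not seq_list:
            raise InterpretError("conservation needs at least one sequence")
        onehot = encode_sequences(seq_list).astype(float)
    n = onehot.shape[0]
    if n == 0:
        raise InterpretError("conservation needs at least one sequence")
    freqs = onehot.mean(axis=0)  # (L, 4)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        info = np.maximum(info - 3.0 / (2.0 * n * np.log(2)), 0.0)
    return ConservationProfile(frequencies=freqs, information=info, n_sequences=n)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Standard cosine of two equal-length profile vectors in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise InterpretError("profiles must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InterpretError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def profile_to_tsv(path: str | Path, values: np.ndarray,
                   column: str = "value") -> None:
    """Write a per-position profile as TSV (1-based position, value)."""
    with open(path, "w") as fh:
        fh.write(f"position\t{column}\n")
        for p, v in enumerate(np.asarray(values).ravel(), start=1):
            fh.write(f"{p}\t{'NA' if np.isnan(v) else f'{v:.6g}'}\n")


def pwm_to_text(path: str | Path, profile: ConservationProfile) -> None:
    """Write the frequency matrix in a plain position-weight-matrix format
    (columns A C G T) consumable by standard logo tools."""
    order = [_BASE_INDEX[b] for b in "ACGT"]
    with open(path, "w") as fh:
        fh.write("PO\tA\tC\tG\tT\n")
        for p, row in enumerate(profile.frequencies[:, order], start=1):
            fh.write(f"{p}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
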