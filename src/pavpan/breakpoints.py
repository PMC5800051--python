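"""Microhomology extraction and size-distribution analysis at PAV breakpoints.

When a deletion is repaired by microhomology-mediated end joining
(MMEJ), the two sides of the breakpoint share a short exact sequence
(the microhomology, MH), one copy of which is lost with the deleted
segment.  Conversely, LTR-retrotransposon insertion duplicates 5 bp of
the target site, leaving a 5-bp signature indistinguishable from MH at
the event level.  The size distribution separates the two: MMEJ yields
a roughly geometric decay of MH lengths, while a retroelement
contribution shows up as an excess mass at exactly 5 bp.

Coordinates are 0-based half-open on the genome that still carries the
deleted segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "Breakpoint",
    "MicrohomologyResult",
    "MhSummary",
    "ExcessResult",
    "extract_microhomology",
    "mh_size_distribution",
    "excess_at_mode",
]


@dataclass(frozen=True)
class Breakpoint:
    """A deletion interval on the sequence that carries the segment."""

    contig_seq: str
    deletion_start: int
    deletion_end: int
    id: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.deletion_start < self.deletion_end <= len(self.contig_seq)):
            raise ValueError("breakpoint interval out of contig bounds")


@dataclass(frozen=True)
class MicrohomologyResult:
    length: int
    motif: str
    side: str  # "left" | "right"
    breakpoint_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.motif) != self.length:
            raise ValueError("motif length must equal reported MH length")


def _common_prefix_len(seq: str, i: int, j: int, limit: int) -> int:
    k = 0
    while k < limit and seq[i + k] == seq[j + k]:
        k += 1
    return k


def _common_suffix_len(seq: str, i: int, j: int, limit: int) -> int:
    # longest k with seq[i-k:i] == seq[j-k:j]
    k = 0
    while k < limit and seq[i - 1 - k] == seq[j - 1 - k]:
        k += 1
    return k


def extract_microhomology(bp: Breakpoint, canonicalize: bool = True) -> MicrohomologyResult:
    """Maximal exact microhomology at a deletion breakpoint.

    Right-side MH: the longest k such that the first k bases of the
    deleted segment equal the k bases immediately following the
    deletion.  Left-side MH: the longest k such that the last k bases of
    the deleted segment equal the k bases immediately preceding it.  The
    reported MH is the larger of the two; ties go to the right side.

    Because a deletion inside an MH tract can be placed anywhere along
    the tract without changing the removed sequence, the window is first
    shifted to its leftmost equivalent placement (``canonicalize``),
    which makes the reported length invariant to placement ambiguity.
    A deletion flush with a contig edge simply contributes 0 from the
    side that has no flank.
    """
    seq = bp.contig_seq
    s, e = bp.deletion_start, bp.deletion_end
    if canonicalize:
        while s > 0 and seq[s - 1] == seq[e - 1]:
            s -= 1
            e -= 1
    dlen = e - s
    right = _common_prefix_len(seq, s, e, min(dlen, len(seq) - e))
    left = _common_suffix_len(seq, e, s, min(dlen, s))
    if right >= left:
        return MicrohomologyResult(length=right, motif=seq[s : s + right],
                                   side="right", breakpoint_id=bp.id)
    return MicrohomologyResult(length=left, motif=seq[e - left : e],
                               side="left", breakpoint_id=bp.id)


@dataclass
class MhSummary:
    n: int
    n_with_mh: int
    fraction_with_mh: float
    mh_min_observed: int | None
    mh_max_observed: int | None
    mh_mean: float | None
    histogram: pd.Series  # index: MH length (>= threshold), values: counts


def mh_size_distribution(
    results: list[MicrohomologyResult] | np.ndarray,
    mh_min: int = 3,
) -> MhSummary:
    """Summarize MH lengths; lengths below ``mh_min`` count as 'no MH'.

    The 3-bp presence threshold reflects that 1-2 bp matches arise by
    chance at almost any junction and carry no repair signal.
    """
    if isinstance(results, (list, tuple)) and results and isinstance(results[0], MicrohomologyResult):
        lengths = np.array([r.length for r in results])
    else:
        lengths = np.asarray(results, dtype=int)
    if lengths.size == 0:
        raise ValueError("no microhomology results supplied")
    with_mh = lengths[lengths >= mh_min]
    hist = pd.Series(with_mh).value_counts().sort_index()
    return MhSummary(
        n=int(lengths.size),
        n_with_mh=int(with_mh.size),
        fraction_with_mh=float(with_mh.size / lengths.size),
        mh_min_observed=int(with_mh.min()) if with_mh.size else None,
        mh_max_observed=int(with_mh.max()) if with_mh.size else None,
        mh_mean=float(with_mh.mean()) if with_mh.size else None,
        histogram=hist,
    )


@dataclass
class ExcessResult:
    geometric_p: float          # ML decay parameter of the fitted null
    null_share_at_mode: float   # share the null predicts at the mode bin
    observed_share_at_mode: float
    excess: float               # observed - null share
    spike_mass: float           # (observed - null) / (1 - null): the point-mass
    #                             parameter of a geometric + spike mixture that
    #                             would produce the observed share at the mode
    bootstrap_se: float
    ci_low: float
    ci_high: float
    spike_se: float = float("nan")


def _fit_truncated_geometric(lengths: np.ndarray, counts: np.ndarray, support: np.ndarray):
    """MLE of the decay parameter p for a geometric law renormalized on ``support``.

    pmf(k) ∝ (1-p)^(k - support.min()); ``lengths``/``counts`` are the
    observed histogram restricted to the fitting bins.
    """
    k0 = support.min()

    def nll(p):
        if not (1e-9 < p < 1 - 1e-9):
            return np.inf
        logw = (support - k0) * np.log1p(-p)
        lognorm = np.log(np.exp(logw).sum())
        ll = (counts * ((lengths - k0) * np.log1p(-p) - lognorm)).sum()
        return -ll

    res = minimize_scalar(nll, bounds=(1e-6, 1 - 1e-6), method="bounded")
    return float(res.x)


def excess_at_mode(
    histogram: pd.Series,
    null: str = "geometric",
    mode_bp: int = 5,
    mh_min: int = 3,
    n_boot: int = 1000,
    seed: int = 0,
) -> ExcessResult:
    """Estimate the excess probability mass at ``mode_bp`` over a geometric null.

    The geometric decay parameter is fitted by maximum likelihood on all
    histogram bins in [mh_min, max observed] *excluding* the mode bin,
    renormalized accordingly.  The null share at the mode is then the
    fitted geometric renormalized over the full range; the excess is the
    observed share minus that prediction.  A seeded multinomial
    bootstrap gives a standard error and a 95% percentile interval.
    """
    if null != "geometric":
        raise ValueError(f"unsupported null {null!r}")
    hist = histogram[histogram.index >= mh_min].sort_index()
    hist = hist[hist > 0]
    if len(hist) < 2:
        raise ValueError("degenerate histogram: need at least two distinct MH lengths")
    lengths = hist.index.to_numpy(dtype=int)
    counts = hist.to_numpy(dtype=float)

    p_hat, obs, null_share, excess = _excess_on_histogram(lengths, counts, mode_bp, mh_min)
    spike = excess / (1.0 - null_share)

    rng = np.random.default_rng(seed)
    total = int(counts.sum())
    probs = counts / counts.sum()
    boot = np.full((n_boot, 2), np.nan)
    for b in range(n_boot):
        resampled = rng.multinomial(total, probs).astype(float)
        if (resampled[lengths != mode_bp] > 0).sum() < 1 or (resampled > 0).sum() < 2:
            continue
        _, _, ns, ex = _excess_on_histogram(lengths, resampled, mode_bp, mh_min)
        boot[b] = (ex, ex / (1.0 - ns))
    boot = boot[~np.isnan(boot[:, 0])]
    if boot.shape[0] > 1:
        se, spike_se = boot.std(axis=0, ddof=1)
        lo, hi = np.percentile(boot[:, 0], [2.5, 97.5])
    else:
        se = spike_se = lo = hi = float("nan")
    return ExcessResult(geometric_p=p_hat, null_share_at_mode=float(null_share),
                        observed_share_at_mode=float(obs), excess=float(excess),
                        spike_mass=float(spike), bootstrap_se=float(se),
                        ci_low=float(lo), ci_high=float(hi), spike_se=float(spike_se))


def _excess_on_histogram(lengths, counts, mode_bp, mh_min):
    """(p_hat, observed share, null share, excess) on one histogram."""
    kmax = int(lengths[counts > 0].max())
    full_support = np.arange(mh_min, kmax + 1)
    fit_support = full_support[full_support != mode_bp]
    total = counts.sum()
    obs_share = float(counts[lengths == mode_bp].sum() / total)
    mask = (lengths != mode_bp) & (counts > 0)
    p = _fit_truncated_geometric(lengths[mask], counts[mask], fit_support)
    w = (1 - p) ** (full_support - mh_min)
    null_share = float(w[full_support == mode_bp][0] / w.sum()) if mode_bp <= kmax else 0.0
    return p, obs_share, null_share, obs_share - null_share
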