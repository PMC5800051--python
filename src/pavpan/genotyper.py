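"""Read-depth genotyping of PAVs via a two-component mixture of regressions.

For each target line, every PAV region *i* yields two numbers: ``x_i``,
the square root of the read count of the region in the donor line
(a proxy for copy number), and ``Y_i``, the square root of the read
count in the target line.  If the region is present in the target
(cluster 1) the two depths scale together; if absent (cluster 0) the
target depth is background noise.  The model is

    Y_i = a_0 + b_0 x_i + E_i   if Z_i = 0  (absent)
    Y_i = a_1 + b_1 x_i + E_i   if Z_i = 1  (present)

with E_i ~ N(0, sigma_k^2) independent, and P(Z_i = 1) = pi.  The square
root is the variance-stabilizing transform for count data, which makes
a homoscedastic Gaussian error a reasonable approximation.

Maximum-likelihood estimation uses EM: the E-step computes posterior
membership probabilities tau_ik from the two Gaussian regression
densities, the M-step solves two weighted least-squares problems.  The
component with the larger slope is always labelled "present".

Calls are made under Bayesian false discovery rate (BFDR) control: with
q_i = 1 - max(tau_i0, tau_i1) the posterior misclassification
probability of the MAP call, regions are sorted by q_i and the largest
prefix whose running mean stays at or below the nominal level is
classified; the rest are left unclassified.  The running mean at the
cut is an estimate of the realized BFDR among classified calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "DepthMatrix",
    "MixtureModelFit",
    "GenotypeCallSet",
    "PanelCalls",
    "fit_mixture",
    "posterior",
    "bfdr_classify",
    "genotype_panel",
    "plot_line_fit",
]

_SIGMA2_FLOOR = 1e-12


class DepthMatrix:
    """Regions x lines read counts with a designated donor column.

    Counts are stored raw; the square-root transform is applied exactly
    once, on access, through :attr:`x` and :meth:`y`.  Calling
    :meth:`sqrt` on an already-transformed matrix raises, guarding
    against accidental double transformation.
    """

    def __init__(self, counts: pd.DataFrame, donor: str, transformed: bool = False):
        counts = counts.astype(float)
        if (counts.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        if donor not in counts.columns:
            raise ValueError(f"donor line {donor!r} not among columns")
        self.counts = counts
        self.donor = donor
        self.transformed = transformed

    @property
    def region_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def lines(self) -> list[str]:
        return list(self.counts.columns)

    def sqrt(self) -> "DepthMatrix":
        """Return the sqrt-transformed matrix; refuse to transform twice."""
        if self.transformed:
            raise ValueError("depth matrix already sqrt-transformed; refusing to transform again")
        return DepthMatrix(np.sqrt(self.counts), self.donor, transformed=True)

    def _values(self, line: str) -> np.ndarray:
        vals = self.counts[line].to_numpy(dtype=float)
        return vals if self.transformed else np.sqrt(vals)

    @property
    def x(self) -> np.ndarray:
        """Donor-line sqrt counts per region."""
        return self._values(self.donor)

    def y(self, line: str) -> np.ndarray:
        """Target-line sqrt counts per region."""
        if line not in self.counts.columns:
            raise KeyError(line)
        return self._values(line)


@dataclass
class MixtureModelFit:
    a0: float
    b0: float
    sigma0_sq: float
    a1: float
    b1: float
    sigma1_sq: float
    pi: float
    tau: np.ndarray  # (n, 2) posterior memberships, rows sum to 1
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    @property
    def params(self) -> dict[str, float]:
        return {"a0": self.a0, "b0": self.b0, "sigma0_sq": self.sigma0_sq,
                "a1": self.a1, "b1": self.b1, "sigma1_sq": self.sigma1_sq,
                "pi": self.pi}


def _log_component_densities(x, y, a0, b0, s0, a1, b1, s1, pi):
    """Per-point log pi_k + log N(y; a_k + b_k x, sigma_k^2), shape (n, 2)."""
    l0 = np.log1p(-pi) + norm.logpdf(y, loc=a0 + b0 * x, scale=np.sqrt(s0))
    l1 = np.log(pi) + norm.logpdf(y, loc=a1 + b1 * x, scale=np.sqrt(s1))
    return np.column_stack([l0, l1])


def _weighted_ls(x, y, w):
    """Weighted least squares of y on (1, x); returns (a, b)."""
    sw = w.sum()
    swx = (w * x).sum()
    swxx = (w * x * x).sum()
    swy = (w * y).sum()
    swxy = (w * x * y).sum()
    det = sw * swxx - swx * swx
    if det <= 1e-300 * max(1.0, sw * swxx):
        # x effectively constant under these weights: intercept-only fit
        return swy / sw, 0.0
    b = (sw * swxy - swx * swy) / det
    a = (swy - b * swx) / sw
    return a, b


def _em(x, y, tau1_init, tol, max_iter):
    n = len(x)
    tau = np.column_stack([1.0 - tau1_init, tau1_init])
    trace: list[float] = []
    params = None
    converged = False
    for it in range(max_iter):
        # M-step
        w0, w1 = tau[:, 0], tau[:, 1]
        if w0.sum() < 2 or w1.sum() < 2:
            raise _DegenerateFit(
                f"component effective weight below 2 ({w0.sum():.3g}, {w1.sum():.3g})")
        a0, b0 = _weighted_ls(x, y, w0)
        a1, b1 = _weighted_ls(x, y, w1)
        s0 = max((w0 * (y - a0 - b0 * x) ** 2).sum() / w0.sum(), _SIGMA2_FLOOR)
        s1 = max((w1 * (y - a1 - b1 * x) ** 2).sum() / w1.sum(), _SIGMA2_FLOOR)
        pi = float(np.clip(w1.mean(), 1e-12, 1 - 1e-12))
        params = (a0, b0, s0, a1, b1, s1, pi)
        # E-step
        logd = _log_component_densities(x, y, *params)
        ll = float(logsumexp(logd, axis=1).sum())
        tau = np.exp(logd - logsumexp(logd, axis=1, keepdims=True))
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-2])):
            converged = True
            break
    a0, b0, s0, a1, b1, s1, pi = params
    fit = MixtureModelFit(a0, b0, s0, a1, b1, s1, pi, tau,
                          loglik_trace=trace, n_iter=len(trace), converged=converged)
    return fit


class _DegenerateFit(ValueError):
    pass


def _canonicalize(fit: MixtureModelFit) -> MixtureModelFit:
    """Ensure cluster 1 ('present') is the component with the larger slope."""
    if fit.b1 >= fit.b0:
        return fit
    return MixtureModelFit(
        a0=fit.a1, b0=fit.b1, sigma0_sq=fit.sigma1_sq,
        a1=fit.a0, b1=fit.b0, sigma1_sq=fit.sigma0_sq,
        pi=1.0 - fit.pi, tau=fit.tau[:, ::-1].copy(),
        loglik_trace=fit.loglik_trace, n_iter=fit.n_iter, converged=fit.converged)


def fit_mixture(
    x: np.ndarray,
    y: np.ndarray,
    init: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 5,
    seed: int = 0,
) -> MixtureModelFit:
    """Fit the two-component regression mixture by EM, best of ``n_starts``.

    ``x`` and ``y`` are sqrt-scale counts of equal length >= 10.  The
    first start splits points at the median of y/x (points scaling with
    the donor vs. background); the remaining starts use random
    responsibilities.  ``init``, if given, is a vector of initial
    cluster-1 responsibilities used as an additional start.  Raises
    ValueError if every start collapses (e.g. all points from one
    cluster); a fit that merely hit ``max_iter`` is returned with
    ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 regions to fit the mixture")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    ratio = y / np.maximum(x, 1e-9)
    split = (ratio > np.median(ratio)).astype(float)
    starts.append(np.clip(split, 0.05, 0.95))
    if init is not None:
        starts.append(np.clip(np.asarray(init, dtype=float), 1e-6, 1 - 1e-6))
    while len(starts) < n_starts:
        starts.append(rng.uniform(0.05, 0.95, size=len(x)))

    best: MixtureModelFit | None = None
    errors: list[str] = []
    for tau1 in starts:
        try:
            fit = _em(x, y, tau1, tol, max_iter)
        except _DegenerateFit as exc:
            errors.append(str(exc))
            continue
        if best is None or fit.loglik_trace[-1] > best.loglik_trace[-1]:
            best = fit
    if best is None:
        raise ValueError(f"degenerate fit: all EM starts collapsed ({errors[0]})")
    best = _canonicalize(best)
    # Two coincident components mean the data carry a single cluster: the
    # mixture is unidentifiable and any split of pi fits equally well.
    line_gap = np.max(np.abs((best.a1 - best.a0) + (best.b1 - best.b0) * x))
    if line_gap < 1e-4 * (1.0 + float(np.std(y))):
        raise ValueError(
            "degenerate fit: both components converged to the same regression line "
            "(all points appear to come from a single cluster)")
    return best


def posterior(fit: MixtureModelFit, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Posterior probability tau_i1 of cluster 'present', computed in log space."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    logd = _log_component_densities(
        x, y, fit.a0, fit.b0, fit.sigma0_sq, fit.a1, fit.b1, fit.sigma1_sq, fit.pi)
    return np.exp(logd[:, 1] - logsumexp(logd, axis=1))


@dataclass
class GenotypeCallSet:
    """Present/absent/unclassified calls for one line under BFDR control."""

    region_ids: list[str]
    calls: np.ndarray            # str array: present | absent | unclassified
    tau_present: np.ndarray      # posterior P(present) per region
    q: np.ndarray                # posterior misclassification prob of MAP call
    alpha: float                 # nominal BFDR level
    bfdr_estimate: float         # running-mean q at the classification cut

    @property
    def classified(self) -> np.ndarray:
        return self.calls != "unclassified"

    @property
    def classified_fraction(self) -> float:
        return float(np.mean(self.classified))

    def to_series(self) -> pd.Series:
        return pd.Series(self.calls, index=self.region_ids)


def bfdr_classify(
    tau_present: np.ndarray,
    alpha: float = 0.01,
    region_ids: list[str] | None = None,
) -> GenotypeCallSet:
    """Classify the most confident prefix of regions at nominal BFDR ``alpha``.

    q_i = 1 - max(tau_i0, tau_i1); regions sorted by ascending q are
    classified as long as the running mean of q (the posterior expected
    FDR of the calls made so far) stays <= alpha.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    tau_present = np.asarray(tau_present, dtype=float)
    if ((tau_present < 0) | (tau_present > 1)).any():
        raise ValueError("posterior probabilities must lie in [0, 1]")
    n = len(tau_present)
    q = 1.0 - np.maximum(tau_present, 1.0 - tau_present)
    order = np.argsort(q, kind="stable")
    running_mean = np.cumsum(q[order]) / np.arange(1, n + 1)
    ok = running_mean <= alpha
    n_classified = int(np.max(np.nonzero(ok)[0]) + 1) if ok.any() else 0

    calls = np.full(n, "unclassified", dtype=object)
    idx = order[:n_classified]
    calls[idx] = np.where(tau_present[idx] >= 0.5, "present", "absent")
    estimate = float(running_mean[n_classified - 1]) if n_classified else float("nan")
    if region_ids is None:
        region_ids = [str(i) for i in range(n)]
    return GenotypeCallSet(region_ids=list(region_ids), calls=calls,
                           tau_present=tau_present, q=q, alpha=alpha,
                           bfdr_estimate=estimate)


def _single_regression(x: np.ndarray, y: np.ndarray):
    """OLS of y on (1, x) with Gaussian errors; returns (a, b, sigma2, loglik)."""
    a, b = _weighted_ls(x, y, np.ones_like(x))
    resid = y - a - b * x
    s2 = max(float(np.mean(resid**2)), _SIGMA2_FLOOR)
    ll = float(norm.logpdf(resid, scale=np.sqrt(s2)).sum())
    return a, b, s2, ll


@dataclass
class PanelCalls:
    """Per-line mixture fits and call sets over a panel."""

    fits: dict[str, MixtureModelFit]
    call_sets: dict[str, GenotypeCallSet]
    skipped: dict[str, str]
    donor: str
    single_cluster: dict[str, dict] = field(default_factory=dict)

    def calls_frame(self) -> pd.DataFrame:
        """Regions x lines matrix of calls, 1/0/NA coded."""
        code = {"present": 1.0, "absent": 0.0, "unclassified": np.nan}
        cols = {line: [code[c] for c in cs.calls]
                for line, cs in self.call_sets.items()}
        any_cs = next(iter(self.call_sets.values()))
        return pd.DataFrame(cols, index=any_cs.region_ids)


def genotype_panel(
    dm: DepthMatrix,
    alpha: float = 0.01,
    seed: int = 0,
    lines: list[str] | None = None,
    single_cluster_slope: float = 0.5,
    **fit_kwargs,
) -> PanelCalls:
    """Fit, compute posteriors and classify every target line independently.

    The donor and the opposite-reference line are processed like any
    other line and serve as positive/negative controls.  A control line
    carries either every region or none, so the two-component mixture is
    unidentifiable there; such lines are detected by comparing the
    mixture against a single regression with BIC (the mixture spends 4
    extra parameters) and by the degenerate-fit guard.  For a
    single-cluster line, calls follow the fitted slope: a slope above
    ``single_cluster_slope`` means the counts track the donor's (all
    present); below, background (all absent).  Lines whose counts are
    all zero are skipped with a reason.
    """
    if dm.counts.empty:
        raise ValueError("empty depth matrix")
    target_lines = lines if lines is not None else dm.lines
    x = dm.x
    n = len(x)
    fits: dict[str, MixtureModelFit] = {}
    call_sets: dict[str, GenotypeCallSet] = {}
    skipped: dict[str, str] = {}
    single_cluster: dict[str, dict] = {}
    for line in target_lines:
        y = dm.y(line)
        if np.all(y == 0):
            skipped[line] = "all counts zero"
            continue
        a, b, s2, ll_single = _single_regression(x, y)
        fit: MixtureModelFit | None
        try:
            fit = fit_mixture(x, y, seed=seed, **fit_kwargs)
            if 2 * (fit.loglik_trace[-1] - ll_single) < 4 * np.log(n):
                fit = None  # mixture not supported by the data
        except ValueError:
            fit = None
        if fit is None:
            present = b >= single_cluster_slope
            tau1 = np.ones(n) if present else np.zeros(n)
            call_sets[line] = bfdr_classify(tau1, alpha=alpha, region_ids=dm.region_ids)
            single_cluster[line] = {
                "a": a, "b": b, "sigma_sq": s2,
                "call": "present" if present else "absent"}
            continue
        tau1 = posterior(fit, x, y)
        call_sets[line] = bfdr_classify(tau1, alpha=alpha, region_ids=dm.region_ids)
        fits[line] = fit
    if not call_sets:
        raise ValueError(f"no line could be genotyped: {skipped}")
    return PanelCalls(fits=fits, call_sets=call_sets, skipped=skipped,
                      donor=dm.donor, single_cluster=single_cluster)


def plot_line_fit(fit: MixtureModelFit, x, y, call_set: GenotypeCallSet, ax=None):
    """Scatter of sqrt counts colored by call, with both regression lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"present": "tab:green", "absent": "tab:red", "unclassified": "black"}
    for call, color in colors.items():
        mask = call_set.calls == call
        ax.scatter(np.asarray(x)[mask], np.asarray(y)[mask], s=6, c=color, label=call)
    xs = np.linspace(float(np.min(x)), float(np.max(x)), 50)
    ax.plot(xs, fit.a1 + fit.b1 * xs, c="tab:green", lw=1)
    ax.plot(xs, fit.a0 + fit.b0 * xs, c="tab:red", lw=1)
    ax.set_xlabel("donor sqrt read count")
    ax.set_ylabel("line sqrt read count")
    ax.legend(frameon=False, fontsize=8)
    return ax
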