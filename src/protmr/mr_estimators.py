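"""Two-sample MR estimators on harmonized exposure/outcome effect pairs.

Implements the Wald ratio, inverse-variance-weighted (IVW) regression
with optional multiplicative random effects, MR-Egger, the weighted
median, and the weighted mode. IVW is the pipeline's primary method; the
Egger intercept doubles as the directional-pleiotropy balance test.

All estimators consume either a list of
:class:`~protmr.sumstats_io.HarmonizedPair` or the four raw arrays
(β_X, σ_X, β_Y, σ_Y). Exposure-side uncertainty σ_X enters only through
the bootstrap procedures of the median/mode estimators; IVW and Egger
use the standard first-order weights 1/σ_Y².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats_io import pairs_to_arrays, normal_p

METHODS = ("wald", "ivw", "egger", "weighted_median", "weighted_mode")


@dataclass
class MREstimate:
    """One method's causal estimate for one exposure→outcome pair."""

    method: str
    beta: float = np.nan
    se: float = np.nan
    pvalue: float = np.nan
    n_iv: int = 0
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    Q: float | None = None
    random_effects: bool = False
    estimable: bool = True
    note: str = ""

    @classmethod
    def not_estimable(cls, method: str, n_iv: int, note: str) -> "MREstimate":
        return cls(method=method, n_iv=n_iv, estimable=False, note=note)


def _arrays(pairs):
    if isinstance(pairs, tuple):
        bx, sx, by, sy = (np.asarray(a, dtype=float) for a in pairs)
    else:
        bx, sx, by, sy = pairs_to_arrays(pairs)
    return bx, sx, by, sy


def wald_ratio(pair) -> MREstimate:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    if isinstance(pair, tuple):
        bx, _, by, sy = (float(v) for v in pair)
    else:
        bx, _, by, sy = (pair.beta_exposure, pair.se_exposure,
                         pair.beta_outcome, pair.se_outcome)
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exposure = 0")
    beta = by / bx
    se = sy / abs(bx)
    return MREstimate("wald", beta, se, float(normal_p(beta / se)), n_iv=1)


def ivw(pairs, random_effects: str = "auto") -> MREstimate:
    """Inverse-variance-weighted estimate (zero-intercept weighted regression).

    beta = Σw·β_X·β_Y / Σw·β_X² with w = 1/σ_Y²; the fixed-effect SE
    (Σw·β_X²)^−1/2 is inflated by √(Q/(n−1)) when the Cochran Q statistic
    is overdispersed (``random_effects="auto"``, the default multiplicative
    random-effects convention); ``"fixed"`` disables the inflation.
    """
    bx, sx, by, sy = _arrays(pairs)
    n = len(bx)
    if n == 0:
        return MREstimate.not_estimable("ivw", 0, "no instruments")
    if n == 1:
        est = wald_ratio((bx[0], sx[0], by[0], sy[0]))
        return MREstimate("ivw", est.beta, est.se, est.pvalue, n_iv=1)
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    if sxx == 0:
        raise ZeroDivisionError("all exposure betas are zero")
    beta = np.sum(w * bx * by) / sxx
    Q = float(np.sum(w * (by - beta * bx) ** 2))
    se = sxx**-0.5
    overdispersed = Q / (n - 1) > 1
    if random_effects == "auto" and overdispersed:
        se *= np.sqrt(Q / (n - 1))
    return MREstimate(
        "ivw", float(beta), float(se), float(normal_p(beta / se)),
        n_iv=n, Q=Q, random_effects=bool(random_effects == "auto" and overdispersed),
    )


def egger(pairs) -> MREstimate:
    """MR-Egger: weighted regression of β_Y on β_X with a free intercept.

    β_X is oriented non-negative before fitting; the intercept estimate,
    SE and p-value form the directional-pleiotropy balance test. p-values
    use t(n−2); SEs come from the plain WLS covariance (residual variance
    RSS/(n−2)), which makes the intercept test an exact t-test under
    homoskedastic independent instruments.
    """
    bx, sx, by, sy = _arrays(pairs)
    n = len(bx)
    if n < 3:
        return MREstimate.not_estimable("egger", n, "needs >= 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ by)
    resid = by - X @ coef
    rss = float(np.sum(w * resid**2))
    sigma2 = rss / (n - 2)
    cov = sigma2 * np.linalg.inv(A)
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    t = stats.t(df=n - 2)
    with np.errstate(divide="ignore"):
        p_slope = max(2 * t.sf(abs(slope / se_slope)) if se_slope > 0 else 0.0,
                      np.finfo(float).tiny)
        p_int = max(2 * t.sf(abs(intercept / se_int)) if se_int > 0 else 0.0,
                    np.finfo(float).tiny)
    return MREstimate(
        "egger", float(slope), float(se_slope), float(p_slope), n_iv=n,
        intercept=float(intercept), intercept_se=float(se_int),
        intercept_p=float(p_int), Q=rss, random_effects=sigma2 > 1,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    s = np.cumsum(w) - w / 2
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] < 0.5:
        return float(r[-1])
    j = np.searchsorted(s, 0.5, side="left")  # first s[j] >= 0.5
    return float(r[j - 1] + (r[j] - r[j - 1]) * (0.5 - s[j - 1]) / (s[j] - s[j - 1]))


def weighted_median(pairs, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of the per-instrument Wald ratios.

    Weights are β_X²/σ_Y² (inverse variance of each ratio to first
    order); the estimate interpolates where the standardized cumulative
    weight crosses one half, and the SE comes from a seeded parametric
    bootstrap resampling β_X and β_Y from their normal errors.
    """
    bx, sx, by, sy = _arrays(pairs)
    n = len(bx)
    if n < 3:
        return MREstimate.not_estimable("weighted_median", n, "needs >= 3 instruments")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(n)
        bys = by + sy * rng.standard_normal(n)
        bxs[bxs == 0] = 1e-300
        boots[b] = _weighted_median_point(bys / bxs, bxs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    p = float(normal_p(beta / se)) if se > 0 else np.nan
    return MREstimate("weighted_median", float(beta), se, p, n_iv=n)


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float,
                grid_size: int = 512) -> float:
    n = len(ratios)
    sd = np.std(ratios, ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    disp = min(sd, iqr / 1.349) if iqr > 0 else sd
    if disp == 0:
        return float(ratios[0])
    h = phi * 0.9 * disp * n ** (-1 / 5)
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, grid_size)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])  # argmax takes the first (smallest) tie


def weighted_mode(pairs, bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int = 0) -> MREstimate:
    """Mode of the weighted kernel density over Wald ratios.

    Normal kernel with bandwidth φ × modified-Silverman rule on the ratio
    dispersion; the density is maximized on a fixed 512-point grid
    spanning the ratios ± 3 bandwidths. SE by seeded parametric bootstrap.
    """
    bx, sx, by, sy = _arrays(pairs)
    n = len(bx)
    if n < 3:
        return MREstimate.not_estimable("weighted_mode", n, "needs >= 3 instruments")
    ratios = by / bx
    weights = bx**2 / sy**2
    weights = weights / weights.sum()
    beta = _mode_point(ratios, weights, bandwidth_factor)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + sx * rng.standard_normal(n)
        bys = by + sy * rng.standard_normal(n)
        bxs[bxs == 0] = 1e-300
        wb = bxs**2 / sy**2
        boots[b] = _mode_point(bys / bxs, wb / wb.sum(), bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    p = float(normal_p(beta / se)) if se > 0 else np.nan
    return MREstimate("weighted_mode", float(beta), se, p, n_iv=n)


def estimate_all(pairs, methods=("ivw", "egger", "weighted_median", "weighted_mode"),
                 n_boot: int = 1000, seed: int = 0) -> dict[str, MREstimate]:
    """Run several estimators on one harmonized instrument set."""
    out: dict[str, MREstimate] = {}
    for m in methods:
        if m == "ivw":
            out[m] = ivw(pairs)
        elif m == "ivw_fe":
            out[m] = ivw(pairs, random_effects="fixed")
            out[m].method = "ivw_fe"
        elif m == "egger":
            out[m] = egger(pairs)
        elif m == "weighted_median":
            out[m] = weighted_median(pairs, n_boot=n_boot, seed=seed)
        elif m == "weighted_mode":
            out[m] = weighted_mode(pairs, n_boot=n_boot, seed=seed + 1)
        elif m == "wald":
            bx, sx, by, sy = _arrays(pairs)
            out[m] = (wald_ratio((bx[0], sx[0], by[0], sy[0]))
                      if len(bx) == 1 else MREstimate.not_estimable(
                          "wald", len(bx), "wald applies to a single instrument"))
        else:
            raise ValueError(f"unknown method {m!r}")
    return out
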