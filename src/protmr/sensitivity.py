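"""Horizontal-pleiotropy detection and multivariable MR.

Three sensitivity analyses around the core estimators:

* :func:`presso` — a residual-sum-of-squares simulation test in the
  style of MR-PRESSO: observed RSS from leave-one-out IVW predictions is
  ranked against a parametric null, globally and per instrument;
  Bonferroni-significant instruments are removed and the IVW estimate
  recomputed, with a distortion test on the shift.
* :func:`heidi_filter` — a HEIDI-style outlier filter comparing each
  instrument's Wald ratio to the reference instrument's (smallest
  exposure p) with a delta-method variance.
* :func:`mvmr_fit` — multivariable weighted least squares of outcome
  z-scores on a variant × protein exposure z-score matrix, estimating
  each protein's effect conditional on the others (the trans-sharing
  adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mr_estimators import MREstimate, ivw
from .sumstats_io import normal_p

MVMR_CLUMP_R2 = 0.01  # stricter pre-clumping threshold for the z-score design


@dataclass
class PressoResult:
    global_rss_observed: float
    global_p: float
    per_iv_outlier_p: dict[str, float]
    outliers_removed: list[str]
    corrected_estimate: MREstimate | None
    distortion_p: float | None
    raw_estimate: MREstimate | None = None
    n_sim: int = 0


@dataclass
class MVMRResult:
    exposures: list[str]
    beta: np.ndarray
    se: np.ndarray
    pvalue: np.ndarray
    n_variants: int
    conditioning: dict[str, list[str]] = field(default_factory=dict)


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for each instrument, O(n) via running sums."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx**2)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def presso(
    pairs,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """RSS-simulation pleiotropy test with outlier removal.

    Observed RSS = Σ_j w_j (β_Yj − β̂_(−j)·β_Xj)² with w = 1/σ_Y² and
    β̂_(−j) the leave-one-out IVW slope. The null distribution re-samples
    β_Y* ~ N(β̂_(−j)·β_Xj, σ_Yj) and recomputes the statistic per
    simulation. Per-instrument terms are ranked the same way; instruments
    with Bonferroni-corrected empirical p < ``outlier_alpha``/n_iv are
    removed and the IVW estimate recomputed. The distortion test ranks
    the observed corrected-vs-raw shift against removals of random
    subsets of the same size.
    """
    from .sumstats_io import pairs_to_arrays

    if isinstance(pairs, tuple):
        bx, sx, by, sy = (np.asarray(a, dtype=float) for a in pairs)
        ids = [f"iv{j}" for j in range(len(bx))]
    else:
        bx, sx, by, sy = pairs_to_arrays(pairs)
        ids = [p.variant_id for p in pairs]
    n = len(bx)
    if n < 4:
        return PressoResult(np.nan, np.nan, {}, [], None, None,
                            raw_estimate=None, n_sim=0)
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2
    loo = _loo_ivw(bx, by, w)
    obs_terms = w * (by - loo * bx) ** 2
    obs_rss = float(np.sum(obs_terms))

    # parametric null: n_sim draws of the full beta_Y vector
    y_sim = loo * bx + sy * rng.standard_normal((n_sim, n))
    sxy_sim = y_sim @ (w * bx)
    sxx = np.sum(w * bx**2)
    loo_sim = (sxy_sim[:, None] - w * bx * y_sim) / (sxx - w * bx**2)
    terms_sim = w * (y_sim - loo_sim * bx) ** 2
    rss_sim = terms_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= obs_rss)) / (n_sim + 1))
    per_p = (1 + np.sum(terms_sim >= obs_terms, axis=0)) / (n_sim + 1)
    cutoff = outlier_alpha / n
    outliers = [ids[j] for j in range(n) if per_p[j] < cutoff]

    raw = ivw((bx, sx, by, sy))
    corrected = raw
    distortion_p: float | None = None
    if outliers:
        keep = np.array([vid not in outliers for vid in ids])
        if keep.sum() >= 1:
            corrected = ivw((bx[keep], sx[keep], by[keep], sy[keep]))
            d_obs = corrected.beta - raw.beta
            n_out = len(outliers)
            d_sim = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(n, size=n_out, replace=False)
                mask = np.ones(n, dtype=bool)
                mask[drop] = False
                d_sim[s] = ivw((bx[mask], sx[mask], by[mask], sy[mask])).beta - raw.beta
            distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (n_sim + 1))
        else:
            corrected = None
    return PressoResult(
        global_rss_observed=obs_rss,
        global_p=global_p,
        per_iv_outlier_p={ids[j]: float(per_p[j]) for j in range(n)},
        outliers_removed=outliers,
        corrected_estimate=corrected,
        distortion_p=distortion_p,
        raw_estimate=raw,
        n_sim=n_sim,
    )


def heidi_filter(pairs, heidi_alpha: float = 0.01):
    """HEIDI-style outlier filter against the top instrument's Wald ratio.

    The reference instrument is the one with the smallest exposure p
    (largest |β_X/σ_X|); for every other instrument the ratio difference
    d_j = ratio_j − ratio_ref is tested with a delta-method variance on
    both traits (reference variance included, covariance ignored).
    Instruments with two-sided p < ``heidi_alpha`` are removed; one more
    pass re-runs the test on the survivors. The reference is never
    removed.

    Returns (kept_pairs, removed_ids).
    """
    from .sumstats_io import pairs_to_arrays

    kept = list(pairs)
    removed: list[str] = []
    for _ in range(2):  # single-pass filter, iterated once
        if len(kept) < 3:
            break
        bx, sx, by, sy = pairs_to_arrays(kept)
        ref = int(np.argmax(np.abs(bx / sx)))
        ratios = by / bx
        var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
        d = ratios - ratios[ref]
        var_d = var + var[ref]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = normal_p(d / np.sqrt(var_d))
        drop = [j for j in range(len(kept)) if j != ref and p[j] < heidi_alpha]
        if not drop:
            break
        removed.extend(kept[j].variant_id if hasattr(kept[j], "variant_id")
                       else f"iv{j}" for j in drop)
        kept = [kept[j] for j in range(len(kept)) if j not in drop]
    return kept, removed


def mvmr_fit(
    z_exposures: np.ndarray,
    z_outcome: np.ndarray,
    exposure_ids: list[str] | None = None,
) -> MVMRResult:
    """Multivariable MR on z-scores: WLS of outcome z on the exposure z matrix.

    No intercept; with unit-variance z-scores the error variance is 1,
    so SEs come from the unscaled (XᵀX)⁻¹. Variants are expected to be
    pre-clumped at r² < 0.01 within 500 kb and significant for at least
    one exposure. Rank deficiency raises naming a collinear exposure pair.
    """
    X = np.atleast_2d(np.asarray(z_exposures, dtype=float))
    y = np.asarray(z_outcome, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("z_exposures and z_outcome row counts differ")
    n_var, n_exp = X.shape
    if exposure_ids is None:
        exposure_ids = [f"exposure{k}" for k in range(n_exp)]
    if len(set(exposure_ids)) != n_exp:
        raise ValueError("exposure ids must be distinct")
    if n_var < n_exp:
        raise ValueError("need at least as many variants as exposures")
    if np.linalg.matrix_rank(X) < n_exp:
        # name an offending pair via pairwise correlation
        C = np.corrcoef(X, rowvar=False)
        np.fill_diagonal(C, 0.0)
        a, b = np.unravel_index(np.nanargmax(np.abs(C)), C.shape)
        raise np.linalg.LinAlgError(
            f"rank-deficient design: exposures {exposure_ids[a]!r} and "
            f"{exposure_ids[b]!r} are collinear"
        )
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    cov = np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    p = normal_p(beta / se)
    return MVMRResult(
        exposures=list(exposure_ids),
        beta=beta, se=se, pvalue=np.asarray(p),
        n_variants=n_var,
        conditioning={e: [x for x in exposure_ids if x != e] for e in exposure_ids},
    )
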