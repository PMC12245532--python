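"""Multi-trait colocalization with approximate Bayes factors.

For a set of traits restricted to one region, the per-variant evidence
that trait *t* is causal at variant *j* is the Wakefield approximate
Bayes factor

    log ABF = ½·log(σ²/(σ²+W²)) + ½·z²·W²/(σ²+W²),  z = β/σ,

with prior effect SD W (0.15 for quantitative traits, 0.2 for binary
log-odds by default). Three configuration families are weighed against
each other:

* null — no trait causal (weight 1);
* independent — every trait causal somewhere, variants independent a
  priori (per-trait prior p1 per variant);
* shared — every trait causal at the same variant (prior p1 for the
  first trait times a conditional sharing prior for each additional
  trait).

``regional_prob`` is the posterior that every trait has a causal variant
in the region; ``alignment_prob`` is the posterior mass of the shared
configuration among all-causal configurations; their product is the
reported posterior that the whole set shares one causal variant. When
either falls below its threshold the trait set is split divisively —
dropping the trait whose removal maximizes the remaining cluster's
alignment — and the remainder re-assessed. This is a deliberately
simplified divisive multi-trait scheme, not a re-implementation of any
published clustering algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sumstats_io import SummaryStatSet

PRIOR_P1 = 1e-4
CONDITIONAL_PRIORS = (0.005, 0.01, 0.02)
W_QUANTITATIVE = 0.15
W_BINARY = 0.2
REGIONAL_THRESHOLD = 0.7
ALIGNMENT_THRESHOLD = 0.7
THRESHOLD_SWEEP = (0.6, 0.7, 0.8, 0.9)


def wakefield_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for one variant–trait association."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("se and prior_sd must be > 0")
    z = beta / se
    shrink = prior_sd**2 / (se**2 + prior_sd**2)
    out = 0.5 * np.log(se**2 / (se**2 + prior_sd**2)) + 0.5 * z**2 * shrink
    return float(out) if out.ndim == 0 else out


@dataclass
class ColocResult:
    trait_set: list[str]
    regional_prob: float
    alignment_prob: float
    shared_prob: float  # regional × alignment, always computed
    posterior_prob: float | None  # reported only when both thresholds pass
    candidate_variant: str | None
    cluster_assignment: dict[str, int] = field(default_factory=dict)
    children: list["ColocResult"] = field(default_factory=list)

    def clusters(self) -> list["ColocResult"]:
        """Leaf clusters of the divisive tree (self if not split)."""
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.clusters())
        return out


def _trait_prior_sd(ss: SummaryStatSet, prior_sd) -> float:
    if prior_sd is not None:
        return prior_sd
    return W_BINARY if ss.trait_kind == "disease" else W_QUANTITATIVE


def _log_abf_matrix(trait_stats: list[SummaryStatSet], variant_ids: list[str],
                    prior_sd) -> np.ndarray:
    """traits × variants matrix of log ABFs over the shared variant index."""
    mat = np.empty((len(trait_stats), len(variant_ids)))
    for t, ss in enumerate(trait_stats):
        W = _trait_prior_sd(ss, prior_sd)
        idx = [ss.loc(v) for v in variant_ids]
        beta, se = ss.beta[idx], ss.se[idx]
        z = beta / se
        shrink = W**2 / (se**2 + W**2)
        mat[t] = 0.5 * np.log(se**2 / (se**2 + W**2)) + 0.5 * z**2 * shrink
    return mat


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    return float(m + np.log(np.sum(np.exp(a - m))))


def _cluster_probs(labf: np.ndarray, p1: float, conditional: tuple[float, ...]):
    """(regional, alignment, best variant index) for one trait set."""
    m, J = labf.shape
    log_p1 = np.log(p1)
    # per-trait evidence of being causal somewhere (independent prior p1/variant)
    per_trait = np.array([_logsumexp(labf[t]) + log_p1 for t in range(m)])
    log_indep = float(np.sum(per_trait))
    # shared configuration: same variant for all traits
    shared_prior = log_p1 + sum(
        np.log(conditional[min(k, len(conditional) - 1)]) for k in range(m - 1)
    )
    joint = labf.sum(axis=0)
    log_shared = _logsumexp(joint) + shared_prior
    # total over null/partial/independent configurations plus shared
    log_any = float(np.sum(np.logaddexp(0.0, per_trait)))
    log_total = np.logaddexp(log_any, log_shared)
    log_causal = np.logaddexp(log_indep, log_shared)
    regional = float(np.exp(log_causal - log_total))
    alignment = float(np.exp(log_shared - log_causal))
    return regional, alignment, int(np.argmax(joint))


def multitrait_coloc(
    trait_stats: list[SummaryStatSet],
    p1: float = PRIOR_P1,
    conditional: tuple[float, ...] = CONDITIONAL_PRIORS,
    regional_threshold: float = REGIONAL_THRESHOLD,
    alignment_threshold: float = ALIGNMENT_THRESHOLD,
    prior_sd: float | None = None,
    variant_ids: list[str] | None = None,
) -> ColocResult:
    """Divisive multi-trait colocalization over one region.

    Traits whose joint regional and alignment probabilities clear the
    thresholds are reported as one colocalized cluster with the top
    shared variant; otherwise the set is split divisively and the parts
    re-assessed. Deterministic; trait order never changes a final
    cluster's posterior (the evidence sums are order-invariant).
    """
    import warnings

    if len(trait_stats) < 2:
        raise ValueError("need at least two traits")
    if variant_ids is None:
        shared = set(trait_stats[0].variant_id)
        for ss in trait_stats[1:]:
            shared &= set(ss.variant_id)
        if not shared:
            raise ValueError("no overlapping variant ids across traits")
        variant_ids = sorted(shared)
    if len(variant_ids) < 10:
        warnings.warn(
            f"region has only {len(variant_ids)} shared variants; "
            "colocalization may be unstable", stacklevel=2)
    labf = _log_abf_matrix(trait_stats, variant_ids, prior_sd)
    names = [ss.trait_id for ss in trait_stats]
    return _divide(trait_stats, names, labf, variant_ids, p1, conditional,
                   regional_threshold, alignment_threshold)


def _singleton(name: str) -> ColocResult:
    return ColocResult(
        trait_set=[name], regional_prob=np.nan, alignment_prob=np.nan,
        shared_prob=np.nan, posterior_prob=None, candidate_variant=None,
        cluster_assignment={name: 0},
    )


def _divide(trait_stats, names, labf, variant_ids, p1, conditional,
            reg_thr, aln_thr) -> ColocResult:
    m = labf.shape[0]
    regional, alignment, best_j = _cluster_probs(labf, p1, conditional)
    shared = regional * alignment
    if regional >= reg_thr and alignment >= aln_thr:
        return ColocResult(
            trait_set=list(names),
            regional_prob=regional,
            alignment_prob=alignment,
            shared_prob=shared,
            posterior_prob=shared,
            candidate_variant=variant_ids[best_j],
            cluster_assignment={t: 0 for t in names},
        )
    parent = ColocResult(
        trait_set=list(names), regional_prob=regional,
        alignment_prob=alignment, shared_prob=shared,
        posterior_prob=None, candidate_variant=None,
    )
    if m == 2:
        parent.children = [_singleton(names[0]), _singleton(names[1])]
        parent.cluster_assignment = {names[0]: 0, names[1]: 1}
        return parent
    # drop the trait whose removal maximizes the remaining alignment
    best_drop, best_aln = 0, -1.0
    for t in range(m):
        rest = np.delete(labf, t, axis=0)
        _, aln, _ = _cluster_probs(rest, p1, conditional)
        if aln > best_aln:
            best_drop, best_aln = t, aln
    rest_idx = [t for t in range(m) if t != best_drop]
    child = _divide([trait_stats[t] for t in rest_idx],
                    [names[t] for t in rest_idx],
                    labf[rest_idx], variant_ids, p1, conditional,
                    reg_thr, aln_thr)
    parent.children = [child, _singleton(names[best_drop])]
    for t in child.trait_set:
        parent.cluster_assignment[t] = 0
    parent.cluster_assignment[names[best_drop]] = 1
    return parent


def threshold_sweep(
    trait_stats: list[SummaryStatSet],
    thresholds: tuple[float, ...] = THRESHOLD_SWEEP,
    **kwargs,
) -> dict[tuple[float, float], ColocResult]:
    """Run colocalization at each (regional, alignment) threshold pair."""
    out = {}
    for rt in thresholds:
        for at in thresholds:
            out[(rt, at)] = multitrait_coloc(
                trait_stats, regional_threshold=rt, alignment_threshold=at,
                **kwargs)
    return out
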