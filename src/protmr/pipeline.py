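"""Bidirectional proteome-wide MR orchestration.

Forward MR treats each protein as exposure and each disease as outcome
("targets"); reverse MR swaps the roles ("biomarkers"). Per
exposure–outcome pair the pipeline builds instruments, runs the
estimators (IVW primary), and applies multiplicity control within the
(direction, iv_mode, ancestry) family; Bonferroni uses m = the number of
actually testable pairs in the family, and m is reported alongside the
flags. Discovery-significant pairs are re-tested in a smaller
replication pQTL panel, pleiotropy sensitivity analyses run on the
significant cis+trans pairs, and significant proteins feed a
phenome-wide scan whose per-category over-representation is scored with
an upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .instruments import InstrumentSet, SelectionParams, build_instrument_set
from .ld import LDCollection
from .mr_estimators import MREstimate, estimate_all
from .sensitivity import PressoResult, heidi_filter, presso
from .sumstats_io import GeneAnnotation, HarmonizedPair, SummaryStatSet

logger = logging.getLogger(__name__)

MIN_CASES = 50
SPECIFICITY_THRESHOLDS = (20, 15, 10, 5)


@dataclass
class PipelineParams:
    selection: SelectionParams = field(default_factory=SelectionParams)
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median", "weighted_mode")
    primary: str = "ivw"
    alpha: float = 0.05
    n_boot: int = 1000
    presso_n_sim: int = 1000
    heidi_alpha: float = 0.01


@dataclass
class AssociationRecord:
    exposure_id: str
    outcome_id: str
    direction: str          # forward | reverse
    ancestry: str
    iv_mode: str            # cis_only | cis_plus_trans
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    instrument_set: InstrumentSet | None = None
    pairs: list[HarmonizedPair] = field(default_factory=list)
    testable: bool = False
    significant_bonferroni: bool = False
    significant_fdr: bool = False
    replicated_p05: bool | None = None
    replicated_fdr: bool | None = None
    replicated_bonferroni: bool | None = None
    direction_consistent: bool | None = None
    presso: PressoResult | None = None
    heidi_removed: list[str] = field(default_factory=list)

    def primary_estimate(self, primary: str = "ivw") -> MREstimate | None:
        est = self.estimates.get(primary)
        return est if est is not None and est.estimable else None


@dataclass
class EnrichmentResult:
    group_id: str
    category_id: str
    N: int
    M: int
    n: int
    k: int
    pvalue: float
    significant: bool = False


@dataclass
class PhewasMatrix:
    z: pd.DataFrame          # proteins × phenotypes
    p: pd.DataFrame
    testable: pd.DataFrame
    categories: dict[str, str]


def run_pair(
    exposure: SummaryStatSet, outcome: SummaryStatSet,
    gene: GeneAnnotation | None, iv_mode: str, ld: LDCollection,
    params: PipelineParams, direction: str, ancestry: str, seed: int,
) -> AssociationRecord:
    iv_set, pairs = build_instrument_set(exposure, outcome, gene, iv_mode,
                                         ld, params.selection)
    rec = AssociationRecord(
        exposure_id=exposure.trait_id, outcome_id=outcome.trait_id,
        direction=direction, ancestry=ancestry, iv_mode=iv_mode,
        instrument_set=iv_set, pairs=pairs, testable=iv_set.testable,
    )
    if iv_set.testable:
        rec.estimates = estimate_all(pairs, params.methods,
                                     n_boot=params.n_boot, seed=seed)
    return rec


def run_direction(
    exposures: dict[str, SummaryStatSet],
    outcomes: dict[str, SummaryStatSet],
    direction: str,
    ancestry: str,
    iv_mode: str,
    ld: LDCollection,
    params: PipelineParams,
    seed: int,
    genes: dict[str, GeneAnnotation] | None = None,
) -> list[AssociationRecord]:
    """All exposure × outcome MR tests for one direction and IV mode.

    Forward runs need ``genes`` (cis classification of protein
    instruments); reverse runs use every clumped disease instrument.
    Pairs with zero instruments are marked not-testable and excluded from
    the multiplicity denominator.
    """
    rng = np.random.default_rng(seed)
    records = []
    for exp_id in sorted(exposures):
        gene = (genes or {}).get(exp_id)
        mode = iv_mode if gene is not None else "cis_plus_trans"
        for out_id in sorted(outcomes):
            records.append(run_pair(
                exposures[exp_id], outcomes[out_id], gene, mode, ld, params,
                direction, ancestry, int(rng.integers(0, 2**31 - 1))))
    return records


def adjust_multiplicity(
    records: list[AssociationRecord],
    method: str = "bonferroni",
    alpha: float = 0.05,
    primary: str = "ivw",
) -> int:
    """Set significance flags within one family of records; returns m.

    ``m`` is the number of testable records (the family size actually
    analyzable); Bonferroni compares raw p against alpha/m, BH uses the
    standard step-up rule. Not-testable records keep False flags.
    """
    testable = [r for r in records if r.testable and r.primary_estimate(primary)]
    m = len(testable)
    if m == 0:
        return 0
    pvals = np.array([r.primary_estimate(primary).pvalue for r in testable])
    if method in ("bonferroni", "both"):
        for r, p in zip(testable, pvals):
            r.significant_bonferroni = bool(p < alpha / m)
    if method in ("bh", "both"):
        flags = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        for r, f in zip(testable, flags):
            r.significant_fdr = bool(f)
    return m


def sensitivity_pass(
    records: list[AssociationRecord],
    params: PipelineParams,
    seed: int,
    min_iv_presso: int = 4,
) -> None:
    """Pleiotropy sensitivity analyses on significant cis+trans records."""
    rng = np.random.default_rng(seed)
    for rec in records:
        if not (rec.significant_bonferroni and rec.iv_mode == "cis_plus_trans"):
            continue
        if len(rec.pairs) >= min_iv_presso:
            rec.presso = presso(rec.pairs, n_sim=params.presso_n_sim,
                                seed=int(rng.integers(0, 2**31 - 1)))
        if len(rec.pairs) >= 3:
            _, removed = heidi_filter(rec.pairs, params.heidi_alpha)
            rec.heidi_removed = removed


def replicate(
    discovery_records: list[AssociationRecord],
    replication_exposures: dict[str, SummaryStatSet],
    outcomes: dict[str, SummaryStatSet],
    ld: LDCollection,
    params: PipelineParams,
    seed: int,
    genes: dict[str, GeneAnnotation] | None = None,
    alpha: float = 0.05,
) -> list[AssociationRecord]:
    """Re-test discovery-significant pairs in the replication pQTL panel.

    Flags: ``replicated_p05`` (raw p < 0.05), ``replicated_fdr`` (BH over
    the replication family), ``replicated_bonferroni`` (alpha over the
    family size); ``direction_consistent`` is the sign match of the
    primary-method beta. Exposures missing from the panel are marked
    not-assessable (flags stay None).
    """
    rng = np.random.default_rng(seed)
    sig = [r for r in discovery_records if r.significant_bonferroni]
    repl_records = []
    assessed: list[tuple[AssociationRecord, AssociationRecord]] = []
    for rec in sig:
        if rec.exposure_id not in replication_exposures:
            logger.info("replication: %s absent from panel", rec.exposure_id)
            continue
        gene = (genes or {}).get(rec.exposure_id)
        rrec = run_pair(
            replication_exposures[rec.exposure_id], outcomes[rec.outcome_id],
            gene, rec.iv_mode if gene is not None else "cis_plus_trans",
            ld, params, rec.direction, rec.ancestry,
            int(rng.integers(0, 2**31 - 1)))
        repl_records.append(rrec)
        if rrec.testable and rrec.primary_estimate(params.primary):
            assessed.append((rec, rrec))
    m = len(assessed)
    if m:
        pvals = np.array([rr.primary_estimate(params.primary).pvalue
                          for _, rr in assessed])
        bh = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        for (rec, rrec), p, fdr_flag in zip(assessed, pvals, bh):
            disc = rec.primary_estimate(params.primary)
            repl = rrec.primary_estimate(params.primary)
            rec.replicated_p05 = bool(p < alpha)
            rec.replicated_fdr = bool(fdr_flag)
            rec.replicated_bonferroni = bool(p < alpha / m)
            rec.direction_consistent = bool(np.sign(disc.beta) == np.sign(repl.beta))
    return repl_records


def overlap_targets_biomarkers(
    forward_records: list[AssociationRecord],
    reverse_records: list[AssociationRecord],
) -> dict[str, dict[str, list[str]]]:
    """Proteins significant in both directions, with per-direction lists."""
    fwd: dict[str, list[str]] = {}
    for r in forward_records:
        if r.significant_bonferroni:
            fwd.setdefault(r.exposure_id, []).append(r.outcome_id)
    rev: dict[str, list[str]] = {}
    for r in reverse_records:
        if r.significant_bonferroni:
            rev.setdefault(r.outcome_id, []).append(r.exposure_id)
    return {
        p: {"forward_outcomes": sorted(fwd[p]), "reverse_exposures": sorted(rev[p])}
        for p in sorted(set(fwd) & set(rev))
    }


def phewas_scan(
    proteins: dict[str, SummaryStatSet],
    phenotypes: dict[str, SummaryStatSet],
    phenotype_meta: pd.DataFrame,
    ld: LDCollection,
    params: PipelineParams,
    seed: int,
    genes: dict[str, GeneAnnotation] | None = None,
    iv_mode: str = "cis_plus_trans",
    min_cases: int = MIN_CASES,
    direction: str = "forward",
) -> PhewasMatrix:
    """Protein × phenotype MR scan over a category-labelled panel.

    Phenotypes with fewer than ``min_cases`` cases are excluded. The z
    matrix holds beta/se of the primary method; not-testable cells are
    NaN with ``testable`` False.
    """
    meta = phenotype_meta.set_index("phenotype_id")
    keep = [p for p in sorted(phenotypes)
            if p in meta.index and int(meta.loc[p, "n_cases"]) >= min_cases]
    prot_ids = sorted(proteins)
    z = pd.DataFrame(np.nan, index=prot_ids, columns=keep)
    pmat = pd.DataFrame(np.nan, index=prot_ids, columns=keep)
    testable = pd.DataFrame(False, index=prot_ids, columns=keep)
    rng = np.random.default_rng(seed)
    for prot in prot_ids:
        for ph in keep:
            if direction == "forward":
                exp, out = proteins[prot], phenotypes[ph]
                gene = (genes or {}).get(prot)
                mode = iv_mode if gene is not None else "cis_plus_trans"
            else:
                exp, out = phenotypes[ph], proteins[prot]
                gene, mode = None, "cis_plus_trans"
            rec = run_pair(exp, out, gene, mode, ld, params, direction,
                           exp.ancestry, int(rng.integers(0, 2**31 - 1)))
            est = rec.primary_estimate(params.primary)
            if rec.testable and est is not None:
                z.loc[prot, ph] = est.beta / est.se
                pmat.loc[prot, ph] = est.pvalue
                testable.loc[prot, ph] = True
    cats = {p: str(meta.loc[p, "category"]) for p in keep}
    return PhewasMatrix(z, pmat, testable, cats)


def phewas_significance(phewas: PhewasMatrix, alpha: float = 0.05,
                        method: str = "bonferroni") -> pd.DataFrame:
    """Per-cell significance flags, Bonferroni over all testable cells."""
    m = int(phewas.testable.to_numpy().sum())
    sig = pd.DataFrame(False, index=phewas.p.index, columns=phewas.p.columns)
    if m == 0:
        return sig
    if method == "bonferroni":
        sig[:] = (phewas.p < alpha / m) & phewas.testable
    else:
        pv = phewas.p.to_numpy()[phewas.testable.to_numpy()]
        flags = multipletests(pv, alpha=alpha, method="fdr_bh")[0]
        arr = np.zeros(phewas.p.shape, dtype=bool)
        arr[phewas.testable.to_numpy()] = flags
        sig[:] = arr
    return sig


def classify_specificity(
    phewas: PhewasMatrix,
    significance: pd.DataFrame | None = None,
    thresholds: tuple[int, ...] = SPECIFICITY_THRESHOLDS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label each protein's phenome-wide footprint.

    ``specific_to_one_disease``: exactly one significant phenotype;
    ``specific_to_one_category``: all significant phenotypes in one
    category; ``pleiotropic_at_k``: ≥ k significant phenotypes, for each
    configured k; proteins with no signal are ``unclassified``.
    """
    if significance is None:
        significance = phewas_significance(phewas, alpha)
    rows = []
    for prot in significance.index:
        hits = [ph for ph in significance.columns if significance.loc[prot, ph]]
        cats = {phewas.categories[ph] for ph in hits}
        labels = []
        if len(hits) == 0:
            labels.append("unclassified")
        if len(hits) == 1:
            labels.append("specific_to_one_disease")
        if len(hits) >= 1 and len(cats) == 1:
            labels.append("specific_to_one_category")
        for k in thresholds:
            if len(hits) >= k:
                labels.append(f"pleiotropic_at_{k}")
        rows.append({"protein": prot, "n_significant": len(hits),
                     "n_categories": len(cats), "labels": labels})
    return pd.DataFrame(rows).set_index("protein")


def hypergeom_tail_p(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric P(X ≥ k) for the over-representation test."""
    if not (0 <= M <= N and 0 <= n <= N and 0 <= k <= min(n, M)):
        raise ValueError(f"inconsistent counts N={N} M={M} n={n} k={k}")
    return float(sps.hypergeom.sf(k - 1, N, M, n))


def enrichment_test(
    group_id: str,
    group_proteins: list[str],
    category_id: str,
    significance: pd.DataFrame,
    categories: dict[str, str],
) -> EnrichmentResult:
    """Over-representation of protein group G in disease category D.

    N = (total phenotypes) × |G|; M = (phenotypes in D) × |G|;
    n = significant (protein, phenotype) signals with protein ∈ G across
    all categories; k = those within D. P = upper-tail hypergeometric.
    """
    phenos = list(significance.columns)
    in_d = [ph for ph in phenos if categories.get(ph) == category_id]
    g = [p for p in group_proteins if p in significance.index]
    N = len(phenos) * len(g)
    M = len(in_d) * len(g)
    sub = significance.loc[g]
    n = int(sub.to_numpy().sum())
    k = int(sub[in_d].to_numpy().sum()) if in_d else 0
    return EnrichmentResult(group_id, category_id, N, M, n, k,
                            hypergeom_tail_p(N, M, n, k))


def enrichment_scan(
    groups: dict[str, list[str]],
    significance: pd.DataFrame,
    categories: dict[str, str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """All group × category tests, Bonferroni over their total number."""
    cat_ids = sorted(set(categories.values()))
    results = []
    for gid in sorted(groups):
        for cid in cat_ids:
            results.append(enrichment_test(gid, groups[gid], cid,
                                           significance, categories))
    m = len(results)
    for r in results:
        r.significant = bool(r.pvalue < alpha / m)
    return results


def records_frame(records: list[AssociationRecord],
                  primary: str = "ivw") -> pd.DataFrame:
    """Flat TSV-ready table, one row per (pair, method)."""
    rows = []
    for r in records:
        base = {
            "exposure_id": r.exposure_id, "outcome_id": r.outcome_id,
            "direction": r.direction, "ancestry": r.ancestry,
            "iv_mode": r.iv_mode, "testable": r.testable,
            "n_iv": len(r.pairs),
            "significant_bonferroni": r.significant_bonferroni,
            "significant_fdr": r.significant_fdr,
            "replicated_p05": r.replicated_p05,
            "replicated_fdr": r.replicated_fdr,
            "replicated_bonferroni": r.replicated_bonferroni,
            "direction_consistent": r.direction_consistent,
        }
        if not r.estimates:
            rows.append({**base, "method": "", "beta": np.nan, "se": np.nan,
                         "pvalue": np.nan})
        for method, est in r.estimates.items():
            rows.append({
                **base, "method": method,
                "beta": est.beta, "se": est.se, "pvalue": est.pvalue,
                "intercept": est.intercept, "intercept_p": est.intercept_p,
                "Q": est.Q, "estimable": est.estimable,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config-driven study runner (CLI backend)


def run_study(config: dict, out_dir: str) -> dict[str, pd.DataFrame]:
    """Run forward + reverse MR from a config mapping of file paths.

    Config keys: ``ancestry``; ``proteins`` and ``diseases`` (trait id →
    summary-stat TSV); ``genes`` (TSV/BED of gene intervals); ``ld_dir``
    (block matrices + sidecars); ``iv_modes``; optional
    ``replication_proteins``; ``alpha``; ``seed``. Writes
    associations.tsv, replication.tsv, overlap.tsv and run.log under
    ``out_dir`` and returns the tables.
    """
    import os

    from .sumstats_io import read_gene_annotations, read_sumstats

    os.makedirs(out_dir, exist_ok=True)
    ancestry = config.get("ancestry", "EUR")
    seed = int(config.get("seed", 0))
    alpha = float(config.get("alpha", 0.05))
    params = PipelineParams(alpha=alpha,
                            methods=tuple(config.get("methods",
                                                     ("ivw", "egger",
                                                      "weighted_median",
                                                      "weighted_mode"))))
    proteins = {tid: read_sumstats(path, tid, "protein", ancestry)
                for tid, path in config["proteins"].items()}
    diseases = {tid: read_sumstats(path, tid, "disease", ancestry)
                for tid, path in config["diseases"].items()}
    genes = {g.protein_id: g for g in read_gene_annotations(config["genes"])}
    ld = LDCollection.load(config["ld_dir"])
    rng = np.random.default_rng(seed)

    all_records: list[AssociationRecord] = []
    repl_tables = []
    for iv_mode in config.get("iv_modes", ["cis_only", "cis_plus_trans"]):
        fwd = run_direction(proteins, diseases, "forward", ancestry, iv_mode,
                            ld, params, int(rng.integers(0, 2**31 - 1)),
                            genes=genes)
        adjust_multiplicity(fwd, "both", alpha, params.primary)
        sensitivity_pass(fwd, params, int(rng.integers(0, 2**31 - 1)))
        all_records.extend(fwd)
        if "replication_proteins" in config:
            repl = {tid: read_sumstats(path, tid, "protein", ancestry)
                    for tid, path in config["replication_proteins"].items()}
            rrecs = replicate(fwd, repl, diseases, ld, params,
                              int(rng.integers(0, 2**31 - 1)), genes=genes,
                              alpha=alpha)
            repl_tables.append(records_frame(rrecs))
    rev = run_direction(diseases, proteins, "reverse", ancestry,
                        "cis_plus_trans", ld, params,
                        int(rng.integers(0, 2**31 - 1)))
    adjust_multiplicity(rev, "both", alpha, params.primary)
    all_records.extend(rev)

    fwd_recs = [r for r in all_records if r.direction == "forward"]
    overlap = overlap_targets_biomarkers(fwd_recs, rev)
    tables = {
        "associations": records_frame(all_records),
        "replication": (pd.concat(repl_tables, ignore_index=True)
                        if repl_tables else pd.DataFrame()),
        "overlap": pd.DataFrame(
            [{"protein": p,
              "forward_outcomes": ";".join(v["forward_outcomes"]),
              "reverse_exposures": ";".join(v["reverse_exposures"])}
             for p, v in overlap.items()]),
    }
    for name, df in tables.items():
        df.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write(f"protmr run ancestry={ancestry} seed={seed} alpha={alpha}\n")
        fh.write(f"proteins={len(proteins)} diseases={len(diseases)} "
                 f"records={len(all_records)}\n")
    return tables
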