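"""Pseudobulk construction, TMM/log-CPM normalization, cell-type
enrichment, and cardiomyopathy-vs-control differential expression.

Counts are nucleus-level (genes × cells, Matrix Market on disk with
genes/cells/donors TSV sidecars). Gene counts are summed into pseudobulk
profiles by donor and cell type, normalized with trimmed-mean-of-M-values
factors, and standardized to log₂ counts per million with pseudocount
0.25.

A gene is *enriched* for a cell type when all of:
(1) mean normalized expression > 4× the mean over the other cell types
    with BH-adjusted p < 0.01 (Welch t on profile-level log-CPM),
(2) ≥ 25% of the cell type's nuclei express it, and
(3) a single-gene rank classifier separates the cell type's nuclei from
    the rest with AUC > 0.6.

Differential expression regresses per-cell-type pseudobulk log-CPM on
disease group (DCM or HCM vs non-failing) adjusted for age and sex, with
observation weights from a lowess mean–variance trend; a gene passes
when expression is ≥50% higher in cardiomyopathy with BH-adjusted
p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.io import mmread
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

FOLD_MIN = 4.0
FDR_MAX = 0.01
FRACTION_MIN = 0.25
AUC_MIN = 0.6
DE_LOG2FC_MIN = np.log2(1.5)
LOGCPM_PSEUDOCOUNT = 0.25

CONDITIONS = ("NF", "DCM", "HCM")


@dataclass
class PseudobulkMatrix:
    counts: np.ndarray                 # genes × profiles, integer sums
    genes: list[str]
    profiles: pd.DataFrame             # donor_id, cell_type, condition, age, sex
    lib_size: np.ndarray
    fraction_expressing: pd.DataFrame  # genes × cell types, nuclei nonzero rate

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.profiles["cell_type"].unique())


def read_singlecell_mtx(directory):
    import os

    counts = np.asarray(mmread(os.path.join(directory, "matrix.mtx")).todense())
    genes = pd.read_csv(os.path.join(directory, "genes.tsv"), sep="\t")["gene_id"].tolist()
    cells = pd.read_csv(os.path.join(directory, "cells.tsv"), sep="\t")
    donors = pd.read_csv(os.path.join(directory, "donors.tsv"), sep="\t")
    return counts.astype(np.int64), genes, cells, donors


def aggregate_pseudobulk(
    counts: np.ndarray, genes: list[str], cells: pd.DataFrame,
    donors: pd.DataFrame,
) -> PseudobulkMatrix:
    """Sum nucleus counts into (donor, cell type) pseudobulk profiles.

    Exact integer sums; profiles with zero nuclei are simply absent.
    Every cell must map to a declared donor.
    """
    counts = np.asarray(counts)
    if counts.shape[1] != len(cells):
        raise ValueError("counts columns must match the cells table")
    donor_meta = donors.set_index("donor_id")
    unknown = set(cells["donor_id"]) - set(donor_meta.index)
    if unknown:
        raise KeyError(f"cells reference unknown donors: {sorted(unknown)[:5]}")
    key = cells["donor_id"].astype(str) + "\t" + cells["cell_type"].astype(str)
    groups = {k: np.flatnonzero(key.to_numpy() == k) for k in key.unique()}
    cols, meta_rows = [], []
    for k in sorted(groups):
        donor_id, cell_type = k.split("\t")
        idx = groups[k]
        cols.append(counts[:, idx].sum(axis=1))
        meta_rows.append({
            "donor_id": donor_id, "cell_type": cell_type,
            "condition": donor_meta.loc[donor_id, "condition"],
            "age": float(donor_meta.loc[donor_id, "age"]),
            "sex": donor_meta.loc[donor_id, "sex"],
            "n_nuclei": len(idx),
        })
    pb = np.column_stack(cols)
    profiles = pd.DataFrame(meta_rows)
    ct_arr = cells["cell_type"].to_numpy()
    frac = pd.DataFrame(
        {ct: (counts[:, ct_arr == ct] > 0).mean(axis=1)
         for ct in sorted(set(ct_arr))},
        index=genes,
    )
    return PseudobulkMatrix(pb, list(genes), profiles, pb.sum(axis=0), frac)


def tmm_factors(pb: PseudobulkMatrix, trim_m: float = 0.3,
                trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference profile is the one whose upper-quartile count fraction
    is closest to the mean; each factor is the precision-weighted mean of
    log-ratios vs the reference after trimming the extreme ``trim_m`` of
    M-values and ``trim_a`` of A-values on each side, exponentiated.
    All-zero profiles are dropped with a warning upstream.
    """
    counts = pb.counts.astype(float)
    lib = pb.lib_size.astype(float)
    if np.any(lib == 0):
        raise ValueError("pseudobulk contains an all-zero profile")
    frac = counts / lib
    uq = np.array([np.quantile(frac[:, j][counts[:, j] > 0], 0.75)
                   if np.any(counts[:, j] > 0) else 0.0
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    xr, lr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        x, l = counts[:, j], lib[j]
        ok = (x > 0) & (xr > 0)
        if not ok.any():
            continue
        M = np.log2((x[ok] / l) / (xr[ok] / lr))
        A = 0.5 * np.log2((x[ok] / l) * (xr[ok] / lr))
        w = 1.0 / ((l - x[ok]) / (l * x[ok]) + (lr - xr[ok]) / (lr * xr[ok]))
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if not keep.any():
            keep = np.ones_like(M, dtype=bool)
        factors[j] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(pb: PseudobulkMatrix, factors: np.ndarray,
            pseudocount: float = LOGCPM_PSEUDOCOUNT) -> np.ndarray:
    """log₂((count + c) / (lib·factor + 2c) × 1e6), applied uniformly."""
    eff_lib = pb.lib_size * factors
    return np.log2((pb.counts + pseudocount) / (eff_lib + 2 * pseudocount) * 1e6)


def auc_single_gene(values: np.ndarray, in_type: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC with midrank tie handling."""
    values = np.asarray(values, dtype=float)
    in_type = np.asarray(in_type, dtype=bool)
    n1 = int(in_type.sum())
    n0 = len(values) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(values)
    u = ranks[in_type].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def gini(values) -> float:
    """Gini coefficient via the sorted closed form; nan when all zero."""
    x = np.sort(np.asarray(values, dtype=float))
    if np.any(x < 0):
        raise ValueError("Gini requires non-negative values")
    n = len(x)
    total = x.sum()
    if total == 0:
        return np.nan
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * total))


def celltype_enrichment(
    pb: PseudobulkMatrix,
    nuclei_counts: np.ndarray,
    cells: pd.DataFrame,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score every (gene, cell type) for enrichment.

    Returns a table with fold_one_vs_rest, pvalue, fdr (BH across genes ×
    cell types), fraction_nuclei, auc, gini (average of the Gini over
    per-cell-type mean nuclei expression and over fraction expressing),
    the enriched flag, and a display ordering key (primary: cell type of
    highest average expression; secondary: mean Gini, descending).
    """
    if len(pb.cell_types) < 2:
        raise ValueError("enrichment needs at least two cell types")
    if factors is None:
        factors = tmm_factors(pb)
    cpm = pb.counts / (pb.lib_size * factors) * 1e6
    lcpm = log_cpm(pb, factors)
    ct_profiles = pb.profiles["cell_type"].to_numpy()
    ct_nuclei = cells["cell_type"].to_numpy()
    cell_types = pb.cell_types
    mean_nuclei_expr = pd.DataFrame(
        {ct: nuclei_counts[:, ct_nuclei == ct].mean(axis=1) for ct in cell_types},
        index=pb.genes,
    )
    rows = []
    for ct in cell_types:
        in_ct = ct_profiles == ct
        mean_in = cpm[:, in_ct].mean(axis=1)
        mean_out = cpm[:, ~in_ct].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = mean_in / mean_out
        t_p = stats.ttest_ind(lcpm[:, in_ct], lcpm[:, ~in_ct], axis=1,
                              equal_var=False, alternative="greater").pvalue
        nuc_in = ct_nuclei == ct
        for g, gene in enumerate(pb.genes):
            rows.append({
                "gene": gene, "cell_type": ct,
                "fold_one_vs_rest": float(fold[g]),
                "pvalue": float(t_p[g]) if np.isfinite(t_p[g]) else 1.0,
                "fraction_nuclei": float(pb.fraction_expressing.loc[gene, ct]),
                "auc": auc_single_gene(nuclei_counts[g], nuc_in),
            })
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    table["enriched"] = (
        (table["fold_one_vs_rest"] > FOLD_MIN)
        & (table["fdr"] < FDR_MAX)
        & (table["fraction_nuclei"] >= FRACTION_MIN)
        & (table["auc"] > AUC_MIN)
    )
    gini_by_gene = {}
    top_ct = {}
    for gene in pb.genes:
        expr = mean_nuclei_expr.loc[gene].to_numpy()
        fracs = pb.fraction_expressing.loc[gene].to_numpy()
        parts = [g for g in (gini(expr), gini(fracs)) if np.isfinite(g)]
        gini_by_gene[gene] = float(np.mean(parts)) if parts else np.nan
        top_ct[gene] = cell_types[int(np.argmax(expr))]
    table["gini"] = table["gene"].map(gini_by_gene)
    table["top_cell_type"] = table["gene"].map(top_ct)
    table["ordering_key"] = list(zip(table["top_cell_type"], -table["gini"]))
    return table


def de_disease_vs_control(
    pb: PseudobulkMatrix,
    contrast: str = "DCM",
    control: str = "NF",
    factors: np.ndarray | None = None,
    min_donors_per_arm: int = 3,
) -> pd.DataFrame:
    """Per-cell-type weighted regression of log-CPM on disease group.

    Design per cell type: intercept + group indicator + age + sex.
    Observation weights follow a voom-style mean–variance trend: an
    unweighted fit per gene yields sqrt-residual-SD vs average log-CPM,
    smoothed by lowess; each observation's weight is the trend evaluated
    at its fitted log-CPM, raised to the −4. The group coefficient is the
    log2 fold change; BH is applied across genes within each cell type.
    Pass = log2FC ≥ log2(1.5) and FDR < 0.01. Cell types with fewer than
    ``min_donors_per_arm`` donors in either arm are marked not testable.
    """
    if factors is None:
        factors = tmm_factors(pb)
    lcpm_all = log_cpm(pb, factors)
    out_rows = []
    for ct in pb.cell_types:
        sel = (pb.profiles["cell_type"] == ct) & \
              (pb.profiles["condition"].isin([contrast, control]))
        idx = np.flatnonzero(sel.to_numpy())
        meta = pb.profiles.iloc[idx]
        n_case = int((meta["condition"] == contrast).sum())
        n_ctrl = int((meta["condition"] == control).sum())
        if n_case < min_donors_per_arm or n_ctrl < min_donors_per_arm:
            for gene in pb.genes:
                out_rows.append({"gene": gene, "cell_type": ct,
                                 "log2fc": np.nan, "pvalue": np.nan,
                                 "fdr": np.nan, "testable": False,
                                 "passes": False})
            continue
        y = lcpm_all[:, idx]
        group = (meta["condition"] == contrast).to_numpy(float)
        sex = (meta["sex"] == "M").to_numpy(float)
        age = meta["age"].to_numpy(float)
        X = np.column_stack([np.ones(len(idx)), group, age, sex])
        keep_cols, labels = [0, 1], ["intercept", "group", "age", "sex"]
        for c in (2, 3):
            if np.std(X[:, c]) > 0:
                keep_cols.append(c)
        X = X[:, keep_cols]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            C = np.corrcoef(X[:, 1:], rowvar=False)
            raise ValueError(
                f"confounded design in cell type {ct}: group is collinear "
                f"with a covariate (|corr| matrix {np.round(C, 3).tolist()})")
        log2fc, pvals = _weighted_de_fit(y, X)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        for g, gene in enumerate(pb.genes):
            out_rows.append({
                "gene": gene, "cell_type": ct,
                "log2fc": float(log2fc[g]), "pvalue": float(pvals[g]),
                "fdr": float(fdr[g]), "testable": True,
                "passes": bool(log2fc[g] >= DE_LOG2FC_MIN and fdr[g] < FDR_MAX),
            })
    return pd.DataFrame(out_rows)


def _weighted_de_fit(y: np.ndarray, X: np.ndarray):
    """voom-style two-pass fit; returns (group coefficients, p-values)."""
    n_genes, n_obs = y.shape
    df = n_obs - X.shape[1]
    if df <= 0:
        raise ValueError("not enough profiles for the design")
    pinv = np.linalg.pinv(X)
    coef0 = y @ pinv.T
    fitted0 = coef0 @ X.T
    resid_sd = np.sqrt(np.sum((y - fitted0) ** 2, axis=1) / df)
    mean_l = y.mean(axis=1)
    trend = lowess(np.sqrt(resid_sd), mean_l, frac=0.6, return_sorted=True)
    tx, ty = trend[:, 0], np.clip(trend[:, 1], 1e-3, None)
    w = np.interp(fitted0, tx, ty) ** -4.0
    log2fc = np.empty(n_genes)
    pvals = np.empty(n_genes)
    tdist = stats.t(df=df)
    for g in range(n_genes):
        Wg = w[g]
        Xw = X * Wg[:, None]
        A = X.T @ Xw
        Ainv = np.linalg.inv(A)
        b = Ainv @ (Xw.T @ y[g])
        resid = y[g] - X @ b
        sigma2 = np.sum(Wg * resid**2) / df
        se = np.sqrt(sigma2 * Ainv[1, 1])
        log2fc[g] = b[1]
        pvals[g] = max(2 * tdist.sf(abs(b[1] / se)), np.finfo(float).tiny)
    return log2fc, pvals
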