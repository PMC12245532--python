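"""Read, validate, and harmonize GWAS summary statistics and gene annotations.

This is the shared format layer for every downstream stage: a
:class:`SummaryStatSet` holds one trait's variant-level marginal
associations (beta, SE, p, N); :func:`harmonize` aligns an outcome study
to the exposure's effect allele, producing the (β_X, σ_X, β_Y, σ_Y)
pairs every MR estimator consumes.

Conventions (both studies assumed on the forward strand):

* only allele-swap harmonization is attempted by default — outcome rows
  whose alleles are the exposure's swapped pair have their beta negated
  and EAF complemented;
* palindromic variants (A/T or C/G) with minor-allele frequency above
  0.42 are dropped as strand-ambiguous;
* coordinates are 1-based inclusive throughout; BED input is converted
  on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

TRAIT_KINDS = ("protein", "disease", "quantitative_biomarker", "medication")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PALINDROMIC_MAF_MAX = 0.42


@dataclass
class SummaryStatSet:
    """One trait's marginal GWAS associations, stored as aligned numpy arrays."""

    trait_id: str
    trait_kind: str = "protein"
    ancestry: str = "EUR"
    variant_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    chrom: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    pos: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    effect_allele: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    other_allele: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    eaf: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta: np.ndarray = field(default_factory=lambda: np.empty(0))
    se: np.ndarray = field(default_factory=lambda: np.empty(0))
    pvalue: np.ndarray = field(default_factory=lambda: np.empty(0))
    n: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self._index: dict[str, int] = {v: i for i, v in enumerate(self.variant_id)}
        if len(self._index) != len(self.variant_id):
            dup = pd.Series(self.variant_id).value_counts()
            raise ValueError(
                f"duplicate variant ids in {self.trait_id}: "
                f"{dup[dup > 1].index.tolist()[:5]}"
            )

    def __len__(self) -> int:
        return len(self.variant_id)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def loc(self, variant_id: str) -> int:
        return self._index[variant_id]

    def validate(self) -> None:
        if np.any(self.se <= 0):
            raise ValueError("se must be > 0")
        if np.any((self.eaf <= 0) | (self.eaf >= 1)):
            raise ValueError("eaf must lie in (0, 1)")
        if np.any((self.pvalue <= 0) | (self.pvalue > 1)):
            raise ValueError("pvalue must lie in (0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in SUMSTAT_COLUMNS})

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, trait_id: str,
        trait_kind: str = "protein", ancestry: str = "EUR",
    ) -> "SummaryStatSet":
        return cls(
            trait_id=trait_id, trait_kind=trait_kind, ancestry=ancestry,
            variant_id=df["variant_id"].astype(str).to_numpy(dtype=object),
            chrom=df["chrom"].astype(str).to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            effect_allele=df["effect_allele"].astype(str).to_numpy(dtype=object),
            other_allele=df["other_allele"].astype(str).to_numpy(dtype=object),
            eaf=df["eaf"].to_numpy(dtype=float),
            beta=df["beta"].to_numpy(dtype=float),
            se=df["se"].to_numpy(dtype=float),
            pvalue=df["pvalue"].to_numpy(dtype=float),
            n=df["n"].to_numpy(dtype=np.int64),
        )

    def subset(self, mask_or_ids) -> "SummaryStatSet":
        if isinstance(mask_or_ids, (list, tuple, set)):
            ids = set(mask_or_ids)
            mask = np.array([v in ids for v in self.variant_id])
        else:
            mask = np.asarray(mask_or_ids)
        out = replace(
            self,
            **{c: getattr(self, c)[mask] for c in SUMSTAT_COLUMNS},
        )
        return out


@dataclass
class GeneAnnotation:
    """A protein-coding gene interval, 1-based inclusive."""

    gene_id: str
    protein_id: str
    chrom: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.stop:
            raise ValueError(f"start > stop for gene {self.gene_id}")


@dataclass
class HarmonizedPair:
    """Exposure/outcome effect pair for one instrument, aligned to the exposure allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float
    eaf_outcome: float
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError("standard errors must be > 0")

    @property
    def wald_ratio(self) -> float:
        return self.beta_outcome / self.beta_exposure


def read_sumstats(
    path, trait_id: str | None = None,
    trait_kind: str = "protein", ancestry: str = "EUR",
) -> SummaryStatSet:
    """Read a tab-separated summary-statistics table.

    Rows with missing beta or SE (or SE ≤ 0) are dropped with a logged
    count; unknown or missing columns and duplicate variant ids raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    unknown = [c for c in df.columns if c not in SUMSTAT_COLUMNS]
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if unknown or missing:
        raise ValueError(
            f"bad summary-statistics header in {path}: "
            f"unknown columns {unknown}, missing columns {missing}; "
            f"expected {SUMSTAT_COLUMNS}"
        )
    bad = df["beta"].isna() | df["se"].isna() | (df["se"] <= 0)
    if bad.any():
        logger.warning("%s: dropped %d rows with missing beta/se or se<=0", path, int(bad.sum()))
        df = df[~bad]
    if trait_id is None:
        trait_id = str(path)
    return SummaryStatSet.from_frame(df.reset_index(drop=True), trait_id, trait_kind, ancestry)


def write_sumstats(ss: SummaryStatSet, path) -> None:
    ss.to_frame().to_csv(path, sep="\t", index=False)


def read_gene_annotations(path, fmt: str | None = None) -> list[GeneAnnotation]:
    """Read gene intervals from BED (0-based half-open) or native TSV (1-based).

    Format is inferred from the extension unless given. BED columns:
    chrom, start, stop, gene_id[, protein_id]; native TSV has a header
    gene_id/protein_id/chrom/start/stop.
    """
    path = str(path)
    if fmt is None:
        fmt = "bed" if path.endswith(".bed") else "tsv"
    if fmt == "bed":
        df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
        genes = []
        for row in df.itertuples(index=False):
            gene_id = str(row[3]) if len(row) > 3 else f"gene{len(genes)}"
            protein_id = str(row[4]) if len(row) > 4 else gene_id
            genes.append(GeneAnnotation(gene_id, protein_id, str(row[0]),
                                        int(row[1]) + 1, int(row[2])))
        return genes
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneAnnotation(str(r.gene_id), str(r.protein_id), str(r.chrom),
                       int(r.start), int(r.stop))
        for r in df.itertuples(index=False)
    ]


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    variant_ids=None,
    palindromic_maf_max: float = PALINDROMIC_MAF_MAX,
    infer_strand: bool = False,
) -> tuple[list[HarmonizedPair], list[tuple[str, str]]]:
    """Align outcome effects to the exposure's effect allele.

    Returns (pairs, dropped) where dropped carries (variant_id, reason)
    for palindromic-ambiguous and allele-incompatible variants.

    With ``infer_strand`` the complement of the outcome alleles is also
    tried (frequency-based strand inference for non-palindromic variants);
    off by default since both studies are assumed forward-strand.
    """
    if variant_ids is None:
        variant_ids = [v for v in exposure.variant_id if v in outcome]
    pairs: list[HarmonizedPair] = []
    dropped: list[tuple[str, str]] = []
    for vid in variant_ids:
        if vid not in exposure or vid not in outcome:
            dropped.append((vid, "missing"))
            continue
        i = exposure.loc(vid)
        j = outcome.loc(vid)
        ea_x = exposure.effect_allele[i].upper()
        oa_x = exposure.other_allele[i].upper()
        ea_y = outcome.effect_allele[j].upper()
        oa_y = outcome.other_allele[j].upper()
        pal = is_palindromic(ea_x, oa_x)
        if pal:
            maf = min(exposure.eaf[i], 1 - exposure.eaf[i])
            if maf > palindromic_maf_max:
                dropped.append((vid, "palindromic_ambiguous"))
                continue
        beta_y = outcome.beta[j]
        eaf_y = outcome.eaf[j]
        if (ea_y, oa_y) == (ea_x, oa_x):
            flipped = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y, eaf_y, flipped = -beta_y, 1 - eaf_y, True
        elif infer_strand and not pal and (
            (_COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y)) == (ea_x, oa_x)
        ):
            flipped = False
        elif infer_strand and not pal and (
            (_COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y)) == (oa_x, ea_x)
        ):
            beta_y, eaf_y, flipped = -beta_y, 1 - eaf_y, True
        else:
            dropped.append((vid, "allele_mismatch"))
            continue
        pairs.append(HarmonizedPair(
            variant_id=vid,
            beta_exposure=float(exposure.beta[i]),
            se_exposure=float(exposure.se[i]),
            beta_outcome=float(beta_y),
            se_outcome=float(outcome.se[j]),
            eaf_exposure=float(exposure.eaf[i]),
            eaf_outcome=float(eaf_y),
            flipped=flipped,
            palindromic=pal,
        ))
    return pairs, dropped


def pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(β_X, σ_X, β_Y, σ_Y) arrays from a list of HarmonizedPair."""
    bx = np.array([p.beta_exposure for p in pairs])
    sx = np.array([p.se_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    sy = np.array([p.se_outcome for p in pairs])
    return bx, sx, by, sy


def normal_p(z) -> np.ndarray:
    """Two-sided normal p-value, floored at the smallest positive float."""
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.maximum(p, np.finfo(float).tiny)
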