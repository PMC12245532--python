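"""Instrumental-variable construction per exposure.

Greedy LD clumping (p < 5e−8, pairwise r² < 0.1 within 500 kb by
default), cis/trans classification against the encoding gene (cis =
within 1 Mb on either side of the gene's start/stop), and proxy
substitution (r² > 0.7, within 500 kb, exposure-significant) for index
variants missing from the outcome study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import LDCollection
from .sumstats_io import (
    GeneAnnotation, HarmonizedPair, SummaryStatSet, harmonize,
)

logger = logging.getLogger(__name__)

P_THRESHOLD = 5e-8
R2_CLUMP = 0.1
WINDOW_KB = 500
R2_PROXY = 0.7
CIS_WINDOW = 1_000_000


@dataclass
class SelectionParams:
    p_threshold: float = P_THRESHOLD
    r2_clump: float = R2_CLUMP
    window_kb: float = WINDOW_KB
    r2_proxy: float = R2_PROXY


@dataclass
class InstrumentMember:
    variant_id: str
    role: str  # index | proxy
    proxy_of: str | None
    cis_trans: str  # cis | trans


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with provenance."""

    exposure_id: str
    members: list[InstrumentMember] = field(default_factory=list)
    selection_params: SelectionParams = field(default_factory=SelectionParams)

    def variant_ids(self) -> list[str]:
        return [m.variant_id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def testable(self) -> bool:
        return len(self.members) > 0


def clump(
    sumstats: SummaryStatSet,
    ld: LDCollection,
    p_threshold: float = P_THRESHOLD,
    r2_threshold: float = R2_CLUMP,
    window_kb: float = WINDOW_KB,
    missing_ld: str = "drop",
) -> list[str]:
    """Greedy LD clumping of genome-wide-significant variants.

    Sort significant variants ascending by p (ties broken by variant id
    for determinism); accept a variant iff its r² with every
    already-accepted variant on the same chromosome within ``window_kb``
    is below ``r2_threshold``. Pairs farther apart than the window are
    treated as independent regardless of r².

    Significant variants absent from the LD panel are dropped with a
    warning (``missing_ld="drop"``, default) or raise (``"fail"``).
    """
    sig = np.flatnonzero(sumstats.pvalue < p_threshold)
    if sig.size == 0:
        return []
    order = sorted(sig, key=lambda i: (sumstats.pvalue[i], str(sumstats.variant_id[i])))
    window_bp = window_kb * 1_000
    accepted: list[int] = []
    for i in order:
        vid = sumstats.variant_id[i]
        if vid not in ld:
            if missing_ld == "fail":
                raise KeyError(f"significant variant {vid} missing from LD panel")
            logger.warning("clump: %s significant but absent from LD panel; dropped", vid)
            continue
        ok = True
        for j in accepted:
            if sumstats.chrom[i] != sumstats.chrom[j]:
                continue
            if abs(int(sumstats.pos[i]) - int(sumstats.pos[j])) > window_bp:
                continue
            if ld.r2(vid, sumstats.variant_id[j]) >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(i)
    return [str(sumstats.variant_id[i]) for i in accepted]


def classify_cis_trans(
    chrom: str, pos: int, gene: GeneAnnotation, window: int = CIS_WINDOW,
) -> str:
    """cis iff on the gene's chromosome within ±1 Mb of its start/stop."""
    if chrom == gene.chrom and gene.start - window <= pos <= gene.stop + window:
        return "cis"
    return "trans"


def find_proxy(
    index_variant: str,
    outcome: SummaryStatSet,
    exposure: SummaryStatSet,
    ld: LDCollection,
    r2_min: float = R2_PROXY,
    window_kb: float = WINDOW_KB,
    p_threshold: float = P_THRESHOLD,
) -> str | None:
    """Best available proxy for an index variant absent from the outcome.

    Candidates must be present in both studies, exposure-significant,
    within the window, and in LD r² > ``r2_min`` with the index. Ties on
    r² break by smaller exposure p, then lexicographic id. ``None`` when
    no candidate qualifies.
    """
    block = ld.block_of(index_variant)
    if block is None:
        return None
    i = exposure.loc(index_variant)
    window_bp = window_kb * 1_000
    best: tuple[float, float, str] | None = None
    for vid in block.variant_ids:
        if vid == index_variant or vid not in outcome or vid not in exposure:
            continue
        j = exposure.loc(vid)
        if exposure.chrom[j] != exposure.chrom[i]:
            continue
        if abs(int(exposure.pos[j]) - int(exposure.pos[i])) > window_bp:
            continue
        if exposure.pvalue[j] >= p_threshold:
            continue
        r2 = ld.r2(index_variant, vid)
        if r2 <= r2_min:
            continue
        key = (-r2, exposure.pvalue[j], str(vid))
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def build_instrument_set(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    gene: GeneAnnotation | None,
    mode: str,
    ld: LDCollection,
    params: SelectionParams | None = None,
) -> tuple[InstrumentSet, list[HarmonizedPair]]:
    """Clump → classify → (cis filter) → proxy-substitute → harmonize.

    ``mode`` is ``cis_only`` or ``cis_plus_trans``; with no gene
    annotation (disease exposures in reverse MR) every instrument is
    labelled trans and the cis filter is unavailable. Proxies carry the
    index variant's exposure effect; their outcome effect is sign-aligned
    through the LD correlation's sign. An empty set marks the exposure
    not-testable.
    """
    if mode not in ("cis_only", "cis_plus_trans"):
        raise ValueError(f"unknown iv mode {mode!r}")
    if mode == "cis_only" and gene is None:
        raise ValueError("cis_only mode requires a gene annotation")
    params = params or SelectionParams()
    index_variants = clump(exposure, ld, params.p_threshold, params.r2_clump,
                           params.window_kb)
    members: list[InstrumentMember] = []
    pairs: list[HarmonizedPair] = []
    for vid in index_variants:
        i = exposure.loc(vid)
        ct = (classify_cis_trans(str(exposure.chrom[i]), int(exposure.pos[i]), gene)
              if gene is not None else "trans")
        if mode == "cis_only" and ct != "cis":
            continue
        if vid in outcome:
            harmonized, _ = harmonize(exposure, outcome, [vid])
            if not harmonized:
                continue
            members.append(InstrumentMember(vid, "index", None, ct))
            pairs.append(harmonized[0])
            continue
        proxy = find_proxy(vid, outcome, exposure, ld, params.r2_proxy,
                           params.window_kb, params.p_threshold)
        if proxy is None:
            logger.info("no proxy found for %s (exposure %s)", vid, exposure.trait_id)
            continue
        harmonized, _ = harmonize(exposure, outcome, [proxy])
        if not harmonized:
            continue
        pair = harmonized[0]
        sign = np.sign(ld.r(vid, proxy)) or 1.0
        j = exposure.loc(vid)
        # proxy carries the index variant's exposure effect; its outcome
        # effect is aligned through the sign of r(index, proxy)
        pair = HarmonizedPair(
            variant_id=proxy,
            beta_exposure=float(exposure.beta[j]),
            se_exposure=float(exposure.se[j]),
            beta_outcome=float(sign * pair.beta_outcome),
            se_outcome=pair.se_outcome,
            eaf_exposure=float(exposure.eaf[j]),
            eaf_outcome=pair.eaf_outcome,
            flipped=pair.flipped,
            palindromic=pair.palindromic,
        )
        members.append(InstrumentMember(proxy, "proxy", vid, ct))
        pairs.append(pair)
    iv_set = InstrumentSet(exposure.trait_id, members, params)
    if not iv_set.testable:
        logger.info("exposure %s: no instruments (not testable)", exposure.trait_id)
    return iv_set, pairs


def instruments_frame(iv_set: InstrumentSet, pairs: list[HarmonizedPair]) -> pd.DataFrame:
    """TSV-ready table: one row per instrument with effect pairs."""
    rows = []
    for m, p in zip(iv_set.members, pairs):
        rows.append({
            "exposure_id": iv_set.exposure_id,
            "variant_id": m.variant_id,
            "role": m.role,
            "proxy_of": m.proxy_of or "",
            "cis_trans": m.cis_trans,
            "beta_x": p.beta_exposure, "se_x": p.se_exposure,
            "beta_y": p.beta_outcome, "se_y": p.se_outcome,
        })
    return pd.DataFrame(rows, columns=[
        "exposure_id", "variant_id", "role", "proxy_of", "cis_trans",
        "beta_x", "se_x", "beta_y", "se_y",
    ])
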