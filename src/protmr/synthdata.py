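"""Synthetic GWAS/pQTL summary statistics and single-cell counts.

The generator defines ground-truth causal structure — which variants
drive each protein (cis and trans), which drive each disease directly,
which protein→disease (γ) and disease→protein (δ) causal paths exist,
and which variants carry horizontally pleiotropic direct effects — and
samples marginal summary statistics with exactly the structure
two-sample MR assumes:

    μ = R · β_joint           (marginal means per LD block)
    β̂ ~ MVN(μ, R / n)         (sampling noise)
    se = 1 / √n

Sampling happens directly in β̂-space; no individual-level genotypes are
generated. A disease trait's joint effects are the sum of its own
liability variants, Σ_p γ_p × (protein p's cis/trans effects), and any
direct pleiotropic effects; a protein's joint effects add
Σ_d δ_d × (disease d's own variant effects) for reverse causation.

Effect sizes are in phenotypic-SD units for proteins and log-odds (the
liability-scale betas are read as log-odds without conversion) for
diseases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmwrite
from scipy.sparse import coo_matrix

from .ld import LDBlock, LDCollection, project_to_psd
from .sumstats_io import SummaryStatSet, GeneAnnotation, normal_p

CIS_WINDOW = 1_000_000

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("A", "T"), ("C", "G")]


# ---------------------------------------------------------------------------
# truth specification


@dataclass
class ProteinSpec:
    protein_id: str
    gene_id: str
    chrom: str
    start: int
    stop: int

    def gene(self) -> GeneAnnotation:
        return GeneAnnotation(self.gene_id, self.protein_id, self.chrom, self.start, self.stop)


@dataclass
class DiseaseSpec:
    disease_id: str
    category: str
    n_cases: int


@dataclass
class CausalVariant:
    variant_id: str
    chrom: str
    pos: int
    beta: float


@dataclass
class TransHub:
    """A shared trans-acting variant with per-protein effects."""

    variant_id: str
    chrom: str
    pos: int
    effects: dict[str, float]


@dataclass
class AncestrySpec:
    n_protein_gwas: int
    n_disease_gwas: int
    ld_seed: int = 0


@dataclass
class TruthSpec:
    """Ground-truth causal structure for one synthetic study."""

    proteins: list[ProteinSpec]
    diseases: list[DiseaseSpec]
    forward_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    reverse_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    cis_architecture: dict[str, list[CausalVariant]] = field(default_factory=dict)
    trans_architecture: list[TransHub] = field(default_factory=list)
    disease_architecture: dict[str, list[CausalVariant]] = field(default_factory=dict)
    pleiotropy: dict[str, dict[str, float]] = field(default_factory=dict)
    ancestries: dict[str, AncestrySpec] = field(default_factory=dict)
    replication_panel_n: int = 1225

    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]

    def disease_ids(self) -> list[str]:
        return [d.disease_id for d in self.diseases]

    def genes(self) -> dict[str, GeneAnnotation]:
        return {p.protein_id: p.gene() for p in self.proteins}

    def validate(self) -> None:
        pids = set(self.protein_ids())
        dids = set(self.disease_ids())
        for (p, d) in self.forward_effects:
            if p not in pids or d not in dids:
                raise ValueError(f"forward effect ({p},{d}) references undeclared ids")
        for (d, p) in self.reverse_effects:
            if p not in pids or d not in dids:
                raise ValueError(f"reverse effect ({d},{p}) references undeclared ids")
        for pid, variants in self.cis_architecture.items():
            if pid not in pids:
                raise ValueError(f"cis architecture for undeclared protein {pid}")
            prot = next(p for p in self.proteins if p.protein_id == pid)
            for cv in variants:
                if cv.chrom != prot.chrom or not (
                    prot.start - CIS_WINDOW <= cv.pos <= prot.stop + CIS_WINDOW
                ):
                    raise ValueError(
                        f"cis variant {cv.variant_id} outside ±1 Mb of gene for {pid}"
                    )
        for did in self.disease_architecture:
            if did not in dids:
                raise ValueError(f"disease architecture for undeclared disease {did}")
        for hub in self.trans_architecture:
            for pid in hub.effects:
                if pid not in pids:
                    raise ValueError(f"trans hub {hub.variant_id} targets undeclared {pid}")
        for spec in self.ancestries.values():
            if spec.n_protein_gwas <= 0 or spec.n_disease_gwas <= 0:
                raise ValueError("sample sizes must be > 0")
        if self.replication_panel_n <= 0:
            raise ValueError("replication panel size must be > 0")

    def to_yaml(self, path) -> None:
        doc = {
            "proteins": [vars(p) for p in self.proteins],
            "diseases": [vars(d) for d in self.diseases],
            "forward_effects": [
                {"protein": p, "disease": d, "gamma": g}
                for (p, d), g in self.forward_effects.items()
            ],
            "reverse_effects": [
                {"disease": d, "protein": p, "delta": v}
                for (d, p), v in self.reverse_effects.items()
            ],
            "cis_architecture": {
                pid: [vars(cv) for cv in cvs] for pid, cvs in self.cis_architecture.items()
            },
            "trans_architecture": [
                {"variant_id": h.variant_id, "chrom": h.chrom, "pos": h.pos,
                 "effects": h.effects}
                for h in self.trans_architecture
            ],
            "disease_architecture": {
                did: [vars(cv) for cv in cvs]
                for did, cvs in self.disease_architecture.items()
            },
            "pleiotropy": self.pleiotropy,
            "ancestries": {k: vars(v) for k, v in self.ancestries.items()},
            "replication_panel_n": self.replication_panel_n,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# LD simulation


def simulate_ld_blocks(
    n_blocks: int, block_size: int, decay: float, seed: int,
    jitter: float = 0.0,
) -> list[LDBlock]:
    """AR(1)-structured LD blocks: r(i, j) = decay^|i−j|, optional jitter.

    Jittered matrices are re-projected to the PSD cone with the unit
    diagonal restored; deterministic given the seed.
    """
    if n_blocks < 1 or block_size < 1 or decay < 0:
        raise ValueError("n_blocks ≥ 1, block_size ≥ 1, decay ≥ 0 required")
    rng = np.random.default_rng(seed)
    idx = np.arange(block_size)
    base = decay ** np.abs(idx[:, None] - idx[None, :])
    blocks = []
    for b in range(n_blocks):
        R = base.copy()
        if jitter > 0:
            noise = rng.normal(0.0, jitter, size=R.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            R = project_to_psd(np.clip(R + noise, -1, 1))
        ids = [f"blk{b}:v{i}" for i in range(block_size)]
        block = LDBlock(ids, R)
        block.validate()
        blocks.append(block)
    return blocks


# ---------------------------------------------------------------------------
# genome layout: LD blocks + variant metadata


@dataclass
class Genome:
    """LD blocks plus per-variant metadata for one simulated ancestry."""

    ld: LDCollection
    variants: pd.DataFrame  # index variant_id; chrom, pos, effect_allele, other_allele, eaf

    def variant_ids(self) -> list[str]:
        return list(self.variants.index)


def _ar1_block(ids: list[str], decay: float) -> LDBlock:
    idx = np.arange(len(ids))
    R = decay ** np.abs(idx[:, None] - idx[None, :])
    return LDBlock(ids, R)


def build_genome(
    truth: TruthSpec,
    block_size: int = 12,
    decay: float = 0.6,
    spacing: int = 20_000,
    seed: int = 0,
) -> Genome:
    """Place every declared causal variant in an AR(1) LD block with nulls.

    Each protein's cis region, each disease's liability locus, and each
    trans hub gets its own block on its own chromosome; declared causal
    variants occupy the first slots, filler (null) variants pad the block
    to ``block_size``. Allele codes and EAFs are drawn deterministically
    from the seed.
    """
    rng = np.random.default_rng(seed)
    blocks: list[LDBlock] = []
    rows = []

    def add_block(prefix: str, chrom: str, anchor_pos: int, causal: list[CausalVariant]):
        ids = [cv.variant_id for cv in causal]
        positions = [cv.pos for cv in causal]
        for k in range(len(causal), block_size):
            ids.append(f"{prefix}:null{k}")
            positions.append(anchor_pos + k * spacing)
        order = np.argsort(positions, kind="stable")
        ids = [ids[i] for i in order]
        positions = [positions[i] for i in order]
        blocks.append(_ar1_block(ids, decay))
        for vid, pos in zip(ids, positions):
            ea, oa = _ALLELE_PAIRS[rng.integers(0, 4)]  # non-palindromic pairs only
            rows.append({
                "variant_id": vid, "chrom": chrom, "pos": pos,
                "effect_allele": ea, "other_allele": oa,
                "eaf": float(rng.uniform(0.05, 0.95)),
            })

    for prot in truth.proteins:
        causal = truth.cis_architecture.get(prot.protein_id, [])
        add_block(prot.protein_id, prot.chrom, prot.start - 200_000, causal)
    for dis in truth.diseases:
        causal = truth.disease_architecture.get(dis.disease_id, [])
        chrom = causal[0].chrom if causal else f"chrD_{dis.disease_id}"
        add_block(dis.disease_id, chrom, 5_000_000, causal)
    if truth.trans_architecture:
        for h, hub in enumerate(truth.trans_architecture):
            add_block(f"hub{h}", hub.chrom, hub.pos,
                      [CausalVariant(hub.variant_id, hub.chrom, hub.pos, 0.0)])
    variants = pd.DataFrame(rows).set_index("variant_id")
    return Genome(LDCollection(blocks), variants)


def beta_joint(truth: TruthSpec, trait_id: str, genome: Genome) -> pd.Series:
    """Joint (conditional) true effects of every genome variant on one trait."""
    beta = pd.Series(0.0, index=genome.variants.index)

    def add(vid: str, value: float) -> None:
        if vid not in beta.index:
            raise KeyError(f"causal variant {vid} not present in genome")
        beta[vid] += value

    if trait_id in set(truth.protein_ids()):
        for cv in truth.cis_architecture.get(trait_id, []):
            add(cv.variant_id, cv.beta)
        for hub in truth.trans_architecture:
            if trait_id in hub.effects:
                add(hub.variant_id, hub.effects[trait_id])
        for (did, pid), delta in truth.reverse_effects.items():
            if pid != trait_id:
                continue
            for cv in truth.disease_architecture.get(did, []):
                add(cv.variant_id, delta * cv.beta)
    elif trait_id in set(truth.disease_ids()):
        for cv in truth.disease_architecture.get(trait_id, []):
            add(cv.variant_id, cv.beta)
        for (pid, did), gamma in truth.forward_effects.items():
            if did != trait_id:
                continue
            for cv in truth.cis_architecture.get(pid, []):
                add(cv.variant_id, gamma * cv.beta)
            for hub in truth.trans_architecture:
                if pid in hub.effects:
                    add(hub.variant_id, gamma * hub.effects[pid])
        for vid, effects in truth.pleiotropy.items():
            if trait_id in effects:
                add(vid, effects[trait_id])
    else:
        raise KeyError(f"trait {trait_id!r} not declared in truth")
    return beta


def simulate_marginal_stats(
    truth: TruthSpec,
    trait_id: str,
    genome: Genome,
    n: int,
    seed: int,
    trait_kind: str | None = None,
    ancestry: str = "EUR",
) -> SummaryStatSet:
    """Sample one trait's marginal summary statistics over the whole genome.

    Per block: μ = R·β_joint, β̂ = μ + L·z/√n with L the Cholesky factor
    of R, se = 1/√n, two-sided normal p. Deterministic given (truth, seed).
    """
    if n <= 0:
        raise ValueError("sample size must be > 0")
    truth_beta = beta_joint(truth, trait_id, genome)
    if trait_kind is None:
        trait_kind = "protein" if trait_id in set(truth.protein_ids()) else "disease"
    rng = np.random.default_rng(seed)
    se_val = 1.0 / np.sqrt(n)
    beta_hat = {}
    for block in genome.ld.blocks:
        b = truth_beta.loc[block.variant_ids].to_numpy()
        mu = block.R @ b
        z = rng.standard_normal(block.size)
        draw = mu + block.cholesky() @ z * se_val
        for vid, val in zip(block.variant_ids, draw):
            beta_hat[vid] = val
    order = genome.variants.index
    beta_arr = np.array([beta_hat[v] for v in order])
    se_arr = np.full(len(order), se_val)
    meta = genome.variants
    return SummaryStatSet(
        trait_id=trait_id, trait_kind=trait_kind, ancestry=ancestry,
        variant_id=np.array(order, dtype=object),
        chrom=meta["chrom"].to_numpy(dtype=object),
        pos=meta["pos"].to_numpy(dtype=np.int64),
        effect_allele=meta["effect_allele"].to_numpy(dtype=object),
        other_allele=meta["other_allele"].to_numpy(dtype=object),
        eaf=meta["eaf"].to_numpy(dtype=float),
        beta=beta_arr,
        se=se_arr,
        pvalue=normal_p(beta_arr / se_arr),
        n=np.full(len(order), n, dtype=np.int64),
    )


def simulate_marginal_stats_pair(
    truth: TruthSpec, trait_a: str, trait_b: str, genome: Genome,
    n_a: int, n_b: int, seed: int, overlap_rho: float = 0.0,
) -> tuple[SummaryStatSet, SummaryStatSet]:
    """Exposure/outcome pair with optional sample-overlap correlation.

    With ``overlap_rho`` > 0 the two studies' sampling errors are
    correlated (cov = ρ·R/√(n_a·n_b) per block), emulating shared
    participants; ρ = 0 reproduces two independent draws.
    """
    if not (0 <= overlap_rho <= 1):
        raise ValueError("overlap_rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seed_a, seed_b = rng.integers(0, 2**31 - 1, size=2)
    ss_a = simulate_marginal_stats(truth, trait_a, genome, n_a, int(seed_a))
    ss_b = simulate_marginal_stats(truth, trait_b, genome, n_b, int(seed_b))
    if overlap_rho > 0:
        mu_a = np.concatenate([
            (blk.R @ beta_joint(truth, trait_a, genome).loc[blk.variant_ids].to_numpy())
            for blk in genome.ld.blocks
        ])
        mu_b_blocks = []
        noise_a = ss_a.beta - _reorder(mu_a, genome, ss_a)
        tb = beta_joint(truth, trait_b, genome)
        start = 0
        new_beta = ss_b.beta.copy()
        for blk in genome.ld.blocks:
            nb = blk.size
            mu_b = blk.R @ tb.loc[blk.variant_ids].to_numpy()
            idx = [ss_b.loc(v) for v in blk.variant_ids]
            na_idx = [ss_a.loc(v) for v in blk.variant_ids]
            resid_b = ss_b.beta[idx] - mu_b
            scaled_a = noise_a[na_idx] * (np.sqrt(n_a) / np.sqrt(n_b))
            new_beta[idx] = mu_b + overlap_rho * scaled_a + np.sqrt(1 - overlap_rho**2) * resid_b
            mu_b_blocks.append(mu_b)
            start += nb
        ss_b.beta = new_beta
        ss_b.pvalue = normal_p(ss_b.beta / ss_b.se)
    return ss_a, ss_b


def _reorder(block_concat: np.ndarray, genome: Genome, ss: SummaryStatSet) -> np.ndarray:
    out = np.empty_like(block_concat)
    k = 0
    for blk in genome.ld.blocks:
        for vid in blk.variant_ids:
            out[ss.loc(vid)] = block_concat[k]
            k += 1
    return out


def scramble_alleles(ss: SummaryStatSet, frac: float, seed: int) -> SummaryStatSet:
    """Recode a random subset of variants on the other allele.

    Swaps effect/other allele, negates beta, and complements EAF — the
    association is unchanged, so harmonization must restore the original
    effect signs. Exercises the allele-alignment path.
    """
    rng = np.random.default_rng(seed)
    flip = rng.random(len(ss)) < frac
    out = ss.subset(np.ones(len(ss), dtype=bool))
    ea = out.effect_allele.copy()
    out.effect_allele = np.where(flip, out.other_allele, out.effect_allele)
    out.other_allele = np.where(flip, ea, out.other_allele)
    out.beta = np.where(flip, -out.beta, out.beta)
    out.eaf = np.where(flip, 1 - out.eaf, out.eaf)
    return out


# ---------------------------------------------------------------------------
# single-cell counts


@dataclass
class DonorSpec:
    donor_id: str
    condition: str  # NF | DCM | HCM
    age: float
    sex: str  # F | M


def make_default_donors(n_nf: int = 8, n_dcm: int = 6, n_hcm: int = 6,
                        seed: int = 0) -> list[DonorSpec]:
    """Donor panel at roughly half the scale of a left-ventricle atlas cohort."""
    rng = np.random.default_rng(seed)
    donors = []
    for cond, count in (("NF", n_nf), ("DCM", n_dcm), ("HCM", n_hcm)):
        for i in range(count):
            donors.append(DonorSpec(
                donor_id=f"{cond}{i}",
                condition=cond,
                age=float(rng.integers(35, 75)),
                sex="F" if rng.random() < 0.5 else "M",
            ))
    return donors


def simulate_singlecell_counts(
    n_genes: int,
    cell_types: list[str],
    donors: list[DonorSpec],
    enriched_gene_map: dict[str, tuple[str, float]] | None = None,
    de_gene_map: dict[str, tuple[str, str, float]] | None = None,
    seed: int = 0,
    nuclei_per_donor_type: int = 60,
    base_mean: float = 2.0,
    dispersion: float = 0.5,
) -> tuple[np.ndarray, list[str], pd.DataFrame, pd.DataFrame]:
    """Negative-binomial nucleus-level counts with planted structure.

    ``enriched_gene_map``: gene → (cell_type, fold) multiplies the gene's
    mean in that cell type, so its pseudobulk one-vs-rest ratio equals the
    fold in expectation. ``de_gene_map``: gene → (cell_type, condition,
    fold) multiplies the mean for nuclei of donors in that condition
    within that cell type (a DCM- or HCM-specific shift).

    Returns (counts genes×cells, gene ids, cells table, donors table).
    """
    enriched_gene_map = enriched_gene_map or {}
    de_gene_map = de_gene_map or {}
    for gmap in (enriched_gene_map, de_gene_map):
        for g, spec in gmap.items():
            if spec[-1] <= 0:
                raise ValueError(f"fold for gene {g} must be > 0")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    gene_base = base_mean * np.exp(rng.normal(0.0, 0.4, size=n_genes))

    cell_rows = []
    for donor in donors:
        for ct in cell_types:
            for k in range(nuclei_per_donor_type):
                cell_rows.append({
                    "cell_id": f"{donor.donor_id}_{ct}_{k}",
                    "cell_type": ct,
                    "donor_id": donor.donor_id,
                })
    cells = pd.DataFrame(cell_rows)
    donor_cond = {d.donor_id: d.condition for d in donors}

    mean = np.tile(gene_base[:, None], (1, len(cells)))
    ct_arr = cells["cell_type"].to_numpy()
    cond_arr = cells["donor_id"].map(donor_cond).to_numpy()
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g, (ct, fold) in enriched_gene_map.items():
        mean[gene_idx[g], ct_arr == ct] *= fold
    for g, (ct, cond, fold) in de_gene_map.items():
        mean[gene_idx[g], (ct_arr == ct) & (cond_arr == cond)] *= fold

    r = 1.0 / dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(np.int64)
    donors_df = pd.DataFrame([vars(d) for d in donors])
    return counts, genes, cells, donors_df


def write_singlecell_mtx(directory, counts, genes, cells: pd.DataFrame,
                         donors: pd.DataFrame) -> None:
    """Write counts as Matrix Market plus genes/cells/donors TSV sidecars."""
    import os

    os.makedirs(directory, exist_ok=True)
    mmwrite(os.path.join(directory, "matrix.mtx"), coo_matrix(counts))
    pd.DataFrame({"gene_id": genes}).to_csv(
        os.path.join(directory, "genes.tsv"), sep="\t", index=False)
    cells.to_csv(os.path.join(directory, "cells.tsv"), sep="\t", index=False)
    donors.to_csv(os.path.join(directory, "donors.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# study factory


def make_truth(
    n_proteins: int = 50,
    n_diseases: int = 6,
    n_cis: int = 2,
    cis_beta: float = 0.15,
    n_trans_hubs: int = 0,
    trans_beta: float = 0.08,
    n_disease_variants: int = 3,
    disease_variant_beta: float = 0.08,
    forward_effects: dict[tuple[int, int], float] | None = None,
    reverse_effects: dict[tuple[int, int], float] | None = None,
    pleiotropy: list[tuple[int, int, float]] | None = None,
    n_protein_gwas: int = 20_000,
    n_disease_gwas: int = 100_000,
    replication_n: int = 1_225,
    seed: int = 0,
) -> TruthSpec:
    """Assemble a regular synthetic study layout.

    Effect maps are keyed by (protein index, disease index); pleiotropy
    entries (protein index, disease index, beta) give that protein's
    first cis variant a direct disease effect bypassing the protein.
    Proteins sit on their own chromosomes with a 50 kb gene body; each
    disease's own liability variants sit on a dedicated chromosome.
    """
    rng = np.random.default_rng(seed)
    proteins = [
        ProteinSpec(f"P{i:03d}", f"GENE{i:03d}", f"chr{i + 1}",
                    1_000_000, 1_050_000)
        for i in range(n_proteins)
    ]
    categories = ["ischemic", "arrhythmia", "structural", "vascular"]
    diseases = [
        DiseaseSpec(f"D{j:02d}", categories[j % len(categories)],
                    int(rng.integers(500, 20_000)))
        for j in range(n_diseases)
    ]
    cis_arch = {
        p.protein_id: [
            CausalVariant(f"{p.protein_id}:cis{k}", p.chrom,
                          p.start - 150_000 + 120_000 * k, cis_beta)
            for k in range(n_cis)
        ]
        for p in proteins
    }
    dis_arch = {
        d.disease_id: [
            CausalVariant(f"{d.disease_id}:risk{k}", f"chrD{j + 1}",
                          5_000_000 + 120_000 * k, disease_variant_beta)
            for k in range(n_disease_variants)
        ]
        for j, d in enumerate(diseases)
    }
    hubs = []
    for h in range(n_trans_hubs):
        targets = rng.choice(n_proteins, size=min(3, n_proteins), replace=False)
        hubs.append(TransHub(
            f"hub{h}:lead", f"chrT{h + 1}", 9_000_000 + 50_000 * h,
            {proteins[t].protein_id: trans_beta for t in targets},
        ))
    fwd = {
        (proteins[i].protein_id, diseases[j].disease_id): g
        for (i, j), g in (forward_effects or {}).items()
    }
    rev = {
        (diseases[j].disease_id, proteins[i].protein_id): v
        for (i, j), v in (reverse_effects or {}).items()
    }
    pleio: dict[str, dict[str, float]] = {}
    for (i, j, b) in pleiotropy or []:
        vid = cis_arch[proteins[i].protein_id][0].variant_id
        pleio.setdefault(vid, {})[diseases[j].disease_id] = b
    truth = TruthSpec(
        proteins=proteins, diseases=diseases,
        forward_effects=fwd, reverse_effects=rev,
        cis_architecture=cis_arch, trans_architecture=hubs,
        disease_architecture=dis_arch, pleiotropy=pleio,
        ancestries={"EUR": AncestrySpec(n_protein_gwas, n_disease_gwas)},
        replication_panel_n=replication_n,
    )
    truth.validate()
    return truth


def simulate_study(
    truth: TruthSpec, genome: Genome, ancestry: str = "EUR",
    seed: int = 0, replication: bool = False,
) -> tuple[dict[str, SummaryStatSet], dict[str, SummaryStatSet]]:
    """Sample every protein and disease GWAS for one ancestry.

    Returns (protein_stats, disease_stats) keyed by trait id. With
    ``replication`` the protein panel is re-sampled at the smaller
    replication sample size (an independent second pQTL study).
    """
    spec = truth.ancestries[ancestry]
    rng = np.random.default_rng(seed)
    n_prot = truth.replication_panel_n if replication else spec.n_protein_gwas
    protein_stats = {}
    for pid in truth.protein_ids():
        protein_stats[pid] = simulate_marginal_stats(
            truth, pid, genome, n_prot, int(rng.integers(0, 2**31 - 1)),
            ancestry=ancestry)
    disease_stats = {}
    for did in truth.disease_ids():
        disease_stats[did] = simulate_marginal_stats(
            truth, did, genome, spec.n_disease_gwas,
            int(rng.integers(0, 2**31 - 1)), ancestry=ancestry)
    return protein_stats, disease_stats
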