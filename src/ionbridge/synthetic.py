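"""Synthetic data generators with planted ground truth.

Every input class the pipeline consumes can be generated here: two-batch
bulk cohorts with module structure and tumor effects, evidence-channel PPI
graphs with planted bridge paths, drug-evidence records spanning all target
tiers, and negative-binomial single-cell knockout datasets with planted
target knockdown, mediator shifts and co-expression disruption.

Counts are negative binomial with log-normally distributed gene means.
Co-expression is planted through shared Gaussian latent factors mapped
through the NB mean (bulk modules) or through a Gaussian copula on the NB
quantile function (single-cell pairs), which gives controllable rank
correlations compatible with count noise. One global seed expands into
per-generator substreams so adding a generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .bulk_de import NORMAL, TUMOR, BulkCohort
from .druggability import TIERS, DrugEvidenceRecord
from .evidence import CONTROL, SingleCellKODataset

# substream tags: adding a generator never perturbs the draws of another
_BULK, _PPI, _DRUG, _PERTURB = 11, 23, 37, 41


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2 (dispersion -> 0 is Poisson)."""
    mean = np.maximum(np.asarray(mean, float), 1e-9)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# bulk cohorts
# ---------------------------------------------------------------------------

_DEFAULT_MODULE_SIZES = (718, 194, 300, 250, 200, 180, 160, 150, 140, 130, 120, 110, 100)
_DEFAULT_MODULE_EFFECTS = (0.8, 0.6) + (0.0,) * 11


@dataclass
class BulkSimSpec:
    """Simulation spec for a module-structured two-condition bulk cohort.

    Defaults mirror the discovery-cohort design this package targets:
    42 tumor / 43 normal samples from two batches and 13 co-expression
    modules, the two disease-associated modules sized 718 and 194 genes.
    ``module_trait_effect`` is the standardized mean shift of each module's
    latent factor in tumor samples.
    """

    n_genes: int = 5000
    n_tumor: int = 42
    n_normal: int = 43
    n_batches: int = 2
    n_modules: int = 13
    module_sizes: tuple[int, ...] = _DEFAULT_MODULE_SIZES
    module_trait_effect: tuple[float, ...] = _DEFAULT_MODULE_EFFECTS
    de_genes: tuple[tuple[str, float], ...] = ()
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.1
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_tumor, self.n_normal, self.n_batches) <= 0:
            raise ValueError("all counts must be positive")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if len(self.module_trait_effect) != self.n_modules:
            raise ValueError("module_trait_effect length must equal n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        if self.batch_shift_sd < 0 or self.batch_scale_sd < 0:
            raise ValueError("batch SDs must be nonnegative")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")


def bulk_gene_ids(n: int) -> pd.Index:
    return pd.Index([f"G{i + 1:05d}" for i in range(n)], name="gene")


def generate_bulk_cohort(spec: BulkSimSpec) -> tuple[BulkCohort, pd.DataFrame]:
    """Generate an NB bulk cohort; returns (cohort, per-gene ground truth).

    Genes within a module share a per-sample latent factor (unit loading on
    the log2-mean scale) so their pairwise correlations are elevated; the
    factor mean is shifted by ``module_trait_effect`` in tumor samples.
    Listed ``de_genes`` carry their log2FC as a tumor mean multiplier.
    Batches carry per-gene location shifts and residual-scale factors.
    """
    rng = _rng(spec.seed, _BULK)
    genes = bulk_gene_ids(spec.n_genes)
    n_samp = spec.n_tumor + spec.n_normal
    samples = pd.Index(
        [f"T{i + 1:03d}" for i in range(spec.n_tumor)]
        + [f"N{i + 1:03d}" for i in range(spec.n_normal)],
        name="sample",
    )
    is_tumor = np.r_[np.ones(spec.n_tumor, bool), np.zeros(spec.n_normal, bool)]
    condition = pd.Series(np.where(is_tumor, TUMOR, NORMAL), index=samples)
    batch_idx = np.arange(n_samp) % spec.n_batches
    rng.shuffle(batch_idx)
    batch = pd.Series([f"batch{b + 1}" for b in batch_idx], index=samples)

    module_of = np.full(spec.n_genes, "grey", dtype=object)
    pos = 0
    for m, size in enumerate(spec.module_sizes):
        module_of[pos : pos + size] = f"M{m + 1}"
        pos += size

    base = rng.normal(5.0, 1.5, size=spec.n_genes)  # log2 mean counts
    log2mean = np.tile(base[:, None], (1, n_samp))

    # shared latent factors (unit loading) with tumor mean shift
    pos = 0
    for m, size in enumerate(spec.module_sizes):
        delta = spec.module_trait_effect[m]
        f = rng.normal(0.0, 1.0, size=n_samp) + delta * is_tumor
        log2mean[pos : pos + size, :] += f[None, :]
        pos += size

    planted_lfc = pd.Series(0.0, index=genes)
    for gene, lfc in spec.de_genes:
        if gene not in genes:
            raise ValueError(f"de_gene {gene!r} not in gene universe")
        gi = genes.get_loc(gene)
        log2mean[gi, is_tumor] += lfc
        planted_lfc[gene] = lfc

    # batch location shift and residual-scale factor, per (gene, batch)
    shift = rng.normal(0.0, spec.batch_shift_sd, size=(spec.n_genes, spec.n_batches))
    scale = np.exp(rng.normal(0.0, spec.batch_scale_sd, size=(spec.n_genes, spec.n_batches)))
    noise = rng.normal(0.0, 0.25, size=(spec.n_genes, n_samp))
    log2mean += shift[:, batch_idx] + noise * scale[:, batch_idx]

    depth = np.exp(rng.normal(0.0, 0.15, size=n_samp))
    mean = np.exp2(log2mean) * depth[None, :]
    counts = _nb_draw(rng, mean, spec.nb_dispersion)

    cohort = BulkCohort(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        condition=condition,
        batch=batch,
    )
    truth = pd.DataFrame(
        {
            "module": module_of,
            "planted_log2FC": planted_lfc.values,
            "is_de": planted_lfc.values != 0.0,
        },
        index=genes,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# PPI graphs
# ---------------------------------------------------------------------------

CHANNELS = ("experimental", "database", "textmining", "coexpression")


@dataclass
class PlantedPath:
    """One hub -> channel path to plant, with per-edge channel scores.

    ``edge_scores`` holds one dict per consecutive edge; keys are evidence
    channels plus an optional explicit ``combined`` (0-1000). Without an
    explicit combined score the STRING-style noisy-or of the channels is
    used: 1000 * (1 - prod(1 - s/1000)).
    """

    hub: str
    channel: str
    intermediates: tuple[str, ...] = ()
    edge_scores: tuple[dict[str, float], ...] = ()

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.hub, *self.intermediates, self.channel)

    def __post_init__(self) -> None:
        if len(self.intermediates) > 2:
            raise ValueError("planted paths allow at most 2 intermediates (4 nodes)")
        n_edges = len(self.nodes) - 1
        if not self.edge_scores:
            self.edge_scores = tuple({"textmining": 600.0} for _ in range(n_edges))
        if len(self.edge_scores) != n_edges:
            raise ValueError("edge_scores length must equal number of path edges")
        for sc in self.edge_scores:
            for v in sc.values():
                if not 0 <= v <= 1000:
                    raise ValueError("channel scores must lie in [0, 1000]")


@dataclass
class PPISimSpec:
    n_background_genes: int = 50
    planted_paths: tuple[PlantedPath, ...] = ()
    noise_edges: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_genes < 0 or self.noise_edges < 0:
            raise ValueError("counts must be nonnegative")


def combined_from_channels(scores: dict[str, float]) -> float:
    if "combined" in scores:
        return float(scores["combined"])
    keep = 1.0
    for ch in CHANNELS:
        keep *= 1.0 - scores.get(ch, 0.0) / 1000.0
    return 1000.0 * (1.0 - keep)


def generate_ppi_graph(spec: PPISimSpec) -> nx.Graph:
    """Undirected evidence-channel PPI graph with planted bridge paths.

    Noise edges connect background genes only, so they can never create a
    hub -> channel path shorter than a planted one.
    """
    rng = _rng(spec.seed, _PPI)
    g = nx.Graph()
    background = [f"B{i + 1:04d}" for i in range(spec.n_background_genes)]
    g.add_nodes_from(background)

    for path in spec.planted_paths:
        nodes = path.nodes
        for (a, b), sc in zip(zip(nodes[:-1], nodes[1:]), path.edge_scores):
            attrs = {ch: float(sc.get(ch, 0.0)) for ch in CHANNELS}
            attrs["combined_score"] = combined_from_channels(sc)
            g.add_edge(a, b, **attrs)

    n_bg = len(background)
    added = 0
    attempts = 0
    while added < spec.noise_edges and n_bg >= 2 and attempts < 50 * spec.noise_edges:
        attempts += 1
        i, j = rng.choice(n_bg, size=2, replace=False)
        a, b = background[i], background[j]
        if g.has_edge(a, b):
            continue
        combined = float(rng.uniform(400, 999))
        g.add_edge(
            a,
            b,
            experimental=0.0,
            database=0.0,
            textmining=combined,
            coexpression=0.0,
            combined_score=combined,
        )
        added += 1
    return g


def ppi_to_table(g: nx.Graph) -> pd.DataFrame:
    """STRING-dialect edge table (protein1, protein2, channels, combined_score)."""
    rows = [
        {"protein1": a, "protein2": b, **{ch: d.get(ch, 0.0) for ch in CHANNELS},
         "combined_score": d["combined_score"]}
        for a, b, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# drug-evidence records
# ---------------------------------------------------------------------------


def generate_drug_evidence(
    genes: list[str],
    tier_assignment: dict[str, str],
    seed: int = 0,
) -> list[DrugEvidenceRecord]:
    """Evidence records whose fields are consistent with the requested tier."""
    rng = _rng(seed, _DRUG)
    records = []
    for gene in genes:
        tier = tier_assignment.get(gene, "Unknown")
        if tier not in TIERS:
            raise ValueError(f"unknown tier {tier!r} for gene {gene!r}; valid: {TIERS}")
        rec = _record_for_tier(gene, tier, rng)
        records.append(rec)
    return records


def _record_for_tier(gene: str, tier: str, rng: np.random.Generator) -> DrugEvidenceRecord:
    if tier == "ApprovedTarget":
        n_appr = int(rng.integers(1, 4))
        return DrugEvidenceRecord(
            gene=gene, approved_drugs_n=n_appr, max_phase=4,
            tractability_labels=["Approved Drug"],
            dgidb_drug_count=int(rng.integers(3, 25)),
            chembl_mechanisms_n=int(rng.integers(1, 10)),
            chembl_molecules_n=int(rng.integers(1, 20)),
            drug_names=[f"{gene.lower()}-mab-{k}" for k in range(n_appr)],
        )
    if tier == "LateClinicalTarget":
        return DrugEvidenceRecord(
            gene=gene, approved_drugs_n=0, max_phase=3,
            tractability_labels=["Advanced Clinical"],
            dgidb_drug_count=int(rng.integers(1, 10)),
            chembl_mechanisms_n=int(rng.integers(0, 4)),
            chembl_molecules_n=int(rng.integers(0, 8)),
        )
    if tier == "EarlyClinicalTarget":
        return DrugEvidenceRecord(
            gene=gene, approved_drugs_n=0, max_phase=int(rng.integers(1, 3)),
            tractability_labels=["Phase 1 Clinical"],
            dgidb_drug_count=int(rng.integers(0, 5)),
            chembl_mechanisms_n=int(rng.integers(0, 3)),
            chembl_molecules_n=int(rng.integers(0, 5)),
        )
    if tier == "Tractable (Structure/High)":
        return DrugEvidenceRecord(
            gene=gene, approved_drugs_n=0, max_phase=0,
            tractability_labels=["Structure with Ligand", "High-Quality Pocket"],
            dgidb_drug_count=int(rng.integers(0, 3)),
            chembl_mechanisms_n=0, chembl_molecules_n=int(rng.integers(0, 3)),
        )
    if tier == "Tractable (Predicted)":
        return DrugEvidenceRecord(
            gene=gene, approved_drugs_n=0, max_phase=0,
            tractability_labels=["Predicted Tractable"],
            dgidb_drug_count=int(rng.integers(0, 3)),
            chembl_mechanisms_n=0, chembl_molecules_n=0,
        )
    # Unknown: no evidence at all
    return DrugEvidenceRecord(
        gene=gene, approved_drugs_n=0, max_phase=0, tractability_labels=[],
        dgidb_drug_count=0, chembl_mechanisms_n=0, chembl_molecules_n=0,
    )


# ---------------------------------------------------------------------------
# single-cell knockout datasets
# ---------------------------------------------------------------------------


@dataclass
class PerturbSimSpec:
    """Simulation spec for a CRISPRi-style single-cell knockout dataset.

    Scaled-down emulation of a pooled knockout screen: each KO gene gets its
    own cell group plus a shared non-targeting control group, cells cycle
    through ``n_batches`` batches, and counts are zero-inflated NB. The KO
    gene's mean is multiplied by (1 - knockdown_fraction) in its KO cells.
    ``coexpr_pairs`` entries (geneA, geneB, rho_control, rho_ko) plant
    Spearman correlations via a Gaussian copula; rho_ko applies in the cells
    whose KO label equals geneA.
    """

    n_cells_per_group: int = 300
    n_genes: int = 1500
    ko_genes: tuple[str, ...] = (
        "G00001", "G00002", "G00003", "G00004", "G00005", "G00006"
    )
    knockdown_fraction: float = 0.9
    mediator_effects: tuple[tuple[str, str, float], ...] = ()
    coexpr_pairs: tuple[tuple[str, str, float, float], ...] = ()
    n_batches: int = 8
    nb_dispersion: float = 0.4
    zero_inflation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells_per_group, self.n_genes, self.n_batches) <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.knockdown_fraction <= 1.0:
            raise ValueError("knockdown_fraction must lie in [0, 1]")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for a, b, rc, rk in self.coexpr_pairs:
            if abs(rc) > 1 or abs(rk) > 1:
                raise ValueError(f"|rho| > 1 for pair ({a}, {b})")


def _copula_rho(rho_spearman: float) -> float:
    """Latent Gaussian correlation whose copula has the given Spearman rho."""
    return float(np.clip(2.0 * np.sin(np.pi * rho_spearman / 6.0), -0.999, 0.999))


def generate_perturbseq(spec: PerturbSimSpec) -> tuple[SingleCellKODataset, pd.DataFrame]:
    """Zero-inflated NB knockout dataset with planted ground truth.

    Returns (dataset, ground-truth table). Genes involved in knockdowns,
    mediator shifts or co-expression pairs get elevated base means so the
    planted effects are estimable at desk scale.
    """
    rng = _rng(spec.seed, _PERTURB)
    genes = bulk_gene_ids(spec.n_genes)  # shared symbol space with bulk cohorts
    for g in spec.ko_genes:
        if g not in genes:
            raise ValueError(f"ko gene {g!r} not in gene universe")

    groups = [*spec.ko_genes, CONTROL]
    n_cells = spec.n_cells_per_group * len(groups)
    ko_label = np.repeat(groups, spec.n_cells_per_group)
    batch = np.array([f"b{(i % spec.n_batches) + 1}" for i in range(n_cells)])
    cells = pd.Index([f"cell{i + 1:05d}" for i in range(n_cells)], name="cell")

    base_mean = np.exp(rng.normal(0.5, 1.0, size=spec.n_genes))
    # elevated means where effects must be estimable
    special = {g: 25.0 for g in spec.ko_genes}
    for _, med, _ in spec.mediator_effects:
        special.setdefault(med, 20.0)
    for a, b, _, _ in spec.coexpr_pairs:
        special[a] = 30.0
        special.setdefault(b, 30.0)
    for g, m in special.items():
        base_mean[genes.get_loc(g)] = m

    depth = np.exp(rng.normal(0.0, 0.3, size=n_cells))
    mean = base_mean[:, None] * depth[None, :]

    for g in spec.ko_genes:
        gi = genes.get_loc(g)
        mean[gi, ko_label == g] *= 1.0 - spec.knockdown_fraction
    for ko, med, lfc in spec.mediator_effects:
        mi = genes.get_loc(med)
        mean[mi, ko_label == ko] *= 2.0**lfc

    counts = _nb_draw(rng, mean, spec.nb_dispersion)

    # co-expression pairs via Gaussian copula through the NB quantile function
    r = 1.0 / spec.nb_dispersion
    flagged = []
    for a, b, rho_c, rho_k in spec.coexpr_pairs:
        if abs(rho_k) > abs(rho_c):
            flagged.append((a, b))
        ai, bi = genes.get_loc(a), genes.get_loc(b)
        rho_cell = np.where(ko_label == a, _copula_rho(rho_k), _copula_rho(rho_c))
        z1 = rng.standard_normal(n_cells)
        z2 = rho_cell * z1 + np.sqrt(1.0 - rho_cell**2) * rng.standard_normal(n_cells)
        for gi, z in ((ai, z1), (bi, z2)):
            u = stats.norm.cdf(z)
            mu = np.maximum(mean[gi], 1e-9)
            counts[gi] = stats.nbinom.ppf(u, r, r / (r + mu)).astype(np.int64)

    if spec.zero_inflation > 0:
        drop = rng.random(counts.shape) < spec.zero_inflation
        counts = np.where(drop, 0, counts)

    dataset = SingleCellKODataset(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        ko_label=pd.Series(ko_label, index=cells),
        batch=pd.Series(batch, index=cells),
    )
    rows = [
        {"effect": "knockdown", "ko_gene": g, "gene": g,
         "value": spec.knockdown_fraction}
        for g in spec.ko_genes
    ]
    rows += [
        {"effect": "mediator", "ko_gene": ko, "gene": med, "value": lfc}
        for ko, med, lfc in spec.mediator_effects
    ]
    rows += [
        {"effect": "coexpression", "ko_gene": a, "gene": b,
         "value": rho_c, "value_ko": rho_k,
         "flagged": (a, b) in flagged}
        for a, b, rho_c, rho_k in spec.coexpr_pairs
    ]
    truth = pd.DataFrame(rows)
    return dataset, truth
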