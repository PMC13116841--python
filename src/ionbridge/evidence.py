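"""Seven-strategy evidence matrix for KO-gene -> ion-channel pairs.

Each strategy scores one orthogonal signal from a CRISPRi single-cell
knockout dataset on a 0-3 rubric (maximum pair total 21):

S1  batch-level pseudobulk differential expression (padj rubric)
S2  preranked GSEA on the knockout perturbation signature (NES + p rubric)
S3  transcriptome-wide rank of the target's |log2FC| (top-% rubric)
S4  two-part hurdle test: detection rate and expression among detected,
    both adjusted for the cellular detection rate (padj rubric)
S5  indirect mediator network: significantly perturbed genes with a PPI
    edge to the target (evidence-class rubric)
S6  global perturbation magnitude: mean |z| across genes, where z is a
    variance-floored standardized mean difference
S7  co-expression disruption: Spearman rho in KO minus control cells

All rubric breakpoints are strict; breakpoint-equal statistics fall to the
lower score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .bulk_de import bh_adjust

logger = logging.getLogger(__name__)

CONTROL = "control"
STRENGTH_CLASSES = (
    (15.0, "high (>=15)"),
    (10.0, "moderate (10-15)"),
    (5.0, "low (5-10)"),
    (-np.inf, "minimal (<5)"),
)


@dataclass
class SingleCellKODataset:
    """Gene x cell counts with per-cell KO label (or control) and batch."""

    counts: pd.DataFrame  # genes x cells
    ko_label: pd.Series  # per cell: KO gene name or CONTROL
    batch: pd.Series

    def __post_init__(self) -> None:
        self.ko_label = self.ko_label.loc[self.counts.columns]
        self.batch = self.batch.loc[self.counts.columns]
        if CONTROL not in set(self.ko_label):
            raise ValueError("dataset has no control cells")

    @property
    def ko_genes(self) -> list[str]:
        return sorted(set(self.ko_label) - {CONTROL})

    def cells_of(self, group: str) -> pd.Index:
        return self.ko_label.index[self.ko_label == group]

    def normalized(self, scale: float = 1e4) -> pd.DataFrame:
        lib = self.counts.sum(axis=0).replace(0, 1)
        return np.log1p(self.counts.div(lib, axis=1) * scale) / np.log(2)


@dataclass
class EvidenceMatrixRow:
    ko_gene: str
    channel: str
    scores: dict[str, float]  # "S1".."S7"
    raw: dict[str, object] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.scores.values()))

    @property
    def strength_class(self) -> str:
        return strength_class(self.total)


def strength_class(total: float) -> str:
    for cut, label in STRENGTH_CLASSES:
        if total >= cut:
            return label
    raise AssertionError("unreachable")


def total_evidence(scores: dict[str, float]) -> tuple[float, str]:
    """Sum of the seven strategy scores and its strength class.

    Missing strategies count 0 (logged). Totals are capped by construction
    at 21 when each score respects its 0-3 rubric.
    """
    full = {}
    for i in range(1, 8):
        key = f"S{i}"
        if key not in scores or scores[key] is None or np.isnan(scores[key]):
            logger.info("strategy %s missing; counted as 0", key)
            full[key] = 0.0
        else:
            full[key] = float(scores[key])
    total = float(sum(full.values()))
    return total, strength_class(total)


# ---------------------------------------------------------------------------
# rubrics (strict inequalities as printed; equality falls to the lower score)
# ---------------------------------------------------------------------------


def score_s1(padj: float | None) -> float:
    """padj < 0.05 -> 3, < 0.1 -> 2, < 0.2 -> 1, else 0; missing -> 0."""
    if padj is None or np.isnan(padj):
        return 0.0
    if padj < 0.05:
        return 3.0
    if padj < 0.1:
        return 2.0
    if padj < 0.2:
        return 1.0
    return 0.0


def score_s2(nes: float, p: float) -> float:
    """|NES| > 1.5 with p < 0.05 -> 3, |NES| > 1.3 -> 2, > 1.0 -> 1, else 0."""
    a = abs(nes)
    if a > 1.5 and p < 0.05:
        return 3.0
    if a > 1.3:
        return 2.0
    if a > 1.0:
        return 1.0
    return 0.0


def score_s3(top_percent: float) -> float:
    """top 5% -> 3, top 10% -> 2, top 20% -> 1, else 0."""
    if top_percent < 5.0:
        return 3.0
    if top_percent < 10.0:
        return 2.0
    if top_percent < 20.0:
        return 1.0
    return 0.0


def score_s4(padj: float | None) -> float:
    """Same padj rubric as S1, applied to the hurdle-test result."""
    return score_s1(padj)


def score_s5(mediator_class: str) -> float:
    """validated -> 3, predicted -> 2, weak -> 1, none -> 0."""
    return {"validated": 3.0, "predicted": 2.0, "weak": 1.0, "none": 0.0}[
        mediator_class
    ]


def score_s6(mean_abs_z: float) -> float:
    """mean |z| > 0.5 -> 3, > 0.3 -> 2, > 0.1 -> 1, else 0."""
    if mean_abs_z > 0.5:
        return 3.0
    if mean_abs_z > 0.3:
        return 2.0
    if mean_abs_z > 0.1:
        return 1.0
    return 0.0


def score_s7(delta_rho: float | None) -> float:
    """|delta rho| > 0.2 -> 3, > 0.15 -> 2, > 0.1 -> 1, else 0; missing -> 0."""
    if delta_rho is None or np.isnan(delta_rho):
        return 0.0
    a = abs(delta_rho)
    if a > 0.2:
        return 3.0
    if a > 0.15:
        return 2.0
    if a > 0.1:
        return 1.0
    return 0.0


# ---------------------------------------------------------------------------
# strategy statistics
# ---------------------------------------------------------------------------


def pseudobulk_de(
    dataset: SingleCellKODataset,
    ko_gene: str,
    backend: str = "welch",
) -> pd.DataFrame:
    """Batch-level pseudobulk differential expression, KO vs control.

    Cells are summed per (condition, batch); the default backend runs
    Welch's t-test on log2(CPM + 1) pseudobulk profiles with BH adjustment.
    ``backend="pydeseq2"`` swaps in a negative-binomial GLM fit. Genes zero
    in all pseudobulk samples are excluded (logged).
    """
    ko_cells = dataset.cells_of(ko_gene)
    ctrl_cells = dataset.cells_of(CONTROL)
    if len(ko_cells) == 0:
        raise ValueError(f"no cells for KO gene {ko_gene!r}")
    cols, conds = [], []
    for cond, cells in ((ko_gene, ko_cells), (CONTROL, ctrl_cells)):
        batches = sorted(dataset.batch.loc[cells].unique())
        if len(batches) < 2:
            raise ValueError(
                f"condition {cond!r} spans {len(batches)} batch(es); pseudobulk "
                "DE needs >= 2 per condition (use the hurdle test instead)"
            )
        for b in batches:
            sub = cells[dataset.batch.loc[cells] == b]
            cols.append(dataset.counts[sub].sum(axis=1))
            conds.append(cond)
    pb = pd.concat(cols, axis=1)
    pb.columns = [f"{c}_{i}" for i, c in enumerate(conds)]
    conds = pd.Series(conds, index=pb.columns)

    nonzero = pb.sum(axis=1) > 0
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("pseudobulk: %d all-zero genes excluded", dropped)
    pb = pb.loc[nonzero]

    if backend == "pydeseq2":
        return _pydeseq2_de(pb, conds, ko_gene)
    if backend != "welch":
        raise ValueError(f"unknown backend {backend!r}")

    logcpm = np.log2(pb.div(pb.sum(axis=0), axis=1) * 1e6 + 1.0)
    a = logcpm.loc[:, conds == ko_gene].to_numpy(float)
    b = logcpm.loc[:, conds == CONTROL].to_numpy(float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(
        {"log2FC": lfc, "p": p, "padj": bh_adjust(p)}, index=pb.index
    )


def _pydeseq2_de(pb: pd.DataFrame, conds: pd.Series, ko_gene: str) -> pd.DataFrame:
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    meta = pd.DataFrame({"condition": conds.values}, index=pb.columns)
    dds = DeseqDataSet(
        counts=pb.T.astype(int), metadata=meta, design="~condition", quiet=True
    )
    dds.deseq2()
    res = DeseqStats(
        dds, contrast=["condition", ko_gene, CONTROL], quiet=True
    )
    res.summary()
    out = res.results_df
    return pd.DataFrame(
        {
            "log2FC": out["log2FoldChange"],
            "p": out["pvalue"].fillna(1.0),
            "padj": out["padj"].fillna(1.0),
        },
        index=pb.index,
    )


def preranked_gsea(
    ranking: pd.Series,
    gene_set: set[str] | list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> tuple[float, float, float]:
    """Preranked GSEA: weighted KS enrichment with gene-set permutations.

    Returns (ES, NES, p). ES is the extreme of the weighted running sum over
    the metric-sorted gene list; the null is built from random gene sets of
    the same size, NES = ES / mean |null ES| of matching sign, and p is the
    add-one empirical tail probability among same-sign null scores.
    """
    genes = set(gene_set) & set(ranking.index)
    if not genes:
        raise ValueError("gene set does not intersect the ranking")
    order = ranking.sort_values(ascending=False)
    metric = order.to_numpy(float)
    is_hit = order.index.isin(genes)

    es = _enrichment_score(metric, is_hit, weight)
    rng = np.random.default_rng(seed)
    n = len(order)
    size = int(is_hit.sum())
    null = np.empty(n_perm)
    for i in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=size, replace=False)] = True
        null[i] = _enrichment_score(metric, mask, weight)
    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same) == 0:
        return es, 0.0, 1.0
    nes = es / np.mean(np.abs(same))
    p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
    return float(es), float(nes), float(p)


def _enrichment_score(metric: np.ndarray, is_hit: np.ndarray, weight: float) -> float:
    w = np.abs(metric) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    total_hit = hit_w.sum()
    n_miss = (~is_hit).sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0
    running = np.cumsum(hit_w / total_hit - (~is_hit) / n_miss)
    return float(running[np.argmax(np.abs(running))])


def ko_signature(
    dataset: SingleCellKODataset, ko_gene: str, pseudocount: float = 0.01
) -> pd.Series:
    """Per-gene perturbation signature: KO-minus-control log2FC on the
    normalized scale, pseudocount-protected."""
    norm = dataset.normalized()
    ko_mean = norm[dataset.cells_of(ko_gene)].mean(axis=1)
    ctrl_mean = norm[dataset.cells_of(CONTROL)].mean(axis=1)
    return np.log2((ko_mean + pseudocount) / (ctrl_mean + pseudocount))


def transcriptome_rank(
    dataset: SingleCellKODataset, ko_gene: str, target: str
) -> float:
    """Rank of the target's |log2FC| among all genes, as top-% of the
    transcriptome (smaller = stronger). Ties break by gene id."""
    if target not in dataset.counts.index:
        raise KeyError(f"target {target!r} not in matrix")
    sig = ko_signature(dataset, ko_gene).abs()
    order = sorted(sig.index, key=lambda g: (-sig[g], g))
    rank = order.index(target) + 1
    return 100.0 * rank / len(order)


def hurdle_test(
    dataset: SingleCellKODataset,
    ko_gene: str,
    target: str,
    genes: list[str] | None = None,
) -> float:
    """Two-part hurdle test padj for the target, BH-adjusted across genes.

    Part 1 is a logistic model of detection ~ condition + CDR (cellular
    detection rate); part 2 a linear model of normalized expression among
    detected cells ~ condition + CDR. Likelihood-ratio chi-squares are
    summed with their degrees of freedom; a degenerate part (all/none
    detected, or too few detected cells) contributes nothing. ``genes``
    restricts the BH family (default: all genes detected in >= 1 cell).
    """
    table = hurdle_test_all(dataset, ko_gene, genes=genes)
    if target not in table.index:
        raise ValueError(f"hurdle test undefined for {target!r} (never detected)")
    return float(table.loc[target, "padj"])


def hurdle_test_all(
    dataset: SingleCellKODataset,
    ko_gene: str,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    ko_cells = dataset.cells_of(ko_gene)
    ctrl_cells = dataset.cells_of(CONTROL)
    if min(len(ko_cells), len(ctrl_cells)) < 20:
        raise ValueError("hurdle test needs >= 20 cells per condition")
    cells = ko_cells.append(ctrl_cells)
    counts = dataset.counts[cells]
    norm = dataset.normalized()[cells]
    cond = (dataset.ko_label.loc[cells] == ko_gene).to_numpy(float)
    cdr = (counts > 0).mean(axis=0).to_numpy(float)
    cdr = (cdr - cdr.mean()) / (cdr.std() or 1.0)

    candidates = list(dict.fromkeys(genes if genes is not None else counts.index))
    rows = []
    for g in candidates:
        y_det = (counts.loc[g] > 0).to_numpy(float)
        if y_det.sum() == 0:
            continue
        lr, df = 0.0, 0
        if 0 < y_det.sum() < len(y_det):
            lr1 = _logit_lr(y_det, cond, cdr)
            if lr1 is not None:
                lr += lr1
                df += 1
        det = y_det > 0
        if det.sum() >= 4 and len(np.unique(cond[det])) == 2:
            expr = norm.loc[g].to_numpy(float)[det]
            lr += _ols_lr(expr, cond[det], cdr[det])
            df += 1
        if df == 0:
            continue
        rows.append({"gene": g, "chi2": lr, "df": df,
                     "p": float(stats.chi2.sf(lr, df))})
    out = pd.DataFrame(rows).set_index("gene")
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def _logit_lr(y: np.ndarray, cond: np.ndarray, cdr: np.ndarray) -> float | None:
    import statsmodels.api as sm

    x1 = sm.add_constant(np.column_stack([cond, cdr]))
    x0 = sm.add_constant(cdr)
    try:
        with np.errstate(all="ignore"):
            fit1 = sm.Logit(y, x1).fit(disp=0, maxiter=100)
            fit0 = sm.Logit(y, x0).fit(disp=0, maxiter=100)
    except Exception:  # perfect separation / singular design
        return None
    lr = 2.0 * (fit1.llf - fit0.llf)
    return float(max(lr, 0.0)) if np.isfinite(lr) else None


def _ols_lr(y: np.ndarray, cond: np.ndarray, cdr: np.ndarray) -> float:
    import statsmodels.api as sm

    x1 = sm.add_constant(np.column_stack([cond, cdr]))
    x0 = sm.add_constant(cdr)
    fit1 = sm.OLS(y, x1).fit()
    fit0 = sm.OLS(y, x0).fit()
    return float(max(2.0 * (fit1.llf - fit0.llf), 0.0))


def mediator_network(
    de: pd.DataFrame,
    ppi: nx.Graph,
    ko_gene: str,
    target: str,
    min_combined: float = 400.0,
) -> tuple[str, list[str]]:
    """Class of the indirect mediator evidence linking KO to target.

    Mediators are genes significantly perturbed (padj < 0.05, excluding the
    KO gene and target themselves) with a PPI edge to the target. The class
    is "validated" if any mediator edge above the combined-score threshold
    carries experimental or database evidence, "predicted" for other
    above-threshold edges, "weak" for below-threshold associations, "none"
    otherwise. Returns (class, mediator genes).
    """
    sig = set(de.index[de["padj"] < 0.05]) - {ko_gene, target}
    if target not in ppi or not sig:
        return "none", []
    klass, mediators = "none", []
    order = {"none": 0, "weak": 1, "predicted": 2, "validated": 3}
    for g in sorted(sig):
        if not ppi.has_edge(g, target):
            continue
        d = ppi.edges[g, target]
        if d.get("combined_score", 0.0) > min_combined:
            this = (
                "validated"
                if d.get("experimental", 0.0) > 0 or d.get("database", 0.0) > 0
                else "predicted"
            )
        else:
            this = "weak"
        mediators.append(g)
        if order[this] > order[klass]:
            klass = this
    return klass, mediators


def global_perturbation(
    dataset: SingleCellKODataset,
    ko_gene: str,
    sd_floor_quantile: float = 0.10,
) -> float:
    """Mean |z| across genes, z = standardized mean difference with a floor.

    z is the KO-minus-control difference of normalized means divided by the
    pooled per-gene SD, floored at the ``sd_floor_quantile`` quantile of
    positive SDs so near-constant genes cannot blow up the statistic.
    """
    ko_cells = dataset.cells_of(ko_gene)
    ctrl_cells = dataset.cells_of(CONTROL)
    if len(ctrl_cells) < 2:
        raise ValueError("need >= 2 control cells")
    norm = dataset.normalized()
    a = norm[ko_cells].to_numpy(float)
    b = norm[ctrl_cells].to_numpy(float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    n1, n2 = a.shape[1], b.shape[1]
    pooled = np.sqrt(
        ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1))
        / (n1 + n2 - 2)
    )
    positive = pooled[pooled > 0]
    floor = float(np.quantile(positive, sd_floor_quantile)) if len(positive) else 1.0
    z = diff / np.maximum(pooled, max(floor, 1e-12))
    expressed = (a.sum(axis=1) + b.sum(axis=1)) > 0
    return float(np.mean(np.abs(z[expressed])))


def coexpression_disruption(
    dataset: SingleCellKODataset,
    ko_gene: str,
    target: str,
    min_cells: int = 20,
) -> float:
    """Delta rho = Spearman(KO cells) - Spearman(control cells).

    NaN (flagged missing, scoring 0) when either gene is constant within a
    condition.
    """
    norm = dataset.normalized()
    out = {}
    for label, cells in ((ko_gene, dataset.cells_of(ko_gene)),
                         (CONTROL, dataset.cells_of(CONTROL))):
        if len(cells) < min_cells:
            raise ValueError(f"condition {label!r} has < {min_cells} cells")
        x = norm.loc[ko_gene, cells].to_numpy(float)
        y = norm.loc[target, cells].to_numpy(float)
        if x.std() == 0 or y.std() == 0:
            logger.warning("constant gene in condition %s; delta rho missing", label)
            return float("nan")
        out[label], _ = stats.spearmanr(x, y)
    return float(out[ko_gene] - out[CONTROL])


# ---------------------------------------------------------------------------
# per-pair orchestration
# ---------------------------------------------------------------------------


def evidence_row(
    dataset: SingleCellKODataset,
    ko_gene: str,
    channel: str,
    ppi: nx.Graph | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    hurdle_genes: list[str] | None = None,
    n_perm_gsea: int = 500,
    seed: int = 0,
) -> EvidenceMatrixRow:
    """Compute all seven strategies for one KO -> channel pair.

    ``gene_sets`` maps set names to gene collections; S2 uses the set whose
    |NES| is largest (family/pathway panels). Strategies whose inputs are
    unavailable score 0 with the reason recorded in ``raw``.
    """
    raw: dict[str, object] = {}
    scores: dict[str, float] = {}

    try:
        de = pseudobulk_de(dataset, ko_gene)
        padj1 = float(de.loc[channel, "padj"]) if channel in de.index else np.nan
    except ValueError as e:
        de = None
        padj1 = np.nan
        raw["S1_note"] = str(e)
    raw["S1_padj"] = padj1
    scores["S1"] = score_s1(padj1)

    best = (0.0, 0.0, 1.0)
    if gene_sets:
        sig = ko_signature(dataset, ko_gene)
        for i, (name, gs) in enumerate(sorted(gene_sets.items())):
            try:
                es, nes, p = preranked_gsea(
                    sig, gs, n_perm=n_perm_gsea, seed=seed + i
                )
            except ValueError:
                continue
            if abs(nes) > abs(best[1]):
                best = (es, nes, p)
                raw["S2_set"] = name
    raw["S2_nes"], raw["S2_p"] = best[1], best[2]
    scores["S2"] = score_s2(best[1], best[2])

    top_pct = transcriptome_rank(dataset, ko_gene, channel)
    raw["S3_top_percent"] = top_pct
    scores["S3"] = score_s3(top_pct)

    try:
        padj4 = hurdle_test(dataset, ko_gene, channel, genes=hurdle_genes)
    except ValueError as e:
        padj4 = np.nan
        raw["S4_note"] = str(e)
    raw["S4_padj"] = padj4
    scores["S4"] = score_s4(padj4)

    if ppi is not None and de is not None:
        klass, mediators = mediator_network(de, ppi, ko_gene, channel)
        raw["S5_mediators"] = mediators
    else:
        klass = "none"
    raw["S5_class"] = klass
    scores["S5"] = score_s5(klass)

    mean_abs_z = global_perturbation(dataset, ko_gene)
    raw["S6_mean_abs_z"] = mean_abs_z
    scores["S6"] = score_s6(mean_abs_z)

    try:
        drho = coexpression_disruption(dataset, ko_gene, channel)
    except ValueError as e:
        drho = float("nan")
        raw["S7_note"] = str(e)
    raw["S7_delta_rho"] = drho
    scores["S7"] = score_s7(drho)

    return EvidenceMatrixRow(ko_gene=ko_gene, channel=channel, scores=scores, raw=raw)


def evidence_table(rows: list[EvidenceMatrixRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ko_gene": r.ko_gene, "channel": r.channel,
                **{k: r.scores.get(k, 0.0) for k in (f"S{i}" for i in range(1, 8))},
                "total": r.total, "class": r.strength_class,
            }
            for r in rows
        ]
    )
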