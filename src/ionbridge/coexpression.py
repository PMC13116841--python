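"""Weighted co-expression network, modules, and composite hub scoring.

Builds an unsigned soft-threshold adjacency |cor|^beta over the top-variance
genes, the topological overlap matrix (TOM), average-linkage modules on
1 - TOM with a static height cut, module eigengenes (first PC), a one-tailed
permutation module-trait test, and the composite hub score: the unweighted
mean of min-max-normalized gene significance (GS), module membership (MM)
and intramodular connectivity (kWithin). GS and MM are normalized globally
across the candidate set; kWithin within each module so large modules do
not dominate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .bulk_de import TUMOR, bh_adjust

logger = logging.getLogger(__name__)

UNASSIGNED = "grey"


@dataclass
class ModuleSet:
    """Gene -> module assignment with eigengenes and module-trait statistics."""

    assignment: pd.Series  # gene -> module label (UNASSIGNED if none)
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules
    trait_stats: pd.DataFrame = field(default_factory=pd.DataFrame)  # module -> r, p, q

    @property
    def modules(self) -> list[str]:
        labels = [m for m in self.assignment.unique() if m != UNASSIGNED]
        return sorted(labels, key=lambda m: (-(self.assignment == m).sum(), m))

    def genes_of(self, module: str) -> pd.Index:
        return self.assignment.index[self.assignment == module]


def select_top_variable(x: pd.DataFrame, v: int) -> pd.DataFrame:
    """Rows with the V largest variances; ties broken by gene id."""
    if v > x.shape[0]:
        raise ValueError("V exceeds the number of genes")
    var = x.var(axis=1, ddof=1)
    order = sorted(x.index, key=lambda g: (-var[g], g))
    return x.loc[order[:v]]


def soft_adjacency(x: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned adjacency a_ij = |Pearson cor(i, j)|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    mat = x.to_numpy(float)
    sd = mat.std(axis=1)
    if (sd == 0).any():
        warnings.warn("zero-variance genes: correlations set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(mat)
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=x.index, columns=x.index)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    Self-weights are zeroed internally; k is the row sum excluding the
    diagonal; TOM_ii = 1.
    """
    a = adjacency.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = 30,
    cut_height: float = 0.99,
    merge_r: float = 0.75,
    x: pd.DataFrame | None = None,
) -> ModuleSet:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    Clusters smaller than ``min_size`` are left unassigned. If the
    expression matrix ``x`` is given, modules whose eigengenes correlate
    above ``merge_r`` are merged iteratively. Labels are deterministic,
    ordered by decreasing module size ("M1" largest).
    """
    genes = tom.index
    order = np.argsort(genes)  # gene-order invariance
    ordered = genes[order]
    diss = 1.0 - tom.iloc[order, order].to_numpy(float)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=ordered, dtype=object)
    clusters = [
        ordered[raw == c] for c in np.unique(raw) if (raw == c).sum() >= min_size
    ]
    if not clusters:
        raise ValueError(
            "all genes unassigned; lower min_size or raise cut_height"
        )
    clusters.sort(key=lambda idx: (-len(idx), idx[0]))
    for i, idx in enumerate(clusters):
        labels[idx] = f"M{i + 1}"

    if x is not None and len(clusters) > 1:
        labels = _merge_correlated(labels, x, merge_r)
    return ModuleSet(assignment=labels.loc[sorted(genes)])


def _merge_correlated(labels: pd.Series, x: pd.DataFrame, merge_r: float) -> pd.Series:
    while True:
        mods = [m for m in labels.unique() if m != UNASSIGNED]
        if len(mods) < 2:
            break
        eig = {m: module_eigengene(x, labels.index[labels == m]) for m in mods}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                r = float(np.corrcoef(eig[a], eig[b])[0, 1])
                if r > merge_r and (best is None or r > best[0]):
                    best = (r, a, b)
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a
    # relabel deterministically by size
    mods = sorted(
        (m for m in labels.unique() if m != UNASSIGNED),
        key=lambda m: (-(labels == m).sum(), m),
    )
    rename = {m: f"M{i + 1}" for i, m in enumerate(mods)}
    return labels.map(lambda m: rename.get(m, UNASSIGNED))


def module_eigengene(x: pd.DataFrame, module_genes: pd.Index) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Unit variance, sign fixed so the eigengene correlates nonnegatively
    with mean module expression.
    """
    if len(module_genes) == 0:
        raise ValueError("module is empty")
    if x.shape[1] < 2:
        raise ValueError("eigengene needs >= 2 samples")
    sub = x.loc[module_genes].to_numpy(float)
    sd = sub.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    mean_expr = z.mean(axis=0)
    if mean_expr.std() > 0 and np.corrcoef(pc, mean_expr)[0, 1] < 0:
        pc = -pc
    pc = pc / pc.std(ddof=1)
    return pd.Series(pc, index=x.columns, name="eigengene")


def module_trait_permutation(
    eigengene: pd.Series,
    trait: pd.Series,
    b: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-tailed permutation test of Pearson(eigengene, trait as 0/1).

    p = (1 + #{permuted r >= observed r}) / (B + 1); ties count toward the
    numerator, so p is always positive and the test valid.
    """
    if b < 1:
        raise ValueError("B must be >= 1")
    y = (trait.loc[eigengene.index] == TUMOR).to_numpy(float)
    if y.std() == 0:
        raise ValueError("trait is constant")
    e = eigengene.to_numpy(float)
    r_obs = float(np.corrcoef(e, y)[0, 1])
    rng = np.random.default_rng(seed)
    ez = (e - e.mean()) / e.std()
    yz = (y - y.mean()) / y.std()
    n = len(e)
    perms = np.empty(b)
    for i in range(b):
        perms[i] = ez @ rng.permutation(yz) / n
    p = (1.0 + np.sum(perms >= r_obs - 1e-12)) / (b + 1.0)
    return r_obs, float(p)


def module_trait_stats(
    module_set: ModuleSet,
    x: pd.DataFrame,
    trait: pd.Series,
    b: int = 10000,
    seed: int = 0,
) -> ModuleSet:
    """Eigengenes plus (r, permutation p, BH q) for every module."""
    mods = module_set.modules
    eig = pd.DataFrame(
        {m: module_eigengene(x, module_set.genes_of(m)) for m in mods}
    )
    rows = []
    for i, m in enumerate(mods):
        r, p = module_trait_permutation(eig[m], trait, b=b, seed=seed + i)
        rows.append({"module": m, "r": r, "p": p})
    stats = pd.DataFrame(rows).set_index("module")
    stats["q"] = bh_adjust(stats["p"].to_numpy()) if len(stats) else []
    return ModuleSet(assignment=module_set.assignment, eigengenes=eig, trait_stats=stats)


def _minmax(v: pd.Series) -> pd.Series:
    lo, hi = v.min(), v.max()
    if len(v) == 1:
        return pd.Series(0.0, index=v.index)
    if hi == lo:
        return pd.Series(0.5, index=v.index)  # midpoint when min == max
    return (v - lo) / (hi - lo)


def hub_scores(
    x: pd.DataFrame,
    trait: pd.Series,
    module_set: ModuleSet,
    tom: pd.DataFrame,
) -> pd.DataFrame:
    """GS/MM/kWithin with their normalizations and the composite score.

    Candidates are the genes in assigned modules. GS and MM norms are
    global min-max over candidates; kWithin is min-max within its module
    (singleton modules score 0). composite = mean of the three norms.
    """
    y = (trait.loc[x.columns] == TUMOR).to_numpy(float)
    rows = []
    for m in module_set.modules:
        genes = module_set.genes_of(m)
        eig = module_set.eigengenes[m].to_numpy(float)
        sub_tom = tom.loc[genes, genes].to_numpy(float).copy()
        np.fill_diagonal(sub_tom, 0.0)
        kwithin = sub_tom.sum(axis=1)
        expr = x.loc[genes].to_numpy(float)
        for j, g in enumerate(genes):
            e = expr[j]
            gs = float(np.corrcoef(e, y)[0, 1]) if e.std() > 0 else 0.0
            mm = float(np.corrcoef(e, eig)[0, 1]) if e.std() > 0 else 0.0
            rows.append(
                {"gene": g, "module": m, "GS": gs, "MM": mm, "kWithin": kwithin[j]}
            )
    table = pd.DataFrame(rows).set_index("gene")
    if table.empty:
        return table
    table["GSnorm"] = _minmax(table["GS"])
    table["MMnorm"] = _minmax(table["MM"])
    kn = pd.Series(0.0, index=table.index)
    for m in module_set.modules:
        idx = table.index[table["module"] == m]
        if len(idx) == 1:
            kn[idx] = 0.0
        else:
            kn[idx] = _minmax(table.loc[idx, "kWithin"])
    table["kWithinnorm"] = kn
    table["composite"] = (
        table["GSnorm"] + table["MMnorm"] + table["kWithinnorm"]
    ) / 3.0
    return table


def select_hub_genes(
    scores: pd.DataFrame,
    trait_stats: pd.DataFrame,
    top_n: int = 100,
    q_threshold: float | None = 0.05,
    top_k_modules: int | None = None,
    include: list[str] | None = None,
) -> list[str]:
    """Top-N hub genes by composite score from trait-associated modules.

    Genes must have GS > 0 and come from a selected module: either modules
    with q < ``q_threshold`` (default) or the ``top_k_modules`` by
    correlation strength. ``include`` forces externally validated genes into
    the list ahead of the ranking. Ties break lexicographically by gene id.
    """
    if top_k_modules is not None:
        chosen = (
            trait_stats.sort_values(["r", "p"], ascending=[False, True])
            .head(top_k_modules)
            .index
        )
    elif q_threshold is not None:
        chosen = trait_stats.index[trait_stats["q"] < q_threshold]
    else:
        chosen = trait_stats.index
    pool = scores[(scores["module"].isin(chosen)) & (scores["GS"] > 0)]
    if pool.empty:
        warnings.warn("empty hub candidate set", stacklevel=2)
        return list(include or [])
    ranked = sorted(pool.index, key=lambda g: (-pool.loc[g, "composite"], g))
    forced = [g for g in (include or []) if g in scores.index]
    ranked = forced + [g for g in ranked if g not in forced]
    if len(ranked) < top_n:
        warnings.warn(
            f"only {len(ranked)} hub candidates available (requested {top_n})",
            stacklevel=2,
        )
    return ranked[:top_n]
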