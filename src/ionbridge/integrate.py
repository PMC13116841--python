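"""Composite validation scoring, quadrant classification and orchestration.

The two perturbation modalities are combined per hub -> channel pair as

    composite = 0.6 * (evidence-matrix total / 21)
              + 0.4 * (mean virtual-KO percentile / 100)

and each pair is placed in a validation-by-druggability quadrant
(Discovery Opportunity / Target Development / Need Further Validation /
Low Priority). ``run_pipeline`` drives the whole analysis end-to-end on a
self-generated synthetic study, writing a TSV/JSON artifact per stage plus
a manifest with the config hash and all seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bridge as br
from . import bulk_de as de
from . import coexpression as coex
from . import druggability as drug
from . import evidence as ev
from . import io as ioh
from . import synthetic as syn
from . import vgae

logger = logging.getLogger(__name__)

QUADRANTS = (
    "Discovery Opportunity",
    "Target Development",
    "Need Further Validation",
    "Low Priority",
)


def composite_score(
    perturbseq_total: float,
    vgae_percentiles: list[float] | tuple[float, ...],
) -> tuple[float, bool]:
    """0.6 * (total/21) + 0.4 * (mean percentile/100); returns (score, partial).

    With no percentile available the Perturb-seq term alone is returned and
    the result flagged partial.
    """
    if not 0 <= perturbseq_total <= 21:
        raise ValueError("perturbseq_total must lie in [0, 21]")
    pcts = [p for p in vgae_percentiles if p is not None and not np.isnan(p)]
    if any(not 0 <= p <= 100 for p in pcts):
        raise ValueError("percentiles must lie in [0, 100]")
    term1 = 0.6 * (perturbseq_total / 21.0)
    if not pcts:
        return term1, True
    return term1 + 0.4 * (float(np.mean(pcts)) / 100.0), False


def quadrant(
    validation: float,
    drug_score: float,
    v_threshold: float = 0.5,
    d_threshold: float = 0.5,
) -> str:
    """2x2 classification; X = validation, Y = druggability, strict >.

    Values exactly at a threshold fall to the lower/left cell.
    """
    if not (0 < v_threshold < 1 and 0 < d_threshold < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    high_v = validation > v_threshold
    high_d = drug_score > d_threshold
    if high_v and high_d:
        return "Discovery Opportunity"
    if high_v:
        return "Target Development"
    if high_d:
        return "Need Further Validation"
    return "Low Priority"


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

STAGES = ("de", "hub", "drugscore", "bridges", "evidence", "vgae_ko", "integrate")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "results/demo",
    "stages": list(STAGES),
    "bulk": {
        "n_genes": 1500, "n_tumor": 30, "n_normal": 30, "n_batches": 2,
        "n_modules": 4, "module_sizes": [200, 150, 100, 80],
        "module_trait_effect": [0.9, 0.7, 0.0, 0.0],
    },
    "channels": {
        # curated universe: gene id -> family; log2FCs come from the DE stage
        "G01401": "K+", "G01402": "Cl-", "G01403": "Glu", "G01404": "RyR",
        "G01405": "GABA", "G01406": "AQP",
    },
    "channel_lfc": 1.0,  # planted up-regulation of channel genes (one planted down)
    "de": {"fdr": 0.05, "fc": 1.5},
    "hub": {"top_variable": 400, "top_n": 40, "perms": 500,
            "beta": 6.0, "min_size": 30, "cut_height": 0.99},
    "ppi": {"n_background_genes": 40, "noise_edges": 60, "min_score": 400},
    "perturb": {"n_cells_per_group": 250, "n_genes": 1500, "n_batches": 6,
                "knockdown_fraction": 0.9, "mediator_lfc": 1.5,
                "rho_control": 0.5, "rho_ko": 0.2},
    "evidence": {"n_perm_gsea": 300, "hurdle_panel": 120},
    "vgae_ko": {"top_variable": 150, "k": 8, "epochs": 100,
                "bagging_perms": 20, "n_controls": 30},
    "integrate": {"v_threshold": 0.5, "d_threshold": 0.5},
}


_REPLACE_KEYS = {"channels"}  # data mappings are replaced, not deep-merged


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if (
            isinstance(v, dict)
            and isinstance(out.get(k), dict)
            and k not in _REPLACE_KEYS
        ):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None, **overrides) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        cfg = _merge(cfg, yaml.safe_load(Path(path).read_text()) or {})
    return _merge(cfg, overrides)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _require(out: Path, stage: str, *files: str) -> None:
    missing = [f for f in files if not (out / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage '{stage}' needs upstream artifact(s) {missing}; "
            "run the producing stage first"
        )


def run_pipeline(config: dict | None = None, **overrides) -> dict:
    """Run the staged pipeline (or any contiguous suffix) on synthetic data.

    Stages: de -> hub -> drugscore -> bridges -> evidence -> vgae_ko ->
    integrate. Each stage writes its artifacts under ``outdir`` and later
    stages reload them from disk, so a rerun with a subset of stages resumes
    from cached outputs. Returns a manifest dict (also written as
    manifest.json) with the config hash, per-stage seeds, timings and record
    counts.
    """
    cfg = _merge(config or DEFAULT_CONFIG, overrides)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "config_hash": _config_hash({k: v for k, v in cfg.items() if k != "outdir"}),
        "seed": seed,
        "stages": {},
    }
    for stage in cfg["stages"]:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; valid: {STAGES}")
        t0 = time.perf_counter()
        counts = _STAGE_FUNCS[stage](cfg, out, _stage_seed(seed, stage))
        manifest["stages"][stage] = {
            "seed": _stage_seed(seed, stage),
            "seconds": round(time.perf_counter() - t0, 2),
            "records": counts,
        }
    ioh.write_json(manifest, out / "manifest.json")
    return manifest


def _stage_de(cfg: dict, out: Path, seed: int) -> int:
    bulk_cfg = dict(cfg["bulk"])
    channels = cfg["channels"]
    de_genes = [(g, cfg["channel_lfc"]) for g in list(channels)[:-1]]
    de_genes.append((list(channels)[-1], -1.0))  # one down-regulated channel
    spec = syn.BulkSimSpec(
        **{k: tuple(v) if isinstance(v, list) else v for k, v in bulk_cfg.items()},
        de_genes=tuple(de_genes),
        seed=seed,
    )
    cohort, truth = syn.generate_bulk_cohort(spec)
    ioh.write_cohort(cohort, out / "cohort")
    ioh.write_tsv(truth, out / "bulk_truth.tsv")
    norm = de.cpm_log_normalize(cohort.counts)
    corrected = de.batch_correct(norm, cohort.batch, cohort.condition)
    ioh.write_tsv(corrected, out / "corrected.tsv")
    result = de.welch_de(corrected, cohort.condition,
                         fdr=cfg["de"]["fdr"], fc=cfg["de"]["fc"])
    ioh.write_tsv(result.table, out / "de.tsv")
    return int(result.table["is_DEG"].sum())


def _stage_hub(cfg: dict, out: Path, seed: int) -> int:
    _require(out, "hub", "corrected.tsv", "cohort.meta.tsv")
    x = ioh.read_tsv(out / "corrected.tsv")
    meta = ioh.read_tsv(out / "cohort.meta.tsv")
    hub_cfg = cfg["hub"]
    top = coex.select_top_variable(x, hub_cfg["top_variable"])
    adj = coex.soft_adjacency(top, beta=hub_cfg["beta"])
    tom = coex.topological_overlap(adj)
    modules = coex.detect_modules(
        tom, min_size=hub_cfg["min_size"], cut_height=hub_cfg["cut_height"], x=top
    )
    modules = coex.module_trait_stats(
        modules, top, meta["condition"], b=hub_cfg["perms"], seed=seed
    )
    scores = coex.hub_scores(top, meta["condition"], modules, tom)
    hubs = coex.select_hub_genes(scores, modules.trait_stats, top_n=hub_cfg["top_n"])
    ioh.write_tsv(modules.assignment.to_frame("module"), out / "modules.tsv")
    ioh.write_tsv(modules.trait_stats, out / "trait_stats.tsv")
    ioh.write_tsv(scores, out / "hub_scores.tsv")
    (out / "hubs.txt").write_text("\n".join(hubs) + "\n")
    return len(hubs)


def _stage_drugscore(cfg: dict, out: Path, seed: int) -> int:
    _require(out, "drugscore", "hubs.txt")
    hubs = (out / "hubs.txt").read_text().split()
    tiers = {}
    tier_cycle = list(drug.TIERS)
    for i, g in enumerate(hubs):
        tiers[g] = tier_cycle[i % len(tier_cycle)]
    records = syn.generate_drug_evidence(hubs, tiers, seed=seed)
    # curated exclusion flags on two approved-tier genes
    approved = [r for r in records if r.approved_drugs_n > 0]
    if len(approved) >= 2:
        approved[0].immune_direction = "suppressive"
        approved[1].promotes_tumor_suppressor_channel = True
    ioh.write_drug_evidence(records, out / "drug_evidence.json")
    scores = [drug.drug_evidence_score(r) for r in records]
    candidates, log = drug.repurposing_filter(scores, {r.gene: r for r in records})
    ioh.write_tsv(drug.scores_table(scores), out / "drug_scores.tsv")
    ioh.write_tsv(log, out / "exclusions.tsv", index=False)
    return len(candidates)


def _stage_bridges(cfg: dict, out: Path, seed: int) -> int:
    _require(out, "bridges", "hubs.txt", "de.tsv")
    hubs = (out / "hubs.txt").read_text().split()
    de_table = ioh.read_tsv(out / "de.tsv")
    universe = br.IonChannelUniverse(
        families=pd.Series(cfg["channels"], name="family")
    )
    top2 = hubs[:2]
    # planted intermediate: a gene guaranteed to exist in both the bulk and
    # the single-cell universes, clear of the channel block
    shared_n = min(cfg["bulk"]["n_genes"], cfg["perturb"]["n_genes"])
    intermediate = f"G{shared_n - 199:05d}"
    paths = (
        syn.PlantedPath(
            hub=top2[0], channel=list(cfg["channels"])[0],
            edge_scores=({"experimental": 500.0, "combined": 666.0},),
        ),
        syn.PlantedPath(
            hub=top2[1], channel=list(cfg["channels"])[1],
            intermediates=(intermediate,),
            edge_scores=(
                {"textmining": 700.0, "combined": 700.0},
                {"database": 400.0, "combined": 520.0},
            ),
        ),
    )
    ppi_cfg = cfg["ppi"]
    graph = syn.generate_ppi_graph(
        syn.PPISimSpec(
            n_background_genes=ppi_cfg["n_background_genes"],
            planted_paths=paths, noise_edges=ppi_cfg["noise_edges"], seed=seed,
        )
    )
    ioh.write_ppi(graph, out / "ppi_edges.tsv")
    eligible = br.filter_channels(universe, de_table["log2FC"])
    found = br.find_bridge_paths(
        graph, hubs, eligible, min_score=ppi_cfg["min_score"]
    )
    table = br.bridge_table(found, universe)
    ioh.write_tsv(table, out / "bridges.tsv", index=False)
    ioh.write_tsv(
        pd.Series(cfg["channels"], name="family").rename_axis("gene").to_frame(),
        out / "channel_universe.tsv",
    )
    return len(found)


def _load_bridge_pairs(out: Path) -> list[tuple[str, str, tuple[str, ...]]]:
    table = pd.read_csv(out / "bridges.tsv", sep="\t")
    pairs = []
    for _, row in table.iterrows():
        nodes = tuple(row["path"].split(" -> "))
        pairs.append((row["hub"], row["channel"], nodes))
    return pairs


def _stage_evidence(cfg: dict, out: Path, seed: int) -> int:
    _require(out, "evidence", "bridges.tsv", "ppi_edges.tsv")
    pairs = _load_bridge_pairs(out)
    p_cfg = cfg["perturb"]
    ko_genes = tuple(dict.fromkeys(h for h, _, _ in pairs))
    mediators = tuple(
        (h, nodes[1], p_cfg["mediator_lfc"])
        for h, _, nodes in pairs if len(nodes) > 2
    )
    coexpr = tuple(
        (h, c, p_cfg["rho_control"], p_cfg["rho_ko"]) for h, c, _ in pairs
    )
    spec = syn.PerturbSimSpec(
        n_cells_per_group=p_cfg["n_cells_per_group"],
        n_genes=p_cfg["n_genes"],
        ko_genes=ko_genes,
        knockdown_fraction=p_cfg["knockdown_fraction"],
        mediator_effects=mediators,
        coexpr_pairs=coexpr,
        n_batches=p_cfg["n_batches"],
        seed=seed,
    )
    dataset, sc_truth = syn.generate_perturbseq(spec)
    ioh.write_sc_dataset(dataset, out / "perturbseq")
    ioh.write_tsv(sc_truth, out / "perturb_truth.tsv", index=False)
    ppi = ioh.read_ppi(out / "ppi_edges.tsv")
    gene_sets = {"channel_panel": set(cfg["channels"])}
    rng = np.random.default_rng(seed)
    panel_n = cfg["evidence"]["hurdle_panel"]
    rows = []
    for i, (hub, channel, _) in enumerate(pairs):
        panel = sorted(
            set(rng.choice(dataset.counts.index, size=panel_n, replace=False))
            | {channel}
        )
        rows.append(
            ev.evidence_row(
                dataset, hub, channel, ppi=ppi, gene_sets=gene_sets,
                hurdle_genes=panel,
                n_perm_gsea=cfg["evidence"]["n_perm_gsea"], seed=seed + i,
            )
        )
    ioh.write_tsv(ev.evidence_table(rows), out / "evidence_matrix.tsv", index=False)
    ioh.write_json(
        [{"ko_gene": r.ko_gene, "channel": r.channel, "raw": r.raw} for r in rows],
        out / "evidence_detail.json",
    )
    return len(rows)


def _stage_vgae(cfg: dict, out: Path, seed: int) -> int:
    _require(out, "vgae_ko", "bridges.tsv", "perturbseq.mtx")
    pairs = _load_bridge_pairs(out)
    dataset = ioh.read_sc_dataset(out / "perturbseq")
    v_cfg = cfg["vgae_ko"]
    norm = vgae.normalize_counts(dataset.counts)
    required = sorted({g for _, _, nodes in pairs for g in nodes})
    graph = vgae.build_grn(
        norm, v=v_cfg["top_variable"], k=v_cfg["k"],
        required_genes=required, seed=seed,
    )
    model, wt = vgae.train_vgae(
        graph, vgae.VGAEConfig(epochs=v_cfg["epochs"]), seed=seed
    )
    hubs = sorted({h for h, _, _ in pairs})
    hub_kl = {h: vgae.kl_per_gene(wt, vgae.virtual_ko(model, graph, h)) for h in hubs}
    rows, bagging_all = [], {}
    for hub, channel, nodes in pairs:
        ranked = vgae.rank_and_percentile(hub_kl[hub])
        boot = vgae.bagging_consistency(
            model, graph, norm, hub, list(nodes[1:]),
            n_perm=v_cfg["bagging_perms"], seed=seed,
        )
        bagging_all[(hub, channel)] = boot
        status, validated = vgae.classify_validation({"synthetic": boot}, nodes)
        rows.append({
            "hub": hub, "channel": channel,
            "percentile": float(ranked.loc[channel, "percentile"]),
            "bootstrap_pct": float(boot[channel]),
            "status": status,
            "validated_genes": ";".join(g for g, _ in validated),
        })
    control = vgae.negative_control(
        model, graph, wt, hub_kl,
        pairs={h: [c] for h, c, _ in pairs},
        n_controls=v_cfg["n_controls"], seed=seed,
    )
    ioh.write_tsv(pd.DataFrame(rows), out / "vgae_ko.tsv", index=False)
    ioh.write_json(
        {
            "seed": seed,
            "control_genes": control.control_genes,
            "u_statistic": control.u_statistic,
            "p_value": control.p_value,
            "median_fold_change": control.median_fold_change,
            "pair_percentiles": control.pair_percentiles.to_dict("records"),
            "model_weights_sha256": model.weights_hash(),
        },
        out / "vgae_control.json",
    )
    return len(rows)


def _stage_integrate(cfg: dict, out: Path, seed: int) -> int:
    _require(out, "integrate", "evidence_matrix.tsv", "vgae_ko.tsv",
             "drug_scores.tsv")
    evm = pd.read_csv(out / "evidence_matrix.tsv", sep="\t")
    vk = pd.read_csv(out / "vgae_ko.tsv", sep="\t")
    drugs = ioh.read_tsv(out / "drug_scores.tsv")
    rows = []
    for _, row in evm.iterrows():
        hub, channel = row["ko_gene"], row["channel"]
        pcts = vk.loc[
            (vk["hub"] == hub) & (vk["channel"] == channel), "percentile"
        ].tolist()
        comp, partial = composite_score(row["total"], pcts)
        d = float(drugs.loc[hub, "total"]) if hub in drugs.index else 0.0
        rows.append({
            "hub": hub, "channel": channel, "perturbseq_total": row["total"],
            "mean_vgae_percentile": float(np.mean(pcts)) if pcts else np.nan,
            "composite": comp, "partial": partial, "drug_score": d,
            "quadrant": quadrant(
                comp, d,
                v_threshold=cfg["integrate"]["v_threshold"],
                d_threshold=cfg["integrate"]["d_threshold"],
            ),
        })
    ioh.write_tsv(pd.DataFrame(rows), out / "composite.tsv", index=False)
    return len(rows)


_STAGE_FUNCS = {
    "de": _stage_de,
    "hub": _stage_hub,
    "drugscore": _stage_drugscore,
    "bridges": _stage_bridges,
    "evidence": _stage_evidence,
    "vgae_ko": _stage_vgae,
    "integrate": _stage_integrate,
}
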