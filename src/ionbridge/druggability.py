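"""Drug-evidence scoring, target tiers and repurposing exclusion rules.

Each gene's evidence record is condensed into four component scores in
[0, 1] and a weighted total:

    DrugEvidenceScore = 0.50*S_phase + 0.25*S_tract + 0.15*S_DGIdb + 0.10*S_ChEMBL

S_phase is 1 for any approved drug, else max_phase/4. S_tract maps
tractability labels by case-insensitive substring with precedence
approved/clinical > phase > structure/high > medium/predicted > low, taking
the maximum over labels. S_DGIdb = log(1+n)/log(31) capped at 1, and
S_ChEMBL is the same transform applied to the larger of the mechanism and
molecule counts. Immune direction and tumor-suppressor-channel promotion
are curated annotations, never inferred from the evidence itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

TIERS = (
    "ApprovedTarget",
    "LateClinicalTarget",
    "EarlyClinicalTarget",
    "Tractable (Structure/High)",
    "Tractable (Predicted)",
    "Unknown",
)

WEIGHTS = {"phase": 0.50, "tract": 0.25, "dgidb": 0.15, "chembl": 0.10}

# (patterns, score) in precedence order; first matching row wins per label
_TRACT_TABLE = (
    (("approved", "clinical"), 1.0),
    (("phase",), 0.8),
    (("structure", "high"), 0.6),
    (("medium", "predicted"), 0.4),
    (("low",), 0.2),
)

_LOG_CAP = math.log(31.0)  # empirical cap of 30 drugs -> score 1.0


@dataclass
class DrugEvidenceRecord:
    """Per-gene drug evidence snapshot (OpenTargets/DGIdb/ChEMBL-like fields)."""

    gene: str
    approved_drugs_n: int = 0
    max_phase: int = 0
    tractability_labels: list[str] = field(default_factory=list)
    dgidb_drug_count: int = 0
    chembl_mechanisms_n: int = 0
    chembl_molecules_n: int = 0
    drug_names: list[str] = field(default_factory=list)
    immune_direction: str = "n/a"  # enhancing | suppressive | n/a
    promotes_tumor_suppressor_channel: bool = False

    def __post_init__(self) -> None:
        for name in ("approved_drugs_n", "dgidb_drug_count",
                     "chembl_mechanisms_n", "chembl_molecules_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.max_phase not in (0, 1, 2, 3, 4):
            raise ValueError("max_phase must be in 0..4")


@dataclass
class DrugScore:
    gene: str
    s_phase: float
    s_tract: float
    s_dgidb: float
    s_chembl: float
    total: float
    tier: str
    druggable: bool
    repurposing_candidate: bool = False
    exclusion_reasons: list[str] = field(default_factory=list)


def phase_score(record: DrugEvidenceRecord) -> float:
    """1.0 with any approved drug, otherwise max_phase / 4."""
    if record.approved_drugs_n > 0:
        return 1.0
    return record.max_phase / 4.0


def tractability_score(labels: list[str]) -> float:
    """Maximum pattern-matched score across labels; empty list scores 0."""
    best = 0.0
    for label in labels:
        low = label.lower()
        for patterns, score in _TRACT_TABLE:
            if any(p in low for p in patterns):
                best = max(best, score)
                break
    return best


def dgidb_score(n_drugs: int) -> float:
    """log(1+n)/log(31), clipped to 1 above the 30-drug cap."""
    if n_drugs < 0:
        raise ValueError("n_drugs must be nonnegative")
    return min(1.0, math.log1p(n_drugs) / _LOG_CAP)


def chembl_score(n_mechanisms: int, n_molecules: int) -> float:
    """max of the two log-normalized counts, clipped to 1."""
    if n_mechanisms < 0 or n_molecules < 0:
        raise ValueError("counts must be nonnegative")
    return min(1.0, max(math.log1p(n_mechanisms), math.log1p(n_molecules)) / _LOG_CAP)


def assign_tier(record: DrugEvidenceRecord, s_tract: float | None = None) -> str:
    """First matching tier: Approved > LateClinical > EarlyClinical >
    Tractable (Structure/High) > Tractable (Predicted) > Unknown."""
    if s_tract is None:
        s_tract = tractability_score(record.tractability_labels)
    if record.approved_drugs_n > 0:
        return "ApprovedTarget"
    if record.max_phase >= 3:
        return "LateClinicalTarget"
    if record.max_phase in (1, 2):
        return "EarlyClinicalTarget"
    if s_tract >= 0.6:
        return "Tractable (Structure/High)"
    if s_tract > 0:
        return "Tractable (Predicted)"
    return "Unknown"


def drug_evidence_score(record: DrugEvidenceRecord) -> DrugScore:
    """Component scores, weighted total, tier and the druggable flag.

    A gene is druggable if it has approved drugs (OpenTargets-style
    evidence) or candidate compounds (DGIdb).
    """
    s_p = phase_score(record)
    s_t = tractability_score(record.tractability_labels)
    s_d = dgidb_score(record.dgidb_drug_count)
    s_c = chembl_score(record.chembl_mechanisms_n, record.chembl_molecules_n)
    total = (
        WEIGHTS["phase"] * s_p
        + WEIGHTS["tract"] * s_t
        + WEIGHTS["dgidb"] * s_d
        + WEIGHTS["chembl"] * s_c
    )
    return DrugScore(
        gene=record.gene,
        s_phase=s_p,
        s_tract=s_t,
        s_dgidb=s_d,
        s_chembl=s_c,
        total=total,
        tier=assign_tier(record, s_t),
        druggable=record.approved_drugs_n > 0 or record.dgidb_drug_count > 0,
    )


def repurposing_filter(
    scores: list[DrugScore],
    records: dict[str, DrugEvidenceRecord],
) -> tuple[list[DrugScore], pd.DataFrame]:
    """Druggable genes minus curated exclusions, with an exclusion log.

    Excludes genes whose agents are immunosuppressive and genes promoting a
    flagged tumor-suppressor ion channel; a gene flagged both ways is
    excluded once with both reasons logged. Genes without a record are
    retained with an "unannotated" warning entry.
    """
    candidates: list[DrugScore] = []
    log_rows: list[dict[str, str]] = []
    for score in scores:
        if not score.druggable:
            continue
        rec = records.get(score.gene)
        reasons = []
        if rec is None:
            log_rows.append({"gene": score.gene, "action": "retained",
                             "reason": "unannotated"})
            logger.warning("gene %s retained without annotation", score.gene)
        else:
            if rec.immune_direction == "suppressive":
                reasons.append("immunosuppressive agent")
            if rec.promotes_tumor_suppressor_channel:
                reasons.append("promotes tumor suppressor ion channel")
        if reasons:
            score.repurposing_candidate = False
            score.exclusion_reasons = reasons
            log_rows.extend(
                {"gene": score.gene, "action": "excluded", "reason": r} for r in reasons
            )
        else:
            score.repurposing_candidate = True
            candidates.append(score)
    log = pd.DataFrame(log_rows, columns=["gene", "action", "reason"])
    return candidates, log


def scores_table(scores: list[DrugScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene, "S_phase": s.s_phase, "S_tract": s.s_tract,
                "S_dgidb": s.s_dgidb, "S_chembl": s.s_chembl, "total": s.total,
                "tier": s.tier, "druggable": s.druggable,
                "repurposing_candidate": s.repurposing_candidate,
                "exclusion_reason": "; ".join(s.exclusion_reasons),
            }
            for s in scores
        ]
    ).set_index("gene")
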