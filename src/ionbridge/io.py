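"""Readers and writers for the pipeline's on-disk formats.

All tables are tab-delimited UTF-8 with a header row. Count matrices can be
round-tripped either as dense TSV (genes x samples) or MatrixMarket MTX
with gene/cell sidecar TSVs. Drug-evidence records are JSON, one object per
gene.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .bulk_de import BulkCohort
from .druggability import DrugEvidenceRecord
from .evidence import SingleCellKODataset
from .synthetic import CHANNELS


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_cohort(cohort: BulkCohort, prefix: str | Path) -> None:
    prefix = Path(prefix)
    write_tsv(cohort.counts, prefix.with_suffix(".counts.tsv"))
    meta = pd.DataFrame({"condition": cohort.condition, "batch": cohort.batch})
    meta.index.name = "sample"
    write_tsv(meta, prefix.with_suffix(".meta.tsv"))


def read_cohort(prefix: str | Path) -> BulkCohort:
    prefix = Path(prefix)
    counts = read_tsv(prefix.with_suffix(".counts.tsv"))
    meta = read_tsv(prefix.with_suffix(".meta.tsv"))
    return BulkCohort(
        counts=counts, condition=meta["condition"], batch=meta["batch"]
    )


def write_sc_dataset(ds: SingleCellKODataset, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(ds.counts.to_numpy())
    spio.mmwrite(str(prefix.with_suffix(".mtx")), mat)
    pd.Series(ds.counts.index, name="gene").to_csv(
        prefix.with_suffix(".genes.tsv"), sep="\t", index=False
    )
    meta = pd.DataFrame({"ko_gene": ds.ko_label, "batch": ds.batch})
    meta.index.name = "cell"
    write_tsv(meta, prefix.with_suffix(".cells.tsv"))


def read_sc_dataset(prefix: str | Path) -> SingleCellKODataset:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).tocsr().toarray()
    genes = pd.read_csv(prefix.with_suffix(".genes.tsv"), sep="\t")["gene"]
    meta = read_tsv(prefix.with_suffix(".cells.tsv"))
    counts = pd.DataFrame(
        np.asarray(mat, dtype=np.int64), index=pd.Index(genes, name="gene"),
        columns=meta.index,
    )
    return SingleCellKODataset(
        counts=counts, ko_label=meta["ko_gene"], batch=meta["batch"]
    )


def write_ppi(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "protein1": a, "protein2": b,
            **{ch: d.get(ch, 0.0) for ch in CHANNELS},
            "combined_score": d["combined_score"],
        }
        for a, b, d in graph.edges(data=True)
    ]
    write_tsv(pd.DataFrame(rows), path, index=False)


def read_ppi(path: str | Path) -> nx.Graph:
    table = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in table.iterrows():
        attrs = {ch: float(row.get(ch, 0.0)) for ch in CHANNELS}
        attrs["combined_score"] = float(row["combined_score"])
        g.add_edge(str(row["protein1"]), str(row["protein2"]), **attrs)
    return g


def write_drug_evidence(records: list[DrugEvidenceRecord], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = [dataclasses.asdict(r) for r in records]
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_drug_evidence(path: str | Path) -> list[DrugEvidenceRecord]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [DrugEvidenceRecord(**item) for item in payload]


def write_json(obj: object, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o: object) -> object:
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default), encoding="utf-8")
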