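"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from ionbridge import bulk_de as bde
from ionbridge import evidence as ev
from ionbridge import synthetic as syn


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def small_bulk():
    """Two-module cohort, 20v20, one planted DE gene (log2FC 2.0)."""
    spec = syn.BulkSimSpec(
        n_genes=300, n_tumor=20, n_normal=20, n_batches=2,
        n_modules=2, module_sizes=(40, 30), module_trait_effect=(0.8, 0.0),
        de_genes=(("G00100", 2.0),), seed=1,
    )
    return syn.generate_bulk_cohort(spec)


@pytest.fixture(scope="session")
def small_bulk_corrected(small_bulk):
    cohort, _ = small_bulk
    norm = bde.cpm_log_normalize(cohort.counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bde.batch_correct(norm, cohort.batch, cohort.condition), cohort


def make_strong_perturb(seed: int) -> tuple[ev.SingleCellKODataset, pd.DataFrame]:
    """Strong pair (knockdown 0.9, mediator log2FC 2, rho 0.52 -> 0.25) on
    G00001 -> G00120 plus a null KO G00002 with unplanted channel G00130."""
    spec = syn.PerturbSimSpec(
        n_cells_per_group=250, n_genes=400,
        ko_genes=("G00001", "G00002"),
        knockdown_fraction=0.9,
        mediator_effects=(("G00001", "G00050", 2.0),),
        coexpr_pairs=(("G00001", "G00120", 0.52, 0.25),),
        n_batches=4, seed=seed,
    )
    return syn.generate_perturbseq(spec)


def make_overwhelming_perturb(seed: int) -> ev.SingleCellKODataset:
    """Overwhelming-signal regime for virtual-knockout consistency: the KO
    gene is tightly co-expressed with its channel (rho 0.9 -> 0.2) and
    dropout-free, so the regulatory coupling survives log-scale Pearson."""
    spec = syn.PerturbSimSpec(
        n_cells_per_group=250, n_genes=400, ko_genes=("G00001",),
        knockdown_fraction=0.9, nb_dispersion=0.3,
        coexpr_pairs=(("G00001", "G00120", 0.9, 0.2),),
        n_batches=4, zero_inflation=0.0, seed=seed,
    )
    return syn.generate_perturbseq(spec)[0]


@pytest.fixture(scope="session")
def strong_perturb():
    return make_strong_perturb(0)


@pytest.fixture(scope="session")
def null_perturb():
    """No planted effects: KO label present but knockdown fraction 0."""
    spec = syn.PerturbSimSpec(
        n_cells_per_group=500, n_genes=300, ko_genes=("G00001",),
        knockdown_fraction=0.0, n_batches=4, seed=7,
    )
    return syn.generate_perturbseq(spec)[0]


@pytest.fixture(scope="session")
def control_split(null_perturb):
    """Control-vs-control dataset: half the control cells relabeled FAKE."""
    ctrl = null_perturb.cells_of(ev.CONTROL)
    labels = null_perturb.ko_label.loc[ctrl].copy()
    labels.loc[ctrl[: len(ctrl) // 2]] = "FAKE"
    return ev.SingleCellKODataset(
        counts=null_perturb.counts[list(ctrl)],
        ko_label=labels,
        batch=null_perturb.batch.loc[ctrl],
    )
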