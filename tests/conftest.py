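"""Shared fixtures and helpers for the methsplice test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import methsplice as ms
from methsplice import coupling, qc


@pytest.fixture(scope="session")
def tiny_ds():
    return ms.make_fixture("tiny", seed=7)


@pytest.fixture(scope="session")
def small_ds():
    return ms.make_fixture("small", seed=1)


def psi_matrix(ds, cohort: str) -> pd.DataFrame:
    """PSI of a simulated cohort, using the dataset's own bin widths."""
    c = ds.cohorts[cohort]
    widths = pd.Series(ds.bins["width"].to_numpy(),
                       index=ds.bins["gene_id"] + ":" + ds.bins["bin_id"])
    return coupling.compute_psi(c.inclusion, c.exclusion, widths)


def diffcor_for_cohort(ds, cohort: str) -> pd.DataFrame:
    """EWAS scans for both groups of one cohort plus the Fisher-z screen.

    Mirrors the pipeline's ewas + diffcor stages on in-memory data, with the
    same small-group adaptations (PC count and minimum samples shrink with the
    smallest group).
    """
    c = ds.cohorts[cohort]
    probes_ok = qc.filter_probes(ds.probes)
    combos = coupling.build_gene_combinations(probes_ok, ds.introns, ds.bins)
    psi = psi_matrix(ds, cohort)
    pcs = qc.top_principal_components(qc.beta_to_m(c.beta), 2)
    min_group = int(c.sheet["condition"].value_counts().min())
    n_pcs = int(np.clip(min_group - 3, 0, 2))
    min_samples = min(5, min_group)
    scans = {
        g: coupling.ewas_scan(c.beta, psi, combos, pcs, c.sheet, g,
                              min_samples=min_samples, n_pcs=n_pcs)
        for g in ("DCM", "control")
    }
    keys = ["probe_id", "gene_id", "bin_id"]
    dcm = scans["DCM"].rename(columns={"r": "r_dcm", "n": "n_dcm"})
    ctrl = scans["control"].rename(columns={"r": "r_control", "n": "n_control"})
    return coupling.diffcor_scan(dcm[keys + ["r_dcm", "n_dcm"]],
                                 ctrl[keys + ["r_control", "n_control"]])


@pytest.fixture(scope="session")
def small_replication(small_ds):
    """Directional-replication table of the small fixture (both cohorts)."""
    screen = diffcor_for_cohort(small_ds, "screening")
    repl = diffcor_for_cohort(small_ds, "replication")
    return coupling.directional_replication(screen, repl)
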