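"""Shared fixtures: small designs, simulated screens, crafted activity tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import dmscreen as dm
from dmscreen.synthetic import SimulationConfig

CONDITIONS = ["vehicle", "EC50", "EC100", "Emax"]


@pytest.fixture(scope="session")
def small_design() -> dm.ReceptorDesign:
    """24 residues, 2 segments, 456 designed variants."""
    return dm.make_design(24, 2, seed=11)


@pytest.fixture(scope="session")
def clean_screen(small_design):
    """Error-free simulated mapping run: truth must be exactly recoverable."""
    config = SimulationConfig(
        seed=3, barcodes_per_variant=3, reads_per_barcode=6,
        deletion_rate=0.0, chimera_rate=0.0, collision_rate=0.0,
        synonymous_rate=0.05, seq_error_rate=0.0,
    )
    library, reads = dm.simulate_mapping_reads(small_design, config)
    return library, reads, config


@pytest.fixture(scope="session")
def noisy_screen(small_design):
    """Default-rate simulated mapping run with all error modes injected."""
    config = SimulationConfig(seed=4, barcodes_per_variant=6, reads_per_barcode=15)
    library, reads = dm.simulate_mapping_reads(small_design, config)
    return library, reads, config


@pytest.fixture(scope="session")
def recovered_screen():
    """End-to-end run at the study's stated scale: ~1000 variants x 10
    barcodes, 2e6 reads per column, NB dispersion 0.1. Ground-truth barcode
    identities are used so this isolates the counting/normalisation stages.
    """
    design = dm.make_design(53, 8, seed=2)  # 53 x 19 = 1007 variants
    config = SimulationConfig(seed=7, depth=2e6, nb_dispersion=0.1)
    library = dm.simulate_library(design, config)
    counts = dm.simulate_counts(library, config)
    bmap = library.rename(columns={"truth_class": "call_class"})[
        ["barcode", "variant", "call_class", "position", "wt_aa", "mut_aa"]]
    table, summary = dm.activity_pipeline(counts, bmap, rpm_max=np.inf)
    return design, config, library, table, summary


def make_activity_table(
    L: int = 30,
    conditions: list[str] | None = None,
    activity_fn=None,
    n_frameshift: int = 30,
    fs_sd: float = 0.2,
    sem: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Crafted activity table: 19 substitutions per residue plus frameshifts.

    ``activity_fn(position, mut_aa, condition)`` supplies missense
    activities (default 1.0); frameshift activities are drawn with mean 1
    and SD ``fs_sd``, then shifted/scaled to hit those moments exactly.
    """
    rng = np.random.default_rng(seed)
    conditions = conditions or CONDITIONS
    aas = "ACDEFGHIKLMNPQRSTVWY"
    wt = [aas[rng.integers(20)] for _ in range(L)]
    rows = []
    for cond in conditions:
        for pos in range(1, L + 1):
            for mut in aas:
                if mut == wt[pos - 1]:
                    continue
                a = 1.0 if activity_fn is None else activity_fn(pos, mut, cond)
                rows.append(dict(
                    variant=f"{wt[pos-1]}{pos}{mut}", call_class="missense",
                    condition=cond, activity=a, sd=0.1, sem=sem, cv=0.1,
                    n_barcodes=10, position=pos, wt_aa=wt[pos - 1], mut_aa=mut))
        fs = rng.normal(1.0, fs_sd, n_frameshift)
        fs = (fs - fs.mean()) / fs.std(ddof=1) * fs_sd + 1.0  # exact moments
        for i, a in enumerate(fs):
            rows.append(dict(
                variant=f"fs_{i}", call_class="frameshift", condition=cond,
                activity=a, sd=0.1, sem=sem, cv=0.1, n_barcodes=1,
                position=pd.NA, wt_aa="", mut_aa=""))
    return pd.DataFrame(rows)


@pytest.fixture()
def flat_activity() -> pd.DataFrame:
    return make_activity_table(L=12, seed=1)
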