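import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import twolibde as tl

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def tiny_table():
    """Four genes covering co-expressed, specific and silent cases."""
    return tl.CountTable(
        gene_id=["g1", "g2", "g3", "g4"],
        length_bp=[1000, 2000, 500, 1500],
        count_a=[10, 0, 40, 0],
        count_b=[12, 7, 0, 0],
        lib_total_a=1_000_000,
        lib_total_b=2_000_000,
    )


@pytest.fixture(scope="session")
def null_simulation():
    """10,000-gene Poisson null at study-scale depth, with AC p-values."""
    cfg = tl.SimulationConfig(
        n_genes=10_000, frac_de=0.0, frac_specific_a=0.0, frac_specific_b=0.0,
        dispersion=0.0, seed=42,
    )
    table, truth = tl.generate_counts(cfg)
    pvals = tl.ac_pvalues(table.count_a, table.count_b,
                          table.lib_total_a, table.lib_total_b)
    return table, truth, pvals


@pytest.fixture(scope="session")
def planted_runs():
    """Ten seeds of a 10% DE simulation (|lfc| = 2, 1e7-read libraries)."""
    runs = []
    for seed in range(10):
        cfg = tl.SimulationConfig(
            n_genes=5000, lib_size_a=10**7, lib_size_b=10**7,
            frac_de=0.1, lfc_mean=2.0, lfc_sd=0.0,
            frac_specific_a=0.0, frac_specific_b=0.0,
            dispersion=0.0, seed=seed,
        )
        table, truth = tl.generate_counts(cfg)
        de = tl.de_table(table)
        runs.append(de.merge(truth, on="gene_id"))
    return runs


def sensitivity_and_fdp(merged):
    true_de = merged["label"].isin(["up", "down"])
    called = merged["call"] != "not_significant"
    sens = (called & true_de).sum() / max(int(true_de.sum()), 1)
    fdp = (called & ~true_de).sum() / max(int(called.sum()), 1)
    return float(sens), float(fdp)
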