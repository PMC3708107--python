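import numpy as np
import pytest

from rnasnip import BackgroundTable, RnaSnpConfig, TableSet
from rnasnip import background as bg

#: conditions of the full-scale null protocol (length 400, SNP at the centre,
#: GC drawn from the 0.5 decile); sample sizes are scaled for a desk run
NULL_LENGTH = 400
NULL_POS = 200
NULL_GC = (0.5, 0.6)
N_GLOBAL = 250
N_SCAN = 300

THERMO = RnaSnpConfig(backend="thermo")
BUILTIN = RnaSnpConfig(backend="builtin")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def null_global():
    """Thermodynamic-backend null sample of d_max and r_min (global fold)."""
    r = np.random.default_rng(101)
    return bg.sample_null_joint(
        [("d_max", "global"), ("r_min", "global")],
        NULL_LENGTH, NULL_GC, NULL_POS, N_GLOBAL, r, THERMO,
        min_samples=N_GLOBAL)


@pytest.fixture(scope="session")
def null_scan():
    """Thermodynamic-backend null sample of d# and d_max (scanning fold)."""
    r = np.random.default_rng(102)
    return bg.sample_null_joint(
        [("d_sharp", "scanning"), ("d_max", "scanning")],
        NULL_LENGTH, NULL_GC, NULL_POS, N_SCAN, r, THERMO,
        min_samples=N_SCAN)


def _table_from_sample(sample, params_fit) -> BackgroundTable:
    family = "beta" if sample.measure == "r_min" else "gumbel"
    params = params_fit(sample)
    return BackgroundTable(
        measure=sample.measure, backend=sample.backend, engine="thermo",
        family=family,
        cells={(sample.length, 0.55, 0.5): {"params": params,
                                            "n": len(sample), "ks": None}})


@pytest.fixture(scope="session")
def tables_thermo(null_global, null_scan) -> TableSet:
    """Background tables fitted from the session null samples."""
    ts = TableSet()
    ts[("d_max", "global")] = _table_from_sample(
        null_global[("d_max", "global")], bg.fit_gumbel)
    ts[("r_min", "global")] = _table_from_sample(
        null_global[("r_min", "global")], bg.fit_beta)
    ts[("d_sharp", "scanning")] = _table_from_sample(
        null_scan[("d_sharp", "scanning")], bg.fit_gumbel)
    ts[("d_max", "scanning")] = _table_from_sample(
        null_scan[("d_max", "scanning")], bg.fit_gumbel)
    return ts


@pytest.fixture(scope="session")
def builtin_tables() -> TableSet:
    """Small builtin-backend tables (length 195) for fast pipeline tests."""
    r = np.random.default_rng(103)
    length = 195
    joint = bg.sample_null_joint(
        [("d_max", "global"), ("r_min", "global")],
        length, 0.5, length // 2, 120, r, BUILTIN, min_samples=120)
    scan = bg.sample_null_joint(
        [("d_sharp", "scanning"), ("d_max", "scanning")],
        length, 0.5, length // 2, 120, r, BUILTIN, min_samples=120)
    ts = TableSet()
    for key, fit in ((("d_max", "global"), bg.fit_gumbel),
                     (("r_min", "global"), bg.fit_beta)):
        ts[key] = _table_from_sample(joint[key], fit)
    for key in (("d_sharp", "scanning"), ("d_max", "scanning")):
        ts[key] = _table_from_sample(scan[key], bg.fit_gumbel)
    return ts
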