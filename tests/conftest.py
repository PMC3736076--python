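import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from admetprof import DescriptorVector, default_range_table, default_tag_schema

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ranges():
    return default_range_table()


@pytest.fixture(scope="session")
def schema():
    return default_tag_schema()


def make_random_vectors(seed: int, n: int, missing_rate: float = 0.15):
    """Random descriptor vectors spanning well beyond every compliance
    range, with missing values sprinkled in — shared input for oracle-
    equivalence and implication tests."""
    rng = np.random.default_rng(seed)
    spans = {
        "mw": (0.0, 2000.0), "log_p": (-10.0, 25.0), "hba": (0.0, 60.0),
        "hbd": (0.0, 40.0), "nrb": (0.0, 80.0),
        "s_mol": (50.0, 3000.0), "s_mol_hfob": (0.0, 2000.0),
        "v_mol": (100.0, 6000.0), "log_s_wat": (-15.0, 5.0),
        "ci_log_s_wat": (-15.0, 5.0), "log_k_hsa": (-5.0, 5.0),
        "log_bb": (-8.0, 4.0), "bip_caco2": (0.0, 5000.0),
        "mdck": (0.0, 5000.0), "ind_coh": (0.0, 0.2), "glob": (0.2, 1.0),
        "qp_polrz": (0.0, 150.0), "log_herg": (-10.0, 0.0),
        "log_kp": (-12.0, 2.0), "jm": (0.0, 1e5), "percent_hoa": (0.0, 100.0),
    }
    vectors = []
    for _ in range(n):
        dv = DescriptorVector()
        for name, (lo, hi) in spans.items():
            if rng.random() < missing_rate:
                continue
            value = lo + (hi - lo) * rng.random()
            if name in ("nrb",):
                value = int(value)
            dv.set(name, value, provenance="tag")
        if rng.random() >= missing_rate:
            dv.set("n_metab", int(rng.integers(0, 30)), provenance="tag")
        vectors.append(dv)
    return vectors


def brute_force_stars(dv, table):
    """Independent re-count of out-of-range descriptors: a plain loop
    with explicit comparisons, no shared code with the rule engine."""
    stars = 0
    evaluated = 0
    for entry in table:
        value = getattr(dv, entry.descriptor)
        if value is None:
            continue
        evaluated += 1
        below = entry.lower is not None and value < entry.lower
        above = entry.upper is not None and value > entry.upper
        if below or above:
            stars += 1
    return stars, evaluated
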