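import numpy as np
import pytest

from netprog.config import AnalysisConfig
from netprog.simulate import SimulationConfig, generate_network, generate_omics_survival


@pytest.fixture(scope="session")
def planted_cohort():
    """Small cohort with one strongly prognostic 8-gene module."""
    sim = SimulationConfig(
        n_genes=120, n_modules=1, module_size=8, p_in=0.9, p_out=0.02,
        n_patients=200, effect_log_hr=0.8, frac_active_features=0.7,
        censoring_rate=0.3, seed=7,
    )
    net, truth = generate_network(sim)
    ds = generate_omics_survival(net, truth, sim)
    return sim, net, truth, ds


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects: survival independent of all features."""
    sim = SimulationConfig(
        n_genes=80, n_modules=1, module_size=6, p_in=0.8, p_out=0.02,
        n_patients=150, effect_log_hr=0.0, censoring_rate=0.25, seed=11,
    )
    net, truth = generate_network(sim)
    ds = generate_omics_survival(net, truth, sim)
    return sim, net, truth, ds


@pytest.fixture()
def fast_cfg():
    """Analysis config scaled for unit tests."""
    return AnalysisConfig(
        seed=3, n_cv_splits=20, n_permutations=20, perm_cv_splits=5,
        nmf_runs=15, discovery_n_perm=20, fixed_alpha=0.1,
    )


def brute_force_cindex(risk, time, event):
    """Independent pair-enumeration oracle for Harrell's C."""
    risk, time, event = map(np.asarray, (risk, time, event))
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            permissible = (time[i] < time[j] and event[i] == 1) or (
                time[i] == time[j] and event[i] == 1 and event[j] == 0
            )
            if not permissible:
                continue
            den += 1
            if risk[i] > risk[j]:
                num += 1
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den
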