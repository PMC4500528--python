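import numpy as np
import pytest

import gembayes as gb


@pytest.fixture(scope="session")
def three_marker_panel() -> gb.MarkerPanel:
    d = np.full((3, 3), 0.03)
    np.fill_diagonal(d, 0.0)
    return gb.MarkerPanel(np.full(3, 0.25), d)


@pytest.fixture(scope="session")
def exp1_scenario() -> gb.Scenario:
    return gb.experiment1_scenario()


@pytest.fixture(scope="session")
def small_gem_data(exp1_scenario):
    """One modest genotype-effect-model dataset shared across tests."""
    sc = gb.experiment1_scenario(n_cases=400, n_controls=400)
    return sc, gb.simulate_case_control(sc, rng=123)


@pytest.fixture(scope="session")
def small_aem_data():
    sc = gb.small_sample_scenario(n_cases=250, n_controls=250)
    return sc, gb.simulate_case_control(sc, rng=321)


@pytest.fixture(scope="session")
def single_marker_scenario() -> gb.Scenario:
    """Tiny one-marker binary-disease scenario for enumeration oracles."""
    panel = gb.MarkerPanel([0.25])
    params = gb.RiskParams(
        beta0=[0.0], beta_t=[0.5], beta_a=[[0.3]], beta_at=[[0.4]],
        beta_d=[[0.2]], beta_dt=[[0.1]], model_kind=gb.GEM,
    )
    from gembayes.simulate import make_scenario

    design = gb.StudyDesign([60, 40], pi=[0.01])
    return make_scenario(panel, 0.4, gb.MisclassSpec(xi0=0.2, xi1=0.25), params, design)
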