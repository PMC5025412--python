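import numpy as np
import pytest

import dcequip
from dcequip import presets
from dcequip.synthetic import PopulationSpec, draw_population, simulate_choices


@pytest.fixture(scope="session")
def coding():
    return presets.default_coding()


@pytest.fixture(scope="session")
def attributes():
    return list(presets.ATTRIBUTES)


@pytest.fixture(scope="session")
def blocked_plan(attributes):
    """24-run near-orthogonal plan paired against its least-dominant
    comparator and blocked into 4 respondent blocks."""
    plan = dcequip.generate_fractional_design(attributes, 24, seed=11, n_iter=2000)
    comparator = dcequip.choose_comparator(plan, presets.SIGN_ASSUMPTIONS)
    plan = dcequip.build_choice_sets(plan, comparator)
    return dcequip.block_design(plan, 4, seed=12)


@pytest.fixture(scope="session")
def homogeneous_data(blocked_plan, coding):
    """Choices simulated from one shared coefficient vector (no
    heterogeneity), the conditional logit's data-generating process."""
    pop = presets.mn1_like_population(400, seed=21)
    pop0 = PopulationSpec(
        kind="normal", columns=pop.columns, means=pop.means,
        sds=np.zeros_like(pop.sds), n_respondents=400, seed=21,
    )
    truth = draw_population(pop0)
    data = simulate_choices(truth, blocked_plan, coding, seed=22)
    return pop0, truth, data


@pytest.fixture(scope="session")
def mn1_data(blocked_plan, coding):
    """Mixed-logit study conditions: 500 respondents with normally
    heterogeneous preferences on a blocked 23-set design."""
    pop = presets.mn1_like_population(500, seed=31)
    truth = draw_population(pop)
    data = simulate_choices(truth, blocked_plan, coding, seed=32)
    return pop, truth, data


@pytest.fixture(scope="session")
def two_class_data(blocked_plan, coding):
    """Discrete-mixture study conditions: 600 respondents from two
    well-separated preference classes with shares 0.6/0.4."""
    pop = presets.two_class_population(600, seed=41)
    truth = draw_population(pop)
    data = simulate_choices(truth, blocked_plan, coding, seed=42)
    return pop, truth, data
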