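import numpy as np
import pytest

from picoma import ExperimentDesign, GxE, SimulationParams
from picoma.simulate import Mutation, simulate_ma_experiment


@pytest.fixture
def quiet_params() -> SimulationParams:
    """A mutation-free, noise-free experiment: deterministic growth only."""
    return SimulationParams(
        design=ExperimentDesign(n_lines=5, n_bottlenecks=4),
        base_divisions_per_day=1.0,
        seed=11,
    )


@pytest.fixture
def planted_experiment():
    """A mutation-free experiment with hand-injected mutations.

    Three lines carry known condition-specific effects on divisions/day
    (keys: benign via benign_effect, 'standard' and 'stress'): L001 is
    deleterious everywhere, L002 conditionally beneficial under stress,
    L003 deleterious under stress only.  Ground truth is exact because
    the simulator itself adds no mutations.
    """
    params = SimulationParams(
        design=ExperimentDesign(n_lines=6, n_bottlenecks=3),
        gxe=GxE(conditions=("standard", "stress")),
        count_noise_cv=0.02,
        seed=7,
    )
    experiment = simulate_ma_experiment(params)
    inject = {
        "L001": Mutation("deleterious", np.exp(-0.08),
                         {"standard": np.exp(-0.08), "stress": np.exp(-0.08)}),
        "L002": Mutation("beneficial", np.exp(-0.02),
                         {"standard": np.exp(-0.02), "stress": np.exp(0.10)}),
        "L003": Mutation("deleterious", 1.0,
                         {"standard": 1.0, "stress": np.exp(-0.12)}),
    }
    for line_id, mutation in inject.items():
        experiment.mutations[line_id].append(mutation)
    return experiment, inject
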