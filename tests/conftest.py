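import hypothesis.strategies as st
import pytest

from pestgame import GameParameters, ScenarioBatch, baseline_parameters, generate_scenarios
from pestgame.scenarios import BASELINE_VALUES, default_ranges

ORACLE_SEED = 20240901


@pytest.fixture(scope="session")
def baseline_c2() -> GameParameters:
    return baseline_parameters(2.0)


@pytest.fixture(scope="session")
def baseline_c4() -> GameParameters:
    return baseline_parameters(4.0)


@pytest.fixture(scope="session")
def random_scenarios():
    """50 seeded random scenarios within the default sampling ranges."""
    return generate_scenarios(ScenarioBatch(seed=ORACLE_SEED, n=50))


def parameter_sets() -> st.SearchStrategy[GameParameters]:
    """Valid parameter draws bracketing the baseline by [0.5x, 2x]."""
    ranges = default_ranges()
    return st.fixed_dictionaries(
        {
            name: st.floats(
                min_value=lo, max_value=hi, allow_nan=False, allow_infinity=False
            )
            for name, (lo, hi) in ranges.items()
        }
    ).map(lambda d: GameParameters(**d))


def efforts() -> st.SearchStrategy[float]:
    return st.floats(min_value=0.0, max_value=20.0, allow_nan=False)


def gains() -> st.SearchStrategy[float]:
    return st.floats(min_value=1e-3, max_value=10.0, allow_nan=False)
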