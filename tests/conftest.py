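import numpy as np
import pytest

from t2dmeta.syndata import SynthConfig, generate_dataset, preprocess


@pytest.fixture(scope="session")
def small_cohort():
    """A preprocessed 160-gene cohort with a planted signal (session-cached)."""
    raw = generate_dataset(
        SynthConfig(
            n_genes=160, n_dia=12, n_nondia=18, n_informative=16, effect_size=2.5, seed=7
        )
    )
    return preprocess(raw)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


class ScriptedRng:
    """Stub generator replaying fixed draws, for stage-equation oracles."""

    def __init__(self, draws):
        self._draws = list(draws)

    def _next(self, size=None):
        v = self._draws.pop(0)
        arr = np.asarray(v, dtype=float)
        if size is not None and arr.shape == ():
            arr = np.full(size, float(arr))
        return arr if size is not None else float(arr)

    def random(self, size=None):
        return self._next(size)

    def uniform(self, low=0.0, high=1.0, size=None):
        u = self._next(size)
        return low + (high - low) * u

    def integers(self, n):
        return int(self._next())


@pytest.fixture()
def scripted_rng():
    return ScriptedRng
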