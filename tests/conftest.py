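import numpy as np
import pytest

from lineup2ht import (
    FitOptions,
    LineupDesign,
    ModelSpec,
    ResponseTable,
    RestrictionMap,
    base_model_spec,
    load_fixture,
)

#: Fast deterministic optimizer settings for simulation-heavy tests.
FAST_FIT = FitOptions(n_restarts=0, tolerance=1e-9)


@pytest.fixture(scope="session")
def table1() -> ResponseTable:
    """Reanalysis frequencies (559 decisions, two instruction conditions)."""
    return load_fixture("horry_reanalysis")


@pytest.fixture(scope="session")
def table2() -> ResponseTable:
    """Conceptual-replication frequencies (1420 decisions)."""
    return load_fixture("replication")


@pytest.fixture(scope="session")
def base_spec() -> ModelSpec:
    """Base model: b and dA equated across the two conditions, c = 0.16667."""
    return base_model_spec()


@pytest.fixture(scope="session")
def feasible_table() -> ResponseTable:
    """A table compatible with interior 2-HT parameters in every condition.

    Rounded expected counts under interior generating values; the
    unrestricted model can fit such data exactly (it is saturated there).
    """
    from lineup2ht import category_probabilities

    truth = np.array([[0.4, 0.35, 0.05, 0.15], [0.5, 0.45, 0.05, 0.15]])
    probs = category_probabilities(truth, 0.16667)
    counts = np.rint(probs.reshape(2, 2, 3) * 500).astype(int)
    return ResponseTable(("FYC", "noFYC"), counts, label="feasible")


@pytest.fixture()
def single_condition_spec() -> ModelSpec:
    return ModelSpec(
        design=LineupDesign(),
        condition_names=("only",),
        restrictions=RestrictionMap(()),
    )


def make_table(counts, conditions=("FYC", "noFYC"), label="test") -> ResponseTable:
    return ResponseTable(tuple(conditions), np.asarray(counts), label=label)
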