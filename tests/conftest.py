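import numpy as np
import pandas as pd
import pytest

from densyield import reference as ref


@pytest.fixture(scope="session")
def design_densities() -> np.ndarray:
    return np.array(ref.DESIGN_DENSITIES)


@pytest.fixture(scope="session")
def pooled_hoerl() -> tuple[float, float, float]:
    return ref.POOLED_HOERL


@pytest.fixture()
def noise_free_hoerl_table(design_densities, pooled_hoerl) -> pd.DataFrame:
    from densyield import evaluate

    y = evaluate("hoerl", pooled_hoerl, design_densities)
    return pd.DataFrame({"density": design_densities, "yield": y})


def printed_population_rows(include_partial: bool = False):
    """Printed population-family parameter rows usable as admissible
    parameter sets (skips the row whose last parameter was illegible)."""
    for mid, params, sd, r in ref.POPULATION_FAMILY_RANKING:
        if not include_partial and any(p is None for p in params):
            continue
        yield mid, params, sd, r


def printed_single_plant_rows():
    yield from ref.SINGLE_PLANT_FAMILY_RANKING
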