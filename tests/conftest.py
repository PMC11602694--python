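import warnings

import numpy as np
import pandas as pd
import pytest

import thermalgarden as tg
from thermalgarden import phenotype as ph

# statsmodels mixed-model convergence chatter is expected on tiny panels
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_panel():
    """Default-condition necrosis panel after the inclusion rule."""
    sim = tg.simulate_necrosis_panel(tg.SimConfig(seed=11))
    return ph.apply_inclusion_rule(ph.validate_panel(sim.panel))


@pytest.fixture(scope="session")
def default_scores(default_panel):
    return tg.fit_fitness_pca(default_panel).scores


@pytest.fixture(scope="session")
def genotypes_low_fst():
    return tg.simulate_genotypes(tg.SimConfig(seed=11, theta_target=0.02)).matrix


def toy_panel(trajs: dict, population: str = "PopA", year: int = 2015) -> pd.DataFrame:
    """Build a panel from {colony_id: [daily values]} dicts."""
    rows = []
    for cid, vals in trajs.items():
        for d, v in enumerate(vals, start=1):
            rows.append((cid, population, year, d, float(v)))
    return pd.DataFrame(rows, columns=["colony_id", "population", "year",
                                       "day", "necrosis_pct"])


def flat_series(temp: float = 20.0, years=(2004, 2009)) -> pd.DataFrame:
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    return pd.DataFrame({"date": dates, "temp_c": np.full(len(dates), temp)})
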