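import numpy as np
import pytest

from pheoscreen import qhts, simulate
from pheoscreen.datasets import load_epirubicin_saha, load_top50_hits

DEFAULT_MIX = {"1.1": 0.02, "1.2": 0.03, "2.1": 0.02, "2.2": 0.03,
               "3": 0.02, "4": 0.88}


@pytest.fixture(scope="session")
def top50():
    return load_top50_hits()


@pytest.fixture(scope="session")
def combo_table():
    return load_epirubicin_saha()


def run_screen(n, noise_sd, seed, mix=None, low_efficacy_fraction=0.3):
    """Generate plates, normalize, fit and classify; return fits+truth."""
    truth = simulate.gen_screen_library(
        n, mix or DEFAULT_MIX, seed=seed,
        low_efficacy_fraction=low_efficacy_fraction)
    plates, cmap = simulate.gen_plate_reads(truth, noise_sd=noise_sd,
                                            seed=seed + 1)
    normalized = qhts.normalize_screen(plates)
    series = qhts.extract_titrations(normalized, cmap)
    ann = cmap[["compound_id", "category"]].drop_duplicates("compound_id")
    fits = qhts.fit_screen(series, annotations=ann)
    return fits.merge(truth, on="compound_id", validate="one_to_one")


@pytest.fixture(scope="session")
def noiseless_screen():
    """A small noiseless screen shared across tests (no state mutation)."""
    mix = {"1.1": 0.15, "1.2": 0.15, "2.1": 0.1, "2.2": 0.15, "3": 0.1,
           "4": 0.35}
    return run_screen(120, 0.0, seed=42, mix=mix)


def series_from_params(bottom, top, ic50, hill, concentrations=None,
                       compound_id="synthetic"):
    conc = (simulate.titration_concentrations() if concentrations is None
            else np.asarray(concentrations, float))
    resp = qhts.four_param_logistic(conc, bottom, top, ic50, hill)
    return qhts.TitrationSeries(compound_id, conc, resp)
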