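import numpy as np
import pytest

from viseam import synthetic
from viseam.series import NDVI, LAISeries, VISeries


@pytest.fixture(scope="session")
def clean_pixel():
    """One uncontaminated temperate pixel with LAI-consistent truth."""
    phen = synthetic.PhenologyParams(
        base_vi=0.15, peak_vi=0.85, green_up_doy=120, senescence_doy=280,
        transition_steepness=0.06, inter_annual_jitter=0.0)
    truth, lai = synthetic.generate_truth(phen, n_years=2, seed=0)
    return truth, lai


@pytest.fixture(scope="session")
def contaminated_pixel():
    """One temperate pixel with 40% cloud cover and missing steps."""
    phen = synthetic.PhenologyParams(
        base_vi=0.2, peak_vi=0.85, transition_steepness=0.06,
        inter_annual_jitter=0.0)
    truth, lai = synthetic.generate_truth(phen, n_years=2, seed=1)
    cont = synthetic.ContaminationParams(cloud_fraction=0.4, seed=1)
    observed, qa = synthetic.contaminate(truth, cont)
    return truth, observed, lai, qa


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small stratified corpus for training tests."""
    return synthetic.make_benchmark(20, index_kind=NDVI, seed=7)


def make_vi(values, kind=NDVI):
    v = np.asarray(values, dtype=float)
    if v.size % 46 != 0:  # pad to the grid with a neutral constant
        pad = 46 - (v.size % 46)
        v = np.concatenate([v, np.full(pad, v[-1])])
    return VISeries(values=v, index_kind=kind)
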