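import numpy as np
import pytest

from ppbc import GeneratorConfig, generate_cohort, generate_roi_markers

CONFOUNDERS = ["age_dx", "n_children", "breastfed", "menopause", "fam_hx", "bmi"]


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(seed=20260109))


@pytest.fixture(scope="session")
def small_dataset():
    """A small correlated-marker dataset with known TSLB effects."""
    cfg = GeneratorConfig(seed=42, n_parous=150, n_nulliparous=50, p_markers=8)
    cohort = generate_cohort(cfg)
    rois = generate_roi_markers(cohort, cfg)
    return cfg, cohort, rois


@pytest.fixture(scope="session")
def uncorrelated_dataset():
    """Independent null markers: no TSLB effects, no factors, no woman effect."""
    cfg = GeneratorConfig(
        seed=7, n_parous=120, n_nulliparous=0, p_markers=4,
        marker_names=["m1", "m2", "m3", "m4"], tslb_effects={},
        factor_loadings=np.zeros((4, 1)), woman_sd=0.0,
    )
    cohort = generate_cohort(cfg)
    rois = generate_roi_markers(cohort, cfg)
    return cfg, cohort, rois
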