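import numpy as np
import pytest

from sulcprofile.features import extract_features, feature_table
from sulcprofile.profiles import DepthProfile, Hemisphere
from sulcprofile.smoothing import invert_depths, smooth_profile
from sulcprofile.synthetic import GeneratorConfig, groundtruth_table, simulate_cohort


def make_profile(depths, subject="s1", hemi=Hemisphere.LEFT, **kw):
    return DepthProfile(subject_id=subject, hemisphere=hemi, depths=np.asarray(depths, float), **kw)


def smoothed_from_values(values, subject="s1", hemi=Hemisphere.LEFT):
    """Wrap explicit inverted grid values as an already-smoothed profile."""
    return make_profile(values, subject=subject, hemi=hemi, inverted=True, smoothed=True)


@pytest.fixture(scope="session")
def small_cohort():
    """30-subject synthetic cohort with ground truth, smoothed profiles and features."""
    cfg = GeneratorConfig(n_subjects=30, seed=5)
    cohort, truths = simulate_cohort(cfg)
    smoothed = [smooth_profile(invert_depths(p)) for p in cohort.active_profiles()]
    features = [extract_features(p) for p in smoothed]
    table = feature_table(cohort, features)
    return {
        "config": cfg,
        "cohort": cohort,
        "truth": groundtruth_table(truths),
        "smoothed": smoothed,
        "features": features,
        "table": table,
    }
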