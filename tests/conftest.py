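import numpy as np
import pytest

from vbmglobals.synthetic import (
    CohortSpec,
    ImageGenSpec,
    default_region_specs,
    generate_cohort,
    generate_gm_images,
    make_synthetic_atlas,
    update_cohort_globals,
)


@pytest.fixture(scope="session")
def cohort60():
    """Small two-sex cohort: 10 per decade, ages 18-77."""
    return generate_cohort(CohortSpec(n_per_decade=10, seed=11))


@pytest.fixture(scope="session")
def cohort420():
    """Full-size study cohort: 70 per decade."""
    return generate_cohort(CohortSpec(seed=5))


@pytest.fixture(scope="session")
def tiny_atlas():
    """16-region parcellation on a 16^3 grid."""
    return make_synthetic_atlas((16, 16, 16), n_regions=16, seed=7)


@pytest.fixture(scope="session")
def tiny_regions(tiny_atlas):
    return default_region_specs(tiny_atlas, seed=13)


@pytest.fixture(scope="session")
def tiny_study(cohort60, tiny_atlas, tiny_regions):
    """Generated images plus the cohort with image-derived globals."""
    spec = ImageGenSpec(grid_shape=(16, 16, 16), seed=17)
    unsm, sm, truth = generate_gm_images(cohort60, tiny_regions, tiny_atlas, spec)
    cohort = update_cohort_globals(cohort60, unsm)
    return {
        "cohort": cohort,
        "atlas": tiny_atlas,
        "regions": tiny_regions,
        "unsmoothed": unsm,
        "smoothed": sm,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def atlas116():
    """AAL-cardinality parcellation (58 per hemisphere) on a 24^3 grid."""
    return make_synthetic_atlas((24, 24, 24), n_regions=116, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
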