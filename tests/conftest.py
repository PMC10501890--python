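import numpy as np
import pytest

from pedbrain import PhantomSpec, generate_cohort, generate_phantom
from pedbrain.phantom import sample_class_features

#: class mix of the study cohort: 75 tumors of four types plus 19 normals
STUDY_MIX = {
    "ependymoma": 14 / 94,
    "medulloblastoma": 21 / 94,
    "pilocytic_astrocytoma": 19 / 94,
    "brainstem_glioma": 21 / 94,
    "none": 19 / 94,
}

#: small grid used by fast tests (large enough for every lobe to host a tumor)
FAST_DIMS = (48, 48, 24)


@pytest.fixture(scope="session")
def study_mix():
    return dict(STUDY_MIX)


@pytest.fixture(scope="session")
def tumor_case():
    """One ependymoma-like phantom with every lesion type switched on."""
    rng = np.random.default_rng(0)
    feats = sample_class_features("ependymoma", rng, "typical")
    spec = PhantomSpec(tumor_class="ependymoma", target_features=feats, seed=3)
    return generate_phantom(spec, case_id="fixture_ependymoma")


@pytest.fixture(scope="session")
def normal_case():
    return generate_phantom(PhantomSpec(seed=4), case_id="fixture_normal")


@pytest.fixture(scope="session")
def fast_cohort(study_mix):
    """Eight small phantoms (incl. normals) for network smoke tests."""
    base = PhantomSpec(grid_dims=FAST_DIMS, tumor_radius_vox=5.0)
    _, cases = generate_cohort(8, study_mix, base, seed=21,
                               feature_sampling="typical")
    return cases


def interleaved_split(cases, every: int = 4):
    """Deterministic train/val split mixing classes across both parts."""
    train = [c for i, c in enumerate(cases) if i % every != every - 1]
    val = [c for i, c in enumerate(cases) if i % every == every - 1]
    return train, val
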