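import numpy as np
import pandas as pd
import pytest

import prorad as pr

#: Grid used for imaging tests: small enough to keep the suite fast while
#: still exercising anisotropic voxels and all region geometry.
SMALL_GRID = (48, 48, 40)


@pytest.fixture(scope="session")
def zero_noise_study():
    """A noise-free single-patient study with 3 biopsy ROIs + ground truth."""
    cfg = pr.SyntheticConfig.zero_noise(grid_shape=SMALL_GRID, rng_seed=7)
    study, gt = pr.generate_study(cfg, patient_index=0, n_biopsies=3)
    return cfg, study, gt


@pytest.fixture(scope="session")
def zero_noise_habitats(zero_noise_study):
    _cfg, study, _gt = zero_noise_study
    return pr.compute_habitats(study)


@pytest.fixture(scope="session")
def zero_noise_features(zero_noise_study, zero_noise_habitats):
    _cfg, study, _gt = zero_noise_study
    pk = pr.fit_study_pk(study)
    return pr.extract_all(study, zero_noise_habitats, pk)


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """One full pipeline run on the small grid; shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = pr.PipelineConfig(
        synthetic=pr.SyntheticConfig(grid_shape=SMALL_GRID), seed=3)
    manifest = pr.run_pipeline(cfg, out)
    feats = pd.read_csv(out / "features.tsv", sep="\t", index_col=0)
    return cfg, out, manifest, feats


@pytest.fixture(scope="session")
def dense_aif():
    """Parker AIF on a 1 s grid out to 6.5 min."""
    t = np.linspace(0.0, 6.5, int(6.5 * 60) + 1)
    return pr.parker_aif(t)


def make_flat_study(dce_matrix: np.ndarray, t_min: np.ndarray) -> pr.MpMRIStudy:
    """Wrap a (voxels x time) matrix as a 1-D-geometry study, for
    decomposition tests where anatomy is irrelevant."""
    n, T = dce_matrix.shape
    shape = (n, 1, 1)
    ones = np.ones(shape, dtype=bool)
    half = np.zeros(shape, dtype=bool)
    half[: n // 2] = True
    first = np.zeros(shape, dtype=bool)
    first[0] = True
    last = np.zeros(shape, dtype=bool)
    last[-1] = True
    return pr.MpMRIStudy(
        t2w=np.zeros(shape), adc=np.full(shape, 1000.0),
        dce=dce_matrix.reshape(n, 1, 1, T), t_min=t_min,
        voxel_size_mm=(1.0, 1.0, 1.0),
        masks={"prostate": ones, "pz": half, "tz": ones & ~half,
               "urethra": np.zeros(shape, dtype=bool),
               "nat_pz": first, "nat_tz": last},
    )
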