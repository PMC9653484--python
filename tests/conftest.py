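import numpy as np
import pytest

import remcortex as rc


@pytest.fixture(scope="session")
def session30():
    """A 30-min default-parameter synthetic session containing REM sleep."""
    cfg = rc.SimConfig(seed=0, duration_s=1800)
    rec, gt = rc.generate_session(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def pre30(session30):
    """Preprocessed movie of the 30-min session, aligned to the atlas."""
    cfg, rec, gt = session30
    atlas = rc.synthetic_atlas(cfg.image_shape)
    pre = rc.preprocess_movie(rec.movie, rate=rec.movie_rate, reference=atlas)
    return pre, atlas


@pytest.fixture(scope="session")
def template30(session30, pre30):
    cfg, rec, gt = session30
    pre, _ = pre30
    return rc.compute_pc1rem(pre, gt.hypnogram)


@pytest.fixture(scope="session")
def hyp3h_coeffs():
    """A 3-h hypnogram with planted pattern coefficients (no movie)."""
    from remcortex.synth import generate_pattern_coefficients
    cfg = rc.SimConfig(seed=1, duration_s=3 * 3600)
    hyp = rc.generate_hypnogram(cfg)
    coeffs, events = generate_pattern_coefficients(hyp, cfg)
    return cfg, hyp, coeffs, events


def make_preprocessed(dff, rate=10.0, vessel_mask=None, region_map=None):
    """Bare PreprocessedMovie around a given dff array (for unit tests)."""
    from remcortex.preprocess import PreprocessedMovie
    dff = np.asarray(dff, dtype=np.float32)
    if vessel_mask is None:
        vessel_mask = np.zeros(dff.shape[1:], bool)
    return PreprocessedMovie(dff=dff, rate=rate, f0=np.ones(dff.shape[1:]),
                             vessel_mask=vessel_mask, region_map=region_map)
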