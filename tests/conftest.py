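"""Shared fixtures: small phantoms reused across the suite."""

import warnings

import numpy as np
import pytest

import wmfunnet as w

warnings.filterwarnings("ignore", message=".*zero-variance.*")
warnings.filterwarnings("ignore", message=".*dropping degenerate.*")


@pytest.fixture(scope="session")
def small_spec():
    return w.PhantomSpec(shape=(14, 14, 14), n_volumes=120, n_participants=3, seed=1)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return w.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def preprocessed_phantom(small_phantom):
    """The small phantom run through the full denoising chain, with the
    group WM mask (corpus callosum removed, as in the pipeline)."""
    ph = small_phantom
    clean = [
        w.preprocess(b, m, t, n_discard=10)[0]
        for b, m, t in zip(ph.bolds, ph.motion, ph.tpms)
    ]
    wm = w.build_wm_group_mask(ph.tpms)
    wm.mask &= ~(ph.cc_truth > 0)
    wm = w.drop_empty_voxels(wm, clean)
    return ph, clean, wm


@pytest.fixture(scope="session")
def group_fc(preprocessed_phantom):
    ph, clean, wm = preprocessed_phantom
    return ph, wm, w.build_group_fc(clean, wm, stride=2)


@pytest.fixture(scope="session")
def phantom_tree(tmp_path_factory):
    """A phantom written to disk as a BIDS-like tree."""
    root = tmp_path_factory.mktemp("phantom")
    spec = w.PhantomSpec(shape=(12, 12, 12), n_volumes=20, n_participants=3, seed=7)
    phantom = w.make_phantom(spec, root)
    return root, spec, phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
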