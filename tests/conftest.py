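"""Shared fixtures: desk-scale geometry, trained tiny networks, and one
end-to-end pipeline run reused by the slower tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

GRID = 64


@pytest.fixture(scope="session")
def desk_params():
    from fresco.training import desk_acquisition

    return desk_acquisition(GRID)


@pytest.fixture(scope="session")
def training_sets():
    """20 training + 4 held-out phantom pairs at the desk grid."""
    from fresco.training import make_phantom_pairs

    train = make_phantom_pairs(None, n_phantoms=20, seed=11, grid=GRID, n_blocks=1)
    heldout = make_phantom_pairs(None, n_phantoms=4, seed=99, grid=GRID, n_blocks=1)
    return {"train": train, "heldout": heldout}


@pytest.fixture(scope="session")
def trained_models(training_sets):
    """Tiny suppression and segmentation U-Nets trained on 20 phantom blocks."""
    from fresco.recon_net import UNetSpec, train_suppressor
    from fresco.seg_net import train_segmenter
    from fresco.training import make_seg_pairs

    pairs = training_sets["train"]
    recon_spec = UNetSpec(n_scales=2, init_filters=8, blocks_per_scale=2, lr=1e-3)
    recon, recon_hist = train_suppressor(pairs, recon_spec, epochs=10, seed=0)
    seg_spec = UNetSpec(
        n_scales=2, init_filters=6, blocks_per_scale=2, lr=2e-3, out_channels=1
    )
    seg, seg_hist = train_segmenter(
        make_seg_pairs(pairs, recon), seg_spec, epochs=6, seed=0
    )
    return {
        "recon": recon,
        "recon_spec": recon_spec,
        "recon_hist": recon_hist,
        "seg": seg,
        "seg_spec": seg_spec,
        "seg_hist": seg_hist,
    }


@pytest.fixture(scope="session")
def eval_phantom():
    """Held-out rest phantom for end-to-end monitoring recovery."""
    from fresco.phantom import PhantomConfig, generate_phantom

    cfg = PhantomConfig(
        grid=GRID,
        duration_s=20.0,
        hr_bpm=75.0,
        hr_ramp=(21.0, 22.0, 75.0),  # flat heart rate: ramp after the end
        sv_ml=80.0,
        sv_peak_ml=80.0,
        n_coils=4,
        seed=1234,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def pipeline_result(trained_models, eval_phantom, desk_params):
    from fresco.stream import run_pipeline

    return run_pipeline(
        eval_phantom,
        trained_models["recon"],
        trained_models["seg"],
        desk_params,
        crop=GRID,
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
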