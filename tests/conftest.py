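"""Shared fixtures: small phantoms, and one session-scoped trained ensemble
used by the end-to-end evaluation tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cavityseg import (
    PhantomSpec,
    desk_config,
    extract_mask_slices,
    extract_slices,
    generate_cohort,
    generate_phantom,
    normalize_intensity,
    train,
)
from cavityseg.preprocess import PLANES

settings.register_profile("ci", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("ci")

#: Network/slice resolution used throughout the desk-scale tests (native for
#: the 64^3 phantom grid, so extraction/reassembly is exact).
DESK_RESOLUTION = 64


def identity_affine() -> np.ndarray:
    return np.eye(4)


def stack_pairs(subjects, plane, resolution=DESK_RESOLUTION):
    """(image stack, mask stack) training pairs from cohort tuples."""
    out = []
    for vol, mask, _parc, sid in subjects:
        norm = normalize_intensity(vol)
        out.append((
            extract_slices(norm, plane, resolution=resolution, subject_id=sid),
            extract_mask_slices(mask, plane, resolution=resolution, subject_id=sid),
        ))
    return out


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec phantom triple (volume, mask, parcellation)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def trained_setup():
    """Three plane models trained on 20 phantoms (16 train / 4 val, 10 epochs,
    fixed seeds), plus 5 held-out test phantoms and 5 control specs.

    Session-scoped because training takes minutes; every end-to-end test
    shares this one ensemble.
    """
    cohort = generate_cohort(25, seed=20)
    train_set, val_set, test_set = cohort[:16], cohort[16:20], cohort[20:]
    models = {}
    for i, plane in enumerate(PLANES):
        cfg = desk_config(seed=7 + i, epochs=10)
        models[plane] = train(
            stack_pairs(train_set, plane), stack_pairs(val_set, plane), cfg
        )
    control_specs = [
        PhantomSpec(seed=1000 + j, cavity_radius_mm=0.0) for j in range(5)
    ]
    return {
        "models": models,
        "train_set": train_set,
        "val_set": val_set,
        "test_set": test_set,
        "control_specs": control_specs,
    }
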