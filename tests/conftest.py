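"""Shared fixtures: phantoms, extracted cohorts, helper utilities."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from mammodensity.features import default_layout, extract_features
from mammodensity.io import background_mask, crop_tag
from mammodensity.phantom import PhantomSpec, generate_cohort, generate_phantom


def extract_cohort(images, layout=None, tag_policy="none"):
    """Feature table + aligned truth/status frames for a generated cohort."""
    layout = layout or default_layout()
    rows = {}
    for image_id, img, _truth in images:
        if tag_policy == "auto":
            img = crop_tag(img, policy="auto")
        mask = background_mask(img)
        rows[image_id] = extract_features(img, mask, layout=layout)
    table = pd.DataFrame(rows).T[list(layout.slots)]
    table.index.name = "id"
    return table


@pytest.fixture(scope="session")
def phantom30():
    """One 256x256 phantom at 30% target density, with tag."""
    return generate_phantom(PhantomSpec(target_pd=30.0, tag=True, seed=7))


@pytest.fixture(scope="session")
def phantom30_features(phantom30):
    img, truth = phantom30
    img = crop_tag(img, policy="auto")
    mask = background_mask(img)
    return img, mask, extract_features(img, mask)


@pytest.fixture(scope="session")
def recovery_cohort():
    """100-phantom cohort (no case/control structure) with extracted
    features, for parameter-recovery checks."""
    images, manifest = generate_cohort(50, 50, pd_shift=0.0, seed=11)
    features = extract_cohort(images)
    return features, manifest.set_index("id")


@pytest.fixture(scope="session")
def risk_cohort():
    """200 cases + 200 controls with a 0.8 sqrt-PD case shift, extracted."""
    images, manifest = generate_cohort(200, 200, pd_shift=0.8, seed=23)
    features = extract_cohort(images)
    return features, manifest.set_index("id")
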