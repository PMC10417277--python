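"""Shared fixtures: compact synthetic plates and optics used across tests.

Unit tests run on deliberately small fields (200x200 px, ~40 cells) so the
whole suite stays fast; the acceptance tests build their own larger plates
at the scales their checks require.
"""

import numpy as np
import pytest

import hcsplice as h


@pytest.fixture(scope="session")
def small_optics() -> h.OpticsSpec:
    return h.OpticsSpec(field_shape=(200, 200))


@pytest.fixture(scope="session")
def flat_optics() -> h.OpticsSpec:
    """Optics with no gradient and no noise: pure signal model."""
    return h.OpticsSpec(
        field_shape=(200, 200), background_gradient_amplitude=0.0, noise_sd=0.0
    )


def make_layout(
    wells: dict,
    conditions: dict,
    min_fields: int = 3,
) -> h.PlateLayout:
    return h.parse_layout(
        {"plate": {"min_fields": min_fields}, "conditions": conditions, "wells": wells}
    )


@pytest.fixture(scope="session")
def three_well_layout() -> h.PlateLayout:
    """WT-like vs mutant-like sample wells plus an untransfected control."""
    return make_layout(
        wells={
            "A1": {"condition": "WT", "role": "sample"},
            "A2": {"condition": "mut", "role": "sample"},
            "H1": {"condition": "mock", "role": "negative_control"},
        },
        conditions={
            "WT": {"inclusion_mean": 0.35, "cells_per_field": 40},
            "mut": {"inclusion_mean": 0.85, "cells_per_field": 40},
            "mock": {"transfection_rate": 0.0, "cells_per_field": 40,
                     "role": "negative_control"},
        },
    )


@pytest.fixture(scope="session")
def small_plate(three_well_layout, small_optics) -> h.PlateDataset:
    return h.generate_plate(three_well_layout, small_optics, seed=7)


@pytest.fixture(scope="session")
def small_result(small_plate, three_well_layout) -> h.PipelineResult:
    return h.analyze_plate(small_plate, three_well_layout)


def disc_image(shape, centers, radius, fg=600.0, bg=100.0, dtype=np.uint16):
    """Flat-background image with bright discs at the given (y, x) centres."""
    img = np.full(shape, bg, dtype=np.float64)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = fg
    return img.astype(dtype)
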