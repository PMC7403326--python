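"""Shared phantom fixtures.

Volumes are generated programmatically at session scope where reuse across
test modules pays (the finger phantom and the noisy rendered volume are the
expensive ones).
"""

import numpy as np
import pytest

from mucoct import PhantomSpec, build_lut, generate_phantom, render_grayscale


@pytest.fixture(scope="session")
def lut2um():
    """13-direction LUT at 2 µm isotropic spacing."""
    return build_lut(13, (2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def flat_slab():
    spec = PhantomSpec(
        kind="flat_slab", volume_dims=(64, 300, 300), voxel_spacing=(2.0, 2.0, 2.0),
        slab_thickness=100.0,
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def sinusoid_300():
    spec = PhantomSpec(
        kind="sinusoid", volume_dims=(240, 300, 300), voxel_spacing=(2.0, 2.0, 2.0),
        slab_thickness=100.0, villus_height=300.0, wavelength=250.0,
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def finger_crypt():
    """Finger villi h=300 µm with 150 µm crypts; lateral extent chosen so a
    centred 0.5 mm rectangle's edges fall between villi and crypt wells."""
    spec = PhantomSpec(
        kind="finger_villi", volume_dims=(300, 350, 350), voxel_spacing=(2.0, 2.0, 2.0),
        slab_thickness=250.0, villus_height=300.0, villus_radius=25.0, villus_pitch=125.0,
        crypt_depth=150.0, crypt_radius=15.0,
    )
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_render():
    """Sinusoidal mucosa rendered at levels 50/200 with blur and sigma=15 noise."""
    spec = PhantomSpec(
        kind="sinusoid", volume_dims=(96, 96, 96), voxel_spacing=(2.0, 2.0, 2.0),
        slab_thickness=40.0, villus_height=100.0, wavelength=96.0,
    )
    binary = generate_phantom(spec)
    gray = render_grayscale(binary, noise_sigma=15.0, blur_sigma=2.0, seed=7)
    return binary, gray
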