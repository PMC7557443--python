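import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from adhesivect.distribution import AnchorPoints, AreaWidthDistribution
from adhesivect.phantom import PhantomSpec, generate_phantom
from adhesivect.swmodel import build_model_from_anchors
from adhesivect.volume import AdhesiveMask


@pytest.fixture(scope="session")
def constant_phantom():
    """Noise-free constant 0.1 mm film on a 0.005 mm grid."""
    spec = PhantomSpec(
        grid_shape=(96, 64, 64),
        voxel_size=0.005,
        base_thickness=0.1,
        variation_amplitude=0.0,
        noise_sigma=0.0,
        seed=0,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def variable_phantom():
    """Noise-free gently varying film (slope small next to the thickness)."""
    spec = PhantomSpec(
        grid_shape=(64, 96, 96),
        voxel_size=0.005,
        base_thickness=0.1,
        variation_amplitude=0.03,
        correlation_length=0.15,
        noise_sigma=0.0,
        seed=5,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Same film with the default intensity noise level."""
    spec = PhantomSpec(
        grid_shape=(64, 96, 96),
        voxel_size=0.005,
        base_thickness=0.1,
        variation_amplitude=0.03,
        correlation_length=0.15,
        noise_sigma=8.0,
        seed=5,
    )
    return spec, *generate_phantom(spec)


def random_blob_mask(seed: int, shape=(24, 24, 24), voxel_size=0.01) -> AdhesiveMask:
    """Smoothed-noise blob mask for oracle sweeps."""
    rng = np.random.default_rng(seed)
    field = gaussian_filter(rng.standard_normal(shape), 2.0)
    mask = field > np.quantile(field, 0.7)
    return AdhesiveMask(mask, voxel_size)


def slab_mask(k: int, voxel_size=0.01, margin=10, lateral=20) -> AdhesiveMask:
    m = np.zeros((k + 2 * margin, lateral, lateral), dtype=bool)
    m[margin : margin + k] = True
    return AdhesiveMask(m, voxel_size)


GROUP4_ANCHORS = AnchorPoints(
    w0=0.0, S0=0.0, wM=0.015, SM=0.015, wI=0.18, SI=0.002, wmax=0.36, Sm=0.0
)

GROUP1_ANCHORS = AnchorPoints(
    w0=0.0, S0=0.0, wM=0.07, SM=0.014, wI=0.2, SI=0.008, wmax=0.4, Sm=0.002
)


def distribution_from_model(model, bin_width=0.01) -> AreaWidthDistribution:
    """Sample a piecewise model at bin centres into a distribution object."""
    edges = np.arange(model.knots[0], model.wmax + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = centers <= model.wmax
    centers, edges = centers[keep], edges[: keep.sum() + 1]
    areas = np.maximum(model.evaluate(centers), 0.0)
    return AreaWidthDistribution(edges, areas, {"synthesized": True})


def random_anchor_model(rng: np.random.Generator):
    """A random valid model from random anchors (either template)."""
    template = "A" if rng.random() < 0.5 else "B"
    if template == "A":
        w0 = rng.uniform(0.0, 0.03)
        wM = w0 + rng.uniform(0.04, 0.1)
    else:
        w0 = 0.0
        wM = rng.uniform(0.008, 0.045)
    wI = wM + rng.uniform(0.03, 0.2)
    wmax = wI + rng.uniform(0.03, 0.2)
    SM = rng.uniform(0.005, 0.05)
    anchors = AnchorPoints(
        w0=w0,
        S0=rng.uniform(0.0, 0.2) * SM,
        wM=wM,
        SM=SM,
        wI=wI,
        SI=rng.uniform(0.02, 0.6) * SM,
        wmax=wmax,
        Sm=rng.uniform(0.0, 0.3) * SM,
    )
    return build_model_from_anchors(anchors, template), anchors
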