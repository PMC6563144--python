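"""Synthetic brightfield microscopy: phantoms, z-stacks and in-flow frames.

This module emulates the acquisition side of a brightfield imaging-flow
platform so the learning stages can be exercised with complete ground
truth.  Cells are modelled as parametric shape masks — discs for round
yeast and beads, a disc with a smaller tangent disc for budding cells,
capsules for fission (rod-shaped) yeast and pointed lenses for
lemon-shaped yeast — rendered with edge-localised brightfield contrast.

Image formation is deliberately phenomenological rather than a rigorous
diffraction model: defocus is a Gaussian blur whose scale grows linearly
with distance from the focal plane,

    sigma(z) = sigma0 + defocus_slope * |z|,

and a signed through-focus asymmetry multiplies the dark edge ring by
``1 + asym_strength * sign(z) * min(|z|, z_sat)``, mimicking the
bright/dark ring inversion real brightfield optics exhibit through focus.
With a purely symmetric blur the sign of the z-displacement would be
fundamentally unidentifiable, and the signed regression stages could not
work; the asymmetry term is what makes the sign learnable.  The interior
contrast term is left untouched by the asymmetry so that shape remains
visible at any defocus.

All intensities are floats in [0, 1]; integer bit depths exist only at
file boundaries.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

SPECIES = ("round", "budding", "rod", "lemon", "bead")

#: default characteristic-size samplers (µm), kept inside the 3-12 µm
#: range of the yeast species being emulated; beads are rigid 6 µm spheres
_SIZE_RANGES = {
    "round": {"radius": (2.0, 3.5)},
    "budding": {"radius": (2.0, 3.2), "bud_ratio": (0.5, 0.75)},
    "rod": {"length": (7.0, 12.0), "width": (3.0, 4.0)},
    "lemon": {"length": (6.0, 10.0), "width": (4.0, 5.5)},
    "bead": {"radius": (3.0, 3.0)},
}


@dataclass(frozen=True)
class OpticalModel:
    """Phenomenological brightfield image formation parameters.

    sigma0, defocus_slope are in px and px/µm; asym_strength is the signed
    through-focus contrast coefficient; z_sat (µm) caps the asymmetry so
    contrast stays bounded at large defocus.
    """

    sigma0: float = 1.2
    defocus_slope: float = 1.0
    asym_strength: float = 0.3
    background: float = 0.55
    noise_std: float = 0.02
    px_size: float = 0.25
    z_sat: float = 3.0
    edge_width: float = 1.5          # px, width of the dark edge ring
    edge_depth: float = 0.25         # intensity drop of the in-focus ring
    interior_gain: float = 0.10      # intensity lift inside the cell body
    motion_blur_px: float = 0.0      # optional along-flow box blur

    def __post_init__(self):
        vals = (self.sigma0, self.defocus_slope, self.asym_strength,
                self.background, self.noise_std, self.px_size, self.z_sat)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("optical model parameters must be finite")
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        if self.defocus_slope < 0:
            raise ValueError("defocus_slope must be >= 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if self.px_size <= 0:
            raise ValueError("px_size must be > 0")

    def blur_sigma(self, z_um: float) -> float:
        """Gaussian blur scale (px) at displacement ``z_um`` from focus."""
        return self.sigma0 + self.defocus_slope * abs(z_um)

    def asym_factor(self, z_um: float) -> float:
        """Signed edge-contrast multiplier at displacement ``z_um``."""
        return 1.0 + self.asym_strength * np.sign(z_um) * min(abs(z_um), self.z_sat)


@dataclass(frozen=True)
class CellPhantom:
    """One cell (or bead) to render: shape, size, pose and z-displacement.

    size_params are µm: ``radius`` for round/bead, ``radius`` + ``bud_ratio``
    for budding, ``length`` + ``width`` for rod/lemon.  ``xy`` is the centre
    in px (row, col); ``z`` is the signed displacement from focus in µm.
    """

    species: str
    size_params: dict
    orientation: float = 0.0
    xy: tuple[float, float] = (0.0, 0.0)
    z: float = 0.0

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        size = self.characteristic_size()
        if not 3.0 <= size <= 12.0:
            raise ValueError(
                f"characteristic size {size:.2f} um outside the 3-12 um range")

    def characteristic_size(self) -> float:
        """Largest extent of the shape in µm."""
        p = self.size_params
        if self.species in ("round", "bead"):
            return 2.0 * p["radius"]
        if self.species == "budding":
            return 2.0 * p["radius"] * (1.0 + p["bud_ratio"])
        return p["length"]


@dataclass(frozen=True)
class ZStackSpec:
    n_slices: int = 41
    spacing: float = 0.25            # µm between slices
    frame_size: tuple[int, int] = (48, 48)
    seed: int = 0
    focal_index: int | None = None   # defaults to the centre slice

    def __post_init__(self):
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def focus(self) -> int:
        return self.n_slices // 2 if self.focal_index is None else self.focal_index


@dataclass(frozen=True)
class FlowSequenceSpec:
    n_frames: int = 100
    species_mixture: dict = field(default_factory=lambda: {"round": 0.5, "rod": 0.5})
    event_rate: float = 0.9
    z_distribution: dict = field(default_factory=lambda: {"kind": "normal",
                                                          "mean": 0.0, "std": 1.0})
    orientation_bias: float = 4.0    # von Mises kappa toward the flow axis
    frame_size: tuple[int, int] = (160, 160)
    seed: int = 0

    def __post_init__(self):
        props = np.array(list(self.species_mixture.values()), dtype=float)
        if (props < 0).any():
            raise ValueError("mixture proportions must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if not 0.0 <= self.event_rate <= 1.0:
            raise ValueError("event_rate must be in [0, 1]")


@dataclass
class Frame:
    pixels: np.ndarray               # (H, W) float32 in [0, 1]
    px_size: float


@dataclass
class ZStack:
    slices: np.ndarray               # (n, H, W) float32
    px_size: float
    spacing: float
    z_labels: np.ndarray             # (n,) signed µm of object centre from focus


# ------------------------------------------------------------ shape masks

def _shape_sdf(phantom: CellPhantom, px_size: float, shape: tuple[int, int]) -> np.ndarray:
    """Signed distance (px, negative inside) of the phantom outline."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float32)
    cy, cx = phantom.xy
    y = rr - cy
    x = cc - cx
    # rotate into shape coordinates (major axis = u)
    co, si = np.cos(phantom.orientation), np.sin(phantom.orientation)
    u = co * x + si * y
    v = -si * x + co * y
    p = {k: val / px_size for k, val in phantom.size_params.items()
         if k != "bud_ratio"}
    sp = phantom.species
    if sp in ("round", "bead"):
        return np.hypot(u, v) - p["radius"]
    if sp == "budding":
        r_m = p["radius"]
        r_b = r_m * phantom.size_params["bud_ratio"]
        d_m = np.hypot(u, v) - r_m
        d_b = np.hypot(u - (r_m + r_b), v) - r_b
        return np.minimum(d_m, d_b)
    if sp == "rod":
        half = max(p["length"] / 2 - p["width"] / 2, 0.0)
        uc = np.clip(u, -half, half)
        return np.hypot(u - uc, v) - p["width"] / 2
    # lemon: intersection of two discs gives a pointed lens along u
    a = p["length"] / 2
    b = p["width"] / 2
    if a < b:
        a, b = b, a
    big_r = (a * a + b * b) / (2 * b)
    off = big_r - b
    d1 = np.hypot(u, v - off) - big_r
    d2 = np.hypot(u, v + off) - big_r
    return np.maximum(d1, d2)


def _phantom_deviation(phantom: CellPhantom, optics: OpticalModel,
                       shape: tuple[int, int]) -> np.ndarray:
    """Blurred intensity deviation from background for one phantom."""
    sdf = _shape_sdf(phantom, optics.px_size, shape)
    ew = optics.edge_width
    edge = np.exp(-0.5 * (sdf / ew) ** 2)
    interior = 1.0 / (1.0 + np.exp(np.clip(sdf / ew, -30, 30)))
    dev = (optics.interior_gain * interior
           - optics.edge_depth * optics.asym_factor(phantom.z) * edge)
    sigma = optics.blur_sigma(phantom.z)
    dev = ndimage.gaussian_filter(dev, sigma, mode="constant")
    if optics.motion_blur_px > 0:
        size = max(int(round(optics.motion_blur_px)), 1)
        dev = ndimage.uniform_filter1d(dev, size, axis=1, mode="constant")
    return dev.astype(np.float32)


def _check_fit(phantom: CellPhantom, optics: OpticalModel,
               shape: tuple[int, int]) -> None:
    extent_px = phantom.characteristic_size() / optics.px_size / 2
    margin = extent_px + 2.0 * optics.blur_sigma(phantom.z)
    cy, cx = phantom.xy
    h, w = shape
    if (cy - margin < 0 or cx - margin < 0
            or cy + margin > h - 1 or cx + margin > w - 1):
        warnings.warn("phantom support clipped by the frame boundary",
                      stacklevel=3)


def render_phantom(phantom: CellPhantom, optics: OpticalModel,
                   frame_size: tuple[int, int], seed: int | None = None,
                   rng: np.random.Generator | None = None) -> Frame:
    """Render a single phantom into a noisy brightfield frame.

    Deterministic given ``seed`` (or the state of ``rng``).  Noise is added
    last; intensities are clipped to [0, 1].
    """
    h, w = frame_size
    if not np.isfinite(phantom.z):
        raise ValueError("phantom z must be finite")
    support = 2 * int(np.ceil(2 * optics.blur_sigma(phantom.z))) + 1
    if min(h, w) < support:
        raise ValueError(
            f"frame {frame_size} too small for blur support {support} px")
    _check_fit(phantom, optics, frame_size)
    img = optics.background + _phantom_deviation(phantom, optics, (h, w))
    if optics.noise_std > 0:
        if rng is None:
            rng = np.random.default_rng(0 if seed is None else seed)
        img = img + rng.normal(0.0, optics.noise_std, size=img.shape)
    return Frame(np.clip(img, 0.0, 1.0).astype(np.float32), optics.px_size)


def render_multi(phantoms: list[CellPhantom], optics: OpticalModel,
                 frame_size: tuple[int, int], seed: int | None = None) -> Frame:
    """Render several phantoms (each with its own z) into one frame.

    Used for composite events such as an in-focus mother with an
    out-of-focus bud; deviations superpose additively.
    """
    h, w = frame_size
    img = np.full((h, w), optics.background, dtype=np.float32)
    for ph in phantoms:
        img += _phantom_deviation(ph, optics, (h, w))
    if optics.noise_std > 0:
        rng = np.random.default_rng(0 if seed is None else seed)
        img = img + rng.normal(0.0, optics.noise_std, size=img.shape)
    return Frame(np.clip(img, 0.0, 1.0).astype(np.float32), optics.px_size)


def background_frame(optics: OpticalModel, frame_size: tuple[int, int],
                     rng: np.random.Generator) -> Frame:
    img = np.full(frame_size, optics.background, dtype=np.float32)
    if optics.noise_std > 0:
        img = img + rng.normal(0.0, optics.noise_std, size=img.shape)
    return Frame(np.clip(img, 0.0, 1.0).astype(np.float32), optics.px_size)


# ------------------------------------------------------------- z-stacks

def generate_zstack(phantom: CellPhantom, optics: OpticalModel,
                    spec: ZStackSpec) -> ZStack:
    """Render a through-focus stack of one phantom.

    Slice ``i`` is the phantom displaced to ``z + (i - focal_index) *
    spacing``; the returned z labels are those displacements — the signed
    distance of the object centre from the focal plane at each slice.
    """
    rng = np.random.default_rng(spec.seed)
    offsets = (np.arange(spec.n_slices) - spec.focus) * spec.spacing
    z_labels = phantom.z + offsets
    slices = np.empty((spec.n_slices,) + tuple(spec.frame_size), dtype=np.float32)
    for i, z in enumerate(z_labels):
        ph = replace(phantom, z=float(z))
        slices[i] = render_phantom(ph, optics, spec.frame_size, rng=rng).pixels
    return ZStack(slices, optics.px_size, spec.spacing, z_labels)


def sample_phantom(species: str, rng: np.random.Generator,
                   frame_size: tuple[int, int], z: float = 0.0,
                   orientation: float | None = None,
                   orientation_bias: float = 0.0,
                   center_jitter: float = 0.0) -> CellPhantom:
    """Draw a phantom of the given species with randomized size and pose."""
    ranges = _SIZE_RANGES[species]
    params = {k: float(rng.uniform(*v)) for k, v in ranges.items()}
    if orientation is None:
        if orientation_bias > 0:
            orientation = float(rng.vonmises(0.0, orientation_bias))
        else:
            orientation = float(rng.uniform(-np.pi, np.pi))
    h, w = frame_size
    cy, cx = (h - 1) / 2, (w - 1) / 2
    if center_jitter > 0:
        cy += float(rng.normal(0, center_jitter))
        cx += float(rng.normal(0, center_jitter))
    return CellPhantom(species, params, orientation, (cy, cx), z)


def make_z_sampler(spec: dict):
    """Build a z-displacement sampler from a declarative dict.

    Supported kinds: ``normal`` (mean, std), ``uniform`` (low, high),
    ``bimodal`` (means, stds, weights of two normals), ``constant`` (value).
    """
    kind = spec.get("kind", "normal")
    if kind == "normal":
        m, s = spec.get("mean", 0.0), spec.get("std", 1.0)
        return lambda rng, n: rng.normal(m, s, size=n)
    if kind == "uniform":
        lo, hi = spec["low"], spec["high"]
        return lambda rng, n: rng.uniform(lo, hi, size=n)
    if kind == "bimodal":
        means = spec["means"]
        stds = spec.get("stds", [1.0, 1.0])
        weights = np.asarray(spec.get("weights", [0.5, 0.5]), dtype=float)
        weights = weights / weights.sum()

        def sample(rng, n):
            comp = rng.choice(2, size=n, p=weights)
            return rng.normal(np.take(means, comp), np.take(stds, comp))
        return sample
    if kind == "constant":
        val = spec.get("value", 0.0)
        return lambda rng, n: np.full(n, float(val))
    raise ValueError(f"unknown z_distribution kind {kind!r}")


def generate_flow_sequence(spec: FlowSequenceSpec, optics: OpticalModel):
    """Simulate an in-flow image stream: at most one cell event per frame.

    Returns ``(frames, truth)`` where ``truth`` is a DataFrame with one row
    per frame and columns frame, has_cell, species, x_px, y_px, z_um,
    orientation_rad (NaN/empty where has_cell is False).
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.species_mixture.keys())
    probs = np.array([spec.species_mixture[n] for n in names], dtype=float)
    z_sampler = make_z_sampler(spec.z_distribution)

    has_cell = rng.random(spec.n_frames) < spec.event_rate
    species_draws = rng.choice(len(names), size=spec.n_frames, p=probs)
    z_draws = z_sampler(rng, spec.n_frames)

    frames: list[Frame] = []
    rows = []
    jitter = min(spec.frame_size) / 12.0
    for i in range(spec.n_frames):
        if has_cell[i]:
            sp = names[species_draws[i]]
            ph = sample_phantom(sp, rng, spec.frame_size, z=float(z_draws[i]),
                                orientation_bias=spec.orientation_bias,
                                center_jitter=jitter)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                frames.append(render_phantom(ph, optics, spec.frame_size, rng=rng))
            rows.append((i, True, sp, ph.xy[1], ph.xy[0], ph.z, ph.orientation))
        else:
            frames.append(background_frame(optics, spec.frame_size, rng))
            rows.append((i, False, "", np.nan, np.nan, np.nan, np.nan))
    truth = pd.DataFrame(rows, columns=["frame", "has_cell", "species",
                                        "x_px", "y_px", "z_um",
                                        "orientation_rad"])
    return frames, truth
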