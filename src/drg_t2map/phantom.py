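"""Digital DRG phantoms with known voxelwise ground truth.

The phantom is four ellipsoidal "ganglia" (bilateral L5 and S1) embedded in a
uniform background, imaged by the CPMG forward model under a smooth B1 field
and Rician magnitude noise.  Default geometry places the S1 ellipsoids at
about 1.46 times the L5 volume, matching the in-vivo S1 > L5 volume gradient,
with absolute volumes near the cohort level medians (~900 / ~1320 mm³).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .epg import EchoTrainParams, epg_cpmg

__all__ = [
    "DRGDef",
    "B1FieldSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "perturb_mask_as_reader",
]

DRG_LABELS = ("L5-left", "L5-right", "S1-left", "S1-right")


@dataclass(frozen=True)
class DRGDef:
    """One ellipsoidal ganglion: label, centre/semi-axes in mm, true T2 and PD."""

    label: str
    label_value: int
    centre_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    true_t2_ms: float
    true_pd: float = 1.0


@dataclass(frozen=True)
class B1FieldSpec:
    """Smooth multiplicative flip-angle scale field.

    ``constant`` short-circuits to a uniform field.  Otherwise the field is a
    base level plus seeded low-order terms (linear gradients and one Gaussian
    dip) whose coefficient ranges guarantee values within [0.6, 1.1].
    """

    constant: float | None = None
    base: float = 0.92
    gradient_range: float = 0.05  # max |linear| contribution across the FOV
    dip_depth_range: tuple[float, float] = (0.05, 0.15)
    dip_width_mm: float = 25.0


def _default_drgs() -> tuple[DRGDef, ...]:
    # 32x32x12 grid at 1.5x1.5x1.8 mm spans 48 x 48 x 21.6 mm.
    return (
        DRGDef("L5-left", 1, (12.0, 12.0, 10.8), (5.9, 5.5, 6.6), 92.9),
        DRGDef("L5-right", 2, (36.0, 12.0, 10.8), (5.9, 5.5, 6.6), 92.9),
        DRGDef("S1-left", 3, (12.0, 36.0, 10.8), (6.7, 6.3, 7.5), 96.8),
        DRGDef("S1-right", 4, (36.0, 36.0, 10.8), (6.7, 6.3, 7.5), 96.8),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a digital DRG phantom acquisition."""

    grid_shape: tuple[int, int, int] = (32, 32, 12)
    voxel_dims_mm: tuple[float, float, float] = (1.5, 1.5, 1.8)
    drg_defs: tuple[DRGDef, ...] = field(default_factory=_default_drgs)
    background_t2_ms: float = 60.0
    background_pd: float = 0.25
    b1_field: B1FieldSpec = field(default_factory=B1FieldSpec)
    snr: float = 50.0
    t1_ms: float = 1000.0
    echo_params: EchoTrainParams = field(default_factory=EchoTrainParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isinf(self.snr) or self.snr > 0):
            raise ValueError("snr must be positive (or inf for noiseless)")
        for d in self.drg_defs:
            if any(a <= 0 for a in d.semi_axes_mm):
                raise ValueError(f"{d.label}: semi-axes must be positive")
            if not 10 < d.true_t2_ms < 500:
                raise ValueError(f"{d.label}: true_T2 must lie in (10, 500) ms")


@dataclass
class PhantomTruth:
    """Per-voxel ground truth of a generated phantom."""

    t2_ms: np.ndarray
    pd: np.ndarray
    b1: np.ndarray
    noise_sigma: float
    echo_times_ms: np.ndarray
    drg_truth: dict[str, dict]
    affine: np.ndarray


def _voxel_centres_mm(spec: PhantomSpec):
    axes = [
        (np.arange(n) + 0.5) * d
        for n, d in zip(spec.grid_shape, spec.voxel_dims_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _b1_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    b = spec.b1_field
    if b.constant is not None:
        return np.full(spec.grid_shape, float(b.constant))
    xs, ys, zs = _voxel_centres_mm(spec)
    extent = [n * d for n, d in zip(spec.grid_shape, spec.voxel_dims_mm)]
    # Normalised coordinates in [-0.5, 0.5].
    u = [(c - e / 2.0) / e for c, e in zip((xs, ys, zs), extent)]
    g = rng.uniform(-b.gradient_range, b.gradient_range, size=3)
    field_ = b.base + g[0] * u[0] + g[1] * u[1] + g[2] * u[2]
    depth = rng.uniform(*b.dip_depth_range)
    centre = [rng.uniform(0.25 * e, 0.75 * e) for e in extent]
    r2 = sum((c - c0) ** 2 for c, c0 in zip((xs, ys, zs), centre))
    field_ = field_ - depth * np.exp(-r2 / (2.0 * b.dip_width_mm**2))
    return np.clip(field_, 0.6, 1.1)


def _ellipsoid_mask(spec: PhantomSpec, d: DRGDef) -> np.ndarray:
    xs, ys, zs = _voxel_centres_mm(spec)
    q = sum(
        ((c - c0) / a) ** 2
        for c, c0, a in zip((xs, ys, zs), d.centre_mm, d.semi_axes_mm)
    )
    return q <= 1.0


def generate_phantom(spec: PhantomSpec):
    """Simulate a 4D multi-echo acquisition over the phantom.

    Returns ``(volume, mask, truth)``: the 4D magnitude volume (last axis =
    echo), the 3D integer label mask, and a :class:`PhantomTruth` with every
    per-voxel true value.  The noiseless voxel signal is
    ``PD × epg_cpmg(T2, T1, b1(voxel))``; Rician noise adds two independent
    Gaussian channels of width ``sigma = max(PD)/snr`` before taking the
    magnitude.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    b1 = _b1_field(spec, rng)

    t2 = np.full(spec.grid_shape, float(spec.background_t2_ms))
    pd = np.full(spec.grid_shape, float(spec.background_pd))
    mask = np.zeros(spec.grid_shape, dtype=np.int16)
    for d in spec.drg_defs:
        m = _ellipsoid_mask(spec, d)
        if not m.any():
            raise ValueError(f"{d.label}: ellipsoid covers no voxels on the grid")
        if np.any(mask[m] != 0):
            raise ValueError(f"{d.label}: ellipsoids overlap on the grid")
        mask[m] = d.label_value
        t2[m] = d.true_t2_ms
        pd[m] = d.true_pd

    signal = pd[..., None] * epg_cpmg(t2, spec.t1_ms, b1, spec.echo_params)

    if np.isinf(spec.snr):
        sigma = 0.0
        vol = signal
    else:
        sigma = float(pd.max()) / spec.snr
        shape = signal.shape
        vol = np.sqrt(
            (signal + rng.normal(0.0, sigma, shape)) ** 2
            + rng.normal(0.0, sigma, shape) ** 2
        )

    affine = np.diag([*spec.voxel_dims_mm, 1.0])
    drg_truth = {
        d.label: {
            "label_value": d.label_value,
            "true_t2_ms": d.true_t2_ms,
            "true_pd": d.true_pd,
            "n_voxels": int((mask == d.label_value).sum()),
            "volume_mm3": float(
                (mask == d.label_value).sum() * np.prod(spec.voxel_dims_mm)
            ),
        }
        for d in spec.drg_defs
    }
    truth = PhantomTruth(
        t2_ms=t2,
        pd=pd,
        b1=b1,
        noise_sigma=sigma,
        echo_times_ms=spec.echo_params.echo_times_ms,
        drg_truth=drg_truth,
        affine=affine,
    )
    return vol, mask, truth


def perturb_mask_as_reader(
    mask: np.ndarray,
    reader_id: str | int,
    seed: int,
    rate: float = 0.05,
    labels=None,
) -> np.ndarray:
    """Emulate a reader's manual segmentation of each label.

    Boundary voxels are flipped independently: surface voxels of the label are
    removed and adjacent background voxels added, each with probability
    ``rate``, so the expected relative change in voxel count stays well below
    ``rate``.  6-connectivity of each label is preserved (a perturbation that
    would disconnect or empty a label is redrawn; emptying ultimately raises).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    mask = np.asarray(mask)
    out = mask.copy()
    if labels is None:
        labels = [int(v) for v in np.unique(mask) if v != 0]
    if not labels:
        raise ValueError("mask contains no labels")
    for lab in labels:
        if not (mask == lab).any():
            raise ValueError(f"label {lab} absent from mask")
    if rate == 0:
        return out

    reader_key = zlib.crc32(str(reader_id).encode())  # stable across processes
    ss = np.random.SeedSequence([int(seed), reader_key])
    rng = np.random.default_rng(ss)
    struct = ndimage.generate_binary_structure(mask.ndim, 1)

    for lab in labels:
        binary = mask == lab
        for _attempt in range(10):
            inner = binary & ~ndimage.binary_erosion(binary, struct)
            outer = ndimage.binary_dilation(binary, struct) & (out == 0)
            remove = inner & (rng.random(mask.shape) < rate)
            add = outer & (rng.random(mask.shape) < rate)
            new = (binary & ~remove) | add
            if not new.any():
                continue
            _, n_comp = ndimage.label(new, struct)
            if n_comp == 1:
                out[binary & ~new] = 0
                out[new & ~binary] = lab
                break
        else:
            raise ValueError(f"label {lab}: could not perturb without emptying/splitting")
    return out
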