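"""Synthetic 2D diffusion-weighted MRI phantoms with known ground truth.

A phantom is a set of parametric compartments (ellipses or rectangles)
painted onto a background, each carrying a proton-density-like signal
``s0`` and an apparent diffusion coefficient (ADC, mm^2/s).  Optionally a
compartment may specify a per-direction ADC 3-vector to emulate diffusion
anisotropy along three orthogonal encoding directions.

The noiseless signal model is monoexponential decay::

    S(b) = S0 * exp(-b * ADC_direction)

with ``b`` in s/mm^2.  ADC values are stored internally in mm^2/s; the
conventional display scale (x10^-3 mm^2/s) is left to reporting code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Compartment",
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "noiseless_signal",
    "random_phantom_spec",
]

#: Default ADC of background voxels (free-water-like), mm^2/s.
DEFAULT_BACKGROUND_ADC = 2.0e-3

#: Physiologically plausible upper bound for ADC, mm^2/s.
MAX_ADC = 4.0e-3


@dataclass(frozen=True)
class Compartment:
    """A single tissue compartment painted onto the phantom grid.

    Parameters
    ----------
    label : str
        Name of the compartment; lesion labels key the ROI masks.
    shape : {"ellipse", "rectangle"}
        Parametric geometry type.
    center : (float, float)
        Row/column of the geometry centre, in pixel coordinates.
    radii : (float, float)
        Semi-axes (ellipse) or half-sides (rectangle) along the rotated
        row/column axes, in pixels.
    s0 : float
        Noiseless signal at b = 0, arbitrary scanner units, > 0.
    adc : float
        Isotropic ADC in mm^2/s, within [0, 4e-3].
    adc_per_direction : tuple of 3 floats, optional
        Per-direction ADCs (mm^2/s); when given, supersedes ``adc`` and
        ``adc`` is interpreted as their mean for the scalar map.
    rotation : float
        Rotation of the geometry in radians, counter-clockwise.
    is_lesion : bool
        Lesion compartments get a dedicated ROI mask in the ground truth.
    """

    label: str
    shape: str
    center: tuple[float, float]
    radii: tuple[float, float]
    s0: float
    adc: float
    adc_per_direction: tuple[float, float, float] | None = None
    rotation: float = 0.0
    is_lesion: bool = False

    def __post_init__(self) -> None:
        if self.shape not in ("ellipse", "rectangle"):
            raise ValueError(f"unknown compartment shape: {self.shape!r}")
        if self.s0 <= 0:
            raise ValueError("compartment s0 must be > 0")
        if not (0.0 <= self.adc <= MAX_ADC):
            raise ValueError(f"adc must lie in [0, {MAX_ADC}] mm^2/s, got {self.adc}")
        if min(self.radii) <= 0:
            raise ValueError("compartment radii must be positive (zero-area geometry)")
        if self.adc_per_direction is not None:
            if len(self.adc_per_direction) != 3:
                raise ValueError("adc_per_direction must have exactly 3 entries")
            if any(a < 0 for a in self.adc_per_direction):
                raise ValueError("adc_per_direction entries must be >= 0")

    def directional_adc(self) -> tuple[float, float, float]:
        if self.adc_per_direction is not None:
            return tuple(self.adc_per_direction)
        return (self.adc, self.adc, self.adc)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic phantom."""

    grid_shape: tuple[int, int]
    compartments: tuple[Compartment, ...]
    background_s0: float = 0.0
    background_adc: float = DEFAULT_BACKGROUND_ADC
    seed: int = 0

    def to_dict(self) -> dict:
        """Plain-data form for YAML/JSON serialization."""
        return dict(
            grid_shape=list(self.grid_shape),
            background_s0=self.background_s0,
            background_adc=self.background_adc,
            seed=self.seed,
            compartments=[
                dict(
                    label=c.label,
                    shape=c.shape,
                    center=list(c.center),
                    radii=list(c.radii),
                    s0=c.s0,
                    adc=c.adc,
                    adc_per_direction=(
                        None if c.adc_per_direction is None else list(c.adc_per_direction)
                    ),
                    rotation=c.rotation,
                    is_lesion=c.is_lesion,
                )
                for c in self.compartments
            ],
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        comps = tuple(
            Compartment(
                label=c["label"],
                shape=c["shape"],
                center=tuple(c["center"]),
                radii=tuple(c["radii"]),
                s0=c["s0"],
                adc=c["adc"],
                adc_per_direction=(
                    None
                    if c.get("adc_per_direction") is None
                    else tuple(c["adc_per_direction"])
                ),
                rotation=c.get("rotation", 0.0),
                is_lesion=c.get("is_lesion", False),
            )
            for c in d["compartments"]
        )
        return cls(
            grid_shape=tuple(d["grid_shape"]),
            compartments=comps,
            background_s0=d.get("background_s0", 0.0),
            background_adc=d.get("background_adc", DEFAULT_BACKGROUND_ADC),
            seed=d.get("seed", 0),
        )

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 16 or cols < 16:
            raise ValueError("grid_shape dimensions must be >= 16")
        if not self.compartments:
            raise ValueError("at least one compartment is required")
        if self.background_s0 < 0:
            raise ValueError("background_s0 must be >= 0")
        for c in self.compartments:
            r, cc = c.center
            if not (0 <= r < rows and 0 <= cc < cols):
                raise ValueError(
                    f"compartment {c.label!r} centre {c.center} lies outside the grid"
                )
        object.__setattr__(self, "compartments", tuple(self.compartments))


@dataclass
class GroundTruth:
    """Known truth maps for a generated phantom.

    All maps share the phantom grid shape.  ``roi_masks`` maps each lesion
    label to its boolean mask.
    """

    s0_map: np.ndarray
    adc_map: np.ndarray
    adc_dir_maps: np.ndarray | None  # (3, rows, cols) or None
    roi_masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.s0_map.shape)

    def directional_adc_map(self, direction: int) -> np.ndarray:
        if not 0 <= direction <= 2:
            raise ValueError("direction index must be 0, 1 or 2")
        if self.adc_dir_maps is None:
            return self.adc_map
        return self.adc_dir_maps[direction]


def _rasterize(comp: Compartment, grid_shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the geometry."""
    rows, cols = grid_shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    dr = rr - comp.center[0]
    dc = cc - comp.center[1]
    if comp.rotation != 0.0:
        cos_t, sin_t = math.cos(comp.rotation), math.sin(comp.rotation)
        dr, dc = cos_t * dr + sin_t * dc, -sin_t * dr + cos_t * dc
    ar, ac = comp.radii
    if comp.shape == "ellipse":
        mask = (dr / ar) ** 2 + (dc / ac) ** 2 <= 1.0
    else:  # rectangle
        mask = (np.abs(dr) <= ar) & (np.abs(dc) <= ac)
    if not mask.any():
        raise ValueError(
            f"compartment {comp.label!r} rasterizes to zero pixels on {grid_shape}"
        )
    return mask


def generate_phantom(spec: PhantomSpec) -> GroundTruth:
    """Paint compartments onto the grid, later compartments overwriting earlier.

    Deterministic: the geometry is purely parametric and the seed is only
    recorded for downstream acquisition noise.
    """
    rows, cols = spec.grid_shape
    s0 = np.full((rows, cols), float(spec.background_s0))
    adc = np.full((rows, cols), float(spec.background_adc))
    any_aniso = any(c.adc_per_direction is not None for c in spec.compartments)
    adc_dir = None
    if any_aniso:
        adc_dir = np.full((3, rows, cols), float(spec.background_adc))

    roi_masks: dict[str, np.ndarray] = {}
    for comp in spec.compartments:
        mask = _rasterize(comp, spec.grid_shape)
        s0[mask] = comp.s0
        d = comp.directional_adc()
        adc[mask] = float(np.mean(d)) if comp.adc_per_direction is not None else comp.adc
        if adc_dir is not None:
            for j in range(3):
                adc_dir[j][mask] = d[j]
        if comp.is_lesion:
            roi_masks[comp.label] = mask

    for label, mask in roi_masks.items():
        if not mask.any():
            raise ValueError(f"lesion {label!r} has an empty ROI mask")
    return GroundTruth(s0_map=s0, adc_map=adc, adc_dir_maps=adc_dir, roi_masks=roi_masks)


def random_phantom_spec(
    seed: int,
    grid_shape: tuple[int, int] = (64, 64),
    n_tissues: tuple[int, int] = (2, 5),
    s0_range: tuple[float, float] = (800.0, 3200.0),
    adc_range: tuple[float, float] = (0.4e-3, 2.5e-3),
    lesion_adc: float = 0.7e-3,
    lesion_radius: float = 4.0,
    lesion_s0_range: tuple[float, float] = (1500.0, 3000.0),
    background_s0: float = 60.0,
) -> PhantomSpec:
    """Draw a random multi-compartment phantom with one low-ADC lesion.

    Tissue count, ellipse geometry, signal and diffusivity are sampled
    uniformly within the given ranges; the lesion is a small disc placed
    away from the grid edge.  Lesion geometry and ADC defaults are
    placeholders (configurable), not anatomical claims.
    """
    rng = np.random.default_rng(seed)
    rows, cols = grid_shape
    margin = max(lesion_radius + 2.0, min(12.0, min(rows, cols) / 5.0))
    comps: list[Compartment] = []
    for i in range(int(rng.integers(n_tissues[0], n_tissues[1]))):
        comps.append(
            Compartment(
                label=f"tissue{i}",
                shape="ellipse",
                center=(
                    float(rng.uniform(margin, rows - margin)),
                    float(rng.uniform(margin, cols - margin)),
                ),
                radii=(
                    float(rng.uniform(min(5.0, rows / 4.0), rows / 3.5)),
                    float(rng.uniform(min(5.0, cols / 4.0), cols / 3.5)),
                ),
                rotation=float(rng.uniform(0.0, math.pi)),
                s0=float(rng.uniform(*s0_range)),
                adc=float(rng.uniform(*adc_range)),
            )
        )
    comps.append(
        Compartment(
            label="lesion",
            shape="ellipse",
            center=(
                float(rng.uniform(min(margin + 4, rows / 2 - 1), max(rows - margin - 4, rows / 2 + 1))),
                float(rng.uniform(min(margin + 4, cols / 2 - 1), max(cols - margin - 4, cols / 2 + 1))),
            ),
            radii=(lesion_radius, lesion_radius),
            s0=float(rng.uniform(*lesion_s0_range)),
            adc=lesion_adc,
            is_lesion=True,
        )
    )
    return PhantomSpec(
        grid_shape=grid_shape,
        compartments=tuple(comps),
        background_s0=background_s0,
        seed=seed,
    )


def noiseless_signal(gt: GroundTruth, b: float, direction: int = 0) -> np.ndarray:
    """Noise-free monoexponential signal S0 * exp(-b * ADC) for one direction.

    Parameters
    ----------
    gt : GroundTruth
    b : float
        Diffusion weighting in s/mm^2, must be >= 0.
    direction : int
        Orthogonal encoding direction index in {0, 1, 2}.  Isotropic
        phantoms return the same image for every direction.
    """
    if b < 0:
        raise ValueError(f"b-value must be >= 0, got {b}")
    adc = gt.directional_adc_map(direction)
    return gt.s0_map * np.exp(-b * adc)
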