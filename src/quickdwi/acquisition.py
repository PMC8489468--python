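"""Scanner acquisition simulation and the clinical averaging scheme.

Repeated single-acquisition magnitude images are simulated with Rician
noise (magnitude of a complex Gaussian perturbation) and averaged the way
clinical diffusion imagers do: a geometric mean over the orthogonal
encoding directions yields a trace-weighted image per acquisition, and an
arithmetic mean over acquisitions yields the clinical-standard image.
With 3 directions and N repeats the result carries an effective number of
acquisitions of 3*N (e.g. NOA 9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import GroundTruth, noiseless_signal

__all__ = [
    "AcquisitionProtocol",
    "DWIStack",
    "TraceStack",
    "ClinicalImage",
    "acquire",
    "trace_weighted",
    "average_acquisitions",
    "normalize",
    "denormalize",
    "WHOLE_BODY_B_VALUES",
    "LUNG_B_VALUES",
    "WHOLE_BODY_CEILING",
    "LUNG_CEILING",
]

WHOLE_BODY_B_VALUES = (50.0, 600.0, 900.0)
LUNG_B_VALUES = (50.0, 600.0, 800.0, 900.0)
WHOLE_BODY_CEILING = 4095
LUNG_CEILING = 939

_LOG_EPS = 1e-12  # guards log(0) voxels in the geometric mean


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Acquisition parameters of the simulated scan."""

    b_values: tuple[float, ...] = WHOLE_BODY_B_VALUES
    n_directions: int = 3
    n_acquisitions: int = 3
    noise_sigma: float = 20.0
    intensity_ceiling: int = WHOLE_BODY_CEILING
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.b_values:
            raise ValueError("b_values must be nonempty")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b_values must be >= 0")
        if self.n_directions not in (1, 3):
            raise ValueError("n_directions must be 1 or 3")
        if self.n_acquisitions < 1:
            raise ValueError("n_acquisitions must be >= 1")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if self.intensity_ceiling <= 0:
            raise ValueError("intensity_ceiling must be > 0")
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))

    @property
    def noa(self) -> int:
        return self.n_directions * self.n_acquisitions


@dataclass
class DWIStack:
    """Acquired tensor indexed by (b, direction, acquisition, row, col)."""

    data: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        p = self.protocol
        expected = (len(p.b_values), p.n_directions, p.n_acquisitions)
        if self.data.ndim != 5 or self.data.shape[:3] != expected:
            raise ValueError(
                f"stack shape {self.data.shape} inconsistent with protocol axes {expected}"
            )
        if (self.data < 0).any():
            raise ValueError("magnitude images must be >= 0")


@dataclass
class TraceStack:
    """Trace-weighted images, indexed by (b, acquisition, row, col)."""

    data: np.ndarray
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("trace stack must have 4 axes")
        if (self.data < 0).any():
            raise ValueError("trace images must be >= 0")


@dataclass
class ClinicalImage:
    """Clinical-standard averaged image per b-value, with its effective NOA."""

    data: np.ndarray
    noa: int
    protocol: AcquisitionProtocol

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("clinical image must have 3 axes [b, row, col]")
        if (self.data < 0).any():
            raise ValueError("clinical images must be >= 0")


def acquire(
    gt: GroundTruth,
    protocol: AcquisitionProtocol,
    rng: np.random.Generator | None = None,
) -> DWIStack:
    """Simulate every (b, direction, acquisition) magnitude image.

    Each image is independently Rician-noised: ``sqrt((S + n1)^2 + n2^2)``
    with n1, n2 ~ N(0, sigma^2), then clipped to [0, intensity_ceiling]
    mimicking the scanner's integer output range.  Deterministic for a
    fixed protocol seed.
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    rows, cols = gt.grid_shape
    nb, nd, na = len(protocol.b_values), protocol.n_directions, protocol.n_acquisitions
    out = np.empty((nb, nd, na, rows, cols))
    for ib, b in enumerate(protocol.b_values):
        for j in range(nd):
            clean = noiseless_signal(gt, b, direction=j if nd == 3 else 0)
            n1 = rng.normal(0.0, protocol.noise_sigma, size=(na, rows, cols))
            n2 = rng.normal(0.0, protocol.noise_sigma, size=(na, rows, cols))
            out[ib, j] = np.sqrt((clean[None] + n1) ** 2 + n2**2)
    np.clip(out, 0.0, float(protocol.intensity_ceiling), out=out)
    return DWIStack(data=out, protocol=protocol)


def trace_weighted(stack: DWIStack) -> TraceStack:
    """Geometric mean over the direction axis (trace-weighted imaging).

    Computed as ``exp(mean(log(x + eps)))`` with a tiny eps guarding zero
    voxels; for the small direction counts used here the exact product
    path ``(prod x)^(1/n)`` agrees to 1e-10 on positive inputs.
    With a single direction this is the identity.
    """
    x = stack.data
    n = stack.protocol.n_directions
    if n == 1:
        return TraceStack(data=x[:, 0].copy(), protocol=stack.protocol)
    gm = np.exp(np.mean(np.log(x + _LOG_EPS), axis=1))
    # exact path for voxels that are all strictly positive
    exact = np.prod(x, axis=1) ** (1.0 / n)
    positive = (x > 0).all(axis=1)
    gm = np.where(positive, exact, gm)
    return TraceStack(data=gm, protocol=stack.protocol)


def average_acquisitions(traces: TraceStack) -> ClinicalImage:
    """Arithmetic mean over the acquisition axis; records the effective NOA."""
    if traces.data.shape[1] < 1:
        raise ValueError("need at least one acquisition")
    mean = traces.data.mean(axis=1)
    return ClinicalImage(data=mean, noa=traces.protocol.noa, protocol=traces.protocol)


def normalize(img: np.ndarray, ceiling: float) -> np.ndarray:
    """Map raw intensities in [0, ceiling] onto [0, 1] (values clipped first)."""
    if ceiling <= 0:
        raise ValueError("ceiling must be > 0")
    return np.clip(img, 0.0, float(ceiling)) / float(ceiling)


def denormalize(img: np.ndarray, ceiling: float) -> np.ndarray:
    """Inverse of :func:`normalize` on in-range data."""
    if ceiling <= 0:
        raise ValueError("ceiling must be > 0")
    return np.asarray(img) * float(ceiling)
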