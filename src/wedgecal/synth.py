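"""Synthetic gradients, wedge profiles and film scans.

Everything the planning and calibration pipelines consume can be
generated here with known ground truth:

* `make_gradient` — the idealized dose samples of one gradient exposure,
  a linear ramp between the exposure's dose bounds (uniform dose
  density, the natural null for the histogram-equalization objective).
* `make_wedge_profile` — a water-tank-like wedge scan: a linear in-field
  ramp whose 20-80 % chord dynamic range equals a requested eps_W,
  Gaussian penumbrae at the field edges, multiplicative Gaussian noise.
* `make_film_scan` — 48-bit-style RGB film scans (16 bits/channel) of a
  gradient exposure plan plus an unexposed control scan, with a known
  monotone, invertible dose-response in the green channel.

All randomness flows through a single seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import erf

from .dynrange import GradientSpec
from .profiles import WedgeProfile

if TYPE_CHECKING:  # pragma: no cover - type-only import, avoids a cycle
    from .optimize import ExposurePlan

__all__ = [
    "SyntheticProfileParams",
    "SyntheticFilmScan",
    "make_gradient",
    "make_wedge_profile",
    "make_film_scan",
    "film_response",
    "film_response_inverse",
    "CONTROL_LEVEL",
]

# Green-channel response of the synthetic film model, as a fraction of the
# unexposed (control) pixel value:  r(D) = 1 - a*D / (1 + b*D).
# A saturating rational curve: monotone decreasing and invertible up to
# D = 1/(a - b) ~ 33 Gy, comfortably beyond any calibration range used here.
_RESPONSE_A = 0.08  # 1/Gy, initial slope of the darkening
_RESPONSE_B = 0.05  # 1/Gy, saturation rate
CONTROL_LEVEL = 53000  # unexposed 16-bit green/red/blue pixel value


def film_response(dose):
    """Fractional green-channel response r(D) of the synthetic film."""
    dose = np.asarray(dose, dtype=float)
    return 1.0 - _RESPONSE_A * dose / (1.0 + _RESPONSE_B * dose)


def film_response_inverse(response):
    """Dose (Gy) at which the synthetic film gives fractional response r."""
    r = np.asarray(response, dtype=float)
    return (1.0 - r) / (_RESPONSE_A - _RESPONSE_B * (1.0 - r))


@dataclass(frozen=True)
class SyntheticProfileParams:
    """Parameters of a synthetic wedge-profile scan.

    Attributes
    ----------
    field_width : float
        Inter-edge field width, mm.
    target_drc : float
        Dynamic range coefficient the 20-80 % chord segmentation of the
        noise-free profile should recover, in [0, 2).
    penumbra_sigma : float
        Gaussian penumbra width at the field edges, mm.
    noise_sd : float
        Multiplicative Gaussian noise, as a fraction of the CAX value;
        must be < 0.1.
    sample_spacing : float
        Scan resolution, mm (1 mm emulates a water-tank scan).
    seed : int
        Seed for the noise generator.
    """

    field_width: float = 100.0
    target_drc: float = 0.454
    penumbra_sigma: float = 2.0
    noise_sd: float = 0.0
    sample_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width <= 10.0 * self.penumbra_sigma:
            raise ValueError(
                "field_width must exceed 10 * penumbra_sigma "
                f"({self.field_width} <= {10 * self.penumbra_sigma})"
            )
        if not 0.0 <= self.target_drc < 2.0:
            raise ValueError(f"target_drc must lie in [0, 2), got {self.target_drc}")
        if not 0.0 <= self.noise_sd < 0.1:
            raise ValueError(f"noise_sd must lie in [0, 0.1), got {self.noise_sd}")
        if self.sample_spacing <= 0:
            raise ValueError("sample_spacing must be positive")


def make_gradient(spec: GradientSpec) -> np.ndarray:
    """Dose samples of one synthetic gradient exposure.

    Returns ``spec.n_points`` doses equally spaced (inclusive) from the
    exposure's lower to upper bound — a linear ramp with uniform dose
    density.  500 points corresponds to a 10 cm slope read at 0.2 mm
    pixel size (127 dpi).
    """
    if spec.n_points == 1:
        return np.array([spec.cax_dose])
    return np.linspace(spec.lower_bound, spec.upper_bound, spec.n_points)


def _relative_wedge(x: np.ndarray, params: SyntheticProfileParams) -> np.ndarray:
    """Noise-free CAX-normalized wedge field sampled at positions x (mm).

    Exact Gaussian convolution of the in-field linear ramp with the
    boxcar field aperture: with ramp r(y) = 1 - m*y on [-h, h] and a
    Gaussian penumbra kernel of width sigma,

        f(x) = (1 - m*x) * [Phi((x+h)/s) - Phi((x-h)/s)]
               - m * s^2 * [phi_s(x+h) - phi_s(x-h)]

    The closed form avoids grid-discretization of the aperture, so the
    penumbral inflections sit exactly at +-h and the in-field region is
    exactly linear away from the edges.
    """
    half = params.field_width / 2.0
    sigma = params.penumbra_sigma
    # slope chosen so the 20-80 % chord spans target_drc:
    # rd(+-0.3 W) = 1 -+ 0.3*W*m  =>  drc = 0.6*W*m
    slope = params.target_drc / (0.6 * params.field_width)
    z_hi = (x + half) / sigma
    z_lo = (x - half) / sigma
    delta_phi = 0.5 * (erf(z_hi / np.sqrt(2.0)) - erf(z_lo / np.sqrt(2.0)))
    gauss = lambda z: np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)  # noqa: E731
    return (1.0 - slope * x) * delta_phi - slope * sigma * (
        gauss(z_hi) - gauss(z_lo)
    )


def make_wedge_profile(params: SyntheticProfileParams) -> WedgeProfile:
    """Synthesize a wedge-like scanned profile with known dynamic range.

    The profile is a linear in-field ramp (heel on the positive side)
    convolved with a Gaussian penumbra at both field edges, multiplied
    by ``1 + N(0, noise_sd)``, and sampled every ``sample_spacing`` mm
    over the field plus a 4-penumbra margin.  Deterministic per seed.
    """
    half = params.field_width / 2.0
    margin = max(4.0 * params.penumbra_sigma, 10.0)
    n = int(np.floor(2 * (half + margin) / params.sample_spacing)) + 1
    x = (np.arange(n) - (n - 1) / 2.0) * params.sample_spacing
    values = _relative_wedge(x, params)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        values = values * (1.0 + rng.normal(0.0, params.noise_sd, size=n))
    values = np.clip(values, 0.0, None)
    meta = {
        "target_drc": params.target_drc,
        "field_width_mm": params.field_width,
        "penumbra_sigma_mm": params.penumbra_sigma,
        "noise_sd": params.noise_sd,
        "seed": params.seed,
        "synthetic": True,
    }
    return WedgeProfile(x, values, meta)


@dataclass
class SyntheticFilmScan:
    """A synthetic 16-bit/channel RGB scan of one film.

    ``role`` is "exposed" or "control"; ``cax_dose`` is the CAX dose of
    the gradient delivered to an exposed film (None for the control).
    """

    image: np.ndarray
    dpi: float
    role: str
    cax_dose: float | None = None


def _dose_map(
    cax_dose: float, drc: float, shape: tuple[int, int], dpi: float
) -> np.ndarray:
    """Dose delivered to the film, varying along image columns.

    The exposed slope region (CAX dose scaled by a linear relative-dose
    ramp spanning +-drc/2 over the central 60 % of the field chord)
    covers the central 80 % of the image width; a Gaussian penumbra
    drops the dose to zero at the lateral margins.
    """
    height, width = shape
    px_mm = 25.4 / dpi
    x = (np.arange(width) - (width - 1) / 2.0) * px_mm  # mm
    field_half = 0.4 * width * px_mm
    # relative-dose ramp with 20-80 % chord span = drc (same convention
    # as the synthetic wedge profile)
    slope = drc / (0.6 * 2 * field_half) if field_half > 0 else 0.0
    ramp = 1.0 - slope * x
    field = np.where(np.abs(x) <= field_half, ramp, 0.0)
    field = gaussian_filter1d(field, sigma=max(2.0 / px_mm, 1.0), mode="nearest")
    return np.broadcast_to(cax_dose * field, (height, width))


def make_film_scan(
    plan: "ExposurePlan",
    image_shape: tuple[int, int] = (200, 700),
    noise_sd: float = 0.002,
    seed: int = 0,
    dpi: float = 127.0,
) -> tuple[list[SyntheticFilmScan], SyntheticFilmScan]:
    """Synthesize one exposed scan per plan exposure plus a control scan.

    The green channel encodes the film response
    ``CONTROL_LEVEL * film_response(D)`` of the wedge dose pattern; the
    red and blue channels and the control image are uniform at
    ``CONTROL_LEVEL``.  Additive Gaussian noise of sd
    ``noise_sd * CONTROL_LEVEL`` is applied per pixel.  Deterministic
    per seed.

    Returns
    -------
    (exposed, control)
        ``exposed`` is a list of `SyntheticFilmScan` (one per CAX dose
        in the plan, in order); ``control`` is the unexposed scan.
    """
    height, width = image_shape
    if height < 100 or width < 100:
        raise ValueError(f"image must be at least 100x100 px, got {image_shape}")
    rng = np.random.default_rng(seed)

    def _quantize(channel: np.ndarray) -> np.ndarray:
        noisy = channel + rng.normal(0.0, noise_sd * CONTROL_LEVEL, channel.shape)
        return np.clip(np.round(noisy), 0, 65535).astype(np.uint16)

    exposed = []
    for cax in plan.cax_doses:
        dose = _dose_map(cax, plan.drc, (height, width), dpi)
        green = CONTROL_LEVEL * film_response(dose)
        img = np.empty((height, width, 3), dtype=np.uint16)
        img[..., 0] = _quantize(np.full((height, width), float(CONTROL_LEVEL)))
        img[..., 1] = _quantize(green)
        img[..., 2] = _quantize(np.full((height, width), float(CONTROL_LEVEL)))
        exposed.append(
            SyntheticFilmScan(image=img, dpi=dpi, role="exposed", cax_dose=float(cax))
        )

    ctrl = np.empty((height, width, 3), dtype=np.uint16)
    for c in range(3):
        ctrl[..., c] = _quantize(np.full((height, width), float(CONTROL_LEVEL)))
    control = SyntheticFilmScan(image=ctrl, dpi=dpi, role="control")
    return exposed, control
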