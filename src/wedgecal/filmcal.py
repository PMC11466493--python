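"""Radiochromic film calibration from wedge-exposed scans.

Pipeline: green-channel normalized pixel values (PVnorm) are extracted
from 16-bit/channel RGB scans against an unexposed control film, the
central lines are averaged into a 1-D response profile, the profile is
edge-segmented and smoothed like any wedge profile, paired with the dose
ramp implied by the exposure's CAX dose and dynamic range coefficient,
and the merged (response, dose) points from all films are fitted with a
second-order polynomial dose = c0 + c1*r + c2*r^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .profiles import (
    WedgeProfile,
    segment_slope,
    smooth_moving_mean,
)

__all__ = [
    "FilmScan",
    "CalibrationDataset",
    "CalibrationCurve",
    "FilmCalError",
    "load_scan",
    "extract_pvnorm_map",
    "extract_profile",
    "profile_to_calibration",
    "fit_calibration",
    "calibrate_films",
]

MAX_PIXEL = 2**16 - 1


class FilmCalError(ValueError):
    """Raised on invalid film-calibration inputs."""


@dataclass
class FilmScan:
    """A scanned film: 2-D, 3-channel, 16 bits per channel."""

    image: np.ndarray
    dpi: float
    role: str  # "exposed" | "control"
    cax_dose: float | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise FilmCalError(f"expected an HxWx3 image, got shape {img.shape}")
        if img.dtype != np.uint16:
            raise FilmCalError(f"expected 16-bit channels, got dtype {img.dtype}")
        if self.dpi <= 0:
            raise FilmCalError(f"dpi must be positive, got {self.dpi}")
        if self.role not in ("exposed", "control"):
            raise FilmCalError(f"role must be 'exposed' or 'control', got {self.role!r}")
        if self.role == "exposed" and self.cax_dose is None:
            raise FilmCalError("exposed scans need a cax_dose")
        self.image = img

    @property
    def green(self) -> np.ndarray:
        return self.image[..., 1].astype(float)


def load_scan(
    path: str | Path, dpi: float, role: str, cax_dose: float | None = None
) -> FilmScan:
    """Load a 48-bit RGB TIFF scan."""
    img = tifffile.imread(str(path))
    return FilmScan(image=np.asarray(img), dpi=dpi, role=role, cax_dose=cax_dose)


@dataclass
class CalibrationDataset:
    """Merged (PVnorm, dose) calibration points with per-point provenance."""

    responses: np.ndarray
    doses: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.responses.shape != self.doses.shape:
            raise FilmCalError("responses and doses differ in length")
        if np.any(self.doses <= 0):
            raise FilmCalError("doses must be positive")
        if np.any((self.responses <= 0) | (self.responses > 1.2)):
            raise FilmCalError("responses must lie in (0, 1.2]")

    def __len__(self) -> int:
        return self.responses.size

    @staticmethod
    def merge(fragments: list["CalibrationDataset"]) -> "CalibrationDataset":
        return CalibrationDataset(
            responses=np.concatenate([f.responses for f in fragments]),
            doses=np.concatenate([f.doses for f in fragments]),
            provenance=[p for f in fragments for p in f.provenance],
        )


@dataclass
class CalibrationCurve:
    """Fitted dose(response) = c0 + c1*r + c2*r^2, with fit diagnostics."""

    coefficients: np.ndarray  # (c0, c1, c2), ascending powers
    rms_residual_gy: float
    n_points: int

    def predict(self, responses) -> np.ndarray:
        r = np.asarray(responses, dtype=float)
        c0, c1, c2 = self.coefficients
        return c0 + c1 * r + c2 * r * r


def extract_pvnorm_map(exposed: FilmScan, control: FilmScan) -> np.ndarray:
    """Normalized pixel-value map: exposed green / mean control green.

    The unexposed control film provides both the normalization level and
    the background correction in one step.
    """
    if exposed.dpi != control.dpi:
        raise FilmCalError(
            f"dpi mismatch: exposed {exposed.dpi} vs control {control.dpi}"
        )
    if control.role != "control":
        raise FilmCalError("second scan must have role 'control'")
    mean_control = float(control.green.mean())
    if mean_control <= 0:
        raise FilmCalError("control film green channel mean is zero")
    if mean_control >= MAX_PIXEL:
        import warnings

        warnings.warn("control film green channel is saturated", stacklevel=2)
    return exposed.green / mean_control


def extract_profile(
    pv_map: np.ndarray,
    n_lines: int = 25,
    dpi: float = 127.0,
    transpose: bool = False,
) -> WedgeProfile:
    """Average the central lines of a PVnorm map into a 1-D profile.

    The dose gradient is assumed to run along image rows (use
    ``transpose=True`` for the other orientation).  The ``n_lines`` rows
    centered on the image midline are averaged; pixel columns are
    converted to mm via ``dpi``.
    """
    pv_map = np.asarray(pv_map, dtype=float)
    if pv_map.ndim != 2:
        raise FilmCalError(f"expected a 2-D map, got shape {pv_map.shape}")
    if transpose:
        pv_map = pv_map.T
    height = pv_map.shape[0]
    if not 1 <= n_lines <= height:
        raise FilmCalError(f"n_lines must lie in [1, {height}], got {n_lines}")
    if np.ptp(pv_map) < 1e-6:
        raise FilmCalError(
            "PVnorm map is flat; no dose gradient detectable "
            "(is this the control film, or the wrong orientation?)"
        )
    mid = height // 2
    lo = max(mid - n_lines // 2, 0)
    profile = pv_map[lo : lo + n_lines].mean(axis=0)
    px_mm = 25.4 / dpi
    positions = np.arange(profile.size) * px_mm
    return WedgeProfile(positions, profile, {"n_lines": n_lines, "dpi": dpi})


def profile_to_calibration(
    profile: WedgeProfile,
    cax_dose: float,
    drc: float,
    f_low: float = 0.2,
    f_high: float = 0.8,
    smooth_window: int = 25,
    provenance: str = "",
) -> CalibrationDataset:
    """Convert one response profile into (PVnorm, dose) pairs.

    The response profile is edge-segmented over the fractional window
    and smoothed with a moving mean.  The paired dose profile is the
    linear relative-dose ramp of the wedge (20-80 % chord span equal to
    ``drc``, direction opposite to the response since film darkens with
    dose) scaled by the exposure's CAX dose.
    """
    if cax_dose <= 0:
        raise FilmCalError(f"cax_dose must be positive, got {cax_dose}")
    if not 0.0 < drc < 2.0:
        raise FilmCalError(f"drc must lie in (0, 2), got {drc}")
    segment = segment_slope(profile, f_low=f_low, f_high=f_high)
    window = min(smooth_window, segment.positions.size)
    if window % 2 == 0:
        window -= 1
    responses = smooth_moving_mean(
        segment.relative_doses * segment.cax_value, window
    )

    # linear relative-dose ramp across the slope; the chord window
    # (f_low, f_high) spans drc/(f_high - f_low) * ... of the full chord,
    # i.e. relative dose 1 + (x - x_cax) * drc / (0.6 * L) for the
    # default 20-80 % window
    x = segment.positions
    chord = (x[-1] - x[0]) / (f_high - f_low)
    slope = drc / (0.6 * chord)
    offsets = x - segment.cax_position
    # film response falls with dose: orient the dose ramp against the
    # measured response trend
    trend = np.polyfit(offsets, responses, 1)[0]
    sign = -np.sign(trend) if trend != 0 else 1.0
    doses = cax_dose * (1.0 + sign * slope * offsets)
    keep = doses > 0
    return CalibrationDataset(
        responses=responses[keep],
        doses=doses[keep],
        provenance=[provenance] * int(keep.sum()),
    )


def fit_calibration(dataset: CalibrationDataset) -> CalibrationCurve:
    """Least-squares second-order polynomial fit dose = P2(response)."""
    if len(dataset) < 10:
        raise FilmCalError(f"need >= 10 calibration points, got {len(dataset)}")
    if np.ptp(dataset.responses) < 1e-12:
        raise FilmCalError("responses are all equal; fit is rank-deficient")
    coeffs = np.polynomial.polynomial.polyfit(dataset.responses, dataset.doses, 2)
    predicted = np.polynomial.polynomial.polyval(dataset.responses, coeffs)
    rms = float(np.sqrt(np.mean((predicted - dataset.doses) ** 2)))
    return CalibrationCurve(
        coefficients=np.asarray(coeffs), rms_residual_gy=rms, n_points=len(dataset)
    )


def calibrate_films(
    exposed: list[FilmScan],
    control: FilmScan,
    drc: float,
    n_lines: int = 25,
    smooth_window: int = 25,
    f_low: float = 0.2,
    f_high: float = 0.8,
    transpose: bool = False,
) -> tuple[CalibrationCurve, CalibrationDataset]:
    """Full calibration pipeline over a set of exposed films.

    Films sharing the same CAX dose are replicates: their averaged
    PVnorm profile is processed as a single profile before conversion.
    Returns the fitted curve and the merged dataset.
    """
    if not exposed:
        raise FilmCalError("no exposed films given")
    groups: dict[float, list[FilmScan]] = {}
    for scan in exposed:
        groups.setdefault(float(scan.cax_dose), []).append(scan)

    fragments = []
    for cax in sorted(groups):
        profiles = [
            extract_profile(
                extract_pvnorm_map(scan, control),
                n_lines=n_lines,
                dpi=scan.dpi,
                transpose=transpose,
            )
            for scan in groups[cax]
        ]
        mean_values = np.mean([p.values for p in profiles], axis=0)
        averaged = WedgeProfile(
            profiles[0].positions, mean_values, dict(profiles[0].metadata)
        )
        fragments.append(
            profile_to_calibration(
                averaged,
                cax_dose=cax,
                drc=drc,
                f_low=f_low,
                f_high=f_high,
                smooth_window=smooth_window,
                provenance=f"cax_{cax:g}Gy_x{len(groups[cax])}",
            )
        )
    dataset = CalibrationDataset.merge(fragments)
    return fit_calibration(dataset), dataset
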