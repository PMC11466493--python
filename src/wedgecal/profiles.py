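"""Reading, segmenting and normalizing 1-D wedge dose profiles.

A wedge (gradient) field delivers a monotone dose ramp across the field.
This module locates the field edges from the peaks of the numerical
gradient of the scanned profile, extracts the monotonic slope region by
fractional length of the inter-edge chord, and normalizes it to the
central-axis (CAX) value so that the dynamic range coefficient

    eps_W = RD_max - RD_min        (with RD_CAX = 1)

can be read off directly from the segment.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WedgeProfile",
    "SlopeSegment",
    "ProfileError",
    "ProfileParseError",
    "EdgeDetectionError",
    "SegmentTooShortError",
    "read_profile",
    "write_profile",
    "detect_edges",
    "segment_slope",
    "smooth_moving_mean",
]


class ProfileError(ValueError):
    """Base class for profile processing errors."""


class ProfileParseError(ProfileError):
    """Raised when a profile file cannot be parsed."""


class EdgeDetectionError(ProfileError):
    """Raised when the two field edges cannot be located."""


class SegmentTooShortError(ProfileError):
    """Raised when too few samples remain after slope segmentation."""


# metadata keys recognised in '#'-prefixed header lines
_META_KEYS = {"field_size", "depth", "energy", "wedge_angle"}


@dataclass
class WedgeProfile:
    """A sampled 1-D beam profile.

    Parameters
    ----------
    positions : array-like
        Scan positions in mm, strictly increasing.
    values : array-like
        Non-negative dose readings (relative dose or pixel-derived
        response), same length as ``positions``.
    metadata : dict, optional
        Acquisition metadata; recognised keys are ``field_size`` (cm),
        ``depth`` (cm), ``energy`` (MV) and ``wedge_angle`` (deg).
    """

    positions: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.values.ndim != 1:
            raise ProfileError("positions and values must be 1-D")
        if self.positions.size != self.values.size:
            raise ProfileError(
                f"positions ({self.positions.size}) and values "
                f"({self.values.size}) differ in length"
            )
        if self.positions.size < 10:
            raise ProfileError(
                f"profile too short: {self.positions.size} samples (need >= 10)"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ProfileError("positions contain non-finite entries")
        if np.any(np.diff(self.positions) <= 0):
            raise ProfileError("positions must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ProfileError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ProfileError("values must be non-negative")

    def __len__(self) -> int:
        return self.positions.size


@dataclass
class SlopeSegment:
    """The CAX-normalized monotonic slope region of a wedge profile.

    ``relative_doses`` are normalized so the profile interpolates to 1 at
    ``cax_position`` (the midpoint of the inter-edge chord).  ``drc`` is
    the dynamic range coefficient rd_max - rd_min.
    """

    positions: np.ndarray
    relative_doses: np.ndarray
    cax_position: float
    cax_value: float
    rd_max: float
    rd_min: float
    drc: float
    monotonic: bool = True
    warnings: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["positions"] = list(np.asarray(self.positions, dtype=float))
        d["relative_doses"] = list(np.asarray(self.relative_doses, dtype=float))
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _parse_header_line(line: str, metadata: dict) -> None:
    body = line.lstrip("#").strip()
    m = re.match(r"([A-Za-z_][A-Za-z0-9_]*)\s*=\s*(.+)", body)
    if not m:
        return
    key, raw = m.group(1).lower(), m.group(2).strip()
    try:
        value: object = float(raw)
    except ValueError:
        value = raw
    # recognised keys and unknown ones alike are kept; consumers only
    # look up the _META_KEYS entries
    metadata[key] = value


def read_profile(path: str | Path, dialect: str = "csv") -> WedgeProfile:
    """Read a two-column (position_mm, value) profile file.

    The delimiter is auto-detected among comma, tab and whitespace.
    Lines starting with ``#`` are treated as metadata headers of the form
    ``# key=value``.  Positions are sorted ascending on read (values are
    reordered along with them).

    Parameters
    ----------
    path : str or Path
    dialect : {"csv", "two_column_ascii"}
        Accepted for interface symmetry; both dialects are handled by the
        same auto-detecting parser.
    """
    if dialect not in ("csv", "two_column_ascii"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"profile file not found: {path}")

    metadata: dict = {}
    positions: list[float] = []
    values: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            _parse_header_line(stripped, metadata)
            continue
        parts = [p for p in re.split(r"[,\t\s]+", stripped) if p]
        if len(parts) < 2:
            raise ProfileParseError(f"{path}:{lineno}: expected >= 2 columns")
        try:
            pos, val = float(parts[0]), float(parts[1])
        except ValueError:
            raise ProfileParseError(
                f"{path}:{lineno}: non-numeric row {stripped!r}"
            ) from None
        positions.append(pos)
        values.append(val)

    if len(positions) < 10:
        raise ProfileParseError(
            f"{path}: only {len(positions)} samples; need at least 10"
        )
    pos_arr = np.asarray(positions)
    val_arr = np.asarray(values)
    order = np.argsort(pos_arr, kind="stable")
    return WedgeProfile(pos_arr[order], val_arr[order], metadata)


def write_profile(profile: WedgeProfile, path: str | Path) -> None:
    """Write a profile in the two-column CSV dialect read by `read_profile`."""
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in profile.metadata.items()]
    lines += [
        f"{float(p)!r},{float(v)!r}"
        for p, v in zip(profile.positions, profile.values)
    ]
    path.write_text("\n".join(lines) + "\n")


def detect_edges(
    profile: WedgeProfile, smooth_window: int = 5
) -> tuple[float, float]:
    """Locate the two field edges from the numerical-gradient peaks.

    The numerical gradient (central differences, non-uniform spacing
    supported) of the profile peaks at the penumbral inflections.  For a
    dose profile (in-field values high) the left edge is the position of
    the maximum positive gradient and the right edge the position of the
    most negative gradient; an inverted profile (a film-response valley,
    where darkening lowers the in-field values) is handled by the same
    rule with the roles swapped.  On ties the first extremal sample is
    taken.  A light moving mean (default 5 samples; 1 disables)
    suppresses noise-induced spurious gradient extrema on the in-field
    slope without shifting the symmetric penumbral peaks.

    Returns
    -------
    (left_edge, right_edge) : tuple of float, mm

    Raises
    ------
    EdgeDetectionError
        If the gradient has no sign change (single penumbra or monotone
        profile); manual windowing is advised in that case.
    """
    values = (
        profile.values
        if smooth_window <= 1
        else smooth_moving_mean(profile.values, smooth_window)
    )
    grad = np.gradient(values, profile.positions)
    i_pos = int(np.argmax(grad))
    i_neg = int(np.argmin(grad))
    if grad[i_pos] <= 0 or grad[i_neg] >= 0:
        raise EdgeDetectionError(
            "profile gradient has no sign change (no rise/fall pair); "
            "cannot locate two field edges -- consider manual windowing"
        )
    if i_pos == i_neg:  # cannot happen with opposite signs, but be safe
        raise EdgeDetectionError("degenerate gradient extrema")
    left, right = sorted(
        (profile.positions[i_pos], profile.positions[i_neg])
    )
    return float(left), float(right)


def segment_slope(
    profile: WedgeProfile,
    f_low: float = 0.2,
    f_high: float = 0.8,
    sort_nonmonotonic: bool = False,
    smooth_window: int = 1,
) -> SlopeSegment:
    """Extract and normalize the slope region of a wedge profile.

    Keeps samples whose position lies within the fractional window
    ``[left + f_low*L, left + f_high*L]`` of the inter-edge chord
    (length ``L``), then normalizes values by the value linearly
    interpolated at the chord midpoint, taken as the CAX.

    Parameters
    ----------
    f_low, f_high : float
        Fractional window over the inter-edge chord, default 0.2/0.8.
        The wider 0.1/0.9 window captures more of the dose span at the
        cost of including more penumbral curvature.
    sort_nonmonotonic : bool
        If True, the retained relative doses are sorted monotonically
        (direction taken from the segment endpoints).  If False and the
        segment is not monotone, a warning is recorded on the result.
    smooth_window : odd int
        Moving-mean window applied to the profile values before
        windowing and normalization (1 = no smoothing).  Edge detection
        always runs on the raw profile, where the gradient peaks are
        sharpest.  Noisy detector profiles benefit from the 25-sample
        window used for scanned film.
    """
    if not (0.0 <= f_low < f_high <= 1.0):
        raise ValueError(
            f"need 0 <= f_low < f_high <= 1, got ({f_low}, {f_high})"
        )
    left, right = detect_edges(profile)
    values = (
        profile.values
        if smooth_window <= 1
        else smooth_moving_mean(profile.values, smooth_window)
    )
    chord = right - left
    lo = left + f_low * chord
    hi = left + f_high * chord
    mask = (profile.positions >= lo) & (profile.positions <= hi)
    if int(mask.sum()) < 10:
        raise SegmentTooShortError(
            f"only {int(mask.sum())} samples in the {f_low:.2f}-{f_high:.2f} "
            "window; need at least 10"
        )

    cax_position = 0.5 * (left + right)
    cax_value = float(np.interp(cax_position, profile.positions, values))
    if cax_value <= 0:
        raise ProfileError("interpolated CAX value is not positive")

    positions = profile.positions[mask].copy()
    relative = values[mask] / cax_value

    diffs = np.diff(relative)
    monotonic = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    warnings: list[str] = []
    if not monotonic:
        if sort_nonmonotonic:
            descending = relative[-1] < relative[0]
            relative = np.sort(relative)
            if descending:
                relative = relative[::-1].copy()
            monotonic = True
        else:
            warnings.append(
                "segment is not monotonic; consider sort_nonmonotonic=True"
            )

    rd_max = float(relative.max())
    rd_min = float(relative.min())
    return SlopeSegment(
        positions=positions,
        relative_doses=relative,
        cax_position=float(cax_position),
        cax_value=cax_value,
        rd_max=rd_max,
        rd_min=rd_min,
        drc=rd_max - rd_min,
        monotonic=monotonic,
        warnings=warnings,
        metadata=dict(profile.metadata),
    )


def smooth_moving_mean(values, window: int):
    """Centered moving mean with shrink-to-fit boundaries.

    At the boundaries the window is truncated to the available samples
    (the behaviour of MATLAB ``movmean`` and of pandas
    ``rolling(center=True, min_periods=1)``), so the output has the same
    length as the input and a constant input is left unchanged.

    Parameters
    ----------
    values : array-like
    window : odd int
        Window size in samples; must be odd so the center is well
        defined, and no larger than the input.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if window < 1 or window % 2 == 0:
        raise ValueError(
            f"window must be an odd positive integer, got {window} "
            "(the center sample must be well-defined)"
        )
    if window > n:
        raise ValueError(f"window {window} exceeds input length {n}")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
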