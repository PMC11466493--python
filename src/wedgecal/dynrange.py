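"""Dynamic-range algebra for wedge gradient exposures.

A wedge exposure with CAX dose D and dynamic range coefficient eps_W
delivers doses spanning

    LB = D * (1 - eps_W / 2),    UB = D * (1 + eps_W / 2).

Given a calibration range [Dmin, Dmax], the first and last exposures of
a plan are anchored so the pooled doses exactly reach the range ends:

    D1 = Dmin / (1 - eps_W / 2),    DN = Dmax / (1 + eps_W / 2).

The minimal number of exposures needed to cover the range follows from
tiling gradients edge to edge: each tile multiplies the covered upper
dose by (2 + eps_W) / (2 - eps_W), so

    N_min = ceil( ln(Dmax / Dmin) / ln((2 + eps_W) / (2 - eps_W)) ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "GradientSpec",
    "CalibrationRange",
    "AnchorDoses",
    "gradient_bounds",
    "anchor_gradients",
    "estimate_min_exposures",
    "tile_min_exposures",
]


def _check_drc(drc: float) -> None:
    if not 0.0 <= drc < 2.0:
        raise ValueError(
            f"dynamic range coefficient must lie in [0, 2), got {drc} "
            "(a positive lower bound requires 1 - drc/2 > 0)"
        )


@dataclass(frozen=True)
class GradientSpec:
    """One planned gradient exposure.

    Attributes
    ----------
    cax_dose : float
        Dose at the central axis, Gy.
    drc : float
        Dynamic range coefficient eps_W of the wedge field, in [0, 2).
    n_points : int
        Number of dose samples the exposure contributes (detector
        resolution across the slope), default 500.
    """

    cax_dose: float
    drc: float
    n_points: int = 500

    def __post_init__(self) -> None:
        if self.cax_dose <= 0:
            raise ValueError(f"cax_dose must be positive, got {self.cax_dose}")
        _check_drc(self.drc)
        if self.n_points < 1:
            raise ValueError(f"n_points must be >= 1, got {self.n_points}")

    @property
    def lower_bound(self) -> float:
        return self.cax_dose * (1.0 - self.drc / 2.0)

    @property
    def upper_bound(self) -> float:
        return self.cax_dose * (1.0 + self.drc / 2.0)


@dataclass(frozen=True)
class CalibrationRange:
    """Target calibration dose range [d_min, d_max], Gy."""

    d_min: float
    d_max: float

    def __post_init__(self) -> None:
        if not 0.0 < self.d_min < self.d_max:
            raise ValueError(
                f"need 0 < d_min < d_max, got [{self.d_min}, {self.d_max}]"
            )

    @property
    def ratio(self) -> float:
        return self.d_max / self.d_min


class AnchorDoses(NamedTuple):
    """First/last CAX doses of a plan, plus a single-gradient advisory.

    ``single_gradient`` is True when d1 > dn, i.e. the calibration range
    is narrower than one gradient span and a single exposure suffices.
    """

    d1: float
    dn: float
    single_gradient: bool


def gradient_bounds(spec: GradientSpec) -> tuple[float, float]:
    """Dose interval [LB, UB] delivered by one gradient exposure."""
    return spec.lower_bound, spec.upper_bound


def anchor_gradients(range_: CalibrationRange, drc: float) -> AnchorDoses:
    """CAX doses of the first and last gradient of a calibration plan.

    The anchors are chosen so the lower bound of the first gradient
    equals d_min and the upper bound of the last equals d_max (closure
    of the plan onto the calibration range).
    """
    _check_drc(drc)
    d1 = range_.d_min / (1.0 - drc / 2.0)
    dn = range_.d_max / (1.0 + drc / 2.0)
    return AnchorDoses(d1, dn, single_gradient=d1 > dn)


def estimate_min_exposures(range_: CalibrationRange, drc: float) -> int:
    """Analytic minimal number of gradient exposures covering the range.

    Closed form of the greedy edge-to-edge tiling (each successive
    gradient starts where the previous one ends); at least 1.
    """
    _check_drc(drc)
    if drc == 0.0:
        raise ValueError("drc = 0 gradients have zero span; cannot tile")
    growth = (2.0 + drc) / (2.0 - drc)
    n = math.ceil(math.log(range_.ratio) / math.log(growth))
    return max(n, 1)


def tile_min_exposures(range_: CalibrationRange, drc: float) -> int:
    """Count gradients tiled greedily from d_min until d_max is covered.

    Brute-force counterpart of `estimate_min_exposures`: place the first
    gradient with its lower bound at d_min, each next one with its lower
    bound at the previous upper bound, and count until the upper bound
    reaches d_max.
    """
    _check_drc(drc)
    if drc == 0.0:
        raise ValueError("drc = 0 gradients have zero span; cannot tile")
    growth = (2.0 + drc) / (2.0 - drc)
    covered = range_.d_min
    n = 0
    while covered < range_.d_max:
        covered *= growth
        n += 1
    return max(n, 1)
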