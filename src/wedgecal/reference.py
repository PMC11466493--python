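"""Published dynamic range coefficients for a 60-degree physical wedge.

Measured eps_W values for a 6 MV photon beam through a 60-degree wedge,
by square field size (cm) and measurement depth (cm).  The grid is used
as a lookup when choosing wedge-field conditions for a calibration plan:
larger fields and shallower depths give larger dynamic range, but film
strips cut from standard 8x10-inch sheets constrain practical field
sizes to 15x15 cm2 or less, and depths near dose maximum are avoided
because of electron contamination.
"""

from __future__ import annotations

__all__ = ["DRC_6MV_60DEG", "lookup_drc", "max_drc"]

# eps_W by (field_size_cm, depth_cm); 6 MV, 60-degree physical wedge
DRC_6MV_60DEG: dict[tuple[float, float], float] = {
    (5, 1.6): 0.228, (10, 1.6): 0.487, (15, 1.6): 0.704, (20, 1.6): 0.926,
    (5, 5):   0.219, (10, 5):   0.471, (15, 5):   0.698, (20, 5):   0.929,
    (5, 10):  0.215, (10, 10):  0.454, (15, 10):  0.681, (20, 10):  0.902,
    (5, 20):  0.212, (10, 20):  0.426, (15, 20):  0.635, (20, 20):  0.842,
    (5, 30):  0.202, (10, 30):  0.405, (15, 30):  0.599, (20, 30):  0.796,
}


def lookup_drc(field_size_cm: float, depth_cm: float) -> float:
    """eps_W for a tabulated (field size, depth) condition."""
    try:
        return DRC_6MV_60DEG[(field_size_cm, depth_cm)]
    except KeyError:
        raise KeyError(
            f"no tabulated eps_W for field {field_size_cm} cm at depth "
            f"{depth_cm} cm; tabulated field sizes are 5/10/15/20 cm and "
            "depths 1.6/5/10/20/30 cm"
        ) from None


def max_drc(
    max_field_size_cm: float | None = None,
    exclude_buildup: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Largest tabulated eps_W, optionally restricted by field size.

    Returns ``(eps_w, (field_size_cm, depth_cm))``.  Restricting to
    field sizes <= 15 cm reflects the film-strip cutting constraint
    (the shorter dimension of a standard 8x10-inch sheet).  By default
    the 1.6 cm depth is excluded: it sits at the 6 MV depth of dose
    maximum, where electron contamination makes film calibration
    unreliable.
    """
    candidates = {
        key: val
        for key, val in DRC_6MV_60DEG.items()
        if (max_field_size_cm is None or key[0] <= max_field_size_cm)
        and (not exclude_buildup or key[1] > 1.6)
    }
    if not candidates:
        raise ValueError(
            f"no tabulated field size <= {max_field_size_cm} cm"
        )
    key = max(candidates, key=candidates.get)
    return candidates[key], key
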