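"""Deterministic size transforms: girth -> basal area, crown radius, crown area.

All girths are circumferences at breast height (gbh, cm), basal areas are in
cm**2 and crown radii/areas in m / m**2.  A single pooled allometry
``cr = a + b * sqrt(gbh)`` is used for all species; per-species overrides can
be passed anywhere an :class:`AllometryCoefficients` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AllometryCoefficients",
    "PUBLISHED_17",
    "PUBLISHED_8",
    "ROUNDED",
    "VARIANTS",
    "basal_area",
    "gbh_from_basal_area",
    "crown_radius",
    "crown_area",
    "canopy_cover",
]


@dataclass(frozen=True)
class AllometryCoefficients:
    """Coefficients of the crown-radius regression cr = intercept + slope*sqrt(gbh).

    intercept is in m, slope in m * cm**(-1/2).
    """

    intercept: float
    slope: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("crown-radius slope must be positive")


#: 17-species pooled fit (the default).
PUBLISHED_17 = AllometryCoefficients(-1.003, 0.523, "published17")
#: Fit restricted to the eight most abundant species.
PUBLISHED_8 = AllometryCoefficients(-0.959, 0.516, "published8")
#: Rounded coefficients used in the worked size table.
ROUNDED = AllometryCoefficients(-1.0, 0.52, "rounded")

VARIANTS = {c.name: c for c in (PUBLISHED_17, PUBLISHED_8, ROUNDED)}


def basal_area(gbh):
    """Stem basal area (cm**2) from girth at breast height (cm): gbh**2 / (4*pi)."""
    gbh = np.asarray(gbh, dtype=float)
    if np.any(gbh < 0):
        raise ValueError("gbh must be non-negative")
    out = gbh**2 / (4.0 * np.pi)
    return float(out) if out.ndim == 0 else out


def gbh_from_basal_area(ba):
    """Inverse of :func:`basal_area`: gbh = sqrt(4*pi*ba)."""
    ba = np.asarray(ba, dtype=float)
    if np.any(ba < 0):
        raise ValueError("basal area must be non-negative")
    out = np.sqrt(4.0 * np.pi * ba)
    return float(out) if out.ndim == 0 else out


def crown_radius(gbh, coeffs: AllometryCoefficients = PUBLISHED_17):
    """Crown radius (m): max(0, a + b*sqrt(gbh)).

    The zero clamp only binds below gbh ~ 3.7 cm, i.e. under the 10-cm census
    floor; it keeps the transform defined for arbitrary positive girths.
    """
    gbh = np.asarray(gbh, dtype=float)
    if np.any(gbh < 0):
        raise ValueError("gbh must be non-negative")
    out = np.maximum(0.0, coeffs.intercept + coeffs.slope * np.sqrt(gbh))
    return float(out) if out.ndim == 0 else out


def crown_area(cr):
    """Crown (canopy) area in m**2 from crown radius in m: pi * cr**2."""
    cr = np.asarray(cr, dtype=float)
    if np.any(cr < 0):
        raise ValueError("crown radius must be non-negative")
    out = np.pi * cr**2
    return float(out) if out.ndim == 0 else out


def canopy_cover(trees, plot, coeffs: AllometryCoefficients = PUBLISHED_17,
                 census: int = 1, gbh_min: float = 10.0):
    """Total predicted canopy cover (ha) and plot LAI for one census.

    Sums individual crown areas (no overlap subtraction) of trees alive at
    ``census`` with gbh >= ``gbh_min``.  LAI (fold-overlap) is cover divided
    by plot land-surface area.
    """
    gbh_col, status_col = f"gbh_{census}", f"status_{census}"
    alive = trees[trees[status_col] == "alive"]
    alive = alive[alive[gbh_col] >= gbh_min]
    if len(alive) == 0:
        return 0.0, 0.0
    ca = crown_area(crown_radius(alive[gbh_col].to_numpy(), coeffs))
    cover_ha = float(np.sum(ca)) / 1e4
    plot_area_ha = plot.width * plot.length / 1e4
    return cover_ha, cover_ha / plot_area_ha
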