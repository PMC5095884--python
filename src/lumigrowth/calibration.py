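"""Cells-to-light calibration: through-origin regression on plate data.

Wells seeded at known cell densities (design range 100 to 1e6 cells/well) are
imaged, and the photons/sec signal is regressed on cell count through the
origin (zero cells must mean zero signal), y = b * x.  The slope b is the
cells-to-light ratio used everywhere else to convert bioluminescence into
cell number and hence volume.

r-squared is reported in the uncentered convention appropriate for a
no-intercept model, 1 - SS_res / sum(y^2).  Note this differs from the
centered r-squared of an intercept model and is typically closer to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .growth_model import ConversionConstants

__all__ = ["CalibrationPlate", "CalibrationFit", "fit_cells_to_light", "make_conversion", "read_plate_csv"]


@dataclass(frozen=True)
class CalibrationPlate:
    """Well-level calibration data: cell counts, signals, replicate ids."""

    cell_counts: np.ndarray
    signals: np.ndarray
    replicate: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        x = np.asarray(self.cell_counts, dtype=float)
        y = np.asarray(self.signals, dtype=float)
        rep = self.replicate
        rep = np.zeros(len(x), dtype=int) if rep is None else np.asarray(rep)
        object.__setattr__(self, "cell_counts", x)
        object.__setattr__(self, "signals", y)
        object.__setattr__(self, "replicate", rep)
        if not (len(x) == len(y) == len(rep)):
            raise ValueError("cell_counts, signals, replicate must have equal length")
        if np.any(x <= 0):
            raise ValueError("cell counts must be positive")
        if np.any(y < 0):
            raise ValueError("signals must be non-negative")
        if len(np.unique(x)) < 3:
            raise ValueError("at least 3 distinct seeding densities are required")


@dataclass(frozen=True)
class CalibrationFit:
    """Result of the through-origin regression y = slope * x."""

    slope: float            # photons/sec per cell
    slope_se: float         # standard error of the slope
    r_squared: float        # uncentered, in [0, 1]
    n_wells: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")


def fit_cells_to_light(plate: CalibrationPlate) -> CalibrationFit:
    """Least-squares through-origin fit of signal on cell count.

    Equivalent to the closed form b = sum(x*y) / sum(x^2); delegated to an
    OLS fit without constant, which also provides the slope's standard error.
    """
    x = plate.cell_counts
    y = plate.signals
    if np.all(y == 0):
        raise ValueError("all-zero signals: plate carries no calibration information")
    res = sm.OLS(y, x[:, None]).fit()
    slope = float(res.params[0])
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot
    return CalibrationFit(
        slope=slope,
        slope_se=float(res.bse[0]),
        r_squared=r2,
        n_wells=len(x),
    )


def make_conversion(fit: CalibrationFit, cells_per_cm3: float = 1e9) -> ConversionConstants:
    """Package a calibration slope with the cells-per-cm^3 packing rule."""
    if fit.slope <= 0:
        raise ValueError("calibration slope must be > 0")
    return ConversionConstants(photons_per_cell=fit.slope, cells_per_cm3=cells_per_cm3)


def read_plate_csv(path) -> CalibrationPlate:
    """Read plate data from CSV with columns ``cells, signal, replicate``."""
    df = pd.read_csv(path)
    required = {"cells", "signal"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate CSV must have columns {sorted(required)}")
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return CalibrationPlate(
        cell_counts=df["cells"].to_numpy(float),
        signals=df["signal"].to_numpy(float),
        replicate=rep,
    )
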