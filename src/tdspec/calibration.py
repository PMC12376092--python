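"""Linear TDS-vs-helical-length calibration and inverse prediction.

Vibrational delocalization along a continuous alpha-helix grows with the
number of coupled backbone amides, so the apparent transition dipole
strength of the amide I' mode rises linearly with helical length.  A set
of de novo [EK]_N model helices of known (CD-derived) helical residue
counts anchors an ordinary-least-squares line

    TDS = intercept + slope * helical_residues   [D^2]

which, inverted at a measured protein TDS, predicts the length of the
longest continuous alpha-helix in the protein — the apparent TDS reports
the greatest delocalization length present, not an average over helices.

Amide I' frequency also trends with helical length for model peptides,
but is unreliable for globular proteins (solvatochromism, disorder
overlap); :func:`frequency_trend` fits it anyway and flags the caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm

__all__ = [
    "CalibrationPoint",
    "LinearFit",
    "HelixCalibration",
    "HelixPrediction",
    "EK_CALIBRATION_POINTS",
    "fit_calibration",
    "predict_helix_length",
    "predict_tds",
    "frequency_trend",
    "ek_calibration",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration peptide: helical residue count vs measured TDS."""

    helical_residues: float
    tds: float
    tds_sd: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.tds > 0:
            raise ValueError("tds must be > 0 D^2")
        if self.helical_residues < 0:
            raise ValueError("helical_residues must be >= 0")
        if self.tds_sd < 0:
            raise ValueError("tds_sd must be >= 0")


#: measured [EK]_N calibration set: CD-derived helical residues vs TDS
EK_CALIBRATION_POINTS: tuple[CalibrationPoint, ...] = (
    CalibrationPoint(0.0, 0.13, 0.005, "[EK]1"),
    CalibrationPoint(5.9, 0.15, 0.01, "[EK]2"),
    CalibrationPoint(13.2, 0.21, 0.02, "[EK]3"),
    CalibrationPoint(20.2, 0.26, 0.03, "[EK]4"),
)


@dataclass(frozen=True)
class LinearFit:
    """OLS/WLS line y = intercept + slope * x with diagnostics."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    slope_se: float
    intercept_se: float
    cov_slope_intercept: float
    caveat: str = ""


@dataclass(frozen=True)
class HelixCalibration:
    """TDS-vs-helical-residues calibration line.

    slope is in D^2 per residue and must be positive: the calibration is
    only meaningful when TDS increases with helical length.
    """

    fit: LinearFit
    points: tuple[CalibrationPoint, ...]
    weighted: bool = False

    def __post_init__(self) -> None:
        if not self.fit.slope > 0:
            raise ValueError(
                "helix calibration requires a positive slope (TDS increasing "
                "with helical length)"
            )

    @property
    def slope(self) -> float:
        return self.fit.slope

    @property
    def intercept(self) -> float:
        return self.fit.intercept

    @property
    def r_squared(self) -> float:
        return self.fit.r_squared

    @property
    def x_max(self) -> float:
        return max(p.helical_residues for p in self.points)


@dataclass(frozen=True)
class HelixPrediction:
    """Predicted maximum helical length with propagated uncertainty."""

    length: float
    sd: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def _fit_line(x: np.ndarray, y: np.ndarray,
              weights: np.ndarray | None = None) -> LinearFit:
    if np.unique(x).size < 2:
        raise ValueError("degenerate x values: need >= 2 distinct abscissae")
    X = sm.add_constant(x)
    model = sm.WLS(y, X, weights=weights) if weights is not None else sm.OLS(y, X)
    res = model.fit()
    intercept, slope = res.params
    intercept_se, slope_se = res.bse
    cov = res.cov_params()
    resid_dof = max(res.df_resid, 1)
    residual_sd = float(np.sqrt(np.sum(res.resid ** 2) / resid_dof))
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(res.rsquared),
        residual_sd=residual_sd,
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        cov_slope_intercept=float(np.asarray(cov)[0, 1]),
    )


def fit_calibration(points: Sequence[CalibrationPoint],
                    weighted: bool = False) -> HelixCalibration:
    """Fit TDS on helical residues by OLS (or 1/sd^2-weighted WLS).

    Requires >= 3 points with >= 2 distinct helical-residue values.  The
    unweighted fit is the default; the weighted variant uses the
    replicate standard deviations (all must then be positive).
    """
    if len(points) < 3:
        raise ValueError("need >= 3 calibration points")
    x = np.array([p.helical_residues for p in points])
    y = np.array([p.tds for p in points])
    weights = None
    if weighted:
        sds = np.array([p.tds_sd for p in points])
        if np.any(sds <= 0):
            raise ValueError("weighted fit requires positive tds_sd for every point")
        weights = 1.0 / sds ** 2
    fit = _fit_line(x, y, weights)
    return HelixCalibration(fit=fit, points=tuple(points), weighted=weighted)


def ek_calibration(weighted: bool = False) -> HelixCalibration:
    """The built-in [EK]_N calibration line."""
    return fit_calibration(EK_CALIBRATION_POINTS, weighted=weighted)


def predict_helix_length(tds: float, model: HelixCalibration,
                         tds_sd: float = 0.0) -> HelixPrediction:
    """Invert the calibration line: length = (TDS - intercept) / slope.

    First-order (delta-method) uncertainty propagation combines the
    measurement sd with the coefficient standard errors and their
    covariance.  A negative length is reported as 0 with a
    ``below_calibration_range`` flag; lengths beyond the largest
    calibration abscissa are flagged ``extrapolated`` (the line is still
    used — delocalization has no hard cutoff at the calibration maximum).
    """
    m, b = model.slope, model.intercept
    length = (tds - b) / m
    # delta method: dL/dt = 1/m, dL/db = -1/m, dL/dm = -(t-b)/m^2
    dt, db, dm = 1.0 / m, -1.0 / m, -(tds - b) / m ** 2
    var = (dt * tds_sd) ** 2 \
        + (db * model.fit.intercept_se) ** 2 \
        + (dm * model.fit.slope_se) ** 2 \
        + 2.0 * db * dm * model.fit.cov_slope_intercept
    sd = float(np.sqrt(max(var, 0.0)))
    flags: list[str] = []
    if length < 0:
        flags.append("below_calibration_range")
        length = 0.0
    elif length > model.x_max:
        flags.append("extrapolated")
    return HelixPrediction(length=float(length), sd=sd, flags=tuple(flags))


def predict_tds(helical_residues: float, model: HelixCalibration) -> float:
    """Forward prediction: TDS = intercept + slope * helical_residues."""
    if helical_residues < 0:
        raise ValueError("helical_residues must be >= 0")
    return model.intercept + model.slope * helical_residues


def frequency_trend(points: Sequence[tuple[float, float]]) -> LinearFit:
    """OLS of amide I' frequency (cm^-1) on helical residue count.

    Returned with an explicit caveat: the frequency trend holds for model
    peptides but globular proteins do not follow it, so it must not be
    used for length prediction.
    """
    if len(points) < 3:
        raise ValueError("need >= 3 points")
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    fit = _fit_line(x, y)
    return LinearFit(
        **{**fit.__dict__,
           "caveat": "frequency is unreliable for globular proteins; "
                     "do not use for length prediction"},
    )
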