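"""Transition dipole strength (TDS) spectra from 2D IR and linear OD.

A linear IR signal scales with the squared transition dipole |mu|^2 while
a 2D IR signal scales with |mu|^4, so their ratio isolates |mu|^2.  The
TDS spectrum is

    d(w) = [ |dOD_s(w,w)| / OD_s(w) ]
         * [ OD_c(w_max) / |dOD_c(w_max, w_max)| ]
         * [ I_pump(w_max) / I_pump(w) ]
         * |mu_calibrant|^2

where the subscript s is the sample, c the calibrant, dOD(w,w) the
diagonal slice of the 2D spectrum, OD the baseline-corrected linear
optical density, I_pump the pump intensity spectrum, and w_max the
calibrant band maximum.  N-methylacetamide, a single uncoupled amide I'
oscillator with |mu|^2 = 0.12 D^2, is the conventional calibrant.

Because only ratios enter, d(w) is independent of concentration, path
length and beam overlap, and of any global rescaling of the pump.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .baseline import AirPLSConfig, correct_baseline
from .spectra import AxisSpectrum, Grid2DSpectrum, SpectrumDomainError

__all__ = [
    "NMA_MU_SQ",
    "CalibrantRecord",
    "TDSPeak",
    "diagonal_slice",
    "calibrant_record",
    "tds_spectrum",
    "peak_tds",
    "compute_tds",
]

#: TDS of an uncoupled amide I' oscillator (N-methylacetamide), in D^2.
NMA_MU_SQ = 0.12


@dataclass(frozen=True)
class CalibrantRecord:
    """Calibrant quantities entering the TDS normalization.

    omega_max : wavenumber (cm^-1) of the calibrant amide I' maximum,
        located on the baseline-corrected linear OD.
    delta_od_max : |dOD_calibrant(omega_max, omega_max)|.
    od_max : OD_calibrant(omega_max).
    mu_sq : calibrant transition dipole strength in D^2 (default 0.12,
        the N-methylacetamide value).
    """

    omega_max: float
    delta_od_max: float
    od_max: float
    mu_sq: float = NMA_MU_SQ

    def __post_init__(self) -> None:
        if not self.delta_od_max > 0:
            raise ValueError("delta_od_max must be > 0")
        if not self.od_max > 0:
            raise ValueError("od_max must be > 0")
        if not self.mu_sq > 0:
            raise ValueError("mu_sq must be > 0")


@dataclass(frozen=True)
class TDSPeak:
    """A per-mode TDS reading inside an assignment window."""

    omega: float
    tds: float
    window: tuple[float, float]
    assignment: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not (lo <= self.omega <= hi):
            raise ValueError("peak frequency must lie inside its window")
        if not self.tds > 0:
            raise ValueError("peak TDS must be > 0")


def diagonal_slice(spec2d: Grid2DSpectrum) -> AxisSpectrum:
    """Magnitude of the 2D diagonal, |dOD(w, w)|, over the axis overlap.

    For each pump frequency w inside the pump/probe overlap the probe
    value at w is obtained by linear interpolation along that pump row.
    The fundamental lobe is stored negative; its magnitude is returned.
    """
    lo = max(spec2d.pump_axis[0], spec2d.probe_axis[0])
    hi = min(spec2d.pump_axis[-1], spec2d.probe_axis[-1])
    mask = (spec2d.pump_axis >= lo) & (spec2d.pump_axis <= hi)
    if not np.any(mask):
        raise SpectrumDomainError("pump and probe axes share no overlap")
    omegas = spec2d.pump_axis[mask]
    rows = spec2d.delta_od[mask]
    diag = np.array([
        np.interp(w, spec2d.probe_axis, row) for w, row in zip(omegas, rows)
    ])
    return AxisSpectrum(omegas, np.abs(diag), "linear_od",
                        {"kind": "diagonal_slice"})


def calibrant_record(spec2d_cal: Grid2DSpectrum, od_cal: AxisSpectrum,
                     mu_sq: float = NMA_MU_SQ) -> CalibrantRecord:
    """Build the calibrant record from its 2D spectrum and corrected OD.

    ``od_cal`` must already be baseline-corrected.  The band maximum
    w_max is the argmax of the corrected linear OD (the 1D band is
    smoother than the 2D diagonal); |dOD| and OD are evaluated there by
    linear interpolation.  A maximum on the axis boundary means the band
    was not captured and is an error.
    """
    idx = int(np.argmax(od_cal.values))
    if idx in (0, len(od_cal) - 1):
        raise SpectrumDomainError(
            "calibrant OD maximum lies on the axis boundary; band not captured"
        )
    omega_max = float(od_cal.axis[idx])
    od_max = float(od_cal.values[idx])
    diag = diagonal_slice(spec2d_cal)
    delta_od_max = float(diag.interp(np.array([omega_max]))[0])
    return CalibrantRecord(omega_max, delta_od_max, od_max, mu_sq)


def tds_spectrum(diag: AxisSpectrum, od: AxisSpectrum, pump: AxisSpectrum,
                 cal: CalibrantRecord, od_floor_frac: float = 0.05) -> AxisSpectrum:
    """Compute the TDS spectrum d(w) on the sample diagonal axis.

    The common axis is the diagonal-slice axis restricted to the
    intersection of the OD and pump axes; OD and pump are linearly
    interpolated onto it.  The ratio dOD/OD diverges as OD -> 0, so
    points where OD(w) < ``od_floor_frac * max(OD)`` are dropped from the
    output rather than computed (default floor 5%).
    """
    lo = max(diag.axis[0], od.axis[0], pump.axis[0])
    hi = min(diag.axis[-1], od.axis[-1], pump.axis[-1])
    if hi < lo:
        raise SpectrumDomainError("diagonal, OD and pump axes share no overlap")
    common = diag.restrict(lo, hi)
    od_vals = od.interp(common.axis)
    pump_vals = pump.interp(common.axis)
    keep = od_vals >= od_floor_frac * od_vals.max()
    if not np.any(keep):
        raise SpectrumDomainError("all points fall below the OD floor")
    if np.any(pump_vals[keep] <= 0):
        raise SpectrumDomainError("pump intensity must be > 0 on the unmasked overlap")
    pump_at_max = float(pump.interp(np.array([cal.omega_max]))[0])
    d = (common.values[keep] / od_vals[keep]) \
        * (cal.od_max / cal.delta_od_max) \
        * (pump_at_max / pump_vals[keep]) \
        * cal.mu_sq
    return AxisSpectrum(common.axis[keep], d, "tds", {
        "od_floor_frac": od_floor_frac,
        "omega_max": cal.omega_max,
        "mu_sq_calibrant": cal.mu_sq,
        "n_masked": int((~keep).sum()),
    })


def peak_tds(tds: AxisSpectrum, window: tuple[float, float],
             reference: AxisSpectrum | None = None,
             assignment: str = "") -> TDSPeak:
    """Read the per-mode TDS inside an assignment window.

    The peak position is the argmax of the reference spectrum inside the
    window — by default the TDS spectrum itself; pass the 2D diagonal
    magnitude to read d at the 2D band maximum instead.  At least three
    unmasked TDS points must fall inside the window.
    """
    lo, hi = window
    m = (tds.axis >= lo) & (tds.axis <= hi)
    if m.sum() < 3:
        raise SpectrumDomainError(
            f"window [{lo}, {hi}] contains {int(m.sum())} unmasked points; need >= 3"
        )
    if reference is None:
        sub_axis = tds.axis[m]
        idx = int(np.argmax(tds.values[m]))
        omega = float(sub_axis[idx])
        value = float(tds.values[m][idx])
    else:
        rm = (reference.axis >= lo) & (reference.axis <= hi)
        if not np.any(rm):
            raise SpectrumDomainError("reference spectrum has no points in the window")
        omega = float(reference.axis[rm][np.argmax(reference.values[rm])])
        value = float(np.interp(omega, tds.axis[m], tds.values[m]))
    return TDSPeak(omega, value, (float(lo), float(hi)), assignment)


@dataclass
class TDSResult:
    """Full-pipeline output: the TDS spectrum plus intermediates."""

    tds: AxisSpectrum
    calibrant: CalibrantRecord
    sample_od_corrected: AxisSpectrum
    sample_diagonal: AxisSpectrum
    peaks: list[TDSPeak] = field(default_factory=list)


def compute_tds(sample_2d: Grid2DSpectrum, sample_od: AxisSpectrum,
                cal_2d: Grid2DSpectrum, cal_od: AxisSpectrum,
                pump: AxisSpectrum,
                baseline_config: AirPLSConfig = AirPLSConfig(),
                od_floor_frac: float = 0.05,
                mu_sq: float = NMA_MU_SQ,
                windows: Sequence[tuple[tuple[float, float], str]] = (),
                ) -> TDSResult:
    """Run the full TDS pipeline on raw inputs.

    Baseline-corrects both linear ODs with airPLS, builds the calibrant
    record, slices the sample 2D diagonal, forms d(w), and optionally
    reads per-mode peaks in the supplied ``windows`` (list of
    ``((w_lo, w_hi), assignment)`` pairs).
    """
    od_s = correct_baseline(sample_od, baseline_config)
    od_c = correct_baseline(cal_od, baseline_config)
    cal = calibrant_record(cal_2d, od_c, mu_sq)
    diag = diagonal_slice(sample_2d)
    d = tds_spectrum(diag, od_s, pump, cal, od_floor_frac)
    peaks = [peak_tds(d, win, assignment=label) for win, label in windows]
    return TDSResult(d, cal, od_s, diag, peaks)
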