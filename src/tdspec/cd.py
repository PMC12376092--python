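"""Circular dichroism helicity: mean residue ellipticity and percent helix.

Raw far-UV CD ellipticity theta (millidegrees) is converted to mean
residue ellipticity

    [theta] = theta / (l * C * n)        [deg cm^2 / dmol]

with path length l in mm, molar concentration C in mol/L and n residues
(this equals the textbook theta/(10 * l_cm * C * n)).  Percent helicity
compares the measured [theta] at 222 nm against the theoretical maximum
for a perfect helix of the same length,

    [theta]_H = -40000 * (1 - x/n) + 100 * T,

where T is the temperature in Celsius and x is an empirical constant
correcting for non-hydrogen-bonded carbonyls (2.5 for chains of roughly
8-23 residues):

    % helicity = 100 * [theta]_222 / [theta]_H.

A positive ratio of two negative quantities; a disordered line shape can
give a ratio below zero, which is reported as 0% with the raw ratio kept
for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import AxisSpectrum

__all__ = [
    "CDSampleMeta",
    "HelicityResult",
    "mean_residue_ellipticity",
    "theoretical_max_mre",
    "percent_helicity",
    "helical_residues",
    "helicity_from_spectrum",
    "EK_CHAIN_LENGTHS",
]

#: chain lengths of the [EK]_N model helices (N repeats of the 5-residue
#: EAAAK core plus terminal residues give 8, 13, 18, 23 residues)
EK_CHAIN_LENGTHS = {1: 8, 2: 13, 3: 18, 4: 23}


@dataclass(frozen=True)
class CDSampleMeta:
    """Sample metadata needed to normalise a CD measurement.

    path_length : cuvette path length in mm.
    concentration : molar concentration in mol/L.
    n_residues : residue count of the chain.
    temperature : sample temperature in Celsius.
    x_const : empirical end-effect constant (0-3; default 2.5).
    """

    path_length: float
    concentration: float
    n_residues: int
    temperature: float = 21.0
    x_const: float = 2.5

    def __post_init__(self) -> None:
        if not self.path_length > 0:
            raise ValueError("path_length must be > 0 mm")
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0 mol/L")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if not (0 <= self.x_const < self.n_residues):
            raise ValueError("x_const must satisfy 0 <= x < n_residues")


@dataclass(frozen=True)
class HelicityResult:
    """Percent helicity and derived quantities for one CD sample.

    ``percent_helicity`` is clamped at 0 for disordered line shapes; the
    unclamped ratio is kept in ``raw_ratio``.
    """

    mre222: float
    theta_h: float
    percent_helicity: float
    helical_residues: float
    raw_ratio: float


def mean_residue_ellipticity(theta_mdeg: float, meta: CDSampleMeta) -> float:
    """Mean residue ellipticity [theta] = theta / (l * C * n)."""
    return theta_mdeg / (meta.path_length * meta.concentration * meta.n_residues)


def theoretical_max_mre(meta: CDSampleMeta) -> float:
    """[theta]_H for a perfect helix: -40000 (1 - x/n) + 100 T."""
    if meta.n_residues <= meta.x_const:
        raise ValueError("n_residues must exceed x_const")
    return -40000.0 * (1.0 - meta.x_const / meta.n_residues) + 100.0 * meta.temperature


def percent_helicity(mre222: float, theta_h: float) -> tuple[float, float]:
    """Percent helicity with its raw (unclamped) ratio.

    Returns ``(percent, raw_ratio)`` where percent = 100 * mre222/theta_h
    clamped at 0 when the ratio is negative (disordered line shape).
    """
    if theta_h == 0:
        raise ValueError("theta_h must be nonzero")
    raw = 100.0 * mre222 / theta_h
    return (max(raw, 0.0), raw)


def helical_residues(percent: float, n_residues: int) -> float:
    """Number of helical residues, percent/100 * n, to 0.1 residue."""
    if percent < 0:
        raise ValueError("percent must be >= 0")
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return round(percent / 100.0 * n_residues, 1)


def helicity_from_spectrum(cd: AxisSpectrum, meta: CDSampleMeta,
                           wavelength: float = 222.0) -> HelicityResult:
    """Full helicity estimate from a CD spectrum (mdeg vs nm).

    The ellipticity at ``wavelength`` (default 222 nm) is read by linear
    interpolation on the wavelength axis.
    """
    theta222 = float(np.interp(wavelength, cd.axis, cd.values))
    mre222 = mean_residue_ellipticity(theta222, meta)
    theta_h = theoretical_max_mre(meta)
    percent, raw = percent_helicity(mre222, theta_h)
    return HelicityResult(
        mre222=mre222,
        theta_h=theta_h,
        percent_helicity=percent,
        helical_residues=helical_residues(percent, meta.n_residues),
        raw_ratio=raw,
    )
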