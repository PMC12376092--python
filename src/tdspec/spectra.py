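"""Spectral containers and plain-text I/O.

Two containers carry every spectrum in the pipeline: :class:`AxisSpectrum`
(a monotone frequency or wavelength axis paired with values — linear OD,
transmission, pump intensity, TDS, or CD ellipticity, depending on ``role``)
and :class:`Grid2DSpectrum` (a pump x probe matrix of 2D IR delta-OD values).

File dialects are deliberately minimal: UTF-8 CSV with a unit-tagged header
for 1D spectra, and a matrix CSV (first row = probe axis, first column =
pump axis) for 2D spectra.  A file without the expected header unit tag is
rejected rather than guessed, and duplicate axis points are an error, not
averaged — silent averaging hides acquisition problems.

Sign convention for 2D spectra: the fundamental (ground-state bleach /
stimulated emission) diagonal lobe is stored negative, the anharmonically
shifted overtone lobe positive.  Downstream magnitude operations take
absolute values explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np

__all__ = [
    "AxisSpectrum",
    "Grid2DSpectrum",
    "SpectrumFormatError",
    "SpectrumDomainError",
    "ROLES",
    "read_axis_spectrum",
    "write_axis_spectrum",
    "read_grid2d",
    "write_grid2d",
    "od_from_transmission",
]

ROLES = ("linear_od", "transmission", "pump", "tds", "cd")

#: header spellings per role; CD spectra use a wavelength axis in nm
_HEADERS = {
    "cd": "wavelength_nm,ellipticity_mdeg",
    "linear_od": "wavenumber_cm-1,value",
    "transmission": "wavenumber_cm-1,value",
    "pump": "wavenumber_cm-1,value",
    "tds": "wavenumber_cm-1,value",
}


class SpectrumFormatError(ValueError):
    """A spectral file does not conform to the expected dialect."""


class SpectrumDomainError(ValueError):
    """Spectrum values violate a physical precondition (e.g. T <= 0)."""


@dataclass
class AxisSpectrum:
    """A 1D spectrum: strictly monotonic axis plus values of equal length.

    Parameters
    ----------
    axis : array
        Wavenumbers in cm^-1 (IR roles) or wavelengths in nm (role ``cd``),
        strictly monotonic, length >= 2 (length 1 is tolerated only for
        degenerate slices produced internally).
    values : array
        Same length as ``axis``.  Units depend on ``role``: OD and delta-OD
        are dimensionless, pump intensity is arbitrary, TDS is in D^2,
        ellipticity in mdeg.
    role : str
        One of ``linear_od``, ``transmission``, ``pump``, ``tds``, ``cd``.
    meta : dict
        Free-form annotations (convergence flags, ground truth, ...).
    """

    axis: np.ndarray
    values: np.ndarray
    role: str = "linear_od"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.ndim != 1 or self.values.ndim != 1:
            raise SpectrumFormatError("axis and values must be 1-D arrays")
        if self.axis.size != self.values.size:
            raise SpectrumFormatError(
                f"axis length {self.axis.size} != values length {self.values.size}"
            )
        if self.axis.size == 0:
            raise SpectrumFormatError("empty spectrum")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        d = np.diff(self.axis)
        if self.axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise SpectrumFormatError("axis must be strictly monotonic")
        if self.axis.size > 1 and d[0] < 0:  # normalise to ascending order
            self.axis = self.axis[::-1].copy()
            self.values = self.values[::-1].copy()
        if self.role == "transmission" and np.any(self.values <= 0):
            raise SpectrumDomainError("transmission values must be > 0")
        if self.role == "pump" and np.any(self.values < 0):
            raise SpectrumDomainError("pump intensity must be >= 0")

    def __len__(self) -> int:
        return self.axis.size

    def interp(self, axis: np.ndarray) -> np.ndarray:
        """Linearly interpolate values onto ``axis``.

        Extrapolation is forbidden: every requested point must lie inside
        the spectrum's axis range.
        """
        axis = np.asarray(axis, dtype=float)
        if axis.size and (axis.min() < self.axis[0] or axis.max() > self.axis[-1]):
            raise SpectrumDomainError(
                "requested axis extends beyond the spectrum range; "
                "extrapolation is not supported"
            )
        return np.interp(axis, self.axis, self.values)

    def restrict(self, lo: float, hi: float) -> "AxisSpectrum":
        """Return the sub-spectrum with axis points in [lo, hi]."""
        m = (self.axis >= lo) & (self.axis <= hi)
        if not np.any(m):
            raise SpectrumDomainError(f"no axis points in [{lo}, {hi}]")
        return AxisSpectrum(self.axis[m], self.values[m], self.role, dict(self.meta))

    def with_values(self, values: np.ndarray, role: str | None = None,
                    **meta: Any) -> "AxisSpectrum":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return AxisSpectrum(self.axis.copy(), np.asarray(values, dtype=float),
                            role or self.role, new_meta)


@dataclass
class Grid2DSpectrum:
    """A 2D IR spectrum: pump axis x probe axis matrix of delta-OD.

    Both axes are wavenumbers in cm^-1, strictly monotonic ascending after
    construction.  ``delta_od[i, j]`` is the signed delta-OD at pump
    frequency ``pump_axis[i]`` and probe frequency ``probe_axis[j]``.
    """

    pump_axis: np.ndarray
    probe_axis: np.ndarray
    delta_od: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pump_axis = np.asarray(self.pump_axis, dtype=float)
        self.probe_axis = np.asarray(self.probe_axis, dtype=float)
        self.delta_od = np.asarray(self.delta_od, dtype=float)
        for name, ax in (("pump", self.pump_axis), ("probe", self.probe_axis)):
            if ax.ndim != 1 or ax.size < 1:
                raise SpectrumFormatError(f"{name} axis must be a nonempty 1-D array")
            d = np.diff(ax)
            if ax.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise SpectrumFormatError(f"{name} axis must be strictly monotonic")
        if self.delta_od.shape != (self.pump_axis.size, self.probe_axis.size):
            raise SpectrumFormatError(
                f"matrix shape {self.delta_od.shape} does not match axes "
                f"({self.pump_axis.size}, {self.probe_axis.size})"
            )
        if self.pump_axis.size > 1 and self.pump_axis[1] < self.pump_axis[0]:
            self.pump_axis = self.pump_axis[::-1].copy()
            self.delta_od = self.delta_od[::-1].copy()
        if self.probe_axis.size > 1 and self.probe_axis[1] < self.probe_axis[0]:
            self.probe_axis = self.probe_axis[::-1].copy()
            self.delta_od = self.delta_od[:, ::-1].copy()
        lo = max(self.pump_axis[0], self.probe_axis[0])
        hi = min(self.pump_axis[-1], self.probe_axis[-1])
        near = np.any(
            np.abs(self.pump_axis[:, None] - self.probe_axis[None, :]) <= 1.0
        )
        if hi < lo and not near:
            raise SpectrumFormatError(
                "pump and probe axes share no overlap; no diagonal exists"
            )


# ---------------------------------------------------------------------------
# I/O

def _data_lines(path: str) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_axis_spectrum(path: str, role: str = "linear_od") -> AxisSpectrum:
    """Read a two-column CSV spectrum with a unit-tagged header.

    The header must be ``wavenumber_cm-1,value`` (or
    ``wavelength_nm,ellipticity_mdeg`` for ``role='cd'``).  Rows are sorted
    ascending by axis; duplicate axis values are rejected.
    """
    expected = _HEADERS[role]
    rows: list[tuple[float, float]] = []
    header_seen = False
    for lineno, line in _data_lines(path):
        if not header_seen:
            if line.replace(" ", "") != expected:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected header {expected!r}, got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise SpectrumFormatError(
                f"{path}:{lineno}: expected 2 comma-separated cells, got {len(parts)}"
            )
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: non-numeric cell") from exc
    if not header_seen:
        raise SpectrumFormatError(f"{path}: empty file (no header)")
    if not rows:
        raise SpectrumFormatError(f"{path}: no data rows")
    rows.sort(key=lambda r: r[0])
    axis = np.array([r[0] for r in rows])
    if np.any(np.diff(axis) == 0):
        dup = axis[np.nonzero(np.diff(axis) == 0)[0][0]]
        raise SpectrumFormatError(f"{path}: duplicate axis value {dup}")
    return AxisSpectrum(axis, np.array([r[1] for r in rows]), role,
                        {"source": str(path)})


def write_axis_spectrum(spectrum: AxisSpectrum, path: str) -> None:
    """Write a spectrum in the two-column CSV dialect (full precision)."""
    header = _HEADERS[spectrum.role]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for x, y in zip(spectrum.axis, spectrum.values):
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def read_grid2d(path: str) -> Grid2DSpectrum:
    """Read a 2D spectrum matrix CSV.

    First row: empty corner cell (or ``pump\\probe``) followed by the probe
    axis; each subsequent row: pump frequency followed by delta-OD values.
    """
    lines = list(_data_lines(path))
    if not lines:
        raise SpectrumFormatError(f"{path}: empty file")
    header_cells = lines[0][1].split(",")
    corner = header_cells[0].strip()
    if corner not in ("", "pump\\probe"):
        raise SpectrumFormatError(
            f"{path}:{lines[0][0]}: corner cell must be empty or 'pump\\probe', "
            f"got {corner!r}"
        )
    try:
        probe = np.array([float(c) for c in header_cells[1:]])
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}:{lines[0][0]}: non-numeric probe axis") from exc
    pump: list[float] = []
    body: list[list[float]] = []
    for lineno, line in lines[1:]:
        cells = line.split(",")
        if len(cells) != probe.size + 1:
            raise SpectrumFormatError(
                f"{path}:{lineno}: row has {len(cells)} cells, "
                f"expected {probe.size + 1}"
            )
        try:
            pump.append(float(cells[0]))
            body.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{lineno}: non-numeric cell") from exc
    if not body:
        raise SpectrumFormatError(f"{path}: no data rows")
    return Grid2DSpectrum(np.array(pump), probe, np.array(body),
                          {"source": str(path)})


def write_grid2d(spec: Grid2DSpectrum, path: str) -> None:
    """Write a 2D spectrum in the matrix CSV dialect (full precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pump\\probe," + ",".join(repr(float(w)) for w in spec.probe_axis) + "\n")
        for wp, row in zip(spec.pump_axis, spec.delta_od):
            fh.write(f"{float(wp)!r}," + ",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------

def od_from_transmission(transmission: AxisSpectrum,
                         reference: AxisSpectrum) -> AxisSpectrum:
    """Linear optical density from sample and reference probe transmission.

    OD(w) = -log10( I_sample(w) / I_reference(w) ) on the common axis; the
    reference is linearly interpolated onto the sample axis restricted to
    the axis intersection (no extrapolation).
    """
    for s in (transmission, reference):
        if np.any(s.values <= 0):
            raise SpectrumDomainError("transmission spectra must be strictly positive")
    lo = max(transmission.axis[0], reference.axis[0])
    hi = min(transmission.axis[-1], reference.axis[-1])
    if hi < lo:
        raise SpectrumDomainError("sample and reference axes do not overlap")
    sample = transmission.restrict(lo, hi)
    ref_vals = reference.interp(sample.axis)
    od = -np.log10(sample.values / ref_vals)
    return AxisSpectrum(sample.axis, od, "linear_od", {"derived_from": "transmission"})
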