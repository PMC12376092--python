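"""Synthetic spectra with known ground truth.

Emulates the inputs of the TDS pipeline — linear amide I' OD spectra
(1600-1700 cm^-1 band shapes on broad baselines), the Gaussian pump
envelope, 2D IR spectra whose diagonal encodes a known TDS profile, and
far-UV CD spectra of partially helical peptides — so that every pipeline
stage can be tested against a recoverable truth without experimental
data.

The 2D generator inverts the TDS relation: given a scene's band-only OD
and a ground-truth per-band TDS, it sets the diagonal magnitude to

    |dOD(w,w)| = d(w) * OD(w) * [I_pump(w)/I_pump(w_max)]
                 * [dOD_c/OD_c] / mu_sq

so that the analysis pipeline, run forward, must recover d(w).  Where
bands overlap, the ground-truth profile is the OD-weighted mean of the
band TDS values — how an unresolved multi-mode band would present a
single apparent TDS.  Off-diagonal structure is a cosmetic peak pair
(negative fundamental on the diagonal, positive overtone lobe red-shifted
along probe by a configurable anharmonicity); it is constructed to vanish
exactly on the diagonal so it never perturbs the quantity under test.

Every generator is a deterministic function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import numpy as np

from .cd import CDSampleMeta, theoretical_max_mre
from .spectra import AxisSpectrum, Grid2DSpectrum
from .tds import NMA_MU_SQ, CalibrantRecord

__all__ = [
    "BandSpec",
    "SceneSpec",
    "gen_linear_od",
    "gen_pump",
    "gen_2d_from_truth",
    "gen_cd",
    "truth_tds_profile",
    "calibrant_scene",
    "random_scene",
    "generate_measurement",
    "scene_from_dict",
    "scene_to_dict",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class BandSpec:
    """One amide I' band with its ground-truth transition dipole strength.

    center, fwhm : band position and full width at half maximum (cm^-1).
    od_amplitude : integrated band intensity; the line shape is unit-area,
        so the peak OD is roughly 0.94 * od_amplitude / fwhm (Gaussian).
    tds : ground-truth d(w) of this mode, in D^2.
    shape : 'gaussian', 'lorentzian' or 'pseudo_voigt'; ``mixing`` is the
        Lorentzian fraction of a pseudo-Voigt profile.
    """

    center: float
    fwhm: float
    od_amplitude: float
    tds: float
    shape: str = "gaussian"
    mixing: float = 0.5

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be > 0")
        if not self.od_amplitude > 0:
            raise ValueError("od_amplitude must be > 0")
        if not self.tds > 0:
            raise ValueError("tds must be > 0")
        if self.shape not in ("gaussian", "lorentzian", "pseudo_voigt"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (0.0 <= self.mixing <= 1.0):
            raise ValueError("mixing fraction must be in [0, 1]")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        """Unit-area line shape scaled by od_amplitude."""
        x = np.asarray(axis, dtype=float) - self.center
        sigma = self.fwhm / _FWHM_TO_SIGMA
        gauss = np.exp(-0.5 * (x / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        gamma = self.fwhm / 2.0
        lorentz = gamma / (np.pi * (x ** 2 + gamma ** 2))
        if self.shape == "gaussian":
            shape = gauss
        elif self.shape == "lorentzian":
            shape = lorentz
        else:
            shape = self.mixing * lorentz + (1.0 - self.mixing) * gauss
        return self.od_amplitude * shape


@dataclass(frozen=True)
class SceneSpec:
    """A complete synthetic measurement scenario.

    bands : the amide I' modes present.
    baseline_poly : polynomial baseline coefficients (ascending powers of
        (w - axis midpoint), OD units).
    baseline_gauss : optional broad Gaussian background (amplitude,
        center, fwhm) emulating solvent/cell backgrounds.
    noise_sd : i.i.d. Gaussian noise on the linear OD (OD units).
    axis : (w_lo, w_hi, step) in cm^-1.
    pump : (center, fwhm) of the Gaussian pump envelope.
    seed : integer controlling every random draw of the scene.
    """

    bands: tuple[BandSpec, ...]
    baseline_poly: tuple[float, ...] = (0.0,)
    baseline_gauss: tuple[float, float, float] | None = None
    noise_sd: float = 0.0
    axis: tuple[float, float, float] = (1580.0, 1720.0, 1.0)
    pump: tuple[float, float] = (1640.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi, step = self.axis
        if not (hi > lo and step > 0):
            raise ValueError("axis must satisfy w_hi > w_lo with step > 0")
        for b in self.bands:
            if b.center - 2 * b.fwhm < lo or b.center + 2 * b.fwhm > hi:
                raise ValueError(
                    f"axis [{lo}, {hi}] too narrow for band at {b.center} "
                    f"(needs center +/- 2*fwhm)"
                )

    def grid(self) -> np.ndarray:
        lo, hi, step = self.axis
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)

    def band_sum(self, axis: np.ndarray) -> np.ndarray:
        """Band-only (baseline-free, noise-free) OD."""
        total = np.zeros_like(axis, dtype=float)
        for b in self.bands:
            total += b.profile(axis)
        return total

    def baseline(self, axis: np.ndarray) -> np.ndarray:
        mid = 0.5 * (self.axis[0] + self.axis[1])
        x = axis - mid
        base = np.zeros_like(axis, dtype=float)
        for k, c in enumerate(self.baseline_poly):
            base += c * x ** k
        if self.baseline_gauss is not None:
            amp, center, fwhm = self.baseline_gauss
            sigma = fwhm / _FWHM_TO_SIGMA
            base += amp * np.exp(-0.5 * ((axis - center) / sigma) ** 2)
        return base


def _rng(scene: SceneSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([scene.seed, stream])


def gen_linear_od(scene: SceneSpec) -> AxisSpectrum:
    """Linear OD spectrum: band sum + baseline + seeded Gaussian noise.

    The noise-free band sum and the true baseline are stored in the
    metadata (``truth_bands``, ``truth_baseline``).
    """
    axis = scene.grid()
    bands = scene.band_sum(axis)
    base = scene.baseline(axis)
    noise = _rng(scene, 1).normal(0.0, scene.noise_sd, axis.size) \
        if scene.noise_sd > 0 else np.zeros(axis.size)
    return AxisSpectrum(axis, bands + base + noise, "linear_od", {
        "truth_bands": bands,
        "truth_baseline": base,
        "scene_seed": scene.seed,
    })


def gen_pump(scene: SceneSpec) -> AxisSpectrum:
    """Gaussian pump envelope on the scene axis, peak-normalized to 1."""
    axis = scene.grid()
    center, fwhm = scene.pump
    sigma = fwhm / _FWHM_TO_SIGMA
    vals = np.exp(-0.5 * ((axis - center) / sigma) ** 2)
    return AxisSpectrum(axis, vals, "pump", {"pump_center": center,
                                             "pump_fwhm": fwhm})


def truth_tds_profile(scene: SceneSpec, axis: np.ndarray) -> np.ndarray:
    """Ground-truth d(w): OD-weighted mean of band TDS values.

    Where the total band OD vanishes the profile is undefined and NaN is
    returned (those points carry no signal).
    """
    profiles = np.array([b.profile(axis) for b in scene.bands])
    total = profiles.sum(axis=0)
    tds = np.array([b.tds for b in scene.bands])
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (profiles * tds[:, None]).sum(axis=0) / total
    d[total == 0] = np.nan
    return d


def gen_2d_from_truth(scene: SceneSpec, od: AxisSpectrum, pump: AxisSpectrum,
                      cal: CalibrantRecord,
                      anharmonic_shift: float = 16.0,
                      probe_lobe_fwhm: float = 10.0,
                      overtone_frac: float = 0.85,
                      noise_sd: float = 0.0) -> Grid2DSpectrum:
    """Construct a 2D IR spectrum whose diagonal encodes the truth TDS.

    The diagonal magnitude is set by inverting the TDS relation against
    the band-only OD of the scene (baseline excluded: the pipeline's
    baseline correction is expected to remove it from the measured OD).
    The positive overtone lobe is red-shifted along probe by
    ``anharmonic_shift`` and orthogonalized against the diagonal so the
    encoded values are exact.  Seeded noise of ``noise_sd`` is added to
    the whole matrix.
    """
    axis = scene.grid()
    if od.axis.size != axis.size or not np.allclose(od.axis, axis):
        raise ValueError("od spectrum must live on the scene axis")
    band_od = scene.band_sum(axis)
    for b in scene.bands:
        support = (axis >= b.center - 2 * b.fwhm) & (axis <= b.center + 2 * b.fwhm)
        if np.any(band_od[support] == 0):
            raise ValueError("band-only OD vanishes inside a band support")
    d_truth = truth_tds_profile(scene, axis)
    pump_vals = pump.interp(axis)
    pump_at_max = float(pump.interp(np.array([cal.omega_max]))[0])
    amp = np.where(
        np.isnan(d_truth), 0.0,
        np.nan_to_num(d_truth) * band_od * (pump_vals / pump_at_max)
        * (cal.delta_od_max / cal.od_max) / cal.mu_sq,
    )

    # probe-direction lobes: unit-peak Gaussian fundamental; overtone lobe
    # orthogonalized so it vanishes exactly at delta = 0 (the diagonal)
    delta = axis[None, :] - axis[:, None]          # probe - pump
    k = 4.0 * np.log(2.0) / probe_lobe_fwhm ** 2
    g0 = np.exp(-k * delta ** 2)
    g_shift = np.exp(-k * (delta + anharmonic_shift) ** 2)
    g_at_shift = np.exp(-k * anharmonic_shift ** 2)
    overtone = g_shift - g_at_shift * g0
    matrix = amp[:, None] * (-g0 + overtone_frac * overtone)

    if noise_sd > 0:
        matrix = matrix + _rng(scene, 2).normal(0.0, noise_sd, matrix.shape)
    return Grid2DSpectrum(axis.copy(), axis.copy(), matrix, {
        "truth_tds": d_truth,
        "truth_diag": amp,
        "anharmonic_shift": anharmonic_shift,
    })


# ---------------------------------------------------------------------------
# CD generator

def _unit_gauss(axis: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((axis - center) / sigma) ** 2)


def _helix_basis(axis: np.ndarray) -> np.ndarray:
    """Helix MRE shape normalized to +1 at 222 nm (multiply by theta_H)."""
    raw = (1.9 * _unit_gauss(axis, 192.0, 9.0)
           - 0.95 * _unit_gauss(axis, 208.0, 11.0)
           - 1.0 * _unit_gauss(axis, 222.0, 15.5))
    at222 = (1.9 * _unit_gauss(np.array([222.0]), 192.0, 9.0)
             - 0.95 * _unit_gauss(np.array([222.0]), 208.0, 11.0)
             - 1.0)[0]
    return raw / at222


def _coil_basis(axis: np.ndarray) -> np.ndarray:
    """Random-coil MRE shape (deg cm^2/dmol): deep negative band at 198 nm."""
    return (-18000.0 * _unit_gauss(axis, 198.0, 11.0)
            + 300.0 * _unit_gauss(axis, 235.0, 15.0))


def gen_cd(frac_helix: float, meta: CDSampleMeta, noise_sd: float = 0.0,
           seed: int = 0,
           wavelengths: np.ndarray | None = None) -> AxisSpectrum:
    """Synthetic far-UV CD spectrum (raw mdeg vs nm) of known helicity.

    The MRE is a helix/coil two-state mixture scaled so the noise-free
    value at 222 nm equals ``frac_helix * theta_H(meta)``; the coil basis
    contributes (essentially) nothing at 222 nm, so the helicity analysis
    recovers ``frac_helix`` exactly in the noise-free limit.  The MRE is
    converted back to raw millidegrees by inverting the mean-residue
    normalization, and seeded Gaussian noise (mdeg) is added.
    """
    if not (0.0 <= frac_helix <= 1.0):
        raise ValueError("frac_helix must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    axis = np.arange(190.0, 251.0) if wavelengths is None \
        else np.asarray(wavelengths, dtype=float)
    theta_h = theoretical_max_mre(meta)
    mre = (frac_helix * theta_h * _helix_basis(axis)
           + (1.0 - frac_helix) * _coil_basis(axis))
    theta = mre * (meta.path_length * meta.concentration * meta.n_residues)
    noise = np.random.default_rng([seed, 3]).normal(0.0, noise_sd, axis.size) \
        if noise_sd > 0 else np.zeros(axis.size)
    return AxisSpectrum(axis, theta + noise, "cd", {
        "truth_frac_helix": frac_helix,
        "truth_theta_mdeg": theta,
    })


# ---------------------------------------------------------------------------
# ready-made scenes

def calibrant_scene(seed: int = 0, noise_sd: float = 0.0) -> SceneSpec:
    """An NMA-like calibrant: one uncoupled amide I' band, TDS 0.12 D^2."""
    return SceneSpec(
        bands=(BandSpec(center=1625.0, fwhm=22.0, od_amplitude=5.0,
                        tds=NMA_MU_SQ),),
        noise_sd=noise_sd,
        seed=seed,
    )


def random_scene(seed: int, noise_sd: float = 0.0,
                 n_bands: int | None = None) -> SceneSpec:
    """Draw a random but physically plausible amide I' scene.

    One to three bands in 1615-1675 cm^-1 (centers at least 15 cm^-1
    apart), widths 18-27 cm^-1, peak ODs roughly 0.1-0.4, ground-truth
    TDS 0.12-0.35 D^2; a mild linear baseline plus a broad, gently
    curved Gaussian background (FWHM 450-800 cm^-1, centre anywhere in
    1500-1800 cm^-1) that stays slowly varying across the amide I'
    window — a background hump sitting narrowly under the band region
    would be indistinguishable from an unresolved spectral band and is
    not a baseline; pump FWHM swept over 60-200 cm^-1.
    """
    rng = np.random.default_rng([seed, 17])
    k = int(rng.integers(1, 4)) if n_bands is None else n_bands
    centers: list[float] = []
    while len(centers) < k:
        c = float(rng.uniform(1615.0, 1675.0))
        if all(abs(c - c0) >= 15.0 for c0 in centers):
            centers.append(c)
    bands = tuple(
        BandSpec(
            center=c,
            fwhm=float(rng.uniform(18.0, 27.0)),
            od_amplitude=float(rng.uniform(3.0, 9.0)),
            tds=float(rng.uniform(0.12, 0.35)),
            shape="gaussian",
        )
        for c in centers
    )
    return SceneSpec(
        bands=bands,
        baseline_poly=(float(rng.uniform(0.0, 0.15)),
                       float(rng.uniform(-8e-4, 8e-4))),
        baseline_gauss=(float(rng.uniform(0.0, 0.06)),
                        float(rng.uniform(1500.0, 1800.0)),
                        float(rng.uniform(450.0, 800.0))),
        noise_sd=noise_sd,
        axis=(1560.0, 1740.0, 1.0),
        pump=(1640.0, float(rng.uniform(60.0, 200.0))),
        seed=seed,
    )


def generate_measurement(scene: SceneSpec, cal_scene: SceneSpec | None = None,
                         ratio_2d: float = 0.08,
                         snr: float | None = None) -> dict[str, Any]:
    """Generate the full input set of one TDS measurement.

    Produces the sample linear OD and 2D spectrum, a noise-free
    N-methylacetamide-like calibrant pair measured with the same pump,
    and the pump envelope.  ``ratio_2d`` is the instrument-dependent
    2D-to-1D signal ratio at the calibrant maximum (it cancels in the
    analysis).  If ``snr`` is given, Gaussian noise at that
    peak-signal-to-noise ratio is applied to both the sample OD and the
    sample 2D matrix (the calibrant stays noise-free: it is a dedicated
    reference measurement).

    Returns a dict with keys ``sample_2d``, ``sample_od``, ``cal_2d``,
    ``cal_od``, ``pump``, ``scene`` and ``truth_tds`` (the ground-truth
    d(w) profile on the scene axis).
    """
    pump = gen_pump(scene)
    if cal_scene is None:
        cal_scene = calibrant_scene(seed=scene.seed)
    axis_c = cal_scene.grid()
    band_od_c = cal_scene.band_sum(axis_c)
    i_max = int(np.argmax(band_od_c))
    provisional = CalibrantRecord(
        omega_max=float(axis_c[i_max]),
        delta_od_max=ratio_2d * float(band_od_c[i_max]),
        od_max=float(band_od_c[i_max]),
        mu_sq=NMA_MU_SQ,
    )
    cal_od = gen_linear_od(replace(cal_scene, noise_sd=0.0))
    cal_2d = gen_2d_from_truth(replace(cal_scene, noise_sd=0.0), cal_od,
                               pump, provisional)

    noise_sd_2d = 0.0
    if snr is not None:
        od_peak = float(scene.band_sum(scene.grid()).max())
        scene = replace(scene, noise_sd=od_peak / snr)
        clean_2d = gen_2d_from_truth(replace(scene, noise_sd=0.0),
                                     gen_linear_od(replace(scene, noise_sd=0.0)),
                                     pump, provisional)
        noise_sd_2d = float(np.abs(clean_2d.meta["truth_diag"]).max()) / snr
    sample_od = gen_linear_od(scene)
    sample_2d = gen_2d_from_truth(scene, sample_od, pump, provisional,
                                  noise_sd=noise_sd_2d)
    return {
        "sample_2d": sample_2d,
        "sample_od": sample_od,
        "cal_2d": cal_2d,
        "cal_od": cal_od,
        "pump": pump,
        "scene": scene,
        "truth_tds": sample_2d.meta["truth_tds"],
    }


# ---------------------------------------------------------------------------
# scene serialization (YAML/JSON-friendly dicts)

def scene_to_dict(scene: SceneSpec) -> dict[str, Any]:
    return {
        "bands": [
            {"center": b.center, "fwhm": b.fwhm,
             "od_amplitude": b.od_amplitude, "tds": b.tds,
             "shape": b.shape, "mixing": b.mixing}
            for b in scene.bands
        ],
        "baseline_poly": list(scene.baseline_poly),
        "baseline_gauss": list(scene.baseline_gauss)
        if scene.baseline_gauss is not None else None,
        "noise_sd": scene.noise_sd,
        "axis": list(scene.axis),
        "pump": list(scene.pump),
        "seed": scene.seed,
    }


def scene_from_dict(d: dict[str, Any]) -> SceneSpec:
    bands = tuple(BandSpec(**b) for b in d.get("bands", []))
    gauss = d.get("baseline_gauss")
    return SceneSpec(
        bands=bands,
        baseline_poly=tuple(d.get("baseline_poly", (0.0,))),
        baseline_gauss=tuple(gauss) if gauss is not None else None,
        noise_sd=float(d.get("noise_sd", 0.0)),
        axis=tuple(d.get("axis", (1580.0, 1720.0, 1.0))),
        pump=tuple(d.get("pump", (1640.0, 120.0))),
        seed=int(d.get("seed", 0)),
    )
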