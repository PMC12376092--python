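"""Penalized-least-squares baseline estimation for linear OD spectra.

The core of the baseline model is the adaptive iteratively reweighted
penalized least squares (airPLS) scheme: a Whittaker smoother — minimise

    sum_i w_i (y_i - z_i)^2  +  lam * sum (Delta^d z)^2

over candidate baselines z — alternated with residual-driven weight
updates.  Points lying above the current baseline (peaks) are given zero
weight; points below it keep exponentially growing weights, so the
baseline is pulled onto the lower envelope of the spectrum while the
difference penalty keeps it smooth.

Two practical safeguards are applied on top of the plain scheme, and a
refinement pass sharpens the result:

* the weights of an edge window at each end of the spectrum (fraction
  ``edge_frac``) are pinned to the maximum weight, anchoring the
  baseline to the data where the band cannot be (reference airPLS
  implementations do the same);
* the iteration stops early if the negative-residual mass increases
  between iterations — continuing past that point concentrates the
  exponential weights onto the deepest noise minima and drags the
  baseline far below the data in the unweighted band regions;
* finally (``refine=True``), the converged airPLS estimate is used only
  to locate the peak regions: the returned baseline is a uniform-weight
  Whittaker fit anchored on every non-peak point.  Uniform anchoring
  tracks the centre of the noise band instead of its lower envelope and
  gives the spline bridge under each band accurate boundary values and
  slopes, which removes most of the curvature bias of raw airPLS.

The smoothness weight ``lam`` sets the stiffness of the baseline
relative to the grid spacing; the default suits amide-I'-width bands on
a ~1 cm^-1 grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .spectra import AxisSpectrum

__all__ = ["AirPLSConfig", "whittaker_smooth", "airpls_baseline", "correct_baseline"]


@dataclass(frozen=True)
class AirPLSConfig:
    """airPLS parameters.

    lam : smoothness penalty weight (> 0); larger = stiffer baseline.
    max_iter : cap on reweighting iterations (>= 1).
    tol : relative termination threshold, in (0, 1): stop when the mass of
        negative residuals falls below ``tol * sum|y|``.
    diff_order : order of the finite-difference penalty (1, 2 or 3).
    edge_frac : fraction of points at each spectrum end whose weights are
        pinned to the maximum weight (edge anchoring).
    refine : re-estimate the baseline through a uniform-weight anchored
        fit after airPLS has located the peaks.
    peak_frac : fraction of the maximum peak signal above which a point
        counts as peak during refinement.
    """

    lam: float = 5e4
    max_iter: int = 50
    tol: float = 1e-3
    diff_order: int = 2
    edge_frac: float = 0.1
    refine: bool = True
    peak_frac: float = 0.02

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam must be > 0")
        if not (0 < self.tol < 1):
            raise ValueError("tol must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.diff_order not in (1, 2, 3):
            raise ValueError("diff_order must be 1, 2 or 3")
        if not (0 < self.edge_frac <= 0.5):
            raise ValueError("edge_frac must be in (0, 0.5]")
        if not (0 < self.peak_frac < 1):
            raise ValueError("peak_frac must be in (0, 1)")


def _diff_matrix(n: int, order: int) -> sparse.csc_matrix:
    D = sparse.eye(n, format="csc")
    for _ in range(order):
        D = D[1:] - D[:-1]
    return D


def whittaker_smooth(values: np.ndarray, weights: np.ndarray,
                     config: AirPLSConfig = AirPLSConfig()) -> np.ndarray:
    """Weighted Whittaker smoother.

    Solves the banded normal equations (W + lam * D^T D) z = W y for the
    smooth curve z, where W = diag(weights) and D is the ``diff_order``-th
    finite-difference operator.
    """
    y = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.ndim != 1 or w.shape != y.shape:
        raise ValueError("values and weights must be 1-D arrays of equal length")
    n = y.size
    if n < config.diff_order + 1:
        raise ValueError(f"need at least diff_order+1 = {config.diff_order + 1} points")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise np.linalg.LinAlgError("all weights are zero: singular system")
    D = _diff_matrix(n, config.diff_order)
    W = sparse.diags(w, format="csc")
    A = (W + config.lam * (D.T @ D)).tocsc()
    return np.asarray(spsolve(A, w * y))


def _airpls_iterate(y: np.ndarray, config: AirPLSConfig) -> tuple[np.ndarray, int, bool]:
    """Plain airPLS loop; returns (baseline, iterations, converged)."""
    n = y.size
    w = np.ones(n)
    abs_y_sum = np.abs(y).sum()
    z = y.copy()
    m_prev = np.inf
    converged = False
    k = max(1, int(np.ceil(n * config.edge_frac)))
    t = 0
    for t in range(1, config.max_iter + 1):
        z_new = whittaker_smooth(y, w, config)
        d = y - z_new
        neg = d < 0
        m = float(np.abs(d[neg]).sum())
        if m < config.tol * abs_y_sum:
            z = z_new
            converged = True
            break
        if m > m_prev:
            # weight mass no longer shrinking: further iterations would
            # concentrate the weights on noise minima and sink the
            # baseline; keep the previous estimate
            converged = True
            break
        z = z_new
        m_prev = m
        w = np.zeros(n)
        w[neg] = np.exp(t * np.abs(d[neg]) / m)
        w_max = w.max() if w.max() > 0 else 1.0
        w[:k] = w_max
        w[-k:] = w_max
    return z, t, converged


def _refine_baseline(y: np.ndarray, z: np.ndarray,
                     config: AirPLSConfig) -> np.ndarray:
    """Anchored uniform-weight re-fit of the baseline.

    Points whose airPLS-corrected signal exceeds ``peak_frac`` of the
    maximum signal (or four times the noise scale, whichever is larger)
    are treated as peak and excluded; the mask is dilated so band tails
    do not contaminate the anchors.  If too few anchors remain the
    airPLS estimate is returned unchanged.
    """
    signal = y - z
    peak_max = float(signal.max())
    if peak_max <= 0:
        return whittaker_smooth(y, np.ones_like(y), config)
    noise = 1.4826 * np.median(np.abs(np.diff(signal))) / np.sqrt(2.0)
    threshold = max(config.peak_frac * peak_max, 4.0 * noise)
    peak = signal > threshold
    # dilate the peak mask (~10 grid points) to push anchors past band tails
    width = 10
    kernel = np.ones(2 * width + 1)
    peak = np.convolve(peak.astype(float), kernel, mode="same") > 0
    anchors = ~peak
    if anchors.sum() < max(config.diff_order + 2, y.size // 10):
        return z
    return whittaker_smooth(y, anchors.astype(float), config)


def airpls_baseline(spectrum: AxisSpectrum,
                    config: AirPLSConfig = AirPLSConfig()) -> AxisSpectrum:
    """Estimate the baseline of a linear OD spectrum.

    Runs the airPLS iteration (see module docstring) and, when
    ``config.refine`` is set, re-estimates the baseline through the
    anchored uniform-weight fit.  Reaching ``max_iter`` is not an error:
    the current estimate is returned with ``baseline_converged=False``
    in the metadata.
    """
    y = spectrum.values
    if y.size < config.diff_order + 2:
        raise ValueError("spectrum too short for baseline estimation")
    z, iterations, converged = _airpls_iterate(y, config)
    if config.refine:
        z = _refine_baseline(y, z, config)
    return spectrum.with_values(
        z,
        baseline_lam=config.lam,
        baseline_iterations=iterations,
        baseline_converged=converged,
    )


def correct_baseline(spectrum: AxisSpectrum,
                     config: AirPLSConfig = AirPLSConfig()) -> AxisSpectrum:
    """Return ``spectrum - airpls_baseline(spectrum)`` on the same axis.

    The configuration used and the convergence outcome are recorded in
    the result metadata for reproducibility.
    """
    base = airpls_baseline(spectrum, config)
    return spectrum.with_values(
        spectrum.values - base.values,
        baseline_lam=config.lam,
        baseline_iterations=base.meta["baseline_iterations"],
        baseline_converged=base.meta["baseline_converged"],
    )
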