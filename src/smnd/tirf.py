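"""Evanescent-field penetration-depth calibration ("raisin-cake" method).

Gold nanospheres dispersed in a gel above the coverslip serve as point
scatterers at known heights. An epi-illumination z-scan gives each sphere's
absolute z (Gaussian fit of its intensity-vs-z trajectory); a least-squares
plane ``z0 = a·x + b·y + c`` removes the coverslip tilt; the TIRF-mode
signal-to-noise of the same spheres, binned along the corrected z in 100 nm
intervals, decays exponentially with depth. Fitting the binned profile with
an exponential decay convolved with a Gaussian (closed-form exponentially
modified Gaussian, the Gaussian width absorbing the z measurement error)
yields the 1/e penetration depth of the evanescent field.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erfcx

log = logging.getLogger(__name__)

__all__ = [
    "SphereRecord",
    "CalibrationResult",
    "ZProfileFit",
    "fit_z_profile",
    "fit_tilt_plane",
    "estimate_noise_floor",
    "estimate_penetration_depth",
    "calibrate_from_zscan",
]


@dataclass
class SphereRecord:
    """One gold nanosphere: lateral position, epi-derived z, TIRF SNR."""

    x: float
    y: float
    z: float
    tirf_snr: float


@dataclass
class CalibrationResult:
    """Tilt plane and fitted penetration depth."""

    plane: tuple[float, float, float]        # (a, b, c) of z0 = ax + by + c
    penetration_depth: float                 # nm
    sigma_z: float                           # Gaussian width of the depth fit, nm
    residual: float                          # RSS of the binned-SNR fit
    n_bins: int

    def __post_init__(self) -> None:
        if not (self.penetration_depth > 0):
            raise ValueError("penetration depth must be positive")


class ZProfileFit(NamedTuple):
    z_peak: float
    sigma: float
    valid: bool


def fit_z_profile(z: np.ndarray, intensity: np.ndarray) -> ZProfileFit:
    """Gaussian fit of one intensity-vs-z trajectory; returns the peak z.

    A profile whose maximum sits at either end of the scan (peak outside the
    range, e.g. a monotone trajectory) is flagged invalid.
    """
    z = np.asarray(z, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if z.size < 5:
        raise ValueError("need at least 5 z samples")
    imax = int(np.argmax(inten))
    if imax == 0 or imax == z.size - 1:
        return ZProfileFit(z_peak=float(z[imax]), sigma=float("nan"), valid=False)

    span = z[-1] - z[0]
    p0 = [float(inten.max() - inten.min()), float(z[imax]), span / 6.0, float(inten.min())]

    def gauss(zz, amp, z0, sig, off):
        return off + amp * np.exp(-0.5 * ((zz - z0) / sig) ** 2)

    try:
        popt, _ = curve_fit(gauss, z, inten, p0=p0,
                            bounds=([0, z[0], 1e-6, -np.inf],
                                    [np.inf, z[-1], 10 * span, np.inf]), maxfev=2000)
    except RuntimeError:
        return ZProfileFit(z_peak=float(z[imax]), sigma=float("nan"), valid=False)
    return ZProfileFit(z_peak=float(popt[1]), sigma=float(popt[2]), valid=True)


def fit_tilt_plane(x, y, z) -> tuple[tuple[float, float, float], np.ndarray]:
    """Least-squares plane ``z0 = a·x + b·y + c`` through sphere positions.

    Returns ``((a, b, c), corrected_z)`` where ``corrected_z = z − z0``.
    Raises on fewer than 3 spheres or (near-)collinear lateral positions.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    if x.size < 3:
        raise ValueError("need at least 3 spheres to fit a plane")
    design = np.column_stack([x, y, np.ones_like(x)])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max())) < 3:
        raise ValueError("sphere positions are collinear; plane is underdetermined")
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    a, b, c = (float(v) for v in coef)
    corrected = z - (a * x + b * y + c)
    return (a, b, c), corrected


def estimate_noise_floor(image: np.ndarray, fraction: float = 0.14) -> float:
    """Noise sd estimated from the dimmest ``fraction`` (14%) of pixels."""
    pix = np.asarray(image, dtype=float).ravel()
    if pix.size == 0:
        raise ValueError("empty image")
    k = max(1, int(math.floor(fraction * pix.size)))
    lowest = np.sort(pix)[:k]
    return float(np.std(lowest))


def _emg(z, amplitude, depth, sigma):
    """``amplitude · [exp(−z/depth) ⊛ N(0, σ²)](z)``, numerically stable.

    Closed form: ``A·exp(σ²/2d² − z/d)·erfc((σ²/d − z)/(√2σ))``; evaluated via
    erfcx with a log-space branch where erfcx would overflow.
    """
    z = np.asarray(z, dtype=float)
    v = (sigma ** 2 / depth - z) / (math.sqrt(2.0) * sigma)
    out = np.empty_like(z)
    small = v > -25.0
    out[small] = erfcx(v[small]) * np.exp(-z[small] ** 2 / (2.0 * sigma ** 2))
    out[~small] = 2.0 * np.exp(sigma ** 2 / (2.0 * depth ** 2) - z[~small] / depth)
    return amplitude * out


def estimate_penetration_depth(corrected_z, tirf_snr, bin_nm: float = 100.0,
                               min_per_bin: int = 3, weighted: bool = False) -> CalibrationResult:
    """Fit the binned SNR-vs-depth profile with an exponential ⊛ Gaussian.

    SNR values are binned along the tilt-corrected z in ``bin_nm`` intervals;
    bins with fewer than ``min_per_bin`` spheres are dropped (logged). The bin
    means are fitted with ``S(z) = S0·[exp(−(z−ζ)/d)·H(z−ζ) ⊛ N(0, σ_z²)]``
    where ``d`` is the penetration depth, σ_z absorbs the z measurement error
    (bounded by the bin width, far above any realistic epi-scan error), and
    the onset ζ accounts for the tilt-corrected axis being defined only up to
    an offset (the least-squares plane sits at the mean sphere height, so the
    coverslip — where the decay starts — lies below z = 0). Set
    ``weighted=True`` to weight bins by their sphere counts.
    """
    z = np.asarray(corrected_z, dtype=float)
    snr = np.asarray(tirf_snr, dtype=float)
    edges = np.arange(math.floor(z.min() / bin_nm) * bin_nm,
                      z.max() + bin_nm, bin_nm)
    if edges.size < 4:
        raise ValueError("corrected z range spans fewer than 3 bins")
    idx = np.digitize(z, edges) - 1
    zb, sb, nb = [], [], []
    n_dropped = 0
    for b in range(edges.size - 1):
        sel = idx == b
        if sel.sum() < min_per_bin:
            n_dropped += int(sel.sum() > 0)
            continue
        zb.append(z[sel].mean())
        sb.append(snr[sel].mean())
        nb.append(int(sel.sum()))
    if n_dropped:
        log.info("dropped %d sparse z bins (<%d spheres)", n_dropped, min_per_bin)
    if len(zb) < 3:
        raise ValueError("fewer than 3 usable z bins after sparsity filtering")
    zb = np.asarray(zb)
    sb = np.asarray(sb)
    nb = np.asarray(nb, dtype=float)

    span = zb.max() - zb.min()
    # initial depth from a log-linear regression on the decaying bins
    pos = sb > 0
    d0 = span / 3.0
    if pos.sum() >= 2:
        slope = np.polyfit(zb[pos], np.log(sb[pos]), 1)[0]
        if slope < -1e-12:
            d0 = -1.0 / slope
    d0 = float(np.clip(d0, 2.0, 10.0 * span))
    # sigma_z models the z measurement error of the epi scan — far below bin width
    z_min = float(zb.min())
    p0 = [2.0 * float(sb.max()), d0, 0.2 * bin_nm, z_min]
    lo = [0.0, 1.0, 1e-3, z_min - bin_nm]
    hi = [np.inf, 50.0 * max(span, bin_nm), 0.5 * bin_nm, z_min + bin_nm]

    def model(zz, amp, depth, sigma, onset):
        return _emg(zz - onset, amp, depth, sigma)

    sigma_w = 1.0 / np.sqrt(nb) if weighted else None
    try:
        popt, _ = curve_fit(model, zb, sb, p0=p0, bounds=(lo, hi),
                            sigma=sigma_w, maxfev=5000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"penetration-depth fit did not converge on {len(zb)} bins "
            f"(z span {span:.0f} nm, SNR range {sb.min():.3g}–{sb.max():.3g})") from exc
    amp, depth, sigma_z, _onset = (float(v) for v in popt)
    if depth >= hi[1] * 0.99 or amp <= 0:
        raise RuntimeError(
            f"penetration-depth fit degenerate (depth {depth:.3g} nm at bound, "
            f"amplitude {amp:.3g}); SNR profile may be flat")
    rss = float(np.sum((model(zb, *popt) - sb) ** 2))
    return CalibrationResult(plane=(0.0, 0.0, 0.0), penetration_depth=depth,
                             sigma_z=sigma_z, residual=rss, n_bins=len(zb))


def calibrate_from_zscan(dataset, bin_nm: float = 100.0, weighted: bool = False) -> CalibrationResult:
    """End-to-end calibration from a (synthetic or measured) z-scan dataset.

    Expects an object with ``x``, ``y``, ``z_grid``, ``epi_profiles`` and
    ``tirf_snr`` attributes (see :class:`smnd.synthetic.ZScanDataset`). Fits
    every epi profile, drops invalid ones, removes the coverslip tilt and
    estimates the penetration depth.
    """
    peaks, keep = [], []
    for i, prof in enumerate(dataset.epi_profiles):
        fit = fit_z_profile(dataset.z_grid, prof)
        if fit.valid:
            peaks.append(fit.z_peak)
            keep.append(i)
    if len(keep) < 3:
        raise ValueError("fewer than 3 spheres with valid z profiles")
    keep = np.asarray(keep)
    plane, corrected = fit_tilt_plane(dataset.x[keep], dataset.y[keep], np.asarray(peaks))
    result = estimate_penetration_depth(corrected, dataset.tirf_snr[keep],
                                        bin_nm=bin_nm, weighted=weighted)
    return CalibrationResult(plane=plane, penetration_depth=result.penetration_depth,
                             sigma_z=result.sigma_z, residual=result.residual,
                             n_bins=result.n_bins)
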