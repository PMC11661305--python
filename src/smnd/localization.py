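"""Localization engine: from raw movies to quality-filtered localization tables.

The processing chain mirrors standard SMLM practice: temporal background
subtraction, local-maximum candidate detection, 2D Gaussian PSF fitting on
9×9 pixel subregions, per-localization error estimation (Thompson-style),
quality filtering on FWHM / localization error / SNR, duplicate merging
across consecutive frames, and drift correction by redundant
cross-correlation (RCC).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

__all__ = [
    "PsfFit",
    "subtract_background",
    "detect_candidates",
    "fit_psf",
    "localization_error",
    "theoretical_fwhm",
    "quality_filter",
    "remove_duplicates",
    "correct_drift",
    "localize_movie",
]

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))   # 2.3548...

# default quality thresholds: FWHM 117–600 nm inclusive, error ≤ 20 nm, SNR > 3.6
DEFAULT_FWHM_RANGE = (117.0, 600.0)
DEFAULT_ERROR_MAX = 20.0
DEFAULT_SNR_MIN = 3.6


@dataclass
class PsfFit:
    """Result of a 2D Gaussian fit to one PSF subregion.

    Model: ``I(x, y) = b + A · exp(−½[((x−x0)/σx)² + ((y−y0)/σy)²])``.
    Positions/widths in nm relative to the subregion origin; ``photons`` is
    the integrated count ``2π·A·σx·σy / a²`` for pixel size ``a``; ``snr`` is
    the fitted amplitude over the residual background sd.
    """

    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    amplitude: float
    offset: float
    photons: float
    bg_sd: float
    valid: bool

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * 0.5 * (self.sigma_x + self.sigma_y)

    @property
    def snr(self) -> float:
        return self.amplitude / self.bg_sd if self.bg_sd > 0 else math.inf


def subtract_background(movie: np.ndarray, window: int = 50) -> np.ndarray:
    """Subtract the temporal mean of neighboring frames from every frame.

    Each output frame is the input frame minus the mean of up to ``window``
    frames before and ``window`` after it, the frame itself excluded; at the
    movie edges the available frames are used. This removes static background
    (scattering, fiducials) while leaving single-frame events intact.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError(f"expected (frames, ny, nx) movie, got shape {movie.shape}")
    t = movie.shape[0]
    if t == 1:
        warnings.warn("single-frame movie: background equals the frame, output is zero")
        return np.zeros_like(movie)
    eff = min(window, t - 1)
    if eff < window:
        log.info("background window shrunk from %d to %d (movie has %d frames)", window, eff, t)

    csum = np.concatenate([np.zeros((1,) + movie.shape[1:]), np.cumsum(movie, axis=0)])
    out = np.empty_like(movie)
    for i in range(t):
        lo, hi = max(0, i - eff), min(t - 1, i + eff)
        total = csum[hi + 1] - csum[lo] - movie[i]
        out[i] = movie[i] - total / (hi - lo)
    return out


def _robust_sd(frame: np.ndarray) -> float:
    med = np.median(frame)
    return 1.4826 * float(np.median(np.abs(frame - med)))


def detect_candidates(frame: np.ndarray, min_snr: float = DEFAULT_SNR_MIN,
                      merge_px: float = 9.0) -> list[tuple[int, int]]:
    """Candidate emitter pixels: strict 3×3 local maxima above the noise floor.

    A pixel qualifies if it exceeds all 8 neighbors and is brighter than
    ``min_snr`` times the frame's robust (MAD-based) noise sd. Candidates
    closer than ``merge_px`` pixels collapse to the brighter one. Returns
    (row, col) tuples.
    """
    frame = np.asarray(frame, dtype=float)
    sd = _robust_sd(frame)
    c = frame[1:-1, 1:-1]
    strict_max = np.ones_like(c, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            strict_max &= c > frame[1 + dr:frame.shape[0] - 1 + dr,
                                    1 + dc:frame.shape[1] - 1 + dc]
    strict_max &= c > min_snr * sd
    rows, cols = np.nonzero(strict_max)
    rows, cols = rows + 1, cols + 1
    if rows.size == 0:
        return []

    order = np.argsort(-frame[rows, cols])           # brightest first
    kept: list[tuple[int, int]] = []
    for i in order:
        r, col = int(rows[i]), int(cols[i])
        if all((r - kr) ** 2 + (col - kc) ** 2 >= merge_px ** 2 for kr, kc in kept):
            kept.append((r, col))
    return kept


def _gauss2d(coords, x0, y0, sx, sy, amp, off):
    x, y = coords
    return (off + amp * np.exp(-0.5 * (((x - x0) / sx) ** 2 + ((y - y0) / sy) ** 2))).ravel()


def fit_psf(subregion: np.ndarray, pixel_size: float) -> PsfFit:
    """Fit the 5+1-parameter 2D Gaussian to one PSF subregion (typically 9×9).

    Two-pass nonlinear least squares: an unweighted pass supplies starting
    values and a noise estimate, then the fit is repeated with per-pixel
    shot-noise weights (variance ≈ expected signal + background variance),
    which brings the estimator's scatter in line with the localization-error
    formula. Returns nm-scale center and widths (relative to the subregion
    origin), integrated photons ``N = 2π·A·σx·σy/a²`` and the residual
    background sd. Non-convergence or a width pinned at the fit bounds flags
    the result invalid (to be dropped and counted by callers).
    """
    win = np.asarray(subregion, dtype=float)
    ny, nx = win.shape
    ygrid, xgrid = np.mgrid[0:ny, 0:nx]
    xy = ((xgrid + 0.5) * pixel_size, (ygrid + 0.5) * pixel_size)

    off0 = float(win.min())
    amp0 = float(win.max() - off0)
    w = np.clip(win - off0, 0, None) + 1e-12
    x0_0 = float((xy[0] * w).sum() / w.sum())
    y0_0 = float((xy[1] * w).sum() / w.sum())
    s0 = 0.3 * nx * pixel_size / 2.0

    lo = [0.0, 0.0, 0.2 * pixel_size, 0.2 * pixel_size, 0.0, -np.inf]
    hi = [nx * pixel_size, ny * pixel_size, 3.0 * nx * pixel_size, 3.0 * ny * pixel_size,
          np.inf, np.inf]
    try:
        popt, _ = curve_fit(_gauss2d, xy, win.ravel(),
                            p0=[x0_0, y0_0, s0, s0, max(amp0, 1e-6), off0],
                            bounds=(lo, hi), maxfev=2000)
        valid = True
        # second pass: weight pixels by their expected shot-noise variance
        model1 = _gauss2d(xy, *popt).reshape(win.shape)
        bg_var = float(np.var(win - model1))
        weights = np.sqrt(np.clip(model1 - popt[5], 0.0, None) + bg_var)
        floor = max(1e-3 * weights.max(), 1e-12)
        try:
            popt, _ = curve_fit(_gauss2d, xy, win.ravel(), p0=popt,
                                sigma=np.clip(weights, floor, None).ravel(),
                                bounds=(lo, hi), maxfev=2000)
        except RuntimeError:
            pass                             # keep the unweighted solution
    except RuntimeError:
        popt = [x0_0, y0_0, s0, s0, amp0, off0]
        valid = False
    x0, y0, sx, sy, amp, off = (float(v) for v in popt)
    eps = 1e-6
    if valid and (sx <= lo[2] + eps or sy <= lo[3] + eps or sx >= hi[2] - eps or sy >= hi[3] - eps):
        valid = False

    model = _gauss2d(xy, *popt).reshape(win.shape)
    bg_sd = float(np.std(win - model))
    photons = 2.0 * math.pi * amp * sx * sy / pixel_size ** 2
    return PsfFit(x0=x0, y0=y0, sigma_x=sx, sigma_y=sy, amplitude=amp,
                  offset=off, photons=photons, bg_sd=bg_sd, valid=valid)


def localization_error(sigma: float, n_photons: float, pixel_size: float, bg_sd: float) -> float:
    """Predicted localization error (nm) from photon statistics.

    ``error² = σ²/N + a²/(12N) + 8π·σ⁴·b²/(a²·N²)`` — photon shot noise,
    pixelation, and background noise terms — with σ the PSF Gaussian width,
    N the integrated photons, a the pixel size and b the background sd.
    """
    sigma = np.asarray(sigma, dtype=float)
    n = np.asarray(n_photons, dtype=float)
    if np.any(n <= 0):
        raise ValueError("photon count must be > 0")
    if pixel_size <= 0:
        raise ValueError("pixel size must be > 0")
    var = (sigma ** 2 / n
           + pixel_size ** 2 / (12.0 * n)
           + 8.0 * math.pi * sigma ** 4 * np.asarray(bg_sd, float) ** 2
           / (pixel_size ** 2 * n ** 2))
    out = np.sqrt(var)
    return float(out) if out.ndim == 0 else out


def theoretical_fwhm(wavelength: float, numerical_aperture: float) -> float:
    """Diffraction-limited PSF FWHM, ``0.51·λ/NA`` (nm)."""
    if numerical_aperture <= 0:
        raise ValueError("numerical aperture must be > 0")
    return 0.51 * wavelength / numerical_aperture


def quality_filter(table: pd.DataFrame, fwhm_range=DEFAULT_FWHM_RANGE,
                   error_max: float = DEFAULT_ERROR_MAX,
                   snr_min: float = DEFAULT_SNR_MIN) -> pd.DataFrame:
    """Keep localizations with FWHM ∈ [117, 600] nm, error ∈ [0, 20] nm, SNR > 3.6.

    FWHM is computed from the mean of the fitted widths. Bounds on FWHM and
    error are inclusive; the SNR bound is strict. Removal counts per criterion
    are logged.
    """
    required = {"sigma_x_nm", "sigma_y_nm", "loc_error_nm", "snr"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks required columns: {sorted(missing)}")
    fwhm = FWHM_FACTOR * 0.5 * (table["sigma_x_nm"] + table["sigma_y_nm"])
    ok_fwhm = (fwhm >= fwhm_range[0]) & (fwhm <= fwhm_range[1])
    ok_err = (table["loc_error_nm"] >= 0) & (table["loc_error_nm"] <= error_max)
    ok_snr = table["snr"] > snr_min
    log.info("quality_filter removed: fwhm=%d, error=%d, snr=%d of %d",
             int((~ok_fwhm).sum()), int((~ok_err).sum()), int((~ok_snr).sum()), len(table))
    return table[ok_fwhm & ok_err & ok_snr].reset_index(drop=True)


def remove_duplicates(table: pd.DataFrame, merge_radius: float = 50.0,
                      max_frame_gap: int = 1) -> pd.DataFrame:
    """Merge re-detections of the same emitter across nearby frames.

    Localizations within ``merge_radius`` nm whose frame gap is at most
    ``max_frame_gap`` are chained transitively and collapsed to a single
    record at the photon-weighted mean position with summed photons; the
    earliest frame and the remaining columns of the brightest member are kept.
    """
    if len(table) == 0:
        return table.copy()
    df = table.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = df["frame"].to_numpy()
    xy = df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    parent = np.arange(len(df))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # link each localization to spatially-close ones in the preceding frames
    for f in np.unique(frames):
        cur = np.flatnonzero(frames == f)
        prev = np.flatnonzero((frames < f) & (frames >= f - max_frame_gap))
        if cur.size == 0 or prev.size == 0:
            continue
        tree = cKDTree(xy[prev])
        for i in cur:
            hits = tree.query_ball_point(xy[i], r=merge_radius)
            for h in hits:
                ri, rj = find(i), find(prev[h])
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    roots = np.array([find(i) for i in range(len(df))])
    out_rows = []
    for root in np.unique(roots):
        members = df.iloc[np.flatnonzero(roots == root)]
        if len(members) == 1:
            out_rows.append(members.iloc[0])
            continue
        w = members["photons"].to_numpy(dtype=float)
        w = w / w.sum() if w.sum() > 0 else np.full(len(members), 1.0 / len(members))
        rec = members.iloc[int(np.argmax(members["photons"].to_numpy()))].copy()
        rec["x_nm"] = float(members["x_nm"] @ w)
        rec["y_nm"] = float(members["y_nm"] @ w)
        rec["photons"] = float(members["photons"].sum())
        rec["frame"] = int(members["frame"].min())
        out_rows.append(rec)
    return pd.DataFrame(out_rows).sort_values("frame", kind="stable").reset_index(drop=True)


def _render_histogram(xy: np.ndarray, bin_nm: float, extent) -> np.ndarray:
    (x0, x1), (y0, y1) = extent
    nx = max(int(np.ceil((x1 - x0) / bin_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_nm)), 1)
    h, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=[ny, nx],
                             range=[[y0, y0 + ny * bin_nm], [x0, x0 + nx * bin_nm]])
    return h


def correct_drift(table: pd.DataFrame, bin_frames: int = 1000, bin_nm: float = 20.0,
                  min_locs_per_bin: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Redundant cross-correlation drift correction.

    Frames are grouped into temporal bins; each bin is rendered as a 2D
    histogram; sub-pixel shifts between every bin pair are measured by
    upsampled phase cross-correlation and combined by least squares (the
    redundancy averages down registration noise). Per-frame drift is linearly
    interpolated between bin centers and subtracted.

    Returns ``(corrected table, drift trace)`` with the trace holding per-frame
    ``dx_nm``/``dy_nm``.
    """
    from skimage.registration import phase_cross_correlation

    frames = table["frame"].to_numpy()
    f_min, f_max = int(frames.min()), int(frames.max())
    n_bins = max(1, (f_max - f_min + 1 + bin_frames - 1) // bin_frames)
    all_frames = np.arange(f_min, f_max + 1)
    zero_trace = pd.DataFrame({"frame": all_frames,
                               "dx_nm": 0.0, "dy_nm": 0.0})
    if n_bins < 2:
        warnings.warn("fewer than 2 temporal bins; drift correction skipped")
        return table.copy(), zero_trace

    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    extent = ((xy[:, 0].min(), xy[:, 0].max() + 1e-9), (xy[:, 1].min(), xy[:, 1].max() + 1e-9))
    bin_idx = np.clip((frames - f_min) // bin_frames, 0, n_bins - 1)
    counts = np.bincount(bin_idx, minlength=n_bins)
    if np.any(counts < min_locs_per_bin):
        warnings.warn("too few localizations per temporal bin; drift correction skipped")
        return table.copy(), zero_trace

    from scipy.ndimage import gaussian_filter

    # smoothing the sparse renderings stabilizes the cross-correlation peak
    imgs = [gaussian_filter(_render_histogram(xy[bin_idx == b], bin_nm, extent), 2.0)
            for b in range(n_bins)]

    pairs, shifts = [], []
    for i in range(n_bins):
        for j in range(i + 1, n_bins):
            shift, _, _ = phase_cross_correlation(imgs[i], imgs[j], upsample_factor=20,
                                                  normalization=None)
            pairs.append((i, j))
            shifts.append(shift * bin_nm)       # (dy, dx) of img_j relative to img_i
    shifts = np.asarray(shifts)

    # least squares for per-bin drift d_b with d_0 = 0: shift(i, j) = d_j − d_i
    a_mat = np.zeros((len(pairs), n_bins))
    for row, (i, j) in enumerate(pairs):
        a_mat[row, i] = -1.0
        a_mat[row, j] = 1.0
    a_red = a_mat[:, 1:]
    dy = np.concatenate([[0.0], np.linalg.lstsq(a_red, -shifts[:, 0], rcond=None)[0]])
    dx = np.concatenate([[0.0], np.linalg.lstsq(a_red, -shifts[:, 1], rcond=None)[0]])

    bin_centers = f_min + bin_frames * (np.arange(n_bins) + 0.5)
    drift_x = np.interp(all_frames, bin_centers, dx)
    drift_y = np.interp(all_frames, bin_centers, dy)

    out = table.copy()
    out["x_nm"] = out["x_nm"] - drift_x[frames - f_min]
    out["y_nm"] = out["y_nm"] - drift_y[frames - f_min]
    trace = pd.DataFrame({"frame": all_frames, "dx_nm": drift_x, "dy_nm": drift_y})
    return out, trace


def localize_movie(movie: np.ndarray, pixel_size: float, window: int = 50,
                   min_snr: float = DEFAULT_SNR_MIN, fit_half: int = 4,
                   apply_filter: bool = True) -> pd.DataFrame:
    """Full chain: background subtraction → detection → PSF fitting → filtering.

    Returns a localization table in the documented CSV schema with positions
    in nm (image coordinate frame, origin at the corner of pixel (0, 0)).
    """
    sub = subtract_background(movie, window=window)
    records = []
    n_invalid = 0
    size = 2 * fit_half + 1
    for t in range(sub.shape[0]):
        frame = sub[t]
        for r, c in detect_candidates(frame, min_snr=min_snr):
            if (r - fit_half < 0 or c - fit_half < 0
                    or r + fit_half + 1 > frame.shape[0] or c + fit_half + 1 > frame.shape[1]):
                continue
            win = frame[r - fit_half:r + fit_half + 1, c - fit_half:c + fit_half + 1]
            fit = fit_psf(win, pixel_size)
            if not fit.valid or fit.photons <= 0:
                n_invalid += 1
                continue
            sigma = 0.5 * (fit.sigma_x + fit.sigma_y)
            err = localization_error(sigma, fit.photons, pixel_size, fit.bg_sd)
            records.append({
                "x_nm": (c - fit_half) * pixel_size + fit.x0,
                "y_nm": (r - fit_half) * pixel_size + fit.y0,
                "frame": t,
                "photons": fit.photons,
                "sigma_x_nm": fit.sigma_x,
                "sigma_y_nm": fit.sigma_y,
                "bg_sd": fit.bg_sd,
                "snr": fit.snr,
                "loc_error_nm": err,
                "truth_id": -1,
            })
    if n_invalid:
        log.info("dropped %d invalid PSF fits", n_invalid)
    table = pd.DataFrame(records, columns=[
        "x_nm", "y_nm", "frame", "photons", "sigma_x_nm", "sigma_y_nm",
        "bg_sd", "snr", "loc_error_nm", "truth_id"])
    if apply_filter and len(table):
        table = quality_filter(table)
    return table
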