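"""Synthetic data generation for the smND pipeline.

Every stage of the pipeline can be exercised against data with known ground
truth: 2D membrane fields of monomer/dimer/trimer complexes imaged by a
photoconvertible tag, raw PSF movies, gold-nanosphere z-scan stacks for
evanescent-depth calibration, and diffraction-limited puncta images.

The oligomer-field generator is the forward model behind the theoretical
neighbor-density distribution (``PND_theo``): complexes are placed as a dilute
spatial Poisson process on a flat membrane patch, a size-``k`` complex exposes
``k`` subunits on a regular ``k``-gon of fixed edge length, each subunit is
photoconverted/detected independently with probability ``p_detect``, and every
detected subunit yields one localization (plus optional blink re-counts)
displaced by isotropic Gaussian localization noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OligomerFieldConfig",
    "SyntheticTruth",
    "simulate_oligomer_field",
    "simulate_movie",
    "simulate_zscan_pair",
    "simulate_puncta_image",
]

#: column order of the localization-table CSV written by this package
LOCALIZATION_COLUMNS = [
    "x_nm", "y_nm", "frame", "photons", "sigma_x_nm", "sigma_y_nm",
    "bg_sd", "snr", "loc_error_nm", "truth_id",
]


@dataclass(frozen=True)
class OligomerFieldConfig:
    """Parameters of a synthetic membrane field of oligomeric complexes.

    Parameters
    ----------
    field_width, field_height : float
        Membrane patch extent in nm.
    complex_density : float
        Complexes per µm² (dilute; ignored if ``n_complexes`` is given).
    fractions : tuple of float
        Complex-level mixture ``(f_M, f_D, f_T)``; must sum to 1.
    subunit_spacing : float
        Intra-complex edge length in nm. Default 5 nm, matching the footprint
        of a small membrane transporter (~10 nm × 5 nm per subunit).
    p_detect : float
        Probability that a subunit is photoconverted and detected.
    sigma_loc : float
        Localization precision (1D Gaussian std) in nm.
    blink_mean : float
        Mean number of EXTRA localizations per detected subunit
        (``1 + Poisson(blink_mean)`` localizations total); 0 means blinks
        were merged upstream and each detected subunit is counted once.
    background_density : float
        Spurious localizations per µm².
    seed : int
        RNG seed; identical seeds give bit-identical output.
    n_complexes : int or None
        If set, place exactly this many complexes instead of drawing
        ``Poisson(density × area)``.
    n_frames : int
        Number of camera frames localizations are spread over (uniformly).
    """

    field_width: float = 20000.0
    field_height: float = 20000.0
    complex_density: float = 5.0
    fractions: tuple[float, float, float] = (0.2, 0.15, 0.65)
    subunit_spacing: float = 5.0
    p_detect: float = 0.6
    sigma_loc: float = 10.0
    blink_mean: float = 0.0
    background_density: float = 0.2
    seed: int = 0
    n_complexes: int | None = None
    n_frames: int = 1000

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (3,) or not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ValueError(f"fractions must be 3 finite non-negatives, got {self.fractions}")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 within 1e-9, got sum {f.sum()!r}")
        for name in ("field_width", "field_height", "complex_density", "subunit_spacing",
                     "sigma_loc", "blink_mean", "background_density"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if not (0.0 <= self.p_detect <= 1.0):
            raise ValueError(f"p_detect must be in [0, 1], got {self.p_detect!r}")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field dimensions must be positive")

    @property
    def area_um2(self) -> float:
        return self.field_width * self.field_height / 1e6

    def with_fractions(self, fractions) -> "OligomerFieldConfig":
        """Copy of this config with the mixture fractions replaced."""
        return replace(self, fractions=tuple(float(v) for v in fractions))


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated oligomer field.

    ``loc_source[i]`` is the subunit index that produced localization ``i``,
    or -1 for a background localization.
    """

    complex_centers: np.ndarray          # (n_complexes, 2) nm
    complex_sizes: np.ndarray            # (n_complexes,) in {1,2,3}
    subunit_positions: np.ndarray        # (n_subunits, 2) nm
    subunit_complex: np.ndarray          # (n_subunits,) complex index
    subunit_detected: np.ndarray         # (n_subunits,) bool
    loc_source: np.ndarray               # (n_localizations,) subunit index or -1
    config: OligomerFieldConfig = field(repr=False, default=None)

    @property
    def n_background(self) -> int:
        return int(np.sum(self.loc_source < 0))

    def localization_fraction_by_size(self, k: int) -> float:
        """Fraction of non-background localizations emitted by size-``k`` complexes."""
        src = self.loc_source[self.loc_source >= 0]
        if src.size == 0:
            return float("nan")
        sizes = self.complex_sizes[self.subunit_complex[src]]
        return float(np.mean(sizes == k))


def _kgon_vertices(k: int, edge: float, rng: np.random.Generator, n: int) -> np.ndarray:
    """Vertices of ``n`` randomly oriented regular ``k``-gons with the given edge, about the origin.

    Returns an (n, k, 2) array. A monomer sits at the origin exactly.
    """
    if k == 1:
        return np.zeros((n, 1, 2))
    circum_r = edge / (2.0 * math.sin(math.pi / k))
    theta0 = rng.uniform(0.0, 2.0 * math.pi, size=n)[:, None]
    angles = theta0 + 2.0 * math.pi * np.arange(k)[None, :] / k
    return circum_r * np.stack([np.cos(angles), np.sin(angles)], axis=-1)


def simulate_oligomer_field(config: OligomerFieldConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate one membrane field and return (localization table, truth).

    The localization table has the documented CSV columns (positions in nm,
    camera frame, photons, fitted widths, background sd, SNR, predicted
    localization error, and a ``truth_id`` linking back to the truth record's
    ``loc_source``). Photon counts and fit widths are plausible fill-in values
    drawn once per localization; the geometric content (positions, counts,
    mixture) is what carries the ground truth.
    """
    rng = np.random.default_rng(config.seed)

    if config.n_complexes is not None:
        n_complex = int(config.n_complexes)
    else:
        n_complex = int(rng.poisson(config.complex_density * config.area_um2))

    centers = np.column_stack([
        rng.uniform(0.0, config.field_width, size=n_complex),
        rng.uniform(0.0, config.field_height, size=n_complex),
    ])
    sizes = rng.choice([1, 2, 3], size=n_complex, p=np.asarray(config.fractions, float))

    # subunit positions, grouped by oligomer size for vectorized k-gon layout
    sub_pos_parts, sub_cx_parts = [], []
    for k in (1, 2, 3):
        idx = np.flatnonzero(sizes == k)
        if idx.size == 0:
            continue
        verts = _kgon_vertices(k, config.subunit_spacing, rng, idx.size)
        pos = centers[idx][:, None, :] + verts            # (m, k, 2)
        sub_pos_parts.append(pos.reshape(-1, 2))
        sub_cx_parts.append(np.repeat(idx, k))
    if sub_pos_parts:
        subunit_pos = np.concatenate(sub_pos_parts)
        subunit_cx = np.concatenate(sub_cx_parts)
    else:
        subunit_pos = np.zeros((0, 2))
        subunit_cx = np.zeros(0, dtype=int)

    detected = rng.random(subunit_pos.shape[0]) < config.p_detect

    det_idx = np.flatnonzero(detected)
    if config.blink_mean > 0:
        n_locs_per = 1 + rng.poisson(config.blink_mean, size=det_idx.size)
    else:
        n_locs_per = np.ones(det_idx.size, dtype=int)
    src = np.repeat(det_idx, n_locs_per)
    loc_xy = subunit_pos[src] + rng.normal(0.0, config.sigma_loc, size=(src.size, 2))

    n_bg = int(rng.poisson(config.background_density * config.area_um2))
    bg_xy = np.column_stack([
        rng.uniform(0.0, config.field_width, size=n_bg),
        rng.uniform(0.0, config.field_height, size=n_bg),
    ])

    xy = np.concatenate([loc_xy, bg_xy])
    source = np.concatenate([src, np.full(n_bg, -1, dtype=int)])
    n_loc = xy.shape[0]

    # plausible per-localization photometry (fill-in, not ground truth)
    photons = rng.gamma(shape=4.0, scale=250.0, size=n_loc)
    sigma_fit = rng.normal(130.0, 10.0, size=n_loc).clip(80.0, 250.0)
    bg_sd = rng.gamma(2.0, 1.5, size=n_loc)
    snr = rng.gamma(6.0, 2.0, size=n_loc) + 3.7
    table = pd.DataFrame({
        "x_nm": xy[:, 0],
        "y_nm": xy[:, 1],
        "frame": rng.integers(0, config.n_frames, size=n_loc),
        "photons": photons,
        "sigma_x_nm": sigma_fit,
        "sigma_y_nm": sigma_fit,
        "bg_sd": bg_sd,
        "snr": snr,
        "loc_error_nm": np.full(n_loc, float(config.sigma_loc)),
        "truth_id": source,
    })

    truth = SyntheticTruth(
        complex_centers=centers,
        complex_sizes=sizes,
        subunit_positions=subunit_pos,
        subunit_complex=subunit_cx,
        subunit_detected=detected,
        loc_source=source,
        config=config,
    )
    return table, truth


# ---------------------------------------------------------------------------
# raw movie rendering


def _integrated_gaussian(shape: tuple[int, int], x_nm: float, y_nm: float,
                         photons: float, psf_sigma: float, pixel_size: float) -> np.ndarray:
    """Expected photon count per pixel for one emitter (error-function integrated PSF)."""
    from scipy.special import erf

    ny, nx = shape
    s = math.sqrt(2.0) * psf_sigma
    xe = np.arange(nx + 1) * pixel_size
    ye = np.arange(ny + 1) * pixel_size
    fx = 0.5 * (erf((xe[1:] - x_nm) / s) - erf((xe[:-1] - x_nm) / s))
    fy = 0.5 * (erf((ye[1:] - y_nm) / s) - erf((ye[:-1] - y_nm) / s))
    return photons * np.outer(fy, fx)


def simulate_movie(
    emitters,
    psf_sigma: float,
    pixel_size: float,
    background_level: float = 0.0,
    frames: int = 1,
    shape: tuple[int, int] = (64, 64),
    noise: bool = True,
    activation: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render a raw camera movie of point emitters.

    Parameters
    ----------
    emitters : sequence of (x_nm, y_nm, photons)
        Emitter positions (nm, relative to the image origin) and total photons.
    psf_sigma : float
        PSF Gaussian std in nm; must be positive.
    pixel_size : float
        Camera pixel size in nm.
    background_level : float
        Constant expected background per pixel (counts).
    frames : int
        Number of frames.
    shape : (ny, nx)
        Frame shape in pixels.
    noise : bool
        Apply Poisson shot noise to the expected counts.
    activation : array (n_emitters, frames) of bool, optional
        Which frames each emitter is on in. Default: each emitter active in
        exactly one uniformly random frame.
    seed : int
        RNG seed.

    Returns
    -------
    numpy.ndarray of shape (frames, ny, nx), float64.
    """
    if psf_sigma <= 0:
        raise ValueError(f"psf_sigma must be > 0, got {psf_sigma!r}")
    rng = np.random.default_rng(seed)
    emitters = [(float(x), float(y), float(p)) for x, y, p in emitters]
    ny, nx = shape
    for x, y, _ in emitters:
        if not (0.0 <= x <= nx * pixel_size and 0.0 <= y <= ny * pixel_size):
            raise ValueError(f"emitter at ({x}, {y}) nm outside frame bounds")

    if activation is None:
        activation = np.zeros((len(emitters), frames), dtype=bool)
        on_frames = rng.integers(0, frames, size=len(emitters))
        activation[np.arange(len(emitters)), on_frames] = True
    activation = np.asarray(activation, dtype=bool)

    movie = np.full((frames, ny, nx), float(background_level))
    for i, (x, y, p) in enumerate(emitters):
        spot = _integrated_gaussian((ny, nx), x, y, p, psf_sigma, pixel_size)
        for t in np.flatnonzero(activation[i]):
            movie[t] += spot
    if noise:
        movie = rng.poisson(movie).astype(float)
    return movie


# ---------------------------------------------------------------------------
# gold-nanosphere z-scan pair for evanescent-depth calibration


@dataclass
class ZScanDataset:
    """Synthetic raisin-cake calibration dataset.

    ``z_grid``/``epi_profiles`` are the epi-illumination intensity-vs-z
    trajectories of each gold nanosphere; ``tirf_snr`` the TIRF-mode
    signal-to-noise of the same spheres. ``true_z``/``true_height`` record the
    truth (absolute z and height above the tilted coverslip).
    """

    x: np.ndarray
    y: np.ndarray
    z_grid: np.ndarray                 # (n_z,) nm
    epi_profiles: np.ndarray           # (n_spheres, n_z) counts
    tirf_snr: np.ndarray               # (n_spheres,)
    true_z: np.ndarray                 # (n_spheres,) nm
    true_height: np.ndarray            # (n_spheres,) nm above the coverslip plane
    depth_true: float
    tilt: tuple[float, float, float]


def simulate_zscan_pair(
    n_spheres: int = 84,
    tilt: tuple[float, float, float] = (0.0, 0.0, 0.0),
    depth_true: float = 50.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    fov_nm: float = 40000.0,
    z_spread: float = 150.0,
    z_range: tuple[float, float] = (-1500.0, 1500.0),
    z_step: float = 10.0,
    focus_sigma: float = 300.0,
    epi_amplitude: float = 1000.0,
    snr0: float = 100.0,
) -> ZScanDataset:
    """Simulate the paired epi z-scan / TIRF acquisition of gold nanospheres.

    Spheres sit at heights ``|N(0, z_spread)|`` above a tilted coverslip plane
    ``z0 = a·x + b·y + c``. Epi profiles are Gaussian intensity-vs-z curves of
    width ``focus_sigma`` peaked at each sphere's z; TIRF SNR decays as
    ``exp(-height/depth_true)`` with multiplicative Gaussian noise of relative
    sd ``noise_sd`` applied to both channels.
    """
    if depth_true <= 0:
        raise ValueError("depth_true must be > 0")
    rng = np.random.default_rng(seed)
    a, b, c = tilt
    x = rng.uniform(0.0, fov_nm, size=n_spheres)
    y = rng.uniform(0.0, fov_nm, size=n_spheres)
    height = np.abs(rng.normal(0.0, z_spread, size=n_spheres)) if z_spread > 0 else np.zeros(n_spheres)
    z = a * x + b * y + c + height

    z_grid = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    clean = epi_amplitude * np.exp(-0.5 * ((z_grid[None, :] - z[:, None]) / focus_sigma) ** 2)
    epi = clean * (1.0 + noise_sd * rng.normal(size=clean.shape)) if noise_sd > 0 else clean

    tirf = snr0 * np.exp(-height / depth_true)
    if noise_sd > 0:
        tirf = tirf * (1.0 + noise_sd * rng.normal(size=n_spheres))

    return ZScanDataset(x=x, y=y, z_grid=z_grid, epi_profiles=epi, tirf_snr=tirf,
                        true_z=z, true_height=height, depth_true=depth_true, tilt=tilt)


# ---------------------------------------------------------------------------
# diffraction-limited puncta images


def simulate_puncta_image(
    n_puncta: int,
    area_um2=0.2,
    peak_intensity=200.0,
    background: float = 20.0,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.1,
    min_separation_um: float = 1.0,
    noise_sd: float = 2.0,
    seed: int = 0,
):
    """Render an image of disk-shaped puncta on a flat background.

    ``area_um2`` and ``peak_intensity`` may be scalars or per-punctum
    sequences. Puncta are placed by rejection sampling so that centers are at
    least ``min_separation_um`` apart (overlaps, if forced by crowding, are
    flagged in the truth records).

    Returns ``(image, truth)`` where truth is a list of dicts with keys
    ``area_um2``, ``centroid_px``, ``intensity``, ``overlapping``.
    """
    rng = np.random.default_rng(seed)
    areas = np.broadcast_to(np.asarray(area_um2, float), (n_puncta,)).copy()
    peaks = np.broadcast_to(np.asarray(peak_intensity, float), (n_puncta,)).copy()
    ny, nx = shape
    radii_px = np.sqrt(areas / math.pi) / pixel_size_um
    if np.any(radii_px > min(ny, nx) / 2):
        raise ValueError("punctum larger than the image")

    centers: list[tuple[float, float]] = []
    overlapping = []
    min_sep_px = min_separation_um / pixel_size_um
    for i in range(n_puncta):
        placed = False
        r = radii_px[i]
        for _ in range(2000):
            cy = rng.uniform(r + 1, ny - r - 1)
            cx = rng.uniform(r + 1, nx - r - 1)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= min_sep_px ** 2 for py, px in centers):
                placed = True
                break
        centers.append((cy, cx))
        overlapping.append(not placed)

    img = np.full(shape, float(background))
    yy, xx = np.mgrid[0:ny, 0:nx]
    truth = []
    for (cy, cx), r, pk, area, ov in zip(centers, radii_px, peaks, areas, overlapping):
        disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r ** 2
        img[disk] += pk
        truth.append({"area_um2": float(area), "centroid_px": (float(cy), float(cx)),
                      "intensity": float(pk), "overlapping": bool(ov)})
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=shape)
    return img, truth
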