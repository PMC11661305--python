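"""The smND assay: neighbor density, PND distributions, and mixture fitting.

The assay infers the oligomeric-state composition of a membrane protein from
single-molecule localization data without resolving individual complexes.
For every localization the *neighbor density* (ND) is the number of OTHER
localizations inside a circle of fixed diameter (40 nm by default) centered
on it. The normalized histogram of ND over all localizations is the
experimental probability of neighbor density, ``PND_exp``. A forward Monte
Carlo model of the imaging process (the oligomer-field generator in
:mod:`smnd.synthetic`) produces the theoretical counterpart ``PND_theo`` for
any candidate mixture of monomers, dimers and trimers; a residual-square grid
search over the mixture simplex then yields the complex-level fractions
``(f_M, f_D, f_T)`` and the weighted average subunit number
``N̄ = Σ_k k·f_k``.

The companion statistic TNPD (*two nearest pairwise distance*) is, for each
localization, the mean of the distances to its two nearest neighbors; its
pooled distribution is a model-free indicator of subunit separation.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "NDProfile",
    "MixtureFit",
    "compute_nd",
    "pnd_theoretical",
    "fit_mixture",
    "weighted_average_subunits",
    "compute_tnpd",
    "clear_pnd_cache",
]

DEFAULT_DIAMETER_NM = 40.0


@dataclass
class NDProfile:
    """Per-localization neighbor densities and their normalized distribution."""

    nd: np.ndarray                # (n,) integer neighbor counts
    pnd: np.ndarray               # normalized histogram over ND = 0, 1, 2, ...
    radius_nm: float
    n_localizations: int

    def __post_init__(self) -> None:
        total = float(np.sum(self.pnd))
        if self.n_localizations > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"PND must sum to 1, got {total!r}")

    @classmethod
    def from_nd(cls, nd: np.ndarray, radius_nm: float) -> "NDProfile":
        nd = np.asarray(nd, dtype=int)
        counts = np.bincount(nd) if nd.size else np.zeros(1, dtype=int)
        pnd = counts / counts.sum() if nd.size else counts.astype(float)
        return cls(nd=nd, pnd=pnd, radius_nm=float(radius_nm), n_localizations=int(nd.size))


@dataclass
class MixtureFit:
    """Fitted complex-level oligomer fractions.

    ``fractions`` is ``(f_M, f_D, f_T)``; ``nbar`` the weighted average number
    of subunits per complex; ``rss`` the residual sum of squares between
    ``PND_exp`` and the best ``PND_theo``. ``fraction_se`` holds bootstrap
    standard errors when bootstrap resampling was requested.
    """

    fractions: tuple[float, float, float]
    nbar: float
    rss: float
    nuisance: "object"
    fraction_se: tuple[float, float, float] | None = None
    nbar_se: float | None = None

    @property
    def f_monomer(self) -> float:
        return self.fractions[0]

    @property
    def f_dimer(self) -> float:
        return self.fractions[1]

    @property
    def f_trimer(self) -> float:
        return self.fractions[2]


def _positions(localizations) -> np.ndarray:
    """Accept an (n, 2) array or a localization table with x_nm/y_nm columns."""
    if isinstance(localizations, pd.DataFrame):
        return localizations[["x_nm", "y_nm"]].to_numpy(dtype=float)
    pts = np.asarray(localizations, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected (n, 2) positions, got shape {pts.shape}")
    return pts


def compute_nd(localizations, diameter_nm: float = DEFAULT_DIAMETER_NM) -> NDProfile:
    """Neighbor density of every localization within a circle of ``diameter_nm``.

    The circle is defined by its DIAMETER (40 nm default), i.e. neighbors are
    other localizations at distance ≤ diameter/2. The count excludes the focal
    localization itself. Implemented with a k-d tree; equals the all-pairs
    brute force exactly (boundary inclusive).
    """
    pts = _positions(localizations)
    if pts.shape[0] < 1:
        raise ValueError("need at least one localization")
    radius = diameter_nm / 2.0
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius, return_length=True)
    nd = np.asarray(counts, dtype=int) - 1      # drop self
    return NDProfile.from_nd(nd, radius_nm=radius)


def compute_tnpd(localizations) -> np.ndarray:
    """Two-nearest-pairwise-distance statistic, one value per localization.

    For each localization, the mean of the distances to its first and second
    nearest neighbors (in nm). Requires at least 3 points.
    """
    pts = _positions(localizations)
    if pts.shape[0] < 3:
        raise ValueError("TNPD needs at least 3 localizations")
    tree = cKDTree(pts)
    dists, _ = tree.query(pts, k=3)
    return dists[:, 1:3].mean(axis=1)


def weighted_average_subunits(fractions, states=(1, 2, 3)) -> float:
    """Weighted average number of subunits per complex, ``N̄ = Σ_k k·f_k``."""
    f = np.asarray(fractions, dtype=float)
    k = np.asarray(states, dtype=float)
    if f.shape != k.shape:
        raise ValueError("fractions and states must have the same length")
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError(f"fractions must be non-negative and sum to 1, got {fractions!r}")
    return float(np.sum(k * f))


# ---------------------------------------------------------------------------
# theoretical PND by forward Monte Carlo, cached on a fraction grid

_PND_CACHE: dict[tuple, np.ndarray] = {}


def clear_pnd_cache() -> None:
    _PND_CACHE.clear()


def _nuisance_key(config) -> tuple:
    return (
        round(config.field_width, 6), round(config.field_height, 6),
        round(config.complex_density, 9), round(config.subunit_spacing, 6),
        round(config.p_detect, 9), round(config.sigma_loc, 6),
        round(config.blink_mean, 9), round(config.background_density, 9),
        config.n_complexes,
    )


def _point_seed(fractions: tuple, key: tuple, base_seed: int) -> int:
    """Deterministic per-grid-point seed (< 2**31), independent of call order."""
    h = hashlib.blake2b(repr((fractions, key, base_seed)).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)


def pnd_theoretical(fractions, nuisance, n_mc: int = 3,
                    seed: int = 0, diameter_nm: float = DEFAULT_DIAMETER_NM) -> np.ndarray:
    """``PND_theo`` for a candidate mixture, by forward Monte Carlo.

    Simulates ``n_mc`` replicate oligomer fields at the given complex-level
    ``fractions`` with the nuisance parameters (detection probability,
    localization precision, density, spacing, blinking, background) taken from
    ``nuisance`` (an :class:`~smnd.synthetic.OligomerFieldConfig`), pools the
    neighbor counts and returns the normalized PND histogram. Results are
    cached on a grid keyed by the rounded fractions and the nuisance hash, so
    repeated fits under matched conditions reuse the same Monte Carlo draws.

    ``n_mc`` should be large enough that each PND bin's Monte-Carlo standard
    error is below ~0.005; with the default dilute nuisance (≥3000 complexes
    per replicate) 3 replicates suffice.
    """
    from dataclasses import replace

    from .synthetic import simulate_oligomer_field

    f = tuple(round(float(v), 4) for v in fractions)
    if any(v < -1e-9 for v in f) or abs(sum(f) - 1.0) > 1e-3:
        raise ValueError(f"invalid fractions {fractions!r}")
    f = tuple(max(v, 0.0) for v in f)
    s = sum(f)
    f = tuple(v / s for v in f)
    if not all(np.isfinite(v) for v in f):
        raise ValueError(f"non-finite fractions {fractions!r}")

    key = (f, _nuisance_key(nuisance), n_mc, int(seed), round(diameter_nm, 6))
    cached = _PND_CACHE.get(key)
    if cached is not None:
        return cached

    base = _point_seed(f, key[1], int(seed))
    counts = np.zeros(1, dtype=float)
    for rep in range(n_mc):
        cfg = replace(nuisance.with_fractions(f), seed=(base + rep) % (2**31 - 1))
        table, _ = simulate_oligomer_field(cfg)
        if len(table) == 0:
            continue
        prof = compute_nd(table, diameter_nm=diameter_nm)
        c = np.bincount(prof.nd)
        if c.size > counts.size:
            counts = np.pad(counts, (0, c.size - counts.size))
        counts[: c.size] += c
    total = counts.sum()
    pnd = counts / total if total > 0 else counts
    _PND_CACHE[key] = pnd
    return pnd


def _residual(pnd_exp: np.ndarray, pnd_theo: np.ndarray) -> float:
    n = max(pnd_exp.size, pnd_theo.size)
    a = np.pad(pnd_exp, (0, n - pnd_exp.size))
    b = np.pad(pnd_theo, (0, n - pnd_theo.size))
    return float(np.sum((a - b) ** 2))


def _simplex_grid(step: float) -> list[tuple[float, float, float]]:
    """All (f_M, f_D, f_T) on the simplex with the given resolution."""
    n = int(round(1.0 / step))
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i / n, j / n, (n - i - j) / n))
    return pts


def _grid_search(pnd_exp, candidates, nuisance, n_mc, seed, diameter_nm):
    best, best_rss = None, np.inf
    for f in candidates:
        theo = pnd_theoretical(f, nuisance, n_mc=n_mc, seed=seed, diameter_nm=diameter_nm)
        rss = _residual(pnd_exp, theo)
        if rss < best_rss:
            best, best_rss = f, rss
    return best, best_rss


def fit_mixture(pnd_exp: NDProfile, nuisance, states=(1, 2, 3),
                grid_step: float = 0.01, coarse_step: float = 0.05,
                n_mc: int = 3, n_boot: int = 100, seed: int = 0,
                diameter_nm: float | None = None) -> MixtureFit:
    """Fit complex-level oligomer fractions to an experimental PND.

    Minimizes ``Σ_n (PND_exp(n) − PND_theo(n; f))²`` over the mixture simplex
    by a deterministic coarse-to-fine grid search (``coarse_step`` then
    ``grid_step`` in a neighborhood of the coarse optimum). Bootstrap standard
    errors (``n_boot`` resamples of the per-localization ND values, refit over
    the already-evaluated grid) are attached when ``n_boot > 0``.
    """
    if states != (1, 2, 3) and tuple(states) != (1, 2, 3):
        raise NotImplementedError("only monomer/dimer/trimer states are supported")
    if pnd_exp.n_localizations < 1000:
        warnings.warn(
            f"PND built from only {pnd_exp.n_localizations} localizations; "
            "fitted fractions will have wide uncertainty", stacklevel=2)
    if np.count_nonzero(pnd_exp.pnd) < 2:
        raise ValueError("degenerate PND (single occupied bin); mixture fit refused")
    if diameter_nm is None:
        diameter_nm = 2.0 * pnd_exp.radius_nm

    coarse = _simplex_grid(coarse_step)
    best, _ = _grid_search(pnd_exp.pnd, coarse, nuisance, n_mc, seed, diameter_nm)

    fine = [f for f in _simplex_grid(grid_step)
            if abs(f[0] - best[0]) <= coarse_step + 1e-9
            and abs(f[1] - best[1]) <= coarse_step + 1e-9]
    best, best_rss = _grid_search(pnd_exp.pnd, fine + [best], nuisance, n_mc, seed, diameter_nm)

    se = nbar_se = None
    if n_boot > 0:
        evaluated = {k[0] for k in _PND_CACHE
                     if k[1] == _nuisance_key(nuisance) and k[2] == n_mc and k[3] == int(seed)}
        evaluated = sorted(evaluated)
        rng = np.random.default_rng(seed)
        boots = []
        nd = pnd_exp.nd
        for _ in range(n_boot):
            resample = nd[rng.integers(0, nd.size, size=nd.size)]
            prof = NDProfile.from_nd(resample, radius_nm=pnd_exp.radius_nm)
            fb, _ = _grid_search(prof.pnd, evaluated, nuisance, n_mc, seed, diameter_nm)
            boots.append(fb)
        boots = np.asarray(boots)
        se = tuple(np.std(boots, axis=0, ddof=1))
        nbar_se = float(np.std(boots @ np.array([1.0, 2.0, 3.0]), ddof=1))

    return MixtureFit(fractions=best, nbar=weighted_average_subunits(best),
                      rss=best_rss, nuisance=nuisance, fraction_se=se, nbar_se=nbar_se)
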