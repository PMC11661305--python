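"""Trimer-dissociation limiting models bounding the trimer fraction.

A trimeric membrane protein can leave the trimeric state along two limiting
routes, each governed by an equilibrium constant:

* **Model 1** — a trimer sheds one subunit, yielding a monomer and a dimer
  (T → M + D), governed by ``K1``. Per initial trimer with dissociation extent
  ``x``, the complex counts are T = 1−x, M = x, D = x.
* **Model 2** — a trimer falls apart directly into three monomers (T → 3M),
  governed by ``K2``. Counts are T = 1−x, M = 3x, D = 0.

Only the limits ``K1/K2 → ∞`` (model 1) and ``K2/K1 → ∞`` (model 2) are used:
they bracket the trimer fraction inferred by the smND assay, model 1 giving
the lower and model 2 the upper limit. The equilibrium constants themselves
are never estimated. Both models are one-parameter constraints plugged into
the same residual-square machinery as the unconstrained mixture fit, so
residuals are directly comparable.

Subunit conservation (3T + 2D + M = 3 per initial trimer) holds exactly at
every extent, and the implied weighted average subunit number is
``N̄ = 3/(1+x)`` under model 1 and ``3/(1+2x)`` under model 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .neighbor import (
    MixtureFit,
    NDProfile,
    _grid_search,
    fit_mixture,
    weighted_average_subunits,
)

__all__ = ["mixture_from_extent", "fit_dissociation", "trimer_bounds", "DissociationFit"]


def mixture_from_extent(model: int, x: float) -> tuple[float, float, float]:
    """Complex-level fractions ``(f_M, f_D, f_T)`` at dissociation extent ``x``.

    ``x`` is the fraction of initial trimers that have dissociated, in [0, 1].
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"dissociation extent must be in [0, 1], got {x!r}")
    if model == 1:
        total = 1.0 + x                     # complexes per initial trimer
        return (x / total, x / total, (1.0 - x) / total)
    if model == 2:
        total = 1.0 + 2.0 * x
        return (3.0 * x / total, 0.0, (1.0 - x) / total)
    raise ValueError(f"model must be 1 or 2, got {model!r}")


@dataclass
class DissociationFit:
    """Best-fit dissociation extent under one limiting model."""

    model: int
    extent: float
    fractions: tuple[float, float, float]
    trimer_fraction: float
    nbar: float
    rss: float


def fit_dissociation(pnd_exp: NDProfile, model: int, nuisance,
                     grid_step: float = 0.01, coarse_step: float = 0.05,
                     n_mc: int = 3, seed: int = 0) -> DissociationFit:
    """One-dimensional residual-square grid search over the extent ``x``.

    Uses the same Monte-Carlo ``PND_theo`` cache as :func:`smnd.neighbor.fit_mixture`,
    with the mixture constrained to the model's dissociation line.
    """
    if np.count_nonzero(pnd_exp.pnd) < 2:
        raise ValueError("degenerate PND (single occupied bin); dissociation fit refused")
    diameter = 2.0 * pnd_exp.radius_nm

    xs = np.arange(0.0, 1.0 + 1e-12, coarse_step)
    cands = {round(float(x), 6): mixture_from_extent(model, float(x)) for x in xs}
    inv = {v: k for k, v in cands.items()}
    best_f, _ = _grid_search(pnd_exp.pnd, list(cands.values()), nuisance, n_mc, seed, diameter)
    x0 = inv[best_f]

    xs_fine = np.arange(max(0.0, x0 - coarse_step), min(1.0, x0 + coarse_step) + 1e-12, grid_step)
    cands = {round(float(x), 6): mixture_from_extent(model, float(x)) for x in xs_fine}
    cands[x0] = mixture_from_extent(model, x0)
    inv = {v: k for k, v in cands.items()}
    best_f, best_rss = _grid_search(pnd_exp.pnd, list(cands.values()), nuisance, n_mc, seed, diameter)
    x_hat = inv[best_f]

    return DissociationFit(
        model=model, extent=x_hat, fractions=best_f, trimer_fraction=best_f[2],
        nbar=weighted_average_subunits(best_f), rss=best_rss,
    )


def trimer_bounds(pnd_exp: NDProfile, nuisance, unconstrained: MixtureFit | None = None,
                  **fit_kwargs) -> tuple[DissociationFit, DissociationFit]:
    """Lower and upper trimer-fraction limits from the two dissociation models.

    Returns ``(model1_fit, model2_fit)``; model 1's trimer fraction is the
    lower limit and model 2's the upper. If an unconstrained
    :class:`~smnd.neighbor.MixtureFit` is supplied, a loud warning is emitted
    when the expected ordering lower ≤ unconstrained ≤ upper is violated
    beyond the fit's bootstrap uncertainty.
    """
    m1 = fit_dissociation(pnd_exp, 1, nuisance, **fit_kwargs)
    m2 = fit_dissociation(pnd_exp, 2, nuisance, **fit_kwargs)
    if m1.trimer_fraction > m2.trimer_fraction:
        warnings.warn(
            f"model-1 trimer fraction {m1.trimer_fraction:.3f} exceeds model-2 "
            f"{m2.trimer_fraction:.3f}; bounds are not ordered", stacklevel=2)
    if unconstrained is not None:
        tol = 3.0 * (unconstrained.fraction_se[2] if unconstrained.fraction_se else 0.05)
        ft = unconstrained.f_trimer
        if ft < m1.trimer_fraction - tol or ft > m2.trimer_fraction + tol:
            warnings.warn(
                f"unconstrained trimer fraction {ft:.3f} falls outside the model "
                f"bounds [{m1.trimer_fraction:.3f}, {m2.trimer_fraction:.3f}]", stacklevel=2)
    return m1, m2
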