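"""Spectral preprocessing: SG filtering, rubber-band baseline, EMSC, recipes.

Four named recipes cover the two blocks in their non-derivative and
second-derivative forms:

``raman_nonderiv``
    SG(poly 2, window 15, deriv 0) → rubber-band baseline → truncation to
    3200–2400 and 1900–500 cm⁻¹ → EMSC with cubic baseline model.
``raman_deriv``
    SG(2, 15, 2) → EMSC (cubic) → truncation to 1800–900 cm⁻¹.
``ftir_nonderiv``
    EMSC (cubic).
``ftir_deriv``
    SG(2, 15, 2) → EMSC (quadratic) → truncation to 1800–900 cm⁻¹.

EMSC fits each spectrum ``s ≈ a·m + Σ_k c_k u^k`` (``m`` a reference
spectrum, ``u`` the wavenumber axis rescaled to [−1, 1]) and returns
``(s − Σ c_k u^k)/a``, removing additive polynomial baselines and dividing
out the multiplicative scatter gain.  The reference defaults to the mean
spectrum of the set being corrected; for calibration work the reference is
fitted on the training partition only and reused for the test partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import DesignError, RecipeError
from .spectra_io import CHEMISTRY_COLUMNS, META_COLUMNS, SpectraSet

__all__ = [
    "PreprocessRecipe",
    "savgol",
    "rubberband_baseline",
    "truncate_regions",
    "emsc",
    "apply_recipe",
    "fit_apply_recipe",
    "average_technical_replicates",
    "make_recipe",
    "RECIPE_NAMES",
]


# ---------------------------------------------------------------------------
# individual steps
# ---------------------------------------------------------------------------

def _grid_spacing(grid: np.ndarray) -> float:
    d = np.diff(grid)
    if d.size == 0:
        raise RecipeError("grid has a single point")
    if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9):
        raise RecipeError("SG filtering requires a uniform grid")
    return float(abs(d[0]))


def savgol(
    sset: SpectraSet, polynomial: int = 2, window: int = 15, derivative_order: int = 0
) -> SpectraSet:
    """Per-row Savitzky–Golay filtering / differentiation.

    Derivatives are scaled by the grid spacing, so a derivative of order
    ``d`` is in intensity units per (cm⁻¹)^d.  The descending grid is flipped
    to ascending internally so that derivative signs follow the wavenumber
    axis; edges use a polynomial fit on the one-sided window.
    """
    if window % 2 == 0 or window <= polynomial:
        raise RecipeError("window must be odd and larger than the polynomial order")
    if derivative_order > polynomial:
        raise RecipeError("derivative order cannot exceed the polynomial order")
    if window > sset.n_points:
        raise RecipeError(
            f"window ({window}) larger than grid length ({sset.n_points})"
        )
    delta = _grid_spacing(sset.grid)
    asc = sset.matrix[:, ::-1]
    out = savgol_filter(
        asc, window_length=window, polyorder=polynomial,
        deriv=derivative_order, delta=delta, axis=1, mode="interp",
    )
    return sset.with_matrix(out[:, ::-1])


def _lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Piecewise-linear baseline through the lower convex hull of (x, y)."""
    hull = [0]
    for i in range(1, x.size):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (x[a] - x[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (x[i] - x[o])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def rubberband_baseline(sset: SpectraSet) -> SpectraSet:
    """Subtract the lower-convex-hull ("rubber band") baseline per spectrum.

    The corrected spectrum is zero exactly at the hull vertices (including
    both endpoints) and non-negative on every hull chord, which removes
    broad baseline drifts while preserving peak shapes.  Peaks must point
    upward.  Idempotent.
    """
    if sset.n_points < 3:
        raise RecipeError("rubber-band baseline needs at least 3 grid points")
    x = sset.grid[::-1]  # ascending for the hull walk
    out = np.empty_like(sset.matrix)
    for i, row in enumerate(sset.matrix):
        y = row[::-1]
        out[i] = (y - _lower_hull_baseline(x, y))[::-1]
    return sset.with_matrix(out)


def truncate_regions(sset: SpectraSet, regions: Sequence[Sequence[float]]) -> SpectraSet:
    """Restrict the grid to a union of closed [lo, hi] wavenumber intervals."""
    regs = [(min(r), max(r)) for r in regions]
    for i, (lo1, hi1) in enumerate(regs):
        for lo2, hi2 in regs[i + 1:]:
            if lo1 <= hi2 and lo2 <= hi1:
                raise RecipeError(f"regions overlap: [{lo1},{hi1}] and [{lo2},{hi2}]")
    keep = np.zeros(sset.n_points, dtype=bool)
    for lo, hi in regs:
        keep |= (sset.grid >= lo) & (sset.grid <= hi)
    if not keep.any():
        raise RecipeError("truncation produced an empty grid")
    return sset.with_matrix(sset.matrix[:, keep], grid=sset.grid[keep])


def emsc(
    sset: SpectraSet,
    reference: np.ndarray | str = "mean",
    poly_degree: int = 3,
    return_model: bool = False,
):
    """Extended multiplicative signal correction.

    Least-squares fit of each spectrum to ``a·m + Σ_{k=0..d} c_k u^k`` with
    ``m`` the reference spectrum and ``u`` the wavenumber axis rescaled to
    [−1, 1]; the corrected spectrum is ``(s − Σ c_k u^k)/a``.  Output is
    invariant to multiplicative rescaling of the input.

    With ``return_model=True`` also returns a dict holding the reference and
    the per-spectrum coefficients (``a`` and the polynomial terms).
    """
    if poly_degree not in (1, 2, 3):
        raise RecipeError("poly_degree must be 1, 2 or 3")
    if isinstance(reference, str):
        if reference != "mean":
            raise RecipeError(f"unknown reference spec {reference!r}")
        m = sset.matrix.mean(axis=0)
    else:
        m = np.asarray(reference, dtype=float)
        if m.size != sset.n_points:
            raise RecipeError("reference length does not match the grid")
    g = sset.grid
    mid, half = (g.max() + g.min()) / 2.0, (g.max() - g.min()) / 2.0
    u = (g - mid) / half
    design = np.column_stack([m] + [u**k for k in range(poly_degree + 1)])
    coef, _, rank, _ = np.linalg.lstsq(design, sset.matrix.T, rcond=None)
    if rank < design.shape[1]:
        raise RecipeError(
            "EMSC design matrix is singular (reference collinear with the "
            "baseline polynomials); choose a different reference spectrum"
        )
    a = coef[0]
    if np.any(np.abs(a) < 1e-12):
        bad = int(np.argmin(np.abs(a)))
        raise RecipeError(
            f"EMSC multiplicative coefficient vanishes for row {bad}; "
            "choose a different reference spectrum"
        )
    baseline = (design[:, 1:] @ coef[1:]).T
    corrected = (sset.matrix - baseline) / a[:, None]
    out = sset.with_matrix(corrected)
    if return_model:
        model = {"reference": m, "a": a.copy(), "poly_coefs": coef[1:].T.copy(), "degree": poly_degree}
        return out, model
    return out


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

RECIPE_NAMES = ("raman_nonderiv", "raman_deriv", "ftir_nonderiv", "ftir_deriv")


@dataclass
class PreprocessRecipe:
    """Ordered preprocessing step list; steps are applied strictly in order.

    Each step is ``(name, params)`` with name in {"savgol", "rubberband",
    "truncate", "emsc"}.
    """

    name: str
    steps: list[tuple[str, dict]] = field(default_factory=list)
    block: str = ""


def make_recipe(name: str) -> PreprocessRecipe:
    if name == "raman_nonderiv":
        steps = [
            ("savgol", {"polynomial": 2, "window": 15, "derivative_order": 0}),
            ("rubberband", {}),
            ("truncate", {"regions": [[3200, 2400], [1900, 500]]}),
            ("emsc", {"poly_degree": 3}),
        ]
        block = "raman"
    elif name == "raman_deriv":
        steps = [
            ("savgol", {"polynomial": 2, "window": 15, "derivative_order": 2}),
            ("emsc", {"poly_degree": 3}),
            ("truncate", {"regions": [[1800, 900]]}),
        ]
        block = "raman"
    elif name == "ftir_nonderiv":
        steps = [("emsc", {"poly_degree": 3})]
        block = "ftir"
    elif name == "ftir_deriv":
        steps = [
            ("savgol", {"polynomial": 2, "window": 15, "derivative_order": 2}),
            ("emsc", {"poly_degree": 2}),
            ("truncate", {"regions": [[1800, 900]]}),
        ]
        block = "ftir"
    else:
        raise RecipeError(f"unknown recipe {name!r}; expected one of {RECIPE_NAMES}")
    return PreprocessRecipe(name=name, steps=steps, block=block)


def fit_apply_recipe(
    sset: SpectraSet, recipe: PreprocessRecipe
) -> tuple[SpectraSet, np.ndarray | None]:
    """Apply a recipe, fitting the EMSC reference on this set.

    Returns the processed set and the EMSC reference actually used (the mean
    spectrum at the EMSC stage), so the same reference can be reused on a
    held-out partition via :func:`apply_recipe`.
    """
    out, ref = _run_recipe(sset, recipe, emsc_reference=None)
    return out, ref


def apply_recipe(
    sset: SpectraSet,
    recipe: PreprocessRecipe,
    emsc_reference: np.ndarray | None = None,
) -> SpectraSet:
    """Apply a recipe; optionally with a pre-fitted EMSC reference spectrum."""
    out, _ = _run_recipe(sset, recipe, emsc_reference=emsc_reference)
    return out


def _run_recipe(sset, recipe, emsc_reference):
    cur = sset
    used_ref = None
    for step, params in recipe.steps:
        if step == "savgol":
            cur = savgol(cur, **params)
        elif step == "rubberband":
            cur = rubberband_baseline(cur)
        elif step == "truncate":
            cur = truncate_regions(cur, **params)
        elif step == "emsc":
            ref = emsc_reference if emsc_reference is not None else cur.matrix.mean(axis=0)
            used_ref = np.asarray(ref, dtype=float)
            cur = emsc(cur, reference=used_ref, poly_degree=params.get("poly_degree", 3))
        else:
            raise RecipeError(f"unknown recipe step {step!r}")
    return cur, used_ref


# ---------------------------------------------------------------------------
# replicate averaging
# ---------------------------------------------------------------------------

_BIO_KEYS = ["strain", "pi_level", "ca_level", "bio_rep"]


def average_technical_replicates(sset: SpectraSet) -> SpectraSet:
    """Average technical replicates into one row per biological sample.

    Averaging happens after preprocessing so the two blocks gain
    sample-to-sample correspondence (216 spectra → 72 samples).  Metadata of
    a replicate group must agree on everything but the technical-replicate
    index; chemistry is per biological sample already, so the first row of
    each group is kept.
    """
    meta = sset.meta
    groups = meta.groupby(_BIO_KEYS, sort=True).indices
    grid_rows, meta_rows, chem_rows = [], [], []
    for key in sorted(groups, key=lambda k: tuple(map(str, k))):
        idx = np.sort(groups[key])
        sub = meta.iloc[idx]
        for col in ("laser_power_mw", "block"):
            if sub[col].nunique() > 1:
                raise DesignError(
                    f"inconsistent {col!r} within replicate group {key}"
                )
        grid_rows.append(sset.matrix[idx].mean(axis=0))
        row = sub.iloc[0][META_COLUMNS].to_dict()
        row["tech_rep"] = 0
        row["sample_id"] = (
            f"{row['strain']}-Pi{row['pi_level']:g}-Ca{int(row['ca_level'])}"
            f"-B{int(row['bio_rep'])}"
        )
        meta_rows.append(row)
        if sset.chemistry is not None:
            chem_rows.append(sset.chemistry.iloc[idx[0]].to_dict())
    return SpectraSet(
        sset.grid.copy(),
        np.asarray(grid_rows),
        pd.DataFrame(meta_rows),
        pd.DataFrame(chem_rows) if chem_rows else None,
    ).validate()
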