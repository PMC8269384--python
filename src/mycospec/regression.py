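"""PLSR calibration of biomass constituents and band-intensity ratios.

Single-response partial least squares (PLS1) is fitted by the classical
NIPALS weight/score/deflation scheme on mean-centered data; regression
coefficient vectors are kept for every number of latent components A up to
the requested maximum.  Cross-validation inside the calibration partition
leaves one biological sample out at a time (all of its technical replicates
together), and the working number of components AOpt is the smallest A
whose cross-validated RMSE is insignificantly higher than the minimum —
by default within 5% relative, with the one-standard-error rule available.

Calibration/validation splitting follows the study design: models are built
on one biological replicate and validated on the other, with the EMSC
reference refitted on the calibration partition only.

Band-intensity ratios read intensities at the grid points nearest two
wavenumbers on non-derivative data.  Three pairs are preset:
lipids I(1747)/I(1445), polyphosphates I(1163)/I(1155), and carotenoids
I(1523)/I(1445).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, LeakageError
from .preprocess import PreprocessRecipe, apply_recipe, fit_apply_recipe
from .spectra_io import SpectraSet

__all__ = [
    "PLSRModel",
    "fit_plsr",
    "cross_validate_plsr",
    "select_aopt",
    "validate_bioreplicate",
    "band_ratio",
    "RATIO_PRESETS",
]


# ---------------------------------------------------------------------------
# PLS1
# ---------------------------------------------------------------------------


@dataclass
class PLSRModel:
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (A, p)
    x_loadings: np.ndarray  # (A, p)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A)
    coefs: np.ndarray  # (A, p): coefficient vector for each 1..A
    rmse_cal: np.ndarray  # (A,)
    n_components: int
    rmsecv: np.ndarray | None = None
    cv_fold_sse: np.ndarray | None = None  # (folds, A) summed squared errors
    cv_fold_n: np.ndarray | None = None
    aopt: int | None = None

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        a = (n_components or self.aopt or self.n_components) - 1
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.coefs[a] + self.y_mean


def fit_plsr(
    X: SpectraSet | np.ndarray, y: np.ndarray, max_components: int
) -> PLSRModel:
    """Fit single-response PLS by NIPALS with per-A coefficient vectors.

    Extraction stops early if the residual X or y variance is exhausted, so
    ``n_components`` on the returned model may be smaller than requested.
    """
    X = X.matrix if isinstance(X, SpectraSet) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise DesignError(f"y length {y.size} != number of rows {n}")
    if np.std(y) == 0:
        raise DesignError("response has zero variance")
    max_components = min(max_components, n - 1, p)

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean
    X0 = Xr.copy()
    y0 = yr.copy()

    W, P, Q, T = [], [], [], []
    eps = 1e-12 * max(1.0, float((X0**2).sum()))
    for _ in range(max_components):
        w = Xr.T @ yr
        nw = float(np.linalg.norm(w))
        if nw**2 <= eps:
            break
        w /= nw
        t = Xr @ w
        tt = float(t @ t)
        if tt <= eps:
            break
        pvec = Xr.T @ t / tt
        q = float(yr @ t / tt)
        Xr = Xr - np.outer(t, pvec)
        yr = yr - q * t
        W.append(w)
        P.append(pvec)
        Q.append(q)
        T.append(t)
    if not W:
        raise DesignError("no PLS component could be extracted")
    W = np.asarray(W)
    P = np.asarray(P)
    Q = np.asarray(Q)
    T = np.asarray(T).T

    A = W.shape[0]
    coefs = np.empty((A, p))
    rmse_cal = np.empty(A)
    for a in range(1, A + 1):
        Wa, Pa, qa = W[:a].T, P[:a].T, Q[:a]
        beta = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
        coefs[a - 1] = beta
        resid = y0 - X0 @ beta
        rmse_cal[a - 1] = float(np.sqrt(np.mean(resid**2)))
    return PLSRModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coefs=coefs,
        rmse_cal=rmse_cal,
        n_components=A,
    )


def cross_validate_plsr(
    X: SpectraSet | np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    max_components: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-group-out cross-validated RMSE per number of components.

    ``groups`` identifies biological samples: all technical replicates of a
    sample are held out together.  Returns (rmsecv, fold_sse, fold_n) where
    fold_sse is (folds, A) and folds with fewer extracted components reuse
    their deepest model for larger A.
    """
    X = X.matrix if isinstance(X, SpectraSet) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if uniq.size < 2:
        raise DesignError("cross-validation needs at least 2 groups")
    fold_sse = np.zeros((uniq.size, max_components))
    fold_n = np.zeros(uniq.size)
    for fi, g in enumerate(uniq):
        test = groups == g
        train = ~test
        model = fit_plsr(X[train], y[train], max_components)
        for a in range(1, max_components + 1):
            pred = model.predict(X[test], n_components=min(a, model.n_components))
            fold_sse[fi, a - 1] = float(((y[test] - pred) ** 2).sum())
        fold_n[fi] = int(test.sum())
    rmsecv = np.sqrt(fold_sse.sum(axis=0) / fold_n.sum())
    return rmsecv, fold_sse, fold_n


def select_aopt(
    model_or_rmsecv: PLSRModel | np.ndarray,
    tolerance_rule: str = "relative",
    tol: float = 0.05,
) -> int:
    """Smallest A with insignificantly higher RMSECV than the minimum.

    ``relative`` accepts any A with RMSECV ≤ (1 + tol)·min RMSECV; ``one_se``
    uses the one-standard-error rule (needs per-fold errors on the model).
    """
    if isinstance(model_or_rmsecv, PLSRModel):
        model = model_or_rmsecv
        if model.rmsecv is None:
            raise DesignError("no cross-validation results on this model")
        rmsecv = model.rmsecv
        fold_sse, fold_n = model.cv_fold_sse, model.cv_fold_n
    else:
        model = None
        rmsecv = np.asarray(model_or_rmsecv, dtype=float)
        fold_sse = fold_n = None
    amin = int(np.argmin(rmsecv))
    if tolerance_rule == "relative":
        threshold = (1.0 + tol) * rmsecv[amin]
    elif tolerance_rule == "one_se":
        if fold_sse is None:
            raise DesignError("one_se rule requires per-fold CV errors")
        fold_rmse = np.sqrt(fold_sse[:, amin] / fold_n)
        se = float(fold_rmse.std(ddof=1) / np.sqrt(fold_rmse.size))
        threshold = rmsecv[amin] + se
    else:
        raise DesignError(f"unknown tolerance rule {tolerance_rule!r}")
    aopt = int(np.flatnonzero(rmsecv <= threshold)[0]) + 1
    if model is not None:
        model.aopt = aopt
    return aopt


# ---------------------------------------------------------------------------
# bioreplicate validation
# ---------------------------------------------------------------------------


def _r2_rmse(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    ss_res = float(((y_true - y_pred) ** 2).sum())
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return r2, float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def _bio_aggregate(sset: SpectraSet, y: np.ndarray, pred: np.ndarray):
    """Mean prediction (and first response) per biological sample."""
    ids = sset.bio_ids().to_numpy()
    uniq = pd.unique(ids)
    yt = np.empty(uniq.size)
    yp = np.empty(uniq.size)
    for i, u in enumerate(uniq):
        m = ids == u
        yt[i] = y[m][0]
        yp[i] = float(pred[m].mean())
    return uniq, yt, yp


def validate_bioreplicate(
    train: SpectraSet,
    test: SpectraSet,
    response: str,
    max_components: int = 10,
    recipe: PreprocessRecipe | None = None,
    aopt_rule: str = "relative",
    aopt_tol: float = 0.05,
    allow_overlap: bool = False,
) -> dict:
    """Calibrate on one biological replicate, validate on the other.

    ``response`` names a chemistry column present on both sets.  When a
    recipe is given it is fitted on the calibration partition (the EMSC
    reference is its mean at the EMSC stage) and applied unchanged to the
    validation partition.  Models are fitted on replicate-level spectra;
    reported predictions are replicate means per biological sample.
    Overlapping sample ids raise :class:`LeakageError` unless
    ``allow_overlap`` is set (degenerate sanity checks only).
    """
    shared = set(train.meta["sample_id"]) & set(test.meta["sample_id"])
    if shared and not allow_overlap:
        raise LeakageError(
            f"{len(shared)} sample id(s) appear in both partitions, "
            f"e.g. {sorted(shared)[0]!r}"
        )
    for part, name in ((train, "train"), (test, "test")):
        if part.chemistry is None or response not in part.chemistry.columns:
            raise DesignError(f"{name} partition lacks chemistry column {response!r}")

    if recipe is not None:
        train_pp, ref = fit_apply_recipe(train, recipe)
        test_pp = apply_recipe(test, recipe, emsc_reference=ref)
    else:
        train_pp, test_pp = train, test

    y_train = train_pp.chemistry[response].to_numpy(dtype=float)
    y_test = test_pp.chemistry[response].to_numpy(dtype=float)
    model = fit_plsr(train_pp, y_train, max_components)
    groups = train_pp.bio_ids().to_numpy()
    rmsecv, fold_sse, fold_n = cross_validate_plsr(
        train_pp, y_train, groups, model.n_components
    )
    model.rmsecv, model.cv_fold_sse, model.cv_fold_n = rmsecv, fold_sse, fold_n
    aopt = select_aopt(model, tolerance_rule=aopt_rule, tol=aopt_tol)

    pred_cal = model.predict(train_pp.matrix, n_components=aopt)
    pred_val = model.predict(test_pp.matrix, n_components=aopt)
    _, yt_cal, yp_cal = _bio_aggregate(train_pp, y_train, pred_cal)
    ids_val, yt_val, yp_val = _bio_aggregate(test_pp, y_test, pred_val)
    r2_cal, rmse_cal = _r2_rmse(yt_cal, yp_cal)
    r2_val, rmse_val = _r2_rmse(yt_val, yp_val)
    return {
        "response": response,
        "aopt": aopt,
        "aopt_rule": aopt_rule,
        "aopt_tol": aopt_tol,
        "max_components": max_components,
        "n_components_extracted": model.n_components,
        "r2_cal": r2_cal,
        "rmse_cal": rmse_cal,
        "r2_val": r2_val,
        "rmse_val": rmse_val,
        "rmsecv": rmsecv.tolist(),
        "n_train_spectra": train_pp.n_samples,
        "n_test_spectra": test_pp.n_samples,
        "n_train_bio": int(pd.unique(groups).size),
        "n_test_bio": int(ids_val.size),
        "response_range": [float(np.min(y_test)), float(np.max(y_test))],
        "model": model,
    }


# ---------------------------------------------------------------------------
# band ratios
# ---------------------------------------------------------------------------

RATIO_PRESETS = {
    "lipids": (1747.0, 1445.0),
    "polyphosphates": (1163.0, 1155.0),
    "carotenoids": (1523.0, 1445.0),
}


def band_ratio(
    sset: SpectraSet,
    numerator: float | None = None,
    denominator: float | None = None,
    preset: str | None = None,
) -> pd.DataFrame:
    """Per-sample intensity ratio at two wavenumbers (nearest grid points).

    Intended for non-derivative preprocessed data, where band intensities
    are positive.  Scale-invariant per spectrum.
    """
    if preset is not None:
        try:
            numerator, denominator = RATIO_PRESETS[preset]
        except KeyError:
            raise DesignError(
                f"unknown preset {preset!r}; expected {sorted(RATIO_PRESETS)}"
            ) from None
    if numerator is None or denominator is None:
        raise DesignError("give either a preset or both wavenumbers")
    g = sset.grid
    for wn in (numerator, denominator):
        if not (g.min() <= wn <= g.max()):
            raise DesignError(
                f"wavenumber {wn} cm⁻¹ outside grid [{g.min():.1f}, {g.max():.1f}]"
            )
    i_num = int(np.argmin(np.abs(g - numerator)))
    i_den = int(np.argmin(np.abs(g - denominator)))
    inum = sset.matrix[:, i_num]
    iden = sset.matrix[:, i_den]
    tiny = np.finfo(float).eps * np.abs(sset.matrix).max()
    if np.any(np.abs(iden) <= tiny):
        bad = int(np.flatnonzero(np.abs(iden) <= tiny)[0])
        raise DesignError(
            f"denominator intensity at {denominator} cm⁻¹ is ~0 for sample "
            f"{sset.meta['sample_id'].iloc[bad]!r}"
        )
    out = sset.meta[["sample_id", "strain", "pi_level", "ca_level", "bio_rep", "tech_rep"]].copy()
    out["numerator_cm1"] = float(g[i_num])
    out["denominator_cm1"] = float(g[i_den])
    out["intensity_num"] = inum
    out["intensity_den"] = iden
    out["ratio"] = inum / iden
    return out
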