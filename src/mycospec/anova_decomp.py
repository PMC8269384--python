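"""ANOVA-model decomposition of spectral matrices over the cultivation design.

For one strain's replicate-averaged spectra (a balanced 3 Pi × 2 Ca ×
2 bioreplicate layout, 12 rows), the grand-mean-centered data matrix is
written as a sum of effect matrices — calcium, phosphate, their
interaction, biological replicate — plus a residual.  Each main-effect
matrix replaces rows by the mean spectrum of the corresponding factor
level; the interaction effect is the Ca × Pi cell mean minus both main
effects (the classical two-way decomposition, so main effects are not
double-counted).  For the balanced design the effect matrices are mutually
orthogonal and their squared Frobenius norms (sums of squares) are
additive.

Factor importance is reported as each factor's share of the sum over the
four design factors (summing to 100%); the residual share is reported
separately against the total sum of squares.  This is the decomposition
underlying ANOVA-PCA and ASCA; the score-level analyses of those methods
are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError
from .spectra_io import SpectraSet

__all__ = [
    "VariationDecomposition",
    "decompose_by_design",
    "variation_contributions",
    "decompose_all_strains",
]

FACTORS = ("ca", "pi", "ca_pi", "bio_rep")


@dataclass
class VariationDecomposition:
    strain: str
    effects: dict[str, np.ndarray]  # per-factor effect matrices (n × p)
    residual: np.ndarray
    ss: dict[str, float]  # per-factor sums of squares
    ss_residual: float
    ss_total: float


def _level_means(Xc: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(Xc)
    for lv in pd.unique(labels):
        m = labels == lv
        out[m] = Xc[m].mean(axis=0)
    return out


def decompose_by_design(sset: SpectraSet) -> VariationDecomposition:
    """Decompose one strain's matrix into design-factor effects + residual.

    Requires technical replicates already averaged and a complete balanced
    design: exactly one row per (Pi, Ca, bioreplicate) cell.  An unbalanced
    layout raises, because the additivity of the sums of squares would fail
    silently otherwise.
    """
    meta = sset.meta
    strains = meta["strain"].unique()
    if strains.size != 1:
        raise DesignError(f"expected a single strain, found {sorted(strains)}")
    cells = meta.groupby(["pi_level", "ca_level", "bio_rep"]).size()
    if (cells != 1).any() or len(cells) != 12:
        raise DesignError(
            "design is unbalanced: need exactly one row per "
            f"(Pi, Ca, bioreplicate) cell, 12 rows total; got\n{cells}"
        )

    X = sset.matrix
    grand = X.mean(axis=0)
    Xc = X - grand
    ca = meta["ca_level"].to_numpy()
    pi = meta["pi_level"].to_numpy()
    rep = meta["bio_rep"].to_numpy()
    cell = np.char.add(pi.astype(str), np.char.add("|", ca.astype(str)))

    e_ca = _level_means(Xc, ca)
    e_pi = _level_means(Xc, pi)
    e_cell = _level_means(Xc, cell)
    e_int = e_cell - e_ca - e_pi
    e_rep = _level_means(Xc, rep)
    residual = Xc - e_ca - e_pi - e_int - e_rep

    effects = {"ca": e_ca, "pi": e_pi, "ca_pi": e_int, "bio_rep": e_rep}
    ss = {k: float((v**2).sum()) for k, v in effects.items()}
    return VariationDecomposition(
        strain=str(strains[0]),
        effects=effects,
        residual=residual,
        ss=ss,
        ss_residual=float((residual**2).sum()),
        ss_total=float((Xc**2).sum()),
    )


def variation_contributions(decomp: VariationDecomposition) -> dict[str, float]:
    """Factor contributions (%) normalized over the four design factors.

    The residual share is reported separately as a percentage of the total
    sum of squares, alongside (not inside) the 100% normalization.
    """
    denom = sum(decomp.ss[f] for f in FACTORS)
    if denom == 0:
        raise DesignError("all factor sums of squares are zero; contributions undefined")
    out = {f: 100.0 * decomp.ss[f] / denom for f in FACTORS}
    out["residual"] = (
        100.0 * decomp.ss_residual / decomp.ss_total if decomp.ss_total > 0 else 0.0
    )
    return out


def decompose_all_strains(raman: SpectraSet, ftir: SpectraSet) -> pd.DataFrame:
    """Per-strain, per-block contribution table (rows = strain × block).

    Both blocks must be preprocessed and replicate-averaged.  Columns:
    strain, block, ca, pi, ca_pi, bio_rep (normalized to 100 together) and
    residual (share of total SS).
    """
    rows = []
    for block_name, sset in (("raman", raman), ("ftir", ftir)):
        strains = sorted(sset.meta["strain"].unique())
        for strain in strains:
            sub = sset.select((sset.meta["strain"] == strain).to_numpy())
            if len(sub.meta) == 0:
                raise DesignError(f"strain {strain} missing from block {block_name}")
            dec = decompose_by_design(sub)
            contrib = variation_contributions(dec)
            rows.append({"strain": strain, "block": block_name, **contrib})
    return pd.DataFrame(rows)
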