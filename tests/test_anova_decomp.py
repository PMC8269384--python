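"""ANOVA-model variance decomposition over the cultivation design."""

import numpy as np
import pandas as pd
import pytest

from mycospec.anova_decomp import (
    FACTORS,
    decompose_all_strains,
    decompose_by_design,
    variation_contributions,
)
from mycospec.errors import DesignError
from mycospec.spectra_io import META_COLUMNS, SpectraSet


def balanced_meta(strain="Mc1"):
    rows = []
    for pi in (0.5, 1.0, 4.0):
        for ca in (0, 1):
            for rep in (1, 2):
                rows.append(
                    {
                        "sample_id": f"{strain}-Pi{pi:g}-Ca{ca}-B{rep}",
                        "strain": strain,
                        "pi_level": pi,
                        "ca_level": ca,
                        "bio_rep": rep,
                        "tech_rep": 0,
                        "laser_power_mw": 500.0,
                        "block": "raman",
                    }
                )
    return pd.DataFrame(rows)[META_COLUMNS]


def balanced_set(matrix, strain="Mc1"):
    matrix = np.asarray(matrix, dtype=float)
    grid = np.arange(float(matrix.shape[1]), 0.0, -1.0)
    return SpectraSet(grid, matrix, balanced_meta(strain)).validate()


def pi_only_matrix(p=30, scale=1.0, rng=None):
    """Rows equal to their Pi-level mean pattern; no other structure."""
    rng = rng or np.random.default_rng(0)
    meta = balanced_meta()
    patterns = {pi: rng.normal(size=p) * scale for pi in (0.5, 1.0, 4.0)}
    return np.array([patterns[pi] for pi in meta["pi_level"]])


class TestDecompose:
    def test_pi_only_structure(self):
        sset = balanced_set(pi_only_matrix())
        dec = decompose_by_design(sset)
        contrib = variation_contributions(dec)
        assert contrib["pi"] == pytest.approx(100.0, abs=1e-8)
        for f in ("ca", "ca_pi", "bio_rep", "residual"):
            assert contrib[f] == pytest.approx(0.0, abs=1e-8)

    def test_effects_reconstruct_input(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 20))
        dec = decompose_by_design(balanced_set(X))
        recon = sum(dec.effects.values()) + dec.residual + X.mean(axis=0)
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_ss_additivity_balanced(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 25))
        dec = decompose_by_design(balanced_set(X))
        total = sum(dec.ss.values()) + dec.ss_residual
        assert total == pytest.approx(dec.ss_total, rel=1e-6)

    def test_effect_matrices_orthogonal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 25))
        dec = decompose_by_design(balanced_set(X))
        mats = list(dec.effects.values()) + [dec.residual]
        for i in range(len(mats)):
            for j in range(i + 1, len(mats)):
                inner = abs(float((mats[i] * mats[j]).sum()))
                assert inner <= 1e-8 * dec.ss_total

    def test_unbalanced_design_rejected(self):
        sset = balanced_set(np.zeros((12, 5)))
        with pytest.raises(DesignError, match="unbalanced"):
            decompose_by_design(sset.select(np.arange(11)))

    def test_multiple_strains_rejected(self):
        sset = balanced_set(np.random.default_rng(4).normal(size=(12, 5)))
        meta = sset.meta.copy()
        meta.loc[0, "strain"] = "Uv"
        with pytest.raises(DesignError, match="single strain"):
            decompose_by_design(SpectraSet(sset.grid, sset.matrix, meta))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 15))
        sset = balanced_set(X)
        perm = rng.permutation(12)
        c1 = variation_contributions(decompose_by_design(sset))
        c2 = variation_contributions(decompose_by_design(sset.select(perm)))
        for f in c1:
            assert c1[f] == pytest.approx(c2[f], abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(12, 15))
        c1 = variation_contributions(decompose_by_design(balanced_set(X)))
        c2 = variation_contributions(decompose_by_design(balanced_set(13.0 * X)))
        for f in c1:
            assert c1[f] == pytest.approx(c2[f], abs=1e-9)


class TestContributions:
    def test_equal_ss_gives_quarter_each(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 10))
        dec = decompose_by_design(balanced_set(X))
        dec.ss = {f: 2.5 for f in FACTORS}
        contrib = variation_contributions(dec)
        for f in FACTORS:
            assert contrib[f] == pytest.approx(25.0, abs=1e-12)

    def test_sum_to_100(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            dec = decompose_by_design(balanced_set(rng.normal(size=(12, 8))))
            contrib = variation_contributions(dec)
            assert sum(contrib[f] for f in FACTORS) == pytest.approx(100.0, abs=1e-10)

    def test_all_zero_ss_rejected(self):
        dec = decompose_by_design(balanced_set(np.ones((12, 5))))
        with pytest.raises(DesignError, match="undefined"):
            variation_contributions(dec)

    def test_null_noise_shares_follow_degrees_of_freedom(self):
        """Pure noise splits SS across factors in proportion to their df
        (Ca 1, Pi 2, interaction 2, bioreplicate 1 → 1/6, 1/3, 1/3, 1/6)."""
        rng = np.random.default_rng(9)
        reps = 200
        shares = np.empty((reps, 4))
        for r in range(reps):
            dec = decompose_by_design(balanced_set(rng.normal(size=(12, 40))))
            contrib = variation_contributions(dec)
            shares[r] = [contrib[f] for f in FACTORS]
        expected = 100 * np.array([1, 2, 2, 1]) / 6.0
        mean = shares.mean(axis=0)
        sem = shares.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(mean - expected) <= 3 * sem)


class TestAllStrains:
    def test_identical_blocks_identical_tables(self, default_dataset):
        from mycospec.preprocess import average_technical_replicates, fit_apply_recipe, make_recipe

        raman, _, _ = default_dataset
        rd = average_technical_replicates(
            fit_apply_recipe(raman, make_recipe("raman_deriv"))[0]
        )
        tab = decompose_all_strains(rd, rd)
        a = tab[tab.block == "raman"].drop(columns="block").reset_index(drop=True)
        b = tab[tab.block == "ftir"].drop(columns="block").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_single_factor_zero_residual(self):
        rng = np.random.default_rng(10)
        mats = {s: pi_only_matrix(rng=rng) for s in ("Ar", "Mc1")}
        sets = [balanced_set(m, strain=s) for s, m in mats.items()]
        grid = sets[0].grid
        both = SpectraSet(
            grid,
            np.vstack([s.matrix for s in sets]),
            pd.concat([s.meta for s in sets], ignore_index=True),
        )
        tab = decompose_all_strains(both, both)
        assert (tab["residual"].abs() < 1e-8).all()
        assert (tab["pi"] > 99.999).all()

    def test_pi_dominates_default_synthetic_design(self, default_dataset):
        """Phosphate concentration is the dominant driver of spectral
        variation in the synthetic design, for every strain and block."""
        from mycospec.preprocess import average_technical_replicates, fit_apply_recipe, make_recipe

        raman, ftir, _ = default_dataset
        rd = average_technical_replicates(fit_apply_recipe(raman, make_recipe("raman_deriv"))[0])
        fd = average_technical_replicates(fit_apply_recipe(ftir, make_recipe("ftir_deriv"))[0])
        tab = decompose_all_strains(rd, fd)
        top = tab[["ca", "pi", "ca_pi", "bio_rep"]].idxmax(axis=1)
        assert (top == "pi").mean() > 0.5
        uv = tab[tab.strain == "Uv"]
        assert (uv[["ca", "pi", "ca_pi", "bio_rep"]].idxmax(axis=1) == "pi").all()
        # Mc2's calcium-dependent carotenoids live only in the Raman block,
        # so its calcium-linked share is larger there than in FTIR
        mc2 = tab[tab.strain == "Mc2"].set_index("block")
        assert (
            mc2.loc["raman", "ca"] + mc2.loc["raman", "ca_pi"]
            > mc2.loc["ftir", "ca"] + mc2.loc["ftir", "ca_pi"]
        )
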