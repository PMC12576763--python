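"""Eigengenes, Spearman screening, interaction variable."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sugarnet as sn
from sugarnet import eigentrait
from sugarnet.mcl import ModulePartition


def _df(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    )


class TestEigengene:
    def test_identical_profiles_recover_profile(self, rng):
        profile = rng.normal(size=20)
        X = _df(np.tile(profile, (5, 1)))
        e = sn.eigengene(X, list(X.index))
        assert e.variance_explained == pytest.approx(1.0)
        assert np.corrcoef(e.scores, profile)[0, 1] == pytest.approx(1.0)
        assert np.linalg.norm(e.scores) == pytest.approx(1.0)

    def test_anticorrelated_pair_degenerate_case(self, rng):
        x = rng.normal(size=15)
        X = _df(np.vstack([x, -2.0 * x + 3.0]))
        e = sn.eigengene(X, ["g0", "g1"])
        assert e.variance_explained == pytest.approx(1.0)
        # mean standardized profile is zero: fallback orientation fires,
        # deterministically making the first nonzero score positive
        nz = np.flatnonzero(np.abs(e.scores.to_numpy()) > 1e-12)
        assert e.scores.iloc[nz[0]] > 0

    def test_orientation_follows_mean_profile(self, planted_dataset):
        X, truth = planted_dataset
        members = truth.module_members(1)
        e = sn.eigengene(X, members, module=1)
        sub = X.loc[members]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
        assert np.corrcoef(e.scores, z.mean(axis=0))[0, 1] >= 0

    def test_recovers_planted_latent(self, planted_dataset):
        """Low-noise planted module: |Spearman(eigengene, latent)| > 0.95."""
        X, truth = planted_dataset
        e = sn.eigengene(X, truth.module_members(1), module=1)
        rho = stats.spearmanr(e.scores, truth.latents.loc[1, e.scores.index]).statistic
        assert abs(rho) > 0.95

    def test_first_pc_optimality_vs_covariance_oracle(self, rng):
        """Variance explained >= any single gene's share, and matches an
        eigendecomposition of the sample covariance (independent route)."""
        X = _df(rng.normal(size=(8, 25)))
        e = sn.eigengene(X, list(X.index))
        Z = ((X.T - X.mean(axis=1)) / X.std(axis=1, ddof=0)).T.to_numpy()
        C = Z @ Z.T
        eigvals = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert e.variance_explained == pytest.approx(eigvals[0] / eigvals.sum(), abs=1e-10)
        for row in Z:
            proj = Z @ row / np.linalg.norm(row)
            assert e.variance_explained >= (proj**2).sum() / (Z**2).sum() - 1e-10

    def test_errors(self, rng):
        X = _df(rng.normal(size=(4, 10)))
        with pytest.raises(ValueError):
            sn.eigengene(X, ["g0"])
        with pytest.raises(KeyError):
            sn.eigengene(X, ["g0", "missing"])


class TestSpearman:
    def test_equals_pearson_on_ranks(self, rng):
        for _ in range(10):
            x, y = rng.normal(size=30), rng.normal(size=30)
            rho, _ = eigentrait.spearman(x, y)
            expected = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(expected, abs=1e-12)
            assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_small_n_p_value(self):
        # n=4, perfect monotone: 2/4! permutations reach |rho|=1
        rho, p = eigentrait.spearman(np.arange(4.0), np.array([2.0, 3.0, 5.0, 9.0]))
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_monotone_transform_gives_rho_one(self, rng):
        x = rng.normal(size=25)
        rho, _ = eigentrait.spearman(x, np.exp(3 * x))
        assert rho == pytest.approx(1.0)


class TestScreen:
    @staticmethod
    def _make(design, seed=0, pop_rho=0.9):
        from sugarnet import simulate as sim

        specs = [
            sn.PlantedModuleSpec(m, 20, "trait_only", within_module_cor=0.95)
            for m in (1, 2, 3)
        ]
        X, truth = sn.generate_expression(design, specs, n_noise_genes=0, seed=seed)
        L = pd.DataFrame(0.0, index=list(sim.ASSAY_TRAITS), columns=[1, 2, 3])
        L.loc["rubisco", 1] = 1.0
        traits = sn.generate_traits(
            design,
            truth,
            loadings=L,
            trait_noise_sd=sim.attenuation_noise_sd(1.0, pop_rho),
            seed=seed + 100,
        )
        part = ModulePartition(
            assignment={g: m for g, m in truth.gene_to_module.items()},
            members={m: truth.module_members(m) for m in (1, 2, 3)},
        )
        return X, truth, traits, part

    def test_planted_coupling_selected_null_not(self, design48):
        X, truth, traits, part = self._make(design48, seed=3)
        egs = eigentrait.module_eigengenes(X, part)
        res = sn.screen_modules(egs, traits)
        sel = res[res["selected"]]
        assert ((sel["module"] == 1) & (sel["variable"] == "rubisco")).any()
        assert not ((sel["module"] != 1) & (sel["variable"] == "rubisco")).any()

    def test_bonferroni_family_size(self, design48):
        X, truth, traits, part = self._make(design48, seed=4)
        egs = eigentrait.module_eigengenes(X, part)
        res = sn.screen_modules(egs, traits)
        assert len(res) == 3 * 7  # modules x variables
        ok = res.dropna(subset=["p_bonf"])
        assert np.allclose(
            ok["p_bonf"], np.minimum(1.0, ok["pvalue"] * 21), atol=1e-12
        )
        assert (ok["p_bonf"] >= ok["pvalue"] - 1e-12).all()

    def test_constant_variable_flagged_not_selected(self, design48):
        X, truth, traits, part = self._make(design48, seed=5)
        traits["flat"] = 1.0
        egs = eigentrait.module_eigengenes(X, part)
        res = sn.screen_modules(egs, traits)
        flat = res[res["variable"] == "flat"]
        assert flat["constant"].all()
        assert not flat["selected"].any()


class TestInteractionVariable:
    def test_centered_product_values(self, design48):
        v = sn.interaction_variable(design48)
        d = design48.set_index("sample_id")
        same = ((d["genotype"] == "R") & (d["nitrogen"] == 270)) | (
            (d["genotype"] == "NR") & (d["nitrogen"] == 10)
        )
        assert np.allclose(v[same.index[same]], 0.25)
        assert np.allclose(v[same.index[~same]], -0.25)

    def test_orthogonal_to_main_effects_in_balanced_design(self, design48):
        v = sn.interaction_variable(design48).to_numpy()
        g = (design48["genotype"] == "R").astype(float).to_numpy()
        n = (design48["nitrogen"] == 270).astype(float).to_numpy()
        assert abs(np.corrcoef(v, g)[0, 1]) < 1e-12
        assert abs(np.corrcoef(v, n)[0, 1]) < 1e-12

    def test_interaction_module_selected_only_for_interaction(self, design48):
        X, truth = sn.generate_expression(
            design48,
            [sn.PlantedModuleSpec(1, 20, "interaction", effect_size=6.0, within_module_cor=0.95)],
            n_noise_genes=0,
            seed=9,
        )
        part = ModulePartition(
            assignment=dict.fromkeys(truth.genes, 1), members={1: truth.genes}
        )
        egs = eigentrait.module_eigengenes(X, part)
        traits = pd.DataFrame(
            {
                "genotype": (design48["genotype"] == "R").astype(float).to_numpy(),
                "nitrogen": (design48["nitrogen"] == 270).astype(float).to_numpy(),
                "interaction": sn.interaction_variable(design48).to_numpy(),
            },
            index=design48["sample_id"],
        )
        res = sn.screen_modules(egs, traits)
        sel = dict(zip(res["variable"], res["selected"]))
        assert sel["interaction"]
        assert not sel["genotype"] and not sel["nitrogen"]
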