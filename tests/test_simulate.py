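"""Synthetic-data generator: design arithmetic, determinism, calibration."""

import numpy as np
import pandas as pd
import pytest

import sugarnet as sn
from sugarnet import simulate as sim


@pytest.mark.parametrize("n_reps,expected", [(3, 48), (1, 16), (5, 80)])
def test_design_is_full_factorial(n_reps, expected):
    d = sn.generate_design(n_reps)
    assert len(d) == expected
    assert d["sample_id"].is_unique
    cells = d.groupby(["genotype", "nitrogen", "segment"]).size()
    assert len(cells) == 16 and (cells == n_reps).all()


def test_design_rejects_nonpositive_replicates():
    with pytest.raises(ValueError):
        sn.generate_design(0)


def test_expression_deterministic(design48):
    spec = [sn.PlantedModuleSpec(1, 10, "nitrogen")]
    X1, t1 = sn.generate_expression(design48, spec, n_noise_genes=20, seed=5)
    X2, t2 = sn.generate_expression(design48, spec, n_noise_genes=20, seed=5)
    pd.testing.assert_frame_equal(X1, X2)
    assert t1.gene_to_module == t2.gene_to_module
    X3, _ = sn.generate_expression(design48, spec, n_noise_genes=20, seed=6)
    assert not X1.equals(X3)


def test_expression_rejects_degenerate_inputs(design48):
    with pytest.raises(ValueError):
        sn.generate_expression(design48.iloc[:0], [], n_noise_genes=10)
    with pytest.raises(ValueError):
        sn.generate_expression(design48, [], n_noise_genes=0)
    with pytest.raises(ValueError):
        sn.PlantedModuleSpec(1, 1, "noise")
    with pytest.raises(ValueError):
        sn.PlantedModuleSpec(1, 5, "weather")


def test_perfect_module_is_perfectly_correlated(design48):
    spec = [sn.PlantedModuleSpec(1, 8, "nitrogen", within_module_cor=1.0)]
    X, _ = sn.generate_expression(design48, spec, n_noise_genes=0, seed=3)
    R = np.corrcoef(X.to_numpy())
    assert np.allclose(R, 1.0, atol=1e-10)


def test_null_module_has_no_contrast_shift(design48):
    spec = [sn.PlantedModuleSpec(1, 40, "noise", effect_size=0.0)]
    X, _ = sn.generate_expression(design48, spec, n_noise_genes=0, seed=7)
    hi = design48.loc[design48["nitrogen"] == 270, "sample_id"]
    lo = design48.loc[design48["nitrogen"] == 10, "sample_id"]
    diff = X[hi].mean(axis=1) - X[lo].mean(axis=1)
    assert abs(diff.mean()) < 0.1  # no systematic nitrogen shift


def test_within_module_correlation_calibration(design48):
    """Empirical mean within-module |r| lands within +-0.05 of the target,
    averaged over 50 seeds at n=48 (Monte-Carlo calibration contract)."""
    for target in (0.8, 0.95):
        means = []
        for seed in range(50):
            X, _ = sn.generate_expression(
                design48,
                [sn.PlantedModuleSpec(1, 30, "trait_only", within_module_cor=target)],
                n_noise_genes=0,
                seed=seed,
            )
            R = np.corrcoef(X.to_numpy())
            means.append(np.mean(np.abs(R[np.triu_indices(30, 1)])))
        assert abs(np.mean(means) - target) < 0.05


def test_two_modules_separate(design48):
    """Independent-latent modules: high within, low between correlation
    (band frozen from a 50-seed Monte-Carlo run)."""
    within, between = [], []
    for seed in range(5):
        specs = [
            sn.PlantedModuleSpec(1, 50, "trait_only", within_module_cor=0.95),
            sn.PlantedModuleSpec(2, 50, "trait_only", within_module_cor=0.95),
        ]
        X, _ = sn.generate_expression(design48, specs, n_noise_genes=0, seed=seed)
        R = np.corrcoef(X.to_numpy())
        w = np.concatenate(
            [R[:50, :50][np.triu_indices(50, 1)], R[50:, 50:][np.triu_indices(50, 1)]]
        )
        within.append(np.mean(np.abs(w)))
        between.append(np.mean(np.abs(R[:50, 50:])))
    assert 0.90 <= np.mean(within) <= 1.0
    assert np.mean(between) < 0.5


def test_signed_module_has_anticorrelated_members(design48):
    spec = [sn.PlantedModuleSpec(1, 30, "nitrogen", signed=True, within_module_cor=0.95)]
    X, truth = sn.generate_expression(design48, spec, n_noise_genes=0, seed=2)
    signs = np.sign([truth.loadings[g] for g in X.index])
    assert (signs > 0).any() and (signs < 0).any()
    R = np.corrcoef(X.to_numpy())
    assert R.min() < -0.8  # strong negative edges exist


def test_trait_perfectly_tracks_latent(design48):
    X, truth = sn.generate_expression(
        design48, [sn.PlantedModuleSpec(1, 5, "trait_only")], n_noise_genes=0, seed=1
    )
    L = pd.DataFrame(0.0, index=list(sim.ASSAY_TRAITS), columns=[1])
    L.loc["rubisco", 1] = 1.0
    traits = sn.generate_traits(design48, truth, loadings=L, trait_noise_sd=1e-12, seed=4)
    from scipy.stats import spearmanr

    rho = spearmanr(traits["rubisco"], truth.latents.loc[1, traits.index]).statistic
    assert rho == pytest.approx(1.0)


def test_trait_attenuation_closed_form(design48):
    """cor = lambda / sqrt(lambda^2 + sigma^2): choosing sigma for a 0.8
    population correlation recovers ~0.8 empirically."""
    sigma = sim.attenuation_noise_sd(1.0, 0.8)
    assert sigma == pytest.approx(0.75)
    cors = []
    for seed in range(30):
        X, truth = sn.generate_expression(
            design48, [sn.PlantedModuleSpec(1, 5, "trait_only")], n_noise_genes=0, seed=seed
        )
        L = pd.DataFrame(0.0, index=list(sim.ASSAY_TRAITS), columns=[1])
        L.loc["rubisco", 1] = 1.0
        tr = sn.generate_traits(design48, truth, loadings=L, trait_noise_sd=sigma, seed=seed + 500)
        cors.append(np.corrcoef(tr["rubisco"], truth.latents.loc[1, tr.index])[0, 1])
    assert abs(np.mean(cors) - 0.8) < 0.05


def test_traits_loadings_mismatch_raises(design48):
    X, truth = sn.generate_expression(
        design48, [sn.PlantedModuleSpec(1, 5, "trait_only")], n_noise_genes=0, seed=1
    )
    bad = pd.DataFrame(0.0, index=list(sim.ASSAY_TRAITS), columns=[1, 99])
    with pytest.raises(ValueError):
        sn.generate_traits(design48, truth, loadings=bad)


def test_annotations_planted_coverage_and_background(planted_dataset):
    X, truth = planted_dataset
    ann = sn.generate_annotations(
        truth, n_terms=40, planted={1: "GO:PLANT"}, background_rate=0.05, seed=9
    )
    assert not ann.duplicated(["gene_id", "term_id"]).any()
    members = set(truth.module_members(1))
    covered = set(ann.loc[ann["term_id"] == "GO:PLANT", "gene_id"]) & members
    assert len(covered) / len(members) >= 0.8
    background = ann[ann["term_id"] != "GO:PLANT"]
    rate = len(background) / (40 * len(truth.genes))
    assert abs(rate - 0.05) < 0.02


def test_annotations_unknown_module_raises(planted_dataset):
    _, truth = planted_dataset
    with pytest.raises(ValueError):
        sn.generate_annotations(truth, planted={42: "GO:X"})


def test_missing_values_injected_on_request(design48):
    X, _ = sn.generate_expression(
        design48,
        [sn.PlantedModuleSpec(1, 50, "trait_only")],
        n_noise_genes=50,
        seed=8,
        missing_rate=0.2,
    )
    frac = X.isna().to_numpy().mean()
    assert 0.15 < frac < 0.25


def test_tap_family_planting():
    genes = [f"g{i}" for i in range(200)]
    tab = sim.plant_tap_families(genes, {"MYB": 0.574, "bHLH": 0.2, "WRKY": 0.226}, seed=1)
    prop = (tab["term_id"] == "MYB").mean()
    assert abs(prop - 0.574) < 0.1
    with pytest.raises(ValueError):
        sim.plant_tap_families(genes, {"MYB": 0.5, "bHLH": 0.2}, seed=1)
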