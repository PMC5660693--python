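"""Synthetic study generator: design structure, determinism, factor model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from moanet.enrichment import read_gmt
from moanet.moa_stats import fit_moa_anova
from moanet.preprocess import mean_center_by_batch, to_log_ratios
from moanet.simulate import (
    ConfigurationError,
    ModuleSpec,
    StudyDesign,
    generate_class_pair,
    generate_null_study,
    generate_probe_level,
    generate_study,
    write_module_gmt,
)


class TestStudyDesign:
    def test_default_design_has_45_treated_samples(self, design):
        annot = design.annotation()
        treated = annot[annot["role"] == "treated"]
        assert len(treated) == 45
        assert treated["chemical"].nunique() == 15
        assert treated["moa"].nunique() == 5
        # triplicate per chemical
        assert set(treated.groupby("chemical").size()) == {3}

    def test_classes_cover_nine_rm_and_six_nrm_chemicals(self, design):
        annot = design.annotation()
        treated = annot[annot["role"] == "treated"]
        per_class = treated.drop_duplicates("chemical")["class"].value_counts()
        assert per_class["RM"] == 9 and per_class["NRM"] == 6

    def test_every_treated_sample_has_matched_controls(self, design):
        from moanet.preprocess import control_group_key

        annot = design.annotation()
        ctl_groups = {
            control_group_key(r.vehicle, r.route)
            for r in annot[annot["role"] == "control"].itertuples()
        }
        for r in annot[annot["role"] == "treated"].itertuples():
            assert control_group_key(r.vehicle, r.route) in ctl_groups
        assert len(ctl_groups) == 3

    def test_chemical_maps_to_single_moa(self):
        with pytest.raises(ConfigurationError):
            StudyDesign(chemicals={
                "AhR": ["X", "Y", "Z"], "CAR/PXR": ["X", "B", "C"],
                "PPARA": ["D", "E", "F"], "Cytotox": ["G", "H", "I"],
                "DNA_damage": ["J", "K", "L"],
            })


class TestGenerateStudy:
    def test_same_seed_bitwise_identical(self, design):
        mods = [ModuleSpec("M1", 40)]
        a = generate_study(design, mods, n_genes=300, seed=11)
        b = generate_study(design, mods, n_genes=300, seed=11)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert a[2].module_of_gene == b[2].module_of_gene

    def test_module_overflow_rejected(self, design):
        with pytest.raises(ConfigurationError):
            generate_study(design, [ModuleSpec("M1", 400)], n_genes=300, seed=0)

    def test_controls_carry_no_module_or_moa_signal(self, design):
        expr, annot, truth = generate_study(
            design, [ModuleSpec("M1", 50, eigengene_loading_range=(0.9, 0.9))],
            n_genes=200, seed=3, noise_sd=0.1,
        )
        ctl = expr.loc[:, (annot["role"] == "control").to_numpy()]
        genes = truth.module_genes("M1")
        # control-side correlations of module genes are pure noise
        C = np.corrcoef(ctl.loc[genes].to_numpy())
        iu = np.triu_indices(len(genes), 1)
        assert abs(C[iu].mean()) < 0.15

    def test_noise_free_unit_loading_gives_perfect_correlation(self, design):
        # loading 1 means the gene IS the eigengene: r = 1 among treated
        expr, annot, truth = generate_study(
            design, [ModuleSpec("M1", 10, eigengene_loading_range=(1.0, 1.0))],
            n_genes=50, seed=5, noise_sd=1.0, batch_sd=0.0,
        )
        genes = truth.module_genes("M1")
        treated = expr.loc[genes, (annot["role"] == "treated").to_numpy()]
        C = np.corrcoef(treated.to_numpy())
        assert np.allclose(C, 1.0, atol=1e-10)


class TestFactorModel:
    def test_within_module_correlation_matches_closed_form(self):
        # r_ij = l_i l_j / sqrt((l_i^2+(1-l_i^2)s^2)(l_j^2+(1-l_j^2)s^2))
        noise_sd = 1.0
        mods = [ModuleSpec("M1", 60, eigengene_loading_range=(0.4, 0.9))]
        diffs = []
        for seed in range(8):
            ref, _, truth = generate_class_pair(
                mods, n_genes=80, n_samples_per_class=45, noise_sd=noise_sd, seed=seed
            )
            genes = truth.module_genes("M1")
            lam = np.array([truth.loadings[g] for g in genes])
            denom = np.sqrt(lam**2 + (1 - lam**2) * noise_sd**2)
            expected = np.outer(lam / denom, lam / denom)
            C = np.corrcoef(ref.loc[genes].to_numpy())
            iu = np.triu_indices(len(genes), 1)
            diffs.append((C - expected)[iu].mean())
        assert abs(np.mean(diffs)) < 0.05

    def test_non_preserved_module_is_decorrelated_in_test_class(self):
        mods = [ModuleSpec("M1", 50, eigengene_loading_range=(0.8, 0.8), preserved_in_test=False)]
        ref, test, truth = generate_class_pair(mods, 100, 45, 1.0, seed=2)
        genes = truth.module_genes("M1")
        iu = np.triu_indices(len(genes), 1)
        r_ref = np.corrcoef(ref.loc[genes].to_numpy())[iu].mean()
        r_test = np.corrcoef(test.loc[genes].to_numpy())[iu].mean()
        assert r_ref > 0.5
        assert abs(r_test) < 0.1
        # variance is matched between classes
        assert test.loc[genes].to_numpy().var() == pytest.approx(
            ref.loc[genes].to_numpy().var(), rel=0.15
        )


class TestProbeLevel:
    def test_zero_probe_noise_gives_perfectly_correlated_probes(self, design, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 12)),
                            index=[f"ps{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(12)])
        probes, pmap, rogue = generate_probe_level(expr, probes_per_set=3,
                                                   probe_noise_sd=0.0, seed=1)
        assert not rogue
        for set_id in expr.index:
            block = probes.loc[pmap[pmap == set_id].index].to_numpy()
            C = np.corrcoef(block)
            assert np.allclose(C, 1.0, atol=1e-10)

    def test_rogue_sets_score_near_reciprocal_probe_count(self, rng):
        # all-rogue probes are i.i.d. noise: PC1 variance fraction should
        # match the Monte-Carlo eigenvalue oracle for white-noise covariance
        P, n, n_sets = 4, 45, 300
        expr = pd.DataFrame(rng.normal(size=(n_sets, n)),
                            index=[f"ps{i}" for i in range(n_sets)],
                            columns=[f"s{i}" for i in range(n)])
        probes, pmap, rogue = generate_probe_level(
            expr, probes_per_set=P, probe_noise_sd=2.0, rogue_probe_fraction=1.0, seed=7
        )
        assert len(rogue) == n_sets
        from moanet.preprocess import pvac_filter

        scores, _ = pvac_filter(probes, pmap, threshold=0.5)
        # oracle: eigenvalues of Wishart-type covariance of P iid probes
        oracle = []
        org = np.random.default_rng(0)
        for _ in range(1000):
            X = org.normal(size=(P, n))
            Xc = X - X.mean(axis=1, keepdims=True)
            ev = np.linalg.eigvalsh(Xc @ Xc.T)
            oracle.append(ev[-1] / ev.sum())
        assert scores["score"].mean() == pytest.approx(np.mean(oracle), abs=0.02)
        assert scores["kept"].mean() < 0.05  # nearly all dropped at 0.5

    def test_probes_per_set_must_be_at_least_two(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 5)))
        with pytest.raises(ConfigurationError):
            generate_probe_level(expr, probes_per_set=1, seed=0)


class TestNullStudy:
    def test_anova_pvalues_uniform_on_null(self, design):
        passed = 0
        n_seeds = 30
        for seed in range(n_seeds):
            expr, annot = generate_null_study(design, n_genes=800, seed=seed)
            ratios = to_log_ratios(mean_center_by_batch(expr, annot["route"]), annot)
            res = fit_moa_anova(ratios, annot)
            ks = stats.kstest(res.table["p"], "uniform")
            passed += ks.pvalue > 0.01
        assert passed >= 0.9 * n_seeds

    def test_bh_gate_makes_no_discoveries_on_null(self, design):
        # binomial oracle: per-gene P(q < 0.01) under the null is at most
        # about 0.01/m-level; across 15 seeds x 800 genes expect ~0 calls
        total = 0
        for seed in range(15):
            expr, annot = generate_null_study(design, n_genes=800, seed=100 + seed)
            ratios = to_log_ratios(mean_center_by_batch(expr, annot["route"]), annot)
            res = fit_moa_anova(ratios, annot)
            total += int(res.table["significant"].sum())
        assert total <= 2

    def test_null_study_deterministic(self, design):
        a = generate_null_study(design, n_genes=50, seed=9)[0]
        b = generate_null_study(design, n_genes=50, seed=9)[0]
        pd.testing.assert_frame_equal(a, b)


def test_module_gmt_roundtrip(tmp_path, design):
    mods = [ModuleSpec("M1", 20), ModuleSpec("M2", 15)]
    _, _, truth = generate_study(design, mods, n_genes=100, seed=4)
    path = tmp_path / "modules.gmt"
    write_module_gmt(truth, path)
    coll = read_gmt(path)
    assert set(coll) == {"M1", "M2"}
    assert sorted(coll.members("M1")) == sorted(truth.module_genes("M1"))


def test_power_for_large_planted_effects(design):
    """Effects spread over 4x noise sd are essentially always gated in."""
    missed = total = 0
    for seed in range(5):
        expr, annot, truth = generate_study(
            design, [], n_genes=500, seed=seed, moa_affected_fraction=0.1,
            moa_effect_sd=3.0,
        )
        ratios = to_log_ratios(mean_center_by_batch(expr, annot["route"]), annot)
        res = fit_moa_anova(ratios, annot)
        sig = set(res.significant_genes())
        for g, eff in truth.moa_effects.items():
            vals = np.array(list(eff.values()))
            if vals.max() - vals.min() >= 4.0:
                total += 1
                missed += g not in sig
    assert total > 50
    assert missed / total <= 0.01
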