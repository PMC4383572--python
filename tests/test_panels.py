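"""ANOVA/BH/PCA primitives and panel derivation + clustering validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import estroscreen as es
from estroscreen.errors import DesignError, EmptyPanelError
from estroscreen.panels import default_panel_spec_2h, default_panel_spec_24h
from tests._oracles import bh_stepup, correlation_eig_pca
from tests.conftest import make_study

finite = st.floats(-100, 100, allow_nan=False)


class TestOnewayAnova:
    def test_hand_oracle(self):
        # SS_between 1.5 on 1 df; MS_within 1.0 on 4 df
        F, p = es.oneway_anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(1.5)
        assert p == pytest.approx(float(stats.f.sf(1.5, 1, 4)))

    def test_equal_means_give_zero_f(self):
        F, _ = es.oneway_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(0.0)

    def test_fully_degenerate_flagged(self):
        assert es.oneway_anova([2, 2, 2, 2], ["a", "a", "b", "b"]) == (0.0, 1.0)

    def test_zero_within_variance_with_signal(self):
        F, p = es.oneway_anova([0, 0, 1, 1], ["a", "a", "b", "b"])
        assert F == np.inf and p == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(DesignError):
            es.oneway_anova([1, 2, 3], ["a"] * 3)

    @given(data=st.lists(st.tuples(finite, st.booleans()), min_size=6, max_size=24))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_two_groups_equal_pooled_t_squared(self, data):
        a = [v for v, g in data if g]
        b = [v for v, g in data if not g]
        if len(a) < 2 or len(b) < 2 or (len(set(a)) == 1 and len(set(b)) == 1):
            return
        F, _ = es.oneway_anova(a + b, ["a"] * len(a) + ["b"] * len(b))
        t, _ = stats.ttest_ind(a, b)
        if not np.isfinite(F):
            return
        assert F == pytest.approx(t ** 2, abs=1e-10, rel=1e-10)

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            groups = [rng.normal(rng.normal(), 1, rng.integers(3, 8)) for _ in range(3)]
            F, p = es.oneway_anova(np.concatenate(groups),
                                   np.repeat(["a", "b", "c"], [len(g) for g in groups]))
            ref = stats.f_oneway(*groups)
            assert F == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestBhAdjust:
    def test_step_up_hand_oracle(self):
        out = es.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert es.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(es.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_never_decreases_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        assert (es.bh_adjust(p) >= p - 1e-15).all()

    def test_matches_hand_coded_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(es.bh_adjust(p), bh_stepup(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            es.bh_adjust([0.5, 1.5])


class TestPrincipalComponents:
    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        _, loadings, _ = es.principal_components(rng.normal(size=(10, 6)))
        assert np.allclose(loadings.T @ loadings, np.eye(loadings.shape[1]), atol=1e-10)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        _, _, vf = es.principal_components(rng.normal(size=(9, 5)))
        assert (vf >= 0).all() and vf.sum() == pytest.approx(1.0)

    def test_rank_one_data_concentrates_variance(self):
        base = np.array([1.0, 2.0, 0.5, -1.0, 3.0, 0.0])
        X = np.outer([1, -2, 0.5, 3], base) + np.arange(4)[:, None]
        _, _, vf = es.principal_components(X)
        assert vf[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 6))
        _, loadings, vf = es.principal_components(X)
        w, V = correlation_eig_pca(X)
        k = min(loadings.shape[1], 5)
        for j in range(k):
            if w[j] < 1e-10:
                continue
            dot = abs(np.dot(loadings[:, j], V[:, j]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(vf[:k], (w / w.sum())[:k], atol=1e-8)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            es.principal_components(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))


def _contrast_study(seed, n_probes=5000, n_planted=150, n_per_group=20,
                    effect=0.5, noise=0.25):
    """Two-group design with planted contrast-separating probes.

    Twenty samples per group: with thousands of null probes a handful of
    them are significant *and* low-variance by chance, and on standardized
    (correlation-scale) loadings such nulls rank with weak planted probes
    unless the group size pins down per-probe variances well.
    """
    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    values = rng.normal(0, noise, size=(n_probes, n_samples))
    signs = rng.choice([-1.0, 1.0], size=n_planted)
    values[:n_planted, n_per_group:] += np.outer(signs * effect, np.ones(n_per_group))
    ids = [f"planted_{i:03d}" for i in range(n_planted)] + \
          [f"null_{i:04d}" for i in range(n_probes - n_planted)]
    study = make_study(
        values,
        treatments=["vehicle"] * n_per_group + ["testcmp"] * n_per_group,
        times=[2] * n_samples,
        roles=["vehicle"] * n_per_group + ["reference"] * n_per_group,
        class_labels=["vehicle"] * n_per_group + ["short_acting"] * n_per_group,
        probe_ids=ids,
    )
    spec = es.PanelSpec(time_hr=2, contrast_a=("vehicle",), contrast_b=("short_acting",))
    return study, spec


class TestDerivePanel:
    def test_selects_only_planted_contrast_probes(self):
        study, spec = _contrast_study(seed=0)
        panel = es.derive_panel(study, spec)
        assert len(panel.probes) == 50
        assert all(p.startswith("planted_") for p in panel.probes)

    def test_small_candidate_pool_taken_entirely(self):
        study, spec = _contrast_study(seed=1, n_probes=3, n_planted=3)
        spec = es.PanelSpec(time_hr=2, contrast_a=("vehicle",),
                            contrast_b=("short_acting",), k=3)
        panel = es.derive_panel(study, spec)
        assert sorted(panel.probes) == ["planted_000", "planted_001", "planted_002"]

    def test_deterministic_including_order(self):
        study, spec = _contrast_study(seed=2)
        a = es.derive_panel(study, spec)
        b = es.derive_panel(study, spec)
        assert a.probes == b.probes
        pd.testing.assert_series_equal(a.weights, b.weights)

    def test_probe_order_permutation_equivariant(self):
        study, spec = _contrast_study(seed=3, n_probes=400, n_planted=60)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(study.probe_ids))
        shuffled = es.ExpressionStudy(values=study.values.iloc[perm],
                                      metadata=study.metadata).validate()
        a = es.derive_panel(study, spec)
        b = es.derive_panel(shuffled, spec)
        assert set(a.probes) == set(b.probes)

    def test_empty_candidates_name_the_stage(self):
        # probes constant within every group: every ANOVA is degenerate
        # (F = 0, p = 1) and the filter empties the candidate set
        values = np.tile(np.arange(20, dtype=float)[:, None], (1, 8))
        study = make_study(
            values,
            treatments=["vehicle"] * 4 + ["t"] * 4,
            times=[2] * 8,
            roles=["vehicle"] * 4 + ["reference"] * 4,
            class_labels=["vehicle"] * 4 + ["short_acting"] * 4,
        )
        spec = es.PanelSpec(time_hr=2, contrast_a=("vehicle",),
                            contrast_b=("short_acting",))
        with pytest.raises(EmptyPanelError) as err:
            es.derive_panel(study, spec)
        assert err.value.stage == "anova"

    def test_axis_is_unit_norm(self, reference_build):
        _, art = reference_build
        assert np.linalg.norm(art.panel_24h.axis) == pytest.approx(1.0)
        assert set(art.panel_24h.directions.unique()) <= {-1, 1}

    def test_default_panels_come_from_admissible_archetypes(self, reference_build):
        _, art = reference_build
        ok2 = tuple(default_panel_spec_2h().candidate_patterns)
        ok24 = tuple(default_panel_spec_24h().candidate_patterns)
        assert all(p.rsplit("_", 1)[0] in ok2 for p in art.panel_2h.probes)
        assert all(p.rsplit("_", 1)[0] in ok24 for p in art.panel_24h.probes)


class TestValidatePanelClustering:
    def test_default_reference_panels_separate_perfectly(self, reference_build):
        _, art = reference_build
        assert art.ari_2h == 1.0
        assert art.ari_24h == 1.0

    def test_permuted_labels_score_zero_in_expectation(self, reference_build):
        # ARI is chance-corrected: against random relabelings its mean is ~0
        # (individual values are coarsely quantized at 8 contrast samples)
        cfg, art = reference_build
        study = art.corrected
        rng = np.random.default_rng(0)
        aris = []
        for _ in range(200):
            meta = study.metadata.copy()
            sel = (meta["time_hr"] == 24) & meta["class_label"].isin(
                ["short_acting", "long_acting"])
            meta.loc[sel, "class_label"] = rng.permutation(
                meta.loc[sel, "class_label"].to_numpy())
            shuffled = es.ExpressionStudy(values=study.values, metadata=meta)
            try:
                aris.append(es.validate_panel_clustering(shuffled, art.panel_24h))
            except DesignError:
                continue
        assert len(aris) > 100
        assert abs(np.mean(aris)) < 0.1

    def test_identical_samples_in_different_classes_cap_agreement(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, size=(30, 1))
        values = np.concatenate([
            base + rng.normal(0, 0.05, size=(30, 3)),  # class A-ish
            base + 2 + rng.normal(0, 0.05, size=(30, 3)),  # class B-ish
        ], axis=1)
        values[:, 2] = values[:, 3]  # one A sample identical to a B sample
        study = make_study(
            values,
            treatments=["vehicle"] * 3 + ["t"] * 3,
            times=[24] * 6,
            roles=["vehicle"] * 3 + ["reference"] * 3,
            class_labels=["short_acting"] * 3 + ["long_acting"] * 3,
        )
        panel = es.BiomarkerPanel(
            spec=es.PanelSpec(time_hr=24, contrast_a=("short_acting",),
                              contrast_b=("long_acting",)),
            probes=list(study.probe_ids),
            directions=pd.Series(1, index=study.probe_ids),
            weights=pd.Series(1.0, index=study.probe_ids),
            centroid_a=pd.Series(0.0, index=study.probe_ids),
            centroid_b=pd.Series(1.0, index=study.probe_ids),
        )
        assert es.validate_panel_clustering(study, panel) < 1.0

    def test_single_class_rejected(self, reference_build):
        _, art = reference_build
        study = art.corrected
        meta = study.metadata.copy()
        meta["class_label"] = "short_acting"
        broken = es.ExpressionStudy(values=study.values, metadata=meta)
        with pytest.raises(DesignError):
            es.validate_panel_clustering(broken, art.panel_24h)


class TestPanelPersistence:
    def test_json_round_trip_preserves_scores(self, reference_build, tmp_path):
        _, art = reference_build
        es.save_panel(art.panel_24h, tmp_path / "p.json")
        back = es.load_panel(tmp_path / "p.json")
        assert back.probes == art.panel_24h.probes
        x = art.panel_24h.centroid_b
        assert es.longevity_score(x, back) == pytest.approx(
            es.longevity_score(x, art.panel_24h))
        assert es.longevity_score(x, back) == pytest.approx(1.0)
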