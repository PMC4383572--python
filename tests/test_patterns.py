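"""Pattern extraction: filters, correlation seeding, labeling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import estroscreen as es
from estroscreen.errors import DesignError, UndefinedCorrelationError
from estroscreen.patterns import UNASSIGNED, UNCLASSIFIED
from tests._oracles import brute_force_patterns, plain_corr
from tests.conftest import make_study

finite = st.floats(-50, 50, allow_nan=False)


class TestProfileSnr:
    def test_flat_profile_is_zero(self):
        assert es.profile_snr([3.0] * 6, ["a", "a", "a", "b", "b", "b"]) == 0.0

    def test_noiseless_signal_hits_cap(self):
        assert es.profile_snr([0, 0, 1, 1], ["a", "a", "b", "b"], snr_cap=1e6) == 1e6

    def test_hand_oracle(self):
        # range of means 3; pooled variance (2 + 2) / 4 = 1
        snr = es.profile_snr([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        assert snr == pytest.approx(3.0)

    def test_single_group_rejected(self):
        with pytest.raises(DesignError):
            es.profile_snr([1, 2, 3], ["a", "a", "a"])

    @given(shift=finite, scale=st.floats(0.01, 100),
           vals=st.lists(finite, min_size=6, max_size=6))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_shift_and_scale_invariance(self, shift, scale, vals):
        labels = ["a", "a", "a", "b", "b", "b"]
        base = es.profile_snr(vals, labels)
        moved = es.profile_snr([v * scale + shift for v in vals], labels)
        assert moved == pytest.approx(base, rel=1e-6, abs=1e-9)


class TestProfileMagnitude:
    def test_flat_profile(self):
        assert es.profile_magnitude([1.0] * 4, ["v", "v", "t", "t"], "v") == 0.0

    def test_absolute_value_of_down_response(self):
        mag = es.profile_magnitude([0, 0, -2, -2, 0, 0],
                                   ["v", "v", "a", "a", "b", "b"], "v")
        assert mag == pytest.approx(2.0)

    def test_takes_maximum_over_groups(self):
        mag = es.profile_magnitude([0, 0, 1, 1, 0.5, 0.5],
                                   ["v", "v", "a", "a", "b", "b"], "v")
        assert mag == pytest.approx(1.0)

    def test_missing_vehicle_rejected(self):
        with pytest.raises(DesignError):
            es.profile_magnitude([1, 2], ["a", "b"], "v")


class TestPearsonR:
    @pytest.mark.parametrize("x,y,expected", [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 3), (1, 3, 2), 0.5),
    ])
    def test_known_values(self, x, y, expected):
        assert es.pearson_r(x, y) == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            es.pearson_r([1, 1, 1], [1, 2, 3])

    @given(vals=st.lists(st.tuples(finite, finite), min_size=5, max_size=20))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_plain_formula(self, vals):
        x = [v[0] for v in vals]
        y = [v[1] for v in vals]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        assert es.pearson_r(x, y) == pytest.approx(plain_corr(x, y), abs=1e-9)


def _planted_study(n_null=100, per_group=50, noise=0.0, seed=0):
    """Three orthogonal planted groups + null probes over a 2-group design."""
    rng = np.random.default_rng(seed)
    n_samples = 12
    treatments = ["vehicle"] * 3 + ["a"] * 3 + ["b"] * 3 + ["c"] * 3
    times = [2] * 12
    roles = ["vehicle"] * 3 + ["reference"] * 9
    shapes = {
        "g1": np.repeat([0, 2, 0, 0], 3),
        "g2": np.repeat([0, 0, 2, 0], 3),
        "g3": np.repeat([0, 0, 0, 2], 3),
    }
    rows, ids = [], []
    for g, shape in shapes.items():
        for i in range(per_group):
            rows.append(shape + rng.normal(0, noise, n_samples))
            ids.append(f"{g}_{i:03d}")
    for i in range(n_null):
        rows.append(rng.normal(0, 0.05, n_samples) if noise == 0
                    else rng.normal(0, noise, n_samples))
        ids.append(f"null_{i:03d}")
    return make_study(np.array(rows), treatments, times, roles, probe_ids=ids), shapes


class TestExtractPatterns:
    def test_noiseless_planted_groups_recovered_exactly(self):
        study, shapes = _planted_study()
        pats = es.extract_patterns(study, es.PatternParams(min_cluster=5))
        assert len(pats) == 3
        found = {frozenset(p.members) for p in pats}
        expected = {
            frozenset(f"{g}_{i:03d}" for i in range(50)) for g in shapes
        }
        assert found == expected

    def test_pure_noise_yields_no_patterns(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            values = rng.normal(0, 0.25, size=(1000, 12))
            study = make_study(values,
                               treatments=["vehicle"] * 3 + ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                               times=[2] * 12,
                               roles=["vehicle"] * 3 + ["reference"] * 9)
            assert es.extract_patterns(study) == []

    def test_duplicated_probe_shares_pattern(self):
        study, _ = _planted_study(per_group=20, n_null=0)
        values = study.values.copy()
        values.loc["g1_dup"] = values.loc["g1_000"]
        dup = es.ExpressionStudy(values=values, metadata=study.metadata).validate()
        pats = es.extract_patterns(dup, es.PatternParams(min_cluster=5))
        home = [p for p in pats if "g1_000" in p.members]
        assert len(home) == 1 and "g1_dup" in home[0].members

    def test_members_disjoint_and_correlated_with_seed_or_profile(self):
        study, _ = _planted_study(noise=0.6, seed=3)
        params = es.PatternParams(min_cluster=5)
        pats = es.extract_patterns(study, params)
        assert pats, "expected at least one pattern"
        seen = set()
        for p in pats:
            assert not (seen & set(p.members))
            seen |= set(p.members)
            seed_row = study.values.loc[p.seed_probe].to_numpy()
            init = p.initial_profile.to_numpy()
            for m in p.members:
                row = study.values.loc[m].to_numpy()
                r = max(es.pearson_r(row, seed_row), es.pearson_r(row, init))
                assert r >= params.r_min - 1e-12

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_tiny_studies(self, seed):
        cfg = es.SimConfig(n_probes=12, probes_per_archetype=1, n_replicates=3,
                           batches=1, noise_sd=0.2, batch_shift_sd=0.0, seed=seed)
        study = es.batch_correct(es.simulate_reference_study(cfg).expression)
        params = es.PatternParams(r_min=0.6, snr_min=1.0, mag_min=0.3, min_cluster=2)
        pats = es.extract_patterns(study, params)
        expected = brute_force_patterns(study, params)
        assert [sorted(p.members) for p in pats] == expected


class TestAssignToPatterns:
    def _patterns(self):
        idx = [f"s{i}" for i in range(6)]
        return [
            es.Pattern(id=1, profile=pd.Series([0, 0, 1, 1, 2, 2], index=idx), members=["a"]),
            es.Pattern(id=2, profile=pd.Series([2, 2, 1, 1, 0, 0], index=idx), members=["b"]),
        ]

    def test_argmax_assignment(self):
        assert es.assign_to_patterns([0, 0.1, 1, 0.9, 2, 2.1], self._patterns(), 0.7) == 1

    def test_below_threshold_unassigned(self):
        assert es.assign_to_patterns([0, 5, -3, 2, 0, 1], self._patterns(), 0.99) == UNASSIGNED

    def test_exact_tie_prefers_smaller_id(self):
        pats = self._patterns()
        pats[1].profile = pats[0].profile.copy()
        assert es.assign_to_patterns([0, 0, 1, 1, 2, 2], pats, 0.7) == 1


class TestLabelPattern:
    def test_planted_archetypes_label_themselves(self, templates):
        cfg = es.SimConfig(n_probes=70, probes_per_archetype=10, noise_sd=0.0,
                           batch_shift_sd=0.0, seed=1)
        study = es.batch_correct(es.simulate_reference_study(cfg).expression)
        pats = es.extract_patterns(study, es.PatternParams(min_cluster=5))
        assert len(pats) == 7
        truth = es.simulate_reference_study(cfg).probe_truth
        for p in pats:
            label = es.label_pattern(p, study, templates)
            assert label == truth[p.members[0]]

    def test_negated_sustained_up_is_sustained_down(self, templates):
        cfg = es.SimConfig(n_probes=70, probes_per_archetype=10, noise_sd=0.0,
                           batch_shift_sd=0.0, seed=1)
        study = es.batch_correct(es.simulate_reference_study(cfg).expression)
        pats = es.extract_patterns(study, es.PatternParams(min_cluster=5))
        by_label = {es.label_pattern(p, study, templates): p for p in pats}
        flipped = by_label["sustained_up"]
        flipped.profile = -flipped.profile
        assert es.label_pattern(flipped, study, templates) == "sustained_down"

    def test_noise_pattern_is_unclassified(self, templates):
        cfg = es.SimConfig(n_probes=70, probes_per_archetype=10, seed=2)
        study = es.batch_correct(es.simulate_reference_study(cfg).expression)
        rng = np.random.default_rng(0)
        for _ in range(10):
            noise = es.Pattern(id=99, profile=pd.Series(
                rng.normal(0, 1, study.values.shape[1]), index=study.sample_ids),
                members=["x"])
            assert es.label_pattern(noise, study, templates) == UNCLASSIFIED
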