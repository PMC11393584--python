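import numpy as np
import pytest
from scipy import stats

from psynet.errors import ParameterError
from psynet.ggm import precision_to_pcor
from psynet.simulate import (
    GSES_ITEMS,
    EdgeEdit,
    GeneratorConfig,
    apply_edge_edits,
    default_base_edits,
    default_group_edits,
    equal_probability_thresholds,
    generate_two_group_study,
    make_network_pair,
    make_true_network,
    pcor_to_covariance,
    sample_likert,
    thresholds_from_cumprobs,
)


class TestMakeTrueNetwork:
    def test_edge_count_is_floor_of_density(self):
        net = make_true_network(p=19, density=0.3, seed=1)
        assert net.edge_count() == int(np.floor(0.3 * 19 * 18 / 2)) == 51

    def test_zero_density_gives_identity_covariance(self):
        net = make_true_network(p=6, density=0.0, seed=1)
        assert net.edge_count() == 0
        assert np.allclose(pcor_to_covariance(net), np.eye(6))

    @pytest.mark.parametrize("seed", range(5))
    def test_implied_precision_positive_definite(self, seed):
        net = make_true_network(p=12, density=0.4, seed=seed)
        assert np.linalg.eigvalsh(net.precision()).min() > 0

    def test_cross_community_edges_mostly_negative(self):
        comm = {f"A{i}": "a" for i in range(6)} | {f"B{i}": "b" for i in range(6)}
        net = make_true_network(communities=comm, density=0.5, seed=3,
                                cross_negative_prob=1.0)
        cross = [
            net.pcor[i, j]
            for i in range(6) for j in range(6, 12)
            if net.pcor[i, j] != 0
        ]
        assert cross and all(w < 0 for w in cross)


class TestCovarianceMap:
    def test_two_node_partial_equals_marginal(self):
        net = make_true_network(p=2, density=1.0, weight_range=(0.5, 0.5), seed=0)
        cov = pcor_to_covariance(net)
        assert cov[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_roundtrip_through_precision(self):
        net = make_true_network(p=5, density=0.6, seed=9)
        cov = pcor_to_covariance(net)
        back = precision_to_pcor(np.linalg.inv(cov))
        assert np.abs(back - net.pcor).max() < 1e-10


class TestEdgeEdits:
    def setup_method(self):
        self.net = make_true_network(labels=GSES_ITEMS, density=0.3, seed=0)

    def test_remove_zeroes_the_edge(self):
        edited = apply_edge_edits(self.net, [EdgeEdit("S2", "S3", "set", 0.16)])
        out = apply_edge_edits(edited, [EdgeEdit("S2", "S3", "remove")])
        assert out.pcor[out.index("S2"), out.index("S3")] == 0.0

    def test_add_plants_exact_weight(self):
        base = apply_edge_edits(self.net, [EdgeEdit("S3", "S6", "set", 0.0)])
        out = apply_edge_edits(base, [EdgeEdit("S3", "S6", "add", 0.11)])
        assert out.pcor[out.index("S3"), out.index("S6")] == pytest.approx(0.11)

    def test_strengthen_plants_exact_weight(self):
        base = apply_edge_edits(self.net, [EdgeEdit("S5", "S7", "set", 0.13)])
        out = apply_edge_edits(base, [EdgeEdit("S5", "S7", "strengthen", 0.28)])
        assert out.pcor[out.index("S5"), out.index("S7")] == pytest.approx(0.28)

    def test_add_on_existing_edge_rejected(self):
        base = apply_edge_edits(self.net, [EdgeEdit("S1", "S2", "set", 0.2)])
        with pytest.raises(ParameterError):
            apply_edge_edits(base, [EdgeEdit("S1", "S2", "add", 0.1)])

    def test_repair_preserves_edited_edges(self):
        # force a repair by planting a very strong edge structure
        edits = [EdgeEdit("S1", "S2", "set", 0.6), EdgeEdit("S2", "S3", "set", 0.6),
                 EdgeEdit("S1", "S3", "set", -0.45)]
        out = apply_edge_edits(self.net, edits)
        for e in edits:
            assert out.pcor[out.index(e.i), out.index(e.j)] == pytest.approx(e.weight)
        assert np.linalg.eigvalsh(out.precision()).min() > 0


class TestSampleLikert:
    def test_shape_and_category_range(self):
        cov = np.eye(4)
        thr = [equal_probability_thresholds(4)] * 4
        s = sample_likert(cov, thr, 100, seed=0)
        assert s.frame.shape == (100, 4)
        assert s.frame.min().min() >= 1 and s.frame.max().max() <= 4

    def test_extreme_thresholds_force_single_category(self):
        cov = np.eye(3)
        thr = [np.array([10.0, 11.0, 12.0])] * 3
        s = sample_likert(cov, thr, 50, seed=1)
        assert (s.frame.to_numpy() == 1).all()

    def test_deterministic_under_seed(self):
        cov = pcor_to_covariance(make_true_network(p=5, density=0.5, seed=2))
        thr = [equal_probability_thresholds(4)] * 5
        a = sample_likert(cov, thr, 200, seed=9).frame
        b = sample_likert(cov, thr, 200, seed=9).frame
        assert a.equals(b)

    def test_discretized_correlation_matches_threshold_model(self):
        """Observed Pearson r of 4-category items vs the closed-form value
        implied by the latent bivariate normal and the cut-points."""
        rho = 0.6
        cov = np.array([[1, rho], [rho, 1]])
        thr = equal_probability_thresholds(4)
        s = sample_likert(cov, [thr, thr], 50_000, seed=3)
        x = s.frame.to_numpy(dtype=float)
        obs = np.corrcoef(x, rowvar=False)[0, 1]

        # closed form: X = 1 + sum_k 1{Z > t_k}; Cov from bivariate survival
        mvn = stats.multivariate_normal(mean=[0, 0], cov=cov)
        surv1 = stats.norm.sf(thr)
        cov_xy = 0.0
        for tk in thr:
            for ul in thr:
                joint = 1 - stats.norm.cdf(tk) - stats.norm.cdf(ul) + mvn.cdf([tk, ul])
                cov_xy += joint - stats.norm.sf(tk) * stats.norm.sf(ul)
        var_x = 0.0
        for a, ta in enumerate(thr):
            for b, tb in enumerate(thr):
                if a == b:
                    var_x += surv1[a] * (1 - surv1[a])
                else:
                    var_x += min(surv1[a], surv1[b]) - surv1[a] * surv1[b]
        expected = cov_xy / var_x
        assert obs == pytest.approx(expected, abs=0.03)
        assert abs(obs) <= rho + 0.03  # discretization attenuates


class TestTwoGroupStudy:
    def test_row_counts_match_config(self):
        cfg = GeneratorConfig(n_control=120, n_depressed=60, seed=1)
        study = generate_two_group_study(cfg)
        assert len(study.control) == 120 and len(study.depressed) == 60

    def test_bit_identical_under_same_seed(self):
        a = generate_two_group_study(GeneratorConfig(n_control=80, n_depressed=40, seed=4))
        b = generate_two_group_study(GeneratorConfig(n_control=80, n_depressed=40, seed=4))
        assert a.combined_frame().equals(b.combined_frame())
        assert np.array_equal(a.truth_control.pcor, b.truth_control.pcor)

    def test_empty_edits_share_one_network(self):
        cfg = GeneratorConfig(n_control=50, n_depressed=50, base_edits=[],
                              group_edits=[], strength_gap=None, seed=2)
        study = generate_two_group_study(cfg)
        assert np.array_equal(study.truth_control.pcor, study.truth_depressed.pcor)

    def test_planted_strength_gap_is_exact(self):
        study = generate_two_group_study(GeneratorConfig(n_control=50, n_depressed=50, seed=3))
        gap = (study.truth_control.global_strength()
               - study.truth_depressed.global_strength())
        assert gap == pytest.approx(0.25, abs=1e-12)

    def test_group_edits_pin_change_profile_weights(self):
        study = generate_two_group_study(GeneratorConfig(n_control=50, n_depressed=50, seed=3))
        td = study.truth_depressed
        for e in default_group_edits():
            got = td.pcor[td.index(e.i), td.index(e.j)]
            assert got == pytest.approx(0.0 if e.action == "remove" else e.weight)

    def test_network_pair_without_gap_keeps_unedited_edges(self):
        comm = {s: "self-efficacy" for s in GSES_ITEMS}
        ctrl, dep = make_network_pair(communities=comm, density=0.3,
                                      base_edits=default_base_edits(),
                                      group_edits=default_group_edits(), seed=6)
        edited = {frozenset((e.i, e.j)) for e in default_group_edits()}
        for i in range(10):
            for j in range(i + 1, 10):
                pair = frozenset((GSES_ITEMS[i], GSES_ITEMS[j]))
                if pair not in edited:
                    assert dep.pcor[i, j] == ctrl.pcor[i, j]

    def test_bad_cumprobs_rejected(self):
        with pytest.raises(ParameterError):
            thresholds_from_cumprobs((0.5, 0.4, 0.9))
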