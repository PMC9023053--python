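import math

import numpy as np
import pytest

from tcrconv.generative_model import (
    CapacityError,
    RecombinationModel,
    enumerate_rearrangements,
    estimate_ball_pgen,
    exact_ball_pgen,
    generate_null_repertoire,
    generate_study,
    plant_convergent_cluster,
    sample_rearrangement,
    simulate_productive,
)


def degenerate_model():
    """Zero deletions, zero insertions: always emits CASFF."""
    return RecombinationModel(
        v_segments={"TRBV1": "TGTGCCAGC"},
        j_segments={"TRBJ1": "TTTTTC"},
        v_deletion_dist=[1.0],
        j_deletion_dist=[1.0],
        insertion_length_dist=[1.0],
        insertion_base_probs=[0.25, 0.25, 0.25, 0.25],
        vj_usage={("TRBV1", "TRBJ1"): 1.0},
    )


def frameshift_model():
    """Forced 1-nt insert: never in frame, always rejected."""
    return RecombinationModel(
        v_segments={"TRBV1": "TGTGCCAGC"},
        j_segments={"TRBJ1": "TTTTTC"},
        v_deletion_dist=[1.0],
        j_deletion_dist=[1.0],
        insertion_length_dist=[0.0, 1.0],
        insertion_base_probs=[0.25, 0.25, 0.25, 0.25],
        vj_usage={("TRBV1", "TRBJ1"): 1.0},
    )


class TestSampleRearrangement:
    def test_degenerate_model_deterministic(self):
        for seed in range(5):
            v, j, nt, aa = sample_rearrangement(degenerate_model(), seed)
            assert aa == "CASFF"
            assert nt == "TGTGCCAGCTTTTTC"

    def test_frame_rule_rejection(self):
        for seed in range(5):
            assert sample_rearrangement(frameshift_model(), seed) is None

    def test_seed_determinism(self, human_model):
        a = sample_rearrangement(human_model, 7)
        b = sample_rearrangement(human_model, 7)
        assert a == b

    def test_productive_filter(self, human_model):
        rng = np.random.default_rng(0)
        seqs = simulate_productive(human_model, "TRBV1", "TRBJ1", 2000, rng)
        assert len(seqs) == 2000
        for s in seqs:
            assert s[0] == "C" and s[-1] in "FW" and "*" not in s


class TestExactEnumeration:
    def test_toy_four_events(self, toy):
        probs, reject = enumerate_rearrangements(toy, "TRBV1", "TRBJ1")
        assert probs == {"CASSGFF": 0.25, "CASSFF": 0.25, "CASGFF": 0.25, "CASFF": 0.25}
        assert reject == 0.0

    def test_ball_pgen_hand_enumeration(self, toy):
        # CASSFF's ball: itself (1/4) + CASGFF (1/4, one mismatch at pos 4)
        assert exact_ball_pgen(toy, "CASSFF", "TRBV1", "TRBJ1") == pytest.approx(0.5)
        # CASFF is the only producible length-5 sequence
        assert exact_ball_pgen(toy, "CASFF", "TRBV1", "TRBJ1") == pytest.approx(0.25)
        assert exact_ball_pgen(toy, "CASSGFF", "TRBV1", "TRBJ1") == pytest.approx(0.25)

    def test_degenerate_model_prob_one(self):
        assert exact_ball_pgen(degenerate_model(), "CASFF", "TRBV1", "TRBJ1") == 1.0

    def test_unreachable_length_zero(self, toy):
        assert exact_ball_pgen(toy, "CASSSSFF", "TRBV1", "TRBJ1") == 0.0

    def test_probabilities_plus_rejection_sum_to_one(self, toy, toy_ins):
        for model in (toy, toy_ins, degenerate_model(), frameshift_model()):
            probs, reject = enumerate_rearrangements(model, "TRBV1", "TRBJ1")
            assert sum(probs.values()) + reject == pytest.approx(1.0, abs=1e-9)

    def test_insertion_model_rejection_mass(self, toy_ins):
        # 1-codon inserts: 3 of 64 codons are stops -> rejection 0.5 * 3/64
        probs, reject = enumerate_rearrangements(toy_ins, "TRBV1", "TRBJ1")
        assert reject == pytest.approx(0.5 * 3 / 64)
        # every length-6 product CASXFF is in the ball of CASSFF
        expect = (0.5 * 61 / 64) / (1 - reject)
        assert exact_ball_pgen(toy_ins, "CASSFF", "TRBV1", "TRBJ1") == pytest.approx(expect)

    def test_capacity_error(self, human_model):
        with pytest.raises(CapacityError):
            enumerate_rearrangements(human_model, "TRBV1", "TRBJ1", max_events=1000)


class TestEstimateBallPgen:
    def test_degenerate_support(self):
        est = estimate_ball_pgen(degenerate_model(), "CASFF", "TRBV1", "TRBJ1", 1000, 10, 0)
        assert est.point == 1.0
        assert est.std_error == 0.0

    def test_within_three_se_of_exact(self, toy):
        est = estimate_ball_pgen(toy, "CASSFF", "TRBV1", "TRBJ1", 10_000, 20, 3)
        assert abs(est.point - 0.5) <= 3 * est.std_error

    def test_unreachable_length(self, toy):
        est = estimate_ball_pgen(toy, "CASSSSFF", "TRBV1", "TRBJ1", 2000, 10, 0)
        assert est.point == 0.0
        assert est.std_error == 0.0

    def test_unknown_vj_raises(self, toy):
        with pytest.raises(ValueError):
            estimate_ball_pgen(toy, "CASSFF", "TRBV9", "TRBJ1", 100, 10, 0)

    def test_deterministic_given_seed(self, human_model):
        a = estimate_ball_pgen(human_model, "CASSGGGGTF", "TRBV2", "TRBJ2", 2000, 10, 5)
        b = estimate_ball_pgen(human_model, "CASSGGGGTF", "TRBV2", "TRBJ2", 2000, 10, 5)
        assert a == b


class TestGenerateNullRepertoire:
    def test_contract(self, human_model):
        rep = generate_null_repertoire(human_model, 100, seed=1)
        assert len(rep) == 100
        assert len(set(rep.keys())) == 100
        assert sum(c.freq for c in rep.clonotypes) == pytest.approx(1.0, abs=1e-9)
        assert all(c.count >= 2 for c in rep.clonotypes)

    def test_determinism(self, human_model):
        a = generate_null_repertoire(human_model, 50, seed=9)
        b = generate_null_repertoire(human_model, 50, seed=9)
        assert [(c.key, c.count) for c in a.clonotypes] == [(c.key, c.count) for c in b.clonotypes]

    def test_geometric_count_law_mean(self, human_model):
        p = 0.5
        rep = generate_null_repertoire(human_model, 10_000, ("geometric", p), seed=2)
        counts = np.array([c.count for c in rep.clonotypes])
        expect = 1 + 1 / p  # counts are 1 + Geometric(p)
        se = np.sqrt((1 - p) / p**2 / len(counts))
        assert abs(counts.mean() - expect) < 3 * se

    def test_capacity_error_on_tiny_support(self):
        with pytest.raises(CapacityError):
            generate_null_repertoire(degenerate_model(), 10, seed=0)


@pytest.fixture(scope="module")
def planted(human_model):
    rep = generate_null_repertoire(human_model, 200, seed=4)
    return plant_convergent_cluster(rep, human_model, 5, 0.1, seed=8)


@pytest.fixture(scope="module")
def study(human_model):
    return generate_study(
        human_model,
        {"n_background": 150, "n_dp_background": 60, "n_nondp_background": 120,
         "n_matrix_rows": 100, "n_replicates": 6},
        seed=12,
    )


class TestPlantConvergentCluster:
    def test_star_structure(self, planted):
        rep, truth = planted
        assert len(truth) == 5
        seqs = [k.split("|")[0] for k in truth]
        seed_aa = next(k.split("|")[0] for k, v in truth.items() if v["is_seed"])
        for s in seqs:
            assert len(s) == len(seed_aa)
            assert sum(a != b for a, b in zip(s, seed_aa)) <= 1
        for a in seqs:
            for b in seqs:
                assert sum(x != y for x, y in zip(a, b)) <= 2

    def test_target_frequency_exact(self, planted):
        rep, truth = planted
        planted_freq = sum(c.freq for c in rep.clonotypes if "|".join(c.key) in truth)
        assert planted_freq == pytest.approx(0.1, abs=1e-9)

    def test_same_vj_and_counts_survive_singletons(self, planted):
        rep, truth = planted
        vjs = {tuple(k.split("|")[1:]) for k in truth}
        assert len(vjs) == 1
        planted_counts = [c.count for c in rep.clonotypes if "|".join(c.key) in truth]
        assert all(c >= 2 for c in planted_counts)

    def test_oversized_cluster_raises(self, human_model):
        rep = generate_null_repertoire(human_model, 20, seed=4)
        with pytest.raises(ValueError):
            plant_convergent_cluster(rep, human_model, 500, 0.1, seed=8)


class TestGenerateStudy:
    def test_planted_keys_in_repertoires(self, study):
        planted = {k for k, t in study.truth.items() if t.get("planted_cluster_id")}
        assert planted
        for name in ("DP", "nonDP", "FFT"):
            keys = {"|".join(c.key) for c in study.repertoires[name].clonotypes}
            assert planted <= keys

    def test_truth_keys_subset_of_repertoire_union(self, study):
        union = set()
        for rep in study.repertoires.values():
            union |= {"|".join(c.key) for c in rep.clonotypes}
        union |= set(study.counts.index)
        assert set(study.truth) <= union

    def test_enrichment_one_gives_equal_planted_freq(self, human_model):
        s = generate_study(
            human_model,
            {"n_background": 100, "n_dp_background": 80, "n_nondp_background": 80,
             "enrichment": 1.0, "n_matrix_rows": 50},
            seed=3,
        )
        planted = {k for k, t in s.truth.items() if t.get("planted_cluster_id")}
        f_dp = sum(c.freq for c in s.repertoires["DP"].clonotypes if "|".join(c.key) in planted)
        f_non = sum(c.freq for c in s.repertoires["nonDP"].clonotypes if "|".join(c.key) in planted)
        assert f_dp == pytest.approx(f_non, abs=1e-9)

    def test_nb_fold_change_mean(self, study):
        cond_b = "IL21combo"
        expanded = [k for k, t in study.truth.items() if t.get("true_log2fc")]
        assert len(expanded) == 20
        counts = study.counts
        cols_a = [c for c, cond in study.design.items() if cond == "IL2high"]
        cols_b = [c for c, cond in study.design.items() if cond == cond_b]
        m_a = counts.loc[expanded, cols_a].to_numpy().mean()
        m_b = counts.loc[expanded, cols_b].to_numpy().mean()
        ratio = m_b / m_a
        # NB at dispersion 0.1, 6 reps x 20 clonotypes: ratio within ~3 SE of 8
        assert 5.5 < ratio < 11.5

    def test_zero_log2fc_gives_equal_means(self, human_model):
        s = generate_study(
            human_model,
            {"n_background": 100, "n_dp_background": 60, "n_nondp_background": 60,
             "n_expanded": 0, "n_matrix_rows": 80, "dispersion": 0.0},
            seed=5,
        )
        cols_a = [c for c, cond in s.design.items() if cond == "IL2high"]
        cols_b = [c for c, cond in s.design.items() if cond == "IL21combo"]
        m_a = s.counts[cols_a].to_numpy().mean()
        m_b = s.counts[cols_b].to_numpy().mean()
        assert m_b == pytest.approx(m_a, rel=0.05)


class TestModelSerialization:
    def test_yaml_round_trip(self, human_model, tmp_path):
        p = tmp_path / "model.yaml"
        human_model.to_yaml(p)
        back = RecombinationModel.from_yaml(p)
        assert back.v_segments == human_model.v_segments
        assert back.vj_usage == human_model.vj_usage
        np.testing.assert_allclose(back.insertion_length_dist, human_model.insertion_length_dist)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            RecombinationModel(
                v_segments={"TRBV1": "TGT"},
                j_segments={"TRBJ1": "TTC"},
                v_deletion_dist=[0.5, 0.4],  # sums to 0.9
                j_deletion_dist=[1.0],
                insertion_length_dist=[1.0],
                insertion_base_probs=[0.25, 0.25, 0.25, 0.25],
                vj_usage={("TRBV1", "TRBJ1"): 1.0},
            )
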