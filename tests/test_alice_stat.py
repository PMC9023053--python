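import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrconv.alice_stat import (
    bh_adjust,
    count_neighbors,
    neighbor_pvalue,
    normalized_hits,
    run_alice,
)
from tcrconv.generative_model import generate_null_repertoire, plant_convergent_cluster
from tcrconv.repertoire_io import Repertoire

from .conftest import N_BATCHES, N_SIM, make_repertoire


def brute_force_neighbors(rep):
    """O(n^2) all-pairs oracle for d_obs."""
    out = {}
    cl = rep.clonotypes
    for i, a in enumerate(cl):
        d = 0
        for k, b in enumerate(cl):
            if i == k:
                continue
            if a.v_gene != b.v_gene or a.j_gene != b.j_gene:
                continue
            if len(a.cdr3_aa) != len(b.cdr3_aa):
                continue
            if sum(x != y for x, y in zip(a.cdr3_aa, b.cdr3_aa)) <= 1:
                d += 1
        out[a.key] = d
    return out


def bh_oracle(p):
    """Literal step-up procedure."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank, 1.0)
        q[i] = val
        prev = val
    return q


class TestCountNeighbors:
    def test_worked_example(self, small_rep):
        d = count_neighbors(small_rep)
        assert d[("CASSF", "TRBV1", "TRBJ1")] == 2
        assert d[("CASTF", "TRBV1", "TRBJ1")] == 1
        assert d[("CASSG", "TRBV1", "TRBJ1")] == 1

    def test_vj_class_rule(self):
        rep = make_repertoire(
            [("CASSF", "TRBV1", "TRBJ1", 2), ("CASSF", "TRBV1", "TRBJ2", 2)]
        )
        assert set(count_neighbors(rep).values()) == {0}

    def test_singleton_repertoire(self):
        rep = make_repertoire([("CASSF", "TRBV1", "TRBJ1", 2)])
        assert count_neighbors(rep) == {("CASSF", "TRBV1", "TRBJ1"): 0}

    def test_duplicate_keys_rejected(self):
        rep = make_repertoire(
            [("CASSF", "TRBV1", "TRBJ1", 2), ("CASSF", "TRBV1", "TRBJ1", 3)]
        )
        with pytest.raises(ValueError):
            count_neighbors(rep)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_fixtures(self, human_model, seed):
        rep = generate_null_repertoire(human_model, 300, seed=seed)
        assert count_neighbors(rep) == brute_force_neighbors(rep)


class TestNeighborPvalue:
    def test_zero_neighbors_p_one(self):
        assert neighbor_pvalue(0, 5.0) == 1.0
        assert neighbor_pvalue(0, 0.0) == 1.0

    def test_closed_form(self):
        expect = 1 - math.exp(-0.1) * (1 + 0.1)
        assert neighbor_pvalue(2, 0.1) == pytest.approx(expect, rel=1e-9)
        assert neighbor_pvalue(2, 0.1) == pytest.approx(0.004679, abs=1e-6)

    def test_vanishing_lambda_limit(self):
        assert neighbor_pvalue(1, 1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            neighbor_pvalue(-1, 0.5)
        with pytest.raises(ValueError):
            neighbor_pvalue(1, -0.5)


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.001, 0.02, 0.03]), [0.003, 0.03, 0.03]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        p=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12, atol=1e-15)

    @given(
        p=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=20)
    )
    @settings(max_examples=50, deadline=None)
    def test_q_at_least_p(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)


class TestRunAlice:
    def test_no_neighbors_possible(self, human_model, sim_cache):
        rep = make_repertoire(
            [("CASSNPSHVNRDVGTF", "TRBV1", "TRBJ1", 3), ("CASSNFSGDVGTF", "TRBV2", "TRBJ1", 2)]
        )
        results = run_alice(rep, human_model, n_sim=N_SIM, n_batches=N_BATCHES, sim_cache=sim_cache)
        assert all(r.p_value == 1.0 for r in results)
        assert not any(r.is_hit for r in results)

    def test_planted_cluster_flagged(self, human_model, sim_cache):
        rep = generate_null_repertoire(human_model, 500, seed=21)
        rep2, truth = plant_convergent_cluster(rep, human_model, 10, 0.05, seed=22)
        results = run_alice(rep2, human_model, n_sim=N_SIM, n_batches=N_BATCHES, sim_cache=sim_cache)
        hits = {r.key for r in results if r.is_hit}
        planted = {tuple(k.split("|")) for k in truth}
        assert hits & planted

    def test_hits_invariant_under_count_rescaling(self, human_model, sim_cache):
        rep = generate_null_repertoire(human_model, 300, seed=31)
        rep2, _ = plant_convergent_cluster(rep, human_model, 8, 0.05, seed=32)
        scaled = make_repertoire(
            [(c.cdr3_aa, c.v_gene, c.j_gene, c.count * 10) for c in rep2.clonotypes]
        )
        r1 = run_alice(rep2, human_model, n_sim=N_SIM, n_batches=N_BATCHES, sim_cache=sim_cache)
        r2 = run_alice(scaled, human_model, n_sim=N_SIM, n_batches=N_BATCHES, sim_cache=sim_cache)
        assert {r.key for r in r1 if r.is_hit} == {r.key for r in r2 if r.is_hit}
        assert normalized_hits(r1, len(rep2)) == normalized_hits(r2, len(scaled))

    def test_hits_invariant_under_row_permutation(self, human_model, sim_cache):
        rep = generate_null_repertoire(human_model, 300, seed=41)
        rep2, _ = plant_convergent_cluster(rep, human_model, 8, 0.05, seed=42)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(rep2)))
        shuffled = Repertoire(rep2.sample_id, [rep2.clonotypes[i] for i in perm])
        r1 = run_alice(rep2, human_model, n_sim=N_SIM, n_batches=N_BATCHES, sim_cache=sim_cache)
        r2 = run_alice(shuffled, human_model, n_sim=N_SIM, n_batches=N_BATCHES, sim_cache=sim_cache)
        assert {r.key for r in r1 if r.is_hit} == {r.key for r in r2 if r.is_hit}

    def test_singletons_removed_before_testing(self, human_model, sim_cache):
        rep = make_repertoire(
            [("CASSNPSHVNRDVGTF", "TRBV1", "TRBJ1", 5), ("CATSNPSHVNRDVGTF", "TRBV1", "TRBJ1", 1)]
        )
        results = run_alice(rep, human_model, n_sim=N_SIM, n_batches=N_BATCHES, sim_cache=sim_cache)
        assert len(results) == 1  # singleton dropped
        assert results[0].d_obs == 0

    def test_unknown_vj_class_skipped(self, toy, caplog):
        rep = make_repertoire(
            [("CASSF", "TRBV99", "TRBJ99", 3), ("CASSFF", "TRBV1", "TRBJ1", 2)]
        )
        results = run_alice(rep, toy, n_sim=1000, n_batches=10)
        assert len(results) == 1
        assert results[0].key == ("CASSFF", "TRBV1", "TRBJ1")

    def test_monotone_in_neighbors(self, human_model, sim_cache):
        # adding a neighbor never increases p of the focal clonotype
        base_rows = [("CASSNPSHVNRDVGTF", "TRBV1", "TRBJ1", 4)]
        variants = ["CATSNPSHVNRDVGTF", "CASANPSHVNRDVGTF", "CASSNPAHVNRDVGTF"]
        prev_p = None
        focal = ("CASSNPSHVNRDVGTF", "TRBV1", "TRBJ1")
        for k in range(len(variants) + 1):
            rows = base_rows + [(v, "TRBV1", "TRBJ1", 2) for v in variants[:k]]
            res = run_alice(
                make_repertoire(rows), human_model,
                n_sim=N_SIM, n_batches=N_BATCHES, sim_cache=sim_cache,
            )
            p = next(r.p_value for r in res if r.key == focal)
            if prev_p is not None:
                assert p <= prev_p + 1e-12
            prev_p = p

    def test_q_factor_auto_calibrates(self, human_model, sim_cache):
        rep = generate_null_repertoire(human_model, 2000, seed=77)
        results = run_alice(
            rep, human_model, n_sim=N_SIM, n_batches=N_BATCHES,
            sim_cache=sim_cache, q_factor="auto",
        )
        tested = [r for r in results if r.d_obs > 0 and r.lambda_expected > 0]
        ratios = sorted(r.d_obs / r.lambda_expected for r in tested)
        # after calibration the typical observed/expected ratio is near 1
        median = ratios[len(ratios) // 2]
        assert 0.5 < median < 2.0


class TestNormalizedHits:
    def test_arithmetic(self, human_model, sim_cache):
        class FakeResult:
            def __init__(self, hit):
                self.is_hit = hit

        results = [FakeResult(True)] * 12 + [FakeResult(False)] * 100
        assert normalized_hits(results, 3000) == pytest.approx(0.004)
        assert normalized_hits([FakeResult(False)], 10) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            normalized_hits([], 0)
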