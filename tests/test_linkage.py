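import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from introgramap.linkage import (
    LinkageSubgroup,
    TwoPointEstimate,
    dominant_class_probs,
    estimate_rf_codominant,
    estimate_rf_dominant,
    group_loci,
    kosambi_cM,
    kosambi_inverse,
)
from conftest import make_f2_codominant_counts, make_f2_dominant_counts


# -- independent oracles ------------------------------------------------

def grid_oracle_codominant(counts, step=0.001):
    """Brute-force likelihood grid for the 3x3 F2 table (coupling F1)."""
    counts = np.asarray(counts, float)
    haps = [(0, 0), (1, 1), (0, 1), (1, 0)]
    best_r, best_ll = 0.0, -np.inf
    for r in np.arange(0.0, 0.5 + step / 2, step):
        p_hap = [(1 - r) / 2, (1 - r) / 2, r / 2, r / 2]
        probs = np.zeros((3, 3))
        for (a1, b1), p1 in zip(haps, p_hap):
            for (a2, b2), p2 in zip(haps, p_hap):
                probs[a1 + a2, b1 + b2] += p1 * p2
        ll = float(np.sum(counts * np.log(np.maximum(probs, 1e-300))))
        if ll > best_ll:
            best_r, best_ll = float(r), ll
    return best_r, best_ll


def grid_oracle_dominant(counts, phase, step=0.001):
    counts = np.asarray(counts, float).ravel()
    best_r, best_ll = 0.0, -np.inf
    for r in np.arange(0.0, 0.5 + step / 2, step):
        k = (1 - r) ** 2 if phase == "coupling" else r ** 2
        probs = np.array([(2 + k) / 4, (1 - k) / 4, (1 - k) / 4, k / 4])
        ll = float(np.sum(counts * np.log(np.maximum(probs, 1e-300))))
        if ll > best_ll:
            best_r, best_ll = float(r), ll
    return best_r, best_ll


class TestCodominant:
    def test_perfect_linkage(self):
        counts = np.zeros((3, 3))
        counts[0, 0], counts[1, 1], counts[2, 2] = 25, 50, 25
        est = estimate_rf_codominant(counts)
        assert est.r_hat == pytest.approx(0.0, abs=1e-6)
        assert est.lod > 3

    def test_independent_loci(self):
        # balanced product of two 1:2:1 segregations
        marg = np.array([0.25, 0.5, 0.25])
        counts = 400 * np.outer(marg, marg)
        est = estimate_rf_codominant(counts)
        assert est.r_hat == pytest.approx(0.5, abs=1e-3)
        assert est.lod < 0.05

    def test_em_recovers_simulated_r(self):
        rng = np.random.default_rng(1)
        for r in (0.05, 0.2, 0.35):
            errs = [abs(estimate_rf_codominant(
                make_f2_codominant_counts(r, 1000, rng)).r_hat - r)
                for _ in range(30)]
            assert np.mean(errs) < 0.03

    def test_agrees_with_grid_oracle_on_random_tables(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            if rng.random() < 0.5:
                counts = make_f2_codominant_counts(rng.uniform(0, 0.5), 200, rng)
            else:
                counts = rng.multinomial(150, rng.dirichlet(np.ones(9))).reshape(3, 3)
            est = estimate_rf_codominant(counts)
            r_g, ll_g = grid_oracle_codominant(counts)
            ll_at_hat = float(np.sum(counts * np.log(np.maximum(
                _probs_codominant(est.r_hat), 1e-300))))
            assert ll_at_hat >= ll_g - 1e-6  # EM at least as good as the grid
            if ll_g - ll_at_hat > 1e-9:
                assert abs(est.r_hat - r_g) <= 0.001

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            estimate_rf_codominant(np.zeros((3, 3)))


def _probs_codominant(r):
    haps = [(0, 0), (1, 1), (0, 1), (1, 0)]
    p_hap = [(1 - r) / 2, (1 - r) / 2, r / 2, r / 2]
    probs = np.zeros((3, 3))
    for (a1, b1), p1 in zip(haps, p_hap):
        for (a2, b2), p2 in zip(haps, p_hap):
            probs[a1 + a2, b1 + b2] += p1 * p2
    return probs


class TestDominant:
    def test_moment_oracle_on_model_consistent_table(self):
        # coupling with both-absent = (1-r)^2/4 = 81/400 -> moment r = 0.10
        counts = [[281, 19], [19, 81]]
        moment = 1 - math.sqrt(4 * 81 / 400)
        est = estimate_rf_dominant(counts, "coupling")
        assert moment == pytest.approx(0.10, abs=1e-12)
        assert est.r_hat == pytest.approx(moment, abs=0.01)

    def test_no_recombinant_classes(self):
        counts = [[300, 0], [0, 100]]
        est = estimate_rf_dominant(counts, "coupling")
        assert est.r_hat == pytest.approx(0.0, abs=1e-6)

    def test_repulsion_detected_on_complementary_pattern(self):
        # never jointly absent, complementary presence: repulsion at r ~ 0
        counts = [[200, 100], [100, 0]]
        est = estimate_rf_dominant(counts, phase="unknown")
        assert est.phase == "repulsion"
        assert est.r_hat < 0.05

    def test_phase_tie_reported_unknown(self):
        # r = 0.5 makes both phase models identical
        k = 0.25
        counts = 400 * np.array([[(2 + k) / 4, (1 - k) / 4], [(1 - k) / 4, k / 4]])
        est = estimate_rf_dominant(counts, phase="unknown")
        assert est.phase == "unknown"

    def test_low_information_flag(self):
        est = estimate_rf_dominant([[4, 0], [0, 0]], "coupling")
        assert est.low_information

    def test_agrees_with_grid_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            phase = "coupling" if rng.random() < 0.5 else "repulsion"
            counts = make_f2_dominant_counts(rng.uniform(0, 0.5), 300, phase, rng)
            est = estimate_rf_dominant(counts, phase)
            r_g, ll_g = grid_oracle_dominant(counts, phase)
            ll_hat = float(np.sum(np.asarray(counts).ravel()
                                  * np.log(np.maximum(
                                      dominant_class_probs(est.r_hat, phase).ravel(),
                                      1e-300))))
            assert ll_hat >= ll_g - 1e-6

    def test_lod_zero_at_independence_positive_when_linked(self):
        rng = np.random.default_rng(4)
        linked = make_f2_dominant_counts(0.05, 400, "coupling", rng)
        est = estimate_rf_dominant(linked, "coupling")
        assert est.lod > 3
        free = 400 * dominant_class_probs(0.5, "coupling")
        assert estimate_rf_dominant(free, "coupling").lod == pytest.approx(0.0, abs=1e-6)


class TestGrouping:
    def _est(self, a, b, r, lod=10.0):
        return TwoPointEstimate(a, b, r, lod, "coupling", 100)

    def test_edge_definition(self):
        groups = group_loci([self._est("a", "b", 0.05), self._est("b", "c", 0.4)])
        top = {frozenset(s.members) for s in groups[0.25]}
        assert top == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_chain_dissolves_at_strict_threshold(self):
        ests = [self._est("a", "b", 0.2), self._est("b", "c", 0.2)]
        groups = group_loci(ests)
        assert {frozenset(s.members) for s in groups[0.25]} == {frozenset("abc")}
        assert {frozenset(s.members) for s in groups[0.05]} == {
            frozenset("a"), frozenset("b"), frozenset("c")}

    def test_lod_gate(self):
        groups = group_loci([self._est("a", "b", 0.01, lod=1.0)])
        assert {frozenset(s.members) for s in groups[0.25]} == {
            frozenset("a"), frozenset("b")}

    def test_monotone_refinement(self):
        rng = np.random.default_rng(5)
        names = [f"m{i}" for i in range(12)]
        ests = [self._est(a, b, float(rng.uniform(0, 0.5)), float(rng.uniform(0, 20)))
                for i, a in enumerate(names) for b in names[i + 1:]]
        groups = group_loci(ests, markers=names)
        thresholds = sorted(groups, reverse=True)
        for loose, strict in zip(thresholds, thresholds[1:]):
            for sub in groups[strict]:
                # every strict subgroup sits inside exactly one loose subgroup
                assert sum(sub.members <= big.members for big in groups[loose]) == 1


class TestKosambi:
    def test_zero(self):
        assert kosambi_cM(0.0) == 0.0

    def test_closed_form_value(self):
        assert kosambi_cM(0.1) == pytest.approx(25 * math.log(1.2 / 0.8), rel=1e-12)
        assert round(kosambi_cM(0.1), 2) == 10.14

    def test_round_trip_exact(self):
        for r in np.arange(0.01, 0.50, 0.01):
            assert abs(kosambi_inverse(kosambi_cM(float(r))) - r) < 1e-12

    @given(st.floats(0.0, 0.49), st.floats(0.0, 0.49))
    def test_strictly_increasing(self, r1, r2):
        if r1 == r2:
            return
        lo, hi = sorted((r1, r2))
        assert kosambi_cM(lo) < kosambi_cM(hi)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi_cM(0.5)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)
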