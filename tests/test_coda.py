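"""Compositional algebra: closure, clr, perturbation, Aitchison geometry.

Expected values for the worked example were computed independently with
50-digit arithmetic (mpmath) from the published 4-decimal compositions.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ionodiag.coda as coda
from ionodiag.coda import (ClrVector, Composition, CompositionError,
                           PartAlignmentError, aitchison_distance, clr_inverse,
                           clr_transform, close, perturb,
                           perturbation_difference, rank_imbalance,
                           subcomposition, NUTRIENTS, PARTS)
from ionodiag.worked_example import (OBSERVED, PRINTED_DISTANCE,
                                     PRINTED_PERTURBATION, REFERENCE)
from conftest import random_compositions

# mpmath oracle values for the worked example (50-digit evaluation)
CLR_OBSERVED = [1.0128438241970954, -1.7748331976938876, 0.4863666791373037,
                -1.9200152075383856, -1.5145500994302212, 3.7101880013280955]
PERTURBATION = [0.0931241726966684, 0.0970677169371835, 0.1694583593572380,
                0.1621165689124489, 0.3824288292293666, 0.0958043528670944]
OBSERVED_5PART = [0.5601118359739049, 0.0344827586206896, 0.3308480894687791,
                  0.0298229263746505, 0.0447343895619757]
DISTANCE_5PART = 1.1417083590297752
DISTANCE_6PART = 1.2272256382628373


class TestClose:
    @pytest.mark.parametrize("raw, expected", [
        ((2, 2, 4), (0.25, 0.25, 0.5)),
        ((0.25, 0.25, 0.5), (0.25, 0.25, 0.5)),
        # ratios of the worked-example pair; oracle: arbitrary-precision sum
        ((0.9334, 0.9730, 1.6986, 1.6250, 3.8333, 0.9603),
         (0.0931202362424677, 0.0970709126461550, 0.1694600742248294,
          0.1621174029290873, 0.3824274711680434, 0.0958039027894169)),
    ])
    def test_proportionality(self, raw, expected):
        parts = tuple(f"p{i}" for i in range(len(raw)))
        got = close(raw, parts)
        np.testing.assert_allclose(got.values, expected, atol=1e-12)
        assert got.values.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("raw", [(1.0, 0.0, 2.0), (1.0, -0.5, 2.0),
                                     (1.0, np.inf, 2.0), (1.0, np.nan, 2.0)])
    def test_rejects_invalid_entries(self, raw):
        with pytest.raises(CompositionError):
            close(raw, ("a", "b", "c"))


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        c = close(np.ones(6))
        np.testing.assert_allclose(clr_transform(c).values, 0.0, atol=1e-12)

    def test_worked_example_values(self):
        np.testing.assert_allclose(clr_transform(OBSERVED).values,
                                   CLR_OBSERVED, atol=1e-12)

    def test_sum_zero_and_round_trip_on_random_compositions(self, rng):
        comps = random_compositions(rng, 1000)
        for row in comps:
            c = Composition(row, PARTS)
            v = clr_transform(c)
            assert abs(v.values.sum()) < 1e-9
            back = clr_inverse(v)
            np.testing.assert_allclose(back.values, c.values, atol=1e-9)

    def test_matches_scikit_bio_clr(self, rng):
        from skbio.stats.composition import clr as skbio_clr
        comps = random_compositions(rng, 50)
        ours = np.array([clr_transform(Composition(r, PARTS)).values
                         for r in comps])
        np.testing.assert_allclose(ours, skbio_clr(comps), atol=1e-12)

    def test_inverse_absorbs_additive_constants(self):
        v = clr_transform(OBSERVED).values
        shifted = np.exp(v + 3.7)  # un-centred log vector
        np.testing.assert_allclose(close(shifted, PARTS).values,
                                   OBSERVED.values, atol=1e-12)

    def test_inverse_of_zero_is_uniform(self):
        c = clr_inverse(ClrVector(np.zeros(6), PARTS))
        np.testing.assert_allclose(c.values, 1 / 6, atol=1e-12)

    def test_inverse_rejects_overflow(self):
        with pytest.raises(CompositionError):
            clr_inverse(ClrVector(np.array([600.0, -600.0]), ("a", "b")))


class TestPerturbation:
    def test_uniform_is_neutral(self):
        uniform = close(np.ones(6))
        np.testing.assert_allclose(perturb(OBSERVED, uniform).values,
                                   OBSERVED.values, atol=1e-12)

    def test_worked_example_difference_matches_published_vector(self):
        pert = perturbation_difference(OBSERVED, REFERENCE)
        np.testing.assert_allclose(pert.values, PERTURBATION, atol=1e-12)
        np.testing.assert_allclose(pert.values, PRINTED_PERTURBATION, atol=2e-3)

    def test_perturbing_observed_reaches_reference(self):
        pert = perturbation_difference(OBSERVED, REFERENCE)
        np.testing.assert_allclose(perturb(OBSERVED, pert).values,
                                   REFERENCE.values, atol=2e-3)

    def test_group_action_identities(self, rng):
        comps = random_compositions(rng, 200)
        for a_row, b_row in zip(comps[:100], comps[100:]):
            a, b = Composition(a_row, PARTS), Composition(b_row, PARTS)
            np.testing.assert_allclose(
                perturb(a, perturbation_difference(a, b)).values,
                b.values, atol=1e-9)
            p = close(rng.uniform(0.1, 10, 6), PARTS)
            np.testing.assert_allclose(
                perturbation_difference(a, perturb(a, p)).values,
                p.values, atol=1e-9)

    def test_ratio_and_clr_formulations_agree(self, rng):
        comps = random_compositions(rng, 100)
        for a_row, b_row in zip(comps[:50], comps[50:]):
            a, b = Composition(a_row, PARTS), Composition(b_row, PARTS)
            via_ratio = perturbation_difference(a, b).values
            delta = clr_transform(b).values - clr_transform(a).values
            via_clr = clr_inverse(ClrVector(delta - delta.mean(), PARTS)).values
            np.testing.assert_allclose(via_ratio, via_clr, atol=1e-9)

    def test_self_difference_is_uniform(self):
        np.testing.assert_allclose(
            perturbation_difference(OBSERVED, OBSERVED).values, 1 / 6,
            atol=1e-12)

    def test_mismatched_parts_raise(self):
        other = close(np.ones(6), tuple("abcdef"))
        with pytest.raises(PartAlignmentError):
            perturb(OBSERVED, other)
        with pytest.raises(PartAlignmentError):
            perturbation_difference(OBSERVED, other)


class TestSubcomposition:
    def test_drop_filling_value(self):
        sub = subcomposition(OBSERVED, NUTRIENTS)
        assert sub.parts == NUTRIENTS
        assert sub.values.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(sub.values, OBSERVED_5PART, atol=1e-12)

    def test_keep_all_is_identity(self):
        sub = subcomposition(OBSERVED, PARTS)
        np.testing.assert_allclose(sub.values, OBSERVED.values, atol=1e-12)

    def test_unknown_or_tiny_selection_raises(self):
        with pytest.raises(PartAlignmentError):
            subcomposition(OBSERVED, ("N", "Zn"))
        with pytest.raises(CompositionError):
            subcomposition(OBSERVED, ("N",))


def brute_force_aitchison(a, b):
    """Pairwise log-ratio formula: d² = (1/2D) Σ_i Σ_j (ln(a_i/a_j) − ln(b_i/b_j))²."""
    a, b = np.asarray(a), np.asarray(b)
    d = a.size
    total = 0.0
    for i in range(d):
        for j in range(d):
            total += (np.log(a[i] / a[j]) - np.log(b[i] / b[j])) ** 2
    return np.sqrt(total / (2 * d))


class TestAitchisonDistance:
    def test_identity(self):
        assert aitchison_distance(OBSERVED, OBSERVED) == 0.0

    def test_worked_example_five_and_six_part(self):
        d5 = aitchison_distance(OBSERVED, REFERENCE)
        assert d5 == pytest.approx(DISTANCE_5PART, abs=1e-12)
        assert d5 == pytest.approx(PRINTED_DISTANCE, abs=0.02)
        assert aitchison_distance(OBSERVED, REFERENCE, parts=None) == \
            pytest.approx(DISTANCE_6PART, abs=1e-12)

    def test_metric_axioms_on_random_triples(self, rng):
        comps = random_compositions(rng, 150)
        for a_r, b_r, c_r in zip(comps[:50], comps[50:100], comps[100:]):
            a = Composition(a_r, PARTS)
            b = Composition(b_r, PARTS)
            c = Composition(c_r, PARTS)
            dab = aitchison_distance(a, b, parts=None)
            assert dab == pytest.approx(aitchison_distance(b, a, parts=None),
                                        abs=1e-12)
            assert dab > 0
            assert dab <= (aitchison_distance(a, c, parts=None)
                           + aitchison_distance(c, b, parts=None) + 1e-9)

    def test_perturbation_invariance(self, rng):
        comps = random_compositions(rng, 90)
        for a_r, b_r, c_r in zip(comps[:30], comps[30:60], comps[60:]):
            a = Composition(a_r, PARTS)
            b = Composition(b_r, PARTS)
            c = Composition(c_r, PARTS)
            before = aitchison_distance(a, b, parts=None)
            after = aitchison_distance(perturb(a, c), perturb(b, c), parts=None)
            assert after == pytest.approx(before, abs=1e-9)

    def test_agrees_with_pairwise_logratio_oracle(self, rng):
        comps = random_compositions(rng, 40)
        for a_r, b_r in zip(comps[:20], comps[20:]):
            a = Composition(a_r, PARTS)
            b = Composition(b_r, PARTS)
            assert aitchison_distance(a, b, parts=None) == pytest.approx(
                brute_force_aitchison(a_r, b_r), abs=1e-9)

    def test_too_few_parts_rejected(self):
        with pytest.raises(CompositionError):
            aitchison_distance(OBSERVED, REFERENCE, parts=("N",))


class TestRankImbalance:
    def test_worked_example_signs(self):
        q5 = clr_transform(subcomposition(OBSERVED, NUTRIENTS))
        r5 = clr_transform(subcomposition(REFERENCE, NUTRIENTS))
        ranking = rank_imbalance(ClrVector(r5.values - q5.values, NUTRIENTS))
        status = {e.part: e.status for e in ranking}
        # the reference carries relatively more K, Mg and Ca, less N and P
        assert status["K"] == "deficient"
        assert status["Mg"] == "deficient"
        assert status["Ca"] == "deficient"
        assert status["N"] == "excess"
        assert status["P"] == "excess"
        mags = [e.magnitude for e in ranking]
        assert mags == sorted(mags, reverse=True)

    def test_zero_delta_gives_empty_ranking(self):
        assert rank_imbalance(ClrVector(np.zeros(5), NUTRIENTS)) == []

    def test_inflated_component_flagged_in_excess(self):
        base = close((0.2, 0.3, 0.5), ("a", "b", "c"))
        inflated = close((0.2 * 4, 0.3, 0.5), ("a", "b", "c"))
        delta = clr_transform(base).values - clr_transform(inflated).values
        ranking = rank_imbalance(ClrVector(delta - delta.mean(), ("a", "b", "c")),
                                 parts=("a", "b", "c"))
        assert ranking[0].part == "a"
        assert ranking[0].status == "excess"


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(min_value=1e-4, max_value=1e4), min_size=2,
                max_size=10))
def test_closure_is_idempotent_and_proportional(raw):
    parts = tuple(f"p{i}" for i in range(len(raw)))
    c = close(raw, parts)
    assert c.values.sum() == pytest.approx(1.0, abs=1e-9)
    again = close(c.values, parts)
    np.testing.assert_allclose(again.values, c.values, atol=1e-12)
    ratios = c.values / np.asarray(raw)
    assert np.ptp(ratios) <= 1e-9 * ratios.max()
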