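"""Plate correction, growth scoring, and the niche set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microniche import plates, simulate
from microniche.ecoplate import PLATE_COLUMNS, WATER


def make_plate(rows):
    return pd.DataFrame(rows, columns=list(PLATE_COLUMNS))


def single_well_plate(day0, day7, blank0=0.05, blank7=0.05):
    """One culture, one substrate well plus water blanks (one replicate set)."""
    rows = []
    for rep in (1, 2, 3):
        rows += [
            ("Q1", "", "D-xylose", rep, 0, day0),
            ("Q1", "", "D-xylose", rep, 4, day0),
            ("Q1", "", "D-xylose", rep, 7, day7),
            ("Q1", "", WATER, rep, 0, blank0),
            ("Q1", "", WATER, rep, 4, blank7),
            ("Q1", "", WATER, rep, 7, blank7),
        ]
    return make_plate(rows)


class TestCorrection:
    def test_stated_subtraction_order_hand_example(self):
        # (0.60 - 0.05) - (0.10 - 0.05) = 0.50
        corrected = plates.correct_absorbance(single_well_plate(0.10, 0.60))
        cell = corrected[(corrected["source"] == "D-xylose") & (corrected["day"] == 7)]
        assert np.allclose(cell["absorbance"], 0.50)

    def test_negative_raw_clamped_before_subtraction(self):
        # a raw -0.02 is treated as 0, so day-7 correction sees 0 - blank
        corrected = plates.correct_absorbance(single_well_plate(-0.02, -0.02))
        assert (corrected["absorbance"] >= 0).all()

    def test_all_wells_equal_blank_correct_to_zero(self):
        corrected = plates.correct_absorbance(single_well_plate(0.05, 0.05))
        assert np.allclose(corrected["absorbance"], 0.0)

    def test_missing_day0_raises(self):
        bad = single_well_plate(0.1, 0.6)
        bad = bad[~((bad["source"] == "D-xylose") & (bad["day"] == 0))]
        with pytest.raises(ValueError, match="day-0"):
            plates.correct_absorbance(bad)

    def test_missing_blanks_raises(self):
        bad = single_well_plate(0.1, 0.6)
        bad = bad[bad["source"] != WATER]
        with pytest.raises(ValueError, match="water"):
            plates.correct_absorbance(bad)

    def test_corrected_nonnegative_under_noise(self, noisy_truth):
        ps = simulate.generate_plate_set(noisy_truth)
        corrected = plates.correct_absorbance(ps)
        assert (corrected["absorbance"] >= 0).all()

    def test_day_constant_shift_cancels(self, noiseless_truth):
        ps = simulate.generate_plate_set(noiseless_truth)
        shifted = ps.copy()
        shifted.loc[shifted["day"] == 7, "absorbance"] += 0.3
        a = plates.score_growth(plates.correct_absorbance(ps))
        b = plates.score_growth(plates.correct_absorbance(shifted))
        pd.testing.assert_frame_equal(a, b)

    def test_replicate_order_invariance(self, noisy_truth):
        ps = simulate.generate_plate_set(noisy_truth)
        shuffled = ps.sample(frac=1.0, random_state=0)
        a = plates.score_growth(plates.correct_absorbance(ps)).sort_index()
        b = plates.score_growth(plates.correct_absorbance(shuffled)).sort_index()
        pd.testing.assert_frame_equal(a, b[a.columns])


class TestScoring:
    def test_zero_blanks_strong_mean_is_growth(self):
        corrected = plates.correct_absorbance(single_well_plate(0.05, 0.55))
        calls = plates.score_growth(corrected)
        assert calls.loc["Q1", "D-xylose"] == 1

    def test_quantile_threshold_oracle(self):
        # blank pool {0.00, 0.01, 0.02, 0.03}: the linear-interpolation
        # 0.975 quantile is 0.02 + 0.925 * 0.01 = 0.02925 > mean value 0.02
        rows = []
        for rep, blank7 in zip((1, 2, 3, 4), (0.00, 0.01, 0.02, 0.03)):
            rows += [
                ("Q1", "", "D-xylose", rep, 0, 0.0),
                ("Q1", "", "D-xylose", rep, 7, 0.02),
                ("Q1", "", WATER, rep, 0, 0.0),
                ("Q1", "", WATER, rep, 7, blank7),
            ]
        df = make_plate(rows)
        # bypass blank-mean subtraction effects: feed as already corrected
        corrected = df.assign(context="Q1")
        assert np.quantile([0.0, 0.01, 0.02, 0.03], 0.975) == pytest.approx(0.02925)
        calls = plates.score_growth(corrected, day=7)
        assert calls.loc["Q1", "D-xylose"] == 0

    def test_strictly_greater_at_threshold(self):
        rows = []
        for rep, blank7 in zip((1, 2, 3), (0.02, 0.02, 0.02)):
            rows += [
                ("Q1", "", "D-xylose", rep, 0, 0.0),
                ("Q1", "", "D-xylose", rep, 7, 0.02),
                ("Q1", "", WATER, rep, 0, 0.0),
                ("Q1", "", WATER, rep, 7, blank7),
            ]
        corrected = make_plate(rows).assign(context="Q1")
        calls = plates.score_growth(corrected, day=7)
        assert calls.loc["Q1", "D-xylose"] == 0  # tie is not growth

    def test_too_few_blanks_raises(self):
        rows = [
            ("Q1", "", "D-xylose", 1, 0, 0.0),
            ("Q1", "", "D-xylose", 1, 7, 0.5),
            ("Q1", "", WATER, 1, 0, 0.0),
            ("Q1", "", WATER, 1, 7, 0.0),
        ]
        corrected = make_plate(rows).assign(context="Q1")
        with pytest.raises(ValueError, match="blank"):
            plates.score_growth(corrected, day=7)

    def test_noiseless_calls_equal_truth(self, noiseless_truth, noiseless_calls):
        truth = simulate.truth_niche_frame(noiseless_truth)
        got = noiseless_calls.loc[truth.index, truth.columns].to_numpy()
        assert np.array_equal(got, truth.to_numpy())


class TestSetAlgebra:
    A = frozenset({"c1", "c2"})
    B = frozenset({"c2", "c3"})

    def test_expected_niche(self):
        assert plates.expected_niche(self.A, self.B) == {"c2"}
        assert plates.expected_niche(self.A, self.A) == self.A
        assert plates.expected_niche(self.A, frozenset({"c9"})) == frozenset()

    def test_expansion_variants(self):
        O3 = frozenset({"c1", "c2", "c3"})
        O4 = frozenset({"c1", "c2", "c3", "c4"})
        assert plates.niche_expansion(self.A, self.B, O3, "printed") == {"c1", "c3"}
        assert plates.niche_expansion(self.A, self.B, O4, "printed") == {"c1", "c3"}
        assert plates.niche_expansion(self.A, self.B, O4, "extended") == {"c1", "c3", "c4"}
        both = frozenset({"c2"})  # O = A ∩ B
        for variant in plates.EXPANSION_VARIANTS:
            assert plates.niche_expansion(self.A, self.B, both, variant) == frozenset()

    def test_overlap_index(self):
        a = frozenset({"s1", "s2", "s3"})
        b = frozenset({"s2", "s3", "s4"})
        assert plates.niche_overlap_index(a, b) == pytest.approx(0.5)
        assert plates.niche_overlap_index(a, a) == 1.0
        assert plates.niche_overlap_index(a, frozenset({"x"})) == 0.0
        assert np.isnan(plates.niche_overlap_index(frozenset(), frozenset()))

    def test_classification(self):
        expected = self.A & self.B
        assert plates.classify_pair(self.A, self.B, expected) == plates.CLASS_EXPECTED
        assert (
            plates.classify_pair(self.A, self.B, expected | {"c1"})
            == plates.CLASS_EXPANSION
        )
        assert plates.classify_pair(self.A, self.B, frozenset()) == plates.CLASS_OTHER

    def test_community_emergence(self):
        members = [self.A, self.B]
        union = self.A | self.B
        assert plates.community_emergence(union, members) == frozenset()
        assert plates.community_emergence(union | {"new"}, members) == {"new"}

    def test_community_emergence_synthetic_recovery(self):
        truth = simulate.default_community_truth(seed=21, blank_sd=0.0,
                                                 n_strains=4, n_sources=12)
        unused = sorted(
            set(range(12)) - {
                s for i in range(4) for s in np.flatnonzero(truth.true_niche[i])
            }
        )
        assert unused, "need a community-only source for this check"
        extra = (unused[0],)
        ps = simulate.generate_plate_set(
            truth, include_community=True, community_extra_sources=extra
        )
        calls = plates.score_growth(plates.correct_absorbance(ps))
        community = plates.niche_set(calls.loc["ALL"])
        members = [plates.niche_set(calls.loc[s]) for s in truth.strain_ids]
        expected = {truth.source_names[extra[0]]}
        assert plates.community_emergence(community, members) == expected


class TestSummaries:
    def test_all_expected_pairs(self):
        a = frozenset({"c1"})
        results = [
            plates.PairNicheResult(("Q1", "Q2"), a, a, frozenset(), frozenset(),
                                   1.0, plates.CLASS_EXPECTED)
        ]
        summary = plates.summarize_deformation(results)
        assert summary["fractions"][plates.CLASS_EXPECTED] == 1.0
        assert summary["mean_expansion_sources"] == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            plates.summarize_deformation([])

    def test_noiseless_pair_results_match_truth(self, noiseless_truth,
                                                noiseless_calls):
        results = plates.pair_niche_results(noiseless_calls)
        by_pair = {r.pair: r for r in results}
        names = np.array(noiseless_truth.source_names)
        niche = noiseless_truth.true_niche
        sids = noiseless_truth.strain_ids
        for i, j in noiseless_truth.pairs():
            r = by_pair[tuple(sorted((sids[i], sids[j])))]
            a = set(names[np.flatnonzero(niche[i])])
            b = set(names[np.flatnonzero(niche[j])])
            observed = {names[s] for s in noiseless_truth.pair_observed(i, j)}
            injected = {
                names[s] for (p, s) in noiseless_truth.pair_expansion if p == (i, j)
            }
            # printed formula sees exactly the symmetric difference; the
            # extended variant additionally recovers gains outside A ∪ B
            assert r.expansion_set_printed == (a ^ b)
            assert r.expansion_set_extended == (a ^ b) | (injected - (a | b))
            assert r.observed_set == observed


@given(
    st.tuples(
        st.integers(min_value=0, max_value=2**10 - 1),
        st.integers(min_value=0, max_value=2**10 - 1),
        st.integers(min_value=0, max_value=2**10 - 1),
    )
)
def test_set_algebra_invariants(masks):
    """Expansion sets exclude the expected niche, extended contains printed,
    both sit inside O, and the overlap index is a symmetric Jaccard."""
    universe = [f"s{i}" for i in range(10)]
    a, b, o = (
        frozenset(s for i, s in enumerate(universe) if m >> i & 1) for m in masks
    )
    expected = plates.expected_niche(a, b)
    printed = plates.niche_expansion(a, b, o, "printed")
    extended = plates.niche_expansion(a, b, o, "extended")
    assert printed & expected == frozenset()
    assert extended & expected == frozenset()
    assert printed <= extended <= o
    ov_ab = plates.niche_overlap_index(a, b)
    ov_ba = plates.niche_overlap_index(b, a)
    if a or b:
        assert 0.0 <= ov_ab <= 1.0
        assert ov_ab == ov_ba
        assert (ov_ab == 1.0) == (a == b)
        assert (ov_ab == 0.0) == (not a & b)
    else:
        assert np.isnan(ov_ab) and np.isnan(ov_ba)
    cls = plates.classify_pair(a, b, o)
    if o == expected:
        assert cls == plates.CLASS_EXPECTED
    elif expected <= o and printed:
        assert cls == plates.CLASS_EXPANSION
    else:
        assert cls == plates.CLASS_OTHER
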