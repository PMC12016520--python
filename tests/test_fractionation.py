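"""Fractionation algebra: δ/ε notation, weighted means, ring indices,
ring differences."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpiso import (
    IsotopeValue,
    abundance_weighted_mean,
    delta_bp_from_epsilon,
    delta_from_ratio,
    epsilon_lw,
    ratio_from_delta,
    ring_difference,
    ring_epsilon_slope,
    ring_index_bp,
    ring_index_gdgt,
    weighted_mean,
)
from bpiso.exceptions import BpisoError


def iso(v, s=0.0, n=1):
    return IsotopeValue(v, s, n)


class TestDeltaNotation:
    def test_equal_ratios_give_zero(self):
        assert delta_from_ratio(1.5e-4, 1.5e-4) == 0.0

    def test_minus_500_permil_is_half_the_standard_ratio(self):
        assert ratio_from_delta(-500.0, 1.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("delta", [-999.0, -204.0, 0.0, 350.0])
    def test_round_trip_identity(self, delta):
        r = ratio_from_delta(delta, 1.55746e-4)
        assert delta_from_ratio(r, 1.55746e-4) == pytest.approx(delta, abs=1e-12)

    def test_non_positive_ratio_rejected(self):
        with pytest.raises(ValueError):
            delta_from_ratio(-1.0, 1.0)
        with pytest.raises(ValueError):
            ratio_from_delta(-1000.0)


class TestEpsilon:
    @pytest.mark.parametrize(
        "d_bp, d_w, expected",
        [
            # published worked cells: e-donor 7 h BP-0 and pH 2 BP-0
            (-280.0, -59.7, -234.3),
            (-258.0, -59.8, -210.8),
        ],
    )
    def test_published_worked_cells(self, d_bp, d_w, expected):
        eps = epsilon_lw(iso(d_bp), iso(d_w))
        assert eps.value == pytest.approx(expected, abs=0.05)

    def test_identical_deltas_give_zero(self):
        assert epsilon_lw(iso(-59.7), iso(-59.7)).value == 0.0

    @given(
        d_bp=st.floats(-600, 200),
        d_w=st.floats(-200, 100),
        eps=st.floats(-500, 100),
    )
    @settings(max_examples=50, derandomize=True)
    def test_epsilon_inversion_and_monotonicity(self, d_bp, d_w, eps):
        # delta_bp_from_epsilon is the exact inverse
        e = epsilon_lw(iso(d_bp), iso(d_w)).value
        assert delta_bp_from_epsilon(e, d_w) == pytest.approx(d_bp, abs=1e-9)
        # ε strictly increasing in δ_BP at fixed δ_W
        e_hi = epsilon_lw(iso(d_bp + 1.0), iso(d_w)).value
        assert e_hi > e

    def test_sigma_propagation_first_order(self):
        # against a numeric Jacobian
        eps = epsilon_lw(iso(-280.0, 3.0), iso(-59.7, 0.5))
        h = 1e-6
        de_db = (
            epsilon_lw(iso(-280.0 + h), iso(-59.7)).value
            - epsilon_lw(iso(-280.0 - h), iso(-59.7)).value
        ) / (2 * h)
        de_dw = (
            epsilon_lw(iso(-280.0), iso(-59.7 + h)).value
            - epsilon_lw(iso(-280.0), iso(-59.7 - h)).value
        ) / (2 * h)
        expected = math.hypot(de_db * 3.0, de_dw * 0.5)
        assert eps.sigma == pytest.approx(expected, rel=1e-6)

    def test_water_at_minus_1000_rejected(self):
        with pytest.raises(ValueError):
            epsilon_lw(iso(-280.0), iso(-1000.0))


class TestWeightedMean:
    def test_single_value_unchanged(self):
        v = iso(-204.0, 3.0, 5)
        assert weighted_mean([v]) is v

    def test_unequal_sigma_oracle(self):
        # hand-computed: weights 1 and 0.01
        wm = weighted_mean([iso(-200.0, 1.0), iso(-100.0, 10.0)])
        assert wm.value == pytest.approx((-200.0 * 1 + -100.0 * 0.01) / 1.01)

    def test_equal_sigma_reduces_to_arithmetic_mean(self):
        wm = weighted_mean([iso(-200.0, 2.0), iso(-210.0, 2.0)])
        assert wm.value == pytest.approx(-205.0)
        # error rule: at least the replicate scatter (sample SD ≈ 7.07)
        assert wm.sigma >= np.std([-200, -210], ddof=1) - 1e-6

    @given(
        values=st.lists(st.floats(-300, -100), min_size=2, max_size=8),
        sigma=st.floats(0.5, 10.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_equal_weights_match_mean_and_sigma_never_below_propagated(
        self, values, sigma
    ):
        wm = weighted_mean([iso(v, sigma) for v in values])
        assert wm.value == pytest.approx(np.mean(values), abs=1e-9)
        assert wm.sigma >= sigma / math.sqrt(len(values)) - 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            weighted_mean([])


class TestAbundanceWeightedMean:
    def test_published_75C_cell(self):
        eps = {r: iso(v) for r, v in zip(range(4), [-220.0, -214.0, -226.0, -227.0])}
        wm = abundance_weighted_mean({0: 0.06, 1: 0.13, 2: 0.60, 3: 0.21}, eps)
        assert round(wm.value) == -224

    def test_equal_values_any_abundances(self):
        eps = {r: iso(-200.0) for r in range(4)}
        wm = abundance_weighted_mean({0: 0.7, 1: 0.1, 2: 0.1, 3: 0.1}, eps)
        assert wm.value == pytest.approx(-200.0)

    def test_threshold_excludes_minor_moiety(self):
        with pytest.warns(UserWarning, match="excluded"):
            wm = abundance_weighted_mean(
                {0: 0.97, 1: 0.03}, {0: iso(-200.0), 1: iso(-100.0)}
            )
        assert wm.value == pytest.approx(-200.0)

    def test_nothing_passing_threshold_is_an_error(self):
        with pytest.warns(UserWarning), pytest.raises(BpisoError):
            abundance_weighted_mean({0: 0.04, 1: 0.03}, {0: iso(-200.0)})

    def test_missing_value_excluded_and_renormalized(self):
        # BP-3 present in abundance but n.d. in isotopes
        eps = {0: iso(-230.0), 1: iso(-220.0), 2: iso(-210.0)}
        with pytest.warns(UserWarning):
            wm = abundance_weighted_mean({0: 0.2, 1: 0.3, 2: 0.4, 3: 0.1}, eps)
        expected = (0.2 * -230 + 0.3 * -220 + 0.4 * -210) / 0.9
        assert wm.value == pytest.approx(expected)


class TestRingIndex:
    @pytest.mark.parametrize(
        "abundances, expected",
        [
            ((0.31, 0.39, 0.28, 0.02), 1.01),  # published: e-donor 7 h
            ((0.18, 0.31, 0.36, 0.15), 1.48),  # published: pH 2
            ((1, 0, 0, 0), 0.0),
            ((0, 0, 0, 1), 3.0),
        ],
    )
    def test_bp_ring_index(self, abundances, expected):
        assert ring_index_bp(abundances) == pytest.approx(expected, abs=1e-9)

    def test_gdgt_ring_index(self):
        one_hot = [0.0] * 9
        one_hot[4] = 1.0
        assert ring_index_gdgt(one_hot) == 4.0
        assert ring_index_gdgt([1 / 9] * 9) == pytest.approx(4.0)
        mixed = [0, 0.5, 0, 0.5, 0, 0, 0, 0, 0]
        assert ring_index_gdgt(mixed) == pytest.approx(2.0)

    @given(
        raw=st.lists(st.floats(0.01, 5.0), min_size=4, max_size=4),
        scale=st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance(self, raw, scale):
        assert ring_index_bp(raw) == pytest.approx(
            ring_index_bp([scale * a for a in raw]), rel=1e-9
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ring_index_bp([0, 0, 0, 0])


def brute_force_ring_difference(eps: dict) -> dict:
    """Independent oracle: enumerate every (X, Y) pair, X > Y."""
    out = {}
    rings = sorted(eps)
    for x in rings:
        pairs = [
            (eps[x].value - eps[y].value) / (x - y) for y in rings if y < x
        ]
        if pairs:
            out[x] = sum(pairs) / len(pairs)
    return out


class TestRingDifference:
    def test_published_td21_row(self):
        eps = {r: iso(v) for r, v in zip(range(4), [-214.0, -214.0, -210.0, -189.0])}
        rd = ring_difference(eps)
        assert {r: round(v.value) for r, v in rd.items()} == {0: 0, 1: 0, 2: 3, 3: 14}
        assert rd[3].value == pytest.approx(np.mean([25 / 3, 25 / 2, 21.0]))

    def test_published_td7_row(self):
        eps = {r: iso(v) for r, v in zip(range(4), [-234.0, -230.0, -226.0, -205.0])}
        rd = ring_difference(eps)
        assert {r: round(v.value) for r, v in rd.items()} == {0: 0, 1: 4, 2: 4, 3: 14}

    def test_equal_eps_all_zero(self):
        eps = {r: iso(-210.0) for r in range(4)}
        assert all(v.value == 0.0 for v in ring_difference(eps).values())

    def test_single_moiety_warns_empty(self):
        with pytest.warns(UserWarning):
            assert ring_difference({0: iso(-210.0)}) == {}

    @given(
        values=st.lists(
            st.floats(-260, -160), min_size=2, max_size=4, unique=True
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_brute_force_oracle(self, values):
        eps = {r: iso(v) for r, v in enumerate(values)}
        got = {r: v.value for r, v in ring_difference(eps).items() if r > 0}
        expected = brute_force_ring_difference(eps)
        assert got == pytest.approx(expected)


class TestRingSlope:
    def test_matches_published_chemostat_summary_cells(self):
        # treatment-level mean ring difference = slope of ε on ring number
        rows = {
            7: ([-234.0, -230.0, -226.0, -205.0], 9),
            21: ([-214.0, -214.0, -210.0, -189.0], 8),
            44: ([-214.0, -207.0, -202.0, -199.0], 5),
        }
        for td, (eps_vals, printed) in rows.items():
            eps = {r: iso(v) for r, v in enumerate(eps_vals)}
            assert round(ring_epsilon_slope(eps).value) == printed

    def test_missing_moiety_slope(self):
        # 65°C row: BP-3 n.d., slope over rings 0..2
        eps = {r: iso(v) for r, v in zip(range(3), [-195.0, -193.0, -205.0])}
        assert round(ring_epsilon_slope(eps).value) == -5

    def test_two_moieties_reduce_to_pairwise(self):
        eps = {0: iso(-230.0), 2: iso(-210.0)}
        assert ring_epsilon_slope(eps).value == pytest.approx(10.0)
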