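"""Gini/Lorenz/Theil measures: exact examples, identities, property tests."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equidea.equity import (
    ShareVector,
    contribution_rates,
    equality_band,
    gini_hoover,
    gini_lorenz,
    lorenz_points,
    make_shares,
    theil,
    theil_decompose,
)
from equidea.synthetic import PanelSpec, gen_panel, gen_share_vector


def sv(X, Y=None):
    X = np.asarray(X, dtype=float)
    Y = np.full(X.size, 1.0 / X.size) if Y is None else np.asarray(Y, dtype=float)
    return ShareVector(tuple(f"u{i}" for i in range(X.size)), X, Y)


# -- random share vectors for property tests, derandomised via fixed seeds --
share_vectors = st.builds(
    gen_share_vector,
    n=st.integers(3, 40),
    concentration=st.floats(0.2, 50.0),
    seed=st.integers(0, 10_000),
    base_concentration=st.one_of(st.none(), st.floats(1.0, 50.0)),
)


class TestGini:
    def test_perfect_equality_is_zero(self):
        s = sv([0.25] * 4)
        assert gini_hoover(s).value == 0.0
        assert gini_lorenz(s).value == 0.0

    def test_hoover_two_unit_half(self):
        s = sv([1.0, 0.0], [0.5, 0.5])
        assert gini_hoover(s).value == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [2, 5, 31])
    def test_single_holder_closed_form(self, n):
        X = np.zeros(n)
        X[-1] = 1.0
        assert gini_lorenz(sv(X)).value == pytest.approx(1 - 1 / n)

    @given(shares=share_vectors)
    @settings(max_examples=200, deadline=None)
    def test_hoover_equals_max_lorenz_gap(self, shares):
        pts = np.array(lorenz_points(shares).points)
        max_gap = np.max(pts[:, 0] - pts[:, 1])
        assert gini_hoover(shares).value == pytest.approx(max_gap, abs=1e-12)

    @given(shares=share_vectors)
    @settings(max_examples=200, deadline=None)
    def test_hoover_never_exceeds_lorenz_gini(self, shares):
        assert gini_hoover(shares).value <= gini_lorenz(shares).value + 1e-12

    @given(shares=share_vectors)
    @settings(max_examples=100, deadline=None)
    def test_lorenz_gini_matches_pairwise_oracle(self, shares):
        """O(n^2) oracle: G = ½ ΣΣ Y_i Y_j |r_i − r_j| with r = X/Y."""
        r = shares.X / shares.Y
        G = 0.5 * np.sum(
            shares.Y[:, None] * shares.Y[None, :] * np.abs(r[:, None] - r[None, :])
        )
        assert gini_lorenz(shares).value == pytest.approx(G, abs=1e-10)

    @given(shares=share_vectors)
    @settings(max_examples=100, deadline=None)
    def test_scale_and_permutation_invariance(self, shares):
        perm = np.random.default_rng(0).permutation(shares.k)
        permuted = ShareVector(
            tuple(shares.units[i] for i in perm), shares.X[perm], shares.Y[perm]
        )
        assert gini_lorenz(permuted).value == pytest.approx(gini_lorenz(shares).value)
        assert gini_hoover(permuted).value == pytest.approx(gini_hoover(shares).value)

    def test_pigou_dalton_transfer_never_increases_inequality(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            shares = gen_share_vector(12, concentration=1.0, seed=int(rng.integers(1e6)))
            r = shares.X / shares.Y
            rich, poor = int(np.argmax(r)), int(np.argmin(r))
            delta = 0.25 * (shares.X[rich] - shares.X[poor] * shares.Y[rich] / shares.Y[poor])
            delta = min(delta, 0.5 * shares.X[rich])
            if delta <= 0:
                continue
            X2 = shares.X.copy()
            X2[rich] -= delta
            X2[poor] += delta
            after = ShareVector(shares.units, X2, shares.Y)
            assert gini_lorenz(after).value <= gini_lorenz(shares).value + 1e-12
            if np.all(shares.X > 0):
                assert theil(after) <= theil(shares) + 1e-12

    def test_band_edges_are_half_open(self):
        assert equality_band(0.19) == "absolute equality"
        assert equality_band(0.2) == "relative equality"
        assert equality_band(0.3) == "proper equality"
        assert equality_band(0.4) == "relative inequality"
        assert equality_band(0.5) == "serious inequality"


class TestLorenzCurve:
    def test_diagonal_under_equality(self):
        pts = np.array(lorenz_points(sv([0.2] * 5)).points)
        assert np.allclose(pts[:, 0], pts[:, 1])

    def test_degenerate_concentration(self):
        pts = lorenz_points(sv([1.0, 0.0], [0.5, 0.5])).points
        assert pts == ((0.0, 0.0), (0.5, 0.0), (1.0, 1.0))

    @given(shares=share_vectors)
    @settings(max_examples=100, deadline=None)
    def test_curve_is_convex_and_below_diagonal(self, shares):
        pts = np.array(lorenz_points(shares).points)
        dx = np.diff(pts[:, 0])
        dy = np.diff(pts[:, 1])
        slopes = dy / dx
        assert np.all(np.diff(slopes) >= -1e-9)
        assert np.all(pts[:, 1] <= pts[:, 0] + 1e-12)


class TestTheil:
    def test_equal_shares_zero(self):
        assert theil(sv([0.25] * 4)) == pytest.approx(0.0)

    def test_two_term_hand_value(self):
        # P=(0.5,0.5), resource=(0.25,0.75): 0.5 ln2 + 0.5 ln(2/3)
        s = sv([0.25, 0.75], [0.5, 0.5])
        assert theil(s) == pytest.approx(0.143841, abs=1e-6)

    def test_merging_proportional_units_preserves_index(self):
        a = sv([0.2, 0.2, 0.6], [0.25, 0.25, 0.5])
        b = sv([0.4, 0.6], [0.5, 0.5])
        assert theil(a) == pytest.approx(theil(b))

    def test_zero_resource_share_raises_with_unit_name(self):
        with pytest.raises(ValueError, match="u1"):
            theil(sv([1.0, 0.0], [0.5, 0.5]))


class TestDecomposition:
    @pytest.mark.parametrize("seed", range(10))
    def test_additivity_on_random_grouped_panels(self, seed):
        p = gen_panel(PanelSpec(seed=seed, years=(2013,)))
        shares = make_shares(p, 2013, "beds", "population")
        dec = theil_decompose(p, 2013, "beds", "population")
        assert dec.T_intra + dec.T_inter == pytest.approx(theil(shares), abs=1e-10)
        assert dec.contribution_intra + dec.contribution_inter == pytest.approx(1.0, abs=1e-10)

    def test_homogeneous_groups_have_zero_within(self):
        spec = PanelSpec(
            group_sizes={"eastern": 3, "middle": 3, "western": 3},
            years=(2013,),
            sigmas={k: 0.0 for k in PanelSpec().sigmas},
            seed=0,
        )
        dec = theil_decompose(gen_panel(spec), 2013, "beds", "population")
        assert dec.T_intra == pytest.approx(0.0, abs=1e-12)
        assert dec.T == pytest.approx(dec.T_inter, abs=1e-12)

    def test_single_group_has_zero_between(self, small_panel):
        grouping = {d: "all" for d in small_panel.dmus}
        dec = theil_decompose(small_panel, 2013, "staff", grouping=grouping)
        assert dec.T_inter == pytest.approx(0.0, abs=1e-12)

    def test_ungrouped_dmu_raises(self, small_panel):
        grouping = {d: "g" for d in small_panel.dmus[:-1]}
        with pytest.raises(ValueError, match="group"):
            theil_decompose(small_panel, 2013, "beds", grouping=grouping)


class TestContributionRates:
    def test_constant_ratio_mean(self, small_panel):
        dec = theil_decompose(small_panel, 2013, "beds")
        assert contribution_rates([dec, dec]) == pytest.approx(dec.contribution_intra)

    def test_pooled_mode_differs_from_mean_of_ratios(self):
        d1 = _fake_dec(T=0.2, intra=0.1)
        d2 = _fake_dec(T=0.1, intra=0.09)
        assert contribution_rates([d1, d2]) == pytest.approx((0.5 + 0.9) / 2)
        assert contribution_rates([d1, d2], mode="pooled") == pytest.approx(0.19 / 0.3)

    def test_zero_total_years_excluded(self):
        good = _fake_dec(T=0.2, intra=0.1)
        degenerate = _fake_dec(T=0.0, intra=0.0)
        assert contribution_rates([good, degenerate]) == pytest.approx(0.5)


def _fake_dec(T, intra):
    from equidea.equity import TheilDecomposition

    return TheilDecomposition(T=T, T_intra=intra, T_inter=T - intra, group_terms=())


def test_make_shares_two_dmu_arithmetic(small_panel):
    recs = small_panel.year_records(2013)[:2]
    from equidea.panel import ResourcePanel

    mini = ResourcePanel(
        tuple(
            dataclasses.replace(r, inputs={**r.inputs, "beds": b}, population=1000.0)
            for r, b in zip(recs, (3.0, 1.0))
        )
    )
    s = make_shares(mini, 2013, "beds", "population")
    assert np.allclose(s.X, [0.75, 0.25])
    assert np.allclose(s.Y, [0.5, 0.5])
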