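"""Response functions, information, and likelihoods of the IRT layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import catirt as ct
from catirt.models import CategoryIndexError, ResponseDataError


def item(a=1.0, b=(0.0,), model="GRM"):
    return ct.ItemParameters("x", a, tuple(np.atleast_1d(b)), model)


class TestItemParameters:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            item(a=-1.0)
        with pytest.raises(ValueError):
            item(b=(1.0, 0.5))  # unordered thresholds
        with pytest.raises(ValueError):
            item(b=())
        with pytest.raises(ValueError):
            ct.ItemBank((item(), item()))  # duplicate ids

    def test_dichotomous_is_k2(self):
        assert item().n_categories == 2
        assert item(b=(-1, 0, 1)).n_categories == 4


class TestCumulativeProbability:
    @pytest.mark.parametrize(
        "a,b,theta,expected",
        [
            (1.0, 0.0, 0.0, 0.5),
            (0.818, 2.436, 2.436, 0.5),  # bank item 1 at theta = b
        ],
    )
    def test_half_at_threshold(self, a, b, theta, expected):
        assert ct.cumulative_probability(item(a, (b,)), theta, 1) == pytest.approx(expected)

    def test_saturation(self):
        assert ct.cumulative_probability(item(), 10.0, 1) > 1 - 1e-7
        assert ct.cumulative_probability(item(), -10.0, 1) < 1e-7

    def test_category_index_bounds(self):
        it = item(b=(-1, 0, 1, 2))
        with pytest.raises(CategoryIndexError):
            ct.cumulative_probability(it, 0.0, 0)
        with pytest.raises(CategoryIndexError):
            ct.cumulative_probability(it, 0.0, 5)

    def test_monotone_in_t_and_theta(self, narc_bank):
        it = narc_bank.get("71")
        thetas = np.linspace(-4, 4, 30)
        curves = np.array(
            [[ct.cumulative_probability(it, t, k) for t in thetas] for k in range(1, 5)]
        )
        assert (np.diff(curves, axis=0) <= 0).all()  # decreasing in category
        assert (np.diff(curves, axis=1) > 0).all()  # increasing in theta


class TestCategoryProbabilities:
    def test_k2_midpoint(self):
        assert ct.category_probabilities(item(), 0.0) == pytest.approx([0.5, 0.5])

    def test_item71_matches_direct_cumulative_differences(self, narc_bank):
        """Independent oracle: hand-coded differences of the cumulative curves."""
        it = narc_bank.get("71")
        theta, D = 0.0, narc_bank.D
        star = [1.0] + [expit(D * it.a * (theta - bt)) for bt in it.b] + [0.0]
        expected = np.array([star[t] - star[t + 1] for t in range(5)])
        got = ct.category_probabilities(it, theta)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_floor_category_at_minus_infinity(self, narc_bank):
        probs = ct.category_probabilities(narc_bank.get("71"), -30.0)
        assert probs[0] == pytest.approx(1.0, abs=1e-10)
        assert probs[1:] == pytest.approx(np.zeros(4), abs=1e-10)

    @settings(max_examples=200, derandomize=True)
    @given(
        a=st.floats(0.2, 3.0),
        b1=st.floats(-3, 3),
        gaps=st.lists(st.floats(0.01, 2.0), min_size=0, max_size=4),
        theta=st.floats(-6, 6),
        model=st.sampled_from(["GRM", "GPCM", "PCM"]),
    )
    def test_probabilities_form_a_distribution(self, a, b1, gaps, theta, model):
        b = tuple(b1 + np.concatenate([[0], np.cumsum(gaps)]))
        probs = ct.category_probabilities(item(a, b, model), theta)
        assert probs.shape == (len(b) + 1,)
        assert (probs >= 0).all() and (probs <= 1).all()
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestItemInformation:
    def test_k2_closed_form(self):
        # D^2 a^2 P(1-P) at P = 0.5
        assert ct.item_information(item(1.0), 0.0) == pytest.approx(1.702**2 * 0.25)
        assert ct.item_information(item(2.0), 0.0) == pytest.approx(4 * 1.702**2 * 0.25)

    def test_grm_k2_identical_to_2pl(self):
        it = item(1.3, (0.4,))
        thetas = np.linspace(-4, 4, 50)
        p = expit(1.702 * 1.3 * (thetas - 0.4))
        assert np.allclose(
            ct.item_information(it, thetas), 1.702**2 * 1.3**2 * p * (1 - p), atol=1e-15
        )
        assert np.allclose(ct.category_probabilities(it, thetas)[1], p, atol=1e-15)

    def test_polytomous_matches_finite_difference_oracle(self, narc_bank):
        """Fisher information as sum_t P'_t^2 / P_t with numeric derivatives."""
        it = narc_bank.get("71")
        h = 1e-5
        for theta in np.linspace(-3, 3, 13):
            p_plus = ct.category_probabilities(it, theta + h)
            p_minus = ct.category_probabilities(it, theta - h)
            p = ct.category_probabilities(it, theta)
            dp = (p_plus - p_minus) / (2 * h)
            oracle = float((dp**2 / p).sum())
            assert ct.item_information(it, theta) == pytest.approx(oracle, abs=1e-4)

    def test_nonnegative_everywhere(self, narc_bank):
        thetas = np.linspace(-6, 6, 40)
        for it in narc_bank:
            assert (ct.item_information(it, thetas) >= 0).all()


class TestTestInformation:
    def test_additivity_and_empty_subset(self):
        bank = ct.ItemBank((item(1.5, (0.3,)), ct.ItemParameters("y", 1.5, (0.3,))))
        single = ct.item_information(bank[0], 0.7, D=bank.D)
        assert ct.test_information(bank, 0.7) == pytest.approx(2 * single)
        assert ct.test_information(bank, 0.7, subset=[]) == 0.0

    def test_matches_per_item_loop(self, narc_bank):
        theta = 1.5
        oracle = sum(ct.item_information(it, theta, D=narc_bank.D) for it in narc_bank)
        assert ct.test_information(narc_bank, theta) == pytest.approx(oracle, rel=1e-12)


class TestReliabilityIdentities:
    @pytest.mark.parametrize("info,rho", [(10.0, 0.9), (1.0, 0.0), (4.0, 0.75)])
    def test_reliability_from_information(self, info, rho):
        assert ct.reliability_from_information(info) == pytest.approx(rho)

    def test_se_from_information(self):
        assert ct.se_from_information(4.0) == pytest.approx(0.5)

    def test_domain_errors(self):
        for bad in (0.0, -1.0):
            with pytest.raises(ValueError):
                ct.reliability_from_information(bad)
            with pytest.raises(ValueError):
                ct.se_from_information(bad)

    def test_trait_estimate_identity(self):
        est = ct.TraitEstimate(0.3, 0.5)
        assert est.reliability == 1 - 0.5**2


class TestLogLikelihood:
    def test_single_cell(self):
        bank = ct.ItemBank((item(),))
        assert ct.log_likelihood([[1]], bank, [0.0]) == pytest.approx(np.log(0.5))

    def test_all_missing_row_contributes_zero(self):
        bank = ct.ItemBank((item(),))
        ll = ct.log_likelihood([[1], [-1]], bank, [0.0, 0.0])
        assert ll == pytest.approx(np.log(0.5))

    def test_matches_cell_by_cell_summation(self, small_bank):
        rng = np.random.default_rng(4)
        resp = np.column_stack(
            [rng.integers(0, it.n_categories, 5) for it in small_bank.items[:3]]
        )
        bank3 = ct.ItemBank(small_bank.items[:3])
        thetas = rng.normal(size=5)
        oracle = sum(
            np.log(ct.category_probabilities(bank3[j], thetas[i], D=bank3.D)[resp[i, j]])
            for i in range(5)
            for j in range(3)
        )
        assert ct.log_likelihood(resp, bank3, thetas) == pytest.approx(oracle)

    def test_out_of_range_category_names_item_and_row(self):
        bank = ct.ItemBank((item(),))
        with pytest.raises(ResponseDataError, match="item x.*row 1"):
            ct.log_likelihood([[0], [2]], bank, [0.0, 0.0])


class TestQuadratureGrid:
    def test_weights_normalised_nodes_increasing(self):
        g = ct.QuadratureGrid.standard_normal(101)
        assert g.weights.sum() == pytest.approx(1.0)
        assert (np.diff(g.nodes) > 0).all()
        with pytest.raises(ValueError):
            ct.QuadratureGrid(np.array([0.0, 0.0]), np.array([0.5, 0.5]))

    def test_posterior_variance_never_exceeds_prior_variance(self, narc_bank):
        rng = np.random.default_rng(9)
        prior_var = float(
            ct.DEFAULT_GRID.weights @ ct.DEFAULT_GRID.nodes**2
        )
        from conftest import random_response_pattern

        for _ in range(25):
            ids, resp = random_response_pattern(narc_bank, rng)
            est = ct.eap_estimate(narc_bank, ids, resp)
            assert est.se**2 <= prior_var + 1e-12
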