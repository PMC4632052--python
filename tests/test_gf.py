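"""The GF estimator: point estimates, confidence limits, edge cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flucrate.dataset import FluctuationDataset
from flucrate.exceptions import (
    EstimationError,
    InvalidParameterError,
    UnidentifiableError,
)
from flucrate.gf import (
    GFConfig,
    compute_ci,
    empirical_pgf,
    estimate,
    estimate_b,
    estimate_m,
)
from flucrate.ld_model import mutant_count_cdf
from flucrate.simulate import sample_counts


def perfect_sample(m: float, b: float, n: int = 100_000, nmax: int = 4096) -> np.ndarray:
    """Counts whose empirical distribution equals the model pmf to O(1/n).

    Inverse-CDF at the mid-quantiles (i + 1/2)/n — a deterministic 'perfect
    sample' that turns consistency into a numeric fixed-point check.
    """
    cdf = mutant_count_cdf(m, b, nmax)
    u = (np.arange(n) + 0.5) / n
    return np.searchsorted(cdf, u).astype(np.int64)


class TestEmpiricalPgf:
    def test_direct_arithmetic(self):
        assert empirical_pgf([0, 0, 0], 0.3) == 1.0
        assert empirical_pgf([1], 0.5) == 0.5
        assert empirical_pgf([0, 1, 2, 4], 0.5) == pytest.approx(0.453125)

    def test_zero_to_the_zero_is_one(self):
        assert empirical_pgf([0, 3], 0.0) == pytest.approx(0.5)

    @given(
        counts=st.lists(st.integers(0, 10_000), min_size=1, max_size=50),
        s=st.floats(0.0, 1.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounded_and_permutation_invariant(self, counts, s):
        g = empirical_pgf(counts, s)
        assert 0.0 <= g <= 1.0
        assert empirical_pgf(counts[::-1], s) == pytest.approx(g)


class TestEstimateB:
    @pytest.mark.parametrize("b_true", [0.5, 1.0])
    def test_consistency_on_large_simulated_assays(self, b_true, rng):
        counts = sample_counts(4.0, b_true, 1.0, 50_000, rng)
        b_hat = estimate_b(counts)
        assert b_hat == pytest.approx(b_true, rel=0.03)

    def test_all_zero_counts_unidentifiable(self):
        with pytest.raises(UnidentifiableError):
            estimate_b([0, 0, 0])

    def test_out_of_bracket_ratio_reported(self):
        # a single enormous jackpot among zeros pushes the log-PGF ratio
        # outside the model range for any b in the bracket
        with pytest.raises(EstimationError):
            estimate_b([0] * 50 + [10_000_000], GFConfig(b_min=0.9, b_max=1.1))


class TestEstimateM:
    def test_all_zero_counts_give_zero(self):
        assert estimate_m([0, 0, 0, 0], b=1.0) == 0.0

    def test_consistency_on_large_simulated_assay(self, rng):
        counts = sample_counts(2.0, 1.0, 1.0, 50_000, rng)
        assert estimate_m(counts, b=1.0) == pytest.approx(2.0, abs=0.06)

    @pytest.mark.parametrize("m,b", [(1.0, 1.0), (4.0, 0.5), (2.0, 2.0)])
    def test_perfect_sample_is_a_fixed_point(self, m, b):
        counts = perfect_sample(m, b)
        assert estimate_m(counts, b=b) == pytest.approx(m, abs=1e-3 * max(m, 1))
        assert estimate_b(counts) == pytest.approx(b, abs=2e-3 * b)

    def test_invalid_fitness_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_m([1, 2], b=-1.0)


class TestConfidenceLimits:
    def test_width_shrinks_as_root_n(self, rng):
        widths = {}
        for n in (1000, 4000):
            ws = []
            for _ in range(40):
                counts = sample_counts(4.0, 1.0, 1.0, n, rng)
                b = estimate_b(counts)
                m = estimate_m(counts, b)
                lo, hi, _, _ = compute_ci(counts, m, b)
                ws.append(hi - lo)
            widths[n] = np.median(ws)
        assert widths[1000] / widths[4000] == pytest.approx(2.0, rel=0.2)

    def test_all_zero_counts_have_no_interval(self):
        assert compute_ci([0, 0, 0], 0.0, 1.0, b_fixed=True) == (None, None, None, None)

    def test_limits_bracket_the_point_estimate(self, rng):
        counts = sample_counts(4.0, 1.0, 1.0, 96, rng)
        b = estimate_b(counts)
        m = estimate_m(counts, b)
        m_lo, m_hi, b_lo, b_hi = compute_ci(counts, m, b)
        assert m_lo <= m <= m_hi
        assert b_lo <= b <= b_hi


class TestEstimateOrchestration:
    def test_full_report_on_simulated_assay(self, rng):
        counts = sample_counts(4.0, 1.0, 1.0, 96, rng)
        ds = FluctuationDataset(counts, np.full(96, 3e6))
        res = estimate(ds)
        assert res.m_lower <= res.m <= res.m_upper
        assert res.cl_lower == pytest.approx(res.m_lower)  # z = 1
        assert res.mu == pytest.approx(res.m / 3e6)
        assert res.chi2 is not None and 0 <= res.chi2_pval <= 1
        assert res.fit_warning == (res.chi2_pval < 0.01)
        assert not res.b_was_fixed

    def test_fixed_fitness_mode(self, rng):
        counts = sample_counts(2.0, 1.0, 1.0, 96, rng)
        ds = FluctuationDataset(counts, np.full(96, 1e6))
        res = estimate(ds, b_known=1.0)
        assert res.b == 1.0 and res.b_was_fixed
        assert res.b_lower is None and res.b_upper is None

    def test_plating_efficiency_propagates(self, rng):
        counts = sample_counts(2.0, 1.0, 0.5, 96, rng)
        ds = FluctuationDataset(counts, np.full(96, 1e6))
        res = estimate(ds, b_known=1.0, z=0.5)
        factor = 0.5 / (0.5 * np.log(0.5)) * -1  # (z-1)/(z ln z)
        assert res.m_corr == pytest.approx(res.m * factor)
        # mu_corr = m_corr / (N_p / z)
        assert res.mu_corr == pytest.approx(res.m_corr / (1e6 / 0.5))

    def test_all_zero_dataset_with_fixed_fitness(self):
        ds = FluctuationDataset([0] * 24, np.full(24, 1e6))
        res = estimate(ds, b_known=1.0)
        assert res.m == 0.0 and res.mu == 0.0
        assert res.cl_lower is None and res.cl_upper is None
        assert res.chi2 == 0.0 and res.chi2_pval == 1.0 and res.fit_warning is False

    def test_report_invariant_under_culture_permutation(self, rng):
        counts = sample_counts(4.0, 1.0, 1.0, 96, rng)
        cells = np.full(96, 1e6)
        res1 = estimate(FluctuationDataset(counts, cells))
        res2 = estimate(FluctuationDataset(counts[::-1], cells))
        assert res1.to_dict() == res2.to_dict()

    def test_fixed_true_b_no_less_precise_than_free_b(self, rng):
        # knowing b cannot hurt the m estimate (asymptotically; 5% slack)
        err_fixed, err_free = [], []
        for _ in range(200):
            counts = sample_counts(4.0, 1.0, 1.0, 384, rng)
            err_fixed.append((estimate_m(counts, b=1.0) - 4.0) ** 2)
            b = estimate_b(counts)
            err_free.append((estimate_m(counts, b) - 4.0) ** 2)
        rmse_fixed = np.sqrt(np.mean(err_fixed))
        rmse_free = np.sqrt(np.mean(err_free))
        assert rmse_fixed <= rmse_free * 1.05


class TestGFConfigValidation:
    def test_rejects_misordered_points(self):
        with pytest.raises(InvalidParameterError):
            GFConfig(s1=0.9, s2=0.1)
        with pytest.raises(InvalidParameterError):
            GFConfig(b_min=2.0, b_max=1.0)
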