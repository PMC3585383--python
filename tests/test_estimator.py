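"""Estimator unit and property tests: likelihood, MLE, CIs, bootstrap."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lincnome import (
    ConfidenceEllipsoid,
    EstimationUndefinedError,
    EvidenceCounts,
    InvalidCountsError,
    PoolSizes,
    analytic_confidence,
    bootstrap,
    conservation,
    estimate_report,
    integerize,
    log_likelihood,
    mle_closed_form,
    mle_numeric,
)
from conftest import enumerate_outcome_frequencies


class TestLogLikelihood:
    def test_forced_observation_has_probability_one(self):
        # sampling the entire pools forces (Kh, Km, Kb) = (1, 1, 1)
        c = EvidenceCounts(2, 2, 1, 1, 1)
        assert log_likelihood(PoolSizes(2, 2, 1), c) == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_of_sample_pairs(self):
        freq = enumerate_outcome_frequencies(4, 4, 2, 2, 2)
        for (kh, km, kb), p in freq.items():
            c = EvidenceCounts(2, 2, kh, km, kb)
            assert math.exp(log_likelihood((4, 4, 2), c)) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("pools,samples", [
        ((5, 5, 3), (3, 3)),
        ((6, 4, 2), (4, 2)),
        ((8, 7, 5), (4, 5)),
    ])
    def test_normalizes_over_feasible_outcomes(self, pools, samples):
        lh, lm = samples
        total = 0.0
        for kh in range(lh + 1):
            for km in range(lm + 1):
                for kb in range(min(kh, km) + 1):
                    ll = log_likelihood(pools, EvidenceCounts(lh, lm, kh, km, kb))
                    if ll > -math.inf:
                        total += math.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_incompatible_pools_return_neg_inf_not_exception(self):
        c = EvidenceCounts(10, 10, 5, 5, 2)
        assert log_likelihood((10, 10, 4), c) == -math.inf  # Kh > Nb
        assert log_likelihood((12, 12, 11), c) == -math.inf  # Lh-Kh > Nh-Nb

    def test_invalid_counts_raise(self):
        with pytest.raises(InvalidCountsError):
            EvidenceCounts(10, 10, 11, 5, 2)  # Kh > Lh
        with pytest.raises(InvalidCountsError):
            EvidenceCounts(10, 10, 5, 5, 6)  # Kb > Kh
        with pytest.raises(InvalidCountsError):
            EvidenceCounts(10, 10, -1, 5, 0)


class TestClosedForm:
    @pytest.mark.parametrize("counts,expected", [
        ((3603, 3332, 2030, 2308, 155), (53_649, 43_638, 30_227)),
        ((4662, 4156, 2641, 2888, 196), (68_693, 55_999, 38_914)),
    ])
    def test_published_columns(self, counts, expected):
        est = integerize(mle_closed_form(EvidenceCounts(*counts)))
        assert (est.Nh, est.Nm, est.Nb) == tuple(float(v) for v in expected)

    def test_complete_overlap_fixed_point(self):
        est = mle_closed_form(EvidenceCounts(7, 7, 7, 7, 7))
        assert est.as_array() == pytest.approx([7, 7, 7])

    def test_kb_zero_is_hard_error(self):
        with pytest.raises(EstimationUndefinedError):
            mle_closed_form(EvidenceCounts(10, 10, 5, 5, 0))

    def test_symmetry_under_species_swap(self):
        c = EvidenceCounts(3603, 3332, 2030, 2308, 155)
        a = mle_closed_form(c)
        b = mle_closed_form(c.swapped())
        assert (b.Nh, b.Nm, b.Nb) == (a.Nm, a.Nh, a.Nb)

    def test_ordering_and_monotonicity_in_kb(self):
        prev = None
        for kb in (50, 100, 150):
            est = mle_closed_form(EvidenceCounts(3603, 3332, 2030, 2308, kb))
            assert est.Nb <= min(est.Nh, est.Nm)
            assert est.Nh >= 3603
            if prev is not None:
                assert est.Nh < prev  # more recaptures -> smaller pool
            prev = est.Nh


@st.composite
def evidence_counts(draw):
    lh = draw(st.integers(10, 5000))
    lm = draw(st.integers(10, 5000))
    kh = draw(st.integers(1, lh))
    km = draw(st.integers(1, lm))
    kb = draw(st.integers(1, min(kh, km)))
    return EvidenceCounts(lh, lm, kh, km, kb)


class TestClosedFormProperties:
    @settings(max_examples=200, derandomize=True)
    @given(evidence_counts())
    def test_invariants_hold_for_any_valid_counts(self, counts):
        est = mle_closed_form(counts)
        assert est.Nb <= min(est.Nh, est.Nm) + 1e-9
        assert est.Nh >= counts.Kh  # pool at least as large as its hits
        swapped = mle_closed_form(counts.swapped())
        assert (swapped.Nh, swapped.Nm, swapped.Nb) == (est.Nm, est.Nh, est.Nb)
        assert math.exp(log_likelihood(integer_feasible(est, counts), counts)) > 0


def integer_feasible(est: PoolSizes, counts: EvidenceCounts) -> tuple[int, int, int]:
    """Round the estimate up into the integer feasible cone."""
    nb = max(math.ceil(est.Nb), counts.Kh + counts.Km - counts.Kb)
    nh = max(math.ceil(est.Nh), nb + counts.Lh - counts.Kh, counts.Lh)
    nm = max(math.ceil(est.Nm), nb + counts.Lm - counts.Km, counts.Lm)
    return nh, nm, nb


class TestNumericMLE:
    def test_agrees_with_closed_form_on_random_counts(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            lh, lm = (int(v) for v in rng.integers(200, 5000, 2))
            kh = int(rng.integers(50, lh // 2))
            km = int(rng.integers(50, lm // 2))
            kb = int(rng.integers(5, max(6, min(kh, km) // 3)))
            c = EvidenceCounts(lh, lm, kh, km, kb)
            diff = np.abs(
                mle_numeric(c).as_array() - mle_closed_form(c).as_array()
            )
            assert diff.max() < 1.0

    def test_exact_likelihood_matches_exhaustive_grid_on_tiny_counts(self):
        c = EvidenceCounts(3, 3, 2, 2, 1)
        best, argmax = -math.inf, None
        for nh in range(3, 51):
            for nm in range(3, 51):
                for nb in range(1, min(nh, nm) + 1):
                    ll = log_likelihood((nh, nm, nb), c)
                    if ll > best:
                        best, argmax = ll, (nh, nm, nb)
        est = mle_numeric(c, likelihood="exact")
        assert (est.Nh, est.Nm, est.Nb) == tuple(float(v) for v in argmax)

    def test_forced_complete_overlap(self):
        est = mle_numeric(EvidenceCounts(2, 2, 2, 2, 2))
        assert est.as_array() == pytest.approx([2, 2, 2])

    def test_search_bounds_clip_with_warning(self, caplog):
        c = EvidenceCounts(3603, 3332, 2030, 2308, 155)
        est = mle_numeric(c, search_bounds=((0, 50_000),) * 3)
        assert est.Nh == pytest.approx(50_000)
        assert any("boundary" in r.message for r in caplog.records)


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (55_999.98, 55_999),
        (30_227.35, 30_227),
        (10.0, 10),
    ])
    def test_integerize_truncates(self, value, expected):
        est = integerize(PoolSizes(value, value, value))
        assert est.Nh == expected

    @pytest.mark.parametrize("pools,expected", [
        ((53_649, 43_638, 30_227), (56, 69)),
        ((68_693, 55_999, 38_914), (57, 69)),
        ((100, 100, 100), (100, 100)),
    ])
    def test_conservation_rounds_to_nearest(self, pools, expected):
        assert conservation(PoolSizes(*pools)) == expected

    def test_estimate_report_bundles_conventions(self, counts_120):
        rep = estimate_report(counts_120)
        assert (rep.point.Nh, rep.point.Nm, rep.point.Nb) == (53_649, 43_638, 30_227)
        assert (rep.conservation_human, rep.conservation_mouse) == (56, 69)
        assert rep.loglik_at_mle < 0


class TestAnalyticConfidence:
    def test_ellipsoid_is_highly_elongated(self, counts_120):
        ci = analytic_confidence(counts_120)
        assert isinstance(ci, ConfidenceEllipsoid)
        ratio = ci.axes_halfwidths.max() / ci.axes_halfwidths.min()
        assert ratio > 3.0
        # orthonormal axes
        assert ci.axes_directions @ ci.axes_directions.T == pytest.approx(
            np.eye(3), abs=1e-9
        )

    def test_intervals_shrink_like_inverse_sqrt_of_counts(self, counts_120):
        c = counts_120
        doubled = EvidenceCounts(2 * c.Lh, 2 * c.Lm, 2 * c.Kh, 2 * c.Km, 2 * c.Kb)
        ci1 = analytic_confidence(c)
        ci2 = analytic_confidence(doubled)
        # relative half-widths scale ~ 1/sqrt(2) when all counts double
        rel1 = ci1.per_parameter_95ci / mle_closed_form(c).as_array()
        rel2 = ci2.per_parameter_95ci / mle_closed_form(doubled).as_array()
        assert rel2 / rel1 == pytest.approx(np.full(3, 1 / math.sqrt(2)), rel=0.05)

    def test_small_kb_rejected(self):
        with pytest.raises(EstimationUndefinedError):
            analytic_confidence(EvidenceCounts(10, 10, 5, 5, 1))


class TestBootstrap:
    def test_deterministic_under_fixed_seed(self, counts_120):
        a = bootstrap(counts_120, resamples=50, seed=123)
        b = bootstrap(counts_120, resamples=50, seed=123)
        assert a.ci_95 == b.ci_95
        assert [p.as_array().tolist() for p in a.replicate_estimates] == [
            p.as_array().tolist() for p in b.replicate_estimates
        ]

    def test_replicate_mean_near_point_estimate(self, counts_120):
        boot = bootstrap(counts_120, resamples=1000, seed=0)
        arr = np.array([p.as_array() for p in boot.replicate_estimates])
        point = mle_closed_form(counts_120).as_array()
        sd = arr.std(axis=0, ddof=1)
        assert np.all(np.abs(arr.mean(axis=0) - point) < 3 * sd)

    def test_bookkeeping_of_skipped_replicates(self):
        # Kb = 1: many replicates lose the single pair
        boot = bootstrap(EvidenceCounts(50, 50, 20, 20, 1), resamples=200, seed=5)
        assert boot.n_skipped_kb_zero > 0
        assert len(boot.replicate_estimates) == 200 - boot.n_skipped_kb_zero
        for name, (lo, hi) in boot.ci_95.items():
            assert lo <= hi
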