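"""Agreement statistics: pooled kappa, interpretation bands, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edac.agreement import (
    JudgementPair,
    KappaUndefinedError,
    bootstrap_ci,
    cohen_kappa_2x2,
    confidence_summary,
    kappa_interpretation,
    per_class_kappa,
    percent_agreement,
    pooled_kappa,
)
from edac.core import EDACClass

AV, PO, NO = (
    EDACClass.AVOIDABLE,
    EDACClass.POTENTIALLY_AVOIDABLE,
    EDACClass.NOT_AVOIDABLE,
)


def pairs_from(spec):
    """spec: list of (class, rating_a, rating_b, count)."""
    out = []
    i = 0
    for cls, a, b, n in spec:
        for _ in range(n):
            out.append(JudgementPair(f"p{i}", cls, a, b))
            i += 1
    return out


class TestPercentAgreement:
    def test_reference_fixture(self, fixture_pairs):
        po, count = percent_agreement(fixture_pairs)
        assert count == 139
        assert po == pytest.approx(139 / 160)

    def test_all_concordant(self):
        po, _ = percent_agreement(pairs_from([(AV, True, True, 5)]))
        assert po == 1.0

    def test_half(self):
        po, _ = percent_agreement(
            pairs_from([(AV, True, True, 1), (AV, True, False, 1)])
        )
        assert po == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            percent_agreement([])


class TestPooledKappa:
    def test_perfect_agreement_with_mixed_marginal_is_one(self):
        res = pooled_kappa(pairs_from([(AV, True, True, 6), (NO, False, False, 4)]))
        assert res.kappa == pytest.approx(1.0)
        assert res.po == 1.0

    def test_all_identical_ratings_undefined(self):
        with pytest.raises(KappaUndefinedError):
            pooled_kappa(pairs_from([(AV, True, True, 5)]))

    def test_single_concordant_pair_undefined(self):
        with pytest.raises(KappaUndefinedError):
            per_class_kappa(pairs_from([(AV, True, True, 1)]), AV)

    def test_independent_ratings_give_near_zero_kappa(self):
        """Simulation oracle: rating_b independent of rating_a at matched
        marginals has population kappa 0."""
        rng = np.random.default_rng(42)
        p = 0.6
        a = rng.random(10_000) < p
        b = rng.random(10_000) < p
        pairs = [
            JudgementPair(f"p{i}", AV, bool(x), bool(y))
            for i, (x, y) in enumerate(zip(a, b))
        ]
        assert abs(pooled_kappa(pairs).kappa) < 0.03

    def test_kappa_bounded_by_po_and_ci_brackets(self, fixture_pairs):
        res = pooled_kappa(fixture_pairs)
        assert res.kappa <= res.po
        assert res.ci_low <= res.kappa <= res.ci_high <= 1.0
        # exact defining ratio
        assert res.kappa == pytest.approx((res.po - res.pe) / (1 - res.pe))

    @settings(max_examples=60, derandomize=True)
    @given(
        table=st.tuples(
            st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
        ).filter(lambda t: sum(t) >= 2)
    )
    def test_slot_swap_invariance(self, table):
        """Swapping the a/b slots of any subset of pairs leaves pooled kappa
        unchanged (the estimator is symmetric in rater labels)."""
        n11, n10, n01, n00 = table
        spec = [
            (AV, True, True, n11),
            (AV, True, False, n10),
            (AV, False, True, n01),
            (AV, False, False, n00),
        ]
        pairs = pairs_from(spec)
        swapped = [p.swapped() if i % 2 else p for i, p in enumerate(pairs)]
        try:
            k1 = pooled_kappa(pairs).kappa
        except KappaUndefinedError:
            with pytest.raises(KappaUndefinedError):
                pooled_kappa(swapped)
            return
        assert pooled_kappa(swapped).kappa == pytest.approx(k1)

    @settings(max_examples=60, derandomize=True)
    @given(
        n11=st.integers(0, 15), d=st.integers(0, 15), n00=st.integers(0, 15)
    )
    def test_matches_cohen_kappa_under_symmetric_attribution(self, n11, d, n00):
        """Small-case oracle: with symmetric discordance attribution (equal
        off-diagonal cells) pooled kappa equals classical Cohen's kappa."""
        pairs = pairs_from(
            [
                (AV, True, True, n11),
                (AV, True, False, d),
                (AV, False, True, d),
                (AV, False, False, n00),
            ]
        )
        if not pairs:
            return
        try:
            pooled = pooled_kappa(pairs).kappa
        except KappaUndefinedError:
            return
        assert pooled == pytest.approx(cohen_kappa_2x2(n11, d, d, n00))


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa, label",
        [
            (0.69, "substantial agreement"),
            (0.84, "almost perfect agreement"),
            (0.0, "slight agreement"),
            (0.20, "slight agreement"),
            (0.25, "fair agreement"),
            (0.45, "moderate agreement"),
            (-0.1, "poor agreement"),
            (1.0, "almost perfect agreement"),
        ],
    )
    def test_landis_koch_bands(self, kappa, label):
        assert kappa_interpretation(kappa) == label

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            kappa_interpretation(1.01)


class TestConfidence:
    def test_constant_scores(self):
        pairs = [JudgementPair("a", AV, True, True, 5, 5)]
        s = confidence_summary(pairs)
        assert s["mean"] == 5 and s["sd"] == 0

    def test_mean_and_sample_sd(self):
        pairs = [JudgementPair("a", AV, True, True, 3, 5)]
        s = confidence_summary(pairs)
        assert s["mean"] == 4.0
        assert s["sd"] == pytest.approx(np.std([3, 5], ddof=1))

    def test_recovers_generator_moments(self):
        rng = np.random.default_rng(3)
        confs = np.clip(np.rint(rng.normal(4.0, 0.9, size=(4000, 2))), 1, 5).astype(int)
        pairs = [
            JudgementPair(f"p{i}", NO, True, False, int(c[0]), int(c[1]))
            for i, c in enumerate(confs)
        ]
        s = confidence_summary(pairs)
        # clipping/rounding shrinks the spread slightly; 2 SEs around the
        # empirical truth of the clipped distribution
        truth = confs.ravel()
        assert s["mean"] == pytest.approx(truth.mean())
        assert s["sd"] == pytest.approx(truth.std(ddof=1))

    def test_by_class_keys(self, fixture_pairs):
        pairs = [
            JudgementPair("a", AV, True, True, 4, 5),
            JudgementPair("b", NO, False, False, 2, 3),
        ]
        s = confidence_summary(pairs, by_class=True)
        assert set(s) == {"avoidable", "not_avoidable"}

    def test_no_scores_errors(self, fixture_pairs):
        with pytest.raises(ValueError, match="confidence"):
            confidence_summary(fixture_pairs)


class TestBootstrap:
    def test_degenerate_statistic_interval(self):
        pairs = pairs_from([(AV, True, True, 10), (NO, False, False, 5)])
        lo, hi = bootstrap_ci(pairs, lambda ps: percent_agreement(ps)[0], reps=300, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_brackets_point_estimate(self, fixture_pairs):
        point = pooled_kappa(fixture_pairs).kappa
        lo, hi = bootstrap_ci(
            fixture_pairs, lambda ps: pooled_kappa(ps).kappa, reps=400, seed=1
        )
        assert lo <= point <= hi

    def test_width_shrinks_with_n(self):
        """Quadrupling n should roughly halve the interval width."""
        rng = np.random.default_rng(9)

        def sample(n):
            a = rng.random(n) < 0.7
            flip = rng.random(n) < 0.15
            return [
                JudgementPair(f"p{i}", AV, bool(x), bool(x ^ f))
                for i, (x, f) in enumerate(zip(a, flip))
            ]

        lo1, hi1 = bootstrap_ci(sample(250), lambda ps: pooled_kappa(ps).kappa, reps=400, seed=2)
        lo2, hi2 = bootstrap_ci(sample(1000), lambda ps: pooled_kappa(ps).kappa, reps=400, seed=3)
        ratio = (hi1 - lo1) / (hi2 - lo2)
        assert 1.3 < ratio < 3.1

    def test_too_few_reps_rejected(self, fixture_pairs):
        with pytest.raises(ValueError):
            bootstrap_ci(fixture_pairs, lambda ps: 0.0, reps=50, seed=0)
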