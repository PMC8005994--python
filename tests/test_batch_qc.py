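import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from masscap import (
    CapsuleObservation,
    ValidationError,
    acceptance_value,
    acceptance_value_from_summary,
    evaluate_batch,
    homogeneity,
    mass_uniformity,
    powder_loss,
    uniformity_test,
)
from masscap.batch_qc import default_k, reference_value

from conftest import make_batch


def av_oracle(values, k):
    """Independent brute-force acceptance value: enumerate the M branches
    and take the one consistent with the mean (case T <= 101.5)."""
    values = list(values)
    mean = sum(values) / len(values)
    s = (sum((v - mean) ** 2 for v in values) / (len(values) - 1)) ** 0.5
    candidates = []
    for m in (mean, 98.5, 101.5):
        if m == mean and not 98.5 <= mean <= 101.5:
            continue
        if m == 98.5 and not mean < 98.5:
            continue
        if m == 101.5 and not mean > 101.5:
            continue
        candidates.append(abs(m - mean) + k * s)
    assert len(candidates) == 1
    return candidates[0]


class TestAcceptanceValue:
    def test_all_on_target_gives_zero(self):
        assert acceptance_value([100.0] * 30) == 0.0

    def test_uniform_underdose_hits_m_branch(self):
        assert acceptance_value([97.0] * 30) == pytest.approx(1.5)

    def test_within_band_av_is_k_times_sd(self):
        vals = [99.0, 100.0, 101.0] * 10  # mean 100, inside [98.5, 101.5]
        s = np.std(vals, ddof=1)
        assert acceptance_value(vals, 2.0) == pytest.approx(2.0 * s)

    def test_matches_brute_force_oracle_on_random_samples(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(2, 40)
            vals = rng.normal(rng.uniform(80, 120), rng.uniform(0.1, 10), n)
            vals = np.abs(vals)
            k = rng.choice([2.0, 2.4])
            assert acceptance_value(vals, k) == pytest.approx(
                av_oracle(vals, k), rel=1e-12, abs=1e-12
            )

    def test_continuity_at_branch_points(self):
        eps = 1e-9
        for edge in (98.5, 101.5):
            below = acceptance_value([edge - eps] * 5 + [edge - eps] * 5, 2.0)
            at = acceptance_value([edge] * 10, 2.0)
            assert below == pytest.approx(at, abs=1e-6)

    def test_needs_two_values(self):
        with pytest.raises(ValidationError):
            acceptance_value([100.0])

    def test_rejects_negative_contents(self):
        with pytest.raises(ValidationError):
            acceptance_value([100.0, -1.0])

    def test_default_k_is_n_based(self):
        assert default_k(10) == 2.4
        assert default_k(30) == 2.0

    @given(
        mean=st.floats(80, 120),
        sd=st.floats(0, 10),
        n=st.integers(3, 40),
        k=st.sampled_from([2.0, 2.4]),
    )
    @settings(max_examples=200, deadline=None)
    def test_av_lower_bound_k_times_s(self, mean, sd, n, k):
        """AV >= k*s always; equality iff the mean is inside [98.5, 101.5]."""
        rng = np.random.default_rng(abs(hash((mean, sd, n))) % 2**31)
        vals = np.abs(rng.normal(mean, sd, n))
        s = float(np.std(vals, ddof=1))
        av = acceptance_value(vals, k)
        assert av >= k * s - 1e-9
        inside = 98.5 <= vals.mean() <= 101.5
        assert (abs(av - k * s) < 1e-9) == inside


class TestSummaryAV:
    def test_published_failing_batch(self):
        # label 0.5 mg, mean 0.427 mg, SD 2.28 % of mean, k = 2.0
        av = acceptance_value_from_summary(0.427, 2.28, 0.5, 2.0)
        assert round(av, 1) == 17.0

    def test_zero_sd_on_target(self):
        assert acceptance_value_from_summary(1.0, 0.0, 1.0, 2.0) == 0.0

    def test_rounded_inputs_near_printed_value(self):
        av = acceptance_value_from_summary(2.61, 6.36, 2.5, 2.0)
        assert av == pytest.approx(16.07, abs=0.2)

    @given(
        mean=st.floats(85, 115),
        sd=st.floats(0.01, 8),
        n=st.integers(5, 40),
        label=st.sampled_from([0.5, 1.0, 2.0, 2.5, 4.0]),
    )
    @settings(max_examples=150, deadline=None)
    def test_consistency_with_raw_sample(self, mean, sd, n, label):
        """Summary-form AV equals the raw-sample AV for exact summaries."""
        rng = np.random.default_rng(abs(hash((mean, sd, n, label))) % 2**31)
        contents = np.abs(rng.normal(mean * label / 100, sd * label / 100, n))
        raw_av = acceptance_value(contents / label * 100, 2.0)
        m = contents.mean()
        sd_rel = 100 * np.std(contents, ddof=1) / m
        summary_av = acceptance_value_from_summary(m, sd_rel, label, 2.0)
        assert summary_av == pytest.approx(raw_av, rel=1e-9, abs=1e-9)


class TestUniformityTest:
    def test_single_mode_fail_above_15(self):
        res = uniformity_test([85.4] * 15 + [85.4 + 3.9] * 15, k=2.0)
        assert res.av > 15
        assert not res.passed

    def test_all_identical_on_target_passes_every_mode(self):
        assert uniformity_test([100.0] * 30, mode="single").passed
        assert uniformity_test([100.0] * 30, mode="compendial").passed
        assert uniformity_test([100.0] * 10, mode="compendial").passed

    def test_compendial_stage2_individual_unit_rule(self):
        # Stage 1 fails (huge spread in first 10); stage 2 AV small but one
        # unit deviates > 25 % from M -> fail.
        vals = [70.0, 130.0] * 5 + [100.0] * 20
        res = uniformity_test(vals, mode="compendial")
        assert res.stage == 2
        assert not res.passed

    def test_compendial_mode_rejects_wrong_n(self):
        with pytest.raises(ValidationError):
            uniformity_test([100.0] * 12, mode="compendial")


class TestPowderLoss:
    def test_zero_loss_when_net_fill_equals_target(self):
        b = make_batch([1.0] * 3, gross=[174.0] * 3, weighed_blend=300.0)
        assert powder_loss(b) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # m_t = 8651 mg, net fill 8400 mg -> 2.90 %
        b = make_batch([1.0] * 30, gross=[74.0 + 280.0] * 30,
                       weighed_blend=8651.0)
        assert powder_loss(b) == pytest.approx(2.9014, abs=5e-4)

    def test_all_empty_capsules_lose_everything(self):
        b = make_batch([0.0] * 3, gross=[74.0] * 3, weighed_blend=300.0)
        assert powder_loss(b) == pytest.approx(100.0)

    def test_negative_loss_allowed_not_clamped(self):
        b = make_batch([1.0] * 3, gross=[200.0] * 3, weighed_blend=300.0)
        assert powder_loss(b) < 0

    def test_tare_exceeding_gross_errors(self):
        b = make_batch([0.0] * 3, gross=[50.0] * 3, weighed_blend=300.0)
        with pytest.raises(ValidationError, match="tare exceeds"):
            powder_loss(b)

    def test_antitone_in_total_gross_mass(self):
        lo = make_batch([1.0] * 3, gross=[250.0] * 3, weighed_blend=600.0)
        hi = make_batch([1.0] * 3, gross=[270.0] * 3, weighed_blend=600.0)
        assert powder_loss(hi) < powder_loss(lo)


class TestMassUniformity:
    def test_equal_masses(self):
        assert mass_uniformity([290.0] * 5) == 0.0

    def test_hand_arithmetic(self):
        assert mass_uniformity([98.0, 100.0, 102.0]) == pytest.approx(2.0)

    def test_scale_invariance(self):
        base = mass_uniformity([98.0, 100.0, 102.0])
        assert mass_uniformity([980.0, 1000.0, 1020.0]) == pytest.approx(base)

    def test_needs_two(self):
        with pytest.raises(ValidationError):
            mass_uniformity([100.0])


class TestHomogeneity:
    def test_proportional_content_gives_zero(self):
        caps = [
            CapsuleObservation(i + 1, 74.0 + m, 0.01 * m)
            for i, m in enumerate([280.0, 290.0, 300.0])
        ]
        assert homogeneity(caps, 74.0) == pytest.approx(0.0, abs=1e-10)

    def test_two_quotients_hand_arithmetic(self):
        # quotients 0.009 and 0.011 -> SD/mean = 0.0014142/0.01 = 14.14 %
        caps = [
            CapsuleObservation(1, 174.0, 0.9),
            CapsuleObservation(2, 174.0, 1.1),
        ]
        assert homogeneity(caps, 74.0) == pytest.approx(14.142, abs=5e-3)

    def test_unit_invariance_of_content(self):
        caps_mg = [CapsuleObservation(1, 174.0, 0.9),
                   CapsuleObservation(2, 172.0, 1.1)]
        caps_ug = [CapsuleObservation(1, 174.0, 900.0),
                   CapsuleObservation(2, 172.0, 1100.0)]
        assert homogeneity(caps_mg, 74.0) == pytest.approx(
            homogeneity(caps_ug, 74.0)
        )

    def test_non_positive_net_mass_errors(self):
        caps = [CapsuleObservation(1, 60.0, 0.9),
                CapsuleObservation(2, 174.0, 1.1)]
        with pytest.raises(ValidationError, match="net mass"):
            homogeneity(caps, 74.0)


class TestEvaluateBatch:
    def test_three_capsule_batch_against_spreadsheet(self):
        # Hand-checked: contents {0.95, 1.00, 1.05} mg (label 1 mg),
        # gross {360, 364, 368} mg, tare 74, weighed blend 900 mg.
        # contents%: {95, 100, 105}: mean 100, s 5 -> AV = 2*5 = 10
        # net fill = 1092 - 222 = 870 -> loss = 30/900*100 = 3.333 %
        # mass SDrel = 4/364*100 = 1.0989 %
        # quotients {0.0033217, 0.0034483, 0.0035714}: SDrel = 3.6242 %
        b = make_batch(
            [0.95, 1.00, 1.05],
            gross=[360.0, 364.0, 368.0],
            weighed_blend=900.0,
        )
        rep = evaluate_batch(b, k=2.0)
        assert rep.acceptance_value == pytest.approx(10.0)
        assert rep.powder_loss == pytest.approx(3.3333, abs=1e-3)
        assert rep.sd_rel_mass == pytest.approx(1.0989, abs=1e-3)
        assert rep.mean_content == pytest.approx(1.0)
        assert rep.sd_rel_content == pytest.approx(5.0)
        assert rep.sd_rel_content_mass_ratio == pytest.approx(3.6227, abs=5e-4)
        assert rep.av_ok and not rep.loss_ok and rep.mass_ok

    def test_flags_consistent_with_thresholds(self):
        b = make_batch(
            [0.95, 1.00, 1.05],
            gross=[360.0, 364.0, 368.0],
            weighed_blend=900.0,
        )
        rep = evaluate_batch(b, k=2.0)
        row = rep.as_row()
        assert row["av_ok"] == (row["av"] <= 15.0)
        assert row["loss_ok"] == (row["powder_loss_pct"] <= 3.0)
        assert row["mass_ok"] == (row["sd_rel_mass_pct"] <= 5.0)

    def test_reference_value_branches(self):
        assert reference_value(100.0) == 100.0
        assert reference_value(95.0) == 98.5
        assert reference_value(110.0) == 101.5
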