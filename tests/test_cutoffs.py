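"""Stratified mean − 2SD cutoffs and microcephaly classification."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cephalomine import (
    ConfigError,
    CutoffTable,
    GeneratorConfig,
    StratumError,
    build_cutoff_table,
    classify_cohort,
    classify_microcephaly,
    compute_cutoff,
    generate_cohort,
    prevalence,
)

# Published-style reference strata: per-stratum HC mean ± SD (cm) and the
# mean − 2SD cutoffs they imply (one-decimal display).
REFERENCE_STRATA = [
    # sex, bin_low, bin_high, mean, sd, cutoff (1 d.p.)
    ("female", -math.inf, 1.60, 53.5, 2.4, 48.7),
    ("female", 1.60, 1.70, 54.3, 2.2, 49.9),
    ("female", 1.70, 1.80, 54.7, 2.2, 50.3),
    ("female", 1.80, math.inf, 55.6, 2.6, 50.4),
    ("male", -math.inf, 1.60, 55.2, 2.3, 50.6),
    ("male", 1.80, math.inf, 56.7, 2.5, 51.7),
]


def reference_table() -> CutoffTable:
    frame = pd.DataFrame(
        [
            {
                "sex": sex,
                "bin_low_m": lo,
                "bin_high_m": hi,
                "n": 100,
                "mean_hc_cm": mean,
                "sd_hc_cm": sd,
                "cutoff_cm": compute_cutoff(mean, sd),
            }
            for sex, lo, hi, mean, sd, _ in REFERENCE_STRATA
        ]
    )
    return CutoffTable.from_frame(frame)


class TestComputeCutoff:
    @pytest.mark.parametrize("mean,sd,expected", [
        (m, s, c) for _, _, _, m, s, c in REFERENCE_STRATA
    ])
    def test_reference_strata_one_decimal(self, mean, sd, expected):
        assert round(compute_cutoff(mean, sd), 1) == expected

    def test_zero_sd_identity(self):
        assert compute_cutoff(55.0, 0.0) == 55.0

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigError):
            compute_cutoff(55.0, -1.0)


class TestBuildCutoffTable:
    def test_single_stratum_hand_computation(self):
        cohort = pd.DataFrame(
            {
                "sex": ["female"] * 4,
                "height_m": [1.55] * 4,
                "hc_cm": [51.0, 53.0, 55.0, 57.0],
            }
        )
        table = build_cutoff_table(cohort)
        assert len(table.strata) == 1
        s = table.strata[0]
        assert s.n == 4
        assert s.mean_hc == pytest.approx(54.0)
        assert s.sd_hc == pytest.approx(math.sqrt(20 / 3))
        assert s.cutoff == pytest.approx(54.0 - 2 * math.sqrt(20 / 3))

    def test_all_male_cohort_flags_missing_female_strata(self):
        cohort = pd.DataFrame(
            {
                "sex": ["male"] * 10,
                "height_m": np.linspace(1.5, 1.9, 10),
                "hc_cm": np.linspace(53, 58, 10),
            }
        )
        table = build_cutoff_table(cohort)
        assert all(s.sex == "male" for s in table.strata)
        assert {m[0] for m in table.missing_strata} == {"female"}

    def test_singleton_stratum_raises_with_name(self):
        cohort = pd.DataFrame(
            {"sex": ["female"], "height_m": [1.55], "hc_cm": [50.0]}
        )
        with pytest.raises(StratumError, match="female"):
            build_cutoff_table(cohort)

    def test_matches_per_stratum_independent_computation(self, default_cohort, default_cutoffs):
        # no cross-stratum leakage: each cell equals a standalone
        # computation on the subset
        for s in default_cutoffs.strata:
            sub = default_cohort[
                (default_cohort["sex"] == s.sex)
                & (default_cohort["height_m"] >= s.bin_low)
                & (default_cohort["height_m"] < s.bin_high)
            ]["hc_cm"]
            assert s.n == len(sub)
            assert s.mean_hc == pytest.approx(sub.mean(), abs=1e-12)
            assert s.sd_hc == pytest.approx(sub.std(ddof=1), abs=1e-12)

    def test_translation_equivariance(self, default_cohort):
        base = build_cutoff_table(default_cohort)
        shifted = default_cohort.copy()
        target = base.strata[0]
        mask = (
            (shifted["sex"] == target.sex)
            & (shifted["height_m"] >= target.bin_low)
            & (shifted["height_m"] < target.bin_high)
        )
        shifted.loc[mask, "hc_cm"] += 1.5
        new = build_cutoff_table(shifted).strata[0]
        assert new.cutoff == pytest.approx(target.cutoff + 1.5, abs=1e-9)

    def test_eight_strata_partition(self, default_cutoffs):
        assert len(default_cutoffs.strata) + len(default_cutoffs.missing_strata) == 8

    def test_cutoffs_close_to_generator_closed_form(self):
        # compare large-sample stratum cutoffs with the analytic
        # mean − 2SD implied by the generator's mixture model
        cfg = GeneratorConfig(n_subjects=40_000, seed=21)
        df = generate_cohort(cfg)
        table = build_cutoff_table(df)
        for s in table.strata:
            if s.n < 2000:
                continue  # small cells are sampling-noise dominated
            mu_h = cfg.height_mean_female if s.sex == "female" else cfg.height_mean_male
            a = (s.bin_low - mu_h) / cfg.height_sd
            b = (s.bin_high - mu_h) / cfg.height_sd
            tn = stats.truncnorm(a, b, loc=mu_h, scale=cfg.height_sd)
            offset = 0.0 if s.sex == "female" else cfg.hc_male_offset_cm
            pi, delta = cfg.low_tail_inflation, cfg.low_tail_shift_cm
            mean = (
                cfg.hc_intercept_cm
                + cfg.hc_height_slope_cm_per_m * tn.mean()
                + offset
                - pi * delta
            )
            var = (
                cfg.hc_height_slope_cm_per_m**2 * tn.var()
                + cfg.hc_residual_sd_cm**2
                + pi * (1 - pi) * delta**2
            )
            analytic = mean - 2 * math.sqrt(var)
            assert s.cutoff == pytest.approx(analytic, abs=0.3)

    def test_round_trip_csv(self, tmp_path, default_cutoffs):
        path = tmp_path / "cutoffs.csv"
        default_cutoffs.write_csv(path)
        back = CutoffTable.read_csv(path)
        for a, b in zip(default_cutoffs.strata, back.strata):
            assert a == b


class TestClassify:
    def test_below_cutoff_true(self):
        table = reference_table()
        subject = {"sex": "female", "height_m": 1.55, "hc_cm": 48.0}
        assert classify_microcephaly(subject, table) is True

    def test_exactly_at_cutoff_false(self):
        table = reference_table()
        cutoff = table.lookup("female", 1.55).cutoff
        subject = {"sex": "female", "height_m": 1.55, "hc_cm": cutoff}
        assert classify_microcephaly(subject, table) is False

    def test_tall_male_boundary(self):
        table = reference_table()
        subject = {"sex": "male", "height_m": 1.85, "hc_cm": 51.6}
        assert classify_microcephaly(subject, table) is True

    def test_missing_stratum_raises(self):
        table = reference_table()  # has no male 1.60-1.70 row
        with pytest.raises(StratumError):
            classify_microcephaly(
                {"sex": "male", "height_m": 1.65, "hc_cm": 50.0}, table
            )

    def test_order_invariance(self, default_cohort, default_cutoffs):
        flags = classify_cohort(default_cohort, default_cutoffs)
        shuffled = default_cohort.sample(frac=1, random_state=0)
        flags_shuffled = classify_cohort(shuffled, default_cutoffs)
        restored = pd.Series(flags_shuffled, index=shuffled.index).sort_index()
        assert (restored.to_numpy() == flags).all()


class TestPrevalence:
    def test_no_positives(self):
        cohort = pd.DataFrame(
            {
                "sex": ["female"] * 4,
                "height_m": [1.55] * 4,
                "hc_cm": [54.0, 54.0, 54.0, 54.0],
            }
        )
        table = build_cutoff_table(cohort)
        # zero SD => cutoff equals the common value; nobody strictly below
        result = prevalence(cohort, table)
        assert (result.count, result.proportion) == (0, 0.0)

    def test_printed_style_rounding(self):
        # 119 positives of 2,508 prints as 4.7% at one decimal
        assert round(100 * 119 / 2508, 1) == 4.7

    def test_default_cohort_prevalence_plausible(self, default_cohort, default_cutoffs):
        result = prevalence(default_cohort, default_cutoffs)
        assert 0.03 < result.proportion < 0.065
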