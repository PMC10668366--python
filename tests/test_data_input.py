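import math

import numpy as np
import pytest

import trialbf as tb
from conftest import exact_moments


class TestSummarizeRaw:
    def test_textbook_values(self):
        s = tb.summarize_raw(tb.RawGroups((1.0, 2.0, 3.0), (2.0, 3.0, 4.0)))
        assert s.mean_x == 2.0 and s.mean_y == 3.0
        assert s.sd_x == pytest.approx(1.0) and s.sd_y == pytest.approx(1.0)
        assert s.mode == "raw"

    def test_moments_match_manual_single_pass(self):
        rng = np.random.default_rng(7)
        x = tuple(rng.normal(1.0, 2.0, size=23))
        y = tuple(rng.normal(0.0, 1.5, size=17))
        s = tb.summarize_raw(tb.RawGroups(x, y))
        mean_x = sum(x) / len(x)
        var_x = sum((v - mean_x) ** 2 for v in x) / (len(x) - 1)
        assert s.mean_x == pytest.approx(mean_x, rel=1e-12)
        assert s.sd_x == pytest.approx(math.sqrt(var_x), rel=1e-12)

    def test_constant_group_is_flagged_downstream(self):
        s = tb.summarize_raw(tb.RawGroups((1.0, 1.0, 1.0), (1.0, 2.0, 3.0)))
        assert s.sd_x == 0.0  # usable: pooled variance still positive
        tb.t_from_summary(s)

    @pytest.mark.parametrize(
        "x, y, err",
        [
            ((1.0,), (1.0, 2.0), tb.InvalidInputError),
            ((1.0, np.nan), (1.0, 2.0), tb.InvalidInputError),
            ((1.0, np.inf, 2.0), (1.0, 2.0), tb.InvalidInputError),
        ],
    )
    def test_bad_groups_rejected(self, x, y, err):
        with pytest.raises(err):
            tb.summarize_raw(tb.RawGroups(x, y))

    def test_both_groups_constant_rejected(self):
        with pytest.raises(tb.InvalidInputError):
            tb.summarize_raw(tb.RawGroups((2.0, 2.0), (5.0, 5.0)))


class TestLoadOutcomes:
    def test_reads_plain_column_with_header_and_blanks(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("value\n1.5\n\n2.5\n-3\n")
        assert tb.load_outcomes(p) == (1.5, 2.5, -3.0)

    def test_non_numeric_body_is_an_error_not_skipped(self, tmp_path):
        p = tmp_path / "x.txt"
        p.write_text("1.0\noops\n2.0\n")
        with pytest.raises(tb.InvalidInputError, match="non-numeric"):
            tb.load_outcomes(p)


class TestStudySummaryValidation:
    def test_requires_exactly_one_input_mode(self):
        with pytest.raises(tb.InvalidInputError):
            tb.StudySummary(5, 5, 0.0, 1.0, sd_x=1.0, sd_y=1.0,
                            ci_margin=0.2, ci_level=0.95)
        with pytest.raises(tb.InvalidInputError):
            tb.StudySummary(5, 5, 0.0, 1.0)

    def test_percent_ci_level_rejected_with_hint(self):
        with pytest.raises(tb.InvalidInputError, match="0.95, not 95"):
            tb.StudySummary(5, 5, 0.0, 1.0, ci_margin=0.2, ci_level=95,
                            mode="means_ci")

    def test_group_sizes_below_two_rejected(self):
        with pytest.raises(tb.InvalidDesignError):
            tb.StudySummary(1, 5, 0.0, 1.0, sd_x=1.0, sd_y=1.0)


class TestBuildDesign:
    def test_single_margin_expands_symmetrically(self):
        spec = tb.build_design("equivalence", interval=0.2)
        assert (spec.interval_lower, spec.interval_upper) == (-0.2, 0.2)

    def test_asymmetric_interval_preserved(self):
        spec = tb.build_design("equivalence", interval=(-0.3, 0.2))
        assert (spec.interval_lower, spec.interval_upper) == (-0.3, 0.2)

    @pytest.mark.parametrize("interval", [0, (0, 0)])
    def test_zero_interval_is_point_null(self, interval):
        assert tb.build_design("equivalence", interval=interval).is_point_null

    def test_errors(self):
        with pytest.raises(tb.InvalidDesignError):
            tb.build_design("superiority")  # missing direction
        with pytest.raises(tb.InvalidDesignError):
            tb.build_design("equivalence", interval=(0.3, -0.3))
        with pytest.raises(tb.InvalidDesignError):
            tb.build_design("equivalence", interval=-0.1)
        with pytest.raises(tb.InvalidDesignError):
            tb.build_design("noninferiority", direction="high", ni_margin=-1.0)


class TestCanonicalize:
    def test_high_direction_is_identity(self):
        s = tb.StudySummary(5, 6, 1.0, 2.0, sd_x=1.0, sd_y=1.0)
        spec = tb.build_design("superiority", direction="high")
        assert tb.canonicalize(s, spec) == (s, spec)

    def test_low_direction_negates_mean_difference_once(self):
        s = tb.StudySummary(193, 205, 4.7, 4.8, ci_margin=0.19, ci_level=0.95,
                            mode="means_ci")
        spec = tb.build_design("noninferiority", direction="low", ni_margin=1.0)
        s2, spec2 = tb.canonicalize(s, spec)
        assert s2.mean_y - s2.mean_x == pytest.approx(-0.1)
        assert spec2.direction == "high"
        assert tb.canonicalize(s2, spec2) == (s2, spec2)  # idempotent

    def test_equivalence_untouched(self):
        s = tb.StudySummary(5, 6, 1.0, 2.0, sd_x=1.0, sd_y=1.0)
        spec = tb.build_design("equivalence", interval=0.2)
        assert tb.canonicalize(s, spec) == (s, spec)


class TestStandardizeMargins:
    def test_already_standardized_is_identity(self):
        s = tb.StudySummary(10, 10, 0.0, 1.0, sd_x=2.0, sd_y=2.0)
        stat = tb.t_from_summary(s)
        spec = tb.build_design("noninferiority", direction="high", ni_margin=0.5)
        assert tb.standardize_margins(spec, stat) == spec

    def test_outcome_units_divided_by_pooled_sd(self):
        s = tb.StudySummary(10, 10, 0.0, 1.0, sd_x=2.0, sd_y=2.0)
        stat = tb.t_from_summary(s)
        spec = tb.build_design("noninferiority", direction="high",
                               ni_margin=1.0, ni_margin_std=False)
        out = tb.standardize_margins(spec, stat)
        assert out.ni_margin == pytest.approx(0.5)
        assert out.ni_margin_std

    def test_ci_mode_recovers_pooled_sd(self, sleepiness_summary):
        stat = tb.t_from_ci(sleepiness_summary)
        spec = tb.build_design("noninferiority", direction="low",
                               ni_margin=1.0, ni_margin_std=False)
        out = tb.standardize_margins(spec, stat)
        assert out.ni_margin == pytest.approx(1.0378, abs=5e-4)


def test_raw_and_summary_paths_agree_to_machine_precision():
    rng = np.random.default_rng(11)
    x = exact_moments(14, 0.3, 1.1, rng)
    y = exact_moments(19, 0.9, 0.9, rng)
    via_raw = tb.superiority_test(direction="high", x=x, y=y)
    s = tb.StudySummary(
        n_x=14, n_y=19,
        mean_x=float(np.mean(x)), mean_y=float(np.mean(y)),
        sd_x=float(np.std(x, ddof=1)), sd_y=float(np.std(y, ddof=1)),
    )
    via_summary = tb.superiority_test(direction="high", n_x=14, n_y=19,
                                      mean_x=s.mean_x, mean_y=s.mean_y,
                                      sd_x=s.sd_x, sd_y=s.sd_y)
    assert via_raw.bf.log_bf == pytest.approx(via_summary.bf.log_bf, abs=1e-12)
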