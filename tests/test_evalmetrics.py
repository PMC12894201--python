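"""evalmetrics: confusion tallies, metric definitions, Wilson/exact intervals."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from sdbscreen.evalmetrics import (
    ConfusionMatrix,
    clopper_pearson_ci,
    confusion,
    format_report,
    metrics,
    reconstruct_confusion,
    wilson_ci,
    write_report,
)


class TestConfusion:
    def test_mixed_tally(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert cm.fp == 0 and cm.fn == 0

    def test_all_negative_predictions(self):
        cm = confusion([1] * 5, [0] * 5)
        assert cm.tp == 0 and cm.fn == 5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])
        with pytest.raises(ValueError, match="binary"):
            confusion([1, 2], [1, 0])
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=2)

    def test_agrees_with_brute_force_tally(self):
        rng = np.random.default_rng(0)
        yt = rng.integers(0, 2, 500)
        yp = rng.integers(0, 2, 500)
        cm = confusion(yt, yp)
        brute = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for a, b in zip(yt, yp):
            key = ("t" if a == b else "f") + ("p" if b == 1 else "n")
            brute[key] += 1
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (
            brute["tp"], brute["fp"], brute["fn"], brute["tn"])


class TestMetrics:
    def test_validation_matrix_reproduces_printed_percentages(self):
        """The n=92 subject-validation matrix yields the reported metric set."""
        m = metrics(ConfusionMatrix(tp=34, fp=12, fn=13, tn=33))
        assert m["sensitivity"].percent == 72.3
        assert m["specificity"].percent == 73.3
        assert m["ppv"].percent == 73.9
        assert m["npv"].percent == 71.7
        assert m["accuracy"].percent == 72.8
        assert m["f1"].percent == 73.1

    def test_perfect_matrix(self):
        m = metrics(ConfusionMatrix(tp=50, fp=0, fn=0, tn=50))
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1"):
            assert m[name].percent == 100.0

    def test_zero_denominator_undefined_not_zero(self):
        m = metrics(ConfusionMatrix(tp=0, fp=0, fn=10, tn=10))
        assert m["ppv"].estimate is None and "denominator" in m["ppv"].note
        assert m["sensitivity"].estimate == 0.0

    def test_f1_has_no_ci(self):
        m = metrics(ConfusionMatrix(tp=30, fp=10, fn=10, tn=30))
        assert m["f1"].ci_low is None
        assert m["accuracy"].ci_low is not None


class TestReconstruction:
    def test_unique_matrix_from_printed_validation_metrics(self):
        found = reconstruct_confusion(92, 72.3, 73.3, 73.9, 71.7)
        assert found == [ConfusionMatrix(tp=34, fp=12, fn=13, tn=33)]


def _wilson_by_grid_inversion(k, n, confidence=0.95, grid=200001):
    """Independent oracle: invert the binomial score test over a fine p-grid."""
    z2 = stats.norm.ppf(0.5 + confidence / 2.0) ** 2
    p = np.linspace(0.0, 1.0, grid)
    phat = k / n
    with np.errstate(divide="ignore", invalid="ignore"):
        accept = (phat - p) ** 2 <= z2 * p * (1 - p) / n
    inside = p[accept]
    return inside.min(), inside.max()


class TestWilson:
    @pytest.mark.parametrize("k,n", [(50, 100), (0, 10), (10, 10), (34, 47), (1, 92), (91, 92)])
    def test_closed_form_matches_score_test_inversion(self, k, n):
        lo, hi = wilson_ci(k, n)
        glo, ghi = _wilson_by_grid_inversion(k, n)
        assert lo == pytest.approx(glo, abs=1e-4)
        assert hi == pytest.approx(ghi, abs=1e-4)

    def test_worked_values(self):
        lo, hi = wilson_ci(50, 100)
        assert (round(lo, 4), round(hi, 4)) == (0.4038, 0.5962)
        lo0, hi0 = wilson_ci(0, 10)
        assert lo0 == 0.0 and hi0 == pytest.approx(0.2775, abs=1e-4)
        assert wilson_ci(10, 10)[1] == 1.0

    def test_agrees_with_statsmodels(self):
        smp = pytest.importorskip("statsmodels.stats.proportion")
        for k, n in [(3, 10), (45, 92), (70, 92)]:
            lo, hi = wilson_ci(k, n)
            slo, shi = smp.proportion_confint(k, n, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_reflection_symmetry(self):
        for k, n in [(10, 40), (0, 15), (33, 92)]:
            lo, hi = wilson_ci(k, n)
            rlo, rhi = wilson_ci(n - k, n)
            assert lo == pytest.approx(1 - rhi, abs=1e-12)
            assert hi == pytest.approx(1 - rlo, abs=1e-12)

    @pytest.mark.parametrize("phat", [0.25, 0.5, 0.75])
    def test_width_shrinks_with_n(self, phat):
        widths = []
        for n in (20, 40, 80, 160, 320):
            k = int(round(phat * n))
            lo, hi = wilson_ci(k, n)
            widths.append(hi - lo)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_coverage_at_n92(self):
        """95% Wilson interval covers p=0.5 in 93-97% of 10,000 seeded draws."""
        rng = np.random.default_rng(12345)
        draws = rng.binomial(92, 0.5, size=10_000)
        covered = 0
        cache = {}
        for k in draws:
            if k not in cache:
                cache[k] = wilson_ci(int(k), 92)
            lo, hi = cache[k]
            covered += lo <= 0.5 <= hi
        assert 0.93 <= covered / 10_000 <= 0.97

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(5, 0)
        with pytest.raises(ValueError):
            wilson_ci(11, 10)


class TestClopperPearson:
    def test_contains_wilson_for_moderate_counts(self):
        """The exact interval is conservative: at least as wide as Wilson."""
        for k, n in [(34, 47), (33, 45), (67, 92)]:
            wlo, whi = wilson_ci(k, n)
            elo, ehi = clopper_pearson_ci(k, n)
            assert elo <= wlo + 1e-12 and ehi >= whi - 1e-12

    def test_matches_statsmodels_beta(self):
        smp = pytest.importorskip("statsmodels.stats.proportion")
        for k, n in [(0, 10), (34, 47), (92, 92)]:
            lo, hi = clopper_pearson_ci(k, n)
            slo, shi = smp.proportion_confint(k, n, method="beta")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)


class TestReports:
    def test_report_files_written(self, tmp_path):
        cm = ConfusionMatrix(tp=34, fp=12, fn=13, tn=33)
        out = tmp_path / "report.tsv"
        write_report(cm, out, title="Validation")
        table = out.read_text()
        assert "sensitivity\t72.3" in table
        human = out.with_suffix(".tsv.txt").read_text()
        assert "TP=34" in human and "72.3" in human

    def test_format_report_shows_both_interval_families(self):
        text = format_report(ConfusionMatrix(tp=34, fp=12, fn=13, tn=33))
        assert "wilson" in text and "exact" in text
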