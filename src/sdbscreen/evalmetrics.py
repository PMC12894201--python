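"""Confusion matrices, classification metrics, and binomial confidence intervals.

All reported proportions (sensitivity, specificity, PPV, NPV, accuracy) carry
95% Wilson score intervals — the score-test inversion for a binomial
proportion — and, alongside, exact Clopper-Pearson intervals from the beta
quantiles.  Both are printed in reports: Wilson is the standard choice for
moderate n, Clopper-Pearson is conservative; at screening-study sample sizes
the difference is visible and worth surfacing.  F1, a harmonic mean of two
proportions, carries no binomial interval.

Percentages are reported to one decimal place.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "accuracy", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with positive class = 1."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
        if self.n < 1:
            raise ValueError("confusion matrix must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion with its confidence interval(s); None CI when undefined
    (zero denominator) or not applicable (F1)."""

    name: str
    estimate: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    method: str | None = None
    note: str | None = None

    @property
    def percent(self) -> float | None:
        return None if self.estimate is None else round(100.0 * self.estimate, 1)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Tally a 2x2 confusion matrix from binary label sequences."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
    )


def wilson_ci(successes: int, trials: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Center ``(p + z^2/2n) / (1 + z^2/n)`` with half-width
    ``z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n)``.  Exact endpoints at
    k = 0 (lower bound 0) and k = n (upper bound 1).
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid k={successes}, n={trials}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    n = float(trials)
    p = successes / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo, hi = center - half, center + half
    if successes == 0:
        lo = 0.0
    if successes == trials:
        hi = 1.0
    return max(0.0, lo), min(1.0, hi)


def clopper_pearson_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial interval from beta quantiles."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid k={successes}, n={trials}")
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    hi = 1.0 if successes == trials else stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    return float(lo), float(hi)


_CI_FUNCS = {"wilson": wilson_ci, "exact": clopper_pearson_ci}


def _proportion_metric(
    name: str, k: int, n: int, confidence: float, method: str
) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(name, None, note=f"undefined: zero denominator for {name}")
    lo, hi = _CI_FUNCS[method](k, n, confidence)
    return MetricWithCI(name, k / n, lo, hi, method=method)


def metrics(
    cm: ConfusionMatrix, confidence: float = 0.95, ci_method: str = "wilson"
) -> dict[str, MetricWithCI]:
    """Sensitivity, specificity, PPV, NPV, accuracy (each with a binomial CI)
    and F1 (no CI) from a confusion matrix.

    Zero-denominator metrics are returned as undefined with a reason, never
    silently 0.
    """
    if ci_method not in _CI_FUNCS:
        raise ValueError(f"unknown CI method {ci_method!r}")
    out = {
        "sensitivity": _proportion_metric("sensitivity", cm.tp, cm.tp + cm.fn, confidence, ci_method),
        "specificity": _proportion_metric("specificity", cm.tn, cm.tn + cm.fp, confidence, ci_method),
        "ppv": _proportion_metric("ppv", cm.tp, cm.tp + cm.fp, confidence, ci_method),
        "npv": _proportion_metric("npv", cm.tn, cm.tn + cm.fn, confidence, ci_method),
        "accuracy": _proportion_metric("accuracy", cm.tp + cm.tn, cm.n, confidence, ci_method),
    }
    sens, ppv = out["sensitivity"].estimate, out["ppv"].estimate
    if sens is None or ppv is None or (sens + ppv) == 0:
        out["f1"] = MetricWithCI("f1", None, note="undefined: sensitivity or PPV undefined")
    else:
        out["f1"] = MetricWithCI("f1", 2 * ppv * sens / (ppv + sens))
    return out


def reconstruct_confusion(
    n: int,
    sensitivity_pct: float,
    specificity_pct: float,
    ppv_pct: float,
    npv_pct: float,
    decimals: int = 1,
) -> list[ConfusionMatrix]:
    """Every nonnegative-integer 2x2 matrix of total ``n`` whose four
    proportions round to the given percentages at ``decimals`` places.

    Exhaustive enumeration over (tp, fp, fn); used to recover a published
    confusion matrix from printed metrics.
    """
    def match(k: int, d: int, target: float) -> bool:
        return d > 0 and round(100.0 * k / d, decimals) == round(target, decimals)

    found = []
    for tp, fp in itertools.product(range(n + 1), repeat=2):
        for fn in range(n - tp - fp + 1):
            tn = n - tp - fp - fn
            if (
                match(tp, tp + fn, sensitivity_pct)
                and match(tn, tn + fp, specificity_pct)
                and match(tp, tp + fp, ppv_pct)
                and match(tn, tn + fn, npv_pct)
            ):
                found.append(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
    return found


def format_report(
    cm: ConfusionMatrix, confidence: float = 0.95, title: str = "Classification report"
) -> str:
    """Human-readable report: counts plus every metric with Wilson and exact CIs."""
    lines = [
        title,
        "=" * len(title),
        f"n = {cm.n}   TP={cm.tp}  FP={cm.fp}  FN={cm.fn}  TN={cm.tn}",
        "",
        f"{'metric':<12} {'estimate':>9} {'wilson ' + format(confidence, '.0%'):>18} {'exact ' + format(confidence, '.0%'):>18}",
    ]
    wilson = metrics(cm, confidence, "wilson")
    exact = metrics(cm, confidence, "exact")
    for name in METRIC_NAMES:
        w, e = wilson[name], exact[name]
        if w.estimate is None:
            lines.append(f"{name:<12} {'undefined':>9}   ({w.note})")
        elif name == "f1":
            lines.append(f"{name:<12} {w.percent:>8.1f}% {'—':>18} {'—':>18}")
        else:
            wci = f"{100*w.ci_low:.1f}–{100*w.ci_high:.1f}%"
            eci = f"{100*e.ci_low:.1f}–{100*e.ci_high:.1f}%"
            lines.append(f"{name:<12} {w.percent:>8.1f}% {wci:>18} {eci:>18}")
    return "\n".join(lines)


def write_report(
    cm: ConfusionMatrix,
    path: str | Path,
    confidence: float = 0.95,
    title: str = "Classification report",
) -> None:
    """Write the tabular metric report (TSV) and a human-readable summary."""
    path = Path(path)
    wilson = metrics(cm, confidence, "wilson")
    exact = metrics(cm, confidence, "exact")
    with open(path, "w") as fh:
        fh.write("metric\testimate_pct\twilson_low_pct\twilson_high_pct\texact_low_pct\texact_high_pct\n")
        for name in METRIC_NAMES:
            w, e = wilson[name], exact[name]
            if w.estimate is None:
                fh.write(f"{name}\tNA\tNA\tNA\tNA\tNA\n")
            elif name == "f1":
                fh.write(f"{name}\t{w.percent:.1f}\tNA\tNA\tNA\tNA\n")
            else:
                fh.write(
                    f"{name}\t{w.percent:.1f}\t{100*w.ci_low:.1f}\t{100*w.ci_high:.1f}"
                    f"\t{100*e.ci_low:.1f}\t{100*e.ci_high:.1f}\n"
                )
    path.with_suffix(path.suffix + ".txt").write_text(
        format_report(cm, confidence, title) + "\n"
    )
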