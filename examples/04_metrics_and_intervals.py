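"""Reconstruct a published subject-validation confusion matrix from its four
printed proportions and report every metric with Wilson and exact intervals.

With n = 92 subjects and sensitivity/specificity/PPV/NPV printed to one
decimal, exhaustive enumeration of nonnegative-integer 2x2 matrices leaves
exactly one solution — enough to recover the accuracy and F1 as well.
"""

from sdbscreen import format_report, reconstruct_confusion

matches = reconstruct_confusion(
    92, sensitivity_pct=72.3, specificity_pct=73.3, ppv_pct=73.9, npv_pct=71.7
)
print(f"consistent integer matrices at n=92: {len(matches)}")
cm = matches[0]
print(format_report(cm, title="Subject-level validation (reconstructed)"))

# The Wilson column is the score-test inversion for a binomial proportion;
# the exact column is the conservative Clopper-Pearson interval.  Both are
# shown because at n = 92 their widths differ visibly.
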