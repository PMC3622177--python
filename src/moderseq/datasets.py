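"""Published summary tables from the Sec24a-deficient mouse study.

These are the printed inputs the genetics statistics operate on: genotype
counts from Sec24a intercrosses (tested against Mendelian ratios),
complete-blood-count group summaries (mean +/- sd, tested with pooled
t-tests), and plasma-cholesterol epistasis comparisons on Apoe- and
Ldlr-null backgrounds (mean +/- sem, tested with Welch t-tests).
"""

from __future__ import annotations

from fractions import Fraction

from .io_formats import CrossCounts, GroupSummary

F = Fraction

#: Intercross genotype counts (observed offspring per genotype class).
INTERCROSS_COUNTS: dict[str, CrossCounts] = {
    # Sec24a +/gt x +/gt: 1:2:1 expectation
    "sec24a_gt_intercross": CrossCounts(
        ("+/+", "+/gt", "gt/gt"), (36, 70, 38), (F(1, 4), F(1, 2), F(1, 4))),
    # Sec24a +/cgt x +/cgt (conditional gene-trap allele)
    "sec24a_cgt_intercross": CrossCounts(
        ("+/+", "+/cgt", "cgt/cgt"), (7, 13, 10), (F(1, 4), F(1, 2), F(1, 4))),
    # Sec24a +/gt2 x +/gt2 (second independent allele)
    "sec24a_gt2_intercross": CrossCounts(
        ("+/+", "+/gt2", "gt2/gt2"), (17, 30, 14), (F(1, 4), F(1, 2), F(1, 4))),
    # Sec24a +/gt Sec24b +/- x Sec24a gt/gt: four classes at 1:1:1:1
    "sec24a_sec24b_cross": CrossCounts(
        ("a+/gt", "a+/gt b+/-", "agt/gt", "agt/gt b+/-"),
        (19, 30, 23, 20), (F(1, 4), F(1, 4), F(1, 4), F(1, 4))),
    # Sec24a +/gt Sec24d +/gt x Sec24a gt/gt: four classes at 1:1:1:1
    "sec24a_sec24d_cross": CrossCounts(
        ("a+/gt", "a+/gt d+/gt", "agt/gt", "agt/gt d+/gt"),
        (21, 28, 26, 20), (F(1, 4), F(1, 4), F(1, 4), F(1, 4))),
}

#: Complete-blood-count survey: wild type (n=10) vs Sec24a gt/gt (n=6),
#: printed as mean +/- sd; the printed p-values reproduce under the pooled
#: t-test.  HGB and HCT do not reproduce exactly under any single variant
#: and are kept here for completeness only.
CBC_COMPARISONS: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "WBC": (GroupSummary("wt", 11.77, 2.67, "sd", 10),
            GroupSummary("gt/gt", 11.53, 1.60, "sd", 6)),
    "RBC": (GroupSummary("wt", 9.89, 0.41, "sd", 10),
            GroupSummary("gt/gt", 9.28, 0.46, "sd", 6)),
    "HGB": (GroupSummary("wt", 12.9, 0.7, "sd", 10),
            GroupSummary("gt/gt", 12.7, 0.5, "sd", 6)),
    "HCT": (GroupSummary("wt", 50.2, 1.5, "sd", 10),
            GroupSummary("gt/gt", 49.2, 2.7, "sd", 6)),
    "MCV": (GroupSummary("wt", 50.78, 0.97, "sd", 10),
            GroupSummary("gt/gt", 52.72, 0.66, "sd", 6)),
    "MCH": (GroupSummary("wt", 13.06, 0.35, "sd", 10),
            GroupSummary("gt/gt", 13.48, 0.23, "sd", 6)),
    "RDW": (GroupSummary("wt", 12.92, 0.61, "sd", 10),
            GroupSummary("gt/gt", 12.62, 0.70, "sd", 6)),
}

#: Plasma total cholesterol (mg/dl) on receptor-pathway-null backgrounds,
#: printed as mean +/- sem; Welch is the default for sem-sourced summaries.
EPISTASIS_COMPARISONS: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "apoe_null": (GroupSummary("Apoe-/-", 272.0, 13.0, "sem", 8),
                  GroupSummary("Apoe-/- Sec24a gt/gt", 277.0, 14.0, "sem", 7)),
    "ldlr_null": (GroupSummary("Ldlr-/-", 211.0, 9.0, "sem", 14),
                  GroupSummary("Ldlr-/- Sec24a gt/gt", 197.0, 12.0, "sem", 11)),
}
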