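"""Reference sample sizes of the multi-ancestry depression meta-analysis.

Published per-group case/control counts of the study this toolkit's
workflows are modelled on. They serve as canonical inputs for worked
examples and sanity checks (cohort accounting, inflation rescaling);
no individual-level data are involved.
"""

from .sumstats import StudyMeta

#: Per-ancestry-group meta-analysis sample sizes (broad depression
#: definition). Non-European groups are the study's newly added cohorts;
#: the European entry is the previously published discovery data.
GROUP_SAMPLE_SIZES: dict[str, StudyMeta] = {
    "AFR": StudyMeta("meta_AFR", "AFR", n_cases=36_818, n_controls=161_679),
    "EAS": StudyMeta("meta_EAS", "EAS", n_cases=21_980, n_controls=360_956),
    "SAS": StudyMeta("meta_SAS", "SAS", n_cases=4_505, n_controls=27_176),
    "HIS": StudyMeta("meta_HIS", "HIS", n_cases=25_013, n_controls=352_946),
    "EUR": StudyMeta("meta_EUR", "EUR", n_cases=258_364, n_controls=571_252),
}

#: Totals of the combined multi-ancestry meta-analysis as published
#: (totals reflect the final analysed set, not a plain sum of the
#: per-group entries above).
MULTI_ANCESTRY_TOTALS = {"n_cases": 345_389, "n_controls": 1_469_702}

#: Genomic inflation of the multi-ancestry meta-analysis and the LDSC
#: intercept used to correct its test statistics.
MULTI_ANCESTRY_LAMBDA = 1.687
MULTI_ANCESTRY_LDSC_INTERCEPT = 1.019


def non_european_totals() -> tuple[int, int]:
    """Summed case and control counts of the four non-European groups."""
    groups = [g for k, g in GROUP_SAMPLE_SIZES.items() if k != "EUR"]
    return (sum(g.n_cases for g in groups), sum(g.n_controls for g in groups))
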