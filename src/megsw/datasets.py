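"""Published group-level summaries of the emulated study cohort.

The study itself deposited no MEG recordings; what it did publish is the
demographic/neuropsychological summary table of its analysed sample
(24 healthy controls, 18 patients with Alzheimer's disease). Those printed
summaries — group means, standard deviations, counts — are sufficient inputs
to recompute the between-group test statistics (pooled-variance Student t and
Pearson chi-square), which is done by
:func:`demographic_comparisons`.
"""

from __future__ import annotations

from .core import GroupComparison
from .stats import chi_square_2x2, two_sample_t_from_summary

__all__ = ["COHORT_SUMMARY", "SEX_COUNTS", "demographic_comparisons"]

#: Group sizes of the analysed sample.
N_CONTROL = 24
N_AD = 18

#: variable -> ((control mean, control sd), (AD mean, AD sd))
COHORT_SUMMARY: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "age": ((68.4, 6.9), (71.8, 6.2)),
    "education_years": ((12.1, 3.0), (11.6, 2.6)),
    "mmse": ((28.8, 0.9), (22.0, 3.6)),
    "wmsr_attention_concentration": ((105.0, 11.7), (87.8, 16.0)),
    "wmsr_general_memory": ((100.7, 10.5), (66.1, 12.8)),
    "wmsr_verbal_memory": ((100.0, 11.0), (70.5, 11.6)),
    "wmsr_visual_memory": ((102.1, 11.4), (67.4, 14.3)),
    "wmsr_delayed_recall": ((98.8, 11.7), (60.8, 11.1)),
}

#: (control male, control female, AD male, AD female)
SEX_COUNTS: tuple[int, int, int, int] = (15, 9, 11, 7)


def demographic_comparisons() -> dict[str, GroupComparison]:
    """Recompute every between-group statistic from the published summaries."""
    out: dict[str, GroupComparison] = {}
    for variable, ((m1, s1), (m2, s2)) in COHORT_SUMMARY.items():
        out[variable] = two_sample_t_from_summary(
            m1, s1, N_CONTROL, m2, s2, N_AD, variable=variable
        )
    out["sex"] = chi_square_2x2(*SEX_COUNTS, variable="sex")
    return out
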