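"""Reference confusion counts from the published audit of 1070 RCTs.

The audit tested every trial with the SCT I² test and tallied the results
against RoB 2 ratings in four analyses.  Only these printed tallies are
stored; every derived statistic (FOR, CIs, −LR, ...) is recomputed by
:mod:`sctbias.diagnostics` at run time.
"""

from __future__ import annotations

from .diagnostics import ConfusionCounts, DiagnosticSummary, summarize

#: Printed confusion tables: overall RoB 2 rating vs I² test (main
#: analysis of 1070 trials), the sensitivity rerun adding 140
#: median-reported trials, the rerun excluding 131 non-age baseline
#: variables, and the RoB 2 domain-1 subgroup of 768 trials.
REFERENCE_COUNTS: dict[str, ConfusionCounts] = {
    "main": ConfusionCounts(tp=37, fn=46, tn=562, fp=425),
    "sensitivity_median_added": ConfusionCounts(tp=45, fn=49, tn=629, fp=487),
    "sensitivity_age_only": ConfusionCounts(tp=40, fn=41, tn=559, fp=438),
    "domain1_subgroup": ConfusionCounts(tp=3, fn=42, tn=635, fp=88),
}


def reference_summaries(
    prevalence_rounding: int | None = 1,
) -> dict[str, DiagnosticSummary]:
    """Recompute the full diagnostic summary for each reference analysis."""
    return {
        name: summarize(counts, prevalence_rounding=prevalence_rounding)
        for name, counts in REFERENCE_COUNTS.items()
    }
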