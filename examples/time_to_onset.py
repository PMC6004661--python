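"""Time-to-onset comparison of the two drug classes.

Derives per-report event times (days from drug start to GERD-like onset for
cases; to end of drug use for censored non-cases; administrative cap at 365
days), estimates Kaplan-Meier curves per class and compares them by the
log-rank test.  The default generator gives GLP-1 receptor agonists a
shorter onset latency (Weibull median ~42 days vs ~104 days).
"""

import numpy as np

from pvsignal import (
    apply_exclusions,
    default_config,
    dpp4_class,
    gerd_pt_set,
    glp1_class,
    km_curve,
    logrank,
    simulate,
    survival_records,
)

reports = apply_exclusions(simulate(default_config(n_reports=30_000, seed=11)))
pts = gerd_pt_set()

groups = {}
for cls in (glp1_class(), dpp4_class()):
    records, excluded = survival_records(reports, cls, pts)
    groups[cls.class_name] = records
    events = [r.time for r in records if r.event]
    print(
        f"{cls.class_name}: {len(records)} usable records ({excluded} excluded "
        f"for missing dates), {len(events)} onsets, median onset day "
        f"{np.median(events):.0f}"
    )
    curve = km_curve(records)
    day180 = curve.survival[curve.times <= 180][-1]
    print(f"  KM survival (event-free fraction) at day 180: {day180:.3f}")

res = logrank(groups["GLP-1-RAs"], groups["DPP-4-Is"])
print(f"log-rank: chi2 = {res.statistic:.2f}, p = {res.p_value:.2e}")
print()
print("A small p-value says the onset-time profiles differ: GERD-like symptoms")
print("appear earlier under GLP-1 receptor agonists than under DPP-4 inhibitors.")
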