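"""Stratified signal detection.

Partitions a filtered report set by sex or by an age threshold (decade
buckets only, so the threshold must sit on a bucket boundary; the default 70
puts buckets 70-79 and above in the older stratum), recomputes the full
disproportionality result inside each stratum as a standalone case/non-case
analysis (each stratum uses its own size as N), and compares the strata by
their signal values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .contingency import build_table
from .dispro import BcpnnPriors, SignalResult, analyze, compare_signal_values
from .reports import DrugClassDef, PTSet, ReportSet, SEXES


@dataclass(frozen=True)
class StratumSpec:
    """Which axis to split on: 'sex', or 'age' with a decade threshold."""

    axis: str
    age_threshold: int = 70

    def __post_init__(self) -> None:
        if self.axis not in ("sex", "age"):
            raise ValueError("axis must be 'sex' or 'age'")
        if self.axis == "age" and self.age_threshold % 10 != 0:
            raise ValueError("age threshold must sit on a decade-bucket boundary")

    @property
    def labels(self) -> tuple[str, str]:
        if self.axis == "sex":
            return SEXES
        return (f">={self.age_threshold}y", f"<{self.age_threshold}y")


def split(reports: ReportSet, spec: StratumSpec) -> tuple[ReportSet, ReportSet]:
    """Disjoint partition: (male, female) or (older, younger).

    Requires the inclusion filters to have run already, so sex and a numeric
    decade bucket are present on every report.
    """
    if spec.axis == "sex":
        return (
            reports.filter(lambda r: r.sex == "male"),
            reports.filter(lambda r: r.sex == "female"),
        )
    thr = spec.age_threshold
    return (
        reports.filter(lambda r: r.age_lower_bound is not None and r.age_lower_bound >= thr),
        reports.filter(lambda r: r.age_lower_bound is not None and r.age_lower_bound < thr),
    )


@dataclass(frozen=True)
class StratifiedResult:
    spec: StratumSpec
    result_a: SignalResult  # male / older
    result_b: SignalResult  # female / younger
    verdict: str  # a_dominant | b_dominant | no_difference | not_evaluable


def stratified_signals(
    reports: ReportSet,
    target: DrugClassDef | str,
    pts: PTSet,
    spec: StratumSpec,
    priors: BcpnnPriors | None = None,
    yates: bool = False,
    include_concomitant: bool = False,
) -> StratifiedResult:
    """Per-stratum signal results plus the signal-value dominance verdict."""
    stratum_a, stratum_b = split(reports, spec)
    label = target.class_name if isinstance(target, DrugClassDef) else target
    la, lb = spec.labels
    res_a = analyze(
        build_table(stratum_a, target, pts, include_concomitant=include_concomitant),
        target=f"{label}[{la}]", event_set=pts.name, priors=priors, yates=yates,
    )
    res_b = analyze(
        build_table(stratum_b, target, pts, include_concomitant=include_concomitant),
        target=f"{label}[{lb}]", event_set=pts.name, priors=priors, yates=yates,
    )
    verdict = compare_signal_values(res_a.signal_value, res_b.signal_value)
    return StratifiedResult(spec=spec, result_a=res_a, result_b=res_b, verdict=verdict)
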