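"""Disproportionality statistics and signal criteria.

Given the case/non-case 2x2 table this module computes:

* ROR, the reporting odds ratio ad/bc, with the Woolf (log-normal) 95%
  interval exp(ln ROR ± z sqrt(1/a + 1/b + 1/c + 1/d));
* PRR, the proportional reporting ratio (a/(a+b)) / (c/(c+d));
* the Pearson chi-square statistic of the table;
* IC, the BCPNN information component — the posterior expectation of
  log2 of the observed-to-expected joint reporting probability under the
  original Bayesian confidence propagation neural network closed form, with
  credible bounds at E(IC) ± k posterior standard deviations;
* the signal value ln(PRR) + ln(chi-square), a scalar used to compare
  association strength between two strata.

Signal criteria follow the lower-bound convention (ROR lower 95% bound > 1,
IC lower bound > 0); an *inverse* signal — disproportionately few reports,
suggesting a negative association — requires the upper bounds to exclude the
null (ROR upper bound < 1, IC upper bound < 0).

Undefined-value convention: ROR, PRR and the signal value are undefined on
zero cells and are carried as None (rendered as a dash); the IC is defined
for every table thanks to shrinkage, but is flagged not-evaluable for signal
purposes when a = 0, matching how drugs with no case reports are presented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .contingency import ContingencyTable

__all__ = [
    "BcpnnPriors", "SignalResult", "ror_with_ci", "prr", "chi2", "ic_with_ci",
    "signal_value", "compare_signal_values", "analyze", "detect",
    "round_half_up", "results_to_frame",
]


def round_half_up(x: float | None, ndigits: int = 2) -> float | None:
    """Round half away from zero, the convention of published signal tables."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BcpnnPriors:
    """Pseudo-count priors of the original BCPNN information component.

    ``alpha1``/``beta1`` are the marginal prior successes, ``alpha``/``beta``
    the marginal prior totals, and ``gamma11`` the joint prior pseudo-count.
    The defaults (1, 1, 2, 2, 1) give the symmetric uniform-prior
    configuration under which IC shrinks toward 0 for sparse cells.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha, self.beta, self.gamma11) <= 0:
            raise ValueError("all BCPNN prior parameters must be positive")


def ror_with_ci(
    t: ContingencyTable, z: float = 1.96
) -> tuple[float | None, float | None, float | None]:
    """Reporting odds ratio with the Woolf log-normal interval.

    Undefined (None, None, None) when any cell is zero: the odds ratio or
    its variance estimate degenerates, and published tables print a dash.
    """
    a, b, c, d = t.as_tuple()
    if min(a, b, c, d) == 0:
        return (None, None, None)
    ror = (a * d) / (b * c)
    half = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (ror, ror * math.exp(-half), ror * math.exp(half))


def prr(t: ContingencyTable) -> float | None:
    """Proportional reporting ratio; None when the comparator rate is zero."""
    a, b, c, d = t.as_tuple()
    if a + b == 0 or c == 0 or c + d == 0:
        return None
    return (a / (a + b)) / (c / (c + d))


def chi2(t: ContingencyTable, yates: bool = False) -> float | None:
    """Pearson chi-square of the 2x2 table (optional Yates correction).

    None when any marginal is zero (the statistic is undefined).
    """
    a, b, c, d = t.as_tuple()
    if min(a + b, c + d, a + c, b + d) == 0:
        return None
    stat, _, _, _ = stats.chi2_contingency(
        np.array([[a, b], [c, d]]), correction=yates
    )
    return float(stat)


def ic_with_ci(
    t: ContingencyTable, priors: BcpnnPriors | None = None, k: float = 2.0
) -> tuple[float, float, float]:
    """BCPNN information component with k-standard-deviation credible bounds.

    The closed-form posterior moments of IC = log2( p(drug, event) /
    (p(drug) p(event)) ) under Dirichlet/Beta priors: with C = N, cx = n1+,
    cy = n+1, cxy = a and prior pseudo-counts (alpha1, beta1, alpha, beta,
    gamma11), the joint prior gamma is scaled so that the prior expectation
    of IC is 0; the variance combines the three Beta posterior variances on
    the log2 scale.  Defined for every table, including zero cells.
    """
    p = priors or BcpnnPriors()
    a, b, c, d = t.as_tuple()
    C = a + b + c + d
    cx = t.n1plus
    cy = t.nplus1
    cxy = a
    gamma = p.gamma11 * (C + p.alpha) * (C + p.beta) / ((cx + p.alpha1) * (cy + p.beta1))
    e_ic = math.log2(
        (cxy + p.gamma11) * (C + p.alpha) * (C + p.beta)
        / ((C + gamma) * (cx + p.alpha1) * (cy + p.beta1))
    )
    v_ic = (
        (C - cxy + gamma - p.gamma11) / ((cxy + p.gamma11) * (1 + C + gamma))
        + (C - cx + p.alpha - p.alpha1) / ((cx + p.alpha1) * (1 + C + p.alpha))
        + (C - cy + p.beta - p.beta1) / ((cy + p.beta1) * (1 + C + p.beta))
    ) / math.log(2) ** 2
    sd = math.sqrt(v_ic)
    return (e_ic, e_ic - k * sd, e_ic + k * sd)


def signal_value(t: ContingencyTable, yates: bool = False) -> float | None:
    """ln(PRR) + ln(chi-square); None when either factor is non-positive
    or undefined."""
    p = prr(t)
    x = chi2(t, yates=yates)
    if p is None or x is None or p <= 0 or x <= 0:
        return None
    return math.log(p) + math.log(x)


def compare_signal_values(sv_a: float | None, sv_b: float | None) -> str:
    """Two-group dominance verdict on signal values.

    Group A dominates when sv_a > 2*sv_b (strictly), and symmetrically for
    B; otherwise the groups are not distinguished.  Undefined inputs make
    the comparison not evaluable.
    """
    if sv_a is None or sv_b is None:
        return "not_evaluable"
    if sv_a > 2 * sv_b:
        return "a_dominant"
    if sv_b > 2 * sv_a:
        return "b_dominant"
    return "no_difference"


@dataclass(frozen=True)
class SignalResult:
    """Full disproportionality result for one drug(-class) x event-set pair."""

    target: str
    event_set: str
    table: ContingencyTable
    ror: float | None
    ror_lo: float | None
    ror_hi: float | None
    prr: float | None
    chi2: float | None
    ic: float
    ic_lo: float
    ic_hi: float
    ic_evaluable: bool
    signal_value: float | None
    signal_ror: bool = False
    signal_ic: bool = False
    inverse_ror: bool = False
    inverse_ic: bool = False

    @property
    def signal_both(self) -> bool:
        return self.signal_ror and self.signal_ic

    @property
    def inverse_both(self) -> bool:
        return self.inverse_ror and self.inverse_ic


def detect(result: SignalResult) -> SignalResult:
    """Apply the interval-based signal and inverse-signal criteria.

    signal_ror  <=> ROR 95% lower bound > 1     signal_ic  <=> IC lower bound > 0
    inverse_ror <=> ROR 95% upper bound < 1     inverse_ic <=> IC upper bound < 0

    Undefined statistics never raise a flag.
    """
    sig_ror = result.ror_lo is not None and result.ror_lo > 1.0
    inv_ror = result.ror_hi is not None and result.ror_hi < 1.0
    sig_ic = result.ic_evaluable and result.ic_lo > 0.0
    inv_ic = result.ic_evaluable and result.ic_hi < 0.0
    return replace(
        result,
        signal_ror=sig_ror, signal_ic=sig_ic,
        inverse_ror=inv_ror, inverse_ic=inv_ic,
    )


def analyze(
    table: ContingencyTable,
    target: str = "",
    event_set: str = "",
    priors: BcpnnPriors | None = None,
    z: float = 1.96,
    k: float = 2.0,
    yates: bool = False,
) -> SignalResult:
    """Compute every statistic for one table and apply the signal criteria."""
    ror, lo, hi = ror_with_ci(table, z=z)
    ic, ic_lo, ic_hi = ic_with_ci(table, priors=priors, k=k)
    result = SignalResult(
        target=target,
        event_set=event_set,
        table=table,
        ror=ror, ror_lo=lo, ror_hi=hi,
        prr=prr(table),
        chi2=chi2(table, yates=yates),
        ic=ic, ic_lo=ic_lo, ic_hi=ic_hi,
        ic_evaluable=table.a > 0,
        signal_value=signal_value(table, yates=yates),
    )
    return detect(result)


def results_to_frame(results, ndigits: int = 2):
    """Serialize results to a DataFrame mirroring published signal tables.

    Point estimates and bounds are rounded half-up at serialization only;
    undefined entries become NaN (rendered as a dash downstream).
    """
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "target": r.target,
            "event_set": r.event_set,
            "n11": r.table.a,
            "n1plus": r.table.n1plus,
            "ror": round_half_up(r.ror, ndigits),
            "ror_lo": round_half_up(r.ror_lo, ndigits),
            "ror_hi": round_half_up(r.ror_hi, ndigits),
            "ic": round_half_up(r.ic if r.ic_evaluable else None, ndigits),
            "ic_lo": round_half_up(r.ic_lo if r.ic_evaluable else None, ndigits),
            "ic_hi": round_half_up(r.ic_hi if r.ic_evaluable else None, ndigits),
            "prr": round_half_up(r.prr, ndigits),
            "chi2": round_half_up(r.chi2, ndigits),
            "signal_ror": r.signal_ror,
            "signal_ic": r.signal_ic,
            "signal_both": r.signal_both,
            "inverse_ror": r.inverse_ror,
            "inverse_ic": r.inverse_ic,
            "signal_value": round_half_up(r.signal_value, ndigits),
        })
    return pd.DataFrame(rows)
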