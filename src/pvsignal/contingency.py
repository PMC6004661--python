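"""Case/non-case 2x2 contingency tables.

The disproportionality design cross-classifies every report in the filtered
database by exposure (target drug or class among its suspect drugs) and
outcome (any event PT in the query set):

              event        no event
  exposed       a (n11)      b          n1+ = a+b
  unexposed     c            d          N  = a+b+c+d
                n+1 = a+c

The comparator is *all other reports in the database*: class-wide analyses do
not remove same-class drugs from the comparator, so d = N - n1+ - c.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reports import DrugClassDef, PTSet, ReportSet, classify_case, is_exposed


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # exposed, event  (n11)
    b: int  # exposed, no event
    c: int  # unexposed, event
    d: int  # unexposed, no event

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n1plus(self) -> int:
        """Reports exposed to the target drug (all adverse events)."""
        return self.a + self.b

    @property
    def nplus1(self) -> int:
        """Reports with the target event (all drugs)."""
        return self.a + self.c

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def table_from_marginals(n11: int, n1plus: int, nplus1: int, n_total: int) -> ContingencyTable:
    """Reconstruct the 2x2 table from the marginal counts a study prints.

    Published disproportionality tables report n11, the drug total n1+, the
    event total n+1 and the database size N; the remaining cells follow by
    subtraction, which is what makes printed signal values exactly
    recomputable.
    """
    if n11 > n1plus:
        raise ValueError(f"n11={n11} exceeds drug marginal n1plus={n1plus}")
    if n11 > nplus1:
        raise ValueError(f"n11={n11} exceeds event marginal nplus1={nplus1}")
    if n1plus + nplus1 - n11 > n_total:
        raise ValueError(
            f"marginals n1plus={n1plus}, nplus1={nplus1} inconsistent with N={n_total}"
        )
    return ContingencyTable(
        a=n11, b=n1plus - n11, c=nplus1 - n11, d=n_total - n1plus - nplus1 + n11
    )


def build_table(
    reports: ReportSet,
    target: DrugClassDef | str,
    pts: PTSet,
    include_concomitant: bool = False,
) -> ContingencyTable:
    """Count the 2x2 table over a (filtered) report set.

    Each report contributes to exactly one cell regardless of how many
    matching drugs or PTs it lists, so the four cells always sum to the
    number of reports.
    """
    a = b = c = d = 0
    for r in reports:
        case = classify_case(r, pts)
        exposed = is_exposed(r, target, include_concomitant=include_concomitant)
        if exposed and case:
            a += 1
        elif exposed:
            b += 1
        elif case:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)
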