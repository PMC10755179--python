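"""Clone-screen association: 2x2 tables, Fisher's exact test, prevalence.

The screen scores clonal isolates on two binary traits — whether the clone
fruits in isolation and whether it carries the called variant — yielding a
2x2 table per line (or pooled per gene region). Significance uses Fisher's
exact test computed from first principles: with the margins fixed, the
two-sided p-value is the sum of hypergeometric probabilities of all tables
no more probable than the observed one (minimum-likelihood method, the
common software default), with a small relative tolerance for floating-point
ties. Probabilities are computed in log space via cumulative log-factorials.

Prevalence of non-fruiting among clonal plaques is reported with an exact
(Clopper-Pearson) binomial confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from scipy.stats import beta as beta_dist

TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of the four clone types.

    a: carriers & non-fruiting, b: non-carriers & non-fruiting,
    c: carriers & fruiting,     d: non-carriers & fruiting.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("all cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple:
        return (self.a, self.b, self.c, self.d)

    def carrier_pct_nonfruiting(self) -> Optional[float]:
        """Carriers among non-fruiters, in percent; None when no non-fruiters."""
        n = self.a + self.b
        return None if n == 0 else 100.0 * self.a / n

    def carrier_pct_fruiting(self) -> Optional[float]:
        n = self.c + self.d
        return None if n == 0 else 100.0 * self.c / n


_LOGFACT = [0.0]


def _logfact(n: int) -> float:
    while len(_LOGFACT) <= n:
        _LOGFACT.append(_LOGFACT[-1] + math.log(len(_LOGFACT)))
    return _LOGFACT[n]


def _log_hypergeom(a: int, r1: int, c1: int, n: int) -> float:
    """log P(A = a) with margins (r1, n - r1) x (c1, n - c1) fixed."""
    return (_logfact(r1) + _logfact(n - r1) + _logfact(c1) + _logfact(n - c1)
            - _logfact(n) - _logfact(a) - _logfact(r1 - a)
            - _logfact(c1 - a) - _logfact(n - r1 - c1 + a))


def fisher_exact(t: ContingencyTable) -> float:
    """Two-sided Fisher's exact p-value by the minimum-likelihood method."""
    if t.total < 1:
        raise ValueError("table total must be >= 1")
    n = t.total
    r1 = t.a + t.b
    c1 = t.a + t.c
    a_min = max(0, r1 + c1 - n)
    a_max = min(r1, c1)
    log_obs = _log_hypergeom(t.a, r1, c1, n)
    cutoff = log_obs + math.log1p(TIE_RTOL)
    p = 0.0
    for a in range(a_min, a_max + 1):
        lp = _log_hypergeom(a, r1, c1, n)
        if lp <= cutoff:
            p += math.exp(lp)
    return min(p, 1.0)


@dataclass(frozen=True)
class OddsRatio:
    value: Optional[float]  # None marks the undefined 0/0 case
    infinite: bool = False


def odds_ratio(t: ContingencyTable) -> OddsRatio:
    """(a*d)/(b*c); infinite when b*c = 0 < a*d, undefined when both are 0."""
    if t.total < 1:
        raise ValueError("table total must be >= 1")
    ad, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        if ad == 0:
            return OddsRatio(value=None)
        return OddsRatio(value=math.inf, infinite=True)
    return OddsRatio(value=ad / bc)


def build_contingency(records, group_by: str = "line", region_map=None) -> dict:
    """Tally clone-screen records into 2x2 tables.

    ``group_by`` is "line", "variant" or "region" (the latter requires
    ``region_map``: variant_id -> region). The partition is exhaustive:
    every record lands in exactly one cell of its group's table.
    """
    if group_by not in ("line", "variant", "region"):
        raise ValueError("group_by must be line, variant or region")
    cells: dict = {}
    for r in records:
        if group_by == "line":
            key = r.line
        elif group_by == "variant":
            key = r.variant_id
        else:
            if region_map is None or r.variant_id not in region_map:
                raise ValueError(f"variant {r.variant_id!r} has no region assignment")
            key = region_map[r.variant_id]
        counts = cells.setdefault(key, [0, 0, 0, 0])
        idx = (0 if not r.fruits else 2) + (0 if r.carries else 1)
        counts[idx] += 1
    return {k: ContingencyTable(*v) for k, v in cells.items()}


@dataclass
class GroupResult:
    table: ContingencyTable
    p_value: float
    odds: OddsRatio
    carrier_pct_nonfruiting: Optional[float]
    carrier_pct_fruiting: Optional[float]


@dataclass
class ScreenReport:
    per_line: dict   # line -> GroupResult
    per_region: dict  # region -> GroupResult


def _group_result(table: ContingencyTable) -> GroupResult:
    return GroupResult(
        table=table,
        p_value=fisher_exact(table),
        odds=odds_ratio(table),
        carrier_pct_nonfruiting=table.carrier_pct_nonfruiting(),
        carrier_pct_fruiting=table.carrier_pct_fruiting(),
    )


def screen_report(records, region_map: dict) -> ScreenReport:
    """Per-line tests plus region-pooled aggregates.

    Every variant must have a region assignment; aggregation across lines is
    simple pooling of the cell counts.
    """
    for r in records:
        if r.variant_id not in region_map:
            raise ValueError(f"variant {r.variant_id!r} has no region assignment")
    per_line = {line: _group_result(t)
                for line, t in build_contingency(records, "line").items()}
    per_region = {reg: _group_result(t)
                  for reg, t in build_contingency(records, "region",
                                                  region_map).items()}
    return ScreenReport(per_line=per_line, per_region=per_region)


@dataclass(frozen=True)
class Prevalence:
    proportion: float
    ci_low: float
    ci_high: float
    k: int
    n: int
    conf: float


def prevalence(k: int, n: int, conf: float = 0.95) -> Prevalence:
    """Proportion k/n with an exact Clopper-Pearson interval at ``conf``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    alpha = 1.0 - conf
    low = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return Prevalence(proportion=k / n, ci_low=low, ci_high=high,
                      k=k, n=n, conf=conf)


def mean_or_none(values) -> Optional[float]:
    vals = [v for v in values if v is not None]
    if not vals:
        warnings.warn("no data for mean", stacklevel=2)
        return None
    return sum(vals) / len(vals)
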