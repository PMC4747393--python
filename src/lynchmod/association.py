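"""Burden-phenotype association statistics built from first principles.

Contingency construction, two-sided Fisher exact test (probability-mass
ordering, computed in log space), Pearson chi-square (upper tail via the
regularized incomplete gamma function), two-sample t, the Kaplan-Meier
product-limit estimator and the Mantel-Cox log-rank test.  scipy supplies
only distribution tails (incomplete gamma, Student t); every statistic is
assembled here.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import special, stats as _scipy_stats

from .cohort import PhenotypeLabel
from .curation import BurdenProfile
from .errors import DegenerateTableError


@dataclass(frozen=True)
class ContingencyTable:
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.row_labels):
            raise ValueError("row label / count mismatch")
        for row in self.counts:
            if len(row) != len(self.col_labels):
                raise ValueError("column label / count mismatch")
            if any(c < 0 for c in row):
                raise ValueError("negative count")
        if len(self.row_labels) < 2 or len(self.col_labels) < 2:
            raise ValueError("contingency table must be at least 2x2")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    def margins(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.matrix
        return m.sum(axis=1), m.sum(axis=0)


@dataclass(frozen=True)
class TestResult:
    p_value: float
    method: str
    statistic: Optional[float] = None
    df: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    time: float  # event or censoring age, years
    event: bool
    group: str  # low_burden | high_burden

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")


def load_published_burden_distribution() -> ContingencyTable:
    """The printed 6x2 burden-by-phenotype distribution shipped as a fixture."""
    ref = resources.files("lynchmod.data").joinpath("published_burden.json")
    payload = json.loads(ref.read_text())
    rows = tuple(str(level) for level in payload["burden_levels"])
    counts = tuple(
        (int(n), int(p)) for n, p in zip(payload["neutral"], payload["poor"])
    )
    return ContingencyTable(rows, ("neutral", "poor"), counts)


def burden_table(
    profiles: Iterable[BurdenProfile],
    phenotypes: dict[str, PhenotypeLabel | str],
    max_count: Optional[int] = None,
) -> ContingencyTable:
    """Cross-tabulate exact burden counts (rows) against phenotype (columns)."""
    profiles = list(profiles)
    if not profiles:
        raise DegenerateTableError("empty cohort")
    missing = [p.subject_id for p in profiles if p.subject_id not in phenotypes]
    if missing:
        raise DegenerateTableError(
            f"phenotype missing for subjects: {', '.join(sorted(missing))}"
        )
    top = max(p.n_risk_variants_non_mmr for p in profiles)
    if max_count is None:
        max_count = top
    pooled = top > max_count
    n_rows = max_count + 1
    counts = np.zeros((n_rows, 2), dtype=np.int64)
    for p in profiles:
        label = phenotypes[p.subject_id]
        name = label.label if isinstance(label, PhenotypeLabel) else str(label)
        col = {"neutral": 0, "poor": 1}[name]
        counts[min(p.n_risk_variants_non_mmr, max_count), col] += 1
    rows = [str(i) for i in range(n_rows)]
    if pooled:
        rows[-1] = f"{max_count}+"
    return ContingencyTable(
        tuple(rows),
        ("neutral", "poor"),
        tuple(tuple(int(x) for x in row) for row in counts),
    )


def dichotomize(table: ContingencyTable, k: int = 2) -> ContingencyTable:
    """Collapse burden rows into (0..k-1) vs (>=k), preserving margins."""
    m = table.matrix
    if not 1 <= k <= len(table.row_labels) - 1:
        raise DegenerateTableError(
            f"cannot dichotomize {len(table.row_labels)} rows at k={k}"
        )
    low = tuple(int(x) for x in m[:k].sum(axis=0))
    high = tuple(int(x) for x in m[k:].sum(axis=0))
    return ContingencyTable(
        (f"0-{k - 1}" if k > 1 else "0", f">={k}"),
        table.col_labels,
        (low, high),
    )


def _log_hypergeom_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(X = a) for the 2x2 hypergeometric with fixed margins."""
    n = r1 + r2
    lg = math.lgamma
    return (
        lg(r1 + 1) - lg(a + 1) - lg(r1 - a + 1)
        + lg(r2 + 1) - lg(c1 - a + 1) - lg(r2 - c1 + a + 1)
        - (lg(n + 1) - lg(c1 + 1) - lg(n - c1 + 1))
    )


def fisher_exact_2x2(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test by probability-mass ordering.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed that of the observed table
    (with a 1e-7 relative tolerance against floating-point ties), computed
    in log space.
    """
    m = table.matrix
    if m.shape != (2, 2):
        raise DegenerateTableError("Fisher exact test requires a 2x2 table")
    (a, b), (c, d) = m
    r1, r2, c1 = a + b, c + d, a + c
    if 0 in (r1, r2, c1, b + d):
        raise DegenerateTableError("zero margin")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    lp_obs = _log_hypergeom_pmf(int(a), int(r1), int(r2), int(c1))
    cutoff = lp_obs + math.log1p(1e-7)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = _log_hypergeom_pmf(x, int(r1), int(r2), int(c1))
        if lp <= cutoff:
            total += math.exp(lp)
    return TestResult(
        p_value=min(1.0, total), method="fisher_exact_two_sided"
    )


def pearson_chi_square(table: ContingencyTable) -> TestResult:
    """Pearson chi-square of independence, no continuity correction."""
    obs = table.matrix.astype(float)
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("zero margin")
    expected = np.outer(rows, cols) / obs.sum()
    if (expected < 5).any():
        warnings.warn(
            "chi-square expected counts below 5; the asymptotic p-value "
            "may be unreliable",
            stacklevel=2,
        )
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(special.gammaincc(df / 2.0, statistic / 2.0))
    return TestResult(
        p_value=p, method="pearson_chi_square", statistic=statistic, df=df
    )


def two_sample_t(
    group1: Sequence[float], group2: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sided two-sample t-test (pooled variance by default)."""
    x, y = np.asarray(group1, float), np.asarray(group2, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = n1 + n2 - 2
    if se2 == 0:
        t = 0.0 if diff == 0 else math.inf
    else:
        t = float(diff / math.sqrt(se2))
    p = float(2 * _scipy_stats.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    method = "welch_t" if welch else "student_t_pooled"
    return TestResult(p_value=min(1.0, p), method=method, statistic=t, df=None)


@dataclass(frozen=True)
class KMCurve:
    group: str
    times: tuple[float, ...]
    n_risk: tuple[int, ...]
    n_event: tuple[int, ...]
    survival: tuple[float, ...]

    def at(self, t: float) -> float:
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s


def kaplan_meier(records: Iterable[SurvivalRecord]) -> dict[str, KMCurve]:
    """Product-limit survival estimate per group.

    At tied times, events are processed before censorings: subjects censored
    at t remain in the risk set for an event at t.
    """
    by_group: dict[str, list[SurvivalRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec)
    curves = {}
    for group, recs in sorted(by_group.items()):
        event_times = sorted({r.time for r in recs if r.event})
        at_risk = len(recs)
        s = 1.0
        times, risks, events, survival = [], [], [], []
        removed = sorted(recs, key=lambda r: (r.time, not r.event))
        idx = 0
        for t in event_times:
            while idx < len(removed) and (
                removed[idx].time < t
            ):
                at_risk -= 1
                idx += 1
            d = sum(1 for r in recs if r.event and r.time == t)
            s *= 1.0 - d / at_risk
            times.append(t)
            risks.append(at_risk)
            events.append(d)
            survival.append(s)
        curves[group] = KMCurve(
            group, tuple(times), tuple(risks), tuple(events), tuple(survival)
        )
    return curves


def log_rank(records: Iterable[SurvivalRecord]) -> TestResult:
    """Mantel-Cox log-rank test between two groups.

    statistic = (sum_j (O1j - E1j))^2 / sum_j Vj over distinct event times,
    with the hypergeometric variance Vj; p from chi-square with 1 df.
    """
    recs = list(records)
    groups = sorted({r.group for r in recs})
    if len(groups) != 2:
        raise ValueError(f"log-rank requires exactly two groups, got {groups}")
    if not any(r.event for r in recs):
        raise ValueError("no events observed")
    g1 = groups[0]
    event_times = sorted({r.time for r in recs if r.event})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = [r for r in recs if r.time >= t]
        n = len(at_risk)
        n1 = sum(1 for r in at_risk if r.group == g1)
        d = sum(1 for r in recs if r.event and r.time == t)
        d1 = sum(1 for r in recs if r.event and r.time == t and r.group == g1)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        statistic = 0.0 if o_minus_e == 0 else math.inf
    else:
        statistic = o_minus_e**2 / var
    p = (
        float(special.gammaincc(0.5, statistic / 2.0))
        if math.isfinite(statistic)
        else 0.0
    )
    return TestResult(
        p_value=p, method="log_rank_mantel_cox", statistic=statistic, df=1
    )
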