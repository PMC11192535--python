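"""Parasitism-assay and host-choice statistics.

Replicate-level assay records are reduced to the field's standard summary
statistics:

* parasitism rate  = (1 − emerged host adults / total hosts) × 100
* emergence rate   = (emerged wasps / total hosts) × 100
* oviposition index = (N1 − Nx) / (N1 + Nx) × 100, the signed preference for
  the 1-day-old host side in a two-choice assay
* superparasitism fold recovery = mean super rate / mean mono rate

Preference indices are tested against zero with the Wilcoxon signed-rank test
(exact p by full sign enumeration for small n, computed with a dynamic program
over signed midranks) and group comparisons use the Mann-Whitney U test.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NoInformationError

__all__ = [
    "ParasitismAssayRecord",
    "ChoiceAssayRecord",
    "DissectionRecord",
    "RateSummary",
    "TestResult",
    "parasitism_rate",
    "emergence_rate",
    "oviposition_index",
    "signed_rank_test",
    "mann_whitney_u",
    "fold_recovery",
    "summarize_conditions",
    "oviposition_rate",
]

logger = logging.getLogger("effectorscan")

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_MWU_MAX_N = 16


@dataclass
class ParasitismAssayRecord:
    replicate: str
    host_species: str
    host_age_days: int
    mode: str  # mono | super
    n_hosts: int
    n_emerged_host_adults: int
    n_emerged_wasps: int

    def __post_init__(self) -> None:
        if self.mode not in ("mono", "super"):
            raise InputError(f"mode must be 'mono' or 'super'; got {self.mode!r}")
        if not 0 <= self.n_emerged_host_adults <= self.n_hosts:
            raise InputError(
                f"replicate {self.replicate!r}: emerged host adults "
                f"({self.n_emerged_host_adults}) outside [0, {self.n_hosts}]"
            )
        if not 0 <= self.n_emerged_wasps <= self.n_hosts:
            raise InputError(
                f"replicate {self.replicate!r}: emerged wasps "
                f"({self.n_emerged_wasps}) outside [0, {self.n_hosts}]"
            )
        if self.n_emerged_host_adults + self.n_emerged_wasps > self.n_hosts:
            raise InputError(
                f"replicate {self.replicate!r}: emerged adults + wasps exceed hosts"
            )


@dataclass
class ChoiceAssayRecord:
    replicate: str
    age_x: int
    n1: int  # eggs in 1-day-old hosts (left side)
    nx: int  # eggs in X-day-old hosts (right side)
    duration_h: float = 2.0

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.nx < 0:
            raise InputError(
                f"replicate {self.replicate!r}: egg counts must be >= 0"
            )


@dataclass
class DissectionRecord:
    replicate: str
    group: str  # PH (previously parasitized host) | NH (non-parasitized host)
    n_dissected: int
    n_with_eggs: int

    def __post_init__(self) -> None:
        if self.group not in ("PH", "NH"):
            raise InputError(f"group must be 'PH' or 'NH'; got {self.group!r}")
        if not 0 <= self.n_with_eggs <= self.n_dissected:
            raise InputError(
                f"replicate {self.replicate!r}: n_with_eggs outside [0, n_dissected]"
            )


@dataclass
class RateSummary:
    condition: tuple
    metric: str  # parasitism | emergence | oviposition_rate
    rates: list[float]
    mean: float
    sem: float  # NaN for a single replicate
    n: int


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    n: int
    method_detail: dict = field(default_factory=dict)


def parasitism_rate(record: ParasitismAssayRecord) -> float:
    """Percentage of hosts parasitized: (1 − emerged adults / hosts) × 100."""
    if record.n_hosts == 0:
        raise InputError(f"replicate {record.replicate!r}: n_hosts is 0")
    return (1.0 - record.n_emerged_host_adults / record.n_hosts) * 100.0


def emergence_rate(record: ParasitismAssayRecord) -> float:
    """Percentage of hosts yielding an adult wasp: (wasps / hosts) × 100."""
    if record.n_hosts == 0:
        raise InputError(f"replicate {record.replicate!r}: n_hosts is 0")
    return record.n_emerged_wasps / record.n_hosts * 100.0


def oviposition_index(n1: int, nx: int) -> float:
    """(N1 − Nx) / (N1 + Nx) × 100; positive means preference for the 1-day side."""
    if n1 < 0 or nx < 0:
        raise InputError("egg counts must be >= 0")
    if n1 + nx == 0:
        raise InputError(
            "oviposition index undefined for a replicate with zero eggs on both sides"
        )
    return (n1 - nx) / (n1 + nx) * 100.0


def oviposition_rate(record: DissectionRecord) -> float:
    """Percentage of dissected hosts containing at least one wasp egg."""
    if record.n_dissected == 0:
        raise InputError(f"replicate {record.replicate!r}: n_dissected is 0")
    return record.n_with_eggs / record.n_dissected * 100.0


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-sided p over all 2^n equiprobable sign assignments.

    ``ranks2`` are the (mid)ranks doubled to integers; ``w2`` the doubled
    positive-rank sum.  The dynamic program tabulates the null distribution of
    the doubled statistic, which is exactly the full sign enumeration.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w2))
    p_upper = float(counts[w2:].sum())
    p_lower = float(counts[: w2 + 1].sum())
    return min(1.0, 2.0 * min(p_upper, p_lower))


def signed_rank_test(
    values: Iterable[float], mu: float = 0.0, zero_method: str = "wilcox"
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of symmetry about ``mu``.

    Zeros are dropped before ranking (Wilcoxon's convention; ``pratt`` ranks
    them and then discards their ranks).  Ties receive midranks.  The p value
    is exact — equivalent to enumerating all 2^n sign assignments — for
    n <= 25, and a normal approximation with tie and continuity corrections
    otherwise.  The policy actually used is recorded in ``method_detail``.
    """
    if zero_method not in ("wilcox", "pratt"):
        raise InputError(f"zero_method must be 'wilcox' or 'pratt'; got {zero_method!r}")
    d = np.asarray(list(values), dtype=float) - mu
    if d.size == 0 or (d == 0).all():
        raise NoInformationError("all values equal mu; the signed-rank test is undefined")
    n_zero = int((d == 0).sum())
    if zero_method == "wilcox":
        d_used = d[d != 0]
        ranks = stats.rankdata(np.abs(d_used))
    else:  # pratt: rank zeros too, then drop their ranks
        ranks_all = stats.rankdata(np.abs(d))
        d_used = d[d != 0]
        ranks = ranks_all[d != 0]
    n = d_used.size
    w_plus = float(ranks[d_used > 0].sum())
    has_ties = len(np.unique(np.abs(d_used))) < n or (zero_method == "pratt" and n_zero)
    detail = {
        "zero_method": zero_method,
        "n_zeros_dropped": n_zero,
        "ties": bool(has_ties),
    }
    if n <= EXACT_SIGNED_RANK_MAX_N:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact_p(ranks2, 2 * w_plus)
        detail["method"] = "exact sign enumeration"
    else:
        mean = ranks.sum() / 2.0
        var = float((ranks**2).sum()) / 4.0  # midranks embed the tie correction
        dev = w_plus - mean
        z = (dev - 0.5 * np.sign(dev)) / math.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
        detail["method"] = "normal approximation with continuity correction"
    return TestResult("wilcoxon_signed_rank", w_plus, min(1.0, p), n, detail)


def mann_whitney_u(groupA: Sequence[float], groupB: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test between two independent groups.

    The exact null distribution (labeling enumeration) is used when
    nA + nB <= 16 with no ties across groups; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(list(groupA), dtype=float)
    b = np.asarray(list(groupB), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (a.size + b.size) <= EXACT_MWU_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    detail = {
        "method": "exact labeling enumeration" if exact else
        "normal approximation with tie and continuity corrections",
        "ties": bool(has_ties),
        "nA": int(a.size),
        "nB": int(b.size),
    }
    return TestResult(
        "mann_whitney_u", float(res.statistic), float(res.pvalue), a.size + b.size, detail
    )


def fold_recovery(
    summary_mono: RateSummary, summary_super: RateSummary
) -> float:
    """Fold change of the super- over the mono-parasitism mean rate."""
    if summary_mono.metric != summary_super.metric:
        raise InputError(
            f"fold recovery compares like metrics; got {summary_mono.metric!r} "
            f"vs {summary_super.metric!r}"
        )
    if summary_mono.mean == 0:
        raise InputError("fold recovery undefined: mono mean rate is 0")
    return summary_super.mean / summary_mono.mean


def summarize_conditions(
    records: Iterable[ParasitismAssayRecord],
) -> list[RateSummary]:
    """Per-condition mean ± SEM of replicate parasitism and emergence rates.

    Conditions are keyed by (host species, host age, mode); output order is
    deterministic (sorted condition key, parasitism before emergence).
    """
    rows = []
    for rec in records:
        rows.append(
            {
                "condition": (rec.host_species, rec.host_age_days, rec.mode),
                "parasitism": parasitism_rate(rec),
                "emergence": emergence_rate(rec),
            }
        )
    if not rows:
        return []
    df = pd.DataFrame(rows)
    out: list[RateSummary] = []
    for condition, sub in sorted(df.groupby("condition"), key=lambda kv: kv[0]):
        for metric in ("parasitism", "emergence"):
            rates = [float(r) for r in sub[metric]]
            n = len(rates)
            mean = float(np.mean(rates))
            sem = float(np.std(rates, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
            out.append(RateSummary(condition, metric, rates, mean, sem, n))
    return out


def choice_indices(
    records: Iterable[ChoiceAssayRecord], warn: bool = True
) -> dict[int, list[float]]:
    """Oviposition indices per comparison age; zero-egg replicates excluded."""
    out: dict[int, list[float]] = {}
    for rec in records:
        if rec.n1 + rec.nx == 0:
            if warn:
                logger.warning(
                    "choice replicate %r (age %d): zero eggs on both sides; "
                    "excluded from the index",
                    rec.replicate,
                    rec.age_x,
                )
            continue
        out.setdefault(rec.age_x, []).append(oviposition_index(rec.n1, rec.nx))
    return out
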