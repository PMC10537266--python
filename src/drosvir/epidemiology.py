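"""Prevalence estimation and co-infection association tests.

Prevalence is the fraction of libraries within a project whose virus read
count passed the presence threshold, with exact (Clopper-Pearson) binomial
confidence intervals — appropriate because several viruses appear in only
a handful of libraries per project.

Association between two viruses is tested on the 2x2 cross-tabulation of
presence calls with Fisher's exact test, computed here from first
principles: the hypergeometric distribution of the both-infected cell with
all margins fixed, evaluated through log-gamma so tables from thousands of
libraries do not overflow.  The two-sided p-value follows the
point-probability ("minimum likelihood") rule — the sum of probabilities
of all tables with the same margins whose point probability does not
exceed that of the observed table — matching the convention of the
standard R implementation.  A tail-doubling alternative is available for
comparison.  The co-infection scan deliberately applies a raw significance
threshold (default 0.01) per pair with no multiplicity correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "CoinfectionTable",
    "ExactTestResult",
    "estimate_prevalence",
    "coinfection_table",
    "fisher_exact",
    "coinfection_scan",
]


@dataclass
class CoinfectionTable:
    """2x2 cross-tabulation of presence calls for a virus pair."""

    project: str
    virus_a: str
    virus_b: str
    n11: int  # both present
    n10: int  # A only
    n01: int  # B only
    n00: int  # neither

    def __post_init__(self):
        for cell in ("n11", "n10", "n01", "n00"):
            if getattr(self, cell) < 0:
                raise ValueError(f"cell {cell} must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass
class ExactTestResult:
    p_value: float
    odds_ratio: float
    alternative: str = "two-sided"


def estimate_prevalence(
    calls: pd.DataFrame,
    projects: pd.Series,
    level: float = 0.95,
    include_zero: bool = False,
) -> pd.DataFrame:
    """Per-(project, virus) prevalence with Clopper-Pearson intervals.

    ``calls`` is the boolean libraries x viruses matrix; ``projects`` maps
    each library to its project.  By default only combinations with at
    least one positive library are reported; ``include_zero`` adds the
    all-negative rows.
    """
    projects = projects.reindex(calls.index)
    alpha = 1.0 - level
    rows = []
    for project, members in projects.groupby(projects).groups.items():
        sub = calls.loc[list(members)]
        n = len(sub)
        if n == 0:
            warnings.warn(f"project {project!r} has no libraries; skipped")
            continue
        for virus in calls.columns:
            k = int(sub[virus].sum())
            if k == 0 and not include_zero:
                continue
            low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
            high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
            rows.append(
                {"project": project, "virus": virus, "k": k, "n": n,
                 "p_hat": k / n, "ci_low": low, "ci_high": high, "level": level}
            )
    return pd.DataFrame(
        rows, columns=["project", "virus", "k", "n", "p_hat", "ci_low", "ci_high", "level"]
    )


def coinfection_table(
    calls: pd.DataFrame,
    projects: pd.Series,
    virus_a: str,
    virus_b: str,
    project: str,
) -> CoinfectionTable:
    """Cross-tabulate two viruses' presence calls within one project."""
    for v in (virus_a, virus_b):
        if v not in calls.columns:
            raise ValueError(f"virus {v!r} absent from the call matrix")
    members = projects.reindex(calls.index) == project
    a = calls.loc[members, virus_a].to_numpy(dtype=bool)
    b = calls.loc[members, virus_b].to_numpy(dtype=bool)
    return CoinfectionTable(
        project=project,
        virus_a=virus_a,
        virus_b=virus_b,
        n11=int(np.sum(a & b)),
        n10=int(np.sum(a & ~b)),
        n01=int(np.sum(~a & b)),
        n00=int(np.sum(~a & ~b)),
    )


def _log_hypergeom_pmf(k: np.ndarray, n: int, r1: int, c1: int) -> np.ndarray:
    """log P(N11 = k) with margins r1 (row A), c1 (column B) fixed, n total."""
    r2 = n - r1

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logC(r1, k) + logC(r2, c1 - k) - logC(n, c1)


def fisher_exact(
    table: CoinfectionTable,
    alternative: str = "two-sided",
    two_sided_rule: str = "point-probability",
) -> ExactTestResult:
    """Exact test of association on a 2x2 table with fixed margins.

    ``alternative`` is one of ``two-sided``, ``greater`` or ``less``
    (tails refer to the both-infected cell).  For the two-sided test the
    default point-probability rule sums the probabilities of all feasible
    tables no more likely than the observed one; ``two_sided_rule=
    "doubling"`` doubles the smaller tail instead (capped at 1).  The odds
    ratio is the sample odds ratio n11*n00 / (n10*n01), infinite when a
    denominator cell is zero while the numerator cells are positive, and
    undefined (nan) for degenerate margins.
    """
    n11, n10, n01, n00 = table.n11, table.n10, table.n01, table.n00
    n = table.total
    r1 = n11 + n10
    c1 = n11 + n01
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, n, r1, c1)
    logp -= np.logaddexp.reduce(logp)  # renormalize for numerical safety
    obs = n11 - lo
    if alternative == "greater":
        p = float(np.exp(np.logaddexp.reduce(logp[obs:])))
    elif alternative == "less":
        p = float(np.exp(np.logaddexp.reduce(logp[: obs + 1])))
    elif alternative == "two-sided":
        if two_sided_rule == "point-probability":
            # relative tolerance absorbs floating-point ties, as in R
            mask = logp <= logp[obs] + np.log1p(1e-7)
            p = float(np.exp(np.logaddexp.reduce(logp[mask])))
        elif two_sided_rule == "doubling":
            upper = np.exp(np.logaddexp.reduce(logp[obs:]))
            lower = np.exp(np.logaddexp.reduce(logp[: obs + 1]))
            p = float(min(1.0, 2.0 * min(upper, lower)))
        else:
            raise ValueError(f"unknown two_sided_rule {two_sided_rule!r}")
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(1.0, max(p, 0.0))

    if n10 * n01 > 0:
        odds = (n11 * n00) / (n10 * n01)
    elif n11 * n00 > 0:
        odds = float("inf")
    else:
        odds = float("nan")
    return ExactTestResult(p_value=p, odds_ratio=odds, alternative=alternative)


def coinfection_scan(
    calls: pd.DataFrame,
    projects: pd.Series,
    alpha: float = 0.01,
    min_positive: int = 1,
) -> pd.DataFrame:
    """Test all virus pairs within every project.

    Pairs are tested only where both viruses have at least ``min_positive``
    positive libraries in the project.  Results carry the 2x2 counts, the
    sample odds ratio, the exact two-sided p-value and a significance flag
    at ``alpha`` — no multiple-testing correction is applied, mirroring a
    raw per-pair threshold.
    """
    projects = projects.reindex(calls.index)
    rows = []
    for project in sorted(projects.dropna().unique()):
        members = projects == project
        sub = calls.loc[members]
        active = [v for v in calls.columns if sub[v].sum() >= min_positive]
        for virus_a, virus_b in itertools.combinations(active, 2):
            tab = coinfection_table(calls, projects, virus_a, virus_b, project)
            res = fisher_exact(tab)
            rows.append(
                {"project": project, "virus_a": virus_a, "virus_b": virus_b,
                 "n11": tab.n11, "n10": tab.n10, "n01": tab.n01, "n00": tab.n00,
                 "odds_ratio": res.odds_ratio, "p_value": res.p_value,
                 "significant": res.p_value < alpha}
            )
    return pd.DataFrame(
        rows,
        columns=["project", "virus_a", "virus_b", "n11", "n10", "n01", "n00",
                 "odds_ratio", "p_value", "significant"],
    )
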