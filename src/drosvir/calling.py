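"""Presence/absence calling of viruses with index-hopping correction.

Virus reads detected in a multiplexed sequencing library do not prove the
flies in that library were infected: on patterned flow cells a small
fraction of reads relocates between lane-mates ("index hopping" or
"barcode switching"), so a heavily infected library seeds low-level counts
across its whole lane.  The caller therefore declares a virus present in a
library only when its read count reaches both

* a relative threshold: at least ``rel_threshold`` (default 1%) of the
  count in the library with the most reads for that virus, and
* an absolute floor (default 150 reads), selectable from the discordance
  between duplicate samples.

The module also verifies each library's sex from sex-limited marker genes,
estimates the switching rate from marker reads observed in the wrong sex,
and flags groups of viruses whose counts are so strongly correlated across
libraries that a common contamination source is more plausible than
independent infections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_MALE_MARKERS",
    "DEFAULT_FEMALE_MARKERS",
    "InfectionCalls",
    "SwitchingRateEstimate",
    "verify_sex",
    "estimate_switching_rate",
    "call_infections",
    "select_abs_threshold",
    "flag_contaminant_clusters",
]

# FlyBase identifiers of the sex-limited genes used to verify library sex.
DEFAULT_MALE_MARKERS = (
    "FBgn0011669",
    "FBgn0011694",
    "FBgn0046294",
    "FBgn0053340",
    "FBgn0250832",
    "FBgn0259795",
    "FBgn0259971",
    "FBgn0259975",
    "FBgn0262099",
    "FBgn0262623",
    "FBgn0270925",
)
DEFAULT_FEMALE_MARKERS = (
    "FBgn0000355",
    "FBgn0000356",
    "FBgn0000358",
    "FBgn0000359",
    "FBgn0000360",
)

DEFAULT_THRESHOLD_GRID = (10, 25, 50, 100, 150, 200, 300, 500)


@dataclass
class InfectionCalls:
    """Boolean presence calls plus the thresholds that produced them."""

    present: pd.DataFrame
    rel_threshold: float
    abs_threshold: float
    #: per-virus maximum read count within each thresholding scope
    per_virus_max: pd.DataFrame

    def __post_init__(self):
        if not self.present.dtypes.map(lambda d: d == bool).all():
            self.present = self.present.astype(bool)


@dataclass
class SwitchingRateEstimate:
    """Barcode-switching rate from wrong-sex marker gene reads."""

    rate: float
    n_wrong: int
    n_total: int
    ci: tuple[float, float]
    level: float = 0.95
    undefined: bool = False
    per_lane: pd.DataFrame = field(default_factory=pd.DataFrame)


def _marker_subsets(
    gene_counts: pd.DataFrame,
    male_markers: Sequence[str],
    female_markers: Sequence[str],
):
    male = [g for g in male_markers if g in gene_counts.index]
    female = [g for g in female_markers if g in gene_counts.index]
    missing = (set(male_markers) - set(male)) | (set(female_markers) - set(female))
    if missing:
        warnings.warn(
            f"{len(missing)} marker gene(s) absent from the count matrix: "
            + ", ".join(sorted(missing))
        )
    if not male and not female:
        raise ValueError("none of the marker genes are present in the count matrix")
    if not male or not female:
        raise ValueError("need at least one male and one female marker in the matrix")
    return male, female


def verify_sex(
    gene_counts: pd.DataFrame,
    male_markers: Sequence[str] = DEFAULT_MALE_MARKERS,
    female_markers: Sequence[str] = DEFAULT_FEMALE_MARKERS,
    ratio: float = 2.0,
) -> pd.Series:
    """Call each library male/female/ambiguous from marker expression.

    Marker counts are CPM-normalized (per library) and summed per marker
    set; a library is called male when the male sum is at least ``ratio``
    times the female sum, female in the reverse case, ambiguous otherwise
    (including when both sums are zero).
    """
    male, female = _marker_subsets(gene_counts, male_markers, female_markers)
    sizes = gene_counts.sum(axis=0).astype(float)
    sizes[sizes == 0] = np.nan
    cpm = gene_counts.div(sizes, axis=1) * 1e6
    m = cpm.loc[male].sum(axis=0)
    f = cpm.loc[female].sum(axis=0)
    out = pd.Series("ambiguous", index=gene_counts.columns, dtype=object)
    both_zero = (m == 0) & (f == 0)
    out[(m >= ratio * f) & ~both_zero] = "male"
    out[(f >= ratio * m) & ~both_zero] = "female"
    out[m.isna() | f.isna()] = "ambiguous"
    return out


def estimate_switching_rate(
    gene_counts: pd.DataFrame,
    verified_sex: pd.Series,
    male_markers: Sequence[str] = DEFAULT_MALE_MARKERS,
    female_markers: Sequence[str] = DEFAULT_FEMALE_MARKERS,
    lanes: pd.Series | None = None,
    level: float = 0.95,
) -> SwitchingRateEstimate:
    """Estimate the index-hop rate from wrong-sex marker reads.

    Pools female-marker reads observed in verified-male libraries and
    male-marker reads in verified-female libraries over all marker reads in
    sexed libraries; a Clopper-Pearson binomial interval is attached.  When
    the design offers no wrong-sex signal (a single-sex experiment) the
    estimate is returned with ``undefined=True``.
    """
    male, female = _marker_subsets(gene_counts, male_markers, female_markers)
    verified_sex = verified_sex.reindex(gene_counts.columns)
    male_libs = verified_sex[verified_sex == "male"].index
    female_libs = verified_sex[verified_sex == "female"].index
    if len(male_libs) == 0 or len(female_libs) == 0:
        return SwitchingRateEstimate(
            rate=float("nan"), n_wrong=0, n_total=0, ci=(float("nan"), float("nan")),
            level=level, undefined=True,
        )

    def tally(libs) -> tuple[int, int, int]:
        wrong_m = int(gene_counts.loc[female, list(set(libs) & set(male_libs))].to_numpy().sum())
        wrong_f = int(gene_counts.loc[male, list(set(libs) & set(female_libs))].to_numpy().sum())
        sexed = list((set(libs) & set(male_libs)) | (set(libs) & set(female_libs)))
        total = int(gene_counts.loc[male + female, sexed].to_numpy().sum())
        return wrong_m + wrong_f, total, len(sexed)

    per_lane_rows = []
    if lanes is not None:
        lanes = lanes.reindex(gene_counts.columns)
        for lane, members in lanes.groupby(lanes).groups.items():
            w, t, ns = tally(list(members))
            per_lane_rows.append(
                {"lane": lane, "n_wrong": w, "n_total": t,
                 "rate": w / t if t else float("nan"), "n_sexed_libraries": ns}
            )
    n_wrong, n_total, _ = tally(list(gene_counts.columns))
    rate = n_wrong / n_total if n_total else float("nan")
    ci = _clopper_pearson(n_wrong, n_total, level) if n_total else (float("nan"),) * 2
    return SwitchingRateEstimate(
        rate=rate, n_wrong=n_wrong, n_total=n_total, ci=ci, level=level,
        undefined=n_total == 0, per_lane=pd.DataFrame(per_lane_rows),
    )


def _clopper_pearson(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def call_infections(
    virus_counts: pd.DataFrame,
    rel_threshold: float = 0.01,
    abs_threshold: float = 150,
    projects: pd.Series | None = None,
) -> InfectionCalls:
    """Apply the relative + absolute presence rule.

    A virus is present in a library when its count is at least
    ``max(rel_threshold * per_virus_max, abs_threshold)``, where the
    per-virus maximum is taken within each project when ``projects`` is
    given (the default scope in the pipeline) and over all libraries
    otherwise.
    """
    counts = virus_counts.drop(columns=["total_reads"], errors="ignore")
    if counts.empty:
        return InfectionCalls(
            present=counts.astype(bool),
            rel_threshold=rel_threshold,
            abs_threshold=abs_threshold,
            per_virus_max=pd.DataFrame(index=["all"], columns=counts.columns),
        )
    if projects is None:
        scope = pd.Series("all", index=counts.index)
    else:
        scope = projects.reindex(counts.index)
    per_max = counts.groupby(scope).max()
    cutoffs = np.maximum(
        rel_threshold * per_max.loc[scope.to_numpy()].to_numpy(), abs_threshold
    )
    present = pd.DataFrame(
        counts.to_numpy() >= cutoffs, index=counts.index, columns=counts.columns
    )
    return InfectionCalls(
        present=present,
        rel_threshold=rel_threshold,
        abs_threshold=abs_threshold,
        per_virus_max=per_max,
    )


def select_abs_threshold(
    virus_counts: pd.DataFrame,
    duplicate_ids: pd.Series,
    candidate_thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    rel_threshold: float = 0.01,
    projects: pd.Series | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the absolute floor that minimizes duplicate discordance.

    For each candidate, discordance is the fraction of (duplicate pair,
    virus) combinations whose two presence calls disagree.  The smallest
    candidate attaining the minimum is returned together with the full
    profile, preserving sensitivity when several candidates tie.
    """
    dup = duplicate_ids.reindex(virus_counts.index).fillna("")
    pairs = []
    for label, members in dup[dup != ""].groupby(dup[dup != ""]).groups.items():
        members = list(members)
        if len(members) == 2:
            pairs.append(members)
    if not pairs:
        raise ValueError(
            "no duplicate pairs available; use the default absolute threshold of 150"
        )
    rows = []
    for t in candidate_thresholds:
        calls = call_infections(
            virus_counts, rel_threshold=rel_threshold, abs_threshold=t, projects=projects
        ).present
        disagreements = sum(
            int((calls.loc[a] != calls.loc[b]).sum()) for a, b in pairs
        )
        n_comb = len(pairs) * calls.shape[1]
        rows.append({"abs_threshold": t, "discordance": disagreements / n_comb,
                     "n_discordant": disagreements, "n_combinations": n_comb})
    profile = pd.DataFrame(rows)
    best = profile["discordance"].min()
    chosen = float(profile.loc[profile["discordance"] == best, "abs_threshold"].min())
    return chosen, profile


def flag_contaminant_clusters(
    virus_counts: pd.DataFrame,
    r_min: float = 0.95,
) -> list[set[str]]:
    """Flag virus groups whose counts co-vary like a common source.

    Pairwise Pearson correlation of log1p read counts across libraries;
    viruses joined by r >= ``r_min`` form connected components, and every
    component of size >= 2 is reported.  Count profiles this tightly
    coupled across hundreds of libraries are the signature of contaminating
    RNA or hopping from a single unreported source rather than independent
    infections.
    """
    counts = virus_counts.drop(columns=["total_reads"], errors="ignore")
    if counts.shape[0] < 3:
        raise ValueError("need at least 3 libraries to assess co-variation")
    x = np.log1p(counts.to_numpy(dtype=float))
    keep = []
    for j, v in enumerate(counts.columns):
        if np.ptp(x[:, j]) == 0:
            warnings.warn(f"virus {v!r} has constant counts; correlation undefined, excluded")
        else:
            keep.append(j)
    if len(keep) < 2:
        return []
    sub = x[:, keep]
    labels = [counts.columns[j] for j in keep]
    r = np.corrcoef(sub, rowvar=False)
    adj = r >= r_min
    # connected components by union-find over the adjacency
    parent = list(range(len(labels)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if adj[i, j]:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i, lab in enumerate(labels):
        comps.setdefault(find(i), set()).add(lab)
    return sorted((c for c in comps.values() if len(c) >= 2), key=lambda c: sorted(c)[0])
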