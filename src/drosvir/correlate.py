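"""Cross-virus correlation of estimated expression changes and volcano tables."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import virus_coef, interaction_coef

__all__ = ["effect_matrix", "correlate_effects", "volcano_table", "CorrelationReport"]


def effect_matrix(
    results: dict[str, "pd.DataFrame | object"],
    include_interactions: bool = True,
) -> pd.DataFrame:
    """Assemble a genes x (virus, coefficient) logFC matrix.

    ``results`` maps virus name to either a :class:`~drosvir.de.VirusDEResults`
    or its ``table`` DataFrame.  Columns are ``<virus>`` for the main
    effect and ``<virus>:sex`` for the interaction (where fitted); genes
    are the union of tested genes, NaN where a gene was not tested.
    """
    columns = {}
    for virus, res in results.items():
        table = getattr(res, "table", res)
        for coef, label in (
            (virus_coef(virus), virus),
            (interaction_coef(virus), f"{virus}:sex"),
        ):
            if not include_interactions and label.endswith(":sex"):
                continue
            sub = table[table["coefficient"] == coef]
            if sub.empty:
                continue
            columns[label] = sub.set_index("gene")["logFC"]
    return pd.DataFrame(columns)


@dataclass
class CorrelationReport:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    significant: pd.DataFrame
    method: str
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format pair table (upper triangle)."""
        rows = []
        cols = list(self.r.columns)
        for a, b in itertools.combinations(cols, 2):
            rows.append(
                {"effect_a": a, "effect_b": b, "r": self.r.at[a, b],
                 "n": int(self.n.at[a, b]), "p": self.p.at[a, b],
                 "significant": bool(self.significant.at[a, b])}
            )
        return pd.DataFrame(rows)


def correlate_effects(
    em: pd.DataFrame,
    method: str = "pearson",
    alpha: float = 0.001,
    min_genes: int = 3,
) -> CorrelationReport:
    """Pairwise correlation between logFC columns on shared genes.

    Pearson by default (a Spearman rank option is provided); p-values come
    from the t transform of r with n - 2 degrees of freedom.  Pairs with
    fewer than ``min_genes`` shared genes are reported as undefined (NaN,
    not significant).  Entries with p >= ``alpha`` are masked in
    ``significant`` (the blank squares of a correlation heat map).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    cols = list(em.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    for i in range(k):
        n.iloc[i, i] = em[cols[i]].notna().sum()
    for a, b in itertools.combinations(cols, 2):
        shared = em[[a, b]].dropna()
        n.at[a, b] = n.at[b, a] = len(shared)
        if len(shared) < min_genes:
            r.at[a, b] = r.at[b, a] = np.nan
            p.at[a, b] = p.at[b, a] = np.nan
            continue
        if method == "pearson":
            rv, pv = stats.pearsonr(shared[a], shared[b])
        else:
            rv, pv = stats.spearmanr(shared[a], shared[b])
        r.at[a, b] = r.at[b, a] = rv
        p.at[a, b] = p.at[b, a] = pv
    significant = (p < alpha) & p.notna()
    np.fill_diagonal(significant.values, True)
    return CorrelationReport(r=r, p=p, n=n, significant=significant,
                             method=method, alpha=alpha)


def volcano_table(
    results: pd.DataFrame,
    coefficient: str | None = None,
    neg_log10_cap: float = 300.0,
) -> pd.DataFrame:
    """Figure-ready table of logFC vs -log10 adjusted p per gene.

    ``results`` is a per-(gene, coefficient) table carrying ``logFC``,
    ``p_adj`` and ``de_class``; -log10(p_adj) is capped so exact zeros
    remain plottable.
    """
    table = getattr(results, "table", results)
    if table.empty:
        return pd.DataFrame(columns=["gene", "coefficient", "logFC",
                                     "neg_log10_p_adj", "de_class"])
    if coefficient is not None:
        table = table[table["coefficient"] == coefficient]
    with np.errstate(divide="ignore"):
        neg = -np.log10(table["p_adj"].to_numpy(dtype=float))
    out = pd.DataFrame(
        {"gene": table["gene"].to_numpy(),
         "coefficient": table["coefficient"].to_numpy(),
         "logFC": table["logFC"].to_numpy(),
         "neg_log10_p_adj": np.minimum(neg, neg_log10_cap),
         "de_class": table["de_class"].to_numpy()}
    )
    return out
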