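"""Per-gene mixed-model differential expression for virus infection.

For each virus, expression (log2 counts-per-million with a prior count) is
modelled per gene as

    expression ~ sex + virus + sex:virus + (1 | dataset_genotype_tissue)

with uninfected females as the reference.  Libraries are restricted to the
projects in which the virus was called present.  Term-dropping rules: if
the retained libraries contain one sex only, or the virus was called in
one sex only, the sex term and the interaction are dropped; strata with a
single level (single dataset, single genotype, single tissue) are dropped
from the random-intercept label, and when the label has a single level the
fit reduces to ordinary least squares.

The single-random-intercept linear mixed model is fitted by restricted
maximum likelihood, profiling out the residual variance and optimizing the
1-D variance ratio; Wald t statistics use a Satterthwaite-type
denominator-degrees-of-freedom approximation from the curvature of the
REML criterion.  Residual variances can then be shrunk towards a common
prior (an empirical-Bayes inverse-gamma fit by moments on the log
variances, in the style of limma's moderated t), p-values are adjusted by
the Benjamini-Hochberg step-up rule, and genes are classified up/down/ns
at |logFC| > 0.5 and adjusted p < 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .simulate import COEF_SEX, virus_coef, interaction_coef

__all__ = [
    "DEModelSpec",
    "VirusDEModel",
    "VirusDEResults",
    "build_design",
    "normalize_logcpm",
    "filter_genes",
    "fit_gene_model",
    "moderate_variances",
    "adjust_bh",
    "classify_de",
]

LFC_CUT = 0.5
ALPHA_ADJ = 0.001


@dataclass
class DEModelSpec:
    """Resolved model specification for one virus."""

    virus: str
    fixed_terms: list[str]
    random_group: str | None
    libraries: list[str]
    #: design matrix (libraries x columns, incl. intercept)
    design: pd.DataFrame = field(repr=False, default=None)
    #: random-intercept labels aligned with ``libraries`` (None -> OLS)
    groups: pd.Series | None = field(repr=False, default=None)


def build_design(
    meta: pd.DataFrame,
    calls: pd.DataFrame,
    virus: str,
    sex_col: str = "sex",
) -> DEModelSpec:
    """Restrict libraries and resolve the fixed/random terms for a virus."""
    if virus not in calls.columns:
        raise ValueError(f"virus {virus!r} absent from the call matrix")
    calls_v = calls[virus].reindex(meta.index).fillna(False)
    if not calls_v.any():
        raise ValueError(f"virus {virus!r} was never called present")
    projects_with = meta.loc[calls_v, "project"].unique()
    libs = meta.index[meta["project"].isin(projects_with)]
    sub = meta.loc[libs]
    status = calls_v.loc[libs].astype(float)

    sexes = set(sub[sex_col].unique())
    infected_sexes = set(sub.loc[status == 1.0, sex_col].unique())
    use_sex = len(sexes & {"male", "female"}) == 2 and len(infected_sexes) == 2

    X = pd.DataFrame({"Intercept": 1.0}, index=libs)
    terms = []
    if use_sex:
        X[COEF_SEX] = (sub[sex_col] == "male").astype(float)
        terms.append("sex")
    X[virus_coef(virus)] = status
    terms.append("virus")
    if use_sex:
        X[interaction_coef(virus)] = X[COEF_SEX] * status
        terms.append("sex:virus")

    # random-intercept label: concatenate the multi-level strata only
    parts = []
    for col in ("project", "genotype", "tissue"):
        if col in sub.columns and sub[col].nunique() > 1:
            parts.append(col)
    if parts:
        label = "_".join(parts)
        groups = sub[parts[0]].astype(str)
        for col in parts[1:]:
            groups = groups + "_" + sub[col].astype(str)
        if groups.nunique() < 2:
            label, groups = None, None
    else:
        label, groups = None, None
    return DEModelSpec(
        virus=virus,
        fixed_terms=terms,
        random_group=label,
        libraries=list(libs),
        design=X,
        groups=groups,
    )


def normalize_logcpm(
    counts: pd.DataFrame,
    prior_count: float = 0.5,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """log2 counts-per-million with a prior count.

    ``log2((count + prior) / (library_size + 2 * prior) * 1e6)``.  By
    default the library size is the column total; pass ``lib_sizes`` to
    use effective (normalized) sizes instead.  Libraries with zero total
    counts are dropped with a warning.
    """
    sizes = counts.sum(axis=0).astype(float) if lib_sizes is None else lib_sizes.astype(float)
    sizes = sizes.reindex(counts.columns)
    zero = sizes[sizes == 0].index
    if len(zero):
        warnings.warn(f"dropping {len(zero)} zero-size library(ies): {list(zero)}")
        counts = counts.drop(columns=zero)
        sizes = sizes.drop(zero)
    return np.log2(
        (counts + prior_count).div(sizes + 2 * prior_count, axis=1) * 1e6
    )


def effective_library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios effective library sizes.

    Raw column totals are sensitive to composition: a strong expression
    response concentrated in a subset of genes changes an infected
    library's total and thereby shifts the CPM of every unaffected gene.
    Following the standard RNA-seq practice (DESeq's size factors, edgeR's
    TMM), each library's size factor is the median ratio of its counts to
    the per-gene geometric mean reference, rescaled so the factors average
    one; the effective size is the mean column total times the factor.
    """
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(x)
    ref_ok = np.all(np.isfinite(logs), axis=1)
    if ref_ok.sum() < 10:
        warnings.warn("too few all-positive genes for median-ratio sizes; using totals")
        return counts.sum(axis=0).astype(float)
    ref = logs[ref_ok].mean(axis=1)
    factors = np.exp(np.median(logs[ref_ok] - ref[:, None], axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    mean_total = float(counts.sum(axis=0).mean())
    return pd.Series(mean_total * factors, index=counts.columns)


def filter_genes(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_fraction: float = 0.05
) -> pd.Index:
    """Genes with CPM above ``min_cpm`` in at least ``min_fraction`` of libraries."""
    sizes = counts.sum(axis=0).astype(float)
    sizes[sizes == 0] = np.nan
    cpm = counts.div(sizes, axis=1) * 1e6
    frac = (cpm > min_cpm).mean(axis=1)
    return counts.index[frac >= min_fraction]


# ---------------------------------------------------------------------------
# REML machinery for a single random intercept


class _GroupedDesign:
    """Pre-sorted design shared by all genes of one virus model."""

    def __init__(self, X: np.ndarray, groups: np.ndarray | None):
        self.n, self.p = X.shape
        if groups is None:
            self.order = np.arange(self.n)
            self.X = X
            self.starts = None
            self.sizes = None
        else:
            self.order = np.argsort(groups, kind="stable")
            g = groups[self.order]
            self.X = X[self.order]
            change = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
            self.starts = change
            self.sizes = np.diff(np.r_[change, len(g)])

    def vinv_apply(self, A: np.ndarray, lam: float) -> np.ndarray:
        """(I + lam Z Z')^{-1} A for group-sorted A."""
        if self.starts is None or lam == 0.0:
            return A
        coef = lam / (1.0 + lam * self.sizes)
        sums = np.add.reduceat(A, self.starts, axis=0)
        return A - np.repeat(coef[:, None] * sums, self.sizes, axis=0)

    def logdet_v(self, lam: float) -> float:
        if self.starts is None:
            return 0.0
        return float(np.sum(np.log1p(lam * self.sizes)))


def _reml_neg2ll_profiled(lam: float, gd: _GroupedDesign, y: np.ndarray):
    """Profiled REML -2 log-likelihood (up to a constant) and by-products."""
    Xv = gd.vinv_apply(gd.X, lam)
    yv = gd.vinv_apply(y[:, None], lam)[:, 0]
    xtvx = gd.X.T @ Xv
    xtvy = Xv.T @ y
    ytvy = float(y @ yv)
    try:
        L = np.linalg.cholesky(xtvx)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - float(xtvy @ beta)
    rss = max(rss, 1e-300)
    nmp = gd.n - gd.p
    logdet_xtvx = 2.0 * float(np.sum(np.log(np.diag(L))))
    crit = gd.logdet_v(lam) + logdet_xtvx + nmp * np.log(rss)
    return crit, (beta, xtvx, rss)


def _reml_neg2ll_full(theta: np.ndarray, gd: _GroupedDesign, y: np.ndarray) -> float:
    """Unprofiled REML -2ll in theta = (sigma2_e, sigma2_b), for curvature."""
    s2e, s2b = theta
    if s2e <= 0 or s2b < 0:
        return np.inf
    lam = s2b / s2e
    Xv = gd.vinv_apply(gd.X, lam)
    yv = gd.vinv_apply(y[:, None], lam)[:, 0]
    xtvx = gd.X.T @ Xv / s2e
    xtvy = Xv.T @ y / s2e
    ytvy = float(y @ yv) / s2e
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - float(xtvy @ beta)
    logdet_v = gd.logdet_v(lam) + gd.n * np.log(s2e)
    return logdet_v + logdet_xtvx + quad


def _coef_var(theta: np.ndarray, gd: _GroupedDesign) -> np.ndarray:
    """diag of (X' V(theta)^{-1} X)^{-1}."""
    s2e, s2b = theta
    lam = max(s2b, 0.0) / s2e
    Xv = gd.vinv_apply(gd.X, lam)
    xtvx = gd.X.T @ Xv / s2e
    return np.diag(np.linalg.inv(xtvx))


def _satterthwaite_df(
    gd: _GroupedDesign, y: np.ndarray, theta: np.ndarray
) -> np.ndarray:
    """Satterthwaite-type df per coefficient from the REML curvature."""
    h = np.maximum(np.abs(theta) * 1e-4, 1e-8)
    # asymptotic covariance of the variance components: 2 * inverse Hessian
    # of the -2 REML log-likelihood
    H = np.zeros((2, 2))
    f0 = _reml_neg2ll_full(theta, gd, y)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            tpp = _reml_neg2ll_full(theta + ei + ej, gd, y)
            tpm = _reml_neg2ll_full(theta + ei - ej, gd, y)
            tmp = _reml_neg2ll_full(theta - ei + ej, gd, y)
            tmm = _reml_neg2ll_full(theta - ei - ej, gd, y)
            vals = np.array([tpp, tpm, tmp, tmm])
            if not np.all(np.isfinite(vals)):
                return np.full(gd.p, float(gd.n - gd.p))
            H[i, j] = H[j, i] = (tpp - tpm - tmp + tmm) / (4 * h[i] * h[j])
    _ = f0
    try:
        cov_theta = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(gd.p, float(gd.n - gd.p))
    # gradient of each coefficient's variance wrt theta
    var0 = _coef_var(theta, gd)
    grads = np.zeros((gd.p, 2))
    for i in range(2):
        ei = np.eye(2)[i] * h[i]
        vp = _coef_var(theta + ei, gd)
        lo = theta - ei
        if lo[1] < 0 or lo[0] <= 0:
            grads[:, i] = (vp - var0) / h[i]
        else:
            grads[:, i] = (vp - _coef_var(lo, gd)) / (2 * h[i])
    denom = np.einsum("pi,ij,pj->p", grads, cov_theta, grads)
    nmp = float(gd.n - gd.p)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = 2.0 * var0**2 / denom
    df = np.where(np.isfinite(df) & (df > 0), df, nmp)
    return np.minimum(df, nmp)


def _fit_single(
    gd: _GroupedDesign, y_sorted: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float, bool]:
    """Fit one gene; returns (beta, se, df, sigma2, lam, mixed)."""
    nmp = gd.n - gd.p
    if gd.starts is None:
        # ordinary least squares
        beta, rss_arr, rank, _ = np.linalg.lstsq(gd.X, y_sorted, rcond=None)
        resid = y_sorted - gd.X @ beta
        rss = float(resid @ resid)
        sigma2 = rss / nmp
        cov = sigma2 * np.linalg.inv(gd.X.T @ gd.X)
        se = np.sqrt(np.diag(cov))
        return beta, se, np.full(gd.p, float(nmp)), sigma2, 0.0, False

    res = optimize.minimize_scalar(
        lambda u: _reml_neg2ll_profiled(np.exp(u), gd, y_sorted)[0],
        bounds=(-15.0, 12.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(np.exp(res.x))
    crit0, extras0 = _reml_neg2ll_profiled(0.0, gd, y_sorted)
    crit, extras = _reml_neg2ll_profiled(lam, gd, y_sorted)
    if extras is None or crit0 <= crit:
        lam, crit, extras = 0.0, crit0, extras0
    beta, xtvx, rss = extras
    sigma2 = rss / nmp
    cov = sigma2 * np.linalg.inv(xtvx)
    se = np.sqrt(np.diag(cov))
    if lam <= 1e-6:
        df = np.full(gd.p, float(nmp))
        return beta, se, df, sigma2, 0.0, True
    theta = np.array([sigma2, lam * sigma2])
    df = _satterthwaite_df(gd, y_sorted, theta)
    return beta, se, df, sigma2, lam, True


def fit_gene_model(
    expression: pd.Series | np.ndarray,
    design: pd.DataFrame,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Fit one gene's expression against the design.

    Returns one row per design column with ``logFC`` (the coefficient on
    the log2 expression scale), ``se``, ``stat`` (Wald t), ``df`` and
    ``p``.  With ``groups`` given and holding >= 2 levels a single
    random-intercept model is fitted by REML; otherwise ordinary least
    squares with residual degrees of freedom.
    """
    X = design.to_numpy(dtype=float)
    y = np.asarray(expression, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("expression and design have mismatched lengths")
    g = None
    if groups is not None and pd.Series(groups).nunique() > 1:
        g = pd.Series(groups).to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    gd = _GroupedDesign(X, g)
    beta, se, df, sigma2, lam, mixed = _fit_single(gd, y[gd.order])
    stat = beta / se
    p = 2.0 * stats.t.sf(np.abs(stat), df)
    return pd.DataFrame(
        {"coefficient": list(design.columns), "logFC": beta, "se": se,
         "stat": stat, "df": df, "p": p, "sigma2": sigma2, "lambda": lam,
         "mixed": mixed}
    )


def moderate_variances(
    s2: np.ndarray, df: np.ndarray | float
) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of residual variances.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    residual variances by moments on log s^2 and returns the posterior
    variances ``(d0 s0^2 + d s^2) / (d0 + d)`` together with the prior
    hyperparameters.  With an (effectively) infinite prior df all
    variances collapse to the common value; a degenerate spread skips
    moderation with a warning.
    """
    s2 = np.asarray(s2, dtype=float)
    if s2.size < 10:
        raise ValueError("need at least 10 genes to fit the variance prior")
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 10 or np.allclose(s2[ok], s2[ok][0]):
        warnings.warn("degenerate variance distribution; moderation skipped")
        return s2.copy(), 0.0, float(np.median(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2) + np.log(df[ok] / 2)
    ev = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df[ok] / 2)))
    if ev <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
        post = np.full_like(s2, s0_sq)
        post[~ok] = s2[~ok]
        return post, d0, s0_sq
    # solve trigamma(d0/2) = ev for d0
    d0 = 2.0 * _trigamma_inverse(ev)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2) - np.log(d0 / 2)))
    post = s2.copy()
    post[ok] = (d0 * s0_sq + df[ok] * s2[ok]) / (d0 + df[ok])
    return post, float(d0), s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton, as in limma's fitFDist)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving, monotone, capped at 1; input order is retained.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    if m == 0:
        return arr.copy()
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def classify_de(
    results: pd.DataFrame, lfc_cut: float = LFC_CUT, alpha: float = ALPHA_ADJ
) -> pd.Series:
    """Classify genes as up / down / ns from logFC and adjusted p."""
    up = (results["logFC"] > lfc_cut) & (results["p_adj"] < alpha)
    down = (results["logFC"] < -lfc_cut) & (results["p_adj"] < alpha)
    out = pd.Series("ns", index=results.index, dtype=object)
    out[up] = "up"
    out[down] = "down"
    return out


class VirusDEModel:
    """Differential-expression model for one virus.

    Parameters
    ----------
    gene_counts : DataFrame, genes x libraries (featureCounts-style counts)
    meta : DataFrame indexed by library with ``project``, ``genotype``,
        ``tissue`` and ``sex`` columns
    calls : boolean DataFrame, libraries x viruses
    virus : which virus's presence/absence to model

    The constructor restricts libraries to the projects where the virus was
    called, resolves the fixed terms and the random-intercept label,
    filters weakly expressed genes and computes log2-CPM.  ``fit`` returns
    a :class:`VirusDEResults`.
    """

    def __init__(
        self,
        gene_counts: pd.DataFrame,
        meta: pd.DataFrame,
        calls: pd.DataFrame,
        virus: str,
        *,
        sex_col: str = "sex",
        prior_count: float = 0.5,
        min_cpm: float = 1.0,
        min_fraction: float = 0.05,
    ):
        self.virus = virus
        self.spec = build_design(meta, calls, virus, sex_col=sex_col)
        counts = gene_counts[self.spec.libraries]
        self.genes = filter_genes(counts, min_cpm=min_cpm, min_fraction=min_fraction)
        self.lib_sizes = effective_library_sizes(counts.loc[self.genes])
        self.logcpm = normalize_logcpm(
            counts.loc[self.genes], prior_count=prior_count, lib_sizes=self.lib_sizes
        )
        self.spec.libraries = list(self.logcpm.columns)
        self.spec.design = self.spec.design.loc[self.spec.libraries]
        if self.spec.groups is not None:
            self.spec.groups = self.spec.groups.loc[self.spec.libraries]

    @classmethod
    def from_frames(cls, gene_counts, meta, calls, virus, **kw) -> "VirusDEModel":
        return cls(gene_counts, meta, calls, virus, **kw)

    def fit(self, moderate: bool = True) -> "VirusDEResults":
        X = self.spec.design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        g = self.spec.groups.to_numpy() if self.spec.groups is not None else None
        gd = _GroupedDesign(X, g)
        ysorted = self.logcpm.to_numpy(dtype=float)[:, gd.order]
        rows = []
        skipped = []
        for gi, gene in enumerate(self.genes):
            try:
                beta, se, df, sigma2, lam, mixed = _fit_single(gd, ysorted[gi])
            except (np.linalg.LinAlgError, ValueError) as err:  # pragma: no cover
                skipped.append((gene, str(err)))
                continue
            rows.append((gene, beta, se, df, sigma2, lam))
        cols = list(self.spec.design.columns)
        p = len(cols)
        table = pd.DataFrame(
            {
                "gene": np.repeat([r[0] for r in rows], p),
                "coefficient": np.tile(cols, len(rows)),
                "logFC": np.concatenate([r[1] for r in rows]),
                "se": np.concatenate([r[2] for r in rows]),
                "df": np.concatenate([r[3] for r in rows]),
                "sigma2": np.repeat([r[4] for r in rows], p),
                "lambda": np.repeat([r[5] for r in rows], p),
            }
        )
        table["stat"] = table["logFC"] / table["se"]
        table["p"] = 2.0 * stats.t.sf(np.abs(table["stat"]), table["df"])
        prior = None
        if moderate and len(rows) >= 10:
            resid_df = float(gd.n - gd.p)
            s2 = np.array([r[4] for r in rows])
            s2_post, d0, s0_sq = moderate_variances(s2, resid_df)
            shrink = np.sqrt(np.repeat(s2_post / s2, p))
            table["se"] = table["se"] * shrink
            table["stat"] = table["logFC"] / table["se"]
            extra = min(d0, 1e6)
            table["df"] = table["df"] + extra
            table["p"] = 2.0 * stats.t.sf(np.abs(table["stat"]), table["df"])
            prior = {"d0": d0, "s0_sq": s0_sq}
        # BH within each coefficient across genes
        table["p_adj"] = np.nan
        for coef in cols:
            mask = table["coefficient"] == coef
            table.loc[mask, "p_adj"] = adjust_bh(table.loc[mask, "p"].to_numpy())
        table["de_class"] = classify_de(table)
        return VirusDEResults(
            virus=self.virus,
            spec=self.spec,
            table=table.reset_index(drop=True),
            moderation=prior,
            skipped=skipped,
        )


class VirusDEResults:
    """Fitted per-gene coefficients for one virus.

    ``table`` has one row per (gene, coefficient) with logFC, se, stat,
    df, p, p_adj and de_class.
    """

    def __init__(self, virus, spec, table, moderation=None, skipped=()):
        self.virus = virus
        self.spec = spec
        self.table = table
        self.moderation = moderation
        self.skipped = list(skipped)

    def coefficients(self) -> list[str]:
        return list(self.spec.design.columns)

    def coef_table(self, coefficient: str) -> pd.DataFrame:
        sub = self.table[self.table["coefficient"] == coefficient]
        if sub.empty:
            raise KeyError(coefficient)
        return sub.set_index("gene")

    def class_counts(self) -> pd.DataFrame:
        """Up/down/ns tallies per biological coefficient (intercept omitted)."""
        rows = []
        for coef in self.coefficients():
            if coef == "Intercept":
                continue
            sub = self.table[self.table["coefficient"] == coef]
            counts = sub["de_class"].value_counts()
            rows.append(
                {"coefficient": coef,
                 "up": int(counts.get("up", 0)),
                 "down": int(counts.get("down", 0)),
                 "ns": int(counts.get("ns", 0))}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        n_genes = self.table["gene"].nunique()
        lines = [
            f"Differential expression: {self.virus}",
            f"  libraries: {len(self.spec.libraries)}   genes tested: {n_genes}",
            f"  fixed terms: {' + '.join(self.spec.fixed_terms)}",
            f"  random intercept: {self.spec.random_group or '(none; OLS)'}",
        ]
        if self.moderation:
            d0 = self.moderation["d0"]
            lines.append(
                f"  variance moderation: prior df {d0:.2f}, prior s2 "
                f"{self.moderation['s0_sq']:.4f}"
            )
        lines.append(f"  classification: |logFC| > {LFC_CUT}, BH-adjusted p < {ALPHA_ADJ}")
        cc = self.class_counts()
        for _, row in cc.iterrows():
            lines.append(
                f"  {row['coefficient']:<30s} up {row['up']:>5d}  down "
                f"{row['down']:>5d}  ns {row['ns']:>5d}"
            )
        return "\n".join(lines)
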