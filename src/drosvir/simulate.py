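"""Synthetic multi-project RNA-seq data with planted virus infections.

The generator emulates the structure of a collection of published
*Drosophila melanogaster* sequencing projects that were incidentally
infected with natural viruses:

* libraries grouped into projects, genotypes, tissues and sequencing lanes;
* a true per-library infection status per virus, drawn at a per-project
  prevalence;
* virus read counts that are large (log-normally distributed titres) in
  truly infected libraries, while uninfected libraries on the same lane
  receive a small Poisson number of "hopped" reads through index
  hopping / barcode switching;
* host gene counts that are negative-binomial with log2-scale fixed effects
  for sex, virus presence and their interaction, plus a normal random
  intercept per dataset-genotype-tissue group;
* strictly sex-limited marker genes used downstream to verify library sex,
  with an optional leakage flag that lets wrong-sex marker reads appear at
  the hop rate so the switching-rate estimator has signal.

Everything is deterministic given ``SimConfig.seed``; per-stage substreams
are derived from a single :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_experiment",
    "simulate_virus_counts",
    "simulate_gene_counts",
]

COEF_SEX = "sex_male"


def virus_coef(virus: str) -> str:
    """Column label of the main-effect coefficient for ``virus``."""
    return f"virus[{virus}]"


def interaction_coef(virus: str) -> str:
    """Column label of the sex:virus interaction coefficient for ``virus``."""
    return f"sex_male:virus[{virus}]"


@dataclass
class SimConfig:
    """Configuration of the synthetic experiment.

    Parameters mirror the study design being emulated: a handful of
    projects of O(100) single-fly libraries each, viruses at prevalences
    of a few to tens of percent, infected titres spanning orders of
    magnitude, and an index-hop rate of order 10^-3.
    """

    n_projects: int = 2
    libraries_per_project: int = 100
    lanes_per_project: int = 2
    #: virus label -> prevalence (scalar, shared by projects) or one value
    #: per project.
    viruses: Mapping[str, float | Sequence[float]] = field(
        default_factory=lambda: {"nora_virus": 0.3, "DAV": 0.1}
    )
    hop_rate: float = 0.002
    #: median virus reads in a truly infected library (log-normal scale).
    infected_titer_mean: float = 1e5
    titer_log_sd: float = 1.0
    n_genes: int = 2000
    n_marker_male: int = 12
    n_marker_female: int = 5
    nb_dispersion: float = 0.2
    # planted expression effects (log2 fold changes); each affected gene
    # receives +lfc or -lfc with equal probability.
    virus_lfc: float = 1.0
    virus_affected_fraction: float = 0.1
    interaction_lfc: float = 1.0
    interaction_affected_fraction: float = 0.05
    sex_lfc: float = 1.0
    sex_affected_fraction: float = 0.1
    group_sd: float = 0.5
    lib_size_mean: float = 1e6
    lib_size_log_sd: float = 0.3
    baseline_log2_sd: float = 2.0
    genotypes_per_project: int = 2
    tissues: Sequence[str] = ("whole",)
    #: sexes cycled over libraries; a single entry gives a single-sex design
    sexes: Sequence[str] = ("male", "female")
    duplicate_pairs_per_project: int = 0
    marker_leakage: bool = False
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field."""
        for name in (
            "n_projects",
            "libraries_per_project",
            "lanes_per_project",
            "n_genes",
            "genotypes_per_project",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive count")
        for name in ("n_marker_male", "n_marker_female", "duplicate_pairs_per_project"):
            if int(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= float(self.hop_rate) < 1.0:
            raise ValueError("hop_rate must lie in [0, 1)")
        if not self.viruses:
            raise ValueError("viruses must name at least one virus")
        for v, prev in self.viruses.items():
            arr = np.atleast_1d(np.asarray(prev, dtype=float))
            if arr.size not in (1, self.n_projects):
                raise ValueError(
                    f"viruses[{v!r}] prevalence must be scalar or one value per project"
                )
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"viruses[{v!r}] prevalence must lie in [0, 1]")
        for name in (
            "infected_titer_mean",
            "titer_log_sd",
            "nb_dispersion",
            "lib_size_mean",
        ):
            if float(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "virus_affected_fraction",
            "interaction_affected_fraction",
            "sex_affected_fraction",
        ):
            if not 0.0 <= float(getattr(self, name)) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if float(self.group_sd) < 0:
            raise ValueError("group_sd must be non-negative")
        if self.n_marker_male + self.n_marker_female >= self.n_genes:
            raise ValueError("n_genes must exceed the number of marker genes")
        if not self.sexes or not set(self.sexes) <= {"male", "female"}:
            raise ValueError("sexes must be a non-empty subset of {'male', 'female'}")
        if 2 * self.duplicate_pairs_per_project > self.libraries_per_project:
            raise ValueError(
                "duplicate_pairs_per_project must not exceed half the libraries"
            )

    def prevalence(self, virus: str, project_index: int) -> float:
        arr = np.atleast_1d(np.asarray(self.viruses[virus], dtype=float))
        return float(arr[0] if arr.size == 1 else arr[project_index])


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic data."""

    #: boolean libraries x viruses
    infection_status: pd.DataFrame
    #: genes x coefficients, zero for unaffected genes (log2 scale)
    true_logfc: pd.DataFrame
    hop_rate: float
    #: per dataset-genotype-tissue group log2 offset
    group_intercepts: pd.Series
    male_markers: list[str] = field(default_factory=list)
    female_markers: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "hop_rate": self.hop_rate,
            "infection_status": {
                "libraries": list(self.infection_status.index),
                "viruses": list(self.infection_status.columns),
                "values": self.infection_status.astype(int).values.tolist(),
            },
            "true_logfc": {
                "genes": list(self.true_logfc.index),
                "coefficients": list(self.true_logfc.columns),
                "values": self.true_logfc.values.tolist(),
            },
            "group_intercepts": self.group_intercepts.to_dict(),
            "male_markers": self.male_markers,
            "female_markers": self.female_markers,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        status = pd.DataFrame(
            np.asarray(payload["infection_status"]["values"], dtype=bool),
            index=payload["infection_status"]["libraries"],
            columns=payload["infection_status"]["viruses"],
        )
        lfc = pd.DataFrame(
            np.asarray(payload["true_logfc"]["values"], dtype=float),
            index=payload["true_logfc"]["genes"],
            columns=payload["true_logfc"]["coefficients"],
        )
        return cls(
            infection_status=status,
            true_logfc=lfc,
            hop_rate=float(payload["hop_rate"]),
            group_intercepts=pd.Series(payload["group_intercepts"], dtype=float),
            male_markers=list(payload["male_markers"]),
            female_markers=list(payload["female_markers"]),
        )


def _make_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for p in range(config.n_projects):
        project = f"PRJSYN{p + 1:03d}"
        genotypes = [f"{project}_G{g + 1}" for g in range(config.genotypes_per_project)]
        # sexes alternate within lane blocks so every stratum (lane,
        # genotype, tissue) contains both sexes and is not confounded
        # with any other
        lane_block = -(-config.libraries_per_project // config.lanes_per_project)
        n_sex = len(config.sexes)
        for i in range(config.libraries_per_project):
            lane = f"{project}_L{i // lane_block + 1}"
            genotype = genotypes[(i // n_sex) % len(genotypes)]
            tissue = config.tissues[(i // (n_sex * len(genotypes))) % len(config.tissues)]
            rows.append(
                {
                    "library_id": f"{project}_lib{i + 1:04d}",
                    "project": project,
                    "genotype": genotype,
                    "tissue": tissue,
                    "lane": lane,
                    "sex": config.sexes[i % n_sex],
                    "duplicate_id": "",
                }
            )
    meta = pd.DataFrame(rows).set_index("library_id", drop=False)

    # duplicate pairs: technical re-sequencing of an existing library, kept
    # on the same lane so both members share the hopping environment.
    dup_rows = []
    for p in range(config.n_projects):
        project = f"PRJSYN{p + 1:03d}"
        proj_ids = [i for i in meta.index if meta.at[i, "project"] == project]
        chosen = rng.choice(proj_ids, size=config.duplicate_pairs_per_project, replace=False)
        for d, orig in enumerate(chosen):
            dup_label = f"{project}_dup{d + 1}"
            meta.at[orig, "duplicate_id"] = dup_label
            row = meta.loc[orig].copy()
            row["library_id"] = f"{orig}_rep"
            row["duplicate_id"] = dup_label
            dup_rows.append(row)
    if dup_rows:
        meta = pd.concat([meta, pd.DataFrame(dup_rows).set_index("library_id", drop=False)])
    meta.index.name = None
    return meta


def _draw_status(config: SimConfig, meta: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    viruses = list(config.viruses)
    projects = sorted(meta["project"].unique())
    status = pd.DataFrame(False, index=meta.index, columns=viruses)
    primary = ~meta.index.str.endswith("_rep")
    for v in viruses:
        for pi, project in enumerate(projects):
            mask = (meta["project"] == project) & primary
            n = int(mask.sum())
            draws = rng.random(n) < config.prevalence(v, pi)
            status.loc[mask, v] = draws
    # duplicates inherit the infection status of their originals
    for lib in meta.index[~primary]:
        status.loc[lib] = status.loc[lib[: -len("_rep")]]
    return status


def simulate_virus_counts(
    status: pd.DataFrame,
    lanes: pd.Series,
    hop_rate: float,
    infected_titer_mean: float,
    titer_log_sd: float,
    rng: np.random.Generator,
    duplicate_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Draw per-library virus read counts from the hop model.

    Truly infected libraries receive a Poisson count around a log-normal
    latent titre (median ``infected_titer_mean``).  Every uninfected
    library then receives a Poisson number of hopped reads with mean
    ``hop_rate * lane_total / (lane_size - 1)`` where ``lane_total`` is the
    summed count of that virus among its lane-mates' infections.  Duplicate
    libraries (``duplicate_of``) share the latent titre of their original,
    so their counts are independent Poisson re-samples of the same truth.
    """
    if not status.index.equals(lanes.index):
        raise ValueError("status and lane assignment must index the same libraries")
    duplicate_of = dict(duplicate_of or {})
    counts = pd.DataFrame(0, index=status.index, columns=status.columns, dtype=np.int64)
    n = len(status.index)
    # latent titres, shared within duplicate pairs
    titers = pd.DataFrame(0.0, index=status.index, columns=status.columns)
    for v in status.columns:
        infected = status[v].to_numpy()
        lam = np.zeros(n)
        draw = np.exp(
            rng.normal(np.log(infected_titer_mean), titer_log_sd, size=n)
        )
        lam[infected] = draw[infected]
        titers[v] = lam
    for lib, orig in duplicate_of.items():
        titers.loc[lib] = titers.loc[orig]
    for v in status.columns:
        lam = titers[v].to_numpy()
        obs = np.zeros(n, dtype=np.int64)
        pos = lam > 0
        obs[pos] = rng.poisson(lam[pos])
        counts[v] = obs
    if hop_rate > 0:
        for lane, members in lanes.groupby(lanes).groups.items():
            idx = list(members)
            size = len(idx)
            if size < 2:
                continue
            for v in status.columns:
                lane_total = int(counts.loc[idx, v].sum())
                if lane_total == 0:
                    continue
                mean = hop_rate * lane_total / (size - 1)
                uninfected = [i for i in idx if not status.at[i, v]]
                if uninfected:
                    counts.loc[uninfected, v] += rng.poisson(mean, size=len(uninfected))
    return counts


def _plant_effects(
    config: SimConfig,
    gene_ids: list[str],
    viruses: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the planted log2 fold changes; marker genes are never affected."""
    coefs = [COEF_SEX] + [virus_coef(v) for v in viruses] + [interaction_coef(v) for v in viruses]
    lfc = pd.DataFrame(0.0, index=gene_ids, columns=coefs)
    n_marker = config.n_marker_male + config.n_marker_female
    eligible = np.array(gene_ids[n_marker:])

    def plant(column: str, fraction: float, magnitude: float) -> None:
        k = int(round(fraction * len(eligible)))
        if k == 0 or magnitude == 0:
            return
        chosen = rng.choice(eligible, size=k, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k)
        lfc.loc[chosen, column] = signs * magnitude

    plant(COEF_SEX, config.sex_affected_fraction, config.sex_lfc)
    for v in viruses:
        plant(virus_coef(v), config.virus_affected_fraction, config.virus_lfc)
        plant(interaction_coef(v), config.interaction_affected_fraction, config.interaction_lfc)
    return lfc


def group_label(meta: pd.DataFrame) -> pd.Series:
    """Dataset-genotype-tissue label used for the random intercept."""
    return (
        meta["project"].astype(str)
        + "_"
        + meta["genotype"].astype(str)
        + "_"
        + meta["tissue"].astype(str)
    )


def simulate_gene_counts(
    meta: pd.DataFrame,
    infection_status: pd.DataFrame,
    true_logfc: pd.DataFrame,
    nb_dispersion: float,
    male_markers: Sequence[str],
    female_markers: Sequence[str],
    lib_sizes: pd.Series,
    group_intercepts: pd.Series,
    rng: np.random.Generator,
    baseline_log2: pd.Series | None = None,
    baseline_log2_sd: float = 2.0,
    marker_leakage: bool = False,
    hop_rate: float = 0.0,
    duplicate_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Draw negative-binomial gene counts under the planted linear model.

    The per-gene, per-library log2 mean is baseline + sex effect + virus
    effects + sex:virus effects + group intercept; expected counts are the
    library size times the per-library renormalized composition (so column
    sums concentrate around ``lib_sizes``).  ``nb_dispersion`` is the usual
    NB overdispersion (variance mu + phi mu^2), realized as gamma-Poisson.
    Marker genes express in one sex only; with ``marker_leakage`` a total of
    ``hop_rate`` times each lane's marker reads relocates into opposite-sex
    lane-mates, giving the switching-rate estimator its signal.
    """
    gene_ids = list(true_logfc.index)
    libs = list(meta.index)
    n_genes, n_libs = len(gene_ids), len(libs)
    viruses = list(infection_status.columns)

    if baseline_log2 is None:
        baseline_log2 = pd.Series(
            rng.normal(0.0, baseline_log2_sd, size=n_genes), index=gene_ids
        )
    eta = np.tile(baseline_log2.to_numpy()[:, None], (1, n_libs))

    is_male = (meta["sex"].to_numpy() == "male").astype(float)
    eta += np.outer(true_logfc[COEF_SEX].to_numpy(), is_male)
    for v in viruses:
        inf = infection_status[v].reindex(libs).to_numpy().astype(float)
        eta += np.outer(true_logfc[virus_coef(v)].to_numpy(), inf)
        eta += np.outer(true_logfc[interaction_coef(v)].to_numpy(), inf * is_male)
    groups = group_label(meta)
    eta += group_intercepts.reindex(groups.to_numpy()).to_numpy()[None, :]

    # marker genes are strictly sex-limited
    male_rows = [gene_ids.index(g) for g in male_markers]
    female_rows = [gene_ids.index(g) for g in female_markers]
    weights = np.exp2(eta)
    female_cols = is_male == 0.0
    male_cols = ~female_cols
    weights[np.ix_(male_rows, np.where(female_cols)[0])] = 0.0
    weights[np.ix_(female_rows, np.where(male_cols)[0])] = 0.0

    # per-library compositional renormalization
    props = weights / weights.sum(axis=0, keepdims=True)
    mu = props * lib_sizes.reindex(libs).to_numpy()[None, :]

    phi = float(nb_dispersion)
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    else:
        lam = mu
    # duplicate libraries re-sample counts around the original's latent rate
    duplicate_of = dict(duplicate_of or {})
    if duplicate_of:
        col = {lib: j for j, lib in enumerate(libs)}
        for lib, orig in duplicate_of.items():
            lam[:, col[lib]] = lam[:, col[orig]]
    counts = rng.poisson(lam)

    if marker_leakage and hop_rate > 0:
        lanes = meta["lane"]
        col = {lib: j for j, lib in enumerate(libs)}
        for lane, members in lanes.groupby(lanes).groups.items():
            idx = [col[m] for m in members]
            male_idx = [j for j in idx if is_male[j] == 1.0]
            female_idx = [j for j in idx if is_male[j] == 0.0]
            for rows, src, dst in (
                (male_rows, male_idx, female_idx),
                (female_rows, female_idx, male_idx),
            ):
                if not src or not dst:
                    continue
                for g in rows:
                    total = counts[g, src].sum()
                    if total == 0:
                        continue
                    counts[g, dst] += rng.poisson(hop_rate * total / len(dst), size=len(dst))

    return pd.DataFrame(counts, index=gene_ids, columns=libs)


def simulate_experiment(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate metadata, virus counts, gene counts and ground truth.

    Returns ``(meta, virus_counts, gene_counts, truth)``.  ``virus_counts``
    carries one integer column per virus plus a ``total_reads`` column
    (host + viral reads).  Deterministic given ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_meta, rng_status, rng_effects, rng_genes, rng_virus = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    meta = _make_metadata(config, rng_meta)
    duplicate_of = {
        lib: lib[: -len("_rep")] for lib in meta.index if lib.endswith("_rep")
    }
    status = _draw_status(config, meta, rng_status)
    viruses = list(config.viruses)

    male_markers = [f"male_marker_{i + 1:02d}" for i in range(config.n_marker_male)]
    female_markers = [f"female_marker_{i + 1:02d}" for i in range(config.n_marker_female)]
    n_other = config.n_genes - len(male_markers) - len(female_markers)
    gene_ids = male_markers + female_markers + [f"gene_{i + 1:05d}" for i in range(n_other)]

    true_logfc = _plant_effects(config, gene_ids, viruses, rng_effects)
    groups = sorted(group_label(meta).unique())
    group_intercepts = pd.Series(
        rng_effects.normal(0.0, config.group_sd, size=len(groups)), index=groups
    )
    lib_sizes = pd.Series(
        np.exp(
            rng_genes.normal(np.log(config.lib_size_mean), config.lib_size_log_sd, len(meta))
        ),
        index=meta.index,
    )

    gene_counts = simulate_gene_counts(
        meta,
        status,
        true_logfc,
        config.nb_dispersion,
        male_markers,
        female_markers,
        lib_sizes,
        group_intercepts,
        rng_genes,
        baseline_log2_sd=config.baseline_log2_sd,
        marker_leakage=config.marker_leakage,
        hop_rate=config.hop_rate,
        duplicate_of=duplicate_of,
    )
    virus_counts = simulate_virus_counts(
        status,
        meta["lane"],
        config.hop_rate,
        config.infected_titer_mean,
        config.titer_log_sd,
        rng_virus,
        duplicate_of=duplicate_of,
    )
    virus_counts = virus_counts.copy()
    virus_counts["total_reads"] = (
        gene_counts.sum(axis=0).reindex(meta.index)
        + virus_counts[viruses].sum(axis=1)
    ).astype(np.int64)

    truth = SyntheticTruth(
        infection_status=status,
        true_logfc=true_logfc,
        hop_rate=config.hop_rate,
        group_intercepts=group_intercepts,
        male_markers=male_markers,
        female_markers=female_markers,
    )
    return meta, virus_counts, gene_counts, truth


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["viruses"] = {k: (list(v) if isinstance(v, (list, tuple)) else v) for k, v in config.viruses.items()}
    d["tissues"] = list(config.tissues)
    d["sexes"] = list(config.sexes)
    return d


def config_from_dict(d: Mapping) -> SimConfig:
    d = dict(d)
    for key in ("tissues", "sexes"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)
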