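"""Synthetic multi-batch expression cohorts with planted subtypes.

The generator emulates the structure of a merged multi-dataset tumor
cohort: four latent transcriptional subgroups with disjoint marker-gene
blocks, additive/multiplicative per-(batch, gene) effects, and clinical
covariates coupled to the subgroups (one subgroup carries an elevated
recurrence rate and a high BRAF-mutation prevalence; BRAF-mutant samples
have proportionally shorter progression-free survival).

An optional contingent of "outlier" samples emulates low-tumor-purity
specimens: attenuated, non-specific expression of *all* subgroup marker
programs plus inflated measurement noise.  Such borderline profiles are
the ones that negative-silhouette filtering is meant to remove.

The clinical table printed in the source cohort's patient summary ships as
a packaged fixture (:func:`load_table1_fixture`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .enrichment import GeneSetCollection

SUBGROUP_NAMES = ("C1", "C2", "C3", "C4")
OUTLIER_LABEL = "outlier"

#: default per-subgroup clinical frequencies: the BRAF-driven subgroup (C2)
#: carries a 42% recurrence rate and 71% BRAF prevalence; C1 has a single
#: recurrence among 11 samples (9%), C3 one BRAF-mutant recurrence (~8%).
DEFAULT_RECURRENCE = (0.09, 0.42, 0.075, 0.0)
DEFAULT_BRAF = (0.0, 0.71, 0.08, 0.0)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Defaults mirror the merged-cohort geometry: 53 core samples in four
    subgroups of 11/18/13/11 across three batches, 100 marker genes per
    subgroup with a 1.5-SD expression shift, and batch effects of the same
    order as the biological noise.
    """

    n_genes: int = 5000
    subgroup_sizes: tuple[int, ...] = (11, 18, 13, 11)
    n_batches: int = 3
    markers_per_subgroup: int = 100
    marker_effect: float = 1.5
    batch_shift_sd: float = 0.5
    batch_scale_range: tuple[float, float] = (0.8, 1.25)
    noise_sd: float = 1.0
    recurrence_prob: tuple[float, ...] = DEFAULT_RECURRENCE
    braf_prob: tuple[float, ...] = DEFAULT_BRAF
    braf_pfs_hazard_ratio: float = 4.0
    median_pfs_months: float = 36.0
    n_outliers: int = 0
    outlier_marker_weight: float = 0.5
    outlier_noise_mult: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.subgroup_sizes) <= 0:
            raise ValueError("subgroup_sizes must sum to a positive sample count")
        n_sub = len(self.subgroup_sizes)
        if self.markers_per_subgroup * n_sub > self.n_genes:
            raise ValueError("marker blocks do not fit within n_genes")
        for probs in (self.recurrence_prob, self.braf_prob):
            if len(probs) != n_sub:
                raise ValueError("per-subgroup probability vectors must match subgroup count")
            if not all(0.0 <= p <= 1.0 for p in probs):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_batches < 1:
            raise ValueError("need at least one batch")
        lo, hi = self.batch_scale_range
        if not (0 < lo <= hi):
            raise ValueError("batch_scale_range must be positive and ordered")

    @property
    def subgroup_names(self) -> tuple[str, ...]:
        return tuple(f"C{i + 1}" for i in range(len(self.subgroup_sizes)))

    @property
    def n_samples(self) -> int:
        return sum(self.subgroup_sizes) + self.n_outliers


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort (for recovery tests)."""

    subgroup: pd.Series                 # per-sample planted label (or "outlier")
    batch: pd.Series
    markers: dict[str, list[str]]       # subgroup -> marker gene IDs (disjoint)
    config: CohortConfig = field(repr=False)

    def __post_init__(self) -> None:
        if not self.subgroup.index.equals(self.batch.index):
            raise ValueError("subgroup and batch labels must cover identical samples")
        blocks = list(self.markers.values())
        seen: set[str] = set()
        for block in blocks:
            if seen & set(block):
                raise ValueError("marker blocks must be pairwise disjoint")
            seen |= set(block)

    @property
    def marker_genes(self) -> list[str]:
        return [g for block in self.markers.values() for g in block]

    @property
    def structured_samples(self) -> pd.Index:
        return self.subgroup.index[self.subgroup != OUTLIER_LABEL]

    @property
    def outlier_samples(self) -> pd.Index:
        return self.subgroup.index[self.subgroup == OUTLIER_LABEL]


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None):
    """Simulate a multi-batch expression cohort with planted subgroups.

    Expression of gene g in sample j is
    ``baseline_g + effect * 1[g marker of subgroup(j)] + gamma_{b(j),g} +
    eps`` with ``eps ~ N(0, (delta_{b(j),g} * noise_sd)^2)``; gamma is the
    additive and delta the multiplicative per-(batch, gene) effect.
    Clinical covariates are drawn per subgroup; PFS times are exponential
    with the BRAF hazard multiplier and administratively censored at the
    75th percentile of the simulated event times.

    Returns ``(ExpressionMatrix, clinical table, CohortTruth)``.  Identical
    seed and config reproduce the output bit for bit.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = config.subgroup_names
    n_struct = sum(config.subgroup_sizes)
    n_total = config.n_samples

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"S{j:03d}" for j in range(n_total)]

    subgroup = pd.Series(
        [name for name, size in zip(names, config.subgroup_sizes) for _ in range(size)]
        + [OUTLIER_LABEL] * config.n_outliers,
        index=sample_ids, name="subgroup",
    )
    # deterministic interleaving keeps every batch represented in every subgroup
    batch = pd.Series(
        [f"batch{j % config.n_batches}" for j in range(n_total)],
        index=sample_ids, name="batch",
    )

    markers = {
        name: gene_ids[i * config.markers_per_subgroup:(i + 1) * config.markers_per_subgroup]
        for i, name in enumerate(names)
    }

    baseline = rng.normal(7.0, 1.0, size=config.n_genes)
    gamma = rng.normal(0.0, config.batch_shift_sd, size=(config.n_batches, config.n_genes))
    lo, hi = config.batch_scale_range
    delta = rng.uniform(lo, hi, size=(config.n_batches, config.n_genes))

    mean = np.tile(baseline[:, None], (1, n_total))
    for i, name in enumerate(names):
        cols = np.flatnonzero((subgroup == name).to_numpy())
        rows = slice(i * config.markers_per_subgroup, (i + 1) * config.markers_per_subgroup)
        mean[rows, cols[None, :]] += config.marker_effect
    out_cols = np.flatnonzero((subgroup == OUTLIER_LABEL).to_numpy())
    if out_cols.size:
        n_marker_rows = config.markers_per_subgroup * len(names)
        mean[:n_marker_rows, out_cols[None, :]] += (
            config.outlier_marker_weight * config.marker_effect
        )

    batch_idx = np.array([int(b[5:]) for b in batch])
    mean += gamma[batch_idx, :].T
    noise_scale = delta[batch_idx, :].T * config.noise_sd
    if out_cols.size:
        noise_scale[:, out_cols] *= config.outlier_noise_mult
    values = mean + rng.normal(size=(config.n_genes, n_total)) * noise_scale

    expr = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=sample_ids), batch)
    clinical = _draw_clinical(config, rng, subgroup, names)
    truth = CohortTruth(subgroup=subgroup, batch=batch, markers=markers, config=config)
    return expr, clinical, truth


def _draw_clinical(config, rng, subgroup, names) -> pd.DataFrame:
    """Per-sample clinical covariates coupled to the planted subgroups."""
    sub_index = {name: i for i, name in enumerate(names)}
    mean_rec = float(np.mean(config.recurrence_prob))
    mean_braf = float(np.mean(config.braf_prob))
    age_mean = {"C1": 32.0, "C2": 30.0, "C3": 14.0, "C4": 26.0}
    histology_mix = {
        "C1": (["DNT"], [1.0]),
        "C2": (["GG", "PXA"], [0.8, 0.2]),
        "C3": (["GG", "DNT"], [0.9, 0.1]),
        "C4": (["DNT", "GG"], [0.5, 0.5]),
    }
    rows = []
    for sample_id, label in subgroup.items():
        if label == OUTLIER_LABEL:
            p_rec, p_braf = mean_rec, mean_braf
            age_mu, (histologies, weights) = 28.0, (["DNT", "GG"], [0.5, 0.5])
        else:
            i = sub_index[label]
            p_rec, p_braf = config.recurrence_prob[i], config.braf_prob[i]
            age_mu = age_mean.get(label, 28.0)
            histologies, weights = histology_mix.get(label, (["DNT", "GG"], [0.5, 0.5]))
        age = float(np.clip(rng.normal(age_mu, 8.0), 3.0, 75.0))
        histology = rng.choice(histologies, p=np.array(weights) / np.sum(weights))
        recurrence = bool(rng.random() < p_rec)
        braf = "V600E" if rng.random() < p_braf else "WT"
        engel = "Ia" if rng.random() < 0.88 else "IIIa"
        hazard = np.log(2.0) / config.median_pfs_months
        if braf == "V600E":
            hazard *= config.braf_pfs_hazard_ratio
        pfs = rng.exponential(1.0 / hazard)
        rows.append({
            "sample_id": sample_id, "histology": histology, "age": round(age, 1),
            "engel": engel, "recurrence": recurrence, "braf": braf,
            "cluster": label, "pfs_time": pfs, "pfs_event": 1,
        })
    table = pd.DataFrame(rows)
    horizon = float(np.quantile(table["pfs_time"], 0.75))
    censored = table["pfs_time"] > horizon
    table.loc[censored, "pfs_time"] = horizon
    table.loc[censored, "pfs_event"] = 0
    table["pfs_time"] = table["pfs_time"].round(2).clip(lower=0.01)
    return table


def generate_gene_sets(
    truth: CohortTruth,
    set_size: int = 50,
    n_random_sets: int = 20,
    seed: int | None = None,
) -> GeneSetCollection:
    """One "planted" set per subgroup (sampled from its marker block) plus
    ``n_random_sets`` sets of non-marker genes.  Serialisable to GMT."""
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if set_size > truth.config.markers_per_subgroup:
        raise ValueError("set_size exceeds the marker block size")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for name, block in truth.markers.items():
        members = sorted(rng.choice(block, size=set_size, replace=False))
        sets[f"PLANTED_{name}"] = list(members)
        descriptions[f"PLANTED_{name}"] = f"markers of planted subgroup {name}"
    marker_set = set(truth.marker_genes)
    all_genes = [f"G{i:05d}" for i in range(truth.config.n_genes)]
    background = [g for g in all_genes if g not in marker_set]
    for r in range(n_random_sets):
        members = sorted(rng.choice(background, size=set_size, replace=False))
        sets[f"RANDOM_{r + 1:02d}"] = list(members)
        descriptions[f"RANDOM_{r + 1:02d}"] = "random non-marker genes"
    return GeneSetCollection(sets, descriptions)


def load_table1_fixture() -> pd.DataFrame:
    """Clinical summary table of the 18-patient transcriptional cohort.

    Columns: patient number, sex, age at surgery (years), Engel outcome,
    neuropathological diagnosis, associated FCD, hippocampal sclerosis,
    WHO grade, CD34, IDH status, MIB index, death, recurrence, and the
    transcriptional cluster label.
    """
    path = resources.files("leatsubtype").joinpath("data/table1.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"mib": str})
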