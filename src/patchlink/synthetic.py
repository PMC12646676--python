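"""Synthetic patch-seq cohort generator with planted, recoverable structure.

The generator emulates a multi-donor islet patch-seq study comparing
nondiabetic (ND) and type 1 diabetic (T1D) donors: negative-binomial gene
counts with marker-gene structure and dropout, per-cell-type
electrophysiology drawn from multivariate normals, condition-specific cell
composition (T1D cohorts are alpha-dominant with rare surviving beta
cells), planted ND-vs-T1D differential expression in alpha cells, and
planted monotone gene-electrophysiology couplings realised through a
Gaussian copula.  Every planted effect is recorded in a
:class:`GroundTruth` so downstream stages can be scored against it.

Default cohort shape mirrors a realistic study: 17 ND donors contributing
~22 cells each and 9 T1D donors contributing ~77 cells each, with T1D beta
cells rare (tens of cells across the cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CELL_TYPES,
    DEFAULT_MARKERS,
    EPHYS_FEATURES,
    PatchSeqDataset,
)
from . import io as plio

# Per-(condition, type) electrophysiology feature means, in raw units
# (pF, fF/pF, pA/pF, pC/pF).  Inward currents are negative.  T1D alpha
# cells are larger and hyperresponsive (more exocytosis, larger Ca2+/Na+
# currents); T1D beta cells show increased exocytosis and Ca2+ currents.
_ALPHA_ND = (4.5, 20.0, 10.0, 10.0, -9.0, -5.0, -0.9, -45.0)
_BETA_ND = (7.5, 10.0, 6.0, 4.0, -6.0, -9.0, -1.4, -25.0)
DEFAULT_EPHYS_MEANS: dict[tuple[str, str], tuple[float, ...]] = {
    ("ND", "alpha"): _ALPHA_ND,
    ("T1D", "alpha"): (5.5, 30.0, 15.0, 15.0, -12.0, -6.5, -1.2, -60.0),
    ("ND", "beta"): _BETA_ND,
    ("T1D", "beta"): (7.5, 15.0, 8.0, 7.0, -8.5, -11.5, -1.7, -25.0),
    ("ND", "delta"): (3.5, 25.0, 12.0, 12.0, -8.0, -6.0, -0.8, -35.0),
    ("T1D", "delta"): (3.5, 25.0, 12.0, 12.0, -8.0, -6.0, -0.8, -35.0),
    ("ND", "gamma"): (4.0, 8.0, 4.0, 4.0, -5.0, -4.0, -0.5, -20.0),
    ("T1D", "gamma"): (4.0, 8.0, 4.0, 4.0, -5.0, -4.0, -0.5, -20.0),
    ("ND", "acinar"): (9.0, 2.0, 1.0, 1.0, -2.0, -2.0, -0.2, -5.0),
    ("T1D", "acinar"): (9.0, 2.0, 1.0, 1.0, -2.0, -2.0, -0.2, -5.0),
}

#: Biological coefficient of variation applied to every feature when no
#: explicit covariance is supplied (diagonal covariance, sd = 0.45 |mean|,
#: floored at 0.5 in the feature's units).
DEFAULT_EPHYS_CV = 0.45

DEFAULT_PROPS = {
    "ND": {"alpha": 0.65, "beta": 0.28, "delta": 0.04, "gamma": 0.02, "acinar": 0.01},
    "T1D": {"alpha": 0.86, "beta": 0.025, "delta": 0.06, "gamma": 0.035, "acinar": 0.02},
}


class ConfigError(ValueError):
    """Raised for infeasible or invalid generator configurations."""


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort.

    Counts are negative binomial with per-gene mean ``mu_g`` drawn
    log-normally (``exp(N(nb_mean_log_mu, nb_mean_log_sigma))``) and
    dispersion ``nb_dispersion`` (variance ``mu + mu^2 / dispersion``).
    Marker genes are elevated ``marker_boost``-fold in their own type;
    planted DE genes are shifted by ``de_log2fc`` log2 units in T1D alpha
    cells only; planted linked genes share a latent Gaussian copula of
    correlation ``rho_true`` with ``linked_property`` within alpha cells.
    """

    n_donors_nd: int = 17
    n_donors_t1d: int = 9
    cells_per_donor: dict[str, int] = field(
        default_factory=lambda: {"ND": 22, "T1D": 77}
    )
    n_genes: int = 2000
    cell_type_props: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(p) for c, p in DEFAULT_PROPS.items()}
    )
    nb_mean_log_mu: float = 0.0
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 1.0
    marker_boost: float = 100.0
    marker_base_mean: float = 5.0
    #: dispersion of marker genes; high-mean transcripts are relatively much
    #: tighter than the genome-wide baseline (empirical mean-dispersion trend)
    marker_dispersion: float = 10.0
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    n_linked_genes: int = 20
    rho_true: float = 0.5
    linked_property: str = "total_exo"
    planted_mean_range: tuple[float, float] = (5.0, 50.0)
    donor_sd: float = 0.1
    dropout_rate: float = 0.0
    glucose: float = 5.0
    ephys_means: dict[tuple[str, str], tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EPHYS_MEANS)
    )
    ephys_cov: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        for cond, props in self.cell_type_props.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"cell_type_props[{cond!r}] sums to {total}, not 1")
            unknown = set(props) - set(CELL_TYPES)
            if unknown:
                raise ConfigError(f"unknown cell types in props: {sorted(unknown)}")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if not -1 < self.rho_true < 1:
            raise ConfigError("|rho_true| must be < 1")
        if self.linked_property not in EPHYS_FEATURES:
            raise ConfigError(f"unknown linked_property {self.linked_property!r}")
        n_markers = sum(len(v) for v in DEFAULT_MARKERS.values())
        n_planted = n_markers + self.n_de_genes + self.n_linked_genes
        if n_planted > self.n_genes:
            raise ConfigError(
                f"infeasible config: {n_planted} marker+DE+linked genes "
                f"exceed n_genes={self.n_genes}"
            )
        if self.ephys_cov is not None:
            cov = np.asarray(self.ephys_cov, dtype=float)
            if cov.shape != (len(EPHYS_FEATURES),) * 2:
                raise ConfigError("ephys_cov must be 8x8")
            if not np.allclose(cov, cov.T):
                raise ConfigError("ephys_cov must be symmetric")
            if np.min(np.linalg.eigvalsh(cov)) < -1e-8:
                raise ConfigError("ephys_cov must be positive semi-definite")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Planted structure of a generated cohort."""

    cell_type_of: pd.Series          # cell id -> type label
    de_genes: pd.Series              # gene -> planted log2FC (T1D alpha)
    linked_genes: pd.DataFrame       # gene -> (property, rho_true)
    donor_of: pd.Series              # cell id -> donor id
    condition_of: pd.Series          # donor id -> ND / T1D


def _nb_p(theta: float, mu: np.ndarray) -> np.ndarray:
    """Success probability of numpy/scipy's NB(theta, p) with mean mu."""
    return theta / (theta + mu)


def _cov_for(mean: np.ndarray, cov: np.ndarray | None) -> np.ndarray:
    if cov is not None:
        return np.asarray(cov, dtype=float)
    sd = np.maximum(DEFAULT_EPHYS_CV * np.abs(mean), 0.5)
    return np.diag(sd**2)


def generate_dataset(config: GeneratorConfig) -> tuple[PatchSeqDataset, GroundTruth]:
    """Draw one cohort from the generative model; reproducible from seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    theta = config.nb_dispersion

    # --- gene universe ----------------------------------------------------
    marker_genes = [g for ms in DEFAULT_MARKERS.values() for g in ms]
    n_other = config.n_genes - len(marker_genes)
    other = [f"GENE{i:05d}" for i in range(n_other)]
    gene_ids = marker_genes + other
    de_genes = other[: config.n_de_genes]
    linked = other[config.n_de_genes: config.n_de_genes + config.n_linked_genes]

    base_mu = np.exp(
        rng.normal(config.nb_mean_log_mu, config.nb_mean_log_sigma, size=config.n_genes)
    )
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for g in marker_genes:
        base_mu[gene_pos[g]] = config.marker_base_mean
    # planted genes get moderate baseline expression so that detection
    # filters (>= 50% of cells) retain them and recovery is well-defined
    lo, hi = config.planted_mean_range
    planted = de_genes + linked
    if planted:
        base_mu[[gene_pos[g] for g in planted]] = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=len(planted))
        )

    marker_type_of_gene = {
        g: t for t, ms in DEFAULT_MARKERS.items() for g in ms
    }

    # --- donors and cells -------------------------------------------------
    donors, conditions = [], []
    for i in range(config.n_donors_nd):
        donors.append(f"ND{i + 1:02d}")
        conditions.append("ND")
    for i in range(config.n_donors_t1d):
        donors.append(f"T1D{i + 1:02d}")
        conditions.append("T1D")
    condition_of_donor = pd.Series(conditions, index=donors, name="condition")
    donor_effect = {d: rng.normal(0.0, config.donor_sd) for d in donors}

    cells, cell_donor, cell_cond, cell_type = [], [], [], []
    types = list(CELL_TYPES)
    for donor, cond in zip(donors, conditions):
        n_cells = int(config.cells_per_donor[cond])
        probs = np.array([config.cell_type_props[cond].get(t, 0.0) for t in types])
        drawn = rng.choice(len(types), size=n_cells, p=probs)
        for j, ti in enumerate(drawn):
            cells.append(f"{donor}_c{j + 1:03d}")
            cell_donor.append(donor)
            cell_cond.append(cond)
            cell_type.append(types[ti])
    n_cells_total = len(cells)
    cell_type = np.array(cell_type, dtype=object)
    cell_cond = np.array(cell_cond, dtype=object)

    # --- per-cell expected means -----------------------------------------
    log_mu = np.log(base_mu)[:, None] + np.array(
        [donor_effect[d] for d in cell_donor]
    )[None, :]
    mu = np.exp(log_mu)
    for g, t in marker_type_of_gene.items():
        own = cell_type == t
        mu[gene_pos[g], own] *= config.marker_boost
    t1d_alpha = (cell_cond == "T1D") & (cell_type == "alpha")
    if de_genes:
        rows = [gene_pos[g] for g in de_genes]
        mu[np.ix_(rows, np.flatnonzero(t1d_alpha))] *= 2.0 ** config.de_log2fc

    theta_g = np.full(config.n_genes, theta)
    theta_g[[gene_pos[g] for g in marker_genes]] = config.marker_dispersion
    counts = rng.negative_binomial(theta_g[:, None], _nb_p(theta_g[:, None], mu))

    # --- electrophysiology ------------------------------------------------
    ephys = np.empty((n_cells_total, len(EPHYS_FEATURES)))
    prop_z = np.empty(n_cells_total)  # standardized linked-property value
    prop_idx = EPHYS_FEATURES.index(config.linked_property)
    for cond in ("ND", "T1D"):
        for t in types:
            sel = np.flatnonzero((cell_cond == cond) & (cell_type == t))
            if sel.size == 0:
                continue
            mean = np.asarray(config.ephys_means[(cond, t)], dtype=float)
            cov = _cov_for(mean, config.ephys_cov)
            draws = rng.multivariate_normal(mean, cov, size=sel.size,
                                            method="cholesky")
            ephys[sel] = draws
            sd = np.sqrt(cov[prop_idx, prop_idx])
            prop_z[sel] = (draws[:, prop_idx] - mean[prop_idx]) / sd

    # --- planted gene-ephys couplings (Gaussian copula, alpha cells) ------
    # For each linked gene, the gene's latent normal is rho * z_prop +
    # sqrt(1-rho^2) * eps, mapped through the NB quantile function; the
    # latent pair (gene, property) is then bivariate normal with
    # correlation rho, so ranks correlate at ~ (6/pi) asin(rho/2).
    rho = config.rho_true
    alpha_cells = np.flatnonzero(cell_type == "alpha")
    if linked and alpha_cells.size:
        eps = rng.standard_normal((len(linked), alpha_cells.size))
        z_gene = rho * prop_z[alpha_cells][None, :] + np.sqrt(1 - rho**2) * eps
        u = stats.norm.cdf(z_gene)
        for k, g in enumerate(linked):
            row = gene_pos[g]
            mu_row = mu[row, alpha_cells]
            counts[row, alpha_cells] = stats.nbinom.ppf(
                u[k], theta, _nb_p(theta, mu_row)
            ).astype(np.int64)

    if config.dropout_rate > 0:
        keep = rng.random(counts.shape) >= config.dropout_rate
        counts = counts * keep

    # --- metadata ---------------------------------------------------------
    age_rng = {"ND": (12, 46), "T1D": (13, 44)}
    meta = pd.DataFrame(
        {
            "donor": cell_donor,
            "condition": cell_cond,
            "glucose": config.glucose,
            "sex": rng.choice(["M", "F"], size=n_cells_total, p=[0.6, 0.4]),
            "age": [
                float(rng.integers(*age_rng[c])) for c in cell_cond
            ],
            "bmi": np.round(np.clip(rng.normal(23.0, 3.0, n_cells_total), 16.0, 30.0), 1),
            "cit": np.round(rng.uniform(2.0, 24.0, n_cells_total), 1),
        },
        index=pd.Index(cells, name="cell_id"),
    )
    # demographics are donor-level attributes: make them constant per donor
    for col in ("sex", "age", "bmi", "cit"):
        meta[col] = meta.groupby("donor")[col].transform("first")

    ephys_df = pd.DataFrame(ephys, index=meta.index, columns=list(EPHYS_FEATURES))
    dataset = PatchSeqDataset(counts.astype(np.int64), gene_ids, cells, meta, ephys_df)
    truth = GroundTruth(
        cell_type_of=pd.Series(cell_type, index=meta.index, name="cell_type"),
        de_genes=pd.Series(
            [config.de_log2fc] * len(de_genes), index=de_genes, name="log2fc",
            dtype=float,
        ),
        linked_genes=pd.DataFrame(
            {"property": [config.linked_property] * len(linked),
             "rho_true": [rho] * len(linked)},
            index=pd.Index(linked, name="gene"),
        ),
        donor_of=pd.Series(cell_donor, index=meta.index, name="donor"),
        condition_of=condition_of_donor,
    )
    return dataset, truth


def expected_spearman(rho: float) -> float:
    """Rank correlation implied by a Gaussian copula with correlation rho."""
    return 6.0 / np.pi * np.arcsin(rho / 2.0)


def build_gene_sets(
    dataset: PatchSeqDataset,
    truth: GroundTruth,
    n_decoy_sets: int = 20,
    decoy_size_range: tuple[int, int] = (15, 200),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Planted-truth gene sets plus random decoys for enrichment testing.

    Decoy sets are drawn uniformly from non-planted genes with sizes
    uniform on ``decoy_size_range``.
    """
    rng = np.random.default_rng(seed)
    planted = set(truth.de_genes.index) | set(truth.linked_genes.index)
    pool = [g for g in dataset.gene_ids if g not in planted]
    sets: dict[str, list[str]] = {}
    if len(truth.de_genes):
        sets["PLANTED_DE"] = list(truth.de_genes.index)
    if len(truth.linked_genes):
        sets["PLANTED_LINKED"] = list(truth.linked_genes.index)
    lo, hi = decoy_size_range
    for i in range(n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(pool), size=min(size, len(pool)), replace=False)
        sets[f"DECOY{i + 1:03d}"] = [pool[j] for j in sorted(members)]
    return sets


def write_fixture(
    dataset: PatchSeqDataset,
    truth: GroundTruth,
    directory,
    n_decoy_sets: int = 20,
    decoy_size_range: tuple[int, int] = (15, 200),
    seed: int = 0,
) -> dict[str, object]:
    """Write dataset, truth tables and a GMT (truth + decoy sets) to disk.

    The GMT contains the planted DE and linked gene sets plus
    ``n_decoy_sets`` random decoys drawn uniformly from non-planted genes,
    sized uniformly on ``decoy_size_range``.
    """
    paths = plio.write_dataset(dataset, directory)
    directory = Path(directory)
    paths["truth_cell_types"] = plio.write_table(
        truth.cell_type_of.to_frame(), directory / "truth_cell_types.tsv"
    )
    paths["truth_de_genes"] = plio.write_table(
        truth.de_genes.to_frame(), directory / "truth_de_genes.tsv", index_label="gene"
    )
    paths["truth_linked_genes"] = plio.write_table(
        truth.linked_genes, directory / "truth_linked_genes.tsv", index_label="gene"
    )
    cond = truth.condition_of.to_frame()
    paths["truth_donors"] = plio.write_table(
        cond, directory / "truth_donors.tsv", index_label="donor"
    )

    sets = build_gene_sets(dataset, truth, n_decoy_sets, decoy_size_range, seed)
    paths["gmt"] = plio.write_gmt(sets, directory / "gene_sets.gmt")
    return paths
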