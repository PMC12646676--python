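"""End-to-end orchestration: typing -> fingerprinting -> DE/GSEA ->
correlations -> consistency -> enrichment, from a single config.

A single seed fans out deterministically to per-stage seeds (spawned from
``numpy.random.SeedSequence``) so stages are individually re-runnable.
All thresholds actually applied are echoed in the JSON run report; the
report and every TSV are byte-identical across runs with the same config
and seed.  Wall-clock timings go to ``run.log`` only, which is outside
the determinism contract.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as plio
from .correlate import (
    bootstrap_correlations,
    detection_filter,
    multi_property_consistency,
)
from .datatypes import EPHYS_FEATURES, MarkerScheme, PatchSeqDataset
from .de import wilcoxon_de
from .enrich import (
    gsea_preranked,
    ora_hypergeometric,
    risk_enrichment_fisher,
    set_cover_weights,
    weighted_set_cover,
)
from .fingerprint import TrainConfig, audit_classifier, score_cells, train_classifier
from .preprocess import annotate_cell_types, exclude_outliers, normalize_cpm, \
    normalize_cp10k_log
from .synthetic import GeneratorConfig, generate_dataset

logger = logging.getLogger("patchlink")

#: Derived property: depolarization-evoked exocytosis per unit Ca2+ charge
#: entry (secretory efficacy of Ca2+ influx).
EXO_CA_RATIO = "exo_ca_ratio"

DEFAULT_PROPERTIES = (*EPHYS_FEATURES, "alpha_score", EXO_CA_RATIO)


class PipelineError(RuntimeError):
    pass


@dataclass
class Thresholds:
    detection: float = 0.5
    z: float = 3.0
    p: float = 0.05
    fdr: float = 0.1
    min_properties: int = 3

    def validate(self) -> None:
        if not 0 < self.detection <= 1:
            raise PipelineError("detection threshold must be in (0, 1]")
        if self.z <= 0 or not 0 < self.p < 1 or not 0 < self.fdr < 1:
            raise PipelineError("invalid threshold configuration")
        if self.min_properties < 1:
            raise PipelineError("min_properties must be >= 1")


@dataclass
class PipelineConfig:
    """Inputs, stratum, statistical gates and output location for a run."""

    input_dir: str | None = None          # dataset directory, or None
    synthetic: dict | None = None         # GeneratorConfig overrides, or None
    cell_type: str = "alpha"
    glucose: float | None = None          # None: no glucose filter
    properties: tuple[str, ...] = DEFAULT_PROPERTIES
    B: int = 1000
    n_perm: int = 1000
    thresholds: Thresholds = field(default_factory=Thresholds)
    gene_sets: str | None = None          # GMT path; fixture GMT used if present
    risk_lists: dict[str, str] = field(default_factory=dict)  # name -> path
    correlation_condition: str = "T1D"
    seed: int = 0
    outdir: str = "patchlink_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        cfg = cls(**{**raw, "thresholds": thr})
        if "properties" in raw:
            cfg.properties = tuple(raw["properties"])
        return cfg

    def validate(self) -> None:
        self.thresholds.validate()
        if self.input_dir is None and self.synthetic is None:
            raise PipelineError("config needs either input_dir or a synthetic block")
        if self.B < 1 or self.n_perm < 1:
            raise PipelineError("B and n_perm must be >= 1")


def _stage_seeds(seed: int, names: tuple[str, ...]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


STAGES = ("simulate", "fingerprint", "bootstrap", "gsea_de", "gsea_corr", "ora")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as
    ``report.json`` in the output directory)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed, STAGES)
    thr = config.thresholds
    report: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "thresholds": {
            "detection": thr.detection, "z": thr.z, "p": thr.p,
            "fdr": thr.fdr, "min_properties": thr.min_properties,
        },
        "config": {
            "cell_type": config.cell_type, "glucose": config.glucose,
            "properties": list(config.properties), "B": config.B,
            "n_perm": config.n_perm,
            "correlation_condition": config.correlation_condition,
        },
        "stages": {},
    }
    t_all = time.perf_counter()
    try:
        _run_stages(config, outdir, seeds, report)
    except Exception as exc:  # annotate the failing stage, then re-raise
        stage = report.get("failed_stage", "unknown")
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.info("total wall time %.2f s", time.perf_counter() - t_all)
        logger.removeHandler(handler)
        handler.close()
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _timed(report: dict, stage: str):
    report["failed_stage"] = stage
    logger.info("stage %s start", stage)
    return time.perf_counter()


def _done(report: dict, stage: str, t0: float, **counts) -> None:
    logger.info("stage %s done in %.2f s: %s", stage, time.perf_counter() - t0, counts)
    report["stages"][stage] = counts
    report.pop("failed_stage", None)


def _run_stages(config, outdir, seeds, report):
    thr = config.thresholds

    # --- load or simulate -------------------------------------------------
    t0 = _timed(report, "input")
    truth = None
    if config.synthetic is not None:
        gen = GeneratorConfig(**{**config.synthetic, "seed": seeds["simulate"]})
        dataset, truth = generate_dataset(gen)
    else:
        dataset = plio.read_dataset_dir(config.input_dir)
    _done(report, "input", t0, **{k: v for k, v in dataset.summary().items()
                                  if not isinstance(v, dict)})

    # --- typing -----------------------------------------------------------
    t0 = _timed(report, "cell_typing")
    cp10k = normalize_cp10k_log(dataset)
    types = annotate_cell_types(cp10k, dataset.gene_ids, dataset.cell_ids,
                                MarkerScheme())
    plio.write_table(types.to_frame(), outdir / "cell_types.tsv")
    _done(report, "cell_typing", t0,
          **{f"n_{t}": int((types == t).sum()) for t in types.unique()})

    meta = dataset.cell_meta
    strata = pd.DataFrame({
        "cell_type": types, "condition": meta["condition"], "glucose": meta["glucose"],
    })

    # --- outlier exclusion on electrophysiology ---------------------------
    ephys = dataset.ephys
    if ephys is not None:
        t0 = _timed(report, "outliers")
        logger.info("outlier threshold |z| > %s within (type, condition, glucose)",
                    thr.z)
        ephys, removed = exclude_outliers(ephys, strata, z_threshold=thr.z)
        plio.write_table(removed, outdir / "excluded_outliers.tsv", index_label="row")
        _done(report, "outliers", t0, n_values_removed=int(len(removed)))

    # --- fingerprinting ---------------------------------------------------
    scores = None
    if ephys is not None:
        t0 = _timed(report, "fingerprint")
        nd_ab = types.isin(["alpha", "beta"]) & (meta["condition"] == "ND")
        train_cells = [c for c in dataset.cell_ids
                       if nd_ab.get(c, False)
                       and c in ephys.index and not ephys.loc[c].isna().any()]
        X = ephys.loc[train_cells]
        y = types.loc[train_cells].to_numpy()
        from sklearn.model_selection import train_test_split

        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=0.2, stratify=y, random_state=seeds["fingerprint"],
        )
        model = train_classifier(
            X_tr, y_tr, TrainConfig(seed=seeds["fingerprint"])
        )
        audit = audit_classifier(model, X_te, y_te)
        model.save(outdir / "fingerprint_model")
        (outdir / "fingerprint_audit.json").write_text(
            json.dumps(audit.to_dict(), indent=1, sort_keys=True)
        )
        scores, skipped = score_cells(model, ephys)
        plio.write_table(scores, outdir / "alpha_scores.tsv")
        _done(report, "fingerprint", t0, n_train=len(X_tr), n_heldout=len(X_te),
              heldout_accuracy=round(audit.accuracy, 4),
              balanced_accuracy=round(audit.balanced_accuracy, 4),
              n_scored=len(scores), n_skipped=len(skipped))
    else:
        logger.warning("no electrophysiology table: fingerprinting skipped")
        report["stages"]["fingerprint"] = {"skipped": "no ephys table"}

    # --- stratum selection ------------------------------------------------
    in_stratum = types == config.cell_type
    if config.glucose is not None:
        in_stratum &= meta["glucose"] == config.glucose
    stratum_cells = np.array([in_stratum.get(c, False) for c in dataset.cell_ids])
    if stratum_cells.sum() == 0:
        raise PipelineError(f"no cells in stratum {config.cell_type!r}")

    # --- differential expression -----------------------------------------
    t0 = _timed(report, "differential_expression")
    cpm = normalize_cpm(dataset)
    is_t1d = (meta["condition"].to_numpy() == "T1D") & stratum_cells
    is_nd = (meta["condition"].to_numpy() == "ND") & stratum_cells
    sel = is_t1d | is_nd
    de_table = wilcoxon_de(
        cpm[:, sel], dataset.gene_ids, is_t1d[sel]
    )
    plio.write_table(de_table, outdir / "de_results.tsv", index_label="gene")
    n_sig = int((de_table["q"] < thr.fdr).sum())
    _done(report, "differential_expression", t0,
          n_cells_t1d=int(is_t1d.sum()), n_cells_nd=int(is_nd.sum()),
          n_genes_tested=int(de_table["tested"].sum()), n_de_at_fdr=n_sig)

    # --- gene sets --------------------------------------------------------
    sets = {}
    gmt_path = config.gene_sets
    if gmt_path is None and config.input_dir is not None:
        candidate = Path(config.input_dir) / "gene_sets.gmt"
        gmt_path = candidate if candidate.exists() else None
    if gmt_path is not None:
        sets = plio.read_gmt(gmt_path)
    elif truth is not None:
        from .synthetic import build_gene_sets

        sets = build_gene_sets(dataset, truth, seed=seeds["simulate"])

    # --- GSEA on DE z scores ----------------------------------------------
    if sets:
        t0 = _timed(report, "gsea_de")
        tested = de_table[de_table["tested"]]
        gsea_de = gsea_preranked(tested["z"], sets, n_perm=config.n_perm,
                                 seed=seeds["gsea_de"])
        sig = gsea_de[gsea_de["q"] < thr.fdr]
        cover = weighted_set_cover(
            {s: sets[s] for s in sig.index}, set_cover_weights(sig["q"])
        )
        gsea_de = gsea_de.assign(in_set_cover=gsea_de.index.isin(cover))
        plio.write_table(gsea_de, outdir / "gsea_de.tsv", index_label="set")
        _done(report, "gsea_de", t0, n_sets=len(gsea_de),
              n_significant=int(len(sig)), n_after_set_cover=len(cover))

    # --- correlations ------------------------------------------------------
    if ephys is not None:
        t0 = _timed(report, "correlation")
        corr_cells = stratum_cells & (
            meta["condition"].to_numpy() == config.correlation_condition
        )
        cell_idx = np.flatnonzero(corr_cells)
        cell_names = [dataset.cell_ids[i] for i in cell_idx]
        detected = detection_filter(dataset.counts[:, cell_idx], thr.detection)
        genes = [g for g, keep in zip(dataset.gene_ids, detected) if keep]
        # rank on raw counts: Spearman is invariant to any per-gene monotone
        # transform, and per-cell scaling would re-break count ties by
        # library size, coupling every gene's ranks to total counts
        sub = dataset.counts[np.flatnonzero(detected)][:, cell_idx]

        props = pd.DataFrame(index=pd.Index(cell_names), dtype=float)
        eph = ephys.reindex(cell_names)
        for f in EPHYS_FEATURES:
            props[f] = eph[f]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = eph["total_exo"] / np.abs(eph["ca_integral"])
        props[EXO_CA_RATIO] = ratio.replace([np.inf, -np.inf], np.nan)
        if scores is not None:
            props["alpha_score"] = scores["alpha_score"].reindex(cell_names)

        tables = {}
        for k, prop_name in enumerate(config.properties):
            if prop_name not in props.columns:
                logger.warning("property %s unavailable; skipped", prop_name)
                continue
            tables[prop_name] = bootstrap_correlations(
                sub, genes, props[prop_name].to_numpy(),
                B=config.B, seed=seeds["bootstrap"] + k,
                p_threshold=thr.p,
            )
            plio.write_table(tables[prop_name],
                             outdir / f"correlation_{prop_name}.tsv",
                             index_label="gene")
        consistent = multi_property_consistency(
            tables, min_properties=thr.min_properties, p_threshold=thr.p
        )
        plio.write_table(consistent, outdir / "consistent_genes.tsv",
                         index_label="gene")
        _done(report, "correlation", t0, n_cells=len(cell_names),
              n_genes_detected=len(genes), n_properties=len(tables),
              n_consistent=len(consistent))

        # GSEA on bootstrap-mean rho for the first available property
        if sets and tables:
            t0 = _timed(report, "gsea_correlation")
            lead = next(iter(tables))
            ranked = tables[lead]["rho_boot_mean"].dropna()
            gsea_corr = gsea_preranked(ranked, sets, n_perm=config.n_perm,
                                       seed=seeds["gsea_corr"])
            plio.write_table(gsea_corr, outdir / f"gsea_correlation_{lead}.tsv",
                             index_label="set")
            _done(report, "gsea_correlation", t0, property=lead,
                  n_sets=len(gsea_corr),
                  n_significant=int((gsea_corr["q"] < thr.fdr).sum()))

        # ORA of consistent genes against the detected universe
        if sets and len(consistent):
            t0 = _timed(report, "ora")
            ora = ora_hypergeometric(list(consistent.index), genes, sets)
            plio.write_table(ora, outdir / "ora_consistent.tsv", index_label="set")
            _done(report, "ora", t0, n_sets=len(ora),
                  n_significant=int((ora["q"] < thr.fdr).sum()))
    else:
        logger.warning("no electrophysiology table: correlation stages skipped")
        report["stages"]["correlation"] = {"skipped": "no ephys table"}

    # --- genetic-risk enrichment -------------------------------------------
    if config.risk_lists:
        t0 = _timed(report, "risk_enrichment")
        tested_genes = list(de_table.index[de_table["tested"]])
        up = list(de_table.index[(de_table["q"] < thr.fdr)
                                 & (de_table["log2fc"] > 0)])
        rows = []
        for name, path in sorted(config.risk_lists.items()):
            risk = [g for g in plio.read_gene_list(path) if g in set(tested_genes)]
            res = risk_enrichment_fisher(up, risk, tested_genes, list_name=name)
            rows.append(res.to_dict())
        risk_df = pd.DataFrame(rows).set_index("list")
        plio.write_table(risk_df, outdir / "risk_enrichment.tsv", index_label="list")
        _done(report, "risk_enrichment", t0, n_lists=len(rows))

    report["outputs"] = sorted(
        p.name for p in Path(config.outdir).iterdir()
        if p.suffix in {".tsv", ".json"} and p.name != "report.json"
    )
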