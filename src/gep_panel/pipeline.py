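"""End-to-end discovery -> validation workflow driven by one config.

Stage order mirrors the discovery procedure: batch adjustment, CUR-leverage
probe selection, pairwise differential expression with FDR + fold-change
filtering, NMF consensus clustering of the panel submatrix, canonical
biplot, and LDA validation on a held-out cohort. Every intermediate product
is written as plain TSV so any stage can be rerun in isolation, and a JSON
manifest records parameters, seeds, per-stage dimensions and output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batch_adjust, canonical_biplot, cur_select, diff_expr, lda_classify, nmf_cluster
from .data_model import ExpressionStudy, read_study, subset_probes, write_panel, write_study
from .synthetic_data import SimulationSpec, simulate_study

logger = logging.getLogger(__name__)

DEFAULT_PAIRS = [("DA", "GBM"), ("AA", "GBM"), ("DA", "AA")]
#: seed offset separating the simulated validation cohort from discovery
VALIDATION_SEED_OFFSET = 10007
VALIDATION_GROUP_SIZES = {"DA": 14, "AA": 24, "GBM": 75}


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Exactly one of ``input_paths`` (dict with matrix/annotation/metadata
    paths, optionally validation_* counterparts) or ``simulation`` (a
    :class:`SimulationSpec`) must be given.
    """

    outdir: str = "pipeline_out"
    input_paths: dict | None = None
    simulation: SimulationSpec | None = None
    simulate_validation: bool = True
    top_k: int = 1000
    alpha: float = 0.05
    fc_min: float = 4.0
    moderated: bool = True
    rank_policy: str = "full"
    nmf_k_range: tuple = (2, 3, 4)
    nmf_restarts: int = 30
    lda_mode: str = "transfer"  # or "refit"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_paths is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_paths or simulation must be supplied"
            )
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be positive")
        if self.lda_mode not in ("transfer", "refit"):
            raise ValueError("lda_mode must be 'transfer' or 'refit'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulation"})
        if sim is not None:
            if "n_per_group" in sim:
                sim["n_per_group"] = dict(sim["n_per_group"])
            if "probes_per_gene" in sim:
                sim["probes_per_gene"] = tuple(sim["probes_per_gene"])
            cfg.simulation = SimulationSpec(**sim)
        if "nmf_k_range" in raw:
            cfg.nmf_k_range = tuple(raw["nmf_k_range"])
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, sep="\t", **kw)


def _load_cohorts(config: PipelineConfig):
    if config.simulation is not None:
        study, truth = simulate_study(config.simulation)
        validation = None
        if config.simulate_validation:
            vspec = SimulationSpec(**{**asdict_spec(config.simulation)})
            vspec.n_per_group = dict(VALIDATION_GROUP_SIZES)
            # same probe layout as discovery, independent samples
            if vspec.probe_layout_seed is None:
                vspec.probe_layout_seed = config.simulation.seed
            vspec.seed = config.simulation.seed + VALIDATION_SEED_OFFSET
            validation, _ = simulate_study(vspec)
        return study, validation, truth
    paths = config.input_paths
    study = read_study(paths["matrix"], paths["annotation"], paths["metadata"])
    validation = None
    if "validation_matrix" in paths:
        validation = read_study(
            paths["validation_matrix"],
            paths.get("validation_annotation", paths["annotation"]),
            paths["validation_metadata"],
        )
    return study, validation, None


def asdict_spec(spec: SimulationSpec) -> dict:
    d = asdict(spec)
    # asdict recurses into DataFrames and BatchParams; keep the originals
    d["de_profile"] = spec.de_profile
    d["batch_spec"] = spec.batch_spec
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "top_k": config.top_k,
            "alpha": config.alpha,
            "fc_min": config.fc_min,
            "moderated": config.moderated,
            "rank_policy": config.rank_policy,
            "nmf_k_range": list(config.nmf_k_range),
            "nmf_restarts": config.nmf_restarts,
            "lda_mode": config.lda_mode,
            "seed": config.seed,
        },
        "stages": [],
        "outputs": {},
    }

    def stage_done(name: str, **info):
        logger.info("stage %s: %s", name, info)
        manifest["stages"].append({"name": name, **info})

    # -- input --------------------------------------------------------------
    try:
        study, validation, truth = _load_cohorts(config)
    except Exception as exc:
        raise StageError("input", "load-failed", str(exc)) from exc
    write_study(
        study, out / "discovery_matrix.tsv", out / "annotation.tsv", out / "metadata.tsv"
    )
    stage_done("input", n_probes=study.n_probes, n_samples=study.n_samples,
               groups={g: int(len(study.group_indices(g))) for g in study.groups})

    # -- batch adjustment ---------------------------------------------------
    if len(study.batches) >= 2:
        try:
            study, model = batch_adjust.combat_adjust(study)
        except Exception as exc:
            raise StageError("adjust", "combat-failed", str(exc)) from exc
        _write_tsv(model.gamma_star_log2(), out / "batch_locations.tsv")
        stage_done("adjust", n_batches=len(study.batches),
                   degenerate_probes=len(model.degenerate_probes))
    else:
        stage_done("adjust", skipped="single batch")
    _write_tsv(study.to_frame(), out / "adjusted_matrix.tsv", index_label="probe_id")

    # -- CUR probe selection ------------------------------------------------
    try:
        lev = cur_select.svd_leverages(study, rank_policy=config.rank_policy)
        k = min(config.top_k, study.n_probes)
        selected = cur_select.top_k(lev, k)
    except Exception as exc:
        raise StageError("select-cur", "leverage-failed", str(exc)) from exc
    _write_tsv(lev.leverages.to_frame(), out / "leverages.tsv")
    study_sel = subset_probes(study, selected)
    stage_done("select-cur", rank_used=lev.rank_used,
               variance_absorbed=lev.variance_absorbed,
               probes_in=study.n_probes, probes_out=len(selected))

    # -- differential expression -------------------------------------------
    pairs = [(a, b) for a, b in DEFAULT_PAIRS
             if a in study.groups and b in study.groups]
    try:
        records = diff_expr.run_comparisons(study_sel, pairs, moderated=config.moderated)
        panel = diff_expr.select_panel(records, alpha=config.alpha, fc_min=config.fc_min)
    except Exception as exc:
        raise StageError("diffexpr", "test-failed", str(exc)) from exc
    _write_tsv(records, out / "records.tsv", index=False)
    summary = diff_expr.comparison_summary(records, alpha=config.alpha)
    _write_tsv(summary["per_comparison"], out / "comparison_summary.tsv", index=False)
    if len(panel) == 0:
        raise StageError("diffexpr", "empty-panel",
                         "no gene passed the FDR and fold-change thresholds")
    write_panel(panel, out / "panel.tsv")
    stage_done("diffexpr", comparisons=len(pairs), records=len(records),
               panel_genes=len(panel))

    # -- panel submatrix: best-FC representative probe per gene -------------
    hits = records[(records["p_adj"] < config.alpha) & (records["fc"] >= config.fc_min)]
    rep = (
        hits.sort_values(["fc", "probe_id"], ascending=[False, True])
        .groupby("gene_symbol", sort=False)["probe_id"].first()
    )
    rep_probes = [rep[g] for g in panel.genes]
    panel_study = subset_probes(study, rep_probes)
    _write_tsv(panel_study.to_frame(), out / "panel_matrix.tsv", index_label="probe_id")

    # -- NMF consensus clustering -------------------------------------------
    try:
        results, recommended = nmf_cluster.consensus_cluster(
            panel_study.matrix,
            K_range=[k for k in config.nmf_k_range if k <= min(panel_study.matrix.shape)],
            n_restarts=config.nmf_restarts,
            seed=config.seed,
        )
    except Exception as exc:
        raise StageError("nmf", "consensus-failed", str(exc)) from exc
    best = results[recommended]
    model = nmf_cluster.nmf_factorize(panel_study.matrix, recommended, seed=config.seed)
    _write_tsv(pd.DataFrame(model.W, index=panel.genes,
                            columns=[f"C{k + 1}" for k in range(model.K)]),
               out / "W.tsv")
    _write_tsv(pd.DataFrame(model.H, index=[f"C{k + 1}" for k in range(model.K)],
                            columns=panel_study.sample_ids),
               out / "H.tsv")
    _write_tsv(pd.DataFrame(best.consensus, index=panel_study.sample_ids,
                            columns=panel_study.sample_ids),
               out / "consensus.tsv")
    _write_tsv(pd.DataFrame({"cluster": best.cluster_labels},
                            index=pd.Index(panel_study.sample_ids, name="sample_id")),
               out / "labels.tsv")
    _write_tsv(pd.DataFrame({"cophenetic": {k: r.cophenetic for k, r in results.items()}}),
               out / "cophenetic.tsv", index_label="K")
    stage_done("nmf", recommended_K=recommended,
               cophenetic={int(k): r.cophenetic for k, r in results.items()})

    # -- canonical biplot ---------------------------------------------------
    try:
        biplot = canonical_biplot.fit_canonical_biplot(panel_study)
    except Exception as exc:
        raise StageError("biplot", "fit-failed", str(exc)) from exc
    _write_tsv(biplot.sample_coordinates, out / "biplot_samples.tsv")
    _write_tsv(biplot.group_coordinates.assign(radius=biplot.group_radii),
               out / "biplot_groups.tsv")
    var_coords = biplot.variable_coordinates.copy()
    var_coords.index = panel.genes
    _write_tsv(var_coords, out / "biplot_variables.tsv", index_label="gene")
    stage_done("biplot", n_axes=len(biplot.eigenvalues),
               eigenvalues=[float(v) for v in biplot.eigenvalues])

    # -- LDA validation -----------------------------------------------------
    if validation is not None:
        val_panel = subset_probes(validation, rep_probes)
        try:
            if config.lda_mode == "transfer":
                lda = lda_classify.fit_lda(panel_study)
            else:
                lda = lda_classify.fit_lda(val_panel)
            report = lda_classify.classify(lda, val_panel)
        except Exception as exc:
            raise StageError("lda", "classify-failed", str(exc)) from exc
        _write_tsv(report.confusion, out / "lda_confusion.tsv", index_label="true")
        stage_done("lda", mode=config.lda_mode,
                   accuracy=report.accuracy,
                   n_test=int(report.confusion.to_numpy().sum()))
    else:
        stage_done("lda", skipped="no validation cohort")

    for p in sorted(out.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
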