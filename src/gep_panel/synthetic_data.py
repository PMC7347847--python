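"""Synthetic multi-cohort expression studies with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes: RMA-style log2 intensities, three unbalanced histological groups
(DA/AA/GBM), multiple probes per gene, a small set of truly differential
genes riding on a flat non-differential background, and optional per-cohort
location/scale batch effects of exactly the form an empirical-Bayes batch
adjustment can represent.

The differential profile defaults to the published 27-gene discriminatory
panel: per-group mean log2 expression for each gene (``table2_profile``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ExpressionStudy

GROUPS = ("DA", "AA", "GBM")

# 27 discriminatory genes: mean log2 expression in DA / AA / GBM.
_PANEL_PROFILE = {
    "GABRG2": (7.72, 7.30, 5.62),
    "CNTN3": (7.75, 7.64, 5.49),
    "GABRB2": (7.90, 7.79, 5.84),
    "SPX": (8.07, 7.77, 5.84),
    "DPP10": (8.09, 7.86, 6.07),
    "FSTL5": (8.27, 7.06, 5.53),
    "SH3GL2": (9.75, 9.16, 7.47),
    "SFRP2": (9.87, 8.50, 7.15),
    "ETNPPL": (10.31, 9.84, 7.19),
    "SHOX2": (4.83, 5.82, 7.23),
    "IBSP": (5.04, 5.22, 7.20),
    "IGF2BP3": (5.25, 6.06, 7.66),
    "LOX": (5.37, 5.65, 7.48),
    "HS3ST3B1": (5.49, 5.98, 7.81),
    "XIST": (5.50, 8.33, 7.64),
    "PTX3": (6.29, 6.26, 8.57),
    "POSTN": (6.46, 6.61, 9.10),
    "TOP2A": (6.49, 7.44, 8.64),
    "VEGFA": (6.94, 7.26, 9.13),
    "COL3A1": (7.00, 7.20, 9.64),
    "NNMT": (7.25, 7.31, 9.65),
    "COL1A2": (7.44, 7.80, 9.97),
    "COL1A1": (7.47, 7.45, 9.80),
    "PDPN": (7.89, 7.98, 9.91),
    "CHI3L1": (8.65, 9.31, 11.86),
    "IGFBP3": (8.73, 9.43, 10.81),
    "ANXA1": (9.09, 9.65, 11.12),
}


def table2_profile() -> pd.DataFrame:
    """Per-group mean log2 expression for the 27 panel genes.

    Returns a ``(27, 3)`` DataFrame indexed by gene symbol with columns
    ``DA``, ``AA``, ``GBM``.
    """
    return pd.DataFrame.from_dict(
        _PANEL_PROFILE, orient="index", columns=list(GROUPS)
    ).astype(float)


@dataclass
class BatchParams:
    """Distribution of one batch's per-probe location/scale effects.

    Each probe row in the batch receives an additive shift
    ``gamma ~ Normal(shift_mean, shift_sd)`` and a noise-scale factor
    ``delta = exp(Normal(log_scale_mean, log_scale_sd))``.
    """

    shift_mean: float = 0.0
    shift_sd: float = 0.0
    log_scale_mean: float = 0.0
    log_scale_sd: float = 0.0


@dataclass
class SimulationSpec:
    """Study-design parameters for one simulated cohort.

    Defaults mirror the discovery-cohort composition (19 DA / 28 AA /
    108 GBM) with the 27-gene differential profile on a flat background at
    log2 intensity 7, homoscedastic Gaussian noise of sd 0.5 log2 units, and
    a single batch (no batch effects).
    """

    n_per_group: dict = field(
        default_factory=lambda: {"DA": 19, "AA": 28, "GBM": 108}
    )
    n_background_genes: int = 973
    probes_per_gene: tuple = (1, 3)  # inclusive uniform range
    de_profile: pd.DataFrame | None = None  # default: table2_profile()
    background_mean: float = 7.0
    noise_sd: float = 0.5
    heteroscedastic: bool = False
    var_df: float = 4.0  # scaled-inverse-chi-square df for heteroscedastic sd
    n_batches: int = 1
    batch_spec: dict | None = None  # batch name -> BatchParams
    seed: int = 0
    #: seed for platform-level structure (probe counts per gene, per-probe
    #: noise sd); defaults to ``seed``. Set it equal across cohorts to share
    #: one probe layout between discovery and validation.
    probe_layout_seed: int | None = None

    def validate(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group must name at least one group")
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
            if n < 1:
                raise ValueError(f"group {g} needs a positive sample count")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene must be a 1-based range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.var_df <= 2:
            raise ValueError("var_df must exceed 2 for a finite variance mean")

    def profile(self) -> pd.DataFrame:
        prof = self.de_profile if self.de_profile is not None else table2_profile()
        missing = [g for g in self.n_per_group if g not in prof.columns]
        if missing:
            raise ValueError(f"de_profile lacks group columns {missing}")
        return prof


@dataclass
class GroundTruth:
    """What was planted: differential genes, batch effects, true labels."""

    de_genes: pd.DataFrame  # gene x group means actually used
    gamma: pd.DataFrame | None  # probe x batch additive shifts
    delta: pd.DataFrame | None  # probe x batch noise-scale factors
    group: list[str]
    batch: list[str]
    probe_sd: np.ndarray | None = None  # per-probe noise sd actually used


def _probe_ids(genes: list[str], counts: np.ndarray) -> tuple[list, list]:
    probes, symbols = [], []
    for g, c in zip(genes, counts):
        for k in range(int(c)):
            probes.append(f"{g}.p{k + 1}")
            symbols.append(g)
    return probes, symbols


def simulate_study(spec: SimulationSpec) -> tuple[ExpressionStudy, GroundTruth]:
    """Draw one cohort under ``spec``; deterministic given ``spec.seed``.

    Each probe's value is its gene's group mean (background genes share one
    mean across groups) plus batch shift plus scale-modulated Gaussian noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    layout_seed = (
        spec.probe_layout_seed if spec.probe_layout_seed is not None else spec.seed
    )
    layout_rng = np.random.default_rng(layout_seed)
    prof = spec.profile()

    de_genes = list(prof.index)
    bg_genes = [f"BG{i + 1:05d}" for i in range(spec.n_background_genes)]
    genes = de_genes + bg_genes
    lo, hi = spec.probes_per_gene
    counts = layout_rng.integers(lo, hi + 1, size=len(genes))
    probe_ids, gene_symbols = _probe_ids(genes, counts)
    j = len(probe_ids)

    group_labels: list[str] = []
    for g in GROUPS:
        if g in spec.n_per_group:
            group_labels += [g] * spec.n_per_group[g]
    i = len(group_labels)
    # round-robin batch assignment within each group: groups span batches,
    # avoiding complete group/batch confounding
    batch_names = [f"B{b + 1}" for b in range(spec.n_batches)]
    batch_labels = [batch_names[k % spec.n_batches] for k in range(i)]
    sample_ids = [f"S{k + 1:03d}" for k in range(i)]

    # per-probe per-sample means
    gene_of_probe = np.array(
        [de_genes.index(g) if g in prof.index else -1 for g in gene_symbols]
    )
    mean_grid = np.full((j, i), float(spec.background_mean))
    garr = np.asarray(group_labels)
    for gi, gname in enumerate(de_genes):
        rows = np.flatnonzero(gene_of_probe == gi)
        for grp in spec.n_per_group:
            cols = np.flatnonzero(garr == grp)
            mean_grid[np.ix_(rows, cols)] = prof.loc[gname, grp]

    if spec.heteroscedastic:
        # sd^2 ~ noise_sd^2 * var_df / chisq(var_df): scaled inverse chi-square
        chi = layout_rng.chisquare(spec.var_df, size=j)
        probe_sd = spec.noise_sd * np.sqrt(spec.var_df / np.maximum(chi, 1e-12))
    else:
        probe_sd = np.full(j, float(spec.noise_sd))
    noise = rng.standard_normal((j, i)) * probe_sd[:, None]

    gamma = delta = None
    if spec.n_batches > 1 or spec.batch_spec:
        params = spec.batch_spec or {}
        barr = np.asarray(batch_labels)
        gamma = pd.DataFrame(0.0, index=probe_ids, columns=batch_names)
        delta = pd.DataFrame(1.0, index=probe_ids, columns=batch_names)
        for b in batch_names:
            bp = params.get(b, BatchParams())
            gamma[b] = rng.normal(bp.shift_mean, bp.shift_sd, size=j)
            delta[b] = np.exp(rng.normal(bp.log_scale_mean, bp.log_scale_sd, size=j))
        shift = np.zeros((j, i))
        scale = np.ones((j, i))
        for b in batch_names:
            cols = np.flatnonzero(barr == b)
            shift[:, cols] = gamma[b].to_numpy()[:, None]
            scale[:, cols] = delta[b].to_numpy()[:, None]
        matrix = mean_grid + shift + scale * noise
    else:
        matrix = mean_grid + noise

    study = ExpressionStudy(
        matrix=matrix,
        probe_ids=probe_ids,
        gene_symbols=gene_symbols,
        sample_ids=sample_ids,
        group=group_labels,
        batch=batch_labels,
    )
    truth = GroundTruth(
        de_genes=prof.copy(),
        gamma=gamma,
        delta=delta,
        group=group_labels,
        batch=batch_labels,
        probe_sd=probe_sd,
    )
    return study, truth


def inject_batch_effects(
    study: ExpressionStudy, batch_spec: dict, seed: int = 0
) -> tuple[ExpressionStudy, GroundTruth]:
    """Apply per-probe, per-batch location/scale effects to an existing study.

    For probe g in batch b: ``y' = m_g + gamma_gb + delta_gb * (y - m_g)``
    where ``m_g`` is the probe's grand mean — an additive shift plus a
    multiplicative widening of the residual, i.e. exactly the family of
    distortions the empirical-Bayes batch adjustment models.
    """
    for b in study.batches:
        if b not in batch_spec:
            raise KeyError(f"batch {b!r} absent from batch_spec")
    rng = np.random.default_rng(seed)
    j = study.n_probes
    m = study.matrix.mean(axis=1, keepdims=True)
    out = study.matrix.copy()
    gamma = pd.DataFrame(0.0, index=study.probe_ids, columns=study.batches)
    delta = pd.DataFrame(1.0, index=study.probe_ids, columns=study.batches)
    for b in study.batches:
        bp = batch_spec[b]
        g = rng.normal(bp.shift_mean, bp.shift_sd, size=j)
        d = np.exp(rng.normal(bp.log_scale_mean, bp.log_scale_sd, size=j))
        gamma[b], delta[b] = g, d
        cols = study.batch_indices(b)
        out[:, cols] = m + g[:, None] + d[:, None] * (study.matrix[:, cols] - m)
    truth = GroundTruth(
        de_genes=pd.DataFrame(),
        gamma=gamma,
        delta=delta,
        group=list(study.group),
        batch=list(study.batch),
    )
    return study.with_matrix(out), truth
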