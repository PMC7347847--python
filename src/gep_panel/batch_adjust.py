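"""Empirical-Bayes location/scale batch-effect adjustment and PCA scores.

Implements the parametric ComBat model for multi-cohort expression data:
each probe row is standardized against its grand mean and pooled variance,
per-batch location (gamma) and scale (delta^2) estimates are shrunk toward
batch-level priors fitted across probes by the method of moments (normal
prior on gamma, inverse-gamma prior on delta^2), and the data are
back-transformed with the shrunk estimates. Shrinkage borrows strength
across probes, stabilizing small cohorts.

By default the biological group labels are NOT protected as covariates,
since group and cohort are partially confounded across independent series;
``protect_groups=True`` includes them in the standardization model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionStudy

logger = logging.getLogger(__name__)

#: pooled variances at or below this are treated as zero (degenerate probes)
_VAR_EPS = 1e-12


@dataclass
class BatchAdjustModel:
    """Fitted parameters of the empirical-Bayes batch adjustment.

    All per-batch grids are probe x batch DataFrames; ``gamma_star`` and
    ``delta2_star`` are the EB-shrunk counterparts of the raw ``gamma_hat``
    and ``delta2_hat``. ``gamma_star`` is expressed on the standardized scale;
    multiply by ``sqrt(var_pooled)`` for log2 units.
    """

    grand_mean: pd.Series  # per-probe alpha-hat
    var_pooled: pd.Series  # per-probe pooled variance
    gamma_hat: pd.DataFrame
    delta2_hat: pd.DataFrame
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series  # per-batch normal-prior mean
    tau2: pd.Series  # per-batch normal-prior variance
    a_prior: pd.Series  # per-batch inverse-gamma shape
    b_prior: pd.Series  # per-batch inverse-gamma rate
    n_iterations: pd.Series
    degenerate_probes: list[str]

    def gamma_star_log2(self) -> pd.DataFrame:
        """Shrunk batch locations back on the log2 scale."""
        return self.gamma_star.mul(np.sqrt(self.var_pooled), axis=0)


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2 * s2 + m**2) / s2

def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m**3) / s2


def combat_adjust(
    study: ExpressionStudy,
    *,
    protect_groups: bool = False,
    max_iter: int = 100,
    conv: float = 1e-6,
) -> tuple[ExpressionStudy, BatchAdjustModel]:
    """Remove batch effects from ``study``; returns adjusted study + model.

    Requires at least two batches, each with at least two samples. Probes
    with zero pooled variance cannot be standardized and are set to their
    grand mean with a warning.
    """
    batches = study.batches
    if len(batches) < 2:
        raise ValueError("batch adjustment needs at least two batches")
    batch_idx = {b: study.batch_indices(b) for b in batches}
    for b, idx in batch_idx.items():
        if len(idx) < 2:
            raise ValueError(f"batch {b!r} has fewer than two samples")

    y = study.matrix  # J x I
    j, n = y.shape
    n_b = np.array([len(batch_idx[b]) for b in batches], dtype=float)

    # design: batch one-hot, optionally group dummies (drop first)
    design_cols = [np.isin(np.arange(n), batch_idx[b]).astype(float) for b in batches]
    n_batch_cols = len(design_cols)
    if protect_groups:
        groups = study.groups
        garr = np.asarray(study.group)
        for g in groups[1:]:
            design_cols.append((garr == g).astype(float))
    design = np.column_stack(design_cols)  # I x P

    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)  # P x J
    grand = (n_b / n) @ beta[:n_batch_cols]  # J
    stand_mean = np.tile(grand[:, None], (1, n))
    if design.shape[1] > n_batch_cols:
        stand_mean = stand_mean + (design[:, n_batch_cols:] @ beta[n_batch_cols:]).T
    resid = y - (design @ beta).T
    var_pooled = (resid**2).mean(axis=1)

    degenerate = var_pooled <= _VAR_EPS
    if degenerate.any():
        logger.warning(
            "%d zero-variance probes adjusted to their grand mean",
            int(degenerate.sum()),
        )
    sd = np.sqrt(np.where(degenerate, 1.0, var_pooled))
    z = (y - stand_mean) / sd[:, None]

    probe_index = pd.Index(study.probe_ids, name="probe_id")
    gamma_hat = pd.DataFrame(0.0, index=probe_index, columns=batches)
    delta2_hat = pd.DataFrame(1.0, index=probe_index, columns=batches)
    gamma_star = pd.DataFrame(0.0, index=probe_index, columns=batches)
    delta2_star = pd.DataFrame(1.0, index=probe_index, columns=batches)
    gamma_bar = pd.Series(0.0, index=batches)
    tau2 = pd.Series(0.0, index=batches)
    a_prior = pd.Series(np.nan, index=batches)
    b_prior = pd.Series(np.nan, index=batches)
    n_iterations = pd.Series(0, index=batches)

    ok = ~degenerate
    adjusted_z = z.copy()
    for bi, b in enumerate(batches if ok.any() else []):
        idx = batch_idx[b]
        zb = z[np.ix_(ok, idx)]
        g_hat = zb.mean(axis=1)
        d2_hat = zb.var(axis=1, ddof=1)
        gamma_hat.loc[ok, b] = g_hat
        delta2_hat.loc[ok, b] = d2_hat

        gbar = g_hat.mean()
        t2 = g_hat.var(ddof=1) if g_hat.size > 1 else 0.0
        gamma_bar[b], tau2[b] = gbar, t2
        have_var_prior = d2_hat.size > 1 and d2_hat.var(ddof=1) > 0
        if have_var_prior:
            a = _aprior(d2_hat)
            bp = _bprior(d2_hat)
            a_prior[b], b_prior[b] = a, bp

        nb = len(idx)
        g_star = g_hat.copy()
        d2_star = np.maximum(d2_hat, _VAR_EPS)
        it = 0
        for it in range(1, max_iter + 1):
            g_new = (
                (nb * t2 * g_hat + d2_star * gbar) / (nb * t2 + d2_star)
                if t2 > 0
                else np.full_like(g_hat, gbar)
            )
            if have_var_prior:
                ssq = ((zb - g_new[:, None]) ** 2).sum(axis=1)
                d2_new = (bp + 0.5 * ssq) / (nb / 2 + a - 1)
            else:
                d2_new = d2_star
            if np.max(np.abs(g_new - g_star)) < conv:
                g_star, d2_star = g_new, d2_new
                break
            g_star, d2_star = g_new, d2_new
        n_iterations[b] = it
        gamma_star.loc[ok, b] = g_star
        delta2_star.loc[ok, b] = d2_star
        adjusted_z[np.ix_(ok, idx)] = (zb - g_star[:, None]) / np.sqrt(
            np.maximum(d2_star, _VAR_EPS)
        )[:, None]

    out = adjusted_z * sd[:, None] + stand_mean
    out[degenerate] = stand_mean[degenerate]

    model = BatchAdjustModel(
        grand_mean=pd.Series(grand, index=probe_index),
        var_pooled=pd.Series(var_pooled, index=probe_index),
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        a_prior=a_prior,
        b_prior=b_prior,
        n_iterations=n_iterations,
        degenerate_probes=[p for p, d in zip(study.probe_ids, degenerate) if d],
    )
    return study.with_matrix(out), model


def pca_scores(study: ExpressionStudy, n_components: int) -> pd.DataFrame:
    """Sample x component PCA scores of the probe-centered matrix.

    Each probe is centered across samples before the SVD, so scores have zero
    column means and component variances are non-increasing. Used to
    visualize cohort stabilization before/after batch adjustment.
    """
    max_comp = min(study.n_samples - 1, study.n_probes)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds feasible {max_comp}"
        )
    xc = study.matrix - study.matrix.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(xc.T, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    return pd.DataFrame(
        scores,
        index=pd.Index(study.sample_ids, name="sample_id"),
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
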