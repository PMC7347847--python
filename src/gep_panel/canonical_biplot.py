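"""Canonical (MANOVA) biplot: samples, group means and gene vectors in the
space of maximal between-group discrimination.

The canonical axes solve the generalized eigenproblem

    B u = lambda S_W u

with B the between-group scatter (sum of n_g outer products of group-mean
deviations) and S_W the pooled within-group covariance (divisor n - G).
Axes are S_W-orthonormal, so canonical sample scores have identity
within-group covariance and the between-group scatter of scores along axis
a equals lambda_a. With G groups there are at most G - 1 nontrivial axes
(two for the three glioma subtypes). Gene markers default to structure
correlations (gene <-> canonical-variate correlations), which are stable
when the gene count approaches the sample count; raw eigenvector weights
are available instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .data_model import ConsistencyError, ExpressionStudy

logger = logging.getLogger(__name__)


@dataclass
class CanonicalBiplotModel:
    canonical_axes: np.ndarray  # J x A, S_W-orthonormal columns
    eigenvalues: np.ndarray  # length A, non-increasing, >= 0
    group_coordinates: pd.DataFrame  # G x A
    sample_coordinates: pd.DataFrame  # I x A
    variable_coordinates: pd.DataFrame  # J x A
    B: np.ndarray  # between-group scatter, J x J
    W_scatter: np.ndarray  # pooled within-group scatter, J x J
    grand_mean: np.ndarray
    feature_ids: list
    classes: list
    group_radii: pd.Series  # 95% confidence-circle radius per group
    ridge: float = 0.0


def _scatter_matrices(m: np.ndarray, groups: np.ndarray):
    """Between-group scatter, pooled within covariance, means, counts."""
    classes = list(dict.fromkeys(groups))
    n, j = m.shape
    grand = m.mean(axis=0)
    b = np.zeros((j, j))
    w = np.zeros((j, j))
    means, counts = [], []
    for g in classes:
        sub = m[groups == g]
        mu = sub.mean(axis=0)
        d = mu - grand
        b += len(sub) * np.outer(d, d)
        w += (sub - mu).T @ (sub - mu)
        means.append(mu)
        counts.append(len(sub))
    sw = w / (n - len(classes))
    return classes, np.array(means), np.array(counts), grand, b, sw


def fit_canonical_biplot(
    study: ExpressionStudy,
    *,
    marker_scaling: str = "correlation",
    ridge: float | None = None,
) -> CanonicalBiplotModel:
    """Fit the canonical biplot of a (panel-restricted) study.

    ``marker_scaling`` selects gene-vector coordinates: ``"correlation"``
    (structure correlations) or ``"weight"`` (raw eigenvector loadings).
    A ridge term is added to the within covariance only when it is singular.
    """
    groups = np.asarray(study.group)
    classes_all = study.groups
    if len(classes_all) < 2:
        raise ValueError("canonical biplot needs at least two groups")
    for g in classes_all:
        if len(study.group_indices(g)) < 2:
            raise ValueError(f"group {g!r} needs at least two samples")
    m = study.matrix.T.astype(float)  # samples x features
    classes, means, counts, grand, b, sw = _scatter_matrices(m, groups)

    j = sw.shape[0]
    used_ridge = 0.0
    if ridge is None:
        try:
            linalg.cholesky(sw)
        except linalg.LinAlgError:
            used_ridge = 1e-8 * np.trace(sw) / j
            if used_ridge <= 0:
                used_ridge = 1e-8
            logger.warning("singular within-scatter; adding ridge %.3g", used_ridge)
    else:
        used_ridge = ridge
    sw_r = sw + used_ridge * np.eye(j)

    eigvals, eigvecs = linalg.eigh(b, sw_r)  # ascending, S_W-orthonormal
    order = np.argsort(eigvals)[::-1]
    n_axes = min(len(classes) - 1, j)
    eigvals = np.clip(eigvals[order][:n_axes], 0.0, None)
    axes = eigvecs[:, order][:, :n_axes]

    axis_names = [f"Axis{a + 1}" for a in range(n_axes)]
    centered = m - grand
    sample_scores = centered @ axes
    group_scores = (means - grand) @ axes

    if marker_scaling == "correlation":
        sd_x = m.std(axis=0, ddof=1)
        sd_s = sample_scores.std(axis=0, ddof=1)
        cov = centered.T @ (sample_scores - sample_scores.mean(axis=0)) / (len(m) - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_coords = cov / np.outer(sd_x, sd_s)
        var_coords = np.nan_to_num(var_coords)
    elif marker_scaling == "weight":
        var_coords = axes
    else:
        raise ValueError(f"unknown marker scaling {marker_scaling!r}")

    # 95% circles: canonical scores have unit within-group covariance, so the
    # mean of group g lies within sqrt(chi2_{2,0.95}/n_g) of its estimate
    radii = pd.Series(
        np.sqrt(stats.chi2.ppf(0.95, df=min(2, n_axes)) / counts), index=classes
    )
    return CanonicalBiplotModel(
        canonical_axes=axes,
        eigenvalues=eigvals,
        group_coordinates=pd.DataFrame(group_scores, index=classes, columns=axis_names),
        sample_coordinates=pd.DataFrame(
            sample_scores, index=study.sample_ids, columns=axis_names
        ),
        variable_coordinates=pd.DataFrame(
            var_coords, index=study.probe_ids, columns=axis_names
        ),
        B=b,
        W_scatter=sw,
        grand_mean=grand,
        feature_ids=list(study.probe_ids),
        classes=classes,
        group_radii=radii,
        ridge=used_ridge,
    )


def project_samples(model: CanonicalBiplotModel, study: ExpressionStudy) -> pd.DataFrame:
    """Project new samples onto fitted canonical axes (same features, order)."""
    if list(study.probe_ids) != model.feature_ids:
        raise ConsistencyError("feature set/order differs from the fitted model")
    scores = (study.matrix.T - model.grand_mean) @ model.canonical_axes
    return pd.DataFrame(
        scores,
        index=study.sample_ids,
        columns=model.sample_coordinates.columns,
    )
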