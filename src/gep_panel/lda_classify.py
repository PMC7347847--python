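"""Linear discriminant classification of tumors from panel-gene expression.

Gaussian LDA with a pooled within-class covariance: class g scores

    delta_g(x) = x' S^-1 mu_g - mu_g' S^-1 mu_g / 2 + log pi_g

and samples are assigned to the argmax. Priors default to empirical class
frequencies. When the pooled covariance is ill-conditioned (panel size close
to the cohort size), a small ridge proportional to the mean diagonal is
added. Used to quantify how well the discovered panel separates the
histological subtypes on a held-out cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .data_model import ConsistencyError, ExpressionStudy

logger = logging.getLogger(__name__)

_RIDGE_FACTOR = 1e-6
_COND_LIMIT = 1e10


@dataclass
class LDAModel:
    classes: list
    class_means: np.ndarray  # G x J
    pooled_covariance: np.ndarray  # J x J
    priors: np.ndarray  # G, sums to 1
    feature_ids: list
    precision: np.ndarray = None  # cached inverse (possibly ridged)
    ridge: float = 0.0


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame  # true x predicted counts
    accuracy: float
    misassigned: pd.DataFrame  # sample_id, true, predicted
    posteriors: pd.DataFrame  # sample x class


def fit_lda(
    study: ExpressionStudy, *, uniform_priors: bool = False
) -> LDAModel:
    """Fit pooled-covariance LDA on a (panel-restricted) training study."""
    classes = study.groups
    if len(classes) < 2:
        raise ValueError("LDA needs at least two classes")
    m = study.matrix.T.astype(float)
    n, j = m.shape
    means, resid, counts = [], [], []
    for g in classes:
        idx = study.group_indices(g)
        if len(idx) < 2:
            raise ValueError(f"class {g!r} has fewer than two samples")
        sub = m[idx]
        mu = sub.mean(axis=0)
        means.append(mu)
        resid.append(sub - mu)
        counts.append(len(idx))
    cov = np.vstack(resid).T @ np.vstack(resid) / (n - len(classes))

    ridge = 0.0
    diag_mean = float(np.trace(cov) / j)
    if diag_mean <= 0 or np.linalg.cond(cov) > _COND_LIMIT:
        ridge = _RIDGE_FACTOR * diag_mean if diag_mean > 0 else 1e-8
        logger.warning("ill-conditioned pooled covariance; ridge %.3g", ridge)
    precision = linalg.inv(cov + ridge * np.eye(j))

    priors = (
        np.full(len(classes), 1 / len(classes))
        if uniform_priors
        else np.array(counts, dtype=float) / n
    )
    return LDAModel(
        classes=classes,
        class_means=np.array(means),
        pooled_covariance=cov,
        priors=priors,
        feature_ids=list(study.probe_ids),
        precision=precision,
        ridge=ridge,
    )


def discriminant_scores(model: LDAModel, x: np.ndarray) -> np.ndarray:
    """Linear discriminant scores, one column per class."""
    a = model.precision @ model.class_means.T  # J x G
    c = -0.5 * np.einsum("gj,jg->g", model.class_means, a) + np.log(model.priors)
    return x @ a + c


def classify(model: LDAModel, study: ExpressionStudy) -> ClassificationReport:
    """Classify a test study; features must match the training order."""
    if list(study.probe_ids) != model.feature_ids:
        raise ConsistencyError("feature set/order differs from the trained model")
    scores = discriminant_scores(model, study.matrix.T.astype(float))
    # softmax over classes for posteriors
    z = scores - scores.max(axis=1, keepdims=True)
    post = np.exp(z)
    post /= post.sum(axis=1, keepdims=True)
    pred = [model.classes[k] for k in np.argmax(scores, axis=1)]

    truth = list(study.group)
    labels = list(dict.fromkeys(model.classes + [g for g in study.groups if g not in model.classes]))
    confusion = pd.DataFrame(0, index=labels, columns=model.classes, dtype=int)
    for t, p in zip(truth, pred):
        confusion.loc[t, p] += 1
    correct = sum(t == p for t, p in zip(truth, pred))
    mis = pd.DataFrame(
        [
            {"sample_id": s, "true": t, "predicted": p}
            for s, t, p in zip(study.sample_ids, truth, pred)
            if t != p
        ],
        columns=["sample_id", "true", "predicted"],
    )
    return ClassificationReport(
        confusion=confusion,
        accuracy=correct / len(truth),
        misassigned=mis,
        posteriors=pd.DataFrame(post, index=study.sample_ids, columns=model.classes),
    )
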