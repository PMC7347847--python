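"""CUR-style leverage scores for probe selection.

The leverage of probe j is the mean of its squared loadings on the first R
right singular vectors of the (column-centered) sample x probe matrix:

    l_j = (1/R) * sum_{r=1..R} v_{jr}^2

With orthonormal singular vectors the leverages sum to one, so l_j is the
share of the retained variability contributed by probe j — the CUR notion of
a variable's influence. R defaults to the numerical rank ("all variability
absorbed"); a cumulative-variance fraction can be requested instead.
Probes are ranked by descending leverage; the top k are the most variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ExpressionStudy

#: cumulative variance fraction defining the "all variability" rank policy
_FULL_RANK_FRACTION = 1.0 - 1e-8


@dataclass
class LeverageResult:
    """Per-probe leverages, the rank used, and the descending-leverage order."""

    leverages: pd.Series  # probe_id -> l_j, in study order
    rank_used: int
    variance_absorbed: float
    selected_probes: list[str]  # all probes, descending leverage


def svd_leverages(
    study: ExpressionStudy,
    rank_policy: str | int = "full",
    *,
    center: bool = True,
) -> LeverageResult:
    """Compute CUR leverages for every probe of ``study``.

    ``rank_policy`` is ``"full"`` (numerical rank), ``"fraction:<f>"`` /
    a float in (0, 1] (smallest R whose cumulative variance fraction reaches
    f), or an explicit integer R. Probes occupy the right-singular-vector
    dimension; the matrix is centered per probe so leverage reflects
    variability rather than mean intensity (``center=False`` gives the
    uncentered reading).
    """
    if study.n_samples < 2:
        raise ValueError("need at least two samples")
    m = study.matrix.T.astype(float)  # samples x probes
    if center:
        m = m - m.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(m, full_matrices=False)
    total = float((s**2).sum())
    if total <= 0:
        raise ValueError("degenerate matrix: no variability to decompose")

    cumfrac = np.cumsum(s**2) / total
    if isinstance(rank_policy, str) and rank_policy == "full":
        r = int(np.searchsorted(cumfrac, _FULL_RANK_FRACTION) + 1)
    else:
        if isinstance(rank_policy, str):
            if rank_policy.startswith("fraction:"):
                frac = float(rank_policy.split(":", 1)[1])
            else:
                raise ValueError(f"unknown rank policy {rank_policy!r}")
        elif isinstance(rank_policy, float):
            frac = rank_policy
        else:
            r = int(rank_policy)
            if not 1 <= r <= len(s):
                raise ValueError(f"rank {r} infeasible for {len(s)} components")
            frac = None
        if frac is not None:
            if not 0 < frac <= 1:
                raise ValueError("variance fraction must lie in (0, 1]")
            r = int(np.searchsorted(cumfrac, frac - 1e-12) + 1)
    r = min(r, len(s))

    lev = (vt[:r] ** 2).sum(axis=0) / r
    leverages = pd.Series(
        lev, index=pd.Index(study.probe_ids, name="probe_id"), name="leverage"
    )
    # descending leverage; ties broken lexicographically by probe id
    order = sorted(study.probe_ids, key=lambda p: (-leverages[p], p))
    return LeverageResult(
        leverages=leverages,
        rank_used=r,
        variance_absorbed=float(cumfrac[r - 1]),
        selected_probes=order,
    )


def top_k(result: LeverageResult, k: int) -> list[str]:
    """The ``k`` highest-leverage probe ids (descending; deterministic ties)."""
    j = len(result.selected_probes)
    if not 1 <= k <= j:
        raise ValueError(f"k={k} outside [1, {j}]")
    return result.selected_probes[:k]
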