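"""Pairwise differential expression with FDR and fold-change filtering.

Each pair of groups is compared per probe with a two-sample pooled-variance
t-test. By default the test is moderated: per-probe variances are shrunk
toward a common prior fitted across probes by the method of moments on
log-variances (an empirical-Bayes hierarchical model with a scaled-inverse-
chi-square prior), giving the posterior variance

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and t statistics on d0 + d degrees of freedom — the standard moderated t of
microarray analysis. P-values are Benjamini-Hochberg adjusted within each
comparison, and probes passing both the FDR threshold and a linear-scale
fold-change cut (FC = 2^|difference of log2 means|) are collapsed to the
discriminatory gene panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .data_model import ExpressionStudy, GenePanel

RECORD_COLUMNS = [
    "probe_id",
    "gene_symbol",
    "comparison",
    "mean_a",
    "mean_b",
    "t_stat",
    "p_raw",
    "p_adj",
    "fc",
    "direction",
]

_MAX_D0 = 1e8  # treat larger fitted prior df as infinite


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-fit (d0, s0^2) of the scaled-inverse-chi-square variance prior.

    Uses the distribution of log sample variances: for s^2 on ``df`` degrees
    of freedom around gene variances drawn from the prior,
    ``var(log s^2) = trigamma(df/2) + trigamma(d0/2)``. Returns
    ``d0 = inf`` when the observed spread is no wider than pure chi-square
    noise (fully shared variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(s2.mean()) if s2.size else 1.0
    e = np.log(s2)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        d0 = np.inf
        log_s02 = e.mean() - special.polygamma(0, df / 2) + np.log(df / 2)
    else:
        d0 = 2 * trigamma_inverse(evar)
        log_s02 = (
            e.mean()
            - special.polygamma(0, df / 2)
            + np.log(df / 2)
            + special.polygamma(0, d0 / 2)
            - np.log(d0 / 2)
        )
    return float(d0), float(np.exp(log_s02))


def pairwise_test(
    study: ExpressionStudy,
    group_a: str,
    group_b: str,
    *,
    moderated: bool = True,
    d0_override: float | None = None,
    s02_override: float | None = None,
) -> pd.DataFrame:
    """Two-sample (moderated) t-tests of ``group_a`` vs ``group_b`` per probe.

    Returns one record per probe with means, statistic, raw and BH-adjusted
    p-values, linear fold-change and direction. Probes with zero pooled
    variance get p = 0 when the means differ and p = 1 otherwise.
    """
    ia = study.group_indices(group_a)
    ib = study.group_indices(group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError(
            f"groups {group_a!r}/{group_b!r} need >= 2 samples each "
            f"(got {len(ia)}/{len(ib)})"
        )
    xa, xb = study.matrix[:, ia], study.matrix[:, ib]
    na, nb = len(ia), len(ib)
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    df = na + nb - 2
    ss = ((xa - ma[:, None]) ** 2).sum(axis=1) + ((xb - mb[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    zero_var = s2 <= 0

    if moderated:
        if d0_override is None:
            d0, s02 = fit_variance_prior(s2, df)
        else:
            d0 = float(d0_override)
            s02 = float(s02_override) if s02_override is not None else float(
                np.mean(s2[~zero_var])
            )
        if np.isfinite(d0) and d0 > 0:
            s2_used = (d0 * s02 + df * s2) / (d0 + df)
            df_used = min(d0 + df, _MAX_D0)
        elif d0 == 0:
            s2_used, df_used = s2, df
        else:  # infinite prior df: fully shrunk
            s2_used = np.full_like(s2, s02)
            df_used = _MAX_D0
    else:
        s2_used, df_used = s2, df

    delta = ma - mb
    denom = np.sqrt(s2_used * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, delta / denom, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df_used)
    # degenerate probes: no within-group variability anywhere
    degenerate = (denom <= 0) & zero_var
    p = np.where(degenerate, np.where(delta != 0, 0.0, 1.0), p)
    t_deg = np.where(delta > 0, np.inf, np.where(delta < 0, -np.inf, 0.0))
    t = np.where(degenerate, t_deg, t)

    comparison = f"{group_a} vs {group_b}"
    records = pd.DataFrame(
        {
            "probe_id": study.probe_ids,
            "gene_symbol": study.gene_symbols,
            "comparison": comparison,
            "mean_a": ma,
            "mean_b": mb,
            "t_stat": t,
            "p_raw": p,
            "p_adj": bh_adjust(p),
            "fc": 2.0 ** np.abs(delta),
            "direction": np.where(delta >= 0, f"up in {group_a}", f"up in {group_b}"),
        }
    )
    return records[RECORD_COLUMNS]


def run_comparisons(
    study: ExpressionStudy, pairs: list[tuple[str, str]], *, moderated: bool = True
) -> pd.DataFrame:
    """Concatenate :func:`pairwise_test` records over several group pairs."""
    frames = [
        pairwise_test(study, a, b, moderated=moderated) for a, b in pairs
    ]
    return pd.concat(frames, ignore_index=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def select_panel(
    records: pd.DataFrame, alpha: float = 0.05, fc_min: float = 4.0
) -> GenePanel:
    """Collapse significant, high-fold-change records into a gene panel.

    Keeps records with ``p_adj < alpha`` and ``fc >= fc_min`` (union over
    comparisons), groups surviving probes by gene, and records each gene's
    direction from its maximum-fold-change probe. Genes are ordered by
    descending best fold-change.
    """
    if records.empty:
        raise ValueError("no records to select from")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    hits = records[(records["p_adj"] < alpha) & (records["fc"] >= fc_min)]
    if hits.empty:
        return GenePanel(genes=[], probes={}, direction={})
    best = (
        hits.sort_values(["fc", "probe_id"], ascending=[False, True])
        .groupby("gene_symbol", sort=False)
        .first()
    )
    genes = list(best.sort_values("fc", ascending=False).index)
    probes = {
        g: sorted(hits.loc[hits["gene_symbol"] == g, "probe_id"].unique())
        for g in genes
    }
    direction = {g: best.loc[g, "direction"] for g in genes}
    return GenePanel(genes=genes, probes=probes, direction=direction)


def comparison_summary(records: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Per-comparison counts of significant probes by direction.

    Returns ``{"per_comparison": DataFrame, "intersections": dict}`` where
    intersections counts significant probes shared between comparison pairs.
    """
    sig = records[records["p_adj"] < alpha]
    rows = []
    sig_sets: dict[str, set] = {}
    for comp in records["comparison"].unique():
        sub = sig[sig["comparison"] == comp]
        a, b = comp.split(" vs ")
        rows.append(
            {
                "comparison": comp,
                "n_significant": len(sub),
                f"up_in_first": int((sub["direction"] == f"up in {a}").sum()),
                f"up_in_second": int((sub["direction"] == f"up in {b}").sum()),
            }
        )
        sig_sets[comp] = set(sub["probe_id"])
    inter = {}
    comps = sorted(sig_sets)  # key order independent of record order
    for i in range(len(comps)):
        for k in range(i + 1, len(comps)):
            inter[f"{comps[i]} & {comps[k]}"] = len(
                sig_sets[comps[i]] & sig_sets[comps[k]]
            )
    return {"per_comparison": pd.DataFrame(rows), "intersections": inter}
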