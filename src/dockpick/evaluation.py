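"""Evaluation metrics, the protocol-selection policy and significance tests.

Two complementary views of predictive quality are reported, both as RMSE
and Pearson's R aggregated as mean (±1 std) over cross-validation folds:

- protocol-centric: metrics per docking protocol, plus an Average row;
- ligand-centric: all (complex, protocol) pairs of a fold's validation
  set pooled into one vector pair.

The selection policy picks, per complex, the protocol with the minimum
predicted RMSDmin/RMSDave and the maximum predicted nRMSD. Whether the
selected protocols beat each fixed protocol is assessed with a one-sided
two-sample Mann–Whitney test (α = 0.01 by default).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import TARGETS, LabelMatrix

__all__ = [
    "pearson_r",
    "rmse",
    "per_protocol_eval",
    "ligand_centric_eval",
    "select_protocol",
    "oracle_selection",
    "mann_whitney_one_sided",
    "selection_comparison",
    "per_family_eval",
]

EXACT_MW_MAX_N = 12


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN (flagged missing) when either
    vector is constant or shorter than 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def rmse(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def _as_values(labels) -> np.ndarray:
    return labels.values if isinstance(labels, LabelMatrix) else np.asarray(labels, dtype=float)


def _fold_indices(plan, ids):
    folds = plan.fold_of(ids)
    return [np.flatnonzero(folds == f) for f in range(plan.k)]


def per_protocol_eval(predictions, labels, plan, ids=None) -> pd.DataFrame:
    """Protocol-centric metrics table.

    ``predictions`` is (n, 3, P) — each complex predicted by the model of
    the fold that held it out — and ``labels`` (n, P, 3). Metrics are
    computed per fold over that fold's validation complexes, then
    aggregated as mean ± std across folds. The final "Average" row
    aggregates the per-protocol means across protocols.
    """
    values = _as_values(labels)
    pred = np.asarray(predictions, dtype=float)
    n, _, p = pred.shape
    if values.shape != (n, p, 3):
        raise ValueError(f"labels shape {values.shape} incompatible with predictions {pred.shape}")
    if ids is None:
        ids = labels.complex_ids if isinstance(labels, LabelMatrix) else [str(i) for i in range(n)]
    missing = [i for i in ids if i not in plan.assignment]
    if missing:
        raise ValueError(f"predictions missing for complexes outside the plan: {missing[:3]}")
    protocols = labels.protocols if isinstance(labels, LabelMatrix) else [f"protocol-{j}" for j in range(p)]

    per_fold = np.full((plan.k, p, 3, 2), np.nan)  # fold, protocol, target, (rmse, r)
    for f, idx in enumerate(_fold_indices(plan, ids)):
        for j in range(p):
            for t in range(3):
                yt = values[idx, j, t]
                ph = pred[idx, t, j]
                ok = np.isfinite(yt)
                if ok.sum() == 0:
                    raise ValueError(f"no labels for protocol {protocols[j]} in fold {f}")
                per_fold[f, j, t, 0] = rmse(yt[ok], ph[ok])
                per_fold[f, j, t, 1] = pearson_r(yt[ok], ph[ok])

    rows = []
    for j in range(p):
        for t, tname in enumerate(TARGETS):
            rows.append({
                "protocol": protocols[j],
                "target": tname,
                "rmse_mean": np.nanmean(per_fold[:, j, t, 0]),
                "rmse_std": np.nanstd(per_fold[:, j, t, 0]),
                "r_mean": np.nanmean(per_fold[:, j, t, 1]),
                "r_std": np.nanstd(per_fold[:, j, t, 1]),
            })
    df = pd.DataFrame(rows)
    for t in TARGETS:
        sub = df[df["target"] == t]
        df = pd.concat(
            [df, pd.DataFrame([{
                "protocol": "Average",
                "target": t,
                "rmse_mean": sub["rmse_mean"].mean(),
                "rmse_std": sub["rmse_mean"].std(ddof=0),
                "r_mean": sub["r_mean"].mean(),
                "r_std": sub["r_mean"].std(ddof=0),
            }])],
            ignore_index=True,
        )
    return df


def ligand_centric_eval(predictions, labels, plan, ids=None, target: str = "rmsd_ave",
                        per_complex: bool = False) -> dict:
    """Ligand-centric metrics: pool all (complex, protocol) pairs of each
    fold's validation set into one vector pair, then aggregate over folds.

    With ``per_complex=True`` the alternative convention is used: R is
    computed per complex across protocols and averaged within the fold.
    """
    values = _as_values(labels)
    pred = np.asarray(predictions, dtype=float)
    t = TARGETS.index(target)
    if ids is None:
        ids = labels.complex_ids if isinstance(labels, LabelMatrix) else [str(i) for i in range(len(pred))]

    rs, errs = [], []
    for idx in _fold_indices(plan, ids):
        yt = values[idx, :, t]
        ph = pred[idx, t, :]
        ok = np.isfinite(yt)
        if per_complex:
            per = [pearson_r(yt[i][ok[i]], ph[i][ok[i]]) for i in range(len(idx)) if ok[i].sum() >= 2]
            rs.append(float(np.nanmean(per)))
        else:
            rs.append(pearson_r(yt[ok], ph[ok]))
        errs.append(rmse(yt[ok], ph[ok]))
    return {
        "target": target,
        "r_mean": float(np.nanmean(rs)),
        "r_std": float(np.nanstd(rs)),
        "rmse_mean": float(np.mean(errs)),
        "rmse_std": float(np.std(errs)),
        "per_fold_r": rs,
        "per_fold_rmse": errs,
    }


def select_protocol(prediction) -> np.ndarray:
    """Per-target protocol choice: argmin over protocols for RMSDmin and
    RMSDave, argmax for nRMSD; ties break to the lowest registry index.

    Accepts (3, P) or (batch, 3, P); returns matching (3,) or (batch, 3)
    integer indices.
    """
    pred = np.asarray(prediction, dtype=float)
    squeeze = pred.ndim == 2
    if squeeze:
        pred = pred[None]
    if pred.shape[1] != 3 or pred.shape[2] < 1:
        raise ValueError("prediction must be (batch, 3, P) with P >= 1")
    choice = np.stack(
        [
            np.argmin(pred[:, 0], axis=1),
            np.argmin(pred[:, 1], axis=1),
            np.argmax(pred[:, 2], axis=1),
        ],
        axis=1,
    )
    return choice[0] if squeeze else choice


def oracle_selection(labels) -> np.ndarray:
    """Selection computed from the experimental labels themselves (the
    best achievable policy); NaN entries are never chosen."""
    values = _as_values(labels)  # (n, P, 3)
    stacked = values.transpose(0, 2, 1).copy()  # (n, 3, P)
    stacked[:, :2][np.isnan(stacked[:, :2])] = np.inf
    stacked[:, 2][np.isnan(stacked[:, 2])] = -np.inf
    return select_protocol(stacked)


def _exact_mw(x, y, alternative: str):
    """Exact one-sided p by full enumeration of the C(n+m, n) role
    assignments of the combined sample; ties handled by half counts."""
    combined = np.concatenate([x, y])
    n = len(x)
    u_obs = _u_stat(x, y)
    total = comb(len(combined), n)
    hits = 0
    for pick in combinations(range(len(combined)), n):
        mask = np.zeros(len(combined), dtype=bool)
        mask[list(pick)] = True
        u = _u_stat(combined[mask], combined[~mask])
        if alternative == "less" and u <= u_obs + 1e-12:
            hits += 1
        elif alternative == "greater" and u >= u_obs - 1e-12:
            hits += 1
    return u_obs, hits / total


def _u_stat(x, y) -> float:
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_one_sided(x, y, alternative: str = "less"):
    """One-sided two-sample Mann–Whitney test.

    ``alternative='less'`` tests whether ``x`` is stochastically smaller
    than ``y``. Small samples (combined n ≤ 12) are evaluated exactly by
    enumeration; larger ones use the normal approximation with tie and
    continuity corrections. Returns (U, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    if x.size + y.size <= EXACT_MW_MAX_N:
        return _exact_mw(x, y, alternative)
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def selection_comparison(selection, labels, alpha: float = 0.01,
                         bonferroni: bool = False) -> pd.DataFrame:
    """Compare experimental outcomes under the selected protocols against
    every fixed protocol.

    For each target and protocol, the distribution of experimental values
    obtained by following ``selection`` (an (n, 3) index array) is tested
    against the protocol's own distribution — 'less' for the RMSD targets,
    'greater' for nRMSD. Returns one row per (target, protocol) with means,
    the U statistic, the p-value and a significance flag at ``alpha``.
    """
    values = _as_values(labels)
    sel = np.asarray(selection, dtype=int)
    n, p = values.shape[0], values.shape[1]
    if sel.shape != (n, 3):
        raise ValueError(f"selection shape {sel.shape} != ({n}, 3)")
    protocols = labels.protocols if isinstance(labels, LabelMatrix) else [f"protocol-{j}" for j in range(p)]
    n_tests = p if bonferroni else 1

    rows = []
    for t, tname in enumerate(TARGETS):
        chosen = values[np.arange(n), sel[:, t], t]
        chosen = chosen[np.isfinite(chosen)]
        direction = "greater" if tname == "n_rmsd" else "less"
        for j in range(p):
            fixed = values[:, j, t]
            fixed = fixed[np.isfinite(fixed)]
            u, pval = mann_whitney_one_sided(chosen, fixed, alternative=direction)
            rows.append({
                "target": tname,
                "protocol": protocols[j],
                "mean_selected": float(np.mean(chosen)),
                "mean_protocol": float(np.mean(fixed)),
                "U": u,
                "p_value": pval,
                "significant": pval * n_tests < alpha,
            })
    return pd.DataFrame(rows)


def per_family_eval(predictions, labels, plan, families, ids=None,
                    target: str = "rmsd_ave", top_n: int = 30,
                    min_count: int = 3) -> pd.DataFrame:
    """Pooled Pearson R restricted to each of the ``top_n`` most populous
    protein families, averaged over folds.

    Families are ranked by complex count (descending, ties by name). A
    family contributing fewer than ``min_count`` validation complexes to a
    fold is flagged missing (NaN) for that fold.
    """
    values = _as_values(labels)
    pred = np.asarray(predictions, dtype=float)
    t = TARGETS.index(target)
    if ids is None:
        ids = labels.complex_ids if isinstance(labels, LabelMatrix) else [str(i) for i in range(len(pred))]
    fam = [families[i] for i in ids] if isinstance(families, dict) else list(families)
    fam = np.asarray(fam, dtype=object)

    counts: dict[str, int] = {}
    for f in fam:
        counts[f] = counts.get(f, 0) + 1
    ranked = sorted(counts, key=lambda f: (-counts[f], f))[:top_n]

    fold_idx = _fold_indices(plan, ids)
    rows = []
    for family in ranked:
        member = fam == family
        per_fold = []
        for idx in fold_idx:
            sub = idx[member[idx]]
            if len(sub) < min_count:
                per_fold.append(np.nan)
                continue
            yt = values[sub, :, t]
            ph = pred[sub, t, :]
            ok = np.isfinite(yt)
            per_fold.append(pearson_r(yt[ok], ph[ok]))
        rows.append({
            "family": family,
            "n_complexes": counts[family],
            "r_mean": float(np.nanmean(per_fold)) if np.isfinite(per_fold).any() else float("nan"),
            "r_std": float(np.nanstd(per_fold)) if np.isfinite(per_fold).any() else float("nan"),
        })
    return pd.DataFrame(rows)
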