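"""Cross-group differential statistics on PI tables and marker-gene calling.

The central contrast is a two-sample t-test, per interaction unit, on the
PI evidence score (log2 fold change x -log10 adjusted p) across the
samples of the primary and recurrent arms. Marker genes are called with a
Wilcoxon rank-sum test under the usual single-cell conventions: detected
fraction and log2 fold-change prefilters, Benjamini-Hochberg adjustment
over the tested genes only.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError
from .io_formats import GROUPS


def bh_adjust(p_values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    Input values must lie in [0, 1]; returns the adjusted values in the
    input order with step-up monotonicity enforced.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InvalidParameterError("p-values must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# PI table assembly and differential test


def assemble_pi(
    results: Sequence[pd.DataFrame], sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Align per-sample PI rows into a unit x sample table.

    ``results`` are per-sample proximity or communication result frames
    (each with a ``sample_id`` column, a ``pi`` column, and either
    ``type_a``/``type_b`` or ``sender``/``receiver``/``ligand``/
    ``receptor`` identifier columns). Units missing or not testable in a
    sample are imputed PI = 0; ``n_imputed`` counts such samples per unit.
    Units absent from every sample are dropped.

    Returns a frame indexed by unit id with one column per sample plus
    ``n_imputed``.
    """
    if not results:
        raise InvalidParameterError("no result frames given")
    counts = sample_sheet["group"].value_counts()
    for g in GROUPS:
        if counts.get(g, 0) < 2:
            raise InvalidParameterError(f"need >= 2 samples in group {g!r}")

    frames = []
    for res in results:
        if res.empty:
            continue
        res = res.copy()
        if {"type_a", "type_b"}.issubset(res.columns) and "ligand" not in res.columns:
            unit = res["type_a"].astype(str) + "--" + res["type_b"].astype(str)
        elif {"sender", "receiver", "ligand", "receptor"}.issubset(res.columns):
            unit = (
                res["sender"].astype(str)
                + "->"
                + res["receiver"].astype(str)
                + ":"
                + res["ligand"].astype(str)
                + "-"
                + res["receptor"].astype(str)
            )
        else:
            raise InvalidParameterError(
                "result frame has neither proximity nor communication "
                "identifier columns"
            )
        sub = pd.DataFrame(
            {
                "unit": unit,
                "sample_id": res["sample_id"].astype(str),
                "pi": res["pi"].astype(float),
            }
        )
        if "testable" in res.columns:
            sub = sub[res["testable"].to_numpy(dtype=bool)]
        sub = sub.dropna(subset=["pi"])
        frames.append(sub)
    if not frames:
        raise InvalidParameterError("all result frames empty")
    long = pd.concat(frames, ignore_index=True)

    sample_ids = list(sample_sheet["sample_id"].astype(str))
    table = long.pivot_table(
        index="unit", columns="sample_id", values="pi", aggfunc="first"
    ).reindex(columns=sample_ids)
    n_imputed = table.isna().sum(axis=1).astype(int)
    table = table.fillna(0.0)
    table["n_imputed"] = n_imputed
    table.index.name = "unit"
    return table


def differential_pi(
    table: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    variant: str = "student",
) -> pd.DataFrame:
    """Two-sample t-test on PI per unit, primary vs recurrent samples.

    ``variant`` selects Student's pooled-variance test (default; stable at
    3-vs-3) or Welch. The t statistic is oriented recurrent minus primary,
    so ``direction`` (its sign) is positive for units stronger in the
    recurrent arm. Degenerate cases: both groups constant and equal gives
    p = 1; zero variance with unequal means gives p = 0 and a
    ``degenerate`` flag.

    Returns per-unit rows with mean PI per group, t, df, p, the p < .05
    ``significant`` flag and ``direction``.
    """
    if variant not in ("student", "welch"):
        raise InvalidParameterError(f"unknown variant {variant!r}")
    sheet = sample_sheet.assign(sample_id=sample_sheet["sample_id"].astype(str))
    ids = {g: list(sheet.loc[sheet["group"] == g, "sample_id"]) for g in GROUPS}
    for g in GROUPS:
        if len(ids[g]) < 2:
            raise InvalidParameterError(f"need >= 2 samples in group {g!r}")
        missing = [s for s in ids[g] if s not in table.columns]
        if missing:
            raise InvalidParameterError(f"samples missing from table: {missing}")

    P = table[ids["primary"]].to_numpy(dtype=float)
    R = table[ids["recurrent"]].to_numpy(dtype=float)
    n1, n2 = P.shape[1], R.shape[1]
    m1, m2 = P.mean(axis=1), R.mean(axis=1)
    v1 = P.var(axis=1, ddof=1)
    v2 = R.var(axis=1, ddof=1)

    if variant == "student":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full(len(m1), float(n1 + n2 - 2))
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )

    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = np.empty(len(t))
    degenerate = np.zeros(len(t), dtype=bool)
    ok = se > 0
    p[ok] = 2 * scipy.stats.t.sf(np.abs(t[ok]), df[ok])
    zero_se = ~ok
    equal = zero_se & (diff == 0)
    unequal = zero_se & (diff != 0)
    t[equal], p[equal] = 0.0, 1.0
    t[unequal] = np.sign(diff[unequal]) * np.inf
    p[unequal] = 0.0
    degenerate[unequal] = True
    df[zero_se] = np.nan

    return pd.DataFrame(
        {
            "unit": table.index,
            "mean_pi_primary": m1,
            "mean_pi_recurrent": m2,
            "t": t,
            "df": df,
            "p_value": p,
            "significant": p < 0.05,
            "direction": np.sign(diff).astype(int),
            "degenerate": degenerate,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum marker genes


def _ranksum_tiecorrected(
    X_in: np.ndarray, X_out: np.ndarray
) -> np.ndarray:
    """Vectorised two-sided Wilcoxon rank-sum p per row.

    Normal approximation with tie correction and continuity correction,
    matching ``scipy.stats.mannwhitneyu(method="asymptotic")``.
    """
    n1, n2 = X_in.shape[1], X_out.shape[1]
    n = n1 + n2
    pooled = np.concatenate([X_in, X_out], axis=1)
    ranks = scipy.stats.rankdata(pooled, axis=1)
    R1 = ranks[:, :n1].sum(axis=1)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # per-row tie term sum(t^3 - t) over tie groups
    s = np.sort(pooled, axis=1)
    tie_term = np.zeros(len(pooled))
    for i in range(len(pooled)):
        _, cnt = np.unique(s[i], return_counts=True)
        tie_term[i] = (cnt.astype(float) ** 3 - cnt).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(U - mu) - 0.5) / sigma
    z = np.where(sigma > 0, np.maximum(z, 0.0), 0.0)
    return np.clip(2 * scipy.stats.norm.sf(z), 0.0, 1.0)


def wilcoxon_markers(
    expr,
    groups: np.ndarray | pd.Series | list,
    contrast: tuple[str, str] | str,
    gene_ids: Sequence[str] | None = None,
    min_pct: float = 0.25,
    min_lfc: float = 0.25,
) -> pd.DataFrame:
    """Marker genes by Wilcoxon rank-sum on log-normalised expression.

    Parameters
    ----------
    expr
        Log-normalised gene x observation matrix (dense or CSR).
    groups
        Per-observation labels.
    contrast
        Either ``(A, B)`` for an A-vs-B contrast or a single label for
        one-vs-rest.
    min_pct, min_lfc
        Prefilter: a gene is tested only when its in-group detected
        fraction exceeds ``min_pct`` and its log2 fold change exceeds
        ``min_lfc`` (strict). Untested genes are excluded from the BH
        denominator and reported with NaN p.

    log2FC follows the pseudocount convention
    ``log2((mean expm1(x_in) + 1) / (mean expm1(x_out) + 1))``; a gene
    passes when detected fraction in-group > ``min_pct``, log2FC >
    ``min_lfc`` and adjusted p < .05.
    """
    groups = np.asarray(groups)
    if isinstance(contrast, str):
        in_mask = groups == contrast
        out_mask = ~in_mask
        label = f"{contrast}-vs-rest"
    else:
        a, b = contrast
        in_mask = groups == a
        out_mask = groups == b
        label = f"{a}-vs-{b}"
    if in_mask.sum() < 3 or out_mask.sum() < 3:
        raise InvalidParameterError(
            f"contrast {label}: both sides need >= 3 observations"
        )

    X = np.asarray(expr.todense()) if hasattr(expr, "todense") else np.asarray(expr)
    X = X.astype(float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(X.shape[0])]
    X_in, X_out = X[:, in_mask], X[:, out_mask]

    pct_in = (X_in > 0).mean(axis=1)
    pct_out = (X_out > 0).mean(axis=1)
    lfc = np.log2(
        (np.expm1(X_in).mean(axis=1) + 1) / (np.expm1(X_out).mean(axis=1) + 1)
    )
    tested = (pct_in > min_pct) & (lfc > min_lfc)

    p = np.full(X.shape[0], np.nan)
    adj = np.full(X.shape[0], np.nan)
    if tested.any():
        p[tested] = _ranksum_tiecorrected(X_in[tested], X_out[tested])
        adj[tested] = bh_adjust(p[tested])

    return pd.DataFrame(
        {
            "gene": list(gene_ids),
            "contrast": label,
            "log2_fc": lfc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "p_value": p,
            "adj_p_value": adj,
            "tested": tested,
            "pass": tested & (adj < 0.05),
        }
    )


def deg_direction_summary(tables: Sequence[pd.DataFrame]) -> dict:
    """UpSet-style overlap of passing genes across DEG tables.

    Returns ``{"n_tables": ..., "genes_by_k": {k: count of genes passing
    in exactly k tables}, "opposite_direction": count of genes whose
    log2FC sign differs between two tables where both pass,
    "total_genes": distinct passing genes}``.
    """
    if len(tables) < 2:
        raise InvalidParameterError("need >= 2 DEG tables")
    passing: list[dict[str, float]] = []
    for t in tables:
        sub = t.loc[t["pass"].astype(bool)]
        passing.append(dict(zip(sub["gene"], sub["log2_fc"])))

    all_genes = sorted(set().union(*[set(p) for p in passing]))
    by_k: dict[int, int] = {}
    opposite = 0
    for g in all_genes:
        ks = [p[g] for p in passing if g in p]
        by_k[len(ks)] = by_k.get(len(ks), 0) + 1
        if any(np.sign(x) != np.sign(y) for x, y in combinations(ks, 2)):
            opposite += 1
    return {
        "n_tables": len(tables),
        "genes_by_k": by_k,
        "opposite_direction": opposite,
        "total_genes": len(all_genes),
    }
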