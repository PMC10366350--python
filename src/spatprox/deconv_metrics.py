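"""Spot annotation by signature enrichment and deconvolution heterogeneity metrics.

Two complementary views of per-spot composition:

* PAGE (parametric analysis of gene set enrichment) scores each spot
  against each cell-type gene signature. For signature ``c`` of size ``m``
  the statistic is ``Z = (S_m - mu) * sqrt(m) / delta``, where fold
  changes are gene expression values centred on the gene's mean across
  spots, ``S_m`` is their mean over the signature genes and ``mu``,
  ``delta`` are the mean and standard deviation of the fold changes over
  all genes in that spot.
* Deconvolution heterogeneity: the number of cell types contributing more
  than 1% prediction score to a spot, the fraction of spots with more
  than five contributing types, and the spot-level Shannon index
  ``H = -sum p ln p`` (nats) of the renormalised score vector.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

from .errors import InvalidParameterError
from .io_formats import GROUPS, SpatialSample, log_normalize


def page_scores(
    sample: SpatialSample,
    signatures: Mapping[str, Sequence[str]],
    expr: sp.spmatrix | np.ndarray | None = None,
) -> pd.DataFrame:
    """PAGE enrichment Z-scores, spots x signatures.

    Expression is library-size log-normalised unless a pre-normalised
    gene x spot matrix is passed via ``expr``. Signatures with no gene in
    the sample's universe are dropped with a warning. Spots whose
    fold-change standard deviation is zero get NaN Z-scores.
    """
    if sample.n_spots < 2:
        raise InvalidParameterError("PAGE needs at least 2 spots")
    X = log_normalize(sample) if expr is None else expr
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, dtype=float)

    gene_idx = {g: i for i, g in enumerate(sample.gene_ids)}
    F = X - X.mean(axis=1, keepdims=True)  # fold change vs gene mean
    mu = F.mean(axis=0)
    delta = F.std(axis=0, ddof=1)

    cols = {}
    for name, genes in signatures.items():
        rows = [gene_idx[g] for g in dict.fromkeys(genes) if g in gene_idx]
        m = len(rows)
        if m == 0:
            warnings.warn(
                f"signature {name!r} shares no genes with the sample; dropped",
                stacklevel=2,
            )
            continue
        S = F[rows].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (S - mu) * np.sqrt(m) / delta
        cols[name] = np.where(delta > 0, z, np.nan)
    if not cols:
        raise InvalidParameterError("no signature intersects the gene universe")
    return pd.DataFrame(cols, index=sample.spot_ids)


def annotate_spots(page: pd.DataFrame) -> pd.Series:
    """Dominant signature per spot (argmax PAGE Z), NaN-safe."""
    return page.idxmax(axis=1)


# ---------------------------------------------------------------------------
# deconvolution heterogeneity


def contributing_count(
    scores: pd.DataFrame, threshold: float = 0.01
) -> pd.Series:
    """Number of cell types whose prediction score strictly exceeds ``threshold``."""
    if not 0 <= threshold < 1:
        raise InvalidParameterError("threshold must lie in [0, 1)")
    return (scores > threshold).sum(axis=1).rename("n_contributing")


def heterogeneity_fraction(counts: pd.Series | np.ndarray, cutoff: int = 5) -> float:
    """Fraction of spots with strictly more than ``cutoff`` contributing types."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise InvalidParameterError("empty count vector")
    return float((counts > cutoff).mean())


def shannon_index(scores: pd.DataFrame) -> pd.Series:
    """Per-spot Shannon index (nats) of the renormalised score row.

    Rows are renormalised to sum one; ``0 ln 0`` is taken as 0. All-zero
    rows yield NaN and a warning (they carry no composition information).
    """
    vals = scores.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    bad = totals <= 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} all-zero score rows; Shannon undefined there",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        p = vals / totals[:, None]
        h = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    h = np.where(bad, np.nan, h)
    return pd.Series(h, index=scores.index, name="shannon")


def heterogeneity_profile(
    scores: pd.DataFrame, threshold: float = 0.01, cutoff: int = 5
) -> dict:
    """Per-sample heterogeneity summary from a deconvolution score table."""
    counts = contributing_count(scores, threshold)
    h = shannon_index(scores)
    return {
        "counts": counts,
        "shannon": h,
        "fraction_high": heterogeneity_fraction(counts, cutoff),
        "mean_shannon": float(h.mean(skipna=True)),
    }


def compare_heterogeneity(
    profiles: Mapping[str, dict], sample_sheet: pd.DataFrame
) -> pd.DataFrame:
    """Primary-vs-recurrent comparison of heterogeneity summaries.

    Primary inference is a two-sample t-test on per-sample summaries (the
    high-heterogeneity fraction and the mean Shannon index); a pooled
    spot-level Mann-Whitney rank-sum on Shannon values is reported as a
    secondary, pseudoreplicated view. Returns one row per metric with
    t / statistic, df, p and group means.
    """
    sheet = sample_sheet.assign(sample_id=sample_sheet["sample_id"].astype(str))
    ids = {g: list(sheet.loc[sheet["group"] == g, "sample_id"]) for g in GROUPS}
    for g in GROUPS:
        if len(ids[g]) < 2:
            raise InvalidParameterError(f"need >= 2 samples in group {g!r}")
        missing = [s for s in ids[g] if s not in profiles]
        if missing:
            raise InvalidParameterError(f"profiles missing for {missing}")

    rows = []
    for metric in ("fraction_high", "mean_shannon"):
        a = np.array([profiles[s][metric] for s in ids["primary"]])
        b = np.array([profiles[s][metric] for s in ids["recurrent"]])
        if np.allclose(a.var(), 0) and np.allclose(b.var(), 0) and a.mean() == b.mean():
            t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
        else:
            res = scipy.stats.ttest_ind(b, a)
            t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        rows.append(
            {
                "metric": metric,
                "level": "per_sample",
                "test": "t",
                "statistic": t,
                "df": df,
                "p_value": p,
                "mean_primary": float(a.mean()),
                "mean_recurrent": float(b.mean()),
            }
        )

    pooled_p = np.concatenate(
        [profiles[s]["shannon"].dropna().to_numpy() for s in ids["primary"]]
    )
    pooled_r = np.concatenate(
        [profiles[s]["shannon"].dropna().to_numpy() for s in ids["recurrent"]]
    )
    if np.array_equal(np.sort(pooled_p), np.sort(pooled_r)):
        stat, p = 0.0, 1.0
    else:
        res = scipy.stats.mannwhitneyu(pooled_r, pooled_p, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    rows.append(
        {
            "metric": "shannon",
            "level": "pooled_spots",
            "test": "mannwhitney",
            "statistic": stat,
            "df": np.nan,
            "p_value": p,
            "mean_primary": float(pooled_p.mean()),
            "mean_recurrent": float(pooled_r.mean()),
        }
    )
    return pd.DataFrame(rows)
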