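"""Rank-based annotation enrichment in one or more dimensions.

Values (fold changes, correlation scores, ...) are converted to ranks and
scaled linearly to [-1, 1].  A gene set is then tested for a mean scaled-rank
difference against the background of all other items: one-way ANOVA for a
single dimension, a two-group multivariate ANOVA (Pillai's trace with its F
approximation) for several dimensions jointly.  Hypergeometric
overrepresentation with the log10 observed/expected "strength" statistic is
also provided.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def scale_ranks(values) -> pd.Series | pd.DataFrame:
    """Rank values and scale the ranks linearly to [-1, 1].

    Ranks use the average-rank convention for ties; rank r in {1..n} maps to
    ``2*(r-1)/(n-1) - 1`` so the smallest value gets -1 and the largest +1.
    Missing values are ignored when ranking and stay missing.  Accepts a 1-D
    sequence/Series or a DataFrame (items x dimensions, ranked per column).

    Parameters
    ----------
    values : array-like, Series or DataFrame

    Returns
    -------
    Same shape as the input, as Series/DataFrame of scaled ranks.
    """
    if isinstance(values, pd.DataFrame):
        return values.apply(lambda col: scale_ranks(col), axis=0)
    ser = pd.Series(values, dtype=float)
    out = pd.Series(np.nan, index=ser.index, dtype=float)
    valid = ser.notna()
    n = int(valid.sum())
    if n == 0:
        return out
    if n == 1:
        warnings.warn("single item: scaled rank set to 0", stacklevel=2)
        out[valid] = 0.0
        return out
    ranks = sps.rankdata(ser[valid].to_numpy())
    out[valid] = 2.0 * (ranks - 1.0) / (n - 1.0) - 1.0
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted p-values (q-values) in the original order, with the
    usual monotonicity enforcement.  NaN inputs yield NaN outputs and do not
    count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    mask = ~np.isnan(flat)
    pv = flat[mask]
    if pv.size and (pv.min() < 0 or pv.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out.reshape(p.shape)
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # step-up: enforce monotone non-decreasing from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out_flat = out.ravel()
    out_flat[mask] = adj
    return out_flat.reshape(p.shape)


def _member_mask(index: pd.Index, members) -> np.ndarray:
    if isinstance(members, (pd.Series, np.ndarray)) and np.asarray(members).dtype == bool:
        mask = np.asarray(members, dtype=bool)
        if mask.shape[0] != len(index):
            raise ValueError("boolean membership length does not match items")
        return mask
    member_set = set(members)
    return index.isin(member_set)


def enrich_1d(ranks: pd.Series, members) -> tuple[float, float]:
    """One-dimensional enrichment of a set against the background.

    Score is mean(scaled rank | set) - mean(scaled rank | background); the
    p-value comes from a two-group one-way ANOVA.

    Parameters
    ----------
    ranks : Series of scaled ranks indexed by item.
    members : iterable of item labels or boolean mask.

    Returns
    -------
    (score, p)
    """
    ranks = pd.Series(ranks, dtype=float).dropna()
    mask = _member_mask(ranks.index, members)
    n_in = int(mask.sum())
    if n_in == 0 or n_in == len(ranks):
        raise ValueError("set must be a non-empty proper subset of the items")
    inside = ranks.to_numpy()[mask]
    outside = ranks.to_numpy()[~mask]
    score = float(inside.mean() - outside.mean())
    p = float(sps.f_oneway(inside, outside).pvalue)
    return score, p


def _pillai_two_group(x_in: np.ndarray, x_out: np.ndarray,
                      labels: Sequence[str]) -> float:
    """Two-group MANOVA p-value via Pillai's trace and its exact F transform.

    With two groups Pillai's trace has a single non-zero eigenvalue, and
    F = V/(1-V) * (n - p - 1)/p on (p, n - p - 1) df, n the total sample size
    and p the number of dimensions.
    """
    n1, n2 = x_in.shape[0], x_out.shape[0]
    n, p = n1 + n2, x_in.shape[1]
    if n - p - 1 < 1:
        raise ValueError("more dimensions than residual degrees of freedom")
    d = x_in.mean(axis=0) - x_out.mean(axis=0)
    r_in = x_in - x_in.mean(axis=0)
    r_out = x_out - x_out.mean(axis=0)
    E = r_in.T @ r_in + r_out.T @ r_out
    H = (n1 * n2 / n) * np.outer(d, d)
    T = H + E
    if np.linalg.matrix_rank(T) < p:
        resid = np.vstack([r_in, r_out])
        cols = _collinear_columns(resid, labels)
        raise np.linalg.LinAlgError(
            "singular within-group covariance; collinear dimensions: "
            + ", ".join(cols)
        )
    V = float(np.trace(H @ np.linalg.solve(T, np.eye(p))))
    V = min(max(V, 0.0), 1.0 - 1e-15)
    F = V / (1.0 - V) * (n - p - 1) / p
    return float(sps.f.sf(F, p, n - p - 1))


def _collinear_columns(resid: np.ndarray, labels: Sequence[str]) -> list[str]:
    sd = resid.std(axis=0)
    flagged = [labels[j] for j in np.where(sd < 1e-12)[0]]
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(resid, rowvar=False)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if abs(c[i, j]) > 1 - 1e-10:
                flagged.extend([labels[i], labels[j]])
    return sorted(set(flagged)) or list(labels)


def enrich_nd(ranks: pd.DataFrame, members) -> tuple[pd.Series, float]:
    """Multidimensional enrichment: per-dimension scores plus one overall p.

    Items with a missing rank in any dimension are dropped listwise.  With a
    single dimension the p-value reduces to that of :func:`enrich_1d`.

    Returns
    -------
    (scores, p) : per-dimension mean-difference scores, overall Pillai p.
    """
    ranks = pd.DataFrame(ranks).dropna(axis=0, how="any")
    if ranks.shape[1] < 1:
        raise ValueError("at least one dimension required")
    if ranks.shape[0] <= ranks.shape[1]:
        raise ValueError("need more items than dimensions")
    mask = _member_mask(ranks.index, members)
    n_in = int(mask.sum())
    if n_in == 0 or n_in == len(ranks):
        raise ValueError("set must be a non-empty proper subset of the items")
    x = ranks.to_numpy(dtype=float)
    x_in, x_out = x[mask], x[~mask]
    scores = pd.Series(x_in.mean(axis=0) - x_out.mean(axis=0),
                       index=ranks.columns)
    p = _pillai_two_group(x_in, x_out, [str(c) for c in ranks.columns])
    return scores, p


def enrich_gene_sets(ranks, gene_sets: Mapping[str, Iterable[str]],
                     min_size: int = 2) -> pd.DataFrame:
    """Test a collection of gene sets; one BH family across the collection.

    Parameters
    ----------
    ranks : Series (1-D) or DataFrame (N-D) of scaled ranks.
    gene_sets : mapping set name -> iterable of item ids.
    min_size : smallest within-universe set size tested.

    Returns
    -------
    DataFrame with one row per testable set: per-dimension score columns
    (``score`` or ``score:<dim>``), ``n_set``, ``p``, ``fdr``.
    """
    one_d = isinstance(ranks, pd.Series) or (
        isinstance(ranks, pd.DataFrame) and ranks.shape[1] == 1)
    frame = pd.DataFrame(ranks).dropna(axis=0, how="any")
    universe = frame.index
    rows = []
    for name, genes in gene_sets.items():
        used = universe.intersection(pd.Index(list(set(genes))))
        if len(used) < min_size or len(used) == len(universe):
            continue
        scores, p = enrich_nd(frame, used)
        row = {"set": name, "n_set": len(used), "p": p}
        if one_d:
            row["score"] = float(scores.iloc[0])
        else:
            for dim, s in scores.items():
                row[f"score:{dim}"] = float(s)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["set", "n_set", "p", "fdr"])
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def overrepresentation(hits: Iterable[str], gene_sets: Mapping[str, Iterable[str]],
                       background: Iterable[str]) -> pd.DataFrame:
    """Hypergeometric overrepresentation of hits within annotated sets.

    For each set: overlap q between the k hits and the m set members among N
    background items; p = P(X >= q) under Hypergeometric(N, m, k); the
    strength of the overrepresentation is s = log10(N*q/(k*m)), the log10
    ratio of observed to expected overlap (missing when q = 0).  BH FDR is
    computed across the supplied collection (one family per collection).
    """
    bg = pd.Index(pd.unique(pd.Series(list(background))))
    N = len(bg)
    hit_set = set(hits)
    if not hit_set.issubset(set(bg)):
        raise ValueError("hits must be a subset of the background")
    k = len(hit_set)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & set(bg)
        m = len(members)
        if m == 0:
            continue
        if N < k or N < m:
            raise ValueError("background smaller than hit list or set")
        q = len(hit_set & members)
        p = float(sps.hypergeom.sf(q - 1, N, m, k))
        s = float(np.log10(N * q / (k * m))) if q > 0 and k > 0 else np.nan
        rows.append({"set": name, "q": q, "m": m, "k": k, "N": N,
                     "p": p, "strength": s})
    if not rows:
        return pd.DataFrame(
            columns=["set", "q", "m", "k", "N", "p", "strength", "fdr"])
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
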