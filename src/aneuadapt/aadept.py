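"""AADEPT: aneuploidy-associated differential expression in tumorigenesis.

For each gene, the AADEPT score is the Spearman rank correlation across a
patient cohort between the tumor aneuploidy score (number of altered
autosomal arms) and the tumor-minus-matched-normal expression or protein
abundance change.  Cohort preprocessing follows the standard pipeline:
valid-fraction gene filter, per-sample upper-quartile normalization, log2
transform, matched-normal subtraction, and exclusion of whole-genome-doubled
patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .copy_number import filter_wgd
from .rank_enrichment import bh_adjust


@dataclass
class CohortOmics:
    """Per-patient aneuploidy scores plus gene x patient delta matrix.

    ``deltas`` holds tumor-minus-normal log2 changes (genes x patients);
    every patient column has an aneuploidy score; WGD-excluded patients are
    absent by construction.
    """

    deltas: pd.DataFrame
    aneuploidy_score: pd.Series
    ploidy: pd.Series | None = None
    cancer_type: pd.Series | None = None

    def __post_init__(self):
        patients = self.deltas.columns
        if not patients.isin(self.aneuploidy_score.index).all():
            raise ValueError("every patient needs an aneuploidy score")
        self.aneuploidy_score = self.aneuploidy_score.loc[patients]


def upper_quartile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample (column) by the 75th percentile of its positive values."""
    out = matrix.astype(float).copy()
    for col in out.columns:
        vals = out[col]
        positive = vals[vals > 0]
        if positive.empty:
            raise ValueError(f"sample {col} has no positive values")
        out[col] = vals / float(np.percentile(positive, 75))
    return out


def prepare_expression_deltas(tumor: pd.DataFrame, normal: pd.DataFrame,
                              ploidy: pd.Series,
                              aneuploidy_scores: pd.Series,
                              min_valid_fraction: float = 0.6,
                              wgd_cutoff: float = 2.5) -> CohortOmics:
    """Build the tumor-minus-normal delta matrix with cohort filters applied.

    Steps: keep genes with valid (non-missing, positive) values in at least
    ``min_valid_fraction`` of samples (tumor and normal columns pooled);
    upper-quartile normalize each sample; log2 transform; subtract the
    matched normal from each tumor; drop whole-genome-doubled patients
    (ploidy >= ``wgd_cutoff``) and patients lacking a matched normal.
    """
    shared = tumor.columns.intersection(normal.columns)
    n_unmatched = len(tumor.columns) - len(shared)
    if n_unmatched:
        warnings.warn(f"{n_unmatched} patient(s) lack a matched normal and "
                      "were dropped", stacklevel=2)
    tumor = tumor[shared]
    normal = normal[shared]
    genes = tumor.index.intersection(normal.index)
    tumor, normal = tumor.loc[genes], normal.loc[genes]

    pooled = pd.concat([tumor, normal], axis=1)
    valid = pooled.notna() & (pooled > 0)
    keep_genes = valid.mean(axis=1) >= min_valid_fraction
    tumor, normal = tumor[keep_genes], normal[keep_genes]

    def _log_uq(m: pd.DataFrame) -> pd.DataFrame:
        m = m.where(m.notna() & (m > 0))
        m = upper_quartile_normalize(m)
        return np.log2(m)

    deltas = _log_uq(tumor) - _log_uq(normal)

    ploidy = pd.Series(ploidy)
    records = pd.DataFrame({"sample_id": shared,
                            "ploidy": ploidy.reindex(shared).to_numpy()})
    retained = [p for p in filter_wgd(records, cutoff=wgd_cutoff)
                if p in deltas.columns]
    deltas = deltas[retained]
    return CohortOmics(
        deltas=deltas,
        aneuploidy_score=pd.Series(aneuploidy_scores).reindex(retained),
        ploidy=ploidy.reindex(retained),
    )


def _spearman_pvalues(rho: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation on n-2 df."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.where(n > 2, p, np.nan)


def aadept_scores(cohort: CohortOmics) -> pd.DataFrame:
    """Per-gene AADEPT table: Spearman rho, n, p (t approximation), BH FDR.

    Average ranks are used for ties.  Genes with missing deltas use the
    pairwise-complete patients; a gene constant across patients gets a
    missing rho.
    """
    as_values = cohort.aneuploidy_score.to_numpy(dtype=float)
    if np.unique(as_values[~np.isnan(as_values)]).size < 2:
        raise ValueError("aneuploidy score is constant across the cohort")
    if cohort.deltas.shape[1] < 3:
        raise ValueError("need at least 3 patients")
    mat = cohort.deltas.to_numpy(dtype=float)
    n_genes, n_pat = mat.shape
    rho = np.full(n_genes, np.nan)
    n_used = np.zeros(n_genes, dtype=int)

    complete = ~np.isnan(mat).any(axis=1)
    if complete.any():
        x = mat[complete]
        rx = sps.rankdata(x, axis=1)
        ry = sps.rankdata(as_values)
        rx = rx - rx.mean(axis=1, keepdims=True)
        ry = ry - ry.mean()
        denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rx @ ry) / denom
        rho[complete] = r
        n_used[complete] = n_pat
    for i in np.where(~complete)[0]:
        ok = ~np.isnan(mat[i])
        n_used[i] = int(ok.sum())
        if n_used[i] >= 3 and np.unique(as_values[ok]).size >= 2:
            res = sps.spearmanr(mat[i, ok], as_values[ok])
            rho[i] = res.statistic
    p = _spearman_pvalues(rho, n_used.astype(float))
    out = pd.DataFrame({"rho": rho, "n": n_used, "p": p},
                       index=cohort.deltas.index)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out
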