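"""Differential protein abundance, dosage compensation and arm scaling.

Intensity matrices are filtered (contaminants, reverse hits, site-only
identifications, incomplete protein groups), log2-transformed, cleaned of
batch effects by a least-squares model that preserves the biological groups,
and scale-normalized per sample.  Pairwise comparisons use moderated
t-statistics: per-protein variances are shrunk toward a common prior whose
parameters (d0, s0) are estimated by the method of moments on log residual
variances, and p-values are BH-adjusted.  Arm-level dosage compensation is
the difference between the mean genomic log2 ratio of an arm and the mean
log2 protein fold change of the genes it encodes; the scaling classifier
tests tumor proteins against the 3/2 single-copy-gain expectation with
Welch's tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .copy_number import SegmentedProfile, segment_series
from .rank_enrichment import bh_adjust

LOG2_3_OVER_2 = float(np.log2(1.5))


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_intensities(raw: pd.DataFrame, annotations: pd.DataFrame,
                           flags: pd.DataFrame | None = None,
                           log_transform: bool = True) -> pd.DataFrame:
    """Filter, log2-transform, batch-clean and scale a raw intensity matrix.

    Parameters
    ----------
    raw : protein x sample intensity matrix (raw scale unless
        ``log_transform=False``).
    annotations : per-sample sheet indexed by sample with at least 'batch';
        'line' and 'passage' (if present) define the biological groups whose
        effects are preserved during batch cleaning.
    flags : optional boolean DataFrame indexed by protein with any of the
        columns contaminant / reverse / site_only; flagged rows are removed.

    Returns the processed complete-case log2 matrix.
    """
    mat = pd.DataFrame(raw).astype(float)
    annotations = pd.DataFrame(annotations)
    if not pd.Index(mat.columns).isin(annotations.index).all():
        raise ValueError("annotations must cover every sample column")
    annotations = annotations.loc[mat.columns]
    if flags is not None:
        flagged = pd.DataFrame(flags).reindex(mat.index).fillna(False)
        drop = flagged.any(axis=1)
        mat = mat[~drop]
    mat = mat.dropna(axis=0, how="any")
    if log_transform:
        if (mat <= 0).any().any():
            raise ValueError("raw intensities must be positive for log2")
        mat = np.log2(mat)
    if mat.empty:
        raise ValueError("no protein groups left after filtering")

    # per-sample scale normalization on the log2 scale: subtract each
    # sample's median log-ratio to the row-median reference profile
    # (median-of-log-ratios, as in size-factor normalization).  The shared
    # between-protein baseline cancels exactly, so the per-sample offset
    # estimate is far less noisy than a plain median centering.  Batch
    # cleaning comes last so batch means are removed exactly in the output.
    reference = mat.median(axis=1)
    offsets = mat.sub(reference, axis=0).median(axis=0)
    mat = mat - offsets
    return _remove_batch_effects(mat, annotations)


def _remove_batch_effects(mat: pd.DataFrame,
                          annotations: pd.DataFrame) -> pd.DataFrame:
    """Subtract estimated batch effects, keeping biological group effects.

    Per protein, fits intensities on group dummies (full rank) plus batch
    dummies (first batch as baseline) by least squares and removes only the
    batch part.
    """
    batches = annotations["batch"].astype(str)
    if batches.nunique() <= 1:
        return mat
    group_cols = [c for c in ("line", "passage") if c in annotations.columns]
    if group_cols:
        groups = annotations[group_cols].astype(str).agg("|".join, axis=1)
    else:
        groups = pd.Series("all", index=annotations.index)
    G = pd.get_dummies(groups).to_numpy(dtype=float)
    B = pd.get_dummies(batches, drop_first=True).to_numpy(dtype=float)
    X = np.hstack([G, B])
    coef = np.linalg.lstsq(X, mat.to_numpy().T, rcond=None)[0]
    batch_part = B @ coef[G.shape[1]:, :]
    return mat - batch_part.T


# ---------------------------------------------------------------------------
# moderated differential abundance

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x = x - step
        if x <= 0:
            x = 1e-8
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_prior_variance(s2: np.ndarray, df: float,
                            d0_cap: float = 1e6) -> tuple[float, float]:
    """Method-of-moments estimate of the variance prior (d0, s0^2).

    Matches the mean and variance of log sample variances to the scaled
    inverse-chi-square model: with z = log(s^2),
    E[z] = log(s0^2) + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    and Var[z] = trigamma(df/2) + trigamma(d0/2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return d0_cap, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if var_e <= 0:
        d0 = d0_cap
    else:
        d0 = 2.0 * _trigamma_inverse(var_e)
        d0 = min(d0, d0_cap)
    s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2.0)
                         - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_diff_abundance(matrix: pd.DataFrame, groups: pd.Series,
                             contrast: tuple[str, str],
                             d0_override: float | None = None) -> pd.DataFrame:
    """Moderated two-group comparison of log2 intensities, per protein.

    log2 FC = mean(group a) - mean(group b); the pooled within-group variance
    is shrunk as s~^2 = (d0*s0^2 + df*s^2)/(d0 + df); t = FC / (s~ *
    sqrt(1/n1 + 1/n2)) on d0 + df degrees of freedom; BH FDR across proteins.
    ``d0_override=0`` recovers the ordinary pooled two-sample t-test.
    """
    groups = pd.Series(groups).loc[matrix.columns]
    a, b = contrast
    xa = matrix.loc[:, (groups == a).to_numpy()].to_numpy(dtype=float)
    xb = matrix.loc[:, (groups == b).to_numpy()].to_numpy(dtype=float)
    n1, n2 = xa.shape[1], xb.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 replicates on each side")
    df = n1 + n2 - 2
    fc = xa.mean(axis=1) - xb.mean(axis=1)
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((xb - xb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df
    if d0_override is None:
        d0, s0_sq = estimate_prior_variance(s2, df)
    else:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    if np.isfinite(d0) and d0 > 0:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    elif d0 == 0:
        s2_tilde, df_total = s2, float(df)
    else:
        s2_tilde, df_total = np.full_like(s2, s0_sq), np.inf
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / se
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    out = pd.DataFrame({"log2fc": fc, "t": t, "p": p,
                        "s2": s2, "df_prior": d0}, index=matrix.index)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def build_fold_change_table(matrix: pd.DataFrame, sample_sheet: pd.DataFrame,
                            comparisons: pd.DataFrame) -> pd.DataFrame:
    """Run every configured comparison; long table with group labels.

    ``comparisons`` rows need name, group (G1/G2/G3), line_a/passage_a
    (numerator) and line_b/passage_b (denominator); samples are grouped by
    (line, passage).
    """
    sheet = pd.DataFrame(sample_sheet).set_index("sample")
    labels = sheet["line"].astype(str) + "|" + sheet["passage"].astype(str)
    frames = []
    for _, row in pd.DataFrame(comparisons).iterrows():
        ga = f"{row['line_a']}|{row['passage_a']}"
        gb = f"{row['line_b']}|{row['passage_b']}"
        res = moderated_diff_abundance(matrix, labels, (ga, gb))
        res = res.reset_index().rename(columns={res.index.name or "index":
                                                "protein"})
        res.insert(1, "comparison", row["name"])
        res.insert(2, "group", row["group"])
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# dosage compensation

def _order_genes(catalog) -> pd.DataFrame:
    genes = catalog.genes.copy()
    genes["midpoint"] = (genes["start"] + genes["end"]) // 2
    return genes.sort_values(["chromosome", "midpoint"])


def segment_fold_changes(fold_changes: pd.Series, catalog,
                         alpha: float = 0.01, min_width: int = 3,
                         n_perm: int = 1000, seed: int = 0,
                         sample_id: str = "fc") -> SegmentedProfile:
    """Segment protein fold changes ordered by genomic gene position.

    Proteins without catalog coordinates are excluded (count reported via a
    warning).  Segment start/end are taken from the first/last gene of each
    run of proteins.
    """
    genes = _order_genes(catalog)
    fc = pd.Series(fold_changes).dropna()
    unmapped = len(fc) - int(fc.index.isin(genes["gene_id"]).sum())
    if unmapped:
        warnings.warn(f"{unmapped} protein(s) without genomic coordinates "
                      "excluded", stacklevel=2)
    genes = genes[genes["gene_id"].isin(fc.index)]
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in genes.groupby("chromosome", sort=False):
        x = fc.loc[grp["gene_id"]].to_numpy(dtype=float)
        if x.size == 0:
            continue
        bps = (segment_series(x, alpha=alpha, min_width=min_width,
                              n_perm=n_perm, rng=rng)
               if x.size >= min_width else [])
        bounds = [0, *bps, x.size]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append({"chromosome": chrom, "start": int(starts[a]),
                         "end": int(ends[b - 1]),
                         "mean_log2": float(x[a:b].mean()),
                         "median_log2": float(np.median(x[a:b])),
                         "n_bins": b - a})
    return SegmentedProfile(sample_id=sample_id, segments=pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "mean_log2",
                       "median_log2", "n_bins"]))


def arm_dosage_compensation(dna_profile: SegmentedProfile,
                            protein_fold_changes: pd.Series, catalog,
                            arms_of_interest=None) -> pd.DataFrame:
    """Per-arm dosage compensation = mean DNA log2 ratio - mean protein FC.

    Both inputs must be relative to the same parental reference.  The DNA
    term is the overlap-length-weighted mean of segment ratios on the arm;
    the protein term is the mean fold change of catalog genes on the arm.
    Arms without proteins are omitted with a warning.
    """
    fc = pd.Series(protein_fold_changes).dropna()
    segs = dna_profile.segments
    rows = []
    arm_iter = catalog.arms.itertuples(index=False)
    for arm_row in arm_iter:
        key = (arm_row.chromosome, arm_row.arm)
        if arms_of_interest is not None and key not in set(arms_of_interest):
            continue
        on_chrom = segs[segs["chromosome"] == arm_row.chromosome]
        overlap = (np.minimum(on_chrom["end"], arm_row.end)
                   - np.maximum(on_chrom["start"], arm_row.start)).clip(lower=0)
        w = overlap.to_numpy(dtype=float)
        if w.sum() <= 0:
            warnings.warn(f"arm {key} has no DNA segments; omitted",
                          stacklevel=2)
            continue
        dna_log2 = float(np.average(on_chrom["mean_log2"].to_numpy(), weights=w))
        gene_ids = catalog.genes_on_arm(*key)["gene_id"]
        arm_fc = fc.loc[fc.index.intersection(gene_ids)]
        if arm_fc.empty:
            warnings.warn(f"arm {key} has no quantified proteins; omitted",
                          stacklevel=2)
            continue
        protein_log2 = float(arm_fc.mean())
        rows.append({"chromosome": arm_row.chromosome, "arm": arm_row.arm,
                     "dna_log2": dna_log2, "protein_log2": protein_log2,
                     "compensation": dna_log2 - protein_log2,
                     "n_proteins": int(arm_fc.size)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scaling with arm gain in tumors

def _welch(mean1, var1, n1, mean2, var2, n2):
    se2 = var1 / n1 + var2 / n2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2 ** 2 / ((var1 / n1) ** 2 / (n1 - 1)
                         + (var2 / n2) ** 2 / (n2 - 1))
    return se, df


def classify_arm_scaling(tumor_deltas: pd.DataFrame,
                         arm_gain_status: pd.DataFrame, catalog,
                         fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Classify proteins as scaling / non-scaling with arm gain in tumors.

    For each protein, tumors are split by gain status of its encoding arm
    and the mean tumor-minus-normal delta difference is tested with Welch's
    t-test.  One-sided (alternative: difference < log2(3/2)) with BH FDR <
    ``fdr_threshold`` marks non_scaling; otherwise a two-sided test with a
    significant positive difference marks scaling; everything else is
    unclassified.  Proteins with fewer than 2 tumors on either side are
    unclassified with low_n flagged.

    Parameters
    ----------
    tumor_deltas : genes x patients matrix of tumor-minus-normal log2 values.
    arm_gain_status : boolean DataFrame indexed by (chromosome, arm) tuples
        or a MultiIndex, columns = patients; True where the arm is gained.
    """
    gain = pd.DataFrame(arm_gain_status)
    gain.index = pd.Index([tuple(i) if not isinstance(i, tuple) else i
                           for i in gain.index])
    patients = tumor_deltas.columns.intersection(gain.columns)
    deltas = tumor_deltas[patients]
    gain = gain[patients]
    gene_arm = catalog.genes.set_index("gene_id")[["chromosome", "arm"]]

    rows = []
    stats = {}
    for gene in deltas.index:
        if gene not in gene_arm.index:
            continue
        key = tuple(gene_arm.loc[gene])
        if key not in gain.index:
            continue
        if key not in stats:
            stats[key] = gain.loc[key].to_numpy(dtype=bool)
        mask = stats[key]
        x = deltas.loc[gene].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        g, n = x[ok & mask], x[ok & ~mask]
        if g.size < 2 or n.size < 2:
            rows.append({"protein": gene, "diff": np.nan, "p_one": np.nan,
                         "p_two": np.nan, "low_n": True})
            continue
        diff = g.mean() - n.mean()
        se, dfw = _welch(g.mean(), g.var(ddof=1), g.size,
                         n.mean(), n.var(ddof=1), n.size)
        if se == 0:
            rows.append({"protein": gene, "diff": diff, "p_one": np.nan,
                         "p_two": np.nan, "low_n": True})
            continue
        t_one = (diff - LOG2_3_OVER_2) / se
        p_one = float(sps.t.cdf(t_one, dfw))          # H1: diff < log2(3/2)
        t_two = diff / se
        p_two = float(2.0 * sps.t.sf(abs(t_two), dfw))
        rows.append({"protein": gene, "diff": diff, "p_one": p_one,
                     "p_two": p_two, "low_n": False})
    out = pd.DataFrame(rows).set_index("protein")
    out["fdr_one"] = bh_adjust(out["p_one"].to_numpy())
    out["fdr_two"] = bh_adjust(out["p_two"].to_numpy())
    non_scaling = out["fdr_one"] < fdr_threshold
    scaling = (~non_scaling & (out["fdr_two"] < fdr_threshold)
               & (out["diff"] > 0))
    cls = np.where(out["low_n"], "unclassified",
                   np.where(non_scaling, "non_scaling",
                            np.where(scaling, "scaling", "unclassified")))
    out["classification"] = cls
    return out
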