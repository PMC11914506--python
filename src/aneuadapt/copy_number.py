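"""Copy-number profile segmentation and arm-level aneuploidy summaries.

The input is a table of binned log2 copy-number ratios relative to a
reference (typically the unevolved parental line).  Profiles are partitioned
into constant-mean segments by recursive binary segmentation with a
permutation test for change-point acceptance (the CBS algorithm family).
Segments feed three summaries:

* arm event calls — an arm is gained/lost when same-direction altered
  segments (|log2 ratio| > 0.2) cover more than 75% of its length;
* the aneuploidy score — the number of autosomal arms called gained or lost;
* the total-relative-DNA heuristic D = sum_i round(2*(2^q_i - 1)) * L_i,
  the approximate number of base pairs gained (signed) or altered (unsigned)
  relative to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY", "x", "y", "23", "24"}

BIN_COLUMNS = ["chromosome", "start", "end", "log2_ratio"]
SEGMENT_COLUMNS = ["chromosome", "start", "end",
                   "mean_log2", "median_log2", "n_bins"]


@dataclass
class SegmentedProfile:
    """Piecewise-constant log2 copy-number ratios for one sample.

    ``segments`` has columns (chromosome, start, end, mean_log2, median_log2,
    n_bins) with 0-based half-open coordinates, non-overlapping and sorted
    within each chromosome.
    """

    sample_id: str
    segments: pd.DataFrame
    reference_id: str | None = None

    def __post_init__(self):
        self.segments = pd.DataFrame(self.segments)[SEGMENT_COLUMNS].copy()
        for chrom, grp in self.segments.groupby("chromosome", sort=False):
            grp = grp.sort_values("start")
            if (grp["end"].to_numpy()[:-1] > grp["start"].to_numpy()[1:]).any():
                raise ValueError(f"overlapping segments on {chrom}")
        if (self.segments["n_bins"] < 1).any():
            raise ValueError("segments must contain at least one bin")


def normalize_to_reference(profile_bins: pd.DataFrame,
                           reference_bins: pd.DataFrame) -> pd.DataFrame:
    """Subtract a reference profile bin-wise (matching bin grids required)."""
    prof = pd.DataFrame(profile_bins).reset_index(drop=True)
    ref = pd.DataFrame(reference_bins).reset_index(drop=True)
    grid = ["chromosome", "start", "end"]
    if len(prof) != len(ref) or not prof[grid].equals(ref[grid]):
        raise ValueError("bin grids of profile and reference do not match")
    out = prof.copy()
    out["log2_ratio"] = prof["log2_ratio"].to_numpy() - ref["log2_ratio"].to_numpy()
    return out


def _split_statistics(x: np.ndarray, min_width: int) -> np.ndarray:
    """|mean_left - mean_right| * sqrt(n_l*n_r/n) for every admissible split.

    Returns an array aligned with split positions 1..n-1; inadmissible
    splits (either side shorter than ``min_width``) are -inf.
    """
    n = x.size
    cs = np.cumsum(x)
    i = np.arange(1, n)
    mean_l = cs[:-1] / i
    mean_r = (cs[-1] - cs[:-1]) / (n - i)
    stat = np.abs(mean_l - mean_r) * np.sqrt(i * (n - i) / n)
    stat[(i < min_width) | (n - i < min_width)] = -np.inf
    return stat


def _best_split(x: np.ndarray, min_width: int) -> tuple[int, float]:
    stat = _split_statistics(x, min_width)
    j = int(np.argmax(stat))
    return j + 1, float(stat[j])


def _accept_split(x: np.ndarray, obs: float, n_perm: int, alpha: float,
                  min_width: int, rng: np.random.Generator) -> bool:
    if not np.isfinite(obs) or obs <= 0:
        return False
    perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    cs = np.cumsum(perms, axis=1)
    n = x.size
    i = np.arange(1, n)
    mean_l = cs[:, :-1] / i
    mean_r = (cs[:, -1:] - cs[:, :-1]) / (n - i)
    stat = np.abs(mean_l - mean_r) * np.sqrt(i * (n - i) / n)
    admissible = (i >= min_width) & (n - i >= min_width)
    null_max = stat[:, admissible].max(axis=1)
    p = (1.0 + np.count_nonzero(null_max >= obs - 1e-12)) / (n_perm + 1.0)
    return p <= alpha


def segment_series(x: np.ndarray, alpha: float = 0.01, min_width: int = 3,
                   n_perm: int = 1000,
                   rng: np.random.Generator | None = None) -> list[int]:
    """Change points of a 1-D series by recursive binary segmentation.

    Each candidate split maximizes the standardized mean-shift statistic and
    is accepted when a within-segment permutation test gives p <= alpha.

    Returns sorted interior breakpoint indices (segment i spans
    ``[b_i, b_{i+1})`` over the implied breakpoints ``0, ..., len(x)``).
    """
    x = np.asarray(x, dtype=float)
    rng = rng or np.random.default_rng(0)
    breaks: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        if seg.size < 2 * min_width:
            return
        j, obs = _best_split(seg, min_width)
        if _accept_split(seg, obs, n_perm, alpha, min_width, rng):
            breaks.append(lo + j)
            recurse(lo, lo + j)
            recurse(lo + j, hi)

    recurse(0, x.size)
    return sorted(breaks)


def segment_profile(bins: pd.DataFrame, alpha: float = 0.01,
                    min_width: int = 3, n_perm: int = 1000, seed: int = 0,
                    sample_id: str = "sample",
                    reference_id: str | None = None) -> SegmentedProfile:
    """Segment binned log2 ratios chromosome by chromosome.

    Parameters
    ----------
    bins : DataFrame with columns chromosome, start, end, log2_ratio
        (0-based half-open bins, sorted by position within chromosome).
    alpha : permutation significance threshold for accepting a change point.
    min_width : minimum segment width in bins.
    n_perm : permutations per candidate change point.
    seed : seed for the permutation stream (deterministic output).
    """
    bins = pd.DataFrame(bins)[BIN_COLUMNS]
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in bins.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        x = grp["log2_ratio"].to_numpy(dtype=float)
        if x.size == 0:
            warnings.warn(f"chromosome {chrom} has no bins; skipped",
                          stacklevel=2)
            continue
        if x.size < min_width:
            bps: list[int] = []
        else:
            bps = segment_series(x, alpha=alpha, min_width=min_width,
                                 n_perm=n_perm, rng=rng)
        bounds = [0, *bps, x.size]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append({
                "chromosome": chrom,
                "start": int(starts[a]),
                "end": int(ends[b - 1]),
                "mean_log2": float(x[a:b].mean()),
                "median_log2": float(np.median(x[a:b])),
                "n_bins": b - a,
            })
    return SegmentedProfile(sample_id=sample_id,
                            segments=pd.DataFrame(rows, columns=SEGMENT_COLUMNS),
                            reference_id=reference_id)


def reconstruct_bins(profile: SegmentedProfile, bins: pd.DataFrame) -> pd.DataFrame:
    """Piecewise-constant reconstruction of a bin table from segment means."""
    out = pd.DataFrame(bins)[BIN_COLUMNS].copy()
    values = np.full(len(out), np.nan)
    for _, seg in profile.segments.iterrows():
        mask = ((out["chromosome"] == seg["chromosome"])
                & (out["start"] >= seg["start"]) & (out["end"] <= seg["end"]))
        values[mask.to_numpy()] = seg["mean_log2"]
    out["log2_ratio"] = values
    return out


def call_arm_events(profile: SegmentedProfile, catalog,
                    log2_threshold: float = 0.2,
                    coverage_threshold: float = 0.75) -> pd.DataFrame:
    """Call per-arm gain/loss events from a segmented profile.

    An arm is called gained (lost) when segments with log2 ratio above
    ``log2_threshold`` (below its negative) cover more than
    ``coverage_threshold`` of the arm length; gains and losses on one arm do
    not sum.  ``altered_fraction`` reports the larger same-direction covered
    fraction.

    Returns a DataFrame with columns sample_id, chromosome, arm,
    altered_fraction, direction ('gain'/'loss'/'neutral').
    """
    segs = profile.segments
    rows = []
    for _, arm_row in catalog.arms.iterrows():
        chrom, arm = arm_row["chromosome"], arm_row["arm"]
        a0, a1 = arm_row["start"], arm_row["end"]
        arm_len = a1 - a0
        on_chrom = segs[segs["chromosome"] == chrom]
        overlap = np.minimum(on_chrom["end"], a1) - np.maximum(on_chrom["start"], a0)
        overlap = np.maximum(overlap, 0)
        covered = float(overlap.sum())
        if covered <= 0:
            warnings.warn(
                f"arm {chrom}{arm} of sample {profile.sample_id} has no "
                "covered base pairs; reported neutral", stacklevel=2)
            rows.append({"sample_id": profile.sample_id, "chromosome": chrom,
                         "arm": arm, "altered_fraction": 0.0,
                         "direction": "neutral"})
            continue
        q = on_chrom["mean_log2"].to_numpy()
        gain_bp = float(overlap.to_numpy()[q > log2_threshold].sum())
        loss_bp = float(overlap.to_numpy()[q < -log2_threshold].sum())
        gain_frac, loss_frac = gain_bp / arm_len, loss_bp / arm_len
        if gain_frac > coverage_threshold:
            direction, frac = "gain", gain_frac
        elif loss_frac > coverage_threshold:
            direction, frac = "loss", loss_frac
        else:
            direction, frac = "neutral", max(gain_frac, loss_frac)
        rows.append({"sample_id": profile.sample_id, "chromosome": chrom,
                     "arm": arm, "altered_fraction": frac,
                     "direction": direction})
    return pd.DataFrame(rows)


def aneuploidy_score(calls: pd.DataFrame, autosomes_only: bool = True) -> pd.Series:
    """Aneuploidy score: number of arms called gained or lost, per sample."""
    calls = pd.DataFrame(calls)
    if autosomes_only:
        calls = calls[~calls["chromosome"].astype(str).isin(SEX_CHROMOSOMES)]
    altered = calls["direction"] != "neutral"
    return (calls.assign(altered=altered)
            .groupby("sample_id")["altered"].sum().astype(int))


def filter_wgd(records: pd.DataFrame, cutoff: float = 2.5) -> list[str]:
    """Samples retained after the whole-genome-doubling ploidy filter.

    Keeps samples with ploidy strictly below ``cutoff``; samples with a
    missing ploidy are dropped with a warning.
    """
    records = pd.DataFrame(records)
    missing = records["ploidy"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} sample(s) lack a ploidy value "
                      "and were dropped", stacklevel=2)
        records = records[~missing]
    keep = records.loc[records["ploidy"] < cutoff, "sample_id"]
    return list(keep)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def total_relative_dna(profile: SegmentedProfile, signed: bool = False) -> float:
    """Total relative DNA D = sum_i round(R_i) * L_i in base pairs.

    ``R_i = 2*(2^q_i - 1)`` approximates the copy-number difference of
    segment i versus the (assumed diploid) reference; it is rounded
    half-away-from-zero to the nearest integer.  ``signed=True`` nets gains
    against losses; the default sums absolute altered base pairs.  Autosomal
    segments only.
    """
    segs = profile.segments
    segs = segs[~segs["chromosome"].astype(str).isin(SEX_CHROMOSOMES)]
    q = segs["mean_log2"].to_numpy(dtype=float)
    length = (segs["end"] - segs["start"]).to_numpy(dtype=float)
    r = _round_half_away(2.0 * (np.exp2(q) - 1.0))
    if not signed:
        r = np.abs(r)
    return float(np.sum(r * length))
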