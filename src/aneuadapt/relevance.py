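"""Protein relevance score for aneuploidy-specific adaptation patterns.

Fold changes of each comparison are ranked across proteins and scaled to
[-1, 1], then grouped: G1 = unevolved polysomic line vs parental wild type,
G2 = evolved polysomic line vs its unevolved counterpart, G3 = evolved
disomic control vs its unevolved counterpart.  The score of a protein is

    S = | sum(G1 ranks) + sum(G2 ranks) - penalty |

where the penalty is the G3 rank of largest magnitude sharing the sign of
sum(G2) (0 if none, or if sum(G2) = 0), discounting changes attributable to
prolonged passaging alone.  Empirical p-values come from recomputing scores
on matrices whose protein labels are permuted independently within each
comparison column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rank_enrichment import scale_ranks

GROUPS = ("G1", "G2", "G3")


@dataclass
class GroupedRankSet:
    """Scaled fold-change ranks (proteins x comparisons) with group labels."""

    ranks: pd.DataFrame
    groups: pd.Series   # per comparison column: G1 / G2 / G3

    def __post_init__(self):
        self.groups = pd.Series(self.groups).loc[self.ranks.columns]
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown comparison groups: {unknown}")

    def columns_in(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])


def grouped_ranks_from_fold_changes(fold_changes: pd.DataFrame,
                                    groups: pd.Series) -> GroupedRankSet:
    """Rank/scale a protein x comparison fold-change matrix per comparison.

    Only proteins quantified in every comparison are retained (the count of
    excluded proteins is reported via a warning).
    """
    fc = pd.DataFrame(fold_changes)
    complete = fc.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} protein(s) missing from at least one "
                      "comparison excluded from relevance scoring",
                      stacklevel=2)
    ranks = scale_ranks(fc[complete])
    return GroupedRankSet(ranks=ranks, groups=groups)


def _scores_from_matrix(mat: np.ndarray, g1: np.ndarray, g2: np.ndarray,
                        g3: np.ndarray) -> np.ndarray:
    """Vectorized relevance scores; mat is proteins x comparisons."""
    sum_g1 = mat[:, g1].sum(axis=1) if g1.size else np.zeros(mat.shape[0])
    sum_g2 = mat[:, g2].sum(axis=1) if g2.size else np.zeros(mat.shape[0])
    penalty = np.zeros(mat.shape[0])
    if g3.size:
        r3 = mat[:, g3]
        sign = np.sign(sum_g2)[:, None]
        same_sign = np.sign(r3) == sign
        magnitudes = np.where(same_sign, np.abs(r3), 0.0)
        penalty = magnitudes.max(axis=1) * np.sign(sum_g2)
    return np.abs(sum_g1 + sum_g2 - penalty)


def _group_indices(grs: GroupedRankSet):
    cols = list(grs.ranks.columns)
    return tuple(np.array([cols.index(c) for c in grs.columns_in(g)],
                          dtype=int) for g in GROUPS)


def relevance_scores(grs: GroupedRankSet) -> pd.Series:
    """Per-protein relevance score S >= 0 (see module docstring)."""
    mat = grs.ranks.to_numpy(dtype=float)
    g1, g2, g3 = _group_indices(grs)
    return pd.Series(_scores_from_matrix(mat, g1, g2, g3),
                     index=grs.ranks.index, name="relevance_score")


def empirical_pvalues(scores: pd.Series, grs: GroupedRankSet,
                      n_perm: int = 100_000, seed: int = 0) -> pd.DataFrame:
    """Permutation-based empirical p-values for observed relevance scores.

    Null scores are obtained by permuting the protein labels independently
    within each comparison column and recomputing scores, pooling all
    proteins of every permuted matrix until at least ``n_perm`` null draws
    exist.  p = (1 + #{null >= observed}) / (1 + B): the add-one estimator,
    never 0.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 proteins")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: the attainable p floor "
                      "is coarse", stacklevel=2)
    rng = np.random.default_rng(seed)
    mat = grs.ranks.to_numpy(dtype=float)
    g1, g2, g3 = _group_indices(grs)
    n_prot = mat.shape[0]
    n_rounds = int(np.ceil(n_perm / n_prot))
    null_chunks = []
    for _ in range(n_rounds):
        perm = rng.permuted(mat, axis=0)   # independent shuffle per column
        null_chunks.append(_scores_from_matrix(perm, g1, g2, g3))
    null = np.concatenate(null_chunks)[:n_perm]
    null.sort()
    obs = scores.to_numpy(dtype=float)
    n_ge = null.size - np.searchsorted(null, obs - 1e-12, side="left")
    p = (1.0 + n_ge) / (1.0 + null.size)
    return pd.DataFrame({"score": obs, "p": p, "n_perm": null.size},
                        index=scores.index)
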