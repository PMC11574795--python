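"""Inter-subject similarity and typicality of connectivity patterns.

"Idiosyncrasy" — elevated inter-individual variability of functional network
organization — is quantified by correlating each participant's edge vector
(Fisher-z FC pattern, or reconfiguration pattern) with every other
participant's.  The pairwise Pearson correlations are Fisher-z transformed
into an inter-subject matrix, from which two per-subject scores derive:

* similarity — mean z-correlation with all *other members of the same group*;
* typicality — mean z-correlation with all members of a reference
  (typically-developing) group; reference members get the leave-one-out mean
  within their own group, which serves as the within-reference baseline the
  other group is compared against.

Group differences in either score are tested by permuting group labels:
the observed statistic is Cohen's d between the two groups' scores, the null
re-derives the scores from the *fixed* inter-subject matrix under shuffled
labels (pattern correlations are never recomputed), and the two-sided p is
(1 + #{|d_perm| >= |d_obs|}) / (B + 1).  When the number of distinct label
assignments is small the full enumeration is used instead of Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

from .connectivity import CLIP
from .exceptions import DegenerateInputError

#: switch from Monte Carlo to exhaustive label enumeration at or below this count
ENUMERATION_LIMIT = 20_000


@dataclass
class PermutationResult:
    """Observed Cohen's d, permutation p-value and the null's bookkeeping."""

    observed_d: float
    p: float
    B: int
    seed: int | None
    method: str  # "exact" (full enumeration) or "mc"


# ---------------------------------------------------------------------------
# inter-subject correlation matrix
# ---------------------------------------------------------------------------


def intersubject_correlation(edges: np.ndarray) -> np.ndarray:
    """n x n Fisher-z matrix of pairwise pattern correlations between subjects.

    ``edges`` is the n x E table of per-subject edge vectors.  The diagonal
    (self-correlation) is excluded as NaN.  Computed once per state; all
    permutation work reuses it.
    """
    edges = np.atleast_2d(np.asarray(edges, dtype=float))
    n, e = edges.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if e < 3:
        raise ValueError("need at least 3 edges")
    sd = edges.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateInputError(
            f"zero-variance connectivity pattern for subject index(es) {dead.tolist()}"
        )
    corr = np.corrcoef(edges)
    z = np.arctanh(np.clip(corr, -1 + CLIP, 1 - CLIP))
    z = 0.5 * (z + z.T)  # corrcoef is only symmetric to rounding
    np.fill_diagonal(z, np.nan)
    return z


# ---------------------------------------------------------------------------
# per-subject scores
# ---------------------------------------------------------------------------


def _as_binary_masks(labels, groups=None):
    labels = np.asarray(labels)
    if groups is None:
        groups = tuple(dict.fromkeys(labels.tolist()))
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, got {groups}")
    mask_a = labels == groups[0]
    mask_b = labels == groups[1]
    if not (mask_a | mask_b).all():
        raise ValueError("labels contain subjects outside the two groups")
    return mask_a, mask_b, groups


def similarity_scores(S: np.ndarray, labels) -> np.ndarray:
    """Within-group mean z-correlation per subject, excluding self.

    Defined only for groups of size >= 2.
    """
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    n = S.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length does not match matrix size")
    S0 = np.nan_to_num(S, nan=0.0)
    scores = np.empty(n)
    for g in dict.fromkeys(labels.tolist()):
        m = labels == g
        ng = int(m.sum())
        if ng < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        scores[m] = S0[np.ix_(m, m)].sum(axis=1) / (ng - 1)
    return scores


def typicality_scores(S: np.ndarray, labels, reference_group="TD") -> np.ndarray:
    """Mean z-correlation to the reference group per subject.

    Non-reference subjects average over all reference members; reference
    members get their leave-one-out within-reference mean (the baseline).
    """
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    n = S.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length does not match matrix size")
    ref = labels == reference_group
    n_ref = int(ref.sum())
    if n_ref < 2:
        raise ValueError(f"reference group {reference_group!r} needs >= 2 subjects")
    S0 = np.nan_to_num(S, nan=0.0)
    to_ref = S0[:, ref].sum(axis=1)
    scores = to_ref / n_ref
    scores[ref] = to_ref[ref] / (n_ref - 1)
    return scores


# ---------------------------------------------------------------------------
# effect size
# ---------------------------------------------------------------------------


def cohens_d(x, y) -> float:
    """Cohen's d with the pooled-SD (n_x + n_y - 2) denominator."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("Cohen's d requires at least 2 observations per group")
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    diff = x.mean() - y.mean()
    if pooled_var == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled_var))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def _d_for_masks(S0: np.ndarray, G: np.ndarray, n_a: int, n_b: int, metric: str):
    """Cohen's d per column of the boolean membership matrix G (m x B).

    G[:, j] marks group-A members in assignment j; scores are re-derived from
    the fixed matrix S0 (diagonal zeroed) for every assignment.
    """
    rowsums = S0.sum(axis=1, keepdims=True)
    SA = S0 @ G  # sum of z to A-members (self excluded via zero diagonal)
    SB = rowsums - SA
    if metric == "similarity":
        scores = np.where(G, SA / (n_a - 1), SB / (n_b - 1))
    elif metric == "typicality":
        # B is the reference: LOO within B for its members, mean-to-B otherwise
        scores = np.where(G, SB / n_b, SB / np.maximum(n_b - 1, 1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    sum_a = (scores * G).sum(axis=0)
    sum_b = (scores * ~G).sum(axis=0)
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    sq_a = (scores**2 * G).sum(axis=0)
    sq_b = (scores**2 * ~G).sum(axis=0)
    var_a = (sq_a - n_a * mean_a**2) / (n_a - 1)
    var_b = (sq_b - n_b * mean_b**2) / (n_b - 1)
    pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
    pooled = np.clip(pooled, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mean_a - mean_b) / np.sqrt(pooled)
    return np.where(pooled == 0, 0.0, d)


def permutation_group_test(
    S: np.ndarray,
    labels,
    metric: str = "similarity",
    B: int = 10_000,
    seed: int | np.random.SeedSequence | None = None,
    groups: tuple | None = None,
    enumeration_limit: int = ENUMERATION_LIMIT,
) -> PermutationResult:
    """Label-permutation test of a group difference in similarity/typicality.

    ``groups=(a, b)`` fixes the contrast direction (d > 0 means a > b); for
    ``metric="typicality"`` group b is the reference.  Group sizes are
    preserved under permutation, so every null assignment keeps both groups
    at size >= 2.  If the number of distinct assignments C(n, n_a) does not
    exceed ``enumeration_limit`` the exact null is enumerated; otherwise B
    Monte-Carlo draws are used and the p-value honours the +1 convention
    (p >= 1/(B+1)).
    """
    if B < 99:
        raise ValueError("B must be >= 99")
    S = np.asarray(S, dtype=float)
    labels = np.asarray(labels)
    mask_a, mask_b, groups = _as_binary_masks(labels, groups)
    keep = mask_a | mask_b
    S_sub = S[np.ix_(keep, keep)]
    in_a = mask_a[keep]
    m = S_sub.shape[0]
    n_a = int(in_a.sum())
    n_b = m - n_a
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need >= 2 subjects")
    S0 = np.nan_to_num(S_sub, nan=0.0)

    d_obs = float(_d_for_masks(S0, in_a[:, None], n_a, n_b, metric)[0])

    total = comb(m, n_a)
    seed_int = None
    if total <= enumeration_limit:
        G = np.zeros((m, total), dtype=bool)
        for j, idx in enumerate(combinations(range(m), n_a)):
            G[list(idx), j] = True
        d_null = _d_for_masks(S0, G, n_a, n_b, metric)
        hits = int(np.sum(np.abs(d_null) >= abs(d_obs) - 1e-12))
        p = hits / total
        return PermutationResult(
            observed_d=d_obs, p=float(p), B=total, seed=None, method="exact"
        )

    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
    else:
        seed_int = seed
        rng = np.random.default_rng(seed)
    keys = rng.random((m, B))
    order = np.argsort(keys, axis=0)
    G = order < n_a  # each column: uniformly random subset of size n_a
    d_null = _d_for_masks(S0, G, n_a, n_b, metric)
    hits = int(np.sum(np.abs(d_null) >= abs(d_obs) - 1e-12))
    p = (1 + hits) / (B + 1)
    return PermutationResult(
        observed_d=d_obs, p=float(p), B=B, seed=seed_int, method="mc"
    )
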