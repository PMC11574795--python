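"""Group-level statistics: edge-wise tests, FDR, distribution tests, subgrouping.

Edge-wise group contrasts use independent-samples t-tests over the 120-edge
family with Benjamini-Hochberg false-discovery-rate correction.  Whole-
distribution contrasts compare the group-averaged edge values of two samples
with the Wilcoxon/Mann-Whitney rank-sum test (reported as a signed z) and the
two-sample Kolmogorov-Smirnov test.  Note the distribution tests treat the E
group-averaged edges as exchangeable observations even though edges of one
connectome are dependent; this mirrors the analysis convention being
reproduced and is not a statistical endorsement.

Participants are split by task performance: autistic participants at or above
the accuracy cutoff (default 90%) form the typically-performing subgroup
(TP-ASD), those below it the lower-performing subgroup (LP-ASD); typically-
developing participants below the cutoff are excluded from the TD comparison
subgroup (TDs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import SubjectRecord

#: switch to the exact rank-sum null when the pooled sample is this small (no ties)
EXACT_RANKSUM_MAX_N = 10

#: p-values are floored at the smallest positive normal float so underflowed
#: asymptotic tails stay inside (0, 1] and remain valid FDR inputs
_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class DistributionComparison:
    """Rank-sum and Kolmogorov-Smirnov comparison of two samples.

    ``ranksum_z`` is positive when x tends to be larger than y.
    """

    ranksum_z: float
    ranksum_p: float
    ks_D: float
    ks_p: float
    n_x: int
    n_y: int


# ---------------------------------------------------------------------------
# multiple-comparison correction
# ---------------------------------------------------------------------------


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and reject flags.

    Returns ``(p_adjusted, reject)`` with ``reject[i] = p_adjusted[i] < q``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if not np.all(np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    _, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj < q


# ---------------------------------------------------------------------------
# edge-wise tests
# ---------------------------------------------------------------------------


def edge_ttest(
    edges_a: np.ndarray,
    edges_b: np.ndarray,
    q: float = 0.05,
    equal_var: bool = True,
    edge_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sided independent-samples t-test per edge, sign convention A - B.

    Pooled-variance Student's t by default (Welch via ``equal_var=False``).
    The raw p-values of the E-edge family are BH-adjusted at rate ``q``.
    Edges with zero pooled variance yield no defined statistic; they are
    flagged ``degenerate``, excluded from the FDR family and warned about.
    """
    a = np.atleast_2d(np.asarray(edges_a, dtype=float))
    b = np.atleast_2d(np.asarray(edges_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups have different numbers of edges")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} edge(s) with zero pooled variance were "
            "excluded from the FDR family",
            stacklevel=2,
        )
    p_adj = np.full_like(p, np.nan)
    reject = np.zeros(p.size, dtype=bool)
    ok = ~degenerate
    if ok.any():
        p_adj[ok], reject[ok] = bh_fdr(p[ok], q=q)
    out = pd.DataFrame(
        {
            "edge": np.arange(p.size),
            "t": t,
            "p": np.where(degenerate, np.nan, p),
            "p_adj": p_adj,
            "reject": reject,
            "degenerate": degenerate,
        }
    )
    if edge_labels is not None:
        out.insert(1, "edge_label", edge_labels)
    return out


def group_edge_means(edges: np.ndarray) -> np.ndarray:
    """Per-edge mean across the subjects (rows) of one group."""
    edges = np.atleast_2d(np.asarray(edges, dtype=float))
    if edges.shape[0] < 1:
        raise ValueError("need at least one subject")
    return edges.mean(axis=0)


# ---------------------------------------------------------------------------
# distribution tests
# ---------------------------------------------------------------------------


def ranksum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Returns ``(z, p)``.  z is the tie- and continuity-corrected normal
    approximation of the Mann-Whitney U statistic, positive when x tends to
    be larger than y.  For pooled samples of at most 10 observations with no
    ties, p comes from the exact permutation null instead of the normal
    approximation (the z statistic is still reported).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    nx, ny = x.size, y.size
    n = nx + ny
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = ranks[:nx].sum() - nx * (nx + 1) / 2.0  # Mann-Whitney U of x
    mu = nx * ny / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3) - counts).sum())
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:  # every pooled value identical
        return 0.0, 1.0
    diff = u - mu
    if diff == 0:
        z = 0.0
    else:
        z = (diff - 0.5 * math.copysign(1.0, diff)) / math.sqrt(sigma2)
    if n <= EXACT_RANKSUM_MAX_N and tie_term == 0:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        )
    else:
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(z), float(max(p, _P_FLOOR))


def ks_test(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov sup-distance D and asymptotic two-sided p."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(1.0, max(res.pvalue, _P_FLOOR)))


def compare_distributions(x, y) -> DistributionComparison:
    """Rank-sum + KS comparison of two samples (z positive when x is larger)."""
    z, p = ranksum_test(x, y)
    d, kp = ks_test(x, y)
    return DistributionComparison(
        ranksum_z=z, ranksum_p=p, ks_D=d, ks_p=kp, n_x=len(x), n_y=len(y)
    )


# ---------------------------------------------------------------------------
# performance subgrouping
# ---------------------------------------------------------------------------


def composite_accuracy(rec: SubjectRecord) -> float:
    """Mean of single-word and abstract-word accuracies; NaN if either is missing."""
    return (rec.acc_sw + rec.acc_aw) / 2.0


def assign_subgroups(
    records: list[SubjectRecord], threshold: float = 0.90
) -> pd.DataFrame:
    """Split the cohort by composite task accuracy at ``threshold``.

    ASD subjects at or above the cutoff become TP-ASD, below it LP-ASD
    (together a partition of the ASD sample).  TD subjects below the cutoff
    are excluded from the TD comparison subgroup; the rest form TDs.  The
    boundary value counts as typical-performing.  Records with missing
    accuracy stay "unassigned" with a warning.  Updates ``rec.subgroup``
    in place and returns a per-subject table.
    """
    rows = []
    for rec in records:
        acc = composite_accuracy(rec)
        if math.isnan(acc):
            label = "unassigned"
            warnings.warn(
                f"subject {rec.subject_id}: composite accuracy unavailable; "
                "left unassigned",
                stacklevel=2,
            )
        elif rec.group == "ASD":
            label = "TP-ASD" if acc >= threshold else "LP-ASD"
        else:
            label = "TDs" if acc >= threshold else "excluded"
        rec.subgroup = label
        rows.append(
            {"subject_id": rec.subject_id, "composite_accuracy": acc, "subgroup": label}
        )
    return pd.DataFrame(rows)
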