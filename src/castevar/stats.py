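"""Between-group comparisons over per-library measurements.

Kruskal-Wallis with Dunn's post-hoc for SNV counts; one-way ANOVA with
Tukey's HSD for ts/tv and dN/dS.  Groups are castes or populations with,
typically, three libraries each; no minimum-n refusal is made beyond the
mathematical contracts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "PairwiseComparison", "kruskal_wallis", "dunn_posthoc",
           "anova_oneway", "tukey_hsd"]

_ADJUSTMENTS = {"none": None, "bonferroni": "bonferroni", "holm": "holm",
                "fdr_bh": "fdr_bh", "bh": "fdr_bh"}


@dataclass(frozen=True)
class PairwiseComparison:
    label_a: str
    label_b: str
    estimate: float  # z statistic (Dunn) or mean difference a - b (Tukey)
    p_raw: float
    p_adj: float


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: int | tuple[int, int] | None
    p_value: float | None
    pairwise: list[PairwiseComparison] | None = None


def _check_groups(groups: Mapping[str, Sequence[float]], min_groups: int = 2):
    if len(groups) < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {len(groups)}")
    for label, values in groups.items():
        if len(values) == 0:
            raise ValueError(f"group {label!r} is empty")


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups."""
    _check_groups(groups)
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    n_total = sum(len(a) for a in arrays)
    if n_total < 3:
        raise ValueError(f"need at least 3 observations in total, got {n_total}")
    df = len(groups) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # All values tied: tie correction removes the entire rank variance.
        return TestResult("kruskal_wallis", 0.0, df, 1.0)
    h, p = scipy.stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(h), df, float(p))


def dunn_posthoc(groups: Mapping[str, Sequence[float]], adjustment: str = "fdr_bh") -> TestResult:
    """Dunn's pairwise post-hoc on mean ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with the
    tie term T = sum(t^3 - t) / (12(N - 1)).  Two-sided normal p-values,
    adjusted by the configured method (Benjamini-Hochberg by default).
    """
    _check_groups(groups)
    if adjustment not in _ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = scipy.stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for lab, arr in zip(labels, arrays):
        mean_ranks[lab] = float(np.mean(ranks[start : start + len(arr)]))
        start += len(arr)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1)) \
        if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    zs, p_raws, pairs = [], [], []
    for a, b in combinations(labels, 2):
        n_a, n_b = len(groups[a]), len(groups[b])
        denom_sq = var_base * (1.0 / n_a + 1.0 / n_b)
        if denom_sq <= 0:
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / math.sqrt(denom_sq)
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        zs.append(z)
        p_raws.append(min(p, 1.0))
        pairs.append((a, b))

    method = _ADJUSTMENTS[adjustment]
    if method is None:
        p_adj = list(p_raws)
    else:
        p_adj = list(multipletests(p_raws, method=method)[1])
    pairwise = [
        PairwiseComparison(a, b, z, pr, pa)
        for (a, b), z, pr, pa in zip(pairs, zs, p_raws, p_adj)
    ]
    max_abs = max(abs(z) for z in zs)
    return TestResult("dunn", max_abs, None, None, pairwise)


def _sums_of_squares(arrays: list[np.ndarray]) -> tuple[float, float, int, int]:
    grand = np.concatenate(arrays)
    gm = grand.mean()
    ssb = sum(len(a) * (a.mean() - gm) ** 2 for a in arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    return float(ssb), float(ssw), len(arrays) - 1, len(grand) - len(arrays)


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Classical one-way ANOVA (between/within decomposition).

    Degenerate cases are reported as values rather than errors: zero
    within-group variance with nonzero between gives F = inf, p = 0; a fully
    constant input gives an undefined (NaN) F with p = 1.
    """
    _check_groups(groups)
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    ssb, ssw, dfb, dfw = _sums_of_squares(arrays)
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult("anova", float("nan"), (dfb, dfw), 1.0)
        return TestResult("anova", float("inf"), (dfb, dfw), 0.0)
    if dfw <= 0:
        raise ValueError("each group needs >= 2 values for a finite F")
    f = (ssb / dfb) / (ssw / dfw)
    p = float(scipy.stats.f.sf(f, dfb, dfw))
    return TestResult("anova", float(f), (dfb, dfw), p)


def tukey_hsd(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """All pairwise mean differences with studentized-range adjusted p."""
    _check_groups(groups)
    labels = list(groups)
    arrays = [np.asarray(groups[lab], dtype=float) for lab in labels]
    ssb, ssw, dfb, dfw = _sums_of_squares(arrays)
    pairwise: list[PairwiseComparison] = []
    if ssw == 0.0:
        # No within-group variance: equal means are indistinguishable (p=1),
        # unequal means are separated with certainty (p=0).
        for i, j in combinations(range(len(labels)), 2):
            diff = float(arrays[i].mean() - arrays[j].mean())
            p = 1.0 if diff == 0.0 else 0.0
            pairwise.append(PairwiseComparison(labels[i], labels[j], diff, p, p))
        max_abs = max(abs(c.estimate) for c in pairwise)
        return TestResult("tukey_hsd", max_abs, (dfb, dfw), None, pairwise)
    res = scipy.stats.tukey_hsd(*arrays)
    for i, j in combinations(range(len(labels)), 2):
        diff = float(res.statistic[i, j])
        p = float(res.pvalue[i, j])
        pairwise.append(PairwiseComparison(labels[i], labels[j], diff, p, p))
    max_abs = max(abs(c.estimate) for c in pairwise)
    return TestResult("tukey_hsd", max_abs, (dfb, dfw), None, pairwise)
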