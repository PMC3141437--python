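"""Phylogenetically independent contrasts and downstream rate/correlation tests.

Under Brownian motion, differences between sister lineages scaled by the
square root of their summed (corrected) branch lengths are independent
standard-normal draws, turning n tip values on a binary tree into n-1
independent data points. On top of the contrast table this module provides

* a two-sample Wilcoxon rank-sum test on contrast magnitudes between the two
  major clades (is the trait evolving faster in one clade?), exact by full
  enumeration for small samples, and
* correlation/regression through the origin of positivized contrast pairs
  (the standard way to relate two traits on a phylogeny).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError
from .trees import Phylogeny


@dataclass
class ContrastTable:
    """One standardized contrast per internal node of a binary tree."""

    table: pd.DataFrame  # node_id, raw, sd, contrast, clade

    def __len__(self) -> int:
        return len(self.table)

    def standardized(self, clade: Optional[str] = None) -> np.ndarray:
        t = self.table
        if clade is not None:
            t = t[t["clade"] == clade]
        return t["contrast"].to_numpy()


def pic(tree: Phylogeny, tip_values: dict,
        clade_map: Optional[dict] = None) -> ContrastTable:
    """Felsenstein's independent contrasts on a binary rooted tree.

    At each internal node with daughter working values ``x_a, x_b`` and
    corrected branch lengths ``v_a, v_b``: the raw contrast is ``x_a - x_b``,
    its standard deviation ``sqrt(v_a + v_b)``, the node's working value the
    precision-weighted mean of the daughters, and the node's own branch
    length is inflated by ``v_a * v_b / (v_a + v_b)``.

    ``clade_map`` (tip label -> clade label) assigns each contrast to a clade
    when every descendant tip of its node carries that clade label
    ("clade1"/"clade2"); contrasts spanning clades or touching outgroup or
    unassigned tips are labelled "excluded".
    """
    idx = tree.index()
    if not tree.is_binary():
        raise ValidationError(
            "independent contrasts require a fully binary tree; "
            "resolve polytomies first"
        )
    for v in range(idx.n_nodes):
        if idx.parent[v] >= 0 and (idx.length[v] is None or idx.length[v] <= 0):
            raise ValidationError(
                f"branch above {idx.labels[v]!r} must have positive length"
            )
    for label in idx.tip_index:
        if label not in tip_values:
            raise ValidationError(f"tip {label!r} has no value")
    work = np.zeros(idx.n_nodes)
    vlen = np.zeros(idx.n_nodes)
    tipsets = [None] * idx.n_nodes
    rows = []
    for v in range(idx.n_nodes):
        if idx.is_tip[v]:
            work[v] = tip_values[idx.labels[v]]
            vlen[v] = idx.length[v]
            tipsets[v] = {idx.labels[v]}
            continue
        a, b = idx.children[v]
        va, vb = vlen[a], vlen[b]
        raw = work[a] - work[b]
        sd = math.sqrt(va + vb)
        work[v] = (work[a] / va + work[b] / vb) / (1.0 / va + 1.0 / vb)
        extra = va * vb / (va + vb)
        vlen[v] = (idx.length[v] if idx.parent[v] >= 0 else 0.0) + extra
        tipsets[v] = tipsets[a] | tipsets[b]
        clade = "excluded"
        if clade_map is not None:
            labels = {clade_map.get(t, "unassigned") for t in tipsets[v]}
            if len(labels) == 1:
                only = labels.pop()
                if only in ("clade1", "clade2"):
                    clade = only
        rows.append({
            "node_id": idx.labels[v],
            "raw": raw,
            "sd": sd,
            "contrast": raw / sd,
            "clade": clade,
        })
    return ContrastTable(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# clade rate test
# ---------------------------------------------------------------------------

@dataclass
class RateTestResult:
    statistic: float  # rank sum of the first group
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal"


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-tailed exact rank-sum p by enumeration over all splits.

    Midranks handle ties; the null distribution of the group-1 rank sum is
    built by dynamic programming over which pooled observations fall in
    group 1, so the p-value is exact even with ties.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r2 = np.round(ranks * 2).astype(int)  # integers (midranks are .5 steps)
    n1 = len(x)
    obs = int(round(r2[:n1].sum()))
    max_sum = int(r2.sum())
    # dp[k][s] = number of size-k subsets of pooled items with doubled-rank sum s
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in r2:
        for k in range(n1, 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    dist = dp[n1]
    total = dist.sum()
    mean = (r2.sum() * n1) / len(pooled)
    dev = abs(obs - mean)
    sums = np.arange(max_sum + 1)
    p = dist[np.abs(sums - mean) >= dev - 1e-9].sum() / total
    return float(min(1.0, p))


def clade_rate_test(contrasts: ContrastTable,
                    alpha_groups=("clade1", "clade2"),
                    exact_max_n: int = 12) -> RateTestResult:
    """Wilcoxon rank-sum test on |standardized contrasts| between two clades.

    Contrasts labelled "excluded" (the basal between-clade contrast and any
    contrast spanning outgroup tips) are dropped. The p-value is exact (full
    enumeration, ties included) when both groups have at most ``exact_max_n``
    contrasts, otherwise a normal approximation with tie and continuity
    correction is used.
    """
    g1, g2 = alpha_groups
    x = np.abs(contrasts.standardized(g1))
    y = np.abs(contrasts.standardized(g2))
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("each clade needs at least one contrast")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        p = _exact_ranksum_p(x, y)
        method = "exact"
    else:
        n1, n2 = len(x), len(y)
        n = n1 + n2
        mean = n1 * (n + 1) / 2.0
        # tie correction to the rank-sum variance
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return RateTestResult(w, 1.0, n1, n2, "normal")
        dev = abs(w - mean)
        z = max(0.0, dev - 0.5) / math.sqrt(var)  # continuity correction
        p = 2.0 * stats.norm.sf(z)
        p = float(min(1.0, p))
        method = "normal"
    return RateTestResult(statistic=w, p_value=p,
                          n1=len(x), n2=len(y), method=method)


# ---------------------------------------------------------------------------
# regression through the origin
# ---------------------------------------------------------------------------

@dataclass
class OriginRegression:
    slope: float
    r: float
    p_value: float
    n: int


def positivize(x: np.ndarray, y: np.ndarray):
    """Flip the signs of each (x, y) pair so that x >= 0."""
    flip = np.where(x < 0, -1.0, 1.0)
    return x * flip, y * flip


def origin_regression(x_contrasts, y_contrasts) -> OriginRegression:
    """Correlation and regression through the origin of contrast pairs.

    Pairs are positivized first (sign flips leave the through-origin
    correlation invariant). slope = sum(xy)/sum(x^2);
    r = sum(xy)/sqrt(sum(x^2) sum(y^2)); the two-tailed p comes from
    t = r*sqrt((n-1)/(1-r^2)) on n-1 degrees of freedom (through-origin
    convention: no intercept is estimated, so only one df is lost).
    """
    x = np.asarray(x_contrasts, dtype=float)
    y = np.asarray(y_contrasts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y contrast vectors differ in length")
    n = len(x)
    if n < 3:
        raise ValidationError("need at least 3 contrast pairs")
    if np.allclose(x, 0):
        raise ValidationError("all x contrasts are zero")
    x, y = positivize(x, y)
    sxy = float(np.dot(x, y))
    sxx = float(np.dot(x, x))
    syy = float(np.dot(y, y))
    slope = sxy / sxx
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else 0.0
    if abs(r) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = r * math.sqrt((n - 1) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return OriginRegression(slope=slope, r=r, p_value=p, n=n)
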