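"""Phylogenetic independent contrasts and the category correlation screen.

Traits measured at the tips of a phylogeny are not independent data points;
the Felsenstein contrast transform turns n tip values into n-1 independent
contrasts under Brownian motion. Correlations between contrast sets are
computed through the origin, and categories of gene counts are screened
against proteome size with the R > 0.5, p < 0.05 rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trees import PhyloTree, TreeNode, root_to_tip_lengths

__all__ = [
    "ContrastSet",
    "CorrelationResult",
    "contrasts",
    "pic_correlation",
    "category_screen",
    "branch_length_correlation",
]


@dataclass
class ContrastSet:
    values: np.ndarray        # one standardized contrast per internal node
    node_variances: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def contrasts(tree: PhyloTree, trait: Mapping[str, float]) -> ContrastSet:
    """Standardized independent contrasts for a rooted binary tree.

    At each internal node the contrast is (x_L - x_R)/sqrt(v_L + v_R); the
    ancestral value is the variance-weighted average of the children and the
    node's own branch is lengthened by v_L*v_R/(v_L + v_R).
    """
    if not tree.rooted:
        raise ValueError("contrasts require a rooted tree")
    missing = set(tree.tip_labels) - set(trait)
    if missing:
        raise ValueError(f"trait missing for tips: {sorted(missing)[:5]}")

    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    out_c: list[float] = []
    out_v: list[float] = []
    for node in tree.postorder():
        if node.is_tip:
            values[id(node)] = float(trait[node.label])
            lengths[id(node)] = node.length
            continue
        if len(node.children) != 2:
            raise ValueError(
                "contrasts require a binary tree; resolve polytomies first "
                "(see trees.resolve_polytomies)"
            )
        left, right = node.children
        v_l = lengths[id(left)]
        v_r = lengths[id(right)]
        total = v_l + v_r
        if total <= 0:
            raise ValueError("zero combined branch length at an internal node")
        out_c.append((values[id(left)] - values[id(right)]) / np.sqrt(total))
        out_v.append(total)
        values[id(node)] = (v_r * values[id(left)] + v_l * values[id(right)]) / total
        lengths[id(node)] = node.length + v_l * v_r / total
    return ContrastSet(values=np.array(out_c), node_variances=np.array(out_v))


def pic_correlation(
    tree: PhyloTree, trait_x: Mapping[str, float], trait_y: Mapping[str, float]
) -> tuple[float, float]:
    """Correlation through the origin of the contrasts of two traits.

    R = Σ u_i w_i / sqrt(Σ u_i² Σ w_i²); the two-sided p-value comes from
    t = R sqrt((m-1)/(1-R²)) on m-1 degrees of freedom, m = contrast count.
    Returns (nan, nan) when either contrast set is identically zero.
    """
    u = contrasts(tree, trait_x).values
    w = contrasts(tree, trait_y).values
    m = len(u)
    if m < 3:
        raise ValueError("need at least 3 contrasts for a correlation test")
    # constant traits have no variation to correlate (exact zero contrasts up
    # to floating-point residue of the weighted-average recursion)
    if np.ptp(list(trait_x.values())) == 0 or np.ptp(list(trait_y.values())) == 0:
        return float("nan"), float("nan")
    su, sw = np.sum(u * u), np.sum(w * w)
    if su == 0 or sw == 0:
        return float("nan"), float("nan")
    r = float(np.sum(u * w) / np.sqrt(su * sw))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((m - 1) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=m - 1))
    return r, p


@dataclass
class CorrelationResult:
    category: str
    r: float
    p: float
    n_contrasts: int
    significant: bool
    slope_reduction: float | None = None
    degenerate: bool = False


def _slope_reduction(
    counts: Mapping[str, float], sizes: Mapping[str, float]
) -> float | None:
    """Percent drop in OLS-fitted count from the largest to smallest proteome.

    The best-fit line is the ordinary tip-level regression of category count
    on proteome size (our construction; no formula is standard here).
    """
    species = sorted(sizes)
    x = np.array([sizes[s] for s in species], dtype=float)
    y = np.array([counts.get(s, 0) for s in species], dtype=float)
    if np.ptp(x) == 0:
        return None
    slope, intercept = np.polyfit(x, y, 1)
    top = slope * x.max() + intercept
    bottom = slope * x.min() + intercept
    if top == 0:
        return None
    return float(100.0 * (top - bottom) / top)


def category_screen(
    tree: PhyloTree,
    category_counts: pd.DataFrame,
    proteome_sizes: Mapping[str, float],
    r_threshold: float = 0.5,
    alpha: float = 0.05,
    fdr: bool = False,
) -> list[CorrelationResult]:
    """Screen every category's gene counts against proteome size, PIC-corrected.

    ``category_counts`` is species x category. A category is flagged
    significant when R > r_threshold and p < alpha (raw p by default; pass
    ``fdr=True`` for Benjamini-Hochberg adjusted p). Categories with constant
    counts yield undefined R and are reported degenerate, non-significant.
    """
    sizes = dict(proteome_sizes)
    results: list[CorrelationResult] = []
    for cat in category_counts.columns:
        counts = category_counts[cat].to_dict()
        r, p = pic_correlation(tree, counts, sizes)
        degenerate = bool(np.isnan(r))
        results.append(
            CorrelationResult(
                category=cat,
                r=r,
                p=p,
                n_contrasts=tree.n_tips - 1,
                significant=False,
                slope_reduction=_slope_reduction(counts, sizes),
                degenerate=degenerate,
            )
        )
    ps = np.array([res.p for res in results])
    if fdr:
        valid = ~np.isnan(ps)
        adj = np.full_like(ps, np.nan)
        if valid.any():
            adj[valid] = stats.false_discovery_control(ps[valid])
        ps = adj
    for res, p_eff in zip(results, ps):
        res.significant = (
            not res.degenerate and res.r > r_threshold and p_eff < alpha
        )
    return results


def branch_length_correlation(
    tree: PhyloTree, proteome_sizes: Mapping[str, float]
) -> CorrelationResult:
    """PIC correlation between root-to-tip branch length and proteome size."""
    lengths = root_to_tip_lengths(tree)
    r, p = pic_correlation(tree, lengths, dict(proteome_sizes))
    degenerate = bool(np.isnan(r))
    return CorrelationResult(
        category="root_to_tip_length",
        r=r,
        p=p,
        n_contrasts=tree.n_tips - 1,
        significant=not degenerate and r > 0.5 and p < 0.05,
        degenerate=degenerate,
    )
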