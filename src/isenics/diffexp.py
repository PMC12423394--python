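"""Differential expression between senescence groups, gene-set overlap
tests, and generic nonparametric group comparisons.

The DE engine contrasts high- vs low-ICSS units (medium units are dropped
before testing, mirroring their low score variance).  Fold changes are
linear-scale ratios of group means with a pseudocount; p-values come from
Welch's t-test on log2(x+1) values; FDR control is Benjamini-Hochberg.
Significance cuts are context presets:

=============  =========  =====================
context        p cut      fold-change cut
=============  =========  =====================
bulk           p < 0.01   FC > 2 or FC < 1/2
immune_cell    p < 0.01   FC > 1.2 or FC < 1/1.2
immunotherapy  p <= 0.05  FC > 2 or FC < 1/2
=============  =========  =====================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import GroupAssignment
from .errors import GroupSizeError, ValidationError
from .io import ExpressionMatrix, GeneList

__all__ = [
    "DeGene",
    "OverlapTest",
    "CONTEXT_CUTS",
    "differential_expression",
    "de_table",
    "fisher_overlap",
    "group_difference_test",
    "bh_adjust",
]

# context -> (p cut, linear FC cut, p comparison is strict "<")
CONTEXT_CUTS: dict[str, tuple[float, float, bool]] = {
    "bulk": (0.01, 2.0, True),
    "immune_cell": (0.01, 1.2, True),
    "immunotherapy": (0.05, 2.0, False),
}


@dataclass
class DeGene:
    gene: str
    log2fc: float
    fold_change: float
    p_value: float
    q_value: float
    significant: bool
    context: str


@dataclass
class OverlapTest:
    """2x2 overlap table with Fisher's exact test.

    ``table`` rows are membership in set A, columns membership in set B:
    [[in both, A only], [B only, neither]].  ``odds_ratio`` is the sample
    odds ratio, +inf when a zero cell makes it so.
    """

    table: np.ndarray
    odds_ratio: float
    p_value: float
    universe_size: int


def differential_expression(
    matrix: ExpressionMatrix,
    groups: GroupAssignment,
    context: str = "bulk",
    pseudocount: float = 1.0,
) -> list[DeGene]:
    """Per-gene high-vs-low differential expression.

    fold_change = (mean_high + pseudocount) / (mean_low + pseudocount) on the
    linear scale; p from Welch's t on log2(x+1); q by Benjamini-Hochberg;
    significance by the ``context`` cuts.  A gene with no variance in either
    group (e.g. all-zero) gets FC from the means and p = 1.
    """
    if context not in CONTEXT_CUTS:
        raise ValidationError(f"unknown context {context!r}; expected {sorted(CONTEXT_CUTS)}")
    label_map = groups.as_dict()
    unit_pos = {u: i for i, u in enumerate(matrix.unit_ids)}
    high = [unit_pos[u] for u in groups.unit_ids if label_map[u] == "high" and u in unit_pos]
    low = [unit_pos[u] for u in groups.unit_ids if label_map[u] == "low" and u in unit_pos]
    if len(high) < 3 or len(low) < 3:
        raise GroupSizeError(
            f"need >= 3 units per group; got {len(high)} high, {len(low)} low"
        )
    linear = matrix.values if matrix.scale != "log1p_tpm" else np.expm1(matrix.values)
    logx = np.log2(linear + 1.0)
    xh, xl = logx[:, high], logx[:, low]
    mean_h = linear[:, high].mean(axis=1)
    mean_l = linear[:, low].mean(axis=1)
    fc = (mean_h + pseudocount) / (mean_l + pseudocount)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # constant genes are an expected, handled case (p set to 1 below)
        _warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_ind(xh, xl, axis=1, equal_var=False)
        p = np.asarray(t_res.pvalue, dtype=float)
    p = np.where(np.isfinite(p), p, 1.0)
    q = bh_adjust(p)
    p_cut, fc_cut, strict = CONTEXT_CUTS[context]
    p_ok = p < p_cut if strict else p <= p_cut
    fc_ok = (fc > fc_cut) | (fc < 1.0 / fc_cut)
    sig = p_ok & fc_ok
    return [
        DeGene(g, float(np.log2(fc[i])), float(fc[i]), float(p[i]), float(q[i]),
               bool(sig[i]), context)
        for i, g in enumerate(matrix.gene_ids)
    ]


def de_table(degenes: list[DeGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [d.gene for d in degenes],
            "log2fc": [d.log2fc for d in degenes],
            "fold_change": [d.fold_change for d in degenes],
            "p": [d.p_value for d in degenes],
            "q": [d.q_value for d in degenes],
            "significant": [d.significant for d in degenes],
        }
    )


def fisher_overlap(set_a: GeneList, set_b: GeneList, universe: GeneList) -> OverlapTest:
    """Two-sided Fisher's exact test for the overlap of two gene sets.

    Both sets must be subsets of the universe.  The two-sided p sums
    hypergeometric probabilities of tables at most as probable as the
    observed one.
    """
    uni = universe.genes
    for name, s in (("set_a", set_a), ("set_b", set_b)):
        extra = s.genes - uni
        if extra:
            raise ValidationError(f"{name} not a subset of universe: {sorted(extra)[:10]}")
    both = len(set_a.genes & set_b.genes)
    a_only = len(set_a.genes) - both
    b_only = len(set_b.genes) - both
    neither = len(uni) - both - a_only - b_only
    table = np.array([[both, a_only], [b_only, neither]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if a_only * b_only == 0:
        odds = np.inf if both * neither > 0 else (0.0 if both == 0 and neither == 0 else np.nan)
        if np.isnan(odds):
            odds = np.inf
    else:
        odds = both * neither / (a_only * b_only)
    return OverlapTest(table, float(odds), float(p), len(uni))


def group_difference_test(values, labels) -> tuple[float, float]:
    """Rank-based comparison of >= 2 groups.

    Two groups: Wilcoxon rank-sum / Mann-Whitney U (exact for small
    tie-free samples, tie-corrected normal approximation otherwise).
    Three or more: Kruskal-Wallis with tie correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValidationError("values and labels must have equal length")
    uniq = list(dict.fromkeys(labels.tolist()))
    groups = [values[labels == u] for u in uniq]
    if len(groups) < 2:
        raise GroupSizeError("need >= 2 groups")
    small = [u for u, g in zip(uniq, groups) if len(g) < 2]
    if small:
        raise GroupSizeError(f"groups with < 2 values: {small}")
    if len(groups) == 2:
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method="auto")
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
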