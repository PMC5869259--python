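"""Differential expression between the two physiological states.

Fold change is the difference of normalized (log2-scale) state means,
post minus pre; significance is a two-sample pooled-variance t-test on
the per-animal normalized values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import NormalizedExpression

__all__ = [
    "fold_change",
    "test_gene",
    "build_de_table",
    "top_genes",
    "volcano_table",
]

#: -log10 cap used when a p-value underflows to exactly zero
P_FLOOR = 1e-300


def fold_change(mean_pre: float, mean_post: float) -> float:
    """FC = post-state mean minus pre-state mean (normalized scale)."""
    return mean_post - mean_pre


def test_gene(
    values_pre: np.ndarray, values_post: np.ndarray
) -> tuple[float, float, float]:
    """Pooled-variance two-sample t-test; returns (fc, t, two-sided p).

    Degenerate pooled variance: equal means give (0, 0, 1); unequal means
    give p = 0 with an infinite t and a warning.
    """
    pre = np.asarray(values_pre, float)
    post = np.asarray(values_post, float)
    if pre.size < 2 or post.size < 2:
        raise ValueError("need at least 2 values per state")
    n1, n2 = pre.size, post.size
    fc = fold_change(pre.mean(), post.mean())
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * pre.var(ddof=1) + (n2 - 1) * post.var(ddof=1)) / df
    if pooled <= 0.0:
        if fc == 0.0:
            return 0.0, 0.0, 1.0
        warnings.warn(
            "zero pooled variance with unequal means; reporting p = 0",
            RuntimeWarning,
        )
        return fc, float(np.sign(fc) * np.inf), 0.0
    t_stat = fc / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p_value = 2.0 * stats.t.sf(abs(t_stat), df)
    return float(fc), float(t_stat), float(p_value)


def build_de_table(
    norm: NormalizedExpression,
    p_threshold: float = 0.05,
    fc_top: float = 3.0,
    p_top: float = 0.01,
) -> pd.DataFrame:
    """Per-gene DE table over the normalized per-animal values.

    Columns: gene_id (index), mean_pre, mean_post, fc, t_stat, p_value,
    is_de (p < p_threshold), is_top (|fc| >= fc_top and p <= p_top),
    direction (up iff fc > 0).
    """
    if norm.values.shape[0] < 1:
        raise ValueError("no genes in normalized expression")
    pre_animals = norm.animals_in_state("pre")
    post_animals = norm.animals_in_state("post")
    pre = norm.values.loc[:, pre_animals].to_numpy()
    post = norm.values.loc[:, post_animals].to_numpy()
    rows = [test_gene(pre[i], post[i]) for i in range(pre.shape[0])]
    fc, t_stat, p_value = (np.array(v) for v in zip(*rows))
    table = pd.DataFrame(
        {
            "mean_pre": norm.state_means["pre"],
            "mean_post": norm.state_means["post"],
            "fc": fc,
            "t_stat": t_stat,
            "p_value": p_value,
        },
        index=norm.values.index,
    )
    table.index.name = "gene_id"
    table["is_de"] = table["p_value"] < p_threshold
    table["is_top"] = (table["fc"].abs() >= fc_top) & (table["p_value"] <= p_top)
    table["direction"] = np.where(table["fc"] > 0, "up", "down")
    return table


def top_genes(de_table: pd.DataFrame, fc_top: float = 3.0, p_top: float = 0.01) -> pd.DataFrame:
    """The |fc| >= fc_top and p <= p_top subset, sorted by fc descending."""
    mask = (de_table["fc"].abs() >= fc_top) & (de_table["p_value"] <= p_top)
    return de_table[mask].sort_values("fc", ascending=False)


def volcano_table(de_table: pd.DataFrame) -> pd.DataFrame:
    """fc vs -log10 p plotting table; p = 0 is capped at -log10(1e-300)."""
    if de_table.shape[0] == 0:
        raise ValueError("DE table is empty")
    p = de_table["p_value"].clip(lower=P_FLOOR)
    return pd.DataFrame(
        {
            "fc": de_table["fc"],
            "neg_log10_p": -np.log10(p),
            "is_de": de_table["is_de"],
        },
        index=de_table.index,
    )
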