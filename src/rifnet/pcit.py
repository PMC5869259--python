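"""PCIT co-expression network inference.

For every trio of nodes (x, y, z) the three first-order partial
correlations are computed and a per-trio tolerance ``eps`` is formed as
the mean of the ratios partial/direct over the trio's three edges (ratios
whose direct correlation is below a 1e-12 guard are excluded).  The edge
(x, y) is flagged as explained by z when::

    |r_xy| <= |eps * r_xz|  and  |r_xy| <= |eps * r_yz|

An edge survives only if no third node flags it.  The surviving edges,
weighted by their Pearson correlation, form the co-expression network.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .normalize import NormalizedExpression

__all__ = [
    "partial_correlation",
    "correlation_matrix",
    "pcit_prune",
    "build_network",
]

GUARD = 1e-12


def partial_correlation(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation of x and y given z."""
    for name, val in (("r_xy", r_xy), ("r_xz", r_xz), ("r_yz", r_yz)):
        if not -1.0 <= val <= 1.0:
            raise ValueError(f"{name}={val} outside [-1, 1]")
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 0.0:
        raise ValueError(
            "partial correlation undefined: |r_xz| or |r_yz| equals 1"
        )
    return (r_xy - r_xz * r_yz) / np.sqrt(denom_sq)


def correlation_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between the rows of ``values`` (nodes x samples)."""
    r = np.corrcoef(values.to_numpy(float))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=values.index, columns=values.index)


def _keep_mask(R: np.ndarray) -> np.ndarray:
    """Boolean upper-triangular-symmetric mask of surviving edges.

    Vectorized over node pairs for each conditioning node z: O(n^3) time,
    O(n^2) memory.
    """
    n = R.shape[0]
    absR = np.abs(R)
    keep = np.ones((n, n), dtype=bool)
    np.fill_diagonal(keep, False)
    small = absR < GUARD
    eye = np.eye(n, dtype=bool)

    for z in range(n):
        rz = R[:, z]
        with np.errstate(divide="ignore", invalid="ignore"):
            # A[x, y] = partial(x, y | z) / r_xy
            denom = np.sqrt(np.outer(1.0 - rz**2, 1.0 - rz**2))
            P = (R - np.outer(rz, rz)) / denom
            A = np.where(small | eye, np.nan, P / R)
            # S[c, x] = partial(x, z | c) / r_xz
            denom_cz = np.sqrt((1.0 - R**2) * (1.0 - rz**2)[:, None])
            Pcz = (rz[None, :] - R * rz[:, None]) / denom_cz
            undef_xz = np.abs(rz)[None, :] < GUARD
            S = np.where(undef_xz, np.nan, Pcz / rz[None, :])
        # invalidate entries whose pair involves the conditioner itself
        A[z, :] = np.nan
        A[:, z] = np.nan
        S[z, :] = np.nan  # conditioning on z for the (x, z) edge
        S[:, z] = np.nan  # the "pair" (z, z)
        np.fill_diagonal(S, np.nan)  # conditioner equal to x

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            eps = np.nanmean(np.stack([A, S.T, S]), axis=0)

        abs_eps = np.abs(eps)
        lim_x = abs_eps * np.abs(rz)[:, None]
        lim_y = abs_eps * np.abs(rz)[None, :]
        flag = (absR <= lim_x) & (absR <= lim_y)
        flag &= ~np.isnan(eps)
        flag[z, :] = False
        flag[:, z] = False
        np.fill_diagonal(flag, False)
        keep &= ~flag
    return keep


def pcit_prune(corr: pd.DataFrame) -> nx.Graph:
    """Apply the PCIT trio rule to a correlation matrix; returns the
    surviving network with correlation edge weights."""
    R = corr.to_numpy(float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    nodes = list(corr.index)
    n = len(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    if n < 3:
        warnings.warn(
            "fewer than 3 nodes: no trio exists, all pairs retained",
            RuntimeWarning,
        )
        for i in range(n):
            for j in range(i + 1, n):
                g.add_edge(nodes[i], nodes[j], weight=float(R[i, j]))
        return g
    keep = _keep_mask(R)
    ii, jj = np.nonzero(np.triu(keep, 1))
    for i, j in zip(ii, jj):
        g.add_edge(nodes[i], nodes[j], weight=float(R[i, j]))
    return g


def build_network(
    norm: NormalizedExpression,
    de_table: pd.DataFrame,
    rif_table: pd.DataFrame | None = None,
    extra_nodes: list[str] = (),
) -> nx.Graph:
    """PCIT network over DE genes, significant TFs and any extra nodes.

    Correlations are computed across all animals of the analysis tissue
    (both states pooled).  Node attributes: is_tf, is_de, degree.
    """
    de_ids = list(de_table.index[de_table["is_de"]]) if len(de_table) else []
    tf_ids = (
        list(rif_table.index[rif_table["significant"]]) if rif_table is not None else []
    )
    node_ids = sorted(set(de_ids) | set(tf_ids) | set(extra_nodes))
    if len(node_ids) < 3:
        raise ValueError(
            f"network needs at least 3 nodes; got {len(node_ids)} "
            "(DE genes + significant TFs + extra nodes)"
        )
    missing = [nid for nid in node_ids if nid not in norm.values.index]
    if missing:
        raise ValueError(f"node id(s) absent from normalized matrix: {missing[:5]}")
    corr = correlation_matrix(norm.values.loc[node_ids])
    g = pcit_prune(corr)
    de_set, tf_set = set(de_ids), set(tf_ids)
    for node in g.nodes:
        g.nodes[node]["is_tf"] = node in tf_set
        g.nodes[node]["is_de"] = node in de_set
        g.nodes[node]["degree"] = g.degree[node]
    return g
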