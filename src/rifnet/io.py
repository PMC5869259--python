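"""Readers and writers for the pipeline's tab-delimited formats.

All tables are UTF-8 TSV with mandatory headers; newline conventions
(LF/CRLF) are normalized on read and numeric parsing is
locale-independent (C locale via pandas).
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .normalize import CountMatrix, MixedModelFit, NormalizedExpression, SampleDesign

__all__ = [
    "read_counts",
    "read_design",
    "read_tf_list",
    "read_bundle",
    "write_normalized",
    "read_normalized",
    "write_fit_report",
    "write_de_table",
    "read_de_table",
    "write_rif_table",
    "read_rif_table",
    "write_network",
    "read_network",
    "write_trios",
]

FLOAT_FMT = "%.10g"


def _read_tsv(path: str, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    except OSError as exc:
        raise OSError(f"cannot read {path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return df


def read_design(path: str) -> SampleDesign:
    df = _read_tsv(path, SampleDesign.REQUIRED)
    return SampleDesign(table=df)


def read_counts(counts_path: str, design_path: str) -> CountMatrix:
    """Assemble a CountMatrix from the counts TSV (gene_id,
    exon_length_kb, one column per sample) and the design TSV (which
    carries mapped_reads_millions)."""
    df = _read_tsv(counts_path, ("gene_id", "exon_length_kb"))
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{counts_path}: duplicate gene id {dup!r}")
    df = df.set_index("gene_id")
    lengths = pd.to_numeric(df.pop("exon_length_kb"), errors="coerce")
    if lengths.isna().any():
        bad = lengths.index[lengths.isna()][0]
        raise ValueError(f"{counts_path}: non-numeric exon length for gene {bad!r}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise ValueError(
                f"{counts_path}: non-numeric count at gene {row!r}, sample {col!r}"
            )
        df[col] = vals
    design = _read_tsv(design_path, ("sample_id", "mapped_reads_millions"))
    depth = pd.to_numeric(
        design.set_index("sample_id")["mapped_reads_millions"], errors="coerce"
    )
    missing = [s for s in df.columns if s not in depth.index]
    if missing:
        raise ValueError(
            f"{design_path}: no mapped_reads_millions for sample(s) {missing[:5]}"
        )
    return CountMatrix(
        counts=df.astype(np.int64),
        exon_length_kb=lengths,
        mapped_reads_millions=depth.reindex(df.columns),
    )


def read_tf_list(path: str) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def read_bundle(directory: str) -> tuple[CountMatrix, SampleDesign, list[str]]:
    counts = os.path.join(directory, "counts.tsv")
    design = os.path.join(directory, "design.tsv")
    tf = os.path.join(directory, "tf_list.txt")
    return read_counts(counts, design), read_design(design), read_tf_list(tf)


def write_normalized(norm: NormalizedExpression, values_path: str, means_path: str) -> None:
    values = norm.values.copy()
    values.index.name = "gene_id"
    values.to_csv(values_path, sep="\t", float_format=FLOAT_FMT)
    means = norm.state_means.copy()
    means.columns = [f"mean_{c}" for c in means.columns]
    means.index.name = "gene_id"
    means.to_csv(means_path, sep="\t", float_format=FLOAT_FMT)


def read_normalized(
    values_path: str, design: SampleDesign, tissue: str
) -> NormalizedExpression:
    df = _read_tsv(values_path, ("gene_id",)).set_index("gene_id")
    states = design.animal_states().reindex(df.columns)
    if states.isna().any():
        bad = states.index[states.isna()][0]
        raise ValueError(f"{values_path}: column {bad!r} is not a known animal id")
    state_means = pd.DataFrame(
        {
            state: df.loc[:, states.index[states == state]].mean(axis=1)
            for state in ("pre", "post")
        }
    )
    return NormalizedExpression(
        values=df, animal_states=states, state_means=state_means, tissue=tissue
    )


def write_fit_report(fit: MixedModelFit, path: str) -> None:
    report = {
        "mu": float(fit.mu),
        "var_gene": float(fit.var_gene),
        "var_gapt": float(fit.var_gapt),
        "var_resid": float(fit.var_resid),
        "converged": bool(fit.converged),
        "n_iterations": int(fit.n_iterations),
        "n_genes": int(len(fit.gene_effects)),
        "n_libraries": int(len(fit.library_effects)),
        "n_cells": int(fit.interaction_effects.shape[1]),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(report, fh, sort_keys=True)


def write_de_table(de_table: pd.DataFrame, path: str) -> None:
    de_table.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_de_table(path: str) -> pd.DataFrame:
    df = _read_tsv(path, ("gene_id", "fc", "p_value", "is_de")).set_index("gene_id")
    for col in ("is_de", "is_top"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col] == "True"
    return df


def write_rif_table(rif_table: pd.DataFrame, path: str) -> None:
    rif_table.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_rif_table(path: str) -> pd.DataFrame:
    df = _read_tsv(path, ("tf_id", "rif1", "rif2", "significant")).set_index("tf_id")
    if df["significant"].dtype == object:
        df["significant"] = df["significant"] == "True"
    return df


def write_network(
    g: nx.Graph, edges_path: str, nodes_path: str, sif_path: str | None = None
) -> None:
    """Edge list TSV (x, y, weight), node attribute TSV and optional SIF."""
    edges = sorted((min(x, y), max(x, y), d.get("weight", 1.0)) for x, y, d in g.edges(data=True))
    pd.DataFrame(edges, columns=["x", "y", "weight"]).to_csv(
        edges_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    nodes = [
        {
            "node_id": n,
            "is_tf": bool(g.nodes[n].get("is_tf", False)),
            "is_de": bool(g.nodes[n].get("is_de", False)),
            "degree": g.degree[n],
        }
        for n in sorted(g.nodes)
    ]
    pd.DataFrame(nodes).to_csv(nodes_path, sep="\t", index=False)
    if sif_path is not None:
        with open(sif_path, "w", encoding="utf-8") as fh:
            for x, y, _ in edges:
                fh.write(f"{x}\tco\t{y}\n")


def read_network(edges_path: str, nodes_path: str) -> nx.Graph:
    edges = _read_tsv(edges_path, ("x", "y", "weight"))
    nodes = _read_tsv(nodes_path, ("node_id",))
    g = nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(
            row["node_id"],
            is_tf=row.get("is_tf", False) in (True, "True"),
            is_de=row.get("is_de", False) in (True, "True"),
        )
    for _, row in edges.iterrows():
        g.add_edge(row["x"], row["y"], weight=float(row["weight"]))
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree[n]
    return g


def write_trios(scores, path: str) -> None:
    rows = [
        {
            "tf_a": s.tf_triplet[0],
            "tf_b": s.tf_triplet[1],
            "tf_c": s.tf_triplet[2],
            "coverage": s.coverage,
            "redundancy": s.redundancy,
        }
        for s in scores
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
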