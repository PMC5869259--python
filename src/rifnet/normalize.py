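"""Expression normalization: RPKM, expressed-gene filtering, log2 transform
and mixed-model normalization with EM-REML variance components.

The observation model for a log2 expression value of gene ``j`` in sample
``s`` is::

    y[j, s] = mu + L[lib(s)] + G[j] + GAPT[j, cell(s)] + e[j, s]

where ``L`` is a fixed per-library effect (constrained to sum to zero),
``G`` a random per-gene effect, ``GAPT`` a random gene x (animal, state,
tissue) interaction and ``e`` the residual.  ``cell(s)`` denotes the
(animal, tissue) combination a library was prepared from; an animal's
physiological state is a function of the animal, so the cell index also
carries the state.  Normalized per-sample expression is the sum of the
``G`` and ``GAPT`` solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "MixedModelFit",
    "NormalizedExpression",
    "compute_rpkm",
    "filter_expressed",
    "log2_transform",
    "fit_mixed_model",
    "extract_normalized",
]

STATES = ("pre", "post")


def _cell_key(animal: str, tissue: str) -> str:
    return f"{animal}|{tissue}"


@dataclass
class CountMatrix:
    """Raw read counts per gene x sample, with per-gene exon lengths (kb)
    and per-sample totals of mapped reads (millions)."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    exon_length_kb: pd.Series  # indexed by gene id
    mapped_reads_millions: pd.Series  # indexed by sample id

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        lengths = self.exon_length_kb.reindex(idx)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][0]
            raise ValueError(f"missing exon length for gene {missing!r}")
        if (lengths <= 0).any():
            bad = lengths.index[lengths <= 0][0]
            raise ValueError(f"non-positive exon length for gene {bad!r}")
        depths = self.mapped_reads_millions.reindex(cols)
        if depths.isna().any():
            missing = depths.index[depths.isna()][0]
            raise ValueError(f"missing mapped-read total for sample {missing!r}")
        if (depths <= 0).any():
            bad = depths.index[depths <= 0][0]
            raise ValueError(f"non-positive mapped-read total for sample {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SampleDesign:
    """Sample annotation: animal, physiological state, tissue and library.

    ``table`` columns: sample_id, animal_id, state (pre/post), tissue,
    library_id; optionally mapped_reads_millions.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "animal_id", "state", "tissue", "library_id")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"design table missing required column {col!r}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id in design: {dup!r}")
        bad_states = set(self.table["state"]) - set(STATES)
        if bad_states:
            raise ValueError(f"unknown state value(s): {sorted(bad_states)}; expected {STATES}")
        if set(self.table["state"]) != set(STATES):
            raise ValueError("both 'pre' and 'post' states must be present")
        n_states = self.table.groupby("animal_id")["state"].nunique()
        if (n_states > 1).any():
            bad = n_states.index[n_states > 1][0]
            raise ValueError(f"animal {bad!r} maps to more than one state")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def animal_states(self) -> pd.Series:
        """state per animal, indexed by animal id."""
        return self.table.drop_duplicates("animal_id").set_index("animal_id")["state"]

    def cell_of_sample(self) -> pd.Series:
        t = self.table
        return pd.Series(
            [_cell_key(a, ti) for a, ti in zip(t["animal_id"], t["tissue"])],
            index=t["sample_id"].to_numpy(),
        )


def compute_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """RPKM[j, s] = counts[j, s] / (mapped reads in millions x exon kb)."""
    cm.validate()
    depth = cm.mapped_reads_millions.reindex(cm.counts.columns).to_numpy(float)
    length = cm.exon_length_kb.reindex(cm.counts.index).to_numpy(float)
    denom = np.outer(length, depth)
    return pd.DataFrame(
        cm.counts.to_numpy(float) / denom, index=cm.counts.index, columns=cm.counts.columns
    )


def filter_expressed(
    rpkm: pd.DataFrame, threshold: float = 0.2
) -> tuple[list[str], pd.DataFrame]:
    """Retain genes whose mean RPKM across samples is >= ``threshold``.

    Returns the retained gene ids and a per-gene report with the mean and
    the decision.  The boundary is inclusive.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = rpkm.mean(axis=1)
    expressed = means >= threshold
    report = pd.DataFrame({"mean_rpkm": means, "expressed": expressed})
    return list(rpkm.index[expressed]), report


def log2_transform(rpkm: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """y = log2(rpkm + offset); ``offset`` must be positive so zeros map to
    a finite value (log2(0 + 1) = 0 with the default)."""
    if offset <= 0:
        raise ValueError("offset must be > 0")
    values = np.asarray(rpkm, float)
    if (values < 0).any():
        raise ValueError("negative RPKM values are not allowed")
    out = np.log2(values + offset)
    if isinstance(rpkm, pd.DataFrame):
        return pd.DataFrame(out, index=rpkm.index, columns=rpkm.columns)
    return out


@dataclass
class MixedModelFit:
    mu: float
    library_effects: pd.Series  # indexed by library id, sums to zero
    gene_effects: pd.Series  # G solutions, indexed by gene id
    interaction_effects: pd.DataFrame  # GAPT solutions, genes x cells
    var_gene: float
    var_gapt: float
    var_resid: float
    converged: bool
    n_iterations: int
    cell_of_sample: pd.Series = field(repr=False)  # sample id -> cell key

    def fitted(self, design: SampleDesign) -> pd.DataFrame:
        """Fitted values mu + L + G + GAPT, genes x samples."""
        t = design.table
        cells = self.cell_of_sample
        lib = t.set_index("sample_id")["library_id"]
        samples = list(cells.index)
        fixed = self.mu + self.library_effects.reindex(lib.reindex(samples)).to_numpy()
        rand = (
            self.gene_effects.to_numpy()[:, None]
            + self.interaction_effects.loc[:, cells.reindex(samples)].to_numpy()
        )
        return pd.DataFrame(
            fixed[None, :] + rand, index=self.gene_effects.index, columns=samples
        )


def _validate_fit_inputs(y: pd.DataFrame, design: SampleDesign) -> None:
    if y.shape[0] < 2:
        raise ValueError("mixed model requires at least 2 genes")
    design.validate()
    if set(y.columns) != set(design.table["sample_id"]):
        raise ValueError("sample ids of expression matrix and design do not match")
    per_state = design.table.drop_duplicates("animal_id").groupby("state").size()
    if (per_state < 2).any() or len(per_state) < 2:
        raise ValueError("need at least 2 animals in each state")
    sizes = design.table.groupby("library_id").size()
    if (sizes < 1).any():
        raise ValueError("singular design: a library spans no samples")


def fit_mixed_model(
    y: pd.DataFrame,
    design: SampleDesign,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> MixedModelFit:
    """EM-REML fit of the library + gene + gene-x-cell mixed model.

    ``y`` is the log2 expression matrix (genes x samples).  Iterates EM
    updates of (var_gene, var_gapt, var_resid) to relative tolerance
    ``tol``; the fixed library effects are re-estimated by GLS at each
    iteration and the random-effect solutions are BLUPs at the converged
    variance components.
    """
    _validate_fit_inputs(y, design)
    t = design.table.set_index("sample_id").loc[list(y.columns)].reset_index()
    samples = list(y.columns)
    genes = list(y.index)
    Y = y.to_numpy(float)
    n_genes, n_samples = Y.shape

    libs = sorted(t["library_id"].unique())
    lib_idx = t["library_id"].map({l: i for i, l in enumerate(libs)}).to_numpy()
    cells = sorted({_cell_key(a, ti) for a, ti in zip(t["animal_id"], t["tissue"])})
    cell_map = {c: i for i, c in enumerate(cells)}
    cell_idx = np.array(
        [cell_map[_cell_key(a, ti)] for a, ti in zip(t["animal_id"], t["tissue"])]
    )
    n_cells = len(cells)
    n_libs = len(libs)

    # incidence matrices (samples x libraries / cells)
    X = np.zeros((n_samples, n_libs))
    X[np.arange(n_samples), lib_idx] = 1.0
    Zc = np.zeros((n_samples, n_cells))
    Zc[np.arange(n_samples), cell_idx] = 1.0
    W = np.hstack([np.ones((n_samples, 1)), Zc])  # per-gene random design [G | GAPT]
    saturated = n_libs == n_samples

    ybar = Y.mean(axis=0)  # per-sample mean over genes; carries mu + L

    # degenerate data: no residual variation at all
    total_var = float(np.var(Y - Y.mean()))
    if total_var < 1e-24:
        mu = float(Y.mean())
        return MixedModelFit(
            mu=mu,
            library_effects=pd.Series(0.0, index=pd.Index(libs, name="library_id")),
            gene_effects=pd.Series(0.0, index=pd.Index(genes, name="gene_id")),
            interaction_effects=pd.DataFrame(0.0, index=genes, columns=cells),
            var_gene=0.0,
            var_gapt=0.0,
            var_resid=0.0,
            converged=True,
            n_iterations=0,
            cell_of_sample=pd.Series(
                [cells[i] for i in cell_idx], index=np.asarray(samples, object)
            ),
        )

    v0 = total_var / 3.0
    vg, vi, ve = v0, v0, v0
    converged = False
    n_iter = 0
    floor = total_var * 1e-12

    for n_iter in range(1, max_iter + 1):
        # --- fixed effects by GLS on the per-gene-averaged data ---
        if saturated:
            m = ybar.copy()  # fitted per-sample fixed value equals the mean
        else:
            V0 = vg + vi * (Zc @ Zc.T) + ve * np.eye(n_samples)
            Vi = np.linalg.inv(V0)
            XtVi = X.T @ Vi
            m_lib = np.linalg.solve(XtVi @ X, XtVi @ ybar)
            m = X @ m_lib
        R = Y - m[None, :]

        # --- per-gene BLUPs (identical coefficient matrix for every gene) ---
        d_inv = np.concatenate([[1.0 / max(vg, floor)], np.full(n_cells, 1.0 / max(vi, floor))])
        M = (W.T @ W) / ve + np.diag(d_inv)
        Minv = np.linalg.inv(M)
        U = (R @ W) @ Minv.T / ve  # genes x (1 + n_cells)
        G = U[:, 0]
        GAPT = U[:, 1:]
        fitted_rand = U @ W.T
        resid = R - fitted_rand

        # Var(u | y) per gene is Minv in this scaling, so the EM trace
        # corrections enter without an extra residual-variance factor
        vg_new = (float(G @ G) + n_genes * Minv[0, 0]) / n_genes
        tr_cells = float(np.trace(Minv[1:, 1:]))
        vi_new = (float((GAPT * GAPT).sum()) + n_genes * tr_cells) / (n_genes * n_cells)
        ve_new = float((R * resid).sum()) / (n_genes * n_samples - n_libs)
        ve_new = max(ve_new, floor)

        denom = max(vg, floor) + max(vi, floor) + max(ve, floor)
        delta = (abs(vg_new - vg) + abs(vi_new - vi) + abs(ve_new - ve)) / denom
        vg, vi, ve = vg_new, vi_new, ve_new
        if delta < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"EM-REML did not converge after {max_iter} iterations "
            f"(last relative change {delta:.2e})",
            RuntimeWarning,
        )

    # final solutions at the converged components
    if saturated:
        m = ybar.copy()
    else:
        V0 = vg + vi * (Zc @ Zc.T) + ve * np.eye(n_samples)
        Vi = np.linalg.inv(V0)
        XtVi = X.T @ Vi
        m_lib = np.linalg.solve(XtVi @ X, XtVi @ ybar)
        m = X @ m_lib
    R = Y - m[None, :]
    d_inv = np.concatenate([[1.0 / max(vg, floor)], np.full(n_cells, 1.0 / max(vi, floor))])
    M = (W.T @ W) / ve + np.diag(d_inv)
    U = np.linalg.solve(M, (R @ W).T).T / ve
    G = U[:, 0]
    GAPT = U[:, 1:]

    # report mu + sum-to-zero library effects
    if saturated:
        lib_means = pd.Series(m, index=t["library_id"].to_numpy()).groupby(level=0).mean()
        lib_means = lib_means.reindex(libs).to_numpy()
    else:
        lib_means = m_lib
    mu = float(lib_means.mean())
    L = lib_means - mu

    return MixedModelFit(
        mu=mu,
        library_effects=pd.Series(L, index=pd.Index(libs, name="library_id")),
        gene_effects=pd.Series(G, index=pd.Index(genes, name="gene_id")),
        interaction_effects=pd.DataFrame(GAPT, index=genes, columns=cells),
        var_gene=float(vg),
        var_gapt=float(vi),
        var_resid=float(ve),
        converged=converged,
        n_iterations=n_iter,
        cell_of_sample=pd.Series(
            [cells[i] for i in cell_idx], index=np.asarray(samples, object)
        ),
    )


@dataclass
class NormalizedExpression:
    """Normalized per-animal expression (G + GAPT solutions) for one tissue
    plus per-state gene means."""

    values: pd.DataFrame  # genes x animals
    animal_states: pd.Series  # animal id -> state
    state_means: pd.DataFrame  # genes x ["pre", "post"]
    tissue: str

    def animals_in_state(self, state: str) -> list[str]:
        return list(self.animal_states.index[self.animal_states == state])


def extract_normalized(
    fit: MixedModelFit,
    design: SampleDesign,
    tissue_of_interest: str,
    include_mu: bool = True,
) -> NormalizedExpression:
    """Per-animal normalized values x[j, k] = G[j] + GAPT[j, cell(k, tissue)]
    for the selected tissue, with per-state means.

    With ``include_mu`` (default) the grand mean is added back so values
    sit on the abundance (log2) scale rather than centered at zero; state
    differences, tests and correlations are invariant to this shift, but
    the abundance-weighted regulator scores downstream are not.
    """
    tissues = design.tissues
    if tissue_of_interest not in tissues:
        raise ValueError(
            f"tissue {tissue_of_interest!r} not in design; available: {tissues}"
        )
    sub = design.table[design.table["tissue"] == tissue_of_interest]
    animals = sorted(sub["animal_id"].unique())
    cells = [_cell_key(a, tissue_of_interest) for a in animals]
    missing = [c for c in cells if c not in fit.interaction_effects.columns]
    if missing:
        raise ValueError(f"fit has no interaction solutions for cell(s) {missing}")
    values = fit.interaction_effects.loc[:, cells].to_numpy() + fit.gene_effects.to_numpy()[:, None]
    if include_mu:
        values = values + fit.mu
    values = pd.DataFrame(values, index=fit.gene_effects.index, columns=animals)
    states = design.animal_states().reindex(animals)
    state_means = pd.DataFrame(
        {
            state: values.loc[:, states.index[states == state]].mean(axis=1)
            for state in STATES
        }
    )
    return NormalizedExpression(
        values=values,
        animal_states=states,
        state_means=state_means,
        tissue=tissue_of_interest,
    )
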