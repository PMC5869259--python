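"""Regulatory impact factor (RIF) scoring of transcription factors.

For each TF *i* and DE gene *j*, with per-state mean expressions
``e1`` (pre) and ``e2`` (post), per-state Pearson correlations ``r1`` and
``r2``, ``a = (e1 + e2) / 2``, ``d = e2 - e1``, ``PIF = a * d`` and
differential wiring ``dw = r1 - r2``::

    RIF1_i = (1 / n_de) * sum_j PIF_j * dw_ij**2
    RIF2_i = (1 / n_de) * sum_j (e1_j * r1_ij)**2 - (e2_j * r2_ij)**2

Both scores are z-standardized across TFs; a TF is significant when
either |z| reaches the threshold (default 1.96).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import NormalizedExpression

__all__ = [
    "RIFInputs",
    "raw_scores",
    "condition_correlations",
    "build_rif_inputs",
    "compute_rif",
    "select_key_regulators",
]


def _state_correlations(
    tf_vals: np.ndarray, de_vals: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlations between rows of tf_vals and rows of de_vals
    over the shared sample axis; zero-variance rows yield r = 0 and are
    reported through the returned flag matrix."""
    tf_sd = tf_vals.std(axis=1)
    de_sd = de_vals.std(axis=1)
    tf_c = tf_vals - tf_vals.mean(axis=1, keepdims=True)
    de_c = de_vals - de_vals.mean(axis=1, keepdims=True)
    cov = tf_c @ de_c.T / tf_vals.shape[1]
    denom = np.outer(tf_sd, de_sd)
    degenerate = denom == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(degenerate, 0.0, cov / np.where(degenerate, 1.0, denom))
    return np.clip(r, -1.0, 1.0), degenerate


def condition_correlations(
    norm: NormalizedExpression, tf_ids: list[str], de_ids: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Within-state TF x DE-gene Pearson correlations across animals.

    Returns (r1, r2, degenerate): TF x DE-gene frames for the pre and post
    states, plus a boolean frame marking pairs where either vector had
    zero variance in at least one state (r forced to 0 there).
    """
    missing = [g for g in list(tf_ids) + list(de_ids) if g not in norm.values.index]
    if missing:
        raise ValueError(f"id(s) absent from normalized matrix: {missing[:5]}")
    for state in ("pre", "post"):
        if len(norm.animals_in_state(state)) < 3:
            raise ValueError(f"need >= 3 animals in state {state!r} for correlations")
    out = {}
    flags = {}
    for state in ("pre", "post"):
        animals = norm.animals_in_state(state)
        tf_vals = norm.values.loc[tf_ids, animals].to_numpy()
        de_vals = norm.values.loc[de_ids, animals].to_numpy()
        r, degenerate = _state_correlations(tf_vals, de_vals)
        out[state] = pd.DataFrame(r, index=tf_ids, columns=de_ids)
        flags[state] = degenerate
    degenerate = pd.DataFrame(flags["pre"] | flags["post"], index=tf_ids, columns=de_ids)
    return out["pre"], out["post"], degenerate


@dataclass
class RIFInputs:
    e1: pd.Series  # DE-gene mean normalized expression, pre state
    e2: pd.Series  # same, post state
    r1: pd.DataFrame  # TF x DE-gene within-pre correlations
    r2: pd.DataFrame  # TF x DE-gene within-post correlations

    def validate(self) -> None:
        if len(self.e1) < 1:
            raise ValueError("need at least one DE gene")
        if self.r1.shape[0] < 2:
            raise ValueError("need at least two TFs (z-scores need a spread)")
        for name, r in (("r1", self.r1), ("r2", self.r2)):
            if (r.to_numpy() < -1 - 1e-12).any() or (r.to_numpy() > 1 + 1e-12).any():
                raise ValueError(f"{name} contains values outside [-1, 1]")
        if not (self.r1.index.equals(self.r2.index) and self.r1.columns.equals(self.r2.columns)):
            raise ValueError("r1 and r2 must share TF and DE-gene axes")
        if not self.e1.index.equals(self.e2.index):
            raise ValueError("e1 and e2 must share the DE-gene axis")


def build_rif_inputs(
    norm: NormalizedExpression, tf_ids: list[str], de_ids: list[str]
) -> RIFInputs:
    r1, r2, _ = condition_correlations(norm, tf_ids, de_ids)
    return RIFInputs(
        e1=norm.state_means.loc[de_ids, "pre"],
        e2=norm.state_means.loc[de_ids, "post"],
        r1=r1,
        r2=r2,
    )


def raw_scores(inputs: RIFInputs) -> pd.DataFrame:
    """Unstandardized RIF1/RIF2 per TF."""
    inputs.validate()
    e1 = inputs.e1.to_numpy(float)
    e2 = inputs.e2.to_numpy(float)
    r1 = inputs.r1.to_numpy(float)
    r2 = inputs.r2.to_numpy(float)
    n_de = e1.size

    a = (e1 + e2) / 2.0
    d = e2 - e1
    pif = a * d
    dw = r1 - r2
    rif1 = (pif[None, :] * dw**2).sum(axis=1) / n_de
    rif2 = ((e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2).sum(axis=1) / n_de
    table = pd.DataFrame({"rif1": rif1, "rif2": rif2}, index=inputs.r1.index)
    table.index.name = "tf_id"
    return table


def compute_rif(inputs: RIFInputs, threshold: float = 1.96) -> pd.DataFrame:
    """RIF1/RIF2 raw scores, z-scores and significance flags per TF."""
    table = raw_scores(inputs)
    for col, zcol in (("rif1", "z1"), ("rif2", "z2")):
        sd = table[col].std(ddof=1)
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(
                f"standard deviation of {col} is zero; degenerate input "
                "(all TFs scored identically) cannot be z-standardized"
            )
        table[zcol] = (table[col] - table[col].mean()) / sd
    table["significant"] = (table["z1"].abs() >= threshold) | (
        table["z2"].abs() >= threshold
    )
    return table


def select_key_regulators(rif_table: pd.DataFrame, threshold: float = 1.96) -> list[str]:
    """TF ids with |z1| >= threshold or |z2| >= threshold."""
    mask = (rif_table["z1"].abs() >= threshold) | (rif_table["z2"].abs() >= threshold)
    return list(rif_table.index[mask])
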