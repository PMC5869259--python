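"""Synthetic experiment generator.

Emits a read-count matrix, a sample design table and a TF list with known
ground truth: planted differentially expressed genes (additive post-state
shifts on the log2 scale) and planted regulators whose correlation with
their target genes changes between the two physiological states
(differential wiring).

Log2 expression is drawn under the same mixed model the normalization
module fits::

    y[j, s] = mu + L[lib(s)] + G[j] + GAPT[j, cell(s)] + e[j, s]

Counts are back-computed by inverting the RPKM formula (rpkm = 2**y,
counts = rpkm * mapped_millions * length_kb, rounded half-to-even) with
gene lengths drawn log-uniform on [0.2, 20] kb and library sizes
log-uniform on [40, 80] million mapped reads.

Randomness: one master seed spawns named child streams (one per draw
category) via ``numpy.random.SeedSequence.spawn``, so every sub-draw is
reproducible and insensitive to the order other draws happen in.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import CountMatrix, SampleDesign, _cell_key

__all__ = ["SimulationConfig", "GroundTruth", "simulate_experiment", "write_fixture_bundle"]

# fixed spread of the per-library nuisance effect (log2 scale); overridable
# through SimulationConfig.lib_sd for noiseless test scenarios
DEFAULT_LIB_SD = 0.1

_STREAMS = (
    "lengths",
    "depths",
    "lib_effects",
    "gene_effects",
    "interactions",
    "residuals",
    "labels",
    "wiring",
)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 500
    n_tf: int = 50
    n_animals_per_state: int = 6
    n_tissues: int = 5
    n_libraries: int = 72
    var_gene: float = 1.0
    var_gapt: float = 0.5
    var_resid: float = 0.25
    prop_de: float = 0.1
    de_effect: float = 2.0
    n_planted_regulators: int = 0
    wiring_shift: float = 1.0
    r_pre: float | None = None  # pre-state TF-target correlation; None -> -wiring_shift/2
    mean_log_expr: float = 5.0
    seed: int = 0
    lib_sd: float = DEFAULT_LIB_SD

    def wiring_correlations(self) -> tuple[float, float]:
        """(r_pre, r_post) planted within-state correlations; post is
        pre + wiring_shift."""
        rp = -self.wiring_shift / 2.0 if self.r_pre is None else self.r_pre
        return rp, rp + self.wiring_shift

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.n_tf <= self.n_genes):
            raise ValueError("need 0 <= n_tf <= n_genes")
        if not (0 <= self.n_planted_regulators <= self.n_tf):
            raise ValueError("need 0 <= n_planted_regulators <= n_tf")
        if self.n_animals_per_state < 1 or self.n_tissues < 1:
            raise ValueError("n_animals_per_state and n_tissues must be positive")
        for name in ("var_gene", "var_gapt", "var_resid", "lib_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.prop_de <= 1.0):
            raise ValueError("prop_de must be in [0, 1]")
        n_cells = 2 * self.n_animals_per_state * self.n_tissues
        if self.n_libraries < n_cells:
            raise ValueError(
                f"n_libraries ({self.n_libraries}) must cover every "
                f"animal x tissue cell ({n_cells})"
            )
        if not (0.0 <= self.wiring_shift <= 2.0):
            raise ValueError("wiring_shift must be in [0, 2]")
        # clamping a planted correlation to [-1, 1] would silently destroy
        # the requested wiring change, so such configs are rejected outright
        rp, rpost = self.wiring_correlations()
        limit = 1.0 - 1e-9  # |r| = 1 makes the planted signal degenerate
        if not (abs(rp) <= limit and abs(rpost) <= limit):
            raise ValueError(
                f"unachievable wiring: pre/post correlations ({rp:.3f}, "
                f"{rpost:.3f}) must lie strictly inside [-1, 1]; lower "
                "wiring_shift or adjust r_pre"
            )
        if self.n_planted_regulators > 0:
            n_de = int(round(self.prop_de * self.n_genes))
            if n_de < self.n_planted_regulators:
                raise ValueError(
                    "each planted regulator needs at least one DE target gene; "
                    f"got {n_de} DE genes for {self.n_planted_regulators} regulators"
                )


@dataclass
class GroundTruth:
    """Planted structure of a simulated experiment."""

    de_effects: dict[str, float]  # DE gene -> signed log2 shift (post - pre)
    regulators: dict[str, dict[str, float]]  # TF -> {target -> wiring change r1 - r2}
    variance_components: tuple[float, float, float]  # (var_gene, var_gapt, var_resid)

    def effect(self, gene_id: str) -> float:
        return self.de_effects.get(gene_id, 0.0)

    @property
    def de_genes(self) -> list[str]:
        return sorted(self.de_effects)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleDesign, list[str], GroundTruth]:
    """Generate a seeded synthetic experiment with planted ground truth."""
    config.validate()
    rng = _streams(config.seed)

    n_animals = 2 * config.n_animals_per_state
    animals = [f"A{i + 1:02d}" for i in range(n_animals)]
    animal_state = {
        a: ("pre" if i < config.n_animals_per_state else "post")
        for i, a in enumerate(animals)
    }
    tissues = [f"t{i + 1}" for i in range(config.n_tissues)]

    # one sample per library; the first n_cells libraries cover each
    # (animal, tissue) cell once, extra libraries replicate cells starting
    # from the LAST tissue so the first tissue (the analysis tissue) keeps
    # a clean one-library-per-animal layout
    cells = [(a, ti) for ti in tissues for a in animals]
    extra = config.n_libraries - len(cells)
    replicate_cells = [cells[-(i % len(cells)) - 1] for i in range(extra)]
    sample_cells = cells + replicate_cells

    rows = []
    for i, (animal, tissue) in enumerate(sample_cells):
        rows.append(
            {
                "sample_id": f"S{i + 1:03d}",
                "animal_id": animal,
                "state": animal_state[animal],
                "tissue": tissue,
                "library_id": f"L{i + 1:03d}",
            }
        )
    design_df = pd.DataFrame(rows)
    n_samples = len(design_df)

    genes = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    tf_ids = sorted(rng["labels"].choice(genes, size=config.n_tf, replace=False))
    non_tf = [g for g in genes if g not in set(tf_ids)]
    n_de = int(round(config.prop_de * config.n_genes))
    n_de = min(n_de, len(non_tf))
    de_genes = sorted(rng["labels"].choice(non_tf, size=n_de, replace=False))
    regulators = sorted(
        rng["labels"].choice(tf_ids, size=config.n_planted_regulators, replace=False)
    )

    gene_pos = {g: i for i, g in enumerate(genes)}
    cell_keys = [_cell_key(a, ti) for a, ti in cells]
    cell_pos = {c: i for i, c in enumerate(cell_keys)}
    sample_cell_idx = np.array(
        [cell_pos[_cell_key(a, ti)] for a, ti in sample_cells]
    )
    post_cells = np.array([animal_state[a] == "post" for a, _ in cells])

    L = rng["lib_effects"].normal(0.0, config.lib_sd, size=n_samples)
    G = rng["gene_effects"].normal(0.0, np.sqrt(config.var_gene), size=config.n_genes)
    GAPT = rng["interactions"].normal(
        0.0, np.sqrt(config.var_gapt), size=(config.n_genes, len(cells))
    )
    E = rng["residuals"].normal(
        0.0, np.sqrt(config.var_resid), size=(config.n_genes, n_samples)
    )

    # planted DE: additive post-state shift in the interaction terms
    de_effects = {g: float(config.de_effect) for g in de_genes}
    for g in de_genes:
        GAPT[gene_pos[g], post_cells] += config.de_effect

    # planted regulators: each regulator takes a block of DE genes as
    # targets; the target's combined (GAPT + e) deviation is rebuilt to
    # correlate with the regulator's at -shift/2 pre and +shift/2 post
    truth_reg: dict[str, dict[str, float]] = {}
    if regulators:
        r_pre, r_post = config.wiring_correlations()
        sigma_tot = np.sqrt(config.var_gapt + config.var_resid)
        post_samples = post_cells[sample_cell_idx]
        blocks = np.array_split(np.arange(len(de_genes)), len(regulators))
        wrng = rng["wiring"]
        for reg, block in zip(regulators, blocks):
            jr = gene_pos[reg]
            reg_dev = GAPT[jr, sample_cell_idx] + E[jr]
            unit = reg_dev / sigma_tot if sigma_tot > 0 else np.zeros(n_samples)
            targets = [de_genes[b] for b in block]
            truth_reg[reg] = {t: r_pre - r_post for t in targets}
            for tgt in targets:
                jt = gene_pos[tgt]
                r_s = np.where(post_samples, r_post, r_pre)
                z = wrng.normal(0.0, 1.0, size=n_samples)
                dev = sigma_tot * (r_s * unit + np.sqrt(1.0 - r_s**2) * z)
                # keep the planted DE shift; replace the stochastic part
                GAPT[jt, :] = 0.0
                GAPT[jt, post_cells] = config.de_effect
                E[jt] = dev

    Y = (
        config.mean_log_expr
        + L[None, :]
        + G[:, None]
        + GAPT[:, sample_cell_idx]
        + E
    )

    length_kb = np.exp(
        rng["lengths"].uniform(np.log(0.2), np.log(20.0), size=config.n_genes)
    )
    depth_m = np.exp(rng["depths"].uniform(np.log(40.0), np.log(80.0), size=n_samples))
    rpkm = np.exp2(Y)
    counts = np.rint(rpkm * depth_m[None, :] * length_kb[:, None]).astype(np.int64)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                            columns=design_df["sample_id"].to_numpy()),
        exon_length_kb=pd.Series(length_kb, index=pd.Index(genes, name="gene_id")),
        mapped_reads_millions=pd.Series(
            depth_m, index=design_df["sample_id"].to_numpy()
        ),
    )
    design = SampleDesign(table=design_df)
    truth = GroundTruth(
        de_effects=de_effects,
        regulators=truth_reg,
        variance_components=(config.var_gene, config.var_gapt, config.var_resid),
    )
    return cm, design, list(tf_ids), truth


def write_fixture_bundle(
    cm: CountMatrix,
    design: SampleDesign,
    tf_list: list[str],
    truth: GroundTruth,
    directory_path: str,
) -> dict[str, str]:
    """Write counts/design/TF-list/ground-truth files; returns their paths.

    Schemas match the readers in :mod:`rifnet.io` (tab-delimited, UTF-8,
    headers mandatory).  The counts file carries the per-gene exon length;
    the design file carries the per-sample mapped-read total.
    """
    if len(cm.gene_ids) == 0:
        raise ValueError("cannot write a fixture bundle with an empty gene set")
    os.makedirs(directory_path, exist_ok=True)
    paths = {
        "counts": os.path.join(directory_path, "counts.tsv"),
        "design": os.path.join(directory_path, "design.tsv"),
        "tf_list": os.path.join(directory_path, "tf_list.txt"),
        "ground_truth": os.path.join(directory_path, "ground_truth.tsv"),
    }
    try:
        counts_out = cm.counts.copy()
        counts_out.insert(0, "exon_length_kb", cm.exon_length_kb.reindex(cm.counts.index))
        counts_out.index.name = "gene_id"
        counts_out.to_csv(paths["counts"], sep="\t", float_format="%.10g")

        design_out = design.table.copy()
        design_out["mapped_reads_millions"] = (
            cm.mapped_reads_millions.reindex(design_out["sample_id"]).to_numpy()
        )
        design_out.to_csv(paths["design"], sep="\t", index=False, float_format="%.10g")

        with open(paths["tf_list"], "w", encoding="utf-8") as fh:
            for tf in tf_list:
                fh.write(f"{tf}\n")

        records = []
        for gene, eff in sorted(truth.de_effects.items()):
            records.append(("de", gene, "", eff))
        for reg, targets in sorted(truth.regulators.items()):
            for tgt, dw in sorted(targets.items()):
                records.append(("regulator", reg, tgt, dw))
        for name, value in zip(("var_gene", "var_gapt", "var_resid"),
                               truth.variance_components):
            records.append(("variance", name, "", value))
        pd.DataFrame(
            records, columns=["record_type", "id", "target_id", "value"]
        ).to_csv(paths["ground_truth"], sep="\t", index=False, float_format="%.10g")
    except OSError as exc:
        raise OSError(f"failed writing fixture bundle to {directory_path}: {exc}") from exc
    return paths


def read_ground_truth(path: str) -> GroundTruth:
    """Inverse of the ground-truth writer in :func:`write_fixture_bundle`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    de = {
        r["id"]: float(r["value"])
        for _, r in df[df["record_type"] == "de"].iterrows()
    }
    regs: dict[str, dict[str, float]] = {}
    for _, r in df[df["record_type"] == "regulator"].iterrows():
        regs.setdefault(r["id"], {})[r["target_id"]] = float(r["value"])
    var = df[df["record_type"] == "variance"].set_index("id")["value"]
    return GroundTruth(
        de_effects=de,
        regulators=regs,
        variance_components=(
            float(var["var_gene"]), float(var["var_gapt"]), float(var["var_resid"])
        ),
    )
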