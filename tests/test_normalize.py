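import numpy as np
import pandas as pd
import pytest

from rifnet.normalize import (
    CountMatrix,
    MixedModelFit,
    SampleDesign,
    compute_rpkm,
    extract_normalized,
    filter_expressed,
    fit_mixed_model,
    log2_transform,
)
from rifnet.simulate import SimulationConfig, simulate_experiment

from conftest import run_normalization


def make_cm(counts, lengths, depths):
    genes = [f"g{i}" for i in range(len(lengths))]
    samples = [f"s{i}" for i in range(len(depths))]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        exon_length_kb=pd.Series(lengths, index=genes),
        mapped_reads_millions=pd.Series(depths, index=samples),
    )


class TestRPKM:
    def test_unit_arithmetic(self):
        # 100 reads / (50 million mapped x 2 kb) = 1.0
        cm = make_cm([[100]], [2.0], [50.0])
        assert compute_rpkm(cm).iloc[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_counts_zero_rpkm(self):
        cm = make_cm([[0]], [2.0], [50.0])
        assert compute_rpkm(cm).iloc[0, 0] == 0.0

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 1000, size=(20, 6))
        lengths = rng.uniform(0.2, 20.0, size=20)
        depths = rng.uniform(40.0, 80.0, size=6)
        rpkm = compute_rpkm(make_cm(counts, lengths, depths)).to_numpy()
        for j in range(20):
            for s in range(6):
                expected = counts[j, s] / (depths[s] * lengths[j])
                assert rpkm[j, s] == pytest.approx(expected, rel=1e-12)

    def test_split_sample_invariance(self):
        # splitting a sample into two half-depth samples and averaging
        # their RPKM reproduces the original RPKM
        rng = np.random.default_rng(1)
        counts = 2 * rng.integers(0, 500, size=(10, 1))
        lengths = rng.uniform(0.5, 5.0, size=10)
        full = compute_rpkm(make_cm(counts, lengths, [60.0])).to_numpy()[:, 0]
        halves = compute_rpkm(
            make_cm(np.hstack([counts // 2, counts // 2]), lengths, [30.0, 30.0])
        ).to_numpy()
        np.testing.assert_allclose(halves.mean(axis=1), full, rtol=1e-12)

    def test_zero_depth_names_offender(self):
        with pytest.raises(ValueError, match="s0"):
            make_cm([[1]], [2.0], [0.0])

    def test_zero_length_names_offender(self):
        with pytest.raises(ValueError, match="g0"):
            make_cm([[1]], [0.0], [50.0])


class TestFilterExpressed:
    def test_boundary_is_inclusive(self):
        rpkm = pd.DataFrame([[0.2, 0.2, 0.2]], index=["g"], columns=list("abc"))
        kept, report = filter_expressed(rpkm, threshold=0.2)
        assert kept == ["g"]
        assert bool(report.loc["g", "expressed"])

    def test_all_zero_removed(self):
        rpkm = pd.DataFrame([[0.0, 0.0]], index=["g"], columns=list("ab"))
        kept, _ = filter_expressed(rpkm)
        assert kept == []

    def test_oracle_scan(self):
        rng = np.random.default_rng(2)
        rpkm = pd.DataFrame(
            rng.exponential(0.3, size=(50, 8)),
            index=[f"g{i}" for i in range(50)],
        )
        kept, _ = filter_expressed(rpkm, threshold=0.2)
        expected = {
            g for g in rpkm.index
            if sum(rpkm.loc[g]) / rpkm.shape[1] >= 0.2
        }
        assert set(kept) == expected

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_expressed(pd.DataFrame([[1.0]]), threshold=-0.1)


class TestLog2Transform:
    def test_one_plus_one(self):
        out = log2_transform(pd.DataFrame([[1.0]]), offset=1.0)
        assert out.iloc[0, 0] == pytest.approx(1.0)

    def test_zero_maps_to_zero(self):
        out = log2_transform(pd.DataFrame([[0.0]]), offset=1.0)
        assert out.iloc[0, 0] == 0.0

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(3)
        rpkm = pd.DataFrame(rng.exponential(5.0, size=(7, 4)))
        out = log2_transform(rpkm, offset=1.0).to_numpy()
        for j in range(7):
            for s in range(4):
                assert out[j, s] == pytest.approx(
                    np.log2(rpkm.iloc[j, s] + 1.0), rel=1e-12
                )

    def test_negative_rpkm_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log2_transform(pd.DataFrame([[-0.5]]))

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            log2_transform(pd.DataFrame([[1.0]]), offset=0.0)


def two_tissue_design(n_pre=3, n_post=3, tissues=("t1", "t2"), replicates=0):
    animals = [f"A{i}" for i in range(n_pre + n_post)]
    rows = []
    i = 0
    cells = [(a, t) for t in tissues for a in animals]
    if replicates:
        cells = cells + cells[-replicates:]
    for a, t in cells:
        rows.append(
            {
                "sample_id": f"s{i}", "animal_id": a,
                "state": "pre" if animals.index(a) < n_pre else "post",
                "tissue": t, "library_id": f"l{i}",
            }
        )
        i += 1
    return SampleDesign(table=pd.DataFrame(rows))


class TestMixedModel:
    def test_constant_data(self):
        design = two_tissue_design()
        y = pd.DataFrame(
            3.5, index=[f"g{i}" for i in range(4)],
            columns=[f"s{i}" for i in range(len(design.table))],
        )
        fit = fit_mixed_model(y, design)
        assert fit.mu == pytest.approx(3.5)
        assert np.allclose(fit.library_effects, 0.0)
        assert np.allclose(fit.gene_effects, 0.0)
        assert np.allclose(fit.interaction_effects, 0.0)
        assert fit.var_gene == fit.var_gapt == fit.var_resid == 0.0
        assert fit.converged

    def test_noiseless_limit_reproduces_observations(self):
        # residual-free data: fitted values recover observations
        rng = np.random.default_rng(4)
        # replicate libraries let the residual component be identified (-> 0)
        design = two_tissue_design(replicates=4)
        t = design.table
        genes = [f"g{i}" for i in range(30)]
        G = rng.normal(0, 1, 30)
        cells = sorted({f"{a}|{ti}" for a, ti in zip(t.animal_id, t.tissue)})
        GAPT = rng.normal(0, 0.7, size=(30, len(cells)))
        L = rng.normal(0, 0.1, len(t))
        y = np.empty((30, len(t)))
        for s in range(len(t)):
            c = cells.index(f"{t.animal_id[s]}|{t.tissue[s]}")
            y[:, s] = 5.0 + L[s] + G + GAPT[:, c]
        y = pd.DataFrame(y, index=genes, columns=t.sample_id.to_numpy())
        # EM contracts the residual component slowly near the zero
        # boundary, so give it room
        fit = fit_mixed_model(y, design, tol=1e-14, max_iter=60000)
        fitted = fit.fitted(design)
        assert np.abs(fitted.to_numpy() - y.to_numpy()).max() < 1e-6

    def test_shift_invariance(self):
        cfg = SimulationConfig(n_genes=60, n_tf=0, prop_de=0.0, n_tissues=2,
                               n_libraries=26, n_animals_per_state=3, seed=5)
        cm, design, _, _ = simulate_experiment(cfg)
        y = log2_transform(compute_rpkm(cm))
        fit0 = fit_mixed_model(y, design)
        fit1 = fit_mixed_model(y + 2.5, design)
        assert fit1.mu - fit0.mu == pytest.approx(2.5, abs=1e-8)
        np.testing.assert_allclose(
            fit1.gene_effects, fit0.gene_effects, atol=1e-8
        )
        np.testing.assert_allclose(
            fit1.interaction_effects, fit0.interaction_effects, atol=1e-8
        )
        assert fit1.var_gene == pytest.approx(fit0.var_gene, abs=1e-8)
        assert fit1.var_gapt == pytest.approx(fit0.var_gapt, abs=1e-8)
        assert fit1.var_resid == pytest.approx(fit0.var_resid, abs=1e-8)

    def test_random_effect_solutions_centered(self, small_experiment):
        fit = small_experiment["fit"]
        for sol in (fit.gene_effects.to_numpy(),
                    fit.interaction_effects.to_numpy().ravel()):
            sd = sol.std()
            assert abs(sol.mean()) < 1e-6 * max(sd, 1e-12)

    def test_independent_dense_mme_oracle(self):
        """Structured solver vs an independently assembled dense Henderson
        system at the same variance components."""
        cfg = SimulationConfig(n_genes=15, n_tf=0, prop_de=0.1, n_tissues=2,
                               n_animals_per_state=3, n_libraries=14, seed=3)
        cm, design, _, _ = simulate_experiment(cfg)
        y = log2_transform(compute_rpkm(cm))
        fit = fit_mixed_model(y, design)

        t = design.table.set_index("sample_id").loc[list(y.columns)].reset_index()
        libs = sorted(t.library_id.unique())
        cells = sorted({f"{a}|{ti}" for a, ti in zip(t.animal_id, t.tissue)})
        genes = list(y.index)
        ns, ng, nc = len(t), len(genes), len(cells)
        X = np.zeros((ns * ng, len(libs)))
        Z1 = np.zeros((ns * ng, ng))
        Z2 = np.zeros((ns * ng, ng * nc))
        yv = np.zeros(ns * ng)
        for j in range(ng):
            for s in range(ns):
                row = j * ns + s
                X[row, libs.index(t.library_id[s])] = 1
                Z1[row, j] = 1
                Z2[row, j * nc + cells.index(f"{t.animal_id[s]}|{t.tissue[s]}")] = 1
                yv[row] = y.iloc[j, s]
        W = np.hstack([X, Z1, Z2])
        C = W.T @ W
        q = len(libs)
        C[q:q + ng, q:q + ng] += np.eye(ng) * fit.var_resid / fit.var_gene
        C[q + ng:, q + ng:] += np.eye(ng * nc) * fit.var_resid / fit.var_gapt
        sol, *_ = np.linalg.lstsq(C, W.T @ yv, rcond=None)
        np.testing.assert_allclose(sol[q:q + ng], fit.gene_effects, atol=1e-6)
        np.testing.assert_allclose(
            sol[q + ng:].reshape(ng, nc), fit.interaction_effects, atol=1e-6
        )
        np.testing.assert_allclose(
            sol[:q], fit.mu + fit.library_effects.to_numpy(), atol=1e-6
        )

    def test_mismatched_samples_rejected(self):
        design = two_tissue_design()
        y = pd.DataFrame(1.0, index=["g0", "g1"], columns=["bogus1", "bogus2"])
        with pytest.raises(ValueError, match="sample ids"):
            fit_mixed_model(y, design)

    def test_too_few_animals_rejected(self):
        design = two_tissue_design(n_pre=1, n_post=3)
        y = pd.DataFrame(
            1.0, index=["g0", "g1"],
            columns=design.table["sample_id"].to_numpy(),
        )
        with pytest.raises(ValueError, match="2 animals"):
            fit_mixed_model(y, design)


class TestExtractNormalized:
    def make_fit(self, mu=0.0):
        return MixedModelFit(
            mu=mu,
            library_effects=pd.Series({"l0": 0.0}),
            gene_effects=pd.Series({"g0": 2.0}),
            interaction_effects=pd.DataFrame(
                {"A0|t1": [-1.0], "A1|t1": [0.5]}, index=["g0"]
            ),
            var_gene=1.0, var_gapt=1.0, var_resid=1.0,
            converged=True, n_iterations=1,
            cell_of_sample=pd.Series({"s0": "A0|t1", "s1": "A1|t1"}),
        )

    def design(self):
        return SampleDesign(table=pd.DataFrame(
            {
                "sample_id": ["s0", "s1"],
                "animal_id": ["A0", "A1"],
                "state": ["pre", "post"],
                "tissue": ["t1", "t1"],
                "library_id": ["l0", "l0"],
            }
        ))

    def test_additivity(self):
        norm = extract_normalized(self.make_fit(), self.design(), "t1",
                                  include_mu=False)
        assert norm.values.loc["g0", "A0"] == pytest.approx(1.0)

    def test_grand_mean_added_by_default(self):
        norm = extract_normalized(self.make_fit(mu=5.0), self.design(), "t1")
        assert norm.values.loc["g0", "A0"] == pytest.approx(6.0)

    def test_unknown_tissue_lists_available(self):
        with pytest.raises(ValueError, match="t1"):
            extract_normalized(self.make_fit(), self.design(), "liver")

    def test_state_mean_is_arithmetic_mean(self, small_experiment):
        norm = small_experiment["norm"]
        for state in ("pre", "post"):
            animals = norm.animals_in_state(state)
            expected = norm.values.loc[:, animals].mean(axis=1)
            np.testing.assert_allclose(
                norm.state_means[state], expected, atol=1e-10
            )

    def test_shrinkage_collapses_to_gene_effect(self):
        # as var_gapt/var_resid -> 0, per-animal values approach mu + G
        devs = []
        for vi in (0.5, 0.002):
            # replicate libraries identify the var_gapt/var_resid split
            cfg = SimulationConfig(n_genes=80, n_tf=0, prop_de=0.0,
                                   var_gapt=vi, var_resid=0.25,
                                   n_tissues=1, n_libraries=24, seed=9)
            *_, fit, norm = run_normalization(cfg)
            centered = norm.values.to_numpy() - (
                fit.mu + fit.gene_effects.to_numpy()[:, None]
            )
            devs.append(np.abs(centered).max())
        assert devs[1] < devs[0] / 5
        assert devs[1] < 0.1
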