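"""Scan pipeline: residualisation, cis pairing, orchestration, utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import sim_block
from tissueqtl import (
    CollinearCovariatesError,
    ExpressionBlock,
    GeneAnnotation,
    ScanConfig,
    SubjectMismatchError,
    cis_pairs,
    genotypes_hwe,
    joint_test,
    fit_null,
    residualize,
    run_scan,
    winsorized_mean,
)
from tissueqtl.io import GenotypeMatrix
from tissueqtl.simulate import SimulationConfig, simulate_gene


def _subjects(n):
    return [f"S{i}" for i in range(n)]


def _panel(seed=0, n=60, t=3, n_genes=5, n_snps=20, spike=None):
    """Synthetic tissue tables + genotype matrix + annotations."""
    rng = np.random.default_rng(seed)
    subjects = _subjects(n)
    snps = [genotypes_hwe(n, 0.3, rng) for _ in range(n_snps)]
    meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(n_snps)],
            "chrom": "1",
            "pos": [1000 * (j + 1) for j in range(n_snps)],
        }
    )
    geno = GenotypeMatrix(
        meta=meta, dosages=np.vstack([s.dosages for s in snps]), subject_ids=subjects
    )
    tables = {f"T{k}": pd.DataFrame(index=[f"g{i}" for i in range(n_genes)],
                                    columns=subjects, dtype=float)
              for k in range(t)}
    ann = []
    for i in range(n_genes):
        cfg = SimulationConfig(n=n, t=t, maf=0.3, seed=seed)
        if spike is not None and i == spike[0]:
            cfg = SimulationConfig(n=n, t=t, maf=0.3, beta=spike[2], seed=seed)
            block = simulate_gene(cfg, snps[spike[1]], rng)
        else:
            block = simulate_gene(cfg, snps[0], np.random.default_rng((seed, i)))
            # null genes: expression independent of any SNP
            block = ExpressionBlock(np.random.default_rng((seed, i, 1)).normal(size=(n, t)))
        for k in range(t):
            tables[f"T{k}"].loc[f"g{i}"] = block.values[:, k]
        ann.append(GeneAnnotation(f"g{i}", "1", 1000 * (i * 4 + 1)))
    return tables, geno, ann


class TestResidualize:
    def test_intercept_only_centers_each_tissue(self, rng):
        expr = sim_block(20, 3, tau=0.5, eps=1.0, rng=rng, alpha=[1.0, 2.0, 3.0])
        cov = pd.DataFrame(index=expr.subject_ids)  # no columns -> intercept only
        out = residualize(expr, cov)
        assert np.allclose(np.nanmean(out.values, axis=0), 0.0, atol=1e-12)

    def test_perfect_predictor_zeroes_residuals(self, rng):
        expr = sim_block(15, 2, tau=0.5, eps=1.0, rng=rng)
        cov = pd.DataFrame({"self": expr.values[:, 0]}, index=expr.subject_ids)
        out = residualize(expr, cov)
        assert np.allclose(out.values[:, 0], 0.0, atol=1e-8)

    def test_residuals_orthogonal_to_covariates(self, rng):
        expr = sim_block(30, 3, tau=0.5, eps=1.0, rng=rng, missing=0.2)
        cov = pd.DataFrame(
            rng.normal(size=(30, 2)), columns=["age", "batch"], index=expr.subject_ids
        )
        out = residualize(expr, cov)
        covmat = cov.to_numpy()
        for j in range(3):
            rows = out.mask[:, j]
            for k in range(covmat.shape[1]):
                assert abs(np.dot(out.values[rows, j], covmat[rows, k])) < 1e-8

    def test_collinear_covariates_named_in_error(self, rng):
        expr = sim_block(10, 2, tau=0.5, eps=1.0, rng=rng)
        x = rng.normal(size=10)
        cov = pd.DataFrame(
            {"a": x, "b": 2 * x, "c": rng.normal(size=10)}, index=expr.subject_ids
        )
        with pytest.raises(CollinearCovariatesError, match="b"):
            residualize(expr, cov)

    def test_mask_is_preserved(self, rng):
        expr = sim_block(20, 3, tau=0.5, eps=1.0, rng=rng, missing=0.3)
        out = residualize(expr, pd.DataFrame(index=expr.subject_ids))
        assert np.array_equal(out.mask, expr.mask)


class TestCisPairs:
    def _meta(self, positions, chrom="1"):
        return pd.DataFrame(
            {"snp_id": [f"s{i}" for i in range(len(positions))],
             "chrom": chrom, "pos": positions}
        )

    def test_zero_distance_is_paired(self):
        pairs = cis_pairs([GeneAnnotation("g", "1", 500)], self._meta([500]), 100)
        assert list(pairs["g"]) == [0]

    def test_window_boundary_is_inclusive(self):
        genes = [GeneAnnotation("g", "1", 200_000)]
        meta = self._meta([100_000, 99_999, 300_000, 300_001])
        pairs = cis_pairs(genes, meta, 100_000)
        assert sorted(pairs["g"]) == [0, 2]

    def test_chromosome_must_match(self):
        pairs = cis_pairs([GeneAnnotation("g", "2", 500)], self._meta([500]), 100)
        assert len(pairs["g"]) == 0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(17)
        genes = [
            GeneAnnotation(f"g{i}", rng.choice(["1", "2"]), int(rng.integers(1, 10**6)))
            for i in range(10)
        ]
        meta = pd.DataFrame(
            {
                "snp_id": [f"s{j}" for j in range(200)],
                "chrom": rng.choice(["1", "2"], size=200),
                "pos": rng.integers(1, 10**6, size=200),
            }
        )
        window = 50_000
        pairs = cis_pairs(genes, meta, window)
        for gene in genes:
            brute = [
                j
                for j in range(200)
                if meta.chrom[j] == gene.chrom and abs(meta.pos[j] - gene.tss) <= window
            ]
            assert sorted(pairs[gene.gene_id].tolist()) == sorted(brute)


class TestRunScan:
    def test_genomewide_tests_cartesian_product(self):
        tables, geno, ann = _panel(n_genes=5, n_snps=20)
        res = run_scan(tables, geno, None, ScanConfig(mode="genomewide"))
        assert res.n_tested == 100
        assert res.threshold == pytest.approx(0.05 / 100)

    def test_cis_mode_tests_exactly_cis_pairs(self):
        tables, geno, ann = _panel(n_genes=5, n_snps=20)
        window = 3000
        res = run_scan(tables, geno, ann, ScanConfig(mode="cis", window=window))
        expected = cis_pairs(ann, geno.meta, window)
        assert res.n_tested == sum(len(v) for v in expected.values())

    def test_planted_eqtl_is_top_hit_and_significant(self):
        tables, geno, ann = _panel(seed=3, spike=(2, 7, 1.2))
        res = run_scan(tables, geno, None, ScanConfig(mode="genomewide"))
        top = res.pairs.sort_values("p_value").iloc[0]
        assert (top.gene_id, top.snp_id) == ("g2", "snp7")
        assert bool(top.significant)

    def test_null_fit_once_per_gene(self, monkeypatch):
        import tissueqtl.scan as scan_mod

        calls = []
        orig = scan_mod.fit_null

        def counting(expr, **kw):
            calls.append(1)
            return orig(expr, **kw)

        monkeypatch.setattr(scan_mod, "fit_null", counting)
        tables, geno, ann = _panel(n_genes=3, n_snps=10)
        run_scan(tables, geno, None, ScanConfig(mode="genomewide"))
        assert len(calls) == 3

    def test_scan_pvalues_match_direct_joint_test(self):
        from tissueqtl.io import assemble_block

        tables, geno, ann = _panel(n_genes=2, n_snps=5)
        res = run_scan(tables, geno, None, ScanConfig(mode="genomewide"))
        fit = fit_null(assemble_block("g0", tables, geno.subject_ids))
        for j in range(5):
            direct = joint_test(fit, geno.vector(j))
            row = res.pairs[(res.pairs.gene_id == "g0") & (res.pairs.snp_id == f"snp{j}")]
            assert row.p_value.iloc[0] == pytest.approx(direct.p_value, rel=1e-12)

    def test_permutation_table_and_determinism(self):
        tables, geno, ann = _panel(n_genes=3, n_snps=10)
        cfg = ScanConfig(mode="cis", window=10_000, permutations=30, seed=5)
        a = run_scan(tables, geno, ann, cfg)
        b = run_scan(tables, geno, ann, cfg)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        assert {"gene_id", "observed_min_p", "adjusted_p", "B", "seed",
                "flag", "bh_adjusted_p"} <= set(a.genes.columns)
        assert (a.genes.adjusted_p >= 1 / 31).all()

    def test_subject_mismatch_lists_difference(self):
        tables, geno, ann = _panel(n_genes=2, n_snps=4)
        bad = GenotypeMatrix(
            meta=geno.meta, dosages=geno.dosages, subject_ids=geno.subject_ids[:-1] + ["ZZ"]
        )
        with pytest.raises(SubjectMismatchError, match="ZZ"):
            run_scan(tables, bad, None, ScanConfig(mode="genomewide"))


class TestWinsorizedMean:
    def test_zero_fraction_is_arithmetic_mean(self):
        assert winsorized_mean([1.0, 2.0, 6.0], 0.0) == pytest.approx(3.0)

    def test_symmetric_order_statistic_replacement(self):
        # lowest and highest floor(0.25*4)=1 values clamped to nearest retained
        assert winsorized_mean([1.0, 2.0, 3.0, 100.0], 0.25) == pytest.approx(2.5)

    def test_matches_scipy_winsorize(self, rng):
        from scipy.stats.mstats import winsorize

        v = rng.normal(size=37)
        for frac in [0.05, 0.1, 0.25]:
            ref = float(winsorize(v, limits=(frac, frac)).mean())
            assert winsorized_mean(v, frac) == pytest.approx(ref)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30), st.floats(0, 0.49))
    def test_permutation_invariance(self, values, frac):
        rng = np.random.default_rng(0)
        shuffled = list(values)
        rng.shuffle(shuffled)
        assert winsorized_mean(values, frac) == pytest.approx(
            winsorized_mean(shuffled, frac), nan_ok=True
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            winsorized_mean([], 0.1)
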