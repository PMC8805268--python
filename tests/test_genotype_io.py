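"""Genotype parsing, kNN imputation, phenotype correction, partitioning."""

import numpy as np
import pandas as pd
import pytest

from dkpc.containers import MISSING, SnpGeneMap
from dkpc.errors import FormatError, ImputationError, ParameterError
from dkpc.io import (
    correct_phenotype,
    genotype_pcs,
    knn_impute,
    partition_by_gene,
    read_genotypes,
    write_genotypes_plink_raw,
    write_genotypes_tsv,
)

from conftest import make_genotypes, make_phenotype


class TestReadGenotypes:
    def test_plink_raw_all_zeros(self, tmp_path):
        raw = tmp_path / "g.raw"
        raw.write_text(
            "FID IID PAT MAT SEX PHENOTYPE rs1_A rs2_G\n"
            "f1 i1 0 0 1 -9 0 0\n"
            "f2 i2 0 0 2 -9 0 0\n"
            "f3 i3 0 0 1 -9 0 0\n"
        )
        g = read_genotypes(raw, format="plink_raw")
        assert g.sample_ids == ["i1", "i2", "i3"]
        assert g.snp_ids == ["rs1", "rs2"]  # allele suffix stripped
        assert (g.values == 0).all()

    def test_plink_raw_na_becomes_missing(self, tmp_path):
        raw = tmp_path / "g.raw"
        raw.write_text(
            "FID IID PAT MAT SEX PHENOTYPE rs1_A\nf1 i1 0 0 1 -9 NA\nf2 i2 0 0 1 -9 2\n"
        )
        g = read_genotypes(raw, format="plink_raw")
        assert g.values[0, 0] == MISSING
        assert g.values[1, 0] == 2

    def test_malformed_header_rejected(self, tmp_path):
        bad = tmp_path / "g.raw"
        bad.write_text("IID FID X Y Z W rs1_A\na b 0 0 0 0 1\n")
        with pytest.raises(FormatError):
            read_genotypes(bad, format="plink_raw")

    def test_bad_cell_names_row_and_column(self, tmp_path):
        bad = tmp_path / "g.tsv"
        bad.write_text("sample\trs1\trs2\ns1\t0\t3\n")
        with pytest.raises(FormatError, match="rs2"):
            read_genotypes(bad, format="tsv")

    def test_tsv_roundtrip(self, tmp_path, rng):
        vals = rng.integers(0, 3, size=(8, 4)).astype(np.int8)
        vals[2, 1] = MISSING
        g = make_genotypes(vals)
        write_genotypes_tsv(g, tmp_path / "g.tsv")
        back = read_genotypes(tmp_path / "g.tsv", format="tsv")
        assert back.sample_ids == g.sample_ids
        assert back.snp_ids == g.snp_ids
        assert (back.values == g.values).all()

    def test_plink_raw_roundtrip(self, tmp_path, rng):
        vals = rng.integers(0, 3, size=(5, 3)).astype(np.int8)
        g = make_genotypes(vals)
        write_genotypes_plink_raw(g, tmp_path / "g.raw")
        back = read_genotypes(tmp_path / "g.raw", format="plink_raw")
        assert (back.values == g.values).all()
        assert back.snp_ids == g.snp_ids


def _brute_force_knn_impute(values, k):
    """Independent oracle: explicit pairwise loops, shared-SNP-normalised
    Euclidean distance, mode over the k nearest observed neighbours."""
    values = values.astype(float)
    n, p = values.shape
    out = values.copy()
    for i in range(n):
        for j in range(p):
            if values[i, j] != MISSING:
                continue
            dists = []
            for t in range(n):
                if t == i or values[t, j] == MISSING:
                    continue
                shared = [
                    c for c in range(p)
                    if values[i, c] != MISSING and values[t, c] != MISSING
                ]
                if not shared:
                    d = np.inf
                else:
                    d = np.sqrt(
                        sum((values[i, c] - values[t, c]) ** 2 for c in shared)
                        / len(shared)
                    )
                dists.append((d, t))
            dists.sort(key=lambda x: (x[0], x[1]))
            nearest = [t for _, t in dists[:k]]
            votes = [values[t, j] for t in nearest]
            best = min(
                set(votes), key=lambda v: (-votes.count(v), v)
            )  # mode, smaller value on ties
            out[i, j] = best
    return out.astype(np.int8)


class TestKnnImpute:
    def test_complete_matrix_unchanged(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(12, 6)))
        out = knn_impute(g, k=5)
        assert (out.values == g.values).all()

    def test_hand_computed_mode(self):
        # sample 0 misses SNP1; samples 1, 2 are its 2 nearest on SNP0
        # (distance 0), both carry genotype 2 at SNP1 -> imputed 2
        vals = np.array([[1, MISSING], [1, 2], [1, 2], [2, 0]], dtype=np.int8)
        out = knn_impute(make_genotypes(vals), k=2)
        assert out.values[0, 1] == 2

    def test_mode_tie_breaks_to_smaller_genotype(self):
        vals = np.array([[1, MISSING], [1, 0], [1, 2], [0, 1]], dtype=np.int8)
        out = knn_impute(make_genotypes(vals), k=2)
        # neighbours at distance 0 carry {0, 2}: tie -> smaller genotype
        assert out.values[0, 1] == 0

    def test_matches_brute_force_oracle(self, rng):
        vals = rng.integers(0, 3, size=(50, 10)).astype(np.int8)
        mask = rng.random((50, 10)) < 0.05
        vals[mask] = MISSING
        g = make_genotypes(vals)
        out = knn_impute(g, k=10)
        oracle = _brute_force_knn_impute(vals, k=10)
        assert (out.values == oracle).all()

    def test_idempotent_and_preserves_observed(self, rng):
        vals = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        mask = rng.random((30, 8)) < 0.1
        vals[mask] = MISSING
        g = make_genotypes(vals)
        once = knn_impute(g, k=4)
        assert not once.has_missing
        assert (once.values[~mask] == vals[~mask]).all()
        twice = knn_impute(once, k=4)
        assert (twice.values == once.values).all()

    def test_all_missing_snp_raises(self):
        vals = np.array([[1, MISSING], [0, MISSING], [2, MISSING]], dtype=np.int8)
        with pytest.raises(ImputationError, match="snp1"):
            knn_impute(make_genotypes(vals), k=1)

    def test_k_too_large_raises(self):
        vals = np.array([[1, MISSING], [0, 1], [2, 1]], dtype=np.int8)
        with pytest.raises(ParameterError):
            knn_impute(make_genotypes(vals), k=3)


class TestCorrectPhenotype:
    def test_phenotype_equal_to_pc1_gives_zero_residuals(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(40, 10)))
        pc1 = genotype_pcs(g, 1)[:, 0]
        y = make_phenotype(3.0 + 2.0 * pc1, kind="raw")
        out = correct_phenotype(y, g, n_pcs=1)
        assert out.kind == "corrected"
        assert np.abs(out.values).max() < 1e-10

    def test_zero_pcs_centers_only(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(15, 5)))
        y = make_phenotype(rng.normal(size=15) + 7, kind="raw")
        out = correct_phenotype(y, g, n_pcs=0)
        np.testing.assert_allclose(out.values, y.values - y.values.mean(), atol=1e-12)

    def test_residuals_orthogonal_to_all_pcs(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(50, 20)))
        y = make_phenotype(rng.normal(size=50), kind="raw")
        out = correct_phenotype(y, g, n_pcs=7)
        pcs = genotype_pcs(g, 7)
        assert abs(out.values.mean()) < 1e-10
        for j in range(7):
            r = np.corrcoef(out.values, pcs[:, j])[0, 1]
            assert abs(r) < 1e-8

    def test_confounded_simulation_residual_uncorrelated_with_pc1(self):
        from dkpc.simulate import SimulationConfig, simulate_study

        cfg = SimulationConfig(
            n=300, n_genes=5, snps_per_gene=5, confounder_sd=1.5,
            missing_rate=0.0, seed=11,
        )
        st = simulate_study(cfg)
        out = correct_phenotype(st.phenotype, st.genotypes, n_pcs=7)
        pc1 = genotype_pcs(st.genotypes, 1)[:, 0]
        assert abs(np.corrcoef(out.values, pc1)[0, 1]) < 1e-8

    def test_rank_deficient_design_raises(self):
        # five identical SNP columns -> only one informative PC
        vals = np.tile(np.array([[0], [2], [1], [1]], dtype=np.int8), (1, 5))
        g = make_genotypes(vals)
        y = make_phenotype([0.0, 1.0, 2.0, 0.5], kind="raw")
        with pytest.raises(ParameterError, match="fewer"):
            correct_phenotype(y, g, n_pcs=3)


class TestPartitionByGene:
    def _map(self, pairs):
        return SnpGeneMap(pd.DataFrame(pairs, columns=["snp", "gene"]))

    def test_min_snps_threshold_drops_small_genes(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(10, 7)))
        m = self._map(
            [(f"snp{i}", "geneA") for i in range(5)]
            + [(f"snp{i}", "geneB") for i in (5, 6)]
        )
        blocks = partition_by_gene(g, m, min_snps=3)
        assert [b.gene_id for b in blocks] == ["geneA"]
        assert blocks[0].n_snps == 5

    def test_min_snps_one_keeps_everything(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(10, 7)))
        m = self._map(
            [(f"snp{i}", "geneA") for i in range(5)]
            + [(f"snp{i}", "geneB") for i in (5, 6)]
        )
        blocks = partition_by_gene(g, m, min_snps=1)
        assert sorted(b.gene_id for b in blocks) == ["geneA", "geneB"]

    def test_multi_gene_snp_appears_in_each_block(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(10, 6)))
        m = self._map(
            [(f"snp{i}", "geneA") for i in range(3)]
            + [(f"snp{i}", "geneB") for i in range(2, 6)]
        )
        blocks = partition_by_gene(g, m, min_snps=3)
        by_gene = {b.gene_id: b for b in blocks}
        assert "snp2" in by_gene["geneA"].snp_ids
        assert "snp2" in by_gene["geneB"].snp_ids

    def test_values_extracted_bit_exactly(self, rng):
        vals = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        g = make_genotypes(vals)
        m = self._map([(f"snp{j}", "geneA") for j in (1, 4, 7)])
        (block,) = partition_by_gene(g, m)
        assert (block.values == vals[:, [1, 4, 7]]).all()
        assert block.snp_ids == ["snp1", "snp4", "snp7"]

    def test_synthetic_study_block_structure(self):
        from dkpc.simulate import SimulationConfig, simulate_genotypes

        cfg = SimulationConfig(n=30, n_genes=20, snps_per_gene=10, seed=5)
        g, m = simulate_genotypes(cfg)
        blocks = partition_by_gene(g, m)
        assert len(blocks) == 20
        assert all(b.n_snps == 10 for b in blocks)

    def test_disjoint_map_raises(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(5, 3)))
        m = self._map([("other1", "geneA"), ("other2", "geneA"), ("other3", "geneA")])
        with pytest.raises(ParameterError):
            partition_by_gene(g, m)


class TestKnnImputeByGene:
    def test_within_gene_distances_differ_from_global(self):
        # gene A's SNPs make samples 1,2 nearest to sample 0; the SNPs of
        # gene B (noise for gene A) would pick sample 3 instead
        vals = np.array(
            [
                [1, 1, MISSING, 0, 0, 0],
                [1, 1, 2, 2, 2, 2],
                [1, 1, 2, 2, 2, 2],
                [2, 0, 0, 0, 0, 0],
            ],
            dtype=np.int8,
        )
        g = make_genotypes(vals)
        m = SnpGeneMap(
            pd.DataFrame(
                [("snp0", "geneA"), ("snp1", "geneA"), ("snp2", "geneA")]
                + [(f"snp{j}", "geneB") for j in (3, 4, 5)],
                columns=["snp", "gene"],
            )
        )
        from dkpc.io import knn_impute_by_gene

        within = knn_impute_by_gene(g, m, k=2)
        assert within.values[0, 2] == 2  # neighbours by gene-A SNPs: samples 1,2
        globl = knn_impute(g, k=2)
        assert globl.values[0, 2] == 0  # gene-B SNPs pull sample 3 closest

    def test_complete_matrix_passthrough(self, rng):
        g = make_genotypes(rng.integers(0, 3, size=(10, 4)))
        m = SnpGeneMap(
            pd.DataFrame(
                [(f"snp{j}", "geneA") for j in range(4)], columns=["snp", "gene"]
            )
        )
        from dkpc.io import knn_impute_by_gene

        out = knn_impute_by_gene(g, m, k=3)
        assert (out.values == g.values).all()
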