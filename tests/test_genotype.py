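"""Genotype IO, QC filtering, imputation, GRM and PCA."""

import numpy as np
import pandas as pd
import pytest

from gsfoundry import genotype, simulate
from gsfoundry.genotype import MarkerMatrix


def toy_matrix(codes, **kw):
    codes = np.asarray(codes, dtype=float)
    n, p = codes.shape
    return MarkerMatrix(
        line_ids=np.array([f"L{i}" for i in range(n)]),
        marker_ids=np.array([f"M{j}" for j in range(p)]),
        codes=codes, **kw)


class TestHapMapIO:
    def test_parse_letter_calls_with_minor_allele_counting(self, tmp_path):
        path = tmp_path / "g.hmp.txt"
        header = "\t".join(
            ["rs#", "alleles", "chrom", "pos", "strand", "assembly#",
             "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
             "L1", "L2", "L3", "L4"])
        # A frequency 5/8: A major, T minor -> count T
        row = "\t".join(["m1", "A/T", "1", "100", "+", "NA", "NA", "NA",
                         "NA", "NA", "NA", "AA", "AT", "TT", "AA"])
        path.write_text(header + "\n" + row + "\n")
        m = genotype.read_genotypes(path, format="hapmap")
        np.testing.assert_array_equal(m.codes[:, 0], [0, 1, 2, 0])
        assert m.maf()[0] == pytest.approx(3 / 8)

    def test_multiallelic_markers_dropped(self, tmp_path):
        path = tmp_path / "g.hmp.txt"
        header = "\t".join(["rs#"] + ["x"] * 10 + ["L1", "L2"])
        header = header.replace("rs#\tx", "rs#\talleles", 1)
        good = "\t".join(["m1", "A/T", "1", "100"] + ["NA"] * 7
                         + ["AA", "AT"])
        tri = "\t".join(["m2", "A/T/G", "1", "200"] + ["NA"] * 7
                        + ["AA", "AG"])
        path.write_text(header + "\n" + good + "\n" + tri + "\n")
        m = genotype.read_genotypes(path, format="hapmap")
        assert list(m.marker_ids) == ["m1"]

    def test_malformed_row_names_line_number(self, tmp_path):
        path = tmp_path / "g.hmp.txt"
        header = "\t".join(["rs#", "alleles"] + ["x"] * 9 + ["L1", "L2"])
        path.write_text(header + "\nm1\tA/T\tshort\n")
        with pytest.raises(ValueError, match="line 2"):
            genotype.read_genotypes(path, format="hapmap")

    def test_hapmap_roundtrip_preserves_codes(self, tmp_path):
        cfg = simulate.SimulationConfig(n_lines=20, n_markers=40, n_qtl=5,
                                        n_locations=2, n_years=1, seed=1)
        m, _ = simulate.simulate_genotypes(cfg)
        m = genotype._count_minor(m)          # writer emits minor-counted codes
        genotype.write_hapmap(m, tmp_path / "g.hmp.txt")
        back = genotype.read_genotypes(tmp_path / "g.hmp.txt",
                                       format="hapmap")
        # ties (MAF exactly 0.5) may flip; compare up to per-marker flips
        same = np.allclose(back.codes, m.codes)
        flipped = np.allclose(back.codes, 2 - m.codes)
        per_marker_ok = np.all(
            (np.abs(back.codes - m.codes).max(axis=0) < 1e-12)
            | (np.abs(back.codes - (2 - m.codes)).max(axis=0) < 1e-12))
        assert same or flipped or per_marker_ok


class TestVcfAndCsvIO:
    def test_numeric_csv_roundtrip_exact(self, tmp_path):
        m = toy_matrix([[0, 1, 2], [2, np.nan, 0], [1, 1, 1]])
        genotype.write_numeric_csv(m, tmp_path / "g.csv")
        back = genotype.read_genotypes(tmp_path / "g.csv",
                                       format="numeric-csv")
        np.testing.assert_array_equal(
            np.nan_to_num(back.codes, nan=-9),
            np.nan_to_num(m.codes, nan=-9))
        assert list(back.line_ids) == list(m.line_ids)

    def test_vcf_het_is_one(self, tmp_path):
        pytest.importorskip("cyvcf2")
        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\ts1\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\t1/1\n"
            "1\t200\ts2\tG\tC\t.\tPASS\t.\tGT\t./.\t0/1\t0/0\n"
            "1\t300\ts3\tG\tC,A\t.\tPASS\t.\tGT\t0/1\t0/1\t0/0\n"
        )
        m = genotype.read_genotypes(vcf, format="vcf")
        assert list(m.marker_ids) == ["s1", "s2"]      # multi-allelic dropped
        s1 = m.codes[:, 0]
        assert s1[0] == 1.0                            # 0/1 -> 1
        # hom-alt vs hom-ref differ by 2 after minor-allele recoding
        assert abs(s1[2] - s1[1]) == 2.0
        assert np.isnan(m.codes[0, 1])                 # ./. missing


class TestFiltering:
    def test_toy_bad_line_and_bad_marker_removed(self):
        # line 3 is 75% missing; marker 2 is 100% het on remaining lines
        codes = np.array([
            [0, 1, 0, 2],
            [0, 1, 2, 0],
            [2, 1, 2, 0],
            [np.nan, np.nan, np.nan, 0],
        ])
        m = toy_matrix(codes)
        out, report = genotype.filter_markers(
            m, maf_min=0.05, het_max=0.10, marker_missing_max=0.20,
            line_missing_max=0.5)
        assert list(out.line_ids) == ["L0", "L1", "L2"]
        assert "M1" not in out.marker_ids          # het rate 1.0
        assert report.n_lines_removed == 1
        assert report.n_markers_removed_het == 1

    def test_low_maf_and_monomorphic_markers_removed(self):
        codes = np.zeros((50, 3))
        codes[:, 1] = 2.0                          # monomorphic non-zero
        codes[0, 2] = 1.0                          # MAF 1/100 = 0.01
        codes[:, 0] = np.tile([0, 2], 25)          # MAF 0.5, kept
        m = toy_matrix(codes)
        out, report = genotype.filter_markers(m, het_max=1.0)
        assert list(out.marker_ids) == ["M0"]
        assert report.n_markers_removed_maf == 2

    def test_filtering_is_idempotent(self, small_panel):
        m, _, _ = small_panel
        once, _ = genotype.filter_markers(m)
        twice, rep2 = genotype.filter_markers(once)
        assert np.array_equal(once.codes, twice.codes)
        assert rep2.n_lines_removed == 0
        assert rep2.n_markers_removed_maf == 0

    def test_everything_filtered_raises(self):
        m = toy_matrix(np.ones((4, 2)))            # all het
        with pytest.raises(ValueError, match="no markers"):
            genotype.filter_markers(m)


class TestImputation:
    def test_missing_cell_gets_marker_mean(self):
        m = toy_matrix([[0], [2], [np.nan]])
        out = genotype.impute_missing(m)
        assert out.codes[2, 0] == pytest.approx(1.0)
        np.testing.assert_array_equal(out.codes[:2, 0], [0, 2])

    def test_no_missing_is_identity_and_means_preserved(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, (30, 10)).astype(float)
        codes[rng.random((30, 10)) < 0.2] = np.nan
        m = toy_matrix(codes)
        out = genotype.impute_missing(m)
        obs_means = np.nanmean(codes, axis=0)
        np.testing.assert_allclose(out.codes.mean(axis=0), obs_means,
                                   atol=1e-12)
        clean = toy_matrix(np.nan_to_num(codes, nan=1.0))
        assert np.array_equal(genotype.impute_missing(clean).codes,
                              clean.codes)

    def test_all_missing_marker_raises(self):
        m = toy_matrix([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="no observed"):
            genotype.impute_missing(m)


class TestGRM:
    def test_hand_computed_three_line_toy(self):
        codes = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        m = toy_matrix(codes)
        p = codes.mean(axis=0) / 2          # (0.5, 0.5)
        W = codes - 2 * p
        c = np.sum(2 * p * (1 - p))         # 1.0
        expected = W @ W.T / c
        K = genotype.compute_grm(m)
        np.testing.assert_allclose(K.values, expected, atol=1e-12)

    def test_duplicated_lines_have_equal_entries(self, small_panel):
        m, _, _ = small_panel
        codes = np.vstack([m.codes, m.codes[[0]]])
        dup = MarkerMatrix(
            line_ids=np.append(m.line_ids, "DUP"),
            marker_ids=m.marker_ids, codes=codes)
        K = genotype.compute_grm(dup).values
        i, j = 0, len(codes) - 1
        assert K[i, i] == pytest.approx(K[j, j], abs=1e-10)
        assert K[i, i] == pytest.approx(K[i, j], abs=1e-10)

    def test_allele_flip_invariance(self, small_panel):
        m, _, _ = small_panel
        K1 = genotype.compute_grm(m).values
        flipped = toy_matrix(m.codes.copy())
        flipped.codes[:, ::3] = 2 - flipped.codes[:, ::3]
        K2 = genotype.compute_grm(flipped).values
        np.testing.assert_allclose(K1, K2, atol=1e-9)

    def test_centering_and_psd(self, small_panel):
        m, _, _ = small_panel
        K = genotype.compute_grm(m).values
        assert float(np.mean(K @ np.ones(K.shape[0]))) == pytest.approx(
            0.0, abs=1e-8)
        ev = np.linalg.eigvalsh(K)
        assert ev.min() > -1e-8

    def test_zero_variance_marker_rejected(self):
        m = toy_matrix([[1.0, 0.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            genotype.compute_grm(m)


class TestPCA:
    def test_rank_two_matrix_has_two_components(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(20, 2)) @ rng.normal(size=(2, 50))
        m = toy_matrix(A)
        with pytest.warns(UserWarning, match="clipped"):
            pcs = genotype.genotype_pca(m, n_components=100)
        assert np.all(pcs.explained_variance_fraction[2:] < 1e-12)
        assert np.all(np.diff(pcs.explained_variance_fraction) <= 1e-15)

    def test_scores_reconstruct_centered_matrix(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, (15, 10)).astype(float)
        m = toy_matrix(codes)
        pcs = genotype.genotype_pca(m, n_components=10)
        W = codes - codes.mean(axis=0)
        # scores = U s; full reconstruction via V from lstsq
        V, *_ = np.linalg.lstsq(pcs.scores, W, rcond=None)
        np.testing.assert_allclose(pcs.scores @ V, W, atol=1e-8)

    def test_pc1_separates_divergent_subpopulations(self):
        cfg = simulate.SimulationConfig(
            n_lines=200, n_markers=500, n_qtl=10, subpop_divergence=0.4,
            n_locations=2, n_years=1, seed=8)
        m, truth = simulate.simulate_genotypes(cfg)
        pcs = genotype.genotype_pca(m, n_components=2)
        sp = truth.subpop_labels.to_numpy()
        sign = np.sign(pcs.scores[:, 0])
        agree = max((sign[sp == 0] > 0).mean() + (sign[sp == 1] < 0).mean(),
                    (sign[sp == 0] < 0).mean() + (sign[sp == 1] > 0).mean())
        assert agree / 2 >= 0.95

    def test_marker_permutation_leaves_scores_unchanged(self, small_panel):
        m, _, _ = small_panel
        pcs1 = genotype.genotype_pca(m, n_components=5)
        rng = np.random.default_rng(3)
        perm = rng.permutation(m.n_markers)
        m2 = toy_matrix(m.codes[:, perm])
        pcs2 = genotype.genotype_pca(m2, n_components=5)
        for k in range(5):
            r = abs(np.corrcoef(pcs1.scores[:, k], pcs2.scores[:, k])[0, 1])
            assert r == pytest.approx(1.0, abs=1e-8)
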