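import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import codonforge as cf
from codonforge.exceptions import UndefinedStatisticError

from _oracles import brute_force_ca, midrank_spearman_oracle


def random_rscu_matrix(rng, n_genes, code):
    """Gene x 59 RSCU matrix from random codon count tables."""
    tables = []
    for _ in range(n_genes):
        counts = {c: int(rng.integers(0, 25)) for c in code.sense_codons}
        counts["GCT"] += 1  # guarantee a non-empty gene
        tables.append(cf.CodonCountTable(counts))
    return cf.build_rscu_matrix(tables, code)


class TestBuildMatrix:
    def test_uniform_genes_all_ones(self, code):
        t = cf.CodonCountTable({c: 7 for c in code.sense_codons})
        matrix = cf.build_rscu_matrix([t, t], code)
        assert matrix.shape == (2, 59)
        assert np.allclose(matrix.to_numpy(), 1.0)

    def test_missing_family_imputed_zero(self, code):
        full = cf.CodonCountTable({c: 3 for c in code.sense_codons})
        no_cys = cf.CodonCountTable(
            {c: 3 for c in code.sense_codons if not c.startswith("TG")})
        matrix = cf.build_rscu_matrix([full, no_cys], code)
        assert matrix.iloc[1][["TGT", "TGC"]].tolist() == [0.0, 0.0]

    def test_always_59_columns(self, code):
        rng = np.random.default_rng(0)
        matrix = random_rscu_matrix(rng, 4, code)
        assert matrix.shape[1] == 59
        assert "ATG" not in matrix.columns and "TGG" not in matrix.columns

    def test_fewer_than_two_genes_rejected(self, code):
        t = cf.CodonCountTable({"GCT": 1})
        with pytest.raises(UndefinedStatisticError):
            cf.build_rscu_matrix([t], code)


class TestCorrespondenceAnalysis:
    def test_proportional_rows_have_zero_inertia(self, code):
        row = np.arange(1.0, 6.0)
        matrix = pd.DataFrame([row, 2 * row, 0.5 * row])
        result = cf.correspondence_analysis(matrix, n_axes=2)
        assert result.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_fixed_toy_matrix_matches_brute_force(self):
        matrix = pd.DataFrame([
            [4.0, 1.0, 2.0, 0.0, 3.0],
            [1.0, 5.0, 1.0, 2.0, 1.0],
            [2.0, 1.0, 4.0, 1.0, 0.0],
            [0.0, 2.0, 1.0, 5.0, 2.0],
        ])
        result = cf.correspondence_analysis(matrix, n_axes=3)
        inertias, coords, total = brute_force_ca(matrix.to_numpy())
        assert result.total_inertia == pytest.approx(total)
        assert np.allclose(result.inertia, inertias[:3])
        for k in range(3):
            got = result.gene_coords.iloc[:, k].to_numpy()
            want = coords[:, k]
            assert np.allclose(got, want) or np.allclose(got, -want)

    def test_total_inertia_is_chi2_over_grand_total(self):
        rng = np.random.default_rng(7)
        m = rng.integers(1, 30, size=(6, 8)).astype(float)
        result = cf.correspondence_analysis(pd.DataFrame(m), n_axes=5)
        grand = m.sum()
        expected = m.sum(axis=1)[:, None] * m.sum(axis=0)[None, :] / grand
        chi2 = ((m - expected) ** 2 / expected).sum()
        assert result.total_inertia == pytest.approx(chi2 / grand)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_rscu_matrices_match_oracle(self, code, seed):
        rng = np.random.default_rng(seed)
        matrix = random_rscu_matrix(rng, int(rng.integers(4, 11)), code)
        result = cf.correspondence_analysis(matrix, n_axes=3)
        inertias, _, total = brute_force_ca(matrix.to_numpy())
        assert np.allclose(result.inertia_fractions,
                           inertias[:3] / total, atol=1e-8)

    def test_axis_orthogonality_under_row_masses(self, code):
        rng = np.random.default_rng(3)
        matrix = random_rscu_matrix(rng, 10, code)
        result = cf.correspondence_analysis(matrix, n_axes=4)
        coords = result.gene_coords.to_numpy()
        w = result.row_masses.to_numpy()
        gram = (coords * w[:, None]).T @ coords
        off_diag = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off_diag)) < 1e-8

    def test_inertia_fractions_non_increasing(self, code):
        rng = np.random.default_rng(4)
        matrix = random_rscu_matrix(rng, 8, code)
        result = cf.correspondence_analysis(matrix, n_axes=5)
        assert np.all(np.diff(result.inertia_fractions) <= 1e-12)

    def test_matches_vegan_unconstrained_ca(self, code, tmp_path):
        """Inertia fractions agree with R vegan's cca() on the same
        matrix (independent implementation)."""
        rng = np.random.default_rng(12)
        matrix = random_rscu_matrix(rng, 7, code)
        result = cf.correspondence_analysis(matrix, n_axes=5)
        csv = tmp_path / "m.csv"
        matrix.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            m <- as.matrix(read.csv("{csv}"))
            ev <- cca(m)$CA$eig
            cat(sprintf("%.12f", ev / sum(ev)), sep="\\n")
        """)
        proc = subprocess.run(["Rscript", "-e", script],
                              capture_output=True, text=True, check=True)
        vegan = np.array([float(v) for v in proc.stdout.split()])
        assert np.allclose(result.inertia_fractions, vegan[:5], atol=1e-8)

    def test_zero_grand_total_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cf.correspondence_analysis(pd.DataFrame(np.zeros((3, 4))))


class TestOrientation:
    def test_gc3_anchor_gives_nonnegative_correlation(self, code):
        rng = np.random.default_rng(5)
        matrix = random_rscu_matrix(rng, 10, code)
        result = cf.correspondence_analysis(matrix, n_axes=3)
        anchor = pd.Series(rng.random(10), index=matrix.index)
        cf.orient_axes(result, anchor)
        for axis in result.gene_coords.columns:
            rho, _ = cf.spearman(result.gene_coords[axis], anchor)
            assert rho >= 0

    def test_orientation_is_deterministic(self, code):
        rng = np.random.default_rng(6)
        matrix = random_rscu_matrix(rng, 8, code)
        anchor = pd.Series(np.arange(8.0), index=matrix.index)
        a = cf.orient_axes(cf.correspondence_analysis(matrix, 3), anchor)
        b = cf.orient_axes(cf.correspondence_analysis(matrix, 3), anchor)
        pd.testing.assert_frame_equal(a.gene_coords, b.gene_coords)


class TestAxisCorrelations:
    def test_axis_equal_to_index_gives_rho_one(self, code):
        rng = np.random.default_rng(8)
        matrix = random_rscu_matrix(rng, 10, code)
        result = cf.correspondence_analysis(matrix, n_axes=2)
        records = pd.DataFrame(
            {"gc3": result.gene_coords["axis1"].rank()},
            index=matrix.index)
        table = cf.axis_index_correlations(result, records,
                                           columns=("gc3",))
        assert table.loc["axis1", ("gc3", "rho")] == pytest.approx(1.0)

    def test_constant_index_flagged_undefined(self, code):
        rng = np.random.default_rng(9)
        matrix = random_rscu_matrix(rng, 6, code)
        result = cf.correspondence_analysis(matrix, n_axes=2)
        records = pd.DataFrame({"enc": np.full(6, 61.0)}, index=matrix.index)
        table = cf.axis_index_correlations(result, records, columns=("enc",))
        assert np.isnan(table.loc["axis1", ("enc", "rho")])

    def test_codon_correlations_match_midrank_oracle(self, code):
        rng = np.random.default_rng(10)
        matrix = random_rscu_matrix(rng, 8, code)
        result = cf.correspondence_analysis(matrix, n_axes=2)
        table = cf.axis_codon_correlations(result, matrix)
        codon = "GCT"
        want = midrank_spearman_oracle(
            result.gene_coords["axis1"].tolist(), matrix[codon].tolist())
        assert table.loc["axis1", (codon, "rho")] == pytest.approx(want)

    def test_twofold_partners_anticorrelate(self, code):
        """RSCU of two-codon family partners sums to 2, so their axis
        correlations carry opposite signs when both are defined."""
        rng = np.random.default_rng(11)
        matrix = random_rscu_matrix(rng, 10, code)
        result = cf.correspondence_analysis(matrix, n_axes=1)
        table = cf.axis_codon_correlations(result, matrix)
        r_t = table.loc["axis1", ("TTT", "rho")]
        r_c = table.loc["axis1", ("TTC", "rho")]
        if not (np.isnan(r_t) or np.isnan(r_c) or r_t == 0 or r_c == 0):
            assert np.sign(r_t) == -np.sign(r_c)
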