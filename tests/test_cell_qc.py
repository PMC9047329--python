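"""Cell filtering, marker typing, differential genes and signatures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orgscope import (
    GroupSpec,
    MarkerSet,
    Program,
    TruthConfig,
    assign_types,
    coexpression_fraction,
    expression_bins,
    filter_cells,
    generate_population,
    mito_ratio,
    select_degs,
    tpm_normalize,
)

TWO_ARM = (GroupSpec("tumor", "invivo"), GroupSpec("normal", "invivo"))


def _tpm_from_counts(arr, genes=None, cells=None):
    counts = pd.DataFrame(
        arr,
        index=genes or [f"g{i}" for i in range(arr.shape[0])],
        columns=cells or [f"c{i}" for i in range(arr.shape[1])],
    )
    return tpm_normalize(counts)


class TestFilterCells:
    def test_exactly_2000_detected_genes_removed(self, rng):
        """The detected-gene threshold is strict: exactly 2000 fails."""
        base = rng.integers(1, 10, size=(2500, 3))
        counts = pd.DataFrame(base, columns=["a", "b", "c"])
        counts.iloc[2000:, 0] = 0  # cell a detects exactly 2000 genes
        tpm = tpm_normalize(counts)
        kept, diag = filter_cells(tpm, min_genes=2000, min_top2_corr=-2)
        assert "a" not in kept and {"b", "c"} <= set(kept)
        assert diag.loc["a", "reason"] == "low_gene_count"

    def test_identical_cells_all_kept(self):
        col = np.arange(1, 11)
        tpm = _tpm_from_counts(np.tile(col[:, None], (1, 3)))
        kept, diag = filter_cells(tpm, min_genes=5, min_top2_corr=0.6)
        assert len(kept) == 3
        assert np.allclose(diag["top2_corr"], 1.0)

    def test_planted_outliers_fail_correlation(self, rng):
        """5 independent-noise cells fail the top-2 correlation filter exactly."""
        n_genes = 400
        profile = rng.lognormal(2, 1, size=n_genes)
        good = rng.poisson(profile[:, None] * np.ones((1, 40)))
        outliers = rng.poisson(rng.lognormal(2, 1, size=(n_genes, 5)))
        counts = np.hstack([good, outliers])
        cells = [f"good{i}" for i in range(40)] + [f"odd{i}" for i in range(5)]
        tpm = _tpm_from_counts(counts, cells=cells)
        kept, diag = filter_cells(tpm, min_genes=50, min_top2_corr=0.6)
        assert set(cells) - set(kept) == {f"odd{i}" for i in range(5)}
        # brute-force correlation oracle for one cell
        X = np.log2(tpm.to_numpy() + 1)
        c0 = [stats.pearsonr(X[:, 0], X[:, j])[0] for j in range(1, 45)]
        assert diag["top2_corr"].iloc[0] == pytest.approx(sorted(c0)[-2])

    def test_fewer_than_three_cells_error(self):
        tpm = _tpm_from_counts(np.ones((10, 2)))
        with pytest.raises(ValueError):
            filter_cells(tpm)

    def test_monotone_in_thresholds(self, rng):
        counts = rng.poisson(3, size=(300, 30))
        tpm = _tpm_from_counts(counts)
        strict, _ = filter_cells(tpm, min_genes=250, min_top2_corr=0.5)
        relaxed, _ = filter_cells(tpm, min_genes=200, min_top2_corr=0.3)
        assert set(strict) <= set(relaxed)


class TestMitoRatio:
    def test_no_mito_reads(self):
        counts = pd.DataFrame({"c": [5, 5]}, index=["g1", "g2"])
        frac, med = mito_ratio(counts, ["MT-1"])
        assert frac["c"] == 0 and med == 0

    def test_arithmetic(self):
        counts = pd.DataFrame({"c": [134, 866]}, index=["MT-1", "g1"])
        frac, med = mito_ratio(counts, ["MT-1"])
        assert frac["c"] == pytest.approx(0.134)

    def test_zero_read_cell_flagged_nan(self):
        counts = pd.DataFrame({"c": [0, 0], "d": [1, 1]}, index=["MT-1", "g1"])
        frac, _ = mito_ratio(counts, ["MT-1"])
        assert np.isnan(frac["c"]) and frac["d"] == 0.5

    def test_cohort_median_recovered(self):
        """Generator plants a median mitochondrial share of 0.134."""
        cfg = TruthConfig(n_patients=1, cells_per_group=150, groups=TWO_ARM, seed=8)
        truth, matrix = generate_population(cfg)
        mt = list(truth.genes.index[truth.genes["chrom"] == "chrM"])
        _, med = mito_ratio(matrix.counts, mt)
        assert abs(med - 0.134) <= 0.01


class TestAssignTypes:
    def test_single_marker_dominance(self):
        tpm = pd.DataFrame(
            {"c": [100.0, 0, 0, 0]}, index=["EPCAM", "VIM", "THY1", "PTPRC"]
        )
        out = assign_types(tpm)
        assert out.loc["c", "label"] == "epithelial"

    def test_all_zero_cell_unassigned(self):
        tpm = pd.DataFrame({"c": [0.0, 0, 0, 0]}, index=["EPCAM", "VIM", "THY1", "PTPRC"])
        assert assign_types(tpm).loc["c", "label"] == "unassigned"

    def test_missing_markers_error(self):
        tpm = pd.DataFrame({"c": [1.0]}, index=["GAPDH"])
        with pytest.raises(ValueError):
            assign_types(tpm)

    def test_tie_breaks_by_fixed_order(self):
        tpm = pd.DataFrame(
            {"c": [10.0, 10.0, 10.0, 10.0]}, index=["EPCAM", "VIM", "THY1", "PTPRC"]
        )
        # epithelial and immune scores tie; epithelial comes first in order
        out = assign_types(tpm, MarkerSet(types={"epithelial": ["EPCAM"], "immune": ["PTPRC"]}))
        assert out.loc["c", "label"] == "epithelial"

    def test_planted_programs_recovered(self):
        """Marker-score typing reaches >= 95% accuracy at default strength."""
        cfg = TruthConfig(n_patients=1, cells_per_group=300, groups=TWO_ARM, seed=9)
        truth, matrix = generate_population(cfg)
        out = assign_types(matrix.tpm)
        acc = (out["label"] == truth.cells["cell_type"]).mean()
        assert acc >= 0.95


class TestSelectDegs:
    def test_a_only_gene_selected(self):
        tpm = pd.DataFrame(
            {
                **{f"a{i}": [100.0, 50.0] for i in range(10)},
                **{f"b{i}": [0.0, 50.0] for i in range(10)},
            },
            index=["g_spec", "g_flat"],
        )
        out = select_degs(tpm, [f"a{i}" for i in range(10)], [f"b{i}" for i in range(10)])
        assert list(out.index) == ["g_spec"]

    def test_identical_groups_empty(self, rng):
        tpm = _tpm_from_counts(rng.poisson(5, size=(50, 20)))
        cells = list(tpm.columns)
        out = select_degs(tpm, cells[:10], cells[:10])
        assert out.empty

    def test_empty_group_error(self, rng):
        tpm = _tpm_from_counts(rng.poisson(5, size=(10, 4)))
        with pytest.raises(ValueError):
            select_degs(tpm, [], list(tpm.columns))

    def test_disjoint_ab_ba(self, rng):
        tpm = _tpm_from_counts(rng.poisson(5, size=(100, 30)))
        cells = list(tpm.columns)
        ab = select_degs(tpm, cells[:15], cells[15:], logfc_threshold=0.1, min_pct=0, min_diff_pct=0)
        ba = select_degs(tpm, cells[15:], cells[:15], logfc_threshold=0.1, min_pct=0, min_diff_pct=0)
        assert set(ab.index).isdisjoint(ba.index)

    def test_planted_recall_and_fpr(self):
        """50 planted tumor-specific genes: recall >= 0.9, FPR <= 0.01."""
        planted = tuple(f"G{i:05d}" for i in range(50))
        cfg = TruthConfig(
            n_patients=1,
            cells_per_group=150,
            groups=TWO_ARM,
            n_genes=1000,
            cnv_segments=(),
            extra_programs=(
                Program(planted, {"tissue": "tumor"}, fold=8.0,
                        on_frac_carrier=0.8, on_frac_other=0.05),
            ),
            seed=10,
        )
        truth, matrix = generate_population(cfg)
        a = truth.carriers({"tissue": "tumor"})
        b = truth.carriers({"tissue": "normal"})
        out = select_degs(matrix.tpm, a, b)
        hits = set(out.index) & set(planted)
        false_hits = set(out.index) - set(planted) - {"EPCAM", "VIM", "THY1", "PTPRC"}
        nulls = matrix.tpm.shape[0] - len(planted)
        assert len(hits) / len(planted) >= 0.9
        assert len(false_hits) / nulls <= 0.01


class TestSignatures:
    def test_coexpression_threshold_inf(self, rng):
        tpm = _tpm_from_counts(rng.poisson(5, size=(5, 10)), genes=["EPCAM", "VIM", "a", "b", "c"])
        groups = pd.Series(["g"] * 10, index=tpm.columns)
        out = coexpression_fraction(tpm, "EPCAM", "VIM", groups, threshold=np.inf)
        assert out["frac_coexpressing"].iloc[0] == 0

    def test_coexpression_arithmetic(self):
        vals = np.zeros((2, 10))
        vals[:, :2] = 100.0  # 2 of 10 cells co-express
        tpm = pd.DataFrame(vals, index=["EPCAM", "VIM"], columns=[f"c{i}" for i in range(10)])
        groups = pd.Series(["g"] * 10, index=tpm.columns)
        out = coexpression_fraction(tpm, "EPCAM", "VIM", groups)
        assert out["frac_coexpressing"].iloc[0] == pytest.approx(0.2)

    def test_absent_gene_error(self, rng):
        tpm = _tpm_from_counts(rng.poisson(5, size=(2, 5)))
        groups = pd.Series(["g"] * 5, index=tpm.columns)
        with pytest.raises(KeyError):
            coexpression_fraction(tpm, "EPCAM", "VIM", groups)

    def test_planted_coexpressor_fraction_recovered(self, rng):
        """30% planted co-expressors recovered within 0.03 at n=1000."""
        n = 1000
        coexp = rng.random(n) < 0.30
        epcam = np.where(coexp, 50.0, rng.choice([0.0, 50.0], size=n))
        vim = np.where(coexp, 50.0, 0.0)
        tpm = pd.DataFrame([epcam, vim], index=["EPCAM", "VIM"],
                           columns=[f"c{i}" for i in range(n)])
        groups = pd.Series(["g"] * n, index=tpm.columns)
        out = coexpression_fraction(tpm, "EPCAM", "VIM", groups)
        assert abs(out["frac_coexpressing"].iloc[0] - coexp.mean()) < 1e-12
        assert abs(out["frac_coexpressing"].iloc[0] - 0.30) <= 0.03


class TestExpressionBins:
    def test_single_bin_all_ones(self, rng):
        tpm = _tpm_from_counts(rng.poisson(5, size=(2, 10)), genes=["MKI67", "g"])
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=tpm.columns)
        props, p = expression_bins(tpm, groups, bin_edges=())
        assert (props.to_numpy() == 1.0).all()

    def test_uniform_null_p_near_one(self):
        vals = np.array([[0.0] * 10 + [50.0] * 10 + [0.0] * 10 + [50.0] * 10])
        tpm = pd.DataFrame(np.vstack([vals, vals]), index=["MKI67", "g"],
                           columns=[f"c{i}" for i in range(40)])
        groups = pd.Series(["a"] * 20 + ["b"] * 20, index=tpm.columns)
        props, p = expression_bins(tpm, groups, bin_edges=(0.0,))
        assert p > 0.99
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_unsorted_edges_rejected(self, rng):
        tpm = _tpm_from_counts(rng.poisson(5, size=(1, 10)), genes=["MKI67"])
        groups = pd.Series(["a"] * 10, index=tpm.columns)
        with pytest.raises(ValueError):
            expression_bins(tpm, groups, bin_edges=(0.0, 100.0, 10.0))

    def test_planted_shift_detected_with_power(self, rng):
        """2:1 bin-proportion shift at n=500/group: p < 0.01 in >= 90% of reps."""
        reps, hits = 200, 0
        for _ in range(reps):
            a = np.where(rng.random(500) < 2 / 3, 50.0, 0.0)
            b = np.where(rng.random(500) < 1 / 3, 50.0, 0.0)
            tpm = pd.DataFrame([np.concatenate([a, b])], index=["MKI67"],
                               columns=[f"c{i}" for i in range(1000)])
            groups = pd.Series(["a"] * 500 + ["b"] * 500, index=tpm.columns)
            _, p = expression_bins(tpm, groups, bin_edges=(0.0,))
            hits += p < 0.01
        assert hits / reps >= 0.9
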