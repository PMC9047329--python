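"""Expression-CNV: moving-average scores, centering, genomic windows."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from orgscope import (
    CnvSegment,
    GroupSpec,
    TruthConfig,
    cnv_profile,
    filter_cnv_genes,
    gene_cnv_scores,
    generate_population,
    tpm_normalize,
    window_cnv,
)
from orgscope.containers import make_gene_track
from orgscope.cnv_expr import relative_expression

TWO_ARM = (GroupSpec("tumor", "invivo"), GroupSpec("normal", "invivo"))


def brute_force_scores(E: pd.DataFrame, track: pd.DataFrame, k: int = 100) -> pd.DataFrame:
    """Independent O(n*k) recomputation: per gene, average E over the k/2
    ordinal neighbours each side on the same chromosome (self included,
    shrunk at ends), then subtract the per-gene cross-cell mean."""
    half = k // 2
    out = pd.DataFrame(index=E.index, columns=E.columns, dtype=float)
    for chrom in track["chrom"].unique():
        genes = track[track["chrom"] == chrom].sort_values("ordinal").index
        for j, g in enumerate(genes):
            lo, hi = max(0, j - half), min(len(genes), j + half + 1)
            out.loc[g] = E.loc[genes[lo:hi]].mean(axis=0)
    return out.sub(out.mean(axis=1), axis=0)


def brute_force_windows(scores, track, window_bp=10_000_000):
    rows = {}
    for g in scores.index:
        key = (track.loc[g, "chrom"], track.loc[g, "start"] // window_bp)
        rows.setdefault(key, []).append(g)
    data = {key: scores.loc[gs].mean(axis=0) for key, gs in rows.items()}
    return pd.DataFrame(data).T.sort_index()


def _random_instance(rng, n_genes, n_cells, n_chroms=3):
    ids = [f"g{i}" for i in range(n_genes)]
    chroms = [f"chr{rng.integers(1, n_chroms + 1)}" for _ in ids]
    starts = rng.integers(0, 50_000_000, size=n_genes).tolist()
    track = make_gene_track(ids, chroms, starts)
    E = pd.DataFrame(
        rng.lognormal(1, 1, size=(n_genes, n_cells)),
        index=ids,
        columns=[f"c{i}" for i in range(n_cells)],
    ).loc[track.index]
    return E, track


class TestFilterGenes:
    def test_all_zero_gene_removed(self):
        tpm = pd.DataFrame({"c1": [0.0, 1e6], "c2": [0.0, 1e6]}, index=["dead", "live"])
        assert filter_cnv_genes(tpm) == ["live"]

    def test_threshold_is_strict(self):
        # E = log2(TPM/10 + 1) == 1.5 exactly when TPM = 10*(2^1.5 - 1)
        tpm_at_edge = 10 * (2**1.5 - 1)
        tpm = pd.DataFrame(
            {"c": [tpm_at_edge, tpm_at_edge + 1]}, index=["edge", "above"]
        )
        assert filter_cnv_genes(tpm) == ["above"]

    def test_empty_result_errors(self):
        tpm = pd.DataFrame({"c1": [0.0], "c2": [0.0]}, index=["g"])
        with pytest.raises(ValueError, match="min_avg_rel_expr"):
            filter_cnv_genes(tpm)

    def test_matches_brute_force_oracle(self, rng):
        tpm = pd.DataFrame(
            rng.lognormal(3, 2, size=(100, 10)),
            index=[f"g{i}" for i in range(100)],
        )
        expected = [
            g
            for g in tpm.index
            if np.log2(tpm.loc[g] / 10 + 1).mean() > 1.5
        ]
        assert filter_cnv_genes(tpm) == expected


class TestGeneScores:
    def test_constant_matrix_zero_after_centering(self):
        ids = [f"g{i}" for i in range(20)]
        track = make_gene_track(ids, ["chr1"] * 20, list(range(0, 20_000, 1000)))
        E = pd.DataFrame(3.7, index=track.index, columns=["a", "b", "c"])
        scores = gene_cnv_scores(E, track, k=10)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_single_cell_all_zero(self, rng):
        E, track = _random_instance(rng, 30, 1)
        scores = gene_cnv_scores(E, track, k=10)
        assert np.allclose(scores.to_numpy(), 0.0)

    def test_toy_matrix_equals_brute_force(self, rng):
        E, track = _random_instance(rng, 5, 3, n_chroms=1)
        got = gene_cnv_scores(E, track, k=100)
        want = brute_force_scores(E, track, k=100)
        assert np.allclose(got.to_numpy(), want.loc[got.index, got.columns].to_numpy(), atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_randomized_oracle_equivalence(self, seed):
        """Randomized <= 50-gene x <= 20-cell instances match the oracle to 1e-12."""
        rng = np.random.default_rng(seed)
        E, track = _random_instance(rng, int(rng.integers(5, 51)), int(rng.integers(2, 21)))
        k = int(rng.choice([4, 10, 100]))
        got = gene_cnv_scores(E, track, k=k)
        want = brute_force_scores(E, track, k=k)
        assert np.allclose(got.to_numpy(), want.loc[got.index, got.columns].to_numpy(), atol=1e-12)

    def test_shift_invariance(self, rng):
        E, track = _random_instance(rng, 40, 5)
        p1 = window_cnv(gene_cnv_scores(E, track), track)
        p2 = window_cnv(gene_cnv_scores(E + 11.0, track), track)
        assert np.allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-9)


class TestWindows:
    def test_all_genes_one_window_mean(self, rng):
        ids = [f"g{i}" for i in range(10)]
        track = make_gene_track(ids, ["chr1"] * 10, list(range(0, 10_000, 1000)))
        scores = pd.DataFrame(
            rng.normal(size=(10, 4)), index=track.index, columns=list("abcd")
        )
        scores = scores.sub(scores.mean(axis=1), axis=0)
        prof = window_cnv(scores, track)
        assert prof.shape[0] == 1
        assert np.allclose(prof.iloc[0], scores.mean(axis=0))

    def test_empty_windows_missing_not_zero(self):
        ids = ["g1", "g2"]
        track = make_gene_track(ids, ["chr1", "chr1"], [0, 25_000_000])
        scores = pd.DataFrame({"c": [0.5, -0.5]}, index=track.index)
        prof = window_cnv(scores, track)
        assert list(prof.index) == [("chr1", 0), ("chr1", 2)]  # window 1 absent

    def test_windows_match_brute_force(self, rng):
        E, track = _random_instance(rng, 50, 8)
        scores = gene_cnv_scores(E, track, k=10)
        got = window_cnv(scores, track)
        want = brute_force_windows(scores, track)
        assert np.allclose(got.to_numpy(), want.loc[got.index, got.columns].to_numpy(), atol=1e-12)


class TestPlantedSignal:
    def test_planted_gain_separates_windows(self, cnv_cohort):
        truth, matrix = cnv_cohort
        profile, _ = cnv_profile(matrix.tpm, truth.genes)
        carriers = truth.carriers({"tissue": "tumor"})
        others = truth.carriers({"tissue": "normal"})
        diff = profile[carriers].mean(axis=1) - profile[others].mean(axis=1)
        planted = [ix for ix in profile.index if ix[0] == "chr1" and ix[1] in (3, 4, 5)]
        assert (diff.loc[planted] > 0).all()
        null = diff.drop(planted).abs()
        assert (null < diff.loc[planted].min()).mean() > 0.95

    @pytest.mark.parametrize("ratios", [(1.25, 1.5), (1.5, 2.0)])
    def test_monotone_in_copy_ratio(self, ratios):
        """A larger planted copy ratio yields a larger mean carrier score."""
        means = []
        for cr in ratios:
            cfg = TruthConfig(
                n_patients=1,
                cells_per_group=100,
                groups=TWO_ARM,
                n_genes=1500,
                cnv_segments=(
                    CnvSegment("chr1", 30_000_000, 60_000_000, cr, {"tissue": "tumor"}),
                ),
                seed=17,
            )
            truth, matrix = generate_population(cfg)
            profile, _ = cnv_profile(matrix.tpm, truth.genes)
            carriers = truth.carriers({"tissue": "tumor"})
            planted = [ix for ix in profile.index if ix[0] == "chr1" and ix[1] in (3, 4, 5)]
            means.append(profile.loc[planted, carriers].to_numpy().mean())
        assert means[0] < means[1]
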