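"""Metagene profiles, binning, heatmap ordering and junction ratios."""

import numpy as np
import pandas as pd
import pytest

from crackit.annotation import Transcript
from crackit.profiles import (
    anchored_profile,
    bin_edges,
    binned_profile,
    heatmap_matrix,
    junction_ratio,
)
from crackit.synthetic import simulate_junction_reads


def _cov(length=1000, strand_vals=None):
    cov = {("c", "+"): np.zeros(length), ("c", "-"): np.zeros(length)}
    for (s, a, b, v) in strand_vals or []:
        cov[("c", s)][a:b] = v
    return cov


class TestAnchoredProfile:
    def test_uniform_gene_gives_flat_unit_row(self):
        t = Transcript("T", "c", "+", 100, 400)
        cov = _cov(strand_vals=[("+", 100, 400, 2.0)])
        prof = anchored_profile(cov, [t], "TSS", window=(0, 299), weighting="per_gene_unit")
        row = prof.matrix.loc["T"]
        assert row.sum() == pytest.approx(1.0)
        assert row.nunique() == 1

    def test_equal_weighting_ignores_coverage_scale(self):
        ts = [Transcript("A", "c", "+", 100, 300), Transcript("B", "c", "+", 500, 700)]
        cov = _cov(strand_vals=[("+", 100, 300, 1.0), ("+", 500, 700, 10.0)])
        prof = anchored_profile(cov, ts, "TSS", window=(0, 199), weighting="per_gene_unit")
        assert np.allclose(prof.matrix.loc["A"], prof.matrix.loc["B"])

    def test_hpm_sum_is_additive_and_dominated_by_high_coverage(self):
        ts = [Transcript("A", "c", "+", 100, 300), Transcript("B", "c", "+", 500, 700)]
        cov = _cov(strand_vals=[("+", 100, 300, 1.0), ("+", 500, 700, 10.0)])
        prof = anchored_profile(cov, ts, "TSS", window=(0, 199), weighting="hpm_sum")
        assert np.allclose(prof.summary, prof.matrix.loc["A"] + prof.matrix.loc["B"])
        assert prof.summary.iloc[0] == pytest.approx(11.0)

    def test_length_filter_excludes_and_counts(self):
        ts = [Transcript("A", "c", "+", 0, 300), Transcript("B", "c", "+", 400, 900)]
        cov = _cov(strand_vals=[("+", 0, 900, 1.0)])
        prof = anchored_profile(
            cov, ts, "TSS", window=(0, 100), weighting="hpm_sum", length_filter=(400, 2000)
        )
        assert list(prof.matrix.index) == ["B"] and prof.n_excluded == 1

    def test_strand_symmetry(self):
        # a minus-strand gene over the mirrored coverage yields the same row
        L = 1000
        ramp = np.arange(200, dtype=float)
        cov = _cov(L)
        cov[("c", "+")][100:300] = ramp
        cov[("c", "-")][L - 300 : L - 100] = ramp[::-1]
        tp = Transcript("P", "c", "+", 100, 300)
        tm = Transcript("M", "c", "-", L - 300, L - 100)
        prof = anchored_profile(cov, [tp, tm], "TSS", window=(0, 199), weighting="per_gene_unit")
        assert np.allclose(prof.matrix.loc["P"], prof.matrix.loc["M"])


class TestBinnedProfile:
    def test_exact_multiple_uniform(self):
        t = Transcript("T", "c", "+", 0, 500)  # 50 bins x 10 nt
        cov = _cov(strand_vals=[("+", 0, 500, 3.0)])
        prof = binned_profile(cov, [t], n_bins=50)
        assert np.allclose(prof.matrix.loc["T"], 30.0)

    def test_remainder_distributed_five_prime_first(self):
        edges = bin_edges(53, 50)
        sizes = np.diff(edges)
        assert list(sizes[:3]) == [2, 2, 2] and set(sizes[3:]) == {1}

    def test_minus_strand_remainder_at_five_prime_end(self):
        t = Transcript("T", "c", "-", 0, 53)
        cov = _cov(60)
        cov[("c", "-")][:53] = 1.0
        prof = binned_profile(cov, [t], n_bins=50)
        row = prof.matrix.loc["T"].to_numpy()
        assert list(row[:3]) == [2, 2, 2]

    def test_bin_totals_conserve_coverage(self, sim):
        rng = np.random.default_rng(4)
        glen = len(sim.seqs["chrI"])
        cov = {
            ("chrI", "+"): rng.poisson(2, glen).astype(float),
            ("chrI", "-"): rng.poisson(2, glen).astype(float),
        }
        prof = binned_profile(cov, sim.transcripts, n_bins=50)
        for tid, row in prof.matrix.iterrows():
            t = sim.transcript(tid)
            assert row.sum() == pytest.approx(cov[(t.chrom, t.strand)][t.start : t.end].sum())

    def test_too_short_transcript_excluded(self):
        t = Transcript("T", "c", "+", 0, 30)
        prof = binned_profile(_cov(100), [t], n_bins=50)
        assert prof.matrix.empty and prof.n_excluded == 1


class TestHeatmap:
    def test_sorted_by_length(self):
        ts = [
            Transcript("A", "c", "+", 0, 900),
            Transcript("B", "c", "+", 1000, 1700),
            Transcript("C", "c", "+", 2000, 2500),
        ]
        cov = _cov(3000, [("+", 0, 3000, 1.0)])
        prof = anchored_profile(cov, ts, "pA", window=(100, 10), weighting="hpm_sum")
        hm, key = heatmap_matrix(prof, sort="length", transcripts=ts)
        assert list(hm.index) == ["A", "B", "C"]
        assert hm.shape[0] == len(prof.matrix)

    def test_sorted_by_fold_change(self):
        ts = [Transcript("A", "c", "+", 0, 500), Transcript("B", "c", "+", 600, 1100)]
        cov = _cov(1200, [("+", 0, 1200, 1.0)])
        prof = anchored_profile(cov, ts, "TSS", window=(0, 100), weighting="hpm_sum")
        fc = pd.Series({"A": -2.0, "B": 3.0})
        hm, _ = heatmap_matrix(prof, sort="fold_change", fold_changes=fc)
        assert list(hm.index) == ["B", "A"]


class TestJunctionRatio:
    def test_ratio_arithmetic(self, sim, sim_cfg):
        reads, truth = simulate_junction_reads(sim, sim_cfg, 0.8, n_reads=10)
        bc = len(sim_cfg.barcode_table["s1"])
        inserts = [
            (r.read_id, r.seq[sim_cfg.umi_len + bc : -len(sim_cfg.adaptor3)])
            for r in reads
        ]
        df, agg = junction_ratio(inserts, sim.transcripts, sim.seqs, min_overhang=3)
        k = int(truth["is_spliced"].sum())
        assert agg["n_spliced"] == k and agg["n_unspliced"] == 10 - k

    def test_zero_unspliced_flagged_undefined(self, sim, sim_cfg):
        reads, _ = simulate_junction_reads(sim, sim_cfg, 1.0, n_reads=20)
        bc = len(sim_cfg.barcode_table["s1"])
        inserts = [
            (r.read_id, r.seq[sim_cfg.umi_len + bc : -len(sim_cfg.adaptor3)])
            for r in reads
        ]
        df, agg = junction_ratio(inserts, sim.transcripts, sim.seqs)
        assert agg["ratio"] is None and df["ratio"].isna().all()

    def test_truth_labels_recovered_exactly(self, sim, sim_cfg):
        reads, truth = simulate_junction_reads(
            sim, sim_cfg, 0.5, n_reads=400, min_overhang=10
        )
        bc = len(sim_cfg.barcode_table["s1"])
        spliced_truth = dict(zip(truth["read_id"], truth["is_spliced"]))
        # classify each read individually via a one-read call
        n_ok = 0
        for r in reads:
            insert = r.seq[sim_cfg.umi_len + bc : -len(sim_cfg.adaptor3)]
            _, agg = junction_ratio(
                [(r.read_id, insert)], sim.transcripts, sim.seqs, min_overhang=3
            )
            called_spliced = agg["n_spliced"] == 1
            called_unspliced = agg["n_unspliced"] == 1
            assert called_spliced or called_unspliced
            assert called_spliced == bool(spliced_truth[r.read_id])
            n_ok += 1
        assert n_ok == len(reads)

    def test_no_intron_annotation_rejected(self, sim):
        flat = [t for t in sim.transcripts if len(t.exons) == 1]
        with pytest.raises(ValueError, match="intron"):
            junction_ratio([], flat, sim.seqs)
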