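"""Counting, HPM normalization, ratios, correlations and cluster assignment."""

import numpy as np
import pandas as pd
import pytest

from crackit.align import ReadAlignment, Aligner, align_reads
from crackit.annotation import Transcript
from crackit.prep import PrepConfig, run_prep
from crackit.quantify import (
    CLUSTER_TABLE,
    assign_cluster,
    assign_clusters,
    average_replicates,
    binding_ratio,
    count_reads,
    fold_change,
    hits_per_million,
    pearson_matrix,
    select_represented,
)
from crackit.synthetic import simulate_crac_reads


def _t(tid, start, end, strand="+", biotype="mRNA", dubious=False):
    return Transcript(tid, "c", strand, start, end, biotype=biotype, dubious=dubious)


def _a(start, end, strand="+", rid="r"):
    return ReadAlignment(rid, "c", strand, start, end)


class TestCountReads:
    def test_read_inside_transcript_counted_once(self):
        counts, unc = count_reads([_a(110, 150)], [_t("A", 100, 400)])
        assert counts["A"] == 1 and unc == 0

    def test_antisense_read_uncounted(self):
        counts, unc = count_reads([_a(110, 150, strand="-")], [_t("A", 100, 400)])
        assert counts["A"] == 0 and unc == 1

    def test_largest_overlap_wins(self):
        ts = [_t("A", 100, 200), _t("B", 180, 400)]
        counts, _ = count_reads([_a(170, 250)], ts)
        assert counts["B"] == 1 and counts["A"] == 0

    def test_dubious_orfs_excluded(self):
        ts = [_t("A", 100, 400, dubious=True)]
        counts, unc = count_reads([_a(110, 150)], ts, excl_dubious=True)
        assert "A" not in counts.index and unc == 1
        counts, unc = count_reads([_a(110, 150)], ts, excl_dubious=False)
        assert counts["A"] == 1

    def test_empty_annotation_rejected(self):
        with pytest.raises(ValueError):
            count_reads([], [])

    def test_synthetic_counts_match_truth_tally(self, sim, sim_cfg):
        reads, truth = simulate_crac_reads(sim, sim_cfg, "PolII", n_reads=500)
        by_sample, _ = run_prep(reads, PrepConfig(barcode_table=sim_cfg.barcode_table))
        assigned, _ = align_reads(by_sample["s1"], Aligner(sim.seqs), seed=0)
        counts, unc = count_reads(assigned, sim.transcripts, excl_dubious=False)
        tally = truth.drop_duplicates("molecule_id")["transcript_id"].value_counts()
        assert unc == 0
        for tid, n in tally.items():
            assert counts[tid] == n
        assert int(counts.sum()) == int(tally.sum())


class TestHitsPerMillion:
    def test_worked_example(self):
        hpm = hits_per_million(pd.Series({"A": 5, "B": 15}))
        assert hpm["A"] == pytest.approx(250_000)

    def test_single_gene_universe_scales_to_million(self):
        hpm = hits_per_million(pd.Series({"A": 7, "B": 3}), universe=["A"])
        assert hpm["A"] == pytest.approx(1e6)

    def test_scale_invariance(self):
        c = pd.Series({"A": 5, "B": 15})
        assert hits_per_million(2 * c).equals(hits_per_million(c))

    def test_rows_sum_to_million_per_sample(self):
        df = pd.DataFrame({"s1": [3, 7, 10], "s2": [1, 1, 2]}, index=list("ABC"))
        hpm = hits_per_million(df)
        assert np.allclose(hpm.sum(), 1e6)

    def test_zero_total_names_sample(self):
        df = pd.DataFrame({"bad": [0, 0]}, index=list("AB"))
        with pytest.raises(ValueError, match="bad"):
            hits_per_million(df)


class TestBindingRatio:
    def test_examples(self):
        f = pd.Series({"A": 100.0, "B": 0.0})
        p = pd.Series({"A": 50.0, "B": 50.0})
        r = binding_ratio(f, p, pseudocount=0.0)
        assert r.loc["A", "ratio"] == pytest.approx(2.0)
        assert r.loc["B", "ratio"] == pytest.approx(0.0)

    def test_library_scaling_invariance(self):
        f = pd.Series({"A": 100.0, "B": 20.0})
        p = pd.Series({"A": 50.0, "B": 10.0})
        r1 = binding_ratio(f, p, 0.0)["ratio"]
        r2 = binding_ratio(3 * f, 3 * p, 0.0)["ratio"]
        # scaling both libraries equally leaves pc=0 ratios unchanged
        assert np.allclose(r1, r2)

    def test_zero_polii_flagged_with_zero_pseudocount(self):
        r = binding_ratio(pd.Series({"A": 5.0}), pd.Series({"A": 0.0}), 0.0)
        assert bool(r.loc["A", "undefined"])


class TestPearson:
    def test_duplicated_sample_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.poisson(50, size=200).astype(float))
        df = pd.DataFrame({"a": v, "b": v, "c": v * 0 + rng.poisson(50, size=200)})
        corr = pearson_matrix(df, top_n=200)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_independent_vectors_nearly_uncorrelated(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(5, 1, size=(2000, 2)), columns=["a", "b"])
        corr = pearson_matrix(df, top_n=2000)
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.lognormal(4, 1, size=(300, 3)), columns=list("abc"))
        corr = pearson_matrix(df, top_n=100, pseudocount=1.0)
        top = df.mean(axis=1).sort_values(ascending=False).index[:100]
        x = np.log2(df.loc[top] + 1.0).to_numpy()
        for i, a in enumerate("abc"):
            for j, b in enumerate("abc"):
                xi, xj = x[:, i], x[:, j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
                assert corr.loc[a, b] == pytest.approx(num / den)

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            pearson_matrix(pd.DataFrame({"a": [1.0, 2.0]}))


class TestFoldChange:
    def test_examples(self):
        s = pd.Series({"A": 8.0})
        assert fold_change(s, s, 1.0)["A"] == 0.0
        assert fold_change(4 * s, s, 1e-9)["A"] == pytest.approx(2.0, abs=1e-6)

    def test_replicate_averaging_on_log_scale(self):
        fcs = [pd.Series({"A": 1.0}), pd.Series({"A": 3.0})]
        avg, single = average_replicates(fcs)
        assert avg["A"] == pytest.approx(2.0) and not single
        avg1, single1 = average_replicates(fcs[:1])
        assert single1 and avg1.equals(fcs[0])


class TestSelectRepresented:
    COUNTS = {
        "PolII": pd.Series({"A": 50, "B": 5, "C": 20}),
        "Nab3": pd.Series({"A": 30, "B": 50, "C": 0}),
        "Mtr4": pd.Series({"A": 12, "B": 50, "C": 50}),
    }

    def test_zero_threshold_keeps_all(self):
        assert set(select_represented(self.COUNTS, 0)) == {"A", "B", "C"}

    def test_gene_missing_in_one_factor_excluded(self):
        assert select_represented(self.COUNTS, 1) == ["A", "B"]

    def test_threshold_applies_to_every_factor(self):
        assert select_represented(self.COUNTS, 10) == ["A"]


class TestClusters:
    def test_biologically_anchored_examples(self):
        # concerted up-regulation of transcription and surveillance binding
        assert assign_cluster("g", 1, 1, 1).cluster_id == 1
        # global shutdown: less transcription, less Nab3/Mtr4
        assert assign_cluster("g", -1, -1, -1).cluster_id == 8
        # reduced Pol II with increased surveillance binding: clusters 5-7
        assert assign_cluster("g", -1, 1, 1).cluster_id == 5
        assert assign_cluster("g", -1, 1, -1).cluster_id == 6
        assert assign_cluster("g", -1, -1, 1).cluster_id == 7

    def test_sign_triples_biject_onto_eight_ids(self):
        ids = {
            assign_cluster("g", p, n, m).cluster_id
            for p in (1, -1)
            for n in (1, -1)
            for m in (1, -1)
        }
        assert ids == set(range(1, 9))
        assert len(CLUSTER_TABLE) == 8

    def test_missing_fold_change_unclassified(self):
        assert assign_cluster("g", np.nan, 1, 1) is None

    def test_epsilon_dead_band_defaults_down(self):
        a = assign_cluster("g", 0.05, 1, 1, epsilon=0.1)
        assert a.sign_polII == "down" and a.cluster_id == 5

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(9)
        fc = pd.DataFrame(
            rng.normal(0, 2, size=(300, 3)), columns=["PolII", "Nab3", "Mtr4"]
        )
        fc.index = [f"g{i}" for i in range(len(fc))]
        got = assign_clusters(fc)["cluster_id"]
        for tid, row in fc.iterrows():
            signs = tuple("up" if v > 0 else "down" for v in row)
            assert got[tid] == CLUSTER_TABLE[signs]
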