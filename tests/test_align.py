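"""Aligner semantics: 5'-anchored maximal extension, one-deletion recovery,
non-templated tails, multi-mapper assignment, SAM round trips, bedgraph."""

import numpy as np
import pytest

from crackit.align import (
    Aligner,
    ReadAlignment,
    align_reads,
    assign_multimappers,
    coverage_vectors,
    import_sam,
    read_bedgraph,
    write_bedgraph,
    write_sam,
)
from crackit.annotation import revcomp
from crackit.prep import PrepConfig, PreppedRead, run_prep
from crackit.synthetic import simulate_crac_reads


def brute_force_best(seq: str, W: str) -> tuple[int, int | None, int]:
    """Independent oracle: best 5'-anchored match of ``seq`` within one
    strand sequence ``W`` allowing at most one skipped genomic nt.
    Returns (matched, local deletion pos or None, local start) of the best
    (max matched; contiguous preferred; leftmost deletion; leftmost start).
    """
    best = (0, None, -1)
    for p in range(len(W)):
        # contiguous
        m = 0
        while m < len(seq) and p + m < len(W) and seq[m] == W[p + m]:
            m += 1
        if m > best[0]:
            best = (m, None, p)
        # one deletion after j matched bases
        for j in range(1, m + 1):
            q = j
            while q < len(seq) and p + q + 1 < len(W) and seq[q] == W[p + q + 1]:
                q += 1
            if q > best[0]:
                best = (q, p + j, p)
    return best


class TestAlignRead:
    def test_exact_substring_maps_cleanly(self, sim, aligner):
        g = sim.seqs["chrI"]
        seq = g[1000:1040]
        (a,) = aligner.align("r", seq)
        assert (a.chrom, a.start, a.end) == ("chrI", 1000, 1040)
        assert a.strand == "+" and a.tail_seq == "" and not a.deletion_positions

    def test_reverse_complement_maps_to_minus_strand(self, sim, aligner):
        g = sim.seqs["chrI"]
        seq = revcomp(g[2000:2045])
        (a,) = aligner.align("r", seq)
        assert (a.strand, a.start, a.end) == ("-", 2000, 2045)

    def test_single_genomic_deletion_recovered(self, sim, aligner):
        g = sim.seqs["chrI"]
        p, skip = 3000, 3025
        seq = g[p:skip] + g[skip + 1 : p + 46]
        (a,) = aligner.align("r", seq)
        matched, del_local, start = brute_force_best(seq, g)
        assert start == p and del_local == skip
        assert a.deletion_positions == (skip,)
        assert (a.start, a.end) == (p, p + 45 + 1)

    def test_nontemplated_tail_reported(self, sim, aligner):
        g = sim.seqs["chrI"]
        # find a spot where the genome does not continue with A twice
        p = next(
            i for i in range(4000, 5000) if g[i + 40] != "A" and g[i + 41] != "A"
        )
        seq = g[p : p + 40] + "AAAA"
        (a,) = aligner.align("r", seq)
        assert a.tail_seq == "AAAA" and (a.start, a.end) == (p, p + 40)
        matched, del_local, start = brute_force_best(seq, g)
        assert matched == 40 and del_local is None

    def test_templated_tail_absorbed_by_maximal_extension(self, sim, aligner):
        g = sim.seqs["chrI"]
        p = next(i for i in range(5000, 7000) if g[i + 40 : i + 42] == "AA")
        seq = g[p : p + 40] + "AA"  # the genome itself continues with AA
        (a,) = aligner.align("r", seq)
        assert a.tail_seq == "" and a.end == p + 42

    def test_agrees_with_brute_force_on_perturbed_reads(self, sim, aligner):
        g = sim.seqs["chrI"]
        rng = np.random.default_rng(3)
        for _ in range(40):
            p = int(rng.integers(200, len(g) - 300))
            L = int(rng.integers(30, 55))
            kind = int(rng.integers(0, 3))
            if kind == 0:
                seq = g[p : p + L]
            elif kind == 1:
                d = int(rng.integers(20, L - 2))
                seq = g[p : p + d] + g[p + d + 1 : p + L + 1]
            else:
                seq = g[p : p + L] + "".join(
                    rng.choice(list("ACGT"), size=4)
                )
            matched, del_local, start = brute_force_best(seq, g)
            hits = aligner.align("r", seq)
            plus = [a for a in hits if a.strand == "+"]
            if not plus:
                continue  # best hit happened to be on the other strand
            a = min(plus, key=lambda a: a.start)
            assert a.score >= matched or a.start != start
            if a.start == start:
                assert a.score == matched
                dels = (del_local,) if del_local is not None else ()
                assert a.deletion_positions == dels

    def test_short_read_unmapped(self, aligner):
        assert aligner.align("r", "ACGTACGT") == []


class TestMultimappers:
    def _two_locus_aligner(self):
        core = "ATGCCGTAAGCTTGCAGTACCGGATTCAAGCTTGGCC"
        genome = {"c": core + "TTTTTTTTTT" + core}
        return Aligner(genome, seed_len=18), core

    def test_unique_locus_always_chosen(self, sim, aligner):
        g = sim.seqs["chrI"]
        group = aligner.align("r", g[1500:1540])
        assert len(group) == 1
        assert assign_multimappers([group], seed=5)[0] == group[0]

    def test_two_loci_split_within_binomial_interval(self):
        from scipy.stats import binom

        al, core = self._two_locus_aligner()
        group = al.align("r", core)
        assert len(group) == 2 and all(a.n_loci == 2 for a in group)
        n = 10_000
        picks = assign_multimappers([group] * n, seed=11)
        k = sum(1 for a in picks if a.start == 0)
        lo, hi = binom.ppf([0.005, 0.995], n, 0.5)
        assert lo <= k <= hi

    def test_assignment_deterministic_under_seed(self):
        al, core = self._two_locus_aligner()
        group = al.align("r", core)
        a = assign_multimappers([group] * 50, seed=42)
        b = assign_multimappers([group] * 50, seed=42)
        assert a == b


def _aligned_sample(sim, sim_cfg, aligner, factor="Nab3", n=300):
    reads, _ = simulate_crac_reads(sim, sim_cfg, factor, n_reads=n)
    by_sample, _ = run_prep(reads, PrepConfig(barcode_table=sim_cfg.barcode_table))
    assigned, stats = align_reads(by_sample["s1"], aligner, seed=0)
    return assigned, stats


class TestSamRoundTrip:
    def test_export_import_identity(self, sim, sim_cfg, aligner, tmp_path):
        assigned, stats = _aligned_sample(sim, sim_cfg, aligner)
        assert stats["unmapped"] == 0
        path = tmp_path / "x.sam"
        write_sam(assigned, sim.seqs, path)
        groups = import_sam(path, sim.seqs)
        back = assign_multimappers(groups, seed=0)
        key = lambda a: (a.read_id, a.chrom, a.strand, a.start, a.end,
                         a.deletion_positions, a.tail_seq)
        assert sorted(map(key, assigned)) == sorted(map(key, back))

    def _sam(self, tmp_path, genome, lines):
        path = tmp_path / "t.sam"
        hdr = "@HD\tVN:1.6\n" + "".join(
            f"@SQ\tSN:{c}\tLN:{len(s)}\n" for c, s in genome.items()
        )
        path.write_text(hdr + "".join(lines))
        return path

    def test_cigar_deletion_parsed(self, sim, tmp_path):
        g = sim.seqs["chrI"]
        seq = g[100:120] + g[121:136]  # 20M1D15M starting at 100
        line = f"r1\t0\tchrI\t101\t255\t20M1D15M\t*\t0\t0\t{seq}\t{'I'*len(seq)}\n"
        ((a,),) = import_sam(self._sam(tmp_path, sim.seqs, [line]), sim.seqs)
        assert a.deletion_positions == (120,)
        assert (a.start, a.end) == (100, 136)

    def test_soft_clip_becomes_tail_when_non_templated(self, sim, tmp_path):
        g = sim.seqs["chrI"]
        p = next(i for i in range(300, 2000) if g[i + 30] != "A" and g[i + 31] != "A")
        seq = g[p : p + 30] + "AAAAA"
        line = f"r1\t0\tchrI\t{p+1}\t255\t30M5S\t*\t0\t0\t{seq}\t{'I'*35}\n"
        ((a,),) = import_sam(self._sam(tmp_path, sim.seqs, [line]), sim.seqs)
        assert a.tail_seq == "AAAAA" and a.end == p + 30

    def test_templated_soft_clip_absorbed_into_span(self, sim, tmp_path):
        g = sim.seqs["chrI"]
        p = 700
        seq = g[p : p + 35]  # last 5 nt presented as soft clip but templated
        line = f"r1\t0\tchrI\t{p+1}\t255\t30M5S\t*\t0\t0\t{seq}\t{'I'*35}\n"
        ((a,),) = import_sam(self._sam(tmp_path, sim.seqs, [line]), sim.seqs)
        assert a.tail_seq == "" and a.end == p + 35


class TestBedgraph:
    LEN = {"c": 100}

    def _aln(self, start, end, strand="+", dels=(), rid="r"):
        return ReadAlignment(rid, "c", strand, start, end, tuple(dels))

    def test_single_read_single_interval(self, tmp_path):
        vecs = coverage_vectors([self._aln(10, 40)], self.LEN)
        paths = write_bedgraph(vecs, tmp_path / "t")
        assert paths[0].read_text() == "c\t10\t40\t1\n"
        assert paths[1].read_text() == ""

    def test_overlapping_reads_step_profile(self, tmp_path):
        vecs = coverage_vectors([self._aln(10, 30), self._aln(20, 40)], self.LEN)
        paths = write_bedgraph(vecs, tmp_path / "t")
        assert paths[0].read_text() == "c\t10\t20\t1\nc\t20\t30\t2\nc\t30\t40\t1\n"

    def test_deletion_mode_counts_positions(self, tmp_path):
        alns = [self._aln(90 - i, 100, dels=(95,), rid=f"r{i}") for i in range(7)]
        vecs = coverage_vectors(alns, self.LEN, mode="deletions")
        paths = write_bedgraph(vecs, tmp_path / "t")
        assert paths[0].read_text() == "c\t95\t96\t7\n"

    def test_coverage_conserves_alignment_length(self, sim, sim_cfg, aligner):
        assigned, _ = _aligned_sample(sim, sim_cfg, aligner, factor="PolII")
        lengths = {c: len(s) for c, s in sim.seqs.items()}
        vecs = coverage_vectors(assigned, lengths)
        total = sum(v.sum() for v in vecs.values())
        assert total == sum(a.end - a.start for a in assigned)

    def test_round_trip_through_files(self, tmp_path):
        vecs = coverage_vectors(
            [self._aln(5, 25), self._aln(60, 80, strand="-")], self.LEN
        )
        plus, minus = write_bedgraph(vecs, tmp_path / "t")
        back = read_bedgraph(plus, minus, self.LEN)
        for k in vecs:
            assert np.array_equal(vecs[k], back[k])
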