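"""Planted-truth simulator for CRAC libraries.

Generates a toy genome with annotated transcripts (mRNA / CUT / SUT /
snoRNA, both strands, optional single introns), plants Nab3-consensus
motif instances at recorded positions, and simulates factor-specific CRAC
reads carrying every signal the downstream analyses detect:

* crosslink-induced single-nucleotide deletions at the motif-adjacent
  nucleotide (Nab3 libraries),
* non-genome-encoded oligo(A) tails — short in the transcript body,
  longer at the poly(A) site,
* PCR duplicates, sample barcodes and 5' random trimers (UMIs),
* spliced / unspliced junction reads from intron-bearing transcripts.

Every emitted read has exactly one row in a machine-readable truth table,
and a fixed :class:`SimConfig` seed yields byte-identical outputs.
"""

from __future__ import annotations

import zlib
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Transcript, revcomp

__all__ = [
    "TailModel",
    "SimConfig",
    "SyntheticGenome",
    "FastqRead",
    "make_genome",
    "simulate_crac_reads",
    "simulate_junction_reads",
    "write_fastq",
    "rng_for",
]

FastqRead = namedtuple("FastqRead", ["read_id", "seq", "qual"])

FACTORS = ("PolII", "Nab3", "Mtr4", "Nab2", "Cbc1")

TRUTH_COLUMNS = [
    "read_id",
    "molecule_id",
    "transcript_id",
    "genomic_start",
    "genomic_end",
    "strand",
    "planted_deletion_pos",
    "planted_tail_seq",
    "n_pcr_copies",
    "sample",
    "factor",
    "time",
    "is_spliced",
]


def rng_for(seed: int, *parts) -> np.random.Generator:
    """Deterministic child RNG keyed by a base seed plus string/int labels."""
    key = [int(seed) & 0x7FFFFFFF]
    key += [zlib.crc32(str(p).encode()) & 0x7FFFFFFF for p in parts]
    return np.random.default_rng(key)


@dataclass
class TailModel:
    """Oligo(A)-tail generation model.

    Lengths are shifted-geometric (minimum 1 nt) with the stated mean;
    ``pa_window`` is the distance (nt) from the poly(A) site within which a
    read 3' end receives the longer poly(A)-site tail distribution.
    """

    body_mean_len: float = 4.0
    pa_mean_len: float = 12.0
    tail_prob: float = 0.25
    purity: float = 1.0
    pa_window: int = 25
    min_len: int = 1  # set to 2 to plant only tails the oligo(A) rule accepts


@dataclass
class SimConfig:
    seed: int = 0
    n_transcripts: int = 60
    transcript_len_range: tuple[int, int] = (500, 2500)
    intron_fraction: float = 0.25
    motif: str = "TCTTG"
    deletion_prob: float = 0.2
    tail_model: TailModel = field(default_factory=TailModel)
    pcr_dup_mean: float = 1.0
    barcode_table: dict[str, str] = field(
        default_factory=lambda: {"s1": "GTGAGC", "s2": "CACTAG"}
    )
    umi_len: int = 3
    mtr4_offset_mean: float = 25.0
    reads_per_sample: int = 2500
    insert_len_range: tuple[int, int] = (40, 55)
    adaptor3: str = "TGGAATTCTCGGGTGCCAAGG"
    biotype_fractions: dict[str, float] = field(
        default_factory=lambda: {"mRNA": 0.70, "CUT": 0.12, "SUT": 0.10, "snoRNA": 0.08}
    )
    dubious_fraction: float = 0.05
    intergenic_range: tuple[int, int] = (150, 300)
    snoRNA_margin: int = 40
    # heavy-tailed baseline expression: per-transcript lognormal(0, sigma)
    # abundance, times a biotype factor (mRNAs transcribed more on average)
    expression_sigma: float = 0.5
    biotype_expression: dict[str, float] = field(
        default_factory=lambda: {"mRNA": 1.0, "SUT": 0.5, "CUT": 0.4, "snoRNA": 0.7}
    )
    # Per-factor oligo(A) probabilities; factors absent here fall back to
    # tail_model.tail_prob (Mtr4 in particular).
    tail_prob_by_factor: dict[str, float] = field(
        default_factory=lambda: {"PolII": 0.03, "Nab3": 0.05}
    )
    # Mixture weight of downstream (vs 5'-proximal) motif sites for Nab3 at
    # each time point (minutes after shift; 'mock' behaves like 0).
    nab3_downstream_weight: dict = field(
        default_factory=lambda: {0: 0.10, "mock": 0.10, 4: 0.60, 8: 0.75}
    )

    def validate(self) -> None:
        lo, hi = self.transcript_len_range
        if lo > hi:
            raise ValueError("transcript_len_range inverted")
        for p in (
            self.intron_fraction,
            self.deletion_prob,
            self.tail_model.tail_prob,
            self.tail_model.purity,
            self.dubious_fraction,
            *self.tail_prob_by_factor.values(),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.umi_len < 1:
            raise ValueError("umi_len must be >= 1")
        if len(set(self.barcode_table.values())) != len(self.barcode_table):
            raise ValueError("barcodes must be unique")


@dataclass
class SyntheticGenome:
    """Toy genome plus its annotation and planted-motif registry."""

    seqs: dict[str, str]
    transcripts: list[Transcript]
    # one row per planted motif instance:
    # transcript_id, offset (transcript frame, motif start), gstart (genomic
    # start of motif span), xlink_offset, xlink_gpos, five_prime
    motif_sites: pd.DataFrame
    # per-transcript baseline expression weight (relative sampling propensity)
    baseline: dict[str, float] = field(default_factory=dict)

    def transcript(self, tid: str) -> Transcript:
        return next(t for t in self.transcripts if t.transcript_id == tid)


_BASES = np.frombuffer(b"ACGT", dtype="S1")

_BIOTYPE_LEN = {"CUT": (200, 600), "SUT": (250, 700), "snoRNA": (150, 400)}


def _sense_base(genome: dict[str, str], t: Transcript, offset: int) -> str:
    """Sense-strand base at a transcript-frame offset (may lie outside the span)."""
    gpos = t.genomic_pos(offset)
    chrom = genome[t.chrom]
    if not 0 <= gpos < len(chrom):
        return "N"
    b = chrom[gpos]
    return b if t.strand == "+" else revcomp(b)


def make_genome(cfg: SimConfig) -> SyntheticGenome:
    """Build the toy chromosome, transcript annotation, and motif registry."""
    cfg.validate()
    rng = rng_for(cfg.seed, "genome")
    chrom = "chrI"

    # biotype roster
    fracs = cfg.biotype_fractions
    n = cfg.n_transcripts
    counts = {b: int(round(f * n)) for b, f in fracs.items()}
    counts["mRNA"] = max(1, n - sum(v for b, v in counts.items() if b != "mRNA"))
    roster: list[str] = []
    for b in ("mRNA", "CUT", "SUT", "snoRNA"):
        roster += [b] * counts.get(b, 0)
    roster = roster[:n]
    rng.shuffle(roster)

    transcripts: list[Transcript] = []
    cursor = 200
    for i, biotype in enumerate(roster):
        strand = "+" if rng.random() < 0.5 else "-"
        if biotype == "mRNA":
            length = int(rng.integers(*cfg.transcript_len_range, endpoint=True))
        else:
            length = int(rng.integers(*_BIOTYPE_LEN[biotype], endpoint=True))
            if biotype == "snoRNA":
                length += 2 * cfg.snoRNA_margin  # transcribed unit beyond mature ends
        start, end = cursor, cursor + length
        exons: tuple[tuple[int, int], ...] = ((start, end),)
        if (
            biotype == "mRNA"
            and length >= 600
            and rng.random() < cfg.intron_fraction
        ):
            ioff = int(rng.integers(int(0.35 * length), int(0.50 * length)))
            ilen = int(rng.integers(60, 201))
            a, b = start + ioff, start + ioff + ilen  # genomic intron span
            exons = ((start, a), (b, end))
        dubious = biotype == "mRNA" and rng.random() < cfg.dubious_fraction
        transcripts.append(
            Transcript(
                transcript_id=f"T{i:04d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                biotype=biotype,
                exons=exons,
                dubious=dubious,
            )
        )
        cursor = end + int(rng.integers(*cfg.intergenic_range, endpoint=True))

    glen = cursor + 200
    seq = rng.choice(_BASES, size=glen).tobytes().decode()
    seq_l = list(seq)

    # plant motif instances (sense orientation) and record them
    mlen = len(cfg.motif)
    rows = []
    for t in transcripts:
        offsets = [int(rng.integers(25, 81))]  # 5'-proximal instance
        if t.length >= 400:
            for _ in range(int(rng.integers(1, 3))):
                o = int(rng.integers(150, t.length - 80))
                if all(abs(o - p) >= 30 for p in offsets):
                    offsets.append(o)
        for j, off in enumerate(sorted(offsets)):
            # The crosslinked nucleotide (C) is planted with unlike neighbours
            # (motif end on its 5' side, T on its 3' side) so that a planted
            # single-nt deletion is never ambiguous within a homopolymer run.
            block = cfg.motif + "CT"
            if t.strand == "+":
                g = t.start + off
                seq_l[g : g + len(block)] = list(block)
            else:
                g = t.end - off - mlen  # genomic start of the motif span
                gb = t.end - off - len(block)
                seq_l[gb : gb + len(block)] = list(revcomp(block))
            xoff = off + mlen  # crosslinked nucleotide: adjacent, 3' of motif
            rows.append(
                {
                    "transcript_id": t.transcript_id,
                    "offset": off,
                    "gstart": g,
                    "xlink_offset": xoff,
                    "xlink_gpos": t.genomic_pos(xoff),
                    "five_prime": j == 0,
                }
            )
    motif_sites = pd.DataFrame(rows)
    baseline = {
        t.transcript_id: float(
            rng.lognormal(0.0, cfg.expression_sigma)
            * cfg.biotype_expression.get(t.biotype, 1.0)
        )
        for t in transcripts
    }
    return SyntheticGenome({chrom: "".join(seq_l)}, transcripts, motif_sites, baseline)


# ---------------------------------------------------------------------------
# CRAC read simulation


def _draw_tail(rng, mean: float, purity: float, min_len: int = 1) -> str:
    # shifted geometric: L = (min_len - 1) + Geom with the residual mean
    L = (min_len - 1) + int(rng.geometric(1.0 / max(mean - min_len + 1, 1.0)))
    bases = []
    for _ in range(L):
        if purity >= 1.0 or rng.random() < purity:
            bases.append("A")
        else:
            bases.append("CGT"[int(rng.integers(0, 3))])
    return "".join(bases)


def simulate_crac_reads(
    sim: SyntheticGenome,
    cfg: SimConfig,
    factor: str,
    sample: str = "s1",
    time=0,
    transcript_weights: dict[str, float] | None = None,
    n_reads: int | None = None,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Simulate one CRAC library for ``factor`` at one time point.

    Returns the raw multiplexed reads (layout ``[UMI][barcode][insert]
    [3' adaptor]``) and one truth row per emitted read (PCR copies share a
    ``molecule_id``).
    """
    cfg.validate()
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    if sample not in cfg.barcode_table:
        raise ValueError(f"sample {sample!r} not in barcode_table")
    barcode = cfg.barcode_table[sample]
    rng = rng_for(cfg.seed, "crac", factor, sample, time)
    n = n_reads if n_reads is not None else cfg.reads_per_sample

    ts = sim.transcripts
    w = np.array(
        [
            sim.baseline.get(t.transcript_id, 1.0)
            * (transcript_weights or {}).get(t.transcript_id, 1.0)
            for t in ts
        ],
        dtype=float,
    )
    w = w / w.sum()
    motif_by_tid = {
        tid: grp.reset_index(drop=True)
        for tid, grp in sim.motif_sites.groupby("transcript_id")
    }
    down_w = cfg.nab3_downstream_weight.get(time, 0.5)
    tail_prob = cfg.tail_prob_by_factor.get(factor, cfg.tail_model.tail_prob)

    seen: set[tuple[str, str]] = set()
    reads: list[FastqRead] = []
    truth_rows: list[dict] = []
    t_idx = rng.choice(len(ts), size=n, p=w)

    for i in range(n):
        t = ts[int(t_idx[i])]
        L = t.length
        ilen = int(rng.integers(*cfg.insert_len_range, endpoint=True))
        ilen = min(ilen, L)
        del_off = None  # transcript-frame offset of the planted deletion

        if factor in ("Nab3", "Mtr4"):
            sites = motif_by_tid.get(t.transcript_id)
            downstream = sites[~sites["five_prime"]]
            if len(downstream) and rng.random() < down_w:
                row = downstream.iloc[int(rng.integers(0, len(downstream)))]
            else:
                row = sites[sites["five_prime"]].iloc[0]
            xoff = int(row["xlink_offset"])
            if factor == "Nab3":
                u = int(rng.integers(20, 31))
                start_off = max(0, xoff - u)
                end_off = min(L, start_off + ilen)
                if rng.random() < cfg.deletion_prob and end_off >= xoff + 2:
                    del_off = xoff
            else:  # Mtr4: offset downstream of the Nab3 site
                d = int(rng.poisson(cfg.mtr4_offset_mean))
                c = min(max(xoff + d, 20), L - 1)
                start_off = min(max(0, c - ilen // 2), max(0, L - ilen))
                end_off = min(L, start_off + ilen)
        elif factor == "PolII":
            start_off = int(rng.integers(0, max(1, L - ilen + 1)))
            end_off = start_off + ilen
        elif factor == "Nab2":  # poly(A)-site proximal
            start_off = max(0, L - ilen - int(rng.integers(0, 15)))
            end_off = min(L, start_off + ilen)
        else:  # Cbc1: cap-proximal
            start_off = int(rng.integers(0, 12))
            end_off = min(L, start_off + ilen)

        # oligo(A) tail, guaranteed non-templated at the 3' junction
        tail = ""
        if rng.random() < tail_prob:
            near_pa = (L - end_off) <= cfg.tail_model.pa_window
            mean = (
                cfg.tail_model.pa_mean_len if near_pa else cfg.tail_model.body_mean_len
            )
            tail = _draw_tail(rng, mean, cfg.tail_model.purity, cfg.tail_model.min_len)

            # Non-templated guarantee: the next TWO genomic sense bases must
            # differ from the first tail base, so neither direct extension nor
            # a one-nt genomic skip can absorb any part of the tail.
            def _templated(e: int) -> bool:
                return (
                    _sense_base(sim.seqs, t, e) == tail[0]
                    or _sense_base(sim.seqs, t, e + 1) == tail[0]
                )

            min_end = (del_off + 2) if del_off is not None else (start_off + 18)
            shrunk = 0
            while tail and _templated(end_off) and shrunk < 12 and end_off - 1 >= min_end:
                end_off -= 1
                shrunk += 1
            if tail and _templated(end_off):
                tail = ""  # genomic A-run at the junction: skip rather than plant ambiguity

        sense = t.sense_seq(sim.seqs)[start_off:end_off]
        if del_off is not None:
            k = del_off - start_off
            sense = sense[:k] + sense[k + 1 :]
        insert = sense + tail

        umi = "".join(
            "ACGT"[int(b)] for b in rng.integers(0, 4, size=cfg.umi_len)
        )
        tries = 0
        while (umi, insert) in seen and tries < 200:
            umi = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size=cfg.umi_len))
            tries += 1
        seen.add((umi, insert))

        ncopies = 1 + int(rng.poisson(cfg.pcr_dup_mean))
        full = umi + barcode + insert + cfg.adaptor3
        mol = f"{sample}_{factor}_t{time}_m{i:06d}"
        if t.strand == "+":
            gstart, gend = t.start + start_off, t.start + end_off
        else:
            gstart, gend = t.end - end_off, t.end - start_off
        del_gpos = t.genomic_pos(del_off) if del_off is not None else -1
        for c in range(ncopies):
            rid = f"{mol}_c{c}"
            reads.append(FastqRead(rid, full, "I" * len(full)))
            truth_rows.append(
                {
                    "read_id": rid,
                    "molecule_id": mol,
                    "transcript_id": t.transcript_id,
                    "genomic_start": gstart,
                    "genomic_end": gend,
                    "strand": t.strand,
                    "planted_deletion_pos": del_gpos,
                    "planted_tail_seq": tail,
                    "n_pcr_copies": ncopies,
                    "sample": sample,
                    "factor": factor,
                    "time": time,
                    "is_spliced": "",
                }
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


# ---------------------------------------------------------------------------
# junction reads


def simulate_junction_reads(
    sim: SyntheticGenome,
    cfg: SimConfig,
    spliced_fraction: float,
    n_reads: int = 5000,
    read_len: int = 50,
    min_overhang: int = 10,
    sample: str = "s1",
    factor: str = "Mtr4",
    time=0,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Simulate reads spanning exactly one splice junction each.

    Spliced reads join the two exon sequences (intron excluded); unspliced
    reads cross the intron / 3'-exon boundary contiguously.  Every read has
    at least ``min_overhang`` nt on each side of its junction.
    """
    cfg.validate()
    if not 0.0 <= spliced_fraction <= 1.0:
        raise ValueError("spliced_fraction outside [0, 1]")
    if read_len < 2 * min_overhang:
        raise ValueError("read_len shorter than twice min_overhang")
    intronic = [t for t in sim.transcripts if len(t.exons) > 1]
    if not intronic:
        raise ValueError("annotation contains no intron-bearing transcripts")
    barcode = cfg.barcode_table[sample]
    rng = rng_for(cfg.seed, "junction", factor, sample, time)

    seen: set[tuple[str, str]] = set()
    reads: list[FastqRead] = []
    rows: list[dict] = []
    for i in range(n_reads):
        t = intronic[int(rng.integers(0, len(intronic)))]
        seq_t = t.sense_seq(sim.seqs)
        exon_lens = [e - s for s, e in sorted(t.exons)]
        if t.strand == "-":
            exon_lens = exon_lens[::-1]
        L1 = exon_lens[0]
        LI = t.length - sum(exon_lens)
        L2 = exon_lens[1]
        spliced = bool(rng.random() < spliced_fraction)
        if spliced:
            lo = max(min_overhang, read_len - L2)
            hi = min(read_len - min_overhang, L1)
            o1 = int(rng.integers(lo, hi + 1))
            insert = seq_t[L1 - o1 : L1] + seq_t[L1 + LI : L1 + LI + read_len - o1]
            # genomic span of the 3'-exon portion (bookkeeping only)
            a, b = L1 + LI, L1 + LI + read_len - o1
        else:
            B = L1 + LI  # intron / 3'-exon boundary (sense frame)
            lo = max(min_overhang, read_len - L2)
            hi = min(read_len - min_overhang, LI)
            o1 = int(rng.integers(lo, hi + 1))
            insert = seq_t[B - o1 : B - o1 + read_len]
            a, b = B - o1, B - o1 + read_len
        if t.strand == "+":
            gstart, gend = t.start + a, t.start + b
        else:
            gstart, gend = t.end - b, t.end - a

        umi = "".join("ACGT"[int(x)] for x in rng.integers(0, 4, size=cfg.umi_len))
        tries = 0
        while (umi, insert) in seen and tries < 200:
            umi = "".join("ACGT"[int(x)] for x in rng.integers(0, 4, size=cfg.umi_len))
            tries += 1
        seen.add((umi, insert))
        rid = f"{sample}_{factor}_t{time}_j{i:06d}_c0"
        reads.append(
            FastqRead(rid, umi + barcode + insert + cfg.adaptor3, "I" * (len(insert) + len(umi) + len(barcode) + len(cfg.adaptor3)))
        )
        rows.append(
            {
                "read_id": rid,
                "molecule_id": rid[:-3],
                "transcript_id": t.transcript_id,
                "genomic_start": gstart,
                "genomic_end": gend,
                "strand": t.strand,
                "planted_deletion_pos": -1,
                "planted_tail_seq": "",
                "n_pcr_copies": 1,
                "sample": sample,
                "factor": factor,
                "time": time,
                "is_spliced": spliced,
            }
        )
    return reads, pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_fastq(reads: list[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
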