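"""Oligo(A) tail classification and summaries.

A read's non-genome-encoded 3' portion is classified as an oligo(A) tail
when it contains two or more A residues and no more than one-in-five non-A
residues, evaluated on the read-sense strand.  Only reads whose 3' adaptor
was sequenced are candidates — otherwise the true RNA 3' end was not
reached and absence of a tail is uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import ReadAlignment, coverage_vectors
from .annotation import Transcript

__all__ = [
    "TailCall",
    "classify_tail",
    "call_tail",
    "call_tails",
    "tail_fraction",
    "tail_length_metagene",
    "tailed_read_track",
]


def classify_tail(tail_seq: str) -> bool:
    """Oligo(A) rule: >= 2 As and a non-A fraction of at most 1/5."""
    n = len(tail_seq)
    if n == 0:
        return False
    n_a = tail_seq.count("A")
    return n_a >= 2 and (n - n_a) * 5 <= n


@dataclass(frozen=True)
class TailCall:
    read_id: str
    tail_seq: str
    tail_len: int
    n_A: int
    nonA_frac: float
    is_oligoA: bool
    anchor_pos: int  # genomic position of the last templated nucleotide
    chrom: str = ""
    strand: str = "+"
    transcript_id: str | None = None
    sample: str = ""


def call_tail(
    alignment: ReadAlignment,
    had_adaptor3: bool | None = None,
    transcript_id: str | None = None,
) -> TailCall | None:
    """Apply the oligo(A) rule to one alignment's non-templated 3' portion.

    Returns ``None`` when the 3' adaptor was not found — such reads are not
    tail candidates.  ``had_adaptor3`` defaults to the flag carried on the
    alignment.
    """
    if had_adaptor3 is None:
        had_adaptor3 = alignment.had_adaptor3
    if not had_adaptor3:
        return None
    t = alignment.tail_seq
    n = len(t)
    n_a = t.count("A")
    anchor = alignment.end - 1 if alignment.strand == "+" else alignment.start
    return TailCall(
        read_id=alignment.read_id,
        tail_seq=t,
        tail_len=n,
        n_A=n_a,
        nonA_frac=(n - n_a) / n if n else 0.0,
        is_oligoA=classify_tail(t),
        anchor_pos=anchor,
        chrom=alignment.chrom,
        strand=alignment.strand,
        transcript_id=transcript_id,
        sample=alignment.sample,
    )


def call_tails(
    alignments: list[ReadAlignment],
    transcript_of: dict[str, str] | None = None,
) -> list[TailCall]:
    """Tail calls for every adaptor-containing alignment."""
    out = []
    for a in alignments:
        c = call_tail(
            a, transcript_id=(transcript_of or {}).get(a.read_id)
        )
        if c is not None:
            out.append(c)
    return out


def tail_fraction(calls: list[TailCall], min_len: int = 2) -> dict:
    """Fraction of adaptor-containing reads with an oligo(A) tail >= ``min_len`` nt.

    Returns a stats dict; ``fraction_tailed`` is None when there are no
    adaptor-containing reads (undefined, reported as missing).
    """
    total = len(calls)
    n_tailed = sum(1 for c in calls if c.is_oligoA and c.tail_len >= min_len)
    return {
        "total_reads_with_adaptor": total,
        "n_tailed": n_tailed,
        "fraction_tailed": (n_tailed / total) if total else None,
    }


def tail_length_metagene(
    calls: list[TailCall],
    transcripts: list[Transcript],
    anchor: str = "pA",
    window: tuple[int, int] = (300, 50),
) -> pd.Series:
    """Mean oligo(A)-tail length at each position relative to an anchor.

    Positions are transcript-strand-aware offsets of the tail's genomic
    anchor (last templated nucleotide) from the transcript's anchor point
    (``pA`` or ``TSS``); positions with no oligo(A) calls are NaN, not 0.
    """
    before, after = window
    sums = np.zeros(before + after + 1)
    counts = np.zeros(before + after + 1)
    by_tid = {t.transcript_id: t for t in transcripts}
    for c in calls:
        if not c.is_oligoA or c.transcript_id not in by_tid:
            continue
        t = by_tid[c.transcript_id]
        apos = t.pa_site if anchor == "pA" else t.tss
        off = t.offset_of(c.anchor_pos) - t.offset_of(apos)
        i = off + before
        if 0 <= i < len(sums):
            sums[i] += c.tail_len
            counts[i] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(mean, index=np.arange(-before, after + 1), name="mean_tail_len")


def tailed_read_track(
    calls: list[TailCall],
    alignments: list[ReadAlignment],
    chrom_lengths: dict[str, int],
) -> dict[tuple[str, str], np.ndarray]:
    """Coverage restricted to reads with a called oligo(A) tail."""
    tailed_ids = {c.read_id for c in calls if c.is_oligoA}
    keep = [a for a in alignments if a.read_id in tailed_ids]
    return coverage_vectors(keep, chrom_lengths, mode="coverage")


def calls_to_frame(calls: list[TailCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "sample": c.sample,
                "transcript_id": c.transcript_id or "",
                "chrom": c.chrom,
                "strand": c.strand,
                "anchor_pos": c.anchor_pos,
                "tail_seq": c.tail_seq,
                "tail_len": c.tail_len,
                "n_A": c.n_A,
                "nonA_frac": c.nonA_frac,
                "is_oligoA": c.is_oligoA,
            }
            for c in calls
        ]
    )
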