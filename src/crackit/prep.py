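"""FASTQ preprocessing: adaptor clipping, quality trimming/filtering,
homopolymer-artifact removal, barcode demultiplexing and PCR-duplicate
collapsing via the 5' random trimer (UMI).

The stage order mirrors standard CRAC preprocessing: clip the 3' adaptor,
quality-trim and filter, drop homopolymer artifacts, demultiplex on the 5'
linker barcode (stripping UMI + barcode), then collapse reads that are
identical in (UMI, insert) — putative PCR duplicates of one cDNA.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .synthetic import FastqRead

__all__ = [
    "PrepConfig",
    "PreppedRead",
    "read_fastq",
    "clip_adaptor",
    "quality_trim",
    "quality_ok",
    "is_artifact",
    "demultiplex",
    "collapse_duplicates",
    "run_prep",
    "write_prepped_fastq",
    "read_prepped_fastq",
]


@dataclass
class PrepConfig:
    adaptor3: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 5
    min_len_after_clip: int = 27  # umi(3) + barcode(6) + 18 nt mappable insert
    qual_trim_threshold: int = 20
    qual_filter_threshold: int = 20
    qual_filter_frac: float = 0.7
    artifact_max_frac: float = 0.95
    barcode_table: dict[str, str] = field(
        default_factory=lambda: {"s1": "GTGAGC", "s2": "CACTAG"}
    )
    umi_len: int = 3
    barcode_mismatches: int = 0

    def validate(self) -> None:
        if not self.adaptor3:
            raise ValueError("adaptor3 must be non-empty")
        if min(self.qual_trim_threshold, self.qual_filter_threshold) < 0:
            raise ValueError("quality thresholds must be non-negative")
        bcs = list(self.barcode_table.values())
        if len(set(bcs)) != len(bcs):
            raise ValueError("duplicate barcodes in barcode_table")
        if len(set(map(len, bcs))) > 1:
            raise ValueError("barcodes must have equal length")
        if self.umi_len < 1:
            raise ValueError("umi_len must be >= 1")


@dataclass(frozen=True)
class PreppedRead:
    read_id: str
    sample: str
    umi: str
    seq: str  # insert only: UMI, barcode and adaptor removed
    had_adaptor3: bool


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Parse a (possibly gzipped) Phred+33 FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    out = []
    with opener(path, "rt") as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                out.append(FastqRead(title.split()[0], seq.upper(), qual))
        except ValueError as exc:  # malformed record
            raise ValueError(f"{path}: malformed FASTQ near record {len(out) + 1}: {exc}")
    return out


# ---------------------------------------------------------------------------
# per-read operations


def clip_adaptor(
    seq: str, adaptor3: str, min_overlap: int = 5
) -> tuple[str, bool]:
    """Remove the longest read suffix matching a prefix of ``adaptor3``.

    Returns the clipped sequence and whether a confident match
    (>= ``min_overlap`` nt, or the full adaptor anywhere) was found.
    Partial terminal overlaps shorter than ``min_overlap`` are left alone.
    """
    if not adaptor3:
        raise ValueError("adaptor3 must be non-empty")
    idx = seq.find(adaptor3)
    if idx >= 0:
        return seq[:idx], True
    max_ov = min(len(adaptor3), len(seq))
    for ov in range(max_ov - 1, 0, -1):  # longest partial terminal overlap
        if seq.endswith(adaptor3[:ov]):
            if ov >= min_overlap:
                return seq[: len(seq) - ov], True
            break
    return seq, False


def quality_trim(seq: str, qual: str, threshold: int) -> tuple[str, str]:
    """Trim 3' bases with Phred quality below ``threshold`` (fastx-style)."""
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - 33 < threshold:
        end -= 1
    return seq[:end], qual[:end]


def quality_ok(qual: str, threshold: int, frac: float) -> bool:
    """True if at least ``frac`` of bases have Phred quality >= ``threshold``."""
    if not qual:
        return False
    good = sum(1 for q in qual if ord(q) - 33 >= threshold)
    return good / len(qual) >= frac


def is_artifact(seq: str, max_frac: float = 0.95) -> bool:
    """Homopolymer artifact: one nucleotide makes up >= ``max_frac`` of the read."""
    if not seq:
        return True
    return max(Counter(seq).values()) / len(seq) >= max_frac


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def demultiplex(
    reads: list[tuple[FastqRead, bool]], cfg: PrepConfig
) -> tuple[dict[str, list[PreppedRead]], int]:
    """Assign reads to samples by the 5' linker barcode.

    Input items are (read, had_adaptor3) pairs whose sequences still start
    with ``[UMI][barcode]``; both are stripped and the UMI stored.  Returns
    per-sample streams and the count of unassignable reads.
    """
    cfg.validate()
    bc_len = len(next(iter(cfg.barcode_table.values())))
    by_sample: dict[str, list[PreppedRead]] = {s: [] for s in cfg.barcode_table}
    unassigned = 0
    for read, had_adaptor in reads:
        umi = read.seq[: cfg.umi_len]
        bc = read.seq[cfg.umi_len : cfg.umi_len + bc_len]
        hit = None
        for sample, ref in cfg.barcode_table.items():
            if bc == ref or (
                cfg.barcode_mismatches > 0
                and len(bc) == len(ref)
                and _hamming(bc, ref) <= cfg.barcode_mismatches
            ):
                hit = sample
                break
        if hit is None:
            unassigned += 1
            continue
        by_sample[hit].append(
            PreppedRead(
                read_id=read.read_id,
                sample=hit,
                umi=umi,
                seq=read.seq[cfg.umi_len + bc_len :],
                had_adaptor3=had_adaptor,
            )
        )
    return by_sample, unassigned


def collapse_duplicates(
    reads: list[PreppedRead],
) -> tuple[list[PreppedRead], dict[int, int]]:
    """Collapse reads identical in (UMI, insert) to one representative.

    Returns the representatives (first occurrence, input order) and a
    histogram mapping copy-number -> number of collapsed groups.
    """
    groups: dict[tuple[str, str], int] = {}
    reps: list[PreppedRead] = []
    for r in reads:
        key = (r.umi, r.seq)
        if key in groups:
            groups[key] += 1
        else:
            groups[key] = 1
            reps.append(r)
    hist = Counter(groups.values())
    return reps, dict(sorted(hist.items()))


# ---------------------------------------------------------------------------
# pipeline stage


def run_prep(
    reads: list[FastqRead], cfg: PrepConfig
) -> tuple[dict[str, list[PreppedRead]], dict]:
    """Full preprocessing of one multiplexed FASTQ stream.

    Returns collapsed per-sample reads and a stats dict whose per-stage
    counts conserve the input read count.
    """
    cfg.validate()
    n_in = len(reads)
    kept: list[tuple[FastqRead, bool]] = []
    n_short = n_lowqual = n_artifact = 0
    for r in reads:
        seq, had = clip_adaptor(r.seq, cfg.adaptor3, cfg.min_overlap)
        qual = r.qual[: len(seq)]
        seq, qual = quality_trim(seq, qual, cfg.qual_trim_threshold)
        if len(seq) < cfg.min_len_after_clip:
            n_short += 1
            continue
        if not quality_ok(qual, cfg.qual_filter_threshold, cfg.qual_filter_frac):
            n_lowqual += 1
            continue
        insert_preview = seq[cfg.umi_len + len(next(iter(cfg.barcode_table.values()))) :]
        if is_artifact(insert_preview, cfg.artifact_max_frac):
            n_artifact += 1
            continue
        kept.append((FastqRead(r.read_id, seq, qual), had))

    by_sample, n_unassigned = demultiplex(kept, cfg)
    collapsed: dict[str, list[PreppedRead]] = {}
    stats_samples = {}
    for sample, rs in by_sample.items():
        reps, hist = collapse_duplicates(rs)
        collapsed[sample] = reps
        stats_samples[sample] = {
            "assigned": len(rs),
            "unique": len(reps),
            "dup_histogram": {str(k): v for k, v in hist.items()},
        }
    n_assigned = sum(s["assigned"] for s in stats_samples.values())
    stats = {
        "input": n_in,
        "dropped_short": n_short,
        "dropped_low_quality": n_lowqual,
        "dropped_artifact": n_artifact,
        "unassigned": n_unassigned,
        "assigned": n_assigned,
        "samples": stats_samples,
        "conserved": n_in
        == n_short + n_lowqual + n_artifact + n_unassigned + n_assigned,
    }
    return collapsed, stats


# ---------------------------------------------------------------------------
# prepped-read persistence (FASTQ with metadata in the header)


def write_prepped_fastq(reads: list[PreppedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(
                f"@{r.read_id} sample={r.sample} umi={r.umi} adaptor={int(r.had_adaptor3)}\n"
                f"{r.seq}\n+\n{'I' * len(r.seq)}\n"
            )


def read_prepped_fastq(path: str | Path) -> list[PreppedRead]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            rid, *meta = header[1:].split()
            kv = dict(m.split("=", 1) for m in meta)
            out.append(
                PreppedRead(
                    read_id=rid,
                    sample=kv.get("sample", "s1"),
                    umi=kv.get("umi", ""),
                    seq=seq,
                    had_adaptor3=kv.get("adaptor", "1") == "1",
                )
            )
    return out


def write_stats(stats: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
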