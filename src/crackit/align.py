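"""Read alignment and genomic tracks.

The built-in aligner maps prepped inserts to the toy genome with a
5'-anchored, maximal-extension model: a read matches contiguously, or with
exactly one internal 1-nt genomic deletion (the crosslink signature), and
any remaining 3' nucleotides become the non-templated tail candidate.
Maximal extension means a tail can never be extended into the genome at
its junction — the same bias a BLAST-style mapper has at genomic A-runs.

Real libraries enter through :func:`import_sam`, which converts CIGAR D
operations to deletion positions and 3' soft-clips to tail candidates
(subject to the same maximal-extension check).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation import revcomp
from .prep import PreppedRead

__all__ = [
    "ReadAlignment",
    "Aligner",
    "align_reads",
    "assign_multimappers",
    "import_sam",
    "write_sam",
    "coverage_vectors",
    "write_bedgraph",
    "read_bedgraph",
]


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped read: genomic span, crosslink deletions and 3' tail."""

    read_id: str
    chrom: str
    strand: str
    start: int  # 0-based half-open span of the mapped (templated) portion
    end: int
    deletion_positions: tuple[int, ...] = ()
    tail_seq: str = ""  # 3' non-templated nucleotides, read-sense orientation
    n_loci: int = 1
    score: int = 0  # matched read nucleotides
    sample: str = ""
    had_adaptor3: bool = True
    spliced: bool = False  # SAM import: CIGAR contained an N (junction) op

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("alignment span must be non-empty")
        for p in self.deletion_positions:
            if not self.start <= p < self.end:
                raise ValueError("deletion outside alignment span")


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    if a[:n] == b[:n]:
        return n
    lo = 0
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


class Aligner:
    """Seed-and-extend aligner over both strands of a small genome."""

    def __init__(
        self,
        genome: dict[str, str],
        seed_len: int = 18,
        min_match: int = 18,
        max_deletions: int = 1,
    ):
        self.genome = genome
        self.seed_len = seed_len
        self.min_match = min_match
        self.max_deletions = max_deletions
        self.strand_seqs: dict[tuple[str, str], str] = {}
        self.index: dict[str, list[tuple[str, str, int]]] = {}
        k = seed_len
        for chrom, seq in genome.items():
            for strand, W in (("+", seq), ("-", revcomp(seq))):
                self.strand_seqs[(chrom, strand)] = W
                for i in range(len(W) - k + 1):
                    self.index.setdefault(W[i : i + k], []).append((chrom, strand, i))

    def _extend(self, W: str, p: int, seq: str) -> tuple[int, int | None]:
        """Maximal 5'-anchored extension of ``seq`` at local position ``p``.

        Returns (matched read nt, local position of the skipped genomic nt
        or None).  A deletion is used only if it strictly extends the match;
        ties go to the contiguous alignment, and among deletion placements
        the leftmost (5'-most) one achieving the maximum is kept.
        """
        L0 = _common_prefix(seq, W[p : p + len(seq)])
        best, best_del = L0, None
        if self.max_deletions >= 1 and L0 < len(seq):
            for j in range(1, L0 + 1):
                q = j + _common_prefix(seq[j:], W[p + j + 1 : p + j + 1 + len(seq) - j])
                if q > best:
                    best, best_del = q, p + j
        return best, best_del

    def align(self, read_id: str, seq: str, **meta) -> list[ReadAlignment]:
        """All equally best-scoring loci for one insert (empty if unmapped)."""
        if len(seq) < self.seed_len:
            return []
        hits = self.index.get(seq[: self.seed_len], ())
        cands = []
        for chrom, strand, p in hits:
            W = self.strand_seqs[(chrom, strand)]
            matched, del_local = self._extend(W, p, seq)
            if matched >= self.min_match:
                cands.append((chrom, strand, p, matched, del_local))
        if not cands:
            return []
        top = max(c[3] for c in cands)
        out = []
        for chrom, strand, p, matched, del_local in cands:
            if matched < top:
                continue
            span = matched + (1 if del_local is not None else 0)
            if strand == "+":
                start, end = p, p + span
                dels = (del_local,) if del_local is not None else ()
            else:
                n = len(self.genome[chrom])
                start, end = n - (p + span), n - p
                dels = (n - 1 - del_local,) if del_local is not None else ()
            out.append(
                ReadAlignment(
                    read_id=read_id,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    deletion_positions=dels,
                    tail_seq=seq[matched:],
                    score=matched,
                    **meta,
                )
            )
        out.sort(key=lambda a: (a.chrom, a.start, a.strand))
        return [replace(a, n_loci=len(out)) for a in out]


def assign_multimappers(
    groups: list[list[ReadAlignment]], seed: int = 0
) -> list[ReadAlignment]:
    """Uniform random choice among each read's equally scored loci."""
    rng = np.random.default_rng(seed)
    out = []
    for g in groups:
        if not g:
            continue
        out.append(g[int(rng.integers(0, len(g)))] if len(g) > 1 else g[0])
    return out


def align_reads(
    prepped: list[PreppedRead], aligner: Aligner, seed: int = 0
) -> tuple[list[ReadAlignment], dict]:
    """Align prepped reads and randomly assign multi-mappers (seeded)."""
    groups = []
    n_unmapped = 0
    for r in prepped:
        g = aligner.align(
            r.read_id, r.seq, sample=r.sample, had_adaptor3=r.had_adaptor3
        )
        if g:
            groups.append(g)
        else:
            n_unmapped += 1
    assigned = assign_multimappers(groups, seed=seed)
    stats = {
        "input": len(prepped),
        "mapped": len(assigned),
        "unmapped": n_unmapped,
        "multimapped": sum(1 for g in groups if len(g) > 1),
    }
    return assigned, stats


# ---------------------------------------------------------------------------
# SAM I/O


def write_sam(
    alignments: list[ReadAlignment], genome: dict[str, str], path: str | Path
) -> None:
    """Write alignments as plain SAM (deletions as D, tails as 3' soft clips)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.reference_name = a.chrom
            seg.reference_start = a.start
            seg.mapping_quality = 255
            seg.flag = 0 if a.strand == "+" else 16
            gseq = genome[a.chrom][a.start : a.end]
            dels = sorted(a.deletion_positions)
            templated_fwd = "".join(
                b for i, b in enumerate(gseq) if (a.start + i) not in dels
            )
            # CIGAR in reference orientation; M/D segments between deletions
            segs = []
            prev = a.start
            for d in dels:
                segs.append((0, d - prev))  # M
                segs.append((2, 1))  # D
                prev = d + 1
            segs.append((0, a.end - prev))
            segs = [(op, ln) for op, ln in segs if ln > 0]
            # SEQ is stored reference-forward; the read's 3' tail lies at the
            # reference-right end on '+' and reference-left (revcomp'd) on '-'.
            if a.strand == "+":
                if a.tail_seq:
                    segs.append((4, len(a.tail_seq)))
                seg.query_sequence = templated_fwd + a.tail_seq
            else:
                if a.tail_seq:
                    segs.insert(0, (4, len(a.tail_seq)))
                seg.query_sequence = revcomp(a.tail_seq) + templated_fwd
            seg.cigartuples = segs
            seg.query_qualities = pysam.qualitystring_to_array(
                "I" * len(seg.query_sequence)
            )
            tags = [("NH", max(a.n_loci, 1))]
            if a.sample:
                tags.append(("RG", a.sample))
            tags.append(("XA", int(a.had_adaptor3)))
            seg.set_tags(tags)
            fh.write(seg)


def _absorb_clip(
    genome: dict[str, str], chrom: str, strand: str, start: int, end: int, clip: str
) -> tuple[int, int, str]:
    """Maximal-extension check: grow the span through templated clip bases."""
    seq = genome[chrom]
    i = 0
    if strand == "+":
        while i < len(clip) and end + i < len(seq) and clip[i] == seq[end + i]:
            i += 1
        return start, end + i, clip[i:]
    while (
        i < len(clip)
        and start - 1 - i >= 0
        and clip[i] == revcomp(seq[start - 1 - i])
    ):
        i += 1
    return start - i, end, clip[i:]


def import_sam(
    path: str | Path, genome: dict[str, str]
) -> list[list[ReadAlignment]]:
    """Read a SAM file into alignment groups (one group per read).

    CIGAR D ops become deletion positions; 3' soft clips become tail
    candidates subject to the maximal-extension check against the genome
    (templated clip bases are absorbed into the span).  CIGAR N marks the
    alignment as spliced.  Secondary alignments join their read's group for
    :func:`assign_multimappers`.
    """
    import pysam

    if genome is None:
        raise ValueError("genome required for the tail extension check")
    groups: dict[str, list[ReadAlignment]] = {}
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            strand = "-" if seg.is_reverse else "+"
            start = seg.reference_start
            pos = start
            dels: list[int] = []
            spliced = False
            lead_clip = trail_clip = 0
            ct = seg.cigartuples or []
            for k, (op, ln) in enumerate(ct):
                if op in (0, 7, 8):  # M/=/X
                    pos += ln
                elif op == 2:  # D
                    dels.extend(range(pos, pos + ln))
                    pos += ln
                elif op == 3:  # N junction
                    spliced = True
                    pos += ln
                elif op == 4:  # S
                    if k == 0:
                        lead_clip = ln
                    else:
                        trail_clip = ln
            end = pos
            q = seg.query_sequence or ""
            # 3' (read-sense) soft clip: trailing for '+', leading for '-'
            if strand == "+":
                clip = q[len(q) - trail_clip :] if trail_clip else ""
            else:
                clip = revcomp(q[:lead_clip]) if lead_clip else ""
            start, end, tail = _absorb_clip(genome, seg.reference_name, strand, start, end, clip)
            a = ReadAlignment(
                read_id=seg.query_name,
                chrom=seg.reference_name,
                strand=strand,
                start=start,
                end=end,
                deletion_positions=tuple(dels),
                tail_seq=tail,
                score=end - start - len(dels),
                sample=seg.get_tag("RG") if seg.has_tag("RG") else "",
                had_adaptor3=bool(seg.get_tag("XA")) if seg.has_tag("XA") else True,
                spliced=spliced,
            )
            if seg.query_name not in groups:
                order.append(seg.query_name)
            groups.setdefault(seg.query_name, []).append(a)
    out = []
    for rid in order:
        g = sorted(groups[rid], key=lambda a: (a.chrom, a.start, a.strand))
        out.append([replace(a, n_loci=len(g)) for a in g])
    return out


# ---------------------------------------------------------------------------
# coverage tracks


def coverage_vectors(
    alignments: list[ReadAlignment],
    chrom_lengths: dict[str, int],
    mode: str = "coverage",
) -> dict[tuple[str, str], np.ndarray]:
    """Per-strand per-nt vectors: read coverage, deletion counts, or
    coverage restricted to tailed reads (caller pre-filters for the latter)."""
    if mode not in ("coverage", "deletions", "tailed_reads"):
        raise ValueError(f"unknown mode {mode!r}")
    vecs = {
        (c, s): np.zeros(n, dtype=float)
        for c, n in chrom_lengths.items()
        for s in "+-"
    }
    for a in alignments:
        v = vecs[(a.chrom, a.strand)]
        if mode == "deletions":
            for p in a.deletion_positions:
                v[p] += 1
        else:
            v[a.start : a.end] += 1
    return vecs


def write_bedgraph(
    vecs: dict[tuple[str, str], np.ndarray],
    prefix: str | Path,
    scale: float | None = None,
) -> list[Path]:
    """Write plus/minus bedgraph files (0-based half-open, nonzero intervals).

    ``scale`` multiplies values (e.g. 1e6/total for hits-per-million).
    """
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = Path(f"{prefix}.{tag}.bedgraph")
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for (chrom, s), v in sorted(vecs.items()):
                if s != strand:
                    continue
                w = v * scale if scale is not None else v
                # run-length encode
                change = np.flatnonzero(np.diff(w)) + 1
                bounds = np.concatenate(([0], change, [len(w)]))
                for a, b in zip(bounds[:-1], bounds[1:]):
                    val = w[a]
                    if val == 0:
                        continue
                    if float(val).is_integer():
                        fh.write(f"{chrom}\t{a}\t{b}\t{int(val)}\n")
                    else:
                        fh.write(f"{chrom}\t{a}\t{b}\t{val:.6g}\n")
        paths.append(path)
    return paths


def read_bedgraph(
    plus_path: str | Path,
    minus_path: str | Path,
    chrom_lengths: dict[str, int],
) -> dict[tuple[str, str], np.ndarray]:
    vecs = {
        (c, s): np.zeros(n, dtype=float)
        for c, n in chrom_lengths.items()
        for s in "+-"
    }
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        with open(path) as fh:
            for line in fh:
                chrom, a, b, val = line.split()
                vecs[(chrom, strand)][int(a) : int(b)] = float(val)
    return vecs
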