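"""Crosslink-site calling from read microdeletions, and motif scoring.

Reverse transcriptase drops the crosslinked nucleotide during cDNA
synthesis, so single-nucleotide deletions in aligned reads pinpoint
protein-RNA contact sites.  Sites are tallied per genomic position,
ranked, and 13-nt windows around the top sites are scored for the Nab3
consensus (UCUUG / TCTTG in DNA space) plus a k-mer enrichment against a
dinucleotide-preserving shuffle background.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .align import ReadAlignment
from .annotation import Transcript, revcomp

__all__ = [
    "CrosslinkSite",
    "call_deletion_sites",
    "top_sites",
    "extract_windows",
    "consensus_score",
    "strongest_site_per_gene",
    "motif_scan",
    "dinucleotide_shuffle",
]


@dataclass(frozen=True)
class CrosslinkSite:
    chrom: str
    strand: str
    pos: int  # the deleted genomic nucleotide
    deletion_count: int
    transcript_id: str | None = None
    rank: int | None = None


def call_deletion_sites(
    alignments: list[ReadAlignment],
    transcripts: list[Transcript] | None = None,
    restrict_to: set[str] | None = None,
) -> list[CrosslinkSite]:
    """Tally reads deleting each genomic position, strand-aware.

    Sites are annotated to the sense-strand transcript containing them;
    ``restrict_to`` keeps only sites in the given transcript set.
    """
    tally: Counter[tuple[str, str, int]] = Counter()
    for a in alignments:
        for p in a.deletion_positions:
            tally[(a.chrom, a.strand, p)] += 1
    by_pos: dict[tuple[str, str, int], str] = {}
    if transcripts:
        for t in transcripts:
            for key in tally:
                if (
                    key[0] == t.chrom
                    and key[1] == t.strand
                    and t.start <= key[2] < t.end
                ):
                    by_pos.setdefault(key, t.transcript_id)
    sites = []
    for (chrom, strand, pos), n in sorted(tally.items()):
        tid = by_pos.get((chrom, strand, pos))
        if restrict_to is not None and tid not in restrict_to:
            continue
        sites.append(CrosslinkSite(chrom, strand, pos, n, tid))
    return sites


def top_sites(
    sites: list[CrosslinkSite], n: int = 50, scope: set[str] | None = None
) -> list[CrosslinkSite]:
    """Top ``n`` sites by deletion count (ties by coordinate, ascending).

    ``scope`` restricts to sites annotated to the given transcripts.  If
    fewer than ``n`` sites exist, all are returned (with a warning log).
    """
    pool = [s for s in sites if scope is None or s.transcript_id in scope]
    pool.sort(key=lambda s: (-s.deletion_count, s.chrom, s.pos))
    if len(pool) < n:
        import logging

        logging.getLogger(__name__).warning(
            "top_sites: only %d sites available (requested %d)", len(pool), n
        )
    return [replace(s, rank=i + 1) for i, s in enumerate(pool[:n])]


def extract_windows(
    sites: list[CrosslinkSite], genome: dict[str, str], flank: int = 6
) -> tuple[list[str], list[bool]]:
    """Sense-strand sequences of ``2*flank + 1`` nt centred on each site.

    Windows running off a contig end are N-padded and flagged.
    """
    windows, padded = [], []
    for s in sites:
        chrom = genome[s.chrom]
        lo, hi = s.pos - flank, s.pos + flank + 1
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(chrom))
        w = "N" * left_pad + chrom[max(lo, 0) : min(hi, len(chrom))] + "N" * right_pad
        if s.strand == "-":
            w = revcomp(w)
        windows.append(w)
        padded.append(left_pad > 0 or right_pad > 0)
    return windows, padded


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle: permutes a sequence preserving its exact
    dinucleotide composition (random Eulerian walk on the transition graph)."""
    if len(seq) <= 2:
        return seq
    # adjacency lists of the dinucleotide multigraph
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    last = seq[-1]
    # choose a random last edge into each non-terminal vertex so the walk can
    # always finish (spanning in-tree toward the terminal vertex)
    verts = list(adj.keys())
    for tries in range(100):
        last_edge: dict[str, str] = {}
        for v in verts:
            if v != last:
                last_edge[v] = adj[v][int(rng.integers(0, len(adj[v])))]
        # check the chosen last edges lead every vertex to the terminal
        ok = True
        for v in verts:
            if v == last:
                continue
            seen = {v}
            u = v
            while u != last:
                u = last_edge.get(u)
                if u is None or u in seen:
                    ok = False
                    break
                seen.add(u)
            if not ok:
                break
        if ok:
            break
    else:  # pathological composition: give up on structure, plain shuffle
        s = list(seq)
        rng.shuffle(s)
        return "".join(s)
    out = [seq[0]]
    remaining = {}
    for v, edges in adj.items():
        e = list(edges)
        if v in last_edge:
            e.remove(last_edge[v])
        rng.shuffle(e)
        if v in last_edge:
            e.append(last_edge[v])
        remaining[v] = e
    u = seq[0]
    while remaining.get(u):
        nxt = remaining[u].pop(0)
        out.append(nxt)
        u = nxt
    return "".join(out)


def consensus_score(
    windows: list[str],
    consensus: str = "TCTTG",
    kmer_k: int = 5,
    shuffles: int = 50,
    seed: int = 0,
) -> dict:
    """Score windows for consensus conformance and k-mer enrichment.

    A window conforms when the consensus occurs as an exact substring.
    k-mer enrichment is observed/expected counts where the expectation
    comes from dinucleotide-preserving shuffles of the same windows.
    """
    n = len(windows)
    report: dict = {
        "windows": list(windows),
        "consensus": consensus,
        "n_windows": n,
        "n_conforming": 0,
        "fraction": None,
        "kmer_enrichment": {},
    }
    if n == 0:
        return report
    conforming = sum(1 for w in windows if consensus in w)
    report["n_conforming"] = conforming
    report["fraction"] = conforming / n

    if shuffles <= 0:
        return report

    obs: Counter[str] = Counter()
    for w in windows:
        for i in range(len(w) - kmer_k + 1):
            kmer = w[i : i + kmer_k]
            if "N" not in kmer:
                obs[kmer] += 1
    rng = np.random.default_rng(seed)
    exp: Counter[str] = Counter()
    for _ in range(shuffles):
        for w in windows:
            sh = dinucleotide_shuffle(w, rng)
            for i in range(len(sh) - kmer_k + 1):
                kmer = sh[i : i + kmer_k]
                if "N" not in kmer:
                    exp[kmer] += 1
    enrich = {}
    for kmer, o in obs.most_common():
        e = exp.get(kmer, 0) / shuffles
        enrich[kmer] = o / e if e > 0 else float("inf")
    report["kmer_enrichment"] = enrich
    return report


def strongest_site_per_gene(
    sites: list[CrosslinkSite],
) -> tuple[dict[str, CrosslinkSite], int]:
    """Per transcript, the site with the largest deletion count.

    Ties go to the 5'-most site (strand-aware).  Returns the anchor map and
    the number of sites lacking a transcript annotation (omitted).
    """
    best: dict[str, CrosslinkSite] = {}
    n_unannotated = 0
    for s in sites:
        if s.transcript_id is None:
            n_unannotated += 1
            continue
        cur = best.get(s.transcript_id)
        if cur is None or s.deletion_count > cur.deletion_count:
            best[s.transcript_id] = s
        elif s.deletion_count == cur.deletion_count:
            # 5'-most: smaller pos on '+', larger pos on '-'
            if (s.strand == "+" and s.pos < cur.pos) or (
                s.strand == "-" and s.pos > cur.pos
            ):
                best[s.transcript_id] = s
    return best, n_unannotated


def motif_scan(
    transcripts: list[Transcript],
    genome: dict[str, str],
    motif: str = "CTT",
    region: tuple[int, int] = (0, 200),
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Motif occurrences per kilobase in a TSS-proximal window, per transcript.

    ``region`` is (start, end) in transcript-frame offsets from the TSS;
    occurrences may overlap.  ``groups`` optionally labels transcripts
    (e.g. by cluster) for grouped summaries.
    """
    lo, hi = region
    rows = []
    for t in transcripts:
        seq = t.sense_seq(genome)[lo : min(hi, t.length)]
        count = 0
        i = seq.find(motif)
        while i >= 0:
            count += 1
            i = seq.find(motif, i + 1)  # overlapping occurrences allowed
        kb = len(seq) / 1000 if seq else np.nan
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "group": (groups or {}).get(t.transcript_id, ""),
                "n_occurrences": count,
                "region_len": len(seq),
                "per_kb": count / kb if kb else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def sites_to_bed(sites: list[CrosslinkSite]) -> pd.DataFrame:
    """BED6 frame: score column carries the deletion count."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.pos,
                "end": s.pos + 1,
                "name": s.transcript_id or ".",
                "score": s.deletion_count,
                "strand": s.strand,
            }
            for s in sites
        ]
    )
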