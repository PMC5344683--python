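"""Metagene profiles, heatmap matrices and spliced:unspliced ratios.

Two weighting modes mirror the two kinds of metagene used in CRAC work:
``hpm_sum`` adds (HPM-scaled) coverage across genes, so highly bound genes
dominate; ``per_gene_unit`` normalizes each gene's window to total 1 and
averages rows with equal weight, giving a per-gene density profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Transcript

__all__ = [
    "Profile",
    "anchored_profile",
    "binned_profile",
    "heatmap_matrix",
    "junction_ratio",
]

CoverageDict = dict[tuple[str, str], np.ndarray]


@dataclass
class Profile:
    anchor_type: str  # TSS | pA | site | bins
    matrix: pd.DataFrame  # transcripts x positions (or bins)
    weighting: str  # hpm_sum | per_gene_unit
    n_excluded: int = 0

    @property
    def summary(self) -> pd.Series:
        """Column summary: sum for hpm_sum, equal-weight mean for per_gene_unit."""
        if self.weighting == "hpm_sum":
            return self.matrix.sum(axis=0)
        return self.matrix.mean(axis=0)


def _row(
    cov: CoverageDict, t: Transcript, anchor_gpos: int, before: int, after: int
) -> np.ndarray:
    """Strand-aware coverage at offsets -before..after relative to an anchor."""
    v = cov[(t.chrom, t.strand)]
    out = np.zeros(before + after + 1)
    for i, off in enumerate(range(-before, after + 1)):
        g = t.genomic_pos(t.offset_of(anchor_gpos) + off)
        if 0 <= g < len(v):
            out[i] = v[g]
    return out


def anchored_profile(
    cov: CoverageDict,
    transcripts: list[Transcript],
    anchor_type: str = "TSS",
    anchors: dict[str, int] | None = None,
    window: tuple[int, int] = (100, 2800),
    weighting: str = "per_gene_unit",
    length_filter: tuple[int, int] | None = None,
) -> Profile:
    """Coverage relative to a per-transcript anchor.

    ``anchor_type`` is TSS or pA, or "site" with explicit genomic ``anchors``
    (e.g. strongest crosslink sites).  Transcripts without an anchor, outside
    ``length_filter`` (min, max nt), or — in per_gene_unit mode — with an
    empty window are excluded and counted.
    """
    if weighting not in ("hpm_sum", "per_gene_unit"):
        raise ValueError(f"unknown weighting {weighting!r}")
    before, after = window
    rows, index = [], []
    n_excluded = 0
    for t in transcripts:
        if length_filter is not None and not (
            length_filter[0] <= t.length <= length_filter[1]
        ):
            n_excluded += 1
            continue
        if anchor_type == "TSS":
            apos = t.tss
        elif anchor_type == "pA":
            apos = t.pa_site
        else:
            apos = (anchors or {}).get(t.transcript_id)
            if apos is None:
                n_excluded += 1
                continue
        r = _row(cov, t, apos, before, after)
        if weighting == "per_gene_unit":
            tot = r.sum()
            if tot <= 0:
                n_excluded += 1
                continue
            r = r / tot
        rows.append(r)
        index.append(t.transcript_id)
    matrix = pd.DataFrame(
        rows, index=index, columns=np.arange(-before, after + 1)
    )
    return Profile(anchor_type, matrix, weighting, n_excluded)


def bin_edges(length: int, n_bins: int) -> np.ndarray:
    """5'-frame bin boundaries; the remainder goes to the 5'-most bins."""
    q, r = divmod(length, n_bins)
    sizes = np.full(n_bins, q, dtype=int)
    sizes[:r] += 1
    return np.concatenate(([0], np.cumsum(sizes)))


def binned_profile(
    cov: CoverageDict,
    transcripts: list[Transcript],
    n_bins: int = 50,
    weighting: str = "hpm_sum",
) -> Profile:
    """Length-normalized profile: each transcript split into ``n_bins``
    near-equal intervals (remainder distributed 5'-first), bin value = summed
    coverage.  Transcripts shorter than ``n_bins`` are excluded and counted."""
    rows, index = [], []
    n_excluded = 0
    for t in transcripts:
        if t.length < n_bins:
            n_excluded += 1
            continue
        v = cov[(t.chrom, t.strand)][t.start : t.end].astype(float)
        if t.strand == "-":
            v = v[::-1]  # 5' -> 3'
        edges = bin_edges(t.length, n_bins)
        r = np.add.reduceat(v, edges[:-1])
        if weighting == "per_gene_unit":
            tot = r.sum()
            if tot <= 0:
                n_excluded += 1
                continue
            r = r / tot
        rows.append(r)
        index.append(t.transcript_id)
    matrix = pd.DataFrame(rows, index=index, columns=np.arange(n_bins))
    return Profile("bins", matrix, weighting, n_excluded)


def heatmap_matrix(
    profile: Profile,
    sort: str = "length",
    transcripts: list[Transcript] | None = None,
    fold_changes: pd.Series | None = None,
    descending: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Row-ordered matrix for heatmap rendering, plus the sort key per row."""
    if sort == "length":
        if transcripts is None:
            raise ValueError("sort by length needs transcripts")
        key = pd.Series(
            {t.transcript_id: t.length for t in transcripts}
        ).reindex(profile.matrix.index)
    elif sort == "fold_change":
        if fold_changes is None:
            raise ValueError("sort by fold_change needs fold_changes")
        key = fold_changes.reindex(profile.matrix.index)
    else:
        raise ValueError(f"unknown sort {sort!r}")
    order = key.sort_values(ascending=not descending).index
    return profile.matrix.loc[order], key.loc[order]


# ---------------------------------------------------------------------------
# splice junction quantification


def _junction_templates(
    transcripts: list[Transcript], genome: dict[str, str], flank: int = 80
) -> list[dict]:
    """Per intron-bearing transcript: spliced (exon-exon) and unspliced
    (intron-3'exon) junction template sequences with the boundary index."""
    out = []
    for t in transcripts:
        if len(t.exons) < 2:
            continue
        seq_t = t.sense_seq(genome)
        exon_lens = [e - s for s, e in sorted(t.exons)]
        if t.strand == "-":
            exon_lens = exon_lens[::-1]
        L1 = exon_lens[0]
        LI = t.length - sum(exon_lens)
        B = L1 + LI  # sense-frame start of the 3' exon
        left_sp = seq_t[max(0, L1 - flank) : L1]
        left_un = seq_t[max(0, B - flank) : B]
        right = seq_t[B : B + flank]
        out.append(
            {
                "transcript_id": t.transcript_id,
                "spliced": (left_sp + right, len(left_sp)),
                "unspliced": (left_un + right, len(left_un)),
            }
        )
    return out


def junction_ratio(
    read_seqs: list[tuple[str, str]],
    transcripts: list[Transcript],
    genome: dict[str, str],
    min_overhang: int = 3,
    template_flank: int = 80,
) -> tuple[pd.DataFrame, dict]:
    """Spliced:unspliced junction read counts per intron-bearing transcript.

    ``read_seqs`` are (read_id, insert sequence) pairs.  A read counts for a
    junction when it occurs as an exact substring of the junction template
    crossing the boundary with >= ``min_overhang`` nt on each side; reads
    matching junctions of more than one transcript are dropped as ambiguous.
    The aggregate dict pools counts over all transcripts (ratio None when no
    unspliced reads — undefined, flagged).
    """
    templates = _junction_templates(transcripts, genome, template_flank)
    if not templates:
        raise ValueError("annotation contains no intron-bearing transcripts")
    counts = {
        tpl["transcript_id"]: {"n_spliced": 0, "n_unspliced": 0}
        for tpl in templates
    }
    n_ambiguous = n_unmatched = 0
    for _rid, seq in read_seqs:
        matches = []
        for tpl in templates:
            for kind in ("spliced", "unspliced"):
                tseq, b = tpl[kind]
                idx = tseq.find(seq)
                if (
                    idx >= 0
                    and idx <= b - min_overhang
                    and idx + len(seq) >= b + min_overhang
                ):
                    matches.append((tpl["transcript_id"], kind))
        tids = {m[0] for m in matches}
        if len(tids) > 1:
            n_ambiguous += 1
            continue
        if not matches:
            n_unmatched += 1
            continue
        tid, kind = matches[0]
        counts[tid]["n_spliced" if kind == "spliced" else "n_unspliced"] += 1
    rows = []
    for tid, c in counts.items():
        ratio = (
            c["n_spliced"] / c["n_unspliced"] if c["n_unspliced"] > 0 else np.nan
        )
        rows.append({"transcript_id": tid, **c, "ratio": ratio})
    df = pd.DataFrame(rows).set_index("transcript_id")
    tot_s, tot_u = int(df["n_spliced"].sum()), int(df["n_unspliced"].sum())
    aggregate = {
        "n_spliced": tot_s,
        "n_unspliced": tot_u,
        "ratio": tot_s / tot_u if tot_u > 0 else None,
        "n_ambiguous": n_ambiguous,
        "n_unmatched": n_unmatched,
        "min_overhang": min_overhang,
    }
    return df, aggregate
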