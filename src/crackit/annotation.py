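"""Transcript annotation and genome sequence I/O.

All in-memory coordinates are 0-based half-open on the genomic forward
strand.  GFF3 files are written/read 1-based inclusive, with the
transcript-level attributes this toolkit relies on (``ID``, ``biotype``,
``pA_site``, ``dubious``) and one ``exon`` line per exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "Transcript",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Transcript:
    """One annotated transcription unit.

    ``start``/``end`` span the transcribed unit (introns included);
    ``exons`` are genomic intervals sorted by coordinate.  ``pa_site`` is
    the genomic position of the poly(A) site: the strand-aware last
    transcribed nucleotide (``end - 1`` on '+', ``start`` on '-') unless
    the annotation says otherwise.
    """

    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "mRNA"
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    pa_site: int | None = None
    dubious: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.transcript_id}: start must be < end")
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        if self.pa_site is None:
            object.__setattr__(
                self, "pa_site", self.end - 1 if self.strand == "+" else self.start
            )

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        ex = sorted(self.exons)
        return tuple((a[1], b[0]) for a, b in zip(ex, ex[1:]))

    def offset_of(self, gpos: int) -> int:
        """Transcript-frame offset (0 at TSS, increasing 5'->3') of a genomic position."""
        return gpos - self.start if self.strand == "+" else self.end - 1 - gpos

    def genomic_pos(self, offset: int) -> int:
        """Inverse of :meth:`offset_of`."""
        return self.start + offset if self.strand == "+" else self.end - 1 - offset

    def sense_seq(self, genome: dict[str, str]) -> str:
        """Transcribed-unit sequence in transcript orientation (introns included)."""
        s = genome[self.chrom][self.start : self.end]
        return s if self.strand == "+" else revcomp(s)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def write_gff3(transcripts: list[Transcript], path: str | Path) -> None:
    """Write transcripts (and their exons) as GFF3, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            attrs = {
                "ID": t.transcript_id,
                "biotype": t.biotype,
                "pA_site": str(t.pa_site + 1),
            }
            if t.dubious:
                attrs["dubious"] = "1"
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        "crackit",
                        "transcript",
                        str(t.start + 1),
                        str(t.end),
                        ".",
                        t.strand,
                        ".",
                        _fmt_attrs(attrs),
                    ]
                )
                + "\n"
            )
            for i, (es, ee) in enumerate(sorted(t.exons), 1):
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "crackit",
                            "exon",
                            str(es + 1),
                            str(ee),
                            ".",
                            t.strand,
                            ".",
                            _fmt_attrs(
                                {
                                    "ID": f"{t.transcript_id}.exon{i}",
                                    "Parent": t.transcript_id,
                                }
                            ),
                        ]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path) -> list[Transcript]:
    """Read a flat transcript/exon GFF3 back into :class:`Transcript` records."""
    feats: dict[str, dict] = {}
    order: list[str] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr_s = cols
            attrs = _parse_attrs(attr_s)
            if ftype == "transcript":
                tid = attrs["ID"]
                feats[tid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "start": int(start) - 1,
                    "end": int(end),
                    "biotype": attrs.get("biotype", "mRNA"),
                    "pa_site": int(attrs["pA_site"]) - 1 if "pA_site" in attrs else None,
                    "dubious": attrs.get("dubious") == "1",
                }
                order.append(tid)
            elif ftype == "exon":
                exons.setdefault(attrs["Parent"], []).append((int(start) - 1, int(end)))
    out = []
    for tid in order:
        f = feats[tid]
        out.append(
            Transcript(
                transcript_id=tid,
                chrom=f["chrom"],
                strand=f["strand"],
                start=f["start"],
                end=f["end"],
                biotype=f["biotype"],
                exons=tuple(sorted(exons.get(tid, []))),
                pa_site=f["pa_site"],
                dubious=f["dubious"],
            )
        )
    return out
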