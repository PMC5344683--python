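"""Per-transcript counting, normalization, ratios and directional clusters.

Counts are hits-per-million (HPM) normalized over a declared transcript
universe, surveillance-factor binding is expressed relative to Pol II
occupancy (factor:PolII HPM ratio), and genes are grouped into the 2^3 = 8
directional clusters by the signs of their Pol II / Nab3 / Mtr4 log2 fold
changes after nutrient shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .align import ReadAlignment
from .annotation import Transcript

__all__ = [
    "count_reads",
    "hits_per_million",
    "binding_ratio",
    "pearson_matrix",
    "fold_change",
    "average_replicates",
    "select_represented",
    "assign_cluster",
    "assign_clusters",
    "CLUSTER_TABLE",
]

# Sign-triple -> cluster id, Pol II as the most significant bit
# (up, up, up) -> 1 ... (down, down, down) -> 8, order (PolII, Nab3, Mtr4).
CLUSTER_TABLE: dict[tuple[str, str, str], int] = {
    ("up", "up", "up"): 1,
    ("up", "up", "down"): 2,
    ("up", "down", "up"): 3,
    ("up", "down", "down"): 4,
    ("down", "up", "up"): 5,
    ("down", "up", "down"): 6,
    ("down", "down", "up"): 7,
    ("down", "down", "down"): 8,
}


def _transcript_trees(
    transcripts: list[Transcript],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
            t.start, t.end, t.transcript_id
        )
    return trees


def count_reads(
    alignments: list[ReadAlignment],
    transcripts: list[Transcript],
    excl_dubious: bool = True,
    seed: int = 0,
) -> tuple[pd.Series, int]:
    """Count each read toward the sense transcript with the largest overlap.

    Ties are broken uniformly at random (seeded); reads overlapping no
    sense-strand transcript are uncounted.  Returns (counts, n_uncounted);
    the counts index covers every eligible transcript (zeros included).
    """
    if not transcripts:
        raise ValueError("empty annotation")
    eligible = [t for t in transcripts if not (excl_dubious and t.dubious)]
    trees = _transcript_trees(eligible)
    counts = pd.Series(0, index=[t.transcript_id for t in eligible], dtype=int)
    rng = np.random.default_rng(seed)
    uncounted = 0
    for a in alignments:
        tree = trees.get((a.chrom, a.strand))
        hits = tree.overlap(a.start, a.end) if tree is not None else ()
        if not hits:
            uncounted += 1
            continue
        best, best_ov = [], -1
        for iv in sorted(hits, key=lambda iv: (iv.begin, iv.data)):
            ov = min(a.end, iv.end) - max(a.start, iv.begin)
            if ov > best_ov:
                best, best_ov = [iv.data], ov
            elif ov == best_ov:
                best.append(iv.data)
        tid = best[0] if len(best) == 1 else best[int(rng.integers(0, len(best)))]
        counts[tid] += 1
    return counts, uncounted


def hits_per_million(
    counts: pd.DataFrame | pd.Series, universe: list[str] | None = None
) -> pd.DataFrame | pd.Series:
    """Scale counts to hits per million over the universe, per sample.

    The scaling denominator is the count total over ``universe`` rows only,
    so HPM values over the universe sum to 1e6 in every sample.
    """
    if universe is None:
        universe = list(counts.index)
    if not universe:
        raise ValueError("empty universe")
    sub = counts.loc[universe]
    total = sub.sum()
    if isinstance(counts, pd.Series):
        if total == 0:
            raise ValueError("zero total count over universe")
        return counts * 1e6 / total
    zero = total[total == 0]
    if len(zero):
        raise ValueError(f"zero total count over universe in sample(s): {list(zero.index)}")
    return counts * 1e6 / total


def binding_ratio(
    factor_hpm: pd.Series, polII_hpm: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Surveillance-factor binding relative to transcription:
    (factor HPM + pc) / (Pol II HPM + pc), elementwise over a shared universe."""
    factor_hpm, polII_hpm = factor_hpm.align(polII_hpm, join="inner")
    denom = polII_hpm + pseudocount
    ratio = (factor_hpm + pseudocount) / denom
    out = pd.DataFrame(
        {
            "factor_hpm": factor_hpm,
            "polII_hpm": polII_hpm,
            "ratio": ratio.where(denom > 0),
            "pseudocount": pseudocount,
        }
    )
    out["undefined"] = denom <= 0
    return out


def pearson_matrix(
    hpm: pd.DataFrame,
    transcripts: list[Transcript] | None = None,
    top_n: int = 2000,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pairwise Pearson correlation of samples on the top transcribed mRNAs.

    Selection: mRNA-biotype rows ranked by mean HPM across all samples
    (sample-order independent); correlation computed on log2(HPM + pc).
    Constant columns yield NaN correlations (flagged by pandas).
    """
    if hpm.shape[1] < 2:
        raise ValueError("need at least two samples")
    rows = hpm.index
    if transcripts is not None:
        mrna = {t.transcript_id for t in transcripts if t.biotype == "mRNA"}
        rows = [r for r in rows if r in mrna]
    sub = hpm.loc[rows]
    top = sub.mean(axis=1).sort_values(ascending=False).index[:top_n]
    logged = np.log2(sub.loc[top] + pseudocount)
    return logged.corr(method="pearson")


def fold_change(
    sample_hpm: pd.Series, reference_hpm: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2((sample + pc) / (reference + pc)) on matched universes."""
    s, r = sample_hpm.align(reference_hpm, join="inner")
    return np.log2((s + pseudocount) / (r + pseudocount))


def average_replicates(fcs: list[pd.Series]) -> tuple[pd.Series, bool]:
    """Mean of per-replicate log2 fold changes; flags single-replicate input."""
    if not fcs:
        raise ValueError("no replicates")
    avg = pd.concat(fcs, axis=1).mean(axis=1)
    return avg, len(fcs) == 1


def select_represented(
    counts_by_factor: dict[str, pd.Series], min_count: int = 10
) -> list[str]:
    """Transcripts with >= ``min_count`` reads in every factor's time-0 sample."""
    if not counts_by_factor:
        return []
    it = iter(counts_by_factor.values())
    ok = next(it) >= min_count
    for s in it:
        ok = ok & (s.reindex(ok.index, fill_value=0) >= min_count)
    return list(ok.index[ok])


@dataclass(frozen=True)
class ClusterAssignment:
    transcript_id: str
    sign_polII: str
    sign_nab3: str
    sign_mtr4: str
    cluster_id: int


def _sign(fc: float, epsilon: float, band_as: str) -> str:
    if fc > epsilon:
        return "up"
    if fc < -epsilon:
        return "down"
    return band_as


def assign_cluster(
    transcript_id: str,
    fc_polII: float,
    fc_nab3: float,
    fc_mtr4: float,
    epsilon: float = 0.0,
    band_as: str = "down",
) -> ClusterAssignment | None:
    """Map one gene's (Pol II, Nab3, Mtr4) fold-change triple to cluster 1-8.

    Returns None (unclassified) if any fold change is missing.
    """
    if any(pd.isna(v) for v in (fc_polII, fc_nab3, fc_mtr4)):
        return None
    signs = tuple(_sign(v, epsilon, band_as) for v in (fc_polII, fc_nab3, fc_mtr4))
    return ClusterAssignment(transcript_id, *signs, CLUSTER_TABLE[signs])


def assign_clusters(
    fc: pd.DataFrame, epsilon: float = 0.0, band_as: str = "down"
) -> pd.DataFrame:
    """Vectorized cluster assignment; ``fc`` columns: PolII, Nab3, Mtr4."""
    rows = []
    for tid, r in fc.iterrows():
        a = assign_cluster(tid, r["PolII"], r["Nab3"], r["Mtr4"], epsilon, band_as)
        rows.append(
            {
                "transcript_id": tid,
                "sign_polII": a.sign_polII if a else "",
                "sign_nab3": a.sign_nab3 if a else "",
                "sign_mtr4": a.sign_mtr4 if a else "",
                "cluster_id": a.cluster_id if a else 0,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")
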