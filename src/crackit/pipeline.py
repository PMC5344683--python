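"""End-to-end orchestration of the CRAC analysis.

Runs the full experiment shape used throughout: three bait factors
(Pol II, Nab3, Mtr4) x time points after nutrient shift x replicates,
either simulated with planted truth or supplied as FASTQ/SAM via a sample
sheet.  Stages communicate through files in a run directory and every
artifact is listed (with a checksum) in ``manifest.json``, so a fixed seed
yields byte-identical runs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import align as al
from . import crosslink as xl
from . import prep as pp
from . import profiles as pf
from . import quantify as qt
from . import tails as tl
from .annotation import Transcript, read_fasta, read_gff3, write_fasta, write_gff3
from .synthetic import (
    SimConfig,
    SyntheticGenome,
    make_genome,
    rng_for,
    simulate_crac_reads,
    simulate_junction_reads,
    write_fastq,
)

__all__ = [
    "RunConfig",
    "default_sample_sheet",
    "plant_cluster_design",
    "replicate_average",
    "run_pipeline",
]

log = logging.getLogger("crackit.pipeline")

FACTOR_UP_CLUSTERS = {
    "PolII": {1, 2, 3, 4},
    "Nab3": {1, 2, 5, 6},
    "Mtr4": {1, 3, 5, 7},
}


@dataclass
class RunConfig:
    """Single source of truth for every analysis parameter of a run."""

    outdir: Path = Path("crackit_run")
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    # prep thresholds; barcode table is supplied per run from the sample sheet
    prep: pp.PrepConfig = field(default_factory=pp.PrepConfig)
    # quantification / clustering
    min_count: int = 10
    pseudocount: float = 1.0
    epsilon: float = 0.0
    top_n_corr: int = 2000
    # crosslink / motif
    top_n_sites: int = 50
    flank: int = 6
    consensus: str = "TCTTG"
    # profiles
    tss_window: tuple[int, int] = (100, 2800)
    tss_length_filter: tuple[int, int] = (500, 2800)
    site_window: tuple[int, int] = (100, 200)
    n_bins: int = 50
    # junctions
    junction_reads: int = 2000
    junction_read_len: int = 50
    junction_min_overhang: int = 3
    junction_plan: dict = field(
        default_factory=lambda: {
            ("Mtr4", 0): 0.5,
            ("Mtr4", 4): 0.8,
            ("Mtr4", 8): 0.8,
            ("Nab3", 0): 0.3,
            ("Nab3", 4): 0.3,
            ("Nab3", 8): 0.3,
        }
    )
    # real-data entry (optional): paths to genome FASTA and annotation GFF3
    genome_fasta: Path | None = None
    annotation_gff: Path | None = None
    log_level: str = "INFO"


def default_sample_sheet(
    factors=("PolII", "Nab3", "Mtr4"), times=(0, 4, 8), replicates=(1, 2)
) -> pd.DataFrame:
    """The experiment grid: one row per (factor, time, replicate)."""
    rows = [
        {
            "sample_id": f"{f}_t{t}_r{r}",
            "factor": f,
            "time": t,
            "replicate": r,
            "path": "",
        }
        for f, t, r in itertools.product(factors, times, replicates)
    ]
    return pd.DataFrame(rows)


def _barcodes(n: int, length: int = 6) -> list[str]:
    pool = ["".join(p) for p in itertools.product("ACGT", repeat=length)]
    step = max(1, len(pool) // (n + 1))
    return [pool[(i + 1) * step] for i in range(n)]


def plant_cluster_design(mrna_ids: list[str]) -> tuple[pd.Series, dict, dict]:
    """Assign planted directional clusters and per-factor shift multipliers.

    Per factor, a fraction f of genes is shifted up (weight x u) and 1 - f
    down (x d) with u = 16 d and d = 1 / (1 + 15 f), so the total library
    weight is conserved and the expected post-normalization log2 fold
    changes are symmetric and well away from zero.  Clusters 1-7 get equal
    small memberships; cluster 8 (all-down) takes the remainder, matching
    the dominant down-down-down response to glucose withdrawal.
    """
    ids = sorted(mrna_ids)
    N = len(ids)
    if N < 15:
        raise ValueError("need at least 15 mRNAs to plant all eight clusters")
    s = max(1, int(round(N / 20)))
    sizes = {c: s for c in range(1, 8)}
    sizes[8] = N - 7 * s
    planted = {}
    i = 0
    for c in range(1, 9):
        for _ in range(sizes[c]):
            planted[ids[i]] = c
            i += 1
    planted_s = pd.Series(planted, name="planted_cluster")
    f = 4 * s / N  # per-factor up fraction by the cluster table symmetry
    d = 1.0 / (1.0 + 15.0 * f)
    u = 16.0 * d
    weights = {}
    for factor, up_set in FACTOR_UP_CLUSTERS.items():
        weights[factor] = {
            tid: (u if c in up_set else d) for tid, c in planted.items()
        }
    return planted_s, weights, {"up_multiplier": u, "down_multiplier": d, "up_fraction": f}


def replicate_average(
    tables: list[pd.Series | pd.DataFrame],
) -> tuple[pd.Series | pd.DataFrame, bool]:
    """Arithmetic mean across replicate tables; flags single-replicate input."""
    if not tables:
        raise ValueError("no replicates")
    if len(tables) == 1:
        return tables[0], True
    acc = tables[0].copy()
    for t in tables[1:]:
        acc = acc + t
    return acc / len(tables), False


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _transcript_of_map(
    alignments: list[al.ReadAlignment], transcripts: list[Transcript]
) -> dict[str, str]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in transcripts:
        trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
            t.start, t.end, t.transcript_id
        )
    out = {}
    for a in alignments:
        tree = trees.get((a.chrom, a.strand))
        if tree is None:
            continue
        hits = sorted(tree.overlap(a.start, a.end), key=lambda iv: iv.begin)
        if hits:
            best = max(
                hits, key=lambda iv: min(a.end, iv.end) - max(a.start, iv.begin)
            )
            out[a.read_id] = best.data
    return out


class _Artifacts:
    """Collects written files for the manifest."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.files: list[Path] = []

    def path(self, *parts) -> Path:
        p = self.outdir.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        self.files.append(p)
        return p

    def manifest(self) -> dict:
        entries = {}
        for p in self.files:
            rel = str(p.relative_to(self.outdir))
            entries[rel] = {"sha256": _sha256(p), "bytes": p.stat().st_size}
        return entries


def _write_json(obj, path: Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def run_pipeline(cfg: RunConfig, sample_sheet: pd.DataFrame | None = None) -> dict:
    """Execute every stage; returns the result bundle (also written to disk)."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    art = _Artifacts(out)
    results: dict = {"outdir": out}
    stage = "setup"
    try:
        # ------------------------------------------------------------------
        stage = "simulate"
        simulated = sample_sheet is None or (sample_sheet["path"] == "").all()
        if sample_sheet is None:
            sample_sheet = default_sample_sheet()
        sample_sheet = sample_sheet.reset_index(drop=True)
        factors_present = set(sample_sheet["factor"])

        if simulated:
            samples = list(sample_sheet["sample_id"])
            barcode_table = dict(zip(samples, _barcodes(len(samples))))
            sim_cfg = replace(cfg.sim, seed=cfg.seed, barcode_table=barcode_table)
            sim = make_genome(sim_cfg)
            write_fasta(sim.seqs, art.path("genome.fa"))
            write_gff3(sim.transcripts, art.path("annotation.gff3"))
            mrna_ids = [
                t.transcript_id
                for t in sim.transcripts
                if t.biotype == "mRNA" and not t.dubious
            ]
            planted, weight_maps, plant_info = plant_cluster_design(mrna_ids)
            planted.to_frame().to_csv(art.path("truth", "planted_clusters.tsv"), sep="\t")
            results["planted_clusters"] = planted
            results["plant_info"] = plant_info

            paths = []
            for _, row in sample_sheet.iterrows():
                sid, factor, time = row["sample_id"], row["factor"], row["time"]
                w = weight_maps.get(factor, {}) if time != 0 else {}
                reads, truth = simulate_crac_reads(
                    sim, sim_cfg, factor, sample=sid, time=time, transcript_weights=w
                )
                p = art.path("fastq", f"{sid}.fastq")
                write_fastq(reads, p)
                truth.to_csv(art.path("truth", f"{sid}.tsv"), sep="\t", index=False)
                paths.append(str(p))
                log.info("simulate: %s -> %d reads", sid, len(reads))
            sample_sheet = sample_sheet.assign(path=paths)
            genome, transcripts = sim.seqs, sim.transcripts
            results["sim"] = sim
        else:
            if cfg.genome_fasta is None or cfg.annotation_gff is None:
                raise ValueError("real-data run needs genome_fasta and annotation_gff")
            genome = read_fasta(cfg.genome_fasta)
            transcripts = read_gff3(cfg.annotation_gff)
            barcode_table = dict(cfg.prep.barcode_table)
            sim_cfg = cfg.sim
            sim = None
        # persist with run-relative paths so identical runs are byte-identical
        persisted = sample_sheet.assign(
            path=[
                str(Path(p).relative_to(out)) if Path(p).is_absolute() else p
                for p in sample_sheet["path"]
            ]
        )
        persisted.to_csv(art.path("sample_sheet.tsv"), sep="\t", index=False)
        chrom_lengths = {c: len(s) for c, s in genome.items()}

        # ------------------------------------------------------------------
        stage = "prep"
        prep_cfg = replace(
            cfg.prep,
            barcode_table=barcode_table,
            adaptor3=sim_cfg.adaptor3,
            umi_len=sim_cfg.umi_len,
        )
        prepped: dict[str, list[pp.PreppedRead]] = {}
        for _, row in sample_sheet.iterrows():
            sid, path = row["sample_id"], row["path"]
            if str(path).endswith(".sam"):
                continue  # aligned entry, handled below
            reads = pp.read_fastq(path)
            by_sample, stats = pp.run_prep(reads, prep_cfg)
            prepped[sid] = by_sample.get(sid, [])
            pp.write_prepped_fastq(prepped[sid], art.path("prepped", f"{sid}.fastq"))
            pp.write_stats(stats, art.path("prepped", f"{sid}.stats.json"))
            log.info(
                "prep: %s input=%d unique=%d conserved=%s",
                sid, stats["input"], len(prepped[sid]), stats["conserved"],
            )

        # ------------------------------------------------------------------
        stage = "align"
        aligner = al.Aligner(genome)
        alignments: dict[str, list[al.ReadAlignment]] = {}
        coverage: dict[str, dict] = {}
        for _, row in sample_sheet.iterrows():
            sid, path = row["sample_id"], row["path"]
            if str(path).endswith(".sam"):
                groups = al.import_sam(path, genome)
                seed = int(rng_for(cfg.seed, "assign", sid).integers(0, 2**31))
                assigned = al.assign_multimappers(groups, seed=seed)
                stats = {"input": len(groups), "mapped": len(assigned), "unmapped": 0}
            else:
                seed = int(rng_for(cfg.seed, "assign", sid).integers(0, 2**31))
                assigned, stats = al.align_reads(prepped[sid], aligner, seed=seed)
            alignments[sid] = assigned
            al.write_sam(assigned, genome, art.path("aligned", f"{sid}.sam"))
            cov = al.coverage_vectors(assigned, chrom_lengths)
            coverage[sid] = cov
            for p in al.write_bedgraph(cov, out / "tracks" / f"{sid}.coverage"):
                art.files.append(p)
            log.info("align: %s mapped=%d/%d", sid, stats["mapped"], stats["input"])
        # deletion tracks for Nab3 (putative crosslink sites)
        for _, row in sample_sheet[sample_sheet["factor"] == "Nab3"].iterrows():
            sid = row["sample_id"]
            dv = al.coverage_vectors(alignments[sid], chrom_lengths, mode="deletions")
            for p in al.write_bedgraph(dv, out / "tracks" / f"{sid}.deletions"):
                art.files.append(p)

        # ------------------------------------------------------------------
        stage = "count"
        counts = {}
        uncounted = {}
        for _, row in sample_sheet.iterrows():
            sid = row["sample_id"]
            seed = int(rng_for(cfg.seed, "count", sid).integers(0, 2**31))
            c, unc = qt.count_reads(alignments[sid], transcripts, seed=seed)
            counts[sid] = c
            uncounted[sid] = unc
            log.info(
                "count: %s counted=%d uncounted=%d conserved=%s",
                sid, int(c.sum()), unc, int(c.sum()) + unc == len(alignments[sid]),
            )
        counts_df = pd.DataFrame(counts)
        biotype = pd.Series({t.transcript_id: t.biotype for t in transcripts})
        counts_df.insert(0, "biotype", biotype.reindex(counts_df.index))
        counts_df.to_csv(art.path("counts.tsv"), sep="\t")
        counts_df = counts_df.drop(columns="biotype")
        hpm = qt.hits_per_million(counts_df)
        hpm.round(3).to_csv(art.path("hpm.tsv"), sep="\t")
        results["counts"] = counts_df
        results["hpm"] = hpm

        # ------------------------------------------------------------------
        stage = "ratios"

        def _samples(factor, time):
            m = (sample_sheet["factor"] == factor) & (sample_sheet["time"] == time)
            return list(sample_sheet.loc[m, "sample_id"])

        ratios = {}
        if "PolII" in factors_present:
            pol0, _ = replicate_average([hpm[s] for s in _samples("PolII", 0)])
            for factor in ("Nab3", "Mtr4"):
                if factor not in factors_present:
                    continue
                f0, _ = replicate_average([hpm[s] for s in _samples(factor, 0)])
                r = qt.binding_ratio(f0, pol0, pseudocount=cfg.pseudocount)
                r["biotype"] = biotype.reindex(r.index)
                r.round(4).to_csv(art.path(f"ratio_{factor}.tsv"), sep="\t")
                ratios[factor] = r
        else:
            log.warning("ratios: skipped (no PolII samples)")
        results["ratios"] = ratios

        stage = "correlation"
        if counts_df.shape[1] >= 2:
            corr = qt.pearson_matrix(
                hpm, transcripts, top_n=cfg.top_n_corr, pseudocount=cfg.pseudocount
            )
            corr.round(4).to_csv(art.path("pearson.tsv"), sep="\t")
            results["pearson"] = corr

        # ------------------------------------------------------------------
        stage = "fold_change"
        fcs = {}
        for factor in ("PolII", "Nab3", "Mtr4"):
            if factor not in factors_present:
                continue
            s0, s8 = _samples(factor, 0), _samples(factor, 8)
            if not s0 or not s8:
                continue
            per_rep = []
            for i in range(max(len(s0), len(s8))):
                a = s8[min(i, len(s8) - 1)]
                b = s0[min(i, len(s0) - 1)]
                per_rep.append(qt.fold_change(hpm[a], hpm[b], cfg.pseudocount))
            avg, single = qt.average_replicates(per_rep)
            if single:
                log.info("fold_change: %s single replicate (flagged)", factor)
            fcs[factor] = avg
        fc_df = pd.DataFrame(fcs)
        if not fc_df.empty:
            fc_df.round(4).to_csv(art.path("fold_changes.tsv"), sep="\t")
        results["fold_changes"] = fc_df

        stage = "cluster"
        clusters = pd.DataFrame()
        represented: list[str] = []
        if {"PolII", "Nab3", "Mtr4"} <= factors_present:
            t0_counts = {
                f: replicate_average([counts_df[s] for s in _samples(f, 0)])[0]
                for f in ("PolII", "Nab3", "Mtr4")
            }
            represented = qt.select_represented(t0_counts, min_count=cfg.min_count)
            mrna = {
                t.transcript_id
                for t in transcripts
                if t.biotype == "mRNA" and not t.dubious
            }
            represented = [t for t in represented if t in mrna]
            clusters = qt.assign_clusters(
                fc_df.loc[represented], epsilon=cfg.epsilon
            )
            clusters.to_csv(art.path("clusters.tsv"), sep="\t")
            log.info("cluster: %d represented mRNAs", len(represented))
        else:
            missing = {"PolII", "Nab3", "Mtr4"} - factors_present
            log.warning("cluster: skipped (missing factor(s): %s)", sorted(missing))
        results["clusters"] = clusters
        results["represented"] = represented

        # ------------------------------------------------------------------
        stage = "crosslink"
        anchors: dict[str, xl.CrosslinkSite] = {}
        motif_report: dict = {}
        if "Nab3" in factors_present:
            ge_samples = [
                s
                for t in (4, 8)
                for s in _samples("Nab3", t)
            ]
            pooled = [a for s in ge_samples for a in alignments[s]]
            sites = xl.call_deletion_sites(pooled, transcripts)
            xl.sites_to_bed(sites).to_csv(
                art.path("xlink", "nab3_sites.bed"), sep="\t", header=False, index=False
            )
            scope = None
            if not clusters.empty:
                c56 = set(clusters.index[clusters["cluster_id"].isin([5, 6])])
                if c56:
                    scope = c56
            top = xl.top_sites(sites, n=cfg.top_n_sites, scope=scope)
            windows, _padded = xl.extract_windows(top, genome, flank=cfg.flank)
            with open(art.path("xlink", "windows.fasta"), "w") as fh:
                for s, w in zip(top, windows):
                    fh.write(f">{s.chrom}:{s.pos}:{s.strand}\n{w}\n")
            motif_report = xl.consensus_score(
                windows, consensus=cfg.consensus, seed=cfg.seed
            )
            _write_json(
                {k: v for k, v in motif_report.items() if k != "windows"},
                art.path("xlink", "motif_report.json"),
            )
            anchors_full, _ = xl.strongest_site_per_gene(sites)
            anchors = anchors_full
            log.info(
                "crosslink: %d sites, top-%d consensus fraction=%s",
                len(sites), len(top), motif_report.get("fraction"),
            )
        else:
            log.warning("crosslink: skipped (no Nab3 samples)")
        results["motif_report"] = motif_report
        results["anchors"] = anchors

        # ------------------------------------------------------------------
        stage = "profiles"

        def _avg_cov(factor, time):
            sids = _samples(factor, time)
            if not sids:
                return None
            scaled = []
            for s in sids:
                tot = max(1.0, float(sum(v.sum() for v in coverage[s].values())))
                scaled.append({k: v * 1e6 / tot for k, v in coverage[s].items()})
            avg = {
                k: np.mean([sc[k] for sc in scaled], axis=0) for k in scaled[0]
            }
            return avg

        tmap = {t.transcript_id: t for t in transcripts}
        profile_tables = {}
        if "Nab3" in factors_present:
            c56_ts = [
                tmap[tid]
                for tid in (
                    clusters.index[clusters["cluster_id"].isin([5, 6])]
                    if not clusters.empty
                    else [t.transcript_id for t in transcripts if t.biotype == "mRNA"]
                )
                if tid in tmap
            ]
            rows = {}
            for time in (0, 8):
                cov = _avg_cov("Nab3", time)
                if cov is None:
                    continue
                prof = pf.anchored_profile(
                    cov,
                    c56_ts,
                    anchor_type="TSS",
                    window=cfg.tss_window,
                    weighting="hpm_sum",
                    length_filter=cfg.tss_length_filter,
                )
                rows[f"Nab3_t{time}"] = prof.summary
            if rows:
                tss_df = pd.DataFrame(rows)
                tss_df.round(4).to_csv(art.path("profiles", "tss_metagene.tsv"), sep="\t")
                profile_tables["tss"] = tss_df
            # length-normalized 50-bin profile across mRNAs
            mrna_ts = [t for t in transcripts if t.biotype == "mRNA" and not t.dubious]
            rows = {}
            for time in (0, 8):
                cov = _avg_cov("Nab3", time)
                if cov is None:
                    continue
                prof = pf.binned_profile(cov, mrna_ts, n_bins=cfg.n_bins)
                rows[f"Nab3_t{time}"] = prof.summary
            if rows:
                binned_df = pd.DataFrame(rows)
                binned_df.round(4).to_csv(
                    art.path("profiles", "binned_metagene.tsv"), sep="\t"
                )
                profile_tables["binned"] = binned_df
        # Mtr4 relative to the strongest Nab3 site, equal gene weighting
        site_peak_offset = None
        if anchors and "Mtr4" in factors_present:
            cov = _avg_cov("Mtr4", 4) or _avg_cov("Mtr4", 8)
            if cov is not None:
                anchor_pos = {tid: s.pos for tid, s in anchors.items()}
                prof = pf.anchored_profile(
                    cov,
                    [tmap[tid] for tid in anchor_pos if tid in tmap],
                    anchor_type="site",
                    anchors=anchor_pos,
                    window=cfg.site_window,
                    weighting="per_gene_unit",
                )
                if not prof.matrix.empty:
                    summ = prof.summary
                    summ.round(6).to_frame("Mtr4").to_csv(
                        art.path("profiles", "site_metagene.tsv"), sep="\t"
                    )
                    site_peak_offset = int(summ.idxmax())
                    profile_tables["site"] = summ
                    log.info("profiles: Mtr4 peak %+d nt from Nab3 site", site_peak_offset)
        results["site_peak_offset"] = site_peak_offset
        # pA-aligned heatmap (Mtr4), sorted by transcript length
        if "Mtr4" in factors_present:
            cov = _avg_cov("Mtr4", 0)
            if cov is not None:
                mrna_ts = [t for t in transcripts if t.biotype == "mRNA" and not t.dubious]
                prof = pf.anchored_profile(
                    cov, mrna_ts, anchor_type="pA", window=(1000, 100),
                    weighting="hpm_sum",
                )
                hm, _key = pf.heatmap_matrix(prof, sort="length", transcripts=mrna_ts)
                hm.round(4).to_csv(art.path("profiles", "pa_heatmap.tsv"), sep="\t")
        results["profiles"] = profile_tables

        # ------------------------------------------------------------------
        stage = "tails"
        tail_stats: dict = {}
        tail_len_summary: dict = {}
        for factor in ("Mtr4", "PolII"):
            if factor not in factors_present:
                continue
            per_sample = {}
            for t in (0, 4, 8):
                for sid in _samples(factor, t):
                    tom = _transcript_of_map(alignments[sid], transcripts)
                    calls = tl.call_tails(alignments[sid], tom)
                    per_sample[sid] = tl.tail_fraction(calls)
                    if factor == "Mtr4" and t == 0:
                        body = [
                            c.tail_len
                            for c in calls
                            if c.is_oligoA
                            and c.transcript_id
                            and tmap[c.transcript_id].offset_of(c.anchor_pos)
                            < tmap[c.transcript_id].length
                            - cfg.sim.tail_model.pa_window
                        ]
                        pa = [
                            c.tail_len
                            for c in calls
                            if c.is_oligoA
                            and c.transcript_id
                            and tmap[c.transcript_id].offset_of(c.anchor_pos)
                            >= tmap[c.transcript_id].length
                            - cfg.sim.tail_model.pa_window
                        ]
                        tail_len_summary.setdefault("body_lens", []).extend(body)
                        tail_len_summary.setdefault("pa_lens", []).extend(pa)
                    if factor == "Mtr4" and t == 4 and sid == _samples(factor, 4)[0]:
                        track = tl.tailed_read_track(
                            calls, alignments[sid], chrom_lengths
                        )
                        for p in al.write_bedgraph(
                            track, out / "tracks" / f"{sid}.tailed"
                        ):
                            art.files.append(p)
            fractions = [
                v["fraction_tailed"]
                for v in per_sample.values()
                if v["fraction_tailed"] is not None
            ]
            tail_stats[factor] = {
                "per_sample": per_sample,
                "mean_fraction": float(np.mean(fractions)) if fractions else None,
            }
        if tail_len_summary:
            body = tail_len_summary.get("body_lens", [])
            pa = tail_len_summary.get("pa_lens", [])
            tail_stats["mtr4_t0_mean_body_len"] = float(np.mean(body)) if body else None
            tail_stats["mtr4_t0_n_body_calls"] = len(body)
            tail_stats["mtr4_t0_mean_pa_len"] = float(np.mean(pa)) if pa else None
            tail_stats["mtr4_t0_n_pa_calls"] = len(pa)
        if tail_stats:
            _write_json(tail_stats, art.path("tails", "tail_stats.json"))
        results["tail_stats"] = tail_stats

        # ------------------------------------------------------------------
        stage = "junctions"
        junction_results = {}
        if simulated and any(len(t.exons) > 1 for t in transcripts):
            for (factor, time), frac in sorted(cfg.junction_plan.items()):
                if factor not in factors_present:
                    continue
                sid = f"{factor}_t{time}_jx"
                reads, truth = simulate_junction_reads(
                    sim,
                    sim_cfg,
                    spliced_fraction=frac,
                    n_reads=cfg.junction_reads,
                    read_len=cfg.junction_read_len,
                    sample=list(barcode_table)[0],
                    factor=factor,
                    time=time,
                )
                p = art.path("fastq", f"{sid}.fastq")
                write_fastq(reads, p)
                truth.to_csv(art.path("truth", f"{sid}.tsv"), sep="\t", index=False)
                by_sample, _stats = pp.run_prep(pp.read_fastq(p), prep_cfg)
                inserts = [
                    (r.read_id, r.seq)
                    for rs in by_sample.values()
                    for r in rs
                ]
                per_tx, agg = pf.junction_ratio(
                    inserts,
                    transcripts,
                    genome,
                    min_overhang=cfg.junction_min_overhang,
                )
                per_tx.to_csv(art.path("junctions", f"{sid}.tsv"), sep="\t")
                junction_results[sid] = agg
            if junction_results:
                _write_json(junction_results, art.path("junctions", "aggregate.json"))
        results["junctions"] = junction_results

        # ------------------------------------------------------------------
        stage = "manifest"
        manifest = art.manifest()
        _write_json(manifest, out / "manifest.json")
        results["manifest"] = manifest
        return results
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
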