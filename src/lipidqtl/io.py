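"""Readers/writers for on-disk formats, run configuration and the pipeline driver.

Interchange conventions: variant maps are written as minimal VCF (POS 1-based,
REF = BY allele, ALT = AWRI allele) or an equivalent TSV dialect; windows,
blocks and peaks use BED/bedGraph conventions (0-based half-open). Both are
stated in file headers. All writers emit deterministic column and line order;
readers reject unsorted genomic input rather than silently reordering it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .backcross_analysis import DupCall, HaplotypeBlock
from .phenotyping import bin_distribution, plate_normalize
from .synthetic_cross import (
    DEFAULT_RATE_CM_PER_KB,
    S288C_CHROM_LENGTHS,
    GeneticMap,
    Mosaic,
    PoolCounts,
    SegregantCalls,
    TraitModel,
    VariantMap,
    apply_marker_selection,
    build_parental_map,
    default_trait_model,
    facs_sort,
    origin_code,
    origin_label,
    pool_sequencing,
    simulate_f1_segregants,
    trait_values,
)
from .xqtl_mapping import QTLPeak, allele_ratio, call_peaks, null_threshold, pool_delta, window_median

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A file could not be parsed; the message carries the offending location."""


# ---------------------------------------------------------------------------
# Variant map
# ---------------------------------------------------------------------------


def write_variant_vcf(vmap: VariantMap, path) -> None:
    """Minimal VCF: one record per SNV, REF = BY allele, ALT = AWRI allele."""
    header = pysam.VariantHeader()
    for chrom, length in vmap.chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.add_meta("source", f"lipidqtl-{__version__}")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom in vmap.chroms:
            for pos, ref, alt in zip(
                vmap.positions[chrom], vmap.allele_by[chrom], vmap.allele_awri[chrom]
            ):
                rec = out.new_record(contig=chrom, start=int(pos) - 1, alleles=(str(ref), str(alt)))
                out.write(rec)


def read_variant_vcf(path) -> VariantMap:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ParseError(f"{path}: empty variant file")
    with pysam.VariantFile(str(path)) as vf:
        chrom_lengths = {name: vf.header.contigs[name].length for name in vf.header.contigs}
        positions: dict[str, list[int]] = {}
        a_by: dict[str, list[str]] = {}
        a_aw: dict[str, list[str]] = {}
        for rec in vf:
            positions.setdefault(rec.chrom, []).append(rec.pos)
            a_by.setdefault(rec.chrom, []).append(rec.ref)
            a_aw.setdefault(rec.chrom, []).append(rec.alts[0])
    return VariantMap(
        chrom_lengths,
        {c: np.array(p, dtype=np.int64) for c, p in positions.items()},
        {c: np.array(v, dtype="U1") for c, v in a_by.items()},
        {c: np.array(v, dtype="U1") for c, v in a_aw.items()},
    )


def write_variant_tsv(vmap: VariantMap, path) -> None:
    """TSV dialect of the variant map; chromosome lengths in ## header lines."""
    with open(path, "w") as fh:
        fh.write("## lipidqtl variant map; pos is 1-based; REF=BY allele, ALT=AWRI allele\n")
        for chrom, length in vmap.chrom_lengths.items():
            fh.write(f"##length={chrom}:{length}\n")
        vmap.to_frame().to_csv(fh, sep="\t", index=False)


def read_variant_tsv(path) -> VariantMap:
    path = Path(path)
    chrom_lengths: dict[str, int] = {}
    n_header = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("##"):
                break
            n_header += 1
            if line.startswith("##length="):
                try:
                    spec = line.strip().split("=", 1)[1]
                    chrom, length = spec.split(":")
                    chrom_lengths[chrom] = int(length)
                except Exception as exc:
                    raise ParseError(f"{path}:{lineno}: malformed ##length line") from exc
        else:
            raise ParseError(f"{path}: empty variant file")
    df = pd.read_csv(path, sep="\t", skiprows=n_header)
    required = {"chrom", "pos", "allele_by", "allele_awri"}
    if missing := required - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return VariantMap.from_frame(df, chrom_lengths)


def write_variant_table(vmap: VariantMap, path) -> None:
    """Dispatch on extension: .vcf -> minimal VCF, anything else -> TSV dialect."""
    if str(path).endswith(".vcf"):
        write_variant_vcf(vmap, path)
    else:
        write_variant_tsv(vmap, path)


def read_variant_table(path) -> VariantMap:
    if str(path).endswith(".vcf"):
        return read_variant_vcf(path)
    return read_variant_tsv(path)


# ---------------------------------------------------------------------------
# Pool counts / calls / mosaics / tracks
# ---------------------------------------------------------------------------


def write_pool_counts(pool: PoolCounts, path) -> None:
    """TSV with columns chrom, pos, n_by, n_awri (the AD-field analogue of a
    pooled VCF). Ratio orientation downstream is AWRI:BY; the BY:AWRI phrasing
    of some reports is the reciprocal."""
    with open(path, "w") as fh:
        fh.write("## lipidqtl pool counts; pos 1-based; downstream ratio orientation AWRI:BY\n")
        fh.write(f"##pool_label={pool.pool_label}\n")
        fh.write(f"##mean_target_depth={pool.mean_target_depth}\n")
        pool.counts.to_csv(fh, sep="\t", index=False)


def read_pool_counts(path) -> PoolCounts:
    path = Path(path)
    label, depth = "custom", float("nan")
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##pool_label="):
                label = line.strip().split("=", 1)[1]
            elif line.startswith("##mean_target_depth="):
                depth = float(line.strip().split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "n_by", "n_awri"}
    if missing := required - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df[["n_by", "n_awri"]].to_numpy() < 0).any():
        raise ParseError(f"{path}: negative read counts")
    return PoolCounts(pool_label=label, mean_target_depth=depth, counts=df)


def write_segregant_calls(calls: SegregantCalls, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"##segregant_id={calls.segregant_id}\n")
        out = calls.calls.copy()
        out["call"] = [origin_label(c) for c in out["call"]]
        out.to_csv(fh, sep="\t", index=False)


def read_segregant_calls(path) -> SegregantCalls:
    path = Path(path)
    seg_id = path.stem
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("##segregant_id="):
            seg_id = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#")
    if missing := {"chrom", "pos", "call"} - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df["call"] = [origin_code(c) for c in df["call"]]
    return SegregantCalls(segregant_id=seg_id, calls=df)


def write_mosaics_tsv(mosaics: Sequence[Mosaic], path, ids: Sequence[str] | None = None) -> None:
    """Segregant genomes as BED-like rows: segregant, chrom, start, end, origin."""
    ids = ids or [f"seg{i:05d}" for i in range(len(mosaics))]
    frames = []
    for seg_id, mosaic in zip(ids, mosaics):
        df = mosaic.to_frame()
        df.insert(0, "segregant", seg_id)
        frames.append(df)
    with open(path, "w") as fh:
        fh.write("## lipidqtl segregant mosaics; 0-based half-open segments\n")
        for chrom, length in mosaics[0].chrom_lengths.items():
            fh.write(f"##length={chrom}:{length}\n")
        pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)


def read_mosaics_tsv(path) -> tuple[list[Mosaic], list[str]]:
    chrom_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##length="):
                chrom, length = line.strip().split("=", 1)[1].split(":")
                chrom_lengths[chrom] = int(length)
    df = pd.read_csv(path, sep="\t", comment="#")
    mosaics, ids = [], []
    for seg_id, grp in df.groupby("segregant", sort=False):
        mosaics.append(Mosaic.from_frame(grp, chrom_lengths))
        ids.append(str(seg_id))
    return mosaics, ids


def write_window_track(windows: pd.DataFrame, path, value_col: str = "median_freq") -> None:
    """bedGraph-like TSV (chrom, start, end, value, n_snvs); 0-based half-open."""
    cols = ["chrom", "start", "end", value_col]
    if "n_snvs" in windows.columns:
        cols.append("n_snvs")
    with open(path, "w") as fh:
        fh.write("## lipidqtl window track; 0-based half-open; ratio orientation AWRI:BY\n")
        if "window_size" in windows.attrs:
            fh.write(f"##window_size={windows.attrs['window_size']}\n")
        windows[cols].to_csv(fh, sep="\t", index=False)


def read_window_track(path) -> pd.DataFrame:
    window_size = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.startswith("##window_size="):
                window_size = int(line.strip().split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#")
    if window_size is not None:
        df.attrs["window_size"] = window_size
    return df


def write_peaks_bed(peaks: Sequence[QTLPeak], path) -> None:
    """BED6: name = enriched parent, score = 1000 * min(|apex_delta|, 1)."""
    with open(path, "w") as fh:
        fh.write("## lipidqtl QTL peaks; BED6; score = 1000*min(|apex_delta|,1)\n")
        for p in peaks:
            score = int(round(1000 * min(abs(p.apex_delta), 1.0)))
            strand = "+" if p.apex_delta > 0 else "-"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.enriched_parent}\t{score}\t{strand}\n")


def write_blocks_bed(blocks: Sequence[HaplotypeBlock], path) -> None:
    """BED4 per segregant: name = parental origin or 'unassigned'."""
    with open(path, "w") as fh:
        fh.write("## lipidqtl haplotype blocks; BED4\n")
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.origin}\n")


def write_dup_calls_bed(calls: Sequence[DupCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("## lipidqtl duplication calls; BED4; name = mean fold change\n")
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.mean_fold:.3f}\n")


def read_depth_track(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if missing := {"chrom", "start", "end", "depth"} - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_plate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if missing := {"plate", "well", "strain", "od600", "fi_pre", "fi_post"} - set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Declarative configuration for an end-to-end run.

    Defaults mirror the study conditions: a 68,000-SNV map over the 16
    S288C-length chromosomes, a uniform 0.345 cM/kbp genetic map, a top-2%
    FACS gate, 10,000 bp windows, pseudocount 0.5, a >=5-consecutive-SNV block
    rule, 100 histogram bins and pool depths of 738x (average) and 1407x
    (selected).
    """

    n_snvs: int = 68000
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(S288C_CHROM_LENGTHS))
    rate_cm_per_kb: float = DEFAULT_RATE_CM_PER_KB
    n_segregants: int = 10000
    gate_fraction: float = 0.02
    window_size: int = 10000
    pseudocount: float = 0.5
    min_run: int = 5
    n_bins: int = 100
    depth_average: float = 738.0
    depth_selected: float = 1407.0
    error_rate: float = 0.002
    marker_loci: list[tuple[str, int]] = field(default_factory=list)
    marker_origin: str = "BY"
    trait_model: TraitModel = field(default_factory=default_trait_model)
    threshold: float | str = "auto"
    null_sims: int = 20
    null_segregants: int | None = None
    min_windows: int = 2
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_snvs < 1:
            raise ValueError("n_snvs must be >= 1")
        if not (0 < self.gate_fraction <= 1):
            raise ValueError("gate_fraction must be in (0, 1]")
        if self.window_size <= 0 or self.min_run < 1 or self.n_bins < 2:
            raise ValueError("window_size, min_run and n_bins out of range")
        if self.pseudocount < 0 or self.depth_average <= 0 or self.depth_selected <= 0:
            raise ValueError("pseudocount/depths out of range")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")
        if isinstance(self.threshold, str) and self.threshold != "auto":
            raise ValueError("threshold must be a positive float or 'auto'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["marker_loci"] = [[c, int(p)] for c, p in self.marker_loci]
        d["trait_model"] = {
            "baseline": self.trait_model.baseline,
            "noise_sd": self.trait_model.noise_sd,
            "locus_effects": [list(e) for e in self.trait_model.locus_effects],
            "epistasis_terms": [
                [list(t[0]), list(t[1]), t[2]] for t in self.trait_model.epistasis_terms
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(d) - known:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "trait_model" in d and isinstance(d["trait_model"], dict):
            tm = d["trait_model"]
            try:
                d["trait_model"] = TraitModel(
                    baseline=tm["baseline"],
                    locus_effects=[tuple(e) for e in tm.get("locus_effects", [])],
                    epistasis_terms=[
                        (tuple(t[0]), tuple(t[1]), t[2]) for t in tm.get("epistasis_terms", [])
                    ],
                    noise_sd=tm.get("noise_sd", 0.0),
                )
            except KeyError as exc:
                raise ValueError(f"trait_model missing key: {exc}") from exc
        if "marker_loci" in d:
            d["marker_loci"] = [(c, int(p)) for c, p in d["marker_loci"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ParseError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Stable hash over the semantically meaningful fields."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Simulate -> phenotype -> sort -> pool-seq -> map-qtl, writing all
    artifacts plus a manifest with seeds, version and config hash.

    Identical config (including seed) produces byte-identical TSV outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("map", "meiosis", "trait", "pool_avg", "pool_sel", "null"), ss.spawn(6)
        )
    }
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stage = "simulate"
    try:
        vmap = build_parental_map(config.n_snvs, config.chrom_lengths, seeds["map"])
        gmap = GeneticMap.uniform(config.chrom_lengths, config.rate_cm_per_kb)
        write_variant_table(vmap, outdir / "variant_map.tsv")
        segregants = simulate_f1_segregants(vmap, gmap, config.n_segregants, seeds["meiosis"])
        if config.marker_loci:
            segregants = apply_marker_selection(
                segregants, config.marker_loci, config.marker_origin
            )
            if not segregants:
                raise PipelineError("simulate: no marker survivors")
        manifest["stages"][stage] = {"n_snvs": vmap.n_snvs, "n_segregants": len(segregants)}

        stage = "phenotype"
        values = trait_values(segregants, config.trait_model, seeds["trait"])
        by_parent, awri_parent = config.trait_model.parental_values()
        pd.DataFrame(
            {"segregant": [f"seg{i:05d}" for i in range(len(values))], "fi": values}
        ).to_csv(outdir / "traits.tsv", sep="\t", index=False)
        normalized = values / by_parent
        positive = normalized[normalized > 0]
        hist = bin_distribution(
            positive,
            config.n_bins,
            by_parent_value=1.0,
            awri_parent_value=awri_parent / by_parent,
        )
        hist.to_frame().to_csv(outdir / "histogram.tsv", sep="\t", index=False)
        (outdir / "histogram_anchors.json").write_text(
            json.dumps({"by_class": hist.by_class, "awri_class": hist.awri_class}) + "\n"
        )
        manifest["stages"][stage] = {
            "n_values": int(values.size),
            "n_nonpositive_excluded": int(values.size - positive.size),
        }

        stage = "sort"
        selected_idx = facs_sort(values, config.gate_fraction)
        manifest["stages"][stage] = {"n_selected": int(selected_idx.size)}

        stage = "poolseq"
        avg_pool = pool_sequencing(
            segregants, vmap, config.depth_average, config.error_rate, seeds["pool_avg"], "average"
        )
        sel_pool = pool_sequencing(
            [segregants[i] for i in selected_idx],
            vmap,
            config.depth_selected,
            config.error_rate,
            seeds["pool_sel"],
            "selected",
        )
        write_pool_counts(avg_pool, outdir / "pool_average.tsv")
        write_pool_counts(sel_pool, outdir / "pool_selected.tsv")
        manifest["stages"][stage] = {"n_sites": len(avg_pool)}

        stage = "map-qtl"
        win_avg = window_median(
            allele_ratio(avg_pool, config.pseudocount), config.window_size, config.chrom_lengths
        )
        win_sel = window_median(
            allele_ratio(sel_pool, config.pseudocount), config.window_size, config.chrom_lengths
        )
        write_window_track(win_avg, outdir / "windows_average.tsv")
        write_window_track(win_sel, outdir / "windows_selected.tsv")
        delta = pool_delta(win_sel, win_avg)
        write_window_track(delta, outdir / "delta.tsv", value_col="delta")
        if config.threshold == "auto":
            threshold = null_threshold(
                vmap,
                gmap,
                n_segregants=config.null_segregants or config.n_segregants,
                gate_fraction=config.gate_fraction,
                mean_depths=(config.depth_average, config.depth_selected),
                n_sims=config.null_sims,
                window_size=config.window_size,
                pseudocount=config.pseudocount,
                error_rate=config.error_rate,
                seed=seeds["null"],
            )
        else:
            threshold = float(config.threshold)
        peaks = call_peaks(delta, threshold, config.min_windows)
        write_peaks_bed(peaks, outdir / "peaks.bed")
        manifest["stages"][stage] = {
            "n_windows": int(len(delta)),
            "threshold": threshold,
            "n_peaks": len(peaks),
        }
    except PipelineError:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    except Exception as exc:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %s (%d peaks)", outdir, manifest["stages"]["map-qtl"]["n_peaks"])
    return outdir
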