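"""X-QTL mapping from pooled allele counts.

Computes per-SNV parental allele ratios for a sequenced pool, windowed medians
along the genome, the selected-minus-average difference track, a simulation
null for the calling threshold, candidate QTL peaks, and allele enrichment
among individually genotyped top segregants.

Ratios are oriented AWRI:BY internally; the reciprocal (BY:AWRI) is a trivial
transform and is noted in output headers written by :mod:`lipidqtl.io`. The
difference track is computed on the allele-frequency scale by default because
ratio differences are scale-asymmetric; a ratio-scale mode is kept for figure
parity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_cross import (
    AWRI,
    BY,
    ORIGIN_LABELS,
    GeneticMap,
    PoolCounts,
    SegregantCalls,
    VariantMap,
    _rng,
    gate_size,
    pool_sequencing,
    simulate_meiosis,
)

logger = logging.getLogger(__name__)


@dataclass
class QTLPeak:
    """A candidate QTL: a maximal run of windows with a consistent, strong
    allele-frequency difference between the selected and average pools."""

    chrom: str
    start: int
    end: int
    apex_pos: int
    apex_delta: float
    enriched_parent: str
    n_windows: int


@dataclass
class EnrichmentReport:
    """Allele counts at one locus across individually genotyped segregants."""

    locus: tuple[str, int]
    n_strains: int
    n_by: int
    n_awri: int

    @property
    def pct_by(self) -> float:
        return 100.0 * self.n_by / (self.n_by + self.n_awri)

    @property
    def pct_awri(self) -> float:
        return 100.0 * self.n_awri / (self.n_by + self.n_awri)


def allele_ratio(pool: PoolCounts, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-SNV AWRI:BY read ratio and AWRI frequency for a pool.

    ratio = (n_awri + c) / (n_by + c) with pseudocount c (Haldane-Anscombe
    correction keeping ratios finite and positive at zero counts). With c = 0,
    sites where the ratio would be 0 or infinite are dropped with a logged
    count. Zero-depth sites are always dropped (the frequency is undefined).

    Returns columns chrom, pos, depth, ratio_awri_by, freq_awri.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    df = pool.counts
    if df.empty:
        raise ValueError("empty pool counts")
    n_by = df["n_by"].to_numpy(dtype=float)
    n_awri = df["n_awri"].to_numpy(dtype=float)
    depth = n_by + n_awri
    keep = depth > 0
    if pseudocount == 0:
        keep &= (n_by > 0) & (n_awri > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("allele_ratio: dropped %d sites with undefined ratio", n_dropped)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy()[keep],
            "pos": df["pos"].to_numpy()[keep],
            "depth": depth[keep].astype(np.int64),
            "ratio_awri_by": (n_awri[keep] + pseudocount) / (n_by[keep] + pseudocount),
            "freq_awri": n_awri[keep] / depth[keep],
        }
    )
    return out


def _check_sorted(df: pd.DataFrame) -> None:
    """Reject inputs not grouped by chromosome with increasing positions."""
    chroms = df["chrom"].to_numpy()
    if chroms.size == 0:
        return
    change = np.flatnonzero(chroms[1:] != chroms[:-1])
    block_heads = chroms[np.concatenate(([0], change + 1))]
    if len(set(block_heads)) != len(block_heads):
        raise ValueError("input not grouped by chromosome (no silent sort)")
    pos = df["pos"].to_numpy()
    if chroms.size > 1:
        same = chroms[1:] == chroms[:-1]
        if np.any(same & (np.diff(pos) <= 0)):
            raise ValueError("positions not strictly increasing within chromosome")


def window_median(
    ratios: pd.DataFrame,
    window_size: int = 10000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Median allele ratio/frequency in non-overlapping genomic windows.

    Windows tile each chromosome from 0 in steps of ``window_size`` (the last
    window may be shorter when ``chrom_lengths`` is given). A window's median
    is taken over the SNVs with 1-based pos in [start + 1, end]; windows with
    no SNVs are omitted, producing gaps in the track. Input must be sorted by
    (chrom, pos); unsorted input is an error, never silently sorted.

    Returns columns chrom, start, end, n_snvs, median_ratio, median_freq, with
    the window size recorded in ``df.attrs['window_size']``.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    _check_sorted(ratios)
    df = ratios.copy()
    df["start"] = ((df["pos"] - 1) // window_size) * window_size
    grouped = df.groupby(["chrom", "start"], sort=False)
    out = grouped.agg(
        n_snvs=("pos", "size"),
        median_ratio=("ratio_awri_by", "median"),
        median_freq=("freq_awri", "median"),
    ).reset_index()
    out["end"] = out["start"] + window_size
    if chrom_lengths is not None:
        lengths = out["chrom"].map(chrom_lengths)
        out["end"] = np.minimum(out["end"], lengths)
    out = out[["chrom", "start", "end", "n_snvs", "median_ratio", "median_freq"]]
    out.attrs["window_size"] = int(window_size)
    return out


def pool_delta(
    selected: pd.DataFrame,
    average: pd.DataFrame,
    scale: str = "freq",
) -> pd.DataFrame:
    """Selected-minus-average difference per window present in both tracks.

    ``scale='freq'`` (default) differences the median AWRI allele frequency;
    ``scale='ratio'`` differences the median AWRI:BY ratio. Positive delta
    means AWRI enrichment in the selected pool. Windows missing in either
    track are omitted. Both tracks must share the same window size.
    """
    if scale not in ("freq", "ratio"):
        raise ValueError("scale must be 'freq' or 'ratio'")
    ws_sel = selected.attrs.get("window_size")
    ws_avg = average.attrs.get("window_size")
    if ws_sel is not None and ws_avg is not None and ws_sel != ws_avg:
        raise ValueError(f"mismatched window sizes: {ws_sel} vs {ws_avg}")
    col = "median_freq" if scale == "freq" else "median_ratio"
    merged = selected.merge(
        average, on=["chrom", "start", "end"], suffixes=("_sel", "_avg"), how="inner"
    )
    out = merged[["chrom", "start", "end"]].copy()
    out["delta"] = merged[f"{col}_sel"] - merged[f"{col}_avg"]
    out["n_snvs"] = np.minimum(merged["n_snvs_sel"], merged["n_snvs_avg"])
    if ws_sel is not None:
        out.attrs["window_size"] = ws_sel
    out.attrs["scale"] = scale
    return out


def null_threshold(
    variant_map: VariantMap,
    genetic_map: GeneticMap | None = None,
    n_segregants: int = 1000,
    gate_fraction: float = 0.02,
    mean_depths: tuple[float, float] = (738.0, 1407.0),
    n_sims: int = 20,
    quantile: float = 0.99,
    window_size: int = 10000,
    pseudocount: float = 0.5,
    error_rate: float = 0.0,
    seed=None,
) -> float:
    """Selection-free null for the |delta| peak-calling threshold.

    Each simulation draws a fresh segregant population, sequences the whole
    population as the 'average' pool and a random (not trait-selected) subset
    of size ceil(gate_fraction * n) as the 'selected' pool at the stated
    depths, and windows both tracks exactly as the real analysis does. The
    returned threshold is the requested quantile of |delta| pooled over all
    simulations and windows.
    """
    if n_sims < 20:
        raise ValueError("n_sims must be >= 20")
    gmap = genetic_map or GeneticMap.uniform(variant_map.chrom_lengths)
    rng = _rng(seed)
    abs_deltas = []
    for _ in range(n_sims):
        population = [simulate_meiosis(variant_map, gmap, rng) for _ in range(n_segregants)]
        k = gate_size(n_segregants, gate_fraction)
        sel_idx = rng.choice(n_segregants, size=k, replace=False)
        avg_pool = pool_sequencing(
            population, variant_map, mean_depths[0], error_rate, rng, "average"
        )
        sel_pool = pool_sequencing(
            [population[i] for i in sel_idx], variant_map, mean_depths[1], error_rate, rng, "selected"
        )
        win_avg = window_median(allele_ratio(avg_pool, pseudocount), window_size, variant_map.chrom_lengths)
        win_sel = window_median(allele_ratio(sel_pool, pseudocount), window_size, variant_map.chrom_lengths)
        delta = pool_delta(win_sel, win_avg)
        abs_deltas.append(np.abs(delta["delta"].to_numpy()))
    pooled = np.concatenate(abs_deltas)
    thr = float(np.quantile(pooled, quantile))
    logger.info("null_threshold: q%.2f of %d null windows = %.4f", quantile, pooled.size, thr)
    return thr


def call_peaks(delta: pd.DataFrame, threshold: float, min_windows: int = 2) -> list[QTLPeak]:
    """Candidate QTL peaks from the delta track.

    A peak is a maximal run of genomically contiguous windows (each window
    starting where the previous one ends -- a gap in the track breaks a run)
    with |delta| >= threshold and a constant sign. The apex is the window with
    the largest |delta|; the enriched parent is AWRI for positive delta, BY
    for negative.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    peaks: list[QTLPeak] = []
    run: list[tuple[int, int, float]] = []
    run_chrom = None

    def flush() -> None:
        if len(run) >= min_windows:
            deltas = np.array([r[2] for r in run])
            apex = int(np.argmax(np.abs(deltas)))
            apex_start, apex_end, apex_delta = run[apex]
            peaks.append(
                QTLPeak(
                    chrom=run_chrom,
                    start=run[0][0],
                    end=run[-1][1],
                    apex_pos=(apex_start + apex_end) // 2,
                    apex_delta=float(apex_delta),
                    enriched_parent=ORIGIN_LABELS[AWRI if apex_delta > 0 else BY],
                    n_windows=len(run),
                )
            )

    for row in delta.itertuples(index=False):
        d = row.delta
        qualifies = abs(d) >= threshold
        contiguous = (
            run
            and row.chrom == run_chrom
            and row.start == run[-1][1]
            and np.sign(d) == np.sign(run[-1][2])
        )
        if qualifies and contiguous:
            run.append((row.start, row.end, d))
        else:
            flush()
            run = [(row.start, row.end, d)] if qualifies else []
            run_chrom = row.chrom if qualifies else None
    flush()
    return peaks


def allele_enrichment(calls: Sequence[SegregantCalls], locus: tuple[str, int]) -> EnrichmentReport:
    """BY/AWRI allele counts at one locus over genotyped strains.

    Strains with a missing call at the locus are excluded from the
    percentages; a locus uncalled in every strain is an error.
    """
    chrom, pos = locus
    n_by = n_awri = 0
    for sc in calls:
        call = sc.call_at(chrom, pos)
        if call == BY:
            n_by += 1
        elif call == AWRI:
            n_awri += 1
    if n_by + n_awri == 0:
        raise ValueError(f"locus {chrom}:{pos} is uncalled in all {len(calls)} strains")
    return EnrichmentReport(locus=(chrom, int(pos)), n_strains=len(calls), n_by=n_by, n_awri=n_awri)
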