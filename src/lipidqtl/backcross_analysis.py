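"""Backcross-introgression analysis.

Drives a multi-generation backcross in which the highest-FI segregant of each
generation is crossed to the recurrent parent, infers parental-origin
haplotype blocks from per-segregant SNV calls using the >=5-consecutive-SNV
rule, quantifies the retained donor genome against the (1/2)^g drift
expectation, and flags duplicated segments from windowed sequencing depth.

Generation indexing follows the convention in which the F1 founder carries an
expected 50% donor genome and each backcross meiosis halves it, so generation
g has expectation 100 * (1/2)^g percent and F7 corresponds to 0.78% (printed
as 0.8% at one decimal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_cross import (
    AWRI,
    BY,
    ORIGIN_LABELS,
    GeneticMap,
    Mosaic,
    SegregantCalls,
    TraitModel,
    VariantMap,
    _rng,
    apply_marker_selection,
    origin_code,
    origin_label,
    recombine_gamete,
    simulate_segregant_calls,
    trait_values,
)

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class HaplotypeBlock:
    """An inferred parental-origin interval (0-based half-open bp)."""

    chrom: str
    start: int
    end: int
    origin: str  # "BY", "AWRI" or "unassigned"
    n_supporting_snvs: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DupCall:
    """A depth-gain segment consistent with a duplicated chromosome part."""

    chrom: str
    start: int
    end: int
    mean_fold: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LineageRecord:
    """One generation of a backcross lineage: the selected segregant and its
    donor-genome content."""

    generation: int
    segregant_id: str
    trait_value: float
    donor_fraction_pct: float
    mosaic: Mosaic
    blocks: list[HaplotypeBlock] | None = None


def expected_donor_fraction(g: int) -> float:
    """Expected donor-genome percentage at generation g without selection:
    100 * (1/2)^g (g counts meioses separating the generation from the hybrid,
    so the F1 founder is g=1 at 50% and F7 is 0.78125%, printed as 0.8%)."""
    if g < 1:
        raise ValueError("generation must be >= 1")
    return 100.0 * 0.5**g


def run_backcross(
    founder: Mosaic,
    recurrent_parent,
    variant_map,
    genetic_map: GeneticMap,
    trait_model: TraitModel,
    generations: int = 7,
    n_per_gen: int = 190,
    marker_loci: Iterable[tuple[str, int]] = (),
    marker_origin=BY,
    seed=None,
    infer: bool = False,
    miscall_rate: float = 0.0,
    missing_rate: float = 0.0,
    min_run: int = 5,
    max_batches: int = 50,
) -> list[LineageRecord]:
    """Simulate one backcross lineage up to generation F``generations``.

    Starting from the F1 ``founder``, each round crosses the currently selected
    segregant with the recurrent parent (a uniform mosaic), simulates
    marker-surviving segregants in batches of ``n_per_gen`` until ``n_per_gen``
    survivors are collected (bounded by ``max_batches``), phenotypes them under
    ``trait_model`` and carries the argmax-FI segregant forward. The donor
    parent is the opposite of the recurrent parent.

    ``donor_fraction_pct`` is measured on the true simulated mosaic; with
    ``infer=True`` the selected segregant is additionally genotyped
    (``simulate_segregant_calls``) and its haplotype blocks inferred with the
    consecutive-SNV rule, stored on the record.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    rng = _rng(seed)
    recurrent_code = origin_code(recurrent_parent)
    donor_code = 1 - recurrent_code
    recurrent = Mosaic.uniform(recurrent_code, founder.chrom_lengths)
    loci = list(marker_loci)

    def record(gen: int, mosaic: Mosaic, value: float) -> LineageRecord:
        rec = LineageRecord(
            generation=gen,
            segregant_id=f"F{gen}_selected",
            trait_value=float(value),
            donor_fraction_pct=100.0 * mosaic.fraction(donor_code),
            mosaic=mosaic,
        )
        if infer:
            calls = simulate_segregant_calls(
                mosaic, variant_map, miscall_rate, missing_rate, rng, rec.segregant_id
            )
            rec.blocks = infer_blocks(calls, variant_map, min_run=min_run)
            rec.donor_fraction_pct = donor_fraction(
                rec.blocks, donor_code, denominator="genome", chrom_lengths=founder.chrom_lengths
            )
        return rec

    current = founder
    records = [record(1, founder, trait_values([founder], trait_model, rng)[0])]
    for gen in range(2, generations + 1):
        survivors: list[Mosaic] = []
        for batch in range(max_batches):
            children = [recombine_gamete(current, recurrent, genetic_map, rng) for _ in range(n_per_gen)]
            if loci:
                children = apply_marker_selection(children, loci, marker_origin)
            survivors.extend(children)
            if len(survivors) >= n_per_gen:
                survivors = survivors[:n_per_gen]
                break
        else:
            raise RuntimeError(
                f"generation F{gen}: no {n_per_gen} marker survivors after {max_batches} batches"
            )
        values = trait_values(survivors, trait_model, rng)
        best = int(np.argmax(values))
        current = survivors[best]
        records.append(record(gen, current, values[best]))
    return records


def infer_blocks(
    calls: SegregantCalls,
    variant_map: VariantMap,
    min_run: int = 5,
    boundary: str = "snv",
) -> list[HaplotypeBlock]:
    """Parental-origin haplotype blocks from per-segregant SNV calls.

    A maximal run of >= ``min_run`` consecutive same-parent calls becomes an
    assigned block extending between its furthest two SNVs, i.e. the half-open
    interval [first_pos - 1, last_pos). Shorter runs and the intervals between
    assigned blocks are labelled unassigned, never merged into neighbours. The
    returned blocks tile every chromosome of the variant map exactly.

    ``boundary='midpoint'`` instead extends each assigned block to the midpoint
    between its terminal SNV and the nearest flanking call (or to the
    chromosome end when there is none).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if boundary not in ("snv", "midpoint"):
        raise ValueError("boundary must be 'snv' or 'midpoint'")
    df = calls.calls
    blocks: list[HaplotypeBlock] = []
    by_chrom = dict(tuple(df.groupby("chrom", sort=False)))
    for chrom, length in variant_map.chrom_lengths.items():
        grp = by_chrom.get(chrom)
        if grp is None or grp.empty:
            blocks.append(HaplotypeBlock(chrom, 0, length, UNASSIGNED, 0))
            continue
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"{chrom}: calls must be ordered by position")
        vpos = variant_map.positions.get(chrom)
        if vpos is None or np.any(vpos[np.searchsorted(vpos, pos) % vpos.size] != pos):
            raise ValueError(f"{chrom}: calls at positions absent from the variant map")
        cal = grp["call"].to_numpy(dtype=np.int8)
        # maximal runs of identical calls
        change = np.flatnonzero(cal[1:] != cal[:-1]) + 1
        starts = np.concatenate(([0], change))
        stops = np.concatenate((change, [cal.size]))
        assigned = []  # (block_start, block_end, origin_code, run_len)
        for i0, i1 in zip(starts, stops):
            if i1 - i0 < min_run:
                continue
            if boundary == "snv":
                b_start, b_end = int(pos[i0] - 1), int(pos[i1 - 1])
            else:  # midpoint to flanking calls
                b_start = 0 if i0 == 0 else int((pos[i0 - 1] + pos[i0]) // 2)
                b_end = length if i1 == cal.size else int((pos[i1 - 1] + pos[i1]) // 2)
            assigned.append((b_start, b_end, int(cal[i0]), int(i1 - i0)))

        def n_calls_in(lo: int, hi: int) -> int:
            # calls with 0-based coordinate (pos-1) in [lo, hi)
            return int(np.searchsorted(pos - 1, hi, "left") - np.searchsorted(pos - 1, lo, "left"))

        cursor = 0
        for b_start, b_end, code, run_len in assigned:
            if b_start > cursor:
                blocks.append(
                    HaplotypeBlock(chrom, cursor, b_start, UNASSIGNED, n_calls_in(cursor, b_start))
                )
            blocks.append(HaplotypeBlock(chrom, b_start, b_end, ORIGIN_LABELS[code], run_len))
            cursor = b_end
        if cursor < length:
            blocks.append(HaplotypeBlock(chrom, cursor, length, UNASSIGNED, n_calls_in(cursor, length)))
    return blocks


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def donor_fraction(
    blocks: Sequence[HaplotypeBlock],
    donor,
    denominator: str = "genome",
    chrom_lengths: dict[str, int] | None = None,
    exclude: Iterable[tuple[str, int, int]] = (),
) -> float:
    """Percentage of the genome in donor-origin blocks.

    ``denominator='genome'`` (default) uses the total genome length, so the
    (1/2)^g comparison is well-defined even with unassigned intervals;
    ``denominator='assigned'`` uses only assigned bp (error when there are
    none). ``exclude`` regions (e.g. a depth-flagged duplicated segment) are
    subtracted from both numerator and denominator.
    """
    if denominator not in ("genome", "assigned"):
        raise ValueError("denominator must be 'genome' or 'assigned'")
    donor_lab = origin_label(donor)
    excl = list(exclude)

    def effective_length(b: HaplotypeBlock) -> int:
        cut = sum(_overlap(b.start, b.end, s, e) for c, s, e in excl if c == b.chrom)
        return b.length - cut

    donor_bp = sum(effective_length(b) for b in blocks if b.origin == donor_lab)
    if denominator == "assigned":
        assigned_bp = sum(effective_length(b) for b in blocks if b.origin != UNASSIGNED)
        if assigned_bp == 0:
            raise ValueError("no assigned blocks: donor fraction undefined for denominator='assigned'")
        return 100.0 * donor_bp / assigned_bp
    if chrom_lengths is not None:
        total = sum(chrom_lengths.values())
    else:
        total = sum(b.length for b in blocks)
    total -= sum(e - s for _, s, e in excl)
    return 100.0 * donor_bp / total


def detect_duplication(
    depth: pd.DataFrame,
    fold_threshold: float = 1.5,
    min_len: int = 50000,
) -> list[DupCall]:
    """Flag duplicated segments from a windowed depth track.

    Window depths are normalized by the genome-wide median window depth;
    maximal runs of contiguous windows with fold >= ``fold_threshold`` whose
    total length is >= ``min_len`` become duplication calls. Input columns:
    chrom, start, end, depth.
    """
    d = depth["depth"].to_numpy(dtype=float)
    if d.size == 0 or np.all(d == 0):
        raise ValueError("depth track is empty or all zero")
    median = float(np.median(d))
    if median <= 0:
        raise ValueError("genome median depth is zero; cannot normalize")
    fold = d / median
    calls: list[DupCall] = []
    run: list[tuple[int, int, float, int]] = []  # (start, end, fold, width)
    run_chrom = None

    def flush() -> None:
        if not run:
            return
        total = run[-1][1] - run[0][0]
        if total >= min_len:
            widths = np.array([r[3] for r in run], dtype=float)
            folds = np.array([r[2] for r in run])
            calls.append(
                DupCall(
                    chrom=run_chrom,
                    start=run[0][0],
                    end=run[-1][1],
                    mean_fold=float(np.average(folds, weights=widths)),
                )
            )

    rows = zip(depth["chrom"].to_numpy(), depth["start"].to_numpy(), depth["end"].to_numpy(), fold)
    for chrom, start, end, f in rows:
        qualifies = f >= fold_threshold
        contiguous = run and chrom == run_chrom and start == run[-1][1]
        if qualifies and contiguous:
            run.append((int(start), int(end), float(f), int(end - start)))
        else:
            flush()
            run = [(int(start), int(end), float(f), int(end - start))] if qualifies else []
            run_chrom = chrom if qualifies else None
    flush()
    return calls


def lineage_summary(records: Sequence[LineageRecord]) -> pd.DataFrame:
    """Tabular view of a lineage: generation, trait, donor %, expectation."""
    return pd.DataFrame(
        {
            "generation": [r.generation for r in records],
            "segregant_id": [r.segregant_id for r in records],
            "trait_value": [r.trait_value for r in records],
            "donor_fraction_pct": [r.donor_fraction_pct for r in records],
            "expected_pct": [expected_donor_fraction(r.generation) for r in records],
        }
    )
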