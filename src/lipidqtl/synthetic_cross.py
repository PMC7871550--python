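"""Synthetic BY4741 x AWRI1631 cross.

This module generates every upstream object the X-QTL and backcross analyses
consume, so the whole pipeline can be exercised without sequencing data:

* a two-parent SNV map over a 16-chromosome, ~12.07 Mb genome,
* haploid segregant genomes produced by a no-interference meiosis model under
  a genetic map (crossovers Poisson in genetic length, uniform on the cM scale),
* haploid-selection-marker filtering (e.g. the can1/lyp1 markers that force the
  BY allele at the marker loci in every surviving segregant),
* a configurable polygenic trait (additive locus effects, pairwise epistasis,
  Gaussian noise) standing in for Nile Red fluorescence intensity (FI),
* a FACS gate selecting the top fraction of trait values,
* pooled sequencing at the allele-count level (Poisson depth, binomial allele
  sampling with a symmetric base-call error), and per-segregant SNV calls.

Coordinates: SNV positions are 1-based (VCF convention); genome segments and
windows are 0-based half-open. Parental origins are encoded BY=0, AWRI=1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BY = 0
AWRI = 1
ORIGIN_LABELS = ("BY", "AWRI")

_NUCLEOTIDES = np.array(list("ACGT"))

#: Nuclear chromosome lengths of the S288C reference (sacCer3), in bp.
#: Total 12,071,326 bp, which puts ~68,000 SNVs at a mean spacing of ~177.5 bp.
S288C_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230218,
    "chrII": 813184,
    "chrIII": 316620,
    "chrIV": 1531933,
    "chrV": 576874,
    "chrVI": 270161,
    "chrVII": 1090940,
    "chrVIII": 562643,
    "chrIX": 439888,
    "chrX": 745751,
    "chrXI": 666816,
    "chrXII": 1078177,
    "chrXIII": 924431,
    "chrXIV": 784333,
    "chrXV": 1091291,
    "chrXVI": 948066,
}

#: Uniform genome-wide recombination rate, cM per kbp.  Chosen so that a
#: 26.2 kbp physical distance corresponds to ~9 cM (0.345 * 26.2 = 9.04).
DEFAULT_RATE_CM_PER_KB = 0.345

#: Stylized haploid-selection marker loci (can1-like on chrV, lyp1-like on
#: chrXIV); both must be inherited from the BY parent in surviving segregants.
DEFAULT_MARKER_LOCI: tuple[tuple[str, int], ...] = (("chrV", 32000), ("chrXIV", 185000))


def origin_code(origin) -> int:
    """Normalize a parental-origin spec ("BY", "AWRI", 0 or 1) to the int code."""
    if isinstance(origin, (int, np.integer)) and int(origin) in (BY, AWRI):
        return int(origin)
    if isinstance(origin, str):
        key = origin.strip().upper()
        if key.startswith("BY"):
            return BY
        if key.startswith("AWRI"):
            return AWRI
    raise ValueError(f"unknown parental origin: {origin!r}")


def origin_label(origin) -> str:
    return ORIGIN_LABELS[origin_code(origin)]


def _rng(seed) -> np.random.Generator:
    """Accept None, an int seed, a SeedSequence or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class VariantMap:
    """Ordered catalogue of the SNVs distinguishing the two parents.

    ``positions[chrom]`` holds strictly increasing 1-based bp coordinates;
    ``allele_by`` / ``allele_awri`` the parental nucleotides at each site
    (always different). ``chrom_lengths`` declares the genome.
    """

    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray]
    allele_by: dict[str, np.ndarray]
    allele_awri: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.chrom_lengths = {str(c): int(n) for c, n in self.chrom_lengths.items()}
        for chrom in self.positions:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"chromosome {chrom!r} has SNVs but no declared length")
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            self.positions[chrom] = pos
            if pos.size:
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"{chrom}: SNV positions must be strictly increasing")
                if pos[0] < 1 or pos[-1] > self.chrom_lengths[chrom]:
                    raise ValueError(f"{chrom}: SNV positions outside [1, chrom_length]")
            a = np.asarray(self.allele_by[chrom], dtype="U1")
            b = np.asarray(self.allele_awri[chrom], dtype="U1")
            if a.shape != pos.shape or b.shape != pos.shape:
                raise ValueError(f"{chrom}: allele arrays must match positions")
            if np.any(a == b):
                raise ValueError(f"{chrom}: parental alleles must differ at every site")
            self.allele_by[chrom], self.allele_awri[chrom] = a, b

    @property
    def chroms(self) -> list[str]:
        """Chromosomes carrying SNVs, in declared genome order."""
        return [c for c in self.chrom_lengths if c in self.positions]

    @property
    def n_snvs(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def has_site(self, chrom: str, pos: int) -> bool:
        p = self.positions.get(chrom)
        if p is None:
            return False
        i = np.searchsorted(p, pos)
        return bool(i < p.size and p[i] == pos)

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": self.positions[chrom],
                    "allele_by": self.allele_by[chrom],
                    "allele_awri": self.allele_awri[chrom],
                }
            )
            for chrom in self.chroms
        ]
        if not frames:
            return pd.DataFrame(columns=["chrom", "pos", "allele_by", "allele_awri"])
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chrom_lengths: Mapping[str, int]) -> "VariantMap":
        positions, a_by, a_aw = {}, {}, {}
        for chrom, grp in df.groupby("chrom", sort=False):
            positions[chrom] = grp["pos"].to_numpy(dtype=np.int64)
            a_by[chrom] = grp["allele_by"].to_numpy(dtype="U1")
            a_aw[chrom] = grp["allele_awri"].to_numpy(dtype="U1")
        return cls(dict(chrom_lengths), positions, a_by, a_aw)


@dataclass
class GeneticMap:
    """Physical <-> genetic coordinate conversion, piecewise-constant in rate.

    Stored per chromosome as segment end coordinates (bp, ending exactly at the
    chromosome length) and the cumulative genetic position (cM) at each end.
    All rates must be positive, so the cumulative map is strictly increasing
    and invertible.
    """

    chrom_lengths: dict[str, int]
    bp_ends: dict[str, np.ndarray]
    cum_cm: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            ends = np.asarray(self.bp_ends[chrom], dtype=np.int64)
            cum = np.asarray(self.cum_cm[chrom], dtype=float)
            if ends.size != cum.size or ends.size == 0:
                raise ValueError(f"{chrom}: malformed genetic map")
            if np.any(np.diff(np.concatenate(([0], ends))) <= 0) or ends[-1] != length:
                raise ValueError(f"{chrom}: map segments must tile the chromosome exactly")
            if np.any(np.diff(np.concatenate(([0.0], cum))) <= 0):
                raise ValueError(f"{chrom}: recombination rates must be > 0")
            self.bp_ends[chrom], self.cum_cm[chrom] = ends, cum

    @classmethod
    def uniform(
        cls, chrom_lengths: Mapping[str, int], rate_cm_per_kb: float = DEFAULT_RATE_CM_PER_KB
    ) -> "GeneticMap":
        if rate_cm_per_kb <= 0:
            raise ValueError("recombination rate must be > 0")
        lengths = {c: int(n) for c, n in chrom_lengths.items()}
        ends = {c: np.array([n], dtype=np.int64) for c, n in lengths.items()}
        cum = {c: np.array([n / 1000.0 * rate_cm_per_kb]) for c, n in lengths.items()}
        return cls(lengths, ends, cum)

    @classmethod
    def piecewise(
        cls,
        chrom_lengths: Mapping[str, int],
        segments: Mapping[str, Sequence[tuple[int, float]]],
    ) -> "GeneticMap":
        """Build from per-chromosome ``[(end_bp, rate_cm_per_kb), ...]`` pieces."""
        lengths = {c: int(n) for c, n in chrom_lengths.items()}
        bp_ends, cum_cm = {}, {}
        for chrom, length in lengths.items():
            segs = segments[chrom]
            ends = np.array([e for e, _ in segs], dtype=np.int64)
            rates = np.array([r for _, r in segs], dtype=float)
            widths = np.diff(np.concatenate(([0], ends)))
            cum_cm[chrom] = np.cumsum(widths / 1000.0 * rates)
            bp_ends[chrom] = ends
        return cls(lengths, bp_ends, cum_cm)

    def genetic_length(self, chrom: str) -> float:
        """Total genetic length of a chromosome, in cM."""
        return float(self.cum_cm[chrom][-1])

    def bp_to_cm(self, chrom: str, bp) -> np.ndarray | float:
        xp = np.concatenate(([0], self.bp_ends[chrom]))
        fp = np.concatenate(([0.0], self.cum_cm[chrom]))
        out = np.interp(bp, xp, fp)
        return float(out) if np.isscalar(bp) else out

    def cm_to_bp(self, chrom: str, cm) -> np.ndarray | float:
        xp = np.concatenate(([0.0], self.cum_cm[chrom]))
        fp = np.concatenate(([0], self.bp_ends[chrom])).astype(float)
        out = np.interp(cm, xp, fp)
        return float(out) if np.isscalar(cm) else out


def _normalize_segments(ends: np.ndarray, origins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero-length segments and merge adjacent segments of equal origin."""
    ends = np.asarray(ends, dtype=np.int64)
    origins = np.asarray(origins, dtype=np.uint8)
    starts = np.concatenate(([0], ends[:-1]))
    keep = ends > starts
    ends, origins = ends[keep], origins[keep]
    if ends.size > 1:
        change = np.append(origins[1:] != origins[:-1], True)
        ends, origins = ends[change], origins[change]
    return ends, origins


@dataclass
class Mosaic:
    """A haploid segregant genome as parental-origin segments per chromosome.

    ``ends[chrom]`` holds segment end coordinates (0-based half-open; the last
    end equals the chromosome length); ``origins[chrom]`` the matching parental
    codes. Segments tile the chromosome; adjacent segments differ in origin.
    """

    chrom_lengths: dict[str, int]
    ends: dict[str, np.ndarray]
    origins: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            e, o = _normalize_segments(self.ends[chrom], self.origins[chrom])
            if e.size == 0 or e[-1] != length:
                raise ValueError(f"{chrom}: segments must tile [0, chrom_length)")
            if np.any(o > 1):
                raise ValueError(f"{chrom}: origins must be BY (0) or AWRI (1)")
            self.ends[chrom], self.origins[chrom] = e, o

    @classmethod
    def uniform(cls, origin, chrom_lengths: Mapping[str, int]) -> "Mosaic":
        """A genome inherited wholesale from one parent (e.g. the recurrent parent)."""
        code = origin_code(origin)
        lengths = {c: int(n) for c, n in chrom_lengths.items()}
        ends = {c: np.array([n], dtype=np.int64) for c, n in lengths.items()}
        origins = {c: np.array([code], dtype=np.uint8) for c in lengths}
        return cls(lengths, ends, origins)

    def origin_at(self, chrom: str, positions):
        """Parental origin code(s) at 1-based position(s)."""
        if chrom not in self.ends:
            raise KeyError(f"chromosome {chrom!r} not in mosaic")
        p = np.asarray(positions, dtype=np.int64)
        if np.any(p < 1) or np.any(p > self.chrom_lengths[chrom]):
            raise ValueError(f"{chrom}: position outside [1, chrom_length]")
        idx = np.searchsorted(self.ends[chrom], p - 1, side="right")
        out = self.origins[chrom][idx]
        return int(out) if p.ndim == 0 else out

    def fraction(self, origin=AWRI) -> float:
        """Fraction of the genome (by bp) inherited from ``origin``."""
        code = origin_code(origin)
        total = sum(self.chrom_lengths.values())
        bp = 0
        for chrom in self.chrom_lengths:
            e = self.ends[chrom]
            widths = np.diff(np.concatenate(([0], e)))
            bp += int(widths[self.origins[chrom] == code].sum())
        return bp / total

    def n_segments(self) -> int:
        return int(sum(e.size for e in self.ends.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_lengths:
            e = self.ends[chrom]
            starts = np.concatenate(([0], e[:-1]))
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": e,
                        "origin": [ORIGIN_LABELS[o] for o in self.origins[chrom]],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, chrom_lengths: Mapping[str, int]) -> "Mosaic":
        ends, origins = {}, {}
        for chrom, grp in df.groupby("chrom", sort=False):
            ends[chrom] = grp["end"].to_numpy(dtype=np.int64)
            origins[chrom] = np.array([origin_code(o) for o in grp["origin"]], dtype=np.uint8)
        return cls({c: int(n) for c, n in chrom_lengths.items()}, ends, origins)


@dataclass
class TraitModel:
    """Polygenic model for the Nile Red FI proxy of neutral-lipid content.

    ``locus_effects`` are ``(chrom, pos, effect_if_BY, effect_if_AWRI)`` tuples;
    ``epistasis_terms`` are ``((chrom, pos, origin), (chrom, pos, origin), effect)``
    added only when both origin conditions hold. ``noise_sd`` lumps biological
    and instrument noise into one Gaussian term (FI units).
    """

    baseline: float
    locus_effects: list[tuple[str, int, float, float]] = field(default_factory=list)
    epistasis_terms: list[tuple[tuple[str, int, int], tuple[str, int, int], float]] = field(
        default_factory=list
    )
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def parental_values(self) -> tuple[float, float]:
        """Noise-free trait values of the (BY, AWRI) parents."""
        by = self.baseline + sum(e[2] for e in self.locus_effects)
        aw = self.baseline + sum(e[3] for e in self.locus_effects)
        for (c1, p1, o1), (c2, p2, o2), eff in self.epistasis_terms:
            if o1 == BY and o2 == BY:
                by += eff
            if o1 == AWRI and o2 == AWRI:
                aw += eff
        return by, aw


def default_trait_model(noise_sd: float = 10.0) -> TraitModel:
    """Three-locus model calibrated so log2(AWRI parent / BY parent) = 0.66.

    Two AWRI-beneficial loci (PIG1-like on chrXII, PHO23-like on chrXIV) and one
    BY-beneficial locus (RML2-like on chrV, 26.2 kbp from the can1-like marker,
    reproducing the marker-linkage confound). Units are arbitrary FI.
    """
    baseline = 100.0
    rml2_by = 12.0
    by_parent = baseline + rml2_by
    awri_parent = by_parent * 2.0**0.66
    per_locus = (awri_parent - baseline) / 2.0
    loci = [
        ("chrXII", 250000, 0.0, per_locus),  # PIG1-like, AWRI allele beneficial
        ("chrXIV", 560000, 0.0, per_locus),  # PHO23-like, AWRI allele beneficial
        ("chrV", 58200, rml2_by, 0.0),  # RML2-like, BY allele beneficial
    ]
    return TraitModel(baseline=baseline, locus_effects=loci, noise_sd=float(noise_sd))


@dataclass
class PoolCounts:
    """Per-SNV parental allele read counts for one sequenced pool.

    ``counts`` has columns chrom, pos, n_by, n_awri (non-negative integers),
    the in-memory analogue of the AD field of a pooled VCF.
    """

    pool_label: str
    mean_target_depth: float
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.pool_label not in ("average", "selected", "custom"):
            raise ValueError("pool_label must be 'average', 'selected' or 'custom'")
        df = self.counts
        missing = {"chrom", "pos", "n_by", "n_awri"} - set(df.columns)
        if missing:
            raise ValueError(f"pool counts missing columns: {sorted(missing)}")
        for col in ("n_by", "n_awri"):
            vals = df[col].to_numpy()
            if np.any(vals < 0):
                raise ValueError(f"negative read counts in column {col}")
        self.counts = df.astype({"pos": np.int64, "n_by": np.int64, "n_awri": np.int64})

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class SegregantCalls:
    """Per-segregant parental SNV calls; missing sites are simply absent rows."""

    segregant_id: str
    calls: pd.DataFrame  # columns chrom, pos, call (0=BY, 1=AWRI)

    def __post_init__(self) -> None:
        missing = {"chrom", "pos", "call"} - set(self.calls.columns)
        if missing:
            raise ValueError(f"calls missing columns: {sorted(missing)}")
        self.calls = self.calls.astype({"pos": np.int64, "call": np.int8})

    def __len__(self) -> int:
        return len(self.calls)

    def call_at(self, chrom: str, pos: int):
        """Call code at a site, or None if missing/uncalled."""
        sub = self.calls
        hit = sub[(sub["chrom"] == chrom) & (sub["pos"] == pos)]
        if hit.empty:
            return None
        return int(hit["call"].iloc[0])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_parental_map(
    n_snvs: int,
    chrom_lengths: Mapping[str, int] | None = None,
    seed=None,
) -> VariantMap:
    """Draw a two-parent SNV map: positions uniform without replacement per
    chromosome (allocated proportionally to length), alleles distinct nucleotides.
    """
    lengths = {c: int(n) for c, n in (chrom_lengths or S288C_CHROM_LENGTHS).items()}
    total = sum(lengths.values())
    if n_snvs < 1:
        raise ValueError("n_snvs must be >= 1")
    if n_snvs > total:
        raise ValueError(f"n_snvs={n_snvs} exceeds available positions ({total})")
    rng = _rng(seed)
    chroms = list(lengths)
    caps = np.array([lengths[c] for c in chroms], dtype=np.int64)
    counts = rng.multinomial(n_snvs, caps / total)
    # Redistribute any overfull allocation (only possible on tiny genomes).
    excess = int(np.maximum(counts - caps, 0).sum())
    counts = np.minimum(counts, caps)
    while excess > 0:
        spare = caps - counts
        i = int(np.argmax(spare))
        take = min(excess, int(spare[i]))
        counts[i] += take
        excess -= take

    positions, allele_by, allele_awri = {}, {}, {}
    for chrom, k in zip(chroms, counts):
        k = int(k)
        if k == 0:
            continue
        pos = np.sort(rng.choice(lengths[chrom], size=k, replace=False)) + 1
        by_idx = rng.integers(0, 4, size=k)
        awri_idx = (by_idx + rng.integers(1, 4, size=k)) % 4
        positions[chrom] = pos.astype(np.int64)
        allele_by[chrom] = _NUCLEOTIDES[by_idx]
        allele_awri[chrom] = _NUCLEOTIDES[awri_idx]
    return VariantMap(lengths, positions, allele_by, allele_awri)


def _crossover_positions(gmap: GeneticMap, chrom: str, rng: np.random.Generator) -> np.ndarray:
    """Crossover bp positions for one meiosis: Poisson count in Morgans, uniform
    on the genetic scale, no interference. Crossovers landing on the same bp
    after rounding cancel pairwise (even multiplicity leaves no breakpoint)."""
    total_cm = gmap.genetic_length(chrom)
    n = rng.poisson(total_cm / 100.0)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    cm = rng.uniform(0.0, total_cm, size=n)
    bp = np.rint(gmap.cm_to_bp(chrom, np.sort(cm))).astype(np.int64)
    bp = np.clip(bp, 1, gmap.chrom_lengths[chrom] - 1)
    vals, mult = np.unique(bp, return_counts=True)
    return vals[mult % 2 == 1]


def simulate_meiosis(variant_map, genetic_map: GeneticMap, seed=None) -> Mosaic:
    """One gamete of the BY x AWRI F1 hybrid as a parental-origin Mosaic.

    ``variant_map`` may be a VariantMap or a plain chrom->length mapping; the
    genetic map must cover every chromosome.
    """
    rng = _rng(seed)
    lengths = (
        variant_map.chrom_lengths if isinstance(variant_map, VariantMap) else dict(variant_map)
    )
    for chrom in lengths:
        if chrom not in genetic_map.chrom_lengths:
            raise ValueError(f"genetic map does not cover chromosome {chrom!r}")
    ends, origins = {}, {}
    for chrom, length in lengths.items():
        cuts = _crossover_positions(genetic_map, chrom, rng)
        start = int(rng.integers(2))
        e = np.append(cuts, length).astype(np.int64)
        o = ((start + np.arange(e.size)) % 2).astype(np.uint8)
        ends[chrom], origins[chrom] = e, o
    return Mosaic(dict(lengths), ends, origins)


def simulate_f1_segregants(variant_map, genetic_map: GeneticMap, n: int, seed=None) -> list[Mosaic]:
    """n independent F1 segregant genomes from a shared random stream."""
    rng = _rng(seed)
    return [simulate_meiosis(variant_map, genetic_map, rng) for _ in range(n)]


def _splice_homologs(
    homolog_a: tuple[np.ndarray, np.ndarray],
    homolog_b: tuple[np.ndarray, np.ndarray],
    cuts: np.ndarray,
    start: int,
    length: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Alternate between two homolog segment tracks at the crossover cuts."""
    bounds = np.concatenate(([0], cuts, [length]))
    out_ends, out_orgs = [], []
    src = start
    homologs = (homolog_a, homolog_b)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        ends, orgs = homologs[src]
        i = int(np.searchsorted(ends, lo, side="right"))
        j = int(np.searchsorted(ends, hi, side="left"))
        out_ends.append(np.minimum(ends[i : j + 1], hi))
        out_orgs.append(orgs[i : j + 1])
        src ^= 1
    return _normalize_segments(np.concatenate(out_ends), np.concatenate(out_orgs))


def recombine_gamete(parent_a: Mosaic, parent_b: Mosaic, genetic_map: GeneticMap, seed=None) -> Mosaic:
    """One gamete of a diploid whose homologs are two arbitrary mosaics.

    Used by backcrossing, where one homolog is the selected segregant and the
    other the (uniform) recurrent parent.
    """
    rng = _rng(seed)
    lengths = parent_a.chrom_lengths
    ends, origins = {}, {}
    for chrom, length in lengths.items():
        cuts = _crossover_positions(genetic_map, chrom, rng)
        start = int(rng.integers(2))
        ends[chrom], origins[chrom] = _splice_homologs(
            (parent_a.ends[chrom], parent_a.origins[chrom]),
            (parent_b.ends[chrom], parent_b.origins[chrom]),
            cuts,
            start,
            length,
        )
    return Mosaic(dict(lengths), ends, origins)


def apply_marker_selection(
    segregants: Sequence[Mosaic],
    marker_loci: Iterable[tuple[str, int]],
    required_origin,
) -> list[Mosaic]:
    """Keep only segregants carrying ``required_origin`` at every marker locus.

    Models haploid-selection markers (e.g. canavanine selection forcing can1
    from the BY parent). An empty survivor set is returned, not raised.
    """
    code = origin_code(required_origin)
    loci = list(marker_loci)
    survivors = [
        m for m in segregants if all(m.origin_at(c, p) == code for c, p in loci)
    ]
    logger.info(
        "marker selection: %d/%d segregants carry %s at all %d marker loci",
        len(survivors),
        len(segregants),
        ORIGIN_LABELS[code],
        len(loci),
    )
    return survivors


def trait_values(segregants: Sequence[Mosaic], model: TraitModel, seed=None) -> np.ndarray:
    """Vectorized trait values for a pool of segregants (shared noise stream)."""
    rng = _rng(seed)
    n = len(segregants)
    values = np.full(n, model.baseline, dtype=float)
    for chrom, pos, eff_by, eff_awri in model.locus_effects:
        org = np.fromiter((m.origin_at(chrom, pos) for m in segregants), dtype=np.int8, count=n)
        values += np.where(org == AWRI, eff_awri, eff_by)
    for (c1, p1, o1), (c2, p2, o2), eff in model.epistasis_terms:
        org1 = np.fromiter((m.origin_at(c1, p1) for m in segregants), dtype=np.int8, count=n)
        org2 = np.fromiter((m.origin_at(c2, p2) for m in segregants), dtype=np.int8, count=n)
        values += eff * ((org1 == o1) & (org2 == o2))
    if model.noise_sd > 0:
        values += rng.normal(0.0, model.noise_sd, size=n)
    return values


def trait_value(mosaic: Mosaic, model: TraitModel, seed=None) -> float:
    """Trait value of a single segregant (baseline + locus effects + epistasis + noise)."""
    return float(trait_values([mosaic], model, seed)[0])


def gate_size(n: int, gate_fraction: float) -> int:
    """Number of cells collected by a FACS gate: ceil(gate_fraction * n).

    A tiny downward tolerance guards against float round-up (0.02 * 150 must
    select 3 cells, not 4).
    """
    if n < 1:
        raise ValueError("empty population")
    if not (0.0 < gate_fraction <= 1.0):
        raise ValueError("gate_fraction must be in (0, 1]")
    x = gate_fraction * n
    k = int(math.ceil(x - 1e-9 - 4e-16 * x))
    return min(max(k, 1), n)


def facs_sort(values, gate_fraction: float) -> np.ndarray:
    """Indices of the top ``ceil(gate_fraction * n)`` trait values.

    Ties are broken in favour of the lower index (stable sort). The returned
    indices are ordered by decreasing value.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("facs_sort: empty input")
    k = gate_size(vals.size, gate_fraction)
    order = np.argsort(-vals, kind="stable")
    return order[:k]


def pool_allele_freq(pool: Sequence[Mosaic], variant_map: VariantMap) -> dict[str, np.ndarray]:
    """True AWRI allele frequency at every SNV across a pool of genomes."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    freq: dict[str, np.ndarray] = {}
    for chrom in variant_map.chroms:
        b = variant_map.positions[chrom] - 1
        acc = np.zeros(b.size, dtype=np.int64)
        for mosaic in pool:
            idx = np.searchsorted(mosaic.ends[chrom], b, side="right")
            acc += mosaic.origins[chrom][idx]
        freq[chrom] = acc / len(pool)
    return freq


def pool_sequencing(
    pool: Sequence[Mosaic],
    variant_map: VariantMap,
    mean_depth: float,
    error_rate: float = 0.0,
    seed=None,
    pool_label: str = "custom",
) -> PoolCounts:
    """Pooled sequencing at the allele-count level.

    Per SNV: depth ~ Poisson(mean_depth); reads supporting the AWRI allele ~
    Binomial(depth, f*(1-e) + (1-f)*e) where f is the true pool AWRI frequency
    and e a symmetric base-call error rate.
    """
    if len(pool) == 0:
        raise ValueError("empty pool")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = _rng(seed)
    freq = pool_allele_freq(pool, variant_map)
    frames = []
    for chrom in variant_map.chroms:
        f = freq[chrom]
        depth = rng.poisson(mean_depth, size=f.size)
        p = f * (1.0 - error_rate) + (1.0 - f) * error_rate
        n_awri = rng.binomial(depth, p)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": variant_map.positions[chrom],
                    "n_by": depth - n_awri,
                    "n_awri": n_awri,
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    return PoolCounts(pool_label=pool_label, mean_target_depth=float(mean_depth), counts=counts)


def simulate_segregant_calls(
    mosaic: Mosaic,
    variant_map: VariantMap,
    miscall_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed=None,
    segregant_id: str = "segregant",
) -> SegregantCalls:
    """Per-SNV parental calls for one segregant: the true origin, flipped with
    probability ``miscall_rate`` and dropped with probability ``missing_rate``."""
    if not (0.0 <= miscall_rate < 1.0):
        raise ValueError("miscall_rate must be in [0, 1)")
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must be in [0, 1]")
    rng = _rng(seed)
    frames = []
    for chrom in variant_map.chroms:
        pos = variant_map.positions[chrom]
        calls = mosaic.origin_at(chrom, pos).astype(np.int8)
        if miscall_rate > 0:
            flip = rng.random(pos.size) < miscall_rate
            calls = np.where(flip, 1 - calls, calls).astype(np.int8)
        if missing_rate > 0:
            keep = rng.random(pos.size) >= missing_rate
            pos, calls = pos[keep], calls[keep]
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "call": calls}))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["chrom", "pos", "call"])
    return SegregantCalls(segregant_id=segregant_id, calls=df)


def simulate_depth_track(
    chrom_lengths: Mapping[str, int],
    window_size: int = 5000,
    mean_depth: float = 30.0,
    read_len: int = 150,
    dup_regions: Iterable[tuple[str, int, int, float]] = (),
    seed=None,
) -> pd.DataFrame:
    """Windowed sequencing-depth track with optional duplicated regions.

    Read counts per window are Poisson with expectation
    ``mean_depth * window / read_len`` scaled by the copy number of any
    overlapping ``(chrom, start, end, copy)`` region; the reported depth is
    reads * read_len / window. Returns columns chrom, start, end, depth.
    """
    rng = _rng(seed)
    dups = list(dup_regions)
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        factor = np.ones(starts.size, dtype=float)
        for c, s, e, copy in dups:
            if c != chrom:
                continue
            overlap = np.maximum(
                0, np.minimum(ends, e) - np.maximum(starts, s)
            ) / (ends - starts)
            factor += overlap * (copy - 1.0)
        lam = mean_depth * (ends - starts) / read_len * factor
        reads = rng.poisson(lam)
        depth = reads * read_len / (ends - starts)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "depth": depth}))
    return pd.concat(rows, ignore_index=True)


def simulate_plates(
    sample_values: Sequence[float],
    reference_value: float,
    seed=None,
    samples_per_plate: int = 92,
    n_reference: int = 4,
    reference_strain: str = "Y7092",
    plate_scale_sd: float = 0.15,
    fi_pre_mean: float = 200.0,
    fi_pre_sd: float = 10.0,
) -> pd.DataFrame:
    """Microplate OD/fluorescence tables for a panel of segregants.

    Each 96-well plate holds ``samples_per_plate`` segregants plus
    ``n_reference`` replicates of the reference strain. A lognormal per-plate
    scale factor emulates day-to-day instrument drift: raw FI gains are
    value * OD * plate_scale, so the plate-normalized readout recovers
    value / reference_value. Returns columns plate, well, strain, od600,
    fi_pre, fi_post.
    """
    rng = _rng(seed)
    values = np.asarray(sample_values, dtype=float)
    rows = []
    n_plates = max(1, math.ceil(values.size / samples_per_plate))
    wells = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]
    idx = 0
    for p in range(n_plates):
        scale = float(rng.lognormal(0.0, plate_scale_sd))
        plate_id = f"P{p + 1:03d}"
        plate_vals = values[idx : idx + samples_per_plate]
        well_i = 0
        for v in plate_vals:
            od = float(rng.uniform(0.3, 0.6))
            pre = float(rng.normal(fi_pre_mean, fi_pre_sd))
            rows.append((plate_id, wells[well_i], "", od, pre, pre + v * od * scale))
            well_i += 1
        for r in range(n_reference):
            od = float(rng.uniform(0.3, 0.6))
            pre = float(rng.normal(fi_pre_mean, fi_pre_sd))
            rows.append(
                (plate_id, wells[well_i], reference_strain, od, pre, pre + reference_value * od * scale)
            )
            well_i += 1
        idx += len(plate_vals)
    df = pd.DataFrame(rows, columns=["plate", "well", "strain", "od600", "fi_pre", "fi_post"])
    # assign stable sample ids in panel order
    sample_mask = df["strain"] != reference_strain
    df.loc[sample_mask, "strain"] = [f"seg{i:05d}" for i in range(int(sample_mask.sum()))]
    return df
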