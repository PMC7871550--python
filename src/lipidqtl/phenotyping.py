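"""Microplate Nile Red phenotyping.

Turns plate-reader OD/fluorescence readings into a normalized neutral-lipid
proxy, builds the 100-bin log2 frequency distribution used to compare
segregant panels, computes transgressive-segregation fractions, selects top
segregants, and provides the small lipid summary statistics (TAG + SE totals,
two-tailed t-test).

The NL proxy for a well is (FI_post - FI_pre) / OD600; per-plate comparability
is achieved by dividing by the mean proxy of the reference-strain replicates
on the same plate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Strain used for plate normalization (isogenic with BY4741).
REFERENCE_STRAIN = "Y7092"


class InvalidMeasurementError(ValueError):
    """A plate measurement violates a physical precondition (e.g. OD <= 0)."""


def nl_proxy(od600, fi_pre, fi_post):
    """Neutral-lipid proxy: Nile Red FI gain normalized to cell density.

    Accepts scalars or arrays. Negative values (post < pre) are retained but
    logged; an OD600 <= 0 is an invalid measurement.
    """
    od = np.asarray(od600, dtype=float)
    pre = np.asarray(fi_pre, dtype=float)
    post = np.asarray(fi_post, dtype=float)
    if np.any(od <= 0):
        raise InvalidMeasurementError("od600 must be > 0 for NL-proxy computation")
    out = (post - pre) / od
    n_neg = int(np.sum(out < 0))
    if n_neg:
        logger.info("nl_proxy: %d wells with negative FI gain retained", n_neg)
    return float(out) if out.ndim == 0 else out


class MissingReferenceError(ValueError):
    """A plate lacks reference-strain wells needed for normalization."""


def plate_normalize(records: pd.DataFrame, reference_strain: str = REFERENCE_STRAIN) -> pd.DataFrame:
    """Add nl_proxy and plate-normalized columns to a plate table.

    ``records`` must have columns plate, well, strain, od600, fi_pre, fi_post.
    Each well's proxy is divided by the mean proxy of the reference strain on
    the same plate, so reference wells normalize to mean 1 per plate.
    """
    required = {"plate", "well", "strain", "od600", "fi_pre", "fi_post"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    out = records.copy()
    out["nl_proxy"] = nl_proxy(out["od600"], out["fi_pre"], out["fi_post"])
    ref_means = {}
    for plate, grp in out.groupby("plate", sort=False):
        ref = grp.loc[grp["strain"] == reference_strain, "nl_proxy"]
        if ref.empty:
            raise MissingReferenceError(
                f"plate {plate!r} has no {reference_strain!r} reference wells"
            )
        ref_means[plate] = float(ref.mean())
    out["normalized"] = out["nl_proxy"] / out["plate"].map(ref_means)
    return out


@dataclass
class Histogram:
    """Equal-width frequency distribution on the log2(normalized FI) scale.

    Bin ("class") indices are 1-based. ``edges`` has n_bins + 1 entries; bins
    are half-open [left, right) except the last, which is closed so the
    maximum lands in class n_bins.
    """

    edges: np.ndarray
    counts: np.ndarray
    by_class: int | None = None
    awri_class: int | None = None

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        widths = np.diff(self.edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValueError("histogram edges must be strictly increasing and equal width")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    def class_of(self, value: float) -> int:
        """1-based class index of a normalized value."""
        if value <= 0:
            raise InvalidMeasurementError("log2 binning requires positive values")
        x = np.log2(value)
        if x < self.edges[0] or x > self.edges[-1]:
            raise ValueError("value outside the histogram range")
        idx = int(np.searchsorted(self.edges, x, side="right"))
        return min(idx, self.n_bins)

    def class_to_log2(self, class_index) -> np.ndarray | float:
        """log2 value at the center of a (1-based) class; exactly linear in the
        class index with slope (max - min) / n_bins."""
        c = np.asarray(class_index, dtype=float)
        out = self.edges[0] + (c - 0.5) * self.bin_width
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": np.arange(1, self.n_bins + 1),
                "log2_left": self.edges[:-1],
                "log2_right": self.edges[1:],
                "count": self.counts,
            }
        )


def bin_distribution(
    normalized_values,
    n_bins: int = 100,
    by_parent_value: float | None = None,
    awri_parent_value: float | None = None,
    value_range: tuple[float, float] | None = None,
) -> Histogram:
    """Bin normalized FI values into ``n_bins`` equal log2-width classes.

    The range defaults to [min, max] of the data; pass ``value_range`` (on the
    normalized, not log2, scale) to histogram several panels on a common range.
    Non-positive values are an error listing the offending entries; a
    degenerate (zero-width) range is an error rather than a single bin.
    """
    vals = np.asarray(normalized_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two values to bin")
    bad = np.flatnonzero(vals <= 0)
    if bad.size:
        raise InvalidMeasurementError(
            f"{bad.size} non-positive values cannot be log2-binned (indices {bad[:10].tolist()}...)"
        )
    x = np.log2(vals)
    if value_range is not None:
        lo, hi = np.log2(value_range[0]), np.log2(value_range[1])
    else:
        lo, hi = float(x.min()), float(x.max())
    if not hi > lo:
        raise ValueError("degenerate value range: all values equal")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, x, side="right"), 1, n_bins)
    counts = np.bincount(idx - 1, minlength=n_bins)
    hist = Histogram(edges=edges, counts=counts)
    if by_parent_value is not None:
        hist.by_class = hist.class_of(by_parent_value)
    if awri_parent_value is not None:
        hist.awri_class = hist.class_of(awri_parent_value)
    return hist


def class_log2_interp(
    class_index,
    anchor_a: tuple[float, float],
    anchor_b: tuple[float, float],
):
    """log2 value of a class index under the linear class<->log2 mapping fixed
    by two anchor (class, log2) pairs, e.g. the parental-strain classes."""
    (ca, la), (cb, lb) = anchor_a, anchor_b
    if cb == ca:
        raise ValueError("anchor classes must differ")
    slope = (lb - la) / (cb - ca)
    c = np.asarray(class_index, dtype=float)
    out = la + (c - ca) * slope
    return float(out) if out.ndim == 0 else out


def transgressive_fractions(values, by_parent_value: float, awri_parent_value: float):
    """Percentages of segregants strictly below the low parent and strictly
    above the high parent (transgressive segregation / heterosis fractions)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty sample set")
    low, high = by_parent_value, awri_parent_value
    if low > high:
        warnings.warn("parent values out of order; swapping low/high labels", stacklevel=2)
        low, high = high, low
    pct_below = 100.0 * np.sum(vals < low) / vals.size
    pct_above = 100.0 * np.sum(vals > high) / vals.size
    return float(pct_below), float(pct_above)


def select_top(values, k: int) -> np.ndarray:
    """Indices of the k largest values, ties broken in favour of lower index."""
    vals = np.asarray(values, dtype=float)
    if not 1 <= k <= vals.size:
        raise ValueError(f"k={k} out of range for {vals.size} values")
    return np.argsort(-vals, kind="stable")[:k]


@dataclass
class LipidSummary:
    """Group means/SDs of TAG and SE content, mg per g cell dry weight."""

    group: str
    tag_mean: float
    tag_sd: float
    se_mean: float
    se_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.tag_sd < 0 or self.se_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n < 3:
            raise ValueError("lipid summaries require n >= 3 replicates")


def lipid_totals(summary: LipidSummary) -> float:
    """Total neutral lipids (TAG + SE), mg per g CDW."""
    return float(summary.tag_mean + summary.se_mean)


def lipid_totals_ca(summary: LipidSummary) -> int:
    """Total NL rounded to the integer 'ca.' reporting convention."""
    return int(round(lipid_totals(summary)))


def two_tailed_ttest(sample_a, sample_b, equal_var: bool = True) -> float:
    """Two-sided unpaired t-test p-value (Student by default, Welch by flag).

    Two zero-variance samples with equal means return p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.pvalue)
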