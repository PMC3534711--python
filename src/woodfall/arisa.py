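"""Fragment-fingerprint (ARISA-style) peak binning.

Electropherogram peak tables — one per PCR replicate — are binned into
fixed 2-bp windows to absorb size-calling jitter, combined across
replicates with a presence rule (present in ≥1 of 3 replicates by
default), and normalized to relative fluorescence intensities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("woodfall")


@dataclass
class PeakProfile:
    """Called peaks of one capillary-electrophoresis run."""

    sample_id: str
    replicate_id: str
    sizes_bp: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.sizes_bp = np.asarray(self.sizes_bp, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.sizes_bp.shape != self.areas.shape or self.sizes_bp.ndim != 1:
            raise ValueError("sizes and areas must be 1-D arrays of equal length")
        if np.any(self.areas <= 0):
            raise ValueError("peak areas must be positive")


def bin_label(low: float, bin_size: float) -> str:
    return f"bin_{low:06.1f}_{low + bin_size:06.1f}"


def bin_peaks(
    profiles: list[PeakProfile],
    bin_size_bp: float = 2.0,
    frame_offset_bp: float = 0.0,
    size_range: tuple[float, float] = (100.0, 1000.0),
) -> pd.DataFrame:
    """Assign peaks to fixed half-open bins, one row per replicate.

    Bin k covers [low + offset + k·bin_size, low + offset + (k+1)·bin_size);
    a peak exactly on a boundary belongs to the higher bin (lower-closed
    convention).  Areas of multiple peaks in one bin are summed; peaks
    outside the size range are dropped and their count logged.

    Returns a DataFrame indexed by (sample_id, replicate_id) with one
    column per occupied bin.
    """
    if bin_size_bp <= 0:
        raise ValueError("bin size must be positive")
    low, high = size_range
    if low >= high:
        raise ValueError("size range low must be below high")
    anchor = low + frame_offset_bp
    rows: dict[tuple[str, str], dict[str, float]] = {}
    n_dropped = 0
    for prof in profiles:
        key = (prof.sample_id, prof.replicate_id)
        row = rows.setdefault(key, {})
        for size, area in zip(prof.sizes_bp, prof.areas):
            if not (low <= size < high):
                n_dropped += 1
                continue
            k = int(np.floor((size - anchor) / bin_size_bp))
            label = bin_label(anchor + k * bin_size_bp, bin_size_bp)
            row[label] = row.get(label, 0.0) + area
    if n_dropped:
        logger.info("bin_peaks: dropped %d peaks outside %s", n_dropped, size_range)
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df = df.reindex(sorted(df.columns), axis=1)
    df.index = pd.MultiIndex.from_tuples(df.index, names=["sample_id", "replicate_id"])
    return df


def replicate_consensus(
    binned: pd.DataFrame,
    min_present: int = 1,
    expected_replicates: int | None = 3,
) -> pd.DataFrame:
    """Combine PCR replicates into one vector per sample.

    A bin counts as present in a sample if it has non-zero area in at
    least ``min_present`` replicates; its consensus intensity is the mean
    area over the replicates where it is present.
    """
    if min_present < 1:
        raise ValueError("min_present must be >= 1")
    out = {}
    for sample, group in binned.groupby(level="sample_id", sort=True):
        n_rep = len(group)
        if expected_replicates is not None and n_rep != expected_replicates:
            warnings.warn(
                f"sample {sample!r}: {n_rep} replicates "
                f"(expected {expected_replicates}); proceeding",
                stacklevel=2,
            )
        present_count = (group.values > 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_where_present = np.where(
                present_count > 0,
                group.values.sum(axis=0) / np.maximum(present_count, 1),
                0.0,
            )
        consensus = np.where(present_count >= min_present, mean_where_present, 0.0)
        out[sample] = pd.Series(consensus, index=group.columns)
    df = pd.DataFrame.from_dict(out, orient="index")
    df = df.loc[:, (df != 0).any(axis=0)]
    df.index.name = "sample_id"
    return df


def relative_intensities(table: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Divide each value by its profile (row) total so rows sum to 1."""
    if isinstance(table, pd.Series):
        total = table.sum()
        if total <= 0:
            raise ValueError("empty profile: total area is zero")
        return table / total
    totals = table.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(f"empty profiles (zero total area): {list(empty.index)}")
    return table.div(totals, axis=0)


def scan_frame_offset(
    profiles: list[PeakProfile],
    bin_size_bp: float = 2.0,
    size_range: tuple[float, float] = (100.0, 1000.0),
    step_bp: float = 0.1,
) -> float:
    """Pick the frame offset maximizing mean between-replicate similarity.

    Scans offsets in [0, bin_size) at ``step_bp`` resolution; similarity
    between two replicates of the same sample is the Jaccard index of
    their occupied bin sets.  Returns the best offset (ties → smallest).
    """
    best_offset, best_score = 0.0, -np.inf
    for offset in np.arange(0.0, bin_size_bp, step_bp):
        binned = bin_peaks(profiles, bin_size_bp, float(offset), size_range)
        sims = []
        for _, group in binned.groupby(level="sample_id"):
            presence = group.values > 0
            n = presence.shape[0]
            for i in range(n):
                for j in range(i + 1, n):
                    union = np.sum(presence[i] | presence[j])
                    if union:
                        sims.append(np.sum(presence[i] & presence[j]) / union)
        score = float(np.mean(sims)) if sims else 0.0
        if score > best_score + 1e-12:
            best_offset, best_score = float(offset), score
    logger.info("scan_frame_offset: chose offset %.1f bp (score %.4f)",
                best_offset, best_score)
    return best_offset


def peaks_from_frame(df: pd.DataFrame) -> list[PeakProfile]:
    """Build PeakProfiles from a long table with columns
    sample, replicate, size_bp, area."""
    profiles = []
    for (sample, rep), grp in df.groupby(["sample", "replicate"], sort=True):
        profiles.append(
            PeakProfile(str(sample), str(rep), grp["size_bp"].values, grp["area"].values)
        )
    return profiles
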