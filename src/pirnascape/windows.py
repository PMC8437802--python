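"""Genome tiling and per-window fractional-count / RPM / RPKM tables.

The genome is tiled into fixed non-overlapping windows (1 kb by default).
Each alignment of a read in the piRNA size range contributes 1/n_hits to the
window containing its 5' end, so a read's total contributed weight is
(alignments present in the input) / n_hits <= 1.  Counts are normalised to
reads per million 19-32-nt reads (RPM) and then to gap-corrected window
length in kb (RPKM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import AlignedRead, GenomeModel, LibraryStats, five_prime_positions, reads_to_frame

log = logging.getLogger(__name__)

UNITS = ("fractional_count", "RPM", "RPKM")

#: columns of the window coordinate frame
WINDOW_COLUMNS = ["chrom", "start", "end", "effective_length"]


@dataclass
class WindowTable:
    """Per-window values across samples in one stated unit.

    windows: frame with WINDOW_COLUMNS; values: frame aligned on the same
    index with one column per sample; unplaced: per-sample weight that fell
    on chromosomes absent from the tiling.
    """

    windows: pd.DataFrame
    values: pd.DataFrame
    unit: str
    unplaced: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if len(self.windows) != len(self.values):
            raise ValueError("windows/values length mismatch")
        if not self.windows.index.equals(self.values.index):
            raise ValueError("windows/values index mismatch")
        if len(self.values) and (self.values.to_numpy() < 0).any():
            raise ValueError("negative values in window table")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def copy_with(self, values: pd.DataFrame, unit: str,
                  windows: pd.DataFrame | None = None) -> "WindowTable":
        return WindowTable(
            windows=self.windows if windows is None else windows,
            values=values, unit=unit, unplaced=dict(self.unplaced),
        )


def tile_genome(genome: GenomeModel, window_size: int = 1000) -> pd.DataFrame:
    """Consecutive non-overlapping windows covering each chromosome.

    The last window of a chromosome may be shorter.  effective_length is the
    window length minus its overlap with assembly gaps.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    chroms, starts, ends = [], [], []
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        edge = np.arange(0, length + window_size, window_size)
        edge[-1] = min(edge[-1], length)
        if edge[-1] == edge[-2]:
            edge = edge[:-1]
        starts.append(edge[:-1])
        ends.append(edge[1:])
        chroms.extend([chrom] * (len(edge) - 1))
    start = np.concatenate(starts) if starts else np.array([], dtype=int)
    end = np.concatenate(ends) if ends else np.array([], dtype=int)
    eff = np.array(
        [e - s - genome.gap_overlap(c, s, e) for c, s, e in zip(chroms, start, end)],
        dtype=int,
    )
    return pd.DataFrame(
        {"chrom": chroms, "start": start, "end": end, "effective_length": eff}
    )


def _window_lookup(windows: pd.DataFrame):
    """Per-chromosome (row offset, starts array, ends array) for 5'-end binning."""
    lookup = {}
    for chrom, grp in windows.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        if (np.diff(starts) <= 0).any():
            raise ValueError(f"windows on {chrom!r} are not sorted")
        lookup[chrom] = (grp.index.to_numpy(), starts, grp["end"].to_numpy())
    return lookup


def fractional_count(reads: Iterable[AlignedRead] | pd.DataFrame,
                     windows: pd.DataFrame,
                     size_min: int = 24, size_max: int = 31,
                     sample_id: str = "sample") -> WindowTable:
    """Fractional counts of size-selected alignments per window.

    Each alignment of a read with size_min <= read_length <= size_max adds
    1/n_hits to the window containing its 5' end.  Alignments on chromosomes
    absent from the tiling go to a reported unplaced bucket.
    """
    if size_min > size_max:
        raise ValueError("size_min > size_max")
    frame = reads_to_frame(reads)
    counts = np.zeros(len(windows), dtype=float)
    unplaced = 0.0
    in_range = frame[(frame["read_length"] >= size_min)
                     & (frame["read_length"] <= size_max)]
    if len(in_range):
        lookup = _window_lookup(windows)
        fivep = five_prime_positions(in_range)
        weight = 1.0 / in_range["n_hits"].to_numpy(dtype=float)
        chrom_arr = in_range["chrom"].to_numpy()
        for chrom in pd.unique(chrom_arr):
            mask = chrom_arr == chrom
            if chrom not in lookup:
                unplaced += float(weight[mask].sum())
                log.warning("%s: %d alignments on chromosome %r outside tiling",
                            sample_id, int(mask.sum()), chrom)
                continue
            rows, starts, ends = lookup[chrom]
            pos = fivep[mask]
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
            if (~ok).any():
                unplaced += float(weight[mask][~ok].sum())
            np.add.at(counts, rows[idx[ok]], weight[mask][ok])
    values = pd.DataFrame({sample_id: counts}, index=windows.index)
    return WindowTable(windows=windows, values=values, unit="fractional_count",
                       unplaced={sample_id: unplaced})


def count_samples(reads_by_sample: Mapping[str, Iterable[AlignedRead] | pd.DataFrame],
                  windows: pd.DataFrame,
                  size_min: int = 24, size_max: int = 31) -> WindowTable:
    """fractional_count over several samples, assembled into one table."""
    columns, unplaced = {}, {}
    for sample_id, reads in reads_by_sample.items():
        table = fractional_count(reads, windows, size_min, size_max, sample_id)
        columns[sample_id] = table.values[sample_id]
        unplaced[sample_id] = table.unplaced[sample_id]
    values = pd.DataFrame(columns, index=windows.index)
    return WindowTable(windows=windows, values=values,
                       unit="fractional_count", unplaced=unplaced)


def to_rpm(table: WindowTable,
           libs: Mapping[str, LibraryStats] | LibraryStats) -> WindowTable:
    """Normalise fractional counts to reads per million 19-32-nt reads."""
    if table.unit != "fractional_count":
        raise ValueError(f"to_rpm expects fractional counts, got {table.unit}")
    if isinstance(libs, LibraryStats):
        libs = {s: libs for s in table.samples}
    values = table.values.copy()
    for sample in table.samples:
        total = libs[sample].total_19_32
        if total <= 0:
            raise ValueError(f"sample {sample!r}: zero 19-32-nt library total")
        values[sample] = values[sample] * 1e6 / total
    return table.copy_with(values, "RPM")


def to_rpkm(table: WindowTable) -> WindowTable:
    """Normalise RPM by gap-corrected window length in kb; windows with zero
    effective length are dropped (count logged)."""
    if table.unit != "RPM":
        raise ValueError(f"to_rpkm expects RPM, got {table.unit}")
    eff = table.windows["effective_length"].to_numpy(dtype=float)
    keep = eff > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("to_rpkm: dropped %d windows with zero effective length", n_dropped)
    windows = table.windows.loc[keep]
    values = table.values.loc[keep].div(eff[keep] / 1000.0, axis=0)
    return table.copy_with(values, "RPKM", windows=windows)


def filter_min_rpkm(table: WindowTable, threshold: float = 1.0,
                    rule: str = "any_sample",
                    samples: list[str] | None = None) -> WindowTable:
    """Remove windows with RPKM below *threshold* (removal is strict '< 1').

    rule 'any_sample' retains a window if any evaluated sample reaches the
    threshold; 'all_samples' requires all of them.  *samples* restricts which
    columns are evaluated (e.g. wild-type only) while all columns are kept in
    the output.
    """
    if table.unit != "RPKM":
        raise ValueError(f"filter_min_rpkm expects RPKM, got {table.unit}")
    cols = table.samples if samples is None else list(samples)
    sub = table.values[cols]
    if rule == "any_sample":
        keep = (sub >= threshold).any(axis=1)
    elif rule == "all_samples":
        keep = (sub >= threshold).all(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if len(sub) == 0:
        keep = pd.Series(False, index=sub.index)
    return table.copy_with(table.values.loc[keep], "RPKM",
                           windows=table.windows.loc[keep])
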