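"""Retrotransposon-centric quantification.

Multimapping small RNAs saturate TE annotations, so expression of a TE group
is summarised by counting each *read* once per group that any of its
alignments overlaps (>= 1 bp), never once per alignment.  Antisense profiles
against full-length intact (FLI) insertions use perfectly matching reads
only, mirroring how piRNA coverage of potentially mobile elements is
assessed.  Divergence summaries condense RepeatMasker milliDiv values into
boxplot statistics (median, quartiles, 1.5xIQR whiskers) per subfamily.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import AlignedRead, LibraryStats, reads_to_frame


def _te_trees(te: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(te.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, i)
    return trees


def read_te_overlaps(reads: Iterable[AlignedRead] | pd.DataFrame,
                     te: pd.DataFrame,
                     max_vectorised_te: int = 5000) -> pd.DataFrame:
    """(read_id, alignment row, TE row) pairs for every >= 1 bp overlap.

    For annotation sets of desk scale this sweeps one vectorised mask per
    insertion; very large sets fall back to an interval tree queried per
    alignment.
    """
    frame = reads_to_frame(reads).reset_index(drop=True)
    read_rows, te_rows = [], []
    chrom_arr = frame["chrom"].to_numpy()
    starts = frame["start"].to_numpy()
    ends = frame["end"].to_numpy()
    if len(te) <= max_vectorised_te:
        by_chrom = {chrom: np.flatnonzero(chrom_arr == chrom)
                    for chrom in pd.unique(te["chrom"])}
        for j, row in enumerate(te.itertuples(index=False)):
            idx = by_chrom[row.chrom]
            hit = idx[(starts[idx] < row.end) & (ends[idx] > row.start)]
            read_rows.append(hit)
            te_rows.append(np.full(len(hit), j))
        read_rows = np.concatenate(read_rows) if read_rows else np.array([], int)
        te_rows = np.concatenate(te_rows) if te_rows else np.array([], int)
    else:
        trees = _te_trees(te)
        for i in range(len(frame)):
            tree = trees.get(chrom_arr[i])
            if tree is None:
                continue
            for hit in tree.overlap(starts[i], ends[i]):
                read_rows.append(i)
                te_rows.append(hit.data)
    out = pd.DataFrame({"read_row": np.asarray(read_rows, dtype=int),
                        "te_row": np.asarray(te_rows, dtype=int)})
    out["read_id"] = (frame["read_id"].to_numpy()[out["read_row"]]
                      if len(out) else np.array([], dtype=object))
    return out


def assign_reads_once(reads: Iterable[AlignedRead] | pd.DataFrame,
                      te: pd.DataFrame,
                      group_by: str = "group",
                      mode: str = "per_group") -> pd.Series:
    """Distinct-read counts per TE group.

    mode 'per_group': a read adds 1 to every group it overlaps through any
    alignment, and never more than 1 per group however many insertions of
    that group it hits.  mode 'unique_global': each read is assigned to the
    single group with most overlapped alignments (ties broken
    lexicographically) and counts only there.
    """
    frame = reads_to_frame(reads).reset_index(drop=True)
    te = te.reset_index(drop=True)
    pairs = read_te_overlaps(frame, te)
    if pairs.empty:
        return pd.Series(dtype=int, name="n_reads")
    pairs["group"] = te[group_by].to_numpy()[pairs["te_row"]]
    if mode == "per_group":
        membership = pairs[["read_id", "group"]].drop_duplicates()
    elif mode == "unique_global":
        per = (pairs.groupby(["read_id", "group"])["read_row"]
               .nunique().rename("n_aln").reset_index())
        per = per.sort_values(["read_id", "n_aln", "group"],
                              ascending=[True, False, True], kind="stable")
        membership = per.drop_duplicates(subset="read_id")[["read_id", "group"]]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    counts = membership.groupby("group")["read_id"].nunique()
    counts.name = "n_reads"
    return counts.sort_index()


def te_group_rpm(counts: pd.Series, lib: LibraryStats) -> pd.Series:
    """Distinct-read counts -> RPM of 19-32-nt reads."""
    if lib.total_19_32 <= 0:
        raise ValueError(f"sample {lib.sample_id!r}: zero library total")
    rpm = counts * 1e6 / lib.total_19_32
    rpm.name = lib.sample_id
    return rpm


def mean_group_rpm(per_sample_rpm: Mapping[str, pd.Series]) -> pd.Series:
    """Replicate-averaged group RPM (missing groups count as zero)."""
    frame = pd.DataFrame(per_sample_rpm).fillna(0.0)
    return frame.mean(axis=1)


def rank_upregulated(expr_wt: pd.Series, expr_ko: pd.Series,
                     top_n: int | None = None,
                     pseudocount: float = 0.1) -> pd.DataFrame:
    """TE groups ranked by KO/WT RPM fold change (descending).

    Ties break by KO RPM (descending) then group name; groups absent from one
    genotype count as zero there and are flagged when WT is zero.
    """
    groups = sorted(set(expr_wt.index) | set(expr_ko.index))
    wt = expr_wt.reindex(groups).fillna(0.0)
    ko = expr_ko.reindex(groups).fillna(0.0)
    out = pd.DataFrame({
        "group": groups,
        "wt_rpm": wt.to_numpy(),
        "ko_rpm": ko.to_numpy(),
    })
    out["fold_change"] = (out["ko_rpm"] + pseudocount) / (out["wt_rpm"] + pseudocount)
    out["wt_zero"] = out["wt_rpm"] == 0.0
    out = out.sort_values(["fold_change", "ko_rpm", "group"],
                          ascending=[False, False, True], kind="stable")
    out = out.reset_index(drop=True)
    return out.head(top_n) if top_n is not None else out


def antisense_length_profile(reads: Iterable[AlignedRead] | pd.DataFrame,
                             te_subset: pd.DataFrame,
                             lib: LibraryStats,
                             size_range: tuple[int, int] = (24, 32),
                             perfect_only: bool = True) -> pd.Series:
    """RPM of distinct antisense reads per length against a TE subset.

    A read qualifies when some alignment overlaps an insertion on the
    opposite strand, its length is in *size_range*, and (when perfect_only)
    it maps without mismatches.
    """
    if te_subset.empty:
        raise ValueError("empty TE subset")
    frame = reads_to_frame(reads).reset_index(drop=True)
    lo, hi = size_range
    keep = (frame["read_length"] >= lo) & (frame["read_length"] <= hi)
    if perfect_only:
        keep &= frame["mismatches"] == 0
    frame = frame[keep].reset_index(drop=True)
    pairs = read_te_overlaps(frame, te_subset.reset_index(drop=True))
    lengths = pd.Index(range(lo, hi + 1), name="length")
    if pairs.empty:
        return pd.Series(0.0, index=lengths, name=lib.sample_id)
    read_strand = frame["strand"].to_numpy()[pairs["read_row"]]
    te_strand = te_subset["strand"].to_numpy()[pairs["te_row"]]
    anti = pairs[read_strand != te_strand]
    hit = frame.loc[anti["read_row"].unique()]
    counts = (hit.drop_duplicates(subset="read_id")["read_length"]
              .value_counts().to_dict())
    values = [counts.get(length, 0) * 1e6 / lib.total_19_32 for length in lengths]
    return pd.Series(values, index=lengths, name=lib.sample_id)


def divergence_summary(te: pd.DataFrame, group_by: str = "subfamily") -> pd.DataFrame:
    """Boxplot statistics of percent divergence per subfamily (or group).

    Quartiles use linear interpolation between order statistics; whiskers sit
    at the most extreme data points within 1.5xIQR of the box bounds.
    milliDiv is reported as percent (milli_div / 10).
    """
    rows = []
    for name, grp in te.groupby(group_by, sort=True):
        values = grp["milli_div"].to_numpy(dtype=float) / 10.0
        if len(values) == 0:
            continue
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        in_lo = values[values >= lo_fence]
        in_hi = values[values <= hi_fence]
        rows.append({
            group_by: name,
            "n_insertions": len(values),
            "q1": q1, "median": med, "q3": q3,
            "whisker_low": float(in_lo.min()) if len(in_lo) else q1,
            "whisker_high": float(in_hi.max()) if len(in_hi) else q3,
        })
    return pd.DataFrame(rows)
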