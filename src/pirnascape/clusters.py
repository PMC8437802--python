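"""KO/WT fold-change classification of windows into piRNA clusters.

Testes logic: per 1-kb window, the log2 fold change of knockout over
wild-type RPKM (replicates averaged, small pseudocount) is computed at each
time point.  A window is *pre-pachytene* when the fold change is below -2 at
both 9 and 13 dpp; *pachytene* when it is below -2 at 21 dpp while staying
above -2 at 13 dpp (pachytene piRNAs only arise once spermatogenesis reaches
pachytene, so their windows are not yet depleted at 13 dpp).  All
inequalities are strict.  Labelled windows merge into clusters when
immediately adjacent, clusters of the same stage merge into superclusters
when at most 2 kb apart (inclusive), final RPKMs are recomputed over the
merged interval, and clusters are retained when their wild-type piRNA
density exceeds 10 RPM/kb (pre-pachytene; mean of 9 and 13 dpp) or
100 RPM/kb (pachytene; 21 dpp).

The oocyte variant seeds windows from PIWI-IP libraries instead of a
knockout contrast and applies 10-RPM retention filters, excluding the
21-23-nt miRNA/siRNA-rich size range from the wild-type quantity.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import GenomeModel, LibraryStats, five_prime_positions, reads_to_frame
from .windows import WindowTable, filter_min_rpkm, to_rpkm

log = logging.getLogger(__name__)

PRE_PACHYTENE = "pre_pachytene"
PACHYTENE = "pachytene"
OOCYTE = "oocyte"

#: wild-type time points whose piRNA signal defines each stage's density
DEFINING_TIMEPOINTS = {
    PRE_PACHYTENE: ("9dpp", "13dpp"),
    PACHYTENE: ("21dpp",),
}

CLUSTER_COLUMNS = ["chrom", "start", "end", "stage", "n_windows"]


# ---------------------------------------------------------------------------
# design handling
# ---------------------------------------------------------------------------

def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    for col in ("sample", "genotype", "timepoint"):
        if col not in design.columns:
            raise ValueError(f"design table missing column {col!r}")
    if design["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in design table")
    return design


def samples_for(design: pd.DataFrame, genotype: str,
                timepoint: str | None = None) -> list[str]:
    mask = design["genotype"] == genotype
    if timepoint is not None:
        mask &= design["timepoint"] == timepoint
    return list(design.loc[mask, "sample"])


def genotype_timepoint_means(table: WindowTable,
                             design: pd.DataFrame) -> dict[tuple[str, str], pd.Series]:
    """Replicate-averaged per-window values for each genotype x timepoint."""
    means = {}
    for (genotype, timepoint), grp in design.groupby(["genotype", "timepoint"]):
        cols = [s for s in grp["sample"] if s in table.values.columns]
        if cols:
            means[(genotype, timepoint)] = table.values[cols].mean(axis=1)
    return means


# ---------------------------------------------------------------------------
# classification primitives
# ---------------------------------------------------------------------------

def log2_fold_change(ko_rpkm, wt_rpkm, pseudocount: float = 0.01):
    """log2((ko + p) / (wt + p)); antisymmetric: lfc(a, b) = -lfc(b, a).

    The pseudocount keeps knockout-zero windows finite while barely moving
    fold changes of expressed windows.
    """
    ko = np.asarray(ko_rpkm, dtype=float)
    wt = np.asarray(wt_rpkm, dtype=float)
    if (ko < 0).any() or (wt < 0).any():
        raise ValueError("RPKM inputs must be non-negative")
    out = np.log2((ko + pseudocount) / (wt + pseudocount))
    return float(out) if out.ndim == 0 else out


def classify_window(lfc_9dpp: float, lfc_13dpp: float, lfc_21dpp: float,
                    threshold: float = -2.0) -> str | None:
    """Stage label for one window from its per-time-point fold changes.

    Strict inequalities throughout: a fold change exactly at the threshold
    satisfies neither "lower than" nor "higher than".
    """
    if lfc_9dpp < threshold and lfc_13dpp < threshold:
        return PRE_PACHYTENE
    if lfc_21dpp < threshold and lfc_13dpp > threshold:
        return PACHYTENE
    return None


def classify_windows(fold_changes: pd.DataFrame,
                     threshold: float = -2.0) -> pd.Series:
    """Vectorised classify_window over a frame with columns
    lfc_9dpp / lfc_13dpp / lfc_21dpp."""
    l9 = fold_changes["lfc_9dpp"].to_numpy()
    l13 = fold_changes["lfc_13dpp"].to_numpy()
    l21 = fold_changes["lfc_21dpp"].to_numpy()
    stage = np.select(
        [(l9 < threshold) & (l13 < threshold),
         (l21 < threshold) & (l13 > threshold)],
        [PRE_PACHYTENE, PACHYTENE],
        default=None,
    )
    return pd.Series(stage, index=fold_changes.index, dtype=object)


def stage_fold_changes(rpkm: WindowTable, design: pd.DataFrame,
                       pseudocount: float = 0.01) -> pd.DataFrame:
    """Per-window log2(KO/WT RPKM) at each time point, replicates averaged."""
    validate_design(design)
    means = genotype_timepoint_means(rpkm, design)
    out = {}
    for tp in ("9dpp", "13dpp", "21dpp"):
        if ("KO", tp) not in means or ("WT", tp) not in means:
            raise ValueError(f"design lacks a KO/WT pair at time point {tp}")
        out[f"lfc_{tp}"] = log2_fold_change(
            means[("KO", tp)].to_numpy(), means[("WT", tp)].to_numpy(), pseudocount
        )
    return pd.DataFrame(out, index=rpkm.values.index)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_adjacent(labeled_windows: pd.DataFrame) -> pd.DataFrame:
    """Merge maximal runs of immediately adjacent same-stage windows.

    Input: frame with chrom/start/end/stage, sorted by (chrom, start), stage
    non-null.  Windows separated by a filtered-out window do not merge here
    (only the supercluster step can bridge them).
    """
    frame = labeled_windows
    if frame.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    by_pos = frame.sort_values(["chrom", "start"], kind="stable")
    if not (by_pos[["chrom", "start"]].to_numpy()
            == frame[["chrom", "start"]].to_numpy()).all():
        raise ValueError("labeled windows must be sorted by (chrom, start)")
    rows = []
    cur = None
    for row in frame.itertuples(index=False):
        if (cur is not None and row.chrom == cur["chrom"]
                and row.start == cur["end"] and row.stage == cur["stage"]):
            cur["end"] = row.end
            cur["n_windows"] += 1
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "stage": row.stage, "n_windows": 1}
    if cur is not None:
        rows.append(cur)
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def merge_superclusters(clusters: pd.DataFrame, max_gap: int = 2000) -> pd.DataFrame:
    """Transitively merge same-stage clusters at most *max_gap* bp apart
    (inclusive).  Sorts internally; idempotent."""
    if clusters.empty:
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    rows = []
    ordered = clusters.sort_values(["chrom", "stage", "start"], kind="stable")
    for (chrom, stage), grp in ordered.groupby(["chrom", "stage"], sort=False):
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.start - cur["end"] <= max_gap:
                cur["end"] = max(cur["end"], row.end)
                cur["n_windows"] += row.n_windows
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": row.start, "end": row.end,
                       "stage": stage, "n_windows": row.n_windows}
        rows.append(cur)
    out = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# finalisation
# ---------------------------------------------------------------------------

def _interval_fractional_counts(clusters: pd.DataFrame, reads: pd.DataFrame,
                                size_min: int, size_max: int) -> np.ndarray:
    """Fractional count of size-selected alignments whose 5' end lies in each
    cluster interval."""
    sel = reads[(reads["read_length"] >= size_min)
                & (reads["read_length"] <= size_max)]
    counts = np.zeros(len(clusters), dtype=float)
    if sel.empty:
        return counts
    fivep = five_prime_positions(sel)
    weight = 1.0 / sel["n_hits"].to_numpy(dtype=float)
    chrom_arr = sel["chrom"].to_numpy()
    for i, row in enumerate(clusters.itertuples(index=False)):
        mask = (chrom_arr == row.chrom) & (fivep >= row.start) & (fivep < row.end)
        counts[i] = weight[mask].sum()
    return counts


def finalize_clusters(superclusters: pd.DataFrame,
                      reads_by_sample: Mapping[str, pd.DataFrame],
                      libs: Mapping[str, LibraryStats],
                      genome: GenomeModel,
                      design: pd.DataFrame | None = None,
                      size_min: int = 24, size_max: int = 31,
                      include: Iterable[str] | None = None,
                      exclude: Iterable[str] | None = None) -> pd.DataFrame:
    """Recompute final per-sample RPM/RPKM over each merged interval and the
    wild-type piRNA density per stage.

    Manual curation is reproduced declaratively: *include* / *exclude* are
    lists of "chrom:start-end" ids; excluded (or non-included) clusters are
    dropped with a log message.  Intervals that are entirely assembly gap are
    dropped with a warning.
    """
    clusters = superclusters.reset_index(drop=True).copy()
    clusters["cluster_id"] = [
        f"{c}:{s}-{e}" for c, s, e in zip(clusters["chrom"], clusters["start"],
                                          clusters["end"])
    ]
    if include is not None:
        keep = clusters["cluster_id"].isin(set(include))
        log.info("curation include list: dropping %d clusters", int((~keep).sum()))
        clusters = clusters[keep].reset_index(drop=True)
    if exclude is not None:
        drop = clusters["cluster_id"].isin(set(exclude))
        if drop.any():
            log.info("curation exclude list: dropping %d clusters", int(drop.sum()))
        clusters = clusters[~drop].reset_index(drop=True)

    eff_len = np.array([
        row.end - row.start - genome.gap_overlap(row.chrom, row.start, row.end)
        for row in clusters.itertuples(index=False)
    ], dtype=float)
    fully_gapped = eff_len <= 0
    if fully_gapped.any():
        log.warning("dropping %d fully-gapped clusters", int(fully_gapped.sum()))
        clusters = clusters[~fully_gapped].reset_index(drop=True)
        eff_len = eff_len[~fully_gapped]
    clusters["effective_length"] = eff_len.astype(int)

    frames = {s: reads_to_frame(r) for s, r in reads_by_sample.items()}
    for sample, frame in frames.items():
        counts = _interval_fractional_counts(clusters, frame, size_min, size_max)
        rpm = counts * 1e6 / libs[sample].total_19_32
        clusters[f"rpm_{sample}"] = rpm
        clusters[f"rpkm_{sample}"] = rpm / (eff_len / 1000.0)

    if design is not None:
        validate_design(design)
        density = np.zeros(len(clusters))
        for stage, tps in DEFINING_TIMEPOINTS.items():
            mask = (clusters["stage"] == stage).to_numpy()
            if not mask.any():
                continue
            per_tp = []
            for tp in tps:
                cols = [f"rpm_{s}" for s in samples_for(design, "WT", tp)]
                per_tp.append(clusters.loc[mask, cols].mean(axis=1))
            density[mask] = (pd.concat(per_tp, axis=1).mean(axis=1)
                             / (eff_len[mask] / 1000.0))
        clusters["density"] = density
    return clusters


def filter_density(clusters: pd.DataFrame,
                   prepachytene_min: float = 10.0,
                   pachytene_min: float = 100.0,
                   mode: str = "per_kb") -> pd.DataFrame:
    """Retain clusters whose wild-type piRNA density strictly exceeds the
    stage-specific threshold.

    mode 'per_kb' compares density in RPM/kb; 'per_cluster' compares the
    interval's total RPM (density x gap-corrected kb) against the threshold.
    """
    if clusters.empty:
        return clusters
    value = clusters["density"].to_numpy(dtype=float)
    if mode == "per_cluster":
        value = value * clusters["effective_length"].to_numpy() / 1000.0
    elif mode != "per_kb":
        raise ValueError(f"unknown density mode {mode!r}")
    threshold = np.where(clusters["stage"] == PACHYTENE,
                         pachytene_min, prepachytene_min)
    return clusters[value > threshold].reset_index(drop=True)


def cluster_window_sums(clusters: pd.DataFrame, table: WindowTable,
                        columns: list[str]) -> pd.DataFrame:
    """Sum window-table values (RPM is additive) over each cluster interval."""
    out = np.zeros((len(clusters), len(columns)))
    win = table.windows
    vals = table.values[columns].to_numpy()
    chrom_arr = win["chrom"].to_numpy()
    starts = win["start"].to_numpy()
    ends = win["end"].to_numpy()
    for i, row in enumerate(clusters.itertuples(index=False)):
        mask = (chrom_arr == row.chrom) & (starts >= row.start) & (ends <= row.end)
        out[i] = vals[mask].sum(axis=0)
    return pd.DataFrame(out, columns=columns, index=clusters.index)


def density_from_window_rpm(clusters: pd.DataFrame, rpm_table: WindowTable,
                            design: pd.DataFrame) -> pd.DataFrame:
    """Cluster density (RPM/kb) from a window RPM table alone.

    Sums wild-type window RPM over each interval (replicates averaged per
    defining time point, then averaged across time points) and divides by
    plain interval length in kb.  Use finalize_clusters for the
    gap-corrected, read-recounted version.
    """
    validate_design(design)
    out = clusters.reset_index(drop=True).copy()
    density = np.zeros(len(out))
    kb = (out["end"] - out["start"]).to_numpy() / 1000.0
    for stage, tps in DEFINING_TIMEPOINTS.items():
        mask = (out["stage"] == stage).to_numpy()
        if not mask.any():
            continue
        per_tp = []
        for tp in tps:
            cols = [s for s in samples_for(design, "WT", tp)
                    if s in rpm_table.values.columns]
            sums = cluster_window_sums(out[mask], rpm_table, cols)
            per_tp.append(sums.mean(axis=1))
        density[mask] = pd.concat(per_tp, axis=1).mean(axis=1) / kb[mask]
    out["density"] = density
    out["effective_length"] = out["end"] - out["start"]
    return out


# ---------------------------------------------------------------------------
# oocyte variant
# ---------------------------------------------------------------------------

def call_oocyte_clusters(piwil1_windows: WindowTable,
                         piwil3_windows: WindowTable,
                         wt_oocyte_reads: Mapping[str, pd.DataFrame],
                         libs: Mapping[str, LibraryStats],
                         max_gap: int = 2000,
                         min_ip_rpm: float = 10.0,
                         min_wt_rpm: float = 10.0,
                         min_rpkm: float = 1.0) -> pd.DataFrame:
    """Oocyte piRNA clusters seeded from PIWIL1/PIWIL3 IP window RPMs.

    Windows passing the shared RPKM >= 1 step (in either IP library) merge
    into superclusters; retained clusters need >= 10 RPM in PIWIL1 or PIWIL3
    IP (inclusive) and a >= 10 RPM mean over wild-type oocyte samples of
    combined 18-20-nt plus 24-32-nt reads, the 21-23-nt miRNA/siRNA-rich
    population excluded.
    """
    if not piwil1_windows.windows[["chrom", "start", "end"]].equals(
            piwil3_windows.windows[["chrom", "start", "end"]]):
        raise ValueError("PIWIL1/PIWIL3 window tilings differ")
    if piwil1_windows.unit != "RPM" or piwil3_windows.unit != "RPM":
        raise ValueError("IP window tables must be in RPM")

    combined = WindowTable(
        windows=piwil1_windows.windows,
        values=pd.DataFrame({
            "PIWIL1": piwil1_windows.values.iloc[:, 0],
            "PIWIL3": piwil3_windows.values.iloc[:, 0],
        }),
        unit="RPM",
    )
    rpkm = to_rpkm(combined)
    passing = filter_min_rpkm(rpkm, threshold=min_rpkm, rule="any_sample")
    labeled = passing.windows[["chrom", "start", "end"]].copy()
    labeled["stage"] = OOCYTE
    clusters = merge_superclusters(merge_adjacent(labeled), max_gap=max_gap)
    if clusters.empty:
        return clusters

    ip_rpm = cluster_window_sums(clusters, combined, ["PIWIL1", "PIWIL3"])
    clusters["piwil1_rpm"] = ip_rpm["PIWIL1"].to_numpy()
    clusters["piwil3_rpm"] = ip_rpm["PIWIL3"].to_numpy()

    wt_cols = []
    for sample, reads in wt_oocyte_reads.items():
        frame = reads_to_frame(reads)
        short = _interval_fractional_counts(clusters, frame, 18, 20)
        long = _interval_fractional_counts(clusters, frame, 24, 32)
        rpm = (short + long) * 1e6 / libs[sample].total_19_32
        clusters[f"wt_combined_rpm_{sample}"] = rpm
        wt_cols.append(f"wt_combined_rpm_{sample}")
    clusters["wt_combined_rpm"] = clusters[wt_cols].mean(axis=1)

    keep = (
        ((clusters["piwil1_rpm"] >= min_ip_rpm)
         | (clusters["piwil3_rpm"] >= min_ip_rpm))
        & (clusters["wt_combined_rpm"] >= min_wt_rpm)
    )
    return clusters[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class ClusterCaller(BaseEstimator):
    """sklearn-style estimator for the testes KO/WT cluster classification.

    fit() consumes a WindowTable of RPKM values plus a design table mapping
    sample -> (genotype, timepoint) and exposes the fitted per-window fold
    changes, labels and merged supercluster intervals.  Density filtering
    needs read-level recounting and lives in the pipeline helpers
    (finalize_clusters / filter_density), which operate on ``clusters_``.
    """

    def __init__(self, threshold: float = -2.0, pseudocount: float = 0.01,
                 max_gap: int = 2000, min_rpkm: float = 1.0,
                 rpkm_filter_rule: str = "any_sample",
                 rpkm_filter_genotype: str | None = "WT"):
        self.threshold = threshold
        self.pseudocount = pseudocount
        self.max_gap = max_gap
        self.min_rpkm = min_rpkm
        self.rpkm_filter_rule = rpkm_filter_rule
        self.rpkm_filter_genotype = rpkm_filter_genotype

    def fit(self, X: WindowTable, y=None, *, design: pd.DataFrame):
        if X.unit != "RPKM":
            raise ValueError("ClusterCaller.fit expects a WindowTable in RPKM")
        design = validate_design(design)
        if self.rpkm_filter_genotype is not None:
            eval_samples = samples_for(design, self.rpkm_filter_genotype)
        else:
            eval_samples = None
        filtered = filter_min_rpkm(X, threshold=self.min_rpkm,
                                   rule=self.rpkm_filter_rule,
                                   samples=eval_samples)
        fc = stage_fold_changes(filtered, design, pseudocount=self.pseudocount)
        labels = classify_windows(fc, threshold=self.threshold)
        self.fold_changes_ = fc
        self.window_labels_ = labels
        labeled = filtered.windows.loc[labels.notna(),
                                       ["chrom", "start", "end"]].copy()
        labeled["stage"] = labels[labels.notna()]
        self.clusters_ = merge_superclusters(merge_adjacent(labeled),
                                             max_gap=self.max_gap)
        self.n_windows_in_ = len(X.values)
        return self

    def fit_predict(self, X: WindowTable, y=None, *, design: pd.DataFrame):
        """Fit and return the merged supercluster frame."""
        return self.fit(X, design=design).clusters_
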