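"""Read-level piRNA statistics: length distributions, size classes, miRNA
scaling and the 1U/10A nucleotide-bias signature.

Length distributions are a property of reads, not alignments: a read is
counted once regardless of how many places it maps.  The 5'-uridine bias
marks primary piRNAs; an adenosine at position 10 marks ping-pong secondary
piRNAs, so both are computed from a position frequency matrix over
logo-eligible reads (primary alignment, no 5' clipping, 25-31 nt, 5' end
inside an annotated cluster).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AlignedRead, LibraryStats, five_prime_positions, reads_to_frame

SIZE_CLASSES = {"18-20": (18, 20), "21-23": (21, 23),
                "24-27": (24, 27), "28-31": (28, 31)}

BASES = ("A", "C", "G", "U")


def distinct_reads(reads: Iterable[AlignedRead] | pd.DataFrame) -> pd.DataFrame:
    """One row per read (first alignment wins; read-level fields agree)."""
    frame = reads_to_frame(reads)
    return frame.drop_duplicates(subset="read_id", keep="first")


def compute_library_stats(reads: Iterable[AlignedRead] | pd.DataFrame,
                          sample_id: str = "sample",
                          mirna_annotation: pd.DataFrame | None = None,
                          ) -> LibraryStats:
    """Distinct-read totals for normalisation.

    mirna_count is the number of distinct reads with any alignment
    overlapping the miRNA annotation (>= 1 bp) when one is provided, else the
    21-23-nt size class as a proxy for the miRNA/siRNA-rich population.
    """
    frame = reads_to_frame(reads)
    dedup = frame.drop_duplicates(subset="read_id", keep="first")
    lengths = dedup["read_length"]
    total_19_32 = int(((lengths >= 19) & (lengths <= 32)).sum())
    total_18_32 = int(((lengths >= 18) & (lengths <= 32)).sum())
    if mirna_annotation is not None and len(mirna_annotation):
        hit_ids: set[str] = set()
        chrom_arr = frame["chrom"].to_numpy()
        starts = frame["start"].to_numpy()
        ends = frame["end"].to_numpy()
        ids = frame["read_id"].to_numpy()
        for row in mirna_annotation.itertuples(index=False):
            mask = (chrom_arr == row.chrom) & (starts < row.end) & (ends > row.start)
            hit_ids.update(ids[mask])
        mirna_count = len(hit_ids)
    else:
        mirna_count = int(((lengths >= 21) & (lengths <= 23)).sum())
    return LibraryStats(sample_id=sample_id, total_19_32=total_19_32,
                        total_18_32=total_18_32, mirna_count=mirna_count)


def length_profile(reads: Iterable[AlignedRead] | pd.DataFrame,
                   lib: LibraryStats,
                   length_range: tuple[int, int] = (18, 32),
                   denominator: str = "total_19_32",
                   scaling_factor: float = 1.0) -> pd.Series:
    """RPM of distinct reads per length over *length_range* (inclusive)."""
    total = getattr(lib, denominator)
    if total <= 0:
        raise ValueError(f"{denominator} is zero; cannot normalise")
    dedup = distinct_reads(reads)
    lo, hi = length_range
    counts = dedup["read_length"].value_counts().to_dict()
    lengths = range(lo, hi + 1)
    values = [counts.get(length, 0) * 1e6 / total * scaling_factor
              for length in lengths]
    profile = pd.Series(values, index=pd.Index(lengths, name="length"),
                        name=lib.sample_id)
    profile.attrs["scaling_factor"] = scaling_factor
    profile.attrs["denominator"] = denominator
    return profile


def size_class_summary(profile: pd.Series) -> pd.Series:
    """Sum a length profile into the 18-20 / 21-23 / 24-27 / 28-31 bins."""
    for bound in (18, 31):
        if bound not in profile.index:
            raise ValueError("profile must cover lengths 18..31")
    out = {}
    for name, (lo, hi) in SIZE_CLASSES.items():
        out[name] = float(profile.loc[lo:hi].sum())
    return pd.Series(out, name=profile.name)


def mirna_scaling_factor(ko_lib: LibraryStats,
                         wt_libs: Sequence[LibraryStats]) -> float:
    """Scale factor equalising knockout miRNA RPM with the wild-type mean.

    piRNA loss inflates every per-million value in the knockout library; the
    miRNA population is unaffected by the knockout, so its RPM anchors a
    cross-genotype rescaling: factor = mean(WT miRNA RPM) / KO miRNA RPM.
    """
    def mirna_rpm(lib: LibraryStats) -> float:
        if lib.mirna_count <= 0:
            raise ValueError(f"sample {lib.sample_id!r}: zero miRNA count")
        if lib.total_19_32 <= 0:
            raise ValueError(f"sample {lib.sample_id!r}: zero library total")
        return lib.mirna_count * 1e6 / lib.total_19_32

    wt_mean = float(np.mean([mirna_rpm(lib) for lib in wt_libs]))
    return wt_mean / mirna_rpm(ko_lib)


def select_logo_reads(reads: Iterable[AlignedRead] | pd.DataFrame,
                      clusters: pd.DataFrame,
                      length_range: tuple[int, int] = (25, 31)) -> list[str]:
    """Sequences of logo-eligible reads in read orientation (T -> U).

    Eligible: primary alignment, no 5' clipping, length within *length_range*,
    5' end inside a cluster interval.
    """
    frame = reads_to_frame(reads)
    lo, hi = length_range
    mask = (frame["is_primary"].to_numpy()
            & ~frame["clipped5"].to_numpy()
            & (frame["read_length"].to_numpy() >= lo)
            & (frame["read_length"].to_numpy() <= hi))
    in_cluster = np.zeros(len(frame), dtype=bool)
    fivep = five_prime_positions(frame)
    chrom_arr = frame["chrom"].to_numpy()
    for row in clusters.itertuples(index=False):
        in_cluster |= ((chrom_arr == row.chrom)
                       & (fivep >= row.start) & (fivep < row.end))
    kept = frame[mask & in_cluster]
    sequences = []
    for read_id, seq in zip(kept["read_id"], kept["sequence"]):
        if seq is None or seq != seq or seq in (".", ""):
            raise ValueError(f"logo-eligible read {read_id!r} lacks a sequence")
        sequences.append(str(seq).upper().replace("T", "U"))
    return sequences


def position_frequencies(sequences: Sequence[str]) -> pd.DataFrame:
    """Relative base frequencies per 5'-anchored position (1-based index).

    Variable lengths are allowed: position p is computed over the sequences
    of length >= p; N bases are excluded from the denominator.
    """
    if not sequences:
        raise ValueError("no sequences given")
    max_len = max(len(s) for s in sequences)
    counts = np.zeros((max_len, len(BASES)), dtype=float)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for seq in sequences:
        for pos, base in enumerate(seq):
            i = base_idx.get(base)
            if i is not None:
                counts[pos, i] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    pfm = pd.DataFrame(freqs, columns=list(BASES),
                       index=pd.RangeIndex(1, max_len + 1, name="position"))
    pfm.attrs["n_reads"] = len(sequences)
    return pfm


def bias_stats(pfm: pd.DataFrame) -> dict[str, float]:
    """1U/10A signature: U frequency at position 1, A frequency at position 10."""
    u1 = float(pfm.loc[1, "U"]) if 1 in pfm.index else 0.0
    a10 = float(pfm.loc[10, "A"]) if 10 in pfm.index else 0.0
    return {"u1_fraction": u1, "a10_fraction": a10}
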