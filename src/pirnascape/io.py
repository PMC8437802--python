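"""Readers and writers for every external format the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversions to and from
1-based conventions (RepeatMasker ``.out``) happen only at format boundaries.
A read's 5' end is the left alignment edge on "+" and the right edge on "-".

Alignments can come from SAM/BAM (via pysam, requires an NH hit-count tag) or
from a plain tab-separated dialect so that small test inputs never need a
binary dependency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a semantic invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Chromosome lengths plus assembly-gap (N-run) intervals.

    gaps maps chromosome name to a sorted, non-overlapping list of 0-based
    half-open intervals lying within the chromosome.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValidationError("duplicate chromosome names")
        for name in self.chrom_names:
            length = self.chrom_lengths.get(name, 0)
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length")
        for chrom, ivals in self.gaps.items():
            if chrom not in self.chrom_lengths:
                raise ValidationError(f"gaps refer to unknown chromosome {chrom!r}")
            prev_end = 0
            for start, end in ivals:
                if not (0 <= start < end <= self.chrom_lengths[chrom]):
                    raise ValidationError(
                        f"gap [{start},{end}) outside chromosome {chrom!r}"
                    )
                if start < prev_end:
                    raise ValidationError(f"gaps on {chrom!r} unsorted or overlapping")
                prev_end = end

    def gap_overlap(self, chrom: str, start: int, end: int) -> int:
        """Total bp of assembly gap inside [start, end) of *chrom*."""
        total = 0
        for gs, ge in self.gaps.get(chrom, ()):  # gaps are few; linear scan is fine
            total += max(0, min(end, ge) - max(start, gs))
        return total


@dataclass(slots=True)
class AlignedRead:
    """One genomic alignment of one sequenced small-RNA read."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    read_length: int
    n_hits: int
    mismatches: int = 0
    is_primary: bool = True
    clipped5: bool = False
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"read {self.read_id}: start >= end")
        if self.n_hits < 1:
            raise ValidationError(f"read {self.read_id}: n_hits < 1")
        if self.mismatches < 0:
            raise ValidationError(f"read {self.read_id}: negative mismatch count")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"read {self.read_id}: bad strand {self.strand!r}")
        if self.sequence is not None and len(self.sequence) != self.read_length:
            raise ValidationError(
                f"read {self.read_id}: sequence length != read_length"
            )

    @property
    def five_prime(self) -> int:
        """0-based genomic position of the read's 5'-most aligned base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class LibraryStats:
    """Per-library read totals used as normalisation denominators."""

    sample_id: str
    total_19_32: int
    total_18_32: int
    mirna_count: int = 0

    def __post_init__(self) -> None:
        if min(self.total_19_32, self.total_18_32, self.mirna_count) < 0:
            raise ValidationError("library totals must be non-negative")
        if self.total_19_32 > self.total_18_32:
            raise ValidationError("total_19_32 cannot exceed total_18_32")


# columns of the tabular alignment dialect, in file order
TABULAR_COLUMNS = [
    "read_id", "chrom", "start", "end", "strand", "read_length",
    "n_hits", "mismatches", "is_primary", "clipped5", "sequence",
]

# columns of the internal TE annotation frame
TE_COLUMNS = [
    "chrom", "start", "end", "strand", "subfamily", "group",
    "te_class", "milli_div", "is_fli",
]


def reads_to_frame(reads: Iterable[AlignedRead] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a stream of AlignedRead (or an already-tabular frame) to the
    dialect DataFrame used by the counting routines."""
    if isinstance(reads, pd.DataFrame):
        missing = [c for c in TABULAR_COLUMNS[:-1] if c not in reads.columns]
        if missing:
            raise ValidationError(f"alignment frame missing columns: {missing}")
        if "sequence" not in reads.columns:
            reads = reads.assign(sequence=None)
        return reads
    records = [
        (r.read_id, r.chrom, r.start, r.end, r.strand, r.read_length,
         r.n_hits, r.mismatches, r.is_primary, r.clipped5, r.sequence)
        for r in reads
    ]
    return pd.DataFrame(records, columns=TABULAR_COLUMNS)


def frame_to_reads(frame: pd.DataFrame) -> Iterator[AlignedRead]:
    for row in frame.itertuples(index=False):
        seq = row.sequence
        if seq is not None and (seq != seq or seq in (".", "")):  # NaN / placeholder
            seq = None
        yield AlignedRead(
            read_id=str(row.read_id), chrom=str(row.chrom), start=int(row.start),
            end=int(row.end), strand=str(row.strand),
            read_length=int(row.read_length), n_hits=int(row.n_hits),
            mismatches=int(row.mismatches), is_primary=bool(row.is_primary),
            clipped5=bool(row.clipped5), sequence=seq,
        )


def five_prime_positions(frame: pd.DataFrame) -> np.ndarray:
    """Vectorised 5'-end positions for a dialect frame (strand-aware)."""
    return np.where(frame["strand"].to_numpy() == "+",
                    frame["start"].to_numpy(),
                    frame["end"].to_numpy() - 1)


# ---------------------------------------------------------------------------
# chrom.sizes and gap BED
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> GenomeModel:
    """Parse a two-column ``chrom.sizes`` table into a GenomeModel (no gaps)."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            name, raw_len = fields
            try:
                length = int(raw_len)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {raw_len!r}")
            if name in lengths:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            names.append(name)
            lengths[name] = length
    if not names:
        log.warning("chrom sizes file %s is empty", path)
    return GenomeModel(chrom_names=names, chrom_lengths=lengths)


def read_gaps_bed(path: str | Path, genome: GenomeModel) -> GenomeModel:
    """Attach assembly-gap intervals (BED3) to a genome, merging overlaps and
    clipping out-of-bounds intervals with a warning."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, raw_start, raw_end = fields[0], fields[1], fields[2]
            try:
                start, end = int(raw_start), int(raw_end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if chrom not in genome.chrom_lengths:
                raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            clipped = (max(0, start), min(end, genome.chrom_lengths[chrom]))
            if clipped != (start, end):
                log.warning("%s:%d: gap clipped to chromosome bounds", path, lineno)
            if clipped[0] < clipped[1]:
                raw.setdefault(chrom, []).append(clipped)
    merged = {chrom: merge_intervals(ivals) for chrom, ivals in raw.items()}
    return GenomeModel(
        chrom_names=list(genome.chrom_names),
        chrom_lengths=dict(genome.chrom_lengths),
        gaps=merged,
    )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals: sorted, overlapping/adjacent runs merged."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_alignments(path: str | Path, dialect: str = "auto") -> Iterator[AlignedRead]:
    """Stream AlignedRead records from SAM/BAM or the tabular dialect.

    SAM/BAM records must carry an NH hit-count tag; clipped5 is derived from
    the CIGAR string strand-aware (a soft/hard clip adjacent to the read's 5'
    base), and sequences are returned in read orientation.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "sam_bam" if path.suffix.lower() in (".sam", ".bam", ".cram") else "tabular"
    if dialect == "sam_bam":
        yield from _read_sam(path)
    elif dialect == "tabular":
        yield from frame_to_reads(read_alignments_frame(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_sam(path: Path) -> Iterator[AlignedRead]:
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if not rec.has_tag("NH"):
                raise FormatError(f"record {rec.query_name!r} lacks an NH hit-count tag")
            strand = "-" if rec.is_reverse else "+"
            cig = rec.cigartuples or []
            # CIGAR is given in reference orientation: the 5' base of a
            # minus-strand read corresponds to the last CIGAR operation.
            if strand == "+":
                clipped5 = bool(cig) and cig[0][0] in (4, 5)
            else:
                clipped5 = bool(cig) and cig[-1][0] in (4, 5)
            seq = rec.query_sequence
            read_length = rec.infer_read_length() or (len(seq) if seq else 0)
            if seq is not None:
                if strand == "-":
                    seq = _revcomp(seq)
                if len(seq) != read_length:
                    seq = None  # hard-clipped record: stored bases are partial
            mismatches = int(rec.get_tag("NM")) if rec.has_tag("NM") else 0
            yield AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                start=int(rec.reference_start),
                end=int(rec.reference_end),
                strand=strand,
                read_length=int(read_length),
                n_hits=int(rec.get_tag("NH")),
                mismatches=mismatches,
                is_primary=not (rec.is_secondary or rec.is_supplementary),
                clipped5=clipped5,
                sequence=seq,
            )


def read_alignments_frame(path: str | Path) -> pd.DataFrame:
    """Fast path: read the tabular alignment dialect into a DataFrame."""
    frame = pd.read_csv(
        path, sep="\t",
        dtype={"read_id": str, "chrom": str, "strand": str, "sequence": str},
    )
    missing = [c for c in TABULAR_COLUMNS[:-1] if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "sequence" not in frame.columns:
        frame["sequence"] = None
    if (frame["start"] < 0).any():
        raise FormatError(f"{path}: negative coordinates")
    if (frame["start"] >= frame["end"]).any():
        raise FormatError(f"{path}: start >= end")
    if (frame["n_hits"] < 1).any():
        raise ValidationError(f"{path}: n_hits < 1")
    frame["is_primary"] = frame["is_primary"].astype(bool)
    frame["clipped5"] = frame["clipped5"].astype(bool)
    return frame


def write_alignments_tabular(reads: Iterable[AlignedRead] | pd.DataFrame,
                             path: str | Path) -> None:
    frame = reads_to_frame(reads).copy()
    frame["is_primary"] = frame["is_primary"].astype(int)
    frame["clipped5"] = frame["clipped5"].astype(int)
    frame["sequence"] = frame["sequence"].fillna(".")
    frame.to_csv(path, sep="\t", index=False, columns=TABULAR_COLUMNS)


# ---------------------------------------------------------------------------
# RepeatMasker .out and related annotation
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: str | Path,
                          group_map: pd.DataFrame | Mapping[str, str] | None = None,
                          ) -> pd.DataFrame:
    """Parse RepeatMasker ``.out`` into a TE annotation frame (TE_COLUMNS).

    1-based inclusive coordinates become 0-based half-open, strand "C" becomes
    "-", and the percent-divergence column becomes milli_div (x10, rounded).
    Subfamilies absent from group_map keep their own name as group.
    """
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("SW", "score", "There were no")):
            continue  # header lines
        fields = stripped.split()
        try:
            div = float(fields[1])
            chrom = fields[4]
            begin, end = int(fields[5]), int(fields[6])
            strand = fields[8]
            subfamily = fields[9]
            class_family = fields[10]
        except (IndexError, ValueError):
            raise FormatError(f"{path}:{lineno}: unparseable RepeatMasker row")
        te_class = class_family.split("/")[0]
        if te_class not in ("LTR", "LINE", "SINE"):
            te_class = "other"
        rows.append((
            chrom, begin - 1, end, "-" if strand == "C" else strand,
            subfamily, subfamily, te_class, int(round(div * 10)), False,
        ))
    te = pd.DataFrame(rows, columns=TE_COLUMNS)
    if group_map is not None:
        te = apply_group_map(te, group_map)
    if not te.empty and (te["start"] >= te["end"]).any():
        raise ValidationError(f"{path}: TE interval with start >= end")
    return te


def write_repeatmasker_out(te: pd.DataFrame, path: str | Path) -> None:
    """Write a TE frame as a minimal valid RepeatMasker ``.out`` file."""
    header = (
        "   SW   perc perc perc  query     position in query    matching"
        "  repeat          position in repeat\n"
        "score   div. del. ins.  sequence  begin end   (left)   repeat"
        "  class/family    begin end (left) ID\n"
        "\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for i, row in enumerate(te.itertuples(index=False), 1):
            strand = "C" if row.strand == "-" else "+"
            class_family = row.te_class if row.te_class != "other" else "Unknown"
            fh.write(
                f"  500 {row.milli_div / 10:5.1f}  0.0  0.0  {row.chrom} "
                f"{row.start + 1} {row.end} (0) {strand} {row.subfamily} "
                f"{class_family} 1 {row.end - row.start} (0) {i}\n"
            )


def read_group_map(path: str | Path) -> pd.DataFrame:
    """Tab-separated subfamily -> (group, te_class, is_active) mapping."""
    gm = pd.read_csv(path, sep="\t", dtype={"subfamily": str, "group": str})
    for col in ("subfamily", "group"):
        if col not in gm.columns:
            raise FormatError(f"{path}: group map missing column {col!r}")
    if "is_active" in gm.columns:
        gm["is_active"] = gm["is_active"].astype(bool)
    return gm


def apply_group_map(te: pd.DataFrame,
                    group_map: pd.DataFrame | Mapping[str, str]) -> pd.DataFrame:
    te = te.copy()
    if isinstance(group_map, pd.DataFrame):
        mapping = dict(zip(group_map["subfamily"], group_map["group"]))
        if "is_active" in group_map.columns:
            active = dict(zip(group_map["subfamily"], group_map["is_active"]))
            te["is_active"] = te["subfamily"].map(active).fillna(False).astype(bool)
    else:
        mapping = dict(group_map)
    te["group"] = te["subfamily"].map(mapping).fillna(te["subfamily"])
    return te


def mark_fli(te: pd.DataFrame, fli_intervals: pd.DataFrame) -> pd.DataFrame:
    """Flag insertions whose (chrom, start, end) match a row of the FLI BED."""
    te = te.copy()
    keys = set(zip(fli_intervals["chrom"], fli_intervals["start"], fli_intervals["end"]))
    te["is_fli"] = [
        (c, s, e) in keys for c, s, e in zip(te["chrom"], te["start"], te["end"])
    ]
    return te


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed3(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            rows.append((fields[0], int(fields[1]), int(fields[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_bed3(frame: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\n")


def write_clusters_bed(clusters: pd.DataFrame, path: str | Path,
                       track_name: str = "piRNA_clusters") -> None:
    """Write cluster calls as BED6: stage label in the name column, density
    clamped to 0–1000 in the score column."""
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for row in clusters.itertuples(index=False):
            density = getattr(row, "density", 0.0) or 0.0
            score = int(min(1000, max(0, round(density))))
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.stage}\t{score}\t.\n")


def read_clusters_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = line.split()
            rows.append((fields[0], int(fields[1]), int(fields[2]),
                         fields[3], float(fields[4])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "stage", "score"])


def write_window_bedgraph(windows: pd.DataFrame, values, path: str | Path,
                          track_name: str = "windows") -> None:
    """bedGraph of one per-window value vector, sorted by chrom then start."""
    frame = windows[["chrom", "start", "end"]].copy()
    frame["value"] = np.asarray(values, dtype=float)
    frame = frame.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for row in frame.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")
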