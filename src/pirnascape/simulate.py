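"""Synthetic study generator: genomes, TE annotations and WT/KO small-RNA
alignment libraries with planted ground truth.

The generator emulates the statistical structure of a hamster-style
developmental small-RNA study: stage-specific piRNA clusters that collapse
in the pathway knockout, multimapping reads, stage-typical length
distributions peaking at 27-30 nt, 5'-U and position-10-A biases,
TE-insertion-derived sense/antisense reads, and a large 21-23-nt miRNA
population that becomes dominant in the knockout.  Every emitted library is
deterministic under (seed, config), and machine-readable truth tables plus a
self-audit accompany each run.

Expression levels are specified in RPM of 19-32-nt reads.  When mirna_rpm is
left unset the miRNA population fills the library to ~1e6 RPM, which makes
the planted RPMs self-consistent and reproduces the knockout libraries'
miRNA dominance (the basis of cross-genotype miRNA scaling).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (GenomeModel, TE_COLUMNS, write_alignments_tabular, write_bed3,
                 write_repeatmasker_out)

PRE_PACHYTENE = "pre_pachytene"
PACHYTENE = "pachytene"
OOCYTE = "oocyte"


class SimulationAuditError(RuntimeError):
    """The generator's self-audit found emitted records inconsistent with truth."""


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PlantedCluster:
    chrom: str
    start: int
    end: int
    stage: str
    wt_rpm_per_kb: float
    ko_retention: float = 0.0
    is_decoy: bool = False

    @property
    def kb(self) -> float:
        return (self.end - self.start) / 1000.0


@dataclass
class TESubfamilyConfig:
    name: str
    group: str
    te_class: str = "LTR"
    n_insertions: int = 15
    insertion_length: int = 3000
    divergence_mean: float = 50.0     # milliDiv
    divergence_sd: float = 15.0
    fli_fraction: float = 0.2
    is_active: bool = True
    antisense_rpm: float = 25.0       # identical in WT and KO libraries
    sense_rpm_wt: float = 10.0
    sense_rpm_ko: float | None = None  # None: same as WT
    mismatch_rate: float = 0.3
    multimap_rate: float = 0.3
    max_hits: int = 4

    @property
    def planted_ko_fold(self) -> float:
        """Planted KO/WT fold change of total reads mapping to the group."""
        sense_ko = self.sense_rpm_wt if self.sense_rpm_ko is None else self.sense_rpm_ko
        wt = self.antisense_rpm + self.sense_rpm_wt
        ko = self.antisense_rpm + sense_ko
        return ko / wt if wt > 0 else float("inf")


@dataclass
class SampleConfig:
    sample_id: str
    genotype: str      # "WT" or "KO"
    timepoint: str     # e.g. "9dpp", "13dpp", "21dpp", "oocyte"


DEFAULT_LENGTH_DISTS = {
    PRE_PACHYTENE: {24: 0.05, 25: 0.08, 26: 0.12, 27: 0.20, 28: 0.20,
                    29: 0.15, 30: 0.12, 31: 0.08},
    PACHYTENE: {24: 0.02, 25: 0.03, 26: 0.05, 27: 0.10, 28: 0.15,
                29: 0.25, 30: 0.25, 31: 0.15},
    OOCYTE: {18: 0.10, 19: 0.12, 20: 0.08, 24: 0.10, 25: 0.10, 26: 0.12,
             27: 0.13, 28: 0.13, 29: 0.12, 30: 0.06, 31: 0.04},
}

MIRNA_LENGTH_DIST = {21: 0.25, 22: 0.50, 23: 0.25}
TE_LENGTH_DIST = {24: 0.08, 25: 0.10, 26: 0.13, 27: 0.16, 28: 0.16,
                  29: 0.14, 30: 0.11, 31: 0.07, 32: 0.05}
BACKGROUND_LENGTH_DIST = {n: 1 / 14 for n in range(19, 33)}


@dataclass
class SimulationConfig:
    seed: int = 1
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000})
    gap_fraction: float = 0.02
    gap_length: int = 5000
    window_size: int = 1000
    clusters: list[PlantedCluster] = field(default_factory=list)
    stage_timepoints: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {PRE_PACHYTENE: ("9dpp", "13dpp"),
                                 PACHYTENE: ("21dpp",)})
    length_dists: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LENGTH_DISTS.items()})
    mirna_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(MIRNA_LENGTH_DIST))
    te_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(TE_LENGTH_DIST))
    background_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(BACKGROUND_LENGTH_DIST))
    u1_prob: float = 0.8
    a10_prob: float = 0.5
    clip_rate: float = 0.05
    cluster_multimap_rate: float = 0.15
    cluster_max_hits: int = 4
    te_subfamilies: list[TESubfamilyConfig] = field(default_factory=list)
    n_mirna_loci: int = 40
    mirna_locus_length: int = 80
    mirna_rpm: float | None = None   # None: fill the library to ~1e6 RPM
    background_rpm: float = 0.0
    depth: int = 200_000             # expected 19-32-nt reads per library
    samples: list[SampleConfig] = field(default_factory=list)
    placement_padding: int = 3000    # clearance around planted clusters

    def validate(self) -> None:
        for p in (self.gap_fraction, self.u1_prob, self.a10_prob,
                  self.clip_rate, self.cluster_multimap_rate):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        for cl in self.clusters:
            if cl.chrom not in self.chrom_lengths:
                raise ConfigError(f"cluster on unknown chromosome {cl.chrom!r}")
            if not 0 <= cl.start < cl.end <= self.chrom_lengths[cl.chrom]:
                raise ConfigError(
                    f"cluster [{cl.start},{cl.end}) outside {cl.chrom!r}")
            if not 0.0 <= cl.ko_retention <= 1.0:
                raise ConfigError("ko_retention outside [0, 1]")
            if cl.stage not in self.stage_timepoints:
                raise ConfigError(f"cluster stage {cl.stage!r} has no time points")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ConfigError("duplicate sample ids")

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.genotype, s.timepoint) for s in self.samples],
            columns=["sample", "genotype", "timepoint"])


def hamster_like(seed: int = 1) -> SimulationConfig:
    """The default study: 2 chromosomes x 1 Mb; three pre-pachytene and two
    pachytene clusters above the density thresholds plus one sub-threshold
    decoy; four LTR/LINE subfamilies with FLI subsets and paper-scale planted
    KO sense upregulation; WT/KO x {9, 13, 21 dpp} with two replicates each.
    Noiseless: no genome-wide background reads, knockout retention zero."""
    clusters = [
        PlantedCluster("chr1", 100_000, 103_000, PRE_PACHYTENE, 1200.0),
        PlantedCluster("chr1", 300_000, 302_000, PRE_PACHYTENE, 800.0),
        PlantedCluster("chr1", 600_000, 603_000, PACHYTENE, 4000.0),
        PlantedCluster("chr2", 150_000, 154_000, PRE_PACHYTENE, 1000.0),
        PlantedCluster("chr2", 500_000, 502_000, PACHYTENE, 5000.0),
        # decoy: classifies pre-pachytene but its density stays below 10 RPM/kb
        PlantedCluster("chr2", 800_000, 802_000, PRE_PACHYTENE, 2.0,
                       is_decoy=True),
    ]
    te = [
        # planted KO/WT group folds: 20x, 3.3x, 2x, 1.5x
        TESubfamilyConfig("MYSERV6_int", "MYSERV6", "LTR",
                          antisense_rpm=200.0, sense_rpm_wt=40.0,
                          sense_rpm_ko=4600.0, divergence_mean=30.0),
        TESubfamilyConfig("MYSERV5_int", "MYSERV", "LTR",
                          antisense_rpm=400.0, sense_rpm_wt=100.0,
                          sense_rpm_ko=1250.0, divergence_mean=45.0),
        TESubfamilyConfig("IAPLTR3_int", "IAP", "LTR",
                          antisense_rpm=600.0, sense_rpm_wt=200.0,
                          sense_rpm_ko=1000.0, divergence_mean=40.0),
        TESubfamilyConfig("L1_Ham", "L1", "LINE",
                          antisense_rpm=500.0, sense_rpm_wt=300.0,
                          sense_rpm_ko=700.0, divergence_mean=120.0,
                          divergence_sd=40.0),
    ]
    samples = [
        SampleConfig(f"{geno}_{tp}_r{rep}", geno, tp)
        for tp in ("9dpp", "13dpp", "21dpp")
        for geno in ("WT", "KO")
        for rep in (1, 2)
    ]
    return SimulationConfig(seed=seed, clusters=clusters, te_subfamilies=te,
                            samples=samples)


def oocyte_like(seed: int = 1) -> SimulationConfig:
    """Small oocyte-style study: PIWI-IP libraries plus wild-type oocyte
    libraries over planted oocyte clusters (one abundant, one weak)."""
    clusters = [
        PlantedCluster("chr1", 200_000, 203_000, OOCYTE, 60.0),
        PlantedCluster("chr1", 500_000, 502_000, OOCYTE, 40.0),
        # weak cluster: passes RPKM >= 1 but stays under the 10-RPM filters
        PlantedCluster("chr2", 300_000, 302_000, OOCYTE, 1.5),
    ]
    samples = [
        SampleConfig("PIWIL1_IP", "WT", "oocyte"),
        SampleConfig("PIWIL3_IP", "WT", "oocyte"),
        SampleConfig("WT_oo_r1", "WT", "oocyte"),
        SampleConfig("WT_oo_r2", "WT", "oocyte"),
    ]
    return SimulationConfig(
        seed=seed,
        chrom_lengths={"chr1": 1_000_000, "chr2": 500_000},
        clusters=clusters,
        stage_timepoints={OOCYTE: ("oocyte",)},
        samples=samples,
        te_subfamilies=[],
        depth=150_000,
    )


# ---------------------------------------------------------------------------
# structural elements
# ---------------------------------------------------------------------------

def _overlaps(start: int, end: int, blocked: list[tuple[int, int]]) -> bool:
    return any(start < be and end > bs for bs, be in blocked)


def _place_intervals(rng: np.random.Generator, chrom_len: int, n: int,
                     length: int, blocked: list[tuple[int, int]],
                     max_tries: int = 2000) -> list[tuple[int, int]]:
    placed = []
    for _ in range(n):
        for _ in range(max_tries):
            start = int(rng.integers(0, max(1, chrom_len - length)))
            if not _overlaps(start, start + length, blocked):
                placed.append((start, start + length))
                blocked.append((start, start + length))
                break
        else:
            raise ConfigError("could not place interval; genome too crowded")
    return sorted(placed)


def _blocked_by_clusters(config: SimulationConfig, chrom: str) -> list[tuple[int, int]]:
    pad = config.placement_padding
    return [(cl.start - pad, cl.end + pad)
            for cl in config.clusters if cl.chrom == chrom]


def generate_genome(config: SimulationConfig,
                    rng: np.random.Generator) -> GenomeModel:
    """Chromosomes with gap_fraction covered by N-run intervals placed away
    from planted clusters."""
    gaps: dict[str, list[tuple[int, int]]] = {}
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n_gaps = int(round(config.gap_fraction * length / config.gap_length))
        if n_gaps:
            blocked = _blocked_by_clusters(config, chrom)
            gaps[chrom] = _place_intervals(rng, length, n_gaps,
                                           config.gap_length, blocked)
    return GenomeModel(chrom_names=sorted(config.chrom_lengths),
                       chrom_lengths=dict(config.chrom_lengths), gaps=gaps)


def generate_te_annotation(config: SimulationConfig, genome: GenomeModel,
                           rng: np.random.Generator) -> pd.DataFrame:
    """TE insertions placed away from planted clusters and assembly gaps."""
    blocked_by_chrom = {
        chrom: _blocked_by_clusters(config, chrom)
        + [tuple(g) for g in genome.gaps.get(chrom, [])]
        for chrom in genome.chrom_names
    }
    chrom_weights = np.array([genome.chrom_lengths[c] for c in genome.chrom_names],
                             dtype=float)
    chrom_weights /= chrom_weights.sum()
    rows = []
    for sub in sorted(config.te_subfamilies, key=lambda s: s.name):
        n_fli = int(round(sub.fli_fraction * sub.n_insertions))
        chrom_choice = rng.choice(len(genome.chrom_names), size=sub.n_insertions,
                                  p=chrom_weights)
        strands = rng.choice(["+", "-"], size=sub.n_insertions)
        divs = np.maximum(
            0, np.round(rng.normal(sub.divergence_mean, sub.divergence_sd,
                                   sub.n_insertions))).astype(int)
        for i in range(sub.n_insertions):
            chrom = genome.chrom_names[int(chrom_choice[i])]
            start, end = _place_intervals(
                rng, genome.chrom_lengths[chrom], 1, sub.insertion_length,
                blocked_by_chrom[chrom])[0]
            rows.append((chrom, start, end, str(strands[i]), sub.name, sub.group,
                         sub.te_class, int(divs[i]), i < n_fli))
    te = pd.DataFrame(rows, columns=TE_COLUMNS)
    return te.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def generate_mirna_loci(config: SimulationConfig, genome: GenomeModel,
                        rng: np.random.Generator,
                        te: pd.DataFrame) -> pd.DataFrame:
    blocked_by_chrom = {
        chrom: _blocked_by_clusters(config, chrom)
        + [tuple(g) for g in genome.gaps.get(chrom, [])]
        + [(int(r.start), int(r.end)) for r in
           te[te["chrom"] == chrom].itertuples(index=False)]
        for chrom in genome.chrom_names
    }
    rows = []
    per_chrom = np.full(len(genome.chrom_names),
                        config.n_mirna_loci // max(1, len(genome.chrom_names)))
    per_chrom[0] += config.n_mirna_loci - per_chrom.sum()
    for chrom, n in zip(genome.chrom_names, per_chrom):
        for start, end in _place_intervals(rng, genome.chrom_lengths[chrom],
                                           int(n), config.mirna_locus_length,
                                           blocked_by_chrom[chrom]):
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

_BASE_SET = np.array(list("ACGU"))


def simulate_biased_sequences(rng: np.random.Generator, lengths: np.ndarray,
                              u1_prob: float, a10_prob: float) -> list[str]:
    """Random RNA sequences with planted P(U at position 1) and
    P(A at position 10); off-bias positions are uniform over the other
    three bases so the planted probabilities are exact."""
    sequences = []
    for length in lengths:
        bases = _BASE_SET[rng.integers(0, 4, size=int(length))]
        if rng.random() < u1_prob:
            bases[0] = "U"
        else:
            bases[0] = rng.choice(["A", "C", "G"])
        if length >= 10:
            if rng.random() < a10_prob:
                bases[9] = "A"
            else:
                bases[9] = rng.choice(["C", "G", "U"])
        sequences.append("".join(bases))
    return sequences


def _draw_lengths(rng: np.random.Generator, dist: dict[int, float],
                  n: int) -> np.ndarray:
    lens = np.array(sorted(dist))
    probs = np.array([dist[l] for l in lens], dtype=float)
    probs /= probs.sum()
    return lens[rng.choice(len(lens), size=n, p=probs)]


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _sample_rng(config: SimulationConfig, sample_id: str) -> np.random.Generator:
    ordered = sorted(s.sample_id for s in config.samples)
    return np.random.default_rng([config.seed % (2**31), 1 + ordered.index(sample_id)])


def _cluster_rpm(config: SimulationConfig, cluster: PlantedCluster,
                 sample: SampleConfig) -> float:
    if sample.timepoint not in config.stage_timepoints[cluster.stage]:
        return 0.0
    rpm = cluster.wt_rpm_per_kb * cluster.kb
    if sample.genotype == "KO":
        rpm *= cluster.ko_retention
    return rpm


def simulate_library(config: SimulationConfig, sample_id: str,
                     genome: GenomeModel, te: pd.DataFrame,
                     mirna: pd.DataFrame,
                     rng: np.random.Generator | None = None,
                     ) -> tuple[pd.DataFrame, dict]:
    """One library of sorted tabular alignment records plus truth counts.

    Record counts per component are Poisson around rpm x depth / 1e6; cluster
    reads carry biased sequences; multimappers emit n_hits alignment records
    sharing one read_id (secondaries flagged non-primary)."""
    sample = next(s for s in config.samples if s.sample_id == sample_id)
    if rng is None:
        rng = _sample_rng(config, sample_id)
    depth = config.depth
    rows: list[tuple] = []
    serial = 0
    truth: dict = {"sample": sample_id, "cluster_reads": {}, "te_reads": {},
                   "mirna_reads": 0, "background_reads": 0}

    def new_id() -> str:
        nonlocal serial
        serial += 1
        return f"{sample_id}.{serial:07d}"

    def emit(read_id, chrom, fivep, strand, length, n_hits, mism,
             primary, clipped, seq):
        if strand == "+":
            start, end = int(fivep), int(fivep) + int(length)
        else:
            start, end = int(fivep) - int(length) + 1, int(fivep) + 1
        rows.append((read_id, chrom, start, end, strand, int(length),
                     int(n_hits), int(mism), bool(primary), bool(clipped), seq))

    # --- planted cluster reads (sorted cluster order fixes the draw order)
    planted_rpm_total = 0.0
    for cluster in sorted(config.clusters, key=lambda c: (c.chrom, c.start)):
        rpm = _cluster_rpm(config, cluster, sample)
        planted_rpm_total += rpm
        n = int(rng.poisson(rpm * depth / 1e6))
        truth["cluster_reads"][f"{cluster.chrom}:{cluster.start}-{cluster.end}"] = n
        if n == 0:
            continue
        pos5 = rng.integers(cluster.start, cluster.end, size=n)
        strands = rng.choice(["+", "-"], size=n)
        lengths = _draw_lengths(rng, config.length_dists[cluster.stage], n)
        seqs = simulate_biased_sequences(rng, lengths, config.u1_prob,
                                         config.a10_prob)
        clipped = rng.random(n) < config.clip_rate
        multi = rng.random(n) < config.cluster_multimap_rate
        for i in range(n):
            read_id = new_id()
            k = int(rng.integers(2, config.cluster_max_hits + 1)) if multi[i] else 1
            emit(read_id, cluster.chrom, pos5[i], strands[i], lengths[i], k,
                 0, True, clipped[i], seqs[i])
            for _ in range(k - 1):
                extra5 = int(rng.integers(cluster.start, cluster.end))
                emit(read_id, cluster.chrom, extra5, strands[i], lengths[i], k,
                     0, False, clipped[i], seqs[i])

    # --- TE-derived reads
    te_rpm_total = 0.0
    for sub in sorted(config.te_subfamilies, key=lambda s: s.name):
        ins = te[te["subfamily"] == sub.name].reset_index(drop=True)
        sense_rpm = (sub.sense_rpm_wt if sample.genotype != "KO"
                     or sub.sense_rpm_ko is None else sub.sense_rpm_ko)
        counts = {}
        for orient, rpm in (("antisense", sub.antisense_rpm), ("sense", sense_rpm)):
            te_rpm_total += rpm
            n = int(rng.poisson(rpm * depth / 1e6))
            counts[orient] = n
            if n == 0 or ins.empty:
                continue
            which = rng.integers(0, len(ins), size=n)
            lengths = _draw_lengths(rng, config.te_length_dist, n)
            offsets = rng.integers(0, sub.insertion_length - 33, size=n)
            mism = (rng.random(n) < sub.mismatch_rate).astype(int)
            multi = rng.random(n) < sub.multimap_rate
            for i in range(n):
                row = ins.iloc[int(which[i])]
                if orient == "sense":
                    strand = row["strand"]
                else:
                    strand = "-" if row["strand"] == "+" else "+"
                read_id = new_id()
                k = 1
                targets = [int(which[i])]
                if multi[i] and len(ins) > 1:
                    k = int(rng.integers(2, min(sub.max_hits, len(ins)) + 1))
                    others = rng.choice(
                        [j for j in range(len(ins)) if j != which[i]],
                        size=k - 1, replace=False)
                    targets += [int(j) for j in others]
                for t, tgt in enumerate(targets):
                    trow = ins.iloc[tgt]
                    start = int(trow["start"]) + int(offsets[i])
                    length = int(lengths[i])
                    fivep = start if strand == "+" else start + length - 1
                    emit(read_id, trow["chrom"], fivep, strand, length, k,
                         mism[i], t == 0, False, None)
        truth["te_reads"][sub.name] = counts

    from .io import TABULAR_COLUMNS
    extra_frames: list[pd.DataFrame] = []

    def bulk_ids(n: int) -> np.ndarray:
        nonlocal serial
        numbers = np.char.zfill(
            np.arange(serial + 1, serial + n + 1).astype("U7"), 7)
        serial += n
        return np.char.add(f"{sample_id}.", numbers)

    # --- miRNA reads (library filler unless an explicit RPM is configured)
    if config.mirna_rpm is not None:
        mirna_rpm = config.mirna_rpm
    else:
        mirna_rpm = max(0.0, 1e6 - planted_rpm_total - te_rpm_total
                        - config.background_rpm)
    n = int(rng.poisson(mirna_rpm * depth / 1e6))
    truth["mirna_reads"] = n
    if n and len(mirna):
        which = rng.integers(0, len(mirna), size=n)
        lengths = _draw_lengths(rng, config.mirna_length_dist, n)
        starts = mirna["start"].to_numpy()[which]
        extra_frames.append(pd.DataFrame({
            "read_id": bulk_ids(n),
            "chrom": mirna["chrom"].to_numpy()[which],
            "start": starts, "end": starts + lengths,
            "strand": "+", "read_length": lengths,
            "n_hits": 1, "mismatches": 0,
            "is_primary": True, "clipped5": False, "sequence": None,
        }))

    # --- uniform background (off by default; exercises the RPKM<1 filter)
    n = int(rng.poisson(config.background_rpm * depth / 1e6))
    truth["background_reads"] = n
    if n:
        chroms = genome.chrom_names
        weights = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        chrom_choice = rng.choice(len(chroms), size=n, p=weights)
        lengths = _draw_lengths(rng, config.background_length_dist, n)
        strands = rng.choice(["+", "-"], size=n)
        limits = np.array([genome.chrom_lengths[c] for c in chroms])[chrom_choice]
        fivep = (33 + rng.random(n) * (limits - 66)).astype(int)
        plus = strands == "+"
        starts = np.where(plus, fivep, fivep - lengths + 1)
        extra_frames.append(pd.DataFrame({
            "read_id": bulk_ids(n),
            "chrom": np.array(chroms, dtype=object)[chrom_choice],
            "start": starts, "end": starts + lengths,
            "strand": strands, "read_length": lengths,
            "n_hits": 1, "mismatches": 0,
            "is_primary": True, "clipped5": False, "sequence": None,
        }))

    frame = pd.DataFrame(rows, columns=TABULAR_COLUMNS)
    if extra_frames:
        frame = pd.concat([frame, *extra_frames], ignore_index=True)
    frame = frame.sort_values(["chrom", "start", "end", "read_id"],
                              kind="stable").reset_index(drop=True)
    truth["n_records"] = len(frame)
    truth["n_reads"] = int(frame["read_id"].nunique())
    return frame, truth


# ---------------------------------------------------------------------------
# whole-study emission with truth tables and self-audit
# ---------------------------------------------------------------------------

def write_truth(config: SimulationConfig, outdir: Path,
                library_truth: list[dict], te: pd.DataFrame) -> None:
    truth_dir = outdir / "truth"
    truth_dir.mkdir(parents=True, exist_ok=True)

    thresholds = {PRE_PACHYTENE: 10.0, PACHYTENE: 100.0, OOCYTE: 10.0}
    cluster_rows = []
    for cl in sorted(config.clusters, key=lambda c: (c.chrom, c.start)):
        cluster_rows.append({
            "chrom": cl.chrom, "start": cl.start, "end": cl.end,
            "stage": cl.stage, "wt_rpm_per_kb": cl.wt_rpm_per_kb,
            "ko_retention": cl.ko_retention, "is_decoy": int(cl.is_decoy),
            "expected_supra_threshold":
                int(cl.wt_rpm_per_kb > thresholds[cl.stage]),
        })
    pd.DataFrame(cluster_rows).to_csv(truth_dir / "clusters.tsv", sep="\t",
                                      index=False)

    fold_rows = [{"group": sub.group, "subfamily": sub.name,
                  "planted_ko_fold": sub.planted_ko_fold,
                  "antisense_rpm": sub.antisense_rpm,
                  "sense_rpm_wt": sub.sense_rpm_wt,
                  "sense_rpm_ko": (sub.sense_rpm_wt if sub.sense_rpm_ko is None
                                   else sub.sense_rpm_ko)}
                 for sub in sorted(config.te_subfamilies, key=lambda s: s.name)]
    pd.DataFrame(fold_rows, columns=["group", "subfamily", "planted_ko_fold",
                                     "antisense_rpm", "sense_rpm_wt",
                                     "sense_rpm_ko"]
                 ).to_csv(truth_dir / "te_groups.tsv", sep="\t", index=False)

    params = {"seed": config.seed, "depth": config.depth,
              "u1_prob": config.u1_prob, "a10_prob": config.a10_prob,
              "window_size": config.window_size,
              "background_rpm": config.background_rpm}
    pd.DataFrame([params]).to_csv(truth_dir / "params.tsv", sep="\t", index=False)

    lib_rows = [{"sample": t["sample"], "n_records": t["n_records"],
                 "n_reads": t["n_reads"], "mirna_reads": t["mirna_reads"],
                 "background_reads": t["background_reads"],
                 "cluster_reads": sum(t["cluster_reads"].values()),
                 "te_reads": sum(sum(c.values()) for c in t["te_reads"].values())}
                for t in library_truth]
    pd.DataFrame(lib_rows).to_csv(truth_dir / "library_totals.tsv", sep="\t",
                                  index=False)


def _audit(outdir: Path, library_truth: list[dict]) -> None:
    totals = pd.read_csv(outdir / "truth" / "library_totals.tsv", sep="\t")
    for t in library_truth:
        emitted = pd.read_csv(outdir / "reads" / f"{t['sample']}.tsv", sep="\t")
        row = totals[totals["sample"] == t["sample"]].iloc[0]
        if len(emitted) != int(row["n_records"]):
            raise SimulationAuditError(
                f"{t['sample']}: emitted {len(emitted)} records, "
                f"truth says {row['n_records']}")
        if emitted["read_id"].nunique() != int(row["n_reads"]):
            raise SimulationAuditError(
                f"{t['sample']}: distinct-read count mismatch")


def simulate_study(config: SimulationConfig, outdir: str | Path) -> dict:
    """Emit a complete synthetic study to *outdir*.

    Files: chrom.sizes, gaps.bed, repeats.out, group_map.tsv, fli.bed,
    mirna.bed, design.tsv, reads/<sample>.tsv, truth/*.tsv.  Fully
    deterministic under (seed, config); a self-audit recounts the emitted
    files against the truth tables and raises on mismatch.
    """
    config.validate()
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed % (2**31), 0])

    genome = generate_genome(config, rng)
    te = generate_te_annotation(config, genome, rng)
    mirna = generate_mirna_loci(config, genome, rng, te)

    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f"{chrom}\t{genome.chrom_lengths[chrom]}\n")
    gap_frame = pd.DataFrame(
        [(c, s, e) for c in genome.chrom_names
         for s, e in genome.gaps.get(c, [])],
        columns=["chrom", "start", "end"])
    write_bed3(gap_frame, outdir / "gaps.bed")
    write_repeatmasker_out(te, outdir / "repeats.out")
    gm_rows = [{"subfamily": sub.name, "group": sub.group,
                "te_class": sub.te_class, "is_active": int(sub.is_active)}
               for sub in sorted(config.te_subfamilies, key=lambda s: s.name)]
    pd.DataFrame(gm_rows, columns=["subfamily", "group", "te_class", "is_active"]
                 ).to_csv(outdir / "group_map.tsv", sep="\t", index=False)
    write_bed3(te.loc[te["is_fli"].astype(bool), ["chrom", "start", "end"]],
               outdir / "fli.bed")
    write_bed3(mirna, outdir / "mirna.bed")
    config.design_frame().to_csv(outdir / "design.tsv", sep="\t", index=False)

    library_truth = []
    for sample in config.samples:
        frame, truth = simulate_library(config, sample.sample_id, genome, te, mirna)
        write_alignments_tabular(frame, outdir / "reads" / f"{sample.sample_id}.tsv")
        library_truth.append(truth)
    write_truth(config, outdir, library_truth, te)
    _audit(outdir, library_truth)
    return {"outdir": outdir, "genome": genome, "te": te, "mirna": mirna,
            "design": config.design_frame(), "library_truth": library_truth}
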