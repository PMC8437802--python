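"""End-to-end orchestration: load a study directory, quantify windows, call
clusters, and compute the read-level summaries.

A study directory has the layout emitted by :func:`pirnascape.simulate.simulate_study`:
chrom.sizes, gaps.bed, design.tsv, reads/<sample>.tsv plus the optional
annotation files (repeats.out, group_map.tsv, fli.bed, mirna.bed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clusters as cl
from . import features as ft
from . import io
from . import windows as wd


@dataclass
class Study:
    genome: io.GenomeModel
    design: pd.DataFrame
    reads: dict[str, pd.DataFrame]
    libs: dict[str, io.LibraryStats]
    te: pd.DataFrame | None = None
    group_map: pd.DataFrame | None = None
    mirna: pd.DataFrame | None = None
    fli: pd.DataFrame | None = None


def load_study(path: str | Path) -> Study:
    path = Path(path)
    genome = io.read_chrom_sizes(path / "chrom.sizes")
    if (path / "gaps.bed").exists():
        genome = io.read_gaps_bed(path / "gaps.bed", genome)
    design = cl.validate_design(pd.read_csv(path / "design.tsv", sep="\t"))
    mirna = io.read_bed3(path / "mirna.bed") if (path / "mirna.bed").exists() else None
    reads, libs = {}, {}
    for sample in design["sample"]:
        frame = io.read_alignments_frame(path / "reads" / f"{sample}.tsv")
        reads[sample] = frame
        libs[sample] = ft.compute_library_stats(frame, sample,
                                                mirna_annotation=mirna)
    te = group_map = fli = None
    if (path / "repeats.out").exists():
        if (path / "group_map.tsv").exists():
            group_map = io.read_group_map(path / "group_map.tsv")
        te = io.read_repeatmasker_out(path / "repeats.out", group_map=group_map)
        if (path / "fli.bed").exists():
            fli = io.read_bed3(path / "fli.bed")
            te = io.mark_fli(te, fli)
    return Study(genome=genome, design=design, reads=reads, libs=libs,
                 te=te, group_map=group_map, mirna=mirna, fli=fli)


@dataclass
class TestesResult:
    windows: pd.DataFrame
    rpkm: wd.WindowTable
    caller: cl.ClusterCaller
    clusters: pd.DataFrame          # finalized, density-filtered calls
    all_superclusters: pd.DataFrame  # before the density filter
    libs: dict[str, io.LibraryStats] = field(default_factory=dict)


def run_testes_pipeline(study: Study | str | Path,
                        window_size: int = 1000,
                        size_min: int = 24, size_max: int = 31,
                        threshold: float = -2.0, pseudocount: float = 0.01,
                        max_gap: int = 2000,
                        prepachytene_min: float = 10.0,
                        pachytene_min: float = 100.0,
                        density_mode: str = "per_kb",
                        include=None, exclude=None) -> TestesResult:
    """The testes cluster-discovery pipeline, window tiling to density filter."""
    if not isinstance(study, Study):
        study = load_study(study)
    windows = wd.tile_genome(study.genome, window_size=window_size)
    counts = wd.count_samples(study.reads, windows, size_min, size_max)
    rpm = wd.to_rpm(counts, study.libs)
    rpkm = wd.to_rpkm(rpm)
    caller = cl.ClusterCaller(threshold=threshold, pseudocount=pseudocount,
                              max_gap=max_gap)
    caller.fit(rpkm, design=study.design)
    finalized = cl.finalize_clusters(
        caller.clusters_, study.reads, study.libs, study.genome,
        design=study.design, size_min=size_min, size_max=size_max,
        include=include, exclude=exclude)
    final = cl.filter_density(finalized, prepachytene_min=prepachytene_min,
                              pachytene_min=pachytene_min, mode=density_mode)
    return TestesResult(windows=windows, rpkm=rpkm, caller=caller,
                        clusters=final, all_superclusters=finalized,
                        libs=study.libs)


def run_oocyte_pipeline(study: Study | str | Path,
                        ip_samples: tuple[str, str] = ("PIWIL1_IP", "PIWIL3_IP"),
                        wt_samples: list[str] | None = None,
                        window_size: int = 1000,
                        size_min: int = 24, size_max: int = 31,
                        max_gap: int = 2000) -> pd.DataFrame:
    """Oocyte cluster discovery from PIWI-IP window RPMs."""
    if not isinstance(study, Study):
        study = load_study(study)
    windows = wd.tile_genome(study.genome, window_size=window_size)
    tables = []
    for sample in ip_samples:
        counts = wd.fractional_count(study.reads[sample], windows,
                                     size_min, size_max, sample_id=sample)
        tables.append(wd.to_rpm(counts, {sample: study.libs[sample]}))
    if wt_samples is None:
        wt_samples = [s for s in study.design["sample"] if s not in ip_samples]
    wt_reads = {s: study.reads[s] for s in wt_samples}
    return cl.call_oocyte_clusters(tables[0], tables[1], wt_reads, study.libs,
                                   max_gap=max_gap)
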