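# pirnascape

Windowed piRNA cluster discovery and retrotransposon small-RNA quantification
from knockout/wild-type small-RNA-seq alignments.

## The problem

PIWI-interacting RNAs (piRNAs) are 19–32-nt germline small RNAs that silence
retrotransposons. They arise from discrete genomic loci — piRNA clusters —
whose output collapses when piRNA biogenesis is ablated (e.g. in a *Mov10l1*
knockout). `pirnascape` implements, as a tested and reusable pipeline, the
genomics analyses such a study needs:

- **Cluster discovery in testes.** The genome is tiled into 1-kb windows and
  alignments of 24–31-nt reads are counted fractionally (each alignment of a
  read with *n* genomic hits contributes 1/*n* to the window containing its
  5′ end). Counts are normalised to RPM (per million 19–32-nt reads) and to
  gap-corrected window length (RPKM); windows with RPKM < 1 are removed. With
  log₂FC = log₂((KO + p)/(WT + p)) of replicate-averaged RPKMs, a window is
  **pre-pachytene** when log₂FC < −2 at both 9 and 13 days postpartum (dpp),
  and **pachytene** when log₂FC < −2 at 21 dpp while > −2 at 13 dpp.
  Adjacent same-stage windows merge into clusters, clusters ≤ 2 kb apart into
  superclusters, final RPKMs are recomputed over the merged intervals, and
  clusters are kept when wild-type piRNA density exceeds 10 RPM/kb
  (pre-pachytene) or 100 RPM/kb (pachytene).
- **Cluster discovery in oocytes.** Windows are seeded from PIWIL1/PIWIL3
  immunoprecipitation libraries instead of a knockout contrast; retained
  clusters need ≥ 10 RPM in either IP and ≥ 10 RPM (mean over wild-type
  oocyte samples) of combined 18–20-nt + 24–32-nt reads, excluding the
  21–23-nt miRNA/siRNA-rich population.
- **Read-level piRNA statistics.** Length distributions and size classes
  (18–20 / 21–23 / 24–27 / 28–31 nt), cross-genotype miRNA scaling, and the
  1U/10A ping-pong signature computed from logo-eligible reads (primary
  alignment, unclipped 5′ end, 25–31 nt, inside a cluster).
- **Retrotransposon quantification.** Once-per-read counting of reads over
  TE groups (a multimapper counts once per group it touches, never per
  alignment), antisense per-length profiles of perfectly matching reads over
  full-length intact (FLI) insertions, KO/WT ranking of upregulated groups,
  and RepeatMasker divergence boxplot summaries (median, quartiles,
  1.5×IQR whiskers).
- **A synthetic-study generator** that plants stage-specific clusters,
  nucleotide biases, multimappers, TE-derived reads and miRNA populations
  with machine-readable truth tables, so the entire pipeline is testable
  without any sequencing download.

Formats: `chrom.sizes`, BED/bedGraph, SAM/BAM (NH tag required), RepeatMasker
`.out`, and a plain tab-separated alignment dialect for desk-scale work.

## Worked example

```python
from pirnascape import hamster_like, simulate_study, run_testes_pipeline

simulate_study(hamster_like(seed=3), "study/")   # synthetic KO/WT study
result = run_testes_pipeline("study/")
print(result.clusters[["chrom", "start", "end", "stage", "n_windows", "density"]])
```

```
  chrom   start     end          stage  n_windows      density
0  chr1  100000  103000  pre_pachytene          3  1196.206222
1  chr1  300000  302000  pre_pachytene          2   819.976395
2  chr1  600000  603000      pachytene          3  4010.068730
3  chr2  150000  154000  pre_pachytene          4   993.415890
4  chr2  500000  502000      pachytene          2  4994.467676
```

Exactly the five planted supra-threshold clusters come back, with the stage
assigned from the KO/WT fold-change pattern and the wild-type piRNA density
(RPM per gap-corrected kb, averaged over each stage's defining time points)
that cleared the 10 / 100 RPM-per-kb filters. The sixth planted locus — a
decoy expressed at 2 RPM/kb — classifies as a cluster but is rejected by the
density filter. The `ClusterCaller` class behind this is a scikit-learn-style
estimator (`fit`, `get_params`, fitted `clusters_` / `window_labels_` /
`fold_changes_` attributes) if you want the classification step alone.

The same run from the shell:

```bash
pirnascape simulate --seed 3 --out study/
pirnascape call-clusters --study study/ --out clusters.bed
pirnascape te --study study/ --out-prefix te_tables
```

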