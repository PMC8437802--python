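import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pirnascape import clusters as cl
from pirnascape import windows as wd
from pirnascape.io import GenomeModel, LibraryStats
from conftest import make_read


def make_design():
    rows = []
    for tp in ("9dpp", "13dpp", "21dpp"):
        for geno in ("WT", "KO"):
            rows.append((f"{geno}_{tp}", geno, tp))
    return pd.DataFrame(rows, columns=["sample", "genotype", "timepoint"])


def make_window_table(values: dict, unit="RPKM", window_size=1000):
    n = len(next(iter(values.values())))
    genome = GenomeModel(["c"], {"c": window_size * n})
    tiles = wd.tile_genome(genome, window_size)
    return wd.WindowTable(windows=tiles,
                          values=pd.DataFrame(values, index=tiles.index),
                          unit=unit)


class TestLog2FoldChange:
    def test_closed_form_without_pseudocount(self):
        assert cl.log2_fold_change(1.0, 4.0, pseudocount=0.0) == pytest.approx(-2.0)

    def test_knockout_zero_stays_finite(self):
        value = cl.log2_fold_change(0.0, 10.0, pseudocount=0.01)
        assert value == pytest.approx(math.log2(0.01 / 10.01), abs=1e-9)

    def test_both_zero_is_zero(self):
        assert cl.log2_fold_change(0.0, 0.0) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            cl.log2_fold_change(-1.0, 2.0)

    @given(a=st.floats(0, 1e3), b=st.floats(0, 1e3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_antisymmetry(self, a, b):
        assert cl.log2_fold_change(a, b) == pytest.approx(
            -cl.log2_fold_change(b, a), abs=1e-9)

    def test_pseudocount_shift_bounded_for_expressed_windows(self):
        # decreasing p cannot move the fold change by more than
        # log2((x + p) / x) for the smaller input
        ko, wt, p = 0.5, 9.0, 0.01
        delta = abs(cl.log2_fold_change(ko, wt, p) - cl.log2_fold_change(ko, wt, 0.0))
        assert delta <= math.log2((min(ko, wt) + p) / min(ko, wt)) + 1e-12


class TestClassifyWindow:
    @pytest.mark.parametrize("lfc9,lfc13,lfc21,expected", [
        (-3.0, -2.5, -1.0, "pre_pachytene"),
        (0.0, -1.0, -3.0, "pachytene"),
        (-3.0, -2.0, -3.0, None),   # 13 dpp exactly at threshold: both rules fail
        (-2.0, -2.5, 0.0, None),    # 9 dpp exactly at threshold
        (-1.0, -1.0, -2.0, None),   # 21 dpp exactly at threshold
        (-3.0, -1.0, -3.0, "pachytene"),
        (0.0, 0.0, 0.0, None),
    ])
    def test_strict_rule_boundaries(self, lfc9, lfc13, lfc21, expected):
        assert cl.classify_window(lfc9, lfc13, lfc21) == expected

    def test_vectorised_agrees_with_scalar(self):
        rng = np.random.default_rng(0)
        fc = pd.DataFrame({
            "lfc_9dpp": rng.uniform(-5, 2, 200),
            "lfc_13dpp": rng.uniform(-5, 2, 200),
            "lfc_21dpp": rng.uniform(-5, 2, 200),
        })
        labels = cl.classify_windows(fc)
        for i in range(len(fc)):
            assert labels.iloc[i] == cl.classify_window(
                fc.lfc_9dpp[i], fc.lfc_13dpp[i], fc.lfc_21dpp[i])


class TestMerging:
    def labeled(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "stage"])

    def test_adjacent_same_stage_merge(self):
        out = cl.merge_adjacent(self.labeled(
            [("c", 0, 1000, "pre_pachytene"), ("c", 1000, 2000, "pre_pachytene")]))
        assert out[["start", "end", "n_windows"]].values.tolist() == [[0, 2000, 2]]

    def test_stage_mismatch_splits(self):
        out = cl.merge_adjacent(self.labeled(
            [("c", 0, 1000, "pre_pachytene"), ("c", 1000, 2000, "pachytene")]))
        assert len(out) == 2

    def test_gap_splits_until_supercluster_step(self):
        out = cl.merge_adjacent(self.labeled(
            [("c", 0, 1000, "pachytene"), ("c", 2000, 3000, "pachytene")]))
        assert len(out) == 2
        merged = cl.merge_superclusters(out, max_gap=2000)
        assert merged[["start", "end"]].values.tolist() == [[0, 3000]]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            cl.merge_adjacent(self.labeled(
                [("c", 1000, 2000, "pachytene"), ("c", 0, 1000, "pachytene")]))

    def test_supercluster_gap_2000_merges_2001_does_not(self):
        base = [("c", 0, 3000, "pachytene", 3)]
        near = pd.DataFrame(base + [("c", 5000, 8000, "pachytene", 3)],
                            columns=cl.CLUSTER_COLUMNS)
        far = pd.DataFrame(base + [("c", 5001, 8000, "pachytene", 3)],
                           columns=cl.CLUSTER_COLUMNS)
        assert cl.merge_superclusters(near)[["start", "end"]].values.tolist() == \
            [[0, 8000]]
        assert len(cl.merge_superclusters(far)) == 2

    def test_supercluster_never_mixes_stages(self):
        frame = pd.DataFrame(
            [("c", 0, 1000, "pre_pachytene", 1), ("c", 1500, 2500, "pachytene", 1)],
            columns=cl.CLUSTER_COLUMNS)
        assert len(cl.merge_superclusters(frame)) == 2

    def test_supercluster_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(3)
        starts = np.sort(rng.choice(np.arange(0, 100) * 1000, 20, replace=False))
        frame = pd.DataFrame({
            "chrom": "c", "start": starts, "end": starts + 1000,
            "stage": rng.choice(["pre_pachytene", "pachytene"], 20),
            "n_windows": 1}, columns=cl.CLUSTER_COLUMNS)
        once = cl.merge_superclusters(frame)
        twice = cl.merge_superclusters(once)
        shuffled = cl.merge_superclusters(frame.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(once, twice)
        pd.testing.assert_frame_equal(once, shuffled)

    def test_no_same_stage_output_overlap(self):
        rng = np.random.default_rng(9)
        starts = np.sort(rng.choice(np.arange(0, 200) * 1000, 40, replace=False))
        frame = pd.DataFrame({
            "chrom": "c", "start": starts, "end": starts + 1000,
            "stage": "pre_pachytene", "n_windows": 1}, columns=cl.CLUSTER_COLUMNS)
        out = cl.merge_superclusters(frame)
        assert (out["start"].to_numpy()[1:] > out["end"].to_numpy()[:-1]).all()


class TestDensityFilter:
    def calls(self, stage, density):
        return pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2000],
                             "stage": [stage], "n_windows": [2],
                             "effective_length": [2000], "density": [density]})

    def test_prepachytene_exactly_10_rejected(self):
        assert cl.filter_density(self.calls("pre_pachytene", 10.0)).empty

    def test_prepachytene_11_retained(self):
        assert len(cl.filter_density(self.calls("pre_pachytene", 11.0))) == 1

    def test_pachytene_threshold_is_100(self):
        assert cl.filter_density(self.calls("pachytene", 99.0)).empty
        assert len(cl.filter_density(self.calls("pachytene", 150.0))) == 1

    def test_per_cluster_mode_uses_total_rpm(self):
        # density 60 RPM/kb over 2 kb = 120 RPM total > 100
        calls = self.calls("pachytene", 60.0)
        assert cl.filter_density(calls).empty
        assert len(cl.filter_density(calls, mode="per_cluster")) == 1


def brute_force_cluster_calls(rpkm, rpm, design, threshold=-2.0,
                              pseudocount=0.01, min_rpkm=1.0, max_gap=2000,
                              pre_min=10.0, pac_min=100.0):
    """Direct per-window enumeration of the classification + merging +
    density rules; independent of the library implementation."""
    n = len(rpkm.windows)
    wt_cols = {tp: [s for s, g, t in design.itertuples(index=False)
                    if g == "WT" and t == tp] for tp in ("9dpp", "13dpp", "21dpp")}
    ko_cols = {tp: [s for s, g, t in design.itertuples(index=False)
                    if g == "KO" and t == tp] for tp in ("9dpp", "13dpp", "21dpp")}
    labels = []
    for i in range(n):
        passing = any(rpkm.values[s].iloc[i] >= min_rpkm
                      for cols in wt_cols.values() for s in cols)
        if not passing:
            labels.append(None)
            continue
        lfc = {}
        for tp in ("9dpp", "13dpp", "21dpp"):
            wt = np.mean([rpkm.values[s].iloc[i] for s in wt_cols[tp]])
            ko = np.mean([rpkm.values[s].iloc[i] for s in ko_cols[tp]])
            lfc[tp] = math.log2((ko + pseudocount) / (wt + pseudocount))
        if lfc["9dpp"] < threshold and lfc["13dpp"] < threshold:
            labels.append("pre_pachytene")
        elif lfc["21dpp"] < threshold and lfc["13dpp"] > threshold:
            labels.append("pachytene")
        else:
            labels.append(None)
    # adjacency merge, then transitive gap merge per stage
    runs = []
    for i, label in enumerate(labels):
        win = rpkm.windows.iloc[i]
        if label is None:
            continue
        if runs and runs[-1][3] == label and runs[-1][2] == win["start"] \
                and runs[-1][0] == win["chrom"]:
            runs[-1][2] = win["end"]
        else:
            runs.append([win["chrom"], win["start"], win["end"], label])
    merged = []
    for chrom, start, end, label in runs:
        hit = None
        for m in merged:
            if m[3] == label and m[0] == chrom and start - m[2] <= max_gap:
                hit = m
        if hit is not None:
            hit[2] = max(hit[2], end)
        else:
            merged.append([chrom, start, end, label])
    # density over the merged interval from the full (unfiltered) RPM table
    out = set()
    for chrom, start, end, label in merged:
        tps = ("9dpp", "13dpp") if label == "pre_pachytene" else ("21dpp",)
        per_tp = []
        for tp in tps:
            total = 0.0
            for i in range(n):
                win = rpm.windows.iloc[i]
                if win["chrom"] == chrom and win["start"] >= start \
                        and win["end"] <= end:
                    total += np.mean([rpm.values[s].iloc[i] for s in wt_cols[tp]])
            per_tp.append(total)
        density = np.mean(per_tp) / ((end - start) / 1000.0)
        minimum = pre_min if label == "pre_pachytene" else pac_min
        if density > minimum:
            out.add((chrom, int(start), int(end), label))
    return out


class TestOracleEquivalence:
    def test_random_instances_match_brute_force(self):
        design = make_design()
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(5, 101))
            values = {}
            for s in design["sample"]:
                v = np.where(rng.random(n) < 0.4,
                             rng.gamma(1.0, 30.0, n), 0.0)
                values[s] = np.round(v, 3)
            rpkm = make_window_table(values)  # 1-kb windows: RPM == RPKM
            caller = cl.ClusterCaller().fit(rpkm, design=design)
            withdens = cl.density_from_window_rpm(
                caller.clusters_, rpkm.copy_with(rpkm.values, "RPM"), design)
            final = cl.filter_density(withdens)
            got = {(r.chrom, int(r.start), int(r.end), r.stage)
                   for r in final.itertuples(index=False)}
            expected = brute_force_cluster_calls(
                rpkm, rpkm.copy_with(rpkm.values, "RPM"), design)
            assert got == expected


class TestFinalize:
    def test_rpkm_and_density_definitions(self):
        # interval [0,2000), no gaps, 20 fractional counts, lib 1e6
        genome = GenomeModel(["c"], {"c": 10_000})
        clusters = pd.DataFrame([("c", 0, 2000, "pre_pachytene", 2)],
                                columns=cl.CLUSTER_COLUMNS)
        reads = [make_read(f"r{i}", chrom="c", start=int(p), length=28)
                 for i, p in enumerate(np.linspace(0, 1990, 20))]
        design = make_design()
        libs = {s: LibraryStats(s, 10**6, 10**6) for s in design["sample"]}
        reads_by_sample = {s: wd.reads_to_frame(reads) for s in design["sample"]}
        out = cl.finalize_clusters(clusters, reads_by_sample, libs, genome,
                                   design=design)
        assert out["rpm_WT_9dpp"].iloc[0] == pytest.approx(20.0)
        assert out["rpkm_WT_9dpp"].iloc[0] == pytest.approx(10.0)
        assert out["density"].iloc[0] == pytest.approx(10.0)

    def test_fully_gapped_interval_dropped(self):
        genome = GenomeModel(["c"], {"c": 10_000}, gaps={"c": [(0, 2000)]})
        clusters = pd.DataFrame([("c", 0, 2000, "pre_pachytene", 2)],
                                columns=cl.CLUSTER_COLUMNS)
        out = cl.finalize_clusters(clusters, {}, {}, genome)
        assert out.empty

    def test_exclude_list_drops_cluster(self):
        genome = GenomeModel(["c"], {"c": 10_000})
        clusters = pd.DataFrame([("c", 0, 2000, "pre_pachytene", 2),
                                 ("c", 5000, 6000, "pachytene", 1)],
                                columns=cl.CLUSTER_COLUMNS)
        out = cl.finalize_clusters(clusters, {}, {}, genome,
                                   exclude=["c:0-2000"])
        assert out["cluster_id"].tolist() == ["c:5000-6000"]


class TestOocyte:
    def build(self, p1_rpm, p3_rpm, wt_reads, wt_total=10**6):
        """Three 1-kb windows on one 3-kb chromosome."""
        p1 = make_window_table({"PIWIL1_IP": p1_rpm}, unit="RPM")
        p3 = make_window_table({"PIWIL3_IP": p3_rpm}, unit="RPM")
        libs = {"wt": LibraryStats("wt", wt_total, wt_total)}
        return cl.call_oocyte_clusters(p1, p3, {"wt": wd.reads_to_frame(wt_reads)},
                                       libs)

    def wt_reads(self, n, length=26):
        return [make_read(f"w{i}", chrom="c", start=10 + i, length=length)
                for i in range(n)]

    def test_either_ip_at_exactly_10_retained(self):
        out = self.build([10.0, 0, 0], [3.0, 0, 0], self.wt_reads(15))
        assert out[["start", "end"]].values.tolist() == [[0, 1000]]

    def test_wt_combined_below_10_removed(self):
        out = self.build([12.0, 0, 0], [0.0, 0, 0], self.wt_reads(9))
        assert out.empty

    def test_dicer_sized_reads_excluded_from_wt_quantity(self):
        # abundant 21-23-nt reads contribute nothing to the 18-20 + 24-32 sum
        out = self.build([12.0, 0, 0], [0.0, 0, 0], self.wt_reads(500, length=22))
        assert out.empty

    def test_rpkm_filter_applies_before_merging(self):
        # middle window under 1 RPKM splits the locus into two clusters
        out = self.build([20.0, 0.5, 20.0], [0.0, 0.0, 0.0], self.wt_reads(30))
        assert len(out) == 1  # bridged by the 2-kb supercluster gap
        assert out[["start", "end"]].values.tolist() == [[0, 3000]]
        # but the filtered middle window still counts toward cluster RPM
        assert out["piwil1_rpm"].iloc[0] == pytest.approx(40.5)

    def test_tiling_mismatch_rejected(self):
        p1 = make_window_table({"PIWIL1_IP": [1.0]}, unit="RPM")
        p3 = make_window_table({"PIWIL3_IP": [1.0, 2.0]}, unit="RPM")
        with pytest.raises(ValueError, match="tiling"):
            cl.call_oocyte_clusters(p1, p3, {}, {})


class TestClusterCallerEstimator:
    def test_get_set_params_round_trip(self):
        caller = cl.ClusterCaller(threshold=-1.5)
        params = caller.get_params()
        assert params["threshold"] == -1.5
        caller.set_params(max_gap=5000)
        assert caller.max_gap == 5000

    def test_fit_sets_fitted_attributes(self):
        design = make_design()
        values = {s: [50.0 if g == "WT" else 0.0] * 4
                  for s, g, _ in design.itertuples(index=False)}
        rpkm = make_window_table(values)
        caller = cl.ClusterCaller().fit(rpkm, design=design)
        assert hasattr(caller, "clusters_") and hasattr(caller, "window_labels_")
        assert caller.clusters_["stage"].tolist() == ["pre_pachytene"]
        assert caller.clusters_[["start", "end"]].values.tolist() == [[0, 4000]]
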