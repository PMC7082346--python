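"""Expression chain: FPKM, z-score, strandedness, clustering, fold change."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from virocell import expression as ex
from virocell import synthetic


def em(values: pd.DataFrame, provenance: str) -> ex.ExpressionMatrix:
    return ex.ExpressionMatrix(values, provenance)


class TestFpkm:
    def test_hand_formula(self):
        # 10 fragments, 1 kb gene, library of 1e6 fragments -> FPKM 10
        counts = ex.CountMatrix(
            values=pd.DataFrame(
                {"s1": [10, 1_000_000 - 10]}, index=["g1", "g2"]
            ),
            samples=pd.DataFrame(
                {"treatment": ["uninfected"], "time_min": [0], "replicate": [1]},
                index=["s1"],
            ),
        )
        ann = pd.DataFrame(
            {"length_bp": [1000, 1000], "stratum": ["host", "host"]},
            index=["g1", "g2"],
        )
        m = ex.fpkm(counts, ann)
        assert m.values.loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_count_zero_fpkm(self, small_counts):
        values, meta, ann = small_counts
        m = ex.fpkm(ex.CountMatrix(values, meta), ann)
        assert m.values.loc["p1", "u_t0_r1"] == 0.0

    def test_depth_invariance(self, small_counts):
        values, meta, ann = small_counts
        doubled = values.copy()
        doubled["i_t0_r1"] = 2 * doubled["i_t0_r1"]
        a = ex.fpkm(ex.CountMatrix(values, meta), ann)
        b = ex.fpkm(ex.CountMatrix(doubled, meta), ann)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_strata_normalized_separately(self, small_counts):
        values, meta, ann = small_counts
        m = ex.fpkm(ex.CountMatrix(values, meta), ann)
        # phage gene depth in infected r1 is its own 500 fragments, not 620
        assert m.values.loc["p1", "i_t0_r1"] == pytest.approx(
            500 / 0.5 / (500 / 1e6)
        )

    def test_zero_library_depth_names_sample(self, small_counts):
        values, meta, ann = small_counts
        values = values.copy()
        values["i_t0_r2"] = 0
        with pytest.raises(ValueError, match="i_t0_r2"):
            ex.fpkm(ex.CountMatrix(values, meta), ann)

    def test_missing_annotation_rejected(self, small_counts):
        values, meta, ann = small_counts
        with pytest.raises(ValueError, match="annotation"):
            ex.fpkm(ex.CountMatrix(values, meta), ann.drop("p1"))


class TestLog2AndZscore:
    def test_log2_values(self):
        m = ex.log2_transform(em(pd.DataFrame({"s": [0.0, 1.0, 15.0]}), "fpkm"))
        assert list(m.values["s"]) == pytest.approx([0.0, 1.0, 4.0])

    def test_log2_requires_fpkm_provenance(self):
        with pytest.raises(ValueError, match="provenance|derive"):
            ex.log2_transform(em(pd.DataFrame({"s": [1.0]}), "zscore"))

    def test_log2_rejects_negative(self):
        with pytest.raises(ValueError):
            ex.log2_transform(em(pd.DataFrame({"s": [-1.0]}), "fpkm"))

    def test_zscore_hand_example(self):
        m = ex.zscore_rows(em(pd.DataFrame([[1.0, 2.0, 3.0]]), "log2fpkm"))
        assert list(m.values.iloc[0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_zscore_constant_row_flagged(self):
        m = ex.zscore_rows(
            em(pd.DataFrame([[2.0, 2.0, 2.0]], index=["flat"]), "log2fpkm")
        )
        assert list(m.values.loc["flat"]) == [0.0, 0.0, 0.0]
        assert m.constant_rows == ["flat"]

    def test_zscore_row_moments(self, rng):
        m = ex.zscore_rows(em(pd.DataFrame(rng.normal(5, 2, (20, 8))), "log2fpkm"))
        assert np.abs(m.values.mean(axis=1)).max() < 1e-12
        assert np.abs(m.values.std(axis=1, ddof=1) - 1).max() < 1e-12


class TestStrandedness:
    @pytest.mark.parametrize(
        "rev,both,frac,passed",
        [(98, 100, 0.98, True), (100, 100, 1.0, True), (95, 100, 0.95, False)],
    )
    def test_fraction_and_threshold(self, rev, both, frac, passed):
        rep = ex.strandedness({"lib": rev}, {"lib": both})
        assert rep.table.loc["lib", "fraction"] == pytest.approx(frac)
        assert bool(rep.table.loc["lib", "passed"]) is passed

    def test_zero_mapped_reads_fails_with_reason(self):
        rep = ex.strandedness({"lib": 0}, {"lib": 0})
        assert not rep.all_passed
        assert rep.table.loc["lib", "reason"] == "no mapped reads"


def planted_profiles(n_per_group=10, noise=0.0, seed=0):
    """Three well-separated temporal shapes over six timepoints."""
    rng = np.random.default_rng(seed)
    shapes = np.array(
        [
            [1, 0.8, 0.4, 0.1, 0.0, 0.0],
            [0.0, 0.3, 1.0, 0.9, 0.3, 0.0],
            [0.0, 0.0, 0.1, 0.4, 0.8, 1.0],
        ]
    )
    rows, truth = [], []
    for g, shape in enumerate(shapes):
        for i in range(n_per_group):
            rows.append(shape * rng.uniform(0.5, 2.0) + rng.normal(0, noise, 6))
            truth.append(g)
    idx = [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=idx), pd.Series(truth, index=idx)


class TestTemporalCluster:
    def test_noiseless_two_groups_fully_stable(self):
        profiles, truth = planted_profiles(n_per_group=8)
        z = em(profiles[truth < 2], "zscore")
        tc = ex.temporal_cluster(z, n_clusters=2, b_resamples=25, seed=0)
        assert adjusted_rand_score(truth[truth < 2], tc.labels) == 1.0
        assert (tc.stability == 1.0).all()

    def test_determinism_under_seed(self):
        profiles, _ = planted_profiles(noise=0.15, seed=3)
        z = em(profiles, "zscore")
        a = ex.temporal_cluster(z, seed=42)
        b = ex.temporal_cluster(z, seed=42)
        pd.testing.assert_series_equal(a.labels, b.labels)
        pd.testing.assert_series_equal(a.stability, b.stability)

    def test_gene_order_permutation_invariance(self):
        profiles, _ = planted_profiles(noise=0.1, seed=5)
        shuffled = profiles.sample(frac=1.0, random_state=9)
        a = ex.temporal_cluster(em(profiles, "zscore"), seed=1)
        b = ex.temporal_cluster(em(shuffled, "zscore"), seed=1)
        joined = pd.concat(
            [a.labels.rename("a"), b.labels.rename("b")], axis=1
        )
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_zero_variance_gene_excluded(self):
        profiles, _ = planted_profiles()
        profiles.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            tc = ex.temporal_cluster(em(profiles, "zscore"), seed=0)
        assert "flat" not in tc.labels.index
        assert tc.excluded == ["flat"]

    def test_recovery_at_generator_noise(self):
        """Planted clusters recovered from NB-noised synthetic counts."""
        aris = []
        for seed in range(5):
            spec = synthetic.ExpressionSimSpec(seed=seed)
            counts, ann, truth = synthetic.synth_expression(spec)
            meta = counts.samples
            pg = ann.index[ann["stratum"] == "phage"]
            cols = meta.index[meta["treatment"] == "HP1"]
            with pytest.warns(UserWarning):
                fp = ex.fpkm(counts, ann)
            z = ex.zscore_rows(
                ex.log2_transform(em(fp.values.loc[pg, cols], "fpkm"))
            )
            tc = ex.temporal_cluster(z, seed=seed, times=meta.loc[cols, "time_min"])
            aris.append(
                adjusted_rand_score(truth.cluster_ids.loc[tc.labels.index], tc.labels)
            )
        assert np.mean(aris) >= 0.8

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            ex.temporal_cluster(em(pd.DataFrame(np.eye(4)[:, :2]), "zscore"))


class TestAssignStages:
    def test_peak_order_maps_to_stages(self):
        profiles, truth = planted_profiles(n_per_group=6)
        tc = ex.temporal_cluster(em(profiles, "zscore"), seed=0)
        tc = ex.assign_stages(tc, profiles)
        stage_of_gene = tc.labels.map(tc.stages)
        # group 0 peaks first, group 2 last
        assert (stage_of_gene[truth == 0] == "early").all()
        assert (stage_of_gene[truth == 1] == "middle").all()
        assert (stage_of_gene[truth == 2] == "late").all()

    def test_row_order_invariance(self):
        profiles, truth = planted_profiles(n_per_group=6, seed=2)
        rev = profiles.iloc[::-1]
        a = ex.assign_stages(
            ex.temporal_cluster(em(profiles, "zscore"), seed=0), profiles
        )
        b = ex.assign_stages(ex.temporal_cluster(em(rev, "zscore"), seed=0), rev)
        sa = a.labels.map(a.stages).sort_index()
        sb = b.labels.map(b.stages).sort_index()
        pd.testing.assert_series_equal(sa, sb)

    def test_requires_three_clusters(self):
        profiles, truth = planted_profiles()
        tc = ex.temporal_cluster(em(profiles, "zscore"), n_clusters=4, seed=0)
        with pytest.raises(ValueError, match="3 clusters"):
            ex.assign_stages(tc, profiles)

    def test_indistinguishable_clusters_demand_manual_labels(self):
        # two clusters with byte-identical centroids cannot be staged
        profiles = pd.DataFrame(
            [[1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0], [0, 0.0, 1], [0, 0, 1.0]],
            index=list("abcdef"),
        )
        tc = ex.TemporalClusterAssignment(
            labels=pd.Series([1, 2, 1, 2, 3, 3], index=list("abcdef")),
            stability=pd.Series(1.0, index=list("abcdef")),
            stages={},
            params={},
        )
        with pytest.raises(ValueError, match="manual"):
            ex.assign_stages(tc, profiles)


class TestAdjustedFoldChange:
    def test_f_one_reduces_to_plain_ratio(self):
        inf = pd.DataFrame({0: [15.0]}, index=["g"])
        ctl = pd.DataFrame({0: [10.0]}, index=["g"])
        fc = ex.adjusted_fold_change(inf, ctl, 1.0)
        assert fc.log2fc.loc["g", 0] == pytest.approx(np.log2(16 / 11))

    def test_hand_mixture_example(self):
        # X_I=15, X_U=10, f=0.5 -> X_v = (15 - 5)/0.5 = 20, log2(21/11)
        inf = pd.DataFrame({0: [15.0]}, index=["g"])
        ctl = pd.DataFrame({0: [10.0]}, index=["g"])
        fc = ex.adjusted_fold_change(inf, ctl, 0.5)
        assert fc.log2fc.loc["g", 0] == pytest.approx(np.log2(21 / 11), abs=1e-12)

    def test_equal_means_no_direction(self):
        inf = pd.DataFrame({0: [10.0]}, index=["g"])
        fc = ex.adjusted_fold_change(inf, inf.copy(), 0.7)
        assert fc.log2fc.loc["g", 0] == 0.0
        assert fc.direction.loc["g", 0] == "none"

    def test_direction_follows_sign(self):
        inf = pd.DataFrame({0: [40.0, 2.0]}, index=["up", "down"])
        ctl = pd.DataFrame({0: [10.0, 10.0]}, index=["up", "down"])
        fc = ex.adjusted_fold_change(inf, ctl, 1.0)
        assert fc.direction.loc["up", 0] == "over"
        assert fc.direction.loc["down", 0] == "under"

    def test_deconvolved_signal_floored_at_zero(self):
        inf = pd.DataFrame({0: [1.0]}, index=["g"])
        ctl = pd.DataFrame({0: [10.0]}, index=["g"])
        fc = ex.adjusted_fold_change(inf, ctl, 0.5)  # raw X_v would be -8
        assert fc.log2fc.loc["g", 0] == pytest.approx(np.log2(1 / 11))

    def test_f_zero_rejected(self):
        inf = pd.DataFrame({0: [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            ex.adjusted_fold_change(inf, inf.copy(), 0.0)

    def test_noiseless_truth_recovery(self):
        """Mixture construction and deconvolution are exact inverses."""
        spec = synthetic.ExpressionSimSpec(seed=3, dispersion=0.0)
        counts, ann, truth = synthetic.synth_expression(spec)
        meta = counts.samples
        hg = ann.index[ann["stratum"] == "host"]
        means = {}
        for trt in ("HP1", "uninfected"):
            means[trt] = pd.DataFrame(
                {
                    t: counts.values.loc[
                        hg, meta.index[(meta["treatment"] == trt) & (meta["time_min"] == t)]
                    ].mean(axis=1)
                    for t in spec.time_points
                }
            )
        fc = ex.adjusted_fold_change(
            means["HP1"], means["uninfected"], truth.infected_fraction
        )
        assert (fc.log2fc - truth.true_log2fc).abs().max().max() < 0.05


class TestClassifyDePanel:
    def _fc(self, genes, de, times=(0, 30)):
        vals = pd.DataFrame(0.0, index=genes, columns=list(times))
        for g in de:
            vals.loc[g, times[-1]] = 2.0
        f = pd.Series(1.0, index=list(times))
        direction = pd.DataFrame(
            np.where(vals > 0, "over", "none"), index=vals.index, columns=vals.columns
        )
        return ex.FoldChangeTable(vals, f, direction)

    def test_disjoint_sets(self):
        genes = list("abc")
        panel = ex.classify_de_panel(
            {"HP1": self._fc(genes, ["a", "b"]), "HS2": self._fc(genes, ["c"])}
        )
        assert panel.shared == set()
        assert panel.unique["HP1"] == {"a", "b"} and panel.unique["HS2"] == {"c"}

    def test_identical_sets(self):
        genes = list("abcd")
        panel = ex.classify_de_panel(
            {"HP1": self._fc(genes, ["a", "b"]), "HS2": self._fc(genes, ["a", "b"])}
        )
        assert panel.shared == {"a", "b"} == panel.de_sets["HP1"]

    def test_known_overlap_from_external_calls(self):
        genes = [f"g{i}" for i in range(100)]
        hp1 = set(genes[:70])
        hs2 = set(genes[28:])  # overlap genes 28..69 -> 42 genes
        panel = ex.classify_de_panel(
            {"HP1": self._fc(genes, []), "HS2": self._fc(genes, [])},
            de_calls={"HP1": hp1, "HS2": hs2},
        )
        assert len(panel.shared) == 42
        assert panel.counts()["frac_shared"] == pytest.approx(0.42)

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ex.classify_de_panel(
                {"HP1": self._fc(list("ab"), []), "HS2": self._fc(list("abc"), [])}
            )
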