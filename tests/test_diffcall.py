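import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methclust import (
    ProbeAnnotation,
    aggregate_genes,
    centroid_classifier,
    intersect_pairs,
    probe_deltas,
    region_breakdown,
)
from methclust.diffcall import GeneCall

from conftest import constant_pair_bm, make_bm


class TestProbeDeltas:
    def test_delta_at_threshold_is_hyper(self, pair_groups):
        bm = constant_pair_bm(pair_groups, ["cg1"], [0.10], [0.35])
        (d,) = probe_deltas(bm, "par", "agg")
        assert d.delta == pytest.approx(0.25) and d.hyper

    def test_delta_below_threshold_not_hyper(self, pair_groups):
        bm = constant_pair_bm(pair_groups, ["cg1"], [0.10], [0.29])
        (d,) = probe_deltas(bm, "par", "agg")
        assert d.delta == pytest.approx(0.19) and not d.hyper

    def test_exact_boundary_counts(self, pair_groups):
        bm = constant_pair_bm(pair_groups, ["cg1"], [0.10], [0.30])
        (d,) = probe_deltas(bm, "par", "agg")
        assert d.hyper  # median difference >= 0.2 qualifies

    def test_single_failing_replicate_excludes_probe(self, pair_groups):
        detp = pd.DataFrame(
            0.001, index=["cg1"], columns=list(pair_groups)
        )
        detp.loc["cg1", "agg_r2"] = 0.02
        bm = constant_pair_bm(pair_groups, ["cg1"], [0.10], [0.50], detp=detp)
        (d,) = probe_deltas(bm, "par", "agg")
        assert d.delta == pytest.approx(0.40)
        assert not d.passes_detection and not d.hyper

    def test_median_over_replicates(self, pair_groups):
        values = {
            "par_r1": [0.1], "par_r2": [0.2], "par_r3": [0.3],
            "agg_r1": [0.5], "agg_r2": [0.6], "agg_r3": [0.9],
        }
        bm = make_bm(values, ["cg1"], pair_groups)
        (d,) = probe_deltas(bm, "par", "agg")
        assert d.median_parental == pytest.approx(0.2)
        assert d.median_aggressive == pytest.approx(0.6)

    def test_unknown_line_label(self, pair_groups):
        bm = constant_pair_bm(pair_groups, ["cg1"], [0.1], [0.5])
        with pytest.raises(KeyError):
            probe_deltas(bm, "par", "nonexistent")

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, width=32, allow_nan=False),
                st.floats(0, 1, width=32, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        )
    )
    def test_antisymmetric_in_line_order(self, pair_groups, betas):
        par = [b[0] for b in betas]
        agg = [b[1] for b in betas]
        probes = [f"cg{i}" for i in range(len(betas))]
        bm = constant_pair_bm(pair_groups, probes, par, agg)
        fwd = probe_deltas(bm, "par", "agg")
        rev = probe_deltas(bm, "agg", "par")
        for a, b in zip(fwd, rev):
            assert a.delta == pytest.approx(-b.delta, abs=1e-12)


class TestAggregateGenes:
    def _deltas(self, pair_groups, ann, agg_vals):
        probes = [a.probe_id for a in ann]
        bm = constant_pair_bm(pair_groups, probes, [0.1] * len(probes), agg_vals)
        return probe_deltas(bm, "par", "agg")

    def test_three_hyper_cpgs_calls_gene(self, pair_groups, simple_ann):
        # GA: 3 hyper promoter probes; GB: none
        agg = [0.5, 0.5, 0.5, 0.1, 0.1, 0.1, 0.1, 0.1]
        calls = {c.gene: c for c in aggregate_genes(self._deltas(pair_groups, simple_ann, agg), simple_ann)}
        assert calls["GA"].hyper_gene and calls["GA"].n_hyper_cpgs == 3
        assert "GB" not in calls

    def test_two_hyper_cpgs_insufficient(self, pair_groups, simple_ann):
        agg = [0.5, 0.5, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        calls = {c.gene: c for c in aggregate_genes(self._deltas(pair_groups, simple_ann, agg), simple_ann)}
        assert not calls["GA"].hyper_gene

    def test_min_cpgs_one(self, pair_groups, simple_ann):
        agg = [0.5, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        calls = {c.gene: c for c in aggregate_genes(
            self._deltas(pair_groups, simple_ann, agg), simple_ann, min_cpgs=1)}
        assert calls["GA"].hyper_gene

    def test_promoter_only_ignores_body(self, pair_groups, simple_ann):
        # GA hyper at 2 promoter + 1 body probe -> 2 counted with promoter_only
        agg = [0.5, 0.5, 0.1, 0.5, 0.1, 0.1, 0.1, 0.1]
        calls = {c.gene: c for c in aggregate_genes(
            self._deltas(pair_groups, simple_ann, agg), simple_ann, promoter_only=True)}
        assert calls["GA"].n_hyper_cpgs == 2 and not calls["GA"].hyper_gene

    def test_probe_missing_from_annotation(self, pair_groups, simple_ann):
        bm = constant_pair_bm(pair_groups, ["cgUNKNOWN"], [0.1], [0.5])
        with pytest.raises(KeyError, match="cgUNKNOWN"):
            aggregate_genes(probe_deltas(bm, "par", "agg"), simple_ann)


class TestIntersectPairs:
    def mk(self, gene, hyper=True):
        return GeneCall(gene, "p", 3, hyper, ("cg1", "cg2", "cg3"))

    def test_intersection(self):
        calls = {
            "A": [self.mk("g1"), self.mk("g2")],
            "B": [self.mk("g2"), self.mk("g3")],
            "C": [self.mk("g2")],
        }
        assert list(intersect_pairs(calls)) == ["g2"]

    def test_disjoint_pairs_empty_not_error(self):
        calls = {"A": [self.mk("g1")], "B": [self.mk("g2")]}
        assert intersect_pairs(calls) == {}

    def test_empty_map_is_error(self):
        with pytest.raises(ValueError):
            intersect_pairs({})

    def test_single_pair_degenerate_warns(self):
        with pytest.warns(UserWarning):
            out = intersect_pairs({"A": [self.mk("g1")]})
        assert list(out) == ["g1"]

    def test_supporting_probes_retained_per_pair(self):
        calls = {
            "A": [GeneCall("g", "A", 3, True, ("a1", "a2", "a3"))],
            "B": [GeneCall("g", "B", 4, True, ("b1", "b2", "b3", "b4"))],
        }
        out = intersect_pairs(calls)
        assert out["g"]["A"] == ("a1", "a2", "a3")
        assert out["g"]["B"] == ("b1", "b2", "b3", "b4")


class TestRegionBreakdown:
    def test_one_cpg_per_class(self, pair_groups):
        ann = [
            ProbeAnnotation("cg1", "1", 100, ("G",), ("TSS200",)),
            ProbeAnnotation("cg2", "1", 200, ("G",), ("Body",)),
            ProbeAnnotation("cg3", "1", 300, ("G",), ("3UTR",)),
        ]
        bm = constant_pair_bm(pair_groups, ["cg1", "cg2", "cg3"], [0.1] * 3, [0.5] * 3)
        bd = region_breakdown(["G"], probe_deltas(bm, "par", "agg"), ann)
        assert bd["count"].tolist() == [1, 1, 1]
        assert bd["fraction"].sum() == pytest.approx(1.0)

    def test_5utr_and_first_exon_count_as_promoter(self, pair_groups):
        ann = [
            ProbeAnnotation("cg1", "1", 100, ("G",), ("5UTR",)),
            ProbeAnnotation("cg2", "1", 200, ("G",), ("1stExon",)),
        ]
        bm = constant_pair_bm(pair_groups, ["cg1", "cg2"], [0.1] * 2, [0.5] * 2)
        bd = region_breakdown(["G"], probe_deltas(bm, "par", "agg"), ann)
        assert bd.loc["promoter", "count"] == 2

    def test_no_hyper_cpgs_all_zero(self, pair_groups):
        ann = [ProbeAnnotation("cg1", "1", 100, ("G",), ("Body",))]
        bm = constant_pair_bm(pair_groups, ["cg1"], [0.1], [0.15])
        bd = region_breakdown(["G"], probe_deltas(bm, "par", "agg"), ann)
        assert bd["count"].sum() == 0 and bd["fraction"].sum() == 0

    def test_counts_sum_to_classified_cpgs(self, pair_groups, simple_ann):
        probes = [a.probe_id for a in simple_ann]
        bm = constant_pair_bm(pair_groups, probes, [0.1] * 8, [0.5] * 8)
        deltas = probe_deltas(bm, "par", "agg")
        bd = region_breakdown(["GA", "GB"], deltas, simple_ann)
        assert bd["count"].sum() == 8
        assert bd["fraction"].sum() == pytest.approx(1.0, abs=1e-12)


class TestCentroidClassifier:
    def _two_group_bm(self, g0_beta, g1_beta, probes=("cg1",), n=3, noise=None, seed=0):
        rng = np.random.default_rng(seed)
        groups, values = {}, {}
        for line, base in (("L0", g0_beta), ("L1", g1_beta)):
            for r in range(n):
                sid = f"{line}_r{r}"
                groups[sid] = (line, r)
                eps = rng.normal(0, noise, len(probes)) if noise else 0.0
                values[sid] = np.clip(np.asarray(base, dtype=float) + eps, 0, 1)
        return make_bm(values, list(probes), groups)

    def test_z_score_formula(self):
        # group means 0.1 vs 0.5, pooled sd 0.05 -> marker with z = +8
        bm = self._two_group_bm([0.1], [0.5])
        bm.beta.loc["cg1"] = [0.05, 0.10, 0.15, 0.45, 0.50, 0.55]
        model = centroid_classifier(bm, ("L0", "L1"))
        assert model.marker_probes == ("cg1",)
        assert model.z_scores["cg1"] == pytest.approx(0.4 / 0.05)

    def test_identical_means_not_marker(self):
        bm = self._two_group_bm([0.3], [0.3])
        model = centroid_classifier(bm, ("L0", "L1"))
        assert model.marker_probes == ()

    def test_zero_variance_gives_signed_infinity(self):
        bm = self._two_group_bm([0.1], [0.6])
        model = centroid_classifier(bm, ("L0", "L1"))
        assert model.marker_probes == ("cg1",)
        assert np.isposinf(model.z_scores["cg1"])

    def test_training_data_perfectly_classified_at_m0(self):
        bm = self._two_group_bm([0.2] * 5, [0.6] * 5, probes=[f"cg{i}" for i in range(5)],
                                noise=0.02, seed=1)
        model = centroid_classifier(bm, ("L0", "L1"))
        for line in ("L0", "L1"):
            for s in bm.samples_of(line):
                assert model.assign(bm.beta[s]) == line

    def test_held_out_assignment_recovers_planted_separation(self):
        probes = [f"cg{i}" for i in range(10)]
        bm = self._two_group_bm([0.2] * 10, [0.7] * 10, probes=probes, n=4,
                                noise=0.03, seed=2)
        model = centroid_classifier(bm, ("L0", "L1"))
        rng = np.random.default_rng(3)
        for label, base in (("L0", 0.2), ("L1", 0.7)):
            for _ in range(20):
                s = pd.Series(np.clip(base + rng.normal(0, 0.03, 10), 0, 1), index=probes)
                assert model.assign(s) == label

    def test_needs_two_samples_per_group(self):
        groups = {"a1": ("L0", 1), "b1": ("L1", 1)}
        bm = make_bm({"a1": [0.1], "b1": [0.5]}, ["cg1"], groups)
        with pytest.raises(ValueError):
            centroid_classifier(bm, ("L0", "L1"))
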