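"""Transcript taxonomy, set intersections and histotype contrasts."""

import numpy as np
import pandas as pd
import pytest

from chromotx import classify
from chromotx.classify import ThresholdConfig


def contrast_frame(rows):
    """rows: {gene: (linear_fc, adjp)}"""
    frame = pd.DataFrame(
        {
            "linear_fc": {g: v[0] for g, v in rows.items()},
            "adjp": {g: v[1] for g, v in rows.items()},
        }
    )
    frame.index.name = "gene_id"
    return frame


class TestClassification:
    def test_overupt_conjunction(self):
        vs_ctrl = contrast_frame({"g1": (1.4, 0.01)})
        vs_n = contrast_frame({"g1": (1.2, 0.04)})
        flags = classify.classify_transcripts(vs_ctrl, vs_n)
        assert flags.loc["g1", ["OverT", "UpT", "OverUpT"]].all()
        assert not flags.loc["g1", ["UnderT", "DownT", "OverDownT"]].any()

    def test_boundary_fc_excluded_by_strict_inequality(self):
        vs_ctrl = contrast_frame({"g1": (1.3, 0.001)})
        flags = classify.classify_transcripts(vs_ctrl)
        assert not flags.loc["g1"].any()

    def test_under_and_down(self):
        vs_ctrl = contrast_frame({"g1": (-1.4, 0.02)})
        vs_n = contrast_frame({"g1": (-1.2, 0.03)})
        flags = classify.classify_transcripts(vs_ctrl, vs_n)
        assert flags.loc["g1", "UnderT"] and flags.loc["g1", "DownT"]
        assert not flags.loc["g1", ["OverT", "UpT", "OverUpT", "OverDownT"]].any()

    def test_flag_exclusivity_invariants_on_random_contrasts(self, rng):
        genes = [f"g{i}" for i in range(500)]
        fc = np.where(rng.random(500) < 0.5, 1, -1) * np.exp(rng.normal(0.3, 0.6, 500))
        fc = np.where(np.abs(fc) < 1, np.sign(fc) / np.abs(fc), fc)
        vs_ctrl = contrast_frame(dict(zip(genes, zip(fc, rng.random(500)))))
        fc2 = np.where(rng.random(500) < 0.5, 1, -1) * np.exp(rng.normal(0.3, 0.6, 500))
        fc2 = np.where(np.abs(fc2) < 1, np.sign(fc2) / np.abs(fc2), fc2)
        vs_n = contrast_frame(dict(zip(genes, zip(fc2, rng.random(500)))))
        flags = classify.classify_transcripts(vs_ctrl, vs_n)
        assert not (flags["OverT"] & flags["UnderT"]).any()
        assert not (flags["UpT"] & flags["DownT"]).any()
        assert (flags["OverUpT"] <= (flags["OverT"] & flags["UpT"])).all()
        assert (flags["OverDownT"] <= (flags["OverT"] & flags["DownT"])).all()

    def test_mismatched_universes_rejected(self):
        vs_ctrl = contrast_frame({"g1": (1.4, 0.01)})
        vs_n = contrast_frame({"g2": (1.4, 0.01)})
        with pytest.raises(ValueError, match="universes"):
            classify.classify_transcripts(vs_ctrl, vs_n)


class TestModifiedFC:
    @pytest.mark.parametrize(
        "fc,expected", [(1.5, 0.5), (-1.5, -0.5), (1.0, 0.0), (-1.0, 0.0), (3.2, 2.2)]
    )
    def test_values(self, fc, expected):
        assert classify.modified_fc(fc) == pytest.approx(expected)

    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            classify.modified_fc(0.5)


class TestStrictDegs:
    annotation = pd.DataFrame(
        {
            "gene_id": ["a", "b", "c"],
            "gene_name": ["a", "b", "c"],
            "chrom": ["1", "5", "16"],
            "arm": ["q", "q", "q"],
            "cytoband": ["1q21", "5q11", "16q22"],
            "start": [0, 0, 0],
            "end": [10, 10, 10],
        }
    )

    def test_chromosome_filter_and_thresholds(self):
        vs_ctrl = contrast_frame(
            {"a": (1.4, 0.0005), "b": (2.0, 1e-6), "c": (-1.2, 1e-6)}
        )
        out = classify.select_strict_degs(vs_ctrl, self.annotation)
        # b passes thresholds but sits on chr5; c is inside the FC gap
        assert list(out.index) == ["a"]
        assert out.loc["a", "modified_fc"] == pytest.approx(0.4)

    def test_matches_brute_force_filter(self, rng):
        genes = [f"g{i}" for i in range(200)]
        chroms = rng.choice(["1", "5", "16"], 200)
        ann = pd.DataFrame(
            {
                "gene_id": genes,
                "gene_name": genes,
                "chrom": chroms,
                "arm": ["q"] * 200,
                "cytoband": [f"{c}q11" for c in chroms],
                "start": [0] * 200,
                "end": [10] * 200,
            }
        )
        fc = np.where(rng.random(200) < 0.5, 1, -1) * np.exp(rng.normal(0.4, 0.5, 200))
        fc = np.where(np.abs(fc) < 1, np.sign(fc) / np.abs(fc), fc)
        adjp = rng.random(200) * 0.01
        vs_ctrl = contrast_frame(dict(zip(genes, zip(fc, adjp))))
        out = classify.select_strict_degs(vs_ctrl, ann)
        expected = {
            g
            for g, f, p, c in zip(genes, fc, adjp, chroms)
            if abs(f) > 1.3 and p < 0.001 and c in ("1", "16")
        }
        assert set(out.index) == expected


class TestSharedSets:
    def test_inclusive_intersection(self):
        sets = {"A": {"g1", "g2", "g3"}, "B1": {"g2", "g3"}, "C": {"g3"}}
        venn = classify.shared_gene_sets(sets)
        assert venn.loc["A&B1&C", "n_inclusive"] == 1
        assert venn.loc["A&B1", "n_inclusive"] == 2

    def test_disjoint_sets_have_empty_cells(self):
        sets = {"A": {"g1"}, "B": {"g2"}, "C": {"g3"}}
        venn = classify.shared_gene_sets(sets)
        multi = venn[venn.index.str.contains("&")]
        assert (multi["n_inclusive"] == 0).all()

    def test_identical_sets_concentrate_in_full_cell(self):
        sets = {"A": {"g1", "g2"}, "B": {"g1", "g2"}}
        venn = classify.shared_gene_sets(sets)
        assert venn.loc["A&B", "n_exclusive"] == 2
        assert venn.loc["A", "n_exclusive"] == 0

    def test_exclusive_regions_partition_union(self, rng):
        universe = [f"g{i}" for i in range(60)]
        sets = {
            name: set(rng.choice(universe, size=rng.integers(5, 40), replace=False))
            for name in ("A", "B", "C", "D")
        }
        venn = classify.shared_gene_sets(sets)
        assert venn["n_exclusive"].sum() == len(set().union(*sets.values()))

    def test_core_gene_set(self):
        sets = {"A": {"x", "y"}, "B": {"x", "y"}, "C": {"x"}, "D": {"x", "z"}}
        assert classify.core_gene_set(sets) == {"x"}
        with pytest.raises(ValueError, match="E"):
            classify.core_gene_set(sets, designated=("A", "E"))


class TestOverUnderSummary:
    def test_published_count_arithmetic(self):
        """756 OverT / 180 UnderT give ratio 4.20; 634 shared of a 756-gene
        reference is 83.86%; the reference row itself reads 100%."""
        ref_over = {f"o{i}" for i in range(756)}
        ref_under = {f"u{i}" for i in range(180)}
        b1_over = {f"o{i}" for i in range(634)} | {f"b{i}" for i in range(737 - 634)}
        b1_under = {f"u{i}" for i in range(130)} | {f"v{i}" for i in range(50)}
        table = classify.summarize_over_under(
            {
                "A": {"OverT": ref_over, "UnderT": ref_under},
                "B1": {"OverT": b1_over, "UnderT": b1_under},
            },
            reference="A",
        )
        assert table.loc["A", "ratio"] == 4.20
        assert table.loc["A", "pct_overt_of_ref"] == 100.0
        assert table.loc["B1", "pct_overt_of_ref"] == 83.86
        assert table.loc["B1", "n_overt"] == 737

    def test_zero_undert_ratio_undefined(self):
        table = classify.summarize_over_under(
            {"A": {"OverT": {f"g{i}" for i in range(10)}, "UnderT": set()}},
            reference="A",
        )
        assert np.isnan(table.loc["A", "ratio"])


class TestLobularVsDuctal:
    def test_marker_detected_and_precondition_enforced(self, small_cohort):
        cohort = small_cohort
        marker = cohort.gene_truth.index[cohort.gene_truth["lobular_marker"]][0]
        meta = cohort.metadata
        groups = {
            "A": cohort.group_samples("A"),
            "B1": cohort.group_samples("B1"),
            "D": cohort.group_samples("D1") + cohort.group_samples("D2"),
        }
        found = {}
        for group, samples in groups.items():
            res = classify.lobular_vs_ductal_degs(
                cohort.counts, meta["histotype"], samples
            )
            found[group] = res
            assert marker in res.index and res.loc[marker, "direction"] == "decreased"
        inter = classify.coherent_lvsd_intersection(found)
        assert marker in inter
        # B2 has no lobular samples by construction
        with pytest.raises(ValueError, match="lobular"):
            classify.lobular_vs_ductal_degs(
                cohort.counts, meta["histotype"], cohort.group_samples("B2")
            )

    def test_permuted_histotypes_give_empty_intersection(self, small_cohort):
        cohort = small_cohort
        rng = np.random.default_rng(99)
        hits = 0
        n_rounds = 5
        for _ in range(n_rounds):
            permuted = cohort.metadata["histotype"].copy()
            tumor = cohort.metadata["is_tumor"]
            vals = permuted[tumor].to_numpy()
            rng.shuffle(vals)
            permuted.loc[tumor] = vals
            groups = {
                "A": cohort.group_samples("A"),
                "B1": cohort.group_samples("B1"),
                "D": cohort.group_samples("D1") + cohort.group_samples("D2"),
            }
            found = {}
            for group, samples in groups.items():
                try:
                    found[group] = classify.lobular_vs_ductal_degs(
                        cohort.counts, permuted, samples
                    )
                except ValueError:
                    found[group] = pd.DataFrame(columns=["direction"])
            if classify.coherent_lvsd_intersection(found):
                hits += 1
        assert hits == 0
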