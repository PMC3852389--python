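import itertools

import numpy as np
import pytest

from salmap.comparative import (
    assign_arms,
    compare_order,
    infer_structure,
    pair_homeologs,
    summarize_comparison,
)
from salmap.io import DonorAnnotation, DonorChromosome, MarkerDef
from salmap.mapping import GenomeMap, LinkageGroup


def _map(groups: dict[str, list[str]]) -> GenomeMap:
    lgs = [
        LinkageGroup(
            id=gid,
            markers=markers,
            distances=[10.0] * (len(markers) - 1),
            map_function="kosambi",
            source="consensus",
        )
        for gid, markers in groups.items()
    ]
    return GenomeMap(groups=lgs, unassigned=[], map_function="kosambi", source="consensus")


def _ann(arm_label, centromere=False, homeolog=False, pos=None):
    return DonorAnnotation(
        donor_group=arm_label[:-1],
        arm=arm_label[-1],
        centromere=centromere,
        homeolog=homeolog,
        donor_pos=pos,
    )


class TestArmAssignment:
    def test_two_arms_confirmed_at_min_support(self):
        gmap = _map({"G1": ["a", "b", "c", "d", "e"]})
        ann = {
            "a": _ann("Omy21p"),
            "b": _ann("Omy21p"),
            "c": _ann("Omy21p"),
            "d": _ann("Omy21q"),
            "e": _ann("Omy21q"),
        }
        asg = assign_arms(gmap, ann)["G1"]
        assert asg.confirmed_arms == ["Omy21p", "Omy21q"]

    def test_centromere_markers_excluded(self):
        gmap = _map({"G1": ["a", "b"]})
        ann = {"a": _ann("Omy5p", centromere=True)}
        asg = assign_arms(gmap, ann)["G1"]
        assert asg.hits == [] and asg.excluded_centromere == 1

    def test_homeolog_flagged_markers_excluded(self):
        gmap = _map({"G1": ["a", "b", "c"]})
        ann = {"a": _ann("Omy5p", homeolog=True), "b": _ann("Omy5p"), "c": _ann("Omy5p")}
        asg = assign_arms(gmap, ann)["G1"]
        assert [h.count for h in asg.hits] == [2]
        assert asg.excluded_homeolog == 1

    def test_single_marker_arm_is_putative(self):
        markers = [f"m{i}" for i in range(10)]
        gmap = _map({"G1": markers})
        ann = {m: _ann("Omy11q") for m in markers[:9]}
        ann[markers[9]] = _ann("Omy11p")
        hits = assign_arms(gmap, ann)["G1"].hits
        assert [(h.donor_arm, h.support) for h in hits] == [
            ("Omy11q", "confirmed"),
            ("Omy11p", "putative_single_marker"),
        ]


class TestStructure:
    def _calls(self, arm_sets):
        gmap = _map(
            {f"G{i}": [f"g{i}m{j}" for j in range(len(arms) * 2)] for i, arms in enumerate(arm_sets)}
        )
        ann = {}
        for i, arms in enumerate(arm_sets):
            for j, arm in enumerate(arms):
                ann[f"g{i}m{2 * j}"] = _ann(arm)
                ann[f"g{i}m{2 * j + 1}"] = _ann(arm)
        return infer_structure(assign_arms(gmap, ann))

    def test_multiple_arms_call_metacentric(self):
        calls = self._calls([["Omy11p", "Omy11q", "Omy26a"]])
        assert calls["G0"].call == "metacentric"
        assert calls["G0"].arms == ["Omy11p", "Omy11q", "Omy26a"]

    def test_single_arm_calls_acrocentric(self):
        assert self._calls([["Omy4a"]])["G0"].call == "acrocentric"

    def test_no_annotation_is_unresolved(self):
        gmap = _map({"G1": ["a", "b"]})
        calls = infer_structure(assign_arms(gmap, {}))
        assert calls["G1"].call == "unresolved"

    def test_putative_metacentric_tracked(self):
        markers = [f"m{i}" for i in range(10)]
        gmap = _map({"G1": markers})
        ann = {m: _ann("Omy11q") for m in markers[:9]}
        ann[markers[9]] = _ann("Omy11p")
        calls = infer_structure(assign_arms(gmap, ann))
        assert calls["G1"].call == "metacentric" and calls["G1"].putative


class TestHomeologs:
    def _markers(self, names):
        return [MarkerDef(name=n) for n in names]

    def test_supporting_counts_accumulate(self):
        gmap = _map(
            {"G1": ["x1/i", "x2/i", "x3/i"], "G2": ["x1/ii", "x2/ii", "x3/ii"]}
        )
        pairs, anomalies = pair_homeologs(
            gmap, self._markers(["x1/i", "x1/ii", "x2/i", "x2/ii", "x3/i", "x3/ii"])
        )
        assert len(pairs) == 1
        assert pairs[0].count == 3 and not pairs[0].single_support
        assert anomalies == []

    def test_single_marker_pair_flagged(self):
        gmap = _map({"G1": ["y/i", "a"], "G2": ["y/ii", "b"]})
        pairs, _ = pair_homeologs(gmap, self._markers(["y/i", "y/ii"]))
        assert pairs[0].single_support

    def test_same_group_copies_reported_as_anomaly(self):
        gmap = _map({"G1": ["z/i", "z/ii"]})
        pairs, anomalies = pair_homeologs(gmap, self._markers(["z/i", "z/ii"]))
        assert pairs == [] and anomalies == ["z"]

    def test_unpaired_duplicates_ignored(self):
        gmap = _map({"G1": ["w/i", "a"]})
        pairs, anomalies = pair_homeologs(gmap, self._markers(["w/i"]))
        assert pairs == [] and anomalies == []


class TestOrderComparison:
    def _group(self, markers):
        return LinkageGroup(
            id="G1",
            markers=markers,
            distances=[5.0] * (len(markers) - 1),
            map_function="kosambi",
            source="consensus",
        )

    def test_identical_orders_fully_concordant(self):
        markers = [f"m{i}" for i in range(6)]
        ann = {m: _ann("Omy1q", pos=i / 10) for i, m in enumerate(markers)}
        res = compare_order(self._group(markers), ann, "Omy1q")
        assert res.concordance == pytest.approx(1.0)
        assert res.breakpoints == 0 and res.inverted_block is None

    def test_global_reversal_still_concordant(self):
        markers = [f"m{i}" for i in range(6)]
        ann = {m: _ann("Omy1q", pos=i / 10) for i, m in enumerate(markers)}
        res = compare_order(self._group(markers[::-1]), ann, "Omy1q")
        assert res.concordance == pytest.approx(1.0)
        assert res.inverted_block is None

    def test_inverted_run_detected_and_matches_brute_force(self):
        markers = [f"m{i}" for i in range(8)]
        pos = [0.0, 0.1, 0.5, 0.4, 0.3, 0.2, 0.6, 0.7]  # markers 2-5 reversed
        ann = {m: _ann("Omy1q", pos=p) for m, p in zip(markers, pos)}
        res = compare_order(self._group(markers), ann, "Omy1q")
        assert res.inverted_block is not None
        block, span = res.inverted_block
        assert block == ["m2", "m3", "m4", "m5"]
        assert span == pytest.approx(15.0)  # 3 x 5 cM between block ends
        assert res.breakpoints == 2

        # brute force over contiguous runs as an independent check
        order = np.argsort(np.argsort(pos))
        best = None
        for i, j in itertools.combinations(range(len(pos) + 1), 2):
            if j - i >= 3 and all(
                order[k + 1] == order[k] - 1 for k in range(i, j - 1)
            ):
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
        assert best == (2, 6)

    def test_too_few_shared_markers_is_undefined(self):
        ann = {"a": _ann("Omy1q", pos=0.1), "b": _ann("Omy1q", pos=0.2)}
        res = compare_order(self._group(["a", "b"]), ann, "Omy1q")
        assert res.concordance is None


class TestSummary:
    def _donor(self):
        return {
            "Omy21": DonorChromosome("Omy21", "metacentric", ("Omy21p", "Omy21q")),
            "Omy02": DonorChromosome("Omy02", "metacentric", ("Omy02p", "Omy02q")),
            "Omy30": DonorChromosome("Omy30", "acrocentric", ("Omy30a",)),
        }

    def test_conserved_fission_and_arm_totals(self):
        gmap = _map(
            {
                "G1": ["a1", "a2", "b1", "b2"],  # conserved metacentric
                "G2": ["c1", "c2"],  # one arm of Omy02
                "G3": ["d1", "d2"],  # other arm of Omy02 -> fission
                "G4": ["e1", "e2"],  # conserved acrocentric
            }
        )
        ann = {
            "a1": _ann("Omy21p"), "a2": _ann("Omy21p"),
            "b1": _ann("Omy21q"), "b2": _ann("Omy21q"),
            "c1": _ann("Omy02p"), "c2": _ann("Omy02p"),
            "d1": _ann("Omy02q"), "d2": _ann("Omy02q"),
            "e1": _ann("Omy30a"), "e2": _ann("Omy30a"),
        }
        assignments = assign_arms(gmap, ann)
        structures = infer_structure(assignments)
        summary = summarize_comparison(structures, assignments, self._donor())
        assert summary.conserved_chromosomes == [("G1", "Omy21"), ("G4", "Omy30")]
        assert summary.fissions == ["Omy02"]
        assert summary.fusions == []
        assert summary.haploid_arm_number == 5
        assert summary.n_metacentric == 1 and summary.n_acrocentric == 3

    def test_fusion_of_two_donor_chromosomes(self):
        gmap = _map({"G1": ["a1", "a2", "b1", "b2"]})
        ann = {
            "a1": _ann("Omy21p"), "a2": _ann("Omy21p"),
            "b1": _ann("Omy30a"), "b2": _ann("Omy30a"),
        }
        assignments = assign_arms(gmap, ann)
        summary = summarize_comparison(
            infer_structure(assignments), assignments, self._donor()
        )
        assert summary.fusions == ["G1"]
        assert summary.conserved_chromosomes == []


class TestRecoveryOnSimulatedFamily:
    def test_structure_calls_match_truth_for_supported_groups(
        self, default_family, default_fit
    ):
        ds, truth = default_family
        res = default_fit
        chrom_of = truth.marker_chromosome()
        arm_of = truth.marker_arm()
        structures = truth.structures()
        checked = 0
        for g in res.consensus_map.groups:
            chroms = {chrom_of[m] for m in g.all_markers if m in chrom_of}
            if len(chroms) != 1:
                continue
            chrom = next(iter(chroms))
            true_arms = {
                a.donor_arm_label
                for c in truth.genome.chromosomes
                if c.id == chrom
                for a in c.arms
            }
            support = {arm: 0 for arm in true_arms}
            for m in g.all_markers:
                ann = truth.annotations.get(m)
                if ann is not None and not ann.centromere:
                    support[arm_of[m]] = support.get(arm_of[m], 0) + 1
            if not all(v >= 2 for v in support.values()):
                continue
            checked += 1
            assert res.comparison["structure"][g.id]["call"] == structures[chrom]
        assert checked >= 25

    def test_planted_homeolog_pairs_recovered_exactly(self, default_family, default_fit):
        _, truth = default_family
        res = default_fit
        chrom_of = truth.marker_chromosome()
        group_chrom = {
            g.id: chrom_of[g.all_markers[0]] for g in res.consensus_map.groups
        }
        recovered = {
            frozenset(group_chrom[gid] for gid in h["groups"]): h["count"]
            for h in res.comparison["homeologs"]
        }
        assert recovered == truth.homeolog_chromosome_pairs()
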