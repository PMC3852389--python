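"""Comparative inference against an annotated donor map.

Given a linkage map whose markers carry donor-map arm annotations (e.g.
rainbow-trout arm labels for a Chinook salmon map), this module infers,
per linkage group: which donor chromosome arms it carries (arm homology is
asserted at >= 2 supporting markers, with single-marker hits reported as
putative), whether the group represents a metacentric (two-armed) or
acrocentric (one-armed) chromosome, homeologous group pairs supported by
duplicated (/i, /ii) loci, within-arm marker-order concordance including
inverted blocks, and a genome-level summary of conserved chromosomes,
Robertsonian fusions and fissions.

Markers flagged as mapping to the donor centromere region (``c``) or to
the donor homeolog (``h``, suspected paralog amplification) are excluded
from homology counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import DonorAnnotation, DonorChromosome, MarkerDef, parse_duplicate_name
from .mapping import GenomeMap, LinkageGroup

DEFAULT_MIN_SUPPORT = 2


@dataclass
class ArmHit:
    donor_arm: str
    markers: list[str]
    support: str  # confirmed | putative_single_marker

    @property
    def count(self) -> int:
        return len(self.markers)


@dataclass
class ArmAssignment:
    group_id: str
    hits: list[ArmHit]
    excluded_centromere: int = 0
    excluded_homeolog: int = 0

    @property
    def supported_arms(self) -> list[str]:
        return [h.donor_arm for h in self.hits]

    @property
    def confirmed_arms(self) -> list[str]:
        return [h.donor_arm for h in self.hits if h.support == "confirmed"]


@dataclass
class StructureCall:
    group_id: str
    call: str  # metacentric | acrocentric | unresolved
    arms: list[str]
    putative: bool = False  # call rests on a single-marker arm hit


@dataclass
class HomeologPair:
    groups: frozenset
    count: int
    bases: list[str]
    donor_arms: list[str] = field(default_factory=list)

    @property
    def single_support(self) -> bool:
        return self.count == 1


@dataclass
class OrderComparison:
    group_id: str
    donor_arm: str
    shared_markers: list[str]
    concordance: float | None  # |Kendall tau|, orientation-maximised
    breakpoints: int
    inverted_block: tuple[list[str], float] | None  # (markers, local cM span)


def assign_arms(
    gmap: GenomeMap,
    annotations: dict[str, DonorAnnotation],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> dict[str, ArmAssignment]:
    """Tally donor-arm hits per linkage group.

    Centromere- and homeolog-flagged markers are excluded.  Arms reaching
    ``min_support`` markers are confirmed; single-marker hits are kept as
    putative (the evidence tier used for a terminal translocated fragment).
    """
    out: dict[str, ArmAssignment] = {}
    for group in gmap.groups:
        tallies: dict[str, list[str]] = {}
        excl_c = excl_h = 0
        for marker in group.all_markers:
            ann = annotations.get(marker)
            if ann is None:
                continue
            if ann.centromere:
                excl_c += 1
                continue
            if ann.homeolog:
                excl_h += 1
                continue
            tallies.setdefault(ann.arm_label, []).append(marker)
        hits = [
            ArmHit(
                donor_arm=arm,
                markers=sorted(markers),
                support="confirmed" if len(markers) >= min_support else "putative_single_marker",
            )
            for arm, markers in sorted(tallies.items())
        ]
        hits.sort(key=lambda h: (-h.count, h.donor_arm))
        out[group.id] = ArmAssignment(
            group_id=group.id,
            hits=hits,
            excluded_centromere=excl_c,
            excluded_homeolog=excl_h,
        )
    return out


def infer_structure(assignments: dict[str, ArmAssignment]) -> dict[str, StructureCall]:
    """Call each group metacentric (>= 2 supported donor arms), acrocentric
    (exactly 1) or unresolved (no annotated support)."""
    out: dict[str, StructureCall] = {}
    for gid, asg in assignments.items():
        arms = asg.supported_arms
        if len(arms) >= 2:
            call = "metacentric"
        elif len(arms) == 1:
            call = "acrocentric"
        else:
            call = "unresolved"
        putative = call == "metacentric" and len(asg.confirmed_arms) < 2
        out[gid] = StructureCall(group_id=gid, call=call, arms=arms, putative=putative)
    return out


def pair_homeologs(
    gmap: GenomeMap,
    markers: list[MarkerDef],
    annotations: dict[str, DonorAnnotation] | None = None,
) -> tuple[list[HomeologPair], list[str]]:
    """Pair linkage groups through duplicated (/i, /ii) loci.

    Each base locus with both copies mapped to two different groups
    supports one unordered group pair.  Bases whose two copies land in the
    same group are reported as anomalies, not pairs.
    """
    group_of = gmap.group_of()
    by_base: dict[str, dict[str, str]] = {}
    for m in markers:
        base, tag = parse_duplicate_name(m.name)
        if tag and m.name in group_of:
            by_base.setdefault(base, {})[tag] = m.name
    pairs: dict[frozenset, HomeologPair] = {}
    anomalies: list[str] = []
    for base in sorted(by_base):
        copies = by_base[base]
        if len(copies) < 2:
            continue
        g_i, g_ii = group_of[copies["i"]], group_of[copies["ii"]]
        if g_i == g_ii:
            anomalies.append(base)
            continue
        key = frozenset((g_i, g_ii))
        if key not in pairs:
            pairs[key] = HomeologPair(groups=key, count=0, bases=[])
        pairs[key].count += 1
        pairs[key].bases.append(base)
        if annotations:
            for name in copies.values():
                ann = annotations.get(name)
                if ann and ann.arm_label not in pairs[key].donor_arms:
                    pairs[key].donor_arms.append(ann.arm_label)
    out = sorted(pairs.values(), key=lambda p: tuple(sorted(p.groups)))
    for p in out:
        p.donor_arms.sort()
    return out, anomalies


def _longest_reversed_run(ranks: list[int], min_len: int = 3) -> tuple[int, int] | None:
    """Longest contiguous window whose ranks are exactly descending
    consecutive integers; brute force over all windows."""
    best: tuple[int, int] | None = None
    k = len(ranks)
    for i in range(k):
        for j in range(i + min_len - 1, k):
            window = ranks[i : j + 1]
            if all(b == a - 1 for a, b in zip(window, window[1:])):
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    return best


def compare_order(
    group: LinkageGroup,
    annotations: dict[str, DonorAnnotation],
    donor_arm: str,
    min_shared: int = 3,
) -> OrderComparison:
    """Compare a group's marker order with the donor within-arm order.

    Concordance is the orientation-maximised |Kendall tau| over shared
    ordered markers; breakpoints count adjacencies whose donor ranks are
    not consecutive in the chosen orientation; an inverted block is a
    maximal run of >= 3 consecutive shared markers whose donor order is
    exactly reversed, reported with its local cM span.
    """
    shared = [
        m
        for m in group.markers
        if m in annotations
        and annotations[m].arm_label == donor_arm
        and not annotations[m].centromere
        and annotations[m].donor_pos is not None
    ]
    if len(shared) < min_shared:
        return OrderComparison(
            group_id=group.id,
            donor_arm=donor_arm,
            shared_markers=shared,
            concordance=None,
            breakpoints=0,
            inverted_block=None,
        )
    donor_pos = np.array([annotations[m].donor_pos for m in shared])
    local_rank = np.arange(len(shared))
    tau = stats.kendalltau(local_rank, donor_pos).statistic
    if tau is None or np.isnan(tau):
        tau = 0.0
    orient = -1.0 if tau < 0 else 1.0
    ranks = stats.rankdata(orient * donor_pos, method="ordinal").astype(int).tolist()
    # unsigned adjacencies: a reversed run's internal neighbours are still
    # neighbours in the donor, so only its flanks count as breakpoints
    breakpoints = sum(1 for a, b in zip(ranks, ranks[1:]) if abs(b - a) != 1)
    run = _longest_reversed_run(ranks)
    inverted = None
    if run is not None:
        i, j = run
        pos = group.positions()
        span = abs(pos[shared[j]] - pos[shared[i]])
        inverted = (shared[i : j + 1], float(span))
    return OrderComparison(
        group_id=group.id,
        donor_arm=donor_arm,
        shared_markers=shared,
        concordance=abs(float(tau)),
        breakpoints=breakpoints,
        inverted_block=inverted,
    )


def compare_all_orders(
    gmap: GenomeMap,
    annotations: dict[str, DonorAnnotation],
    assignments: dict[str, ArmAssignment],
    min_shared: int = 3,
) -> list[OrderComparison]:
    out = []
    for group in gmap.groups:
        for hit in assignments[group.id].hits:
            if hit.support != "confirmed":
                continue
            cmp_ = compare_order(group, annotations, hit.donor_arm, min_shared=min_shared)
            if cmp_.concordance is not None:
                out.append(cmp_)
    return out


@dataclass
class ComparativeSummary:
    n_groups: int
    n_metacentric: int
    n_acrocentric: int
    n_unresolved: int
    haploid_arm_number: int
    conserved_chromosomes: list[tuple[str, str]]  # (group, donor chromosome)
    fusions: list[str]  # groups combining arms of >= 2 donor chromosomes
    fissions: list[str]  # donor metacentrics split across >= 2 groups
    pairing_table: list[dict]


def summarize_comparison(
    structures: dict[str, StructureCall],
    assignments: dict[str, ArmAssignment],
    donor_karyotype: dict[str, DonorChromosome],
) -> ComparativeSummary:
    """Genome-level comparison: conserved chromosomes (a group whose
    supported arm set equals a donor chromosome's arm set), Robertsonian
    fusions (arms from several donor chromosomes in one group) and
    fissions (a donor metacentric split over several groups), plus the
    ideogram-style pairing table."""
    arm_to_donor = {
        arm: chrom.name for chrom in donor_karyotype.values() for arm in chrom.arms
    }
    donor_arms = {chrom.name: set(chrom.arms) for chrom in donor_karyotype.values()}

    conserved: list[tuple[str, str]] = []
    fusions: list[str] = []
    donor_groups: dict[str, set[str]] = {}
    pairing = []
    for gid in sorted(assignments):
        asg = assignments[gid]
        arms = set(asg.supported_arms)
        donors = {arm_to_donor[a] for a in arms if a in arm_to_donor}
        for d in donors:
            donor_groups.setdefault(d, set()).add(gid)
        if len(donors) == 1:
            donor = next(iter(donors))
            if arms == donor_arms[donor]:
                conserved.append((gid, donor))
        elif len(donors) >= 2:
            fusions.append(gid)
        pairing.append(
            {
                "group": gid,
                "call": structures[gid].call,
                "arms": sorted(arms),
                "donor_chromosomes": sorted(donors),
            }
        )
    fissions = sorted(
        d
        for d, gids in donor_groups.items()
        if len(gids) >= 2 and donor_karyotype[d].structure == "metacentric"
    )
    calls = [s.call for s in structures.values()]
    supported = {a for asg in assignments.values() for a in asg.supported_arms}
    return ComparativeSummary(
        n_groups=len(structures),
        n_metacentric=calls.count("metacentric"),
        n_acrocentric=calls.count("acrocentric"),
        n_unresolved=calls.count("unresolved"),
        haploid_arm_number=len(supported),
        conserved_chromosomes=sorted(conserved),
        fusions=sorted(fusions),
        fissions=fissions,
        pairing_table=pairing,
    )


def comparison_report(
    gmap: GenomeMap,
    annotations: dict[str, DonorAnnotation],
    donor_karyotype: dict[str, DonorChromosome] | None,
    markers: list[MarkerDef],
    min_support: int = DEFAULT_MIN_SUPPORT,
    min_shared: int = 3,
    extra_maps: dict[str, GenomeMap] | None = None,
) -> dict:
    """Full comparative analysis as a JSON-ready dictionary.

    Arm homology, structure and homeolog pairing use the (consensus) map
    given first; marker-order comparison additionally runs on any
    ``extra_maps`` (e.g. the female map, whose single-parent meioses
    resolve order differences most cleanly).
    """
    assignments = assign_arms(gmap, annotations, min_support=min_support)
    structures = infer_structure(assignments)
    homeologs, anomalies = pair_homeologs(gmap, markers, annotations)
    orders = [
        ("consensus", c)
        for c in compare_all_orders(gmap, annotations, assignments, min_shared=min_shared)
    ]
    for map_name in sorted(extra_maps or {}):
        emap = extra_maps[map_name]
        easg = assign_arms(emap, annotations, min_support=min_support)
        orders += [
            (map_name, c)
            for c in compare_all_orders(emap, annotations, easg, min_shared=min_shared)
        ]
    report = {
        "assignments": {
            gid: {
                "arms": [
                    {"arm": h.donor_arm, "count": h.count, "support": h.support}
                    for h in asg.hits
                ],
                "excluded_centromere": asg.excluded_centromere,
                "excluded_homeolog": asg.excluded_homeolog,
            }
            for gid, asg in assignments.items()
        },
        "structure": {
            gid: {"call": s.call, "arms": s.arms, "putative": s.putative}
            for gid, s in structures.items()
        },
        "homeologs": [
            {
                "groups": sorted(p.groups),
                "count": p.count,
                "bases": sorted(p.bases),
                "donor_arms": p.donor_arms,
                "single_support": p.single_support,
            }
            for p in homeologs
        ],
        "homeolog_anomalies": anomalies,
        "order_comparisons": [
            {
                "map": map_name,
                "group": c.group_id,
                "donor_arm": c.donor_arm,
                "n_shared": len(c.shared_markers),
                "concordance": c.concordance,
                "breakpoints": c.breakpoints,
                "inverted_block": (
                    None
                    if c.inverted_block is None
                    else {
                        "markers": c.inverted_block[0],
                        "span_cM": c.inverted_block[1],
                    }
                ),
            }
            for map_name, c in orders
        ],
    }
    if donor_karyotype:
        summary = summarize_comparison(structures, assignments, donor_karyotype)
        report["summary"] = {
            "n_groups": summary.n_groups,
            "n_metacentric": summary.n_metacentric,
            "n_acrocentric": summary.n_acrocentric,
            "n_unresolved": summary.n_unresolved,
            "haploid_arm_number": summary.haploid_arm_number,
            "conserved_chromosomes": [list(t) for t in summary.conserved_chromosomes],
            "n_conserved": len(summary.conserved_chromosomes),
            "fusions": summary.fusions,
            "fissions": summary.fissions,
            "pairing_table": summary.pairing_table,
        }
    return report
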