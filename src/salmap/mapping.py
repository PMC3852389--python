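"""Linkage-group construction and marker ordering.

Markers are grouped by single-linkage transitive closure over pairwise LOD
(default threshold 3.0) and ordered within groups by minimising SARF, the
sum of adjacent recombination fractions (default ordering LOD 4.0), with a
sliding-window "ripple" verification pass.  Sex-specific maps use one
parent's meioses; the consensus map merges the two sexes, anchors on
framework markers (informative in both parents) ordered on pooled counts,
and inserts the remaining markers sequentially.

Grouping guard.  At this family size a LOD of 3.0 is not genome-wide safe:
with ~48 meioses an unlinked marker pair reaches LOD >= 3 with probability
~2e-4 (two-sided binomial tail after phase minimisation), and a few hundred
markers generate tens of thousands of candidate pairs, so several spurious
joins per map are expected from chance alone.  ``cluster_markers``
therefore admits an edge only if its exact binomial tail probability,
multiplied by the number of pairs tested, stays within a small false-edge
budget (default 0.05 expected spurious edges genome-wide).  A simple
theta ceiling guard is also available and off by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .io import FamilyDataset, MarkerDef
from .twopoint import map_function, transmission_matrix, two_point_matrices

DEFAULT_GROUP_LOD = 3.0
DEFAULT_ORDER_LOD = 4.0
DEFAULT_FP_BUDGET = 0.05


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class TwoPointTable:
    """All-pairs two-point matrices for one meiosis set (one parent, or
    pooled counts over both)."""

    names: list[str]
    n: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    lod: np.ndarray

    def __post_init__(self) -> None:
        self.index = {name: i for i, name in enumerate(self.names)}

    @classmethod
    def from_codes(cls, names: list[str], codes: np.ndarray) -> "TwoPointTable":
        mats = two_point_matrices(codes)
        return cls(names=names, n=mats["n"], r=mats["r"], theta=mats["theta"], lod=mats["lod"])

    @classmethod
    def from_parent(cls, ds: FamilyDataset, parent: str) -> "TwoPointTable":
        names, codes = transmission_matrix(ds, parent)
        return cls.from_codes(names, codes)

    def has(self, a: str, b: str) -> bool:
        return a in self.index and b in self.index and self.n[self.index[a], self.index[b]] > 0

    def get_theta(self, a: str, b: str, default: float = 0.5) -> float:
        if not self.has(a, b):
            return default
        return float(self.theta[self.index[a], self.index[b]])

    def get_lod(self, a: str, b: str) -> float:
        if not self.has(a, b):
            return 0.0
        return float(self.lod[self.index[a], self.index[b]])

    def n_pairs_tested(self) -> int:
        iu = np.triu_indices(len(self.names), k=1)
        return int(np.sum(self.n[iu] > 0))


def pool_tables(tables: list[TwoPointTable]) -> TwoPointTable:
    """Pool recombinant and meiosis counts over several tables (used for
    consensus ordering: R = sum R_s, N = sum N_s)."""
    names = sorted(set(itertools.chain.from_iterable(t.names for t in tables)))
    k = len(names)
    idx = {n: i for i, n in enumerate(names)}
    n = np.zeros((k, k), dtype=np.int64)
    r = np.zeros((k, k), dtype=np.int64)
    for t in tables:
        sel = np.array([idx[nm] for nm in t.names], dtype=np.intp)
        if sel.size == 0:
            continue
        n[np.ix_(sel, sel)] += t.n
        r[np.ix_(sel, sel)] += t.r
    from .twopoint import lod_score

    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(n > 0, r / np.maximum(n, 1), 0.5)
    lod = np.where(n > 0, lod_score(r, np.maximum(n, 1)), 0.0)
    np.fill_diagonal(theta, 0.0)
    np.fill_diagonal(lod, 0.0)
    return TwoPointTable(names=names, n=n, r=r, theta=theta, lod=lod)


@dataclass
class LinkageGroup:
    """Ordered markers with adjacent map distances (cM).

    ``accessory`` markers could not be placed at the ordering LOD and are
    anchored at the position of their strongest partner.
    """

    id: str
    markers: list[str]
    distances: list[float]
    map_function: str
    source: str  # female | male | consensus | file
    accessory: list[tuple[str, float]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return float(sum(self.distances))

    @property
    def all_markers(self) -> list[str]:
        return self.markers + [m for m, _ in self.accessory]

    @property
    def size(self) -> int:
        return len(self.markers) + len(self.accessory)

    def positions(self) -> dict[str, float]:
        out = {}
        cum = 0.0
        for i, m in enumerate(self.markers):
            if i > 0:
                cum += self.distances[i - 1]
            out[m] = cum
        out.update({m: p for m, p in self.accessory})
        return out


@dataclass
class GenomeMap:
    groups: list[LinkageGroup]
    unassigned: list[str]
    map_function: str
    source: str
    dropped: list[str] = field(default_factory=list)
    marker_defs: list[MarkerDef] = field(default_factory=list)

    @property
    def total_length(self) -> float:
        return float(sum(g.total_length for g in self.groups))

    @property
    def marker_count(self) -> int:
        return sum(g.size for g in self.groups)

    def group_of(self) -> dict[str, str]:
        return {m: g.id for g in self.groups for m in g.all_markers}


# --------------------------------------------------------------------------
# grouping
# --------------------------------------------------------------------------

def _edge_list(
    table: TwoPointTable,
    lod_threshold: float,
    fp_budget: float | None,
    max_theta: float | None,
) -> list[tuple[str, str]]:
    k = len(table.names)
    if k < 2:
        return []
    iu = np.triu_indices(k, k=1)
    ok = (table.lod[iu] >= lod_threshold) & (table.n[iu] > 0)
    if max_theta is not None:
        ok &= table.theta[iu] <= max_theta
    if fp_budget is not None:
        n_tests = max(table.n_pairs_tested(), 1)
        pvals = 2.0 * stats.binom.cdf(table.r[iu], np.maximum(table.n[iu], 1), 0.5)
        ok &= np.minimum(pvals, 1.0) * n_tests <= fp_budget
    return [
        (table.names[i], table.names[j])
        for i, j in zip(iu[0][ok], iu[1][ok])
    ]


def cluster_markers(
    tables: TwoPointTable | list[TwoPointTable],
    lod_threshold: float = DEFAULT_GROUP_LOD,
    fp_budget: float | None = DEFAULT_FP_BUDGET,
    max_theta: float | None = None,
) -> tuple[list[list[str]], list[str]]:
    """Partition markers into linkage groups by single-linkage closure.

    Two markers co-group iff connected by a chain of pairs that pass the
    LOD threshold (and the genome-wide false-edge guard, see module
    docstring).  Returns (groups sorted by decreasing size then first
    marker, unassigned singletons).
    """
    if isinstance(tables, TwoPointTable):
        tables = [tables]
    graph = nx.Graph()
    for table in tables:
        graph.add_nodes_from(table.names)
        graph.add_edges_from(_edge_list(table, lod_threshold, fp_budget, max_theta))
    groups: list[list[str]] = []
    unassigned: list[str] = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        if len(members) == 1:
            unassigned.append(members[0])
        else:
            groups.append(members)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups, sorted(unassigned)


# --------------------------------------------------------------------------
# ordering
# --------------------------------------------------------------------------

def sarf(order: list[str], table: TwoPointTable) -> float:
    """Sum of adjacent recombination fractions (missing pairs count 0.5)."""
    return float(
        sum(table.get_theta(a, b) for a, b in zip(order, order[1:]))
    )


def _canonical(order: list[str]) -> list[str]:
    if len(order) > 1 and order[-1] < order[0]:
        return list(reversed(order))
    return list(order)


def _exhaustive_order(markers: list[str], table: TwoPointTable) -> list[str]:
    best_order = None
    best = np.inf
    for perm in itertools.permutations(markers):
        if perm[0] > perm[-1]:
            continue  # an order and its reversal score identically
        cand = list(perm)
        score = sarf(cand, table)
        if score < best - 1e-12 or (
            abs(score - best) <= 1e-12
            and best_order is not None
            and _canonical(cand) < _canonical(best_order)
        ):
            best = score
            best_order = cand
    return best_order or markers


def _greedy_order(markers: list[str], table: TwoPointTable) -> list[str]:
    """Greedy path construction: repeatedly join the closest fragment ends."""
    frags = [[m] for m in sorted(markers)]
    while len(frags) > 1:
        best = None
        for i in range(len(frags)):
            for j in range(i + 1, len(frags)):
                for rev_i in (False, True):
                    for rev_j in (False, True):
                        a = frags[i][0] if rev_i else frags[i][-1]
                        b = frags[j][-1] if rev_j else frags[j][0]
                        cost = table.get_theta(a, b)
                        key = (cost, a, b)
                        if best is None or key < best[0]:
                            best = (key, i, j, rev_i, rev_j)
        _, i, j, rev_i, rev_j = best
        left = list(reversed(frags[i])) if rev_i else frags[i]
        right = list(reversed(frags[j])) if rev_j else frags[j]
        merged = left + right
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]
    return frags[0]


def _two_opt(order: list[str], table: TwoPointTable) -> list[str]:
    order = list(order)
    improved = True
    while improved:
        improved = False
        k = len(order)
        for i in range(k - 1):
            for j in range(i + 1, k):
                cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                if sarf(cand, table) < sarf(order, table) - 1e-12:
                    order = cand
                    improved = True
    return order


def _or_opt(order: list[str], table: TwoPointTable) -> list[str]:
    """Relocate short segments (1-3 markers) to their best slot; catches
    misplacements that segment reversals (2-opt) cannot repair."""
    order = list(order)
    improved = True
    while improved:
        improved = False
        for seg_len in (1, 2, 3):
            k = len(order)
            if k <= seg_len:
                continue
            for i in range(k - seg_len + 1):
                seg = order[i : i + seg_len]
                rest = order[:i] + order[i + seg_len :]
                base = sarf(order, table)
                for s in range(len(rest) + 1):
                    for piece in (seg, seg[::-1]):
                        cand = rest[:s] + piece + rest[s:]
                        if sarf(cand, table) < base - 1e-12:
                            order = cand
                            improved = True
                            break
                    if improved:
                        break
                if improved:
                    break
            if improved:
                break
    return order


def _refine(order: list[str], table: TwoPointTable, window: int = 3) -> list[str]:
    """Local refinement to a stable order: alternate 2-opt, or-opt and
    ripple until none of them improves SARF."""
    while True:
        before = sarf(order, table)
        order = _two_opt(order, table)
        order = _or_opt(order, table)
        order = ripple(order, table, window=window)
        if sarf(order, table) >= before - 1e-12:
            return order


def ripple(
    order: list[str],
    table: TwoPointTable,
    window: int = 3,
    keep_order: set[str] | None = None,
) -> list[str]:
    """Verify an order by permuting every contiguous window; restart the
    scan whenever a permutation strictly lowers SARF.  A window spanning
    the whole group is equivalent to exhaustive search.

    ``keep_order`` freezes the relative order of the named markers (used
    on consensus maps, where the framework order rests on pooled counts
    and must not be rescrambled by single-sex edges)."""
    order = list(order)
    if len(order) < 2:
        return order
    window = min(window, len(order))
    restart = True
    while restart:
        restart = False
        base = sarf(order, table)
        for s in range(len(order) - window + 1):
            seg = order[s : s + window]
            fixed = [m for m in seg if keep_order and m in keep_order]
            for perm in itertools.permutations(seg):
                if fixed and [m for m in perm if m in keep_order] != fixed:
                    continue
                cand = order[:s] + list(perm) + order[s + window :]
                if sarf(cand, table) < base - 1e-12:
                    order = cand
                    restart = True
                    break
            if restart:
                break
    return _canonical(order)


def order_group(
    markers: list[str],
    table: TwoPointTable,
    ordering_lod: float = DEFAULT_ORDER_LOD,
    exhaustive_limit: int = 8,
    ripple_window: int = 3,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Order a linkage group's markers by minimising SARF.

    Markers connected at the ordering LOD form the orderable core (largest
    such component); the rest become accessory, anchored to their
    highest-LOD partner in the core.  Exhaustive search is used for cores
    of up to ``exhaustive_limit`` markers, greedy chaining + 2-opt with a
    ripple pass beyond that.  Returns (ordered core, accessory pairs of
    (marker, anchor marker)).
    """
    markers = sorted(markers)
    if len(markers) == 1:
        return markers, []
    graph = nx.Graph()
    graph.add_nodes_from(markers)
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            if table.get_lod(markers[i], markers[j]) >= ordering_lod:
                graph.add_edge(markers[i], markers[j])
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    core = sorted(comps[0])
    rest = [m for m in markers if m not in set(core)]
    if len(core) == 1:
        ordered = core
    elif len(core) == 2:
        ordered = _canonical(core)
    elif len(core) <= exhaustive_limit:
        ordered = _canonical(_exhaustive_order(core, table))
    else:
        ordered = _greedy_order(core, table)
        ordered = _refine(ordered, table, window=ripple_window)
    accessory = []
    for m in sorted(rest):
        anchor = max(core, key=lambda c: (table.get_lod(m, c), c))
        accessory.append((m, anchor))
    return ordered, accessory


# --------------------------------------------------------------------------
# map assembly
# --------------------------------------------------------------------------

def _assign_ids(groups: list[LinkageGroup]) -> list[LinkageGroup]:
    groups.sort(key=lambda g: (-g.size, g.markers[0] if g.markers else ""))
    for i, g in enumerate(groups):
        g.id = f"LG{i + 1:02d}"
    return groups


def _distances(
    order: list[str], table: TwoPointTable, fn: str
) -> list[float]:
    return [
        float(map_function(min(table.get_theta(a, b), 0.5), fn))
        for a, b in zip(order, order[1:])
    ]


def build_sex_map(
    ds: FamilyDataset,
    parent: str,
    map_fn: str = "haldane",
    lod_group: float = DEFAULT_GROUP_LOD,
    lod_order: float = DEFAULT_ORDER_LOD,
    fp_budget: float | None = DEFAULT_FP_BUDGET,
    max_theta: float | None = None,
    ripple_window: int = 3,
    table: TwoPointTable | None = None,
) -> GenomeMap:
    """Build one parent's linkage map: cluster, order, ripple, distance."""
    if table is None:
        table = TwoPointTable.from_parent(ds, parent)
    source = "female" if parent == "dam" else "male"
    raw_groups, unassigned = cluster_markers(
        table, lod_threshold=lod_group, fp_budget=fp_budget, max_theta=max_theta
    )
    groups: list[LinkageGroup] = []
    for members in raw_groups:
        ordered, accessory = order_group(
            members, table, ordering_lod=lod_order, ripple_window=ripple_window
        )
        dists = _distances(ordered, table, map_fn)
        lg = LinkageGroup(
            id="",
            markers=ordered,
            distances=dists,
            map_function=map_fn,
            source=source,
        )
        pos = lg.positions()
        lg.accessory = [(m, pos[anchor]) for m, anchor in accessory]
        groups.append(lg)
    return GenomeMap(
        groups=_assign_ids(groups),
        unassigned=unassigned,
        map_function=map_fn,
        source=source,
        marker_defs=list(ds.markers),
    )


def _insert_position(order: list[str], marker: str, table: TwoPointTable) -> tuple[int | None, float]:
    """Best insertion slot by SARF; returns (slot, margin to runner-up).

    A ``None`` slot means the placement is unstable (two distinct slots tie
    within 1e-9), mirroring markers that cannot be placed accurately on a
    consensus map."""
    scores = []
    for s in range(len(order) + 1):
        cand = order[:s] + [marker] + order[s:]
        scores.append((sarf(cand, table), s))
    scores.sort()
    if len(scores) > 1 and scores[1][0] - scores[0][0] <= 1e-9:
        return None, 0.0
    return scores[0][1], scores[1][0] - scores[0][0] if len(scores) > 1 else np.inf


def build_consensus_map(
    ds: FamilyDataset,
    female_map: GenomeMap,
    male_map: GenomeMap,
    female_table: TwoPointTable,
    male_table: TwoPointTable,
    map_fn: str = "kosambi",
    lod_order: float = DEFAULT_ORDER_LOD,
    ripple_window: int = 3,
) -> GenomeMap:
    """Merge the sex maps into a sex-averaged consensus map.

    Sex groups sharing at least one marker merge; framework markers
    (informative in both parents) are ordered on pooled counts
    (R = R_f + R_m, N = N_f + N_m); remaining markers are inserted one at a
    time at the SARF-minimising slot, unstable insertions are dropped and
    reported, and the final order is ripple-verified.  Groups with no
    between-sex marker overlap carry over flagged as single-sex.
    """
    pooled = pool_tables([female_table, male_table])
    graph = nx.Graph()
    for prefix, gmap in (("F", female_map), ("M", male_map)):
        for g in gmap.groups:
            node = f"{prefix}:{g.id}"
            graph.add_node(node, markers=set(g.all_markers), source=prefix)
    nodes = list(graph.nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if graph.nodes[nodes[i]]["markers"] & graph.nodes[nodes[j]]["markers"]:
                graph.add_edge(nodes[i], nodes[j])

    both = set(female_table.names) & set(male_table.names)
    groups: list[LinkageGroup] = []
    dropped: list[str] = []
    for comp in nx.connected_components(graph):
        members = sorted(set().union(*(graph.nodes[n]["markers"] for n in comp)))
        sources = {graph.nodes[n]["source"] for n in comp}
        flags = []
        if sources == {"F"}:
            flags.append("female_only")
        elif sources == {"M"}:
            flags.append("male_only")
        framework = sorted(m for m in members if m in both)
        if len(framework) >= 2:
            ordered, accessory = order_group(
                framework, pooled, ordering_lod=lod_order, ripple_window=ripple_window
            )
            insertable = sorted(
                [m for m in members if m not in set(framework)]
                + [m for m, _ in accessory]
            )
        else:
            if not flags:
                flags.append("no_shared_markers")
            ordered = []
            insertable = members
        framework_order = list(ordered)
        for m in insertable:
            if not ordered:
                ordered = [m]
                continue
            slot, _ = _insert_position(ordered, m, pooled)
            if slot is None:
                dropped.append(m)
            else:
                ordered = ordered[:slot] + [m] + ordered[slot:]
        # verify inserted markers only: the female-only and male-only edges
        # are on different recombination scales than the pooled framework
        # edges, so the framework subsequence stays frozen here
        ordered = ripple(
            ordered, pooled, window=ripple_window, keep_order=set(framework_order)
        )
        groups.append(
            LinkageGroup(
                id="",
                markers=ordered,
                distances=_distances(ordered, pooled, map_fn),
                map_function=map_fn,
                source="consensus",
                flags=flags,
            )
        )
    in_groups = {m for g in groups for m in g.all_markers}
    unassigned = sorted(
        (set(female_map.unassigned) | set(male_map.unassigned)) - in_groups
    )
    return GenomeMap(
        groups=_assign_ids(groups),
        unassigned=unassigned,
        dropped=sorted(dropped),
        map_function=map_fn,
        source="consensus",
        marker_defs=list(ds.markers),
    )
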