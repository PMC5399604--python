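"""Tag-SNP selection over a thresholded LD graph.

Selection decomposes the graph into *precincts* (connected components), then
chooses within each precinct a set of tags such that every member site is
either a tag or linked to one at r2 >= threshold — a dominating set of the
precinct.  Small precincts are solved exactly (minimum dominating set by
bounded enumeration); large ones greedily.  A capacity step trims the pooled
tag list to an array budget by raising the minor-allele-frequency floor,
which thins tags without biasing toward any genomic region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .ld import LDGraph

DEFAULT_EXACT_CAP = 15  # max precinct size for exhaustive minimum dominating set


class PrecinctTooLargeError(ValueError):
    """Exact selection refused: precinct exceeds the enumeration cap."""


class InfeasibleCapacityError(ValueError):
    """Capacity below the number of must-include tags."""


@dataclass(frozen=True)
class Precinct:
    """A connected component of the thresholded LD graph."""

    members: tuple[str, ...]  # sorted site ids
    edges: tuple[tuple[str, str, float], ...]

    @property
    def size(self) -> int:
        return len(self.members)

    def adjacency(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {m: {} for m in self.members}
        for a, b, r2 in self.edges:
            adj[a][b] = r2
            adj[b][a] = r2
        return adj

    def closed_neighborhoods(self) -> dict[str, frozenset[str]]:
        adj = self.adjacency()
        return {m: frozenset(adj[m]) | {m} for m in self.members}


@dataclass
class TagSelection:
    """A chosen tag set with its per-site coverage map.

    ``cover`` maps every site of the input universe to its best covering tag
    and the corresponding r2 (a tag covers itself at r2 = 1).  ``modes``
    records, per precinct index, whether it was solved exactly or greedily.
    """

    tags: list[str]  # sorted
    cover: dict[str, tuple[str, float]]
    modes: dict[int, str]
    precinct_of: dict[str, int]
    graph: LDGraph | None = None

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def to_dataframe(self, site_info: Mapping[str, tuple] | None = None) -> pd.DataFrame:
        rows = [
            {
                "id": t,
                "precinct_id": self.precinct_of.get(t, -1),
                "mode": self.modes.get(self.precinct_of.get(t, -1), "greedy"),
            }
            for t in self.tags
        ]
        return pd.DataFrame(rows, columns=["id", "precinct_id", "mode"])

    def cover_to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(s, t, r2) for s, (t, r2) in sorted(self.cover.items())],
            columns=["id", "tag_id", "r2"],
        )
        df.to_csv(path, sep="\t", index=False)


def build_precincts(ldg: LDGraph, universe: Iterable[str]) -> list[Precinct]:
    """Connected components of the LD graph over ``universe``.

    Sites with no edge at the threshold become singleton precincts.  The
    result is deterministically ordered by smallest member id.
    """
    universe = set(universe)
    stray = ldg.nodes - universe
    extra = {x for e in ldg.edges for x in e[:2]} - universe
    if extra:
        raise ValueError(f"LD graph has nodes outside the universe, e.g. {sorted(extra)[:5]}")
    del stray

    G = nx.Graph()
    G.add_nodes_from(universe)
    for a, b, r2 in ldg.edges:
        G.add_edge(a, b, r2=r2)

    precincts = []
    for comp in nx.connected_components(G):
        members = tuple(sorted(comp))
        edges = tuple(
            sorted(
                (min(a, b), max(a, b), float(d["r2"]))
                for a, b, d in G.edges(comp, data=True)
            )
        )
        precincts.append(Precinct(members, edges))
    precincts.sort(key=lambda p: p.members[0])
    return precincts


def select_tags_exact(p: Precinct, cap: int = DEFAULT_EXACT_CAP) -> list[str]:
    """Minimum dominating set of a precinct by bounded enumeration.

    Subsets are enumerated in increasing cardinality and, within a
    cardinality, in lexicographic order of site ids, so the returned optimum
    is the lexicographically smallest one — selection is fully deterministic.
    """
    if p.size > cap:
        raise PrecinctTooLargeError(
            f"precinct of {p.size} sites exceeds exact cap {cap}"
        )
    if p.size == 1:
        return [p.members[0]]
    nbr = p.closed_neighborhoods()
    members = p.members  # already sorted
    full = frozenset(members)
    for k in range(1, p.size + 1):
        for subset in combinations(members, k):
            covered: set[str] = set()
            for s in subset:
                covered |= nbr[s]
            if covered == full:
                return list(subset)
    raise AssertionError("unreachable: full member set always dominates")


def select_tags_greedy(
    p: Precinct, maf: Mapping[str, float] | None = None
) -> list[str]:
    """Greedy dominating set: repeatedly pick the site covering the most
    still-uncovered members; ties broken by higher MAF (better expected
    genotyping performance), then by smaller site id."""
    nbr = p.closed_neighborhoods()
    uncovered = set(p.members)
    tags: list[str] = []
    while uncovered:
        best = max(
            p.members,
            key=lambda s: (
                len(nbr[s] & uncovered),
                maf.get(s, 0.0) if maf else 0.0,
                _reverse_id_key(s),
            ),
        )
        tags.append(best)
        uncovered -= nbr[best]
    return sorted(tags)


class _reverse_id_key:
    """Orders ids descending so max() prefers the smaller id on ties."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_reverse_id_key") -> bool:
        return self.s > other.s

    def __eq__(self, other) -> bool:
        return self.s == other.s


def select_tags(
    ldg: LDGraph,
    universe: Iterable[str],
    exact_cap: int = DEFAULT_EXACT_CAP,
    maf: Mapping[str, float] | None = None,
) -> TagSelection:
    """Whole-pool tag selection: exact per precinct up to ``exact_cap``
    members, greedy beyond, with the per-site best-tag coverage map."""
    precincts = build_precincts(ldg, universe)
    tags: list[str] = []
    modes: dict[int, str] = {}
    precinct_of: dict[str, int] = {}
    cover: dict[str, tuple[str, float]] = {}

    for pi, p in enumerate(precincts):
        for m in p.members:
            precinct_of[m] = pi
        if p.size <= exact_cap:
            chosen = select_tags_exact(p, cap=exact_cap)
            modes[pi] = "exact"
        else:
            chosen = select_tags_greedy(p, maf=maf)
            modes[pi] = "greedy"
        tags.extend(chosen)
        chosen_set = set(chosen)
        adj = p.adjacency()
        for m in p.members:
            if m in chosen_set:
                cover[m] = (m, 1.0)
            else:
                best = max(
                    ((t, r2) for t, r2 in adj[m].items() if t in chosen_set),
                    key=lambda x: (x[1], _reverse_id_key(x[0])),
                )
                cover[m] = best
    return TagSelection(sorted(tags), cover, modes, precinct_of, graph=ldg)


def _reselect_orphans(
    sel: TagSelection,
    kept: set[str],
    maf: Mapping[str, float],
    floor: float,
    thresh: float,
) -> list[str]:
    """Greedy re-cover of floor-eligible sites orphaned by a trim.

    Candidate replacement tags are restricted to sites at or above the
    floor (anything lower would be dropped again); every orphan can tag
    itself, so re-selection always succeeds.
    """
    adj = sel.graph.adjacency() if sel.graph is not None else {}
    orphans = {
        s
        for s in sel.cover
        if s not in kept
        and maf.get(s, 0.0) >= floor - 1e-12
        and not any(t in kept and r2 >= thresh for t, r2 in adj.get(s, {}).items())
    }
    extra: list[str] = []
    allowed = {
        s for s in sel.cover if maf.get(s, 0.0) >= floor - 1e-12 and s not in kept
    }
    covers: dict[str, set[str]] = {}
    for a in allowed:
        c = {a} if a in orphans else set()
        c |= {n for n, r2 in adj.get(a, {}).items() if n in orphans and r2 >= thresh}
        if c:
            covers[a] = c
    uncovered = set(orphans)
    while uncovered:
        best = max(
            covers,
            key=lambda s: (
                len(covers[s] & uncovered),
                maf.get(s, 0.0),
                _reverse_id_key(s),
            ),
        )
        extra.append(best)
        uncovered -= covers.pop(best)
    return extra


def apply_capacity(
    sel: TagSelection,
    ann: pd.DataFrame,
    capacity: int,
    floor_step: float = 0.001,
    base_floor: float = 0.01,
    reselect: bool = False,
) -> tuple[TagSelection, float, pd.DataFrame]:
    """Trim a tag set to an array budget by raising the MAF floor.

    Scans floors upward from ``base_floor`` in ``floor_step`` increments and
    keeps the smallest floor at which the retained tag count fits
    ``capacity``.  Must-include tags are never dropped.  Returns the trimmed
    selection, the chosen floor, and a lost-coverage report listing sites
    whose best remaining tag falls below the graph's r2 threshold (dropped
    tags themselves included, covered only by themselves at r2 = 1 before
    the trim).

    With ``reselect=True`` (off by default: the classic trim accepts the
    coverage loss), sites at or above the floor that lose their tag are
    re-covered by substitute tags drawn from floor-eligible sites, and the
    substitutes count against capacity during the floor scan.

    Raises :class:`InfeasibleCapacityError` when even the must-include tags
    alone exceed capacity.
    """
    if capacity < 0:
        raise ValueError("capacity must be >= 0")
    if floor_step <= 0:
        raise ValueError("floor_step must be > 0")
    a = ann.set_index("id") if "id" in ann.columns else ann
    maf = {t: float(a.loc[t, "maf"]) for t in sel.tags}
    must = {t for t in sel.tags if bool(a.loc[t, "must_include"])}
    if len(must) > capacity:
        raise InfeasibleCapacityError(
            f"{len(must)} must-include tags exceed capacity {capacity}"
        )
    site_maf = dict(maf)
    if reselect:
        for s in sel.cover:
            if s not in site_maf and s in a.index:
                site_maf[s] = float(a.loc[s, "maf"])
    thresh = sel.graph.r2_min if sel.graph is not None else 0.0

    def retained(floor: float) -> list[str]:
        kept = [t for t in sel.tags if t in must or maf[t] >= floor - 1e-12]
        if reselect:
            kept = kept + _reselect_orphans(sel, set(kept), site_maf, floor, thresh)
        return kept

    max_droppable = max(
        (m for t, m in site_maf.items() if t not in must), default=0.0
    )
    floor = base_floor
    kept = retained(floor)
    while len(kept) > capacity:
        floor = round(floor + floor_step, 12)
        kept = retained(floor)
        if floor > max_droppable + floor_step and len(kept) > capacity:
            raise InfeasibleCapacityError(
                f"cannot reach capacity {capacity} by raising the MAF floor"
            )

    kept_set = set(kept)
    adj = sel.graph.adjacency() if sel.graph is not None else {}
    new_cover: dict[str, tuple[str, float]] = {}
    lost_rows = []
    thresh = sel.graph.r2_min if sel.graph is not None else 0.0
    for site, (old_tag, old_r2) in sel.cover.items():
        if site in kept_set:
            new_cover[site] = (site, 1.0)
            continue
        cands = [(t, r2) for t, r2 in adj.get(site, {}).items() if t in kept_set]
        if cands:
            best = max(cands, key=lambda x: (x[1], _reverse_id_key(x[0])))
        else:
            best = ("", 0.0)
        new_cover[site] = best
        if old_tag not in kept_set or site not in kept_set:
            if best[1] < thresh:
                lost_rows.append(
                    {"id": site, "old_tag": old_tag, "old_r2": old_r2, "new_best_r2": best[1]}
                )

    trimmed = TagSelection(
        sorted(kept), new_cover, dict(sel.modes), dict(sel.precinct_of), graph=sel.graph
    )
    report = pd.DataFrame(lost_rows, columns=["id", "old_tag", "old_r2", "new_best_r2"])
    return trimmed, floor, report
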