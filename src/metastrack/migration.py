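"""Metastatic seeding classification from subclone prevalences.

The joint subclone tree and the subclone x site prevalence matrix determine
where each subclone *emerged* and which sites it *founded*:

* **monoclonal seeding** — a subclone at partial prevalence in one site (it
  emerged there, among older cells) and at ~full prevalence in another (every
  tumor cell there descends from it: it founded the site);
* **polyclonal seeding** — two or more related subclones each at low
  prevalence in both of two sites: they co-migrated rather than founded;
* **recolonization** — a site holding an ancestor and a descendant subclone
  but missing the evolutionary intermediates, which live exclusively at
  another site: the descendant evolved elsewhere and invaded back;
* **incubator** — a site where a chain of ancestor-descendant subclones each
  seeded at least one other site: in-situ evolution fueling further spread.

Metastatic waves order site groups by allele-state precedence (a group whose
defining allele state must precede another's was seeded earlier).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from metastrack.cnv import AlleleSpecificState, Order, order_allele_states
from metastrack.errors import UsageError

logger = logging.getLogger(__name__)

MONOCLONAL = "monoclonal"
POLYCLONAL = "polyclonal"
RECOLONIZATION = "recolonization"


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class SubcloneAtlas:
    """Subclone x site prevalence matrix plus site metadata."""

    presence: pd.DataFrame                       # subclones x sites, in [0,1]
    site_meta: dict[str, str] = field(default_factory=dict)  # site -> organ

    @property
    def subclones(self) -> list[str]:
        return list(self.presence.index)

    @property
    def sites(self) -> list[str]:
        return list(self.presence.columns)


@dataclass(frozen=True)
class SeedingEvent:
    source_site: str
    target_site: str
    subclones: tuple[str, ...]
    kind: str
    wave: str | None = None
    ambiguous: bool = False

    def key(self) -> tuple:
        return (self.source_site, self.target_site, self.kind, self.subclones)


@dataclass
class MigrationGraph:
    graph: nx.DiGraph                    # nodes = sites, edge data = events
    events: list[SeedingEvent]
    incubators: set[str]
    wave_order: list[tuple[str, str]]    # (earlier group, later group) pairs
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "sites": sorted(self.graph.nodes),
                "events": [
                    {
                        "source": e.source_site, "target": e.target_site,
                        "kind": e.kind, "subclones": list(e.subclones),
                        "wave": e.wave, "ambiguous": e.ambiguous,
                    }
                    for e in self.events
                ],
                "incubators": sorted(self.incubators),
                "wave_order": [list(p) for p in self.wave_order],
                "warnings": self.warnings,
            },
            indent=2,
        )

    def to_dot(self) -> str:
        lines = ["digraph migration {"]
        for s in sorted(self.graph.nodes):
            shape = "doubleoctagon" if s in self.incubators else "ellipse"
            lines.append(f'  "{s}" [shape={shape}];')
        color = {MONOCLONAL: "blue", POLYCLONAL: "green", RECOLONIZATION: "red"}
        for e in self.events:
            lines.append(
                f'  "{e.source_site}" -> "{e.target_site}" '
                f'[color={color[e.kind]}, label="{"+".join(e.subclones)}"];'
            )
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _tree_distance(tree: nx.DiGraph, a: str, b: str) -> int:
    und = tree.to_undirected(as_view=True)
    try:
        return nx.shortest_path_length(und, a, b)
    except nx.NetworkXNoPath:
        return 10 ** 6


def _ancestors(tree: nx.DiGraph, node: str) -> set[str]:
    return nx.ancestors(tree, node)


# ---------------------------------------------------------------------------
# Seeding classification
# ---------------------------------------------------------------------------

def classify_seeding(
    atlas: SubcloneAtlas,
    joint_tree: nx.DiGraph,
    full_threshold: float = 0.9,
    low_threshold: float = 0.5,
    presence_threshold: float = 0.05,
    waves: dict[str, str] | None = None,
) -> list[SeedingEvent]:
    """Classify monoclonal and polyclonal seeding events.

    A site is *founded* by the most derived subclone whose prevalence there
    reaches ``full_threshold`` (its full-prevalence ancestors were carried
    along in the same cells, not seeded separately).  The founding subclone
    *emerged* at a harbor site where its prevalence is positive but partial;
    the monoclonal edge runs harbor -> founded site, choosing among harbors
    by tree distance to the nearest resident subclone, then by that
    neighbor's prevalence, wave and site name.  Pairs of related subclones
    both below ``low_threshold`` in a pair of sites mark polyclonal
    co-seeding, directed from the site holding their (non-ubiquitous)
    ancestors at higher prevalence.
    """
    missing = set(atlas.subclones) ^ set(joint_tree.nodes)
    if missing:
        raise UsageError(f"atlas and joint tree disagree on subclones: {sorted(missing)}")
    P = atlas.presence
    waves = waves or {}
    events: list[SeedingEvent] = []

    def wave_rank(site: str) -> tuple:
        w = waves.get(site)
        return (0, w) if w is not None else (1, site)

    def harbor_score(s: str, h: str) -> tuple:
        scored = sorted(
            (_tree_distance(joint_tree, s, u), -float(P.loc[u, h]))
            for u in atlas.subclones
            if u != s and P.loc[u, h] >= presence_threshold
        ) or [(10 ** 6, 0.0)]
        return (*scored[0], wave_rank(h), h)

    for t in atlas.sites:
        full = {s for s in atlas.subclones if P.loc[s, t] >= full_threshold}
        deepest = sorted(s for s in full if not (nx.descendants(joint_tree, s) & full))
        for s in deepest:
            row = P.loc[s]
            founded = {u for u in atlas.sites if row[u] >= full_threshold}
            harbors = [h for h in atlas.sites
                       if presence_threshold <= row[h] < full_threshold]
            if not harbors:
                parents = list(joint_tree.predecessors(s))
                if not parents:
                    continue  # the truncal clone: its site is the primary
                prow = P.loc[parents[0]]
                harbors = [h for h in atlas.sites
                           if prow[h] >= presence_threshold and h not in founded]
                if not harbors:
                    logger.warning("subclone %s has no harbor site; skipped", s)
                    continue
                logger.info("subclone %s origin set to its parent's site", s)
            source = min(harbors, key=lambda h: harbor_score(s, h))
            if source != t:
                events.append(
                    SeedingEvent(source, t, (s,), MONOCLONAL, wave=waves.get(t))
                )

    # polyclonal: >=2 related subclones at low prevalence in both sites
    for a, b in itertools.combinations(atlas.sites, 2):
        clones = [
            s for s in atlas.subclones
            if presence_threshold <= P.loc[s, a] < low_threshold
            and presence_threshold <= P.loc[s, b] < low_threshold
        ]
        related = []
        for x, y in itertools.combinations(clones, 2):
            if (
                y in nx.descendants(joint_tree, x)
                or x in nx.descendants(joint_tree, y)
                or set(joint_tree.predecessors(x)) & set(joint_tree.predecessors(y))
            ):
                related.extend([x, y])
        group = tuple(sorted(set(related)))
        if len(group) < 2:
            continue

        def anc_score(site: str) -> float:
            # ancestors at full prevalence in both sites carry no direction
            ancs = set().union(*(_ancestors(joint_tree, g) for g in group))
            informative = [
                u for u in ancs
                if P.loc[u, a] < full_threshold or P.loc[u, b] < full_threshold
            ]
            return max((float(P.loc[u, site]) for u in informative), default=0.0)

        src, tgt = (a, b) if anc_score(a) >= anc_score(b) else (b, a)
        events.append(SeedingEvent(src, tgt, group, POLYCLONAL, wave=waves.get(tgt)))
    return events


def detect_recolonization(
    atlas: SubcloneAtlas,
    joint_tree: nx.DiGraph,
    presence_threshold: float = 0.1,
) -> list[SeedingEvent]:
    """Find descendant subclones that evolved elsewhere and invaded back.

    Site A is recolonized by subclone Y from site B when A holds Y and an
    ancestor X of Y, at least one intermediate on the X->Y path is absent
    from A, and every such missing intermediate is present exclusively at B.

    "Present" here means cells of *exactly* that subclone: its mutational
    prevalence minus its children's (a clone's variants ride along in every
    descendant cell, so cumulative prevalence alone cannot expose a missing
    intermediate).
    """
    P = atlas.presence
    exact = P.copy()
    for s in atlas.subclones:
        kids = list(joint_tree.successors(s))
        if kids:
            exact.loc[s] = P.loc[s] - P.loc[kids].sum(axis=0)
    events: list[SeedingEvent] = []
    seen: set[tuple] = set()
    for site in atlas.sites:
        present = {s for s in atlas.subclones if exact.loc[s, site] >= presence_threshold}
        for x, y in itertools.combinations(sorted(present), 2):
            if x in nx.ancestors(joint_tree, y):
                anc, desc = x, y
            elif y in nx.ancestors(joint_tree, x):
                anc, desc = y, x
            else:
                continue
            path = nx.shortest_path(joint_tree, anc, desc)
            intermediates = path[1:-1]
            missing = [m for m in intermediates if m not in present]
            if not missing:
                continue
            sources = set()
            exclusive = True
            for m in missing:
                sites_m = [t for t in atlas.sites if exact.loc[m, t] >= presence_threshold]
                if len(sites_m) != 1:
                    exclusive = False
                sources.update(sites_m)
            sources.discard(site)
            if not sources or not exclusive:
                continue
            ambiguous = len(sources) > 1
            for b in sorted(sources):
                key = (b, site, desc)
                if key in seen:
                    continue
                seen.add(key)
                events.append(
                    SeedingEvent(b, site, (desc,), RECOLONIZATION, ambiguous=ambiguous)
                )
    return events


def detect_incubators(
    events: list[SeedingEvent],
    joint_tree: nx.DiGraph,
    min_chain: int = 2,
) -> set[str]:
    """Sites where an ancestor-descendant chain of subclones each sourced at
    least one outgoing seeding event."""
    by_site: dict[str, set[str]] = {}
    for e in events:
        for s in e.subclones:
            by_site.setdefault(e.source_site, set()).add(s)
    incubators = set()
    for site, clones in by_site.items():
        if len(clones) < min_chain:
            continue
        # longest ancestor-descendant chain within the site's seeding clones
        sub = nx.DiGraph()
        sub.add_nodes_from(clones)
        for x in clones:
            for y in clones:
                if x != y and y in nx.descendants(joint_tree, x):
                    sub.add_edge(x, y)
        longest = len(nx.dag_longest_path(sub))
        if longest >= min_chain:
            incubators.add(site)
    return incubators


# ---------------------------------------------------------------------------
# Graph and waves
# ---------------------------------------------------------------------------

def wave_order_from_allele_states(
    group_states: dict[str, dict[str, AlleleSpecificState]],
) -> list[tuple[str, str]]:
    """Partial order over groups from allele-state precedence at group-defining
    loci: ``(earlier, later)`` pairs, transitively closed.  Contradictory loci
    raise with both loci named.
    """
    pairs: dict[tuple[str, str], list[str]] = {}
    for locus_name, states in group_states.items():
        for g1, g2 in itertools.combinations(sorted(states), 2):
            rel = order_allele_states(states[g1], states[g2])
            if rel is Order.PRECEDES:
                pairs.setdefault((g1, g2), []).append(locus_name)
            elif rel is Order.FOLLOWS:
                pairs.setdefault((g2, g1), []).append(locus_name)
    order = nx.DiGraph()
    for (a, b), loci in pairs.items():
        if (b, a) in pairs:
            raise UsageError(
                f"contradictory wave order between {a} and {b}: "
                f"loci {loci} vs {pairs[(b, a)]}"
            )
        order.add_edge(a, b)
    if not nx.is_directed_acyclic_graph(order):
        cycle = nx.find_cycle(order)
        raise UsageError(f"cycle among waves: {cycle}")
    closure = nx.transitive_closure_dag(order)
    return sorted(closure.edges)


def build_graph(
    events: list[SeedingEvent],
    groups: dict[str, str] | None = None,
    group_states: dict[str, dict[str, AlleleSpecificState]] | None = None,
    joint_tree: nx.DiGraph | None = None,
    min_chain: int = 2,
) -> MigrationGraph:
    """Assemble the migration graph with wave ordering and consistency checks.

    Edge directions contradicting the wave partial order (an edge from a
    later-wave site into an earlier-wave site's founding) are reported as
    warnings, never silently reversed.
    """
    groups = groups or {}
    wave_order = (
        wave_order_from_allele_states(group_states) if group_states else []
    )
    later_than: dict[str, set[str]] = {}
    for a, b in wave_order:
        later_than.setdefault(b, set()).add(a)

    g = nx.DiGraph()
    warnings: list[str] = []
    for e in events:
        g.add_node(e.source_site)
        g.add_node(e.target_site)
        g.add_edge(e.source_site, e.target_site, event=e)
        gs, gt = groups.get(e.source_site), groups.get(e.target_site)
        if gs and gt and gt in later_than.get(gs, set()):
            warnings.append(
                f"edge {e.source_site}->{e.target_site} runs from wave {gs} "
                f"into earlier wave {gt}"
            )
    incubators = (
        detect_incubators(events, joint_tree, min_chain=min_chain)
        if joint_tree is not None else set()
    )
    return MigrationGraph(
        graph=g, events=list(events), incubators=incubators,
        wave_order=wave_order, warnings=warnings,
    )
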