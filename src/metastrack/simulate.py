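"""Ground-truth simulator for multi-site metastatic cohorts.

The simulator emulates the study design the pipeline targets: one patient,
8-30 tumor sites sampled across organs, ~45-60x whole-genome sequencing with
two matched normals.  A rooted subclone tree carries Poisson-distributed
marker mutations per branch on a copy-stable chromosome (infinite sites:
every variant arises once, at a unique position).  Each site is a mixture of
clones given by *exact* cell fractions; the mutational (cumulative)
prevalence of a clone at a site is the summed fraction of its subtree, so
parent/child sum constraints hold with zero slack by construction.  Reads
are drawn per site and variant as Binomial(depth, expected AF) with
Poisson-distributed depth, purity dilution, and a per-base sequencing error
rate that exercises the somatic-calling clauses.

Scripted scenarios plant the canonical seeding patterns — jumping board,
incubator, recolonization, polyclonal co-seeding, and four CNV-defined
metastatic waves with an allele-state time ordering — together with the
truth events a perfect pipeline must recover.

All randomness flows through one ``numpy`` Generator keyed by the config
seed; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from metastrack.cnv import CopyNumberSegment
from metastrack.errors import ConfigurationError, UsageError
from metastrack.migration import (
    MONOCLONAL,
    POLYCLONAL,
    RECOLONIZATION,
    SeedingEvent,
)
from metastrack.variant_io import MultiSampleVariantTable

DEFAULT_CHROM_LENGTHS = {
    "chr1": 5_000_000,
    "chr2": 5_000_000,
    "chr3": 5_000_000,
    "chr4": 5_000_000,
    "chr14": 5_000_000,
}

SCENARIOS = (
    "jumping_board",
    "incubator",
    "recolonization",
    "polyclonal",
    "four_waves",
)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults mirror the target study design: ~60x depth, two normal skin
    samples, tumor purity above 0.6, and about 33 marker mutations defining
    each subclone.
    """

    seed: int = 0
    n_subclones: int = 6
    tree_shape: str | tuple[int, ...] = "random"   # "random" | "chain" | parent array
    muts_per_branch: float = 33.0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    stable_chrom: str = "chr14"
    n_sites: int = 8
    purity_range: tuple[float, float] = (0.6, 1.0)
    depth_mean: float | None = 60.0                # None -> noiseless exact counts
    n_normals: int = 2
    germline_het_spacing: int | None = 2000        # None -> no inherited hets
    het_chroms: tuple[str, ...] | None = None      # default: all CNV-capable chroms
    error_rate: float = 1e-3
    site_qual: float = 60.0
    min_terminal_prevalence: float = 0.5

    def __post_init__(self):
        if self.n_subclones < 1:
            raise ConfigurationError("n_subclones must be >= 1")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ConfigurationError("purity_range must lie in (0, 1]")


@dataclass
class CloneTree:
    """Rooted subclone tree with per-branch marker variants.

    ``parents[k]`` is the parent index of clone ``k`` (root has -1);
    ``clone_variants[k]`` lists (chrom, pos) of the variants acquired on the
    branch into clone ``k``.
    """

    parents: tuple[int, ...]
    clone_variants: list[list[tuple[str, int]]]

    @property
    def n_clones(self) -> int:
        return len(self.parents)

    @property
    def names(self) -> list[str]:
        return [f"Sc{k + 1}" for k in range(self.n_clones)]

    def children(self, k: int) -> list[int]:
        return [i for i, p in enumerate(self.parents) if p == k]

    def subtree(self, k: int) -> set[int]:
        out, stack = set(), [k]
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(self.children(n))
        return out

    def path_from_root(self, k: int) -> list[int]:
        path = [k]
        while self.parents[path[-1]] >= 0:
            path.append(self.parents[path[-1]])
        return path[::-1]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        names = self.names
        g.add_nodes_from(names)
        for k, p in enumerate(self.parents):
            if p >= 0:
                g.add_edge(names[p], names[k])
        return g


def _make_parents(shape, n: int, rng: np.random.Generator) -> tuple[int, ...]:
    if isinstance(shape, (tuple, list)):
        parents = tuple(int(x) for x in shape)
        if len(parents) != n or parents[0] != -1:
            raise ConfigurationError("scripted parent array must have length "
                                     "n_subclones and root -1 first")
        return parents
    if shape == "chain":
        return tuple(range(-1, n - 1))
    if shape == "random":
        return tuple([-1] + [int(rng.integers(0, k)) for k in range(1, n)])
    raise ConfigurationError(f"unknown tree_shape {shape!r}")


def simulate_tree(config: SimulationConfig, rng: np.random.Generator) -> CloneTree:
    """Draw the clone tree and its marker variants.

    Each branch carries ``max(1, Poisson(muts_per_branch))`` variants at
    unique positions on the copy-stable chromosome — at least one, so every
    branch is observable by presence/absence.
    """
    parents = _make_parents(config.tree_shape, config.n_subclones, rng)
    counts = np.maximum(1, rng.poisson(config.muts_per_branch, size=len(parents)))
    length = config.chrom_lengths[config.stable_chrom]
    total = int(counts.sum())
    pool = rng.choice(length - 1, size=min(length - 1, 4 * total), replace=False) + 1
    if config.germline_het_spacing:
        # avoid the germline het grid (multiples of spacing)
        pool = pool[pool % config.germline_het_spacing != 0]
    pool = pool[:total]
    if len(pool) < total:
        raise ConfigurationError("chromosome too short for requested mutation count")
    variants, k0 = [], 0
    for c in counts:
        variants.append(
            [(config.stable_chrom, int(p)) for p in sorted(pool[k0:k0 + c])]
        )
        k0 += c
    return CloneTree(parents=parents, clone_variants=variants)


# ---------------------------------------------------------------------------
# Compositions
# ---------------------------------------------------------------------------

def prevalence_matrix(tree: CloneTree, fractions: pd.DataFrame) -> pd.DataFrame:
    """Cumulative (mutational) prevalence: per site, the summed exact cell
    fraction of each clone's subtree."""
    prev = pd.DataFrame(0.0, index=fractions.index, columns=fractions.columns)
    for k in range(tree.n_clones):
        cols = sorted(tree.subtree(k))
        prev[k] = fractions[cols].sum(axis=1)
    return prev


def default_composition(
    tree: CloneTree,
    n_sites: int,
    rng: np.random.Generator,
    min_terminal_prevalence: float = 0.5,
) -> pd.DataFrame:
    """Clean site compositions: each site holds one root-to-clone path.

    The first ``n_clones`` sites cover every clone as a terminal (in random
    order); extra sites draw random terminals.  Prevalence decreases linearly
    from 1 at the root to ``min_terminal_prevalence`` at the terminal, so
    every path clone is present and detectable.
    """
    n = tree.n_clones
    terminals = list(rng.permutation(n))
    while len(terminals) < n_sites:
        terminals.append(int(rng.integers(0, n)))
    terminals = terminals[:n_sites]
    sites = [f"S{i + 1:02d}" for i in range(n_sites)]
    frac = pd.DataFrame(0.0, index=sites, columns=range(n))
    for site, t in zip(sites, terminals):
        path = tree.path_from_root(t)
        prev = np.linspace(1.0, min_terminal_prevalence, len(path))
        exact = np.append(prev[:-1] - prev[1:], prev[-1])
        for k, f in zip(path, exact):
            frac.loc[site, k] = f
    return frac


def add_mixture_sites(
    tree: CloneTree,
    fractions: pd.DataFrame,
    n_mixture: int,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str]]:
    """Append sites mixing two incomparable lineages half-and-half.

    Such sites violate the laminar structure of clean compositions and must
    be flagged as mixtures by the phylogeny stage.
    """
    pairs = [
        (a, b)
        for a in range(tree.n_clones)
        for b in range(a + 1, tree.n_clones)
        if a not in tree.subtree(b) and b not in tree.subtree(a)
    ]
    if not pairs:
        raise UsageError("tree has no incomparable clone pair to mix")
    out = fractions.copy()
    names = []
    for i in range(n_mixture):
        a, b = pairs[int(rng.integers(0, len(pairs)))]
        name = f"MX{i + 1}"
        row = pd.Series(0.0, index=fractions.columns)
        for t, share in ((a, 0.5), (b, 0.5)):
            path = tree.path_from_root(t)
            prev = np.linspace(share, share * 0.6, len(path))
            exact = np.append(prev[:-1] - prev[1:], prev[-1])
            for k, f in zip(path, exact):
                row[k] += f
        out.loc[name] = row
        names.append(name)
    return out, names


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _het_af(count_a: int, count_b: int, allele_is_b: bool, purity: float) -> float:
    m = count_b if allele_is_b else count_a
    c = count_a + count_b
    return (purity * m + (1 - purity)) / (purity * c + (1 - purity) * 2)


def simulate_reads(
    config: SimulationConfig,
    tree: CloneTree,
    fractions: pd.DataFrame,
    rng: np.random.Generator,
    purities: dict[str, float] | None = None,
    site_states: dict[tuple[str, str], tuple[int, int]] | None = None,
):
    """Draw per-sample read counts for somatic markers and germline hets.

    Somatic expected AF at a site is ``purity * prevalence / 2`` (het marker
    on a copy-stable diploid chromosome, diluted by normal contamination).
    Germline het AFs follow the allele-specific copy state of the site at
    that chromosome (diploid 1+1 unless overridden by ``site_states``).
    With ``depth_mean=None`` counts are exact (depth 1000, no error reads).

    Returns ``(table, variant_clone, purities)`` where ``variant_clone[i]``
    is the originating clone index of record ``i`` (-1 for germline hets).
    """
    sites = list(fractions.index)
    normals = [f"N{i + 1}" for i in range(config.n_normals)]
    samples = sites + normals
    if purities is None:
        lo, hi = config.purity_range
        purities = {s: float(rng.uniform(lo, hi)) for s in sites}
    site_states = site_states or {}
    prev = prevalence_matrix(tree, fractions)
    noiseless = config.depth_mean is None

    chroms, poss, refs, alts = [], [], [], []
    af_rows, clone_of = [], []

    # germline hets: on a fixed grid, each on one parental allele
    if config.germline_het_spacing:
        het_chroms = config.het_chroms or tuple(
            c for c in config.chrom_lengths if c != config.stable_chrom
        )
        for chrom in het_chroms:
            positions = np.arange(
                config.germline_het_spacing,
                config.chrom_lengths[chrom],
                config.germline_het_spacing,
            )
            on_b = rng.random(len(positions)) < 0.5
            for pos, b in zip(positions, on_b):
                row = [
                    _het_af(*site_states.get((s, chrom), (1, 1)), b, purities[s])
                    for s in sites
                ] + [0.5] * len(normals)
                chroms.append(chrom)
                poss.append(int(pos))
                refs.append("A")
                alts.append("G")
                af_rows.append(row)
                clone_of.append(-1)

    # somatic markers on the stable chromosome
    for k in range(tree.n_clones):
        for chrom, pos in tree.clone_variants[k]:
            row = [purities[s] * float(prev.loc[s, k]) / 2.0 for s in sites]
            row += [0.0] * len(normals)
            chroms.append(chrom)
            poss.append(pos)
            refs.append("C")
            alts.append("T")
            af_rows.append(row)
            clone_of.append(k)

    order = sorted(
        range(len(poss)),
        key=lambda i: (list(config.chrom_lengths).index(chroms[i]), poss[i]),
    )
    chroms = [chroms[i] for i in order]
    poss = [poss[i] for i in order]
    refs = [refs[i] for i in order]
    alts = [alts[i] for i in order]
    clone_of = np.asarray([clone_of[i] for i in order], dtype=int)
    af = np.asarray([af_rows[i] for i in order], dtype=float)

    n, s = af.shape
    if noiseless:
        depth = np.full((n, s), 1000, dtype=int)
        alt_count = np.rint(af * 1000).astype(int)
    else:
        depth = rng.poisson(config.depth_mean, size=(n, s))
        depth = np.maximum(depth, 1)
        q = af + (1 - af) * config.error_rate
        alt_count = rng.binomial(depth, q)

    table = MultiSampleVariantTable(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        qual=np.full(n, config.site_qual),
        multiallelic=np.zeros(n, dtype=bool),
        samples=samples,
        normal_samples=normals,
        depth=depth,
        alt_count=alt_count,
        meta={"seed": config.seed},
    )
    return table, clone_of, purities


# ---------------------------------------------------------------------------
# Scripted scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    name: str
    parents: tuple[int, ...]
    fractions: pd.DataFrame                       # exact clone fractions
    truth_events: list[SeedingEvent]              # subclones given as truth clone names
    incubators: set[str]
    groups: dict[str, str]                        # site -> group / "ungrouped"
    site_states: dict[tuple[str, str], tuple[int, int]]
    segment_overrides: dict[str, list[tuple[str, int, int, int, int]]]
    allele_locus: tuple[str, int, int] | None = None
    wave_order: list[tuple[str, str]] = field(default_factory=list)


def _fractions(parents, site_fracs: dict[str, dict[int, float]]) -> pd.DataFrame:
    n = len(parents)
    df = pd.DataFrame(0.0, index=list(site_fracs), columns=range(n))
    for site, d in site_fracs.items():
        for k, f in d.items():
            df.loc[site, k] = f
    return df


def script_scenario(name: str, config: SimulationConfig) -> ScenarioBundle:
    """Compositions and truth events realizing a named seeding pattern."""
    L = config.chrom_lengths
    if name == "jumping_board":
        parents = (-1, 0, 1, 1)
        frac = _fractions(parents, {
            "BrP": {0: 0.5, 1: 0.5},
            "Ln1": {1: 0.1, 2: 0.6, 3: 0.3},
            "M1": {2: 1.0},
            "M2": {3: 1.0},
        })
        events = [
            SeedingEvent("BrP", "Ln1", ("Sc2",), MONOCLONAL),
            SeedingEvent("Ln1", "M1", ("Sc3",), MONOCLONAL),
            SeedingEvent("Ln1", "M2", ("Sc4",), MONOCLONAL),
        ]
        return ScenarioBundle(name, parents, frac, events, set(),
                              {s: "ungrouped" for s in frac.index}, {}, {})
    if name == "incubator":
        parents = (-1, 0, 1, 2, 3)
        frac = _fractions(parents, {
            "BrP": {0: 0.5, 1: 0.5},
            "Ln10": {1: 0.4, 2: 0.2, 3: 0.2, 4: 0.2},
            "T2": {2: 1.0},
            "T3": {3: 1.0},
            "T4": {4: 1.0},
        })
        events = [
            SeedingEvent("BrP", "Ln10", ("Sc2",), MONOCLONAL),
            SeedingEvent("Ln10", "T2", ("Sc3",), MONOCLONAL),
            SeedingEvent("Ln10", "T3", ("Sc4",), MONOCLONAL),
            SeedingEvent("Ln10", "T4", ("Sc5",), MONOCLONAL),
        ]
        return ScenarioBundle(name, parents, frac, events, {"Ln10"},
                              {s: "ungrouped" for s in frac.index}, {}, {})
    if name == "recolonization":
        parents = (-1, 0, 1, 2, 3)
        frac = _fractions(parents, {
            "BrP": {0: 0.5, 1: 0.5},
            "Ln1": {1: 0.7, 4: 0.3},
            "Ln2": {2: 0.4, 3: 0.4, 4: 0.2},
        })
        events = [
            SeedingEvent("BrP", "Ln1", ("Sc2",), MONOCLONAL),
            SeedingEvent("Ln1", "Ln2", ("Sc3",), MONOCLONAL),
            SeedingEvent("Ln2", "Ln1", ("Sc5",), RECOLONIZATION),
        ]
        return ScenarioBundle(name, parents, frac, events, set(),
                              {s: "ungrouped" for s in frac.index}, {}, {})
    if name == "polyclonal":
        parents = (-1, 0, 1, 1)
        frac = _fractions(parents, {
            "Pa1": {0: 0.2, 1: 0.25, 2: 0.3, 3: 0.25},
            "Lv4": {0: 0.35, 1: 0.2, 2: 0.25, 3: 0.2},
            "Lv5": {2: 1.0},
        })
        events = [
            SeedingEvent("Pa1", "Lv5", ("Sc3",), MONOCLONAL),
            SeedingEvent("Pa1", "Lv4", ("Sc3", "Sc4"), POLYCLONAL),
        ]
        return ScenarioBundle(name, parents, frac, events, set(),
                              {s: "ungrouped" for s in frac.index}, {}, {})
    if name == "four_waves":
        parents = (-1, 0, 1, 2, 2, 2)
        site_fracs = {
            "BrP": {0: 0.6, 1: 0.1, 2: 0.3},
            "Ln0": {2: 0.1, 3: 0.4, 4: 0.3, 5: 0.2},
            "G1a": {1: 1.0}, "G1b": {1: 1.0},
            "G2a": {3: 1.0}, "G2b": {3: 1.0},
            "G3a": {4: 1.0}, "G3b": {4: 1.0},
            "G4a": {5: 1.0}, "G4b": {5: 1.0},
        }
        frac = _fractions(parents, site_fracs)
        events = [
            SeedingEvent("BrP", "G1a", ("Sc2",), MONOCLONAL),
            SeedingEvent("BrP", "G1b", ("Sc2",), MONOCLONAL),
            SeedingEvent("BrP", "Ln0", ("Sc3",), MONOCLONAL),
            SeedingEvent("Ln0", "G2a", ("Sc4",), MONOCLONAL),
            SeedingEvent("Ln0", "G2b", ("Sc4",), MONOCLONAL),
            SeedingEvent("Ln0", "G3a", ("Sc5",), MONOCLONAL),
            SeedingEvent("Ln0", "G3b", ("Sc5",), MONOCLONAL),
            SeedingEvent("Ln0", "G4a", ("Sc6",), MONOCLONAL),
            SeedingEvent("Ln0", "G4b", ("Sc6",), MONOCLONAL),
        ]
        groups = {s: (s[:2] if s.startswith("G") else "ungrouped")
                  for s in frac.index}
        # the gap spans a full 1-Mb bin so binning keeps two discrete events
        gap = (2 * L["chr2"] // 5, 3 * L["chr2"] // 5)
        site_states = {}
        overrides: dict[str, list] = {s: [] for s in frac.index}
        for s in frac.index:
            g = groups[s]
            if g == "G1":
                overrides[s] += [("chr1", 0, L["chr1"], 2, 1),
                                 ("chr3", 0, L["chr3"], 2, 1)]
                site_states[(s, "chr3")] = (2, 1)
            elif g == "G2":
                overrides[s] += [("chr2", 0, gap[0], 1, 0),
                                 ("chr2", gap[1], L["chr2"], 1, 0)]
            elif g == "G3":
                overrides[s] += [("chr4", 0, gap[0], 1, 0),
                                 ("chr4", gap[1], L["chr4"], 1, 0)]
            elif g == "G4":
                overrides[s] += [("chr1", 0, gap[0], 1, 0),
                                 ("chr1", gap[1], L["chr1"], 1, 0)]
            if g in ("G2", "G3", "G4"):
                overrides[s].append(("chr3", 0, L["chr3"], 2, 0))
                site_states[(s, "chr3")] = (2, 0)
        wave_order = [("G1", "G2"), ("G1", "G3"), ("G1", "G4")]
        return ScenarioBundle(name, parents, frac, events, {"BrP"}, groups,
                              site_states, overrides,
                              allele_locus=("chr3", 0, L["chr3"]),
                              wave_order=wave_order)
    raise UsageError(f"unknown scenario {name!r}; options: {', '.join(SCENARIOS)}")


# ---------------------------------------------------------------------------
# Segments and cohort assembly
# ---------------------------------------------------------------------------

def build_segments(
    sites: list[str],
    chrom_lengths: dict[str, int],
    overrides: dict[str, list[tuple[str, int, int, int, int]]] | None = None,
) -> list[CopyNumberSegment]:
    """FACETS-like segment tables per site: diploid baseline plus allele-
    specific overrides (chrom, start, end, count_a, count_b)."""
    overrides = overrides or {}
    segs: list[CopyNumberSegment] = []
    for site in sites:
        per_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
        for chrom, start, end, a, b in overrides.get(site, []):
            per_chrom.setdefault(chrom, []).append((start, end, a, b))
        for chrom, length in chrom_lengths.items():
            events = sorted(per_chrom.get(chrom, []))
            cursor = 0
            for start, end, a, b in events:
                if start > cursor:
                    segs.append(CopyNumberSegment(site, chrom, cursor, start, 2, 0.0, False))
                cn = a + b
                log2 = float(np.log2(cn / 2)) if cn > 0 else -3.0
                segs.append(
                    CopyNumberSegment(site, chrom, start, end, cn, log2, min(a, b) == 0)
                )
                cursor = end
            if cursor < length:
                segs.append(CopyNumberSegment(site, chrom, cursor, length, 2, 0.0, False))
    return segs


@dataclass
class Cohort:
    """A simulated cohort: inputs in pipeline formats plus the truth bundle."""

    config: SimulationConfig
    tree: CloneTree
    fractions: pd.DataFrame
    prevalence: pd.DataFrame
    purities: dict[str, float]
    table: MultiSampleVariantTable
    variant_clone: np.ndarray
    segments: list[CopyNumberSegment]
    scenario: ScenarioBundle | None = None
    mixture_sites: list[str] = field(default_factory=list)

    @property
    def sites(self) -> list[str]:
        return list(self.fractions.index)

    def truth_sample_sets(self) -> set[frozenset]:
        """Per clone, the set of sites carrying its mutations (nonempty only)."""
        out = set()
        for k in range(self.tree.n_clones):
            ss = frozenset(s for s in self.sites if self.prevalence.loc[s, k] > 0)
            if ss:
                out.add(ss)
        return out

    def truth_json(self) -> str:
        return json.dumps(
            {
                "seed": self.config.seed,
                "parents": list(self.tree.parents),
                "clone_names": self.tree.names,
                "fractions": self.fractions.round(6).to_dict(),
                "purities": self.purities,
                "n_variants_per_clone": [len(v) for v in self.tree.clone_variants],
                "mixture_sites": self.mixture_sites,
                "scenario": None if self.scenario is None else {
                    "name": self.scenario.name,
                    "events": [
                        {"source": e.source_site, "target": e.target_site,
                         "kind": e.kind, "subclones": list(e.subclones)}
                        for e in self.scenario.truth_events
                    ],
                    "incubators": sorted(self.scenario.incubators),
                    "groups": self.scenario.groups,
                    "wave_order": [list(p) for p in self.scenario.wave_order],
                },
            },
            indent=2,
        )


def simulate_cohort(
    config: SimulationConfig,
    scenario: str | None = None,
    n_mixture_sites: int = 0,
) -> Cohort:
    """Top-level entry: tree, compositions (scripted or clean), reads, segments."""
    rng = np.random.default_rng(config.seed)
    bundle = None
    if scenario is not None:
        bundle = script_scenario(scenario, config)
        config = SimulationConfig(**{**asdict(config),
                                     "n_subclones": len(bundle.parents),
                                     "tree_shape": bundle.parents})
    tree = simulate_tree(config, rng)
    if bundle is not None:
        fractions = bundle.fractions
    else:
        fractions = default_composition(
            tree, config.n_sites, rng, config.min_terminal_prevalence
        )
    mixture_sites: list[str] = []
    if n_mixture_sites:
        fractions, mixture_sites = add_mixture_sites(tree, fractions, n_mixture_sites, rng)
    table, clone_of, purities = simulate_reads(
        config, tree, fractions, rng,
        site_states=bundle.site_states if bundle else None,
    )
    segments = build_segments(
        list(fractions.index), config.chrom_lengths,
        bundle.segment_overrides if bundle else None,
    )
    return Cohort(
        config=config, tree=tree, fractions=fractions,
        prevalence=prevalence_matrix(tree, fractions),
        purities=purities, table=table, variant_clone=clone_of,
        segments=segments, scenario=bundle, mixture_sites=mixture_sites,
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_vcf(table: MultiSampleVariantTable, path, chrom_lengths=None) -> None:
    """Emit a plain-text VCF 4.2 with per-sample GT:DP:AD."""
    af = table.af
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in range(table.n_records):
            cells = []
            for j in range(len(table.samples)):
                dp = int(table.depth[i, j])
                ad = int(table.alt_count[i, j])
                gt = "0/1" if ad > 0 and not np.isnan(af[i, j]) and af[i, j] > 0.05 else "0/0"
                cells.append(f"{gt}:{dp}:{dp - ad},{ad}")
            fh.write(
                f"{table.chrom[i]}\t{table.pos[i]}\t.\t{table.ref[i]}\t"
                f"{table.alt[i]}\t{table.qual[i]:.0f}\tPASS\t.\tGT:DP:AD\t"
                + "\t".join(cells) + "\n"
            )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write VCF, segments TSV, purity TSV and the truth JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(cohort.table, out / "cohort.vcf", cohort.config.chrom_lengths)
    seg = pd.DataFrame(
        [
            (s.sample, s.chrom, s.start, s.end, s.total_cn, round(s.log2_ratio, 4),
             int(s.loh))
            for s in cohort.segments
        ],
        columns=["sample", "chrom", "start", "end", "total_cn", "log2_ratio", "loh"],
    )
    seg.to_csv(out / "segments.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(cohort.purities.items()), columns=["sample", "purity"]
    ).to_csv(out / "purity.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(cohort.truth_json())


def simulate_expression(
    n_genes: int,
    chrom: str,
    tumor_samples: list[str],
    normal_samples: list[str],
    amplified: tuple[int, int] | None = None,
    fold: float = 2.0,
    base_tpm: float = 100.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Toy TPM matrix with an optional amplified gene block in tumors.

    Returns (expression genes x samples, gene chromosome Series); genes are
    position-ordered.  ``amplified`` is a (start_index, end_index) gene range
    whose tumor expression is scaled by ``fold``.
    """
    rng = rng or np.random.default_rng(0)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    samples = list(tumor_samples) + list(normal_samples)
    tpm = np.full((n_genes, len(samples)), base_tpm)
    if noise_sd:
        tpm = tpm * np.exp(rng.normal(0, noise_sd, size=tpm.shape))
    if amplified is not None:
        lo, hi = amplified
        for j, s in enumerate(samples):
            if s in tumor_samples:
                tpm[lo:hi, j] *= fold
    expr = pd.DataFrame(tpm, index=genes, columns=samples)
    return expr, pd.Series(chrom, index=genes)
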