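"""End-to-end orchestration: variant table -> subclone tree -> migration graph.

These helpers wire the stage modules together the way the full analysis
runs: somatic calling, VAF clustering on the copy-stable chromosome,
purity-corrected prevalences, tree enumeration, and seeding classification.
They are also the entry points the cohort simulator's outputs are scored
through.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from metastrack import migration, phylogeny, subclones
from metastrack.cnv import AlleleSpecificState, infer_allele_state_pair
from metastrack.errors import UsageError
from metastrack.variant_io import INHERITED, MultiSampleVariantTable


def somatic_af_matrix(
    table: MultiSampleVariantTable,
    samples: list[str],
    chroms: list[str] | None = None,
):
    """(af matrix, variant ids) of somatic records on the given chromosomes."""
    rows = table.somatic_flags.copy()
    if chroms is not None:
        rows &= np.isin(table.chrom, np.asarray(chroms, dtype=object))
    sub = table.subset(rows)
    cols = sub.sample_index(samples)
    af = sub.af[:, cols]
    ids = [f"{c}:{p}:{r}>{a}" for c, p, r, a in zip(sub.chrom, sub.pos, sub.ref, sub.alt)]
    return np.nan_to_num(af, nan=0.0), ids, sub.depth[:, cols]


def reconstruct_subclones(
    table: MultiSampleVariantTable,
    purities: dict[str, float],
    samples: list[str] | None = None,
    chroms: list[str] | None = None,
    af_positive: float = 0.05,
    merge_tol: float = 0.1,
    tolerance: float = 0.1,
    min_cluster_size: int = 5,
) -> subclones.SolutionSet:
    """Cluster somatic AFs, correct to prevalences, and enumerate trees."""
    samples = samples if samples is not None else table.tumor_samples
    af, ids, depth = somatic_af_matrix(table, samples, chroms)
    clusters = subclones.cluster_vafs(af, ids, samples, af_positive, merge_tol, depth)
    clusters = subclones.consolidate_clusters(clusters, min_cluster_size)
    subclones.set_prevalences(clusters, purities, af_positive=af_positive)
    sol = subclones.enumerate_trees(clusters, tolerance, af_positive)
    # measurement-noise escalation: if no tree fits at the nominal tolerance,
    # widen it stepwise rather than fail the whole analysis
    for relax in (1.5, 2.0):
        if sol.chosen is not None or not clusters:
            break
        sol = subclones.enumerate_trees(clusters, tolerance * relax, af_positive)
        sol.diagnostics.append(f"tolerance relaxed to {tolerance * relax:g}")
    return sol


def atlas_from_solution(
    solution: subclones.SolutionSet,
) -> tuple[migration.SubcloneAtlas, "pd.DataFrame"]:
    """Subclone x site prevalence atlas and joint tree from a chosen solution."""
    if solution.chosen is None:
        raise UsageError("solution set has no chosen tree")
    P = pd.DataFrame(
        np.vstack([c.prevalence for c in solution.clusters]),
        index=[c.id for c in solution.clusters],
        columns=list(solution.clusters[0].samples),
    )
    atlas = migration.SubcloneAtlas(presence=P)
    return atlas, solution.chosen_graph()


def run_migration_analysis(
    table: MultiSampleVariantTable,
    purities: dict[str, float],
    chroms: list[str] | None = None,
    full_threshold: float = 0.9,
    low_threshold: float = 0.5,
    groups: dict[str, str] | None = None,
    group_states: dict[str, dict[str, AlleleSpecificState]] | None = None,
    **kwargs,
) -> migration.MigrationGraph:
    """Full chain: subclone reconstruction then seeding classification."""
    solution = reconstruct_subclones(table, purities, chroms=chroms, **kwargs)
    atlas, tree = atlas_from_solution(solution)
    events = migration.classify_seeding(
        atlas, tree, full_threshold=full_threshold, low_threshold=low_threshold
    )
    events += migration.detect_recolonization(atlas, tree)
    return migration.build_graph(
        events, groups=groups, group_states=group_states, joint_tree=tree
    )


def inherited_af_vectors(
    table: MultiSampleVariantTable,
    locus: tuple[str, int, int],
    samples: list[str],
) -> np.ndarray:
    """AFs of inherited het variants inside a locus, rows = variants."""
    if table.somatic_status is None:
        raise UsageError("call_somatic has not been run")
    chrom, start, end = locus
    rows = (
        (table.somatic_status == INHERITED)
        & (table.chrom == chrom)
        & (table.pos - 1 >= start)
        & (table.pos - 1 < end)
    )
    sub = table.subset(rows)
    return np.nan_to_num(sub.af[:, sub.sample_index(samples)], nan=0.0)


def infer_group_allele_states(
    table: MultiSampleVariantTable,
    locus: tuple[str, int, int],
    group_reps: dict[str, str],
    group_cn: dict[str, int],
    purities: dict[str, float],
    min_vote: float = 0.9,
) -> dict[str, AlleleSpecificState]:
    """Allele-specific states per group at one locus, in one orientation.

    The lexicographically first group anchors the parental-allele labels;
    every other group's representative sample is jointly inferred against
    the anchor's, so allele A means the same physical chromosome throughout.
    """
    names = sorted(group_reps)
    anchor = names[0]
    afs = {
        g: inherited_af_vectors(table, locus, [group_reps[g]])[:, 0] for g in names
    }
    states: dict[str, AlleleSpecificState] = {}
    for g in names[1:]:
        st_a, st_g, _, _ = infer_allele_state_pair(
            afs[anchor], afs[g],
            cn_1=group_cn[anchor], cn_2=group_cn[g],
            purity_1=purities[group_reps[anchor]],
            purity_2=purities[group_reps[g]],
            locus=locus, samples=(anchor, g), min_vote=min_vote,
        )
        states[anchor] = st_a
        states[g] = AlleleSpecificState(g, locus, st_g.count_a, st_g.count_b)
    if anchor not in states:  # single group
        from metastrack.cnv import _best_split

        split, _ = _best_split(afs[anchor], group_cn[anchor],
                               purities[group_reps[anchor]])
        states[anchor] = AlleleSpecificState(anchor, locus, *split)
    return states


def analyze_cohort(cohort, full_threshold: float = 0.9, low_threshold: float = 0.5):
    """Run the complete analysis on a simulated cohort's outputs.

    Consumes only what the pipeline would see for real data — the variant
    table, segment tables and purities — and returns the migration graph
    (events, incubators, wave order) plus the sample groups.
    """
    from metastrack import cnv
    from metastrack.variant_io import call_somatic, filter_variants

    table = call_somatic(filter_variants(cohort.table))
    stable = [cohort.config.stable_chrom]
    solution = reconstruct_subclones(table, cohort.purities, chroms=stable)
    atlas, tree = atlas_from_solution(solution)
    events = migration.classify_seeding(
        atlas, tree, full_threshold=full_threshold, low_threshold=low_threshold
    )
    events += migration.detect_recolonization(atlas, tree)

    matrix = cnv.bin_log2(cohort.segments)
    groups = cnv.assign_groups(matrix)

    group_states = None
    scenario = cohort.scenario
    if scenario is not None and scenario.allele_locus is not None:
        locus = scenario.allele_locus
        reps, cns = {}, {}
        for site, g in sorted(groups.items()):
            if g == "ungrouped" or g in reps:
                continue
            reps[g] = site
            seg_cn = [
                s.total_cn for s in cohort.segments
                if s.sample == site and s.chrom == locus[0]
            ]
            cns[g] = seg_cn[0] if seg_cn else 2
        if reps:
            states = infer_group_allele_states(
                table, locus, reps, cns, cohort.purities
            )
            group_states = {f"{locus[0]}:{locus[1]}-{locus[2]}": states}

    graph = migration.build_graph(
        events, groups=groups, group_states=group_states, joint_tree=tree
    )
    return graph, groups, solution


def sample_phylogeny_from_table(
    table: MultiSampleVariantTable,
    chroms: list[str] | None = None,
    af_threshold: float = 0.1,
) -> phylogeny.SamplePhylogeny:
    """Encode, cluster, prune mixtures, and build the perfect phylogeny."""
    mat = phylogeny.encode_binary(table, chroms=chroms, af_threshold=af_threshold)
    clusters = phylogeny.cluster_variants(mat)
    mixtures, pruned = phylogeny.flag_mixture_samples(clusters)
    return phylogeny.build_perfect_phylogeny(pruned, mixture_samples=mixtures)
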