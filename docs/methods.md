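# Methods

This note documents the models, the numerical choices, and what the
synthetic cohorts do and do not establish about real data.

## Somatic calling and filtering

Joint filters are applied with strict inequalities exactly as stated:
site quality > 30, per-sample depth > 15 **in every sample** (the stricter
of the two readings of a per-sample depth filter), position kept by the
accessibility mask and rejected by the low-complexity mask (both 0-based
half-open BED; VCF positions are 1-based and converted at the mask
boundary), and a single alternate allele (multi-allelic sites are dropped,
not split). A record is somatic iff every normal shows AF < 0.1 or
alternate count < 5. A zero-depth normal makes the record *indeterminate*:
absence in the germline cannot be asserted, so the record is excluded from
the somatic set rather than imputed. Filtering is idempotent and
order-preserving.

## Allele-specific copy states

For an inherited het variant carried on `m` of `c` tumor copies in a sample
of purity `p`, the expected AF is

    af = (p*m + (1-p)) / (p*c + (1-p)*2),

which reduces to `m/c` in a pure tumor and to 0.5 for any purity when
`c=2, m=1`. Given the AFs of the same inherited variants in two samples,
each sample's copy-number split `(a, b)` (major allele first) is chosen by
least-squares assignment of its AFs to the two expected levels, and each
variant votes on whether the major allele of sample 1 is the major/retained
allele of sample 2. The call requires a >= 0.9 vote fraction; variants
with AF in (0.4, 0.6) at a LOH locus are excluded as uninformative (they
sit at the het band where noise dominates). Allele states are partially
time-ordered by a no-resurrection rule: state Y can follow state X only if
no allele at count 0 in X is positive in Y. This reachability relation is a
preorder; only strict one-directional reachability contributes ordering
constraints to the metastatic waves.

## Copy-number groups

Per-sample log2 ratios are length-weighted into 1-Mb bins; pairwise
distances are Euclidean over bins covered in both samples, clustered by
UPGMA (average linkage). The dendrogram is cut at the largest gap in merge
heights. A cluster of >= 2 samples becomes a group only if its members
co-deviate beyond +/- 0.3 log2 (same sign) in at least 2 discrete,
contiguous bin runs; everything else is `ungrouped`. The +/- 0.3 threshold,
the largest-gap cut, and the 2-event minimum are this package's choices —
the thresholds select chromosome-arm-scale events while ignoring binning
noise. The manual alternative (visual curation with structural-variant
confirmation of group-defining events) is out of scope here.

## Perfect phylogeny

Presence is AF > 0.1, strictly: an AF of exactly 0.1 encodes absent (the
complementary "absent" phrasing leaves the boundary open; strictness is the
deterministic resolution). Mixture samples are removed greedily: the sample
in the intersection of the most conflicting cluster pairs is removed
(ties lexicographic), clusters are re-projected and re-merged, until the
family is laminar. Removing half or more of the samples aborts — at that
point the data globally violates infinite sites rather than containing a
few mixtures. The tree is built by sample-set containment; a synthetic
zero-length root is added only when no truncal cluster spans all samples.

## Subclone reconstruction

**AF clustering.** Variants are first partitioned by presence pattern
(AF >= 0.05, the positivity cutoff for somatic detection). Within a
pattern, AF vectors are grouped by a Gaussian mixture whose per-observation
noise is the *known* binomial read-sampling error `sqrt(af(1-af)/depth)`,
fit by EM with two deterministic initializations (farthest point and
total-AF quantiles) and the component count chosen by AIC. AIC is
deliberately permissive: an unsplit pair of clones cannot be recovered
downstream, whereas an oversplit clone is re-merged by the next step.
Components are then merged greedily (across patterns too, so a variant
whose AF straddles the positivity cutoff in one sample does not strand its
clone-mates) when their mean AFs differ by less than 0.1 in every sample —
and, within a noise cap of 2.5 sd, when the union of their members is
unimodal along the separation axis. The unimodality threshold follows the
Marchenko–Pastur edge `(1+sqrt(s/n))^2`: the split axis is itself selected
from the data, which inflates the variance ratio along it by exactly that
factor under the single-clone null, while two true AF levels are bimodal
well beyond it. Finally, clusters smaller than 30% of the largest cluster
are absorbed into their nearest neighbour: with >= ~30 variants defining a
real clone, anything that small is a noise fragment.

**Prevalence.** `prevalence = af*(p*C_t + (1-p)*2)/(p*C_v)`, capped at 1
with a warning; mean AFs below the positivity cutoff count as absence
(prevalence 0) so that sequencing-error reads cannot leak tiny prevalences
into tree selection. Variants inside a group-shared single-copy deletion
are supported via `C_t = C_v = 1`.

**Tree enumeration.** All rooted trees over the clusters (root = the
cluster with prevalence within tolerance of 1 in at least one sample and
maximal presence set) are enumerated by depth-first parent assignment with
incremental pruning; a tree is kept when in every sample each parent's
prevalence + 0.1 bounds its children's summed prevalence, and each edge
satisfies parent >= child − 0.1 per sample (the tolerance absorbs AF
measurement error). The violation of a tree is the L1 slack actually used,
summed over samples and nodes; the minimal-violation tree is chosen, ties
broken by the deterministic parent-array serialization (which prefers
shallower attachment). A guard rejects > 12 clusters (the enumeration is
exponential); if no tree fits at the nominal tolerance the pipeline widens
it to 0.15 then 0.2 and records that in the solution diagnostics — the
programmatic analog of manual review of borderline solutions.

## Migration classification

Thresholds operationalize exact language that noisy estimates cannot meet
literally: "100% prevalence" is >= 0.9, "low prevalence" is < 0.5, and
presence is >= 0.05 (all configurable). A site is founded by the *most
derived* subclone at full prevalence there — its full-prevalence ancestors
arrived in the same cells and are not separate seedings. The source of a
monoclonal edge is the harbor site (partial prevalence) whose resident
subclones are nearest in the joint tree, preferring the neighbour with the
higher prevalence, then the earliest wave, then the site name. Polyclonal
direction points away from the site holding the clones' informative
ancestors (ancestors at full prevalence in both sites carry no direction)
at higher prevalence.

Recolonization requires "present" to mean cells of *exactly* that
subclone: a clone's variants ride along in every descendant cell, so the
exact fraction is its prevalence minus its children's. Exact fractions are
differences of two noisy estimates, so recolonization uses a stricter
presence threshold (0.1). Ambiguous source sites are all reported and
flagged, never silently resolved; seeding edges that contradict the
allele-state wave order are reported as warnings, never reversed.

An incubator is a site from which at least `min_chain = 2` subclones
forming an ancestor–descendant chain each sourced a seeding event;
intermediates are required to be exclusive to the candidate site (the
configurable default), the conservative reading of in-situ evolution.

## RNA support

Expression CNV scores: log2(TPM+1), centered across samples, 101-gene
center-aligned moving average within chromosome (truncated at the ends,
chromosomes with < 101 genes skipped), minus the mean windowed value over
the normal samples. The scores are sign/extent indicators, not calibrated
copy numbers. Dropout-aware validation uses `P0 = (1-vaf)^depth`, the
binomial probability of sampling zero alternate reads; eligible variants
(genomic VAF > 0.1, RNA depth >= 10) with no alternate reads are skipped
when `P0 > 0.05` and called unexpressed otherwise. `P0` is held at 4
decimal places internally and reported at 2.

## The cohort simulator

The simulator emulates the target study design: one patient, 8–30 tumor
sites, two matched normals, ~60x depth (Poisson-distributed per site and
variant), tumor purity drawn uniformly from (0.6, 1.0), and
`max(1, Poisson(33))` marker mutations per branch of the subclone tree —
33 matching the average mutations defining a subclone in this setting, and
the floor of 1 making every branch observable by presence/absence (a
zero-marker branch is unrecoverable in principle). Site compositions are
*exact* clone fractions; mutational prevalence is the subtree sum, so
parent/child sum constraints hold with zero slack by construction,
including for recolonized sites. Default ("clean") compositions give each
site one root-to-terminal path with prevalence falling linearly from 1 to
0.5, every clone terminal at some site; mixture sites for testing the
phylogeny stage mix two incomparable lineages half-and-half. Sequencing
error adds alternate reads at 1e-3 per base, exercising the somatic-calling
clauses; germline hets sit on a fixed 2-kb grid (>= 10 informative variants
per simulated CNV locus) with AFs reflecting the site's allele-specific
copy state. Noiseless mode (`depth_mean=None`) emits exact counts at depth
1000 with no error reads. A single `numpy` Generator keyed by the seed
drives all draws; identical configs are byte-identical.

Scripted scenarios plant the canonical seeding patterns (jumping board,
incubator, recolonization, polyclonal co-seeding, four CNV-defined waves
with a chromosome-scale allele-state ordering) together with the exact
truth events. Scenario prevalence levels were chosen once so that every
distinguishing AF separation clears the 0.1 clustering tolerance and the
detection cutoffs at the worst purity in the simulated range; levels that
sit exactly on a threshold are not identifiable at 60x by construction, so
the scenarios avoid them.

**What passing does and does not show.** The simulator draws reads from the
same AF model the prevalence correction inverts, with independent binomial
noise and exact segment/purity inputs. Passing therefore validates the
inference machinery and its noise handling, not robustness to mapping
artifacts, segmentation error, purity misestimation, overdispersed
coverage, or mutation-rate variation — none of which the generator
emulates. Problem sizes in the test suite (5-clone/6-site replicate sets,
200 noiseless cohorts, 50 scenario cohorts) are the package's validation
scale; all complete in a couple of minutes on one CPU.

## Known limitations

* Subclone trees are identified from bulk prevalences only; sibling versus
  chain attachments with zero violation are genuinely ambiguous and are
  resolved deterministically, with all enumerated trees reported.
* The enumeration guard (12 clusters) requires pre-merging for richer
  cohorts; raise `merge_tol` or analyze per group.
* Multi-sample assembly resolves conflicting parentage by minimal joint
  violation and reports ties explicitly; it does not search the joint tree
  space.
* Back-mutation and parallel evolution are excluded by assumption
  (infinite sites); heavily rearranged genomes with few copy-stable
  chromosomes weaken the phylogeny substrate.
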