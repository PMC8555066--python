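# metastrack

Reconstruction of metastatic tumor evolution from multi-sample sequencing of
a single patient: somatic variant filtering against matched normals, sample
phylogeny under the infinite-sites assumption, subclone trees with cellular
prevalences, and a classified metastatic migration graph (monoclonal and
polyclonal seeding, recolonization of established sites, subclone
"incubator" sites, and metastatic waves ordered by allele-specific
copy-number states).

The intended user is a cancer-genomics analyst with a jointly called
multi-sample VCF (tumor sites plus >= 1 matched normal), per-sample
copy-number segments with purity estimates (FACETS-style), and optionally
bulk RNA-seq. A fully scriptable cohort simulator with ground truth is
included and drives the test suite.

## The model in brief

**Somatic calling.** A variant is somatic iff in *every* normal sample its
allele fraction (AF) is below 0.1 or its alternate read count is below 5,
after joint quality filters (site quality > 30, depth > 15 in every sample,
accessibility and low-complexity masks, biallelic sites only).

**Sample phylogeny.** On copy-stable chromosomes, somatic variants are
encoded presence/absence per sample (present iff AF > 0.1). Variants with
identical binary vectors form clusters = clones; under infinite sites the
cluster sample-sets must be pairwise nested or disjoint (a perfect
phylogeny). Samples breaking laminarity are mixtures of lineages and are
flagged by greedy conflict removal. Branch lengths are variant counts;
UPGMA on Hamming distances provides an independent concordance check.

**Subclones.** Variants in copy-neutral regions are clustered by AF level
across samples; AF converts to cellular prevalence as

    prevalence = af * (p*C_t + (1-p)*2) / (p*C_v),   capped at 1,

with purity `p`, total copies `C_t` and variant copies `C_v` (for a het
variant in a diploid region: `2*af/p`). All rooted trees over the clusters
are enumerated; a tree is valid when in every sample each node's prevalence
(+/- 0.1 tolerance) accommodates its children's sum, and the
minimal-violation tree is chosen.

**Migration.** A subclone *founded* every site where its prevalence reaches
~1 (operationally >= 0.9) and *emerged* where it is partial: partial -> full
is a monoclonal seeding edge. Two related subclones both at low prevalence
(< 0.5) in two sites mark polyclonal co-seeding. A site holding an ancestor
and a descendant but missing the intermediates — which live exclusively at
another site — was recolonized from there. Allele-specific states (e.g.
one allele amplified with the second retained, versus the second lost)
partially order the CNV-defined sample groups into metastatic waves under a
no-resurrection rule.

## Worked example

Simulate a recolonization cohort and run the full pipeline from the shell:

```
metastrack simulate --seed 11 --scenario recolonization --out-dir cohort
metastrack filter --vcf cohort/cohort.vcf --normals N1,N2 --out table.tsv
metastrack phylo --table table.tsv --chroms chr14 --out-prefix phylo
metastrack subclones --table table.tsv --purity cohort/purity.tsv \
    --chroms chr14 --out subclones.json
metastrack migrate --solution subclones.json --out-prefix migration
```

which prints

```
cohort written to cohort (10155 variant records, 3 sites)
10155 records retained, 159 somatic
tree written to phylo.nwk; 0 mixture sample(s)
4 clusters, 2 trees -> subclones.json
2 events -> migration.json
```

`table.tsv` holds per-sample depth/alt-count/AF with somatic flags (159 of
the ~10k records are somatic markers; the rest are inherited hets used for
allele-specific analysis). `phylo.nwk` is the perfect-phylogeny sample tree
with variant-count branch lengths. `subclones.json` lists the AF clusters,
their per-site prevalences, and every enumerated tree with its violation;
`migration.json` contains the classified seeding edges. The same analysis
is available programmatically via `metastrack.pipeline.analyze_cohort`.

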