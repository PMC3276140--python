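# Methods

## Coordinates, identifiers, and the data model

All coordinates are 1-based and all intervals are closed on both ends,
matching the convention of genetic-map ranges and position-bearing variant
identifiers. A variant's canonical key is `contig_position_base` for SNPs
(the alternate base is part of the identity, since several substitutions can
occur at one site) and `contig_position` for indels. Indel keys deliberately
carry no size: co-located indels of different lengths collapse to one key
for cross-strain matching, while the occurrence matrix retains every
observed size so reports can still distinguish them. An optional
left-normalization step (`left_normalize`) shifts indels to their leftmost
equivalent position before keying, so identical events called at different
anchors in different strains match; whether upstream callers already
normalize is caller-specific, so cross-strain indel identity can differ
marginally between callers.

For deletions, `position` is the first deleted base; for insertions it is
the base after which the inserted sequence sits. VCF anchored REF/ALT
representation is converted on input (REF `TAG`, ALT `T` at POS 100 → a
−2 indel whose first deleted base is 101) and reproduced on output;
structural deletions use symbolic `<DEL>` with an END coordinate.

Contig names may not contain underscores — the identifier grammar depends
on it.

### Call filtering

`FilterPolicy` re-expresses consensus-caller post-filters at the record
level: minimum read depth (default 3), minimum phred-scaled consensus
quality (40), SNPs within 5 bases of an indel dropped, more than 2 SNPs in
any 5-base window dropped, and a minimum map quality (30) applied after the
proximity rules. The proximity and density rules are evaluated against the
full input (not the survivors of the earlier rules), which makes the
partition idempotent: filtering the kept set again changes nothing. Each
rejected record carries the first rule it failed, in the order above.

## Effect classification

Gene models hold exon/CDS/UTR interval lists per strand;
`protein_length = CDS length / 3`, i.e. it counts the terminal stop codon as
one position. Genes whose total CDS length is not divisible by 3 are kept
but flagged and excluded from codon-level classification.

Classification is backed by per-contig lookup arrays built once per
annotation: region class per base (intergenic / UTR / intron / splice /
CDS), owning gene per base, and the 0-based offset of each CDS base within
the gene's spliced, stranded coding sequence. A SNP inside CDS is classified
by substituting the (strand-complemented) alternate base into its codon and
translating with the standard genetic code: synonymous, nonsense (new stop),
or nonsynonymous (including the rare stop-loss). The splice-site window is
the first and last **2 bases of each intron** (canonical donor/acceptor
dinucleotides); the source tables tabulate splice-site hits without defining
a window, so this is our documented choice. 5′/3′ SNP classes mean
**annotated UTRs**, not fixed flanking windows — also a documented choice
where the source is silent.

Indels are classified over their affected span with precedence
splice site > CDS > intron > UTR > intergenic; a CDS-overlapping indel is a
frameshift when its signed size is not a multiple of 3, in-frame otherwise,
and a structural deletion that removes at least one complete CDS exon is a
gene deletion. Insertions affect the junction between their anchor base and
the next. `scan_premature_stops` applies an indel inside the spliced CDS,
translates in the original frame from the start codon, and reports the first
stop strictly before the wild-type terminal stop plus the count of stops
through the wild-type protein length.

The per-strain indel table's "other" column collects indels in annotated
transcripts outside CDS/intron/splice (i.e. UTRs) and indels in genes
without a usable CDS; the source table never defines its membership, so this
is an approximation, stated here once.

## Cross-strain comparison

The occurrence matrix is stored sparsely as key → strain-bitmask; the
contract is purely set-semantic. Multi-allelic records (flagged on input or
split from multi-ALT VCF rows) are excluded by default — in a haploid genome
they are predominantly alignment artifacts — and can be re-included with a
switch. Keys present in every strain are reported separately as putative
reference-background alleles and never count as "unique". Per-gene tallies
deduplicate events by canonical key across carriers.

## Prioritization

The candidate pipeline for a focal strain: resolve the marker interval
(open bounds resolve to 1 or the contig length), restrict effects to it,
keep keys private to the focal strain, keep tier-qualified severities
(tier 1: nonsense, CDS frameshift, gene deletion, splice site; tier 2,
opt-in: nonsynonymous), exclude candidates whose gene carries qualifying
variants in other strains, then fold in knockout metadata: a phenotypically
"normal" knockout demotes a candidate (retained, down-weighted), a
heterokaryon-only knockout is annotated as corroborating possible
essentiality. Shared-gene exclusion is triggered only by **same-or-higher
tier** variants by default (a gene can tolerate nonsynonymous polymorphism
yet not frameshifts); `cross_class_exclusion` widens it. Ranking is
deterministic — tier, then category order (nonsense, frameshift, gene
deletion, splice), then contig and position — so reports reproduce exactly;
real analyses break such ties only with external evidence. The verdict is
`single_candidate` for exactly one survivor, `multiple_candidates` when
several survive but one outranks the rest by tier/category,
`ambiguous` when the best rank is tied, `none` when nothing survives.

Every focal variant receives exactly one status
(`top`, `demoted_ko_normal`, `excluded_shared_orf`, `excluded_not_unique`,
`excluded_outside_interval`, or `excluded_low_severity` — the last covers
in-interval unique variants below the severity cut).

Lineage/mutagen metadata is carried as annotation only and never influences
ranking: variant distribution tracks strain history, not mutagen.

## Summary statistics

Percentages reproduce the printed-table conventions: rounding is
half-away-from-zero at the printed precision, and **the synonymous
percentage uses the non-coding count as its denominator** — a quirk of the
source table (its %Syn column is reproducible only as 100·Syn/NC, verified
on several rows), kept so the printed columns recompute exactly; the other
percentages are over the strain total. Splice-site SNPs fold into the
intron column of the per-strain SNP table, which has no splice class.

Indel size spectra pool insertions and deletions by |size| (a signed mode
exists); "distinct" counts each key once, "mapped" weights by occurrence.
Window profiles use a 10 kb window; the profile step defaults to 1 kb (the
window is conventional, the step is ours). Block segmentation is two-state
run-length with hysteresis: the state flips after `min_run` consecutive
windows beyond the corresponding threshold; thresholds default to the
profile's 90th percentile and median, since block boundaries are described
qualitatively in cohort data.

The spontaneous-rate estimator is the upper bound
µ = (unique SNPs [+ unique indels]) / surveyed genome length, reported to 3
significant figures; unique density per kb is reported to 1 decimal at
≥0.1/kb, else 2. The ti:tv ratio is transitions/transversions over the
supplied set and is undefined (None, with a warning) without transversions.
Annotation-class enrichment compares the class distribution of
nonsense-carrying mutations with the class distribution of all genes and
reports the observed %, background %, and their ratio; no significance test
is attached — the quantity of interest is the ratio itself.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Defaults (one 1 Mb contig, 200 genes, 6 strains) are large enough
to exercise every rule and small enough for seconds-scale runs; the
acceptance properties run 100 such cohorts in about half a minute.

What it emulates, and the targets the defaults were set to:

* **Per-strain divergence** log-spaced 0.32–4.6 SNPs/kb — the roughly
  30-fold range observed across a real classical-mutant cohort (13 k–188 k
  SNPs over a 41 Mb genome), realized as a shared "ancestral" variant pool
  organized in haplotype blocks (default 20 per contig, a fifth of them
  divergence-hot) from which each strain inherits whole blocks (plus a
  positional prefix of one final block — a recombination breakpoint) until
  its target is met, plus a private remainder (default 8% of its variants).
  Per-strain streams are seeded independently, so adding a strain never
  perturbs the others.
* **ti:tv = 3** by construction of alternate-allele choice.
* **Indels ≈ 12% of variants**, sizes skewed small with an excess at |4|
  (tetramers enriched to ~30% TACC/TAGG — cosmetic realism), signs
  symmetric.
* **Purifying selection** as rejection sampling with category-dependent
  retention: nonsense, splice-site, and frame-breaking CDS variants are
  mostly redrawn (base retentions 0.07/0.10/0.075), nonsynonymous partially
  (0.30), synonymous and non-coding always kept. The in-frame CDS indel
  retention is solved from the configured target so that ~24% of size-3
  indels land in CDS while frame-breaking sizes stay under ~2–3% — the
  coding bias the real data shows. Retention for deleterious classes is
  additionally multiplied by a per-gene tolerance (0.05 / 1 / 6 with
  probabilities 0.6 / 0.3 / 0.1): per-gene coding variation in real cohorts
  is strongly overdispersed (most genes untouched, a few hot), and without
  this heterogeneity severe background lesions would scatter uniformly and
  the shared-gene exclusion rule would fire far more often than it does in
  practice. The resulting nonsense rate is ~0.07% of SNPs, matching the
  per-strain category tables.
* **Reference-background variants** (default 25) present in every strain.
* **One planted causative per focal strain** — by default a nonsense SNP and
  a 1-base frameshift in the two least-diverged strains, each inside a
  ~300 kb marker interval (~70 genes, a realistic mapped-interval size),
  planted in a low-tolerance (conserved) gene, mirroring the empirical
  pattern that genes whose disruption causes a phenotype carry no other
  cohort variants. Every planted key is guaranteed absent from all other
  strains.

The truth table records causatives, per-strain private keys, all-strain
background keys, block boundaries, and each strain's inherited blocks.

What the generator does **not** emulate: read-level noise and mapping
artifacts (qualities are drawn to pass the default filters; the filter rules
are tested on dedicated fixtures), callable-fraction variation, clustered
hypermutation processes, gene-length and GC heterogeneity, and overlapping
genes. Passing the recovery property therefore demonstrates the logic of the
comparative analysis under realistic polymorphism *structure*, not
robustness to raw-data pathologies.

Under these defaults the planted gene is returned as the single top
candidate in ≥95% of seeded cohorts; the residual failures are cohorts
where a background severe variant lands in or near the planted gene
(shared-gene collision) or a second unique severe variant survives in the
interval — exactly the failure modes that force a real analysis to a
multiple-candidate verdict.

## Numerical and degenerate-input choices

* Rounding for table reproduction: half-away-from-zero at printed
  precision; rates to 3 significant figures.
* Empty inputs: filtering returns two empty lists; an empty effect set gives
  a zero summary row with a warning; a zero-transversion set makes ti:tv
  None rather than infinite.
* A cohort of one strain makes all-strain flagging degenerate (every key
  flagged, with a warning).
* Contigs shorter than the window give a single truncated window with a
  warning.
* Duplicate (strain, key) pairs collapse with a warning.
* Ties in candidate ranking break by (tier, category order, contig,
  position).

## CLI and reproducibility

The CLI is a thin layer: YAML configuration is fail-closed (unknown keys are
rejected with the accepted list), outputs are deterministically ordered, and
each run writes a manifest with the config hash, seed, package version, and
SHA-256 of every output, so identical config + seed yields identical
checksums. Partial outputs are removed when a command fails.
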