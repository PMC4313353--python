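# Methods

`regevo` reimplements, as a tested library, the comparative analysis of
liver promoter and enhancer evolution across ~20 mammals: replicate
ChIP-seq peak calls are reduced to consensus regulatory elements, elements
are compared across species through whole-genome-alignment-style orthology
maps, and the resulting conservation patterns are summarised as turnover
half-lives, highly conserved / lineage-specific / recently evolved element
sets, sequence (exaptation) ages, and enrichment statistics.  Because the
underlying ChIP-seq data are not bundled, every estimator is exercised on a
seeded synthetic genome-evolution fixture with complete ground truth.

## Consensus elements

A region is reproducible when it overlaps peaks from at least
`min_replicates` (default 2) distinct biological replicates, each shared
span covering at least `min_overlap` (default 0.5) of the shorter of the
two peaks.  "Of the shorter" is a symmetric reading of the 50%-of-length
rule; results are insensitive to the threshold over 0.1–0.8 on realistic
peak noise (tested).  Reproducible peaks connected by qualifying overlaps
are merged transitively into one consensus span; peaks that fail the rule
are discarded and cannot bridge two consensus regions.  Species profiled
with a single individual keep all peaks (`single_replicate_ok`).
Consensus intensity is the mean fold enrichment across supporting
replicates (replicate means first, so a fragmented replicate does not
dominate).  H3K4me3 and H3K27ac consensus regions overlapping by ≥ 50% of
the shorter merge into dual-marked promoters; leftovers become
H3K4me3-only promoters and enhancers (H3K27ac only).

## Orthology projection and conservation calls

An orthology map is an ordered set of block pairs (equal-length spans in
two genomes, half-open coordinates, minus-strand blocks reverse within the
block).  A query projects to `unique` when its covered pieces are
co-linear on one target chromosome with no inter-piece gap exceeding twice
the query length; multi-chromosome, strand-mixed or widely gapped
projections are `split` and treated as non-informative, and queries
touching no block are `unmapped`.  Pure multi-block but contiguous
projections are accepted — discarding every multi-block region would
discard nearly everything on fragmented alignments.

An element is functionally conserved in a second species when its uniquely
projected location overlaps a marked region there by at least 50% of the
*projection's* length (the directional reading of the overlap rule;
monotone-equivalent to the target-anchored reading in the robust range).
Pairwise conservation ratios average the two reciprocal directions, with
uniquely alignable elements as denominators.  Class-level ratios call
conservation against all regions bearing the class's defining mark
(H3K4me3 for promoters, H3K27ac for enhancers), so a promoter whose
acetylation is missed in one species still counts as conserved promoter
activity.

The coverage-based false-negative check (`coverage_false_negative_fraction`)
reports the fraction of "absent" orthologous sites whose read coverage
exceeds mean + 1.96·sd (sample sd) of a control distribution — an upper
bound on calls that reflect sub-threshold signal rather than true absence.

## Turnover model and half-life estimation

Element loss is modelled as memoryless per-lineage exponential decay:
survival over a branch of t Ma is `exp(−t·ln2/h)` with `h` the class
half-life.  Under this model the expected pairwise ratio between species
separated by divergence time T, *conditioned on presence in the anchor
species*, is `A·exp(−T·ln2/h)`: survival along the shared path is implied
by the anchor's presence, so only the partner lineage's T Ma of exposure
remain.  The log-linear OLS fit of ln(ratio) on divergence time therefore
estimates the per-lineage half-life directly; `A` is left free and absorbs
the technical non-conservation floor at T→0 (detection misses).  Mean
lifetime is `h/ln2`.

Confidence intervals: the OLS t-interval on the slope (n−2 df) is provided
but is anti-conservative for all-pairs data, since each species enters
~n−1 points and their errors are correlated.  `fit_decay_jackknife`
therefore refits with each species deleted in turn and uses the jackknife
SE with a t-interval on (n_species − 1) df; this is the interval used in
the recovery experiments, where it attains near-nominal coverage.

Two known small biases of the full peak-level pipeline, measured on the
fixture: (i) dual promoters whose H3K4me3 consensus is missed leak into
the enhancer class and flatten the enhancer decay (~+1% on the fitted
half-life at default noise); (ii) reproducible false-positive peaks form a
~1% absolute, nearly divergence-independent deflation absorbed by the
amplitude.  The parameter-recovery experiment fits ratios computed from
the generator's true element histories, so it measures the estimator
itself; the pipeline simply inherits the extra ~1%.

Distance trees use 1 − ratio as the pairwise distance and Saitou–Nei
neighbor joining (scikit-bio, negative branches clamped to 0).  A monotone
transform of an ultrametric distance is ultrametric, so topology recovery
does not require additivity of 1 − ratio.

## Conserved, lineage-specific and recently evolved sets

Highly conserved: anchor elements with at least one conserved mark in
*every* species of the required high-quality panel (extra species recorded
but not required).  Class by majority rule over observed per-species
states; K4-bearing states count as promoter votes and ties break to
promoter (dual marking subsumes acetylation); the rare all-K4-only element
is classed promoter and flagged.  Significance: 10,000-iteration (1,000 in
scaled runs) permutation test that shuffles, independently per species and
per mark, which anchor elements carry that stratum's conserved labels —
preserving all per-stratum conserved counts — with the add-one estimator
p = (1+#{null ≥ obs})/(1+n_iter), displayed as "< 1/n_iter" when no null
draw reaches the observed count.

Lineage-specific: conserved in all designated within-clade species and in
no *alignable* species outside the clade (ambiguous projections are
non-informative).  Recently evolved: anchor elements with zero conserved
calls anywhere; unalignable species neither rescue nor disqualify, so an
element alignable nowhere is recently evolved.

## Sequence age and repeat enrichment

The sequence age of an element is the divergence time of the most distant
species with a uniquely alignable ortholog of its DNA; no alignable
ortholog means age 0 (species-specific sequence).  Bins: young 0–40 Ma,
mid 40–100 Ma, ancestral ≥ 100 Ma.  Repeat containment requires ≥ 50% of
the *repeat's* length inside the element (repeats are much shorter than
elements; the element-anchored reading would almost never trigger), one
count per family per element.  Enrichment per family (and per class) is an
upper-tail binomial test of the foreground containment fraction at the
background rate, BH-corrected within the analysis; a background rate floor
of 0.5/bg_total keeps the test defined when a family is absent from the
background (flagged).

## Gene association, expression, selection

Regulatory domains follow basal-plus-extension: basal = TSS−5 kb / +1 kb
strand-oriented; extension runs to the nearest neighbouring basal edge,
capped at 1 Mb beyond each basal edge, clipped to the chromosome.
Intergenic intervals are covered by both flanking domains, so elements may
link to several genes (links are ≥1 bp overlaps).  Tissue specificity is
tsps(g) = x_target / mean(x_other) with missing RPKM imputed as 0 — the
delegated formula is not printed anywhere authoritative, so this form was
chosen to make the stated thresholds dimensionally sensible and is
pluggable; liver-specific genes need tsps > 1.5, liver as argmax, and
liver RPKM > 10.  Term enrichment is binomial + BH with a report filter of
q < 0.05 and fold > 2.  PSG association runs three uncorrected tests:
link-level and gene-level hypergeometric tests and a one-sided Wilcoxon
rank-sum on per-gene recent-enhancer proportions (genes with ≥ 1 enhancer
only; link-counting is used when one enhancer hits two PSG domains).

## Conservation-ratio regression

Per-element conservation ratios (conserved/mapped species) are modelled by
plain OLS on the bounded response — no logit transform, matching the
linear-regression framing; marginal R² comes from univariate fits,
cumulative R² from left-to-right prefix models (default order:
reproducibility, intensity, length, TSS distance, GC, constraint fraction,
TFBS count), and feature inter-dependence from pairwise squared Pearson
correlations.  Exactly collinear features are dropped with a warning.

## The synthetic world

Each species' genome is one chromosome tiled by 1 kb blocks (6 Mb
default).  DNA alignability evolves by block turnover (half-life 3,000 Ma)
along the dated 20-taxon fixture tree (root 180 Ma, two marsupial
outgroups, closest pair 13 Ma); two species align at a block iff neither
lineage replaced it since their split, which yields orthology maps, young
vs ancestral DNA, and sequence ages from one process.  Elements (600 dual
promoters, 200 K4-only, 1,000 enhancers at the root; per-lineage
half-lives 900/900/300 Ma; births at 0.25/0.08/1.2 per Ma) die with their
DNA and are born into young DNA (same-branch blocks) or ancestral DNA
(≥100 Ma blocks) with class-specific fractions (0.15/0.15/0.25) — the
exaptation knob.  Peak emulation: per element, mark, replicate, a peak is
emitted with sensitivity 0.95, boundary jitter ≤ 40 bp and log-normal
intensity noise; false positives land on element-free blocks at 2% of the
true peak count per replicate.  Reproducibility *emerges* from detection
sampling.  One species (whale) has a single replicate to exercise that
code path.  Genes, a tissue-expression matrix (ubiquitous vs
tissue-specific mixture), repeats (young-DNA-biased families), constrained
segments and a PSG list with a plantable enhancer association complete the
study.  Everything is a deterministic function of the seed, and
`emit_fixtures` writes byte-stable plain-text files with a checksum
manifest.

What the generator does *not* emulate: nucleotide sequence and motif
content, read-level noise, mappability and assembly gaps, copy-number or
rearrangement variation, correlated replicate failures, and
non-exponential (age-dependent) loss.  Passing tests therefore demonstrate
correctness of the estimators under the stated generative assumptions, not
robustness to every artefact of real ChIP-seq.

## Experiment scales and numerical choices

Recovery experiments use a 10-taxon high-quality panel (fixture pruned to
reference-grade genomes, root 96 Ma) with 5,000 elements per class and 20
seeds; calibration experiments use 200 seeds with 1,000 permutation
iterations and 500 null enrichment simulations over 50 families — sizes
chosen so the whole acceptance computation completes in a couple of
minutes while keeping Monte-Carlo error well inside the asserted
tolerances.  The near-star phylogeny control freezes promoters entirely
(infinite half-life *and* zero birth rate), because births after a species
pair's split are genuine turnover signal and would otherwise dominate the
technical floor being measured.  Binomial tails are validated against
exact rational summation (`fractions.Fraction`) to 1e-12.  All coordinates
are 0-based half-open; strand is ignored by overlap arithmetic and used
only for TSS logic.

## Known limitations

Single chromosome per species in the fixture (multi-chromosome I/O paths
exist but the vectorised projection fast path assumes one target
chromosome per map); gene annotations live in a shared id namespace rather
than per-species orthology; GO DAG propagation is out of scope; the
pipeline's enhancer half-life inherits the ~1% class-assignment bias noted
above.
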