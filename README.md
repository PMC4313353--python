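# regevo

Comparative evolution of gene-regulatory elements across mammals, as a
reusable, tested pipeline.

Active promoters (H3K4me3 ± H3K27ac) and enhancers (H3K27ac only) mapped
by ChIP-seq in the livers of ~20 mammalian species turn over at very
different speeds: enhancer activity is lost rapidly along each lineage
while promoter activity persists several-fold longer, even though the
underlying DNA stays alignable.  `regevo` implements the full analysis
chain behind that kind of study, for computational biologists who want to
re-run, stress-test or extend it:

* **consensus peaks** — replicate peak calls → reproducible consensus
  elements (≥ 2 replicates, ≥ 50% mutual overlap; single-replicate
  species handled), classified into dual-marked promoters, H3K4me3-only
  promoters, and enhancers;
* **cross-species conservation** — interval projection over block-wise
  orthology maps (unique / split / unmapped), conservation calls at ≥ 50%
  overlap of the projected span, reciprocal-averaged pairwise ratios, and
  a read-coverage false-negative check for "absent" calls;
* **turnover kinetics** — memoryless per-lineage loss with survival
  `exp(−t·ln2/h)`; the pairwise conservation ratio between species at
  divergence T, conditioned on the anchor species, decays as
  `A·exp(−T·ln2/h)`, so a log-linear OLS fit of ln(ratio) on divergence
  yields the half-life `h = τ·ln2` and mean lifetime `τ`; CIs from the
  slope t-interval or a delete-one-species jackknife; neighbor-joining
  trees from 1 − ratio distances;
* **element sets** — highly conserved (marked across a required
  high-quality species panel; permutation null with 10⁴ label shuffles
  per species × mark), lineage-specific, and recently evolved elements,
  with majority-rule classification;
* **exaptation ages & repeats** — sequence age from the most distant
  alignable species (young 0–40 Ma / mid 40–100 / ancestral ≥ 100),
  repeat-family binomial enrichment with Benjamini–Hochberg correction;
* **gene context** — GREAT-style basal-plus-extension regulatory domains
  (−5 kb/+1 kb basal, ≤ 1 Mb extension), element–gene links, tissue
  specificity scores and liver-specific gene sets, binomial term
  enrichment, and positively-selected-gene association tests
  (hypergeometric ×2 + Wilcoxon);
* **feature regression** — incremental variance decomposition of
  per-element conservation ratios over experimental and sequence features.

Because the original ChIP-seq compendium is not shipped, the package
includes a first-class synthetic study generator (`regevo.simulate`): a
dated 20-taxon tree, block-grid genomes with DNA turnover, element
birth–death histories with class-specific half-lives, peak-level detection
noise, repeats, genes, expression, and a truth table for every estimator.
All randomness is seed-deterministic and fixtures serialize to plain text
with checksums.

## Worked example

```python
from regevo import SimConfig, simulate_world, MarkClass
from regevo import study
from regevo.turnover import fit_decay_jackknife, nj_tree

world = simulate_world(SimConfig(seed=1))          # 20 species, known truth
cons = study.all_consensus(world)                  # peaks -> elements
human = cons["human"]
counts = {k.value: sum(1 for e in human if e.mark_class is k)
          for k in MarkClass}
print(f"human consensus elements: {len(human)} {counts}")

mat = study.class_ratio_matrix(world, cons, MarkClass.enhancer)
print(f"human-mouse enhancer conservation: {mat.loc['human','mouse']:.3f}")

fit = fit_decay_jackknife(mat, world.tree)
print(f"enhancer half-life: {fit.half_life:.0f} Ma "
      f"[{fit.ci95_half_life[0]:.0f}-{fit.ci95_half_life[1]:.0f}], "
      f"mean lifetime {fit.tau:.0f} Ma, r^2 = {fit.r_squared:.3f}")

rf = world.tree.unrooted_topology_distance(nj_tree(1.0 - mat))
print(f"Robinson-Foulds distance, NJ tree vs generating tree: {rf:.0f}")
```

prints

```
human consensus elements: 1533 {'promoter_dual': 509, 'promoter_k4': 191, 'enhancer': 833}
human-mouse enhancer conservation: 0.746
enhancer half-life: 228 Ma [203-260], mean lifetime 329 Ma, r^2 = 0.966
Robinson-Foulds distance, NJ tree vs generating tree: 0
```

Reading this: of ~1,500 reproducible human elements, enhancers dominate;
three-quarters of human enhancers have conserved activity at their
orthologous location in mouse (90 Ma of divergence); the exponential decay
across all 190 species pairs corresponds to an enhancer activity half-life
of a couple of hundred Ma per lineage (this fixture plants 300 Ma; the
pairwise estimate sits lower because elements born after each split dilute
the ratios — see `docs/methods.md`); and the enhancer non-conservation
distances alone reconstruct the true species topology exactly (RF = 0) —
regulatory turnover is clock-like enough to recover the phylogeny.

The same analysis runs end-to-end from a YAML config:

```bash
regevo run --config run.yaml           # simulate -> ... -> regression
regevo run --config run.yaml --stages decay   # re-fit from cached ratios
regevo mean-lifetime 296               # -> 427.0
```

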