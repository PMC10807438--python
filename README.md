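# microniche

Quantitative analysis of **niche deformation and pairwise interactions in
synthetic bacterial communities**, built for microbial ecologists who profile
carbon-source utilisation of monocultures and co-cultures on Biolog
EcoPlates and measure pairwise antagonism and spent-media (supernatant)
interactions under different resource availabilities.

## What it computes

**Niche set algebra.** Each culture's niche is the set of carbon sources on
which it shows significant growth, encoded as a binary vector over the 31
EcoPlate substrates (`A = (1, 0, 0, …, 1)`). Raw well absorbances (OD-595 at
days 0, 4, 7) are corrected by clamping negatives, subtracting the water
blank, and subtracting the same well's day-0 value; a source is called
"used" when the replicate-mean corrected value exceeds the 97.5th percentile
of the corrected blank values (a two-tailed 5% criterion). For each pair of
strains with monoculture niches A, B and co-culture (observed) niche O:

- expected niche `= A ∩ B`
- niche expansion `= {(A ∪ B) − (A ∩ B)} ∩ O` (set-formula variant; an
  extended variant `O − (A ∩ B)` also counts sources neither strain uses
  alone)
- niche overlap index `= |A ∩ B| / |A ∪ B|` (Jaccard)

Pairs are classified *expected = observed* (O equals A ∩ B), *expansion*, or
flagged *contraction/other*.

**Metabolic and phylogenetic similarity.** Functional distance between two
strains' metabolic networks is `1 − |A ∩ B| / ((|A| + |B|)/2)` over their
metabolite node sets. Phylogenetic distances come from Tajima-Nei distances
on an aligned 16S set (`d = −b ln(1 − p/b)` with the base-composition
correction `b`), a neighbor-joining tree, and patristic (tree-path)
distances.

**Interaction statistics.** Directed inhibition halos are collapsed to
unordered-pair antagonism labels (x and/or y = 1); a binomial GLM (logit
link) regresses antagonism on distance, reporting Wald p-values and
McFadden pseudo-R² (`1 − ℓ/ℓ₀`); the crossing point of the high- and
low-resource logistic curves is solved analytically. McNemar's paired test
compares inhibition frequencies between levels. Spent-media cases are
summarised by `log10(OD_spent / OD_fresh)` with one-sided t tests at
α = 0.05 for positive/negative/neutral classification, plus Welch-type
Dunnett-T3 post hoc comparisons and one-way ANOVA for group contrasts.

**Synthetic data.** A first-class generator draws communities with known
niches and injected cooperative gains, inhibition labels from a known
logistic model, logistic growth curves, and supernatant tables with
prescribed effects — so every stage of the pipeline is testable against
ground truth without any experimental data.

## Worked example

```python
from microniche import plates, simulate, stats

truth = simulate.default_community_truth(seed=42)      # 16 strains, known niches
table = simulate.generate_plate_set(truth)             # 136 plate contexts
calls = plates.score_growth(plates.correct_absorbance(table), day=7)
results = plates.pair_niche_results(calls, variant="printed")
summary = plates.summarize_deformation(results)
print("pairs analysed:        ", summary["n_pairs"])
print("expected = observed:   ", summary["counts"]["expected_equals_observed"])
print("niche expansion:       ", summary["counts"]["expansion"])
print("mean sources gained:   ", round(summary["mean_expansion_sources"], 2))
pe = stats.pearson_corr([r.overlap_index for r in results],
                        [float(r.expansion_count) for r in results])
print(f"expansion vs overlap:   r = {pe.r:.2f}, R^2 = {pe.r_squared:.2f}, p = {pe.p_two_sided:.2g}")
```

prints

```
pairs analysed:         120
expected = observed:    0
niche expansion:        120
mean sources gained:    14.58
expansion vs overlap:   r = -0.86, R^2 = 0.74, p = 2.3e-36
```

All 120 co-cultures of this synthetic community show niche expansion
(every pair of distinct random niches contributes its symmetric difference,
plus injected cooperative gains), gaining on average ~15 carbon sources
over the expected intersection, and expansion is strongly negatively
correlated with the niche overlap index — strains with similar niches have
less room to expand.

The same analyses are available from a shell:

```sh
microniche simulate --seed 1 --out-dir bundle
microniche validate --plates bundle/plates.csv --alignment bundle/alignment.fasta
microniche run-all --plates bundle/plates.csv --node-sets bundle/node_sets.tsv \
    --alignment bundle/alignment.fasta --inhibition bundle/inhibition.csv \
    --growth bundle/growth.csv --supernatant bundle/supernatant.csv --out-dir out
```

`run-all` writes per-stage TSV/CSV outputs plus `summary.json` (all headline
statistics) and `manifest.json` (config hash, seed, version); reruns with
the same inputs and seed are byte-identical.

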