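# Methods

This note documents the models, procedures, parameter choices and known
limitations of `microniche`. Everything stated here is computed by the
package itself (tests or `scripts/acceptance.py`); no external results are
quoted.

## Plate correction and growth scoring

Raw EcoPlate absorbances (OD-595; 31 carbon substrates + water, three
replicates, days 0/4/7) are corrected in a fixed order:

1. clamp raw negatives to zero (instrument artefacts);
2. subtract the mean of the same culture context's water wells at the same
   day (basal, carbon-independent signal);
3. for days after day 0, subtract the same well's day-0 value (initial cell
   density and intrinsic substrate colour);
4. clamp resulting negatives to zero.

Water wells pass through the same arithmetic so that the blank distribution
used for thresholding lives on the corrected scale. A culture is called
positive on a substrate when its replicate-mean corrected value at the
scoring day (day 7 by default; day 4 selectable) is **strictly greater**
than the 97.5th percentile of the corrected blank values at that day —
ties are not growth, matching the two-tailed 5% logic of the criterion.
Quantile rule: linear interpolation between order statistics (the numpy
default), configurable.

**Blank pool.** The percentile is taken over all corrected water wells of
the plate set at the scoring day (`blank_pool="global"`). A per-context
alternative (`"context"`) is available but uses only three blank values,
which makes a 97.5th percentile essentially the sample maximum and
destabilises the threshold; with the global pool the threshold is estimated
from hundreds of blanks and per-cell niche recovery on strong-signal
synthetic data improves from ~93% to ~99%.

**Accuracy floor.** The threshold criterion is by construction a ~2.5%
false-positive test per pure-noise well, and subtracting a blank mean
estimated from only three water wells adds a noise component shared by all
wells of a context. Consequently noisy recovery of a known niche matrix
plateaus around 98–99.5% per cell (false negatives are zero at the default
50:1 signal-to-noise); only the noiseless limit is exact. Property tests
assert exactly this: exact noiseless recovery, zero false negatives, and a
bounded false-positive rate.

## Niche set algebra

With monoculture niches A, B and co-culture niche O (sets of substrates):
expected = A ∩ B; expansion (default, the set-formula variant)
= {(A ∪ B) − (A ∩ B)} ∩ O; an extended variant O − (A ∩ B) additionally
captures substrates neither partner uses alone (consistent with the verbal
notion that "none or only one partner" could use them; which variant to
report is a user choice, default set-formula). Overlap = |A ∩ B| / |A ∪ B|,
undefined (NaN, excluded from correlations) when both niches are empty.
Classification: *expected = observed* requires exact set equality;
*expansion* requires a nonempty expansion set with the expected niche
retained; anything else — loss of expected substrates — is reported as its
own *contraction/other* class rather than merged away. Community-level
emergence is O_community minus the union of member niches.

## Functional distance

`1 − |A ∩ B| / ((|A| + |B|)/2)` over metabolite node sets; the arithmetic
mean denominator (not the minimum) is deliberate — a small network nested
in a large one is *not* maximally similar. Node sets are consumed from TSV;
network construction from 16S sequences is out of scope (database-bound).
The distance is symmetric in [0, 1] with zero diagonal but need not obey
the triangle inequality.

## Phylogenetic distance

Tajima-Nei (1984): d = −b ln(1 − p/b) with
b = (1 − Σ g_i² + p²/h)/2, h = Σ_{i<j} x_ij²/(2 g_i g_j), where g are base
frequencies pooled over the two sequences and x_ij the frequencies of each
unordered mismatch pair. Sites with gaps or ambiguity codes are deleted
pairwise (per-pair complete sites, the common distance-tool default).
p ≥ b (saturation) is flagged NaN, never silently truncated. With equal
composition and a uniform mismatch spectrum the estimator reduces to
−(3/4) ln(1 − 4p/3), which the tests verify to 1e-9, alongside a
site-counting brute-force oracle agreement to 1e-12.

Neighbor joining follows Saitou–Nei: Q_ij = (n−2) d_ij − r_i − r_j, joining
the minimal pair with a deterministic lexicographic tie-break (each cluster
represented by its smallest taxon label); branch lengths from the standard
three-point formulas, negative estimates clamped to zero with the excess
moved to the sibling so the joined distance is preserved; the final three
clusters form the conventional trifurcating root. On additive matrices the
round trip patristic(NJ(D)) = D holds to 1e-9 (tested for 4–8 taxa, and
cross-checked against an independent NJ implementation).

The "phylogenetic distance" handed to downstream regressions is the
patristic distance on the NJ tree (tree-path sum); the raw Tajima-Nei
matrix is also emitted for users who prefer the uncorrected pairwise
estimate.

## Interaction statistics

- **Pair antagonism:** directed halos x (A inhibits B) and y (B inhibits A)
  collapse to an unordered-pair label x ∨ y; self-assays are controls,
  excluded from pair statistics. A 16-strain two-level design has 512 assay
  slots, 32 self controls and 120 pair labels per level.
- **Logistic GLM:** maximum likelihood (IRLS) via statsmodels; Wald
  p-values; pseudo-R² is McFadden's 1 − ℓ/ℓ₀ (the variant standard GLM
  summaries report). Constant predictors and perfect separation are
  diagnosed and refused, never silently returned. Calibration: slope
  recovery within 95% CI at n = 2000 and Wald-test size 5% ± 2% at n = 120
  over 2000 null replicates are part of the acceptance checks.
- **Curve intersection:** two fitted logit curves cross where their linear
  predictors agree, x* = (β₀.low − β₀.high)/(β₁.high − β₁.low); an x*
  outside the observed distance range is flagged.
- **McNemar:** χ² = (|b − c| − κ)²/(b + c) over discordant pair counts;
  continuity correction κ = 1 by default, κ = 0 available; one-sided p is
  half the χ²₁ upper tail. b + c = 0 is undefined and raised.
- **Pearson:** product-moment r, R² = r², t-based two-sided p; pairs with
  flagged-missing values (e.g. undefined overlap indices) are excluded
  pairwise.
- **ANOVA + Dunnett T3:** classical one-way F with (k−1, N−k) df; pairwise
  comparisons use Welch t statistics with Welch–Satterthwaite df, adjusted
  over the m = k(k−1)/2 comparisons by the studentized-maximum-modulus
  bound 1 − (2F_t(|t|) − 1)^m, which reduces exactly to the Welch t test at
  k = 2.
- **Facilitation counting:** one-sided one-sample t against 0 at α = 0.05
  per case, no multiplicity correction (raw per-case counting).

## Growth curves and supernatant ratios

Logistic growth N(t) = K/(1 + ((K − N0)/N0) e^(−rt)) is fitted by bounded
nonlinear least squares; initial values K ← max OD, N0 ← first positive
reading, r ← early-phase log-slope. Noiseless series are recovered to 1e-6
relative error and the fit is scale-equivariant (scaling OD scales K and N0
and leaves r fixed). Monotone-decreasing or all-zero series are rejected;
optimizer non-convergence is returned flagged.

Supernatant cases compare a strain grown in a donor's spent medium with the
same strain in fresh medium. The displayed statistic is
log10(mean OD_spent / mean OD_fresh); significance is tested on
per-replicate log ratios, pairing replicate i spent with replicate i fresh
(the pairing is an analysis choice; replicate labels carry no other
meaning). The high-versus-low contrast is Δ = log-ratio(high) −
log-ratio(low), tested per case on replicate-paired deltas; Δ > 0 means
relative facilitation under high resource availability.

## Synthetic-data generator

The generator emulates the structure of a 16-strain EcoPlate study: 16
monocultures + 120 pairwise co-cultures (+ optionally the full community),
31 substrates + water, three replicates, days 0/4/7. Absorbance model:
baseline 0.08 + per-well day-0 offset (uniform 0–0.05, removed by the
day-0 subtraction) + growth signal (0 at day 0, 60% at day 4, 100% at day
7; default signal 0.5) + i.i.d. Gaussian noise (default SD 0.01). A
co-culture grows on a substrate iff either member does or the pair carries
an injected cooperative gain; by default gains are injected for half the
pairs, 1 + Poisson(1) substrates each, drawn from substrates *neither*
member uses so that they are genuine emergent gains (recoverable downstream
as the extended-minus-printed expansion sets). Niche occupancy is Bernoulli
(p = 0.45) per strain × substrate.

Inhibition labels are Bernoulli(logit⁻¹(β₀ + β₁ d)); antagonistic pairs
realise (x, y) ∈ {(1,0), (0,1), (1,1)} with equal probability. Supernatant
effects default to Normal(0.15, 0.25) log10 units at high resource
availability (positive with probability ≈ 0.73, emulating prevalent
facilitation) and Normal(−0.5, 0.2) at low (near-complete suppression).
Growth curves add Gaussian noise to the logistic mean.

What the generator does **not** model: mechanistic consumer-resource
dynamics or cross-feeding chemistry (gains are injected at the pair level),
plate-position or day-to-day batch effects, heteroscedastic or correlated
well noise, and partial (sub-maximal) growth signals — co-culture wells
where only one member grows develop the full signal, consistent with the
binary treatment of growth. Passing tests therefore demonstrate
correctness of the analysis pipeline under its stated assumptions, not
robustness to every artefact of real plate data.

All generators are deterministic given their seed.

## Numerical and design choices

- Problem sizes in tests and the acceptance script (n = 2000 GLM recovery,
  2000 null replicates at n = 120, 1.2-kb oracle sequences, 20-kb simulated
  alignments, 4–8-taxon NJ round trips) were chosen so the whole suite runs
  in seconds on one CPU while keeping Monte-Carlo standard errors well
  inside the asserted tolerances.
- Day 7 is the default scoring day; day-4 data are generated and corrected
  but excluded from calls unless requested.
- Exact set equality defines *expected = observed*; no tolerance is applied.
- The NJ tie-break (lexicographic by cluster representative) makes tree
  output byte-reproducible across runs and platforms.
- JSON summaries round floats to 10 significant digits to keep reruns
  byte-identical.

## Limitations

- Pair observations share strains, so GLM and correlation p-values inherit
  the usual non-independence caveat of all-pairs designs; no phylogenetic
  or dyadic correction is applied.
- The Tajima-Nei estimator is undefined at high divergence (p ≥ b); NJ
  requires a fully defined matrix, so saturated alignments must be handled
  upstream (shorter distances or a different marker).
- Functional distance depends entirely on the provided node sets; no
  attempt is made to validate their biological provenance.
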