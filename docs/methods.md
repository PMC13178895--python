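# Methods

`nightchorus` re-implements, as a tested pipeline, a nocturnal-soundscape
analysis workflow: four acoustic indices computed per one-minute clip,
z-scored composites of those indices related to annotated sonotype
richness through count GLMs with family selection, and a comparison of
annotation-based and index-based site dissimilarity with permutation
tests. A parametric soundscape simulator supplies seeded study data with
ground truth so every stage is testable without field recordings.

## Recording scheme and spectral conventions

The sampling design the pipeline assumes: two study areas (reserves) of
six sites each, five nights per site, one 2.5-hour nightly window
segmented into 60-second clips at 600-second intervals (15 candidates
per night), one clip selected uniformly at random per site-night —
60 analysed recordings. Audio is mono 16-bit PCM WAV at 44.1 kHz.

Spectrograms use a 484-sample Hann window with 90 % overlap
(hop = 48 samples), giving 242 frequency bins of 44100/484 ≈ 91.1 Hz
(DC bin included, Nyquist excluded) and ≈11 ms windows. Magnitudes are
scaled so a full-scale sine peaks at 0 dBFS; every dB value carries its
reference convention (full-scale, or the clip's spectrogram maximum
where only relative levels matter).

High-pass filtering (the "filtered" dataset variant) is a Butterworth
high-pass at 300 Hz, order 1, applied in a single forward pass; the
order and an optional zero-phase (forward-backward) mode are exposed in
the configuration because the original analysis names only the filter
family and cutoff. The filtered variant attenuates the low-frequency
anthropophony band (0–300 Hz) while retaining 300 Hz–20 kHz.

## The four indices

- **ACT (acoustic activity)** — the amplitude envelope is the mean of
  |samples| over consecutive non-overlapping 200-sample blocks
  (≈4.5 ms), expressed in dB relative to the loudest block; ACT is the
  fraction of blocks strictly above the 5th-percentile envelope level
  plus 5 dB. Scale-invariant by construction.
- **AEI (acoustic evenness)** — for each of twenty 1-kHz bands spanning
  0–20 kHz, the proportion of time-frequency cells above −45 dBFS; AEI
  is the Gini coefficient of those 20 proportions (0 = perfectly even).
  The Gini uses the mean-absolute-difference form
  Σᵢⱼ|xᵢ−xⱼ|/(2n²x̄), with an all-zero vector mapping to 0. Because the
  −45 dBFS threshold is absolute, AEI is deliberately not
  scale-invariant.
- **Hf (spectral entropy)** — Shannon entropy of the mean linear
  amplitude spectrum across frames, normalised by log(242). The mean
  spectrum (rather than the mean of per-frame entropies) was chosen as
  the standard construction for this index family; the alternative is a
  one-line change and is noted as an open interpretation of the source
  analysis.
- **Sm (soundscape saturation)** — the percentage of the 242 bins whose
  within-clip SNR reaches a dB threshold. The SNR estimator: frames are
  pooled into consecutive segments (default 1 s; raw short-window
  periodogram frames are exponentially distributed, with a ≈17.6 dB
  95th–5th quantile spread even for plain noise, so some temporal
  averaging is mandatory); per segment the linear power is averaged per
  bin; each segment spectrum is then normalised by its total power
  before dB conversion; the bin's SNR is the spread between its 95th
  and 5th percentile segment levels. The per-segment normalisation
  makes bin levels *relative*, which is how a dominant fluctuating
  low-frequency component (traffic noise on unfiltered recordings)
  degrades the effective SNR of every bin and forces a higher usable
  threshold on raw files — the behaviour that motivates both the
  high-pass filter and the higher raw-file Sm threshold. A strictly
  local mode (`normalize="none"`, absolute per-bin levels) is also
  provided; it is the right choice when no broadband masker is present
  and is what the localised-saturation unit tests exercise.

### Sm threshold screening

Thresholds from 3.0 to 8.0 dB in 0.1 dB steps (51 values) are screened.
A threshold is **ceiling-flagged** when the median clip Sm is ≥ 99.5 %
(saturation) or when the mean Sm is ≥ 50 % with the coefficient of
variation of site means below 1 % (high saturation with the
between-site variance squeezed out). A zero-variance threshold at
near-zero Sm is useless but is not a ceiling. Among non-ceiling
thresholds the scan picks the maximiser of the mean Efron R² of models
predicting biophony and insect richness from site-mean Sm (ties within
0.01 broken toward the lowest threshold); the default model callback is
a fast Poisson GLM, since Efron's R² depends on the fitted means that
the log-link families share. With no model callback the scan returns
the lowest non-ceiling threshold.

## Richness responses

The sonotype matrix is binary (recording × sonotype) with per-sonotype
taxon labels (insect, bird, frog, mammal, other). Responses per site:
biophony (all four animal groups), insects, and frogs/birds/mammals;
"other" (anthropophony/geophony) never counts. *Accumulated* richness
counts sonotypes present in at least one of the site's nights — the
primary response; mean per-night richness is also computed.

## Composites and count GLMs

Composites are equal-weight sums of z-scored site-mean indices
(z = (x−x̄)/s, n−1 denominator), re-standardised to mean 0 / sd 1. The
composite sets follow the study design: {Hf,Sm}, {AEI,Hf,Sm},
{ACT,Hf,Sm}, {ACT,AEI,Hf,Sm}.

Each response is modelled against one z-scored index or composite with
the reserve as a 0/1 fixed factor (reference = lexicographically first
label) under a log link. Five count families are fitted by direct
maximum likelihood:

- Poisson;
- NB2 (variance μ + μ²/θ) and NB1 (variance μ(1+α), implemented as the
  NB density with θᵢ = μᵢ/α);
- generalized Poisson, P(y) = λ(λ+ξy)^{y−1}e^{−λ−ξy}/y! with
  λ = μ(1−ξ), ξ ∈ [0, 0.95);
- mean-parameterised Conway–Maxwell–Poisson: for dispersion ν the rate
  λᵢ solving E[Y]=μᵢ is found by damped Newton on log λ (the mean's
  derivative with respect to log λ is the variance), with the
  normalising series summed on an adaptive grid (hard cap 10⁴ terms).
  ν = 1 recovers Poisson exactly; ν is optimised within ≈[0.08, 20].

Shape parameters are profiled on an unconstrained scale with multiple
starts from the Poisson solution (Nelder–Mead refinement). Reported per
fit: a two-sided Wald slope p-value from the finite-difference Hessian,
Efron's R² = 1 − Σ(y−μ̂)²/Σ(y−ȳ)², AIC = 2k − 2ℓ with k counting all
estimated parameters including the shape, and
AICc = AIC + 2k(k+1)/(n−k−1) with n = number of sites. Pearson
dispersion is χ²/(n−3) with the family's variance function — the
residual df counts mean-model parameters only, matching the convention
of the mixed-model software this models the workflow of; counting the
shape parameter in the df creates a systematic tie-break artifact.
Selection: minimum AIC; candidates within ΔAIC < 2 are tie-broken
toward the Pearson dispersion closest to 1, and the selection trace
records the decision.

## Dissimilarity analyses

The annotation view uses the binary Jaccard distance on accumulated
site × sonotype presence (insects); the index view range-scales the
four site-mean indices to [0,1], inverts ACT to align directionality,
and uses the Ružička distance (1 − Σmin/Σmax; identical to Jaccard on
binary data). Two all-zero rows get distance 0 with a warning (the
reference implementations leave this undefined; synthetic edge cases
can produce empty sites).

PERMANOVA uses the squared-distance decomposition
(SS_W = Σ_g Σ_{i<j∈g} d²ᵢⱼ/n_g), pseudo-F, R² = SS_B/SS_T, and
permutes raw labels with p = (exceedances+1)/(permutations+1); the
permutation batch is fully vectorised. PERMDISP embeds the matrix by
principal coordinates, handles negative eigenvalues by the
imaginary-axis correction (squared distances on negative axes
subtract, clamped at zero), measures each site's distance to its group
centroid, and permutes those distances under a one-way ANOVA F. NMDS is
non-metric SMACOF (scikit-learn backend, precomputed dissimilarities,
20 restarts by default, seed-deterministic); Kruskal stress-1 is
recomputed independently from the final embedding via isotonic
regression. Between/within mean pairwise dissimilarities summarise the
matrices; singleton groups report a missing within-mean.

## The synthetic soundscape generator

The generator is the testbed's definition of the study conditions:

- **Sonotype pool** — insect stridulation carriers stacked into a
  4.0-7.8 kHz core band (inside the 3.5-10 kHz range where most insect
  calls sit; >= 70 % of carriers in the core, the rest across
  1.4-20 kHz) at a minimum 135 Hz niche spacing — summer choruses stack
  callers into energy-dense bands. Frog/bird/mammal calls sit below
  4 kHz (tonal or FM-sweep, short sparse calls, 12-18 dB above the
  floor); one bat sonotype above 10 kHz. Insect amplitudes are 20-24 dB
  above the noise-floor RMS: a chorus of similar Orthoptera is
  loudness-homogeneous, which also keeps any single caller from
  dominating the clip's total power.
- **Call rendering** — pulse trains are carrier sines gated at the
  pulse rate (8-30 Hz) and duty cycle (0.3-0.8), with a slow frequency
  wobble spanning the template bandwidth (100-400 Hz). Insects trill in
  long bouts (20-60 s) broken by short silences (1-3 s); bout cycles
  run at random phase (choruses are stationary, not synchronised to the
  recorder), and a sonotype assigned to a site-night is guaranteed at
  least one audible bout in its clip. All voices of a sonotype chorus
  in synchronised bouts with independent pulse phases and slight
  detunes, so a sonotype's band still falls quiet between bouts however
  dense its chorus.
- **Density** — along richness gradients each site also receives a
  caller-density multiplier (1.5 at the poorest to 3.5 at the richest
  site): richness covaries with abundance along habitat-quality
  gradients, and denser choruses fill the spectrum more completely.
- **Anthropophony** — traffic/rail rumble: noise low-passed at 25 Hz
  (the deep-bass part of the 0-300 Hz band), 40 dB above the floor RMS,
  with a piecewise-linear dB level curve (sd 3.5 dB, ~12 control points
  per clip) emulating passing vehicles. On raw clips this layer
  dominates total power, so its fluctuation raises every bin's
  relative-level spread and ceilings the Sm scan at low thresholds; the
  300 Hz high-pass removes it almost entirely (the < 25 Hz
  concentration is what an order-1 filter can actually attenuate).
- **Study plans** — `richness_gradient_plan` assigns insect occupancy
  sizes evenly spaced between 5 and 25 across 12 sites (reserves
  interleaved so both span the gradient) plus a random sprinkle of the
  low-frequency sonotypes; detection is Bernoulli per sonotype-night.
  `two_reserve_plan` controls the sonotype-pool overlap between
  reserves: overlap 1 draws all sites from one shared regional pool
  (the no-reserve-effect scenario); overlap 0 gives each reserve its
  own insect community drawn to be genuinely distinct along the axes
  scalar indices can see — spectral concentration (occupied-band span),
  loudness regime, and calling tempo — because dominant-frequency
  placement alone is invisible to band-aggregated indices.

What the generator does **not** emulate: reverberation and propagation,
weather geophony (an optional steady distant-chorus ambience bed
exists but is off by default), amplitude-dependent detectability in
the annotation (detection is presence/absence Bernoulli),
overlapping-call masking in the annotator, and the audio realism of
actual stridulation (calls are gated sinusoids). Passing tests
therefore demonstrate the statistical machinery and the direction of
index responses under controlled conditions, not performance on field
recordings.

### Index response directions in this world

On gradient studies the four indices respond with a consistent sign
structure: Hf and Sm increase with richness x density (more occupied
bins, more saturated bins), while ACT and AEI decrease — dense
choruses tighten the amplitude envelope until the adaptive
5th-percentile-plus-5 dB threshold exceeds nearly every block, and
filling more 1-kHz bands makes the band-energy distribution more even.
This matches the source system's reported behaviour (ACT needed
directional inversion in the dissimilarity analysis, and spectral
entropy declined in the most diverse samples). A direct consequence is
that the *equal-weight* sum of all four z-scored indices largely
cancels on these data: the composite's correlation with richness is
near zero even though each component is individually informative. The
shipped acceptance suite asserts the composite-recovery property as
specified and reports it honestly as failing in this world; the
single-index Sm response (positive Spearman with richness at the
scanned threshold) is robust.

## Numerical choices

- Spectrogram frames: hop = round(wl·(1−overlap)); frame count
  ⌊(N−wl)/hop⌋+1; dB floor at 1e-12 before log conversion.
- Gini: O(n log n) sorted form of the pairwise-difference sum, clamped
  at 0 against round-off; all-zero input → 0.
- CMP: Newton solve to relative mean error 1e-11; series grid sized
  from a moment-based tail bound.
- Optimiser: shape families start from the Poisson fit at several shape
  values; Nelder–Mead with xatol 1e-7 / fatol 1e-9.
- NMDS: convergence eps 1e-9, 500 iterations; degenerate (all-equal)
  distance matrices report converged = False.
- Permutation p-values always use (b+1)/(m+1); permutations that
  recreate the observed grouping count as exceedances, so the minimum
  attainable p is slightly above 1/(m+1) for small designs.
- Master seed fan-out: each named stage (simulation, each permutation
  test, each ordination) derives a stable sub-seed, so stages re-run in
  isolation reproduce the full run.

## Problem sizes in the shipped tests and acceptance script

Audio synthesis at 44.1 kHz is the cost driver, so the shipped suite
runs the field design at reduced clip lengths: the gradient study uses
12 sites × 5 nights × 20 s clips (field: 60 s) with 0.5 s Sm segments,
and the two-reserve concordance studies use 12 sites × 2 nights × 3 s
clips with 499-permutation tests over 100 replicates per scenario.
`scripts/acceptance.py` runs the full pipeline (threshold scan, 48-model
grid, 9,999-permutation dissimilarity tests) on 15 s clips. These sizes
are the package's scaled demonstration of the design; all statistical
settings (spectrogram, grids, permutation counts at acceptance, family
set) are the field values.

## Known limitations

- The Sm estimator's relative-level mode couples a clip's dominant
  fluctuation into every bin by construction; it is the faithful model
  of relative-spectrum processing and of broadband masking, but for
  masker-free audio the local mode is the better measurement.
- Wald p-values at n = 12 are approximate; likelihood-ratio intervals
  would be preferable at this sample size but are not what the
  replicated workflow reports.
- AICc uses n = 12 sites; with five families and four parameters the
  correction is large and the selection is intentionally conservative.
- The equal-weight composite assumes its components point the same way;
  component correlations with richness can differ in sign (the
  band-count mechanics of AEI oppose the bin-filling mechanics of Hf),
  which dilutes composites in worlds where the components disagree —
  visible in the simulator and discussed in the source literature.
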