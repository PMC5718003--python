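# Methods

## Problem setting and model

Bioassay-guided fractionation produces, per chromatographic fraction
k = 1..N, a centroided mass peak list and one scalar activity reading.
The working assumption is **additivity**: the activity of a fraction is a
weighted sum of the amounts of the active compounds it contains,

a_k = Σ_i w_i · amount_{i,k} + ε_k,

with w_i ≥ 0 a compound's potency per unit amount and ε_k assay noise.
Under this assumption a genuinely active compound's elution profile is
(up to noise and the contributions of the other actives) a component of
the activity profile, so profile correlation is an informative ranking
signal. Everything the package computes — and everything its simulator
generates — inherits this assumption; matrix effects, synergy, and
antagonism are outside the model.

## Scores

Let M_j be the intensity profile of mass bin j and A the activity profile,
both over the N fractions, and let v⁰ denote v scaled to unit Euclidean
norm (all-zero vectors stay all-zero and score 0).

* **Score 1** C_j = 100 · Σ_k a⁰_k m⁰_kj. The dot product of unit-norm
  non-negative vectors lies in [0, 1]; it is reported ×100 because every
  working value associated with the method (reported bin scores in the
  20–50 range, a speed-filter threshold above 30) is only consistent with
  a percent-of-perfect-correlation scale.
* **Score 2** = C_j · I with I = Σ_k m_kj the raw summed intensity —
  a compound below the detection limit cannot be recovered regardless of
  shape, and an abundant active drags activity up where it elutes, so
  concentration carries signal.
* **Score 3** = C_j σ² I / N_f², evaluated per chromatographic **group**.
  Groups are maximal contiguous runs of fractions whose intensity is
  strictly greater than the mean of the whole bin profile; each group is
  treated as an independent candidate ("a new mass bin"). C_j for a group
  is computed on the masked full-length profile (out-of-group fractions
  zeroed) against the full activity vector — masking rather than
  truncation keeps every C_j on one comparable scale. σ is the
  **population** standard deviation of the raw in-group intensities
  (sample SD would be undefined for the common single-fraction group) and
  I their sum. The σ²/N_f² factor rewards sharp, concentrated elution and
  penalizes broad flat profiles.

Ranking sorts by the active method's score descending with deterministic
tie-breaks (ascending m/z, then ascending start fraction); ranks are 1..n.
An optional `min_cj` prefilter drops candidates with C_j at or below a
threshold. It is off by default: it exists to thin very large peak lists,
and because C_j multiplies every score it mostly removes candidates that
already rank low — but it also removes genuinely active, weakly
correlated candidates, so it is a speed/recall trade the caller must opt
into.

### Grouping and pooled-bin overestimation

When one mass bin holds two components eluting in different windows, the
pooled profile can harvest correlation from both at once and overstate
Score 1; splitting the bin scores each component on its own masked
profile. Two regimes follow directly from the algebra of the unit-norm
dot product: if activity overlaps **both** regions, each group's C_j is
below the pooled C_j (the pooled value double-counts); if activity
overlaps only **one** region, the matched group's C_j *rises* (the inert
component no longer dilutes the norm) while the unmatched group falls to
~0. Both regimes are asserted in the test suite.

## Preprocessing

Fixed order: S/N filter → blank subtraction → de-isotoping → binning.

* **S/N filter** keeps peaks with S/N strictly greater than the threshold
  (default 4); peaks without an S/N estimate are kept.
* **Blank handling**: replicate blanks are merged within a ppm tolerance
  (intensity-weighted centroid m/z; mean intensity counting absences as
  zero), then a sample peak is removed iff a blank peak lies within
  `tol_ppm` (default 1) *and* the sample intensity is at most
  `ratio` × the blank intensity (default 3). The ratio guard keeps a
  strong genuine signal that happens to coincide with a trace blank peak;
  `ratio=inf` reproduces removal on mass match alone.
* **De-isotoping** processes peaks in descending intensity (ties broken by
  ascending m/z); for each still-retained peak, any retained lower-intensity
  peak within `tol_ppm` of +n × 1.0033548378 Da (n = 1..3) is removed.
  Removed peaks are never used as parents. The operation is idempotent and
  never removes the most intense peak. An optional intensity-plausibility
  cap on the satellite/parent ratio was considered and left out: the
  mass-spacing test alone is the documented behavior, and on simulated
  ground truth it removes exactly the planted satellites.
* **Binning** clusters peaks from all fractions greedily in descending
  intensity: a peak joins the nearest existing bin if it lies within
  `bin_ppm` (default 0.5, interpreted as a tolerance radius) of the bin's
  running intensity-weighted centroid, else it seeds a new bin. A fixed
  m/z grid would split peaks straddling grid edges; greedy centroid
  clustering anchors each bin on its strongest peak. Within a bin, peaks
  from the same fraction are summed into m_kj. Total intensity is
  conserved exactly.

## Enrichment evaluation

A ranking with known active/inactive labels is summarized by its
enrichment curve and trapezoidal AUC. The default convention advances
x by 1/n_inactive per inactive and y by 1/n_active per active — the only
convention in which an ideal ranking scores exactly 1.0 and random scoring
0.5 in expectation for finite lists. The literal
fraction-of-database-screened convention is available for comparison
(ideal = 1 − n_active/2n). Candidates with tied scores are collapsed into
one diagonal segment, which equals the average over their permutations and
makes the AUC independent of sorter order.

## Mass arithmetic

Monoisotopic masses use the NIST values ¹H 1.00782503207, ¹²C 12 (exact),
¹⁴N 14.0030740048, ¹⁶O 15.9949146196, ³²S 31.97207100, ³¹P 30.97376163 Da.
[M−H]⁻ = M − 1.00727646688 Da (the proton mass, i.e. M − m(H) + m(e⁻));
dropping the electron mass would bias every ion by ~0.55 mDa, an order of
magnitude above 15 T FT-ICR accuracy. Masses are kept at full double
precision and rounded only for display.

## The simulator

`synthetic.simulate_dataset` emulates a 33-fraction preparative-LC study:

| parameter | default | rationale |
|---|---|---|
| n_fractions | 33 | sequential 2-min fractions of one preparative run |
| n_compounds / n_active | 200 / 8 | a few hundred detectable constituents, a handful of true actives |
| elution | Gaussian, σ ~ U(0.4, 0.9) fractions | preparative peaks span ~1–3 fractions |
| abundance | log-normal(12, 1) | constituent amounts spanning ~2 orders of magnitude |
| active abundance | log-normal(12 + 2.0·1, 0.35) | see below |
| active contribution | U(0.3, 1.0) of the activity scale | every planted active is assay-detectable |
| activity noise | 5% of the max signal, clipped at 0 | replicate scatter of a plate assay |
| isomer fraction | 0.1 | share of compounds reusing another compound's m/z with independent elution |
| satellites | +1, +2 at n_C·0.0107 and its square-term analog | binomial expectation from the carbon count (n_C ≈ 0.55·m/z/12) |
| blanks | 30 contaminant peaks, 3 replicate blank spectra | constant background with 5% replicate jitter |
| noise peaks | 60 per fraction, log-uniform 5·10²–2·10⁴ | sporadic single-fraction junk dominating real peak lists |
| S/N model | intensity / 200 | a flat noise floor |

Two coupled choices define what "active" means here. First, each active's
peak contribution to the activity profile is drawn comparable (0.3–1.0 of
the scale): a compound whose contribution drowns in assay noise would be
ground-truth-active in name only, and no correlation method could or
should recover it. Second, active abundances sit at the top of the global
abundance distribution (log-mean shifted by 2 SD, tighter spread): an
assay like DPPH responds to microgram-scale quantities while the mass
spectrometer detects nanograms, so the constituents an activity assay can
see are necessarily among the abundant ones. Active elution centers are
stratified across the run with jitter, as a validation panel of standards
covers the elution range. Compound m/z values are drawn with a 20-ppm
minimum spacing and a 5-ppm exclusion around other compounds' +1..+3
satellite positions, so ground truth is unambiguous for de-isotoping
tests. All randomness flows from one seeded generator; identical seeds
give bit-identical datasets.

What the simulator does **not** model: ionization suppression and matrix
effects, detector saturation, retention-time drift between fractions,
tailing/fronting peak shapes, isotopic fine structure, or activity
synergy. Passing tests on simulated data therefore demonstrate the
pipeline's correctness and its behavior under the additive model, not
performance on any particular real extract — in real data the additivity
assumption itself, not the arithmetic, is usually the binding constraint.

Under the defaults, the full method-3 pipeline recovers 6–8 of the 8
planted actives in the top 20 and reaches enrichment AUCs ≥ 0.9 (the
acceptance test runs seed 1; a 12-seed pilot at these conditions gave
mean AUC 0.99), and the method ordering Score 1 < Score 3 ≈ Score 2 in
AUC reproduces the qualitative picture the scoring methods were designed
around. Problem sizes in the test suite (20–33 fractions, 8–200
compounds, ≤ 100 replicates) were chosen so the whole suite runs in well
under a minute of CPU while keeping every statistical assertion
comfortably outside Monte-Carlo noise.

## Numerical and degenerate-input choices

* Unit normalization pre-scales by the max absolute entry before the norm
  so vectors of tiny floats cannot underflow to zero.
* All-zero profiles or activity: C_j = 0, candidate retained.
* Constant bin profile: no fraction strictly exceeds the mean, so no
  groups and no Score-3 candidates — a flat profile carries no elution
  information.
* Fraction indices are 1-based everywhere, matching how fractions are
  labeled at the bench.
* Table-layout readers reject NaN/Inf cells, duplicate or gapped fraction
  indices, and unknown config keys outright; writers emit full-precision
  `repr` floats so read∘write is the identity to 1e-9 or better.
* The activity reader stores scavenging strength (higher = more active);
  converting remaining-%DPPH readings via 100 − x is an explicit option,
  never implicit.
* The bin×fraction matrix reader accepts either unit-norm or 0–100-scaled
  per-bin intensities and records which it detected rather than guessing a
  rescale.

## Known limitations

* Greedy centroid binning is order-canonical (descending intensity) but,
  like all single-pass clusterings, can split a peak cloud wider than two
  tolerance radii differently than an optimal clustering would.
* C_j is a non-centered cosine similarity: a bin with constant nonzero
  intensity correlates with any non-negative activity profile. The
  grouping step (method 3) is the intended mitigation.
* Score 3's σ²·I weighting spans many orders of magnitude on raw
  intensities, so extreme-abundance bins with mediocre correlation can
  outrank weaker true actives; the `min_cj` prefilter trades recall for
  precision there.
* Enrichment AUC treats every candidate equally; it does not capture
  early-recognition emphasis (no BEDROC-style weighting).
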