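# Methods

This note documents the statistical model, the defaults, the design of the
synthetic fixtures, and the numerical choices. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pipeline

The pipeline runs six stages in order:

1. **Seed definition.** Probabilistic seed maps (e.g. cytoarchitectonic
   probability volumes) are resampled to the analysis grid (trilinear,
   clipped to [0, 1]) and thresholded at probability **strictly greater
   than 0.25**. The strict inequality is a deliberate reading of "more
   than 25%"; thresholding happens after resampling. Label volumes always
   use nearest-neighbour resampling — interpolating labels is meaningless.

2. **Seed-based RSFC.** Per subject, the mean BOLD series over the seed's
   voxels is correlated with every in-brain voxel; r is clipped to
   ±(1 − 1e−7) and Fisher-transformed, z = atanh(r). Correlation rather
   than a regression slope is used because it is symmetric and
   scale-free. Voxels with zero temporal variance get z = 0 and can never
   appear connected.

3. **Group inference.** Subject z-maps enter a one-sample t test against
   zero (random effects, df = N − 1). Zero between-subject variance with a
   nonzero mean is reported as ±inf (the voxel is then trivially
   suprathreshold); zero mean with zero variance gives t = 0. The test is
   one-sided (positive coupling) by default, since the pipeline consumes
   *functionally coupled* regions; a two-sided flag exists.

4. **Voxel-level FWE.** Default Bonferroni over the in-brain voxels at
   α = 0.05 — deterministic and conservative. A sign-flip permutation
   alternative (default 1000 flips, seeded) builds a max-statistic null;
   its p-values include the observed labelling, so p ≥ 1/(B+1). Parcels
   covered by **at least 80%** of their volume are retained; any parcel
   sharing even one voxel with any seed is excluded (no tolerance is
   stated for that exclusion, so one voxel triggers it). Overlap is the
   fraction *of the parcel* covered, not of the map.

5. **Decoding.** Terms are binarised at frequency ≥ f_min = 0.001 (the
   common convention for study–term frequency tables; the value is
   configurable). A study activates an ROI when one of its foci lies
   within `radius_mm` of an ROI voxel center; radius 0 means strict
   in-mask membership. Likelihoods are stratum proportions; the forward
   and reverse formulas use a fixed prior of 0.5; association is a
   Pearson chi-square without continuity correction (df = 1); BH-FDR at
   α = 0.05 across the vocabulary. Terms labelled in all or in no studies
   are excluded as non-computable rather than given sentinel posteriors.
   Reporting takes the top 30 terms by posterior (ties broken
   lexicographically for determinism), then drops non-significant terms
   post hoc, then applies the construct allowlist
   (`rank_then_filter`; `filter_then_rank` is available).

6. **Systems decoding, topics, networks.** Each seed–parcel pair is
   decoded with the co-activation reading (study active iff it activates
   seed AND parcel); the union-mask reading is kept as an option because
   the joint ROI can be defined either way. The parcel is also decoded
   alone (cached across seeds). Set difference gives pair-specific terms,
   intersection gives shared terms; the two always partition the pair's
   term list. Non-allowlisted terms are removed before the set
   operations. Pair-specific terms populate the system map
   (seed, term) → parcels, terms are grouped into topics by a hard
   term→topic file (argmax loading with a 0.001 floor when a loading
   matrix is supplied instead), and topic maps are rasterised to voxels
   for directional percentage overlap with the network partition. Voxels
   with network label 0 are reported explicitly as an "unassigned"
   pseudo-network so each row block sums to 100 and is auditable.
   Overlap is computed volumetrically on the shared grid.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| seed probability threshold | 0.25 (strict >) | seed mask definition |
| FWE α / method | 0.05 / Bonferroni | voxel-level group threshold |
| min_overlap | 0.80 (≥) | parcel retention rule |
| prior p | 0.5 | reverse-inference prior, equates term base rates |
| f_min | 0.001 | term binarisation cutoff |
| radius_mm | 0 in the pipeline; 6 in the decoder API | focus-to-ROI matching |
| k | 30 | reported terms per ROI |
| FDR α | 0.05 | BH across vocabulary |

The two radius defaults are intentional. For full-scale atlases a ~6 mm
matching radius is a reasonable smoothing of focus placement error. The
toy fixtures, however, live on a 24³ grid of 2 mm voxels where parcels
span only 10–20 mm: a 6 mm radius makes neighbouring parcels
statistically indistinguishable and saturates every activation rate, so
the pipeline's study conditions use strict in-mask matching and the
generator truncates focus jitter (Gaussian, sd 4 mm) to the source ROI.

## The synthetic fixtures

`synthetic` generates every input with planted ground truth on a 24³,
2 mm grid: 40 block parcels tiling the interior (hemispheres split at the
x midline), each parcel assigned to one of seven named networks; six
probabilistic seed maps (three per hemisphere) with disjoint >0.25 cores;
per seed, four same-hemisphere connected parcels disjoint across seeds.

**BOLD.** Per subject and seed, a latent Gaussian series is shared by the
seed's voxels (population r = 0.9) and by its planted parcels
(population r = `effect_r`, default 0.5); everything else is i.i.d.
noise. T = 400 volumes at TR = 0.8 s and N = 20 subjects mirror a short
high-temporal-resolution resting-state acquisition at desk scale. There
is no hemodynamic model, no temporal autocorrelation and no motion: a
passing recovery test shows the inference chain is correct, not that it
is robust to realistic noise structure.

**Coordinate database.** 2000 studies over a 120-term vocabulary.
Planted associations come in two kinds. *Marginal* terms behave like
classic single-region associations: a study assigned to the term
activates the ROI with probability `signal_rate` = 0.8 against a
`base_rate` = 0.1 chance background. *Conjunction* terms encode the
package's central object — a co-activation association: every "system"
ROI is activated at the same flat marginal rate (`coupling_rate` = 0.5,
which maximises the ρ vs ρ² joint-vs-independent contrast), and in
studies assigned to the term the draws of its ROI set are perfectly
coupled (one shared coin). Such terms are invisible to any single-ROI
decoding — the signal exists only in the joint distribution — which is
exactly the property the pair-decoding stage is supposed to detect and
the region-alone subtraction is supposed to spare. Per seed the truth
plants one two-parcel conjunction term, one single-parcel conjunction
term, a designated pair-only probe, an "anatomical" term marginal on the
seed (excluded from the construct allowlist, like anatomy vocabulary in
real databases), and a region term marginal on one parcel (decodable from
the region alone, hence expected to be subtracted as *shared*). Each
parcel is coupled by exactly one conjunction term and conjunction terms
of one seed are mutually exclusive within a study (prevalence 0.25 each;
marginal terms 0.1, independent): planted effects must not contaminate
each other's negative strata, otherwise they mask one another — the
earlier overlapping design measurably inverted contrasts. Foci are
placed at random member voxels with ROI-truncated jitter; three
background foci per study fall uniformly over the labeled region.

All generators are pure functions of their parameters and an RNG seed
(byte-identical reruns, verified by test); the truth serialises to JSON
losslessly.

## Numerical choices and degeneracies

- r-clipping at 1 − 1e−7 bounds atanh; self-correlated voxels get a large
  finite z rather than inf.
- Chi-square tables with a zero marginal return (stat 0, p 1): the term
  is uninformative, not an error.
- `reverse_inference` is undefined when the forward probability is 0
  (only possible when both likelihoods are 0); such terms are excluded.
- BH q-values are the standard step-up minima, capped at 1.
- Tie-breaks (term ranking) are lexicographic; iteration orders are
  sorted; the end-to-end pipeline is byte-reproducible from its config.
- Empty masks are legal containers but rejected at the point of use
  (seed extraction, overlap denominators, decoding).

## Problem sizes used by the checks

The acceptance script and headline tests use: 500 simulated null group
datasets of N = 20 subjects on a 16³ grid for the FWE rate; 100
repetitions of a 2000-study × 200-term independent database for FDR
control; 10 seeded replicates of the N = 20, T = 400, r = 0.5
resting-state recovery; and one full default-scale pipeline run for the
planted-system recovery. These sizes make the whole suite run in a few
minutes on a single CPU while keeping Monte-Carlo error well inside the
asserted bounds.

## Known limitations

- The synthetic spatial model (block parcels, spherical seeds, uniform
  background foci) has none of the geometry of real cortex; overlap
  percentages on fixtures exercise the arithmetic, not anatomy.
- Random-field-theory FWE and cluster-extent inference are out of scope;
  Bonferroni is conservative under the smoothness of real maps.
- The activation model treats studies as exchangeable and foci as
  independent; no sample-size weighting of studies is attempted.
- Topic assignment is a hard mapping; probabilistic topic loadings are
  reduced by argmax.
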