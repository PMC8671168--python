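# Methods

`distrank` implements the decision core of a CASP-style protein structure
prediction pipeline: given a pool of candidate tertiary-structure models for
one target plus predicted inter-residue distance/contact information, it
scores the models, ranks them, combines the top-ranked ones, parses the
target into domains, and evaluates how well any of those decisions worked.
This note records the models, the tunable parameters, the synthetic study
design, and the numerical choices behind them.

## Structure representation

A model is a single-chain Ca trace (`Structure`): one-letter sequence,
strictly increasing 1-based residue numbers, and an L x 3 coordinate matrix
in angstroms, optionally with Cb positions (Ca reused for glycine).  PDB
input keeps the first model, first chain and the highest-occupancy
alternate location (first on ties); residues without a Ca are dropped with
a warning so the numbering gap stays visible.  All intervals (domains, splice regions) are 1-based inclusive;
the BED-like segment writer converts to 0-based half-open on output.

Geometry diagnostics follow the conventions used when deciding whether a
combined model is structurally sound: a *clash* is a non-adjacent Ca pair
closer than 1.9 A and a *break* is a sequence-adjacent Ca pair farther than
4.5 A.

Contacts are residue pairs at distance <= 8 A; sequence-separation classes
are short 6–11, medium 12–23, long >= 24 (the CASP convention).  The
distance-map schemes `ca` and `cb` are both exposed; the synthetic pipeline
uses `ca` throughout because decoys and combined models are Ca traces.

## Superposition scores

`kabsch` is the closed-form least-squares superposition (SVD of the
covariance, reflection corrected); degenerate (collinear or < 3 point)
inputs are rejected.

GDT-TS is the mean over the 1/2/4/8 A cutoffs of the maximal fraction of
corresponding Ca atoms within the cutoff under a searched superposition.
TM-score is `max (1/L_ref) sum 1/(1+(d_i/d0)^2)` with
`d0 = 1.24 (L_ref - 15)^(1/3) - 1.8`, floored at 0.5 A for short chains.
Residues correspond through their residue numbers; unmatched residues are
excluded from the superposition but still count in `L_ref`.

Both scores need a search over superpositions.  The heuristic seeds Kabsch
fits from all contiguous fragments of lengths 4, 8, 16 and L at stride 4,
and refines each seed by iterating superpose -> keep the residues inside
the cutoff -> re-superpose (at most 10 rounds; the TM search keeps residues
within `max(d0, 4.5)` A).  For chains of at most 12 corresponding residues
the seeds are instead *all* residue subsets of size >= 3, which makes the
per-cutoff maxima exact — every refinement fit is itself a subset fit, so
subset enumeration dominates the search space.  The tests exploit this: an
independent subset-enumeration oracle (built on scipy's rotation
alignment) must agree with the small-chain path to 1e-6.  The searched
scores are symmetric in their arguments and rigid-motion invariant only up
to the heuristic (asserted to 0.02 on random decoys); no claim of
third-decimal agreement with any particular external GDT implementation is
made.  The inner loops are JIT-compiled because consensus scoring needs
~400 pairwise GDT-TS evaluations per 30-model pool.

## Map-matching and contact-matching features

A distance map is rendered to a [0, 1] image by capping distances at 16 A
(contacts live below 8 A; 16 A keeps contrast in the near-contact range)
and dividing by the cap.  The nine map-matching scores of a model against a
predicted map:

| score | definition |
|---|---|
| ssim | windowed structural similarity, 7x7 window, data range 1 |
| psnr | peak signal-to-noise on the images, capped at 100 dB (identical maps are otherwise infinite) |
| gist | cosine similarity of a 4x4-grid x 8-bin gradient-orientation-histogram descriptor |
| rmse | root mean squared difference (A) over off-diagonal cells of the raw maps |
| recall / precision | of predicted <= 8 A cells against observed <= 8 A cells, separation >= 6 (the trivial near-diagonal band is ignored); empty denominators count as 1 |
| phash | 1 − normalised Hamming distance of 64-bit DCT perceptual hashes (32x32 resample, top-left 8x8 block, median threshold excluding the DC term) |
| pearson | correlation over upper-triangle cells with separation >= 6 |
| orb | matched ORB keypoint descriptors / max keypoints on the images scaled to 256x256; 0 when either image yields no keypoints |

The GIST score is an orientation-histogram stand-in for the full
Gabor-filter-bank descriptor, whose exact parameters vary between
implementations; it keeps the "global layout" character of the original.
Recall/precision binarise both maps at 8 A — probability-weighted variants
would need a calibrated predictor, which the plain distance matrix does not
carry.

Contact-matching scores are the precision of the top L/2 predicted
contacts per separation class against the contacts realised in the model's
map; ties in the top-k selection break by (i, j) order so the selection is
deterministic.

## Pool filtering, consensus and the stacked ranker

Within each submitting group, near-duplicate models (pairwise GDT-TS >
0.95) are removed greedily in server-rank order, keeping the better-ranked
representative; cross-group duplicates are never removed.  The consensus
(clustering) score of a model is its mean GDT-TS to every other pool
member.  Rank fusion of several QA methods uses mean rank position rather
than mean raw score, because raw scores from heterogeneous scorers are not
on a common scale.

The stacked quality-assessment regressor (`StackedQA`) predicts true
GDT-TS from the feature vector (9 map scores + 3 contact scores +
consensus + any auxiliary single-model columns).  Level 1 is ten small
feed-forward networks (two hidden layers, 64/32 units, lbfgs, L2 1e-3)
trained by tenfold cross-validation; each training row receives an
out-of-fold level-1 prediction, which joins the standardised input
features as input to the level-2 network of the same shape.  At prediction
time the level-1 output is the mean of the ten networks.  Predictions are
clipped to [0, 1].  Missing feature values are imputed with training-set
column medians (logged).  Everything — fold assignment and weight
initialisation — derives from one integer seed, and refits are
bit-identical.  The learner is deliberately small: the features already
carry most of the signal, and the architecture is pluggable behind the
fit/predict surface.

## Domain parsing

Template hits are kept when E-value <= 1, aligned target length > 40 and
reported coverage > 0.5 ("aligned length" is the hit's target interval, the
reading consistent with the 40-residue rule below; coverage arrives
precomputed in the hit table, so whether it was measured over target or
template stays upstream).  The union of retained intervals is the
template-based cover; every maximal uncovered run longer than 40 residues
becomes a template-free (FM) domain.  Shorter uncovered runs are absorbed
into the adjacent template-based region — the rule that makes "all other
regions template-based" well defined; absorbing a gap between two TBM runs
merges them, so the larger-neighbour tie question never changes the final
segmentation.  No retained hits at all means a single-domain FM target.
Model-based boundary refinement (a manual step in human prediction
pipelines) is out of scope.

## Model combination

Two neighbour-selection presets are exposed, mirroring the two protocol
variants: `server` keeps models with GDT-TS > 0.6 to the reference
(similarity only), `human` keeps models ranked within the top 60 with
GDT-TS > 0.7 *or* RMSD < 3 A.  Both cap the member set at 20 in rank
order; an empty set is legal and simply means the reference stands alone
(the hard-target failure mode).

The consensus engine is superpose-and-average: every member is
Kabsch-superposed onto the reference and the candidate Ca trace is the
unweighted mean including the reference.  This replaces multi-template
rebuilding with an external comparative-modelling engine; the decision
surface around it — the member-selection rules and the acceptance gate —
is unchanged, and the candidate is explicitly a Ca-only trace (flagged in
the output PDB header).  A candidate whose GDT-TS to the reference falls
below 0.9 is rejected, signalling the caller to refine the reference
instead (refinement itself is out of scope).

Region splicing replaces a bad region of one model with the corresponding
region of a donor: the donor is superposed with the TM-score-optimal
transform computed on the residues *outside* the region, the kept model's
coordinates are preserved bit-for-bit outside the region, and the result
is geometry-checked because junctions can legitimately break.

## Evaluation statistics

* Ranking loss: true GDT-TS of the pool's best model minus that of the
  QA-selected top-1 model.
* Z-scores use the population SD (divide by n, the CASP convention;
  switchable to sample SD); predictors are compared by the sum of positive
  Z-scores.  A zero-SD pool yields all-zero Z with a warning.
* Skewness is the unadjusted moment estimator g1 = m3 / m2^1.5.
* Neff greedily clusters alignment rows in file order at > 62% identity,
  where identity counts identical non-gap residues over the query's
  non-gap columns divided by the query's non-gap length; Neff is the
  cluster count, with no additional length normalisation.  The greedy
  order and the denominator are covered by a brute-force oracle test.
* Good-model fraction: strictly above TM-score 0.5.

## Synthetic study design

The generator fabricates the study conditions; its defaults are fixed and
documented here.

**Natives** are self-avoiding Ca traces with exactly 3.8 A virtual bonds:
helix segments (6–14 residues, ideal helix geometry re-parameterised so
consecutive Ca are 3.8 A apart) alternate with extended zigzag segments
(4–8 residues).  Each segment is attached in a random orientation aimed
back toward the body centroid and re-drawn if it comes within 3.5 A of the
existing trace, which folds the chain into a compact globule (radius of
gyration ~ 10–13 A at L = 60) with genuine medium- and long-range
contacts.  Cb atoms sit 1.53 A off the local chain axis.

**Decoys**: each decoy's displacement field has per-atom RMS equal to its
noise level and is chain-smoothed (Gaussian, 3 residues), because
low-frequency deformations spread GDT-TS realistically where independent
per-atom noise would collapse it.  The displacement splits into a shared
per-level "basin" deformation (85% of the variance, `mode_share`) and an
individual remainder: real pools are multi-modal, with bad models
clustered around a few wrong conformations, and that clustering is exactly
what misleads consensus ranking on hard targets.  Setting `mode_share = 0`
recovers independent perturbations symmetric about the native (used where
symmetry is the point, e.g. the combination-improvement trials).  The
default noise ladder (0.8, 2.0, 3.5, 5.5, 8.0 A) spans GDT-TS ~ 0.97 down
to ~ 0.4 with roughly even spacing, so a balanced pool has an
approximately symmetric quality distribution.  The skew knob reweights the
ladder by `exp(skew * level_index)`: at knob 1 a 30-model pool holds ~ 17
worst-level decoys and roughly one near-native model.  Measured score
skewness rises monotonically with the knob on the operating range 0–1
(≈ 0.2 → 1.5); beyond ~ 1 the pool degenerates toward a single bad
cluster and measured skewness falls again.

**Predicted maps** are the native map plus symmetric zero-mean noise of
chosen RMS, mixed 70% spatially smooth / 30% per-cell: learned distance
predictors err in whole regions (badly aligned segments, missed
inter-domain blocks), not cell by cell.  The study default of 2 A RMS
corresponds to a usable but imperfect predictor.  Predicted contacts are
the map cells <= 8 A, scored monotonically decreasing in predicted
distance.  Auxiliary QA columns are true GDT-TS plus N(0, 0.07) clipped to
[0, 1] — the realism level of a decent external single-model scorer.

**Ranking study**: 20 training and 20 held-out targets (L = 60, 30 decoys
each), alternating balanced (skew 0) and hard (skew 1.5) pools, the mix a
blind benchmark presents.  The study reports pooled held-out Spearman
correlation, per-target top-1 losses of the stacked QA, of consensus
alone, and of every single feature column.  The skew-robustness study
re-uses the trained ranker on 7 fresh pools per knob level (0, 0.5, 1.0).
Problem sizes were chosen so the whole suite runs comfortably on one CPU;
larger pools change none of the qualitative conclusions.

**What the fixtures do not emulate**: real side-chain packing and backbone
geometry beyond the Ca trace, sequence-dependent contact propensities,
predictor errors correlated with alignment depth, multi-chain assemblies,
and pools mixing models of different lengths.  Passing tests therefore
demonstrate the decision protocols and the learning machinery, not
end-to-end accuracy on experimental CASP data — the external datasets
those numbers require are deliberately out of scope.

## Numerical choices and degenerate inputs

* PSNR of identical images is capped at 100 dB to keep the feature finite.
* Pearson between maps is defined as 1 for bit-identical maps and 0 when
  either side has zero variance.
* Empty predicted contact sets score precision 0 with a warning; top-k
  selection short of k returns everything available with a warning.
* Constant-label training is allowed but warned about; constant-feature
  columns survive standardisation (unit variance is substituted).
* Zero-SD Z-score pools, zero-variance skewness and zero-variance
  correlations all warn and return the documented neutral values (0, 0,
  NaN respectively) instead of raising.
* Ranking ties break lexicographically by model id everywhere, so every
  ordering is deterministic.
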