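# Methods

## Scope and model

`ctnet` analyses populations of diploid nuclei in which seven chromosomes
(1, 4, 11, 12, 16, 17, 18) are labeled, each contributing two homolog
territory masks. A homolog pair *interacts* when the minimal 3D
border-to-border distance between the masks is at or below 0.28 µm — four
in-plane pixels at the default pitch (dx = dy = 0.07 µm, dz = 0.5 µm).
Distances are always computed in physical micrometres under the
anisotropic spacing, so the pipeline generalizes to other pitches; the
threshold is inclusive, with a 10⁻⁶ µm guard so that an exactly
four-pixel separation (whose binary representation rounds just above
0.28) stays inside the bound.

## Measurement engine

Segmentation offers three criteria that agree closely on well-separated
bimodal signal: the isodata histogram threshold, a band selection from
the histogram-valley level upward, and a descending threshold that stops
at the first background speckle disconnected from the territory core.
Homologs are tagged by volume (a = larger; exact ties broken by the
lexicographically smaller centroid). Per territory the engine reports
volume, centroid (unweighted over mask voxels), principal axes
(4·√eigenvalue of the second-moment matrix, the standard region-property
convention), SR and MPD; per homolog pair PBD, PCD, PBCD and overlap.

Numerical choices:

* Boundaries are mask voxels with a face neighbour outside the mask
  (6-connectivity); component labeling uses 26-connectivity.
* PBD is an exact nearest-neighbour query between the two boundary voxel
  sets (KD-tree on the larger set); it equals the exhaustive
  boundary-pair minimum, which the test suite verifies, and is 0 whenever
  the masks share voxels.
* PBCD is direction-ambiguous (whose periphery, whose centre); the
  smaller of the two directions is reported.
* SR locates the periphery crossing by marching the centre→centroid ray
  at half the finest pitch, so it carries about half-voxel
  discretization error; MPD samples the nucleus-interior distance
  transform at territory voxels.
* Percent overlap has no canonical denominator; the table reports the
  percentage of each partner and their mean.

For a 7-chromosome nucleus the engine emits 14 homolog rows and 91 pair
rows: 84 heterologous and 7 homologous pairs × three distance families =
252 + 21 distance values, plus 28 axis values. (A related published
count of "82" per family is arithmetically inconsistent with the total
of 252 = 84 × 3 it accompanies; this implementation uses 84.)

## Interaction statistics

Each nucleus becomes a symmetric 14×14 binary matrix with 91 informative
upper-triangle positions. Population summaries: per-pair percent of
nuclei with ≥1, =1 and ≥2 contacts (the identity pct≥1 = pct=1 + pct≥2
holds exactly); multiplet patterns of the 2×2 pair block (2a disjoint
contacts, 2b/2c the two triplet orientations — 2b shares a copy of the
lower-numbered chromosome — 3 the alternating chain, 4 saturation);
per-chromosome mean heterologous partner counts (averaged over copies by
default, over the copy-union optionally); homologous-vs-heterologous
frequencies normalized by the 1 vs 4 available contacts; and OLS of mean
SR against sequence length or gene density (bundled, editable constants).

## Cell-cycle comparison

A pair's (=1, ≥2) profile *changes* between conditions when the relative
difference versus the first condition exceeds a tolerance (default 20 %;
a gain from zero always counts as a change). Types: 1 both channels up,
2 both down, 3 singular→multiple switch, 4 the reverse, 5 no change;
single-channel changes are typed 1/2 by direction. Because published
descriptions of the switch direction conflict, `switch_convention`
exposes both readings. Chi-square tests use Pearson's statistic on
counts without continuity correction, against the uniform average
(df = cells − 1) or a second condition (contingency df); zero expected
counts raise with the offending cell named. S:G1 ratio tables flag zero
denominators with NaN rather than emitting infinities.

## Chromatic median

The consensus problem — per-nucleus 7-bit homolog flips plus a binary
median minimizing total Hamming disagreement — is solved by alternating
optimization: exhaustive best response over all 128 flip vectors per
nucleus against the current median, then an entry-wise majority update
(exact ties set to 0, a deterministic, conservative rule), interleaved
with sequential plateau sweeps that re-resolve best-response ties at
random so equal-objective moves can traverse the plateaus separating
local optima. Restarts combine identity and greedy-sequential
initializations, a divide-and-conquer progressive merge (halves aligned
recursively, then joined by the best global flip), a per-chromosome
spectral 2-coloring (sign of the leading eigenvector of the pairwise
agreement-difference Gram matrix), fresh random starts and kicks of the
incumbent; 50 restarts by default. The original formulation of this
problem was attacked with semidefinite programming; the solver here is
deliberately desk-scale and is certified against a brute-force
enumerator: on instances with ≤3 chromosomes and ≤6 nuclei it reaches
the global optimum on 100/100 random draws. On the planted benchmark a
rare draw (about 1 run in 20) converges to a deep non-planted optimum
that none of the initializations escape — the hardness that motivated
the SDP treatment; the recovery criterion (≥95 % of runs) accommodates
it.

The percent matrix uses the converged flips. Thresholds are the smallest
integer percent strictly above the maximum entry of the randomization
controls; network edges are the percent entries at or above the
threshold, tiered into top/middle/bottom thirds (boundaries at ⌈n/3⌉,
ties promoted upward). Sørensen similarity 2|A∩B|/(|A|+|B|) compares a
nucleus's aligned edge set to the model. Note that an efficient aligner
concentrates randomized inputs more strongly than a weaker one would, so
the randomization control here is conservative: thresholds retain only
pairs whose preference clearly exceeds what gauge freedom can fabricate
from density alone.

## Synthetic populations

The generator defines the study conditions the statistics assume:

* 7 chromosomes × 2 homologs; territory volume fractions apportion 15 %
  of the nuclear volume ∝ sequence length (segmented territory cores
  occupy a minority of the nucleus), with the *a* copy 4–6 % larger.
* Nuclei are lumpy ellipsoids, default semi-axes (7.0, 5.5, 2.5) µm with
  ±8 % (CV) cell-to-cell volume variability and a smooth directional
  radius perturbation (irregularity 0.2); S-phase conditions scale the
  volume by +12.5 %, the midpoint of the ~10–15 % range such stages show.
* Per-pair contact probabilities are deliberately heterogeneous
  (baseline table spanning 0.25–0.70, chromosome-17 pairs highest), with
  condition shifts: two altered pairs in the fibroblast S phase,
  chromosome-18 gains and chromosome-12 losses in the epithelial S
  phase. Contact multiplicities 1–4 are drawn with weights
  0.55/0.30/0.10/0.05; homologous contacts have probability 0.08.
* Planted contacts are realized ~90 % as direct overlap (mean shared
  volume ≈ 15 % via a budgeted fill stage) and otherwise as abutment
  within the threshold; all non-contact pairs are kept > 0.28 µm apart
  by exclusion buffers. The interaction matrix recomputed from the
  rendered masks therefore equals the planted truth exactly, which the
  suite asserts population-wide; population contact frequencies are a
  property of the matrix-level sampler alone and are checked against the
  specification probabilities at n = 200 (±10 points).
* Placement: a force layout assigns anchor positions (partners
  attracted, others repelled, weak springs toward a size-stratified
  preferred radius — anchors are spread more widely than the rendered
  centroids end up, because border-blocked growth pulls large
  territories inward); growth is quenched-noise accretion with a
  direction-persistence term (0.3) for asymmetric shapes and a radial
  compactness term (0.5); multi-partner contacts are connected by
  A*-shortest in-mask tendrils. Packing retries redraw geometry (same
  planted truth), growing previously failing territories first, and a
  late-retry relaxation realizes crowded contacts as interpenetration.
* The random-placement null re-grows the exact per-territory volumes
  from uniform seeds with the same growth parameters, territory overlap
  permitted — interactions there arise from crowding alone.

What the generator does **not** emulate: microscope optics (no PSF,
noise, chromatic shift or deconvolution artifacts), multi-round
registration error, territory shape statistics beyond
persistence/compactness, chromatin substructure, and any correlation
between radial position and interaction propensity. Passing tests
therefore demonstrate the correctness and power of the measurement and
consensus machinery under the declared statistical structure, not the
biology of any particular cell line.

## Problem sizes in the test suite

Image-level checks run at 50 nuclei per condition (null-model
comparison, truth fidelity, overlap statistics) and 100 nuclei for the
radial-position regression on a sparse-interaction population, where
placement rather than planted contacts drives position; matrix-level
checks use 60–400 nuclei. The planted-recovery experiment follows the
benchmark: five pairs at 0.6 over a 0.1 background, 60 nuclei, 50
restarts, 20 seeded repetitions. These sizes give binomial standard
errors comfortably inside the asserted tolerances while keeping the
default suite in single-digit minutes.
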