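# Methods

`idrpipe` analyses protein families whose function depends on long
intrinsically disordered regions (IDRs): chromatin modifiers such as the
histone lysine methyltransferases are the motivating case, where most of
the sequence outside the catalytic domain is disordered and harbours short
linear motifs and induced-folding binding regions.  This note documents
the models, parameters and numerical choices, and what the synthetic
benchmark does and does not establish.

## Disorder profiling and IDR segmentation

A disorder profile assigns each residue a propensity in [0, 1].  A residue
is called disordered when its score is at least the threshold (default
0.5); the *disorder rate* of a protein is the fraction of such residues,
and IDRs are the maximal runs of them.  A protein counts as "mostly
disordered" when its rate is strictly above 0.5, and the long-IDR summary
("fraction of proteins with an IDR longer than L", default L = 80) reads
"longer" strictly: an IDR of exactly L residues does not count.

Two score sources are supported:

* **External tracks** (TSV of protein, position, score) — the intended
  route when a dedicated predictor such as IUPred has been run upstream.
* **Built-in stand-in** — the TOP-IDP-style composition scale averaged
  over a centred window (default 21) and mapped through a logistic
  (midpoint = scale mean, slope 4).  This is a transparent composition
  smoother, not a re-implementation of any energy-based predictor: it
  separates segments whose composition is clearly order- or
  disorder-promoting and is adequate for the synthetic benchmark, but it
  will not reproduce a real predictor's output on natural sequences.

`X` residues are tolerated in input but excluded from every
composition-dependent computation (scale averaging, entropy, shuffling).

## Low-complexity regions and homorepeats

LCR detection uses windowed Shannon entropy (window 12): windows at or
below a trigger entropy (2.2 bits) seed a region, which extends across
adjacent windows while entropy stays at or below 2.5 bits; the region is
the union of qualifying windows, and overlapping spans merge.  This is a
deliberate simplification of SEG's two-pass probability refinement; the
thresholds are the conventional ones translated to bits and are
config-exposed, not fitted.  Homorepeats are maximal single-residue runs
of at least 5 residues.  Overlap between region sets is summarised as the
residue-set Jaccard index plus both directional coverage fractions.

## Linear-motif enrichment and the shuffled null

Motif classes are regular expressions with functional tags (e.g. PPI).
Scanning is restricted to mostly disordered proteins, reports every match
start (overlapping occurrences included), and the summary statistic is
the density per 1000 residues of the scanned proteins.

The null model redistributes the pooled disordered residues of the
scanned proteins into synthetic constructs — by default 20 constructs of
10,000 residues, i.e. roughly 10x coverage of a ~20k-residue pool.
Because a pure permutation cannot produce more residues than the pool
holds, two modes exist: `permute` (exact shuffle; requires total length =
pool size; conserves the residue multiset exactly) and `resample`
(i.i.d. draws from the pool composition; default whenever coverage ≠ 1).

Significance is assessed three ways, all reported:

* one-sample t of the per-construct null densities against the observed
  density treated as a fixed value;
* Welch two-sample t of per-protein observed densities against
  per-construct null densities;
* the empirical rank p, (1 + #{null ≥ observed}) / (1 + #null).

The two-sample form is the recommended decision rule.  The one-sample
test treats the observed density as noiseless, which is only defensible
when the observed sample is much larger than one construct; under the
default geometry (one ~20k-residue observation vs twenty 10k constructs)
it is anticonservative, while the empirical rank p is conservative
because the observed unit is tighter than any single construct.  The
Welch form models both sampling variances and is approximately calibrated
(measured false-positive rate ≈ 2–5% at α = 0.05 in the seeded
benchmark).  When the null densities are constant (rare motifs that never
arise in shuffles) the t-based tests are undefined and the empirical p is
the fallback, with a warning.

## Conservation and constrained vs flexible disorder

Sequence conservation of an alignment column is the Jensen–Shannon
divergence (base 2) between the column's residue distribution and a
background (uniform by default), normalised by the divergence of a
single-residue column against that background: a fully conserved column
scores 1, a background-like column 0.  Columns with more than 50% gaps
score 0 (uninformative), and columns where the reference is gapped are
dropped when projecting to reference coordinates.  Scores are smoothed
with a centred moving average of window 3, so single aberrant columns do
not break up conserved runs; the price is that the first and last residue
of a conserved segment bordering divergent sequence are pulled below
threshold (regions shrink by about one residue per edge).

Disorder conservation of a column is the fraction of non-gap rows
predicted disordered there.  Reference-disordered residues are classed as
**constrained disorder** (disorder conserved AND sequence conservation ≥
0.9), **flexible disorder** (disorder conserved only; disorder-
conservation threshold 0.75), or not-conserved disorder.  The 0.9
sequence threshold matches the conventional "constrained" cut-off on a
[0, 1] conservation scale; 0.75 for disorder conservation is this
package's choice.  One JSD-based scorer serves for both the column
conservation and the constrained-region filter; a sum-of-pairs scorer
with sequence weighting could be plugged in behind the same [0, 1]
interface, but a single well-defined scorer keeps the pipeline
self-contained.

## Conserved disordered binding regions and variants

The two-step procedure: (1) candidate binding regions are maximal runs of
binding propensity ≥ 0.5 that are at least 8 residues long; (2) within
each candidate, maximal sub-runs of residues with sequence conservation ≥
0.9 are kept, and by default the 8-residue floor re-applies after
intersection (config-exposed; a whole-region mode that keeps or drops
entire candidates by mean conservation is available by flag — the
residue-level intersection is the default because it yields the tighter,
more defensible region boundaries).  Variants given on protein
coordinates map to a region by closed-interval membership; variants
mapping nowhere are listed, never dropped.

The built-in binding-propensity stand-in is the windowed fraction of
interaction-prone residues (W F Y L I V M R, window 9) multiplied by the
local disorder score and squashed through a logistic — a documented
heuristic capturing the "hydrophobic anchor inside a disordered context"
signature of induced-folding regions.  Real binding predictors (e.g.
ANCHOR output) ingest as external tracks.

## Ensemble helicity

Backbone φ/ψ angles are computed for every model of a multi-model PDB
(first φ and last ψ undefined).  A residue is helical in a frame when
both angles fall in the α basin, default φ ∈ [−90°, −30°], ψ ∈ [−77°,
−17°] — a generous box around the canonical −57°/−47°, configurable
because different secondary-structure assignments draw this boundary
differently.  Occupancy is helical frames divided by usable frames per
residue; residues with no usable frame report as missing rather than 0.
Per-frame contiguous helix runs (minimum length 4 by default) distinguish
genuine helices from isolated residues that happen to fall in the basin.

## The synthetic generator

Proteins are assembled from ordered blocks (order-promoting composition)
and disordered linkers (enriched P, E, S, Q, K; depleted W, C, F, I, Y,
V; frequencies are config data).  Planted features and their exact
coordinates are recorded as ground truth: motif instances (exact count or
Poisson-drawn from a per-1000-aa density), binding regions (≥ 8 aa, with
a conservation class), and variants at region-relative offsets.
Ortholog alignments (default 23 rows, matching typical vertebrate
ortholog sets) are derived from the reference by per-column substitution
with class-specific probabilities (invariant 0, conserved 0.03, divergent
0.5), replacements drawn from the block's composition; small indels
(deletion 0.01/residue, insertion 0.005) occur only outside planted
features so coordinate truth stays exact.  A substitution-probability
override of 1.0 produces composition-preserving column scrambling —
sequence-divergent but still disordered, the flexible-disorder regime.
Oracle score tracks are 0.9 inside planted regions and 0.1 outside, with
optional clipped Gaussian jitter (σ ≤ 0.05).

What this does *not* emulate: realistic phylogeny (star topology, no
tree), natural composition gradients, predictor noise structure, or
motif occurrence biases of real proteomes.  Passing the benchmark shows
the detectors and statistics implement their definitions correctly and
recover known features at the stated noise levels — not that the
stand-in predictors match IUPred/ANCHOR on natural sequences.

Structure ensembles are built from prescribed torsions by internal-
coordinate chain construction (standard bond lengths/angles, trans
peptide), so the realised φ/ψ round-trip to the inputs within numerical
tolerance and ensembles with an exact planted helix fraction can be
written as multi-model PDB.

## Numerical and degenerate-input choices

* Zero-variance t-test cells with differing means report p < 1e−12
  ("means differ, variance 0") instead of dividing by zero; cells with
  n < 2 are flagged untestable, never silently dropped.
* Welch (unequal variance) is the default two-sample test; pooled
  variance is available by flag.  Raw p-values are reported; Bonferroni
  within each comparison group is optional and flagged.
* Group-comparison p-values are not corrected by default (the correction
  choice is the caller's; the option is explicit).
* Region coordinates are 1-based inclusive everywhere; BED output
  (0-based half-open) is the only conversion surface.
* All randomness (generator, null ensemble) flows from explicit integer
  seeds; reruns are byte-identical, and the pipeline report is written
  with sorted keys so repeated runs diff clean.

## Benchmark problem sizes

The packaged benchmark (`scripts/acceptance.py` and the test suite) uses
families of 4–6 proteins of 600 residues (two ordered domains, two
disordered linkers), 23-row ortholog alignments, nulls of 20 × 10,000
residues, 200-replicate calibration/power runs for the enrichment test,
and 20-frame torsion ensembles.  These sizes give stable statistics
(binomial SE of the calibration rate ≈ 1.5%) while keeping a full run in
tens of seconds.

## Known limitations

* The stand-in predictors are composition heuristics; conclusions about
  natural proteins require external predictor tracks.
* The JSD conservation scorer ignores residue similarity (no
  substitution-matrix weighting) and treats columns independently apart
  from the window-3 smoothing.
* Window-3 smoothing trims roughly one residue from each edge of
  conserved segments; planted variants at region edges can therefore
  fall just outside the detected region.
* The LCR detector is a single-pass trigger/extend scheme, not SEG.
* The empirical p of the enrichment test cannot go below
  1/(n_constructs + 1); use more constructs for finer resolution.
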