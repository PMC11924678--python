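# Methods

This note documents the models behind each module, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and the
numerical choices that matter when reproducing results.

## Synthetic locus and pseudoexon annotation (`sarcophen.locus`)

The fixture emulates the *Neb* exon 54–56 neighbourhood in three alleles. The
segment layout is fixed — exon 54 (120 bp), exon 55 (105 bp, in frame),
exon 56 (90 bp), and introns sized so that the ΔExon55 allele carries a 202 bp
pseudoexon inside its residual intron and the humanized allele's intron is
380 − 58 = 322 bp shorter — so coordinates are identical for every seed and
only the sequences vary. The true cryptic splice sites and pseudoexon sequence
of the biological locus are not public; the fixture's sequences are random
subject to the verifiable constraints: canonical GT…AG intron boundaries,
stop-free exons in frame, and a pseudoexon whose translation in the frame
carried in from exon 54 contains exactly two stop codons (rejection sampling;
with ~3 stops expected in 67 random codons, a handful of draws suffices).

The reading frame entering the first modeled exon is a locus parameter
(default 0, exon 54 length a multiple of 3, so the pseudoexon is entered on a
codon boundary); the two-PTC constraint is enforced in whatever frame results.
Coordinates are 0-based half-open (BED) on the + strand; a junction's
`donor_end` is the exclusive end of the upstream segment.

`annotate_pseudoexon` classifies junction ends against annotated exon
boundaries. Exactly one cryptic acceptor and one cryptic donor, in order,
strictly inside one intron, define a pseudoexon; junction sets touching only
annotated boundaries return "no pseudoexon", and anything else (stray
coordinates, one-sided pairs) is an error rather than a guess. Translation
goes through Bio.Seq; complete codons only, stops rendered `*`.

## Inclusion estimation (`sarcophen.splice`)

Junctions with read support below 3 are discarded before estimation (boundary
kept: a count of exactly 3 survives). Inclusion support is summarized from the
two flanking junctions as their arithmetic mean (the standard two-junction PSI
numerator); `method="min"` is available as a conservative alternative. The
proportion ψ̂ = I/(I + J_skip) is invariant under uniform count scaling, so it
is computed on raw counts and per-million normalization is accepted only as
optional metadata. With no informative reads at all, estimation fails loudly
instead of returning 0/0.

The simulator draws the number of pseudoexon-bearing transcripts as
Binomial(n, ψ) and then gives each junction an independent Poisson read count
with mean `depth_per_junction` times its isoform fraction. This is the
simplest generative model with the right mean structure; it reproduces
junction-count dispersion of an idealized sequencing experiment but not
mappability or positional biases, GC effects, or shared-fragment correlations
between the two flanking junctions. Defaults (10,000 transcripts, depth
10,000) put binomial sampling error near 0.25 percentage points at ψ = 0.945,
comfortably inside the ±1-point reporting tolerance used in the recovery
checks. File I/O accepts a headered 5-column BED-like table or the 9-column
header-less splice-junction dialect of common spliced aligners (first four
columns used, sample id from the file stem).

## Thin-filament length (`sarcophen.tfl`)

Each sarcomere unit in a phalloidin line profile is modeled as

    I(x) = b + A                                   |x − c| ≤ w/2
    I(x) = b + A·exp(−(|x − c| − w/2)²/(2σ²))      otherwise

and TFL = w/2 + σ·√(2 ln 2) (the half-width at half maximum of the edge
Gaussian, read as "half the plateau plus half the edge width at half
maximum"). SL is the center-to-center distance of adjacent units; reporting is
restricted to SL ∈ [2.4, 2.8] μm (inclusive endpoints), the physiological
stretch window in which TFL is conventionally quoted.

**Initialization.** The original measurements were fit interactively; this
package automates seeding for reproducibility. Candidate units are maxima of
a Gaussian-smoothed trace (smoothing 0.08 μm) above the trace minimum plus
half the dynamic range, with a prominence floor of 10% of the dynamic range
(float-level ripples on perfectly flat plateaus otherwise split one unit into
several), peaks closer than 3 pixels merged, and each center refined to the
midpoint of the half-maximum region — on a flat-topped unit the raw argmax is
arbitrary within the plateau. Fit windows run trough to trough.

**Masked two-pass fit.** Each window is fit unmasked first; then samples with
|x − c| < `mask_fraction`·w/2 (default 0.5) are de-activated and the fit
repeated. The mask extent is not dictated by any published value; half the
plateau half-width covers a Z-disk bump substantially narrower than the
plateau while keeping most of the plateau in the fit, and it is exposed as a
parameter. Degenerate windows (< 8 active points) are rejected; optimizer
failures clear a `converged` flag and the unit is dropped from aggregation.
The baseline b is fit per unit (local background varies in real sections).

**Neighbour deflation.** At SL 2.6 μm and σ 0.15 μm, the Gaussian edge of
each unit reaches ≈ 2% of amplitude into its neighbours' windows, which biases
an independent per-window fit by a few nanometres in TFL (baseline pulled up,
plateau narrowed). `fit_profile` therefore runs one deflation pass after the
independent fits: each unit is refit on its window with the fitted amplitude
terms of all other units subtracted, reducing the cross-talk to second order.
This keeps the per-window masked fit (`fit_unit`) as the core primitive while
letting the noiseless round trip close to better than 10⁻³ μm. Remaining
overlap error after one pass is negligible at physiological spacing but grows
if units abut (sl ≲ 2·TFL).

**Generator.** Profiles are sums of unit models at spacing `sl`, plus a
central Gaussian bump per unit (relative amplitude 0.15, width 0.10 μm)
emulating actin overlap across the Z-disk, plus i.i.d. Gaussian noise.
Defaults are the study-like conditions: TFL 1.06 μm (WT; 0.96 μm for the
mutant condition), SL 2.6 μm (mid-window), σ 0.15 μm, amplitude 1000 AU over
a 100 AU baseline, pixel 0.065 μm (a 6.45 μm camera pixel behind a 100×
objective). The generator produces an idealized deconvolved 1D profile; it
does not emulate PSF asymmetry, photobleaching, sarcomere disarray or
Z-disk broadening — a real-data fit inherits none of the round-trip
guarantees, only the estimator's structure.

**Aggregation.** Units → bundle means → animal means → genotype means, with n
reported at each level, mirroring a 3-animals × 2-bundles design; two-genotype
comparisons use a Student t-test on animal means. Whether published values are
per-fiber or per-animal means is not stated anywhere authoritative; the
hierarchy here is declared, not inferred.

## Muscle mechanics (`sarcophen.mech`)

PCSA = m·cos θ/(ρ·L_fiber) with fiber length = ratio × optimal length. Muscle
density defaults to 1.056 g·cm⁻³ (standard mammalian value); pennation angle
and fiber-length ratio carry no authoritative printed values and must come
from the experiment or literature presets — the worked example uses EDL-like
θ = 12°, ratio 0.44. Stimulation grids: SOL 1–150 Hz (9 points), EDL the same
plus 200 and 250 Hz.

The force–frequency sigmoid is fit by least squares with data-driven
initialization (extremes for P₀min/P₀max, frequency nearest mid-range force
for F_half, a quarter of the frequency span for k, k > 0 bounded). Flat data
are flagged degenerate (fitted amplitude ≈ 0) rather than erroring. The
extra-sum-of-squares F-test fits one pooled sigmoid to both groups' points
versus one per group; F = [(RSS_p − RSS_s)/4]/[RSS_s/(N − 8)]. When both
models interpolate noiseless data (RSS ≈ 0/0) the statistic is defined as 0
(no evidence of a group effect). Null calibration was checked by random
splits of a shared dataset: p-values are uniform (KS test). The fatigue index
is mean(last 5)/mean(first 5) of the 74-tetanus series. Reported protocols
disagree internally on the fatigue stimulation frequency (40/60 Hz in one
place, 150/200 Hz in another); the simulator leaves it a free parameter.
Twitch kinetics (time to peak, half-relaxation) need force–time traces and
are out of scope.

## Morphometry (`sarcophen.morph`)

Minimum Feret diameter is computed exactly: the minimum caliper width of a
convex polygon is attained with one jaw flush to a hull edge, so the width is
enumerated over convex-hull edge normals (hull via scipy's qhull wrapper). A
0.1° rotation-grid caliper is retained in the tests as an independent oracle;
note the grid can only overestimate, with an error that scales with the
length of the hull edge at the optimum — agreement to 1e-3 relative holds for
compact fiber-like shapes but not for arbitrarily elongated polygons, a
property of the oracle's resolution, not of the exact computation.

The area filter discards fibers with area < 300 (boundary kept); the
threshold is unit-agnostic (measurement units², μm² in all examples) since
the printed filter carries no units. Size bins are half-open [e_i, e_{i+1})
with out-of-range fibers counted in a reported overflow so fiber number is
conserved. Type composition excludes unlabeled fibers from the denominator
and computes the final class as 100 minus the rest so percentages sum to 100
exactly.

The fiber generator produces even-sided regular polygons (6–12 sides) whose
across-flats width 2R·cos(π/n) equals a Normal(mean, sd) draw (truncated at
20% of the mean), randomly rotated and translated with ±0.5% radial jitter —
small enough that the realized minimum Feret stays within ~2% of the target.
Real fiber sections are neither convex-regular nor independent of their
neighbours; the generator validates the geometry pipeline, not segmentation.

## Statistics and orchestration (`sarcophen.stats`, `sarcophen.pipeline`)

The two-group test defaults to the classical pooled-variance Student t-test
(Welch by flag); one-way ANOVA requires ≥ 3 groups. All-zero-variance inputs
are flagged degenerate instead of propagating NaNs. Median survival is the
earliest time the Kaplan–Meier curve drops to 0.5 (lifelines product-limit
estimator); a curve that never reaches 0.5 yields an explicitly undefined
median. The pipeline derives each stage's RNG seed from the manifest seed via
fixed offsets, isolates per-stage failures, and writes a sorted-key
`summary.json`, so equal manifests produce byte-identical summaries. Pooling
WT and HET animals into one control group is a manifest choice, not a
default.

## Problem sizes in tests and examples

The test suite and analysis drivers run on deliberately small but
statistically adequate sizes chosen so every check is sharp: 200-replicate
Monte-Carlo sweeps for estimator consistency (3-SE criterion), 50 seeds for
the masking-bias comparison, 100 polygons for the Feret oracle, 200 random
splits for F-test null uniformity, and 1000 replicates for t-test/ANOVA
type-I calibration. The headline-reproduction script uses 10 profiles per
genotype and sequencing-scale junction depths (10,000 reads/junction).

## Known limitations

- The locus fixture is synthetic; only its printed-fact constraints (lengths,
  PTC count, splice dinucleotides) are meaningful, not its sequence.
- Unit fits assume symmetric edges and a locally constant baseline; strongly
  overlapping or disordered sarcomeres violate the window model.
- The junction simulator ignores read-level artefacts (mapping bias,
  duplicated fragments).
- The F-test treats points within a curve as independent; repeated-measures
  structure within a muscle is not modeled.
- Fiber polygons are assumed simple and sensibly scaled; the area filter's
  "300" is meaningful only in the units the polygons are measured in.
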