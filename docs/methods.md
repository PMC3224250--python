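# Methods

`coldcore` compares psychrophilic (cold-adapted) enzymes with mesophilic
homologs along three structural axes: backbone flexibility read from
crystallographic B-factors, interior void architecture probed at a range of
solvent radii, and buried crystallographic waters.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not show.

## Flexibility from Cα B-factors

Raw B-values (Å²) mix intrinsic atomic motion with lattice disorder and
refinement conventions, so profiles are cleaned and normalized per chain
before any cross-structure comparison:

1. **Outlier filter.** The modified z-score
   `M_i = 0.6745 |X_i − median(X)| / MAD` flags positions with `M_i > 3.5`
   (MAD = median absolute deviation from the median).  A profile with
   MAD = 0 is degenerate — the statistic is undefined — so nothing is
   flagged and the profile is marked; real Cα profiles essentially never
   have MAD = 0.
2. **Normalization.** The default ("printed") form divides by the mean of
   squared non-outlier values: `B′_i = B_i / ⟨B²⟩`.  This form is *not*
   invariant to a global rescaling of B (doubling B halves B′); it is kept
   as the default because it is the exact published form of the procedure
   this package operationalizes, and because all downstream statements are
   about *differences between paired, similarly-scaled profiles*, not about
   absolute B′.  A conventional z-score mode
   (`normalize_b(..., mode="zscore")`) is available.
3. **Pairing.** `ΔB′_i = B′_i(psy) − B′_i(mes)` at every aligned,
   non-gap position that is a non-outlier in both members.  Positive ΔB′
   means the psychrophilic residue is more flexible.  ΔB′ is attributed to
   the **psychrophile's** DSSP class (the mismatch rate between the two
   members' class strings is reported separately via `ss_mismatch_rate`).

Per-class distributions use the eight-state DSSP alphabet (G and I are
never merged into H; "5-turn" means the π-helix class I).  Class means are
tested against zero with a two-sided one-sample t-test; boxplot summaries
use the 1.5·IQR whisker convention.  Classes with fewer than 3 positions
report no test.  Note one structural consequence of the printed
normalization: raising B in one class inflates ⟨B²⟩ and drags the other
classes' ΔB′ slightly negative, so "strand more flexible" and "helix less
flexible" are not separable — only relative statements are meaningful.

## Homolog pairs

Pairs are accepted when both members have ≥ 150 residues, resolution
≤ 2.5 Å (inclusive: reference cohorts contain members at exactly 2.5 Å),
sequence identity ≥ 30%, and thermal classes (psychrophile, mesophile)
from organism growth temperature: [0, 20) / [20, 45) / [45, 100] °C for
psychro-/meso-/thermophiles, with 20 °C belonging to the mesophiles.

Alignment is global Needleman–Wunsch (BLOSUM62, gap open −11, extend −1,
Biopython's `PairwiseAligner`); identity counts identical columns over
aligned non-double-gap columns.  Sequence alignment here stands in for
structure-superposition alignment; for closely related pairs the two
rarely disagree, but the per-position attribution of ΔB′ can differ near
gaps, so externally computed alignments can be supplied as aligned FASTA
and are then used verbatim.

## Voids: cavities and pockets on a grid

A probe of radius p can center itself anywhere farther than
(vdW + p) from every atom center.  On a regular grid (default spacing
0.5 Å; the spacing must not exceed the probe radius):

* accessible cells are grouped by 6-connectivity; components touching the
  bounding box form **bulk solvent**;
* interior components unreachable from bulk are **cavities** (zero exits);
* **pockets** are bulk-connected regions that become enclosed when the
  blocked mask is morphologically closed with a ball of fixed *envelope
  radius* (default 4.0 Å, implemented exactly via two Euclidean distance
  transforms).  The mouth count is the number of connected interface
  patches between pocket cells and the remaining open bulk.

Void volume is cell count × spacing³ — the space available to the *probe
center* ("accessible-surface" volume).  Voids under 1 Å³ are discarded as
discretization dimples.  Default vdW radii are Bondi (1964); radii already
present on atoms are preserved, so generators can plant exact geometry.
Waters and non-water heteroatoms are always excluded from void detection.

Two deliberate definitional choices:

* The envelope radius is **fixed** rather than tied to the probe.  A
  probe-sized closure seals a mouth of aperture A only when p > A/2, so the
  same depression would flip between "open bulk" and "pocket" across a
  probe sweep and total void volume would not be monotone in probe radius.
  With a fixed envelope the molecular boundary is probe-independent and
  the sweep is monotone.  The flip side: depressions with mouths wider
  than ~2× the envelope radius are never pockets, and very wide shallow
  bowls are classified as bulk.
* Per-structure aggregates follow the Cav / Vol / Vol–per–Cav convention:
  cavity count, total cavity volume, and their ratio, at each probe
  radius.  Nothing is normalized by molecular weight.  Cohort averages are
  per-structure-then-cohort.

Grid detection trades the sub-grid precision of alpha-shape/discrete-flow
tools for exact testability: the detector is validated against cages of
analytically known interior volume (error ≈ 1% at 0.5 Å spacing, see
`scripts/acceptance.py`) rather than against another program's output.
Rigid motions change measured volumes by < 2% at 0.5 Å spacing.

### Cavity wall chemistry

Residues line a void when any atom's probe-expanded sphere comes within
one grid diagonal of a void cell center.  Only residues whose lining
contact involves a **side-chain** atom count toward wall chemistry
(backbone chemistry is universal); Gly's CA serves as its side-chain
surrogate.  Classes: hydrophobic (Ala, Cys, Ile, Met, Pro, Val, Leu, Phe,
Trp), polar (Asn, Gln, Gly, Ser, Thr), basic (Arg, His, Lys), acidic
(Glu, Asp).  Tyr, absent from this four-class scheme, is filed under
polar and counted separately in every profile (`n_tyr`); unknown residue
names land in an "other" bucket and are logged, never silently classified.

## Buried waters

Waters are modeled as single spheres (radius 1.4 Å; probe 1.4 Å; both
configurable).  SASA is Shrake–Rupley with a Fibonacci (golden-spiral)
point lattice, 960 points per atom by default; the isolated-sphere error
is ≈ 0.1%, and 92 points is the accepted floor.  Burial is computed by
iterative peeling: compute the SASA of every retained water in the context
of polymer + retained waters, remove **all** waters with area above the
exposure tolerance (0.01 Å², absorbing quadrature noise; the final count
is stable across tolerances 1e-6…1e-2) in the same pass, repeat to a fixed
point.  The loop removes at least one water per pass, so it terminates in
at most n_waters passes; the final set has zero accessible area by
construction, and the result is invariant to water record order.  Note
that exposure is *local* (sphere-point coverage), not flood-fill
reachability: a lone water in a large empty chamber counts as exposed.
For multi-chain entries burial can be run per chain and averaged, or on
the whole deposited polymer (default).

## Cohort statistics

All comparisons are paired (members of a pair share ancestry and
environment): a classical two-sided paired t-test on per-pair differences
(df = n−1; zero-variance differences are reported as degenerate, not as a
p-value), backed by an exact sign/binomial test with both one- and
two-sided p-values reported (one-sided in the direction "psychrophile
greater").  Buried-water counts are additionally correlated across members
(Pearson R²).  Significance defaults to α = 0.01 with **no**
multiple-testing correction across probe radii or metrics; a Bonferroni
option exists and is off by default.  This mirrors the reporting
convention of the comparative literature this package operationalizes;
with ~7 probes × ~7 metrics the expected number of false flags per null
cohort is ≈ 0.5, which the type-I calibration experiment quantifies.

## Synthetic validation cohort

The generator plants known truths; it makes no attempt at physically
realistic protein geometry, rotamers, or energetics.  Components per
member:

* a **sealed cage** — Fibonacci-lattice shell (≈0.8 Å² per atom, jitter
  σ = 0.05 Å, seal-checked) whose probe-accessible interior is a ball of
  exactly known volume;
* a **bottleneck cage** with a ring-rimmed mouth of aperture 1.3 Å: a
  pocket for probes below the aperture, a cavity for water-sized probes
  and above.  This is the mechanism that confines the planted
  average-cavity-size effect to water-sized probes, the same
  count-vs-volume interplay the real comparison turns on;
* snug sub-probe **water cages** (shell-center radius 2.25 Å), each
  sealing exactly one zero-SASA water while presenting no probe-accessible
  interior at any probe in the 0.6–1.8 Å sweep — planted buried-water
  counts are therefore exact and do not perturb cavity statistics;
* a dense Cα lattice block (2.6 Å pitch, void-free at all sweep probes)
  carrying the planted B-profiles and the shared 200-residue sequence;
* surface waters on the outside of the main cage (removed in the first
  peeling pass).

Planted cohort conditions (defaults): 20 pairs; mesophile-scale average
cavity volume 30 Å³; +4 Å³ average-cavity-size effect at the 1.4 Å probe
with pair-difference σ = 3 Å³; wall acidic share +0.15 (taken from the
hydrophobic share, base composition 0.45/0.30/0.12/0.13); +3 buried
waters over a shared per-pair Poisson(6) base with σ ≈ 1 member noise
(design expectation: within-pair count correlation R² ≈ 0.7, the scale
seen in real paired crystal structures; individual 20-pair cohorts
scatter widely around it); B-profiles at baseline 20 Å², noise
σ = 2 Å², 2% planted outliers (×5 median, guaranteed above the M > 3.5
cutoff), and a +4 Å² shift on strand (E) and π-helix (I) classes in the
psychrophile.  The shift size was set by a design power computation: after
the printed normalization couples classes and adds pair-level scale noise,
+4 Å² leaves ≥ 99% detection power for both classes at 20 pairs; smaller
shifts starve the rarer π-helix class.  The secondary-structure strings
over-represent π-helix relative to real DSSP output for the same reason.

What passing synthetic tests shows — and does not.  They show the
detector recovers analytic volumes, classifies mouth topology correctly,
counts planted buried waters exactly, and that the full pipeline detects
all four planted effects at p < 0.01 in ≥ 90% of cohort replicates while
holding the type-I rate at α on null cohorts.  They do **not** show
anything about real protein surfaces: synthetic shells are idealized
spheres, wall composition is painted onto pseudo-atoms rather than built
from rotamers, and the layout places components far apart.  One visible
artifact: *pocket*-level metrics of the synthetic cohort (total pocket
volume, pocket counts) are dominated by grooves between adjacent planted
components and are therefore not planted quantities — only cavity
metrics, wall classes, ΔB′, and buried-water counts carry ground truth.

## Problem sizes and interfaces

Validation experiments run at desk scale by choice: 20-pair cohorts,
100 cohort replicates for recovery rates, 2000 replicates for t-test
calibration, 0.5 Å grids (0.25 Å for the convergence check), and a
single water-sized probe for the recovery sweep (the planted cavity
effect is defined at 1.4 Å; the full 0.6–1.8 Å sweep is exercised by the
analysis drivers and the monotonicity experiment).  The numbered scripts
under `analysis/` are the user-facing drivers; every computation they
perform lives in the importable package, and a cohort of real structures
runs through the same path via a manifest CSV pointing at PDB/mmCIF
files, DSSP outputs, and optional aligned-FASTA alignments.

## Known limitations

* Grid voids have no sub-grid precision; volumes carry ~1–2% bias at
  0.5 Å spacing, and mouth counts depend on the grid at pocket rims.
* The fixed-envelope pocket definition ignores depressions with mouths
  wider than ~8 Å.
* Local (Shrake–Rupley) exposure, not solvent reachability, defines water
  burial; a water in a sealed but roomy chamber is "exposed" by this
  definition and will be peeled.
* Sequence alignment stands in for structural alignment in ΔB′
  attribution.
* The printed B-normalization is scale-sensitive by design; use the
  z-score mode when comparing across profiles with very different mean B.
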