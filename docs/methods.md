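# Methods

## The problem

Electron density maps distributed for x-ray crystallographic structures
(2Fo-Fc "model" maps and Fo-Fc "difference" maps) are sigma-scaled: voxel
values are expressed in multiples of the map's own standard deviation, with
an arbitrary absolute scale and, because the F000 structure-factor term is
omitted, an effectively zero mean.  Density values from different entries
are therefore not comparable, and a density discrepancy cannot be read as
"this blob is worth N electrons".  This package derives, from nothing but
the coordinate model and its 2Fo-Fc map, a per-structure conversion factor
between arbitrary density units and electrons, and uses it to quantify
Fo-Fc discrepancies in absolute electron units.

## The density ratio chain

Every heavy atom of the 20 standard amino acids is assigned one of 13 atom
types (element x bonding character; `_bb` marks backbone atoms) and an
electron count Z_i that folds in its bonded hydrogens, since hydrogens are
not resolvable at typical resolutions.  For atom i, the significant map
voxels (value > 1.5 sigma of all voxels) whose centers lie within the
type's radius form its density cloud, with voxel count V_i and density sum
Σρ.  The chain of per-atom statistics is:

    r_i          = Σρ / (Z_i · q_i)                 density ratio (q_i = occupancy)
    r_norm,i     = r_i · median(V_t) / V_i           voxel-count smoothing
    f_i          = (r_norm,i − median(r_c)) / median(r_c)
    f_corr,i     = f_i + (log b_i − median(log b_t)) · s_t
    r_corr,i     = f_corr,i · median(r_c) + median(r_c)

where median(V_t), median(log b_t) and the slope s_t are statistics of the
same structure's type-t atoms, b_i is the isotropic B-factor and the
logarithm is natural.  s_t is the ordinary-least-squares slope of f against
log(b) per type; types with fewer than three atoms (or no B-factor spread)
take a shipped default slope.  Atom clouds aggregate into residue clouds
(≥ 4 contributing atoms) and chain clouds (≥ 50 atoms) as voxel-set unions
— shared voxels counted once — whose ratios r_r, r_c divide the union
density sum by the summed occupancy-weighted electron counts.  The median
chain ratio median(r_c) is the structure's conversion factor: dividing any
density sum by it yields electrons.

Design choices where the procedure was genuinely open:

* The Eq-1 sum is restricted to significant (> 1.5 sigma) voxels; the
  unthresholded reading is available via `AnalysisConfig.threshold_atom_sums`.
* Occupancy enters as effective electrons Z_i·q_i (equivalent, for ratios,
  to dividing the sum by occupancy; keeps Σρ raw and auditable).
* Alternate locations keep the highest-occupancy conformer (ties resolved
  toward altloc 'A'); zero-occupancy atoms are excluded from ratio
  statistics (the occupancy adjustment is undefined at 0) but retained for
  F000.
* Protonation is the conventional pH-7 state: Lys/Arg protonated, Asp/Glu
  carboxylates deprotonated, His neutral with the ring proton on ND1;
  proline's backbone N is typed like every other backbone N but carries no
  amide hydrogen.  OXT is typed as a carboxylate oxygen.
* Medians use the even-count mean-of-middle-pair convention throughout.
* All medians (V_t, log b_t, r_c) are per structure, never global.

## Difference-map discrepancies in electrons

Fo-Fc voxels beyond 3 sigma (about zero, not about the map mean — deposited
maps are effectively zero-meaned) are partitioned into maximal connected
blobs under 26-neighbor connectivity (6-neighbor available in config).
A blob's electron content is |Σρ| divided by the conversion factor; each
blob is annotated with its nearest model or symmetry-mate atom within 5 Å.
Crystallographic symmetry mates come from the map header's operator records
when present, else from the CRYST1 Hermann–Mauguin symbol, expanded over
the 27 neighbor-cell translations and kept within a 5 Å buffer of the map's
bounding box (the buffer exceeds twice the largest atom radius, so every
voxel near the map has its contributing atoms present).

The F000 estimate sums occupancy-weighted electron counts over the
asymmetric unit — hydrogen-folded counts for standard-residue atoms and
waters, element-only counts for other hetero atoms, whose hydrogens are
unknowable without chemistry perception — multiplied by the space-group
operator count and divided by the cell volume.  It is reported (and can be
added to a map copy) but deliberately does not feed the conversion factor:
without a bulk-solvent model the F000/V offset underestimates the true
absolute offset, whereas the chain median is self-calibrating.

## Radius optimization

The per-type radii are free parameters.  They are optimized so that the
pooled median corrected chain deviation fraction of every type vanishes:
one type per iteration (the one with the largest |median|, ties broken by
type-name order), scanning candidate radii within ±0.3 Å of the incumbent
on a 0.01 Å grid clamped to (0.3, 1.5) Å, adopting the candidate with
|median| closest to zero, then refitting the per-structure slope tables and
the default-slope table (median of per-structure slopes).  Convergence is
max_t |median f_corr| < 0.05.  A type whose best candidate improves its
median by less than 1e-4 is frozen for one round (anti-cycling); an
iteration cap (default 100) guarantees termination with a non-converged
flag.  During a candidate scan the slopes stay frozen at their last-adopted
values; they are refit only after adoption.  Medians are pooled over atoms
across the sample (a median-of-structure-medians variant is a config
switch away in `evaluate_radii` callers).

The package ships two radius tables: the literature covalent-radius
starting set and the archive-optimized set (used by default for real
entries), plus a `SlopeTable` of default B-factor slopes.

## The synthetic forward model

The fixture generator renders every heavy atom as an isotropic Gaussian

    rho(r) = q Z (4π/B')^{3/2} exp(−4π² r² / B'),   B' = b + B_grid

which integrates exactly to qZ electrons, scaled by an arbitrary factor k
and zero-meaned — the same construction crystallographic software uses for
B-factor-smeared point atoms, and the regime in which every quantity the
package estimates has a direct-integration oracle.  Structures are
extended-chain toy proteins (idealized bond lengths, side chains fanned
away from the backbone; geometry realism is irrelevant to the density math)
over a default two-chain, 21-residue sequence that covers all 13 atom
types; the sparse classes (Asn/Gln carbonyls, Cys/Met sulfurs, Lys NZ)
appear 6-8 times per structure so each type supports its own slope fit and
a median statistic whose sampling noise sits well inside the 0.05
consistency band once pooled over a sample.  Defaults:
0.5 Å grid spacing, log-normal B-factors (median 20 Å², sigma of log B
0.3), grid-softening B_grid = 10 Å² (so even sharp atoms span several
voxels at 0.5 Å spacing), full occupancy, P 1 cells with a 6 Å margin.
Difference maps add independent per-voxel Gaussian noise (0.02 e/Å³ before
scaling) and injected Gaussian blobs of known signed electron content.

Multi-entry samples (`sample_specs` / `make_sample`) vary grid spacing
(0.38–0.50 Å), B-factor level (median 15–25 Å²) and map scale (0.5–2,
log-uniform) across entries, emulating archive heterogeneity.  This matters
for radius optimization: V_i is an integer voxel count, so on a single
shared grid median(V_t) is quantized in steps of several percent and the
pooled median deviation fraction cannot be tuned below that granularity;
heterogeneous grids smooth the pooled statistic the same way a sample of
real entries does.

### The generator's "true" radii

In this forward model the rendered map depends only on B-factors, never on
radii; the meaningful ground truth for radius recovery is the
*self-consistent* radius set — the fixed point at which every type's median
corrected chain deviation fraction vanishes under the default generator
conditions.  That set was computed once by running the package's own
optimizer on a fixed-seed 60-entry heterogeneous calibration sample
(tolerance 0.015) and frozen as `SYNTHETIC_TRUE_RADII`; the shipped
default slopes were frozen from the same run.  On five independent
60-entry held-out samples the per-type median corrected chain deviation
fractions at these radii all stay below 0.05 in magnitude (0.037-0.045 at
worst); a single entry's per-type medians scatter more, being order
statistics of 6-86 atoms on one quantized grid.  Recovery experiments then perturb the radii and verify
the optimizer re-finds this fixed point.  These values are synthetic
calibration products, not literature radii.

### What the synthetic world does and does not show

Because atoms are untruncated Gaussians, an atom's sphere captures only a
fraction of its electrons (its neighbors' spheres capture part of the
rest), so the conversion factor measures *in-radius* density per electron.
Blob electron estimates therefore carry the ratio between the blob's
above-threshold fraction and the chains' capture fraction; the acceptance
oracle computes both terms by direct integration of the ground truth and
compares the pipeline's estimate against that expectation.  Passing these
tests demonstrates the pipeline measures exactly what the forward model
says it should; it does not demonstrate absolute-electron accuracy on real
maps, where resolution truncation, bulk solvent, and map-calculation
details shape the density (those effects are out of scope here, as is any
reprocessing of structure factors).

## Numerical choices

* Map statistics use the population standard deviation over all stored
  voxels, computed in float64 from the data block; the header's RMS field
  is ignored (unreliable across producers).
* Density sums accumulate in float64 even for float32 grids, which makes
  deviation fractions invariant to 1e-9 under exact global rescaling.
* Voxel centers sit at fractional (start + index + 0.5)/intervals; the
  voxel center is always the reference point for distances.  Periodic
  wrapping applies only along axes whose stored extent covers a full cell;
  otherwise out-of-extent voxels are skipped and the cloud flagged partial
  (partial and empty clouds are excluded from all medians and fits).
* CCP4 axis permutations are normalized to crystallographic x/y/z at read
  time; only mode 2 (32-bit float) is supported; endianness is detected
  from the machine stamp with a little-endian fallback.
* Duplicate symmetry images are suppressed at 1e-3 Å (special positions).

## Problem sizes

Test and acceptance runs use two-chain 21-residue entries (346 heavy
atoms, ~0.3-0.5M voxel maps), 60-entry held-out samples for the
self-consistency check and 20-entry samples for radius recovery; these
sizes give pooled per-type atom counts of 360-5160 and keep a full
optimization run in the minutes range while exercising every code path at
the same statistical floors (4-atom residues, 50-atom chains) used on real
entries.

## Known limitations

* Only the 20 standard amino acids are typed; ligands, nucleic acids and
  ions enter F000 with element-only counts but never the ratio statistics.
* Radii are resolution-independent; the B-factor correction absorbs part
  of, but not all, resolution dependence.
* No bulk-solvent model; F000/V is an underestimate of the absolute offset.
* Blob connectivity is not periodic across map boundaries.
* The synthetic generator does not simulate Fourier-space effects
  (series truncation ripples, resolution cutoffs, solvent flattening).
* The radius optimization has a soft mode: scaling all radii together
  moves atom and chain ratios nearly in lockstep, so the pooled medians
  change only ~0.7 per Å along that direction versus ~3 per Å for a
  single-type change.  Stopping at the 0.05 criterion therefore pins the
  relative radii tightly but can leave a few hundredths of an Ångström of
  common-scale drift after a strong perturbation.
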