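# Methods

This note records the conventions, models and numerical choices behind
nucdyn's analyses and its synthetic trajectory generator, and what the
synthetic validation does and does not establish about real data.

## Coordinate system and topology

Base pairs are numbered from the dyad: core −73…+73 (147 bp), linkers to
±93 (187 bp total); a 1-based sequential mapping (1…187) is provided for
file I/O.  The superhelical location of bp *i* is SHL = *i*/10.3, using the
canonical ~10.3 bp/turn nucleosomal twist; integer SHL *n* corresponds to
the bp window round(10.3 *n*) ± 2.  Core DNA is split into *inner*
(|*i*| < 37) and *outer* (37 ≤ |*i*| ≤ 73) regions with *linker* beyond;
the 37-bp boundary (~SHL ±3.5) is configurable, and explicit bp windows are
always accepted independently of region labels, because published analyses
mix both conventions (e.g. a ±41…±75 window spans outer core and linker).

Histone chains carry tail ranges (H2A: N 1–16, C 121–130; H2A.Z: N 1–18,
C 123–128; overridable for tail-swap constructs) and approximate
histone-fold annotations (α1, L1, α2, L2, α3, αC, plus αN for H3).  The
annotations drive selections; they are bookkeeping, not structure
prediction.

## Superposition and trimming

Frames are rigid-body fitted (Kabsch SVD) to the reference structure on the
Cα (bead) atoms of the annotated helices of all chains; L1/L2 loops are
excluded from the fit selection by default, since including floppy loops
degrades the fit of the stiff core (both choices are available).  The fit
is idempotent to 1e−6 Å and is cross-checked in the tests against an
independent rotation-alignment oracle.  Equilibration trimming removes
frames before a cut time (200 ns default at 100 ps sampling); the untrimmed
ensemble remains reachable for all-time evolution plots.  File times, when
present and inconsistent with the stated sampling interval, win with a
warning.  Frames are assumed whole; no periodic re-imaging or minimum-image
distances are applied anywhere.

## Unwrapping

A bp is displaced when its center (C1′–C1′ midpoint in all-atom systems,
the bead itself in pseudo-atom systems) deviates more than 7 Å from its own
reference position after superposition.  Each side's unwrapped count is the
longest contiguous displaced run starting at the outermost core bp
(−73 inward, +73 inward); interior excursions and linker bp never count.
The end-anchored rule encodes unwrapping as end peeling and makes the count
monotone in the threshold.  The per-bp-reference definition is implemented
literally; a distance-to-histone-surface variant is deliberately not
offered.

## Free energies

ΔG(i) = −RT ln(f_i/f_max) with R = 1.987204e−3 kcal mol⁻¹ K⁻¹, T = 310 K
default, anchored to exactly 0 at the modal state.  Unvisited states are
undefined (NaN), not +∞ — the relation has no value at f = 0 — and are
rendered as missing in outputs.  No histogram smoothing or reweighting is
applied.  Cross-run errors follow the runs × sides convention: profiles are
computed per run and DNA side, then averaged per i over the profiles
defined there, with SE = sd/√n.  The 2D surface over (DNA Rg, DNA–histone
contacts) uses 60 × 40 bins by default (the bin counts are exposed; no
canonical values exist).  Marginalizing the 2D occupancy and re-inverting
reproduces the 1D profile exactly, which the tests assert as an identity.

## Contacts and distances

A contact is a heavy-atom pair at distance strictly < 4.5 Å.  The strict
inequality is deliberate and documented because many tools use ≤; the
KD-tree implementation shrinks the query radius by one ulp so it equals the
all-pairs definition bit-for-bit.  Selections must be disjoint; hydrogens
are filtered with a warning.  Tail–DNA distances default to the minimum
heavy-atom pair distance against the bp ±41…±75 window on the tail copy's
proximal side (copy 1 ↔ entry side by package convention); a centroid
variant exists as an option.  Correlations are computed on raw series —
Savitzky–Golay smoothing (10 ns window, degree 1, i.e. 101 points at 100 ps
sampling; edges handled by symmetrically shrinking the window) is for
presentation only.

## RMSF

Per-atom fluctuation about the *time-averaged* position (not frame 1),
computed on a superposed ensemble; tails are excluded by default so the
measure reflects the globular core.  Copies × runs aggregate as mean ± SE
per residue position.  Whole-octamer superposition is the default;
per-chain superposition is available.

## Sequence analytics

The packaged human H2A type 1 and H2A.Z.1 sequences were curated offline
from reference knowledge; the H2A.Z.1 entry may differ from the database
record by one residue near the αN/L region (its FASTA header says so), so
all C-tail presets are anchored at the C-terminus as suffix lengths.  Both
published numbering conventions for the C-tails are kept as presets
("methods": H2A 11 / H2A.Z 7 residues; "figures": 10 / 6) with neither
preferred.  Percent identity uses one optimal global alignment with
BLOSUM62, gap open −10 / extend −0.5 (needle-style), identity =
matches/columns; a unit-score scheme (match +1, mismatch 0) is available
but effectively forbids gaps at these penalties and therefore undercounts
identity for diverged homologs.  Formal charges count K/R as +1, D/E as −1,
His as 0 at pH 7 — His protonation would otherwise shift tail charges by
whole units — and termini are ignored.

## The synthetic generator

One bead per bp on a left-handed superhelix (radius 41.9 Å, pitch 25.9 Å,
1.65 turns over 147 bp — generator geometry choices, not fitted values),
straight tangential 20-bp linkers, Cα-like beads for each annotated
histone-fold element on an inner cylinder, and tail bead strings.  Motions:

* **Zipper unwrapping.**  Each side's count i performs one single-bp
  Metropolis move per frame on E(i) = i·ε (reflecting at 0 and a 25-bp
  cap), giving the exact truncated-geometric stationary law
  P(i) ∝ exp(−iε/RT) that the free-energy recovery tests enumerate in
  closed form.  Released bp are displaced 12.5 Å along the outward radial
  direction (linkers ride along): a radial peel rather than a tangential
  straightening, because straightening moves the first released bp by less
  than the detection threshold, while the fixed radial offset guarantees
  every released bp sits > 10 Å from reference against the 7 Å threshold.
  Time is abstract frames; no kinetic realism is intended.
* **Gaping.**  The SHL 3…7 half-turns displace symmetrically by ±δ/2 along
  the superhelix axis (dyad fixed).  δ follows a stationary AR(1) process
  (relaxation 20 frames, sd 1.2 Å) whose mean is solved from the requested
  `gaping_mean` (default 27 Å) via the reference in-plane and axial window
  separations, so the histogram mode of the measured SHL ±4 distance lands
  on the requested value.  Requested means at or below the in-plane
  separation (~19 Å for the default geometry) are rejected as unreachable.
* **Core plasticity.**  Each element receives an isotropic Gaussian
  rigid-body offset per frame; helix σ 0.45 Å, loop σ 0.9 Å by default, so
  loop RMSF is twice helix RMSF — the ordering recovery test.
* **Tail binding.**  H2A-family C-tails bind (beads 3 Å off their outer-DNA
  target beads, following those beads through gaping/unwrapping so the
  bound contact count is an exact constant) or protrude into solvent, with
  bind probability 0.9 − 0.15·i clipped to [0.05, 0.95] on the same side's
  unwrapped count — the programmed anti-correlation.  N-tails couple to the
  gaping offset the same way.  Other tails are static.
* **Noise.**  Isotropic Gaussian noise (default σ 0.5 Å) is added after
  ground truth is recorded, so labels are exact at σ = 0.

Default run lengths used in validation: 10,000 frames for label recovery,
50,000 zipper frames (count-level, the same Markov kernel without
coordinates) for slope recovery, 8,000 frames for the gaping mode —
sizes at which the stochastic tolerances (slope ±10 %, mode ±0.5 Å,
noisy-label agreement ≥ 99 %) are comfortably resolved on one CPU.

**What passing does not show.**  The generator has no force field, no
solvent, no sequence-dependent DNA mechanics, no real tail conformational
ensembles, and abstract time; recovering its ground truth validates the
*estimators* (their definitions, bookkeeping and statistics), not any claim
about real nucleosome thermodynamics.  Real-trajectory results additionally
depend on sampling convergence and force-field quality, which the package
does not assess.

## Degenerate inputs and tie-breaks

Superposition requires ≥ 3 selection atoms; trimming past the last frame,
empty selections, zero-variance correlation inputs, overlapping contact
selections and out-of-span bp indices all raise errors rather than
returning sentinel values.  Histogram modes are reported as the center of
the first maximal bin (0.5 Å bins for gaping).  The slope fit over a
free-energy profile uses states with ≥ 20 samples to keep the
high-i noise out of the regression.

## Known limitations

No PBC handling; no helical-parameter or groove geometry analysis; no
umbrella sampling/WHAM or end-point binding energies; RMSF has no PCA or
B-factor conversion; the 2D projection plane is fixed from the reference
(excursions read outward) rather than refit per frame.  The report pipeline
treats multi-run input as runs of the same system and does not manage
replica metadata beyond run ids.
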