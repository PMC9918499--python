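# nucdyn

Analysis toolkit for nucleosome molecular-dynamics ensembles, built to
quantify how the histone variant **H2A.Z** changes nucleosome behaviour
relative to canonical H2A: DNA end **unwrapping** and its free-energy cost,
gyre **gaping**, histone-core **plasticity**, and **tail–DNA interactions**
— together with a synthetic pseudo-atom trajectory generator that makes
every stage of the pipeline testable against exact ground truth.

It is a library first (see `examples/`), with a thin `nucdyn` command-line
layer for the common file-based workflows.

## Who it is for

Researchers analysing nucleosome MD trajectories (all-atom or
coarse-grained) who need the standard observables of nucleosome dynamics
computed with explicit, documented conventions; and method developers who
want a controllable synthetic nucleosome system with known answers.

## The model and the observables

The nucleosome wraps 147 bp of DNA in ~1.65 left-handed superhelical turns
around the histone octamer; base pairs are indexed from the dyad (bp 0,
core −73…+73, two 20-bp linkers to ±93).  The superhelical location (SHL)
of bp *i* is *i*/10.3 turns.

* **Unwrapping** — after a least-squares fit of the histone-core Cα atoms to
  the reference structure, bp *i* counts as unwrapped when its center (C1′–C1′
  midpoint) lies more than 7 Å from its reference position; each side's
  count is the contiguous displaced run starting at the outermost core bp.
* **Free energy** — Boltzmann inversion of the occupancy of *i* unwrapped bp,

  ΔG(*i*) = −RT ln(*f<sub>i</sub>* / *f*<sub>max</sub>),  *f<sub>i</sub>* = *N<sub>i</sub>*/*N*<sub>total</sub>,

  with R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹ and T = 310 K by default; a 2D
  surface over (DNA radius of gyration, DNA–histone contact count) uses the
  same inversion.  For a zipper process with per-bp cost ε the profile is
  linear with slope ε.
* **Contacts** — pairs of non-hydrogen atoms closer than 4.5 Å (strictly
  less-than), KD-tree accelerated but exactly equal to the all-pairs count.
* **Gaping** — distance between the centroids of the SHL −4 and SHL +4 bp
  windows (±2 bp), the gyre-separation coordinate.
* **RMSF** — per-atom fluctuation about the time-averaged position after
  core superposition, aggregated as mean ± SE over chain copies × runs.
* **Sequences** — percent identity (global alignment), formal tail charges
  (K/R = +1, D/E = −1, His neutral), and C-tail swap constructs for the
  packaged human H2A / H2A.Z.1 sequences.

The synthetic generator produces one bead per bp on the superhelix plus
histone-core and tail beads, and evolves zipper-model unwrapping (Metropolis
moves on E(i) = i·ε, so the stationary law is geometric), mean-reverting
gaping, per-element core fluctuation, and tail binding anti-coupled to
unwrapping — recording exact per-frame ground truth before measurement
noise is added.

## Worked example

Recover the per-bp unwrapping cost from a 50,000-frame zipper simulation
(`examples/02_free_energy_profile.py`):

```text
  i   dG (kcal/mol)   frames
  0          0.000    56210
  1          0.509    24592
  2          1.010    10901
  3          1.513     4818
  4          2.058     1992
  5          2.589      840
  6          3.134      347
  7          3.596      164
fitted slope: 0.515 kcal/mol/bp  (generator epsilon = 0.5)
```

ΔG rises by ~0.5 kcal/mol per unwrapped bp: the Boltzmann inversion reads
the generator's per-bp detachment cost back off the occupancy histogram.
Gaping and tail coupling (`examples/03_gaping_and_tail_contacts.py`):

```text
gaping histogram mode:        27.25 A (programmed 27.0 A)
unwrap vs C-tail contacts r:  -0.438
raw/smoothed contact sd:      5.43 / 1.20
```

The gyre-separation mode matches the programmed 27 Å, and the negative
Pearson r reflects the programmed anti-coupling between DNA unwrapping and
C-tail binding.  The other examples cover unwrapping label recovery, core
RMSF, sequence analytics, and the end-to-end file pipeline
(`nucdyn report`-equivalent) — each prints the numbers it computes and what
they mean.

## Command line

```bash
nucdyn simulate --epsilon 0.5 --frames 2000 --seed 7 --out fixtures/
nucdyn unwrap --top fixtures/synthetic.pdb --topology fixtures/synthetic_topology.toml \
              --traj fixtures/synthetic.xtc --out unwrap.tsv
nucdyn fes1d --in unwrap.tsv --temp 310 --out fes.tsv
nucdyn report --top s.pdb --topology top.toml --traj run1.xtc run2.xtc --out report/
```

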