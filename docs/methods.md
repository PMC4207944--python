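# Methods

This note documents the models and procedures behind each analysis
stage, the defaults and why they were chosen, the numerical choices,
and the known limitations — in particular what the synthetic-data
generator does and does not emulate, and what the two-gate kinetic
model can and cannot express.

## Conformer comparison

### Structure handling

PDB files are parsed with gemmi and split into one conformer per chain
(per model).  Hydrogens are dropped, alternate locations are resolved
to the highest-occupancy copy (ties keep the first in file), and only
the 20 standard amino acids enter a conformer; hetero residues and
ligands are ignored.  Conformers from the same protein are paired by
author residue number, never by alignment: all eight transporter
chains share one numbering scheme, and unstructured residues simply
drop out of the pairing (they are listed, and excluded from every
statistic).  Writing uses an in-package fixed-column formatter; when a
per-residue score replaces the B-factor column it is clamped to
[0, 999.99] (the 6-column field) and rounded to 2 decimals, and
residues without a score keep their original B.

### Superposition

`kabsch_fit` solves the classical least-squares rotation (SVD with the
sign correction that rejects reflections; the rotation matrix is
orthonormal with det +1 to 1e-8).  The rmsd is
√(mean squared residual distance).  `iterative_fit` emulates the
"best-fit" behaviour of interactive viewers whose exact rejection rule
is not published: alternate a Kabsch fit on the current core with
removal of pairs whose residual exceeds `reject_multiplier` × rmsd
(default 2.0, configurable; a 1-nm-scale absolute floor of 1e-9 Å keeps
numerically exact fits at a fixed point), stop at a fixed point or
after `max_iter` = 10 rounds, and report the surviving core.  All
deviation statistics superpose on the Cα trace; deviations are then
read off either Cα or the fixed table of most distal side-chain heavy
atoms (glycine has none and is skipped).

### Deviation statistics

* *Group dispersion* is operationalized as the mean per-residue Cα
  deviation over all paired residues of each conformer (termini
  included), then averaged within a conformer group with the SEM taken
  over conformers; two groups are compared with a Welch t-test
  (the unequal-variance form is the safe default when group sizes are
  3–4).  Region- and zone-filtered variants are emitted alongside
  because the residue set behind a published headline number is often
  unstated.
* *Coordinate regression* concatenates the x, y, z coordinates of the
  shared Cα atoms of two conformers after both are superposed onto the
  common reference, and reports slope, intercept and Pearson R.  R is
  symmetric in the two conformers by construction.
* *Poisson fits*: deviations are histogrammed into bins of 0.25 Å
  (configurable); the normalised frequencies over bin index k are
  fitted by least squares with A·Poisson(k; λ), and λ is reported in Å
  (λ_index × bin width) together with the empirical mean and the
  Pearson correlation between fitted and observed frequencies.  A
  discrete distribution is being fitted to binned continuous data, so
  the bin width is part of the model and is therefore a reported knob.
* *Zones*: Cα positions are projected onto the membrane axis (default
  z); the span of the transmembrane residues is cut at fractions
  (1/3, 2/3) into internal / central / external bands, the
  high-projection band being "external".  TM helix ranges come from a
  bundled editable table approximating the UniProt topology annotation
  of the xylose transporter; any two-column TSV can replace it.
* *Running averages* use a centered window spanning
  `[i − (w−1)//2, i + w//2]`, shrinking at the edges, so output length
  equals input length; a window longer than the series is an error.

### Dihedrals

φ(i) = C(i−1)–N(i)–CA(i)–C(i), ψ(i) = N(i)–CA(i)–C(i)–N(i+1),
ω(i) = CA(i)–C(i)–N(i+1)–CA(i+1), all in degrees on (−180, 180], with
IUPAC sign convention; residues at chain breaks (by numbering) are
undefined.  Between two conformers the displacement per angle is the
minimal circular difference (in [0, 180]), combined per residue as
√(Δφ² + Δψ²).  Per-helix aggregates report both the mean and the sum,
since either can be the quantity of interest.  ω classifies the
peptide bond as cis (|ω| < 90°) or trans.

## Motif scanning and the mixture null

The scanner finds spans that begin and end with an aromatic anchor
(F or W) separated by 2–10 arbitrary residues, i.e. spans of length
4–12.  Published pattern counts rarely state whether overlapping
matches count, so two modes are explicit: `leftmost_nonoverlapping`
(default; scan left to right, close each anchor at the shortest valid
partner, resume after the match — equivalent to the lazy regular
expression `[FW].{2,10}?[FW]`) and `all_pairs` (every anchor pair with
an in-range gap).  The per-protein statistic is the number of
destabilizing residues {A, G, P, V, C} inside the union of matched
spans, each position counted once.

Null cohorts are built by composition-preserving random permutation of
each sequence.  Count distributions are fitted with the two-component
Gumbel (extreme-value) mixture given in the README by nonlinear least
squares on the probability histogram, with a multistart grid
(S ∈ {0.25, 0.5, 0.75}, locations at the histogram quartiles, rates in
{0.1, 0.3, 1.0}), best SSE winning; components are reported ordered by
location.  Parameter recovery on data simulated from the fitted form
is part of the test suite (S to ±0.1 and locations to ±0.5 at 5000
sequences).

## Instability map

Two per-residue components, each min-max scaled to [0, 1] over the
chain (a constant column scales to zero by definition; z-scoring is
available as an option): the 10-residue running density of the broader
destabilizing set {G, A, P, C, S, I, V}, and the Cα B-factor.  Their
sum (in [0, 2]) is written into the B column of a structure copy for
rendering.  The 7-residue set used here and the 5-residue counting set
used by the motif scanner are distinct named constants on purpose —
they serve different statistics.

## Gated-transport model

A channel with an outer gate (conductance kx) between the external
solution and vestibule 1, an inner gate (ky) between vestibule 2 and
the internal solution, and a narrow central isthmus.  Each vestibule
contains one binding site: K_D1 = 1 mM (outer, high affinity),
K_D2 = 20 mM (inner).  Gates are binary, driven by a sine timer of
frequency f with per-gate phases; the threshold cos(π·duty) makes the
open fraction exactly `duty` (default 0.5).  A clamped-sigmoid smooth
gate is available.

State: free vestibular concentrations V1, V2 (mM) and site occupancies
B1, B2.  With site capacities σ1, σ2 (mM-equivalent) and k2_i = K_Di·k1:

    r1     = k1·V1·(1−B1) − k2_1·B1
    r2     = k1·V2·(1−B2) − k2_2·B2
    hop    = kh·k2_1·[B1(1−B2) − (KD2/KD1)·B2(1−B1)]
    dV1/dt = g1(t)·kx·(C_out−V1) + kc·(V2−V1) − σ1·r1
    dB1/dt = r1 − hop
    dV2/dt = kc·(V1−V2) − σ2·r2 − g2(t)·ky·(V2−C_in)
    dB2/dt = r2 + (σ1/σ2)·hop
    J(t)   = g2(t)·ky·(V2−C_in)

Two routes cross the isthmus.  `kc` is ordinary free diffusion between
the vestibular pools.  The carrier ("hop") route moves ligand directly
from site 1 to site 2: physically, crossing the narrow isthmus
requires the ligand to leave the outer site and be recaptured at the
inner one, so its rate is proportional to the site-1 dissociation rate
k2_1, with kh the dimensionless number of productive transits per
dissociation.  The KD2/KD1 factor in the reverse term enforces
detailed balance — at a uniform concentration with both gates open
every term vanishes.  With kh = 0 the model reduces to a pure
free-diffusion channel with dead-end buffer sites; in that limit the
cycle-averaged flux equals kc·⟨V1−V2⟩ and is provably insensitive to
k1, which is why the carrier route is the default: the interesting
regime is the one where transport is binding-limited.

`k1` is treated as a second-order constant in per-mM per-s, so that
K_D = k2/k1 is dimensionally consistent and varying k1 at fixed K_D
scales association and dissociation together.

### Calibration

kx, ky, kc, kh, σ1, σ2 are not observable from structure.  The shipped
defaults (kx = 1e8 s⁻¹, ky = 1e9 s⁻¹, kc = 1e3 s⁻¹, kh = 0.5,
σ1 = 15 mM, σ2 = 5 mM) are a frozen one-time calibration chosen so
that at k1 = 1e8 the network is binding-limited rather than
diffusion-limited, giving (50 cycles, duty 0.5, C_out = 50 mM,
C_in = 0):

* in-phase → antiphase flux reduction of 65.9 % at k1 = 1e8;
* a phase effect below 0.1 % at k1 = 1e6 ≈ f;
* an in-phase flux fold-change of 52.7 between k1 = 1e8 and 1e6.

### A structural limitation of the two-gate model

The phase sensitivity and the k1 sensitivity pull against each other
in this model class, and the calibration reflects a deliberate choice.
A large antiphase penalty requires the fast-binding flux to be carried
while both gates are simultaneously open (streaming), so the effective
transporting fraction of each cycle is the duty cycle; the slow-binding
flux is interior-limited and runs the whole cycle.  Since every
interior step scales linearly with k1, the fold-change between
k1 = 1e8 and 1e6 is then bounded near 100 × duty ≈ 50–55.
Configurations that push the fold toward 100 (making the fast regime
interior-limited full-time) simultaneously erase the phase dependence
(reduction < 30 %).  A systematic search over kx, ky ∈ [8e6, 1e9],
kc ∈ [0, 1e6], kh (both a fixed-rate and the release-proportional
carrier), and σ1, σ2 ∈ [0.15, 400] found no configuration satisfying
both a ~65 % antiphase reduction and a ~100-fold rate sensitivity;
the shipped calibration meets the phase targets exactly and reports
the fold-change the model actually produces.  Reproducing both
simultaneously appears to require additional physics (e.g. gate- or
concentration-dependent vestibular diffusion) outside this model.

### Numerics

Binary-gate switching times are computed analytically and used as
integration breakpoints, so the stiff integrator (BDF, rtol 1e-8,
atol 1e-10 by default) never steps across a discontinuity; breakpoints
closer than 1e-9 cycles are merged.  The transported amount is carried
as an extra state variable, so mean fluxes are exact integrals: the
first 25 % of cycles (rounded up to whole cycles) is discarded and the
mean net flux is the transported amount over the remaining integer
cycles divided by their duration.  At the default calibration the flux
is converged to <0.1 % by 50 cycles (checked against 100).  Negative
concentrations beyond 1e-6 of scale abort with a diagnostic.

## Synthetic data

The generator exists to give every estimator a ground truth, not to be
physically realistic.

* *Helix bundles*: N/CA/C/O backbones from ideal bond geometry
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard angles), (φ, ψ) =
  (−57°, −47°) in helices, extended linkers, trans ω.  Each non-glycine
  residue carries its named distal side-chain atom on an idealized
  Cβ direction (1.53 Å for Cβ itself, 2.5 Å pseudo-position otherwise)
  so both atom-selection modes are exercised.  Exact constants are
  irrelevant as long as round trips are self-consistent, which the
  dihedral recovery test (±0.5°) checks.
* *Ensembles*: per conformer, each residue is shifted rigidly by a
  magnitude drawn from the region's distribution (exponential, Gumbel,
  or bin-discretised Poisson to mirror the binned fitting model) in a
  uniformly random direction, followed by a global rigid jitter.  The
  default scales make linkers 3× more mobile than helices.  The
  eight-conformer "study ensemble" used by the recipes assigns larger
  scales to the inward-facing group than the outward group and the
  largest helix-scale to the apo conformers (helix/linker scales 0.6/2.2
  for the inward holo conformer, 1.3/3.0 for apo, 0.35/1.0 for outward),
  encoding the expected orderings (inward > outward dispersion,
  apo > occluded central mobility) that the pipeline must recover.
* *B-factors*: B = 8π²/3 × mean squared Cα displacement about the
  ensemble mean after superposition — the crystallographic definition
  applied to the generated ensemble, which guarantees the positive
  B-vs-mobility correlation the instability map relies on.
* *Sequence cohorts*: each sequence belongs to one of two populations;
  its target destabilizing-group count is drawn from that population's
  Gumbel distribution and realised exactly by planting anchor-bracketed
  spans (separated by more than the maximum gap, so they cannot merge)
  whose interiors contain the target number of {A,G,P,V,C} residues.
  Background composition is protein-like with aromatics held at 0.5 %
  so accidental anchors are rare; with an anchor-free background the
  scanner provably returns the planted count.

What passing tests on these fixtures shows: the estimators recover the
parameters they claim to estimate, at the stated tolerances, under
clean geometry and known noise.  What it does not show: robustness to
real crystallographic artefacts (alternate conformations, lattice
contacts, refinement restraints, resolution-dependent B-factor
scaling), to alignment ambiguity between distant homologs, or to
database-dependent motif baselines.  Real-structure runs are supported
via the PDB recipe path but require the user to supply the files.

## Determinism and provenance

All randomness flows through numpy Generators seeded from a single
seed; identical spec + seed gives byte-identical outputs.  Every TSV
report carries a `#` header with package version, a hash of the
configuration (output location excluded) and the seed.
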