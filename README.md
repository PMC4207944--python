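# reptation

Analysis toolkit for quantifying the small-scale thermal motions
("reptation") of membrane-transporter conformers, and for simulating
what those motions imply for facilitated diffusion through a gated
channel.

Crystal structures of major-facilitator-superfamily (MFS) transporters
such as the *E. coli* xylose transporter XylE are snapshots of one
protein caught in different conformations (inward/outward-facing,
apo/holo).  Comparing those snapshots residue by residue measures how
mobile each part of the carbon skeleton is — and whether the mobile
regions coincide with sequence motifs known to destabilize
transmembrane helices.  This package implements that comparison
pipeline end to end, plus a kinetic model of transport through a
channel whose two gates open and close periodically.

## What it computes

* **Per-residue deviation profiles** — every conformer is rigidly
  superposed (Kabsch, optionally with iterative outlier rejection) onto
  a reference conformer on its Cα trace; deviations are measured per
  residue for Cα or for the most distal side-chain heavy atom.  Group
  statistics (mean ± SEM over conformer groups, Welch t-test), maximal
  and running-window profiles, inter-conformer coordinate regressions,
  residue-pair distances and least-squares Poisson fits to binned
  deviation histograms are built on top.
* **Backbone dihedral displacements** — φ/ψ/ω per residue; between two
  conformers the wrapped angular differences are combined per residue
  as √(Δφ² + Δψ²), and aggregated per transmembrane helix.
* **Destabilizing-motif statistics** — PROSITE-style scan for
  `[FW]-x(2,10)-[FW]` spans; the residues {A, G, P, V, C} inside the
  union of spans are counted per protein; cohorts are compared to
  composition-preserving shuffle nulls and fitted with a two-component
  extreme-value (Gumbel) mixture

  S·λ₁·exp{−λ₁(X−μ₁)−exp(−λ₁(X−μ₁))} + (1−S)·λ₂·exp{−λ₂(X−μ₂)−exp(−λ₂(X−μ₂))}

  whose weight S measures the non-random sub-population.
* **Instability maps** — a running-window density of the broader
  destabilizing set {G, A, P, C, S, I, V}, min-max scaled and added to
  the scaled crystallographic B-factor, written back into the B-factor
  column of a PDB file for 3D rendering.
* **Gated-transport kinetics** — a deterministic ODE model of a channel
  with an outer and an inner gate driven by a thresholded sine timer,
  two vestibules, and two binding sites (K_D = 1 mM and 20 mM) through
  which ligand transits serially.  See `docs/methods.md` for the
  equations and the calibration of the unobservable transfer constants.
* **Synthetic data with known ground truth** — ideal-geometry helix
  bundles with region-dependent displacement scales, two-population
  sequence cohorts, and ensemble-variance B-factors, so every estimator
  in the pipeline is tested against parameters it is supposed to
  recover.

## Worked example

Gate-phase dependence of net flux through the two-gate channel
(C_out = 50 mM, C_in = 0, f = 10⁶ Hz, duty 0.5):

```python
from reptation import gated_transport as gt

model = gt.GateChannelModel()        # shipped calibration
table = gt.phase_comparison(model, k1_values=(1e6, 1e8),
                            n_cycles=50, rtol=1e-8, atol=1e-10)
print(table)
```

```
             flux_inphase  flux_shifted  reduction_pct
k1
1000000.0       6.276e+06     6.279e+06       -0.04833
100000000.0     3.307e+08     1.129e+08          65.85
```

When ligand association (k1 = 10⁸ per-mM·s) is much faster than gating,
switching the gates from in-phase to antiphase cuts the steady net flux
by 65.9 %; when association is comparable to the gating frequency
(k1 = 10⁶), the phase relationship is irrelevant (−0.05 %).  Fluxes are
in mM·s⁻¹ equivalents per channel volume.

Scanning a transporter-like sequence for destabilizing motifs:

```python
from reptation import motif_scan as ms

seq = ("MNTQYNSSYIFSITLVATLGGLLFGYDTAVISGTVESLNTVFVAPQNLSESAANSLLGFCVA"
       "SALIGCIIGGALGGYCSNRFGRRDSLKIAAVLFFISGVGSAWPELGFTSINPDNTVPVYLAG"
       "YVPEFVIYRIIGGIGVGLASMLSPMYIAELAPAHILGKLVSFYELMITLGIFLGPVCWGPVCW")
matches = ms.find_motifs(seq)                    # [FW]-x(2,10)-[FW]
count = ms.destabilizing_count(seq, matches)     # A/G/P/V/C inside spans
for m in matches:
    print(m.start, m.end, m.span, m.destabilizing_count)
```

```
94 104 FFISGVGSAW 4
165 176 FYELMITLGIF 1
181 187 WGPVCW 4
```

The `WGPVCW` span is the classic helix-breaking core (G-P-V-C flanked
by tryptophans) that marks the unstable central zone of sugar
transporters; it contributes 4 to the protein's destabilizing-group
count (9 in total here).

## Command line

Every analysis is also available as a CLI recipe producing TSV reports
with provenance headers:

```sh
reptation run all --out-dir reports --seed 1     # synthetic fixtures
reptation deviations --pdb-dir structures/       # real PDB files
reptation motifscan --fasta proteins.fasta --shuffles 5
reptation simulate-gates --k1 1e8 --phase2 180 --cycles 50
reptation synth ensemble --seed 7                # write test fixtures
```

With `--pdb-dir`, chains are mapped to the conformer labels 3a, 3b,
4a–4c, 4GBY, 4GBZ, 4GC0 and all deviation statistics are computed
against the inward-facing holo reference 3a.

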