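"""Ground-truth-known synthetic inputs for every pipeline stage.

Three generators, all deterministic per seed:

* an idealised alpha-helical bundle (N/CA/C/O backbone built from ideal
  bond geometry at helix torsions (-57, -47), extended linkers, plus a
  pseudo distal side-chain atom per residue) and perturbed conformer
  ensembles with region-dependent displacement scales — emulating the
  observation that linkers and termini move more than transmembrane
  helices;
* protein-sequence cohorts that are mixtures of two sub-populations
  with different planted destabilizing-group counts — emulating the
  two-component count distributions of membrane-protein cohorts;
* B-factor columns derived from ensemble positional variance
  (B = 8 pi^2 / 3 * mean squared displacement), so that B correlates
  with the per-residue deviation profile as in real crystal data.

Nothing here aims at physical realism (no sterics, no packing); the
point is exact knowledge of the ground truth behind every statistic
the analysis modules estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .structure_io import (
    AA1_TO_3, AtomRecord, Conformer, DISTAL_ATOMS, Residue,
)

# Ideal backbone geometry (Angstrom / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
HELIX_PHI, HELIX_PSI = -57.0, -47.0
LINKER_PHI, LINKER_PSI = -120.0, 130.0

_HELIX_SEQ = "ALREQIVKMF"   # cycled within helices (all have distal atoms)
_LINKER_SEQ = "GSPNT"       # cycled within linkers (includes glycine)


@dataclass
class EnsembleSpec:
    """Geometry and perturbation parameters of a synthetic ensemble."""

    n_helices: int = 12
    helix_length: int = 18
    linker_length: int = 6
    n_conformers: int = 4
    #: per-region displacement distribution: region -> (name, scale in A);
    #: names: "exponential", "gumbel", "poisson" (bin-discretised).
    displacement: dict = field(default_factory=lambda: {
        "helix": ("exponential", 0.3),
        "linker": ("exponential", 0.9),
    })
    jitter_translation: float = 0.5   # global rigid jitter, A
    jitter_rotation_deg: float = 2.0  # global rigid jitter, degrees
    poisson_bin_width: float = 0.25   # bin for the "poisson" distribution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1 or self.helix_length < 1 or self.linker_length < 0:
            raise ValueError("lengths must be positive")
        for region, (name, scale) in self.displacement.items():
            if scale < 0:
                raise ValueError(f"displacement scale for {region!r} negative")

    @property
    def n_residues(self) -> int:
        return (self.n_helices * self.helix_length
                + (self.n_helices - 1) * self.linker_length)

    def region_labels(self) -> pd.Series:
        """Per-residue "helix" / "linker" labels (1-based numbering)."""
        labels = []
        for h in range(self.n_helices):
            labels.extend(["helix"] * self.helix_length)
            if h < self.n_helices - 1:
                labels.extend(["linker"] * self.linker_length)
        index = pd.Index(range(1, len(labels) + 1), name="residue_number")
        return pd.Series(labels, index=index, name="region")

    def tm_ranges(self) -> dict[str, tuple[int, int]]:
        """Helix spans in the format of the TM-range annotation tables."""
        out = {}
        pos = 1
        for h in range(self.n_helices):
            out[f"TM{h + 1}"] = (pos, pos + self.helix_length - 1)
            pos += self.helix_length + self.linker_length
        return out


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position atom d with given c-d bond, b-c-d angle, a-b-c-d torsion."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + bc * d_local[0] + m * d_local[1] + n * d_local[2]


def _sequence(spec: EnsembleSpec) -> str:
    out = []
    hel = 0
    lin = 0
    for region in spec.region_labels():
        if region == "helix":
            out.append(_HELIX_SEQ[hel % len(_HELIX_SEQ)])
            hel += 1
        else:
            out.append(_LINKER_SEQ[lin % len(_LINKER_SEQ)])
            lin += 1
    return "".join(out)


def make_helix_bundle(spec: EnsembleSpec, label: str = "ref") -> Conformer:
    """Build the reference conformer from ideal backbone geometry.

    Helices use (phi, psi) = (-57, -47), linkers an extended
    conformation; omega is trans throughout.  Each non-glycine residue
    additionally carries its named distal side-chain atom placed on an
    idealised C-beta direction, so both atom-selection modes work.
    """
    seq = _sequence(spec)
    regions = spec.region_labels().to_numpy()
    n = len(seq)
    phi = np.where(regions == "helix", HELIX_PHI, LINKER_PHI)
    psi = np.where(regions == "helix", HELIX_PSI, LINKER_PSI)

    coords: list[dict[str, np.ndarray]] = []
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    theta0 = np.radians(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([np.cos(theta0), np.sin(theta0), 0.0])
    coords.append({"N": np.zeros(3), "CA": ca0, "C": c0})
    for i in range(1, n):
        prev = coords[i - 1]
        atom_n = _place_atom(prev["N"], prev["CA"], prev["C"],
                             BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        atom_ca = _place_atom(prev["CA"], prev["C"], atom_n,
                              BOND_N_CA, ANGLE_C_N_CA, 180.0)
        atom_c = _place_atom(prev["C"], atom_n, atom_ca,
                             BOND_CA_C, ANGLE_N_CA_C, phi[i])
        coords.append({"N": atom_n, "CA": atom_ca, "C": atom_c})
    # carbonyl O and pseudo distal side-chain atoms
    for i in range(n):
        cur = coords[i]
        if i + 1 < n:
            cur["O"] = _place_atom(cur["N"], cur["CA"], cur["C"],
                                   BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
        res3 = AA1_TO_3[seq[i]]
        distal = DISTAL_ATOMS.get(res3)
        if distal is not None:
            length = 1.53 if distal == "CB" else 2.5
            cur[distal] = _place_atom(cur["C"], cur["N"], cur["CA"],
                                      length, 110.5, -122.0)

    residues = []
    for i in range(n):
        res3 = AA1_TO_3[seq[i]]
        atoms = {
            name: AtomRecord(atom_name=name, residue_name=res3,
                             residue_number=i + 1, chain_id="A", xyz=xyz)
            for name, xyz in coords[i].items()
        }
        residues.append(Residue(number=i + 1, name=res3, atoms=atoms))
    return Conformer(label=label, source="synthetic", residues=residues)


def _draw_magnitudes(name: str, scale: float, size: int,
                     rng: np.random.Generator, bin_width: float) -> np.ndarray:
    if scale == 0:
        return np.zeros(size)
    if name == "exponential":
        return rng.exponential(scale, size)
    if name == "gumbel":
        return np.clip(rng.gumbel(scale, 0.3 * scale, size), 0.0, None)
    if name == "poisson":
        k = rng.poisson(scale / bin_width, size)
        return bin_width * (k + rng.uniform(0.0, 1.0, size))
    raise ValueError(f"unknown displacement distribution: {name!r}")


def _random_rotation(rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.normal(0.0, angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def perturb_ensemble(
    ref: Conformer,
    spec: EnsembleSpec,
    rng: Optional[np.random.Generator] = None,
    labels: Optional[list[str]] = None,
) -> tuple[list[Conformer], pd.DataFrame]:
    """Perturbed copies of the reference, with recorded ground truth.

    Each conformer receives an independent per-residue displacement
    (magnitude from the region's distribution, direction uniform on the
    sphere, applied rigidly to all atoms of the residue) followed by a
    global rigid jitter.  Returns the conformers and a truth table of
    (conformer, residue_number, region, magnitude).
    """
    rng = rng or np.random.default_rng(spec.seed)
    regions = spec.region_labels()
    if labels is None:
        labels = [f"c{i + 1}" for i in range(spec.n_conformers)]
    conformers = []
    truth_rows = []
    for label in labels:
        n = len(ref)
        mags = np.zeros(n)
        for region, (dist_name, scale) in spec.displacement.items():
            mask = (regions.reindex(ref.residue_numbers) == region).to_numpy()
            mags[mask] = _draw_magnitudes(dist_name, scale, int(mask.sum()),
                                          rng, spec.poisson_bin_width)
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        R = _random_rotation(rng, spec.jitter_rotation_deg)
        shift = rng.normal(0.0, spec.jitter_translation, 3)
        centroid = np.mean(
            [r.coord("CA") for r in ref.residues if r.coord("CA") is not None],
            axis=0,
        )
        residues = []
        for i, res in enumerate(ref.residues):
            disp = mags[i] * directions[i]
            atoms = {}
            for name, rec in res.atoms.items():
                xyz = rec.xyz + disp
                xyz = R @ (xyz - centroid) + centroid + shift
                atoms[name] = AtomRecord(
                    atom_name=name, residue_name=res.name,
                    residue_number=res.number, chain_id="A", xyz=xyz,
                )
            residues.append(Residue(number=res.number, name=res.name, atoms=atoms))
            truth_rows.append((label, res.number, regions.get(res.number, "?"),
                               float(mags[i])))
        conformers.append(Conformer(label=label, source="synthetic", residues=residues))
    truth = pd.DataFrame(
        truth_rows, columns=["conformer", "residue_number", "region", "magnitude"]
    )
    return conformers, truth


def assign_bfactors(
    conformers: list[Conformer], reference: Optional[Conformer] = None
) -> pd.Series:
    """Ensemble-variance B-factors on the reference residue numbering.

    All conformers are superposed onto the reference (first conformer
    by default) on their shared C-alpha trace; for each residue,
    B = 8 pi^2 / 3 * mean squared CA displacement about the ensemble
    mean position.
    """
    from .structure_io import paired_coords
    from . import superpose as sp

    if len(conformers) < 2:
        raise ValueError("assign_bfactors needs at least 2 conformers")
    ref = reference or conformers[0]
    per_residue: dict[int, list[np.ndarray]] = {}
    for conf in conformers:
        moving, fixed, numbers = paired_coords(conf, ref, "calpha")
        fit = sp.kabsch_fit(moving, fixed)
        moved = fit.transform.apply(moving)
        for num, xyz in zip(numbers, moved):
            per_residue.setdefault(num, []).append(xyz)
    out = {}
    for num, positions in per_residue.items():
        arr = np.array(positions)
        mean = arr.mean(axis=0)
        msd = float(np.mean(np.sum((arr - mean) ** 2, axis=1)))
        out[num] = 8.0 * np.pi**2 / 3.0 * msd
    series = pd.Series(out).sort_index()
    series.index.name = "residue_number"
    return series.rename("b_factor")


# ---------------------------------------------------------------------------
# sequence cohorts

#: Background composition: roughly protein-like, with aromatics held low
#: so planted motifs dominate the anchor content.
DEFAULT_COMPOSITION = {
    "A": 0.10, "C": 0.01, "D": 0.055, "E": 0.065, "F": 0.005, "G": 0.075,
    "H": 0.02, "I": 0.06, "K": 0.06, "L": 0.11, "M": 0.025, "N": 0.04,
    "P": 0.05, "Q": 0.04, "R": 0.055, "S": 0.08, "T": 0.055, "V": 0.07,
    "W": 0.005, "Y": 0.02,
}

_NEUTRAL = "L"  # filler residue: neither anchor nor destabilizing


@dataclass
class SequenceCohortSpec:
    """Two-population cohort with planted destabilizing-group counts."""

    n_sequences: int = 500
    length: int = 480
    composition: dict = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    mixture_fraction: float = 0.46   # weight of population 1
    loc1: float = 7.0                # Gumbel location of population-1 counts
    scale1: float = 1.5
    loc2: float = 16.0               # Gumbel location of population-2 counts
    scale2: float = 2.0
    min_gap: int = 2
    max_gap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.composition.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("composition must sum to 1")
        if not 0.0 <= self.mixture_fraction <= 1.0:
            raise ValueError("mixture_fraction must be in [0, 1]")


def synth_sequences(
    spec: SequenceCohortSpec, rng: Optional[np.random.Generator] = None
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate a cohort of sequences with planted motif counts.

    Each sequence belongs to population 1 with probability
    ``mixture_fraction``; its target destabilizing-group count is drawn
    from that population's Gumbel distribution (rounded, clipped at 0)
    and realised by planting anchor-bracketed spans whose interiors
    carry exactly the target number of destabilizing residues.  Planted
    spans are separated by more than ``max_gap`` positions so they do
    not combine into additional matches.

    Returns FASTA-style records and a truth table with the population
    and planted count of every sequence.
    """
    rng = rng or np.random.default_rng(spec.seed)
    letters = np.array(sorted(spec.composition))
    probs = np.array([spec.composition[c] for c in letters])
    probs = probs / probs.sum()
    destab = "AGPVC"
    records = []
    truth_rows = []
    for idx in range(spec.n_sequences):
        pop = 1 if rng.random() < spec.mixture_fraction else 2
        loc = spec.loc1 if pop == 1 else spec.loc2
        scale = spec.scale1 if pop == 1 else spec.scale2
        target = max(int(np.round(rng.gumbel(loc, scale))), 0)
        # build motif spans whose interiors sum exactly to `target`
        spans = []
        remaining = target
        while remaining > 0:
            gap = int(rng.integers(spec.min_gap, spec.max_gap + 1))
            d = min(remaining, gap)
            interior = list(rng.choice(list(destab), d))
            interior += [_NEUTRAL] * (gap - d)
            rng.shuffle(interior)
            anchor = rng.choice(["F", "W"], 2)
            spans.append(anchor[0] + "".join(interior) + anchor[1])
            remaining -= d
        sep = spec.max_gap + 1
        needed = sum(len(s) for s in spans) + sep * (len(spans) + 1)
        if needed > spec.length:
            raise ValueError(
                f"sequence length {spec.length} too short for target count "
                f"{target}")
        seq = list(rng.choice(letters, spec.length, p=probs))
        # place spans left-to-right with random extra offsets, > max_gap apart
        slack = spec.length - needed
        offsets = np.sort(rng.integers(0, slack + 1, size=len(spans)))
        pos = sep
        prev_off = 0
        for off, span in zip(offsets, spans):
            pos += int(off) - prev_off
            prev_off = int(off)
            seq[pos:pos + len(span)] = list(span)
            pos += len(span) + sep
        records.append((f"seq{idx:04d}", "".join(seq)))
        truth_rows.append((f"seq{idx:04d}", pop, target, len(spans)))
    truth = pd.DataFrame(
        truth_rows, columns=["id", "population", "planted_count", "n_motifs"]
    ).set_index("id")
    return records, truth
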