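"""Reading, writing and slicing of protein conformer structures.

A *conformer* here is one crystallographically observed chain of a
transporter: its ordered amino-acid residues with heavy-atom coordinates
and B-factors.  Multi-chain PDB entries are split into one conformer per
chain (per model), so that e.g. a dimeric crystal yields two conformers
that can be compared residue-by-residue.

Parsing is delegated to :mod:`gemmi`; writing uses an explicit
fixed-column PDB formatter so the B-factor rewrite rule is under this
package's control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger("reptation")

#: 3-letter -> 1-letter codes for the 20 standard amino acids.
AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: Most distal heavy side-chain atom used as a side-chain position proxy.
#: Glycine has no side chain and is deliberately absent.
DISTAL_ATOMS = {
    "ALA": "CB", "ARG": "NH2", "ASN": "ND2", "ASP": "CG", "CYS": "SG",
    "GLN": "NE2", "GLU": "CD", "HIS": "NE2", "ILE": "CD1", "LEU": "CD1",
    "LYS": "NZ", "MET": "CE", "PHE": "CZ", "PRO": "CG", "SER": "OG",
    "THR": "CG2", "TRP": "CH2", "TYR": "CZ", "VAL": "CG2",
}

#: Maximum value representable in the fixed-width PDB B-factor column
#: (6 columns, 2 decimals).  Scores are clamped to [0, B_COLUMN_MAX].
B_COLUMN_MAX = 999.99


@dataclass
class AtomRecord:
    """One heavy atom of a residue."""

    atom_name: str
    residue_name: str
    residue_number: int
    chain_id: str
    xyz: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(
                f"atom {self.atom_name} of residue {self.residue_number}: "
                "coordinates must be a finite 3-vector"
            )


@dataclass
class Residue:
    number: int
    name: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def coord(self, atom_name: str) -> np.ndarray | None:
        rec = self.atoms.get(atom_name)
        return None if rec is None else rec.xyz


@dataclass
class Conformer:
    """One chain's ordered residues with coordinates and B-factors."""

    label: str
    source: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(
                f"conformer {self.label}: residue numbers must be strictly increasing"
            )
        self._by_number = {r.number: r for r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, number: int) -> Residue | None:
        return self._by_number.get(number)

    @property
    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    @property
    def sequence(self) -> str:
        """1-letter sequence of residues that carry a C-alpha atom."""
        return "".join(r.one_letter for r in self.residues if "CA" in r.atoms)

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Inclusive ranges of residue numbers missing from the chain."""
        out = []
        nums = self.residue_numbers
        for a, b in zip(nums, nums[1:]):
            if b - a > 1:
                out.append((a + 1, b - 1))
        return out

    def b_factors(self, atom_name: str = "CA") -> dict[int, float]:
        out = {}
        for r in self.residues:
            rec = r.atoms.get(atom_name)
            if rec is not None:
                out[r.number] = rec.b_factor
        return out


@dataclass
class ResiduePairing:
    """Residue-number pairing of two conformers for comparisons.

    Pairing is a function of the author residue number only; residues
    present in one chain but unstructured (missing) in the other are
    excluded from all deviation statistics and listed here.
    """

    common: list[int]
    only_a: list[int]
    only_b: list[int]


def read_structure(
    path: str | Path,
    chain_filter: list[str] | None = None,
    label_map: dict[str, str] | None = None,
) -> list[Conformer]:
    """Read a PDB file and split it into one :class:`Conformer` per chain.

    Hydrogen atoms are ignored, alternate locations are resolved to the
    highest-occupancy copy (ties keep the first in file), and hetero
    (non-standard) residues are excluded.  ``label_map`` renames chains
    (e.g. ``{"A": "3a"}``); unmapped chains keep their chain ID.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    label_map = label_map or {}
    conformers: list[Conformer] = []
    multi_model = len(st) > 1
    for model in st:
        for chain in model:
            if chain_filter is not None and chain.name not in chain_filter:
                continue
            residues = _collect_chain(chain)
            if not residues:
                if chain_filter is not None:
                    raise ValueError(
                        f"chain {chain.name} of {path.name}: no residues"
                    )
                continue
            label = label_map.get(chain.name, chain.name)
            if multi_model:
                label = f"{label}/m{model.num}"
            conformers.append(
                Conformer(
                    label=label,
                    source=f"{path.stem}:{chain.name}",
                    residues=residues,
                )
            )
    if not conformers:
        raise ValueError(f"{path}: no protein chain with residues found")
    return conformers


def _collect_chain(chain: "gemmi.Chain") -> list[Residue]:
    residues: list[Residue] = []
    seen: dict[int, Residue] = {}
    for res in chain:
        if res.name not in AA3_TO_1:
            continue  # hetero residue / ligand / water
        num = res.seqid.num
        residue = seen.get(num)
        if residue is None:
            residue = Residue(number=num, name=res.name)
            seen[num] = residue
            residues.append(residue)
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            prev = residue.atoms.get(atom.name)
            # altloc rule: keep highest occupancy, tie -> first in file
            if prev is not None and atom.occ <= prev.occupancy:
                continue
            residue.atoms[atom.name] = AtomRecord(
                atom_name=atom.name,
                residue_name=res.name,
                residue_number=num,
                chain_id=chain.name,
                xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                b_factor=atom.b_iso,
                occupancy=atom.occ,
            )
    return residues


def select_atoms(conf: Conformer, mode: str) -> list[tuple[int, np.ndarray]]:
    """Return ``(residue_number, xyz)`` pairs for the requested atom set.

    ``"calpha"`` selects CA atoms; ``"distal"`` selects the per-residue
    most distal side-chain heavy atom (:data:`DISTAL_ATOMS`).  Glycine
    and residues whose selected atom is missing are omitted; unknown
    residue codes are skipped with a warning.
    """
    if mode not in ("calpha", "distal"):
        raise ValueError(f"unknown atom selection mode: {mode!r}")
    out: list[tuple[int, np.ndarray]] = []
    skipped = 0
    for res in conf.residues:
        if mode == "calpha":
            atom = "CA"
        else:
            if res.name == "GLY":
                continue
            atom = DISTAL_ATOMS.get(res.name)
            if atom is None:
                skipped += 1
                continue
        xyz = res.coord(atom)
        if xyz is not None:
            out.append((res.number, xyz))
    if skipped:
        logger.warning(
            "select_atoms(%s, distal): %d residues with unknown code skipped",
            conf.label, skipped,
        )
    return out


def pair_residues(a: Conformer, b: Conformer) -> ResiduePairing:
    """Pair two conformers by author residue number.

    Residues absent in either chain (typically unstructured loops in the
    lower-resolution structures) are excluded and listed.
    """
    set_a = set(a.residue_numbers)
    set_b = set(b.residue_numbers)
    common = sorted(set_a & set_b)
    if not common:
        raise ValueError(
            f"conformers {a.label} and {b.label} share no residue numbers"
        )
    return ResiduePairing(
        common=common,
        only_a=sorted(set_a - set_b),
        only_b=sorted(set_b - set_a),
    )


def paired_coords(
    a: Conformer, b: Conformer, mode: str = "calpha"
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Matched coordinate arrays of the two conformers for the atom mode."""
    xa = dict(select_atoms(a, mode))
    xb = dict(select_atoms(b, mode))
    common = [n for n in pair_residues(a, b).common if n in xa and n in xb]
    if not common:
        raise ValueError(
            f"conformers {a.label} and {b.label}: no shared residues with "
            f"{mode} atoms"
        )
    return (
        np.array([xa[n] for n in common]),
        np.array([xb[n] for n in common]),
        common,
    )


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _element_of(atom_name: str) -> str:
    stripped = atom_name.lstrip("0123456789")
    if stripped[:2] in ("CL", "BR", "FE", "ZN", "MG", "SE"):
        return stripped[:2]
    return stripped[0]


def write_structure(
    conf: Conformer,
    path: str | Path,
    scores: dict[int, float] | None = None,
) -> Path:
    """Write a conformer as fixed-column PDB ATOM records.

    If ``scores`` is given, the B-factor column of every atom of a scored
    residue is replaced by the residue score, clamped to
    ``[0, B_COLUMN_MAX]`` and rounded to 2 decimals; residues without a
    score keep their original B.  Scores for residue numbers absent from
    the chain are skipped with a warning.
    """
    path = Path(path)
    scores = dict(scores or {})
    present = set(conf.residue_numbers)
    for num in sorted(scores):
        if num not in present:
            logger.warning(
                "write_structure(%s): score for absent residue %d skipped",
                conf.label, num,
            )
            scores.pop(num)
        elif not np.isfinite(scores[num]):
            raise ValueError(f"score for residue {num} is not finite")
    lines = []
    serial = 0
    chain_id = "A"
    for res in conf.residues:
        for rec in res.atoms.values():
            chain_id = (rec.chain_id or "A")[0]
            break
        break
    for res in conf.residues:
        for rec in res.atoms.values():
            serial += 1
            b = scores.get(res.number, rec.b_factor)
            b = min(max(b, 0.0), B_COLUMN_MAX)
            element = _element_of(rec.atom_name)
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(rec.atom_name, element)}"
                f" {res.name:>3s} {chain_id}{res.number:4d}    "
                f"{rec.xyz[0]:8.3f}{rec.xyz[1]:8.3f}{rec.xyz[2]:8.3f}"
                f"{rec.occupancy:6.2f}{b:6.2f}          {element:>2s}"
            )
    lines.append(f"TER   {serial + 1:5d}      {conf.residues[-1].name:>3s} "
                 f"{chain_id}{conf.residues[-1].number:4d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_scored_structure(
    conf: Conformer, scores: dict[int, float], path: str | Path
) -> Path:
    """PDB copy of ``conf`` with the B column replaced by per-residue scores."""
    return write_structure(conf, path, scores=scores)
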