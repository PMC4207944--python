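"""Backbone torsion angles and inter-conformer angular displacements.

Computes per-residue phi/psi/omega torsions from N, CA, C coordinates
and the combined angular-displacement statistic between two conformers:
for each residue, the minimal circular differences of phi and psi are
combined as ``sqrt(d_phi^2 + d_psi^2)``, a per-residue summary of how
far the local backbone geometry has moved between two structures.

All angles are in degrees on (-180, 180]; displacements are in
[0, 180] per angle and [0, 180*sqrt(2)] combined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structure_io import Conformer


def torsion(p0, p1, p2, p3) -> float:
    """Torsion angle (degrees, (-180, 180]) of four points.

    Sign convention: looking down the p1->p2 bond, the angle from the
    p0 projection to the p3 projection, positive clockwise (IUPAC).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0:
        raise ValueError("degenerate torsion: coincident central atoms")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    deg = float(np.degrees(np.arctan2(y, x)))
    if deg <= -180.0:
        deg += 360.0
    return deg


def backbone_dihedrals(conf: Conformer) -> pd.DataFrame:
    """Per-residue phi/psi/omega table for a conformer.

    phi(i)   = C(i-1)-N(i)-CA(i)-C(i)
    psi(i)   = N(i)-CA(i)-C(i)-N(i+1)
    omega(i) = CA(i)-C(i)-N(i+1)-CA(i+1)

    Angles whose neighbouring residue is missing (chain break by
    residue numbering, or missing backbone atoms) are NaN.  The first
    residue has undefined phi and the last undefined psi/omega.
    """
    if len(conf) < 2:
        raise ValueError(f"conformer {conf.label}: need >= 2 residues for dihedrals")
    rows = []
    residues = conf.residues
    for i, res in enumerate(residues):
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i + 1 < len(residues) else None
        if prev_res is not None and prev_res.number != res.number - 1:
            prev_res = None
        if next_res is not None and next_res.number != res.number + 1:
            next_res = None
        n, ca, c = res.coord("N"), res.coord("CA"), res.coord("C")
        phi = psi = omega = np.nan
        if all(x is not None for x in (n, ca, c)):
            if prev_res is not None and prev_res.coord("C") is not None:
                phi = torsion(prev_res.coord("C"), n, ca, c)
            if next_res is not None and next_res.coord("N") is not None:
                psi = torsion(n, ca, c, next_res.coord("N"))
                if next_res.coord("CA") is not None:
                    omega = torsion(ca, c, next_res.coord("N"), next_res.coord("CA"))
        rows.append((res.number, res.one_letter, phi, psi, omega))
    table = pd.DataFrame(
        rows, columns=["residue_number", "residue", "phi", "psi", "omega"]
    ).set_index("residue_number")
    return table


def wrap_difference(a, b):
    """Minimal circular difference of two angles in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def angular_displacement(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Combined phi/psi displacement between two dihedral tables.

    Residues undefined (NaN phi or psi) in either table are omitted.
    ``combined = sqrt(d_phi^2 + d_psi^2)``.
    """
    common = a.index.intersection(b.index)
    sub_a = a.loc[common]
    sub_b = b.loc[common]
    defined = (
        sub_a["phi"].notna() & sub_a["psi"].notna()
        & sub_b["phi"].notna() & sub_b["psi"].notna()
    )
    if not defined.any():
        raise ValueError("no residues with defined phi/psi shared by both tables")
    sub_a = sub_a[defined]
    sub_b = sub_b[defined]
    d_phi = wrap_difference(sub_a["phi"], sub_b["phi"])
    d_psi = wrap_difference(sub_a["psi"], sub_b["psi"])
    return pd.DataFrame(
        {
            "d_phi": d_phi,
            "d_psi": d_psi,
            "combined": np.sqrt(d_phi**2 + d_psi**2),
        },
        index=sub_a.index,
    )


def classify_cis_trans(omega: float) -> str:
    """Classify a peptide bond by its omega torsion: |omega| < 90 -> cis."""
    if omega is None or (isinstance(omega, float) and np.isnan(omega)):
        return "undefined"
    return "cis" if abs(omega) < 90.0 else "trans"


def tm_displacement_summary(
    displacement: pd.DataFrame, tm_ranges: dict[str, tuple[int, int]]
) -> pd.DataFrame:
    """Aggregate combined displacement per transmembrane helix.

    Both the mean and the sum over each helix's residues are reported,
    since either may be the aggregate of interest.
    """
    rows = []
    for name, (start, stop) in tm_ranges.items():
        sel = displacement.loc[
            (displacement.index >= start) & (displacement.index <= stop), "combined"
        ]
        rows.append(
            (name, start, stop, len(sel),
             float(sel.mean()) if len(sel) else np.nan,
             float(sel.sum()) if len(sel) else np.nan)
        )
    return pd.DataFrame(
        rows, columns=["tm", "start", "stop", "n_residues", "mean_combined",
                       "sum_combined"]
    ).set_index("tm")
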