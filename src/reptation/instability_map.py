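"""Per-residue helical-instability score for 3D mapping.

Combines two normalised components: a running-window density of
helix-destabilizing residues (G, A, P, C, S, I, V) along the sequence,
and the crystallographic B-factor (thermal motion).  Each component is
scaled to [0, 1] over the chain and the two are summed, giving a score
in [0, 2] that can be written back into the B-factor column of a PDB
file for 3D visualisation.

Note the destabilizing set used for mapping (7 residues, including S
and I) is broader than the 5-residue set used for motif counting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deviation_analysis import running_average
from .structure_io import Conformer, write_scored_structure

#: Destabilizing residues for the instability map (broader, 7-residue set).
DESTABILIZING_MAP_SET = frozenset("GAPCSIV")


def density_profile(
    seq: str,
    residue_set: frozenset = DESTABILIZING_MAP_SET,
    window: int = 10,
) -> np.ndarray:
    """Running-window density of destabilizing residues along a sequence."""
    indicator = np.array([1.0 if c in residue_set else 0.0 for c in seq.upper()])
    return np.asarray(running_average(indicator, window))


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a constant column scales to all zeros."""
    values = np.asarray(values, dtype=float)
    span = np.nanmax(values) - np.nanmin(values)
    if span == 0 or not np.isfinite(span):
        return np.zeros_like(values)
    return (values - np.nanmin(values)) / span


def zscore_scale(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    sd = np.nanstd(values)
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(values)
    return (values - np.nanmean(values)) / sd


def combined_score(
    density, b_factors, scaling: str = "minmax"
) -> pd.DataFrame:
    """Sum of per-chain scaled density and scaled B-factor.

    Inputs must share their residue keys (both pandas Series with the
    same index, or equal-length arrays).  With min-max scaling the
    combined score lies in [0, 2].
    """
    if isinstance(density, pd.Series) and isinstance(b_factors, pd.Series):
        if not density.index.equals(b_factors.index):
            b_factors = b_factors.reindex(density.index)
        index = density.index
    else:
        density = np.asarray(density, dtype=float)
        b_factors = np.asarray(b_factors, dtype=float)
        if len(density) != len(b_factors):
            raise ValueError("density and b_factors must align")
        index = pd.RangeIndex(len(density))
    scale = {"minmax": minmax_scale, "zscore": zscore_scale}.get(scaling)
    if scale is None:
        raise ValueError(f"unknown scaling: {scaling!r}")
    dens = scale(np.asarray(density, dtype=float))
    sb = scale(np.asarray(b_factors, dtype=float))
    return pd.DataFrame(
        {"density": dens, "scaled_b": sb, "combined": dens + sb}, index=index
    )


def instability_profile(
    conf: Conformer,
    residue_set: frozenset = DESTABILIZING_MAP_SET,
    window: int = 10,
    scaling: str = "minmax",
) -> pd.DataFrame:
    """End-to-end instability profile of a conformer.

    The sequence density is computed over residues carrying a C-alpha
    (matching the conformer's sequence) and combined with the CA
    B-factor column.
    """
    residues = [r for r in conf.residues if "CA" in r.atoms]
    seq = "".join(r.one_letter for r in residues)
    numbers = [r.number for r in residues]
    dens = pd.Series(density_profile(seq, residue_set, window),
                     index=pd.Index(numbers, name="residue_number"))
    b = pd.Series(conf.b_factors("CA")).reindex(numbers)
    b.index.name = "residue_number"
    return combined_score(dens, b, scaling=scaling)


def write_instability_structure(
    conf: Conformer, profile: pd.DataFrame, path
) -> None:
    """Write the combined score into the B column of a PDB copy."""
    scores = {int(n): float(v) for n, v in profile["combined"].items()}
    write_scored_structure(conf, scores, path)
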