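"""Per-residue deviation statistics between transporter conformers.

Every conformer is rigidly superposed onto a common reference (by
default the inward-facing holo conformer) on its C-alpha trace; the
per-residue deviation is then the Euclidean distance between matched
atoms.  On top of the per-residue tables this module provides running
and maximal-deviation profiles, group statistics (e.g. inward- vs
outward-facing conformer sets), inter-conformer coordinate regressions,
least-squares Poisson fits to binned deviation distributions,
within-conformer residue-pair distances, and a membrane-axis zone
labelling (external / central / internal).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import superpose
from .structure_io import Conformer, paired_coords, select_atoms

#: Transmembrane helix ranges (author residue numbering) used for region
#: annotation.  These bundled defaults approximate the UniProt topology
#: annotation of the E. coli xylose transporter; override with a
#: two-column TSV (tm, start-stop) for other proteins or annotations.
DEFAULT_TM_RANGES: dict[str, tuple[int, int]] = {
    "TM1": (10, 30), "TM2": (55, 75), "TM3": (85, 105), "TM4": (110, 130),
    "TM5": (140, 160), "TM6": (162, 182), "TM7": (276, 296),
    "TM8": (304, 324), "TM9": (330, 350), "TM10": (368, 392),
    "TM11": (420, 445), "TM12": (450, 474),
}

#: Residue pairs spanning the central channel neck region whose
#: within-conformer distances are tabulated by the ``deviations`` recipe.
NECK_RESIDUE_PAIRS: list[tuple[int, int]] = [
    (298, 65), (168, 392), (392, 171), (24, 117), (24, 171), (24, 416),
]


@dataclass
class PoissonFitResult:
    """Least-squares fit of a scaled Poisson mass function to binned data."""

    lambda_hat: float          # rate converted to Angstrom via bin width
    empirical_mean: float      # mean of the raw deviations, Angstrom
    correlation_R: float       # Pearson R between fitted and observed freqs
    bin_width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.lambda_hat <= 0:
            raise ValueError("lambda_hat must be positive")
        if not -1.0 - 1e-12 <= self.correlation_R <= 1.0 + 1e-12:
            raise ValueError("correlation_R outside [-1, 1]")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pearson_R: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.pearson_R <= 1.0 + 1e-12:
            raise ValueError("pearson_R outside [-1, 1]")


def load_tm_ranges(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a TM-range table: lines of ``name<TAB>start<TAB>stop``."""
    out: dict[str, tuple[int, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, start, stop = line.split("\t")
        out[name] = (int(start), int(stop))
    return out


def superpose_onto(
    conf: Conformer, ref: Conformer, fit_mode: str = "kabsch"
) -> superpose.FitResult:
    """Fit ``conf``'s C-alpha trace onto ``ref``'s over paired residues."""
    moving, fixed, numbers = paired_coords(conf, ref, "calpha")
    return superpose.fit(moving, fixed, mode=fit_mode, residue_numbers=numbers)


def per_residue_deviation(
    conf: Conformer,
    ref: Conformer,
    atom_mode: str = "calpha",
    fit_mode: str = "kabsch",
) -> pd.Series:
    """Per-residue deviation (Angstrom) of ``conf`` vs ``ref``.

    The conformer is first superposed onto the reference on paired
    C-alpha atoms; deviations are then measured between the atoms of
    ``atom_mode`` ("calpha" or "distal").  Residues unpaired or missing
    the selected atom are absent from the result.
    """
    fit = superpose_onto(conf, ref, fit_mode=fit_mode)
    moving, fixed, numbers = paired_coords(conf, ref, atom_mode)
    dev = np.linalg.norm(fit.transform.apply(moving) - fixed, axis=1)
    return pd.Series(dev, index=pd.Index(numbers, name="residue_number"),
                     name=conf.label)


def deviation_table(
    conformers: list[Conformer],
    ref: Conformer,
    atom_mode: str = "calpha",
    fit_mode: str = "kabsch",
    tm_ranges: dict[str, tuple[int, int]] | None = None,
    zones: pd.Series | None = None,
) -> pd.DataFrame:
    """Deviation columns of several conformers vs one reference.

    Rows are residue numbers of the reference; a ``region`` column
    annotates TM helix / linker / termini and an optional ``zone``
    column carries the membrane-axis zone labels.
    """
    cols = {
        conf.label: per_residue_deviation(conf, ref, atom_mode, fit_mode)
        for conf in conformers
    }
    table = pd.DataFrame(cols)
    table.insert(
        0, "residue_name",
        [r.one_letter if (r := ref.residue(n)) is not None else "X"
         for n in table.index],
    )
    ranges = DEFAULT_TM_RANGES if tm_ranges is None else tm_ranges
    table["region"] = annotate_regions(table.index, ranges)
    if zones is not None:
        table["zone"] = zones.reindex(table.index)
    return table


def annotate_regions(
    residue_numbers, tm_ranges: dict[str, tuple[int, int]]
) -> list[str]:
    """Label residues as TM helix, linker, or N-/C-terminal tail."""
    starts = min(a for a, _ in tm_ranges.values())
    stops = max(b for _, b in tm_ranges.values())
    labels = []
    for num in residue_numbers:
        label = "linker"
        if num < starts:
            label = "N-term"
        elif num > stops:
            label = "C-term"
        for name, (a, b) in tm_ranges.items():
            if a <= num <= b:
                label = name
                break
        labels.append(label)
    return labels


def conformer_columns(table: pd.DataFrame) -> list[str]:
    """Names of the numeric per-conformer deviation columns of a table."""
    return [c for c in table.columns
            if c not in ("residue_name", "region", "zone")]


def running_average(series, window: int):
    """Centered moving mean with shrinking windows at the edges.

    The window for index ``i`` spans ``[i - (window-1)//2, i + window//2]``
    clipped to the series, so the output has the input's length.  A
    window longer than the series is an error.
    """
    values = np.asarray(series, dtype=float)
    n = len(values)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    left = (window - 1) // 2
    right = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - left)
        hi = min(n, i + right + 1)
        out[i] = np.nanmean(values[lo:hi])
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index, name=series.name)
    return out


def max_deviation_profile(
    table: pd.DataFrame, conformer_subset: list[str] | None = None
) -> pd.Series:
    """Per-residue maximum deviation across a subset of conformers."""
    cols = conformer_subset or conformer_columns(table)
    if not cols:
        raise ValueError("conformer subset is empty")
    return table[cols].max(axis=1).rename("max_deviation")


def top_deviating_residues(
    table: pd.DataFrame,
    n: int = 12,
    region_filter: list[str] | None = None,
) -> pd.DataFrame:
    """Rank residues by maximal deviation (optionally within regions)."""
    sub = table
    if region_filter is not None:
        sub = table[table["region"].isin(region_filter)]
    prof = max_deviation_profile(sub)
    ranked = prof.sort_values(ascending=False).head(n)
    out = pd.DataFrame({
        "residue_name": table.loc[ranked.index, "residue_name"],
        "region": table.loc[ranked.index, "region"],
        "max_deviation": ranked,
    })
    return out


def group_stats(
    table: pd.DataFrame,
    groups: dict[str, list[str]],
    region_filter: list[str] | None = None,
    zone_filter: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Group mean +/- SEM of per-conformer mean deviations, with Welch p.

    Each conformer is first summarised as its mean deviation over the
    selected residues; the group statistic is the mean of those
    summaries with the SEM over conformers.  For exactly two groups a
    Welch two-sample t-test p-value is returned (NaN otherwise or when
    a group has a single member).
    """
    labels = [lab for labs in groups.values() for lab in labs]
    if len(set(labels)) != len(labels):
        raise ValueError("groups must be disjoint")
    sub = table
    if region_filter is not None:
        sub = sub[sub["region"].isin(region_filter)]
    if zone_filter is not None:
        if "zone" not in sub.columns:
            raise ValueError("table has no zone annotation")
        sub = sub[sub["zone"].isin(zone_filter)]
    summaries: dict[str, list[float]] = {}
    rows = []
    for name, labs in groups.items():
        if not labs:
            raise ValueError(f"group {name!r} is empty")
        vals = [float(sub[lab].mean()) for lab in labs]
        summaries[name] = vals
        sem = float(stats.sem(vals)) if len(vals) > 1 else np.nan
        rows.append((name, len(vals), float(np.mean(vals)), sem))
    result = pd.DataFrame(
        rows, columns=["group", "n_conformers", "mean", "sem"]
    ).set_index("group")
    p_value = np.nan
    if len(groups) == 2:
        a, b = summaries.values()
        if len(a) > 1 and len(b) > 1:
            p_value = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return result, p_value


def coordinate_regression(
    conf_a: Conformer,
    conf_b: Conformer,
    ref: Conformer,
    residue_filter: list[int] | None = None,
    fit_mode: str = "kabsch",
) -> RegressionResult:
    """Linear regression between equivalent C-alpha coordinates.

    Both conformers are superposed onto the common reference frame;
    the x, y, z coordinates of their shared C-alpha atoms (optionally
    restricted to ``residue_filter``) are concatenated and regressed.
    """
    fit_a = superpose_onto(conf_a, ref, fit_mode)
    fit_b = superpose_onto(conf_b, ref, fit_mode)
    xa = {n: fit_a.transform.apply(x) for n, x in select_atoms(conf_a, "calpha")}
    xb = {n: fit_b.transform.apply(x) for n, x in select_atoms(conf_b, "calpha")}
    common = sorted(set(xa) & set(xb))
    if residue_filter is not None:
        wanted = set(residue_filter)
        common = [n for n in common if n in wanted]
    if len(common) < 10:
        raise ValueError(
            f"coordinate regression needs >= 10 paired residues, got {len(common)}"
        )
    flat_a = np.concatenate([xa[n] for n in common])
    flat_b = np.concatenate([xb[n] for n in common])
    res = stats.linregress(flat_a, flat_b)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_R=float(res.rvalue),
    )


def fit_poisson(
    deviations, bin_width: float = 0.25
) -> PoissonFitResult:
    """Least-squares fit of a scaled Poisson mass function to binned data.

    Deviations (Angstrom, >= 0) are histogrammed into bins of
    ``bin_width``; the normalised frequencies over bin index ``k`` are
    fitted with ``A * Poisson(k; lambda)``.  The returned rate is
    converted back to Angstrom (``lambda_index * bin_width``) and the
    Pearson correlation between fitted and observed frequencies is the
    goodness-of-fit measure.
    """
    values = np.asarray(deviations, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 30:
        raise ValueError("fit_poisson needs at least 30 values")
    if np.any(values < 0):
        raise ValueError("deviations must be non-negative")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all deviations identical")
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    freqs = counts / counts.sum()
    k = np.arange(n_bins, dtype=float)

    def model(k, amplitude, lam):
        return amplitude * stats.poisson.pmf(np.round(k).astype(int), lam)

    lam0 = max(values.mean() / bin_width, 0.1)
    popt, _ = optimize.curve_fit(
        model, k, freqs, p0=[1.0, lam0],
        bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=10000,
    )
    fitted = model(k, *popt)
    if np.ptp(fitted) == 0:
        corr = 0.0
    else:
        corr = float(stats.pearsonr(fitted, freqs).statistic)
    return PoissonFitResult(
        lambda_hat=float(popt[1] * bin_width),
        empirical_mean=float(values.mean()),
        correlation_R=corr,
        bin_width=bin_width,
        amplitude=float(popt[0]),
    )


def pair_distance(
    conf: Conformer, res_a: int, res_b: int, atom_mode: str = "calpha"
) -> float:
    """Euclidean distance between two residues' selected atoms.

    Measured in the conformer's own frame (no superposition).
    """
    coords = dict(select_atoms(conf, atom_mode))
    for num in (res_a, res_b):
        if num not in coords:
            raise ValueError(
                f"conformer {conf.label}: residue {num} missing or lacks "
                f"the {atom_mode} atom"
            )
    return float(np.linalg.norm(coords[res_a] - coords[res_b]))


def pair_distance_table(
    conformers: list[Conformer],
    pairs: list[tuple[int, int]] | None = None,
    atom_mode: str = "calpha",
) -> pd.DataFrame:
    """Residue-pair distance matrix over a set of conformers.

    Pairs missing in a conformer yield NaN rather than an error, since
    lower-resolution structures lack unstructured residues.
    """
    pairs = pairs or NECK_RESIDUE_PAIRS
    rows = {}
    for conf in conformers:
        row = {}
        for a, b in pairs:
            try:
                row[f"{a}-{b}"] = pair_distance(conf, a, b, atom_mode)
            except ValueError:
                row[f"{a}-{b}"] = np.nan
        rows[conf.label] = row
    return pd.DataFrame(rows).T


def zone_assign(
    ref: Conformer,
    axis=(0.0, 0.0, 1.0),
    fractions: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
    tm_ranges: dict[str, tuple[int, int]] | None = None,
) -> pd.Series:
    """Label residues external / central / internal along the membrane axis.

    C-alpha positions are projected onto ``axis``; the membrane span is
    the min..max projection of the TM residues (all residues if no TM
    table is given) and is cut at the two ``fractions``.  The band at
    the high-projection end is labelled "external".
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis must be non-zero")
    axis = axis / norm
    f1, f2 = fractions
    if not 0.0 <= f1 <= f2 <= 1.0:
        raise ValueError("fractions must satisfy 0 <= f1 <= f2 <= 1")
    coords = select_atoms(ref, "calpha")
    numbers = [n for n, _ in coords]
    proj = np.array([x @ axis for _, x in coords])
    span_proj = proj
    if tm_ranges is not None:
        regions = annotate_regions(numbers, tm_ranges)
        in_tm = np.array([r.startswith("TM") for r in regions])
        if in_tm.any():
            span_proj = proj[in_tm]
    lo, hi = float(span_proj.min()), float(span_proj.max())
    cut1 = lo + f1 * (hi - lo)
    cut2 = lo + f2 * (hi - lo)
    labels = np.where(proj < cut1, "internal",
                      np.where(proj > cut2, "external", "central"))
    return pd.Series(labels, index=pd.Index(numbers, name="residue_number"),
                     name="zone")
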