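"""Scanning protein sequences for F/W-bracketed destabilizing motifs.

Helix-destabilizing stretches are located with a PROSITE-style pattern:
an aromatic anchor (F or W), a gap of 2-10 arbitrary residues, and a
closing anchor, i.e. subsequences of length 4-12 that begin and end
with F or W.  Within the union of matched spans the occurrences of the
destabilizing residues A, G, P, V, C are counted per protein.  Cohort
count distributions are compared against composition-preserving shuffle
nulls and fitted with a two-component extreme-value (Gumbel) mixture

    S*l1*exp{-l1(x-m1) - exp(-l1(x-m1))} + (1-S)*l2*exp{-l2(x-m2) - exp(-l2(x-m2))}

whose mixture weight S measures the non-random sub-population.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Residues counted inside motif spans when building count distributions.
DESTABILIZING_COUNT_SET = frozenset("AGPVC")
#: Motif anchor residues.
DEFAULT_ANCHORS = frozenset("FW")

_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class MotifMatch:
    """One matched span, 0-based half-open indices."""

    start: int
    end: int
    span: str
    destabilizing_count: int

    def __post_init__(self) -> None:
        if not 4 <= len(self.span) <= 12:
            raise ValueError("motif span length outside [4, 12]")


@dataclass
class MixtureFit:
    """Fitted two-component Gumbel mixture parameters."""

    S: float
    lambda1: float
    mu1: float
    lambda2: float
    mu2: float
    correlation_R: float
    converged: bool
    sse: float

    def __post_init__(self) -> None:
        if self.converged:
            if not 0.0 <= self.S <= 1.0:
                raise ValueError("S outside [0, 1]")
            if self.lambda1 <= 0 or self.lambda2 <= 0:
                raise ValueError("rate parameters must be positive")


def _validate(seq: str) -> str:
    seq = seq.upper()
    bad = [i for i, c in enumerate(seq) if c not in _ALPHABET]
    if bad:
        shown = ", ".join(str(i) for i in bad[:10])
        raise ValueError(
            f"sequence contains non-standard residues at positions {shown}"
            + ("..." if len(bad) > 10 else "")
        )
    return seq


def find_motifs(
    seq: str,
    min_gap: int = 2,
    max_gap: int = 10,
    anchors: frozenset = DEFAULT_ANCHORS,
    mode: str = "leftmost_nonoverlapping",
) -> list[MotifMatch]:
    """Find anchor-bracketed spans with a gap of ``min_gap``-``max_gap``.

    ``leftmost_nonoverlapping`` (default) scans left to right, takes at
    each open anchor the shortest valid closing anchor and resumes after
    the match, so spans never overlap.  ``all_pairs`` enumerates every
    anchor pair with a gap in range (spans may overlap).
    """
    seq = _validate(seq)
    if not 0 <= min_gap <= max_gap:
        raise ValueError("need 0 <= min_gap <= max_gap")
    matches: list[MotifMatch] = []

    def emit(i: int, j: int) -> None:
        span = seq[i:j + 1]
        matches.append(MotifMatch(
            start=i, end=j + 1, span=span,
            destabilizing_count=sum(c in DESTABILIZING_COUNT_SET for c in span),
        ))

    if mode == "leftmost_nonoverlapping":
        i = 0
        n = len(seq)
        while i < n:
            if seq[i] in anchors:
                closed = False
                for j in range(i + min_gap + 1, min(i + max_gap + 1, n - 1) + 1):
                    if seq[j] in anchors:
                        emit(i, j)
                        i = j + 1
                        closed = True
                        break
                if closed:
                    continue
            i += 1
    elif mode == "all_pairs":
        anchor_pos = [i for i, c in enumerate(seq) if c in anchors]
        for a_idx, i in enumerate(anchor_pos):
            for j in anchor_pos[a_idx + 1:]:
                gap = j - i - 1
                if gap > max_gap:
                    break
                if gap >= min_gap:
                    emit(i, j)
    else:
        raise ValueError(f"unknown scan mode: {mode!r}")
    return matches


def destabilizing_count(
    seq: str,
    matches: list[MotifMatch],
    residue_set: frozenset = DESTABILIZING_COUNT_SET,
) -> int:
    """Destabilizing residues inside the union of matched spans.

    Overlapping spans are merged first, so every position counts once.
    """
    seq = _validate(seq)
    covered = np.zeros(len(seq), dtype=bool)
    for m in matches:
        covered[m.start:m.end] = True
    return int(sum(1 for i in np.flatnonzero(covered) if seq[i] in residue_set))


def group_count(
    seq: str,
    min_gap: int = 2,
    max_gap: int = 10,
    anchors: frozenset = DEFAULT_ANCHORS,
    mode: str = "leftmost_nonoverlapping",
    residue_set: frozenset = DESTABILIZING_COUNT_SET,
) -> int:
    """Per-protein destabilizing-group count (scan + union count)."""
    matches = find_motifs(seq, min_gap, max_gap, anchors, mode)
    return destabilizing_count(seq, matches, residue_set)


def shuffle_seq(seq: str, rng: np.random.Generator | int | None = None) -> str:
    """Uniform random permutation of a sequence (composition preserved)."""
    rng = np.random.default_rng(rng)
    chars = np.array(list(seq))
    return "".join(rng.permutation(chars))


def count_distribution(group_counts) -> pd.Series:
    """Normalised frequency of each integer count value."""
    counts = pd.Series(group_counts, dtype=int)
    if counts.empty:
        raise ValueError("no counts given")
    dist = counts.value_counts(normalize=True).sort_index()
    dist.index.name = "X"
    return dist.rename("probability")


def gumbel_density(x, lam, mu):
    """Gumbel (extreme-value) density with rate ``lam`` and location ``mu``."""
    z = lam * (np.asarray(x, dtype=float) - mu)
    # far left tail: -z - exp(-z) -> -inf; clamp the exponent to avoid overflow
    exponent = -z - np.exp(np.minimum(-z, 700.0))
    return lam * np.exp(np.maximum(exponent, -745.0))


def gumbel_mixture_density(x, S, lam1, mu1, lam2, mu2):
    return S * gumbel_density(x, lam1, mu1) + (1.0 - S) * gumbel_density(x, lam2, mu2)


def fit_double_gumbel(
    hist: pd.Series,
    init: tuple[float, float, float, float, float] | None = None,
) -> MixtureFit:
    """Nonlinear least-squares fit of the Gumbel mixture to a histogram.

    ``hist`` maps integer count values to probabilities.  Unless an
    explicit ``init`` (S, lam1, mu1, lam2, mu2) is given, a multistart
    grid is used: S in {0.25, 0.5, 0.75}, locations at the histogram
    quartiles, rates in {0.1, 0.3, 1.0}; the best SSE wins.  Components
    are ordered so that mu1 <= mu2.
    """
    hist = hist.dropna()
    if len(hist) < 6:
        raise ValueError("mixture fit needs >= 6 support points")
    x = hist.index.to_numpy(dtype=float)
    y = hist.to_numpy(dtype=float)

    def residuals(theta):
        return gumbel_mixture_density(x, *theta) - y

    cdf = np.cumsum(y) / y.sum()
    quart = [float(x[np.searchsorted(cdf, q)]) for q in (0.25, 0.5, 0.75)]
    if init is not None:
        starts = [list(init)]
    else:
        starts = []
        mu_pairs = [(quart[0], quart[1]), (quart[0], quart[2]), (quart[1], quart[2])]
        for S0 in (0.25, 0.5, 0.75):
            for mu1, mu2 in mu_pairs:
                for lam1 in (0.1, 0.3, 1.0):
                    for lam2 in (0.1, 0.3, 1.0):
                        starts.append([S0, lam1, mu1, lam2, mu2])
    spread = float(np.ptp(x))
    lower = [0.0, 1e-6, x.min() - spread, 1e-6, x.min() - spread]
    upper = [1.0, 50.0, x.max() + spread, 50.0, x.max() + spread]
    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lower, upper)
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lower, upper), max_nfev=2000
            )
        except ValueError:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        return MixtureFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.nan, converged=False, sse=np.nan)
    sse, res = best
    S, lam1, mu1, lam2, mu2 = res.x
    if mu2 < mu1:  # order components by location
        S, lam1, mu1, lam2, mu2 = 1.0 - S, lam2, mu2, lam1, mu1
    fitted = gumbel_mixture_density(x, S, lam1, mu1, lam2, mu2)
    if np.ptp(fitted) == 0 or np.ptp(y) == 0:
        corr = 0.0
    else:
        corr = float(stats.pearsonr(fitted, y).statistic)
    return MixtureFit(
        S=float(S), lambda1=float(lam1), mu1=float(mu1),
        lambda2=float(lam2), mu2=float(mu2),
        correlation_R=corr, converged=bool(res.success), sse=sse,
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Minimal multi-record FASTA reader returning (id, sequence) pairs."""
    records: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                records.append((name, "".join(chunks)))
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def scan_cohort(
    records: list[tuple[str, str]],
    min_gap: int = 2,
    max_gap: int = 10,
    mode: str = "leftmost_nonoverlapping",
    n_shuffles: int = 0,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Scan a cohort of sequences; optionally build a shuffle null.

    Returns per-protein counts (both match counts and destabilizing
    group counts), the cohort count distribution, and, if requested,
    the pooled distribution over ``n_shuffles`` composition-preserving
    shuffles of every sequence.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for name, seq in records:
        matches = find_motifs(seq, min_gap, max_gap, mode=mode)
        rows.append((
            name, len(seq), len(matches),
            destabilizing_count(seq, matches),
        ))
    per_protein = pd.DataFrame(
        rows, columns=["id", "length", "n_matches", "group_count"]
    ).set_index("id")
    out = {
        "per_protein": per_protein,
        "distribution": count_distribution(per_protein["group_count"]),
    }
    if n_shuffles > 0:
        null_counts = []
        for _, seq in records:
            for _ in range(n_shuffles):
                null_counts.append(
                    group_count(shuffle_seq(seq, rng), min_gap, max_gap, mode=mode)
                )
        out["null_distribution"] = count_distribution(null_counts)
    return out
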