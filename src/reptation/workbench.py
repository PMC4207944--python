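"""End-to-end analysis recipes, configuration and report writing.

Each recipe ties the analysis modules into one reproducible report
bundle of TSV tables (deviation profiles, dihedral displacements, motif
statistics, instability maps, gate simulations).  Reports are
deterministic for a given config + seed and carry a ``#``-prefixed
provenance header (package version, config hash, seed).

Recipes run either on real structures (a directory of PDB files with
the conformer label map) or, with no input directory, on synthetic
fixtures whose generator parameters encode the study conditions:
an inward-facing group with larger displacement scales than the
outward-facing group, and apo conformers more mobile than occluded
ones within the helices.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    deviation_analysis as dev,
    dihedral_analysis as dih,
    gated_transport as gt,
    instability_map as im,
    motif_scan as ms,
    synthetic_data as synth,
)
from .structure_io import Conformer, read_structure

logger = logging.getLogger("reptation")

#: chain -> conformer label, per source file stem (lower-cased).
DEFAULT_CONFORMER_MAP: dict[str, dict[str, str]] = {
    "4gby": {"A": "4GBY"},
    "4gbz": {"A": "4GBZ"},
    "4gc0": {"A": "4GC0"},
    "4ja3": {"A": "3a", "B": "3b"},
    "4ja4": {"A": "4a", "B": "4b", "C": "4c"},
}

#: Conformer groups used throughout the reports.
INWARD_GROUP = ["3b", "4a", "4b", "4c"]
OUTWARD_GROUP = ["4GBY", "4GBZ", "4GC0"]
APO_GROUP = ["4a", "4b", "4c"]
OCCLUDED_GROUP = ["3b", "4GBY", "4GBZ"]  # occluded non-reference conformers

#: Displacement scales (Angstrom) of the synthetic study ensemble.
SYNTHETIC_GROUP_SCALES = {
    "3b": {"helix": 0.6, "linker": 2.2},
    "4a": {"helix": 1.3, "linker": 3.0},
    "4b": {"helix": 1.3, "linker": 3.0},
    "4c": {"helix": 1.3, "linker": 3.0},
    "4GBY": {"helix": 0.35, "linker": 1.0},
    "4GBZ": {"helix": 0.35, "linker": 1.0},
    "4GC0": {"helix": 0.35, "linker": 1.0},
}

RECIPES = ("deviations", "dihedrals", "motifscan", "instability", "gates", "all")


@dataclass
class RunConfig:
    """Knobs of a reproduction run; all have documented defaults."""

    reference: str = "3a"
    pdb_dir: str | None = None        # None -> synthetic fixtures
    fasta: str | None = None          # None -> synthetic cohort
    out_dir: str = "reports"
    seed: int = 0
    atom_mode: str = "calpha"
    fit_mode: str = "kabsch"
    bin_width: float = 0.25           # Poisson-fit bin width, Angstrom
    profile_window: int = 4           # running-average window (deviation maps)
    density_window: int = 10          # running-average window (instability)
    zone_fractions: tuple = (1.0 / 3.0, 2.0 / 3.0)
    motif_mode: str = "leftmost_nonoverlapping"
    min_gap: int = 2
    max_gap: int = 10
    n_shuffles: int = 1
    n_sequences: int = 300            # synthetic cohort size
    tm_table: str | None = None       # TSV path; None -> bundled defaults
    gate_k1_values: tuple = (1.0e6, 1.0e8)
    gate_cycles: int = 50

    def tm_ranges(self) -> dict[str, tuple[int, int]]:
        if self.tm_table is not None:
            return dev.load_tm_ranges(self.tm_table)
        return dict(dev.DEFAULT_TM_RANGES)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # output location does not affect results
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def parse_config(path: str | Path) -> RunConfig:
    """Read a plain-text ``key = value`` config file into a RunConfig."""
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        raw = raw.strip()
        if key not in fields:
            raise ValueError(f"unknown config key: {key!r}")
        anno = fields[key].type
        if raw.lower() in ("none", ""):
            kwargs[key] = None
        elif key in ("zone_fractions", "gate_k1_values"):
            kwargs[key] = tuple(float(x) for x in raw.split(","))
        elif "int" in str(anno):
            kwargs[key] = int(raw)
        elif "float" in str(anno):
            kwargs[key] = float(raw)
        else:
            kwargs[key] = raw
    return RunConfig(**kwargs)


def write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, title: str) -> Path:
    from . import __version__
    header = (
        f"# reptation {__version__} | report: {title} | "
        f"config {config.config_hash()} | seed {config.seed}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", float_format="%.6g")
    return path


# ---------------------------------------------------------------------------
# input loading

def load_conformers(config: RunConfig) -> tuple[Conformer, dict[str, Conformer]]:
    """Reference conformer and all labelled conformers.

    With a ``pdb_dir``, every recognised PDB file is read and chains
    are renamed through the conformer label map.  Without one, the
    synthetic study ensemble is generated from the seed.
    """
    if config.pdb_dir is None:
        return synthetic_study_ensemble(config.seed)
    pdb_dir = Path(config.pdb_dir)
    files = sorted(pdb_dir.glob("*.pdb")) + sorted(pdb_dir.glob("*.ent"))
    if not files:
        raise FileNotFoundError(f"no PDB files found in {pdb_dir}")
    conformers: dict[str, Conformer] = {}
    for path in files:
        stem = path.stem.lower()
        label_map = DEFAULT_CONFORMER_MAP.get(stem, {})
        for conf in read_structure(path, label_map=label_map):
            conformers[conf.label] = conf
    if config.reference not in conformers:
        raise FileNotFoundError(
            f"reference conformer {config.reference!r} not among loaded labels "
            f"{sorted(conformers)}")
    ref = conformers[config.reference]
    return ref, conformers


def synthetic_study_ensemble(
    seed: int,
) -> tuple[Conformer, dict[str, Conformer]]:
    """Synthetic eight-conformer ensemble emulating the study conditions."""
    spec = synth.EnsembleSpec(seed=seed, n_conformers=1)
    ref = make_reference(seed)
    rng = np.random.default_rng(seed)
    conformers: dict[str, Conformer] = {"3a": ref}
    for label, scales in SYNTHETIC_GROUP_SCALES.items():
        member_spec = dataclasses.replace(
            spec,
            displacement={
                "helix": ("exponential", scales["helix"]),
                "linker": ("exponential", scales["linker"]),
            },
        )
        members, _ = synth.perturb_ensemble(ref, member_spec, rng=rng,
                                            labels=[label])
        conformers[label] = members[0]
    return ref, conformers


def make_reference(seed: int) -> Conformer:
    spec = synth.EnsembleSpec(seed=seed)
    return synth.make_helix_bundle(spec, label="3a")


def synthetic_tm_ranges() -> dict[str, tuple[int, int]]:
    return synth.EnsembleSpec().tm_ranges()


# ---------------------------------------------------------------------------
# recipes

def run_recipe(name: str, config: RunConfig) -> dict[str, Path]:
    """Run one named recipe (or ``all``) and return the written reports."""
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; choose from {RECIPES}")
    if name == "all":
        out = {}
        for sub in RECIPES[:-1]:
            out.update(run_recipe(sub, config))
        return out
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return {
        "deviations": _recipe_deviations,
        "dihedrals": _recipe_dihedrals,
        "motifscan": _recipe_motifscan,
        "instability": _recipe_instability,
        "gates": _recipe_gates,
    }[name](config, out_dir)


def _tm_ranges_for(config: RunConfig) -> dict[str, tuple[int, int]]:
    if config.pdb_dir is None and config.tm_table is None:
        return synthetic_tm_ranges()
    return config.tm_ranges()


def _recipe_deviations(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    ref, conformers = load_conformers(config)
    others = [c for label, c in conformers.items() if label != ref.label]
    tm_ranges = _tm_ranges_for(config)
    zones = dev.zone_assign(ref, fractions=config.zone_fractions,
                            tm_ranges=tm_ranges)
    table = dev.deviation_table(others, ref, atom_mode="calpha",
                                fit_mode=config.fit_mode,
                                tm_ranges=tm_ranges, zones=zones)
    distal = dev.deviation_table(others, ref, atom_mode="distal",
                                 fit_mode=config.fit_mode,
                                 tm_ranges=tm_ranges, zones=zones)
    cols = dev.conformer_columns(table)
    max_prof = dev.max_deviation_profile(table)
    profile = pd.DataFrame({
        "max_deviation": max_prof,
        f"running_{config.profile_window}mer":
            dev.running_average(max_prof, config.profile_window),
    })
    groups = {
        "inward": [c for c in INWARD_GROUP if c in cols],
        "outward": [c for c in OUTWARD_GROUP if c in cols],
    }
    stats_all, p_all = dev.group_stats(table, groups)
    stats_all["comparison"] = "all_residues"
    stats_all["welch_p"] = p_all
    central = [r for r in table["region"].unique() if r.startswith("TM")]
    apo_occ = {
        "apo": [c for c in APO_GROUP if c in cols],
        "occluded": [c for c in OCCLUDED_GROUP if c in cols],
    }
    stats_tm, p_tm = dev.group_stats(table, apo_occ, region_filter=central,
                                     zone_filter=["central"])
    stats_tm["comparison"] = "central_tm"
    stats_tm["welch_p"] = p_tm
    group_report = pd.concat([stats_all, stats_tm])

    central_tm_residues = [
        int(n) for n in table.index
        if str(table.loc[n, "region"]).startswith("TM")
        and table.loc[n, "zone"] == "central"
    ]
    reg_rows = []
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    for a, b in pairs:
        try:
            res = dev.coordinate_regression(conformers[a], conformers[b], ref,
                                            residue_filter=central_tm_residues,
                                            fit_mode=config.fit_mode)
        except ValueError:
            continue
        reg_rows.append((a, b, res.slope, res.intercept, res.pearson_R))
    regressions = pd.DataFrame(
        reg_rows, columns=["conf_a", "conf_b", "slope", "intercept", "pearson_R"]
    )

    fits = []
    for group_name, labels in groups.items():
        if not labels:
            continue
        values = table[labels].to_numpy().ravel()
        values = values[~np.isnan(values)]
        try:
            fit = dev.fit_poisson(values, bin_width=config.bin_width)
            fits.append((group_name, fit.lambda_hat, fit.empirical_mean,
                         fit.correlation_R, fit.bin_width))
        except (ValueError, RuntimeError):
            logger.warning("Poisson fit failed for group %s", group_name)
    poisson = pd.DataFrame(
        fits, columns=["group", "lambda_A", "mean_A", "pearson_R", "bin_width"]
    ).set_index("group")

    pair_list = dev.NECK_RESIDUE_PAIRS
    if config.pdb_dir is None:
        nums = ref.residue_numbers
        pair_list = [(nums[0], nums[len(nums) // 2]),
                     (nums[len(nums) // 4], nums[3 * len(nums) // 4]),
                     (nums[0], nums[-1])]
    distances = dev.pair_distance_table(list(conformers.values()), pair_list)

    top = dev.top_deviating_residues(
        table, n=12,
        region_filter=[r for r in table["region"].unique() if r.startswith("TM")],
    )

    return {
        "deviation_calpha": write_tsv(table, out_dir / "deviation_calpha.tsv",
                                      config, "per-residue CA deviations"),
        "deviation_distal": write_tsv(distal, out_dir / "deviation_distal.tsv",
                                      config, "per-residue distal side-chain deviations"),
        "profile_max": write_tsv(profile, out_dir / "profile_max.tsv",
                                 config, "maximal deviation profile"),
        "group_stats": write_tsv(group_report, out_dir / "group_stats.tsv",
                                 config, "group dispersion statistics"),
        "regressions": write_tsv(regressions, out_dir / "regressions.tsv",
                                 config, "inter-conformer coordinate regressions"),
        "poisson_fits": write_tsv(poisson, out_dir / "poisson_fits.tsv",
                                  config, "Poisson fits to deviation distributions"),
        "pair_distances": write_tsv(distances, out_dir / "pair_distances.tsv",
                                    config, "channel neck residue-pair distances"),
        "top_residues": write_tsv(top, out_dir / "top_residues.tsv",
                                  config, "largest TM C-alpha deviations"),
    }


def _recipe_dihedrals(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    ref, conformers = load_conformers(config)
    tm_ranges = _tm_ranges_for(config)
    ref_table = dih.backbone_dihedrals(ref)
    dihedral_frames = []
    disp_frames = []
    tm_frames = []
    for label, conf in conformers.items():
        table = dih.backbone_dihedrals(conf)
        t = table.copy()
        t.insert(0, "conformer", label)
        dihedral_frames.append(t)
        if label == ref.label:
            continue
        disp = dih.angular_displacement(table, ref_table)
        d = disp.copy()
        d.insert(0, "conformer", label)
        disp_frames.append(d)
        summary = dih.tm_displacement_summary(disp, tm_ranges)
        summary.insert(0, "conformer", label)
        tm_frames.append(summary)
    return {
        "dihedrals": write_tsv(pd.concat(dihedral_frames),
                               out_dir / "dihedrals.tsv", config,
                               "backbone phi/psi/omega"),
        "angular_displacement": write_tsv(pd.concat(disp_frames),
                                          out_dir / "angular_displacement.tsv",
                                          config, "combined phi/psi displacement"),
        "tm_displacement": write_tsv(pd.concat(tm_frames),
                                     out_dir / "tm_displacement.tsv", config,
                                     "per-TM angular displacement"),
    }


def _recipe_motifscan(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    if config.fasta is not None:
        records = ms.read_fasta(config.fasta)
    else:
        spec = synth.SequenceCohortSpec(n_sequences=config.n_sequences,
                                        min_gap=config.min_gap,
                                        max_gap=config.max_gap,
                                        seed=config.seed)
        records, _ = synth.synth_sequences(spec)
    rng = np.random.default_rng(config.seed)
    result = ms.scan_cohort(records, config.min_gap, config.max_gap,
                            mode=config.motif_mode,
                            n_shuffles=config.n_shuffles, rng=rng)
    dist = result["distribution"]
    outputs = {
        "motif_counts": write_tsv(result["per_protein"],
                                  out_dir / "motif_counts.tsv", config,
                                  "per-protein motif and group counts"),
        "count_distribution": write_tsv(dist.to_frame(),
                                        out_dir / "count_distribution.tsv",
                                        config, "destabilizing-group count distribution"),
    }
    if "null_distribution" in result:
        outputs["null_distribution"] = write_tsv(
            result["null_distribution"].to_frame(),
            out_dir / "null_distribution.tsv", config,
            "shuffle-null count distribution")
    try:
        fit = ms.fit_double_gumbel(dist)
        fit_df = pd.DataFrame([dataclasses.asdict(fit)])
    except ValueError:
        fit_df = pd.DataFrame()
    outputs["mixture_fit"] = write_tsv(fit_df, out_dir / "mixture_fit.tsv",
                                       config, "double-Gumbel mixture fit")
    return outputs


def _recipe_instability(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    ref, conformers = load_conformers(config)
    if config.pdb_dir is None:
        # synthetic reference carries no measured B; derive it from the ensemble
        b = synth.assign_bfactors(list(conformers.values()), reference=ref)
        for res in ref.residues:
            if res.number in b.index:
                for rec in res.atoms.values():
                    rec.b_factor = float(b.loc[res.number])
    profile = im.instability_profile(ref, window=config.density_window)
    pdb_path = out_dir / "instability_map.pdb"
    im.write_instability_structure(ref, profile, pdb_path)
    return {
        "instability_profile": write_tsv(profile,
                                         out_dir / "instability_profile.tsv",
                                         config, "combined instability score"),
        "instability_map": pdb_path,
    }


def _recipe_gates(config: RunConfig, out_dir: Path) -> dict[str, Path]:
    model = gt.GateChannelModel()
    comparison = gt.phase_comparison(model, k1_values=config.gate_k1_values,
                                     n_cycles=config.gate_cycles)
    sim = gt.simulate(model, n_cycles=max(20, config.gate_cycles // 2))
    series = pd.DataFrame({
        "t": sim.t, "V1": sim.V1, "B1": sim.B1,
        "V2": sim.V2, "B2": sim.B2, "flux": sim.flux,
    }).set_index("t")
    return {
        "gate_phase_comparison": write_tsv(comparison,
                                           out_dir / "gate_phase_comparison.tsv",
                                           config, "in-phase vs antiphase net flux"),
        "gate_timeseries": write_tsv(series, out_dir / "gate_timeseries.tsv",
                                     config, "gated-channel trajectories"),
    }
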