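"""Per-state analysis orchestration: one config in, one state report out.

Mirrors the per-ligand-state workflow of the underlying study
(prepowerstroke / ADP-bound / rigor): load the replica ensembles and
their boost logs, compute the configured collective variables, estimate
densities and reweighted free-energy profiles, label basins, cluster
the ensemble, measure RMSD to a reference structure, and write a
machine-readable report with full provenance.

The stages run in a fixed order and the report is deterministic: the
same config over the same inputs reproduces it byte-for-byte apart from
the single timestamp field.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, geometry, reweighting
from .errors import ComparisonError, ConfigError
from .geometry import AtomAnchor
from .io import (
    Ensemble,
    MotifDefinition,
    attach_boost,
    read_boost_log,
    read_pdb_ensemble,
)

logger = logging.getLogger("motorscape.pipeline")

__all__ = [
    "AnalysisConfig",
    "StateReport",
    "load_config",
    "validate_config",
    "run_state_analysis",
    "compare_states",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Validated per-state analysis configuration.

    Built from a YAML document (see :func:`load_config`); every
    cross-reference (motif names in CV definitions, CV names in 2D
    profile requests, file paths) has been resolved by
    :func:`validate_config` before an instance exists.
    """

    state_label: str
    ensemble_paths: list[Path]
    boost_paths: list[Path] = field(default_factory=list)
    boost_dialect: str = "two_column"
    boost_column: int | None = None
    motifs: dict[str, MotifDefinition] = field(default_factory=dict)
    distance_cvs: list[dict] = field(default_factory=list)
    angle_cvs: list[dict] = field(default_factory=list)
    contact_cvs: list[dict] = field(default_factory=list)
    profiles_2d: list[tuple[str, str]] = field(default_factory=list)
    temperature: float = 300.0
    cumulant_order: int = 2
    bins_1d: int = 50
    bins_2d: int = 40
    min_count: int = 20
    basin_depth_threshold: float = 0.5
    cluster_selection: str | None = None
    cluster_cutoff: float = 2.0
    reference_path: Path | None = None
    reference_fit: str | None = None
    reference_measure: str | None = None
    output_dir: Path = Path("motorscape_out")
    contact_probe: float = 1.4
    contact_points: int = 960


def _parse_motifs(raw: dict) -> dict[str, MotifDefinition]:
    motifs = {}
    for name, entry in (raw or {}).items():
        filt = entry.get("filter", "all")
        if isinstance(filt, list):
            filt = tuple(str(x) for x in filt)
        motifs[str(name)] = MotifDefinition(
            name=str(name),
            chain_id=str(entry["chain"]),
            residue_range=(int(entry["range"][0]), int(entry["range"][1])),
            atom_filter=filt,
        )
    return motifs


def validate_config(raw: dict) -> tuple[AnalysisConfig | None, list[str]]:
    """Validate a raw config mapping, reporting every error at once.

    Returns ``(config, [])`` on success or ``(None, errors)`` where
    ``errors`` collects all problems found, not only the first.
    """
    errors: list[str] = []
    if not isinstance(raw, dict):
        return None, ["config document must be a mapping"]
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        errors.append(f"unsupported schema_version {version} (expected {SCHEMA_VERSION})")

    state_label = str(raw.get("state_label", "custom"))
    paths = [Path(p) for p in raw.get("ensemble_paths", [])]
    if not paths:
        errors.append("ensemble_paths must list at least one file")
    for p in paths:
        if not p.exists():
            errors.append(f"ensemble file not found: {p}")

    boost = raw.get("boost", {}) or {}
    boost_paths = [Path(p) for p in boost.get("paths", [])]
    for p in boost_paths:
        if not p.exists():
            errors.append(f"boost log not found: {p}")
    dialect = boost.get("dialect", "two_column")
    if dialect not in ("two_column", "amber_gamd"):
        errors.append(f"unknown boost dialect {dialect!r}")
    boost_column = boost.get("boost_column")
    if dialect == "amber_gamd" and boost_column is None:
        errors.append("boost dialect 'amber_gamd' requires boost_column")
    if boost_paths and len(boost_paths) != len(paths):
        errors.append(
            f"{len(boost_paths)} boost logs for {len(paths)} ensemble files; "
            "counts must match"
        )

    try:
        motifs = _parse_motifs(raw.get("motifs", {}))
    except Exception as exc:  # malformed motif entry
        motifs = {}
        errors.append(f"bad motif definition: {exc}")

    cv_names: set[str] = set()
    distance_cvs = []
    for entry in raw.get("distance_cvs", []) or []:
        name = entry.get("name")
        if not name:
            errors.append("distance CV without a name")
            continue
        ok = True
        for side in ("a", "b"):
            if side not in entry:
                errors.append(f"distance CV {name!r}: missing anchor {side!r}")
                ok = False
        if ok:
            distance_cvs.append(entry)
            cv_names.add(name)

    angle_cvs = []
    for entry in raw.get("angle_cvs", []) or []:
        name = entry.get("name")
        if not name:
            errors.append("angle CV without a name")
            continue
        ok = True
        for side in ("elem1", "elem2"):
            motif = entry.get(side)
            if motif not in motifs:
                errors.append(
                    f"angle CV {name!r}: undefined motif {motif!r}"
                )
                ok = False
        if ok:
            angle_cvs.append(entry)
            cv_names.add(name)

    contact_cvs = []
    for entry in raw.get("contact_cvs", []) or []:
        name = entry.get("name")
        if not name:
            errors.append("contact CV without a name")
            continue
        ok = True
        for side in ("group_a", "group_b"):
            motif = entry.get(side)
            if motif not in motifs:
                errors.append(
                    f"contact CV {name!r}: undefined motif {motif!r}"
                )
                ok = False
        if ok:
            contact_cvs.append(entry)
            cv_names.add(name)

    profiles_2d = []
    for entry in raw.get("profiles_2d", []) or []:
        cv1, cv2 = entry.get("cv1"), entry.get("cv2")
        for cv in (cv1, cv2):
            if cv not in cv_names:
                errors.append(f"2D profile references undefined CV {cv!r}")
        if cv1 in cv_names and cv2 in cv_names:
            profiles_2d.append((cv1, cv2))

    clustering = raw.get("clustering", {}) or {}
    cluster_selection = clustering.get("selection")
    if cluster_selection is not None and cluster_selection not in motifs:
        errors.append(
            f"clustering references undefined motif {cluster_selection!r}"
        )

    reference = raw.get("reference", {}) or {}
    reference_path = Path(reference["path"]) if "path" in reference else None
    if reference_path is not None and not reference_path.exists():
        errors.append(f"reference structure not found: {reference_path}")
    for key in ("fit_selection", "measure_selection"):
        motif = reference.get(key)
        if motif is not None and motif not in motifs:
            errors.append(f"reference {key} references undefined motif {motif!r}")

    rw = raw.get("reweighting", {}) or {}
    order = int(rw.get("cumulant_order", 2))
    if order not in (1, 2, 3):
        errors.append(f"cumulant_order must be 1, 2 or 3, got {order}")
    temperature = float(raw.get("temperature", 300.0))
    if temperature <= 0:
        errors.append("temperature must be positive")

    if errors:
        return None, errors
    config = AnalysisConfig(
        state_label=state_label,
        ensemble_paths=paths,
        boost_paths=boost_paths,
        boost_dialect=dialect,
        boost_column=boost_column,
        motifs=motifs,
        distance_cvs=distance_cvs,
        angle_cvs=angle_cvs,
        contact_cvs=contact_cvs,
        profiles_2d=profiles_2d,
        temperature=temperature,
        cumulant_order=order,
        bins_1d=int(rw.get("bins_1d", 50)),
        bins_2d=int(rw.get("bins_2d", 40)),
        min_count=int(rw.get("min_count", 20)),
        basin_depth_threshold=float(rw.get("basin_depth_threshold", 0.5)),
        cluster_selection=cluster_selection,
        cluster_cutoff=float(clustering.get("cutoff", 2.0)),
        reference_path=reference_path,
        reference_fit=reference.get("fit_selection"),
        reference_measure=reference.get("measure_selection"),
        output_dir=Path(raw.get("output_dir", "motorscape_out")),
        contact_probe=float(raw.get("contact_probe", 1.4)),
        contact_points=int(raw.get("contact_points", 960)),
    )
    return config, []


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate a YAML analysis config; raise on any error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    config, errors = validate_config(raw)
    if errors:
        raise ConfigError(
            f"{path}: {len(errors)} config error(s):\n  " + "\n  ".join(errors)
        )
    return config


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class StateReport:
    """Analysis results for one state, serializable to JSON + CSVs."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True)

    def without_timestamp(self) -> dict:
        clean = dict(self.data)
        clean.pop("generated_at", None)
        return clean

    @classmethod
    def from_json(cls, path: str | Path) -> "StateReport":
        with open(path) as fh:
            return cls(data=json.load(fh))


def _to_builtin(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_builtin(obj.tolist())
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _profile_record(profile: reweighting.FreeEnergyProfile,
                    basins: reweighting.BasinSet) -> dict:
    rec = {
        "dims": profile.dims,
        "cv_names": list(profile.cv_names),
        "temperature": profile.temperature,
        "cumulant_order": profile.cumulant_order,
        "n_frames": profile.n_frames(),
        "pmf_min": float(np.nanmin(profile.pmf)),
        "masked_bin_fraction": float(profile.mask.mean()),
        "basins": [
            {
                "label": b.label,
                "bin_index": list(b.bin_index),
                "pmf_value": b.pmf_value,
                "cv_coordinates": list(b.cv_coordinates),
            }
            for b in basins
        ],
    }
    return rec


def _profile_frame(profile: reweighting.FreeEnergyProfile) -> pd.DataFrame:
    centers = profile.bin_centers
    if profile.dims == 1:
        return pd.DataFrame(
            {
                "center_0": centers[0],
                "pmf": profile.pmf,
                "count": profile.counts,
                "masked": profile.mask,
            }
        )
    g0, g1 = np.meshgrid(centers[0], centers[1], indexing="ij")
    return pd.DataFrame(
        {
            "center_0": g0.ravel(),
            "center_1": g1.ravel(),
            "pmf": profile.pmf.ravel(),
            "count": profile.counts.ravel(),
            "masked": profile.mask.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(name: str, **params):
    logger.info("stage=%s status=start %s", name,
                " ".join(f"{k}={v}" for k, v in params.items()))


def _stage_done(name: str):
    logger.info("stage=%s status=end", name)


def run_state_analysis(config: AnalysisConfig,
                       write_outputs: bool = True) -> StateReport:
    """Execute the per-state pipeline under one validated config.

    Stage order is fixed: load → pair boosts → CVs → densities/peaks →
    1D/2D PMFs → basins → clustering → reference RMSD → report. A
    failure in any stage aborts with the stage named in the exception.
    """
    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "state_label": config.state_label,
        "generated_at": datetime.now(timezone.utc).isoformat(),
        "provenance": {
            "inputs": {
                str(p): _file_sha256(p)
                for p in list(config.ensemble_paths) + list(config.boost_paths)
            },
            "temperature_K": config.temperature,
            "cumulant_order": config.cumulant_order,
            "bins_1d": config.bins_1d,
            "bins_2d": config.bins_2d,
            "min_count": config.min_count,
        },
        "cv_summaries": {},
        "profiles_1d": {},
        "profiles_2d": {},
        "skipped": {},
    }
    profile_frames: dict[str, pd.DataFrame] = {}

    def stage(name, fn, *args, **kwargs):
        _stage(name, **{k: v for k, v in kwargs.pop("log", {}).items()})
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc
        _stage_done(name)
        return result

    # --- load ensembles ------------------------------------------------
    def load() -> Ensemble:
        parts = []
        for i, path in enumerate(config.ensemble_paths):
            ens = read_pdb_ensemble(path, state_label=config.state_label)
            if config.boost_paths:
                logs = read_boost_log(
                    config.boost_paths[i],
                    dialect=config.boost_dialect,
                    boost_column=config.boost_column,
                )
                ens = attach_boost(ens, logs)
            parts.append(ens)
        if len(parts) == 1:
            ensemble = parts[0]
        elif config.boost_paths:
            ensemble = reweighting.combine_replicas(parts)
        else:
            ensemble = Ensemble(
                topology=parts[0].topology,
                coordinates=np.concatenate([p.coordinates for p in parts]),
                replica_id=np.concatenate(
                    [np.full(p.n_frames, r) for r, p in enumerate(parts)]
                ),
                state_label=config.state_label,
            )
        return ensemble

    ensemble = stage("load", load,
                     log={"files": len(config.ensemble_paths)})
    report["n_frames"] = ensemble.n_frames
    dv = ensemble.boost_dV if ensemble.boost_dV is not None \
        else np.zeros(ensemble.n_frames)

    # --- collective variables ------------------------------------------
    def compute_cvs() -> dict[str, geometry.CVSeries]:
        series: dict[str, geometry.CVSeries] = {}
        for entry in config.distance_cvs:
            a, b = entry["a"], entry["b"]
            cv = geometry.distance_cv(
                ensemble,
                AtomAnchor(str(a["chain"]), int(a["residue"]),
                           str(a.get("atom", "CA"))),
                AtomAnchor(str(b["chain"]), int(b["residue"]),
                           str(b.get("atom", "CA"))),
                name=entry["name"],
            )
            series[entry["name"]] = cv
        for entry in config.angle_cvs:
            cv = geometry.crossing_angle(
                ensemble,
                config.motifs[entry["elem1"]],
                config.motifs[entry["elem2"]],
            )
            cv.name = entry["name"]
            series[entry["name"]] = cv
        for entry in config.contact_cvs:
            cv = geometry.contact_area(
                ensemble,
                config.motifs[entry["group_a"]],
                config.motifs[entry["group_b"]],
                probe=config.contact_probe,
                n_points=config.contact_points,
            )
            cv.name = entry["name"]
            series[entry["name"]] = cv
        return series

    cvs = stage("collective_variables", compute_cvs,
                log={"n_cv": len(config.distance_cvs)
                     + len(config.angle_cvs) + len(config.contact_cvs)})

    # --- densities, peaks, summaries ------------------------------------
    def summarize() -> None:
        boosted = ensemble.boost_dV is not None
        for name, cv in cvs.items():
            weights = None
            if boosted:
                weights = reweighting.reweight_factors(
                    cv, dv, temperature=config.temperature,
                    bins=config.bins_1d,
                    cumulant_order=config.cumulant_order,
                )
            most_probable, mean, sd = analysis.state_summary(cv, weights=weights)
            curve = analysis.density_1d(cv, weights=weights)
            peaks = analysis.find_peaks_1d(curve)
            report["cv_summaries"][name] = {
                "unit": cv.unit,
                "most_probable": most_probable,
                "mean": mean,
                "sd": sd,
                "reweighted": boosted,
                "peaks": [
                    {"position": p.position, "density": p.density,
                     "prominence": p.prominence}
                    for p in peaks
                ],
                "bandwidth": peaks.bandwidth,
            }

    stage("densities", summarize)

    # --- free-energy profiles -------------------------------------------
    def profiles() -> None:
        for name, cv in cvs.items():
            try:
                prof = reweighting.pmf_1d(
                    cv, dv, temperature=config.temperature,
                    bins=config.bins_1d,
                    cumulant_order=config.cumulant_order,
                    min_count=config.min_count,
                )
            except reweighting.EmptyProfileError as exc:
                report["skipped"][f"pmf_1d:{name}"] = str(exc)
                continue
            basins = reweighting.find_basins(
                prof, depth_threshold=config.basin_depth_threshold
            )
            report["profiles_1d"][name] = _profile_record(prof, basins)
            profile_frames[f"pmf1d_{name}"] = _profile_frame(prof)
        for cv1, cv2 in config.profiles_2d:
            key = f"{cv1}__{cv2}"
            try:
                prof = reweighting.pmf_2d(
                    cvs[cv1], cvs[cv2], dv,
                    temperature=config.temperature,
                    bins=config.bins_2d,
                    cumulant_order=config.cumulant_order,
                    min_count=config.min_count,
                )
            except reweighting.EmptyProfileError as exc:
                report["skipped"][f"pmf_2d:{key}"] = str(exc)
                continue
            basins = reweighting.find_basins(
                prof, depth_threshold=config.basin_depth_threshold
            )
            report["profiles_2d"][key] = _profile_record(prof, basins)
            profile_frames[f"pmf2d_{key}"] = _profile_frame(prof)

    stage("free_energy_profiles", profiles)

    # --- clustering ------------------------------------------------------
    def cluster() -> None:
        if config.cluster_selection is None:
            report["skipped"]["clustering"] = "no clustering selection configured"
            return
        matrix = analysis.pairwise_rmsd_matrix(
            ensemble, config.motifs[config.cluster_selection]
        )
        result = analysis.cluster_leader(matrix, cutoff=config.cluster_cutoff)
        report["clusters"] = {
            "cutoff": result.cutoff,
            "selection": config.cluster_selection,
            "populations": result.populations.tolist(),
            "centroid_frames": result.centroid_frames.tolist(),
            "assignment": result.assignment.tolist(),
        }

    stage("clustering", cluster)

    # --- reference RMSD ---------------------------------------------------
    def reference_rmsd() -> None:
        if config.reference_path is None:
            report["skipped"]["reference_rmsd"] = "no reference configured"
            return
        ref = read_pdb_ensemble(config.reference_path).frame(0)
        fit = config.motifs[config.reference_fit]
        measure = config.motifs[config.reference_measure or config.reference_fit]
        cv = geometry.rmsd_series(ensemble, ref, fit, measure)
        report["reference_rmsd"] = {
            "reference": str(config.reference_path),
            "fit_selection": config.reference_fit,
            "measure_selection": measure.name,
            "mean": float(cv.values.mean()),
            "min": float(cv.values.min()),
            "max": float(cv.values.max()),
        }

    stage("reference_rmsd", reference_rmsd)

    state_report = StateReport(data=_to_builtin(report))

    if write_outputs:
        def write() -> None:
            out = config.output_dir
            out.mkdir(parents=True, exist_ok=True)
            (out / f"report_{config.state_label}.json").write_text(
                state_report.to_json() + "\n"
            )
            for key, frame in profile_frames.items():
                frame.to_csv(out / f"{key}.csv", index=False)
            cv_frame = pd.DataFrame(
                {"frame": np.arange(ensemble.n_frames)}
                | {name: cv.values for name, cv in cvs.items()}
            )
            cv_frame.to_csv(out / "cv_series.csv", index=False)

        stage("write_report", write, log={"dir": config.output_dir})

    return state_report


# ---------------------------------------------------------------------------
# State comparison
# ---------------------------------------------------------------------------

def compare_states(report_a: StateReport, report_b: StateReport) -> dict:
    """Per-CV deltas between two state reports (b minus a).

    Compares most-probable values of shared CVs and, for shared 2D
    profiles, the shift of the global-minimum basin along each
    coordinate — the way one quantifies, e.g., a cleft-width closure
    between two ligand states.
    """
    cvs_a = report_a.data.get("cv_summaries", {})
    cvs_b = report_b.data.get("cv_summaries", {})
    shared = sorted(set(cvs_a) & set(cvs_b))
    if not shared:
        raise ComparisonError("reports share no collective variables")
    table: dict = {
        "state_a": report_a.data.get("state_label"),
        "state_b": report_b.data.get("state_label"),
        "cv_deltas": {},
        "basin_shifts": {},
    }
    for name in shared:
        table["cv_deltas"][name] = {
            "most_probable_a": cvs_a[name]["most_probable"],
            "most_probable_b": cvs_b[name]["most_probable"],
            "delta": cvs_b[name]["most_probable"] - cvs_a[name]["most_probable"],
        }
    prof_a = report_a.data.get("profiles_2d", {})
    prof_b = report_b.data.get("profiles_2d", {})
    for key in sorted(set(prof_a) & set(prof_b)):
        basins_a = prof_a[key].get("basins", [])
        basins_b = prof_b[key].get("basins", [])
        if not basins_a or not basins_b:
            continue
        m1_a = basins_a[0]["cv_coordinates"]
        m1_b = basins_b[0]["cv_coordinates"]
        table["basin_shifts"][key] = {
            "m1_a": m1_a,
            "m1_b": m1_b,
            "delta": [b - a for a, b in zip(m1_a, m1_b)],
        }
    return table
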