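"""Read and write conformational ensembles and boost-potential logs.

The on-disk carriers are deliberately plain: multi-model PDB
(MODEL/ENDMDL, wwPDB v3.3 fixed columns) for coordinates and small
ASCII logs for the per-frame GaMD boost potential ΔV (kcal/mol).
In memory an ensemble is a single topology shared by a stack of
coordinate frames, which is the invariant every downstream collective
variable relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import (
    BoostLogError,
    FormatError,
    InputError,
    ParseError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "Topology",
    "StructureModel",
    "Ensemble",
    "MotifDefinition",
    "BoostLog",
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_boost_log",
    "resolve_selection",
    "load_motifs",
    "attach_boost",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Topology:
    """Per-atom identity shared by all frames of an ensemble.

    Residue numbers follow the author numbering of the input file
    verbatim; no renumbering is performed, so motif anchors defined in
    a publication's numbering (e.g. V406, K542) select the intended
    atoms.
    """

    atom_serial: np.ndarray      # int
    atom_name: np.ndarray        # str, stripped PDB atom name ("CA", "NZ", ...)
    residue_name: np.ndarray     # str, 3-letter
    residue_number: np.ndarray   # int, author numbering
    chain_id: np.ndarray         # str, single char
    element: np.ndarray          # str, upper case ("C", "N", "H", ...)
    occupancy: np.ndarray        # float

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def atom_keys(self) -> list[tuple[str, int, str]]:
        """(chain, residue_number, atom_name) identity sequence."""
        return list(
            zip(self.chain_id.tolist(), self.residue_number.tolist(),
                self.atom_name.tolist())
        )


@dataclass(frozen=True)
class StructureModel:
    """One conformation: a topology plus one set of coordinates in Å."""

    topology: Topology
    coordinates: np.ndarray  # (n_atoms, 3) float64, Å

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (self.topology.n_atoms, 3):
            raise InputError(
                f"coordinates shape {coords.shape} does not match "
                f"{self.topology.n_atoms} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise InputError("coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)


@dataclass
class Ensemble:
    """Ordered frames sharing one topology, with per-frame metadata.

    ``boost_dV`` is either ``None`` (unboosted ensemble) or an array of
    per-frame GaMD boost potentials in kcal/mol — never partially set.
    """

    topology: Topology
    coordinates: np.ndarray                 # (n_frames, n_atoms, 3), Å
    replica_id: np.ndarray | None = None    # int per frame
    state_label: str = "custom"
    boost_dV: np.ndarray | None = None      # kcal/mol per frame, or None

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise InputError(f"expected (frames, atoms, 3) coordinates, got {coords.shape}")
        if coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"coordinate atom count {coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if not np.all(np.isfinite(coords)):
            raise InputError("coordinates must be finite")
        self.coordinates = coords
        if self.replica_id is None:
            self.replica_id = np.zeros(coords.shape[0], dtype=int)
        else:
            self.replica_id = np.asarray(self.replica_id, dtype=int)
            if len(self.replica_id) != coords.shape[0]:
                raise InputError("replica_id length must equal frame count")
        if self.boost_dV is not None:
            self.boost_dV = np.asarray(self.boost_dV, dtype=float)
            if len(self.boost_dV) != coords.shape[0]:
                raise BoostLogError(
                    f"boost record count {len(self.boost_dV)} does not match "
                    f"frame count {coords.shape[0]}"
                )

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def frame(self, i: int) -> StructureModel:
        return StructureModel(self.topology, self.coordinates[i])

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class MotifDefinition:
    """A named contiguous residue range on one chain, with an atom filter.

    ``atom_filter`` is ``"all"``, ``"heavy"`` (excludes element H),
    ``"CA"``, or an explicit list of atom names.
    """

    name: str
    chain_id: str
    residue_range: tuple[int, int]
    atom_filter: str | Sequence[str] = "all"

    def __post_init__(self):
        start, end = self.residue_range
        if start > end:
            raise InputError(
                f"motif {self.name!r}: residue range start {start} > end {end}"
            )


@dataclass(frozen=True)
class BoostLog:
    """One boost-potential record: frame index (0-based) and ΔV ≥ 0."""

    frame_index: int
    dV: float  # kcal/mol


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, raw_name: str) -> str:
    """Element from PDB atom-name columns when cols 77-78 are blank.

    A name starting in column 13 with a digit (e.g. ``1HB``) is a
    hydrogen variant; otherwise the first alphabetic character wins,
    except two-letter elements left-justified into column 13.
    """
    stripped = atom_name.strip()
    if not stripped:
        return ""
    # Names like "1HB2" or "HG11": hydrogens
    first = stripped[0]
    if first.isdigit():
        for ch in stripped:
            if ch.isalpha():
                return ch.upper()
        return ""
    # Two-character element codes occupy column 13 (raw_name[0] non-blank)
    if len(raw_name) >= 2 and raw_name[0] != " " and stripped[:2].upper() in (
        "FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "SE", "CU", "NI", "CO"
    ) and not stripped[:1] in ("C", "N", "O", "H", "S", "P"):
        return stripped[:2].upper()
    return first.upper()


def _parse_atom_line(line: str, lineno: int) -> dict:
    try:
        serial = int(line[6:11])
        raw_name = line[12:16]
        name = raw_name.strip()
        altloc = line[16:17].strip()
        resname = line[17:20].strip()
        chain = line[21:22]
        resseq = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise ParseError(f"unparseable ATOM record at line {lineno}: {exc}") from exc
    if icode:
        raise ParseError(
            f"insertion code {icode!r} at line {lineno} is not supported"
        )
    if not element:
        element = _infer_element(name, raw_name)
    return dict(
        serial=serial, name=name, altloc=altloc, resname=resname,
        chain=chain, resseq=resseq, xyz=(x, y, z),
        occupancy=occupancy, element=element,
    )


def _resolve_altloc(atoms: list[dict]) -> list[dict]:
    """Keep one location per (chain, residue, atom name).

    The location with the highest occupancy wins; ties break to the
    lexicographically smallest altloc identifier.
    """
    best: dict[tuple, dict] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom["chain"], atom["resseq"], atom["name"])
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            cur = best[key]
            if (atom["occupancy"], _altloc_rank(atom["altloc"])) > (
                cur["occupancy"], _altloc_rank(cur["altloc"])
            ):
                best[key] = atom
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # Higher rank wins on occupancy ties: smaller altloc letter ranks higher.
    if not altloc:
        return 0.0
    return -ord(altloc[0])


def read_pdb_ensemble(path: str | Path, state_label: str = "custom") -> Ensemble:
    """Read a multi-model PDB file into an :class:`Ensemble`.

    One frame per ``MODEL``/``ENDMDL`` block; a file without MODEL
    records is a single implicit model. All models must agree on atom
    count and on the (chain, residue number, atom name) sequence.
    Alternate locations are resolved to the highest-occupancy copy.

    Raises
    ------
    ParseError
        On an unparseable ATOM/HETATM record (message carries the line
        number) or an insertion code (unsupported).
    TopologyError
        When a model disagrees with the first model's topology; the
        message names the first mismatching model.
    """
    path = Path(path)
    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    saw_model_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model_record = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                models.append(current)
                in_model = False
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno))
    if current or (not saw_model_record and not models):
        if current:
            models.append(current)
    if not models or not models[0]:
        raise ParseError(f"{path}: no ATOM records found")

    resolved = [_resolve_altloc(m) for m in models]
    ref = resolved[0]
    ref_keys = [(a["chain"], a["resseq"], a["name"]) for a in ref]
    for i, model in enumerate(resolved[1:], start=2):
        keys = [(a["chain"], a["resseq"], a["name"]) for a in model]
        if len(model) != len(ref):
            raise TopologyError(
                f"{path}: model {i} has {len(model)} atoms, model 1 has {len(ref)}"
            )
        if keys != ref_keys:
            raise TopologyError(
                f"{path}: model {i} atom identity differs from model 1"
            )

    topology = Topology(
        atom_serial=np.array([a["serial"] for a in ref], dtype=int),
        atom_name=np.array([a["name"] for a in ref], dtype=object),
        residue_name=np.array([a["resname"] for a in ref], dtype=object),
        residue_number=np.array([a["resseq"] for a in ref], dtype=int),
        chain_id=np.array([a["chain"] for a in ref], dtype=object),
        element=np.array([a["element"] for a in ref], dtype=object),
        occupancy=np.array([a["occupancy"] for a in ref], dtype=float),
    )
    coords = np.array(
        [[a["xyz"] for a in model] for model in resolved], dtype=float
    )
    return Ensemble(topology=topology, coordinates=coords, state_label=state_label)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def write_pdb_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (wwPDB v3.3 fixed columns).

    Coordinates are written at the format's fixed-point precision
    (%8.3f), so a write/read round trip reproduces them to ≤ 5e-4 Å.
    """
    if ensemble.n_frames == 0 or ensemble.n_atoms == 0:
        raise InputError("cannot write an empty ensemble")
    top = ensemble.topology
    lines: list[str] = []
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i in range(top.n_atoms):
            x, y, z = ensemble.coordinates[f, i]
            for v in (x, y, z):
                if not (-1000.0 < v < 10000.0):
                    raise FormatError(
                        f"coordinate {v:.3f} Å not representable in PDB "
                        "fixed columns"
                    )
            name = top.atom_name[i]
            # PDB convention: 1-3 char names start in column 14
            padded = f" {name:<3s}" if len(name) < 4 else name[:4]
            elem = top.element[i][:2]
            lines.append(
                f"ATOM  {top.atom_serial[i] % 100000:5d} {padded:<4s} "
                f"{top.residue_name[i]:<3s} {top.chain_id[i]:1s}"
                f"{top.residue_number[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{top.occupancy[i]:6.2f}{0.0:6.2f}"
                f"          {elem:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Boost logs
# ---------------------------------------------------------------------------

def read_boost_log(
    path: str | Path,
    dialect: str = "two_column",
    boost_column: int | None = None,
) -> list[BoostLog]:
    """Read a per-frame boost-potential log.

    Dialects
    --------
    ``two_column``
        Whitespace-separated ``<frame:int> <dV:float>`` per line,
        ``#`` comment lines allowed. Frame indices must be strictly
        increasing 0-based integers.
    ``amber_gamd``
        ``#``-prefixed header lines are skipped; each remaining line is
        whitespace-separated numeric columns and ``boost_column`` (0-based,
        required — never guessed) selects the total boost energy. Frame
        index is the data-row order.

    Negative ΔV values are clamped to zero; values below −1e-6 kcal/mol
    additionally emit a warning (GaMD boosts are nonnegative, but logs
    may carry numerical noise near zero).
    """
    path = Path(path)
    records: list[BoostLog] = []
    if dialect == "two_column":
        expected = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                parts = stripped.split()
                if len(parts) < 2:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 'frame dV'"
                    )
                try:
                    idx = int(parts[0])
                    dv = float(parts[1])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from exc
                if idx != expected:
                    raise BoostLogError(
                        f"{path}: line {lineno}: frame index {idx} is "
                        f"non-monotone or duplicated (expected {expected})"
                    )
                expected += 1
                records.append(BoostLog(idx, _clamp_dv(dv, path, lineno)))
    elif dialect == "amber_gamd":
        if boost_column is None:
            raise InputError(
                "dialect 'amber_gamd' requires boost_column (0-based index "
                "of the total boost energy column)"
            )
        frame = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                parts = stripped.split()
                if boost_column >= len(parts):
                    raise ParseError(
                        f"{path}: line {lineno}: boost_column {boost_column} "
                        f"out of range ({len(parts)} columns)"
                    )
                try:
                    dv = float(parts[boost_column])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from exc
                records.append(BoostLog(frame, _clamp_dv(dv, path, lineno)))
                frame += 1
    else:
        raise InputError(f"unsupported boost-log dialect {dialect!r}")
    return records


def _clamp_dv(dv: float, path: Path, lineno: int) -> float:
    if dv < 0.0:
        if dv < -1e-6:
            warnings.warn(
                f"{path}: line {lineno}: negative boost {dv:g} kcal/mol "
                "clamped to 0",
                stacklevel=3,
            )
        return 0.0
    return dv


def attach_boost(
    ensemble: Ensemble, logs: Iterable[BoostLog] | np.ndarray
) -> Ensemble:
    """Pair boost records with an ensemble, enforcing equal counts."""
    if isinstance(logs, np.ndarray):
        dv = np.asarray(logs, dtype=float)
    else:
        dv = np.array([r.dV for r in logs], dtype=float)
    if len(dv) != ensemble.n_frames:
        raise BoostLogError(
            f"boost log has {len(dv)} records but ensemble has "
            f"{ensemble.n_frames} frames"
        )
    return replace(ensemble, boost_dV=dv)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def resolve_selection(ensemble: Ensemble, motif: MotifDefinition) -> np.ndarray:
    """Resolve a motif to sorted atom indices against the topology.

    The selection is purely topological, so it is identical for every
    frame of the ensemble. An empty result raises
    :class:`SelectionError` naming the motif.
    """
    top = ensemble.topology
    if motif.chain_id not in set(top.chain_id.tolist()):
        raise SelectionError(
            f"motif {motif.name!r}: chain {motif.chain_id!r} not in topology"
        )
    start, end = motif.residue_range
    mask = (
        (top.chain_id == motif.chain_id)
        & (top.residue_number >= start)
        & (top.residue_number <= end)
    )
    filt = motif.atom_filter
    if isinstance(filt, str):
        if filt == "all":
            pass
        elif filt == "heavy":
            mask &= top.element != "H"
        elif filt == "CA":
            mask &= top.atom_name == "CA"
        else:
            raise InputError(
                f"motif {motif.name!r}: unknown atom filter {filt!r}"
            )
    else:
        mask &= np.isin(top.atom_name.astype(str), list(filt))
    indices = np.nonzero(mask)[0]
    if len(indices) == 0:
        raise SelectionError(
            f"motif {motif.name!r}: selection is empty "
            f"(chain {motif.chain_id}, residues {start}-{end}, "
            f"filter {filt!r})"
        )
    return indices


def load_motifs(path: str | Path) -> dict[str, MotifDefinition]:
    """Load motif definitions from a YAML config file.

    Schema: a mapping of motif name to
    ``{chain: <char>, range: [start, end], filter: all|heavy|CA|[names]}``.
    ``filter`` defaults to ``all``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InputError(f"{path}: motif config must be a mapping")
    motifs: dict[str, MotifDefinition] = {}
    for name, entry in raw.items():
        try:
            chain = str(entry["chain"])
            rng = entry["range"]
            start, end = int(rng[0]), int(rng[1])
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            raise InputError(f"{path}: motif {name!r}: {exc}") from exc
        filt = entry.get("filter", "all")
        if isinstance(filt, list):
            filt = tuple(str(x) for x in filt)
        motifs[name] = MotifDefinition(
            name=str(name), chain_id=chain,
            residue_range=(start, end), atom_filter=filt,
        )
    return motifs
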