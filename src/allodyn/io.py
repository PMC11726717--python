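"""Topology, trajectory and assay-table readers.

Coordinates are Å throughout.  Residue numbers follow the author (PDB)
numbering of the input file and are the canonical residue key; optional
Ballesteros–Weinstein (BW) labels are an overlay attached from a sidecar
CSV, never a primary key.  Atom indices are 0-based and contiguous.

Only the PDB / DCD / XTC dialects without insertion codes or alternate
locations are supported; anything else fails loudly rather than guessing.
"""

from __future__ import annotations

import csv
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Topology",
    "Trajectory",
    "Selection",
    "DoseResponseDataset",
    "TopologyError",
    "TrajectoryError",
    "SelectionError",
    "read_topology",
    "read_trajectory",
    "read_bw_map",
    "select",
    "read_dose_response",
]


class TopologyError(ValueError):
    """Raised for unparseable or unsupported topology files."""


class TrajectoryError(ValueError):
    """Raised for unreadable trajectories or atom-count mismatches."""


class SelectionError(ValueError):
    """Raised for selection expressions that cannot be resolved."""


@dataclass(frozen=True)
class Topology:
    """Atom metadata for one molecular system.

    Arrays are per-atom and share the same length.  ``bw_map`` maps a
    Ballesteros–Weinstein label such as ``"7.44"`` to an author residue
    number.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    bw_map: dict[str, int] | None = None
    source: Path | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        for arr in (self.elements, self.resids, self.resnames, self.chains):
            if len(arr) != n:
                raise TopologyError("per-atom arrays must share one length")
        if self.bw_map:
            resid_set = set(int(r) for r in self.resids)
            for label, resid in self.bw_map.items():
                if resid not in resid_set:
                    raise TopologyError(
                        f"BW label {label!r} maps to residue {resid}, "
                        "which is absent from the topology"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue numbers in order of first appearance."""
        _, idx = np.unique(self.resids, return_index=True)
        return self.resids[np.sort(idx)]

    def bw_resid(self, label: str) -> int:
        if not self.bw_map:
            raise SelectionError("topology carries no Ballesteros–Weinstein map")
        try:
            return self.bw_map[label]
        except KeyError:
            raise SelectionError(f"no residue mapped to BW label {label!r}") from None

    def heavy_mask(self) -> np.ndarray:
        """Boolean per-atom mask excluding hydrogens."""
        elem = np.char.upper(self.elements.astype(str))
        return elem != "H"


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates bound to a topology.

    ``coordinates`` has shape ``(n_frames, n_atoms, 3)`` in Å.
    """

    topology: Topology
    coordinates: np.ndarray
    replica: int = 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"frame atom count {self.coordinates.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not np.isfinite(self.coordinates).all():
            raise TrajectoryError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class Selection:
    """A resolved atom selection: expression plus 0-based atom indices."""

    expression: str
    indices: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


@dataclass
class DoseResponseDataset:
    """Tidy concentration–response table.

    Columns: ``agonist``, ``agonist_concentration`` (M, > 0),
    ``modulator_concentration`` (M, 0 = vehicle), ``response`` (assay
    units), ``replicate``.  A boolean ``vehicle`` column flags rows at
    zero modulator.
    """

    table: pd.DataFrame

    REQUIRED = (
        "agonist",
        "agonist_concentration",
        "modulator_concentration",
        "response",
        "replicate",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"dose–response table missing columns: {missing}")
        t = self.table
        for col in ("agonist_concentration", "modulator_concentration", "response"):
            vals = pd.to_numeric(t[col], errors="coerce")
            if vals.isna().any():
                bad = t.index[vals.isna()][0]
                raise ValueError(f"non-numeric value in column {col!r} at row {bad}")
            self.table[col] = vals.astype(float)
        if (self.table["agonist_concentration"] <= 0).any():
            raise ValueError("agonist concentrations must be strictly positive")
        if (self.table["modulator_concentration"] < 0).any():
            raise ValueError("modulator concentrations must be non-negative")
        if not np.isfinite(self.table["response"]).all():
            raise ValueError("responses must be finite")
        self.table = self.table.assign(
            vehicle=self.table["modulator_concentration"] == 0.0
        )

    @property
    def n_replicates(self) -> int:
        return self.table["replicate"].nunique()

    def to_csv(self, path: str | Path) -> None:
        self.table.drop(columns=["vehicle"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PDB topology reading


_PDB_RECORD = re.compile(r"^(ATOM  |HETATM)")


def _scan_pdb(path: Path) -> None:
    """Enforce the supported PDB dialect before handing off to MDAnalysis.

    Rejects insertion codes and alternate locations, and flags records
    whose coordinate fields do not parse, naming the offending line.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not _PDB_RECORD.match(line):
                continue
            if len(line.rstrip("\n")) < 54:
                raise TopologyError(f"{path}:{lineno}: truncated ATOM/HETATM record")
            if line[16] not in (" ", "A"):
                raise TopologyError(
                    f"{path}:{lineno}: alternate location {line[16]!r} unsupported"
                )
            if line[26] != " ":
                raise TopologyError(
                    f"{path}:{lineno}: insertion code {line[26]!r} unsupported "
                    "(this dialect is not handled)"
                )
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
                int(line[22:26])
            except ValueError:
                raise TopologyError(
                    f"{path}:{lineno}: malformed ATOM/HETATM record"
                ) from None


def read_bw_map(path: str | Path) -> dict[str, int]:
    """Read a ``residue_number,bw`` sidecar CSV into a BW-label map."""
    mapping: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() in ("residue_number", "resid"):
                continue
            resid, label = int(row[0]), row[1].strip()
            if label in mapping and mapping[label] != resid:
                raise TopologyError(f"BW label {label!r} mapped to two residues")
            mapping[label] = resid
    return mapping


def read_topology(path: str | Path, bw_map: str | Path | dict | None = None) -> Topology:
    """Read a PDB topology, optionally attaching a BW sidecar map."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise TopologyError(f"topology file not found: {path}")
    _scan_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    atoms = u.atoms
    try:
        elements = atoms.elements.astype(str)
    except (AttributeError, mda.exceptions.NoDataError):
        # fall back to the leading letter of the atom name
        elements = np.array([re.sub(r"[^A-Za-z].*", "", n)[:1] for n in atoms.names])
    try:
        chains = atoms.chainIDs.astype(str)
    except (AttributeError, mda.exceptions.NoDataError):
        chains = np.array([str(s) for s in atoms.segids])
    mapping = bw_map
    if isinstance(bw_map, (str, Path)):
        mapping = read_bw_map(bw_map)
    return Topology(
        names=atoms.names.astype(str),
        elements=elements,
        resids=atoms.resids.astype(int),
        resnames=atoms.resnames.astype(str),
        chains=chains,
        bw_map=mapping,
        source=path,
    )


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    topology: Topology,
    replica: int = 0,
) -> Trajectory:
    """Read one replica from one or more DCD/XTC files, concatenated in order."""
    from MDAnalysis.coordinates.DCD import DCDReader
    from MDAnalysis.coordinates.XTC import XTCReader

    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames: list[np.ndarray] = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise TrajectoryError(f"trajectory file not found: {p}")
        suffix = p.suffix.lower()
        if suffix == ".dcd":
            reader_cls = DCDReader
        elif suffix == ".xtc":
            reader_cls = XTCReader
        else:
            raise TrajectoryError(f"unsupported trajectory format: {p.suffix!r}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reader = reader_cls(str(p))
                if reader.n_atoms != topology.n_atoms:
                    raise TrajectoryError(
                        f"{p}: atom count {reader.n_atoms} does not match "
                        f"topology ({topology.n_atoms})"
                    )
                for ts in reader:
                    frames.append(ts.positions.astype(float).copy())
                reader.close()
        except (OSError, EOFError) as exc:
            raise TrajectoryError(f"{p}: unreadable or truncated file: {exc}") from exc
    if not frames:
        raise TrajectoryError("no frames read")
    traj = Trajectory(topology=topology, coordinates=np.stack(frames), replica=replica)
    logger.info("read %d frames (%d file(s)) for replica %d", traj.n_frames, len(paths), replica)
    return traj


# ---------------------------------------------------------------------------
# Selection grammar
#
#   expr     := term ('or' term)*
#   term     := factor ('and' factor)*
#   factor   := '(' expr ')' | primary
#   primary  := 'name' TOKEN | 'resname' TOKEN | 'chain' TOKEN
#             | 'resid' INT['-'INT] | 'bw' LABEL['-'LABEL]


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _SelectionParser:
    def __init__(self, topology: Topology, tokens: list[str]):
        self.top = topology
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        if self.peek() == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primary()

    def primary(self) -> np.ndarray:
        keyword = self.next()
        if keyword == "name":
            return np.char.upper(self.top.names.astype(str)) == self.next().upper()
        if keyword == "resname":
            return np.char.upper(self.top.resnames.astype(str)) == self.next().upper()
        if keyword == "chain":
            return self.top.chains.astype(str) == self.next()
        if keyword == "resid":
            lo, hi = self._int_range(self.next())
            return (self.top.resids >= lo) & (self.top.resids <= hi)
        if keyword == "bw":
            return self._bw(self.next())
        raise SelectionError(f"unknown selection keyword {keyword!r}")

    @staticmethod
    def _int_range(token: str) -> tuple[int, int]:
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", token)
        if not m:
            raise SelectionError(f"bad residue token {token!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        return lo, hi

    def _bw(self, token: str) -> np.ndarray:
        m = re.fullmatch(r"(\d+)\.(\d+)(?:-(\d+)\.(\d+))?", token)
        if not m:
            raise SelectionError(f"bad BW token {token!r}")
        if not self.top.bw_map:
            raise SelectionError("selection uses BW labels but topology has no BW map")
        helix, lo = int(m.group(1)), int(m.group(2))
        if m.group(3):
            if int(m.group(3)) != helix:
                raise SelectionError("BW range must stay within one helix")
            hi = int(m.group(4))
        else:
            hi = lo
        resids: set[int] = set()
        for label, resid in self.top.bw_map.items():
            h, p = label.split(".")
            if int(h) == helix and lo <= int(p) <= hi:
                resids.add(resid)
        if not resids:
            raise SelectionError(f"no residues mapped in BW window {token!r}")
        return np.isin(self.top.resids, sorted(resids))


def select(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression to a deterministic 0-based index list.

    Supported primaries: ``name X``, ``resname X``, ``chain X``,
    ``resid N`` / ``resid N-M``, ``bw H.PP`` / ``bw H.PP-H.QQ``, combined
    with ``and`` / ``or`` and parentheses.
    """
    mask = _SelectionParser(topology, _tokenize(expression)).parse()
    indices = tuple(int(i) for i in np.flatnonzero(mask))
    if not indices:
        logger.warning("selection %r matched no atoms", expression)
    return Selection(expression=expression, indices=indices)


def read_dose_response(path: str | Path) -> DoseResponseDataset:
    """Read a five-column concentration–response CSV into a typed dataset."""
    table = pd.read_csv(path)
    return DoseResponseDataset(table=table)
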