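"""Core domain types: atoms, structures, trajectories and atom selections.

Coordinates are in Å and times in ns throughout. Residue numbering follows the
Ci-VSP sequence (linker M240–K257, TI loop R398–S414) — structures are never
re-indexed. Hydrogens are kept when present; selections default to all atoms.

The native trajectory container is a multi-model PDB plus a sidecar frame
interval; a simple TSV coordinate-series dialect is also supported. No
periodic-boundary handling is performed: all distances downstream are plain
Euclidean distances (synthetic fixtures are non-periodic).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .errors import CongruenceError, ParseError, SelectionError

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSelection",
    "BACKBONE_NAMES",
    "CHARGED_NITROGEN",
    "CARBOXYLATE_OXYGEN",
    "parse_pdb",
    "write_pdb",
    "load_trajectory",
    "write_trajectory",
    "resolve_selection",
]

#: Backbone atom names used for backbone selections and backbone RMSD.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})

#: Basic side-chain nitrogens that can donate a salt bridge
#: (Lys NZ; Arg NE, NH1, NH2), keyed by (residue_name, atom_name).
CHARGED_NITROGEN = frozenset(
    {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
)

#: Acidic carboxylate oxygens (Asp OD1/OD2; Glu OE1/OE2).
CARBOXYLATE_OXYGEN = frozenset(
    {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
)

_CLASS_TAGS = (
    "all",
    "backbone",
    "heavy",
    "sidechain",
    "carbon-only",
    "charged-nitrogen",
    "carboxylate-oxygen",
)


def _element_from_name(name: str) -> str:
    """Best-effort element symbol from a PDB atom name."""
    stripped = name.strip()
    if not stripped:
        return ""
    # Names like "1HB" start with a digit; the element is the first letter.
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return stripped[0].upper()


@dataclass(eq=False)
class Atom:
    """A single atom with Ci-VSP residue numbering and Å coordinates."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("Atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(
                f"Atom {self.serial} ({self.name}) has non-finite coordinates"
            )
        if not self.element:
            self.element = _element_from_name(self.name)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Atom):
            return NotImplemented
        return (
            self.serial == other.serial
            and self.name == other.name
            and self.element == other.element
            and self.residue_name == other.residue_name
            and self.residue_number == other.residue_number
            and self.chain == other.chain
            and np.allclose(self.position, other.position, atol=5e-4)
        )


@dataclass(eq=False)
class Structure:
    """An ordered collection of atoms with unambiguous (chain, resnum, name) lookup."""

    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for atom in self.atoms:
            if atom.key in seen:
                raise ValueError(f"Duplicate atom {atom.key} in structure")
            seen.add(atom.key)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return len(self.atoms) == len(other.atoms) and all(
            a == b for a, b in zip(self.atoms, other.atoms)
        )

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions in Å."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in self.atoms])

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise CongruenceError(
                f"Expected coordinates of shape {(len(self.atoms), 3)}, got {coords.shape}"
            )
        return Structure(
            [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        )

    def find(self, chain: str, residue_number: int, name: str) -> Optional[Atom]:
        for atom in self.atoms:
            if atom.key == (chain, residue_number, name):
                return atom
        return None

    def residue_numbers(self) -> list[int]:
        """Distinct residue numbers in order of first appearance."""
        seen: dict[int, None] = {}
        for atom in self.atoms:
            seen.setdefault(atom.residue_number, None)
        return list(seen)


@dataclass
class Trajectory:
    """A topology plus per-frame coordinates at strictly increasing times (ns)."""

    topology: Structure
    times: np.ndarray
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        expected = (len(self.times), len(self.topology), 3)
        if self.frames.shape != expected:
            raise CongruenceError(
                f"frames shape {self.frames.shape} does not match {expected}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame_spacing(self) -> float:
        """Uniform frame spacing in ns (error if sampling is non-uniform)."""
        if self.n_frames < 2:
            raise CongruenceError("Cannot determine spacing of a <2-frame trajectory")
        deltas = np.diff(self.times)
        if not np.allclose(deltas, deltas[0], rtol=1e-6, atol=1e-9):
            raise CongruenceError("Trajectory sampling is not uniform")
        return float(deltas[0])

    def structure_at(self, i: int) -> Structure:
        return self.topology.with_coordinates(self.frames[i])


@dataclass(frozen=True)
class AtomSelection:
    """Declarative selection of atoms: chain, residue range/set, name set or class tag.

    ``atom_class`` is one of: all, backbone (N/CA/C/O), heavy, sidechain
    (heavy minus backbone), carbon-only, charged-nitrogen (Lys NZ; Arg
    NE/NH1/NH2), carboxylate-oxygen (Asp OD1/OD2; Glu OE1/OE2). An explicit
    ``atom_names`` set overrides the class tag.
    """

    chain: Optional[str] = None
    residues: Optional[frozenset[int]] = None
    atom_names: Optional[frozenset[str]] = None
    atom_class: str = "all"
    label: str = ""

    def __post_init__(self) -> None:
        if self.atom_class not in _CLASS_TAGS:
            raise SelectionError(
                f"Unknown atom class {self.atom_class!r}; expected one of {_CLASS_TAGS}"
            )
        if self.residues is not None and not isinstance(self.residues, frozenset):
            object.__setattr__(self, "residues", frozenset(self.residues))
        if self.atom_names is not None and not isinstance(self.atom_names, frozenset):
            object.__setattr__(
                self, "atom_names", frozenset(n.strip() for n in self.atom_names)
            )

    @classmethod
    def residue_range(
        cls, start: int, stop: int, atom_class: str = "all", chain: Optional[str] = None,
        label: str = "",
    ) -> "AtomSelection":
        """Selection of residues start..stop inclusive."""
        return cls(
            chain=chain,
            residues=frozenset(range(start, stop + 1)),
            atom_class=atom_class,
            label=label or f"{start}-{stop}",
        )

    def describe(self) -> str:
        if self.label:
            return self.label
        parts = []
        if self.chain:
            parts.append(f"chain {self.chain}")
        if self.residues is not None:
            nums = sorted(self.residues)
            parts.append(f"residues {nums[0]}..{nums[-1]}" if nums else "residues {}")
        parts.append(self.atom_class if self.atom_names is None else f"names {sorted(self.atom_names)}")
        return ", ".join(parts)

    def _matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.residues is not None and atom.residue_number not in self.residues:
            return False
        if self.atom_names is not None:
            return atom.name in self.atom_names
        cls = self.atom_class
        if cls == "all":
            return True
        if cls == "backbone":
            return atom.name in BACKBONE_NAMES
        if cls == "heavy":
            return atom.element != "H"
        if cls == "sidechain":
            return atom.element != "H" and atom.name not in BACKBONE_NAMES
        if cls == "carbon-only":
            return atom.element == "C"
        if cls == "charged-nitrogen":
            return (atom.residue_name, atom.name) in CHARGED_NITROGEN
        if cls == "carboxylate-oxygen":
            return (atom.residue_name, atom.name) in CARBOXYLATE_OXYGEN
        raise SelectionError(f"Unknown atom class {cls!r}")  # pragma: no cover


def resolve_selection(structure: Structure, sel: AtomSelection) -> list[int]:
    """Resolve a selection to an ordered list of atom indices.

    The order follows the structure's atom order, so resolution is
    deterministic and idempotent. An empty list is a valid result.
    """
    return [i for i, atom in enumerate(structure.atoms) if sel._matches(atom)]


# ---------------------------------------------------------------------------
# PDB input / output (fixed-column ATOM/HETATM records, MODEL/ENDMDL)
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int, serial_fallback: int) -> Atom:
    def _field(lo: int, hi: int) -> str:
        return line[lo:hi]

    try:
        serial_text = _field(6, 11).strip()
        serial = int(serial_text) if serial_text else serial_fallback
        name = _field(12, 16).strip()
        residue_name = _field(17, 20).strip()
        chain = _field(21, 22).strip() or "A"
        residue_number = int(_field(22, 26).strip())
        x = float(_field(30, 38))
        y = float(_field(38, 46))
        z = float(_field(46, 54))
    except (ValueError, IndexError) as exc:
        raise ParseError(f"Malformed ATOM record at line {lineno}: {exc}") from exc
    element = _field(76, 78).strip() if len(line) >= 78 else ""
    return Atom(
        serial=serial,
        name=name,
        element=element or _element_from_name(name),
        residue_name=residue_name,
        residue_number=residue_number,
        chain=chain,
        position=np.array([x, y, z]),
    )


def _parse_models(text: str) -> list[list[Atom]]:
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    saw_model_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            saw_model_record = True
            if in_model:
                raise ParseError(f"Nested MODEL record at line {lineno}")
            in_model = True
            current = []
        elif record == "ENDMDL":
            if not in_model:
                raise ParseError(f"ENDMDL without MODEL at line {lineno}")
            models.append(current)
            in_model = False
        elif record in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno, len(current) + 1))
    if in_model:
        raise ParseError("MODEL record not closed by ENDMDL")
    if not saw_model_record and current:
        models.append(current)
    return models


def parse_pdb(text: str) -> Structure:
    """Parse a single-model PDB into a Structure.

    Raises ParseError on malformed records (naming the line number), on empty
    input, and on multi-model files (use :func:`load_trajectory` for those).
    """
    models = _parse_models(text)
    if not models or not any(models):
        raise ParseError("No ATOM/HETATM records found")
    if len(models) > 1:
        raise ParseError(
            f"File contains {len(models)} models; use load_trajectory for multi-model input"
        )
    return Structure(models[0])


def _format_atom_name(name: str) -> str:
    # Standard PDB convention: 1-3 character names start in column 14.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _atom_record(atom: Atom) -> str:
    return (
        f"ATOM  {atom.serial:>5d} {_format_atom_name(atom.name)}"
        f" {atom.residue_name:>3s} {atom.chain:1s}{atom.residue_number:>4d}    "
        f"{atom.position[0]:8.3f}{atom.position[1]:8.3f}{atom.position[2]:8.3f}"
        f"  1.00  0.00          {atom.element:>2s}"
    )


def write_pdb(structure: Structure) -> str:
    """Serialize a Structure as fixed-column PDB text (Å to 3 decimals)."""
    lines = [_atom_record(atom) for atom in structure.atoms]
    lines.append("END")
    return "\n".join(lines) + "\n"


def load_trajectory(
    source: str,
    frame_interval: float,
    topology: Optional[Structure] = None,
) -> Trajectory:
    """Load a trajectory from multi-model PDB text or a TSV coordinate series.

    Times are assigned as 0, Δ, 2Δ, ... with Δ = ``frame_interval`` (ns) for
    PDB input. The TSV dialect (header ``time_ns\\tatom_serial\\tx\\ty\\tz``)
    carries explicit times and requires a ``topology``.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    first_line = next((ln for ln in source.splitlines() if ln.strip()), "")
    if first_line.startswith("time_ns"):
        return _load_coordinate_table(source, topology)

    models = _parse_models(source)
    if not models or not any(models):
        raise ParseError("No ATOM/HETATM records found")
    n0 = len(models[0])
    for i, model in enumerate(models[1:], start=2):
        if len(model) != n0:
            raise CongruenceError(
                f"Model {i} has {len(model)} atoms; model 1 has {n0}"
            )
    top = Structure(models[0])
    frames = np.stack(
        [np.stack([a.position for a in model]) for model in models]
    )
    times = np.arange(len(models)) * frame_interval
    return Trajectory(topology=top, times=times, frames=frames)


def write_trajectory(traj: Trajectory) -> str:
    """Serialize a trajectory as multi-model PDB text."""
    chunks = []
    for i in range(traj.n_frames):
        chunks.append(f"MODEL     {i + 1:>4d}")
        frame = traj.frames[i]
        for j, atom in enumerate(traj.topology.atoms):
            chunks.append(_atom_record(replace(atom, position=frame[j])))
        chunks.append("ENDMDL")
    chunks.append("END")
    return "\n".join(chunks) + "\n"


def _load_coordinate_table(source: str, topology: Optional[Structure]) -> Trajectory:
    if topology is None:
        raise ParseError("A coordinate-series table requires an explicit topology")
    serial_to_index = {a.serial: i for i, a in enumerate(topology.atoms)}
    frames: dict[float, np.ndarray] = {}
    lines = [ln for ln in source.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[:5] != ["time_ns", "atom_serial", "x", "y", "z"]:
        raise ParseError("Coordinate table header must be time_ns\tatom_serial\tx\ty\tz")
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        try:
            t = float(parts[0])
            serial = int(parts[1])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"Malformed coordinate row at line {lineno}: {exc}") from exc
        if serial not in serial_to_index:
            raise CongruenceError(f"Atom serial {serial} (line {lineno}) not in topology")
        frames.setdefault(t, np.full((len(topology), 3), np.nan))
        frames[t][serial_to_index[serial]] = xyz
    times = np.array(sorted(frames))
    coords = np.stack([frames[t] for t in times])
    if np.any(~np.isfinite(coords)):
        raise CongruenceError("Coordinate table is missing positions for some atoms")
    return Trajectory(topology=topology, times=times, frames=coords)


def write_coordinate_table(traj: Trajectory) -> str:
    """Serialize a trajectory in the TSV coordinate-series dialect."""
    rows = ["time_ns\tatom_serial\tx\ty\tz"]
    for i, t in enumerate(traj.times):
        for j, atom in enumerate(traj.topology.atoms):
            x, y, z = traj.frames[i, j]
            rows.append(f"{t:.6g}\t{atom.serial}\t{x:.3f}\t{y:.3f}\t{z:.3f}")
    return "\n".join(rows) + "\n"
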