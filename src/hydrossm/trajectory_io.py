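"""Streaming trajectory I/O for orthorhombic MD snapshots.

Two plain-text dialects are supported, both with coordinates in nanometres:

* **GRO** — GROMACS coordinate files, fixed-column records with a trailing
  box line.  Multiple frames may be concatenated in one file.
* **extended XYZ** — count line, comment line carrying a ``Lattice="..."``
  box specification, then one ``species x y z`` record per particle.

Frames are streamed: reading a file returns a :class:`Trajectory` whose
iteration re-opens the file, so no operation ever requires all frames to be
resident in memory at once.  Analysis modules see only :class:`Frame`
objects (box, wrapped positions, species labels) and never file formats.

Only orthorhombic boxes are supported; triclinic input raises
:class:`TrajectoryFormatError`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "SOLVENT_OXYGEN",
    "SOLVENT_OTHER",
    "POLYMER_BEAD",
    "LABELS",
    "Frame",
    "Trajectory",
    "TrajectoryFormatError",
    "default_label_map",
    "read_frames",
    "write_frames",
    "select",
]

#: Species tag for water (solvent) oxygen sites — the particles whose
#: number fluctuations the small-system method samples.
SOLVENT_OXYGEN = "solvent-oxygen"
#: Species tag for all non-oxygen water sites (hydrogens, virtual M-sites).
SOLVENT_OTHER = "solvent-other"
#: Species tag for polymer beads.
POLYMER_BEAD = "polymer-bead"

#: Closed label vocabulary.
LABELS = frozenset({SOLVENT_OXYGEN, SOLVENT_OTHER, POLYMER_BEAD})

# species tokens used when writing XYZ / synthesising atom names
_LABEL_TO_NAME = {SOLVENT_OXYGEN: "OW", SOLVENT_OTHER: "HW", POLYMER_BEAD: "CB"}


class TrajectoryFormatError(ValueError):
    """Raised for malformed trajectory files (carries a line number)."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.line = line


def default_label_map(atom_name: str, residue_name: str = "") -> str:
    """Map an atom name (and optional residue name) to a species label.

    Default convention: names starting ``OW`` are solvent oxygens, water
    hydrogen / virtual sites (``HW*``, ``MW*``, ``M``) are
    ``solvent-other`` and anything else is a polymer bead.
    """
    name = atom_name.strip()
    if name.startswith("OW"):
        return SOLVENT_OXYGEN
    if name.startswith(("HW", "MW")) or name == "M":
        return SOLVENT_OTHER
    return POLYMER_BEAD


@dataclass
class Frame:
    """One simulation snapshot: an orthorhombic box plus labelled positions.

    Positions are wrapped into ``[0, box_length)`` per dimension on
    construction.  ``box_lengths[2]`` is the height ``lz`` of the
    (z-periodic) cell.
    """

    box_lengths: np.ndarray  # (3,) nm
    positions: np.ndarray  # (n, 3) nm, wrapped
    labels: np.ndarray  # (n,) species tags
    frame_time: float = 0.0  # ps
    names: np.ndarray | None = None  # optional per-site atom names

    def __post_init__(self):
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        if self.box_lengths.shape != (3,) or not np.all(self.box_lengths > 0):
            raise ValueError(f"box_lengths must be 3 positive floats, got {self.box_lengths}")
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.positions.shape[0]:
            raise ValueError("labels and positions length mismatch")
        unknown = set(np.unique(self.labels)) - LABELS
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}; vocabulary is {sorted(LABELS)}")
        # wrap into the primary cell (mod is safe for negative coordinates)
        self.positions = np.mod(self.positions, self.box_lengths[None, :])

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def lz(self) -> float:
        return float(self.box_lengths[2])

    @property
    def volume(self) -> float:
        """Closed simulation-box volume V_b in nm^3."""
        return float(np.prod(self.box_lengths))

    def positions_of(self, label: str) -> np.ndarray:
        if label not in LABELS:
            raise KeyError(f"unknown label {label!r}; vocabulary is {sorted(LABELS)}")
        return self.positions[self.labels == label]


class Trajectory:
    """Ordered sequence of frames, possibly lazily produced.

    A trajectory backed by a file or a synthetic generator holds a *factory*
    — a zero-argument callable returning a fresh frame iterator — so each
    analysis pass streams frames without keeping them all in memory.
    """

    def __init__(
        self,
        frames: Sequence[Frame] | None = None,
        *,
        factory: Callable[[], Iterable[Frame]] | None = None,
        n_frames: int | None = None,
        temperature: float | None = None,
        description: str = "",
    ):
        if (frames is None) == (factory is None):
            raise ValueError("provide exactly one of frames or factory")
        if frames is not None:
            frames = list(frames)
            self._factory = lambda: iter(frames)
            self._n_frames = len(frames)
        else:
            self._factory = factory
            self._n_frames = n_frames
        self.temperature = temperature
        self.description = description

    def __iter__(self) -> Iterator[Frame]:
        return iter(self._factory())

    def __len__(self) -> int:
        if self._n_frames is None:
            self._n_frames = sum(1 for _ in self)
        return self._n_frames

    @property
    def first_frame(self) -> Frame:
        for frame in self:
            return frame
        raise ValueError("trajectory is empty")

    def select(self, label: str) -> "Trajectory":
        """Restrict every frame to one species label (see :func:`select`)."""
        if label not in LABELS:
            raise KeyError(f"unknown label {label!r}; vocabulary is {sorted(LABELS)}")
        outer = self._factory

        def _filtered():
            for frame in outer():
                mask = frame.labels == label
                yield Frame(
                    box_lengths=frame.box_lengths,
                    positions=frame.positions[mask],
                    labels=frame.labels[mask],
                    frame_time=frame.frame_time,
                    names=None if frame.names is None else frame.names[mask],
                )

        return Trajectory(
            factory=_filtered,
            n_frames=self._n_frames,
            temperature=self.temperature,
            description=f"{self.description} [select {label}]".strip(),
        )

    def materialize(self) -> "Trajectory":
        """Return an in-memory copy (useful to avoid repeated file passes)."""
        return Trajectory(
            list(self), temperature=self.temperature, description=self.description
        )


def select(traj: Trajectory, label: str) -> Trajectory:
    """Return the trajectory restricted to one species label.

    Frame order and boxes are preserved; empty per-frame selections are
    valid.  An unknown label raises ``KeyError`` listing the vocabulary.
    """
    return traj.select(label)


# ---------------------------------------------------------------------------
# GRO dialect
# ---------------------------------------------------------------------------

def _parse_gro_box(tokens: list[float], path, lineno) -> np.ndarray:
    # GRO box line: v1x v2y v3z [v1y v1z v2x v2z v3x v3y]
    if len(tokens) not in (3, 9):
        raise TrajectoryFormatError(f"box line must have 3 or 9 floats, got {len(tokens)}", path, lineno)
    if len(tokens) == 9 and any(abs(t) > 1e-12 for t in tokens[3:]):
        raise TrajectoryFormatError("triclinic boxes are not supported (orthorhombic only)", path, lineno)
    box = np.array(tokens[:3], dtype=float)
    if not np.all(box > 0):
        raise TrajectoryFormatError(f"non-positive box lengths {box}", path, lineno)
    return box


def _iter_gro(path: Path, label_map) -> Iterator[Frame]:
    lineno = 0
    with open(path) as fh:
        while True:
            title = fh.readline()
            lineno += 1
            if not title:
                return  # clean EOF between frames
            if not title.strip():
                continue
            m = re.search(r"\bt=\s*([-0-9.eE+]+)", title)
            frame_time = float(m.group(1)) if m else 0.0
            count_line = fh.readline()
            lineno += 1
            try:
                n_atoms = int(count_line.strip())
            except ValueError:
                raise TrajectoryFormatError(
                    f"expected atom count, got {count_line.strip()!r}", path, lineno
                ) from None
            positions = np.empty((n_atoms, 3))
            labels = np.empty(n_atoms, dtype=object)
            names = np.empty(n_atoms, dtype=object)
            for i in range(n_atoms):
                line = fh.readline()
                lineno += 1
                if not line:
                    raise TrajectoryFormatError("unexpected EOF inside frame", path, lineno)
                try:
                    res_name = line[5:10].strip()
                    atom_name = line[10:15].strip()
                    positions[i] = (
                        float(line[20:28]),
                        float(line[28:36]),
                        float(line[36:44]),
                    )
                except (ValueError, IndexError):
                    raise TrajectoryFormatError(
                        f"malformed GRO atom record {line.rstrip()!r}", path, lineno
                    ) from None
                names[i] = atom_name
                labels[i] = label_map(atom_name, res_name)
            box_line = fh.readline()
            lineno += 1
            if not box_line or not box_line.strip():
                raise TrajectoryFormatError(
                    "missing box line (box volume V_b is required)", path, lineno
                )
            try:
                tokens = [float(t) for t in box_line.split()]
            except ValueError:
                raise TrajectoryFormatError(
                    f"malformed box line {box_line.strip()!r}", path, lineno
                ) from None
            box = _parse_gro_box(tokens, path, lineno)
            yield Frame(box, positions, labels.astype(str), frame_time, names=names.astype(str))


def _write_gro(frames: Iterable[Frame], path: Path) -> int:
    n_written = 0
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"hydrossm frame t= {frame.frame_time:.4f}\n")
            fh.write(f"{frame.n_particles:5d}\n")
            res_id = 0
            prev_label = None
            for i in range(frame.n_particles):
                label = frame.labels[i]
                name = frame.names[i] if frame.names is not None else _LABEL_TO_NAME[label]
                # new residue whenever an oxygen starts a molecule or the
                # species class changes; keeps SOL groupings readable
                if label == SOLVENT_OXYGEN or prev_label != label and label == POLYMER_BEAD:
                    res_id += 1
                elif prev_label is None:
                    res_id += 1
                res_name = "SOL" if label in (SOLVENT_OXYGEN, SOLVENT_OTHER) else "POL"
                x, y, z = frame.positions[i]
                fh.write(
                    f"{res_id % 100000:5d}{res_name:<5s}{name:>5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
                prev_label = label
            bx, by, bz = frame.box_lengths
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")
            n_written += 1
    return n_written


# ---------------------------------------------------------------------------
# extended-XYZ dialect (coordinates declared in nm, not Angstrom)
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"\bTime=([-0-9.eE+]+)")


def _iter_xyz(path: Path, label_map) -> Iterator[Frame]:
    lineno = 0
    with open(path) as fh:
        while True:
            count_line = fh.readline()
            lineno += 1
            if not count_line:
                return
            if not count_line.strip():
                continue
            try:
                n_atoms = int(count_line.strip())
            except ValueError:
                raise TrajectoryFormatError(
                    f"expected atom count, got {count_line.strip()!r}", path, lineno
                ) from None
            comment = fh.readline()
            lineno += 1
            m = _LATTICE_RE.search(comment)
            if not m:
                raise TrajectoryFormatError(
                    'missing Lattice="..." box in XYZ comment line '
                    "(box volume V_b is required)",
                    path,
                    lineno,
                )
            cell = np.array([float(t) for t in m.group(1).split()])
            if cell.size != 9:
                raise TrajectoryFormatError("Lattice must contain 9 numbers", path, lineno)
            cell = cell.reshape(3, 3)
            if np.any(np.abs(cell - np.diag(np.diag(cell))) > 1e-12):
                raise TrajectoryFormatError(
                    "triclinic lattices are not supported (orthorhombic only)", path, lineno
                )
            box = np.diag(cell).copy()
            if not np.all(box > 0):
                raise TrajectoryFormatError(f"non-positive box lengths {box}", path, lineno)
            tm = _TIME_RE.search(comment)
            frame_time = float(tm.group(1)) if tm else 0.0
            positions = np.empty((n_atoms, 3))
            labels = np.empty(n_atoms, dtype=object)
            names = np.empty(n_atoms, dtype=object)
            for i in range(n_atoms):
                line = fh.readline()
                lineno += 1
                if not line:
                    raise TrajectoryFormatError("unexpected EOF inside frame", path, lineno)
                parts = line.split()
                if len(parts) < 4:
                    raise TrajectoryFormatError(
                        f"malformed XYZ record {line.rstrip()!r}", path, lineno
                    )
                try:
                    positions[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                except ValueError:
                    raise TrajectoryFormatError(
                        f"malformed XYZ record {line.rstrip()!r}", path, lineno
                    ) from None
                names[i] = parts[0]
                labels[i] = label_map(parts[0], "")
            yield Frame(box, positions, labels.astype(str), frame_time, names=names.astype(str))


def _write_xyz(frames: Iterable[Frame], path: Path) -> int:
    n_written = 0
    with open(path, "w") as fh:
        for frame in frames:
            bx, by, bz = frame.box_lengths
            fh.write(f"{frame.n_particles}\n")
            fh.write(
                f'Lattice="{bx:.6f} 0.0 0.0 0.0 {by:.6f} 0.0 0.0 0.0 {bz:.6f}" '
                f"Properties=species:S:1:pos:R:3 Units=nm Time={frame.frame_time:.4f}\n"
            )
            for i in range(frame.n_particles):
                name = frame.names[i] if frame.names is not None else _LABEL_TO_NAME[frame.labels[i]]
                x, y, z = frame.positions[i]
                fh.write(f"{name:<5s} {x:12.6f} {y:12.6f} {z:12.6f}\n")
            n_written += 1
    return n_written


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

_READERS = {"gro": _iter_gro, "xyz": _iter_xyz}
_WRITERS = {"gro": _write_gro, "xyz": _write_xyz}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _READERS:
        raise ValueError(f"unknown trajectory format {fmt!r}; supported: {sorted(_READERS)}")
    return fmt


def read_frames(
    path,
    format: str | None = None,
    label_map: Callable[[str, str], str] = default_label_map,
) -> Trajectory:
    """Open a GRO or extended-XYZ trajectory for streamed reading.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"gro"`` or ``"xyz"``; inferred from the file suffix when omitted.
    label_map:
        ``(atom_name, residue_name) -> label`` mapping; defaults to
        :func:`default_label_map`.

    Returns a lazy :class:`Trajectory`: each iteration re-reads the file,
    wrapping all positions into the box.  Malformed records raise
    :class:`TrajectoryFormatError` with the offending line number; a
    missing box is a hard error because no analysis is possible without
    the reservoir volume.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    reader = _READERS[fmt]
    return Trajectory(
        factory=lambda: reader(path, label_map),
        description=f"{fmt} file {path}",
    )


def write_frames(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory to a GRO or extended-XYZ file.

    The output is re-readable by :func:`read_frames` with positions equal
    to the printed precision (GRO: 0.001 nm; XYZ: 1e-6 nm).  Writing an
    empty trajectory is an error.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    n = _WRITERS[fmt](iter(traj), path)
    if n == 0:
        path.unlink(missing_ok=True)
        raise ValueError("refusing to write an empty trajectory")


def minimum_image(delta: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` may be any array whose last axis has length matching
    ``box_lengths`` (use 2 components for in-plane radial distances,
    3 for full displacements).
    """
    box = np.asarray(box_lengths, dtype=float)
    return delta - box * np.round(delta / box)
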