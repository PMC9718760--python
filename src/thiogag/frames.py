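"""Multi-frame coordinate I/O: PDB (multi-MODEL) and XYZ.

PDB is the canonical interchange format (fixed width, 3-decimal Angstrom).
The XYZ flavor written here carries two extra columns (residue name, residue
id) after the coordinates; the reader accepts both the 4-column standard
form and the 6-column extended form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FrameSet", "FormatError", "read_frames", "write_frames", "extract_ring"]


class FormatError(ValueError):
    """Malformed or inconsistent trajectory file."""


@dataclass
class FrameSet:
    """Consistent atom roster with one coordinate block per frame (A)."""

    atom_names: tuple[str, ...]
    atom_resnames: tuple[str, ...]
    atom_resids: tuple[int, ...]
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    fmt: str = "pdb"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_names):
            raise FormatError("coordinate block does not match the atom roster")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def write_pdb(frameset: FrameSet, path: str | Path, remarks: list[str] = ()) -> None:
    lines = [f"REMARK   1 {r}" for r in remarks]
    for f in range(frameset.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i, (nm, resn, resid) in enumerate(
            zip(frameset.atom_names, frameset.atom_resnames, frameset.atom_resids)
        ):
            x, y, z = frameset.coords[f, i]
            name_field = f" {nm:<3s}" if len(nm) < 4 else nm[:4]
            lines.append(
                f"ATOM  {i + 1:5d} {name_field}{'':1s}{resn:>3s} A{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{_element_of(nm):>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path: str | Path) -> FrameSet:
    frames: list[list[tuple[str, str, int, float, float, float]]] = []
    current: list | None = None
    seen_model = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            seen_model = True
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise FormatError(f"line {lineno}: ENDMDL without MODEL")
            frames.append(current)
            current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                if seen_model:
                    raise FormatError(f"line {lineno}: atom record outside MODEL")
                current = []  # single implicit model
            try:
                nm = line[12:16].strip()
                resn = line[17:20].strip()
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError:
                raise FormatError(f"line {lineno}: malformed ATOM record") from None
            current.append((nm, resn, resid, x, y, z))
    if current:
        frames.append(current)
    if not frames:
        raise FormatError(f"{path}: no frames found")
    roster = [(a[0], a[1], a[2]) for a in frames[0]]
    for f, atoms in enumerate(frames):
        if [(a[0], a[1], a[2]) for a in atoms] != roster:
            raise FormatError(f"frame {f + 1}: atom roster differs from frame 1")
    coords = np.array(
        [[[a[3], a[4], a[5]] for a in atoms] for atoms in frames], dtype=float
    )
    return FrameSet(
        tuple(a[0] for a in roster),
        tuple(a[1] for a in roster),
        tuple(a[2] for a in roster),
        coords,
        fmt="pdb",
    )


def write_xyz(frameset: FrameSet, path: str | Path, comment: str = "") -> None:
    lines = []
    for f in range(frameset.n_frames):
        lines.append(str(frameset.n_atoms))
        lines.append(f"{comment} frame {f + 1}".strip())
        for i, (nm, resn, resid) in enumerate(
            zip(frameset.atom_names, frameset.atom_resnames, frameset.atom_resids)
        ):
            x, y, z = frameset.coords[f, i]
            lines.append(f"{nm:<4s} {x:14.6f} {y:14.6f} {z:14.6f} {resn} {resid}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path, nm_to_angstrom: bool = False) -> FrameSet:
    text = Path(path).read_text().splitlines()
    pos = 0
    frames = []
    while pos < len(text):
        if not text[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(text[pos].strip())
        except ValueError:
            raise FormatError(f"line {pos + 1}: expected atom count") from None
        if pos + 1 + n_atoms >= len(text) + 1:
            raise FormatError(f"line {pos + 1}: truncated frame")
        atoms = []
        for k in range(n_atoms):
            parts = text[pos + 2 + k].split()
            if len(parts) not in (4, 6):
                raise FormatError(f"line {pos + 3 + k}: expected 4 or 6 columns")
            nm = parts[0]
            try:
                xyz = tuple(float(v) for v in parts[1:4])
            except ValueError:
                raise FormatError(f"line {pos + 3 + k}: bad coordinates") from None
            resn = parts[4] if len(parts) == 6 else "UNK"
            resid = int(parts[5]) if len(parts) == 6 else 1
            atoms.append((nm, resn, resid, *xyz))
        frames.append(atoms)
        pos += 2 + n_atoms
    if not frames:
        raise FormatError(f"{path}: no frames found")
    roster = [(a[0], a[1], a[2]) for a in frames[0]]
    for f, atoms in enumerate(frames):
        if [(a[0], a[1], a[2]) for a in atoms] != roster:
            raise FormatError(f"frame {f + 1}: atom roster differs from frame 1")
    coords = np.array(
        [[[a[3], a[4], a[5]] for a in atoms] for atoms in frames], dtype=float
    )
    if nm_to_angstrom:
        coords = coords * 10.0
    return FrameSet(
        tuple(a[0] for a in roster),
        tuple(a[1] for a in roster),
        tuple(a[2] for a in roster),
        coords,
        fmt="xyz",
    )


def read_frames(path: str | Path, fmt: str | None = None,
                nm_to_angstrom: bool = False) -> FrameSet:
    """Load a multi-frame coordinate file; format inferred from the suffix."""
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt == "pdb":
        return read_pdb(path)
    if fmt == "xyz":
        return read_xyz(path, nm_to_angstrom=nm_to_angstrom)
    raise FormatError(f"unsupported trajectory format {fmt!r}")


def write_frames(frameset: FrameSet, path: str | Path, fmt: str | None = None,
                 remarks: list[str] = ()) -> None:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt == "pdb":
        write_pdb(frameset, path, remarks=remarks)
    elif fmt == "xyz":
        write_xyz(frameset, path, comment=" ".join(remarks))
    else:
        raise FormatError(f"unsupported trajectory format {fmt!r}")


DEFAULT_RING_NAMING = {nm: nm for nm in ("O5", "C1", "C2", "C3", "C4", "C5")}


def extract_ring(frameset: FrameSet, frame: int, resid: int,
                 naming: dict[str, str] | None = None) -> np.ndarray:
    """Ordered (6, 3) ring coordinates for one residue of one frame.

    ``naming`` maps the canonical atom roles O5,C1..C5 to the names used in
    the file (e.g. ``{"O5": "O5'"}``).
    """
    naming = {**DEFAULT_RING_NAMING, **(naming or {})}
    lookup = {
        (rid, nm): i
        for i, (nm, rid) in enumerate(zip(frameset.atom_names, frameset.atom_resids))
    }
    idx = []
    for role in ("O5", "C1", "C2", "C3", "C4", "C5"):
        key = (resid, naming[role])
        if key not in lookup:
            raise KeyError(f"residue {resid}: missing ring atom {naming[role]!r}")
        idx.append(lookup[key])
    return frameset.coords[frame, idx]
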