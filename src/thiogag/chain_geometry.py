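"""End-to-end lengths, glycosidic geometry and their ensemble distributions.

The end-to-end distance runs from O1 of the reducing-end residue to the
position-4 exocyclic heteroatom of the non-reducing terminus (O4, or S4 for
4-thio-substituted termini; ``strict_o4`` restricts to O4). All coordinates
are in Angstrom, angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChainTopology",
    "GeometrySeries",
    "MissingAtomError",
    "end_to_end",
    "end_to_end_series",
    "glycosidic_geometry",
    "geometry_series",
    "contour_length",
    "length_histogram",
    "frame_count",
    "retained_duration",
]


class MissingAtomError(KeyError):
    """A required atom is absent from the topology or a frame."""


@dataclass(frozen=True)
class ChainTopology:
    """Atom bookkeeping for one glycan chain in a coordinate ensemble.

    Residues are numbered 1..n from the non-reducing end. ``linkage_triplets``
    holds (C1 donor, heteroatom X, C4 acceptor) atom indices per glycosidic
    bond, ordered from the non-reducing end.
    """

    atom_names: tuple[str, ...]
    atom_resids: tuple[int, ...]
    atom_resnames: tuple[str, ...]
    ring_indices: dict[int, tuple[int, ...]]  # resid -> 6 indices (O5,C1..C5)
    reducing_o1: int
    nonreducing_o4: int
    linkage_triplets: tuple[tuple[int, int, int, str], ...]

    @property
    def n_residues(self) -> int:
        return len(self.ring_indices)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def contour_path(self) -> tuple[int, ...]:
        """Covalent atom path from O1 to the terminal position-4 heteroatom.

        O1 -> C1 -> C2 -> C3 -> C4 of the reducing residue, through each
        glycosidic heteroatom into the next residue, ending at O4/S4.
        """
        resids = sorted(self.ring_indices)
        x_by_acceptor = {}
        for c1, x, c4, _ in self.linkage_triplets:
            x_by_acceptor[self.atom_resids[c4]] = x
        path = [self.reducing_o1]
        for resid in reversed(resids):
            o5, c1, c2, c3, c4, _ = self.ring_indices[resid]
            path += [c1, c2, c3, c4]
            path.append(x_by_acceptor[resid] if resid in x_by_acceptor
                        else self.nonreducing_o4)
        return tuple(path)

    @classmethod
    def from_frameset(cls, frameset, strict_o4: bool = False) -> "ChainTopology":
        """Build a topology from a FrameSet using atom-name conventions.

        Expects per residue atoms O5, C1..C5 and an O4 or S4; O1 on the
        reducing-end (highest-numbered) residue. The O4/S4 of residue i > 1
        is taken as the glycosidic heteroatom of the bond (i-1) -> i.
        """
        names, resids = frameset.atom_names, frameset.atom_resids
        resnames = frameset.atom_resnames
        index: dict[tuple[int, str], int] = {}
        for i, (nm, rid) in enumerate(zip(names, resids)):
            index[(rid, nm)] = i
        residue_ids = sorted(set(resids))
        ring = {}
        for rid in residue_ids:
            try:
                ring[rid] = tuple(index[(rid, nm)] for nm in
                                  ("O5", "C1", "C2", "C3", "C4", "C5"))
            except KeyError as exc:
                raise MissingAtomError(
                    f"residue {rid}: missing ring atom {exc.args[0][1]}"
                ) from None
        red = residue_ids[-1]
        if (red, "O1") not in index:
            raise MissingAtomError(f"residue {red}: missing reducing-end O1")
        nr = residue_ids[0]
        if (nr, "O4") in index:
            o4 = index[(nr, "O4")]
        elif not strict_o4 and (nr, "S4") in index:
            o4 = index[(nr, "S4")]
        else:
            raise MissingAtomError(
                f"residue {nr}: missing non-reducing terminal O4"
                f"{'' if strict_o4 else '/S4'}"
            )
        triplets = []
        for a, b in zip(residue_ids, residue_ids[1:]):
            if (b, "O4") in index:
                x, het = index[(b, "O4")], "O"
            elif (b, "S4") in index:
                x, het = index[(b, "S4")], "S"
            else:
                raise MissingAtomError(f"residue {b}: missing glycosidic O4/S4")
            triplets.append((index[(a, "C1")], x, index[(b, "C4")], het))
        return cls(tuple(names), tuple(resids), tuple(resnames), ring,
                   index[(red, "O1")], o4, tuple(triplets))


def _check_frame(frame: np.ndarray, topology: ChainTopology) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[1] != 3:
        raise ValueError("frame must have shape (n_atoms, 3)")
    if frame.shape[0] != topology.n_atoms:
        raise MissingAtomError(
            f"frame has {frame.shape[0]} atoms, topology expects {topology.n_atoms}"
        )
    return frame


def end_to_end(frame: np.ndarray, topology: ChainTopology) -> float:
    """Distance (A) from reducing O1 to the non-reducing terminal heteroatom."""
    frame = _check_frame(frame, topology)
    return float(np.linalg.norm(frame[topology.reducing_o1]
                                - frame[topology.nonreducing_o4]))


def end_to_end_series(coords: np.ndarray, topology: ChainTopology) -> np.ndarray:
    """Vectorized end-to-end distances over (n_frames, n_atoms, 3) coords."""
    coords = np.asarray(coords, dtype=float)
    d = coords[:, topology.reducing_o1] - coords[:, topology.nonreducing_o4]
    return np.linalg.norm(d, axis=1)


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("coincident atoms in angle computation")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def glycosidic_geometry(
    frame: np.ndarray, topology: ChainTopology
) -> list[tuple[str, float, float, float]]:
    """Per-linkage (heteroatom, C1-X length, X-C4 length, C1-X-C4 angle)."""
    frame = _check_frame(frame, topology)
    out = []
    for c1, x, c4, het in topology.linkage_triplets:
        d1 = float(np.linalg.norm(frame[c1] - frame[x]))
        d2 = float(np.linalg.norm(frame[x] - frame[c4]))
        out.append((het, d1, d2, _angle_deg(frame[c1], frame[x], frame[c4])))
    return out


@dataclass
class GeometrySeries:
    """Per-frame geometry of an ensemble."""

    end_to_end: np.ndarray  # (n_frames,)
    bond_lengths: np.ndarray  # (n_frames, n_linkages, 2): C1-X, X-C4
    angles: np.ndarray  # (n_frames, n_linkages), degrees
    heteroatoms: tuple[str, ...] = field(default_factory=tuple)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in range(len(self.end_to_end)):
            row = {"frame": f, "end_to_end": self.end_to_end[f]}
            for l, het in enumerate(self.heteroatoms):
                row[f"link{l + 1}_het"] = het
                row[f"link{l + 1}_c1x"] = self.bond_lengths[f, l, 0]
                row[f"link{l + 1}_xc4"] = self.bond_lengths[f, l, 1]
                row[f"link{l + 1}_angle"] = self.angles[f, l]
            rows.append(row)
        return pd.DataFrame(rows)


def geometry_series(coords: np.ndarray, topology: ChainTopology) -> GeometrySeries:
    """Compute end-to-end and per-linkage geometry for every frame."""
    coords = np.asarray(coords, dtype=float)
    trip = topology.linkage_triplets
    c1 = coords[:, [t[0] for t in trip]]
    x = coords[:, [t[1] for t in trip]]
    c4 = coords[:, [t[2] for t in trip]]
    v1, v2 = c1 - x, c4 - x
    d1 = np.linalg.norm(v1, axis=2)
    d2 = np.linalg.norm(v2, axis=2)
    if np.any(d1 < 1e-9) or np.any(d2 < 1e-9):
        raise ValueError("coincident linkage atoms")
    cosang = np.clip((v1 * v2).sum(axis=2) / (d1 * d2), -1.0, 1.0)
    return GeometrySeries(
        end_to_end=end_to_end_series(coords, topology),
        bond_lengths=np.stack([d1, d2], axis=2),
        angles=np.degrees(np.arccos(cosang)),
        heteroatoms=tuple(t[3] for t in trip),
    )


def contour_length(frame: np.ndarray, topology: ChainTopology) -> float:
    """Summed covalent path length from O1 to the terminal heteroatom (A).

    Upper bound on the end-to-end distance for any frame.
    """
    frame = _check_frame(frame, topology)
    path = np.asarray(topology.contour_path())
    return float(np.linalg.norm(np.diff(frame[path], axis=0), axis=1).sum())


def length_histogram(values: np.ndarray, bin_width: float = 0.5,
                     start: float = 0.0) -> pd.DataFrame:
    """Histogram table with deterministic edges start + k * bin_width.

    Counts sum to the number of samples; only occupied-range bins are kept.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    if values.min() < start:
        raise ValueError("values below histogram start")
    n_bins = int(np.floor((values.max() - start) / bin_width)) + 1
    edges = start + bin_width * np.arange(n_bins + 1)
    # guard the right edge so the max value falls inside the last bin
    edges[-1] = np.nextafter(edges[-1], np.inf)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame({
        "bin_left": start + bin_width * np.arange(n_bins),
        "bin_right": start + bin_width * (np.arange(n_bins) + 1),
        "count": counts,
    })


def frame_count(production_duration: float, save_interval: float) -> int:
    """Number of saved frames: floor(duration / interval), same time units."""
    if production_duration <= 0 or save_interval <= 0:
        raise ValueError("durations must be positive")
    if save_interval > production_duration:
        raise ValueError("save interval exceeds production duration")
    return int(np.floor(production_duration / save_interval + 1e-9))


def retained_duration(total: float, discard: float) -> float:
    """Production time kept for analysis: total minus discarded equilibration."""
    if total <= 0 or discard < 0:
        raise ValueError("invalid durations")
    if discard >= total:
        raise ValueError("discard must be smaller than the total duration")
    return total - discard
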