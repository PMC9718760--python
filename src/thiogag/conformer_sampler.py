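"""Synthetic conformational ensembles of O- vs S-linked oligosaccharides.

Desk-scale stand-in for microsecond MD: each frame draws a canonical ring
conformer per residue from a configured mixture, joins consecutive rings
through glycosidic internal coordinates whose bond lengths and angles are
Boltzmann-sampled from harmonic parameters (Gaussian with variance
kB*T/(2K) for E = K (x - x0)^2), and draws glycosidic torsions from von
Mises distributions. Exocyclic groups are single pseudo-atoms. A hard-sphere
clash filter resamples torsions of offending frames.

Everything is reproducible bit-for-bit from (spec, seed): per-frame RNG
substreams are spawned from one named SeedSequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chain_geometry import ChainTopology
from .constants import KB_KCAL_PER_MOL_K
from .glycan_model import GlycanChain, chain_to_string
from .ring_pucker import CONFORMER_BY_NAME, canonical_ring

__all__ = [
    "LinkageParams",
    "S_LINK_PARAMS",
    "O_LINK_PARAMS",
    "ChargeSet",
    "S_LINK_CHARGES",
    "TorsionParams",
    "EnsembleSpec",
    "ConformerEnsemble",
    "FrameGenerationError",
    "sample_harmonic",
    "build_chain_ensemble",
    "integer_charge_check",
]


@dataclass(frozen=True)
class LinkageParams:
    """Harmonic glycosidic-linkage parameters (AMBER-style E = K (x-x0)^2)."""

    heteroatom: str  # "O" | "S"
    r0: float  # equilibrium C-X bond length, A
    k_bond: float  # kcal mol^-1 A^-2
    theta0: float  # equilibrium C-X-C angle, degrees
    k_angle: float  # kcal mol^-1 rad^-2

    def __post_init__(self) -> None:
        if min(self.r0, self.k_bond, self.theta0, self.k_angle) <= 0:
            raise ValueError("all linkage parameters must be positive")


#: Gaussian-optimized thio-linkage constants (GAFF "ss" sulfur context).
S_LINK_PARAMS = LinkageParams("S", 1.8392, 215.9, 99.24, 60.2)
#: Natural linkage geometry; force constants mirrored from the S-link values.
O_LINK_PARAMS = LinkageParams("O", 1.43, 215.9, 116.0, 60.2)


@dataclass(frozen=True)
class ChargeSet:
    """Partial charges (e) with the declared total integer charge."""

    charges: tuple[tuple[str, float], ...]
    declared_total: int = 0

    def total(self) -> float:
        return sum(q for _, q in self.charges)


#: RESP charges printed for the S-linked residue linkage region (partial set).
S_LINK_CHARGES = ChargeSet(
    (("S4", -0.46), ("C1", 0.49), ("O5", -0.56), ("C2", 0.31),
     ("C4", 0.20), ("C3", 0.32), ("C5", 0.21)),
    declared_total=0,
)


def integer_charge_check(charges: ChargeSet,
                         tolerance: float = 1e-4) -> tuple[bool, float]:
    """Check that the charge sum matches the declared integer total.

    Returns (passed, residual) with residual = |sum(q) - declared_total|.
    """
    if not charges.charges:
        raise ValueError("empty charge set")
    residual = abs(charges.total() - charges.declared_total)
    return residual <= tolerance, residual


def sample_harmonic(params: LinkageParams, temperature: float, n: int,
                    rng: np.random.Generator | int) -> tuple[np.ndarray, np.ndarray]:
    """Boltzmann samples of the harmonic bond length (A) and angle (degrees).

    E = K (x - x0)^2 at temperature T gives a Gaussian with mean x0 and
    variance kB*T / (2K); the angle is sampled in radians and returned in
    degrees.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    kbt = KB_KCAL_PER_MOL_K * temperature
    lengths = rng.normal(params.r0, np.sqrt(kbt / (2.0 * params.k_bond)), n)
    sigma_rad = np.sqrt(kbt / (2.0 * params.k_angle))
    angles = rng.normal(np.radians(params.theta0), sigma_rad, n)
    return lengths, np.degrees(angles)


# ---------------------------------------------------------------------------
# ensemble specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TorsionParams:
    """Independent von Mises glycosidic torsions (degrees; kappa 0 = uniform)."""

    phi_mean: float = 120.0
    phi_kappa: float = 10.0
    psi_mean: float = 300.0
    psi_kappa: float = 10.0
    spin_mean: float = 270.0
    spin_kappa: float = 10.0

    def __post_init__(self) -> None:
        if min(self.phi_kappa, self.psi_kappa, self.spin_kappa) < 0:
            raise ValueError("concentrations must be >= 0")


#: Default torsion models; the lower S-link concentration is the "floppiness"
#: knob standing in for the force-field differences.
DEFAULT_TORSIONS: dict[str, TorsionParams] = {
    "O": TorsionParams(phi_kappa=10.0, psi_kappa=10.0, spin_kappa=10.0),
    "S": TorsionParams(phi_kappa=3.0, psi_kappa=3.0, spin_kappa=3.0),
}

DEFAULT_MIXTURES: dict[str, dict[str, float]] = {
    "uronic": {"4C1": 1.0},
    "hexosamine": {"4C1": 1.0},
}


@dataclass(frozen=True)
class EnsembleSpec:
    """Everything needed to generate an ensemble reproducibly."""

    chain: GlycanChain
    n_frames: int
    seed: int
    temperature: float = 298.0
    mixtures: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MIXTURES.items()}
    )
    residue_mixtures: dict[int, dict[str, float]] = field(default_factory=dict)
    linkage_params: dict[str, LinkageParams] = field(
        default_factory=lambda: {"O": O_LINK_PARAMS, "S": S_LINK_PARAMS}
    )
    torsions: dict[str, TorsionParams] = field(
        default_factory=lambda: dict(DEFAULT_TORSIONS)
    )
    ring_amplitude: float = 0.57
    clash_radius: float = 1.8
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for cls, weights in list(self.mixtures.items()) + list(
            self.residue_mixtures.items()
        ):
            if not weights:
                raise ValueError(f"empty mixture for {cls!r}")
            for name in weights:
                if name not in CONFORMER_BY_NAME:
                    raise ValueError(f"unknown conformer label {name!r}")
            tot = sum(weights.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {cls!r} sum to {tot}, not 1")


class FrameGenerationError(RuntimeError):
    """Clash-retry limit exceeded while generating a frame."""


@dataclass
class ConformerEnsemble:
    """Generated frames plus topology, per-ring labels and provenance."""

    topology: ChainTopology
    coords: np.ndarray  # (n_frames, n_atoms, 3), A
    labels: np.ndarray  # (n_frames, n_residues) of conformer names
    provenance: dict

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# geometry building blocks
# ---------------------------------------------------------------------------


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float,
          angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors and internal coordinates."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    cross = np.cross(u, v)
    dot = float(np.dot(u, v))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return _axis_rotation(perp, np.pi)
    axis = cross / np.linalg.norm(cross)
    return _axis_rotation(axis, np.arctan2(np.linalg.norm(cross), dot))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


_PSEUDO_BONDS = {"C6": 1.52, "N2": 1.45, "O2": 1.43, "O1": 1.43,
                 "O4": 1.43, "S4": 1.82}


def _von_mises_deg(rng: np.random.Generator, mean_deg: float, kappa: float) -> float:
    if kappa == 0:
        return float(rng.uniform(-180.0, 180.0))
    return float(np.degrees(rng.vonmises(np.radians(mean_deg), kappa)))


# ---------------------------------------------------------------------------
# chain assembly
# ---------------------------------------------------------------------------


def _atom_roster(chain: GlycanChain) -> tuple[list[tuple[str, int, str]], dict]:
    """Atom (name, resid, resname) list and index lookup for a chain."""
    n = len(chain.residues)
    atoms: list[tuple[str, int, str]] = []
    index: dict[tuple[int, str], int] = {}
    for i, res in enumerate(chain.residues):
        resid = i + 1
        resname = res.name[:3].upper() if res.residue_class == "uronic" else "NAG"
        if res.residue_class == "uronic":
            resname = "GCA" if res.name == "GlcA" else "DUA"
        names = ["O5", "C1", "C2", "C3", "C4", "C5"]
        # position-4 heteroatom: terminal free O4/S4 on residue 1, else the
        # glycosidic heteroatom of the bond from residue i-1
        if resid == 1:
            het = "S4" if "4-thio" in res.modifications else "O4"
        else:
            het = "S4" if chain.linkages[i - 1] == "S" else "O4"
        names.append(het)
        names.append("C6")
        names.append("N2" if res.residue_class == "hexosamine" else "O2")
        if resid == n:
            names.append("O1")
        for nm in names:
            index[(resid, nm)] = len(atoms)
            atoms.append((nm, resid, resname))
    return atoms, index


def _build_topology(chain: GlycanChain, atoms, index) -> ChainTopology:
    n = len(chain.residues)
    ring = {
        rid: tuple(index[(rid, nm)] for nm in ("O5", "C1", "C2", "C3", "C4", "C5"))
        for rid in range(1, n + 1)
    }
    het1 = "S4" if (1, "S4") in index else "O4"
    triplets = []
    for i in range(n - 1):
        het = chain.linkages[i]
        xname = "S4" if het == "S" else "O4"
        triplets.append((index[(i + 1, "C1")], index[(i + 2, xname)],
                         index[(i + 2, "C4")], het))
    return ChainTopology(
        atom_names=tuple(a[0] for a in atoms),
        atom_resids=tuple(a[1] for a in atoms),
        atom_resnames=tuple(a[2] for a in atoms),
        ring_indices=ring,
        reducing_o1=index[(n, "O1")],
        nonreducing_o4=index[(1, het1)],
        linkage_triplets=tuple(triplets),
    )


def _place_ring(local: np.ndarray, c1_target: np.ndarray, o5_target: np.ndarray,
                spin_deg: float) -> np.ndarray:
    """Rigidly place a canonical ring so its C1/O5 hit the targets, then spin."""
    c1_l, o5_l = local[1], local[0]
    a_l = o5_l - c1_l
    a_t = o5_target - c1_target
    rot = _rotation_between(a_l / np.linalg.norm(a_l), a_t / np.linalg.norm(a_t))
    placed = (local - c1_l) @ rot.T + c1_target
    spin = _axis_rotation(a_t / np.linalg.norm(a_t), np.radians(spin_deg))
    return (placed - c1_target) @ spin.T + c1_target


#: torsion redraws per residue during sequential chain growth
_GROWTH_RETRIES = 30


def _frame_coords(spec: EnsembleSpec, topo: ChainTopology, index: dict,
                  labels: list[str], rng: np.random.Generator) -> np.ndarray | None:
    """Generate one frame's coordinates given fixed per-ring labels.

    Rings are attached sequentially from the reducing end; each residue's
    torsions are redrawn (bounded retries) if its ring collides with residues
    at least two positions away. Returns None if growth fails, letting the
    caller retry the whole frame.
    """
    chain = spec.chain
    n = len(chain.residues)
    coords = np.zeros((topo.n_atoms, 3))
    rings_local = [canonical_ring(lab, spec.ring_amplitude) for lab in labels]

    def set_ring(rid: int, xyz: np.ndarray) -> None:
        for k, nm in enumerate(("O5", "C1", "C2", "C3", "C4", "C5")):
            coords[index[(rid, nm)]] = xyz[k]

    # reducing-end residue n at the origin in its canonical orientation
    set_ring(n, rings_local[n - 1])
    placed: dict[int, list[int]] = {n: list(topo.ring_indices[n])}
    for i in range(n - 1, 0, -1):  # attach residue i onto residue i+1
        acceptor = i + 1
        het = chain.linkages[i - 1]
        params = spec.linkage_params[het]
        tor = spec.torsions[het]
        far = np.concatenate([placed[r] for r in placed if r >= i + 2]).astype(int) \
            if any(r >= i + 2 for r in placed) else None
        c2 = coords[index[(acceptor, "C2")]]
        c3 = coords[index[(acceptor, "C3")]]
        c4 = coords[index[(acceptor, "C4")]]
        xname = "S4" if het == "S" else "O4"
        local = rings_local[i - 1]
        d_c1o5 = float(np.linalg.norm(local[0] - local[1]))
        for _ in range(_GROWTH_RETRIES + 1):
            lengths, angles = sample_harmonic(params, spec.temperature, 2, rng)
            x = _nerf(c2, c3, c4, float(lengths[0]), 109.47, 60.0)
            phi_t = _von_mises_deg(rng, tor.phi_mean, tor.phi_kappa)
            c1 = _nerf(c3, c4, x, float(lengths[1]), float(angles[0]), phi_t)
            psi_t = _von_mises_deg(rng, tor.psi_mean, tor.psi_kappa)
            o5 = _nerf(c4, x, c1, d_c1o5, 109.47, psi_t)
            spin = _von_mises_deg(rng, tor.spin_mean, tor.spin_kappa)
            ring_xyz = _place_ring(local, c1, o5, spin)
            if far is None:
                break
            d = np.linalg.norm(ring_xyz[:, None, :] - coords[far][None, :, :],
                               axis=2)
            if d.min() >= spec.clash_radius:
                break
        else:
            return None
        coords[index[(acceptor, xname)]] = x
        set_ring(i, ring_xyz)
        placed[acceptor].append(index[(acceptor, xname)])
        placed[i] = list(topo.ring_indices[i])

    # exocyclic pseudo-atoms: radially outward from each ring's centroid
    for rid in range(1, n + 1):
        ring_xyz = coords[list(topo.ring_indices[rid])]
        centroid = ring_xyz.mean(axis=0)
        hosts = [("C5", "C6"), ("C2", "N2" if (rid, "N2") in index else "O2")]
        if rid == 1:
            hosts.append(("C4", "S4" if (1, "S4") in index else "O4"))
        if rid == n:
            hosts.append(("C1", "O1"))
        for host, sub in hosts:
            h = coords[index[(rid, host)]]
            u = h - centroid
            u /= np.linalg.norm(u)
            coords[index[(rid, sub)]] = h + _PSEUDO_BONDS[sub] * u
    return coords


def _has_clash(coords: np.ndarray, topo: ChainTopology, radius: float) -> bool:
    """Any pair of atoms from residues at least two apart closer than radius."""
    resids = np.asarray(topo.atom_resids)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    sep = np.abs(resids[:, None] - resids[None, :])
    mask = np.triu(sep >= 2, k=1)
    return bool(np.any(d[mask] < radius))


def build_chain_ensemble(spec: EnsembleSpec) -> ConformerEnsemble:
    """Generate a reproducible ensemble of 3D frames for the chain spec."""
    chain = spec.chain
    atoms, index = _atom_roster(chain)
    topo = _build_topology(chain, atoms, index)
    n_res = len(chain.residues)

    mixtures = []
    for i, res in enumerate(chain.residues):
        weights = spec.residue_mixtures.get(i + 1, spec.mixtures[res.residue_class])
        names = sorted(weights)
        mixtures.append((names, np.array([weights[nm] for nm in names])))

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_frames)
    coords = np.empty((spec.n_frames, topo.n_atoms, 3))
    labels = np.empty((spec.n_frames, n_res), dtype=object)
    for f in range(spec.n_frames):
        rng = np.random.default_rng(streams[f])
        frame_labels = [
            names[rng.choice(len(names), p=p)] for names, p in mixtures
        ]
        labels[f] = frame_labels
        for attempt in range(spec.max_retries + 1):
            xyz = _frame_coords(spec, topo, index, frame_labels, rng)
            if xyz is None:
                continue
            if n_res < 3 or not _has_clash(xyz, topo, spec.clash_radius):
                coords[f] = xyz
                break
        else:
            raise FrameGenerationError(
                f"frame {f}: steric clash persisted after "
                f"{spec.max_retries} torsion resamples"
            )
    provenance = {
        "generator": "thiogag.conformer_sampler.build_chain_ensemble",
        "chain": chain_to_string(chain),
        "n_frames": spec.n_frames,
        "seed": spec.seed,
        "temperature": spec.temperature,
        "ring_amplitude": spec.ring_amplitude,
    }
    return ConformerEnsemble(topo, coords, labels, provenance)
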