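"""Configuration handling and the end-to-end analysis pipeline.

``run_pipeline`` generates one ensemble per configured chain, then runs the
puckering and geometry analyses and writes deterministic CSV outputs plus a
provenance record. Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .chain_geometry import geometry_series, length_histogram
from .conformer_sampler import (
    EnsembleSpec,
    LinkageParams,
    O_LINK_PARAMS,
    S_LINK_PARAMS,
    TorsionParams,
    DEFAULT_TORSIONS,
    build_chain_ensemble,
)
from .frames import FrameSet, write_frames
from .glycan_model import GlycanChain, heparosan, parse_chain
from .ring_pucker import most_internal_disaccharide, pucker_frequencies, cremer_pople, classify_conformer, sinusoidal_projection

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_config", "frameset_from_ensemble"]

log = logging.getLogger("thiogag")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


_PRESETS = {
    "heparosan_deca_O": lambda: heparosan(10, "O"),
    "heparosan_deca_hemiA": lambda: heparosan(10, "hemi-A"),
}

_KNOWN_KEYS = {
    "seed", "n_frames", "temperature", "chains", "mixtures", "linkage_params",
    "torsions", "ring_amplitude", "clash_radius", "max_retries", "bin_width",
    "output_dir", "log_level",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    chains: dict[str, GlycanChain]
    n_frames: int = 2000
    temperature: float = 298.0
    mixtures: dict[str, dict[str, float]] | None = None
    linkage_params: dict[str, LinkageParams] = field(
        default_factory=lambda: {"O": O_LINK_PARAMS, "S": S_LINK_PARAMS}
    )
    torsions: dict[str, TorsionParams] = field(
        default_factory=lambda: dict(DEFAULT_TORSIONS)
    )
    ring_amplitude: float = 0.57
    clash_radius: float = 1.8
    max_retries: int = 50
    bin_width: float = 0.5
    output_dir: Path = Path("thiogag_out")
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        # output location and log level do not affect the science
        relevant = {k: v for k, v in self.raw.items()
                    if k not in ("output_dir", "log_level")}
        canonical = json.dumps(relevant, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _parse_chain_entry(value: str) -> GlycanChain:
    if value.startswith("preset:"):
        name = value[len("preset:"):]
        if name not in _PRESETS:
            raise ConfigError(f"unknown chain preset {name!r}")
        return _PRESETS[name]()
    return parse_chain(value)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in data:
        raise ConfigError("config must provide a seed")
    chains_raw = data.get("chains") or {
        "o_link": "preset:heparosan_deca_O",
        "s_link": "preset:heparosan_deca_hemiA",
    }
    chains = {name: _parse_chain_entry(v) for name, v in chains_raw.items()}
    lp = {"O": O_LINK_PARAMS, "S": S_LINK_PARAMS}
    for het, kv in (data.get("linkage_params") or {}).items():
        base = lp[het]
        lp[het] = LinkageParams(
            het,
            float(kv.get("r0", base.r0)),
            float(kv.get("k_bond", base.k_bond)),
            float(kv.get("theta0", base.theta0)),
            float(kv.get("k_angle", base.k_angle)),
        )
    tors = dict(DEFAULT_TORSIONS)
    for het, kv in (data.get("torsions") or {}).items():
        base = tors[het]
        tors[het] = TorsionParams(
            float(kv.get("phi_mean", base.phi_mean)),
            float(kv.get("phi_kappa", base.phi_kappa)),
            float(kv.get("psi_mean", base.psi_mean)),
            float(kv.get("psi_kappa", base.psi_kappa)),
            float(kv.get("spin_mean", base.spin_mean)),
            float(kv.get("spin_kappa", base.spin_kappa)),
        )
    return RunConfig(
        seed=int(data["seed"]),
        chains=chains,
        n_frames=int(data.get("n_frames", 2000)),
        temperature=float(data.get("temperature", 298.0)),
        mixtures=data.get("mixtures"),
        linkage_params=lp,
        torsions=tors,
        ring_amplitude=float(data.get("ring_amplitude", 0.57)),
        clash_radius=float(data.get("clash_radius", 1.8)),
        max_retries=int(data.get("max_retries", 50)),
        bin_width=float(data.get("bin_width", 0.5)),
        output_dir=Path(data.get("output_dir", "thiogag_out")),
        raw=data,
    )


def frameset_from_ensemble(ensemble) -> FrameSet:
    topo = ensemble.topology
    return FrameSet(topo.atom_names, topo.atom_resnames, topo.atom_resids,
                    ensemble.coords, fmt="pdb")


def _write_csv(df, path: Path, provenance: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """build-ensemble -> pucker -> geometry -> summary for every chain."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov_tag = f"thiogag {__version__} seed={config.seed} config={config.config_hash()}"
    written: dict[str, Path] = {}
    summary = {}
    seeds = {name: config.seed + 1000 * k for k, name in enumerate(sorted(config.chains))}
    for name in sorted(config.chains):
        chain = config.chains[name]
        log.info("building ensemble %s (%d frames)", name, config.n_frames)
        spec_kwargs = dict(
            chain=chain,
            n_frames=config.n_frames,
            seed=seeds[name],
            temperature=config.temperature,
            linkage_params=config.linkage_params,
            torsions=config.torsions,
            ring_amplitude=config.ring_amplitude,
            clash_radius=config.clash_radius,
            max_retries=config.max_retries,
        )
        if config.mixtures:
            spec_kwargs["mixtures"] = {
                cls: dict(w) for cls, w in config.mixtures.items()
            }
        ensemble = build_chain_ensemble(EnsembleSpec(**spec_kwargs))
        topo = ensemble.topology

        pdb_path = out / f"{name}_ensemble.pdb"
        write_frames(frameset_from_ensemble(ensemble), pdb_path,
                     remarks=[prov_tag, f"chain {name}"])
        written[f"{name}/ensemble"] = pdb_path

        # per-frame pucker table for the most internal disaccharide
        sel = most_internal_disaccharide(topo.n_residues)
        rows = []
        for f in range(ensemble.n_frames):
            for rid in sel:
                st = cremer_pople(ensemble.coords[f, list(topo.ring_indices[rid])])
                lab = classify_conformer(st)
                x, y = sinusoidal_projection(st)
                rows.append({
                    "frame": f, "residue": rid, "Q": st.Q, "theta": st.theta,
                    "phi": st.phi, "label": lab.name, "class": lab.conformer_class,
                    "proj_x": x, "proj_y": y,
                })
        import pandas as pd

        pucker_path = out / f"{name}_pucker.csv"
        _write_csv(pd.DataFrame(rows), pucker_path, prov_tag)
        written[f"{name}/pucker"] = pucker_path

        freq = pucker_frequencies(ensemble.coords, topo.ring_indices,
                                  residues=sel, group_skew_boat=True)
        freq_path = out / f"{name}_pucker_frequencies.csv"
        _write_csv(freq, freq_path, prov_tag)
        written[f"{name}/pucker_frequencies"] = freq_path

        series = geometry_series(ensemble.coords, topo)
        geom_path = out / f"{name}_geometry.csv"
        _write_csv(series.to_frame(), geom_path, prov_tag)
        written[f"{name}/geometry"] = geom_path

        hist = length_histogram(series.end_to_end, bin_width=config.bin_width)
        hist_path = out / f"{name}_end_to_end_histogram.csv"
        _write_csv(hist, hist_path, prov_tag)
        written[f"{name}/histogram"] = hist_path

        summary[name] = {
            "seed": seeds[name],
            "n_frames": ensemble.n_frames,
            "mean_end_to_end": float(np.mean(series.end_to_end)),
            "std_end_to_end": float(np.std(series.end_to_end)),
            "mean_angle_by_het": {
                het: float(np.mean(series.angles[:, [i for i, h in
                                                     enumerate(series.heteroatoms)
                                                     if h == het]]))
                for het in sorted(set(series.heteroatoms))
            },
        }

    prov = {
        "tool": "thiogag",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "numpy": np.__version__,
        "chains": {n: len(c.residues) for n, c in config.chains.items()},
        "summary": summary,
    }
    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    written["provenance"] = prov_path
    return written
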