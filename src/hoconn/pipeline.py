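"""End-to-end orchestration: simulate or ingest, metrics, ICC, summaries.

A run takes a :class:`RunConfig` (constructible from YAML), executes the
requested stages, and writes a deterministic directory layout:

    <out>/
      manifest.json                  run config, seed, per-stage log, file hashes
      atlas.tsv                      the region table used
      timeseries/<sub>_<ses>.tsv     simulated input (simulate mode only)
      metrics/<metric>_icc.tsv       per-connection ICC map
      metrics/<metric>_summary.json  category counts/percentages
      dhofc/omega<w>_mean.tsv        group-mean dHOFC per window length
      dhofc/omega<w>_summary.json    strong-link reliability summary

Re-running with the same config and seed reproduces every numeric output
byte-identically (full-precision decimal text).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import io as hio
from . import reliability as rel
from .dynamic import STRONG_DHOFC_THRESHOLD, WindowSpec, compute_dhofc, threshold_strong
from .simulate import Modulator, SimulationConfig, simulate_dataset
from .static import compute_ahofc, compute_lofc, compute_thofc

__all__ = ["RunConfig", "run", "load_config"]

log = logging.getLogger(__name__)

VALID_METRICS = ("LOFC", "tHOFC", "aHOFC", "dHOFC")


@dataclass(frozen=True)
class RunConfig:
    mode: str = "simulate"                      # "simulate" | "ingest"
    metrics: tuple[str, ...] = ("LOFC",)
    out_dir: str = "hoconn_run"
    seed: int = 0
    # simulate mode
    n_subjects: int = 5
    n_sessions: int = 3
    T: int = 295
    tr_seconds: float = 2.0
    networks: tuple[int, ...] = (6, 6)          # regions per simulated network
    network_names: tuple[str, ...] = ()
    within_network_r: float = 0.5
    between_network_r: float = 0.1
    subject_sd: float = 0.15
    session_sd: float = 0.10
    modulators: tuple[dict, ...] = ()
    # ingest mode
    input_dir: str | None = None
    atlas_path: str | None = None
    # dHOFC options
    dhofc_networks: tuple[str, str] | None = None
    dhofc_rois: tuple[str, ...] = ()
    omega_sweep: tuple[int, ...] = (30,)
    step: int = 1
    strong_threshold: float = STRONG_DHOFC_THRESHOLD

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise ValueError("mode must be 'simulate' or 'ingest'")
        bad = [m for m in self.metrics if m not in VALID_METRICS]
        if bad:
            raise ValueError(f"unknown metrics {bad}; valid: {VALID_METRICS}")
        if not self.metrics:
            raise ValueError("at least one metric required")
        if "dHOFC" in self.metrics and not self.omega_sweep:
            raise ValueError("omega_sweep must be non-empty when dHOFC is requested")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML mapping (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("metrics", "networks", "network_names", "omega_sweep", "dhofc_rois", "modulators"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(
                tuple(v) if isinstance(v, list) else v for v in raw[key]
            )
    if "dhofc_networks" in raw and raw["dhofc_networks"] is not None:
        raw["dhofc_networks"] = tuple(raw["dhofc_networks"])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    written: list[Path] = []

    def record(stage: str, **info) -> None:
        stages.append({"stage": stage, **info})
        log.info("stage %s: %s", stage, info)

    # --- inputs -----------------------------------------------------------
    if config.mode == "simulate":
        from .simulate import two_network_atlas

        names = config.network_names or tuple(
            f"Net{i + 1}" for i in range(len(config.networks))
        )
        atlas = two_network_atlas(config.networks, names)
        mods = tuple(Modulator(**m) for m in config.modulators)
        sim_cfg = SimulationConfig(
            atlas=atlas,
            n_subjects=config.n_subjects,
            n_sessions=config.n_sessions,
            T=config.T,
            tr_seconds=config.tr_seconds,
            within_network_r=config.within_network_r,
            between_network_r=config.between_network_r,
            subject_sd=config.subject_sd,
            session_sd=config.session_sd,
            modulators=mods,
            seed=config.seed,
        )
        tset, _truth = simulate_dataset(sim_cfg)
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        for (sub, ses), ts in tset.entries.items():
            p = ts_dir / f"{sub}_{ses}.tsv"
            hio.write_timeseries(ts, p)
            written.append(p)
        record("simulate", n_subjects=config.n_subjects, n_sessions=config.n_sessions, T=config.T)
    else:
        if not config.input_dir or not config.atlas_path:
            raise ValueError("ingest mode requires input_dir and atlas_path")
        atlas = hio.read_atlas(config.atlas_path)
        tset = _ingest(Path(config.input_dir), config.tr_seconds)
        record("ingest", n_entries=len(tset.entries))

    atlas_path = out / "atlas.tsv"
    hio.write_atlas(atlas, atlas_path)
    written.append(atlas_path)

    # --- static metrics and ICC ------------------------------------------
    met_dir = out / "metrics"
    met_dir.mkdir(exist_ok=True)
    static_requested = [m for m in config.metrics if m != "dHOFC"]
    if static_requested:
        per_subject: dict[str, list[list[hio.ConnectivityMatrix]]] = {
            m: [] for m in static_requested
        }
        for sub in tset.subjects:
            rows: dict[str, list] = {m: [] for m in static_requested}
            for ses in tset.sessions:
                lofc = compute_lofc(tset.get(sub, ses))
                cache = {"LOFC": lofc}
                if "tHOFC" in static_requested or "aHOFC" in static_requested:
                    cache["tHOFC"] = compute_thofc(lofc)
                if "aHOFC" in static_requested:
                    cache["aHOFC"] = compute_ahofc(lofc, cache["tHOFC"])
                for m in static_requested:
                    rows[m].append(cache[m])
            for m in static_requested:
                per_subject[m].append(rows[m])
        for m in static_requested:
            rmap = rel.icc_map(per_subject[m], metric=m)
            icc_mat = hio.ConnectivityMatrix(rmap.icc, "ICC", rmap.roi_ids)
            p = met_dir / f"{m.lower()}_icc.tsv"
            hio.write_matrix(icc_mat, p)
            written.append(p)
            summary = rel.summarize_reliability(rmap)
            sp = met_dir / f"{m.lower()}_summary.json"
            _write_json(summary, sp)
            written.append(sp)
            record(f"icc_{m}", n_connections=summary["n_connections"],
                   n_undefined=summary["n_undefined"])

    # --- dHOFC sweep ------------------------------------------------------
    if "dHOFC" in config.metrics:
        dh_dir = out / "dhofc"
        dh_dir.mkdir(exist_ok=True)
        if config.dhofc_rois:
            rois: Sequence[str] = config.dhofc_rois
        elif config.dhofc_networks:
            rois = [
                r
                for net in config.dhofc_networks
                for r in atlas.rois_in(net)
            ]
        else:
            rois = atlas.roi_ids
        for omega in config.omega_sweep:
            spec = WindowSpec(omega=omega, step=config.step)
            stacks = []
            hypernodes = None
            for sub in tset.subjects:
                row = []
                for ses in tset.sessions:
                    h = compute_dhofc(
                        tset.get(sub, ses), rois, spec,
                        atlas=atlas if config.dhofc_networks else None,
                        networks=config.dhofc_networks,
                    )
                    hypernodes = h.hypernodes
                    row.append(h.values)
                stacks.append(row)
            arr = np.asarray(stacks)                     # (S, k, P, P)
            mean_dh = np.nanmean(arr, axis=(0, 1))
            node_ids = tuple("|".join(p) for p in hypernodes)
            mp = dh_dir / f"omega{omega}_mean.tsv"
            hio.write_matrix(hio.ConnectivityMatrix(mean_dh, "dHOFC", node_ids), mp)
            written.append(mp)
            rmap = rel.icc_map(arr, metric="ICC")
            strong = threshold_strong(mean_dh, config.strong_threshold)
            summary = {
                "omega": omega,
                "window_seconds": spec.seconds(config.tr_seconds),
                "n_hypernodes": len(hypernodes),
                "n_unique_hyperlinks": len(hypernodes) * (len(hypernodes) - 1) // 2,
                "n_strong": int(strong[np.triu_indices_from(strong, k=1)].sum()),
                "all_links": rel.summarize_reliability(rmap),
            }
            if summary["n_strong"] > 0:
                summary["strong_links"] = rel.summarize_reliability(rmap, mask=strong)
            sp = dh_dir / f"omega{omega}_summary.json"
            _write_json(summary, sp)
            written.append(sp)
            record(f"dhofc_omega{omega}", n_strong=summary["n_strong"])

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": stages,
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(written)},
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def _ingest(input_dir: Path, tr_seconds: float) -> hio.ROITimeSeriesSet:
    """Read ``<subject>_<session>.tsv`` files into a complete design."""
    entries = {}
    subjects: list[str] = []
    sessions: list[str] = []
    for p in sorted(input_dir.glob("*.tsv")):
        stem = p.stem
        if "_" not in stem:
            raise ValueError(f"cannot parse subject/session from {p.name}")
        sub, ses = stem.rsplit("_", 1)
        entries[(sub, ses)] = hio.read_timeseries(p, tr_seconds=tr_seconds)
        if sub not in subjects:
            subjects.append(sub)
        if ses not in sessions:
            sessions.append(ses)
    if not entries:
        raise ValueError(f"no .tsv time series found in {input_dir}")
    return hio.ROITimeSeriesSet(entries, tuple(subjects), tuple(sessions))
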