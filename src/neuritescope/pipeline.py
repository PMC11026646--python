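"""Config-driven experiment orchestration.

``run_stage`` executes one stage (``simulate``, ``mito``, ``kymo``,
``morpho``, ``ephys`` or ``report``) over a YAML-described experiment layout
(groups x conditions), writing CSV tables, a summary JSON and a provenance
log into the output directory.  Runs are deterministic for a fixed config
and seed; table floats are rounded to six significant digits at write time
so re-runs diff byte-identically.

The simulate stage writes calibrated TIFFs, ROI JSON, HDF5 recordings and
ground-truth CSVs plus a manifest; the analysis stages read the manifest (or
one assembled by hand for real data) and write their result tables; the
report stage assembles group comparisons with standard statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from . import ephys as E
from . import kymo as K
from . import mito as M
from . import morpho as Mo
from .images import read_image, read_series, read_stack, write_image, write_series, write_stack
from .io import read_recording, spikes_table, write_recording, write_table
from .roi import load_rois, save_rois
from .stats import compare_groups
from .synth import (
    SimParams,
    gen_mea_recording,
    gen_mito_series,
    gen_neurite_image,
    gen_synapse_channels,
    gen_zstack,
)

STAGES = ("simulate", "mito", "kymo", "morpho", "ephys", "report")


@dataclasses.dataclass
class ExperimentConfig:
    outdir: Path
    seed: int = 0
    units: list[dict] = dataclasses.field(default_factory=list)  # group/condition layout
    sim: dict = dataclasses.field(default_factory=dict)          # per-scene param overrides
    stage_params: dict = dataclasses.field(default_factory=dict)  # per-stage config blocks
    comparisons: list[dict] = dataclasses.field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "ExperimentConfig":
        known = {"outdir", "seed", "units", "sim", "stage_params", "comparisons"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config needs an 'outdir'")
        out = Path(raw["outdir"])
        if not out.is_absolute():
            out = base / out
        return cls(
            outdir=out,
            seed=int(raw.get("seed", 0)),
            units=list(raw.get("units", [])),
            sim=dict(raw.get("sim", {})),
            stage_params=dict(raw.get("stage_params", {})),
            comparisons=list(raw.get("comparisons", [])),
        )

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir), "seed": self.seed, "units": self.units,
            "sim": self.sim, "stage_params": self.stage_params,
            "comparisons": self.comparisons,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class ResultsBundle:
    stage: str
    tables: dict[str, pd.DataFrame]
    paths: dict[str, Path]
    log: list[str]

    def write_log(self, outdir: Path) -> Path:
        path = outdir / f"{self.stage}.log"
        path.write_text("\n".join(self.log) + "\n")
        return path


def demo_config(outdir, seed: int = 0) -> ExperimentConfig:
    """A small 2-group x 2-condition layout that runs in seconds."""
    units = [
        {"group": g, "condition": c}
        for g in ("control", "lrrk2") for c in ("PBS", "KA")
    ]
    sim = {
        "mito_series": {"n_tunnels": 4, "n_stationary": 12, "n_motile": 2,
                        "tunnel_length_um": 60.0, "n_frames": 30},
        "neurites": {"n_neurites": 2, "n_termini": 5, "image_shape": [256, 256]},
        "synapses": {"n_puncta": 6, "image_shape": [256, 256],
                     "overlap_diameters_um": [1.0, 1.0, 1.0]},
        "zstack": {"n_slices": 16, "signal_slices": [4, 10], "stack_shape": [64, 64]},
        "mea": {"n_channels": 4, "duration": 60.0,
                "firing_rate_hz": 1.0, "coupled_pairs": [[0, 1, 52.0, 0.8]]},
    }
    comparisons = [
        {"table": "kymo_summary", "value": "motile_ratio", "group": "group"},
        {"table": "mito_counts", "value": "count", "group": "group"},
        {"table": "morpho", "value": "n_boutons", "group": "group"},
        {"table": "ephys_summary", "value": "network_mfr_hz", "group": "group"},
    ]
    return ExperimentConfig(outdir=Path(outdir), seed=seed, units=units, sim=sim,
                            comparisons=comparisons)


def _unit_key(unit: dict) -> str:
    return f"{unit['group']}_{unit['condition']}"


def _sim_params(cfg: ExperimentConfig, unit: dict, scene: str, offset: int) -> SimParams:
    overrides = dict(cfg.sim.get(scene, {}))
    overrides.update(unit.get(scene, {}))
    overrides["seed"] = int(
        hashlib.sha256(f"{cfg.seed}/{_unit_key(unit)}/{scene}".encode()).hexdigest()[:8],
        16,
    ) + offset
    return SimParams.from_dict(overrides)


def _stage_cfg(cfg: ExperimentConfig, name: str, cls):
    return cls(**cfg.stage_params.get(name, {}))


def run_stage(stage: str, cfg: ExperimentConfig) -> ResultsBundle:
    """Run one pipeline stage over the experiment layout."""
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    log = [f"neuritescope {__version__}", f"stage {stage}", f"config {cfg.digest()}"]
    handler = {
        "simulate": _run_simulate, "mito": _run_mito, "kymo": _run_kymo,
        "morpho": _run_morpho, "ephys": _run_ephys, "report": _run_report,
    }[stage]
    bundle = handler(cfg, log)
    for name, table in bundle.tables.items():
        path = cfg.outdir / f"{name}.csv"
        write_table(path, table)
        bundle.paths[name] = path
    bundle.write_log(cfg.outdir)
    return bundle


def _manifest_path(cfg: ExperimentConfig) -> Path:
    return cfg.outdir / "manifest.json"


def _load_manifest(cfg: ExperimentConfig) -> dict:
    path = _manifest_path(cfg)
    if not path.exists():
        raise FileNotFoundError(f"{path} not found; run the simulate stage first "
                                "or provide a manifest for your own data")
    return json.loads(path.read_text())


def _run_simulate(cfg: ExperimentConfig, log: list[str]) -> ResultsBundle:
    manifest: dict = {"units": []}
    for unit in cfg.units:
        key = _unit_key(unit)
        unit_dir = cfg.outdir / key
        unit_dir.mkdir(parents=True, exist_ok=True)
        entry: dict = {"group": unit["group"], "condition": unit["condition"], "key": key}

        if "mito_series" in cfg.sim:
            p = _sim_params(cfg, unit, "mito_series", 0)
            series, truth = gen_mito_series(p)
            write_series(unit_dir / "mito_series.tif", series)
            save_rois(unit_dir / "mito_series.rois.json", p.tunnel_rois())
            truth.to_csv(unit_dir / "mito_series.truth.csv")
            entry["mito_series"] = str(unit_dir / "mito_series.tif")
            entry["rois"] = str(unit_dir / "mito_series.rois.json")
        if "neurites" in cfg.sim:
            p = _sim_params(cfg, unit, "neurites", 0)
            img, truth = gen_neurite_image(p)
            write_image(unit_dir / "neurites.tif", img)
            truth.to_csv(unit_dir / "neurites.truth.csv")
            entry["neurites"] = str(unit_dir / "neurites.tif")
        if "synapses" in cfg.sim:
            p = _sim_params(cfg, unit, "synapses", 0)
            chan_a, chan_b, truth = gen_synapse_channels(p)
            write_image(unit_dir / "piccolo.tif", chan_a)
            write_image(unit_dir / "psd95.tif", chan_b)
            truth.to_csv(unit_dir / "synapses.truth.csv")
            entry["piccolo"] = str(unit_dir / "piccolo.tif")
            entry["psd95"] = str(unit_dir / "psd95.tif")
        if "zstack" in cfg.sim:
            p = _sim_params(cfg, unit, "zstack", 0)
            stack, truth = gen_zstack(p)
            write_stack(unit_dir / "zstack.tif", stack)
            truth.to_json(unit_dir / "zstack.truth.json")
            entry["zstack"] = str(unit_dir / "zstack.tif")
        if "mea" in cfg.sim:
            p = _sim_params(cfg, unit, "mea", 0)
            rec, truth = gen_mea_recording(p)
            write_recording(unit_dir / "recording.h5", rec)
            truth.to_csv(unit_dir / "recording.truth.csv")
            entry["recording"] = str(unit_dir / "recording.h5")

        manifest["units"].append(entry)
        log.append(f"simulated {key}")
    _manifest_path(cfg).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ResultsBundle("simulate", {}, {"manifest": _manifest_path(cfg)}, log)


def _run_mito(cfg: ExperimentConfig, log: list[str]) -> ResultsBundle:
    manifest = _load_manifest(cfg)
    mcfg = _stage_cfg(cfg, "mito", M.MitoConfig)
    count_rows, height_rows = [], []
    for entry in manifest["units"]:
        if "mito_series" in entry:
            series = read_series(entry["mito_series"])
            rois = load_rois(entry["rois"])
            frame = series.frame(0)
            for roi in rois:
                det = M.detect_mitochondria(roi.crop_image(frame), mcfg, roi.tunnel_id)
                count_rows.append(dict(group=entry["group"], condition=entry["condition"],
                                       unit=entry["key"], tunnel=roi.tunnel_id,
                                       count=det.count))
            log.append(f"mito counts {entry['key']}: {len(rois)} tunnels")
        if "zstack" in entry:
            res = M.zstack_height(read_stack(entry["zstack"]), mcfg)
            height_rows.append(dict(group=entry["group"], condition=entry["condition"],
                                    unit=entry["key"], height_um=res.height_um))
            log.append(f"zstack height {entry['key']}: {res.height_um}")
    tables = {"mito_counts": pd.DataFrame(count_rows)}
    if height_rows:
        tables["zstack_heights"] = pd.DataFrame(height_rows)
    return ResultsBundle("mito", tables, {}, log)


def _run_kymo(cfg: ExperimentConfig, log: list[str]) -> ResultsBundle:
    manifest = _load_manifest(cfg)
    kcfg = _stage_cfg(cfg, "kymo", K.KymoConfig)
    all_tracks, all_summary = [], []
    for entry in manifest["units"]:
        if "mito_series" not in entry:
            log.append(f"kymo: {entry['key']} has no series, skipped")
            continue
        series = read_series(entry["mito_series"])
        rois = load_rois(entry["rois"])
        tracks, summary, kymos = K.analyze_series(series, rois, kcfg)
        for frame_cols in (tracks, summary):
            frame_cols.insert(0, "unit", entry["key"])
            frame_cols.insert(0, "condition", entry["condition"])
            frame_cols.insert(0, "group", entry["group"])
        all_tracks.append(tracks)
        all_summary.append(summary)
        kymo_stack = np.stack([k.matrix for k in kymos])
        tifffile.imwrite(Path(entry["mito_series"]).with_suffix(".kymographs.tif"),
                         np.clip(np.rint(kymo_stack), 0, 65535).astype("uint16"),
                         photometric="minisblack")
        log.append(f"kymo {entry['key']}: {len(kymos)} kymographs, {len(tracks)} tracks")
    return ResultsBundle("kymo", {
        "kymo_tracks": pd.concat(all_tracks, ignore_index=True) if all_tracks else pd.DataFrame(),
        "kymo_summary": pd.concat(all_summary, ignore_index=True) if all_summary else pd.DataFrame(),
    }, {}, log)


def _run_morpho(cfg: ExperimentConfig, log: list[str]) -> ResultsBundle:
    manifest = _load_manifest(cfg)
    ocfg = _stage_cfg(cfg, "morpho", Mo.MorphoConfig)
    rows, syn_rows = [], []
    for entry in manifest["units"]:
        if "neurites" in entry:
            img = read_image(entry["neurites"])
            res = Mo.count_boutons(img, ocfg)
            rows.append(dict(group=entry["group"], condition=entry["condition"],
                             unit=entry["key"], n_boutons=res.n_boutons,
                             neurite_area_um2=res.neurite_area_um2,
                             density_per_um2=res.density_per_um2))
            log.append(f"morpho {entry['key']}: {res.n_boutons} boutons")
        if "piccolo" in entry and "psd95" in entry:
            res = Mo.synapse_cooccurrence(read_image(entry["piccolo"]),
                                          read_image(entry["psd95"]), ocfg)
            syn_rows.append(dict(group=entry["group"], condition=entry["condition"],
                                 unit=entry["key"], n_overlaps=res.n_overlaps,
                                 mean_size_um=res.mean_size_um,
                                 n_excluded=res.n_excluded))
    tables = {"morpho": pd.DataFrame(rows)}
    if syn_rows:
        tables["synapses"] = pd.DataFrame(syn_rows)
    return ResultsBundle("morpho", tables, {}, log)


def _run_ephys(cfg: ExperimentConfig, log: list[str]) -> ResultsBundle:
    manifest = _load_manifest(cfg)
    ecfg = _stage_cfg(cfg, "ephys", E.EphysConfig)
    spike_rows, summary_rows, conn_rows = [], [], []
    for entry in manifest["units"]:
        if "recording" not in entry:
            log.append(f"ephys: {entry['key']} has no recording, skipped")
            continue
        rec = read_recording(entry["recording"])
        trains = E.detect_spikes(E.bandpass(rec, ecfg), ecfg)
        rates = E.mean_firing_rate(trains, rec.duration, ecfg)
        binned = [E.bin_spikes(t, ecfg.bin_ms) for t in trains]
        cm = E.network_correlation(binned, ecfg)
        st = spikes_table(trains)
        st.insert(0, "unit", entry["key"])
        spike_rows.append(st)
        pairs = cm.pairs.copy()
        pairs.insert(0, "unit", entry["key"])
        conn_rows.append(pairs)
        summary_rows.append(dict(
            group=entry["group"], condition=entry["condition"], unit=entry["key"],
            network_mfr_hz=rates.network_mean, mfr_sd=rates.network_sd,
            n_active=len(cm.active_electrodes),
            total_network_correlation=cm.total_network_correlation,
            n_included_pairs=cm.n_included,
        ))
        log.append(f"ephys {entry['key']}: MFR {rates.network_mean:.3g} Hz, "
                   f"total r {cm.total_network_correlation:.3g}")
    return ResultsBundle("ephys", {
        "spikes": pd.concat(spike_rows, ignore_index=True) if spike_rows else pd.DataFrame(),
        "connectivity": pd.concat(conn_rows, ignore_index=True) if conn_rows else pd.DataFrame(),
        "ephys_summary": pd.DataFrame(summary_rows),
    }, {}, log)


def _run_report(cfg: ExperimentConfig, log: list[str]) -> ResultsBundle:
    frames = []
    for comp in cfg.comparisons:
        table_path = cfg.outdir / f"{comp['table']}.csv"
        if not table_path.exists():
            log.append(f"report: {table_path.name} missing, comparison skipped")
            continue
        table = pd.read_csv(table_path)
        res = compare_groups(table, value=comp["value"], group=comp.get("group", "group"),
                             paired_on=comp.get("paired_on"),
                             measure=f"{comp['table']}.{comp['value']}")
        frames.append(res)
        log.append(f"report: compared {comp['table']}.{comp['value']}")
    stats = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return ResultsBundle("report", {"statistics": stats}, {}, log)
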