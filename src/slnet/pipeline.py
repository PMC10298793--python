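"""End-to-end orchestration: recordings -> band filtering -> SL -> graphs ->
metrics -> statistics -> channel clustering -> report tables.

One :class:`PipelineConfig` drives the whole run. Per band the pipeline
produces a metrics table (one row per subject and task), pairwise U-test
p-value tables for SWN and global efficiency, Friedman tables over the three
difficulty levels of each task type, a cluster report, a
differentiating-element summary, and a JSON manifest sufficient to
reproduce the run (config echo, seeds, package version).

Connectivity granularity: the per-subject/task graph (SWN, Eg) is built from
the *mean* SL matrix over that task's epochs, while the clustering stage
needs nodal efficiency per stimulus and therefore uses one graph per epoch.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .channel_clustering import (
    E_TASKS,
    P_TASKS,
    build_feature_table,
    cluster_channels,
    differentiating_elements,
    match_cluster_groups,
)
from .graph_metrics import binarize_by_density, compute_metrics, nodal_efficiency
from .group_stats import friedman_test, pairwise_task_table
from .recordings import (
    BAND_BY_NAME,
    MONTAGE,
    BandDefinition,
    MultichannelRecording,
    bandpass_filter,
    read_recording,
    segment_epochs,
)
from .sync_likelihood import SLParameters, default_sl_params, mean_sl, sl_matrix
from .synthetic import MAIN_TASKS, Session, SessionSpec, simulate_session

logger = logging.getLogger("slnet.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    session: SessionSpec | None = None          # synthetic input
    recording_paths: tuple[str, ...] = ()       # or files on disk
    events_paths: tuple[str, ...] = ()
    input_format: str = "delimited"
    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")
    sl_params: SLParameters | None = None       # None = band-adapted recipe
    sl_pref: float = 0.05
    graph_density: float = 0.2
    null_realizations: int = 100
    el_normalization: str = "per_node"
    cluster_k: int = 3
    cluster_tasks: tuple[str, ...] = MAIN_TASKS
    seed: int = 0
    out_dir: str | None = None
    persist_intermediates: bool = True

    def __post_init__(self) -> None:
        if self.session is None and not self.recording_paths:
            raise ValueError("config needs a synthetic session or input paths")
        for b in self.bands:
            if b not in BAND_BY_NAME:
                raise ValueError(f"unknown band {b!r}")
        if not 0 < self.graph_density <= 1:
            raise ValueError("graph_density must lie in (0, 1]")


@dataclass
class PipelineResult:
    """In-memory report bundle of one run (also written to out_dir)."""

    metrics: pd.DataFrame                       # subject x task x band rows
    pairwise_p: dict[tuple[str, str], pd.DataFrame]   # (band, metric) -> table
    friedman: pd.DataFrame
    clusters: dict[str, pd.DataFrame]           # band -> channel report
    differentiating: pd.DataFrame
    manifest: dict


def _collect_epochs(config: PipelineConfig):
    """Epochs keyed (subject, task, stimulus) from synthetic or file input."""
    if config.session is not None:
        session = simulate_session(config.session)
        fs = config.session.coupling.fs
        return session.epochs, fs
    epochs: dict[tuple[str, str, int], MultichannelRecording] = {}
    fs = None
    events_paths = config.events_paths or (None,) * len(config.recording_paths)
    for path, epath in zip(config.recording_paths, events_paths):
        rec, events = read_recording(path, config.input_format, epath)
        fs = rec.fs
        for ep in segment_epochs(rec, events):
            epochs[(ep.subject, ep.task, ep.stimulus)] = ep.recording
    if not epochs:
        raise ValueError("no epochs found in input files")
    return epochs, fs


def _band_params(config: PipelineConfig, band: BandDefinition,
                 fs: float, n_samples: int) -> SLParameters:
    if config.sl_params is not None:
        return config.sl_params
    return default_sl_params(band, fs, n_samples, pref=config.sl_pref)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and return (and optionally write) the report."""
    t_start = time.time()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    epochs, fs = _collect_epochs(config)
    keys = sorted(epochs)
    subjects = sorted({k[0] for k in keys})
    tasks = [t for t in (config.session.tasks if config.session else
                         dict.fromkeys(k[1] for k in keys))
             if any(k[1] == t for k in keys)]
    stimuli = sorted({k[2] for k in keys})
    n_channels = epochs[keys[0]].n_channels
    logger.info("collected %d epochs (%d subjects, %d tasks)",
                len(keys), len(subjects), len(tasks))

    metric_rows = []
    pairwise: dict[tuple[str, str], pd.DataFrame] = {}
    friedman_rows = []
    cluster_reports: dict[str, pd.DataFrame] = {}
    diff_rows = []
    rng_root = np.random.SeedSequence(config.seed)

    for bi, band_name in enumerate(config.bands):
        band = BAND_BY_NAME[band_name]
        stage = f"band {band_name}"
        try:
            params = _band_params(config, band, fs,
                                  epochs[keys[0]].n_samples)
            logger.info("%s: SL params m=%d lag=%d w1=%d w2=%d",
                        stage, params.m, params.lag, params.w1, params.w2)

            # --- SL per epoch ------------------------------------------------
            sl_by_key = {}
            for key in keys:
                filtered = bandpass_filter(epochs[key], band)
                sl_by_key[key] = sl_matrix(filtered, params, band=band_name,
                                           epoch_id="/".join(map(str, key)))

            # --- per subject/task graphs (mean SL) and metrics ---------------
            el_per_epoch = np.full(
                (len(subjects), len(tasks), len(stimuli), n_channels), np.nan
            )
            band_seed = np.random.SeedSequence(config.seed, spawn_key=(bi,))
            null_seed_base = int(band_seed.generate_state(1)[0] % (2**31))
            for si, subject in enumerate(subjects):
                for ti, task in enumerate(tasks):
                    mats = [sl_by_key[k] for k in keys
                            if k[0] == subject and k[1] == task]
                    if not mats:
                        continue
                    msl = mean_sl(mats)
                    adj = binarize_by_density(msl, config.graph_density)
                    gm = compute_metrics(
                        adj,
                        null_realizations=config.null_realizations,
                        seed=null_seed_base + si * len(tasks) + ti,
                        el_normalization=config.el_normalization,
                    )
                    row = {
                        "band": band_name, "subject": subject, "task": task,
                        "L": gm.L, "C": gm.C, "SWN": gm.SWN, "Eg": gm.Eg,
                        "connected": gm.connected,
                    }
                    for c in range(n_channels):
                        row[f"Ch{c + 1:02d}"] = gm.El[c]
                    metric_rows.append(row)
                    if out_dir and config.persist_intermediates:
                        inter = out_dir / "intermediate" / band_name
                        inter.mkdir(parents=True, exist_ok=True)
                        np.savetxt(inter / f"sl_{subject}_{task}.tsv",
                                   msl.values, delimiter="\t", fmt="%.6g")
                        np.savetxt(inter / f"adj_{subject}_{task}.tsv",
                                   adj.a, delimiter="\t", fmt="%d")

                    # per-epoch nodal efficiency for the clustering stage
                    if task in config.cluster_tasks:
                        for k in keys:
                            if k[0] == subject and k[1] == task:
                                eadj = binarize_by_density(
                                    sl_by_key[k], config.graph_density
                                )
                                el_per_epoch[si, ti, stimuli.index(k[2])] = (
                                    nodal_efficiency(
                                        eadj, config.el_normalization
                                    )
                                )

            band_metrics = pd.DataFrame(
                [r for r in metric_rows if r["band"] == band_name]
            )

            # --- statistics --------------------------------------------------
            for metric in ("SWN", "Eg"):
                samples = {
                    t: band_metrics.loc[band_metrics.task == t, metric].to_numpy()
                    for t in tasks
                }
                samples = {t: v for t, v in samples.items() if v.size}
                if len(samples) >= 2:
                    pairwise[(band_name, metric)] = pairwise_task_table(samples)
                for type_name, level_tasks in (("E", E_TASKS), ("P", P_TASKS)):
                    if all(t in samples for t in level_tasks):
                        blocks = np.column_stack(
                            [samples[t] for t in level_tasks]
                        )
                        if blocks.shape[0] >= 2:
                            res = friedman_test(blocks)
                            friedman_rows.append({
                                "band": band_name, "metric": metric,
                                "task_type": type_name,
                                "statistic": res.statistic,
                                "p_value": res.p_value,
                                "n_subjects": blocks.shape[0],
                            })

            # --- channel clustering -----------------------------------------
            cl_tasks = [t for t in config.cluster_tasks if t in tasks]
            if len(cl_tasks) >= 2 and len(stimuli) >= 2:
                assignments = {}
                for t in cl_tasks:
                    ti = tasks.index(t)
                    table = build_feature_table(
                        el_per_epoch[:, ti], band=band_name, task=t
                    )
                    assignments[t] = cluster_channels(
                        table, k=config.cluster_k, seed=config.seed
                    )
                groups = match_cluster_groups(assignments)
                e_avail = [t for t in E_TASKS if t in cl_tasks]
                p_avail = [t for t in P_TASKS if t in cl_tasks]
                report = pd.DataFrame({
                    "channel": [m.channel_label for m in MONTAGE[:n_channels]],
                    "electrode": [m.electrode for m in MONTAGE[:n_channels]],
                    "brodmann": ["/".join(map(str, m.brodmann))
                                 for m in MONTAGE[:n_channels]],
                })
                for t in cl_tasks:
                    report[f"cluster_{t}"] = assignments[t].labels
                diff_e_all: set[int] = set()
                diff_p_all: set[int] = set()
                if e_avail and p_avail:
                    for g in groups:
                        d = differentiating_elements(g, e_avail, p_avail)
                        for ch in d["E"]:
                            diff_e_all.add(ch)
                            diff_rows.append({
                                "band": band_name, "group": g.group_id,
                                "task_type": "E", "channel": f"Ch{ch:02d}",
                                "electrode": MONTAGE[ch - 1].electrode,
                                "brodmann": "/".join(
                                    map(str, MONTAGE[ch - 1].brodmann)),
                            })
                        for ch in d["P"]:
                            diff_p_all.add(ch)
                            diff_rows.append({
                                "band": band_name, "group": g.group_id,
                                "task_type": "P", "channel": f"Ch{ch:02d}",
                                "electrode": MONTAGE[ch - 1].electrode,
                                "brodmann": "/".join(
                                    map(str, MONTAGE[ch - 1].brodmann)),
                            })
                report["differentiating"] = [
                    ("P" if i + 1 in diff_p_all else "")
                    + ("E" if i + 1 in diff_e_all else "")
                    for i in range(n_channels)
                ]
                cluster_reports[band_name] = report
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at stage [{stage}]: {exc}") from exc

    metrics = pd.DataFrame(metric_rows)
    friedman = pd.DataFrame(friedman_rows)
    differentiating = pd.DataFrame(
        diff_rows, columns=["band", "group", "task_type", "channel",
                            "electrode", "brodmann"]
    )
    manifest = {
        "package": "slnet",
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "n_epochs": len(keys),
        "elapsed_s": round(time.time() - t_start, 2),
    }

    if out_dir:
        metrics.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
        for (band_name, metric), table in pairwise.items():
            table.to_csv(out_dir / f"pvalues_{metric}_{band_name}.tsv", sep="\t")
        friedman.to_csv(out_dir / "friedman.tsv", sep="\t", index=False)
        for band_name, report in cluster_reports.items():
            report.to_csv(out_dir / f"clusters_{band_name}.tsv", sep="\t",
                          index=False)
        differentiating.to_csv(out_dir / "differentiating.tsv", sep="\t",
                               index=False)
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    return PipelineResult(
        metrics=metrics, pairwise_p=pairwise, friedman=friedman,
        clusters=cluster_reports, differentiating=differentiating,
        manifest=manifest,
    )


def _config_dict(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _config_dict(getattr(obj, f.name))
                for f in fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _config_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_dict(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML or JSON document."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "session" in doc and doc["session"] is not None:
        sdoc = dict(doc["session"])
        if "coupling" in sdoc and sdoc["coupling"] is not None:
            from .synthetic import CouplingSpec

            cdoc = dict(sdoc["coupling"])
            for key in ("groups",):
                if key in cdoc:
                    cdoc[key] = tuple(tuple(g) for g in cdoc[key])
            if "band" in cdoc:
                cdoc["band"] = tuple(cdoc["band"])
            sdoc["coupling"] = CouplingSpec(**cdoc)
        if "tasks" in sdoc:
            sdoc["tasks"] = tuple(sdoc["tasks"])
        doc["session"] = SessionSpec(**sdoc)
    if "sl_params" in doc and doc["sl_params"] is not None:
        doc["sl_params"] = SLParameters(**doc["sl_params"])
    for key in ("bands", "cluster_tasks", "recording_paths", "events_paths"):
        if key in doc and doc[key] is not None:
            doc[key] = tuple(doc[key])
    return PipelineConfig(**doc)
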