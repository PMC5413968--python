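"""End-to-end orchestration: align, bin, characterize, detect, correct.

The stages mirror the analysis contract: every dataset's model is flexibly
aligned to a reference and its map warped onto the reference grid; datasets
are grouped into resolution bins; per bin, maps low-passed to the bin
ceiling parameterize the ground-state statistical model; each dataset is
then analysed once, at its finest eligible bin — Z-map, blob detection,
per-event background correction and event maps.  Datasets failing a stage
are quarantined (excluded and reported), not fatal.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as al
from . import events as ev
from . import resolution as res
from . import stat_model as sm
from .grid_io import Dataset, read_map, read_model, write_map

__all__ = ["RunConfig", "RunSummary", "load_manifest", "run", "report"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    manifest: str | None = None
    datasets: list[Dataset] | None = None
    reference_id: str | None = None
    out_dir: str | None = None
    seed: int = 0
    # resolution management
    bins: list[float] | None = None
    bin_step: float = 0.1
    # alignment
    window: int = 7
    interpolation: str = "trilinear"
    max_voxel_residue_distance: float = 10.0
    # detection thresholds
    contour: float = 2.5
    min_peak: float = 3.0
    min_volume: float = 10.0
    merge_dist: float = 5.0
    buffer: float = 1.0
    beta_step: float = 0.01
    # characterization: use only explicitly labelled ground-state datasets
    ground_only: bool = False
    write_zmaps: bool = False
    write_event_maps: bool = True

    def __post_init__(self) -> None:
        for name in ("contour", "min_peak", "min_volume", "merge_dist",
                     "buffer", "beta_step", "bin_step"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class RunSummary:
    reference_id: str = ""
    bins: list[float] = field(default_factory=list)
    n_char: dict[float, int] = field(default_factory=dict)
    n_analysis: dict[float, int] = field(default_factory=dict)
    sigma_table: pd.DataFrame | None = None
    events: list[ev.Event] = field(default_factory=list)
    events_table: pd.DataFrame | None = None
    quarantined: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    timings: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "bins": self.bins,
            "n_char": {f"{b:.2f}": n for b, n in self.n_char.items()},
            "n_analysis": {f"{b:.2f}": n for b, n in self.n_analysis.items()},
            "n_events": len(self.events),
            "quarantined": self.quarantined,
            "warnings": self.warnings,
            "timings": {k: round(v, 3) for k, v in self.timings.items()},
        }


def load_manifest(path: str | os.PathLike) -> list[Dataset]:
    """Read a screen manifest (CSV: id, map_path, model_path, resolution,
    role) and load every dataset."""
    table = pd.read_csv(path)
    required = {"id", "map_path", "model_path", "resolution"}
    if not required <= set(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = Path(path).parent
    datasets = []
    for row in table.itertuples():
        mp, pp = Path(row.map_path), Path(row.model_path)
        if not mp.is_absolute():
            mp = base / mp
        if not pp.is_absolute():
            pp = base / pp
        datasets.append(Dataset(
            id=str(row.id),
            map=read_map(mp),
            model=read_model(pp),
            resolution=float(row.resolution),
            role=str(getattr(row, "role", "ground-state-candidate")),
        ))
    return datasets


def _default_bins(resolutions: list[float], step: float) -> list[float]:
    lo, hi = min(resolutions), max(resolutions)
    start = np.ceil(lo / step) * step
    bins = list(np.round(np.arange(start, hi + step / 2, step), 10))
    if not bins or bins[-1] < hi:
        bins.append(round(hi, 10))
    return bins


def run(config: RunConfig) -> RunSummary:
    """Execute the full multi-dataset analysis."""
    t0 = time.time()
    summary = RunSummary()
    if config.datasets is not None:
        datasets = list(config.datasets)
    elif config.manifest is not None:
        datasets = load_manifest(config.manifest)
    else:
        raise ValueError("config needs either datasets or a manifest path")
    if len(datasets) < 2:
        raise ValueError("need at least 2 usable datasets")

    # reference: highest-resolution ground-state candidate unless named
    if config.reference_id is not None:
        reference = next(d for d in datasets if d.id == config.reference_id)
    else:
        ground = [d for d in datasets if d.role != "putative-changed"]
        reference = min(ground or datasets, key=lambda d: d.resolution)
    summary.reference_id = reference.id
    ref_grid = reference.map

    # flexible alignment of every model to the reference
    alignments: dict[str, al.LocalAlignment] = {}
    usable: list[Dataset] = []
    for ds in datasets:
        try:
            alignments[ds.id] = al.flexible_alignment(
                ds.model, reference.model, window=config.window,
                reference_id=reference.id,
            )
            usable.append(ds)
        except al.AlignmentError as exc:
            summary.quarantined[ds.id] = f"alignment: {exc}"
            logger.warning("quarantined %s: %s", ds.id, exc)
    summary.timings["alignment"] = time.time() - t0
    if len(usable) < 2:
        raise ValueError("fewer than 2 datasets survived alignment")

    plan = res.assign_bins([d.resolution for d in usable],
                           config.bins or _default_bins(
                               [d.resolution for d in usable], config.bin_step))
    for i in plan.excluded:
        summary.quarantined[usable[i].id] = "coarser than the coarsest bin"
    summary.bins = plan.bins

    def prepared(ds: Dataset, ceiling: float) -> sm.DensityMap:
        truncated = res.lowpass_truncate(ds.map, ceiling)
        return al.warp_map(
            truncated, alignments[ds.id], ref_grid,
            interpolation=config.interpolation,
            max_residue_distance=config.max_voxel_residue_distance,
        )

    sigma_rows = []
    t1 = time.time()
    for ceiling in plan.bins:
        analysis_idx = plan.analysis[ceiling]
        if not analysis_idx:
            continue
        char_idx = plan.characterization[ceiling]
        char_ds = [usable[i] for i in char_idx]
        char_maps = {}
        for ds in char_ds:
            try:
                char_maps[ds.id] = prepared(ds, ceiling)
            except Exception as exc:  # robustly skip broken datasets
                summary.quarantined[ds.id] = f"preparation: {exc}"
                logger.warning("quarantined %s at %.2f Å: %s", ds.id, ceiling, exc)
        ids = list(char_maps)
        if len(ids) < 2:
            summary.warnings.append(
                f"bin {ceiling:.2f} Å skipped: fewer than 2 characterization maps"
            )
            continue
        restrict = None
        if config.ground_only:
            restrict = {d.id for d in char_ds if d.role != "putative-changed"}
        try:
            model = sm.fit_model([char_maps[i] for i in ids], ids,
                                 restrict_ground=restrict)
        except ValueError as exc:
            summary.warnings.append(f"bin {ceiling:.2f} Å: {exc}")
            continue
        summary.n_char[ceiling] = model.n_char
        summary.n_analysis[ceiling] = len(analysis_idx)
        if model.n_char < sm.CONVERGENCE_N:
            summary.warnings.append(
                f"bin {ceiling:.2f} Å: only {model.n_char} characterization "
                f"datasets (< {sm.CONVERGENCE_N}); statistics may not have converged"
            )
        for ds in char_ds:
            if ds.id in model.sigma:
                sigma_rows.append({"dataset": ds.id, "bin": ceiling,
                                   "resolution": ds.resolution,
                                   "sigma": model.sigma[ds.id]})

        for i in analysis_idx:
            ds = usable[i]
            if ds.id not in char_maps and ds.id not in model.sigma:
                continue
            amap = char_maps.get(ds.id) or prepared(ds, ceiling)
            if ds.id not in model.sigma:
                model.sigma[ds.id] = sm.estimate_sigma(amap, model.mu)
            z = sm.zmap(amap, model, ds.id)
            found = ev.find_blobs(
                z, contour=config.contour, min_peak=config.min_peak,
                min_volume=config.min_volume, merge_dist=config.merge_dist,
            )
            for event in found:
                bdc, diag = ev.estimate_bdc(
                    amap, model.mu, event.voxels,
                    buffer=config.buffer, beta_step=config.beta_step,
                )
                event.bdc = bdc
                event.low_contrast = diag["low_contrast"]
                event.event_map = ev.event_map(amap, model.mu, bdc)
                event.diagnostics = {"bin": ceiling}
            summary.events.extend(found)

        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            write_map(model.mu, out / f"mu_{ceiling:.2f}A.ccp4")
            write_map(model.s, out / f"s_{ceiling:.2f}A.ccp4")
    summary.timings["analysis"] = time.time() - t1

    summary.sigma_table = pd.DataFrame(
        sigma_rows, columns=["dataset", "bin", "resolution", "sigma"]
    ).sort_values(["dataset", "bin"], kind="stable").reset_index(drop=True)
    rows = []
    for k, event in enumerate(summary.events):
        rows.append({
            "dataset": event.dataset_id,
            "event": k,
            "x": round(float(event.centroid[0]), 3),
            "y": round(float(event.centroid[1]), 3),
            "z": round(float(event.centroid[2]), 3),
            "peak_z": round(event.peak_z, 3),
            "volume": round(event.volume, 3),
            "bdc": None if event.bdc is None else round(event.bdc, 2),
            "one_minus_bdc": None if event.bdc is None else round(1 - event.bdc, 2),
            "low_contrast": event.low_contrast,
        })
    summary.events_table = pd.DataFrame(
        rows, columns=["dataset", "event", "x", "y", "z", "peak_z",
                       "volume", "bdc", "one_minus_bdc", "low_contrast"],
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.sigma_table.to_csv(out / "sigma.csv", index=False)
        summary.events_table.to_csv(out / "events.csv", index=False)
        if config.write_event_maps:
            emdir = out / "event_maps"
            emdir.mkdir(exist_ok=True)
            for k, event in enumerate(summary.events):
                if event.event_map is not None:
                    write_map(event.event_map,
                              emdir / f"{event.dataset_id}_event{k}.ccp4")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary.to_json_dict(), fh, indent=2, sort_keys=True)
    summary.timings["total"] = time.time() - t0
    return summary


def report(run_dir: str | os.PathLike) -> tuple[str, dict]:
    """Per-dataset summary of a completed run: resolution, bin, sigma,
    events, peak Z and BDC values.  Returns (text, machine-readable dict)."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(
            f"no run summary at {summary_path}; is {run_dir} a run directory?"
        )
    with open(summary_path) as fh:
        meta = json.load(fh)
    sigma = pd.read_csv(run_dir / "sigma.csv")
    events = pd.read_csv(run_dir / "events.csv")
    rows = []
    for ds_id, grp in sigma.groupby("dataset", sort=True):
        own = grp.loc[grp["bin"].idxmin()]
        ds_events = events[events["dataset"] == ds_id]
        rows.append({
            "dataset": ds_id,
            "resolution": float(own["resolution"]),
            "bin": float(own["bin"]),
            "sigma": float(own["sigma"]),
            "n_events": int(len(ds_events)),
            "max_peak_z": float(ds_events["peak_z"].max()) if len(ds_events) else None,
            "bdcs": [float(b) for b in ds_events["bdc"].dropna()],
        })
    table = pd.DataFrame(rows)
    lines = [
        f"reference: {meta['reference_id']}",
        f"bins (Å): {', '.join(f'{b:.2f}' for b in meta['bins'])}",
        f"events: {meta['n_events']}",
        "",
        table.to_string(index=False) if len(table) else "(no datasets)",
    ]
    if meta.get("warnings"):
        lines += ["", "warnings:"] + [f"  - {w}" for w in meta["warnings"]]
    payload = {"summary": meta, "datasets": rows}
    return "\n".join(lines), payload
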