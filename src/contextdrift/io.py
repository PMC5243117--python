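"""Reading and writing the pipeline's on-disk formats.

BOLD runs travel as 4D NIfTI plus one label NIfTI per ROI/compartment;
behavioral tables and schedules are TSV; configs are YAML. Spreadsheet
variants of the behavioral tables (the format the published source data
ship in) are read through an explicit column-mapping dict rather than
header heuristics.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datatypes import BoldRun, ClipSchedule, DurationReport
from .synthgen import SynthConfig, SynthDataset

logger = logging.getLogger("contextdrift")

__all__ = [
    "save_dataset",
    "load_bold",
    "load_schedule",
    "save_schedule",
    "load_reports",
    "save_reports",
    "load_behavior_table",
    "load_config",
]


def _grid_shape(coords: np.ndarray) -> tuple[int, int, int]:
    return tuple(int(m) + 1 for m in coords.max(axis=0))


def run_to_nifti(run: BoldRun) -> nib.Nifti1Image:
    shape = _grid_shape(run.coords)
    vol = np.zeros((*shape, run.n_trs), dtype=np.float32)
    vol[tuple(run.coords.T)] = run.data
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr))
    return img


def save_schedule(schedule: ClipSchedule, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    schedule.clips.to_csv(out_dir / "clips.tsv", sep="\t", index=False)
    schedule.intervals.to_csv(out_dir / "intervals.tsv", sep="\t", index=False)


def load_schedule(out_dir: Path) -> ClipSchedule:
    out_dir = Path(out_dir)
    return ClipSchedule(
        clips=pd.read_csv(out_dir / "clips.tsv", sep="\t"),
        intervals=pd.read_csv(out_dir / "intervals.tsv", sep="\t"),
    )


def save_reports(
    reports: list[DurationReport], schedule: ClipSchedule, path: Path
) -> None:
    """Single-table TSV: participant_id, interval_id, estimate_s, confidence,
    true_gap_s (confidence = min of the two clip ratings), plus a sibling
    ``*_clip_confidence.tsv`` carrying the raw per-clip ratings."""
    from .behavior import interval_confidence

    gaps = schedule.intervals.set_index("interval_id")["true_gap_s"]
    rows = []
    clip_rows = []
    for r in reports:
        conf = interval_confidence(r, schedule)
        for interval_id, est in r.estimates.items():
            rows.append(
                (r.participant_id, interval_id, float(est),
                 conf.loc[interval_id], float(gaps.loc[interval_id]), r.group)
            )
        for clip_id, c in r.clip_confidence.items():
            clip_rows.append((r.participant_id, clip_id, int(c)))
    path = Path(path)
    pd.DataFrame(
        rows,
        columns=["participant_id", "interval_id", "estimate_s", "confidence",
                 "true_gap_s", "group"],
    ).to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        clip_rows, columns=["participant_id", "clip_id", "confidence"]
    ).to_csv(path.with_name(path.stem + "_clip_confidence.tsv"), sep="\t",
             index=False)


def load_reports(path: Path) -> list[DurationReport]:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    required = {"participant_id", "interval_id", "estimate_s"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if not np.issubdtype(table["estimate_s"].dtype, np.number):
        bad = table[pd.to_numeric(table["estimate_s"], errors="coerce").isna()]
        raise ValueError(
            f"non-numeric estimate at row(s) {list(bad.index + 2)} of {path}"
        )
    clip_path = path.with_name(path.stem + "_clip_confidence.tsv")
    clip_conf = (
        pd.read_csv(clip_path, sep="\t") if clip_path.exists() else None
    )
    reports = []
    for pid, sub in table.groupby("participant_id", sort=True):
        est = pd.Series(
            sub["estimate_s"].to_numpy(dtype=float),
            index=sub["interval_id"].to_numpy(),
        )
        if clip_conf is not None:
            cc = clip_conf.loc[clip_conf["participant_id"] == pid]
            conf = pd.Series(cc["confidence"].to_numpy(),
                             index=cc["clip_id"].to_numpy())
        else:
            conf = pd.Series(dtype=float)
        group = sub["group"].iloc[0] if "group" in sub.columns else "original"
        reports.append(
            DurationReport(participant_id=str(pid), estimates=est,
                           clip_confidence=conf, group=str(group))
        )
    return reports


def load_behavior_table(
    path: Path, mapping: dict[str, str], sheet: str | int = 0
) -> pd.DataFrame:
    """Read a behavioral spreadsheet/TSV through an explicit column mapping.

    ``mapping`` maps canonical names (interval_id, position_s, boundaries,
    original_mean_s, naive_mean_s, ...) to the file's column headers.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path, sheet_name=sheet)
    else:
        table = pd.read_csv(path, sep="\t" if path.suffix == ".tsv" else ",")
    missing = [src for src in mapping.values() if src not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    out = table[[mapping[k] for k in mapping]].copy()
    out.columns = list(mapping)
    return out


def save_dataset(ds: SynthDataset, out_dir: Path) -> dict:
    """Write a synthetic dataset to a directory; returns a manifest dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_schedule(ds.schedule, out_dir)
    save_reports(ds.reports, ds.schedule, out_dir / "reports.tsv")
    save_reports(ds.naive_reports, ds.schedule, out_dir / "naive_reports.tsv")
    with open(out_dir / "boundaries.json", "w") as fh:
        json.dump([list(map(float, b)) for b in ds.boundaries], fh)
    ds.truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    files = ["clips.tsv", "intervals.tsv", "reports.tsv", "naive_reports.tsv",
             "boundaries.json", "truth.tsv"]
    for run in ds.runs:
        name = f"{run.participant_id}_bold.nii.gz"
        nib.save(run_to_nifti(run), out_dir / name)
        files.append(name)
    if ds.runs:
        run0 = ds.runs[0]
        shape = _grid_shape(run0.coords)
        for label in np.unique(run0.roi_labels):
            vol = np.zeros(shape, dtype=np.int16)
            idx = run0.coords[run0.roi_labels == label]
            vol[tuple(idx.T)] = 1
            name = f"mask_{label}.nii.gz"
            nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), out_dir / name)
            files.append(name)
        comp_map = {
            str(label): str(run0.compartments[run0.roi_labels == label][0])
            for label in np.unique(run0.roi_labels)
        }
        with open(out_dir / "compartments.json", "w") as fh:
            json.dump(comp_map, fh, indent=1)
        files.append("compartments.json")
    cfg = {k: v for k, v in vars(ds.config).items() if not k.startswith("_")}
    cfg["roi_specs"] = [list(vars(s).values()) for s in ds.config.roi_specs]
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    files.append("config.yaml")
    return {"files": files}


def load_bold(
    bold_path: Path,
    mask_paths: dict[str, Path],
    compartments: dict[str, str],
    participant_id: str | None = None,
) -> BoldRun:
    """Assemble a BoldRun from a 4D NIfTI and per-ROI mask NIfTIs.

    Voxels are restricted to the union of the masks; all-NaN or partially
    NaN voxels are dropped with a logged count. Mask grids must match the
    BOLD grid.
    """
    img = nib.load(str(bold_path))
    vol = np.asarray(img.dataobj, dtype=float)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    coords_list, labels = [], []
    for label, mpath in mask_paths.items():
        mask = np.asarray(nib.load(str(mpath)).dataobj) > 0
        if mask.shape != vol.shape[:3]:
            raise ValueError(
                f"mask {label!r} grid {mask.shape} does not match BOLD grid "
                f"{vol.shape[:3]}"
            )
        idx = np.argwhere(mask)
        coords_list.append(idx)
        labels.append(np.full(len(idx), label, dtype=object))
    if not coords_list or sum(len(c) for c in coords_list) == 0:
        raise ValueError("no voxels in any mask")
    coords = np.vstack(coords_list)
    roi_labels = np.concatenate(labels)
    data = vol[tuple(coords.T)]
    nan_voxels = np.isnan(data).any(axis=1)
    if nan_voxels.any():
        logger.warning("dropping %d NaN voxel(s) from %s", nan_voxels.sum(),
                       bold_path)
        coords = coords[~nan_voxels]
        roi_labels = roi_labels[~nan_voxels]
        data = data[~nan_voxels]
    comp = np.array([compartments.get(lbl, "grey") for lbl in roi_labels],
                    dtype=object)
    return BoldRun(
        participant_id=participant_id or Path(bold_path).stem.split("_")[0],
        data=data,
        tr=tr,
        coords=coords,
        compartments=comp,
        roi_labels=roi_labels,
    )


def load_config(path: Path) -> SynthConfig:
    from .synthgen import RoiSpec

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "roi_specs" in raw:
        raw["roi_specs"] = tuple(RoiSpec(*spec) for spec in raw["roi_specs"])
    if "clip_duration_range_s" in raw:
        raw["clip_duration_range_s"] = tuple(raw["clip_duration_range_s"])
    return SynthConfig(**raw)
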