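"""Reading and writing time-lapse stacks and ground-truth records.

A :class:`~pollengerm.synthetic_microscopy.TimeLapse` is stored as one
OME-TIFF per channel (axes TZYX, uint16) plus a JSON sidecar
(``acquisition.json``) holding the acquisition metadata -- pixel size,
frame interval, z spacing, noise model. The sidecar is authoritative: a
stack directory without pixel-size metadata is rejected explicitly rather
than silently assuming a default. Round-trips are lossless for integer
count data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic_microscopy import AcquisitionSpec, GroundTruth, TimeLapse
from .growth_models import GrainGeometry

__all__ = [
    "StackFormatError",
    "write_stack",
    "read_stack",
    "write_ground_truth",
    "read_ground_truth",
]

SIDECAR = "acquisition.json"


class StackFormatError(ValueError):
    """A stack directory or file violates the expected layout/metadata."""


def write_stack(tl: TimeLapse, path: str | Path) -> Path:
    """Write a time-lapse to a directory: per-channel OME-TIFF + JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = dataclasses.asdict(tl.acq)
    meta["channels"] = sorted(tl.channels)
    meta["axes"] = "TZYX"
    for name, arr in tl.channels.items():
        tifffile.imwrite(
            path / f"channel_{name}.ome.tif",
            arr,
            ome=True,
            metadata={
                "axes": "TZYX",
                "PhysicalSizeX": tl.acq.pixel_size,
                "PhysicalSizeY": tl.acq.pixel_size,
                "PhysicalSizeZ": tl.acq.z_spacing,
            },
        )
    (path / SIDECAR).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_stack(path: str | Path) -> TimeLapse:
    """Read a time-lapse written by :func:`write_stack`.

    Raises :class:`StackFormatError` naming the offending file or metadata
    key when the layout is malformed (e.g. missing pixel size).
    """
    path = Path(path)
    sidecar = path / SIDECAR
    if not sidecar.exists():
        raise StackFormatError(f"missing sidecar {sidecar}: pixel size unknown")
    meta = json.loads(sidecar.read_text())
    for key in ("pixel_size", "frame_interval", "n_slices"):
        if key not in meta or meta[key] is None:
            raise StackFormatError(f"{sidecar}: missing required metadata key {key!r}")
    names = meta.get("channels")
    if not names:
        raise StackFormatError(f"{sidecar}: missing channel list")
    acq_fields = {f.name for f in dataclasses.fields(AcquisitionSpec)}
    kwargs = {k: v for k, v in meta.items() if k in acq_fields}
    for tup in ("frame_shape", "origin"):
        if tup in kwargs:
            kwargs[tup] = tuple(kwargs[tup])
    acq = AcquisitionSpec(**kwargs)
    channels = {}
    for name in names:
        f = path / f"channel_{name}.ome.tif"
        if not f.exists():
            raise StackFormatError(f"missing channel file {f}")
        arr = tifffile.imread(f)
        # tifffile squeezes singleton axes on read; restore TZYX explicitly
        ny, nx = acq.frame_shape
        arr = np.asarray(arr).reshape(-1, acq.n_slices, ny, nx)
        channels[name] = arr
    return TimeLapse(channels, acq)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Write ground truth as JSON (scalars) + CSV event/series tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    record = {
        "germination_frame": gt.germination_frame,
        "germination_angle": gt.germination_angle,
        "grain": dataclasses.asdict(gt.grain),
        "actin_polarity_angle": gt.actin_polarity_angle,
        "actin_onset_frame": gt.actin_onset_frame,
        "mgu_frame": gt.mgu_frame,
        "mgu_area_um2": gt.mgu_area_um2,
        "transition_frame": gt.transition_frame,
        "scenario": gt.scenario,
        "germination_events": [list(e) for e in gt.germination_events],
        "branch_frame": gt.branch_frame,
    }
    (path / "ground_truth.json").write_text(json.dumps(record, indent=1, sort_keys=True))
    pd.DataFrame(
        {
            "time_min": gt.time_min,
            "area_um2": gt.area_um2,
            "roundness": gt.roundness,
        }
    ).to_csv(path / "ground_truth_series.csv", index=False)
    pd.DataFrame(
        gt.peak_events, columns=["frame", "angle", "amplitude"]
    ).to_csv(path / "ground_truth_events.csv", index=False)
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    record = json.loads((path / "ground_truth.json").read_text())
    series = pd.read_csv(path / "ground_truth_series.csv")
    events = pd.read_csv(path / "ground_truth_events.csv")
    grain_kwargs = record["grain"]
    grain_kwargs["center"] = tuple(grain_kwargs["center"])
    return GroundTruth(
        time_min=series["time_min"].to_numpy(),
        area_um2=series["area_um2"].to_numpy(),
        roundness=series["roundness"].to_numpy(),
        germination_frame=record["germination_frame"],
        germination_angle=record["germination_angle"],
        grain=GrainGeometry(**grain_kwargs),
        peak_events=[tuple(r) for r in events.itertuples(index=False)],
        actin_polarity_angle=record["actin_polarity_angle"],
        actin_onset_frame=record["actin_onset_frame"],
        mgu_frame=record["mgu_frame"],
        mgu_area_um2=record["mgu_area_um2"],
        transition_frame=record["transition_frame"],
        scenario=record["scenario"],
        germination_events=[tuple(e) for e in record["germination_events"]],
        branch_frame=record["branch_frame"],
    )
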