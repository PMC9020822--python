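"""File formats: OME-TIFF images with ground-truth sidecars, long-format
profile CSVs, partition JSONs, FLIP trace CSVs and lifespan cohort CSVs.

Every CSV written by the pipeline starts with a ``#``-prefixed provenance
line embedding the tool version, the seed, and a config hash, so two runs
with equal inputs and configuration are byte-identical; readers skip comment
lines.
"""

from __future__ import annotations

import hashlib
import json
import uuid as uuid_mod
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import ValidationError
from .flip import FlipTrace
from .lifespan import LifespanCohort
from .simulate import GroundTruth, NucleusImage
from .tracing import EnvelopeProfile, RegionPartition


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_line(seed: int | None = None, config: dict | None = None) -> str:
    parts = [f"# capscan={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return " ".join(parts)


def write_csv(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, config: dict | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, config) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def write_image(path: str | Path, image: NucleusImage, sidecar: bool = True) -> None:
    """Write an image as OME-TIFF (CYX, or ZCYX for stacks) plus an optional
    ground-truth JSON sidecar at ``<path>.json``."""
    path = Path(path)
    data = image.data
    if data.ndim == 3:
        axes = "CYX"
    elif data.ndim == 4:
        axes = "ZCYX"
    else:
        raise ValidationError("image data must be (C,Y,X) or (Z,C,Y,X)")
    payload = data.astype(np.float32)
    # deterministic UUID from content so equal (inputs, seed) give
    # byte-identical files
    digest = hashlib.sha256(payload.tobytes() + ",".join(image.channel_names).encode())
    uuid = str(uuid_mod.UUID(bytes=digest.digest()[:16], version=4))
    tifffile.imwrite(
        path,
        payload,
        ome=True,
        metadata={
            "axes": axes,
            "Channel": {"Name": image.channel_names},
            "PhysicalSizeX": image.pixel_size_um,
            "PhysicalSizeY": image.pixel_size_um,
            "UUID": f"urn:uuid:{uuid}",
        },
    )
    if sidecar and image.ground_truth is not None:
        write_ground_truth(Path(str(path) + ".json"), image.ground_truth)


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "contour": truth.contour.tolist(),
        "contour_angles": truth.contour_angles.tolist(),
        "cap_arc": truth.cap_arc.tolist(),
        "true_enrichment": truth.true_enrichment,
        "true_displaced": list(truth.true_displaced),
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        contour=np.asarray(payload["contour"]),
        contour_angles=np.asarray(payload["contour_angles"]),
        cap_arc=np.asarray(payload["cap_arc"], dtype=int),
        true_enrichment=float(payload["true_enrichment"]),
        true_displaced=tuple(payload["true_displaced"]),
        noiseless=np.empty(0),
        expected=np.empty(0),
    )


def read_image(path: str | Path) -> NucleusImage:
    """Read a TIFF/OME-TIFF image; a ``<path>.json`` sidecar, if present, is
    attached as ground truth (without the raster fields)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        names = None
        if tif.ome_metadata:
            # tifffile stores channel names in the OME-XML; fall back to indices
            import re

            names = re.findall(r'Channel[^>]*Name="([^"]+)"', tif.ome_metadata)
    if data.ndim == 2:
        data = data[None]
    if not names or len(names) != data.shape[-3]:
        names = [f"ch{i}" for i in range(data.shape[-3])]
    truth = None
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        truth = read_ground_truth(sidecar)
    return NucleusImage(data=data, channel_names=list(names), ground_truth=truth)


# ---------------------------------------------------------------------------
# profiles and partitions
# ---------------------------------------------------------------------------


def write_profile(
    path: str | Path,
    profile: EnvelopeProfile,
    cell_id: str = "",
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Long-format profile CSV: cell_id, channel, sample_index, angle_rad, value."""
    rows = []
    for c, name in enumerate(profile.channel_names):
        for i in range(profile.n_samples):
            rows.append(
                {
                    "cell_id": cell_id,
                    "channel": name,
                    "sample_index": i,
                    "angle_rad": profile.angles[i],
                    "value": profile.values[c, i],
                }
            )
    write_csv(pd.DataFrame(rows), path, seed=seed, config=config)


def read_profile(path: str | Path, cell_id: str | None = None) -> EnvelopeProfile:
    df = read_csv(path)
    if cell_id is not None:
        df = df[df["cell_id"] == cell_id]
    channels = list(dict.fromkeys(df["channel"]))
    first = df[df["channel"] == channels[0]].sort_values("sample_index")
    angles = first["angle_rad"].to_numpy()
    values = np.stack(
        [
            df[df["channel"] == ch].sort_values("sample_index")["value"].to_numpy()
            for ch in channels
        ]
    )
    return EnvelopeProfile(angles=angles, values=values, channel_names=channels, linewidth=np.nan)


def write_partition(path: str | Path, partition: RegionPartition) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "cap_indices": partition.cap_indices.tolist(),
                "rest_indices": partition.rest_indices.tolist(),
                "background": np.asarray(partition.background).tolist(),
            }
        )
    )


def read_partition(path: str | Path) -> RegionPartition:
    payload = json.loads(Path(path).read_text())
    return RegionPartition(
        cap_indices=np.asarray(payload["cap_indices"], dtype=int),
        rest_indices=np.asarray(payload["rest_indices"], dtype=int),
        background=np.asarray(payload["background"], dtype=float),
    )


# ---------------------------------------------------------------------------
# FLIP traces and lifespan cohorts
# ---------------------------------------------------------------------------


def write_flip_trace(
    path: str | Path, trace: FlipTrace, seed: int | None = None, config: dict | None = None
) -> None:
    frames = np.arange(trace.n_frames)
    df = pd.DataFrame(
        {
            "frame": frames,
            "time_s": trace.time,
            "target": trace.target,
            "control_ne": trace.control_ne,
            "adjacent_cell": trace.adjacent_cell,
            "is_bleach_frame": frames >= trace.bleach_onset_frame,
        }
    )
    write_csv(df, path, seed=seed, config=config)


def read_flip_trace(path: str | Path, label: str = "") -> FlipTrace:
    df = read_csv(path)
    onset = int(df.index[df["is_bleach_frame"].astype(bool)][0])
    return FlipTrace(
        time=df["time_s"].to_numpy(),
        target=df["target"].to_numpy(),
        control_ne=df["control_ne"].to_numpy(),
        adjacent_cell=df["adjacent_cell"].to_numpy(),
        bleach_onset_frame=onset,
        label=label,
    )


def write_cohort(
    path: str | Path, cohort: LifespanCohort, seed: int | None = None, config: dict | None = None
) -> None:
    write_csv(cohort.to_frame(), path, seed=seed, config=config)


def read_cohorts(path: str | Path) -> list[LifespanCohort]:
    """Read a cohort CSV (cell_id, strain, divisions, observed), one cohort
    per strain label."""
    df = read_csv(path)
    return [
        LifespanCohort.from_frame(g, strain=str(strain))
        for strain, g in df.groupby("strain", sort=True)
    ]


__all__ = [
    "config_hash",
    "provenance_line",
    "read_cohorts",
    "read_csv",
    "read_flip_trace",
    "read_ground_truth",
    "read_image",
    "read_partition",
    "read_profile",
    "write_cohort",
    "write_csv",
    "write_flip_trace",
    "write_ground_truth",
    "write_image",
    "write_partition",
    "write_profile",
]
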