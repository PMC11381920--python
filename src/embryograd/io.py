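"""OME-TIFF series I/O and schema-documented table output.

Per-nucleus tables are written as CSV with a leading ``# config_hash=...``
comment line for provenance (read them back with ``pandas.read_csv(...,
comment='#')``); summaries are JSON.  Images in are TIFF/OME-TIFF with axis
order taken from metadata or overridden explicitly; masks out are 16-bit
TIFF.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import EmbryoGradError
from .series import EmbryoImageSeries

FULL_AXES = "TCZYX"


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_series(series: EmbryoImageSeries, path: str | Path) -> None:
    """Write a series as OME-TIFF with TCZYX axes and pixel-size metadata."""
    tifffile.imwrite(
        str(path),
        series.data,
        ome=True,
        metadata={
            "axes": FULL_AXES,
            "PhysicalSizeX": series.pixel_size,
            "PhysicalSizeY": series.pixel_size,
            "PhysicalSizeZ": series.z_step,
            "TimeIncrement": series.time_resolution,
        },
    )


def read_series(
    path: str | Path,
    pixel_size: float | None = None,
    time_resolution: float | None = None,
    axes: str | None = None,
    channel_names: tuple[str, ...] | None = None,
    min_channels: int = 2,
) -> EmbryoImageSeries:
    """Read a TIFF/OME-TIFF into the TCZYX container.

    Axis order is inferred from the file's series metadata unless ``axes``
    overrides it; missing axes are inserted with length 1.  Raises
    EmbryoGradError("channel role unassigned") when the file has fewer than
    ``min_channels`` channels and ("axis order ambiguous") when the order
    cannot be determined.
    """
    with tifffile.TiffFile(str(path)) as tf:
        ser = tf.series[0]
        data = ser.asarray()
        file_axes = axes or ser.axes
        meta = {}
        if tf.ome_metadata:
            meta["ome"] = True
    file_axes = file_axes.upper().replace("S", "C").replace("Q", "")
    if len(file_axes) != data.ndim:
        raise EmbryoGradError(
            f"axis order ambiguous: axes {file_axes!r} vs data ndim {data.ndim}"
        )
    if not set(file_axes) <= set(FULL_AXES):
        raise EmbryoGradError(f"axis order ambiguous: unknown axes in {file_axes!r}")
    # insert missing singleton axes and transpose to TCZYX
    for ax in FULL_AXES:
        if ax not in file_axes:
            data = data[np.newaxis]
            file_axes = ax + file_axes
    data = np.transpose(data, [file_axes.index(ax) for ax in FULL_AXES])
    if data.shape[1] < min_channels:
        raise EmbryoGradError(
            f"channel role unassigned: file has {data.shape[1]} channel(s), "
            f"need {min_channels} (nuclear, signal)"
        )
    if channel_names is None:
        channel_names = tuple(
            ["nuclear", "signal"] + [f"ch{i}" for i in range(2, data.shape[1])]
        )
    return EmbryoImageSeries(
        data,
        pixel_size=pixel_size if pixel_size is not None else 1.0,
        time_resolution=time_resolution if time_resolution is not None else 30.0,
        channel_names=channel_names,
        metadata=meta,
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a labeled mask as 16-bit TIFF."""
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint16))


def write_tables(
    bundle: dict[str, pd.DataFrame | dict],
    out_dir: str | Path,
    cfg_hash: str,
    manifest_extra: dict | None = None,
) -> Path:
    """Write DataFrames as CSV and dicts as JSON, plus a run manifest.

    Every CSV starts with a ``# config_hash=`` comment; every JSON and the
    manifest carry the hash explicitly.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(f"# config_hash={cfg_hash}\n")
                obj.to_csv(fh, index=False)
        else:
            path = out_dir / f"{name}.json"
            with open(path, "w") as fh:
                json.dump({"config_hash": cfg_hash, **obj}, fh, indent=2, default=str)
        files.append(path.name)
    import embryograd

    manifest = {
        "config_hash": cfg_hash,
        "files": files,
        "embryograd_version": embryograd.__version__,
        "numpy_version": np.__version__,
        **(manifest_extra or {}),
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest_path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_tables`."""
    return pd.read_csv(path, comment="#")
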