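"""File I/O: greyscale TIFF frames, results tables, specs and configs.

Results CSVs mirror an ImageJ-style results table (columns ``Label, Area,
Perim., Circ., Solidity, EquivRadius``, micrometre units) so tables written
by either origin interoperate; floats are written at full precision and the
decimal separator is always a period.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .frames import ImageFrame
from .segmentation import ParticleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_image",
    "write_results_csv",
    "read_results_csv",
    "write_ground_truth_csv",
    "write_spec_yaml",
]

RESULT_COLUMNS = ["Label", "Area", "Perim.", "Circ.", "Solidity", "EquivRadius"]
_REQUIRED_COLUMNS = ["Area", "Perim.", "Circ.", "Solidity"]


def read_image(path, pixel_size_um: Optional[float] = None) -> ImageFrame:
    """Read a greyscale 8- or 16-bit TIFF into an :class:`ImageFrame`.

    The spatial calibration comes from the caller's configuration, never
    from TIFF tags; if the file carries a conflicting resolution tag it is
    logged and ignored.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.pages[0].asarray()
            tags = tf.pages[0].tags
            unit_tag = tags.get("ResolutionUnit")
            unit_to_um = {2: 25400.0, 3: 10000.0}.get(
                getattr(getattr(unit_tag, "value", None), "value", getattr(unit_tag, "value", None))
            )
            if pixel_size_um is not None and unit_to_um and "XResolution" in tags:
                num, den = tags["XResolution"].value
                if num and den:
                    tag_um = den / num * unit_to_um
                    if abs(tag_um - pixel_size_um) / pixel_size_um > 0.01:
                        logger.info(
                            "%s: TIFF resolution tag (~%.4g um/px) differs from "
                            "configured calibration (%.4g um/px); using the configuration",
                            path.name, tag_um, pixel_size_um,
                        )
    except Exception as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise IOError(f"{path}: RGB images are not supported; convert to greyscale")
    if arr.ndim != 2:
        raise IOError(f"{path}: expected a single 2-D greyscale page, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise IOError(f"{path}: unsupported bit depth {arr.dtype}; expected uint8 or uint16")
    return ImageFrame(arr, bit_depth=depth, pixel_size_um=pixel_size_um)


def write_image(frame: ImageFrame, path) -> None:
    """Write a frame as an uncompressed greyscale TIFF."""
    tifffile.imwrite(Path(path), frame.pixels)


def records_to_table(records: Sequence[ParticleRecord]) -> pd.DataFrame:
    """Particle records as an ImageJ-style results table (um units)."""
    return pd.DataFrame(
        {
            "Label": [r.label for r in records],
            "Area": [r.area_um2 for r in records],
            "Perim.": [r.perimeter_um for r in records],
            "Circ.": [r.circularity for r in records],
            "Solidity": [r.solidity for r in records],
            "EquivRadius": [r.equiv_radius_um for r in records],
            "CentroidRow": [r.centroid_px[0] for r in records],
            "CentroidCol": [r.centroid_px[1] for r in records],
        },
        columns=RESULT_COLUMNS + ["CentroidRow", "CentroidCol"],
    )


def write_results_csv(records: Sequence[ParticleRecord], path) -> None:
    """Write particle records as CSV (header-only when the list is empty).

    Floats use the shortest lossless decimal representation, so a
    write/read round trip reproduces every field bit-exactly.
    """
    df = records_to_table(records)
    df.to_csv(Path(path), index=False)


def read_results_csv(path) -> List[ParticleRecord]:
    """Read a results CSV back into particle records.

    Tables from the original ImageJ macro lack ``Label``/``EquivRadius``
    columns; the label falls back to the row index and the equivalent
    radius is recomputed from the area.  Missing measurement columns raise
    an error naming the column.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip() for c in df.columns]
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records = []
    for i, row in df.iterrows():
        area = float(row["Area"])
        label = int(row["Label"]) if "Label" in df.columns else i + 1
        if "EquivRadius" in df.columns:
            equiv_radius = float(row["EquivRadius"])
        else:
            equiv_radius = float(np.sqrt(area / np.pi))
        centroid = (
            (float(row["CentroidRow"]), float(row["CentroidCol"]))
            if "CentroidRow" in df.columns and "CentroidCol" in df.columns
            else (float("nan"), float("nan"))
        )
        records.append(
            ParticleRecord(
                label=label,
                area_um2=area,
                perimeter_um=float(row["Perim."]),
                circularity=float(row["Circ."]),
                solidity=float(row["Solidity"]),
                equiv_radius_um=equiv_radius,
                centroid_px=centroid,
            )
        )
    return records


def write_ground_truth_csv(truth, path) -> None:
    """Write the per-object (or per-well) ground truth table of a synthetic
    frame as CSV."""
    table = truth.objects if truth.objects is not None else truth.wells
    if table is None:
        raise ValueError("ground truth holds neither objects nor wells")
    table.to_csv(Path(path), index=False, float_format="%.17g")


def write_spec_yaml(spec, path) -> None:
    """Write a generator spec (dataclass) as a YAML sidecar for provenance."""
    data = dataclasses.asdict(spec)
    for key, value in data.items():
        if isinstance(value, tuple):
            data[key] = list(value)
    with open(Path(path), "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
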