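"""File schemas: coincidence-count CSV, density-matrix JSON, metadata sidecars.

Coincidence tables are plain CSV (comma-separated, UTF-8, mandatory
header) with columns::

    spot_id, strain, region, replicate, repeat,
    signal_setting, idler_setting, counts, integration_s

Density matrices are JSON objects with ``real`` and ``imag`` nested
4×4 arrays in the (HH, HV, VH, VV) basis order.  Every output file gets
a ``<file>.meta.json`` sidecar carrying provenance (seed, config hash,
package version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .states import ANALYZER_LABELS
from .tomography import (
    AnalyzerSetting,
    TomographyProjection,
    TomographySet,
    canonical_settings,
)

__all__ = [
    "COUNTS_COLUMNS",
    "write_counts_table",
    "read_counts_table",
    "tomography_sets_from_frame",
    "write_density_matrix",
    "read_density_matrix",
    "write_image",
    "read_image",
    "write_metadata_sidecar",
    "validate_counts_table",
]

COUNTS_COLUMNS = [
    "spot_id",
    "strain",
    "region",
    "replicate",
    "repeat",
    "signal_setting",
    "idler_setting",
    "counts",
    "integration_s",
]

BASIS_ORDER = ["HH", "HV", "VH", "VV"]


def spots_to_frame(spots) -> pd.DataFrame:
    """Flatten simulated spot measurements into the counts-table schema."""
    rows = []
    for spot in spots:
        for ts in spot.tomographies:
            repeat = ts.metadata.get("repeat", 1)
            for proj in ts.projections:
                rows.append(
                    {
                        "spot_id": spot.spot_id,
                        "strain": spot.strain,
                        "region": spot.region,
                        "replicate": spot.replicate_id,
                        "repeat": repeat,
                        "signal_setting": proj.setting.signal,
                        "idler_setting": proj.setting.idler,
                        "counts": int(proj.counts),
                        "integration_s": proj.integration_time,
                    }
                )
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def write_counts_table(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    frame.to_csv(path, index=False)
    if metadata is not None:
        write_metadata_sidecar(path, metadata)


def read_counts_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def tomography_sets_from_frame(frame: pd.DataFrame) -> list[TomographySet]:
    """Group a counts table into per-(spot, repeat) tomography sets."""
    sets = []
    for (spot_id, repeat), grp in frame.groupby(["spot_id", "repeat"], sort=True):
        projections = [
            TomographyProjection(
                AnalyzerSetting(row.signal_setting, row.idler_setting),
                float(row.counts),
                float(row.integration_s),
            )
            for row in grp.itertuples()
        ]
        first = grp.iloc[0]
        sets.append(
            TomographySet(
                projections,
                metadata={
                    "spot_id": spot_id,
                    "repeat": int(repeat),
                    "strain": first["strain"],
                    "region": first["region"],
                    "replicate": int(first["replicate"]),
                    "label": first.get("label", None),
                },
            )
        )
    return sets


def write_density_matrix(rho: np.ndarray, path, metadata: dict | None = None) -> None:
    path = Path(path)
    payload = {
        "basis": BASIS_ORDER,
        "real": np.asarray(rho).real.tolist(),
        "imag": np.asarray(rho).imag.tolist(),
    }
    if metadata:
        payload["metadata"] = metadata
    path.write_text(json.dumps(payload, indent=1))


def read_density_matrix(path) -> np.ndarray:
    payload = json.loads(Path(path).read_text())
    return np.asarray(payload["real"]) + 1j * np.asarray(payload["imag"])


def write_image(image: np.ndarray, path, metadata: dict | None = None) -> None:
    """Write an intensity image or binary mask as 16-bit TIFF or 8-bit PNG."""
    import tifffile

    path = Path(path)
    img = np.asarray(image)
    if img.dtype == bool:
        img = img.astype(np.uint8) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        lo, hi = float(img.min()), float(img.max())
        scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img, dtype=float)
        tifffile.imwrite(path, (scaled * 65535).astype(np.uint16))
    elif path.suffix.lower() == ".png":
        from PIL import Image

        lo, hi = float(img.min()), float(img.max())
        scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img, dtype=float)
        Image.fromarray((scaled * 255).astype(np.uint8)).save(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    if metadata is not None:
        write_metadata_sidecar(path, metadata)


def read_image(path) -> np.ndarray:
    import tifffile

    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    from PIL import Image

    return np.asarray(Image.open(path).convert("F"), dtype=float)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_metadata_sidecar(path, metadata: dict) -> None:
    from . import __version__

    meta = {"package_version": __version__, **metadata}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1, default=str))


def validate_counts_table(path) -> list[str]:
    """Schema validation of a coincidence-count table.

    Checks column presence, label vocabularies, nonnegative integer
    counts and that every (spot_id, repeat) block carries exactly 16
    distinct settings.  Returns a list of human-readable violations
    (empty when the table is valid).
    """
    violations: list[str] = []
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - report unreadable file
        return [f"unreadable file: {exc}"]
    missing = [c for c in COUNTS_COLUMNS if c not in frame.columns]
    if missing:
        return [f"missing columns: {missing}"]
    for idx, row in frame.iterrows():
        rowno = idx + 2  # header is line 1
        if row["signal_setting"] not in ANALYZER_LABELS:
            violations.append(
                f"row {rowno}: invalid signal_setting {row['signal_setting']!r}"
            )
        if row["idler_setting"] not in ANALYZER_LABELS:
            violations.append(
                f"row {rowno}: invalid idler_setting {row['idler_setting']!r}"
            )
        c = row["counts"]
        if not float(c).is_integer() or c < 0:
            violations.append(f"row {rowno}: counts must be a nonnegative integer, got {c}")
        if row["integration_s"] <= 0:
            violations.append(f"row {rowno}: integration_s must be positive")
    for (spot, repeat), grp in frame.groupby(["spot_id", "repeat"]):
        settings = set(zip(grp["signal_setting"], grp["idler_setting"]))
        if len(grp) != 16 or len(settings) != 16:
            expected = {(s.signal, s.idler) for s in canonical_settings()}
            missing_settings = sorted(expected - settings)
            detail = f"; missing canonical settings: {missing_settings}" if missing_settings else ""
            violations.append(
                f"(spot {spot}, repeat {repeat}): expected 16 distinct settings, "
                f"got {len(settings)} in {len(grp)} rows{detail}"
            )
    return violations
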