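"""Image and table I/O: reading images, pairing brightfield/DAPI files,
flat config files, and the results CSV.

Pairing convention: a field of view is stored as two files sharing a stem
and differing in suffix, e.g. ``a12_BF.tif`` + ``a12_DAPI.tif``.  The
suffixes are configurable (defaults ``_BF`` and ``_DAPI``); the stem is the
field id.  Unmatched files are reported, never silently dropped.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ImagePair",
    "read_image",
    "write_image",
    "pair_images",
    "write_records_csv",
    "read_records_csv",
    "load_config",
    "save_config",
    "RECORD_COLUMNS",
]

IMAGE_EXTENSIONS = {".tif", ".tiff", ".png"}

#: Results CSV schema, in order.
RECORD_COLUMNS = [
    "field_id",
    "group",
    "area_px",
    "integrated_density",
    "mean_gray",
    "nuclei_count",
    "id_per_cell",
    "qc_status",
]


@dataclass(frozen=True)
class ImagePair:
    """One field of view: a brightfield/DAPI file pair with a group label."""

    field_id: str
    bf_path: Path
    dapi_path: Path
    group: str

    def __post_init__(self) -> None:
        if Path(self.bf_path) == Path(self.dapi_path):
            raise ValueError(f"field {self.field_id}: BF and DAPI paths coincide")


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG as an 8-bit ``(H, W, 3)`` RGB array.

    Grayscale files are replicated across three channels; 16-bit inputs are
    linearly rescaled by division by 257 (so 65535 maps to 255); an alpha
    channel is dropped.  Unsupported layouts raise ``ValueError`` naming
    the path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable / not an image
        raise ValueError(f"cannot read {path} as an image: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype == np.uint16:
        arr = np.round(arr / 257.0).astype(np.uint8)
    elif arr.dtype == np.bool_:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported bit depth {arr.dtype}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: unsupported channel layout, shape {arr.shape}")
    return arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write an image (uint8 RGB/gray, or uint16 gray e.g. a label map)."""
    path = Path(path)
    arr = np.asarray(img)
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"refusing to write dtype {arr.dtype}; convert first")
    iio.imwrite(path, arr)


def _default_group(field_id: str) -> str:
    # generator naming is <group>_<k>; fall back to the stem itself
    return field_id.rsplit("_", 1)[0] if "_" in field_id else field_id


def pair_images(
    directory: str | Path,
    bf_suffix: str = "_BF",
    dapi_suffix: str = "_DAPI",
    group_map: Mapping[str, str] | None = None,
) -> tuple[list[ImagePair], list[str]]:
    """Pair brightfield and DAPI files in a directory by filename stem.

    Returns ``(pairs, unpaired)``: pairs sorted lexicographically by
    field id, and the filenames that had no partner.  Group labels come
    from the first ``group_map`` glob pattern matching the field id, else
    from the stem up to its last underscore.  Two files claiming the same
    role for one stem raise ``ValueError``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such directory: {directory}")
    bf_files: dict[str, Path] = {}
    dapi_files: dict[str, Path] = {}
    others: list[str] = []
    for p in sorted(directory.iterdir()):
        if not p.is_file() or p.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        stem = p.stem
        if stem.endswith(bf_suffix):
            fid = stem[: -len(bf_suffix)]
            if fid in bf_files:
                raise ValueError(f"duplicate brightfield stem {fid!r}: {p.name}")
            bf_files[fid] = p
        elif stem.endswith(dapi_suffix):
            fid = stem[: -len(dapi_suffix)]
            if fid in dapi_files:
                raise ValueError(f"duplicate DAPI stem {fid!r}: {p.name}")
            dapi_files[fid] = p
        else:
            others.append(p.name)

    pairs: list[ImagePair] = []
    unpaired: list[str] = list(others)
    for fid in sorted(set(bf_files) | set(dapi_files)):
        if fid in bf_files and fid in dapi_files:
            group = _default_group(fid)
            if group_map:
                for pattern, label in group_map.items():
                    if fnmatch.fnmatch(fid, pattern):
                        group = label
                        break
            pairs.append(
                ImagePair(
                    field_id=fid,
                    bf_path=bf_files[fid],
                    dapi_path=dapi_files[fid],
                    group=group,
                )
            )
        elif fid in bf_files:
            unpaired.append(bf_files[fid].name)
        else:
            unpaired.append(dapi_files[fid].name)
    return pairs, sorted(unpaired)


def write_records_csv(records: Iterable[Any], path: str | Path) -> None:
    """Write field records to CSV with the fixed 8-column schema.

    Comma-delimited, ``.`` decimal separator, UTF-8, with header; numeric
    values are formatted to 10 significant digits so a write→read round
    trip is lossless at that precision.  An empty record list is an error
    and creates no file.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    rows = []
    for rec in records:
        sig = rec.signal
        rows.append(
            {
                "field_id": rec.field_id,
                "group": rec.group,
                "area_px": sig.area_px if sig is not None else "",
                "integrated_density": sig.integrated_density if sig is not None else "",
                "mean_gray": sig.mean_gray if sig is not None else "",
                "nuclei_count": rec.nuclei_count if rec.nuclei_count is not None else "",
                "id_per_cell": rec.id_per_cell if rec.id_per_cell is not None else "",
                "qc_status": rec.qc_status,
            }
        )
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def read_records_csv(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame (schema-checked)."""
    df = pd.read_csv(path, encoding="utf-8")
    if list(df.columns) != RECORD_COLUMNS:
        raise ValueError(
            f"{path}: unexpected columns {list(df.columns)}; expected {RECORD_COLUMNS}"
        )
    return df


def _parse_value(text: str) -> Any:
    low = text.strip().lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text.strip()


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a flat ``key = value`` config file (``#`` starts a comment).

    Recognised keys: ``bf_suffix``, ``dapi_suffix``,
    ``threshold.{r,g,b}_{min,max}``, ``nuclei.min_area_px``,
    ``nuclei.split_touching``, ``qc.interactive``, ``seed``.
    """
    cfg: dict[str, Any] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = line.split("=", 1)
        cfg[key.strip()] = _parse_value(value)
    return cfg


def save_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    lines = [f"{k} = {v}" for k, v in cfg.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
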