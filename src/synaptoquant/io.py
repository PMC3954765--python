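"""File discovery and plain-format I/O (TIFF images, CSV tables)."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from synaptoquant.config import CHANNELS, PipelineConfig
from synaptoquant.types import FieldImageSet

__all__ = ["FieldImageRef", "discover_plate", "load_field", "write_csv"]

#: `<plate>_<well>_s<site>_<channel>.tif`
_NAME_RE = re.compile(
    r"^(?P<plate>[^_]+)_(?P<well>[^_]+)_s(?P<site>\d+)_(?P<channel>[^_.]+)\.tiff?$"
)


@dataclass
class FieldImageRef:
    """Paths of the four channel files of one site (lazy-loading handle)."""

    plate: str
    well: str
    site: int
    paths: dict[str, Path] = field(default_factory=dict)  # canonical channel -> file


def discover_plate(
    root_path: str | Path, config: PipelineConfig | None = None
) -> tuple[list[FieldImageRef], list[dict]]:
    """Enumerate complete sites under a directory of per-channel TIFFs.

    A site is complete when all four channels are present. Incomplete
    sites are skipped and reported; a duplicate file for a channel is an
    error. Returns (refs, skip_report).
    """
    root = Path(root_path)
    channel_map = config.channel_map if config else {ch: ch for ch in CHANNELS}
    sites: dict[tuple[str, str, int], FieldImageRef] = {}
    for p in sorted(root.glob("*.tif")) + sorted(root.glob("*.tiff")):
        m = _NAME_RE.match(p.name)
        if not m:
            continue
        suffix = m.group("channel")
        if suffix not in channel_map:
            continue
        channel = channel_map[suffix]
        key = (m.group("plate"), m.group("well"), int(m.group("site")))
        ref = sites.setdefault(key, FieldImageRef(*key))
        if channel in ref.paths:
            raise ValueError(
                f"duplicate file for channel {channel} of site {key}: "
                f"{ref.paths[channel].name} and {p.name}"
            )
        ref.paths[channel] = p
    complete, skipped = [], []
    for key in sorted(sites):
        ref = sites[key]
        missing = [ch for ch in CHANNELS if ch not in ref.paths]
        if missing:
            skipped.append(
                {"plate": ref.plate, "well": ref.well, "site": ref.site,
                 "missing_channels": ";".join(missing)}
            )
        else:
            complete.append(ref)
    if not complete:
        raise ValueError(f"no complete 4-channel sites found under {root}")
    return complete, skipped


def load_field(ref: FieldImageRef) -> FieldImageSet:
    images = {
        ch: np.asarray(tifffile.imread(path), dtype=np.float64)
        for ch, path in ref.paths.items()
    }
    fis = FieldImageSet(plate=ref.plate, well=ref.well, site=ref.site, images=images)
    fis.validate()
    return fis


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Spreadsheet-safe CSV: '.' decimal, comma separator, NaN as empty."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")
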