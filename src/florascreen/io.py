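"""Reading and writing the pipeline's file formats.

Masks are single-channel PNG/TIFF rasters with 0 = background and
255 = foreground; a metadata CSV (plant_id, genotype, tray, day, path,
mm_per_px) ties mask files to plants and days.  Descriptor output is the
long-format CSV consumed by the growth statistics.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .morphometrics import BinaryMask

__all__ = [
    "load_mask",
    "save_mask",
    "load_metadata",
    "read_fasta",
]

METADATA_COLUMNS = ("plant_id", "genotype", "day", "path", "mm_per_px")


def load_mask(
    path: str | Path,
    mm_per_px: float = 1.0,
    plant_id: str | None = None,
    day: int | None = None,
) -> BinaryMask:
    """Read a 0/255 mask image; infers plant_id/day from a
    ``{plant_id}_{day}`` filename when not given."""
    path = Path(path)
    img = np.asarray(Image.open(path).convert("L"))
    if plant_id is None or day is None:
        stem = path.stem
        if "_" in stem:
            inferred_id, _, inferred_day = stem.rpartition("_")
            plant_id = plant_id or inferred_id
            if day is None and inferred_day.isdigit():
                day = int(inferred_day)
    return BinaryMask(img > 127, mm_per_px=mm_per_px,
                      plant_id=plant_id or path.stem, day=day or 0)


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit 0/255 PNG/TIFF."""
    img = Image.fromarray(np.where(mask.grid, 255, 0).astype(np.uint8))
    img.save(path)


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read the tray metadata CSV and validate required columns."""
    meta = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata CSV missing columns: {missing}")
    return meta


def read_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
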