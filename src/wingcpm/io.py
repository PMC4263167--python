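"""Reading and writing of wing images, categorized patterns, and specimen tables.

Categorized wing patterns (``ColourPattern``) are stored losslessly as indexed
(palette) PNGs with a JSON sidecar carrying the class table; specimen metadata
travels as TSV.  The background is a reserved class (code 0) and, in image
files, a reserved RGB colour so that wing extraction on synthetic renders is
unambiguous.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

#: Canonical class order.  Code 0 is always background; ties in any per-pixel
#: vote are broken toward the earlier class in this order.
CLASSES: tuple[str, ...] = ("background", "black", "orange", "yellow")

#: RGB used when rendering each class.  Background is a reserved colour far
#: from all wing colours.
CLASS_RGB: dict[str, tuple[int, int, int]] = {
    "background": (255, 0, 255),
    "black": (25, 25, 25),
    "orange": (230, 126, 34),
    "yellow": (247, 220, 60),
}

WINGS = ("forewing", "hindwing")
SIDES = ("dorsal", "ventral")
PAIR_CLASSES = ("sympatric", "parapatric", "NA")


class SpecimenTableError(ValueError):
    """Raised for malformed specimen metadata tables."""


@dataclass(eq=False)
class ColourPattern:
    """A categorized wing raster: background plus K colour classes.

    ``grid`` holds small integer class codes indexing into ``classes``;
    ``space`` records whether the raster lives in its native image frame or in
    the common model space defined by alignment.
    """

    grid: np.ndarray
    classes: tuple[str, ...] = CLASSES
    space: str = "native"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int16)
        if self.grid.ndim != 2:
            raise ValueError("pattern grid must be 2-D")
        if self.space not in ("native", "model"):
            raise ValueError(f"unknown space {self.space!r}")
        if self.grid.size and (self.grid.min() < 0 or self.grid.max() >= len(self.classes)):
            raise ValueError("grid holds codes outside the declared class table")

    @property
    def resolution(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean wing mask (non-background pixels)."""
        return self.grid > 0

    @property
    def wing_area(self) -> int:
        return int(self.mask.sum())

    def onehot(self) -> np.ndarray:
        """(K, H, W) indicator stack over all classes including background."""
        k = len(self.classes)
        return (self.grid[None, :, :] == np.arange(k)[:, None, None]).astype(np.float32)

    def to_rgb(self, class_rgb: dict[str, tuple[int, int, int]] | None = None) -> np.ndarray:
        palette = _palette_array(self.classes, class_rgb or CLASS_RGB)
        return palette[self.grid]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ColourPattern):
            return NotImplemented
        return (
            self.classes == other.classes
            and self.space == other.space
            and self.grid.shape == other.grid.shape
            and bool(np.array_equal(self.grid, other.grid))
        )


def _palette_array(classes, class_rgb) -> np.ndarray:
    return np.array([class_rgb[c] for c in classes], dtype=np.uint8)


# ---------------------------------------------------------------------------
# Pattern persistence: indexed PNG + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_pattern(pattern: ColourPattern, path: str | Path) -> None:
    """Write a pattern as an indexed PNG plus a JSON sidecar with the class table.

    The round-trip through :func:`read_pattern` is lossless, cell-exact.
    """
    path = Path(path)
    img = Image.fromarray(pattern.grid.astype(np.uint8), mode="P")
    palette = _palette_array(pattern.classes, CLASS_RGB)
    img.putpalette(palette.ravel().tolist())
    img.save(path, format="PNG")
    meta = {
        "classes": list(pattern.classes),
        "space": pattern.space,
        "palette": palette.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    if pattern.wing_area == 0:
        warnings.warn(f"pattern written to {path} has an empty wing mask", stacklevel=2)


def read_pattern(path: str | Path) -> ColourPattern:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"pattern sidecar {sidecar} is missing; refusing to guess the class table"
        )
    meta = json.loads(sidecar.read_text())
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(f"{path} is not an indexed (palette) PNG")
    grid = np.asarray(img, dtype=np.int16)
    classes = tuple(meta["classes"])
    if grid.size and grid.max() >= len(classes):
        raise ValueError(
            f"{path}: pixel codes exceed the {len(classes)}-entry class table in the sidecar"
        )
    return ColourPattern(grid=grid, classes=classes, space=meta.get("space", "native"))


# ---------------------------------------------------------------------------
# RGB images and masks
# ---------------------------------------------------------------------------

def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(Path(path), format="PNG")


def read_image(path: str | Path, mirrored: bool = False) -> np.ndarray:
    """Read an RGB image; mirrored wings are flipped to the common chirality."""
    arr = np.asarray(Image.open(Path(path)).convert("RGB"))
    if mirrored:
        arr = arr[:, ::-1, :]
    return arr


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8), mode="L").save(
        Path(path), format="PNG"
    )


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(Path(path)).convert("L")) > 127


# ---------------------------------------------------------------------------
# Specimen tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecimenRecord:
    """One photographed wing surface of one specimen."""

    specimen_id: str
    wing: str
    side: str
    genotype: tuple[str, str]  # unordered allele pair, stored sorted
    pair_class: str = "NA"
    image_path: str = ""
    mirrored: bool = False

    def __post_init__(self) -> None:
        if self.wing not in WINGS:
            raise SpecimenTableError(f"unknown wing {self.wing!r}")
        if self.side not in SIDES:
            raise SpecimenTableError(f"unknown side {self.side!r}")
        if self.pair_class not in PAIR_CLASSES:
            raise SpecimenTableError(f"unknown pair_class {self.pair_class!r}")

    @property
    def is_heterozygote(self) -> bool:
        return self.genotype[0] != self.genotype[1]


def pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered allele pair."""
    return tuple(sorted((a, b)))  # type: ignore[return-value]


REQUIRED_COLUMNS = ("specimen_id", "wing", "side", "allele_1", "allele_2")


class SpecimenTable(list):
    """List of :class:`SpecimenRecord` with a QC report attached."""

    def __init__(self, records, qc: dict | None = None):
        super().__init__(records)
        self.qc: dict = qc or {"excluded": [], "warnings": []}


def read_specimen_table(
    path: str | Path,
    alleles: set[str] | None = None,
    check_images: bool = False,
) -> SpecimenTable:
    """Read and validate a specimen metadata TSV/CSV.

    A ``genotype`` column of the form ``"a/b"`` may stand in for the
    ``allele_1``/``allele_2`` pair.  Duplicated specimen_id x wing x side is a
    hard error; records with unreadable image paths are excluded and listed in
    the attached QC report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")

    if "genotype" in df.columns and "allele_1" not in df.columns:
        parts = df["genotype"].str.split("/", expand=True)
        if parts.shape[1] != 2:
            raise SpecimenTableError("genotype column must be of the form 'a/b'")
        df["allele_1"], df["allele_2"] = parts[0], parts[1]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SpecimenTableError(f"missing required column(s): {', '.join(missing)}")

    keys = df["specimen_id"] + "|" + df["wing"] + "|" + df["side"]
    dup = keys[keys.duplicated()]
    if len(dup):
        raise SpecimenTableError(f"duplicated specimen_id x wing x side: {dup.iloc[0]}")

    qc: dict = {"excluded": [], "warnings": []}
    records = []
    for row in df.itertuples(index=False):
        geno = pair_key(row.allele_1, row.allele_2)
        if alleles is not None:
            unknown = [a for a in geno if a not in alleles]
            if unknown:
                qc["warnings"].append(
                    f"{row.specimen_id}: unknown allele(s) {','.join(unknown)}"
                )
        image_path = getattr(row, "image_path", "") or ""
        if check_images and image_path:
            p = Path(image_path)
            if not p.is_absolute():
                p = path.parent / p
            if not p.exists():
                qc["excluded"].append(f"{row.specimen_id}: unreadable image {image_path}")
                continue
        records.append(
            SpecimenRecord(
                specimen_id=row.specimen_id,
                wing=row.wing,
                side=row.side,
                genotype=geno,
                pair_class=(getattr(row, "pair_class", "") or "NA"),
                image_path=image_path,
                mirrored=str(getattr(row, "mirrored", "")).lower() in ("1", "true", "yes"),
            )
        )
    return SpecimenTable(records, qc)


def write_specimen_table(records, path: str | Path) -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "wing": r.wing,
            "side": r.side,
            "allele_1": r.genotype[0],
            "allele_2": r.genotype[1],
            "pair_class": r.pair_class,
            "image_path": r.image_path,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
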