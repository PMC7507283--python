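"""Image and trait-table input/output.

Potted seedlings are photographed from one top view and two side views at
90°; each capture is wrapped in a :class:`ViewImage` whose pixels are
normalized to a common ``[0, 1]`` channel scale regardless of source bit
depth, so that downstream color thresholds are bit-depth independent.
Genotype × trait tables (means or replicate-level) travel as
:class:`TraitTable`, a thin wrapper over a pandas DataFrame with an explicit
``NA`` missing-value marker.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DecodeError, ParseError, ValidationError

#: Missing-value marker used in CSV trait tables (the printed tables use "–"
#: for traits absent at a date, e.g. tiller number at 14 DAS).
NA_MARKER = "NA"


class View(str, enum.Enum):
    """Camera viewpoint of a single capture."""

    TOP = "top"
    SIDE_0 = "side_0"
    SIDE_90 = "side_90"

    @classmethod
    def parse(cls, label: "str | View") -> "View":
        if isinstance(label, View):
            return label
        try:
            return cls(label)
        except ValueError:
            valid = ", ".join(v.value for v in cls)
            raise ValidationError(
                f"unknown view label {label!r}; expected one of: {valid}"
            ) from None


@dataclass(frozen=True)
class ViewImage:
    """One captured RGB raster plus plant metadata.

    ``pixels`` is an (H, W, 3) float array with channels on ``[0, 1]``.
    """

    pixels: np.ndarray
    view: View
    genotype: str
    replicate: int
    das: int
    source_path: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"pixels must be an (H, W, 3) RGB raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("image must be at least 1×1 pixels")
        if self.das <= 0:
            raise ValidationError(f"das must be a positive day count, got {self.das}")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be ≥ 1, got {self.replicate}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "view", View.parse(self.view))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_view_image(
    path: "str | Path",
    view: "str | View",
    genotype: str,
    replicate: int,
    das: int,
) -> ViewImage:
    """Read a PNG/JPEG/TIFF capture and attach metadata.

    Integer rasters are rescaled by their dtype maximum (255 for 8-bit,
    65535 for 16-bit); float rasters are assumed to already sit on [0, 1].
    An alpha channel, if present, is dropped; grayscale is replicated to RGB.
    """
    view = View.parse(view)
    path = Path(path)
    import imageio.v3 as iio

    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises various backend errors
        raise DecodeError(f"cannot decode image {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.ndim != 3:
        raise DecodeError(f"{path}: expected a single-frame raster, got shape {raw.shape}")
    if raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if raw.shape[2] != 3:
        raise DecodeError(f"{path}: expected RGB(A) channels, got {raw.shape[2]}")
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        pixels = raw.astype(float) / scale
    else:
        pixels = raw.astype(float)
        if pixels.size and (pixels.min() < 0 or pixels.max() > 1):
            raise DecodeError(f"{path}: float pixels outside [0, 1]")
    return ViewImage(
        pixels=pixels,
        view=view,
        genotype=genotype,
        replicate=int(replicate),
        das=int(das),
        source_path=str(path),
    )


@dataclass
class ImagingSession:
    """All captures of one plant on one date (at most one per view)."""

    images: dict = field(default_factory=dict)
    calibration: object = None  # ScaleCalibration; kept untyped to avoid cycle

    def add(self, image: ViewImage) -> None:
        if image.view in self.images:
            raise ValidationError(f"duplicate view {image.view.value} in session")
        for other in self.images.values():
            if (other.genotype, other.replicate, other.das) != (
                image.genotype,
                image.replicate,
                image.das,
            ):
                raise ValidationError(
                    "all images in a session must share genotype/replicate/das"
                )
        self.images[image.view] = image

    def __getitem__(self, view) -> ViewImage:
        return self.images[View.parse(view)]

    def __contains__(self, view) -> bool:
        return View.parse(view) in self.images


class TableLevel(str, enum.Enum):
    GENOTYPE_MEAN = "genotype_mean"
    REPLICATE = "replicate"


@dataclass
class TraitTable:
    """Rectangular genotype × trait matrix.

    ``data`` is indexed by genotype label with one float column per trait;
    missing cells are NaN (serialized as ``NA``).
    """

    data: pd.DataFrame
    das: int = 0
    level: TableLevel = TableLevel.GENOTYPE_MEAN
    units: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.columns.duplicated().any():
            raise ValidationError("trait names must be unique")
        self.level = TableLevel(self.level)

    @property
    def genotypes(self) -> list:
        return list(self.data.index)

    @property
    def traits(self) -> list:
        return list(self.data.columns)

    def column(self, trait: str) -> pd.Series:
        if trait not in self.data.columns:
            raise ValidationError(f"unknown trait {trait!r}")
        return self.data[trait]


def read_trait_table(
    path: "str | Path",
    das: int = 0,
    level: "str | TableLevel" = TableLevel.GENOTYPE_MEAN,
) -> TraitTable:
    """Read a CSV with a trait-name header row and genotype labels in column 1.

    Non-numeric cells other than the ``NA`` marker raise :class:`ParseError`
    with the offending row/column coordinates.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty trait table") from None
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no trait columns")
    out = pd.DataFrame(index=frame.index.astype(str))
    for col in frame.columns:
        values = []
        for row_label, cell in frame[col].items():
            cell = cell.strip()
            if cell == NA_MARKER or cell == "":
                values.append(np.nan)
                continue
            try:
                values.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at row {row_label!r}, "
                    f"column {col!r}",
                    row=row_label,
                    column=col,
                ) from None
        out[col] = values
    return TraitTable(data=out, das=das, level=TableLevel(level))


def write_trait_table(table: TraitTable, path: "str | Path") -> None:
    """Write a TraitTable as CSV; NaN cells become the ``NA`` marker.

    Values round-trip exactly through ``repr`` formatting.
    """
    frame = table.data.copy()
    with open(path, "w") as fh:
        fh.write(",".join(["genotype", *map(str, frame.columns)]) + "\n")
        for label, row in frame.iterrows():
            cells = [
                NA_MARKER if pd.isna(v) else repr(float(v)) for v in row.to_numpy()
            ]
            fh.write(",".join([str(label), *cells]) + "\n")
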