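"""Reading, writing and converting images, label masks and RLE submissions.

Three interchangeable representations of an instance segmentation are
supported:

* a *label mask* — a 2D integer image, 0 = background, each positive
  integer one nucleus;
* a directory of *per-object binary masks* (the BBBC038 layout: one PNG
  per nucleus);
* a *run-length encoded* (RLE) submission CSV in the Kaggle dialect —
  pixels numbered 1-based, top-to-bottom within a column then
  left-to-right (column-major).

Conversions are lossless up to label renumbering: masks are always
canonicalized so the label values are exactly ``{0} ∪ {1..n_objects}``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import imageio.v3 as iio
import numpy as np

from .errors import ContractError, FormatError, OverlapError

__all__ = [
    "ImageRecord",
    "LabelMask",
    "RleRecord",
    "DatasetIndex",
    "canonicalize_labels",
    "read_image",
    "read_label_mask",
    "write_label_mask",
    "combine_binary_masks",
    "read_object_mask_dir",
    "rle_encode",
    "rle_decode",
    "read_submission_csv",
    "write_submission_csv",
    "atomic_write_text",
]

GROUPS = (
    "small_fluorescent",
    "large_fluorescent",
    "purple_tissue",
    "pink_purple_tissue",
    "grayscale_tissue",
)

OverlapPolicy = Literal["error", "first-wins"]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ImageRecord:
    """A 2D microscopy image with intensities normalized to [0, 1].

    ``pixels`` is ``(H, W)`` for single-channel images or ``(H, W, 3)``
    for color images.
    """

    image_id: str
    pixels: np.ndarray
    group: str = "unknown"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            pass
        elif px.ndim == 3 and px.shape[2] == 3:
            pass
        else:
            raise ContractError(
                f"image must be (H, W) or (H, W, 3); got shape {px.shape}"
            )
        if px.size == 0:
            raise ContractError("image must contain at least one pixel")
        if not np.all(np.isfinite(px)):
            raise ContractError("image intensities must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ContractError("image intensities must lie in [0, 1]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def luminance(self) -> np.ndarray:
        """Mean over channels; identity for single-channel images."""
        if self.pixels.ndim == 2:
            return self.pixels
        return self.pixels.mean(axis=2)


@dataclass
class LabelMask:
    """An instance segmentation as a canonical 2D integer label image.

    Labels are canonicalized at construction: the positive labels are
    exactly ``1..n_objects``, assigned in ascending original-id order.
    A label's pixels need not be spatially connected.
    """

    image_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ContractError(f"label mask must be 2D and nonempty; got {arr.shape}")
        if arr.min() < 0:
            raise ContractError("label values must be non-negative")
        self.labels = canonicalize_labels(arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def object_support(self, label: int) -> np.ndarray:
        return self.labels == label

    def areas(self) -> np.ndarray:
        """Pixel area per object, index i-1 for label i."""
        return np.bincount(self.labels.ravel(), minlength=self.n_objects + 1)[1:]

    def to_binary_masks(self) -> list[np.ndarray]:
        return [self.labels == k for k in range(1, self.n_objects + 1)]


@dataclass
class RleRecord:
    """One object's run-length encoding (Kaggle dialect).

    Runs are ``(start, length)`` with 1-based starts in column-major
    pixel order, sorted ascending and non-overlapping.
    """

    image_id: str
    runs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0
        for start, length in self.runs:
            if length < 1 or start < 1:
                raise FormatError(f"invalid run ({start}, {length})")
            if start <= prev_end:
                raise FormatError(
                    f"runs overlap or are unsorted at start={start} (image {self.image_id})"
                )
            prev_end = start + length - 1

    def n_pixels(self) -> int:
        return sum(length for _, length in self.runs)


@dataclass
class DatasetIndex:
    """Resolvable listing of images and their target-mask sources."""

    entries: list[tuple[str, Path, Path, str]]  # (image_id, image, mask source, group)
    split: str = "train"
    declared_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ContractError("image_ids must be unique within a split")

    @property
    def image_ids(self) -> list[str]:
        return [e[0] for e in self.entries]


# ---------------------------------------------------------------------------
# canonicalization


def canonicalize_labels(arr: np.ndarray) -> np.ndarray:
    """Relabel a non-negative integer mask to 1..n in ascending original-id order.

    Idempotent: a canonical mask maps to itself.
    """
    arr = np.asarray(arr)
    present = np.unique(arr)
    positive = present[present > 0]
    n = positive.size
    if n == 0:
        return np.zeros(arr.shape, dtype=np.int32)
    if positive[0] == 1 and positive[-1] == n:
        return arr.astype(np.int32, copy=True)
    lut = np.zeros(int(present[-1]) + 1, dtype=np.int32)
    lut[positive] = np.arange(1, n + 1, dtype=np.int32)
    return lut[arr]


# ---------------------------------------------------------------------------
# image and mask files


def read_image(path: str | os.PathLike, image_id: str | None = None) -> ImageRecord:
    """Read a PNG/TIFF image and rescale intensities to [0, 1] by bit depth.

    RGBA inputs are reduced to RGB by dropping the alpha channel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"unreadable image file {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if raw.ndim == 3 and raw.shape[2] == 1:
        raw = raw[:, :, 0]
    if raw.ndim not in (2, 3) or (raw.ndim == 3 and raw.shape[2] != 3):
        raise FormatError(
            f"unsupported channel layout {raw.shape} in {path}; expected 1, 3 or 4 channels"
        )
    if raw.dtype == np.uint8:
        px = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        px = raw.astype(np.float64) / 65535.0
    elif np.issubdtype(raw.dtype, np.floating):
        px = np.clip(raw.astype(np.float64), 0.0, 1.0)
    else:
        info = np.iinfo(raw.dtype)
        px = (raw.astype(np.float64) - info.min) / (info.max - info.min)
    return ImageRecord(image_id=image_id or path.stem, pixels=px)


def read_label_mask(path: str | os.PathLike, image_id: str | None = None) -> LabelMask:
    """Read a single-channel integer label image (PNG/TIFF)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such mask file: {path}")
    raw = np.asarray(iio.imread(path))
    if raw.ndim != 2:
        raise FormatError(f"label mask must be single-channel; got {raw.shape} in {path}")
    return LabelMask(image_id=image_id or path.stem, labels=raw.astype(np.int64))


def write_label_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    path = Path(path)
    arr = mask.labels
    dtype = np.uint16 if arr.max() < 65536 else np.int32
    tmp = path.with_suffix(path.suffix + ".tmp")
    iio.imwrite(tmp, arr.astype(dtype), extension=path.suffix)
    os.replace(tmp, path)


def combine_binary_masks(
    masks: Sequence[np.ndarray],
    policy: OverlapPolicy = "error",
    shape: tuple[int, int] | None = None,
    image_id: str = "",
) -> LabelMask:
    """Stack per-object binary masks into one label mask.

    Labels 1..k are assigned in input order. Under ``policy='error'`` any
    shared pixel raises :class:`OverlapError`; under ``'first-wins'`` the
    earlier object keeps disputed pixels.
    """
    if len(masks) == 0:
        if shape is None:
            raise ContractError("shape is required when combining zero masks")
        return LabelMask(image_id=image_id, labels=np.zeros(shape, dtype=np.int32))
    base_shape = np.asarray(masks[0]).shape
    out = np.zeros(base_shape, dtype=np.int32)
    for k, m in enumerate(masks, start=1):
        m = np.asarray(m).astype(bool)
        if m.shape != base_shape:
            raise ContractError(
                f"mask {k} has shape {m.shape}, expected {base_shape}"
            )
        clash = m & (out > 0)
        if clash.any():
            if policy == "error":
                r, c = np.argwhere(clash)[0]
                raise OverlapError(
                    f"objects {int(out[r, c])} and {k} overlap at pixel ({int(r)}, {int(c)})"
                )
            m = m & (out == 0)
        out[m] = k
    return LabelMask(image_id=image_id, labels=out)


def read_object_mask_dir(
    path: str | os.PathLike,
    policy: OverlapPolicy = "error",
    image_id: str | None = None,
) -> LabelMask:
    """Read a BBBC038-style directory of binary per-object mask PNGs.

    Accepts either a directory of mask images directly, or an image
    directory containing a ``masks/`` subdirectory. Files are combined
    in sorted-name order.
    """
    path = Path(path)
    mask_dir = path / "masks" if (path / "masks").is_dir() else path
    files = sorted(p for p in mask_dir.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"})
    if not files:
        raise FormatError(f"no mask images found under {mask_dir}")
    masks = [np.asarray(iio.imread(p)) > 0 for p in files]
    return combine_binary_masks(masks, policy=policy, image_id=image_id or path.name)


# ---------------------------------------------------------------------------
# run-length encoding (Kaggle submission dialect)


def rle_encode(mask: LabelMask) -> list[RleRecord]:
    """Encode each object of a label mask as column-major 1-based runs.

    Objects are emitted in ascending label order; an all-zero mask
    yields an empty list.
    """
    flat = mask.labels.ravel(order="F")
    records: list[RleRecord] = []
    for lab in range(1, mask.n_objects + 1):
        idx = np.flatnonzero(flat == lab)
        breaks = np.flatnonzero(np.diff(idx) != 1)
        starts = idx[np.concatenate(([0], breaks + 1))]
        ends = idx[np.concatenate((breaks, [idx.size - 1]))]
        runs = [(int(s) + 1, int(e - s) + 1) for s, e in zip(starts, ends)]
        records.append(RleRecord(image_id=mask.image_id, runs=runs))
    return records


def rle_decode(
    records: Sequence[RleRecord],
    height: int,
    width: int,
    policy: OverlapPolicy = "error",
    image_id: str | None = None,
) -> LabelMask:
    """Decode RLE records to a label mask; labels 1..k follow list order."""
    n_pixels = height * width
    flat = np.zeros(n_pixels, dtype=np.int32)
    iid = image_id
    for k, rec in enumerate(records, start=1):
        if iid is None:
            iid = rec.image_id
        for start, length in rec.runs:
            lo, hi = start - 1, start - 1 + length
            if hi > n_pixels:
                raise FormatError(
                    f"run ({start}, {length}) exceeds {height}x{width} image "
                    f"(image {rec.image_id})"
                )
            segment = flat[lo:hi]
            clash = segment > 0
            if clash.any():
                if policy == "error":
                    pos = lo + int(np.flatnonzero(clash)[0])
                    raise OverlapError(
                        f"objects {int(flat[pos])} and {k} overlap at flat pixel {pos + 1}"
                    )
                segment[clash] = -segment[clash]  # mark, restore below
                segment[segment == 0] = k
                segment[segment < 0] = -segment[segment < 0]
            else:
                segment[:] = k
    labels = flat.reshape((width, height)).T  # inverse of ravel(order="F")
    return LabelMask(image_id=iid or "", labels=labels)


def read_submission_csv(path: str | os.PathLike) -> list[RleRecord]:
    """Read a Kaggle-style ``ImageId,EncodedPixels`` submission CSV.

    A blank ``EncodedPixels`` denotes an image present with zero objects
    and produces a record with an empty run list.
    """
    path = Path(path)
    records: list[RleRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["ImageId", "EncodedPixels"]:
            raise FormatError(f"expected header 'ImageId,EncodedPixels' in {path}")
        for row_no, row in enumerate(reader, start=2):
            if not row:
                continue
            image_id = row[0]
            encoded = row[1].strip() if len(row) > 1 else ""
            if not encoded:
                records.append(RleRecord(image_id=image_id, runs=[]))
                continue
            tokens = encoded.split()
            if len(tokens) % 2 != 0:
                raise FormatError(
                    f"odd token count in EncodedPixels at row {row_no} of {path}"
                )
            try:
                nums = [int(t) for t in tokens]
            except ValueError as exc:
                raise FormatError(
                    f"non-integer token in EncodedPixels at row {row_no} of {path}"
                ) from exc
            runs = list(zip(nums[0::2], nums[1::2]))
            records.append(RleRecord(image_id=image_id, runs=runs))
    return records


def write_submission_csv(records: Iterable[RleRecord], path: str | os.PathLike) -> None:
    """Write RLE records as a submission CSV (bit-exact round trip)."""
    lines = ["ImageId,EncodedPixels\n"]
    for rec in records:
        encoded = " ".join(f"{s} {l}" for s, l in rec.runs)
        lines.append(f"{rec.image_id},{encoded}\n")
    atomic_write_text(path, "".join(lines))


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write text via a temporary file + rename so readers never see partial output."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)
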