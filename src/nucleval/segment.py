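"""Configuration-free classical nucleus segmentation.

The segmenter mirrors the reference-pipeline design used to baseline
the challenge: five fixed per-group parameter presets, selected by an
automatic appearance classifier, feeding a three-step pipeline —

1. *pre-processing*: transform the input into a grayscale matrix where
   nuclei are bright, smooth shapes on a dark background, whatever the
   input polarity or stain;
2. *primary identification*: threshold the grayscale image, fill
   holes, split touching nuclei by watershed on the distance transform
   seeded at its local maxima, and filter objects by the expected
   nuclear size;
3. *secondary revision*: seeded watershed from the primary objects
   over the intensity landscape within a re-thresholded foreground,
   which lets eroded objects recover their full support without ever
   splitting an object.

``segment(image)`` takes only the image: every parameter is fixed at
build time and the whole pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_local, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import clear_border, watershed

from .errors import ContractError
from .mask_io import GROUPS, ImageRecord, LabelMask, canonicalize_labels

__all__ = [
    "PipelinePreset",
    "GroupCall",
    "PRESETS",
    "classify_group",
    "to_foreground_grayscale",
    "identify_primary",
    "refine_secondary",
    "segment",
]

# diameter (px) separating "small" from "large" fluorescent nuclei
_SIZE_CUT = 25.0
# background saturation separating white (purple_tissue) from pink backgrounds
_SATURATION_CUT = 0.10
# inter-channel variation below which an RGB image counts as colorless
_COLOR_CUT = 0.02


@dataclass(frozen=True)
class PipelinePreset:
    """Fixed parameters of the three-step pipeline for one image group."""

    group: str
    foreground_transform: str  # identity | invert_luminance | stain_contrast
    smoothing_sigma: float
    threshold_method: str  # otsu_global | otsu_two_class_adaptive
    min_diameter: float
    max_diameter: float
    declump: bool = True
    seed_min_distance: int = 5
    fill_holes: bool = True
    border_policy: str = "keep"  # keep | discard

    def __post_init__(self) -> None:
        if not (0 < self.min_diameter < self.max_diameter):
            raise ContractError("require 0 < min_diameter < max_diameter")
        if self.seed_min_distance < 1:
            raise ContractError("seed_min_distance must be >= 1")


# seed_min_distance tracks the size prior (~min_diameter / 2 per group)
PRESETS: dict[str, PipelinePreset] = {
    "small_fluorescent": PipelinePreset(
        group="small_fluorescent", foreground_transform="identity",
        smoothing_sigma=1.0, threshold_method="otsu_global",
        min_diameter=3.0, max_diameter=40.0, seed_min_distance=4,
    ),
    "large_fluorescent": PipelinePreset(
        group="large_fluorescent", foreground_transform="identity",
        smoothing_sigma=2.0, threshold_method="otsu_global",
        min_diameter=15.0, max_diameter=100.0, seed_min_distance=10,
    ),
    "purple_tissue": PipelinePreset(
        group="purple_tissue", foreground_transform="stain_contrast",
        smoothing_sigma=1.0, threshold_method="otsu_global",
        min_diameter=5.0, max_diameter=45.0, seed_min_distance=2,
    ),
    "pink_purple_tissue": PipelinePreset(
        group="pink_purple_tissue", foreground_transform="stain_contrast",
        smoothing_sigma=1.0, threshold_method="otsu_global",
        min_diameter=4.0, max_diameter=45.0, seed_min_distance=2,
    ),
    "grayscale_tissue": PipelinePreset(
        group="grayscale_tissue", foreground_transform="invert_luminance",
        smoothing_sigma=1.0, threshold_method="otsu_two_class_adaptive",
        min_diameter=5.0, max_diameter=50.0, seed_min_distance=2,
    ),
}


@dataclass
class GroupCall:
    """Predicted appearance group with the features that drove the call."""

    group: str
    is_color: bool
    dark_background: bool
    background_saturation: float
    median_diameter: float
    confidence: str = "high"  # high | low


def _background_is_dark(lum: np.ndarray) -> bool:
    # background dominates the image; its side of the Otsu split holds
    # the majority of pixels
    th = threshold_otsu(lum)
    dark_frac = float(np.mean(lum <= th))
    bg_dark = dark_frac >= 0.5
    return bg_dark


def _rough_median_diameter(lum: np.ndarray, dark_background: bool) -> float:
    work = lum if dark_background else 1.0 - lum
    work = gaussian(work, sigma=1.0, preserve_range=True)
    if np.ptp(work) == 0:
        return 0.0
    fg = work > threshold_otsu(work)
    lbl, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0.0
    dia = [p.equivalent_diameter_area for p in regionprops(lbl) if p.area >= 9]
    return float(np.median(dia)) if dia else 0.0


def classify_group(img: ImageRecord) -> GroupCall:
    """Decision tree over colors, background polarity and object size.

    Follows the grouping rationale of the benchmark: color vs grayscale
    first, then fluorescent (dark background) vs tissue (bright
    background), then a size split for fluorescent images and a
    background-hue split for stained tissue. Deterministic; a constant
    image yields the documented low-confidence fallback.
    """
    lum = img.luminance()
    if np.ptp(lum) == 0:
        return GroupCall(
            group="small_fluorescent", is_color=False, dark_background=True,
            background_saturation=0.0, median_diameter=0.0, confidence="low",
        )
    if img.n_channels == 3:
        # smooth channels first so independent sensor noise does not
        # register as color
        sm = np.stack(
            [gaussian(img.pixels[:, :, c], sigma=1.5, preserve_range=True) for c in range(3)],
            axis=2,
        )
        spread = sm.max(axis=2) - sm.min(axis=2)
        chan_spread = float(np.percentile(spread, 95))
    else:
        spread = np.zeros_like(lum)
        chan_spread = 0.0
    is_color = chan_spread > _COLOR_CUT
    dark_bg = _background_is_dark(lum)
    med_dia = _rough_median_diameter(lum, dark_bg)
    bg_sat = 0.0
    if dark_bg:
        group = "small_fluorescent" if med_dia < _SIZE_CUT else "large_fluorescent"
    elif not is_color:
        group = "grayscale_tissue"
    else:
        th = threshold_otsu(lum)
        bg = lum > th
        bg_sat = float(np.median(spread[bg])) if bg.any() else 0.0
        group = "pink_purple_tissue" if bg_sat > _SATURATION_CUT else "purple_tissue"
    return GroupCall(
        group=group, is_color=is_color, dark_background=dark_bg,
        background_saturation=bg_sat, median_diameter=med_dia,
    )


# ---------------------------------------------------------------------------
# step 1: pre-processing


def to_foreground_grayscale(img: ImageRecord, preset: PipelinePreset) -> np.ndarray:
    """Grayscale matrix with bright nuclei on dark background, in [0, 1]."""
    px = img.pixels
    if preset.foreground_transform == "identity":
        g = img.luminance()
    elif preset.foreground_transform == "invert_luminance":
        g = 1.0 - img.luminance()
    elif preset.foreground_transform == "stain_contrast":
        # normalize each channel before inverting so stain tint and
        # background shading do not dominate the threshold
        if px.ndim == 3:
            chans = []
            for c in range(3):
                ch = px[:, :, c]
                rng = np.ptp(ch)
                chans.append((ch - ch.min()) / rng if rng > 0 else np.zeros_like(ch))
            g = 1.0 - np.mean(chans, axis=0)
        else:
            g = 1.0 - px
    else:
        raise ContractError(f"unknown foreground transform {preset.foreground_transform!r}")
    if preset.smoothing_sigma > 0:
        g = gaussian(g, sigma=preset.smoothing_sigma, preserve_range=True)
    rng = np.ptp(g)
    if rng > 0:
        g = (g - g.min()) / rng
    return np.clip(g, 0.0, 1.0)


# ---------------------------------------------------------------------------
# step 2: primary identification


def _foreground(gray: np.ndarray, preset: PipelinePreset) -> np.ndarray:
    if np.ptp(gray) == 0:
        return np.zeros(gray.shape, dtype=bool)
    global_th = threshold_otsu(gray)
    if preset.threshold_method == "otsu_global":
        fg = gray > global_th
    elif preset.threshold_method == "otsu_two_class_adaptive":
        block = int(2 * preset.max_diameter) | 1
        block = min(block, (min(gray.shape) - 1) | 1)
        local = threshold_local(gray, block_size=max(block, 3), method="gaussian")
        # bound the adaptive surface by the global two-class threshold so
        # flat background regions cannot become foreground
        local = np.clip(local, 0.7 * global_th, 1.3 * global_th)
        fg = gray > local
    else:
        raise ContractError(f"unknown threshold method {preset.threshold_method!r}")
    if preset.fill_holes:
        fg = ndi.binary_fill_holes(fg)
    return fg


def identify_primary(gray: np.ndarray, preset: PipelinePreset) -> LabelMask:
    """Threshold, fill, declump by distance-transform watershed, size-filter."""
    gray = np.asarray(gray, dtype=np.float64)
    fg = _foreground(gray, preset)
    eight = np.ones((3, 3), dtype=int)
    if not fg.any():
        return LabelMask(image_id="", labels=np.zeros(gray.shape, dtype=np.int32))
    comps, _ = ndi.label(fg, structure=eight)
    if preset.declump:
        dist = ndi.distance_transform_edt(fg)
        smooth = ndi.gaussian_filter(dist, sigma=max(1.0, preset.min_diameter / 4.0))
        coords = peak_local_max(
            smooth,
            min_distance=preset.seed_min_distance,
            labels=comps,
            exclude_border=False,
        )
        markers = np.zeros(gray.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        # a component whose plateau produced no peak still gets one seed
        seeded = np.unique(comps[markers > 0])
        missing = np.setdiff1d(np.unique(comps[comps > 0]), seeded)
        next_label = len(coords) + 1
        for comp_id in missing:
            pos = np.unravel_index(
                np.argmax(np.where(comps == comp_id, dist, -1)), gray.shape
            )
            markers[pos] = next_label
            next_label += 1
        labels = watershed(-smooth, markers=markers, mask=fg, connectivity=2)
    else:
        labels = comps
    labels = _filter_by_diameter(labels, preset.min_diameter, preset.max_diameter)
    if preset.border_policy == "discard":
        labels = clear_border(labels)
    return LabelMask(image_id="", labels=canonicalize_labels(labels))


def _filter_by_diameter(labels: np.ndarray, lo: float, hi: float) -> np.ndarray:
    out = labels.copy()
    for p in regionprops(labels):
        if not (lo <= p.equivalent_diameter_area <= hi):
            out[labels == p.label] = 0
    return out


# ---------------------------------------------------------------------------
# step 3: secondary revision


def refine_secondary(
    gray: np.ndarray, primary: LabelMask, preset: PipelinePreset
) -> LabelMask:
    """Seeded watershed from primary objects within a re-thresholded foreground.

    The object count is preserved or reduced (the size prior may remove
    an object, never split one); boundaries move only within the
    foreground.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if primary.shape != gray.shape:
        raise ContractError("primary mask and grayscale image shapes differ")
    if primary.n_objects == 0:
        return LabelMask(image_id=primary.image_id, labels=np.zeros(gray.shape, np.int32))
    fg = _foreground(gray, preset) | (primary.labels > 0)
    labels = watershed(-gray, markers=primary.labels, mask=fg, connectivity=2)
    labels = _filter_by_diameter(labels, preset.min_diameter, preset.max_diameter)
    return LabelMask(image_id=primary.image_id, labels=canonicalize_labels(labels))


# ---------------------------------------------------------------------------
# full pipeline


def segment(
    img: ImageRecord,
    preset_override: Optional[PipelinePreset] = None,
    group_override: Optional[str] = None,
) -> tuple[LabelMask, GroupCall]:
    """Segment one image with no per-image parameters.

    Classifies the group (unless overridden), looks up the fixed
    preset, then runs pre-processing, primary identification and
    secondary revision. Deterministic: identical input, identical mask.
    """
    call = classify_group(img)
    if group_override is not None:
        if group_override not in GROUPS:
            raise ContractError(f"unknown group {group_override!r}")
        call = GroupCall(
            group=group_override, is_color=call.is_color,
            dark_background=call.dark_background,
            background_saturation=call.background_saturation,
            median_diameter=call.median_diameter, confidence="high",
        )
    preset = preset_override or PRESETS[call.group]
    gray = to_foreground_grayscale(img, preset)
    primary = identify_primary(gray, preset)
    refined = refine_secondary(gray, primary, preset)
    refined.image_id = img.image_id
    return refined, call
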