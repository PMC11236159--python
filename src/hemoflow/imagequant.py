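"""Image-stack quantification: fluorescence totals and clot segmentation.

Converts a time-stamped two-channel image stack of the injury-site ROI into
an :class:`~hemoflow.traces.AssayTrace`: per-frame total fluorescence
intensity (the MFI readout is the plain sum of the image matrix over the
ROI, no background subtraction by default) and a segmented clot surface
area. Segmentation is an automated stand-in for manual outlining: global
Otsu threshold on the background-subtracted brightfield frame, a detection
guard against thresholding pure noise, and removal of small connected
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .traces import AssayTrace, VENOUS


class ImageError(ValueError):
    """Raised for malformed stacks, frames or ROIs."""


@dataclass
class ImageStack:
    """Time-stamped image stack of the injury-site ROI.

    ``brightfield`` and (optionally) ``fluorescence`` are (T, rows, cols)
    arrays sharing a shape and the timestamp axis. ``roi`` is a half-open
    pixel rectangle (r0, r1, c0, c1), 0-based row-major; by default the
    full frame. Synthetic stacks carry ground-truth masks/areas for
    segmentation tests.
    """

    brightfield: np.ndarray
    timestamps_s: np.ndarray
    um_per_pixel: float
    fluorescence: Optional[np.ndarray] = None
    roi: Optional[tuple] = None
    shear_setting: str = VENOUS
    patient_id: Optional[str] = None
    truth_masks: Optional[np.ndarray] = None
    truth_areas_um2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.brightfield = np.asarray(self.brightfield, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.brightfield.ndim != 3:
            raise ImageError("brightfield must be a (T, rows, cols) array")
        if self.timestamps_s.size != self.brightfield.shape[0]:
            raise ImageError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps_s) <= 0):
            raise ImageError("timestamps must be strictly increasing")
        if self.um_per_pixel <= 0:
            raise ImageError("um_per_pixel must be positive")
        if self.fluorescence is not None:
            self.fluorescence = np.asarray(self.fluorescence, dtype=float)
            if self.fluorescence.shape != self.brightfield.shape:
                raise ImageError("channel shapes differ")
        if self.roi is None:
            self.roi = (0, self.brightfield.shape[1], 0, self.brightfield.shape[2])

    @property
    def n_frames(self) -> int:
        return self.brightfield.shape[0]


@dataclass
class ClotMask:
    """Binary clot mask for one frame."""

    mask: np.ndarray
    frame_index: int = 0
    flags: list = field(default_factory=list)

    @property
    def pixel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding-based segmentation settings.

    ``polarity`` declares whether clots are darker or brighter than the
    background; ``min_object_px`` removes specks below that size;
    ``detection_sigma_mult`` requires the Otsu class separation to clear
    this many robust background-noise SDs before any pixel is called clot
    (otherwise thresholding pure background would always mask about half
    the frame).
    """

    polarity: str = "dark"
    min_object_px: int = 5
    detection_sigma_mult: float = 4.0

    def __post_init__(self) -> None:
        if self.polarity not in ("dark", "bright"):
            raise ImageError("polarity must be 'dark' or 'bright'")


DEFAULT_SEGMENTATION = SegmentationConfig()


def _check_roi(frame: np.ndarray, roi: tuple) -> tuple:
    r0, r1, c0, c1 = roi
    rows, cols = frame.shape
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ImageError(f"ROI {roi} outside frame bounds {frame.shape} or empty")
    return r0, r1, c0, c1


def total_intensity(frame: np.ndarray, roi: Optional[tuple] = None) -> float:
    """Sum of pixel intensities over the ROI (the MFI readout)."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ImageError("frame must be 2-D")
    if roi is None:
        roi = (0, frame.shape[0], 0, frame.shape[1])
    r0, r1, c0, c1 = _check_roi(frame, roi)
    return float(frame[r0:r1, c0:c1].sum())


def segment_clot(frame: np.ndarray,
                 config: SegmentationConfig = DEFAULT_SEGMENTATION,
                 frame_index: int = 0) -> ClotMask:
    """Segment clot pixels in a brightfield frame.

    Background-subtract (median), orient by polarity, Otsu-threshold, and
    drop small connected components. A constant frame, or one whose Otsu
    threshold does not clear the noise floor, yields an empty mask with an
    explanatory flag rather than an error.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ImageError("frame contains non-finite values")
    background = float(np.median(frame))
    signal = background - frame if config.polarity == "dark" else frame - background
    if np.ptp(signal) == 0:
        return ClotMask(np.zeros(frame.shape, dtype=bool), frame_index,
                        flags=["constant_frame"])
    thr = float(threshold_otsu(signal))
    below, above = signal[signal <= thr], signal[signal > thr]
    # noise estimated from the background (sub-threshold) population only --
    # a frame-wide MAD would be inflated by a large clot; require the class
    # separation to clear the noise floor, else Otsu is just splitting noise
    sigma_bg = 1.4826 * float(np.median(np.abs(below - np.median(below))))
    separation = float(above.mean() - below.mean()) if above.size else 0.0
    if separation <= config.detection_sigma_mult * sigma_bg or thr <= 0:
        return ClotMask(np.zeros(frame.shape, dtype=bool), frame_index,
                        flags=["no_clot_detected"])
    mask = signal > thr
    if config.min_object_px > 1:
        # remove objects strictly smaller than min_object_px
        mask = remove_small_objects(mask, max_size=config.min_object_px - 1)
    return ClotMask(mask, frame_index)


def mask_to_area(mask: ClotMask, um_per_pixel: float) -> float:
    """Pixel count times the squared pixel size, in um^2."""
    if um_per_pixel <= 0:
        raise ImageError("um_per_pixel must be positive")
    return mask.pixel_count * um_per_pixel * um_per_pixel


def stack_to_trace(stack: ImageStack,
                   config: SegmentationConfig = DEFAULT_SEGMENTATION) -> AssayTrace:
    """Quantify a stack into an assay trace (area and fluorescence series).

    Timestamps are preserved as given. A stack without a fluorescence
    channel yields a trace with the intensity series marked missing; image
    stacks carry no flow readout, so the flow series is always missing.
    """
    if stack.n_frames < 2:
        raise ImageError("need at least 2 frames to build a trace")
    r0, r1, c0, c1 = _check_roi(stack.brightfield[0], stack.roi)
    areas = np.empty(stack.n_frames)
    for k in range(stack.n_frames):
        m = segment_clot(stack.brightfield[k, r0:r1, c0:c1], config, frame_index=k)
        areas[k] = mask_to_area(m, stack.um_per_pixel)
    intensity = None
    if stack.fluorescence is not None:
        intensity = np.array([total_intensity(stack.fluorescence[k], stack.roi)
                              for k in range(stack.n_frames)])
    return AssayTrace(time=stack.timestamps_s - stack.timestamps_s[0],
                      area=areas, platelet_intensity=intensity, flow=None,
                      shear_setting=stack.shear_setting,
                      patient_id=stack.patient_id)


# ---------------------------------------------------------------------------
# TIFF I/O (per-frame timestamps in the image description metadata)
# ---------------------------------------------------------------------------

def write_stack_tiff(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF, channels interleaved per frame.

    Pages are ordered (frame, channel); acquisition metadata (timestamps,
    pixel size, channel names, shear setting) travels in the file's JSON
    image description.
    """
    import json

    import tifffile

    channels = ["brightfield"]
    data = [stack.brightfield]
    if stack.fluorescence is not None:
        channels.append("fluorescence")
        data.append(stack.fluorescence)
    pages = np.stack(data, axis=1).astype(np.float32)    # (T, C, H, W)
    meta = {
        "timestamps_s": stack.timestamps_s.tolist(),
        "um_per_pixel": stack.um_per_pixel,
        "channels": channels,
        "shear_setting": stack.shear_setting,
        "patient_id": stack.patient_id,
    }
    tifffile.imwrite(path, pages, description=json.dumps(meta),
                     metadata=None)


def read_stack_tiff(path) -> ImageStack:
    """Read a stack written by :func:`write_stack_tiff`."""
    import json

    import tifffile

    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    channels = meta["channels"]
    if pages.ndim == 3:      # pages come back flat as (T*C, H, W)
        pages = pages.reshape(-1, len(channels), *pages.shape[-2:])
    bf = pages[:, channels.index("brightfield")].astype(float)
    fl = (pages[:, channels.index("fluorescence")].astype(float)
          if "fluorescence" in channels else None)
    return ImageStack(brightfield=bf, fluorescence=fl,
                      timestamps_s=np.asarray(meta["timestamps_s"], dtype=float),
                      um_per_pixel=float(meta["um_per_pixel"]),
                      shear_setting=meta.get("shear_setting", VENOUS),
                      patient_id=meta.get("patient_id"))
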