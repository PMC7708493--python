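"""Station volumes -> normalized, padded 2.5D slice stacks for the network.

Each training/inference sample is a stack of three adjacent axial slices
(below, target, above — with a periodic border at the station ends) from the
water channel, intensity-normalized per station after clipping the brightest
one percent of values, then symmetrically zero-padded in-plane so both
dimensions are divisible by the network's downsampling factor (e.g. a
224 x 174 slice pads to 224 x 192 for a factor-32 network). The padding is
recorded so the predicted label can be cropped back exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import VolumeImage

__all__ = [
    "SliceStack",
    "normalize_station",
    "build_stack",
    "unpad",
    "elastic_augment",
    "select_training_slices",
]


@dataclass
class SliceStack:
    """One 2.5D network input: (H_pad, W_pad, 3) pixels plus provenance.

    ``pad_spec`` is ((top, bottom), (left, right)) zero-pad widths; the two
    sides of each axis differ by at most one (odd totals split floor/ceil).
    """

    pixels: np.ndarray
    pad_spec: tuple[tuple[int, int], tuple[int, int]]
    station_index: int = 0
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"stack must be (H, W, 3), got {self.pixels.shape}")


def normalize_station(volume: VolumeImage, clip_fraction: float = 0.01) -> VolumeImage:
    """Clip the brightest ``clip_fraction`` of intensities, rescale to [0, 1].

    The clip level is the (1 - clip_fraction) quantile over all voxels of the
    station; output is invariant to positive rescaling of the input. A
    constant-intensity station maps to zeros with a warning.
    """
    data = np.asarray(volume.data, dtype=np.float32)
    if data.size == 0:
        raise ValueError("cannot normalize an empty volume")
    clip = float(np.quantile(data, 1.0 - clip_fraction))
    lo = float(data.min())
    if clip <= lo:
        warnings.warn("constant-intensity station normalizes to all zeros", stacklevel=2)
        return volume.with_data(np.zeros_like(data))
    out = np.clip(data, None, clip) / clip
    return volume.with_data(np.clip(out, 0.0, 1.0))


def _pad_amounts(size: int, multiple: int) -> tuple[int, int]:
    total = (-size) % multiple
    return total // 2, total - total // 2


def build_stack(volume: VolumeImage, slice_index: int, pad_multiple: int = 32,
                station_index: int = 0) -> SliceStack:
    """Assemble the 2.5D input stack for one axial slice.

    Channels are slices ``(i-1 mod S, i, i+1 mod S)`` — the periodic border
    makes the first and last slices reuse the opposite station end — then
    both in-plane dims are symmetrically zero-padded up to the next multiple
    of ``pad_multiple``.
    """
    S = volume.data.shape[2]
    if S < 1:
        raise ValueError("station has no slices")
    if not 0 <= slice_index < S:
        raise IndexError(f"slice_index {slice_index} outside [0, {S})")
    idx = [(slice_index - 1) % S, slice_index, (slice_index + 1) % S]
    stack = np.ascontiguousarray(volume.data[:, :, idx]).astype(np.float32)
    pads = (_pad_amounts(stack.shape[0], pad_multiple),
            _pad_amounts(stack.shape[1], pad_multiple))
    padded = np.pad(stack, (pads[0], pads[1], (0, 0)))
    return SliceStack(padded, pads, station_index=station_index, slice_index=slice_index)


def unpad(labels2d: np.ndarray, pad_spec) -> np.ndarray:
    """Exact inverse of the zero-padding applied by :func:`build_stack`."""
    (t, b), (l, r) = pad_spec
    H, W = labels2d.shape[:2]
    if H <= t + b or W <= l + r:
        raise ValueError(f"array of shape {labels2d.shape} inconsistent with pad_spec {pad_spec}")
    return labels2d[t : H - b if b else H, l : W - r if r else W]


def _displacement_field(shape, params, rng) -> np.ndarray:
    """Smooth random displacement field, shape (2, H, W), in pixels."""
    grid = int(params.get("grid_points", 4))
    amplitude = float(params.get("amplitude_px", 10.0))
    sigma = float(params.get("smooth_sigma", 4.0))
    H, W = shape
    coarse = rng.uniform(-amplitude, amplitude, size=(2, grid, grid))
    field = np.empty((2, H, W))
    zoom = (H / grid, W / grid)
    for k in range(2):
        field[k] = ndimage.zoom(coarse[k], zoom, order=1)[:H, :W]
        field[k] = ndimage.gaussian_filter(field[k], sigma)
    return field


def elastic_augment(stack: SliceStack, label2d: np.ndarray, params: dict | None,
                    rng: np.random.Generator):
    """Warp stack and label with one shared smooth random displacement field.

    Image channels are interpolated linearly, the label nearest-neighbour (so
    a binary label stays binary). Zero amplitude returns the inputs unchanged;
    the result is deterministic given the generator state.
    """
    params = params or {}
    if float(params.get("amplitude_px", 10.0)) == 0.0:
        return stack, label2d
    H, W = stack.pixels.shape[:2]
    if label2d.shape != (H, W):
        raise ValueError("stack and label are not spatially aligned")
    field = _displacement_field((H, W), params, rng)
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    coords = np.stack([ii + field[0], jj + field[1]])
    warped = np.empty_like(stack.pixels)
    for c in range(3):
        warped[:, :, c] = ndimage.map_coordinates(
            stack.pixels[:, :, c], coords, order=1, mode="constant", cval=0.0
        )
    warped_label = ndimage.map_coordinates(
        label2d.astype(np.float32), coords, order=0, mode="constant", cval=0.0
    ).astype(label2d.dtype)
    out = SliceStack(warped, stack.pad_spec, stack.station_index, stack.slice_index)
    return out, warped_label


def select_training_slices(station: VolumeImage, drop_ends: int = 2) -> np.ndarray:
    """Slice indices used for training, excluding artefact-prone station ends."""
    if drop_ends < 0:
        raise ValueError("drop_ends must be >= 0")
    S = station.data.shape[2]
    if 2 * drop_ends >= S:
        raise ValueError(f"drop_ends={drop_ends} removes every slice of a {S}-slice station")
    return np.arange(drop_ends, S - drop_ends)
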