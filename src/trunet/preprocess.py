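"""Frame preprocessing and sequence assembly.

Raw IVOCT acquisitions are polar scans (rows = A-lines over a full
rotation, columns = depth samples from the catheter outward).  They are
resampled onto a square Cartesian grid, grouped into temporally ordered
sequence units of length T ending at the segmentation target x_t, and
augmented with the *same* geometric operation applied to every slice of a
unit and to its mask, so spatiotemporal correspondence is preserved.

Conventions (the acquisition itself does not fix them): theta = 0 along
the +x axis, counter-clockwise, row 0 of the polar input at theta = 0;
8-bit inputs are divided by 255 with no per-image standardisation;
rotations are restricted to multiples of 90 degrees so that frame/mask
pairs stay bit-exact under augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

AUGMENT_OPS = ("identity", "hflip", "vflip", "rot90", "rot180", "rot270")

__all__ = ["Frame", "SequenceUnit", "polar_to_cartesian", "group_sequences",
           "augment_unit", "AUGMENT_OPS", "load_frames", "load_mask"]


@dataclass
class Frame:
    pixels: np.ndarray          # H x W float in [0, 1]
    frame_index: int = 0

    def __post_init__(self):
        self.pixels = np.clip(np.asarray(self.pixels, dtype=np.float32), 0.0, 1.0)


@dataclass
class SequenceUnit:
    """Ordered stack of T frames ending at the segmentation target.

    Logical layout is (C, H, W, T); the in-memory array is stored as
    (T, C, H, W) for convolution efficiency.  The last slice is x_t.
    """
    stack: np.ndarray           # (T, C, H, W)
    target_frame_id: int = 0

    @property
    def T(self) -> int:
        return self.stack.shape[0]

    @property
    def target_index(self) -> int:
        return self.T - 1

    @property
    def target(self) -> np.ndarray:
        return self.stack[-1]


def polar_to_cartesian(polar_image: np.ndarray, out_size: int) -> np.ndarray:
    """Resample an (A-lines x depth) polar scan onto an out_size^2 grid.

    The Cartesian pixel at polar coordinates (r, theta) — measured from the
    grid centre (out_size/2, out_size/2) — is bilinearly interpolated from
    the polar image at row theta/(2*pi)*A (with angular wrap-around) and
    column r; radii beyond the last depth column map to 0.
    """
    polar_image = np.asarray(polar_image, dtype=np.float64)
    if polar_image.size == 0 or polar_image.ndim != 2:
        raise ValueError("polar_to_cartesian: need a non-empty 2-D A-lines x depth array")
    n_angles, n_depth = polar_image.shape
    c = out_size / 2.0
    y, x = np.mgrid[0:out_size, 0:out_size]
    r = np.hypot(x - c, y - c)
    theta = np.mod(np.arctan2(y - c, x - c), 2.0 * np.pi)
    rows = theta / (2.0 * np.pi) * n_angles
    # wrap-pad one row so bilinear interpolation across theta=0 is seamless
    padded = np.concatenate([polar_image, polar_image[:1]], axis=0)
    out = ndimage.map_coordinates(padded, [rows, r], order=1,
                                  mode="constant", cval=0.0)
    out[r > n_depth - 1] = 0.0
    return out


def group_sequences(frames, T: int):
    """One sequence unit per target frame.

    Unit t holds the T-1 frames preceding t plus frame t, oldest first; for
    early targets (t < T-1) the first frame is replicated to fill the unit,
    so the number of units equals the number of frames.
    """
    if T < 1:
        raise ValueError("sequence length T must be >= 1")
    arrays = []
    for f in frames:
        px = f.pixels if isinstance(f, Frame) else np.asarray(f, dtype=np.float32)
        if px.ndim == 2:
            px = px[None]          # add channel dim -> (1, H, W)
        arrays.append(px)
    units = []
    for t in range(len(arrays)):
        idx = [max(0, t - (T - 1) + i) for i in range(T)]
        stack = np.stack([arrays[i] for i in idx], axis=0)
        units.append((SequenceUnit(stack=stack, target_frame_id=t), t))
    return units


def _apply_op(arr: np.ndarray, op_id: str, h_axis: int, w_axis: int) -> np.ndarray:
    if op_id == "identity":
        return arr.copy()
    if op_id == "hflip":
        return np.flip(arr, axis=w_axis).copy()
    if op_id == "vflip":
        return np.flip(arr, axis=h_axis).copy()
    if op_id in ("rot90", "rot180", "rot270"):
        k = {"rot90": 1, "rot180": 2, "rot270": 3}[op_id]
        if arr.shape[h_axis] != arr.shape[w_axis]:
            raise ValueError("rotation augmentation requires square frames")
        return np.rot90(arr, k=k, axes=(h_axis, w_axis)).copy()
    raise ValueError(f"unknown augmentation op {op_id!r}")


def augment_unit(unit: SequenceUnit, mask: np.ndarray, op_id: str,
                 rng: np.random.Generator | None = None):
    """Apply one geometric op to every slice of the unit and to the mask.

    ``op_id='random'`` draws uniformly from :data:`AUGMENT_OPS` using ``rng``.
    """
    if op_id == "random":
        if rng is None:
            raise ValueError("op_id='random' requires an rng")
        op_id = AUGMENT_OPS[int(rng.integers(len(AUGMENT_OPS)))]
    stack = _apply_op(unit.stack, op_id, h_axis=2, w_axis=3)
    new_mask = _apply_op(np.asarray(mask), op_id, h_axis=0, w_axis=1)
    return SequenceUnit(stack=stack, target_frame_id=unit.target_frame_id), new_mask


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def load_frames(directory, manifest_order=None):
    """Read grayscale PNG/TIFF frames as Frame objects, values scaled to [0,1]."""
    src = Path(directory)
    if manifest_order is None:
        names = sorted(p.name for p in src.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
    else:
        names = list(manifest_order)
    frames = []
    for i, name in enumerate(names):
        img = Image.open(src / name).convert("F")
        arr = np.asarray(img, dtype=np.float32)
        if arr.max() > 1.0:
            arr = arr / 255.0
        frames.append(Frame(pixels=arr, frame_index=i))
    return frames


def load_mask(path) -> np.ndarray:
    return (np.asarray(Image.open(path)) > 127).astype(np.uint8)
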