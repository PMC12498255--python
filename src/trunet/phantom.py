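"""Synthetic IVOCT pullback phantoms with ground-truth lumen masks.

A phantom emulates the structure the segmentation method exploits: a
star-shaped lumen cross-section whose harmonic contour drifts smoothly
along the pullback axis, a bright vessel-wall band, a central catheter
disc, a guidewire shadow sector, multiplicative speckle, and optional
frame-local blood artifacts that corrupt the image (never the label).
Masks follow the clinical contouring convention: the labeled lumen is the
full star region bounded by the tissue contour — simply connected, with
the catheter footprint and the guidewire shadow labeled as lumen.

Intensity levels before speckle are fixed for reproducibility:
background 0.05, lumen 0.10, wall 0.80, catheter 0.95.

Randomness follows a documented splitting rule: ``SeedSequence(seed)`` is
spawned into ``n_frames + 1`` children — child 0 drives the contour random
walk (and per-frame artifact coin flips), child ``k + 1`` drives the
speckle and artifact texture of frame ``k``, so any single frame can be
re-rendered independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

BACKGROUND_LEVEL = 0.05
LUMEN_LEVEL = 0.10
WALL_LEVEL = 0.80
CATHETER_LEVEL = 0.95

__all__ = [
    "PhantomConfig", "PullbackPhantom", "make_lumen_contour", "rasterize_contour",
    "render_frame", "apply_blood_artifact", "generate_pullback",
    "save_pullback", "load_pullback",
]


@dataclass
class PhantomConfig:
    image_size: int = 64
    n_frames: int = 12
    seq_noise: float = 1.0          # contour random-walk std per frame, pixels
    base_radius: float = 18.0       # pixels
    harmonic_amps: tuple = (3.0, 2.0)   # angular harmonics k=1..len, pixels
    wall_thickness: float = 5.0     # pixels
    catheter_radius: float = 4.0    # pixels
    guidewire_width: float = 0.35   # radians
    blood_artifact_prob: float = 0.25
    blood_severity: float = 0.4     # target occluded angular fraction
    speckle_sigma: float = 0.08     # multiplicative noise std
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        amps = np.abs(np.asarray(self.harmonic_amps, dtype=float))
        if amps.sum() > 0.3 * self.base_radius:
            raise ValueError("sum of harmonic amplitudes exceeds 30% of base_radius")
        if self.base_radius - amps.sum() <= self.catheter_radius:
            raise ValueError("lumen can collapse onto the catheter: "
                             "base_radius - sum|amps| must exceed catheter_radius")
        for name in ("blood_artifact_prob", "blood_severity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PullbackPhantom:
    frames: list = field(default_factory=list)        # H x W float in [0,1]
    masks: list = field(default_factory=list)         # H x W uint8 binary
    artifact_flags: list = field(default_factory=list)
    contour_params: list = field(default_factory=list)  # per-frame dicts
    config: PhantomConfig | None = None

    def __len__(self):
        return len(self.frames)


def make_lumen_contour(base_radius: float, harmonic_amps, phases):
    """Star-shaped contour radius function r(theta).

    ``r(theta) = base_radius + sum_k amp_k * cos(k*theta + phase_k)``
    (harmonics k = 1..len(amps)).  Raises if the amplitude bound would let
    the radius become non-positive.
    """
    amps = np.asarray(harmonic_amps, dtype=float)
    phs = np.asarray(phases, dtype=float)
    if amps.shape != phs.shape:
        raise ValueError("harmonic_amps and phases must have equal length")
    if np.abs(amps).sum() >= base_radius:
        raise ValueError("sum |harmonic_amps| must be < base_radius")

    ks = np.arange(1, amps.size + 1)

    def contour(theta):
        theta = np.asarray(theta, dtype=float)
        if amps.size == 0:
            return np.full_like(theta, base_radius, dtype=float)
        return base_radius + np.cos(np.multiply.outer(theta, ks) + phs) @ amps

    return contour


def _polar_grid(size: int):
    c = size / 2.0
    y, x = np.mgrid[0:size, 0:size]
    dx = x - c
    dy = y - c
    return np.hypot(dx, dy), np.arctan2(dy, dx)


def rasterize_contour(contour, size: int) -> np.ndarray:
    """Binary star-region raster: pixel set iff its polar radius < r(theta)."""
    r, theta = _polar_grid(size)
    return (r < contour(theta)).astype(np.uint8)


def _ang_diff(a, b):
    d = np.mod(a - b + np.pi, 2 * np.pi) - np.pi
    return np.abs(d)


def render_frame(contour, config: PhantomConfig,
                 rng: np.random.Generator | None = None,
                 guidewire_angle: float = 0.0):
    """Render one frame and its lumen mask from a contour function.

    The mask is 1 exactly on pixels with polar radius below r(theta).  The
    annotation convention follows clinical contouring: the lumen contour
    traces the tissue boundary, so the labeled region is simply connected
    and includes the catheter footprint (the catheter is an instrument
    *inside* the lumen); the guidewire shadow does not remove labeled
    lumen either.
    """
    size = config.image_size
    r, theta = _polar_grid(size)
    rb = contour(theta)

    frame = np.full((size, size), BACKGROUND_LEVEL, dtype=np.float64)
    frame[(r >= rb) & (r < rb + config.wall_thickness)] = WALL_LEVEL
    frame[r < rb] = LUMEN_LEVEL
    frame[r < config.catheter_radius] = CATHETER_LEVEL
    # thin bright sheath ring around the catheter
    frame[(r >= config.catheter_radius) & (r < config.catheter_radius + 1.0)] = \
        0.5 * (CATHETER_LEVEL + LUMEN_LEVEL)

    if config.guidewire_width > 0:
        shadow = (_ang_diff(theta, guidewire_angle) < config.guidewire_width / 2.0) & \
                 (r > config.catheter_radius + 1.0)
        frame[shadow] = BACKGROUND_LEVEL

    mask = (r < rb).astype(np.uint8)

    if config.speckle_sigma > 0:
        if rng is None:
            raise ValueError("speckle_sigma > 0 requires an rng")
        frame = frame * (1.0 + config.speckle_sigma * rng.standard_normal(frame.shape))
    return np.clip(frame, 0.0, 1.0), mask


def apply_blood_artifact(frame: np.ndarray, mask: np.ndarray, severity: float,
                         rng: np.random.Generator,
                         contour=None, config: PhantomConfig | None = None):
    """Overlay bright speckled blobs on the lumen boundary.

    Blobs are Gaussian bumps (sigma ~ 5% of image size) centred on contour
    points inside a contiguous angular window of width ``severity * 2*pi``;
    their influence is truncated to that window so the occluded angular
    fraction matches ``severity`` closely.  Only the image is corrupted —
    the label mask is never modified.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    if severity == 0:
        return frame.copy()
    size = frame.shape[0]
    if contour is None or config is None:
        raise ValueError("apply_blood_artifact needs the frame's contour and config")
    r, theta = _polar_grid(size)
    rb = contour(theta)
    sigma = 0.05 * size
    center_angle = rng.uniform(-np.pi, np.pi)
    half_window = severity * np.pi

    # blob centres along the occluded arc, spaced ~sigma apart on the contour
    mean_r = float(np.mean(rb))
    n_blobs = max(2, int(np.ceil(2 * half_window * mean_r / sigma)))
    angles = center_angle + np.linspace(-half_window, half_window, n_blobs)
    bumps = np.zeros_like(frame)
    c = size / 2.0
    for a in angles:
        rr = float(make_contour_radius(contour, a))
        bx = c + rr * np.cos(a)
        by = c + rr * np.sin(a)
        y, x = np.mgrid[0:size, 0:size]
        d2 = (x - bx) ** 2 + (y - by) ** 2
        bumps += np.exp(-d2 / (2.0 * sigma ** 2))

    window = _ang_diff(theta, center_angle) <= half_window
    band = np.abs(r - rb) <= 1.2 * sigma
    weight = np.clip(bumps, 0.0, 1.0) * window * band
    target = WALL_LEVEL * (0.8 + 0.4 * rng.random(frame.shape))
    out = frame * (1.0 - weight) + np.maximum(target, frame + 0.15) * weight
    return np.clip(out, 0.0, 1.0)


def make_contour_radius(contour, angle: float) -> float:
    return float(np.asarray(contour(np.asarray([angle]))).ravel()[0])


def generate_pullback(config: PhantomConfig) -> PullbackPhantom:
    """Generate a full pullback: bounded random-walk contours, rendered
    frames/masks, i.i.d. blood artifacts, fully reproducible from the seed."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_frames + 1)
    walk_rng = np.random.default_rng(children[0])

    amps = np.asarray(config.harmonic_amps, dtype=float).copy()
    n_h = amps.size
    phases = walk_rng.uniform(-np.pi, np.pi, size=n_h)
    base = float(config.base_radius)
    gw_angle = walk_rng.uniform(-np.pi, np.pi)
    amp_cap = 0.3 * config.base_radius

    phantom = PullbackPhantom(config=config)
    for k in range(config.n_frames):
        if k > 0 and config.seq_noise > 0:
            base = base + config.seq_noise * walk_rng.standard_normal()
            amps = amps + config.seq_noise * 0.5 * walk_rng.standard_normal(n_h)
            phases = phases + (config.seq_noise / config.base_radius) * \
                walk_rng.standard_normal(n_h)
            gw_angle += 0.02 * walk_rng.standard_normal()
            # clip to the invariants: bounded amplitudes, no catheter collapse
            base = float(np.clip(base, config.catheter_radius + 0.7 * config.base_radius * 0.3
                                 + 2.0, 0.45 * config.image_size
                                 - config.wall_thickness - 1.0))
            total = np.abs(amps).sum()
            cap = min(amp_cap, base - config.catheter_radius - 2.0)
            if total > cap > 0:
                amps = amps * (cap / total)
        elif k > 0:
            pass  # seq_noise == 0: contour frozen
        contour = make_lumen_contour(base, amps, phases)

        frame_rng = np.random.default_rng(children[k + 1])
        flagged = bool(walk_rng.random() < config.blood_artifact_prob)
        frame, mask = render_frame(contour, config, frame_rng, guidewire_angle=gw_angle)
        if flagged:
            frame = apply_blood_artifact(frame, mask, config.blood_severity,
                                         frame_rng, contour=contour, config=config)
        phantom.frames.append(frame.astype(np.float32))
        phantom.masks.append(mask)
        phantom.artifact_flags.append(flagged)
        phantom.contour_params.append({
            "base_radius": float(base),
            "harmonic_amps": [float(a) for a in amps],
            "phases": [float(p) for p in phases],
            "guidewire_angle": float(gw_angle),
        })
    return phantom


# ---------------------------------------------------------------------------
# persistence: PNG frames + PNG masks + JSON manifest (and optional .npz)
# ---------------------------------------------------------------------------

def save_pullback(phantom: PullbackPhantom, out_dir, archive: bool = False):
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    names = []
    for k, (frame, mask) in enumerate(zip(phantom.frames, phantom.masks)):
        name = f"frame_{k:04d}.png"
        Image.fromarray(np.round(frame * 255).astype(np.uint8)).save(out / "frames" / name)
        Image.fromarray((mask * 255).astype(np.uint8)).save(out / "masks" / name)
        names.append(name)
    manifest = {
        "frame_order": names,
        "artifact_flags": [bool(f) for f in phantom.artifact_flags],
        "contour_params": phantom.contour_params,
        "config": asdict(phantom.config) if phantom.config else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if archive:
        np.savez_compressed(out / "pullback.npz",
                            frames=np.stack(phantom.frames),
                            masks=np.stack(phantom.masks),
                            flags=np.asarray(phantom.artifact_flags))
    return out


def load_pullback(in_dir) -> PullbackPhantom:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    phantom = PullbackPhantom()
    if manifest.get("config"):
        cfg = dict(manifest["config"])
        cfg["harmonic_amps"] = tuple(cfg["harmonic_amps"])
        phantom.config = PhantomConfig(**cfg)
    for name in manifest["frame_order"]:
        frame = np.asarray(Image.open(src / "frames" / name), dtype=np.float32) / 255.0
        mask = (np.asarray(Image.open(src / "masks" / name)) > 127).astype(np.uint8)
        phantom.frames.append(frame)
        phantom.masks.append(mask)
    phantom.artifact_flags = list(manifest["artifact_flags"])
    phantom.contour_params = list(manifest.get("contour_params", []))
    return phantom
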