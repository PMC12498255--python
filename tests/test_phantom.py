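"""Phantom generator: contours, rendering, artifacts, reproducibility."""

import numpy as np
import pytest

from trunet import phantom as ph
from trunet.phantom import (PhantomConfig, apply_blood_artifact, generate_pullback,
                            load_pullback, make_lumen_contour, rasterize_contour,
                            render_frame, save_pullback)

LEVELS = {ph.BACKGROUND_LEVEL, ph.LUMEN_LEVEL, ph.WALL_LEVEL, ph.CATHETER_LEVEL,
          0.5 * (ph.CATHETER_LEVEL + ph.LUMEN_LEVEL)}


def clean_config(**kw):
    base = dict(image_size=64, n_frames=4, seq_noise=0.0, speckle_sigma=0.0,
                blood_artifact_prob=0.0, guidewire_width=0.0, seed=7)
    base.update(kw)
    return PhantomConfig(**base)


# -- contours ---------------------------------------------------------------

def test_zero_harmonic_contour_is_circle():
    c = make_lumen_contour(50.0, [], [])
    theta = np.linspace(0, 2 * np.pi, 33)
    assert np.allclose(c(theta), 50.0)


def test_cosine_contour_endpoints():
    c = make_lumen_contour(50.0, [10.0], [0.0])
    assert c(0.0) == pytest.approx(60.0)
    assert c(np.pi) == pytest.approx(40.0)


def test_amplitude_bound_is_enforced():
    with pytest.raises(ValueError):
        make_lumen_contour(10.0, [6.0, 5.0], [0.0, 0.0])


def test_rasterized_circle_area_matches_pixel_counting():
    c = make_lumen_contour(50.0, [], [])
    area = rasterize_contour(c, 256).sum()
    assert abs(area - np.pi * 50 ** 2) / (np.pi * 50 ** 2) < 0.02


# -- rendering --------------------------------------------------------------

def test_noise_free_frame_is_piecewise_constant():
    cfg = clean_config()
    c = make_lumen_contour(cfg.base_radius, cfg.harmonic_amps, [0.0, 0.0])
    frame, mask = render_frame(c, cfg)
    assert set(np.unique(frame)).issubset(LEVELS)
    assert mask.dtype == np.uint8 and set(np.unique(mask)) <= {0, 1}


def test_mask_is_rasterized_star_region():
    cfg = clean_config()
    c = make_lumen_contour(cfg.base_radius, cfg.harmonic_amps, [0.3, 1.1])
    _, mask = render_frame(c, cfg)
    star = rasterize_contour(c, cfg.image_size)
    assert np.array_equal(mask, star)
    # simply connected: one 4-connected component, no interior holes
    from scipy import ndimage
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, n = ndimage.label(mask, structure=structure)
    assert n == 1
    assert np.array_equal(ndimage.binary_fill_holes(mask), mask.astype(bool))


def test_guidewire_sector_is_background_beyond_catheter():
    cfg = clean_config(guidewire_width=0.5)
    c = make_lumen_contour(cfg.base_radius, [], [])
    frame, mask = render_frame(c, cfg, guidewire_angle=0.0)
    size = cfg.image_size
    y, x = np.mgrid[0:size, 0:size]
    r = np.hypot(x - size / 2, y - size / 2)
    theta = np.arctan2(y - size / 2, x - size / 2)
    sector = (np.abs(theta) < 0.2) & (r > cfg.catheter_radius + 2) & (r < size / 2 - 1)
    assert np.all(frame[sector] == ph.BACKGROUND_LEVEL)
    # the labeled lumen continues under the shadow
    assert mask[sector & (r < cfg.base_radius - 1)].all()


def test_mask_star_shaped_single_run_per_ray():
    cfg = clean_config()
    c = make_lumen_contour(cfg.base_radius, cfg.harmonic_amps, [0.5, 2.0])
    _, mask = render_frame(c, cfg)
    center = cfg.image_size / 2
    for ang in np.linspace(0, 2 * np.pi, 24, endpoint=False):
        rr = np.arange(0, cfg.image_size // 2 - 1)
        xs = np.clip((center + rr * np.cos(ang)).astype(int), 0, cfg.image_size - 1)
        ys = np.clip((center + rr * np.sin(ang)).astype(int), 0, cfg.image_size - 1)
        vals = mask[ys, xs]
        runs = np.count_nonzero(np.diff(vals.astype(int)) == 1)
        assert runs <= 1


# -- blood artifact ---------------------------------------------------------

def test_blood_artifact_zero_severity_is_identity(rng):
    cfg = clean_config()
    c = make_lumen_contour(cfg.base_radius, [], [])
    frame, mask = render_frame(c, cfg)
    out = apply_blood_artifact(frame, mask, 0.0, rng, contour=c, config=cfg)
    assert np.array_equal(out, frame)


def test_blood_artifact_angular_coverage_matches_severity(rng):
    cfg = clean_config(image_size=128, base_radius=36.0, harmonic_amps=(4.0, 3.0))
    c = make_lumen_contour(cfg.base_radius, cfg.harmonic_amps, [0.2, 0.9])
    frame, mask = render_frame(c, cfg)
    severity = 0.4
    covered = []
    for trial in range(5):
        out = apply_blood_artifact(frame, mask, severity,
                                   np.random.default_rng(trial),
                                   contour=c, config=cfg)
        size = cfg.image_size
        y, x = np.mgrid[0:size, 0:size]
        r = np.hypot(x - size / 2, y - size / 2)
        theta = np.arctan2(y - size / 2, x - size / 2)
        boundary = np.abs(r - c(theta)) < 2.0
        raised = boundary & (out > frame + 1e-6)
        bins = np.linspace(-np.pi, np.pi, 73)
        hit = np.histogram(theta[raised], bins=bins)[0] > 0
        total = np.histogram(theta[boundary], bins=bins)[0] > 0
        covered.append(hit.sum() / total.sum())
    assert all(0.35 <= f <= 0.45 for f in covered), covered


def test_blood_artifact_never_touches_mask(rng):
    cfg = clean_config()
    c = make_lumen_contour(cfg.base_radius, [], [])
    frame, mask = render_frame(c, cfg)
    before = mask.copy()
    apply_blood_artifact(frame, mask, 0.5, rng, contour=c, config=cfg)
    assert np.array_equal(mask, before)


# -- pullbacks --------------------------------------------------------------

def test_pullback_seed_determinism():
    cfg = PhantomConfig(image_size=64, n_frames=6, blood_artifact_prob=0.5, seed=42)
    a = generate_pullback(cfg)
    b = generate_pullback(cfg)
    for fa, fb in zip(a.frames, b.frames):
        assert np.array_equal(fa, fb)
    for ma, mb in zip(a.masks, b.masks):
        assert np.array_equal(ma, mb)
    assert a.artifact_flags == b.artifact_flags


def test_pullback_zero_noise_freezes_contour():
    cfg = clean_config(n_frames=5, seq_noise=0.0)
    p = generate_pullback(cfg)
    for m in p.masks[1:]:
        assert np.array_equal(m, p.masks[0])


def test_consecutive_mask_iou_under_unit_noise():
    """1-px contour noise must keep consecutive masks nearly identical —
    the temporal-coupling premise of the sequence model."""
    cfg = PhantomConfig(image_size=160, n_frames=101, seq_noise=1.0,
                        base_radius=50.0, harmonic_amps=(6.0, 4.0),
                        wall_thickness=6.0, catheter_radius=6.0,
                        blood_artifact_prob=0.0, speckle_sigma=0.0, seed=3)
    p = generate_pullback(cfg)
    ious = []
    for m1, m2 in zip(p.masks[:-1], p.masks[1:]):
        inter = np.logical_and(m1, m2).sum()
        union = np.logical_or(m1, m2).sum()
        ious.append(inter / union)
    ious = np.asarray(ious)
    assert ious.mean() > 0.95
    assert np.quantile(ious, 0.01) >= 0.9


def test_artifact_flag_rate_is_binomial():
    cfg = PhantomConfig(image_size=32, n_frames=200, blood_artifact_prob=0.25,
                        base_radius=9.0, harmonic_amps=(1.5,), wall_thickness=3.0,
                        catheter_radius=2.0, seq_noise=0.0, speckle_sigma=0.0, seed=5)
    p = generate_pullback(cfg)
    k = sum(p.artifact_flags)
    n, prob = 200, 0.25
    std = np.sqrt(n * prob * (1 - prob))
    assert abs(k - n * prob) <= 3 * std


def test_config_invariants_rejected():
    with pytest.raises(ValueError):
        PhantomConfig(image_size=16)
    with pytest.raises(ValueError):
        PhantomConfig(base_radius=10.0, harmonic_amps=(4.0,), catheter_radius=8.0)
    with pytest.raises(ValueError):
        PhantomConfig(blood_artifact_prob=1.5)


def test_save_load_round_trip(tmp_path):
    cfg = PhantomConfig(image_size=64, n_frames=3, blood_artifact_prob=0.5, seed=11)
    p = generate_pullback(cfg)
    save_pullback(p, tmp_path / "pb")
    q = load_pullback(tmp_path / "pb")
    assert len(q) == len(p)
    assert q.artifact_flags == p.artifact_flags
    for ma, mb in zip(p.masks, q.masks):
        assert np.array_equal(ma, mb)
    for fa, fb in zip(p.frames, q.frames):
        assert np.abs(fa - fb).max() <= 1 / 255 + 1e-6  # 8-bit quantisation
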