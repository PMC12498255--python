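"""Training loop, evaluation pipeline and the artifact-robustness experiment.

Training follows the reference recipe: SGD on the soft Dice loss, batches
augmented with one geometric op applied identically to every slice of a
sequence unit and to its mask, ConvLSTM memory zero-initialised at every
sequence.  Two hyper-parameter profiles ship: the full-scale profile
(learning rate 0.1, batch 8, 100 epochs) and a desk-scale profile with a
smaller learning rate — 0.1 is routinely divergent at the narrow widths of
desk models.  Momentum defaults to 0.9 with a constant learning rate.

Evaluation post-processes every probability map, scores the five metrics
per image, and reports the mean over all frames and over the
artifact-flagged subset separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES, area_correlation, mask_metrics, soft_dice_loss
from .model import ModelConfig, TRUnet, build_variant, postprocess
from .nn import SGD
from .phantom import PhantomConfig, generate_pullback
from .preprocess import AUGMENT_OPS, augment_unit, group_sequences


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 0.1
    momentum: float = 0.9
    loss: str = "dice"
    optimizer: str = "sgd"
    seed: int = 0
    augment_ops: tuple = AUGMENT_OPS
    dice_epsilon: float = 1.0

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.loss != "dice" or self.optimizer != "sgd":
            raise ValueError("supported recipe: dice loss with SGD")


def desk_train_config(**overrides) -> TrainConfig:
    kw = dict(epochs=10, batch_size=4, learning_rate=0.01)
    kw.update(overrides)
    return TrainConfig(**kw)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_js: list = field(default_factory=list)


@dataclass
class Sample:
    """One training/evaluation item: a sequence unit with its target mask."""
    unit: object
    mask: np.ndarray
    artifact: bool = False
    image_id: str = ""


def make_dataset(phantoms, T: int) -> list:
    """Turn rendered pullbacks into (unit, mask) samples, one per frame."""
    samples = []
    for pi, ph in enumerate(phantoms):
        units = group_sequences(ph.frames, T)
        for unit, t in units:
            samples.append(Sample(unit=unit, mask=np.asarray(ph.masks[t]),
                                  artifact=bool(ph.artifact_flags[t]),
                                  image_id=f"p{pi:03d}_f{t:04d}"))
    return samples


def synthetic_split(n_pullbacks: int, frames_per_pullback: int, T: int,
                    phantom_kw: dict | None = None, seed: int = 0,
                    artifact_prob: float = 0.25):
    """Generate a reproducible set of pullbacks and flatten into samples."""
    kw = dict(phantom_kw or {})
    kw.setdefault("n_frames", frames_per_pullback)
    kw.setdefault("blood_artifact_prob", artifact_prob)
    phantoms = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_pullbacks):
        cfg = PhantomConfig(**kw, seed=int(child.generate_state(1)[0] % (2**31)))
        phantoms.append(generate_pullback(cfg))
    return make_dataset(phantoms, T)


def _forward_batch(model: TRUnet, batch: list, train_cfg: TrainConfig, rng):
    stacks, masks = [], []
    for s in batch:
        op = train_cfg.augment_ops[int(rng.integers(len(train_cfg.augment_ops)))]
        unit, mask = augment_unit(s.unit, s.mask, op)
        stacks.append(unit.stack)
        masks.append(mask)
    x = np.stack(stacks).astype(np.float32)          # (N, T, C, H, W)
    y = np.stack(masks).astype(np.float32)[:, None]  # (N, 1, H, W)
    prob = model(x)
    return soft_dice_loss(prob, y, epsilon=train_cfg.dice_epsilon), prob


def _validate(model: TRUnet, samples: list, train_cfg: TrainConfig):
    model.eval()
    losses, js = [], []
    for s in samples:
        prob = model(s.unit.stack[None].astype(np.float32))
        target = s.mask.astype(np.float32)[None, None]
        losses.append(float(soft_dice_loss(prob, target,
                                           epsilon=train_cfg.dice_epsilon).item()))
        js.append(mask_metrics(postprocess(prob.data[0, 0]), s.mask)["js"])
    model.train()
    return float(np.mean(losses)), float(np.mean(js))


def train(model: TRUnet, dataset: list, config: TrainConfig,
          val_dataset: list | None = None):
    """Seeded SGD/Dice training; returns (model, TrainHistory)."""
    rng = np.random.default_rng(config.seed)
    opt = SGD(model.parameters(), lr=config.learning_rate, momentum=config.momentum)
    history = TrainHistory()
    n = len(dataset)
    model.train()
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = [dataset[i] for i in order[start:start + config.batch_size]]
            loss, _ = _forward_batch(model, batch, config, rng)
            val = float(loss.item())
            if not np.isfinite(val):
                raise FloatingPointError("training aborted: non-finite Dice loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(val)
        history.train_loss.append(float(np.mean(epoch_losses)))
        if val_dataset:
            vloss, vjs = _validate(model, val_dataset, config)
            history.val_loss.append(vloss)
            history.val_js.append(vjs)
    return model, history


def evaluate(model: TRUnet, dataset: list, threshold: float = 0.5):
    """Score post-processed predictions; returns (report dict, per-image df).

    The report holds mean per-image metrics for the full set and for the
    artifact-flagged subset (None if the subset is empty).
    """
    model.eval()
    rows = []
    for s in dataset:
        prob = model(s.unit.stack[None].astype(np.float32)).data[0, 0]
        pred = postprocess(prob, threshold)
        row = {"image_id": s.image_id, "artifact": s.artifact,
               "pred_area": int(pred.sum()), "gt_area": int(np.asarray(s.mask).sum())}
        row.update(mask_metrics(pred, s.mask))
        rows.append(row)
    df = pd.DataFrame(rows)
    report = {"n_images": len(df),
              "aggregation": "mean of per-image metrics",
              "all": {k: float(df[k].mean()) for k in METRIC_NAMES}}
    art = df[df["artifact"]]
    report["n_artifact"] = int(len(art))
    report["artifact"] = ({k: float(art[k].mean()) for k in METRIC_NAMES}
                          if len(art) else None)
    if len(df) >= 2 and df["pred_area"].var() > 0 and df["gt_area"].var() > 0:
        report["area_r"] = area_correlation(df["pred_area"].to_numpy(),
                                            df["gt_area"].to_numpy())
    return report, df


@dataclass
class RobustnessConfig:
    """Scaled-down synthetic replica of the artifact-robustness comparison."""
    image_size: int = 64
    width_multiplier: float = 0.25
    sequence_length: int = 3
    n_train_pullbacks: int = 6
    n_test_pullbacks: int = 3
    frames_per_pullback: int = 10
    epochs: int = 10
    batch_size: int = 4
    learning_rate: float = 0.01
    train_artifact_prob: float = 0.3
    test_blood_severity: float = 0.4
    seeds: tuple = (0, 1, 2)
    sweep_T: tuple = ()          # e.g. (2, 3, 5, 10)


def _phantom_kw(cfg: RobustnessConfig) -> dict:
    return dict(image_size=cfg.image_size)


def run_robustness_seed(cfg: RobustnessConfig, seed: int, model_config: ModelConfig,
                        variants=("full", "-convlstm")) -> dict:
    """Train variant twins on identical phantoms/seeds; score both subsets."""
    train_set = synthetic_split(cfg.n_train_pullbacks, cfg.frames_per_pullback,
                                cfg.sequence_length, _phantom_kw(cfg),
                                seed=1000 + seed, artifact_prob=cfg.train_artifact_prob)
    test_kw = _phantom_kw(cfg)
    test_kw["blood_severity"] = cfg.test_blood_severity
    test_set = synthetic_split(cfg.n_test_pullbacks, cfg.frames_per_pullback,
                               cfg.sequence_length, test_kw,
                               seed=2000 + seed, artifact_prob=0.5)
    tc = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                     learning_rate=cfg.learning_rate, seed=seed)
    out = {}
    for name in variants:
        mc = replace(model_config,
                     use_convlstm=(name != "-convlstm"),
                     use_ca=(name not in ("-ca", "resunet")))
        model = build_variant(mc, rng=np.random.default_rng(seed))
        model, history = train(model, train_set, tc)
        report, _ = evaluate(model, test_set)
        out[name] = {"report": report, "history": history}
    return out


def robustness_experiment(cfg: RobustnessConfig, model_config: ModelConfig | None = None):
    """Full/-ConvLSTM comparison over seeds (+ optional sequence-length sweep).

    Returns (DataFrame with one row per variant/subset/seed, raw results).
    """
    mc = model_config or _default_desk_model(cfg)
    rows, raw = [], {}
    for seed in cfg.seeds:
        res = run_robustness_seed(cfg, seed, mc)
        raw[seed] = res
        for name, r in res.items():
            for subset in ("all", "artifact"):
                metrics = r["report"][subset]
                if metrics is None:
                    continue
                rows.append({"seed": seed, "variant": name, "subset": subset,
                             "n": r["report"]["n_images" if subset == "all"
                                              else "n_artifact"], **metrics})
    for T in cfg.sweep_T:
        mc_t = replace(mc, sequence_length=T)
        cfg_t = replace(cfg, sequence_length=T, seeds=cfg.seeds[:1])
        res = run_robustness_seed(cfg_t, cfg.seeds[0], mc_t, variants=("full",))
        for subset in ("all", "artifact"):
            metrics = res["full"]["report"][subset]
            if metrics is not None:
                rows.append({"seed": cfg.seeds[0], "variant": f"full(T={T})",
                             "subset": subset, "n": None, **metrics})
    return pd.DataFrame(rows), raw


def _default_desk_model(cfg: RobustnessConfig) -> ModelConfig:
    from .calibration import desk_config
    return desk_config(image_size=cfg.image_size,
                       width_multiplier=cfg.width_multiplier,
                       sequence_length=cfg.sequence_length)
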