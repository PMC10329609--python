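"""The two weight networks and their (scaled-down) training loop.

Each residual gets its own encoder-decoder network producing a
per-pixel weight in [0, 1] (final sigmoid).  The networks see exactly
the ingredients of the residuals they gate:

* 2D variant (8 channels):  image I_t (3), normalized depth D_t (1),
  temporal flow F_t (2), parallax flow F'_t (2);
* 3D variant (14 channels): the above plus I_{t-1} (3), D_{t-1} (1)
  and F'_{t-1} (2).

Flow channels are divided by the image dimensions so every channel is
dimensionless and of comparable scale.  Training minimizes the l1 twist
loss through the declarative pose layer (implicit differentiation), with
Adam, an 80/20 train/validation split and early stopping on the
validation loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._nn import Adam, UNet3
from .exceptions import EmptyBatchError, InvalidArgumentError
from .residuals import FrameObservation, WeightMaps

__all__ = [
    "WeightNetParams",
    "TrainConfig",
    "build_input_stack",
    "predict_weights",
    "make_networks",
    "train",
    "sample_training_pairs",
]

logger = logging.getLogger(__name__)

CHANNELS_2D = 8
CHANNELS_3D = 14


def build_input_stack(
    t_frame: FrameObservation, prev_frame: Optional[FrameObservation], variant: str
) -> np.ndarray:
    """Channel-stack the residual ingredients for one weight network.

    Returns (C, H, W) with C = 8 for the 2D variant and 14 for the 3D
    variant (which additionally needs the previous frame).
    """
    if variant not in ("2d", "3d"):
        raise InvalidArgumentError("variant must be '2d' or '3d'")
    intr = t_frame.intrinsics
    scale = np.array([1.0 / intr.width, 1.0 / intr.height])

    def flow_channels(ff):
        if ff is None:
            raise InvalidArgumentError("missing flow field for input stack")
        return np.moveaxis(ff.uv * scale, 2, 0)

    chans = [
        np.moveaxis(t_frame.image, 2, 0),
        t_frame.depth.values[None],
        flow_channels(t_frame.flow),
        flow_channels(t_frame.parallax),
    ]
    if variant == "3d":
        if prev_frame is None:
            raise InvalidArgumentError("3d variant requires the previous frame")
        chans += [
            np.moveaxis(prev_frame.image, 2, 0),
            prev_frame.depth.values[None],
            flow_channels(prev_frame.parallax),
        ]
    stack = np.concatenate(chans, axis=0)
    expected = CHANNELS_2D if variant == "2d" else CHANNELS_3D
    assert stack.shape[0] == expected
    return stack


@dataclass
class WeightNetParams:
    """Both networks' parameters plus the architecture/normalization
    metadata needed to reuse them."""

    net2d: UNet3
    net3d: UNet3
    base_channels: int = 16

    def predict(self, t_frame, prev_frame) -> WeightMaps:
        return predict_weights(
            build_input_stack(t_frame, prev_frame, "2d"),
            build_input_stack(t_frame, prev_frame, "3d"),
            self,
        )

    # -- persistence ---------------------------------------------------
    def save(self, path: str):
        arrays = {}
        for prefix, net in (("w2d", self.net2d), ("w3d", self.net3d)):
            for k, v in net.params.items():
                arrays[f"{prefix}/{k}"] = v
        np.savez(
            path,
            __meta_base_channels=np.array(self.base_channels),
            __meta_in2d=np.array(self.net2d.in_channels),
            __meta_in3d=np.array(self.net3d.in_channels),
            **arrays,
        )

    @classmethod
    def load(cls, path: str) -> "WeightNetParams":
        data = np.load(path)
        base = int(data["__meta_base_channels"])
        net2d = UNet3(int(data["__meta_in2d"]), base)
        net3d = UNet3(int(data["__meta_in3d"]), base)
        for prefix, net in (("w2d", net2d), ("w3d", net3d)):
            for k in net.params:
                net.params[k] = data[f"{prefix}/{k}"].copy()
        return cls(net2d, net3d, base)


def make_networks(seed: int = 0, base_channels: int = 16) -> WeightNetParams:
    """Freshly initialized 2D and 3D weight networks."""
    rng = np.random.default_rng(np.random.SeedSequence([seed % (2**31), 11]))
    net2d = UNet3(CHANNELS_2D, base_channels, rng)
    net3d = UNet3(CHANNELS_3D, base_channels, rng)
    return WeightNetParams(net2d, net3d, base_channels)


def predict_weights(stack2d, stack3d, params: WeightNetParams) -> WeightMaps:
    """Run both networks; outputs are in [0, 1] by the final sigmoid."""
    return WeightMaps(params.net2d.forward(stack2d), params.net3d.forward(stack3d))


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the (desk-scale) training loop.

    The defaults are sized for CPU training at small resolution; the
    ``fullscale`` preset mirrors the regime used for real surgical video
    (half-resolution images, Adam 1e-5, 200 epochs) and is not meant
    for tests.
    """

    epochs: int = 15
    batch_size: int = 8
    learning_rate: float = 1e-3
    val_fraction: float = 0.2
    patience: int = 4
    seed: int = 0
    solver_config: object = None

    @classmethod
    def fullscale(cls) -> "TrainConfig":
        return cls(epochs=200, batch_size=8, learning_rate=1e-5, patience=10)


def _validation_loss(pairs, params: WeightNetParams, solver_config) -> float:
    from .ddn_layer import training_loss
    from .pose_solver import PoseModel

    losses = []
    for t_frame, prev_frame, p_gt in pairs:
        weights = params.predict(t_frame, prev_frame)
        fit = PoseModel(t_frame, prev_frame, weights, solver_config).fit()
        losses.append(training_loss(fit.params, p_gt))
    return float(np.mean(losses))


def train(dataset: Sequence, cfg: TrainConfig = TrainConfig(), params: WeightNetParams | None = None):
    """Train both weight networks end-to-end through the pose argmin.

    ``dataset`` is a sequence of ``(t_frame, prev_frame, p_gt)`` pairs
    (ground-truth twists in the same normalized units the solver uses).
    Returns ``(params, history)``; ``history`` holds one record per
    epoch plus the epoch-0 baseline, and training stops early when the
    validation loss has not improved for ``cfg.patience`` epochs.  Fully
    deterministic under a fixed ``cfg.seed``.
    """
    from .ddn_layer import end_to_end_gradient_step
    from .pose_solver import SolverConfig

    solver_cfg = cfg.solver_config or SolverConfig(mode="weighted", max_iterations=60)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed % (2**31), 23]))
    params = params or make_networks(cfg.seed)

    idx = rng.permutation(len(dataset))
    n_val = max(1, int(round(cfg.val_fraction * len(dataset))))
    val = [dataset[i] for i in idx[:n_val]]
    tr = [dataset[i] for i in idx[n_val:]]
    if not tr:
        raise InvalidArgumentError("dataset too small to split")

    opt2d = Adam(lr=cfg.learning_rate)
    opt3d = Adam(lr=cfg.learning_rate)

    best_val = _validation_loss(val, params, solver_cfg)
    best_params = (params.net2d.copy_params(), params.net3d.copy_params())
    history = [{"epoch": 0, "train_loss": None, "val_loss": best_val}]
    stale = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(tr))
        epoch_losses = []
        skipped = 0
        for start in range(0, len(tr), cfg.batch_size):
            batch = [tr[i] for i in order[start : start + cfg.batch_size]]
            try:
                loss, g2, g3, used = end_to_end_gradient_step(
                    batch, params.net2d, params.net3d, solver_cfg, logger
                )
            except EmptyBatchError:
                skipped += 1
                continue
            epoch_losses.append(loss)
            opt2d.step(params.net2d.params, g2)
            opt3d.step(params.net3d.params, g3)
        if not epoch_losses:
            raise EmptyBatchError(
                f"epoch {epoch}: no batch produced a converged solve"
            )
        val_loss = _validation_loss(val, params, solver_cfg)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
            }
        )
        logger.info(
            "epoch %d: train %.4e val %.4e (skipped batches: %d)",
            epoch,
            history[-1]["train_loss"],
            val_loss,
            skipped,
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = (params.net2d.copy_params(), params.net3d.copy_params())
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stopping at epoch %d", epoch)
                break
    params.net2d.set_params(best_params[0])
    params.net3d.set_params(best_params[1])
    return params, history


# ----------------------------------------------------------------------
def sample_training_pairs(sequence, labels: Sequence[str], n: int, rng) -> list:
    """Sample ``n`` frame pairs ``(t, t + k)`` with interval k in 1..5,
    balancing 'moving' and 'static' pairs to within one.

    ``labels`` are per-frame motion labels (see
    :func:`endovo.synthetic_scene.classify_frames`); a pair takes the
    label of its later frame, whose relative motion it spans.  Returns
    ``(i_prev, i_cur)`` index tuples.
    """
    n_frames = len(sequence)
    if n_frames < 6:
        raise InvalidArgumentError("need at least 6 frames to sample 1-5 intervals")
    if len(labels) != n_frames:
        raise InvalidArgumentError("one label per frame required")
    candidates = {"moving": [], "static": []}
    for t in range(n_frames - 1):
        for k in range(1, 6):
            if t + k < n_frames:
                candidates[labels[t + k]].append((t, t + k))
    pools = {key: val for key, val in candidates.items() if val}
    if not pools:
        raise InvalidArgumentError("no candidate pairs")
    out = []
    counts = {key: 0 for key in pools}
    for i in range(n):
        # pick the currently under-represented non-empty pool
        key = min(pools, key=lambda k: counts[k])
        pool = pools[key]
        out.append(pool[rng.integers(len(pool))])
        counts[key] += 1
    return out
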