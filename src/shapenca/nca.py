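"""Neural cellular automata core: update rules, stochastic firing, iteration.

A cell grid holds one channel vector per pixel: the immutable input image
channels, one output logit channel and a block of hidden channels.  An
update rule is a small convolutional network applied identically at every
cell; each step adds its (signed) update field to the grid at a random
subset of cells (Bernoulli "firing"), and segmentation emerges from
iterating the rule.

Two rule shapes are provided:

* the convolutional base block — k x k perception convolution, 1 x 1
  dense mixing, batch normalization, ReLU, then a linear 1 x 1 output
  projection back to the grid's channel count so updates can be signed;
* the fused two-kernel block used at the coarsest scale — a wide k = 7
  perception convolution followed (after batch norm and ReLU) by a k = 3
  convolution back to the channel count, trading two smaller receptive
  fields for one large one.

Output projections are initialized near zero so an untrained rule is
close to the identity map on the grid — the standard NCA stabilization —
while still letting gradients reach every layer from the first step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["CellGrid", "NCARule", "conv_base_block", "nca_step", "nca_run", "nca_block"]


@dataclass
class CellGrid:
    """NCA state of shape (C, H, W); channels [0, c_in) hold the input image."""

    state: np.ndarray
    c_in: int = 1

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=np.float32)
        if self.state.ndim != 3:
            raise ValueError("state must have shape (C, H, W)")
        if self.state.shape[0] < self.c_in + 1:
            raise ValueError("grid needs at least c_in + 1 channels")

    @classmethod
    def from_image(cls, image: np.ndarray, n_hidden: int) -> "CellGrid":
        image = np.asarray(image, dtype=np.float32)
        c = 1 + 1 + n_hidden
        state = np.zeros((c,) + image.shape, dtype=np.float32)
        state[0] = image
        return cls(state=state, c_in=1)

    @property
    def n_channels(self) -> int:
        return self.state.shape[0]

    @property
    def logit_channel(self) -> np.ndarray:
        return self.state[self.c_in]


class NCARule:
    """Learnable parameters of one local update rule.

    ``kernel`` is the perception kernel size (odd), ``out_kernel`` the
    size of the linear output convolution (1 for the base block, 3 for
    the fused coarse block), ``dense_mix`` inserts the 1 x 1 dense layer
    of the base block between perception and normalization.
    """

    def __init__(
        self,
        n_channels: int,
        hidden_width: int = 32,
        kernel: int = 3,
        out_kernel: int = 1,
        dense_mix: bool = True,
        fire_rate: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        if kernel % 2 != 1 or out_kernel % 2 != 1:
            raise ValueError("kernel sizes must be odd")
        if not 0 < fire_rate <= 1:
            raise ValueError("fire_rate must lie in (0, 1]")
        rng = rng or np.random.default_rng(0)
        self.n_channels = int(n_channels)
        self.hidden_width = int(hidden_width)
        self.kernel = int(kernel)
        self.out_kernel = int(out_kernel)
        self.dense_mix = bool(dense_mix)
        self.fire_rate = float(fire_rate)

        def he(shape, fan_in):
            return ag.parameter(
                rng.normal(0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)
            )

        c, h, k = self.n_channels, self.hidden_width, self.kernel
        self.w_perc = he((h, c, k, k), c * k * k)
        self.b_perc = ag.parameter(np.zeros(h, dtype=np.float32))
        if self.dense_mix:
            self.w_dense = he((h, h, 1, 1), h)
            self.b_dense = ag.parameter(np.zeros(h, dtype=np.float32))
        self.gamma = ag.parameter(np.ones(h, dtype=np.float32))
        self.beta = ag.parameter(np.zeros(h, dtype=np.float32))
        # the rule is applied recurrently and the activation statistics
        # differ per step, so running stats are kept per timestep
        # (recurrent batch normalization); reset_step() rewinds the cursor
        # at the start of each forward pass
        self.running: list[dict] = []
        self._t = 0
        ko = self.out_kernel
        # small (not zero) output init: updates start near the identity but
        # hidden channels receive signal immediately, so gradients reach
        # every layer from the first optimization step
        self.w_out = ag.parameter(
            rng.normal(0, 0.02, size=(c, h, ko, ko)).astype(np.float32)
        )
        self.b_out = ag.parameter(np.zeros(c, dtype=np.float32))

    # -- parameter plumbing -------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps = [self.w_perc, self.b_perc]
        if self.dense_mix:
            ps += [self.w_dense, self.b_dense]
        ps += [self.gamma, self.beta, self.w_out, self.b_out]
        return ps

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for t, stats in enumerate(self.running):
            out[f"running_mean_{t}"] = stats["mean"]
            out[f"running_var_{t}"] = stats["var"]
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(arrays[f"p{i}"], dtype=np.float32).reshape(p.data.shape)
        self.running = []
        t = 0
        while f"running_mean_{t}" in arrays:
            self.running.append(
                {
                    "mean": np.asarray(arrays[f"running_mean_{t}"], dtype=np.float32),
                    "var": np.asarray(arrays[f"running_var_{t}"], dtype=np.float32),
                }
            )
            t += 1

    def config(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "hidden_width": self.hidden_width,
            "kernel": self.kernel,
            "out_kernel": self.out_kernel,
            "dense_mix": self.dense_mix,
            "fire_rate": self.fire_rate,
        }

    # -- forward -------------------------------------------------------
    def reset_step(self) -> None:
        """Rewind the per-timestep normalization-statistics cursor."""
        self._t = 0

    def _step_stats(self, training: bool) -> dict:
        h = self.hidden_width
        idx = self._t
        self._t += 1
        if idx >= len(self.running):
            if training or not self.running:
                self.running.append(
                    {
                        "mean": np.zeros(h, dtype=np.float32),
                        "var": np.ones(h, dtype=np.float32),
                    }
                )
            else:  # more eval steps than were ever trained: reuse the last
                idx = len(self.running) - 1
        return self.running[idx]

    def update(self, x: Tensor, training: bool = False) -> Tensor:
        """Update field for a batched state tensor (N, C, H, W)."""
        z = ag.conv2d(x, self.w_perc, self.b_perc)
        if self.dense_mix:
            z = ag.conv2d(z, self.w_dense, self.b_dense)
        z = ag.batch_norm2d(
            z, self.gamma, self.beta, self._step_stats(training), training
        )
        z = ag.relu(z)
        return ag.conv2d(z, self.w_out, self.b_out)


def _as_batched(grid: CellGrid) -> Tensor:
    if not np.all(np.isfinite(grid.state)):
        raise FloatingPointError("grid state contains non-finite values")
    return ag.constant(grid.state[None])


def conv_base_block(grid: CellGrid, rule: NCARule) -> np.ndarray:
    """Per-pixel update field of the rule applied to one grid (C, H, W).

    Purely local: each output pixel depends only on the perception-kernel
    neighbourhood of the input (plus the out-kernel for the fused block).
    Batch normalization runs in eval mode (running statistics).
    """
    rule.reset_step()
    return rule.update(_as_batched(grid), training=False).data[0]


def _channel_keep(n_channels: int, c_in: int) -> np.ndarray:
    keep = np.ones((1, n_channels, 1, 1), dtype=np.float32)
    keep[0, :c_in] = 0.0
    return keep


def nca_step(grid: CellGrid, rule: NCARule, rng: np.random.Generator) -> CellGrid:
    """One stochastic update: grid + M * update, input channels untouched.

    M is a per-cell Bernoulli(fire_rate) mask shared across channels —
    a cell fires as a unit.
    """
    update = conv_base_block(grid, rule)
    h, w = grid.state.shape[1:]
    if rule.fire_rate >= 1.0:
        fire = np.ones((1, h, w), dtype=np.float32)
    else:
        fire = (rng.random((1, h, w)) < rule.fire_rate).astype(np.float32)
    keep = _channel_keep(grid.n_channels, grid.c_in)[0]
    new_state = grid.state + update * fire * keep
    return CellGrid(state=new_state, c_in=grid.c_in)


def nca_run(
    grid: CellGrid,
    rule: NCARule,
    steps: int,
    rng: np.random.Generator,
    return_trajectory: bool = False,
):
    """``steps``-fold composition of the stochastic update."""
    if steps < 0:
        raise ValueError("steps must be >= 0")
    trajectory = [grid]
    for _ in range(steps):
        grid = nca_step(grid, rule, rng)
        if return_trajectory:
            trajectory.append(grid)
    if return_trajectory:
        return grid, trajectory
    return grid


def nca_block(grid: CellGrid, rule: NCARule) -> np.ndarray:
    """Fused two-kernel update Conv_k2(ReLU(BatchNorm(Conv_k1(state)))).

    The coarse-scale rule: a wide perception convolution (k = 7 by
    default) followed after normalization and ReLU by a k = 3 output
    convolution.  ``rule`` must have ``dense_mix=False`` so the forward
    is exactly the fused composition.
    """
    if rule.dense_mix:
        raise ValueError("fused block rule must not include the dense mixing layer")
    return conv_base_block(grid, rule)
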