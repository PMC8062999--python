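"""Antiparallel RA/FGF morphogen gradients with per-cell noise.

A rostrocaudal strip of tissue is modelled as a grid of
``n_columns x n_positions`` cells (position 0 = rostral).  Retinoic acid
is produced at the rostral boundary and FGF at the caudal boundary; with
uniform degradation both gradients are exponential in position, giving
the antiparallel backbone

    RA(x, t)  = A(t) * exp(-x / lambda)
    FGF(x, t) = A(t) * exp(-(n_positions - 1 - x) / lambda)

The shared amplitude ``A(t)`` rises during early patterning, holds, then
recedes exponentially to a low plateau, mimicking the transient character
of the differentiation signal.  Each cell perceives the backbone through
a multiplicative Ornstein-Uhlenbeck noise factor ``1 + eta`` (stationary
s.d. ``noise_sigma``, correlation time ``noise_tau``), integrated by
Euler-Maruyama alongside the cell dynamics and clipped at zero, so the
across-cell variance at fixed (x, t) is ``sigma^2 * RA(x, t)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MorphogenConfig", "MorphogenField", "make_morphogen_field"]


@dataclass(frozen=True)
class MorphogenConfig:
    n_columns: int = 10
    n_positions: int = 40
    lambda_decay: float = 8.0
    amplitude_max: float = 1.0
    amplitude_low: float = 0.1
    t_rise: float = 5.0
    t_high: float = 30.0
    t_decay: float = 10.0
    noise_sigma: float = 0.15
    noise_tau: float = 1.0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.lambda_decay <= 0 or self.n_positions < 2:
            raise ValueError("invalid grid geometry")


@dataclass
class MorphogenField:
    """Backbone gradients plus the state of the per-cell noise process."""

    cfg: MorphogenConfig
    seed: int
    _eta: np.ndarray = field(init=False)  # (2, n_columns, n_positions)
    _rng: np.random.Generator = field(init=False)

    def __post_init__(self):
        self._rng = np.random.default_rng([self.seed, 0x6D6F7270])
        self._eta = np.zeros((2, self.cfg.n_columns, self.cfg.n_positions))

    # -- deterministic backbone -------------------------------------------

    def amplitude(self, t: float) -> float:
        c = self.cfg
        if t < c.t_rise:
            return c.amplitude_low + (c.amplitude_max - c.amplitude_low) * t / c.t_rise
        if t <= c.t_high:
            return c.amplitude_max
        return c.amplitude_low + (c.amplitude_max - c.amplitude_low) * np.exp(
            -(t - c.t_high) / c.t_decay
        )

    def backbone(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """(RA, FGF) profiles over position at time t."""
        c = self.cfg
        x = np.arange(c.n_positions, dtype=float)
        A = self.amplitude(t)
        ra = A * np.exp(-x / c.lambda_decay)
        fgf = A * np.exp(-(c.n_positions - 1 - x) / c.lambda_decay)
        return ra, fgf

    def final_backbone(self) -> tuple[np.ndarray, np.ndarray]:
        """Low-plateau profiles after the signal has receded."""
        c = self.cfg
        x = np.arange(c.n_positions, dtype=float)
        ra = c.amplitude_low * np.exp(-x / c.lambda_decay)
        fgf = c.amplitude_low * np.exp(-(c.n_positions - 1 - x) / c.lambda_decay)
        return ra, fgf

    # -- noise process ----------------------------------------------------

    def reset_noise(self, seed: int | None = None) -> None:
        self._rng = np.random.default_rng([self.seed if seed is None else seed, 0x6D6F7270])
        self._eta[:] = 0.0

    def step_noise(self, dt: float) -> None:
        c = self.cfg
        if c.noise_sigma == 0.0:
            return
        xi = self._rng.standard_normal(self._eta.shape)
        self._eta += (-self._eta / c.noise_tau) * dt + c.noise_sigma * np.sqrt(
            2.0 * dt / c.noise_tau
        ) * xi

    def perceived(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (RA, FGF), shape (n_columns, n_positions), clipped at 0."""
        ra, fgf = self.backbone(t)
        mul = np.clip(1.0 + self._eta, 0.0, None)
        return ra[None, :] * mul[0], fgf[None, :] * mul[1]


def make_morphogen_field(cfg: MorphogenConfig | None = None, seed: int = 0) -> MorphogenField:
    return MorphogenField(cfg=cfg or MorphogenConfig(), seed=seed)
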