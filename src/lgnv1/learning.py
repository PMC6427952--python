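"""Hebbian/anti-Hebbian plasticity with Dale's-law clipping.

One learning iteration applies the same mini-batch-averaged outer
product ``D = <(s_L - s_b) s_C^T>`` to all four matrices — added to the
feedforward pair (Hebbian), subtracted from the feedback pair
(anti-Hebbian) — then zeroes any weight that crossed its sign constraint
and multiplicatively renormalizes columns (excitatory feedforward and
inhibitory feedback to norm l1; inhibitory feedforward and excitatory
feedback to norm l2).  Because forward and backward matrices receive
equal-and-opposite updates and share a norm, each feedback matrix is
driven toward the negative of its feedforward partner; the squared
Frobenius "anti-symmetry gaps" tracked here measure that convergence.

Training runs a white-noise pre-development phase followed by staged
training on naturalistic patches with a decreasing learning rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import ModelConfig, WeightSet, init_weights, normalize_columns, simulate_batch
from .stimuli import ImageEnsemble, encode_batch, sample_patches, white_noise_patches

__all__ = [
    "TrainingSchedule",
    "TrainingTrace",
    "learning_step",
    "antisymmetry_gap",
    "train",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingSchedule:
    """Epoch counts and learning rates for the two training phases.

    The full schedule is 10,000 white-noise pre-training epochs at rate
    0.5, then 30,000 natural-image epochs in three 10,000-epoch stages
    at rates 0.5, 0.2 and 0.1, with 100-patch mini-batches.
    ``scaled`` shrinks every stage proportionally for desk-scale runs.

    ``pretrain_variance`` is the per-pixel variance of the unit-less
    white-noise patches used during pre-development (default 1, i.e.
    standard white noise; set to None to match the training ensemble).
    """

    pretrain_epochs: int = 10_000
    pretrain_lr: float = 0.5
    pretrain_variance: float | None = 1.0
    lr_stages: tuple[tuple[int, float], ...] = (
        (10_000, 0.5),
        (10_000, 0.2),
        (10_000, 0.1),
    )
    batch_size: int = 100

    def __post_init__(self) -> None:
        if self.pretrain_epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid schedule sizes")
        if self.pretrain_lr <= 0 or any(lr <= 0 for _, lr in self.lr_stages):
            raise ValueError("learning rates must be positive")

    @property
    def train_epochs(self) -> int:
        return sum(n for n, _ in self.lr_stages)

    def scaled(self, factor: float) -> "TrainingSchedule":
        """Shrink all stage lengths by ``factor``, preserving proportions."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return TrainingSchedule(
            pretrain_epochs=max(1, round(self.pretrain_epochs * factor)),
            pretrain_lr=self.pretrain_lr,
            pretrain_variance=self.pretrain_variance,
            lr_stages=tuple(
                (max(1, round(n * factor)), lr) for n, lr in self.lr_stages
            ),
            batch_size=self.batch_size,
        )

    @classmethod
    def desk_scale(cls) -> "TrainingSchedule":
        """Default desk-scale run: 1,000 pre-training + 3,000 training epochs."""
        return cls().scaled(0.1)


@dataclass
class TrainingTrace:
    """Per-epoch diagnostics recorded during :func:`train`."""

    gap_pos: np.ndarray  # ||A_up_pos + A_dn_neg||_F^2
    gap_neg: np.ndarray  # ||A_up_neg + A_dn_pos||_F^2
    mean_rate: np.ndarray  # mean cortical rate over the mini-batch
    frac_active: np.ndarray  # fraction of cortical cells with nonzero rate
    pretrain_epochs: int = 0
    seed: int | None = None

    @property
    def n_epochs(self) -> int:
        return len(self.gap_pos)

    def to_dataframe(self):
        import pandas as pd

        phase = np.where(
            np.arange(self.n_epochs) < self.pretrain_epochs, "pretrain", "train"
        )
        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "phase": phase,
                "gap_pos": self.gap_pos,
                "gap_neg": self.gap_neg,
                "mean_rate": self.mean_rate,
                "frac_active": self.frac_active,
            }
        )


def _as_rate_arrays(batch_states, batch_stimuli=None):
    """Accept either (s_L, s_C) arrays or a list of NetworkState objects."""
    if isinstance(batch_states, (list, tuple)) and hasattr(batch_states[0], "s_L"):
        s_L = np.stack([st.s_L for st in batch_states], axis=1)
        s_C = np.stack([st.s_C for st in batch_states], axis=1)
        return s_L, s_C
    raise TypeError("expected a list of NetworkState; use learning_step_arrays for raw arrays")


def learning_step_arrays(
    weights: WeightSet,
    s_L: np.ndarray,
    s_C: np.ndarray,
    eta: float,
    config: ModelConfig,
) -> WeightSet:
    """Apply one plasticity update given converged batch rates.

    ``s_L`` is (2N, B), ``s_C`` is (M, B).  Returns a new
    :class:`~lgnv1.network.WeightSet`; the input is not modified.
    """
    s_L = np.atleast_2d(np.asarray(s_L, dtype=float))
    s_C = np.atleast_2d(np.asarray(s_C, dtype=float))
    if s_L.ndim == 2 and s_L.shape[0] == 1:
        s_L = s_L.T
    if s_C.ndim == 2 and s_C.shape[0] == 1:
        s_C = s_C.T
    B = s_L.shape[1]
    D = eta * ((s_L - config.s_b) @ s_C.T) / B
    if not np.all(np.isfinite(D)):
        raise FloatingPointError("non-finite learning update")
    # Hebbian on the way up, anti-Hebbian on the way down; clip any
    # sign-crossing weight to zero, then renormalize columns.
    return WeightSet(
        A_up_pos=normalize_columns(np.maximum(weights.A_up_pos + D, 0.0), config.l1),
        A_up_neg=normalize_columns(np.minimum(weights.A_up_neg + D, 0.0), config.l2),
        A_dn_pos=normalize_columns(np.maximum(weights.A_dn_pos - D, 0.0), config.l2),
        A_dn_neg=normalize_columns(np.minimum(weights.A_dn_neg - D, 0.0), config.l1),
    )


def learning_step(
    weights: WeightSet,
    batch_states,
    batch_stimuli,
    eta: float,
    config: ModelConfig,
) -> WeightSet:
    """Plasticity update from a list of converged per-stimulus states."""
    s_L, s_C = _as_rate_arrays(batch_states, batch_stimuli)
    return learning_step_arrays(weights, s_L, s_C, eta, config)


def antisymmetry_gap(weights: WeightSet) -> tuple[float, float]:
    """Squared Frobenius distances between paired forward/backward matrices.

    Returns ``(||A_up_pos + A_dn_neg||^2, ||A_up_neg + A_dn_pos||^2)``;
    both decay toward zero as learning makes the feedback pathway the
    exact sign-reversed mirror of the feedforward one.
    """
    gap_pos = float(np.sum((weights.A_up_pos + weights.A_dn_neg) ** 2))
    gap_neg = float(np.sum((weights.A_up_neg + weights.A_dn_pos) ** 2))
    return gap_pos, gap_neg


def train(
    config: ModelConfig,
    schedule: TrainingSchedule,
    ensemble: ImageEnsemble,
    seed: int,
    weights: WeightSet | None = None,
    progress: bool = False,
) -> tuple[WeightSet, TrainingTrace]:
    """Run white-noise pre-training followed by staged patch training.

    Every epoch draws a fresh mini-batch, encodes it into ON/OFF
    channels, integrates the network to steady state and applies one
    plasticity update.  Pre-training uses Gaussian white-noise patches
    whose variance matches the training ensemble; the staged phase uses
    patches sampled from ``ensemble`` (already whitened and variance
    scaled).  Fully deterministic given ``seed``.

    Returns the trained weights and a per-epoch :class:`TrainingTrace`.
    """
    ss = np.random.SeedSequence(seed)
    rng_init, rng_pre, rng_train = (np.random.default_rng(s) for s in ss.spawn(3))
    if weights is None:
        weights = init_weights(config, rng_init)
    else:
        weights = weights.copy()

    P = config.patch_size
    noise_var = schedule.pretrain_variance
    if noise_var is None:
        noise_var = (
            ensemble.variance_target
            if ensemble.variance_target is not None
            else ensemble.variance()
        )
    total = schedule.pretrain_epochs + schedule.train_epochs
    gap_pos = np.empty(total)
    gap_neg = np.empty(total)
    mean_rate = np.empty(total)
    frac_active = np.empty(total)

    phases: list[tuple[int, float, str]] = [
        (schedule.pretrain_epochs, schedule.pretrain_lr, "pretrain")
    ]
    phases += [(n, lr, "train") for n, lr in schedule.lr_stages]

    iterator = range(total)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, desc="train")
        except ImportError:  # pragma: no cover
            pass
    it = iter(iterator)

    epoch = 0
    for n_epochs, eta, phase in phases:
        for _ in range(n_epochs):
            next(it, None)
            if phase == "pretrain":
                patches = white_noise_patches(
                    schedule.batch_size, P, noise_var, rng_pre
                )
            else:
                patches = sample_patches(
                    ensemble, schedule.batch_size, P, rng_train
                )
            X = encode_batch(patches)
            try:
                _, s_L, _, s_C = simulate_batch(weights, config, X)
                weights = learning_step_arrays(weights, s_L, s_C, eta, config)
            except (FloatingPointError, RuntimeError) as exc:
                raise RuntimeError(
                    f"training diverged at epoch {epoch} ({phase})"
                ) from exc
            gap_pos[epoch], gap_neg[epoch] = antisymmetry_gap(weights)
            mean_rate[epoch] = s_C.mean()
            frac_active[epoch] = (s_C > 0).any(axis=1).mean()
            epoch += 1

    trace = TrainingTrace(
        gap_pos=gap_pos,
        gap_neg=gap_neg,
        mean_rate=mean_rate,
        frac_active=frac_active,
        pretrain_epochs=schedule.pretrain_epochs,
        seed=seed,
    )
    return weights, trace
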