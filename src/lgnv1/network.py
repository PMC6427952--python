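"""Two-layer LGN-V1 rate network: weight structure and dynamics.

The first layer models ON and OFF LGN relay cells (2N units), the second
layer cortical simple cells (M units).  Connectivity obeys Dale's law by
carrying separate non-negative excitatory and non-positive inhibitory
matrices in each direction:

* ``A_up_pos``/``A_up_neg`` — feedforward LGN -> cortex (2N x M);
* ``A_dn_pos``/``A_dn_neg`` — feedback cortex -> LGN (stored LGN-major,
  also 2N x M, column j = feedback from cortical cell j).

Rows 0..N-1 of every matrix are the ON block, rows N..2N-1 the OFF block.

The coupled dynamics (leaky integrator per layer, rectified rates, a
sparsity threshold lambda on the cortical rectifier, and a constant
background drive ``s_b`` to LGN) implement a Dale-constrained variant of
the locally competitive algorithm for sparse coding.  With the leak
offset ``v_leak = -(A_up_pos + A_up_neg)^T s_b`` the resting state
``v_L = s_b, v_C = 0`` is a fixed point in the absence of stimulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelConfig",
    "WeightSet",
    "NetworkState",
    "IntegrationDivergenceError",
    "normalize_columns",
    "init_weights",
    "leak_voltage",
    "simulate_batch",
    "simulate_response",
    "lca_oracle_response",
]

logger = logging.getLogger(__name__)


class IntegrationDivergenceError(RuntimeError):
    """Raised when the Euler integration produces non-finite state."""


@dataclass(frozen=True)
class ModelConfig:
    """Model sizes, time constants and thresholds.

    Attributes
    ----------
    n_lgn : int
        LGN cells per polarity (N); the input patch has N pixels.
    n_cortex : int
        Number of cortical simple cells (M).
    tau_lgn, tau_cortex : float
        Membrane time constants, ms.
    s_b : float
        Spontaneous (background) LGN rate; all rates and intensities
        share one dimensionless activation scale.
    lam : float
        Sparsity threshold of the cortical rectifier.
    dt : float
        Euler integration step, ms.
    n_steps : int
        Euler steps per stimulus presentation.
    l1, l2 : float
        Target column norms: l1 for feedforward excitation and feedback
        inhibition, l2 for feedforward inhibition and feedback
        excitation.
    """

    n_lgn: int = 256
    n_cortex: int = 256
    tau_lgn: float = 12.0
    tau_cortex: float = 12.0
    s_b: float = 2.0
    lam: float = 0.6
    dt: float = 3.0
    n_steps: int = 30
    l1: float = 1.0
    l2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_lgn", "n_cortex", "tau_lgn", "tau_cortex", "lam", "dt", "l1", "l2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.s_b < 0:
            raise ValueError("s_b must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt >= min(self.tau_lgn, self.tau_cortex):
            raise ValueError("dt must be smaller than the membrane time constants")

    @property
    def patch_size(self) -> int:
        p = int(round(np.sqrt(self.n_lgn)))
        if p * p != self.n_lgn:
            raise ValueError("n_lgn is not a perfect square; no square patch")
        return p

    def with_steps(self, n_steps: int) -> "ModelConfig":
        return replace(self, n_steps=n_steps)


@dataclass
class WeightSet:
    """The four sign-constrained connection matrices.

    All matrices are (2N, M).  ``A_up_pos``/``A_dn_pos`` hold
    non-negative excitatory weights, ``A_up_neg``/``A_dn_neg``
    non-positive inhibitory weights.
    """

    A_up_pos: np.ndarray
    A_up_neg: np.ndarray
    A_dn_pos: np.ndarray
    A_dn_neg: np.ndarray

    _FIELDS = ("A_up_pos", "A_up_neg", "A_dn_pos", "A_dn_neg")

    def __post_init__(self) -> None:
        shapes = {getattr(self, f).shape for f in self._FIELDS}
        if len(shapes) != 1:
            raise ValueError(f"weight matrices have inconsistent shapes: {shapes}")

    @property
    def n_lgn(self) -> int:
        return self.A_up_pos.shape[0] // 2

    @property
    def n_cortex(self) -> int:
        return self.A_up_pos.shape[1]

    @property
    def feedforward(self) -> np.ndarray:
        """Composite feedforward matrix A = A_up_pos + A_up_neg."""
        return self.A_up_pos + self.A_up_neg

    @property
    def feedback(self) -> np.ndarray:
        """Composite feedback matrix A_dn = A_dn_pos + A_dn_neg."""
        return self.A_dn_pos + self.A_dn_neg

    def on_block(self, name: str) -> np.ndarray:
        """ON rows (first N) of the named matrix."""
        return getattr(self, name)[: self.n_lgn]

    def off_block(self, name: str) -> np.ndarray:
        """OFF rows (last N) of the named matrix."""
        return getattr(self, name)[self.n_lgn :]

    def copy(self) -> "WeightSet":
        return WeightSet(*(getattr(self, f).copy() for f in self._FIELDS))

    def validate_dale(self, atol: float = 0.0) -> None:
        """Raise if any matrix violates its sign constraint."""
        if self.A_up_pos.min(initial=0.0) < -atol or self.A_dn_pos.min(initial=0.0) < -atol:
            raise ValueError("excitatory matrix contains negative weights")
        if self.A_up_neg.max(initial=0.0) > atol or self.A_dn_neg.max(initial=0.0) > atol:
            raise ValueError("inhibitory matrix contains positive weights")


@dataclass
class NetworkState:
    """Membrane potentials and rates of both layers at one time point."""

    v_L: np.ndarray
    s_L: np.ndarray
    v_C: np.ndarray
    s_C: np.ndarray
    v_leak: np.ndarray


def normalize_columns(W: np.ndarray, target: float) -> np.ndarray:
    """Scale each column to Euclidean norm ``target``; zero columns untouched."""
    norms = np.linalg.norm(W, axis=0)
    zero = norms == 0
    if zero.any():
        logger.debug("normalize_columns: %d zero columns left unscaled", zero.sum())
    scale = np.where(zero, 1.0, target / np.where(zero, 1.0, norms))
    return W * scale


def init_weights(config: ModelConfig, seed: int | np.random.Generator) -> WeightSet:
    """Random initial weights: Exponential(mean 0.5) magnitudes, then normalized.

    Excitatory matrices are drawn non-negative, inhibitory matrices as
    the negated draws; columns are normalized to their target norms
    before any learning.
    """
    rng = np.random.default_rng(seed)
    shape = (2 * config.n_lgn, config.n_cortex)
    draw = lambda: rng.exponential(0.5, size=shape)
    ws = WeightSet(
        A_up_pos=normalize_columns(draw(), config.l1),
        A_up_neg=normalize_columns(-draw(), config.l2),
        A_dn_pos=normalize_columns(draw(), config.l2),
        A_dn_neg=normalize_columns(-draw(), config.l1),
    )
    return ws


def leak_voltage(weights: WeightSet, config: ModelConfig) -> np.ndarray:
    """Cortical leak offset cancelling the background feedforward drive.

    ``v_leak = -(A_up_pos + A_up_neg)^T (s_b * 1)``; recomputed whenever
    the weights change so the resting state stays a fixed point.
    """
    ones = np.full(2 * weights.n_lgn, config.s_b)
    return -(weights.feedforward.T @ ones)


def _check_finite(arr: np.ndarray, step: int, layer: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise IntegrationDivergenceError(
            f"non-finite {layer} state at Euler step {step}"
        )


def simulate_batch(
    weights: WeightSet,
    config: ModelConfig,
    X: np.ndarray,
    v_L0: np.ndarray | None = None,
    v_C0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the coupled dynamics for a batch of stimuli.

    Parameters
    ----------
    X : ndarray (2N,) or (2N, B)
        ON/OFF input vectors, one column per stimulus.
    v_L0, v_C0 : ndarray, optional
        Initial membrane potentials; default is the resting steady state
        (``v_L = s_b``, ``v_C = 0``).

    Returns
    -------
    (v_L, s_L, v_C, s_C) : final-state arrays with the batch shape of X.

    Within each first-order Euler step the layers are updated
    sequentially: the LGN potentials advance first (reading the previous
    cortical rates), then the cortical potentials advance reading the
    freshly updated LGN rates.  Rates are re-thresholded after each
    layer update.  The sequential ordering lets the fast explaining-away
    loop settle within the short per-stimulus integration window; a
    fully synchronous update leaves the competition unresolved at 30
    steps, which destabilizes learning.
    """
    X = np.asarray(X, dtype=float)
    squeeze = X.ndim == 1
    if squeeze:
        X = X[:, None]
    two_n, B = X.shape
    if two_n != 2 * config.n_lgn:
        raise ValueError(f"stimulus length {two_n} != 2N = {2 * config.n_lgn}")

    A = weights.feedforward
    A_dn = weights.feedback
    v_leak = leak_voltage(weights, config)[:, None]

    v_L = np.full((two_n, B), config.s_b) if v_L0 is None else np.broadcast_to(
        np.asarray(v_L0, dtype=float).reshape(two_n, -1), (two_n, B)
    ).copy()
    v_C = np.zeros((config.n_cortex, B)) if v_C0 is None else np.broadcast_to(
        np.asarray(v_C0, dtype=float).reshape(config.n_cortex, -1),
        (config.n_cortex, B),
    ).copy()

    a_L = config.dt / config.tau_lgn
    a_C = config.dt / config.tau_cortex
    s_L = np.maximum(v_L, 0.0)
    s_C = np.maximum(v_C - config.lam, 0.0)
    prev = None
    for step in range(config.n_steps):
        v_L = v_L + a_L * (-v_L + X + A_dn @ s_C + config.s_b)
        _check_finite(v_L, step, "LGN")
        s_L = np.maximum(v_L, 0.0)
        v_C = v_C + a_C * (-v_C + v_leak + A.T @ s_L + s_C)
        _check_finite(v_C, step, "cortical")
        s_C = np.maximum(v_C - config.lam, 0.0)
        if step == config.n_steps - 2:
            prev = (v_L.copy(), v_C.copy())
    if prev is not None and logger.isEnabledFor(logging.DEBUG):
        num = np.linalg.norm(v_L - prev[0]) + np.linalg.norm(v_C - prev[1])
        den = np.linalg.norm(v_L) + np.linalg.norm(v_C)
        logger.debug(
            "simulate_batch: relative state change over last step = %.3e",
            num / den if den > 0 else 0.0,
        )
    if squeeze:
        return v_L[:, 0], s_L[:, 0], v_C[:, 0], s_C[:, 0]
    return v_L, s_L, v_C, s_C


def simulate_response(
    weights: WeightSet,
    config: ModelConfig,
    stimulus,
    record_trajectory: bool = False,
    v_L0: np.ndarray | None = None,
    v_C0: np.ndarray | None = None,
):
    """Integrate one stimulus to its (assumed) steady state.

    ``stimulus`` may be an :class:`~lgnv1.stimuli.OnOffStimulus` or a raw
    length-2N vector.  Returns the final :class:`NetworkState`, plus the
    per-step list of states when ``record_trajectory`` is set.
    """
    x = getattr(stimulus, "x", stimulus)
    x = np.asarray(x, dtype=float)
    v_leak = leak_voltage(weights, config)
    if not record_trajectory:
        v_L, s_L, v_C, s_C = simulate_batch(weights, config, x, v_L0, v_C0)
        return NetworkState(v_L, s_L, v_C, s_C, v_leak)
    # step-by-step replay using the batch integrator one step at a time
    trajectory: list[NetworkState] = []
    cfg1 = config.with_steps(1)
    v_L = np.full(2 * config.n_lgn, config.s_b) if v_L0 is None else np.asarray(v_L0, float)
    v_C = np.zeros(config.n_cortex) if v_C0 is None else np.asarray(v_C0, float)
    for _ in range(config.n_steps):
        v_L, s_L, v_C, s_C = simulate_batch(weights, cfg1, x, v_L, v_C)
        trajectory.append(NetworkState(v_L.copy(), s_L.copy(), v_C.copy(), s_C.copy(), v_leak))
    return trajectory[-1], trajectory


def lca_oracle_response(
    A: np.ndarray, config: ModelConfig, stimulus
) -> np.ndarray:
    """Steady cortical rates of the reduced two-equation sparse-coding system.

    For weights that are exactly anti-symmetric (feedback = -feedforward)
    the full network collapses to the classic locally-competitive form

        tau_L dv_L/dt = -v_L + x - A s_C + s_b,    s_L = max(v_L, 0)
        tau_C dv_C/dt = -v_C + A^T (s_L - s_b) + s_C,  s_C = max(v_C - lam, 0)

    integrated here with the same sequential (LGN-first) Euler scheme.
    Intended purely as an independent cross-check of
    :func:`simulate_batch`.
    """
    A = np.asarray(A, dtype=float)
    x = getattr(stimulus, "x", stimulus)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != A.shape[0]:
        raise ValueError("stimulus length does not match A")
    v_L = np.full(A.shape[0], config.s_b)
    v_C = np.zeros(A.shape[1])
    s_L = np.maximum(v_L, 0.0)
    s_C = np.maximum(v_C - config.lam, 0.0)
    a_L = config.dt / config.tau_lgn
    a_C = config.dt / config.tau_cortex
    for step in range(config.n_steps):
        v_L = v_L + a_L * (-v_L + x - A @ s_C + config.s_b)
        _check_finite(v_L, step, "LGN")
        s_L = np.maximum(v_L, 0.0)
        v_C = v_C + a_C * (-v_C + A.T @ (s_L - config.s_b) + s_C)
        _check_finite(v_C, step, "cortical")
        s_C = np.maximum(v_C - config.lam, 0.0)
    return s_C
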