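"""Receptive-field recovery and parametric characterization.

Provides the per-cell *synaptic field* (net feedforward ON minus OFF
drive), spike-triggered-average (STA) receptive-field estimates probed
with filtered white noise, 2-D Gabor fits with the standard quality
controls, and the derived dimensionless shape numbers
``n_x = sigma_x * f_s`` and ``n_y = sigma_y * f_s`` with their
associated spatial-frequency and orientation bandwidths.

The Gabor model used throughout is

    G(x, y) = beta * cos(2*pi*f_s*x' + phi)
              * exp(-(x'/(2*sigma_x))**2 - (y'/(2*sigma_y))**2)

with (x', y') the coordinates rotated by theta about the center
(x0, y0); x is the column index and y the row index of the patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .network import ModelConfig, WeightSet, simulate_batch
from .stimuli import FilterSpec, apply_zero_phase_filter, build_filter, encode_batch

__all__ = [
    "BANDWIDTH_C",
    "SynapticField",
    "ReceptiveFields",
    "GaborFit",
    "BandwidthResult",
    "synaptic_field",
    "synaptic_fields",
    "sta_receptive_field",
    "gabor",
    "fit_gabor",
    "bandwidths",
    "fit_population",
    "population_table",
]

#: Half-magnitude bandwidth constant sqrt(ln 2) / (2 pi) ~ 0.1325.
#: With the envelope convention exp(-(x'/(2*sigma))**2) the spatial
#: frequency bandwidth is undefined exactly when n_x <= this value
#: (printed threshold ~0.13).
BANDWIDTH_C = float(np.sqrt(np.log(2.0)) / (2.0 * np.pi))


@dataclass
class SynapticField:
    """Net feedforward field of one cortical cell, reshaped to the patch."""

    cell: int
    field: np.ndarray  # (P, P)


@dataclass
class ReceptiveFields:
    """STA receptive-field estimates for the whole population."""

    fields: np.ndarray  # (M, P, P)
    defined: np.ndarray  # (M,) bool; False where the cell never responded
    probe_filter: str
    K: int


@dataclass
class GaborFit:
    """Fitted 2-D Gabor parameters with fit error and quality-control flag."""

    beta: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    f_s: float  # cycles/pixel
    theta: float  # radians in [0, pi)
    phi: float  # radians in [0, 2 pi)
    fit_error: float  # (||residual|| / ||input||)**2
    qc_pass: bool
    success: bool = True

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [self.beta, self.x0, self.y0, self.sigma_x, self.sigma_y,
             self.f_s, self.theta, self.phi]
        )


@dataclass
class BandwidthResult:
    """Shape numbers and half-magnitude bandwidths of a Gabor fit."""

    n_x: float
    n_y: float
    delta_f: float  # octaves; nan when undefined (n_x <= BANDWIDTH_C)
    delta_theta: float  # degrees


def synaptic_field(weights: WeightSet, cell: int) -> SynapticField:
    """Net ON-minus-OFF feedforward drive pattern of one cell.

    ``S_f = (A_ON_up_pos + A_ON_up_neg) - (A_OFF_up_pos + A_OFF_up_neg)``
    for the cell's column, reshaped to the square patch.
    """
    P = int(round(np.sqrt(weights.n_lgn)))
    ff = weights.feedforward[:, cell]
    sf = ff[: weights.n_lgn] - ff[weights.n_lgn :]
    return SynapticField(cell=cell, field=sf.reshape(P, P))


def synaptic_fields(weights: WeightSet) -> np.ndarray:
    """Synaptic fields of all cells, stacked as (M, P, P)."""
    P = int(round(np.sqrt(weights.n_lgn)))
    ff = weights.feedforward
    sf = ff[: weights.n_lgn] - ff[weights.n_lgn :]  # (N, M)
    return sf.T.reshape(weights.n_cortex, P, P)


def _as_filter_spec(probe_filter: FilterSpec | str) -> FilterSpec:
    if isinstance(probe_filter, FilterSpec):
        return probe_filter
    return FilterSpec(kind=probe_filter, cutoff=200.0, image_size=512)


def sta_receptive_field(
    weights: WeightSet,
    config: ModelConfig,
    probe_filter: FilterSpec | str = "whitening",
    K: int = 70_000,
    seed: int | np.random.Generator = 0,
    variance_target: float = 0.2,
    chunk_size: int = 2_000,
) -> ReceptiveFields:
    """Estimate receptive fields by spike-triggered averaging.

    K Gaussian white-noise patches are filtered at patch scale by the
    chosen probe filter (whitening or low-pass; the cutoff in
    cycles/image is rescaled to the patch so cycles-per-pixel match the
    training ensemble), scaled so the filtered probe variance equals
    ``variance_target``, encoded into ON/OFF channels, and presented to
    the network.  Each cell's RF is the response-weighted mean of the
    signed (pre-encoding) probe patches,

        F = (s_1 n_1 + ... + s_K n_K) / (s_1 + ... + s_K).

    Cells that never responded are flagged undefined rather than raising.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    spec = _as_filter_spec(probe_filter)
    P = config.patch_size
    H = build_filter(spec, P)
    # For unit-variance white noise, the filtered per-pixel variance is
    # mean(H^2) (Parseval), so one analytic input scale hits the target.
    gain2 = float(np.mean(H**2))
    sigma_in = np.sqrt(variance_target / gain2)

    rng = np.random.default_rng(seed)
    M = config.n_cortex
    num = np.zeros((M, P * P))
    den = np.zeros(M)
    remaining = K
    while remaining > 0:
        B = min(chunk_size, remaining)
        remaining -= B
        noise = rng.standard_normal((B, P, P)) * sigma_in
        probes = apply_zero_phase_filter(noise, H)
        X = encode_batch(probes)
        _, _, _, s_C = simulate_batch(weights, config, X)
        num += s_C @ probes.reshape(B, -1)
        den += s_C.sum(axis=1)
    defined = den > 0
    fields = np.zeros((M, P, P))
    fields[defined] = (num[defined] / den[defined, None]).reshape(-1, P, P)
    return ReceptiveFields(
        fields=fields, defined=defined, probe_filter=spec.kind, K=K
    )


def gabor(
    shape: tuple[int, int],
    beta: float,
    x0: float,
    y0: float,
    sigma_x: float,
    sigma_y: float,
    f_s: float,
    theta: float,
    phi: float,
) -> np.ndarray:
    """Evaluate the 2-D Gabor model on a pixel grid of the given shape."""
    rows, cols = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dx = cols - x0
    dy = rows - y0
    xp = dx * np.cos(theta) + dy * np.sin(theta)
    yp = -dx * np.sin(theta) + dy * np.cos(theta)
    envelope = np.exp(-((xp / (2.0 * sigma_x)) ** 2) - (yp / (2.0 * sigma_y)) ** 2)
    return beta * np.cos(2.0 * np.pi * f_s * xp + phi) * envelope


def _gabor_initial_guesses(arr: np.ndarray) -> list[np.ndarray]:
    """Multi-start initial parameters from the spectrum peak and moments."""
    size_y, size_x = arr.shape
    w = arr**2
    total = w.sum()
    rows, cols = np.meshgrid(np.arange(size_y), np.arange(size_x), indexing="ij")
    if total > 0:
        x0 = float((w * cols).sum() / total)
        y0 = float((w * rows).sum() / total)
    else:
        x0, y0 = (size_x - 1) / 2.0, (size_y - 1) / 2.0

    # dominant spatial frequency and orientation from the amplitude spectrum
    F = np.abs(np.fft.fft2(arr))
    F[0, 0] = 0.0
    iy, ix = np.unravel_index(np.argmax(F), F.shape)
    fy = np.fft.fftfreq(size_y)[iy]
    fx = np.fft.fftfreq(size_x)[ix]
    f0 = float(np.hypot(fx, fy))
    theta0 = float(np.arctan2(fy, fx)) % np.pi
    f0 = max(f0, 0.02)

    # envelope SDs from second moments in the rotated frame
    dx = cols - x0
    dy = rows - y0
    xp = dx * np.cos(theta0) + dy * np.sin(theta0)
    yp = -dx * np.sin(theta0) + dy * np.cos(theta0)
    if total > 0:
        sx = float(np.sqrt((w * xp**2).sum() / total))
        sy = float(np.sqrt((w * yp**2).sum() / total))
    else:
        sx = sy = 2.0
    sx = np.clip(sx, 0.6, size_x)
    sy = np.clip(sy, 0.6, size_y)
    beta0 = float(np.abs(arr).max())

    starts = []
    for phi0 in (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi):
        starts.append(np.array([beta0, x0, y0, sx, sy, f0, theta0, phi0]))
    # a low-frequency (blob-like) alternative
    starts.append(np.array([beta0, x0, y0, sx, sy, 0.02, theta0, 0.0]))
    return starts


def _gabor_parts(p: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    beta, x0, y0, sx, sy, f_s, theta, phi = p
    dx = cols - x0
    dy = rows - y0
    ct, st = np.cos(theta), np.sin(theta)
    xp = dx * ct + dy * st
    yp = -dx * st + dy * ct
    env = np.exp(-((xp / (2.0 * sx)) ** 2) - (yp / (2.0 * sy)) ** 2)
    arg = 2.0 * np.pi * f_s * xp + phi
    return xp, yp, env, np.cos(arg), np.sin(arg), ct, st


def _gabor_jacobian(p: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the Gabor model w.r.t. its eight parameters."""
    beta, x0, y0, sx, sy, f_s, theta, phi = p
    xp, yp, env, c, s, ct, st = _gabor_parts(p, rows, cols)
    ce = c * env
    dG_dxp = -2.0 * np.pi * f_s * beta * s * env - beta * ce * xp / (2.0 * sx**2)
    dG_dyp = -beta * ce * yp / (2.0 * sy**2)
    J = np.empty(rows.shape + (8,))
    J[..., 0] = ce
    J[..., 1] = dG_dxp * (-ct) + dG_dyp * st
    J[..., 2] = dG_dxp * (-st) + dG_dyp * (-ct)
    J[..., 3] = beta * ce * xp**2 / (2.0 * sx**3)
    J[..., 4] = beta * ce * yp**2 / (2.0 * sy**3)
    J[..., 5] = -beta * s * env * 2.0 * np.pi * xp
    J[..., 6] = dG_dxp * yp - dG_dyp * xp
    J[..., 7] = -beta * s * env
    return J.reshape(-1, 8)


def _canonicalize(p: np.ndarray) -> np.ndarray:
    """Map parameters to beta != sign-ambiguous, theta in [0, pi), phi in [0, 2 pi)."""
    beta, x0, y0, sx, sy, f_s, theta, phi = p
    if beta < 0:
        beta = -beta
        phi += np.pi
    k = np.floor(theta / np.pi)
    theta = theta - k * np.pi
    if k % 2 != 0:
        # theta -> theta + pi flips x', equivalent to phi -> -phi
        phi = -phi
    phi = phi % (2.0 * np.pi)
    return np.array([beta, x0, y0, sx, sy, f_s, theta, phi])


def fit_gabor(arr: np.ndarray, edge_sigma: str = "max") -> GaborFit:
    """Fit the 2-D Gabor model to a patch by multi-start least squares.

    The fit error is the squared ratio of the residual norm to the input
    norm.  Quality control passes when the error is at most 40% and the
    fitted center lies inside the patch at least one envelope SD
    (``max(sigma_x, sigma_y)``) away from every edge.
    """
    arr = np.asarray(arr, dtype=float)
    norm = np.linalg.norm(arr)
    if norm == 0:
        raise ValueError("cannot fit a Gabor to an all-zero input")
    size_y, size_x = arr.shape
    rows, cols = np.meshgrid(np.arange(size_y), np.arange(size_x), indexing="ij")

    def residual(p):
        xp, yp, env, c, _, _, _ = _gabor_parts(p, rows, cols)
        return (p[0] * c * env - arr).ravel()

    def jac(p):
        return _gabor_jacobian(p, rows, cols)

    amp = float(np.abs(arr).max())
    lo = np.array([-8 * amp, -4.0, -4.0, 0.2, 0.2, 0.0, -np.pi, -2 * np.pi])
    hi = np.array(
        [8 * amp, size_x + 3.0, size_y + 3.0, 2.0 * size_x, 2.0 * size_y,
         0.6, 2 * np.pi, 4 * np.pi]
    )

    # rank the candidate starts by initial cost, refine the most promising
    starts = [np.clip(p0, lo, hi) for p0 in _gabor_initial_guesses(arr)]
    starts.sort(key=lambda p0: float(np.sum(residual(p0) ** 2)))
    best = None
    best_cost = np.inf
    any_success = False
    for p0 in starts[:3]:
        try:
            sol = least_squares(
                residual, p0, jac=jac, bounds=(lo, hi), method="trf",
                max_nfev=300,
            )
        except Exception:
            continue
        if sol.cost < best_cost:
            best_cost = sol.cost
            best = sol.x
            any_success = True
    if not any_success:
        return GaborFit(
            beta=np.nan, x0=np.nan, y0=np.nan, sigma_x=np.nan, sigma_y=np.nan,
            f_s=np.nan, theta=np.nan, phi=np.nan, fit_error=np.inf,
            qc_pass=False, success=False,
        )
    p = _canonicalize(best)
    resid = residual(p)
    fit_error = float(np.linalg.norm(resid) ** 2 / norm**2)
    sigma_edge = max(p[3], p[4]) if edge_sigma == "max" else min(p[3], p[4])
    x0, y0 = p[1], p[2]
    center_ok = (
        sigma_edge <= x0 <= (size_x - 1) - sigma_edge
        and sigma_edge <= y0 <= (size_y - 1) - sigma_edge
    )
    qc = fit_error <= 0.40 and center_ok
    return GaborFit(
        beta=float(p[0]), x0=float(x0), y0=float(y0),
        sigma_x=float(p[3]), sigma_y=float(p[4]), f_s=float(p[5]),
        theta=float(p[6]), phi=float(p[7]),
        fit_error=fit_error, qc_pass=bool(qc), success=True,
    )


def bandwidths(fit: GaborFit) -> BandwidthResult:
    """Shape numbers and half-magnitude bandwidths of a fitted Gabor.

    ``n_x = sigma_x * f_s`` and ``n_y = sigma_y * f_s`` count carrier
    cycles across and along the stripes.  The spatial-frequency
    bandwidth ``delta_f = log2((n_x + c) / (n_x - c))`` octaves is
    undefined (returned as nan) when ``n_x <= c``; the orientation
    bandwidth is ``delta_theta = 2 * arctan(c / n_y)`` degrees, with
    ``c = sqrt(ln 2) / (2 pi)``.  Both decrease strictly in their shape
    number.
    """
    if not (fit.sigma_x > 0 and fit.sigma_y > 0 and fit.f_s >= 0):
        raise ValueError("bandwidths need positive sigma_x, sigma_y and f_s >= 0")
    n_x = fit.sigma_x * fit.f_s
    n_y = fit.sigma_y * fit.f_s
    c = BANDWIDTH_C
    delta_f = np.log2((n_x + c) / (n_x - c)) if n_x > c else np.nan
    delta_theta = np.degrees(2.0 * np.arctan2(c, n_y)) if n_y > 0 else 180.0
    return BandwidthResult(
        n_x=float(n_x), n_y=float(n_y),
        delta_f=float(delta_f), delta_theta=float(delta_theta),
    )


def fit_population(fields: np.ndarray) -> list[GaborFit]:
    """Fit every non-zero field in a (M, P, P) stack; zero fields fail QC."""
    fits = []
    for block in fields:
        if np.linalg.norm(block) == 0:
            fits.append(
                GaborFit(
                    beta=np.nan, x0=np.nan, y0=np.nan, sigma_x=np.nan,
                    sigma_y=np.nan, f_s=np.nan, theta=np.nan, phi=np.nan,
                    fit_error=np.inf, qc_pass=False, success=False,
                )
            )
        else:
            fits.append(fit_gabor(block))
    return fits


def population_table(fits: list[GaborFit]):
    """Per-cell fit table (parameters, error, QC, shape numbers, bandwidths)."""
    import pandas as pd

    rows = []
    for cell, fit in enumerate(fits):
        row = {
            "cell": cell, "beta": fit.beta, "x0": fit.x0, "y0": fit.y0,
            "sigma_x": fit.sigma_x, "sigma_y": fit.sigma_y, "f_s": fit.f_s,
            "theta": fit.theta, "phi": fit.phi,
            "fit_error": fit.fit_error, "qc_pass": fit.qc_pass,
        }
        if fit.success and fit.sigma_x > 0:
            bw = bandwidths(fit)
            row.update(
                n_x=bw.n_x, n_y=bw.n_y,
                delta_f=bw.delta_f, delta_theta=bw.delta_theta,
            )
        else:
            row.update(n_x=np.nan, n_y=np.nan, delta_f=np.nan, delta_theta=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
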