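"""Population-level quantification of the emergent phenomena.

Four analyses, each mirroring an experimental protocol for V1 simple
cells:

* **ON/OFF segregation** — the most significant ON and OFF excitatory
  sub-regions of each cell are fitted with elliptical Gaussians and the
  overlap index ``I_o = (W_ON + W_OFF - d) / (W_ON + W_OFF + d)``
  computed from the 30%-of-max half-widths and the center distance
  ``d``; ``I_o`` near or below 0 means segregated sub-regions.
* **Push-pull** — the cell's steady membrane potential to its own
  synaptic field (``P``) and to the contrast-reversed field (``N``),
  normalized to ``max(|P|, |N|) = 1``; the index ``I_p = |P + N|`` is 0
  for perfect push-pull and at most 2.
* **Phase-reversed feedback** — pooled Pearson correlations between the
  synaptic fields and the net cortico-thalamic feedback onto OFF and ON
  LGN cells; anti-symmetric learning drives these toward +1 and -1.
* **Contrast invariance** — preferred circular gratings are found by
  exhaustive grid search, orientation tuning curves measured at five
  contrasts, and the slope of the Gaussian half-height bandwidth versus
  contrast extracted; a slope near zero is contrast invariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .network import ModelConfig, WeightSet, simulate_batch
from .rf_analysis import GaborFit, bandwidths, synaptic_field, synaptic_fields
from .stimuli import (
    CONTRAST_GRID,
    MAX_GRATING_RADIUS,
    ORIENTATION_GRID,
    PHASE_GRID,
    SPATIAL_FREQUENCY_GRID,
    GratingSpec,
    encode_batch,
    generate_grating,
)

__all__ = [
    "EllipseFit",
    "OverlapResult",
    "PushPullResult",
    "TuningResult",
    "most_significant_subregion",
    "fit_ellipse",
    "gaussian_half_width",
    "overlap_from_widths",
    "overlap_index",
    "overlap_population",
    "push_pull_from_potentials",
    "push_pull_index",
    "push_pull_population",
    "feedback_correlation",
    "tuning_bandwidth",
    "bandwidth_contrast_slope",
    "contrast_invariance",
    "contrast_invariance_population",
]

#: Half-width threshold: W is where the Gaussian falls to 30% of its max.
HALF_WIDTH_LEVEL = 0.3
#: Sub-region extraction: weights below this fraction of the block
#: maximum are discarded before taking the connected component.
SUBREGION_FRACTION = 0.2


@dataclass
class EllipseFit:
    """Elliptical Gaussian fit of one excitatory sub-region.

    Model: ``gamma / (2 pi a b) * exp(-x'^2/(2 a^2) - y'^2/(2 b^2))``
    with (x', y') rotated by ``theta`` about (x0, y0); canonicalized so
    ``a >= b`` (``a`` is the major half axis, used by quality control).
    """

    gamma: float
    x0: float
    y0: float
    a: float
    b: float
    theta: float
    fit_error: float
    qc_pass: bool
    success: bool = True


@dataclass
class OverlapResult:
    """Overlap-index decomposition for one cell."""

    cell: int
    w_on: float
    w_off: float
    d: float
    overlap: float  # I_o in (-1, 1]


@dataclass
class PushPullResult:
    """Normalized preferred/anti-preferred potentials and push-pull index."""

    cell: int
    p: float
    n: float
    index: float  # I_p in [0, 2]


@dataclass
class TuningResult:
    """Orientation tuning across contrasts for one cell."""

    cell: int
    preferred: GratingSpec
    orientations: np.ndarray  # degrees
    contrasts: np.ndarray
    curves: np.ndarray  # (n_contrasts, n_orientations) mean rates
    bandwidths_deg: np.ndarray  # nan where the tuning fit failed
    slope: float  # degrees per contrast unit; nan if < 2 valid fits


# ---------------------------------------------------------------------------
# ON/OFF segregation


def most_significant_subregion(
    block: np.ndarray, fraction: float = SUBREGION_FRACTION
) -> np.ndarray:
    """Isolate the connected sub-region containing the block maximum.

    Weights below ``fraction`` of the maximum are removed, the remainder
    labelled into connected components, and the component holding the
    global maximum returned (zeros elsewhere).
    """
    block = np.asarray(block, dtype=float)
    peak = block.max()
    if peak <= 0:
        return np.zeros_like(block)
    mask = block >= fraction * peak
    labels, _ = ndimage.label(mask)
    peak_label = labels[np.unravel_index(np.argmax(block), block.shape)]
    return np.where(labels == peak_label, block, 0.0)


def _ellipse_model(shape, gamma, x0, y0, a, b, theta):
    rows, cols = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dx = cols - x0
    dy = rows - y0
    xp = dx * np.cos(theta) + dy * np.sin(theta)
    yp = -dx * np.sin(theta) + dy * np.cos(theta)
    return (
        gamma / (2.0 * np.pi * a * b)
        * np.exp(-(xp**2) / (2.0 * a**2) - (yp**2) / (2.0 * b**2))
    )


def fit_ellipse(region: np.ndarray, support: np.ndarray | None = None) -> EllipseFit:
    """Least-squares elliptical Gaussian fit of a sub-region.

    When ``support`` (a boolean mask) is given, residuals and the fit
    error are evaluated only on those pixels, so the truncation of the
    sub-region at the 20% contour does not bias the fitted axes.
    Quality control passes when the fit error (squared residual-to-input
    norm ratio) is at most 40% and the major half axis ``a`` is at most
    3 pixels.
    """
    region = np.asarray(region, dtype=float)
    if support is None:
        support = np.ones(region.shape, dtype=bool)
    norm = np.linalg.norm(region[support])
    if norm == 0:
        return EllipseFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.inf, False, success=False)
    size_y, size_x = region.shape
    w = np.maximum(region, 0.0)
    total = w.sum()
    rows, cols = np.meshgrid(np.arange(size_y), np.arange(size_x), indexing="ij")
    x0 = float((w * cols).sum() / total)
    y0 = float((w * rows).sum() / total)
    sx = float(np.sqrt((w * (cols - x0) ** 2).sum() / total))
    sy = float(np.sqrt((w * (rows - y0) ** 2).sum() / total))
    a0 = np.clip(max(sx, sy), 0.4, size_x)
    b0 = np.clip(min(sx, sy), 0.4, size_y)
    gamma0 = float(region.max() * 2.0 * np.pi * a0 * b0)

    def residual(p):
        return (_ellipse_model(region.shape, *p) - region)[support]

    lo = np.array([0.0, -4.0, -4.0, 0.1, 0.1, -np.pi])
    hi = np.array([np.inf, size_x + 3.0, size_y + 3.0, 2.0 * size_x, 2.0 * size_y, 2 * np.pi])
    best, best_cost = None, np.inf
    for theta0 in (0.0, 0.5 * np.pi):
        p0 = np.clip(np.array([gamma0, x0, y0, a0, b0, theta0]), lo, hi)
        try:
            sol = least_squares(residual, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol.x, sol.cost
    if best is None:
        return EllipseFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.inf, False, success=False)
    gamma, x0, y0, a, b, theta = best
    if b > a:  # canonicalize: a is the major half axis
        a, b = b, a
        theta += 0.5 * np.pi
    theta = theta % np.pi
    fit_error = float(np.linalg.norm(residual([gamma, x0, y0, a, b, theta])) ** 2 / norm**2)
    qc = fit_error <= 0.40 and a <= 3.0
    return EllipseFit(float(gamma), float(x0), float(y0), float(a), float(b),
                      float(theta), fit_error, bool(qc))


def gaussian_half_width(fit: EllipseFit, direction: np.ndarray,
                        level: float = HALF_WIDTH_LEVEL) -> float:
    """Half-width of the fitted Gaussian at ``level`` of its maximum,
    measured along the unit ``direction`` (x, y) through the center."""
    ux, uy = direction
    c1 = ux * np.cos(fit.theta) + uy * np.sin(fit.theta)
    c2 = -ux * np.sin(fit.theta) + uy * np.cos(fit.theta)
    sigma_line = 1.0 / np.sqrt(c1**2 / fit.a**2 + c2**2 / fit.b**2)
    return float(sigma_line * np.sqrt(2.0 * np.log(1.0 / level)))


def overlap_from_widths(w_on: float, w_off: float, d: float) -> float:
    """Overlap index ``I_o = (W_ON + W_OFF - d) / (W_ON + W_OFF + d)``."""
    return (w_on + w_off - d) / (w_on + w_off + d)


def overlap_index(
    weights: WeightSet, config: ModelConfig, cell: int
) -> OverlapResult | None:
    """Overlap index of one cell, or None when either sub-region fails QC.

    The ON and OFF feedforward excitatory blocks are reduced to their
    most significant sub-region, fitted with elliptical Gaussians, and
    the 30% half-widths measured along the line joining the two fitted
    centers.
    """
    P = config.patch_size
    on_block = weights.on_block("A_up_pos")[:, cell].reshape(P, P)
    off_block = weights.off_block("A_up_pos")[:, cell].reshape(P, P)
    region_on = most_significant_subregion(on_block)
    region_off = most_significant_subregion(off_block)
    fit_on = fit_ellipse(region_on, support=region_on > 0)
    fit_off = fit_ellipse(region_off, support=region_off > 0)
    if not (fit_on.qc_pass and fit_off.qc_pass):
        return None
    delta = np.array([fit_off.x0 - fit_on.x0, fit_off.y0 - fit_on.y0])
    d = float(np.linalg.norm(delta))
    if d > 0:
        u = delta / d
    else:
        # coincident centers: I_o = 1 regardless of the measurement axis
        u = np.array([np.cos(fit_on.theta), np.sin(fit_on.theta)])
    w_on = gaussian_half_width(fit_on, u)
    w_off = gaussian_half_width(fit_off, u)
    return OverlapResult(
        cell=cell, w_on=w_on, w_off=w_off, d=d,
        overlap=overlap_from_widths(w_on, w_off, d),
    )


def overlap_population(weights: WeightSet, config: ModelConfig):
    """Overlap indices for all QC-passing cells, as a DataFrame."""
    import pandas as pd

    rows = []
    for cell in range(weights.n_cortex):
        res = overlap_index(weights, config, cell)
        if res is not None:
            rows.append(
                {"cell": res.cell, "w_on": res.w_on, "w_off": res.w_off,
                 "d": res.d, "overlap": res.overlap}
            )
    return pd.DataFrame(rows, columns=["cell", "w_on", "w_off", "d", "overlap"])


# ---------------------------------------------------------------------------
# push-pull


def push_pull_from_potentials(p_raw: float, n_raw: float) -> PushPullResult | None:
    """Normalize the two potentials and form ``I_p = |P + N|``."""
    m = max(abs(p_raw), abs(n_raw))
    if m == 0:
        return None
    p, n = p_raw / m, n_raw / m
    return PushPullResult(cell=-1, p=p, n=n, index=abs(p + n))


def push_pull_index(
    weights: WeightSet, config: ModelConfig, cell: int
) -> PushPullResult | None:
    """Push-pull index of one cell.

    The cell's synaptic field, rescaled to unit peak magnitude, is
    presented as the preferred stimulus and its negation as the
    anti-preferred stimulus; the steady membrane potentials are
    normalized jointly and ``I_p = |P + N|`` returned.  Cells with a
    zero synaptic field (or zero potentials) are excluded (None).
    """
    sf = synaptic_field(weights, cell).field
    peak = np.abs(sf).max()
    if peak == 0:
        return None
    sf = sf / peak
    X = encode_batch(np.stack([sf, -sf]))
    v_C = simulate_batch(weights, config, X)[2]
    res = push_pull_from_potentials(float(v_C[cell, 0]), float(v_C[cell, 1]))
    if res is None:
        return None
    res.cell = cell
    return res


def push_pull_population(weights: WeightSet, config: ModelConfig):
    """Push-pull indices for all defined cells, as a DataFrame."""
    import pandas as pd

    sfs = synaptic_fields(weights)
    peaks = np.abs(sfs).max(axis=(1, 2))
    ok = peaks > 0
    scaled = np.where(ok[:, None, None], sfs / np.where(ok, peaks, 1.0)[:, None, None], 0.0)
    X = encode_batch(np.concatenate([scaled, -scaled], axis=0))
    v_C = simulate_batch(weights, config, X)[2]
    M = weights.n_cortex
    rows = []
    for cell in range(M):
        if not ok[cell]:
            continue
        res = push_pull_from_potentials(float(v_C[cell, cell]), float(v_C[cell, M + cell]))
        if res is None:
            continue
        rows.append({"cell": cell, "p": res.p, "n": res.n, "index": res.index})
    return pd.DataFrame(rows, columns=["cell", "p", "n", "index"])


# ---------------------------------------------------------------------------
# phase-reversed feedback


def feedback_correlation(weights: WeightSet) -> tuple[float, float]:
    """Pooled Pearson correlations (r_off, r_on) between synaptic fields
    and the net feedback onto OFF and ON LGN cells.

    All (pixel, cell) pairs are pooled into one scatter per channel.
    """
    N = weights.n_lgn
    ff = weights.feedforward
    sf = (ff[:N] - ff[N:]).ravel()
    fb = weights.feedback
    fb_on = fb[:N].ravel()
    fb_off = fb[N:].ravel()
    for name, arr in (("synaptic field", sf), ("ON feedback", fb_on),
                      ("OFF feedback", fb_off)):
        if np.std(arr) == 0:
            raise ValueError(f"{name} array is constant; correlation undefined")
    r_off = float(np.corrcoef(sf, fb_off)[0, 1])
    r_on = float(np.corrcoef(sf, fb_on)[0, 1])
    return r_off, r_on


# ---------------------------------------------------------------------------
# contrast invariance of orientation tuning

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _recenter(orientations: np.ndarray, center: float) -> np.ndarray:
    """Signed angular offsets from ``center`` on the 180-degree circle."""
    return (orientations - center + 90.0) % 180.0 - 90.0


def tuning_bandwidth(orientations: np.ndarray, responses: np.ndarray) -> float:
    """Half-height bandwidth (degrees) of a Gaussian fit to a tuning curve.

    The curve is recentered on its peak orientation (180-degree
    periodicity respected) and fitted with an offset-free Gaussian
    ``A * exp(-(theta - mu)^2 / (2 w^2))``; the bandwidth is the full
    width at half height, ``2 sqrt(2 ln 2) w``.  Returns nan when the
    curve carries no signal or the fit fails.
    """
    orientations = np.asarray(orientations, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if responses.max() <= 0:
        return np.nan
    peak = orientations[np.argmax(responses)]
    x = _recenter(orientations, peak)

    def residual(p):
        amp, mu, w = p
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * w**2)) - responses

    total = responses.sum()
    w0 = float(np.sqrt((responses * x**2).sum() / total)) if total > 0 else 15.0
    w0 = np.clip(w0, 2.0, 60.0)
    try:
        sol = least_squares(
            residual,
            np.array([responses.max(), 0.0, w0]),
            bounds=([0.0, -45.0, 0.5], [np.inf, 45.0, 180.0]),
        )
    except Exception:
        return np.nan
    if not np.all(np.isfinite(sol.x)):
        return np.nan
    return float(_FWHM * sol.x[2])


def bandwidth_contrast_slope(
    contrasts: np.ndarray, bandwidths_deg: np.ndarray
) -> float:
    """Least-squares slope of bandwidth vs contrast, skipping failed fits.

    Returns nan when fewer than two contrasts have a valid bandwidth.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    bandwidths_deg = np.asarray(bandwidths_deg, dtype=float)
    valid = np.isfinite(bandwidths_deg)
    if valid.sum() < 2:
        return np.nan
    return float(np.polyfit(contrasts[valid], bandwidths_deg[valid], 1)[0])


def _grating_batch(specs: list[GratingSpec]) -> np.ndarray:
    return np.stack([generate_grating(s) for s in specs])


def _responses_to_gratings(
    weights: WeightSet, config: ModelConfig, specs: list[GratingSpec],
    cells: np.ndarray, chunk_size: int = 512,
) -> np.ndarray:
    """Steady rates of the given cells to a list of gratings, (n_specs, n_cells)."""
    out = np.empty((len(specs), len(cells)))
    for start in range(0, len(specs), chunk_size):
        batch = specs[start : start + chunk_size]
        X = encode_batch(_grating_batch(batch))
        s_C = simulate_batch(weights, config, X)[3]
        out[start : start + len(batch)] = s_C[cells].T
    return out


def contrast_invariance_population(
    weights: WeightSet,
    config: ModelConfig,
    fits: list[GaborFit],
    cells: np.ndarray | None = None,
) -> list[TuningResult]:
    """Contrast-invariance analysis for a set of oriented cells.

    ``fits`` are per-cell Gabor fits (used for the radius bound
    ``2.5 * min(sigma_x, sigma_y)`` and, when ``cells`` is omitted, for
    the selection: QC-passing fits with a defined spatial-frequency
    bandwidth whose center is at least 2 pixels from every patch edge).

    The preferred grating is found by exhaustive search at full
    contrast; the mean response to the drifting grating is the steady
    rate averaged over the 12 phase steps.
    """
    P = config.patch_size
    if cells is None:
        cells = []
        for i, fit in enumerate(fits):
            if not (fit.success and fit.qc_pass):
                continue
            bw = bandwidths(fit)
            if not np.isfinite(bw.delta_f):
                continue
            if not (2.0 <= fit.x0 <= P - 3.0 and 2.0 <= fit.y0 <= P - 3.0):
                continue
            cells.append(i)
    cells = np.asarray(cells, dtype=int)
    if cells.size == 0:
        return []

    radii = np.arange(1.0, MAX_GRATING_RADIUS + 1.0)
    search_specs = [
        GratingSpec(r, f, o, p, 1.0, P)
        for r in radii
        for f in SPATIAL_FREQUENCY_GRID
        for o in ORIENTATION_GRID
        for p in PHASE_GRID
    ]
    spec_radius = np.array([s.radius for s in search_specs])
    responses = _responses_to_gratings(weights, config, search_specs, cells)

    # per-cell radius cap from the Gabor envelope, then argmax on the grid;
    # cells that never respond to any allowed grating are unmeasurable
    preferred: dict[int, GratingSpec] = {}
    for j, cell in enumerate(cells):
        fit = fits[cell]
        r_max = min(2.5 * min(fit.sigma_x, fit.sigma_y), MAX_GRATING_RADIUS)
        allowed = spec_radius <= max(r_max, 1.0)
        resp = np.where(allowed, responses[:, j], -np.inf)
        if resp.max() <= 0:
            continue
        preferred[j] = search_specs[int(np.argmax(resp))]

    # group cells sharing (radius, f) so each tuning grid is simulated once
    results: list[TuningResult] = []
    groups: dict[tuple[float, float], list[int]] = {}
    for j, spec in preferred.items():
        groups.setdefault((spec.radius, spec.spatial_frequency), []).append(j)

    n_ori, n_phase, n_con = len(ORIENTATION_GRID), len(PHASE_GRID), len(CONTRAST_GRID)
    for (radius, freq), members in groups.items():
        tuning_specs = [
            GratingSpec(radius, freq, o, p, c, P)
            for c in CONTRAST_GRID
            for o in ORIENTATION_GRID
            for p in PHASE_GRID
        ]
        resp = _responses_to_gratings(
            weights, config, tuning_specs, cells[members]
        ).reshape(n_con, n_ori, n_phase, len(members))
        curves_all = resp.mean(axis=2)  # (n_con, n_ori, n_members)
        for k, j in enumerate(members):
            curves = curves_all[:, :, k]
            bws = np.array(
                [tuning_bandwidth(ORIENTATION_GRID, curves[c]) for c in range(n_con)]
            )
            results.append(
                TuningResult(
                    cell=int(cells[j]),
                    preferred=preferred[j],
                    orientations=ORIENTATION_GRID.copy(),
                    contrasts=CONTRAST_GRID.copy(),
                    curves=curves,
                    bandwidths_deg=bws,
                    slope=bandwidth_contrast_slope(CONTRAST_GRID, bws),
                )
            )
    results.sort(key=lambda r: r.cell)
    return results


def contrast_invariance(
    weights: WeightSet, config: ModelConfig, cell: int, fit: GaborFit
) -> TuningResult | None:
    """Contrast-invariance analysis of a single cell (see population version)."""
    fits: list[GaborFit] = [fit] * (cell + 1)
    out = contrast_invariance_population(
        weights, config, fits, cells=np.array([cell])
    )
    return out[0] if out else None
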