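"""Phasor-domain analysis of TCSPC decay data.

The phasor transform maps each pixel's decay histogram ``I(t)`` to

    g = sum_t I(t) cos(n*omega*t) / sum_t I(t)
    s = sum_t I(t) sin(n*omega*t) / sum_t I(t)

with ``omega = 2*pi/laser_period`` and ``n`` the harmonic. Single
exponentials lie on the universal semicircle ``(g - 1/2)^2 + s^2 = 1/4``;
mixtures lie on chords between their components, weighted by fractional
photon contribution. This linearity is what makes the two-component
free/bound NAD(P)H decomposition a line-circle intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DecayStack",
    "PhasorImage",
    "PhasorCalibration",
    "TwoComponentFit",
    "phasor_transform",
    "calibrate_from_reference",
    "semicircle_point",
    "cell_phasor",
    "decompose_fixed_free",
    "fit_trajectory",
    "phasor_median_filter",
    "mixture_phasor",
]

DEFAULT_TAU_FREE = 0.45          # ns; free NAD(P)H lifetime shared by the populations
DEFAULT_COUNT_THRESHOLD = 30     # photons; pixels below are excluded from cell pooling


@dataclass
class DecayStack:
    """Per-pixel photon-count decay histograms.

    ``counts`` has shape (n_bins, rows, cols); ``bin_centers`` must span
    exactly one laser period (the periodic phasor normalization is invalid
    otherwise).
    """

    counts: np.ndarray
    bin_centers: np.ndarray
    laser_period: float
    channel: str = "NADPH"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be 3-D (time, row, col)")
        if self.counts.shape[0] != self.bin_centers.size:
            raise ValueError("bin_centers length must match the time axis")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        d = np.diff(self.bin_centers)
        if np.any(d <= 0):
            raise ValueError("bin_centers must be strictly increasing")
        width = self.laser_period / self.bin_centers.size
        span = self.bin_centers[-1] - self.bin_centers[0] + width
        if not math.isclose(span, self.laser_period, rel_tol=1e-6):
            raise ValueError(
                f"bin grid spans {span:.6g} ns, not the laser period "
                f"{self.laser_period:.6g} ns; phasor normalization invalid"
            )

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def pooled(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Summed decay over a pixel mask (all pixels when mask is None)."""
        if mask is None:
            return self.counts.sum(axis=(1, 2))
        return self.counts[:, mask].sum(axis=1)


@dataclass
class PhasorImage:
    """Per-pixel phasor coordinates plus photon totals.

    Pixels with zero counts carry NaN in ``g`` and ``s``.
    """

    g: np.ndarray
    s: np.ndarray
    total_counts: np.ndarray
    omega: float
    harmonic: int = 1


@dataclass(frozen=True)
class PhasorCalibration:
    """Phase/modulation correction referencing measured phasors to theory."""

    phase_shift: float
    modulation_factor: float

    def __post_init__(self) -> None:
        if self.modulation_factor <= 0:
            raise ValueError("modulation_factor must be positive")

    def apply(self, g, s):
        z = (np.asarray(g) + 1j * np.asarray(s)) * self.modulation_factor * np.exp(
            1j * self.phase_shift
        )
        return z.real, z.imag


@dataclass
class TwoComponentFit:
    """Free/bound decomposition of a cell phasor at fixed tau_free.

    ``tau_bound`` is NaN when the phasor coincides with the free point
    (pure free signal) or when the fit is invalid. ``residual_flag`` is set
    whenever the input required projection onto the semicircle or clipping
    of alpha; ``valid`` is False when the bound intersection is unphysical.
    """

    alpha_bound: float
    tau_bound: float
    tau_free: float
    residual_flag: bool = False
    valid: bool = True


def semicircle_point(tau: float, omega: float) -> tuple[float, float]:
    """Phasor of a single-exponential decay with lifetime ``tau``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    wt = omega * tau
    g = 1.0 / (1.0 + wt * wt)
    return g, wt * g


def mixture_phasor(alpha: float, tau_free: float, tau_bound: float, omega: float):
    """Closed-form phasor of a two-component mixture (photon-fraction alpha bound)."""
    gf, sf = semicircle_point(tau_free, omega)
    gb, sb = semicircle_point(tau_bound, omega)
    return alpha * gb + (1 - alpha) * gf, alpha * sb + (1 - alpha) * sf


def phasor_transform(
    stack: DecayStack,
    harmonic: int = 1,
    calibration: PhasorCalibration | None = None,
) -> PhasorImage:
    """Pixel-wise phasor transform of a decay stack."""
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    omega = 2.0 * math.pi * harmonic / stack.laser_period
    t = stack.bin_centers
    c = np.cos(omega * t)
    sn = np.sin(omega * t)
    counts = stack.counts.astype(float)
    total = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.tensordot(c, counts, axes=(0, 0)) / total
        s = np.tensordot(sn, counts, axes=(0, 0)) / total
    g[total == 0] = np.nan
    s[total == 0] = np.nan
    if calibration is not None:
        g, s = calibration.apply(g, s)
    return PhasorImage(g=g, s=s, total_counts=total, omega=omega, harmonic=harmonic)


def _pooled_phasor(decay: np.ndarray, bin_centers: np.ndarray, omega: float):
    total = decay.sum()
    if total <= 0:
        raise ValueError("zero-count decay")
    g = float((decay * np.cos(omega * bin_centers)).sum() / total)
    s = float((decay * np.sin(omega * bin_centers)).sum() / total)
    return g, s


def calibrate_from_reference(reference: DecayStack, tau_ref: float,
                             harmonic: int = 1) -> PhasorCalibration:
    """Derive the phase/modulation correction from a reference fluorophore.

    The pooled phasor of the (approximately single-exponential) reference is
    mapped onto the theoretical semicircle point for ``tau_ref``; the
    returned rotation/scaling corrects the instrument response common to all
    measurements at this harmonic.
    """
    omega = 2.0 * math.pi * harmonic / reference.laser_period
    gm, sm = _pooled_phasor(reference.pooled(), reference.bin_centers, omega)
    zm = gm + 1j * sm
    if abs(zm) == 0:
        raise ValueError("reference phasor has zero modulus")
    gt, st = semicircle_point(tau_ref, omega)
    zt = gt + 1j * st
    return PhasorCalibration(
        phase_shift=float(np.angle(zt) - np.angle(zm)),
        modulation_factor=float(abs(zt) / abs(zm)),
    )


def cell_phasor(
    phasor: PhasorImage,
    pixel_set: np.ndarray,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
) -> tuple[float, float]:
    """Photon-weighted mean phasor over a pixel set.

    By linearity of the transform this equals the phasor of the pooled
    decay of those pixels. Pixels below ``count_threshold`` photons are
    excluded (their phasor estimates are shot-noise dominated).
    """
    mask = np.asarray(pixel_set, dtype=bool)
    if mask.shape != phasor.total_counts.shape:
        raise ValueError("pixel_set shape mismatch")
    w = phasor.total_counts.astype(float) * mask
    w[w < count_threshold] = 0.0
    wsum = w.sum()
    if not mask.any() or wsum <= 0:
        raise ValueError("empty or zero-count pixel set")
    valid = w > 0
    g = float(np.sum(w[valid] * phasor.g[valid]) / wsum)
    s = float(np.sum(w[valid] * phasor.s[valid]) / wsum)
    return g, s


def _project_into_semicircle(g: float, s: float) -> tuple[float, float, bool]:
    """Radially project an out-of-circle phasor onto the boundary (toward (1/2, 0))."""
    dx, dy = g - 0.5, s
    r = math.hypot(dx, dy)
    if r <= 0.5 + 1e-12:
        return g, s, False
    f = 0.5 / r
    return 0.5 + dx * f, dy * f, True


def decompose_fixed_free(
    cell_gs: tuple[float, float],
    tau_free: float = DEFAULT_TAU_FREE,
    omega: float = 2.0 * math.pi / 12.5,
    free_point_tol: float = 5e-3,
) -> TwoComponentFit:
    """Two-component decomposition with a fixed free-NAD(P)H lifetime.

    The chord through the free-lifetime semicircle point ``P_f`` and the
    cell phasor is intersected with the universal circle. ``P_f`` is an
    exact root of the quadratic in the chord parameterization anchored at
    ``P_f``, so the bound point ``P_b`` is the unique other root;
    ``tau_bound = s_b / (omega * g_b)`` and ``alpha_bound`` is the cell's
    fractional distance from ``P_f`` to ``P_b``.
    """
    if tau_free <= 0:
        raise ValueError("tau_free must be positive")
    g, s = cell_gs
    if not (np.isfinite(g) and np.isfinite(s)):
        raise ValueError("cell phasor is not finite")
    gf, sf = semicircle_point(tau_free, omega)
    if math.hypot(g - gf, s - sf) <= free_point_tol:
        # within shot-noise tolerance of the free point: pure free signal
        # (without this, noise projected back onto the circle near P_f would
        # masquerade as a short-lifetime pure-bound fit)
        return TwoComponentFit(alpha_bound=0.0, tau_bound=float("nan"),
                               tau_free=tau_free, residual_flag=False)
    g, s, projected = _project_into_semicircle(g, s)
    dg, ds = g - gf, s - sf
    d2 = dg * dg + ds * ds
    # P(u) = P_f + u d; |P(u)-C|^2 = 1/4 has roots u=0 (P_f on circle) and u_b
    u_b = -2.0 * (dg * (gf - 0.5) + ds * sf) / d2
    gb, sb = gf + u_b * dg, sf + u_b * ds
    if u_b <= 0 or sb <= 0 or gb <= 0:
        return TwoComponentFit(alpha_bound=float("nan"), tau_bound=float("nan"),
                               tau_free=tau_free, residual_flag=True, valid=False)
    tau_bound = sb / (omega * gb)
    if tau_bound <= tau_free:
        return TwoComponentFit(alpha_bound=float("nan"), tau_bound=float("nan"),
                               tau_free=tau_free, residual_flag=True, valid=False)
    alpha = 1.0 / u_b  # cell at u=1, bound point at u=u_b
    clipped = alpha > 1.0
    return TwoComponentFit(
        alpha_bound=float(min(alpha, 1.0)),
        tau_bound=float(tau_bound),
        tau_free=tau_free,
        residual_flag=bool(projected or clipped),
    )


def fit_trajectory(
    points: np.ndarray,
    weights: np.ndarray | None = None,
    omega: float = 2.0 * math.pi / 12.5,
) -> tuple[float, float]:
    """Estimate both lifetimes from the pixel-cloud trajectory.

    Fits a total-least-squares line through the weighted (g, s) cloud and
    intersects it with the universal circle; the short- and long-lifetime
    intersections are returned as ``(tau_free, tau_bound)``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n, 2) array of phasor points, n >= 2")
    w = np.ones(pts.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    mu = (w[:, None] * pts).sum(axis=0) / w.sum()
    x = pts - mu
    cov = (w[:, None] * x).T @ x / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-15:
        raise ValueError("degenerate phasor cloud (all points identical)")
    v = evecs[:, -1]  # principal direction = TLS line direction
    # line: mu + t v; intersect |p - C| = 1/2 with C = (1/2, 0)
    m = mu - np.array([0.5, 0.0])
    b = float(m @ v)
    c = float(m @ m) - 0.25
    disc = b * b - c
    if disc <= 0:
        raise ValueError("trajectory line does not intersect the universal circle")
    taus = []
    for t in (-b - math.sqrt(disc), -b + math.sqrt(disc)):
        gg, ss = mu + t * v
        if gg <= 0:
            raise ValueError("trajectory intersection at non-physical g <= 0")
        taus.append(ss / (omega * gg))
    lo, hi = sorted(taus)
    return float(lo), float(hi)


def phasor_median_filter(
    phasor: PhasorImage, radius: int = 1, passes: int = 1,
    count_threshold: int = 0,
) -> PhasorImage:
    """Component-wise median filtering of the g and s images.

    Standard phasor denoising: medians preserve the cloud position while
    shrinking shot-noise scatter. ``radius=0`` is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    g, s = phasor.g.copy(), phasor.s.copy()
    if radius == 0 or passes == 0:
        return PhasorImage(g=g, s=s, total_counts=phasor.total_counts.copy(),
                           omega=phasor.omega, harmonic=phasor.harmonic)
    size = 2 * radius + 1
    valid = phasor.total_counts >= count_threshold
    for arr in (g, s):
        work = arr.copy()
        filled = np.where(np.isfinite(work), work, 0.0)
        for _ in range(passes):
            filled = ndimage.median_filter(filled, size=size, mode="nearest")
        arr[valid & np.isfinite(arr)] = filled[valid & np.isfinite(arr)]
    return PhasorImage(g=g, s=s, total_counts=phasor.total_counts.copy(),
                       omega=phasor.omega, harmonic=phasor.harmonic)
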