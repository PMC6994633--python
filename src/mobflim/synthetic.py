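"""Ground-truthed synthetic FLIM fields.

Emulates the measurement the analysis assumes: per-pixel NAD(P)H decays
that are two-component (free/bound) exponential mixtures wrapped over one
laser period, Poisson photon statistics, an optional circular Gaussian
instrument response, disk-shaped cells with peripheral NAD(P)H enrichment
and a polarized (linear-ramp) intensity distribution, and an FAD intensity
channel tuned so each cell's mean FAD/(FAD + NAD(P)H) matches its true
optical redox ratio.

The wrapped-exponential decay uses the geometric-series closed form of an
infinite exponential tail folded into one period, so the analytic
single-exponential phasor is exact at every lifetime and the generator can
serve as an oracle for the phasor code.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    AcquisitionConfig,
    CellTruth,
    ConfigurationError,
    PerturbationModel,
    PopulationSpec,
    DRAWN_FIELDS,
    _FIELD_RANGES,
)

__all__ = [
    "SyntheticField",
    "sample_population",
    "place_cells",
    "render_field",
    "apply_perturbation",
    "wrapped_exponential_pmf",
    "sample_decay",
    "truth_table",
]

DEFAULT_BAND_FRACTION = 0.3  # peripheral band: distance from center > (1-f)*radius


def wrapped_exponential_pmf(tau: float, acq: AcquisitionConfig) -> np.ndarray:
    """Per-bin photon probabilities of an exponential decay folded into one period.

    The infinite tail of exp(-t/tau) is wrapped back modulo the laser period
    T; summing the geometric series gives, for bin [t0, t1),

        p = (exp(-t0/tau) - exp(-t1/tau)) / (1 - exp(-T/tau))

    which sums to 1 exactly over the period.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    edges = np.arange(acq.n_time_bins + 1) * acq.bin_width
    e = np.exp(-edges / tau)
    p = (e[:-1] - e[1:]) / (1.0 - math.exp(-acq.laser_period / tau))
    return p


def _gaussian_irf_kernel_fft(acq: AcquisitionConfig) -> np.ndarray | None:
    """rfft of a periodic Gaussian IRF centered at t=0 (None when sigma=0)."""
    if acq.irf_sigma == 0:
        return None
    k = np.arange(acq.n_time_bins // 2 + 1)
    wk = 2.0 * math.pi * k / acq.laser_period
    return np.exp(-0.5 * (wk * acq.irf_sigma) ** 2)


def _apply_irf(p: np.ndarray, irf_fft: np.ndarray | None) -> np.ndarray:
    if irf_fft is None:
        return p
    out = np.fft.irfft(np.fft.rfft(p) * irf_fft, n=p.size)
    return np.clip(out, 0.0, None)


def decay_pmf(alpha: float, tau_free: float, tau_bound: float,
              acq: AcquisitionConfig) -> np.ndarray:
    """Two-component wrapped decay, optionally blurred by the Gaussian IRF."""
    p = alpha * wrapped_exponential_pmf(tau_bound, acq) + (1.0 - alpha) * wrapped_exponential_pmf(tau_free, acq)
    return _apply_irf(p, _gaussian_irf_kernel_fft(acq))


def sample_decay(alpha: float, tau_free: float, tau_bound: float,
                 n_photons: float, acq: AcquisitionConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Poisson realization of a pooled two-component decay histogram."""
    return rng.poisson(decay_pmf(alpha, tau_free, tau_bound, acq) * n_photons)


def sample_population(spec: PopulationSpec, seed: int,
                      start_id: int = 1) -> list[CellTruth]:
    """Draw ``spec.n_cells`` independent cell truths (no placement yet).

    Each drawn field is Gaussian around its mean, clipped to the field's
    invariant range; tau_bound is additionally kept above tau_free. Cell
    centers are assigned later by :func:`place_cells`.
    """
    rng = np.random.default_rng(seed)
    cells: list[CellTruth] = []
    for i in range(spec.n_cells):
        draw = {}
        for f in DRAWN_FIELDS:
            v = spec.mean[f] + spec.sd.get(f, 0.0) * rng.standard_normal()
            lo, hi = _FIELD_RANGES[f]
            if lo is not None:
                v = max(v, lo)
            if hi is not None:
                v = min(v, hi)
            draw[f] = float(v)
        if draw["tau_bound_true"] <= draw["tau_free_true"]:
            draw["tau_bound_true"] = draw["tau_free_true"] + 1e-3
        cells.append(CellTruth(cell_id=start_id + i, population=spec.name,
                               center=(0.0, 0.0), **draw))
    return cells


def place_cells(cells: list[CellTruth], frame_shape: tuple[int, int],
                seed: int, margin: float = 1.0,
                max_tries: int = 10_000) -> list[CellTruth]:
    """Assign non-overlapping disk centers inside the frame by rejection sampling."""
    rng = np.random.default_rng(seed)
    placed: list[CellTruth] = []
    rows, cols = frame_shape
    for cell in cells:
        r = cell.radius + margin
        if 2 * r >= min(rows, cols):
            raise ConfigurationError(
                f"cell {cell.cell_id}: radius {cell.radius} does not fit frame {frame_shape}"
            )
        for _ in range(max_tries):
            cy = rng.uniform(r, rows - r)
            cx = rng.uniform(r, cols - r)
            if all(math.hypot(cy - p.center[0], cx - p.center[1])
                   > cell.radius + p.radius + margin for p in placed):
                placed.append(dataclasses.replace(cell, center=(float(cy), float(cx))))
                break
        else:
            raise ConfigurationError(
                f"could not place cell {cell.cell_id} without overlap in {max_tries} tries"
            )
    return placed


@dataclass
class SyntheticField:
    """One rendered field of view with its ground truth."""

    decay_counts: np.ndarray        # (n_bins, rows, cols) uint32
    fad_image: np.ndarray           # (rows, cols) float -> photons
    label_mask: np.ndarray          # (rows, cols) uint16, 0 = background
    truth: pd.DataFrame
    acq: AcquisitionConfig
    nadph_rate: np.ndarray          # noiseless per-pixel expected NAD(P)H photons
    fad_rate: np.ndarray            # noiseless per-pixel expected FAD photons


def _amplitude_profile(cell: CellTruth, rr: np.ndarray, cc: np.ndarray,
                       band_fraction: float, rng: np.random.Generator):
    """Relative intensity over the cell's disk: base x edge band x polarity ramp.

    The linear ramp slope is 4*polarity_offset/radius: for a continuous
    uniform disk the intensity-centroid shift of profile (1 + m*x/R) is
    m*R/4, so this choice makes the rendered polarity match the requested
    offset (exactly for small offsets; clipped at zero beyond 0.25 where
    the relation stays monotone).
    """
    cy, cx = cell.center
    dy, dx = rr - cy, cc - cx
    dist = np.hypot(dy, dx)
    inside = dist <= cell.radius
    a = inside.astype(float)
    band = inside & (dist > (1.0 - band_fraction) * cell.radius)
    a[band] *= cell.edge_enrichment
    if cell.polarity_offset > 0:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        proj = (dx * math.cos(theta) + dy * math.sin(theta)) / cell.radius
        ramp = np.clip(1.0 + 4.0 * cell.polarity_offset * proj, 0.0, None)
        a *= ramp
    return a, inside


def render_field(cells: list[CellTruth], acq: AcquisitionConfig,
                 band_fraction: float = DEFAULT_BAND_FRACTION,
                 fad_noise: bool = True) -> SyntheticField:
    """Render decay stack, FAD image, label mask and truth table for one field.

    Per pixel in cell c the expected NAD(P)H decay is
    ``A_p * [alpha*f(t; tau_b) + (1-alpha)*f(t; tau_f)] + background`` with
    f a unit-area wrapped exponential (circularly IRF-convolved when
    irf_sigma > 0); observed counts are Poisson. Per-pixel FAD intensity is
    set so the cell's mean FAD/(FAD + NAD(P)H) equals orr_true before noise.
    """
    rows, cols = acq.frame_shape
    rng = np.random.default_rng(acq.seed)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    nadph_rate = np.zeros((rows, cols))
    fad_rate = np.zeros((rows, cols))
    label_mask = np.zeros((rows, cols), dtype=np.uint16)
    rate_stack = np.zeros((acq.n_time_bins, rows, cols), dtype=np.float64)

    records = []
    for cell in cells:
        cy, cx = cell.center
        if (cy - cell.radius < 0 or cy + cell.radius > rows - 1
                or cx - cell.radius < 0 or cx + cell.radius > cols - 1):
            raise ConfigurationError(f"cell {cell.cell_id} overlaps the frame boundary")
        a, inside = _amplitude_profile(cell, rr, cc, band_fraction, rng)
        total_a = a.sum()
        if total_a <= 0:
            raise ConfigurationError(f"cell {cell.cell_id}: degenerate intensity profile")
        amp = a * (cell.total_photons / total_a)   # expected NAD(P)H photons per pixel
        if np.any(amp < 0):
            raise ConfigurationError("negative expected rates")
        if np.any(label_mask[inside] != 0):
            raise ConfigurationError(f"cell {cell.cell_id} overlaps a previous cell")
        pmf = decay_pmf(cell.alpha_bound_true, cell.tau_free_true,
                        cell.tau_bound_true, acq)
        rate_stack[:, inside] += pmf[:, None] * amp[inside]
        nadph_rate += amp
        if cell.orr_true >= 1.0:
            raise ConfigurationError(f"cell {cell.cell_id}: orr_true must be < 1 to set FAD")
        fad_rate[inside] += amp[inside] * cell.orr_true / (1.0 - cell.orr_true)
        label_mask[inside] = cell.cell_id
        rec = dataclasses.asdict(cell)
        rec["center_row"], rec["center_col"] = rec.pop("center")
        records.append(rec)

    if acq.background_rate > 0:
        rate_stack += acq.background_rate / acq.n_time_bins
        nadph_rate += acq.background_rate

    decay_counts = rng.poisson(rate_stack).astype(np.uint32)
    fad_image = (rng.poisson(fad_rate).astype(float) if fad_noise else fad_rate.copy())
    truth = pd.DataFrame.from_records(records)
    return SyntheticField(decay_counts=decay_counts, fad_image=fad_image,
                          label_mask=label_mask, truth=truth, acq=acq,
                          nadph_rate=nadph_rate, fad_rate=fad_rate)


def render_fad_stack(cells: list[CellTruth], acq: AcquisitionConfig,
                     tau_bound_fad: float = 2.3, alpha_bound_fad: float = 0.8,
                     tau_free_fad: float = 0.3,
                     band_fraction: float = DEFAULT_BAND_FRACTION) -> SyntheticField:
    """Optional FAD-channel decay stack with a single bound-FAD lifetime.

    The same phasor machinery applied to this stack recovers the bound-FAD
    lifetime; cell intensities are scaled by orr/(1-orr) relative to the
    NAD(P)H photon budget.
    """
    fad_cells = [
        dataclasses.replace(
            c,
            alpha_bound_true=alpha_bound_fad,
            tau_bound_true=tau_bound_fad,
            tau_free_true=tau_free_fad,
            total_photons=c.total_photons * c.orr_true / (1.0 - c.orr_true),
        )
        for c in cells
    ]
    return render_field(fad_cells, acq, band_fraction=band_fraction)


def apply_perturbation(cells: list[CellTruth], model: PerturbationModel,
                       seed: int) -> list[CellTruth]:
    """Return post-treatment truths with tau_bound shifted by the linear model.

    ``tau_post = tau_init + a + b*tau_init + noise``, clipped to stay above
    tau_free; cell ids are preserved so pre/post tables pair by id.
    """
    rng = np.random.default_rng(seed)
    out = []
    for cell in cells:
        delta = (model.intercept + model.slope * cell.tau_bound_true
                 + model.noise_sd * rng.standard_normal())
        tau_post = max(cell.tau_bound_true + delta, cell.tau_free_true + 1e-6)
        out.append(dataclasses.replace(cell, tau_bound_true=float(tau_post)))
    return out


def truth_table(cells: list[CellTruth]) -> pd.DataFrame:
    recs = []
    for c in cells:
        r = dataclasses.asdict(c)
        r["center_row"], r["center_col"] = r.pop("center")
        recs.append(r)
    return pd.DataFrame.from_records(recs)
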