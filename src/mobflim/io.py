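"""Readers/writers for the package's file dialects.

A simulated field on disk is a directory with:

- ``nadph_decay.tif``   multi-page TIFF, one page per time bin, 16-bit counts
- ``nadph_decay.json``  sidecar {laser_period_ns, bin_width_ns, n_bins, harmonic,
  irf_sigma_ns, seed}
- ``fad.tif``           16-bit FAD intensity image
- ``labels.tif``        16-bit cell-id mask (0 = background)
- ``truth.csv``         one row per cell, fixed headers

Phasor images are 2-page 32-bit float TIFFs (g, s) with a JSON sidecar;
per-cell tables are CSV with the fixed MOB header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import AcquisitionConfig
from .phasor import DecayStack, PhasorImage
from .synthetic import SyntheticField

DECAY_TIF = "nadph_decay.tif"
DECAY_JSON = "nadph_decay.json"
FAD_TIF = "fad.tif"
LABELS_TIF = "labels.tif"
TRUTH_CSV = "truth.csv"


class DialectError(ValueError):
    """A file does not match the expected on-disk dialect."""


def _sidecar(acq: AcquisitionConfig) -> dict:
    return {
        "laser_period_ns": acq.laser_period,
        "bin_width_ns": acq.bin_width,
        "n_bins": acq.n_time_bins,
        "harmonic": acq.harmonic,
        "irf_sigma_ns": acq.irf_sigma,
        "background_rate": acq.background_rate,
        "seed": acq.seed,
        "package_version": __version__,
    }


def write_field(field: SyntheticField, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = field.decay_counts
    if counts.max() > np.iinfo(np.uint16).max:
        raise DialectError("decay counts exceed 16-bit range")
    tifffile.imwrite(out / DECAY_TIF, counts.astype(np.uint16))
    with open(out / DECAY_JSON, "w") as fh:
        json.dump(_sidecar(field.acq), fh, indent=1)
    tifffile.imwrite(out / FAD_TIF, np.clip(field.fad_image, 0, 65535).astype(np.uint16))
    tifffile.imwrite(out / LABELS_TIF, field.label_mask.astype(np.uint16))
    field.truth.to_csv(out / TRUTH_CSV, index=False)
    return out


def read_decay_stack(field_dir, channel: str = "NADPH") -> tuple[DecayStack, AcquisitionConfig]:
    d = Path(field_dir)
    tif, sidecar = d / DECAY_TIF, d / DECAY_JSON
    if not sidecar.exists():
        raise DialectError(f"missing sidecar {sidecar}")
    if not tif.exists():
        raise DialectError(f"missing decay TIFF {tif}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    try:
        counts = tifffile.imread(tif)
    except Exception as exc:  # truncated/corrupt file -> descriptive error
        raise DialectError(f"cannot read decay TIFF {tif}: {exc}") from exc
    if counts.ndim != 3:
        raise DialectError("decay TIFF must be a 3-D stack (one page per time bin)")
    n_bins = int(meta["n_bins"])
    if counts.shape[0] != n_bins:
        raise DialectError(
            f"decay TIFF has {counts.shape[0]} pages but the sidecar declares {n_bins} bins"
        )
    acq = AcquisitionConfig(
        laser_period=float(meta["laser_period_ns"]),
        n_time_bins=n_bins,
        harmonic=int(meta.get("harmonic", 1)),
        irf_sigma=float(meta.get("irf_sigma_ns", 0.0)),
        background_rate=float(meta.get("background_rate", 0.0)),
        frame_shape=tuple(counts.shape[1:]),
        seed=int(meta.get("seed", 0)),
    )
    stack = DecayStack(counts=counts, bin_centers=acq.bin_centers,
                       laser_period=acq.laser_period, channel=channel)
    return stack, acq


def read_field(field_dir):
    """Read (stack, acq, fad_image, label_mask, truth_or_None) from a field dir."""
    d = Path(field_dir)
    stack, acq = read_decay_stack(d)
    fad = tifffile.imread(d / FAD_TIF).astype(float)
    labels = tifffile.imread(d / LABELS_TIF)
    truth = pd.read_csv(d / TRUTH_CSV) if (d / TRUTH_CSV).exists() else None
    if fad.shape != labels.shape or fad.shape != stack.counts.shape[1:]:
        raise DialectError("fad/labels/decay shapes disagree")
    return stack, acq, fad, labels, truth


def write_phasor(phasor: PhasorImage, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.stack([phasor.g, phasor.s]).astype(np.float32))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"omega_rad_per_ns": phasor.omega, "harmonic": phasor.harmonic,
                   "package_version": __version__}, fh, indent=1)
    tifffile.imwrite(path.with_name(path.stem + "_counts.tif"),
                     phasor.total_counts.astype(np.float32))


def read_phasor(path) -> PhasorImage:
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 2:
        raise DialectError("phasor TIFF must have exactly 2 pages (g, s)")
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    counts = tifffile.imread(path.with_name(path.stem + "_counts.tif"))
    return PhasorImage(g=arr[0].astype(float), s=arr[1].astype(float),
                       total_counts=counts.astype(float),
                       omega=float(meta["omega_rad_per_ns"]),
                       harmonic=int(meta["harmonic"]))


def write_cells(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise DialectError("cells CSV must contain a 'cell_id' column")
    return df
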