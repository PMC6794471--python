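"""Downstream evaluation: log-domain T2* relaxometry and region SNR.

T2* is fitted per voxel by ordinary least squares of ln(magnitude) against
echo time (simple monoexponential decay S(TE) = S0 * exp(-TE * R2*), so
ln S = ln S0 - TE * R2*). The fit is unweighted — fidelity to the plain
log-domain regression rather than a noise-optimal weighting. Region SNR is
mean signal over its standard deviation within a structure mask, and the
denoising benefit is quantified as the per-region SNR difference between
denoised and original data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EchoSeries:
    """Multi-echo magnitude volumes with strictly increasing echo times (ms)."""

    echo_times: tuple[float, ...]
    magnitudes: tuple[np.ndarray, ...]

    def __post_init__(self):
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 2 or np.any(np.diff(te) <= 0) or np.any(te <= 0):
            raise ValueError("echo_times must be >= 2 strictly increasing positive values")
        if len(self.magnitudes) != te.size:
            raise ValueError("one magnitude volume per echo time required")
        shp = self.magnitudes[0].shape
        if any(m.shape != shp for m in self.magnitudes):
            raise ValueError("echo volumes must share one grid")


@dataclass
class RelaxometryMaps:
    """Voxelwise fit results. Units: echo times in ms, hence r2star in 1/ms
    and t2star in ms. ``valid`` flags voxels where all echoes were positive
    and the fitted decay rate is positive; elsewhere maps hold NaN."""

    r2star: np.ndarray
    t2star: np.ndarray
    s0: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class RegionStats:
    """Summary of one labelled region; snr = mean/std is NaN (undefined)
    when the region is perfectly uniform (std = 0)."""

    label: str
    n_voxels: int
    mean: float
    std: float
    snr: float

    @property
    def snr_defined(self) -> bool:
        return math.isfinite(self.snr)


def fit_t2star(series: EchoSeries, mask: np.ndarray | None = None) -> RelaxometryMaps:
    """Log-domain OLS monoexponential fit: slope = -R2*, intercept = ln(S0).

    Voxels with any nonpositive magnitude (log undefined) are flagged
    invalid, as are voxels whose fitted decay rate is nonpositive (t2star
    would not be a relaxation time there).
    """
    te = np.asarray(series.echo_times, dtype=float)
    vols = np.stack(series.magnitudes, axis=-1)
    valid = np.all(vols > 0, axis=-1)
    if mask is not None:
        valid &= mask.astype(bool)
    if not np.any(valid):
        raise ValueError(f"no valid voxels to fit ({vols[..., 0].size} candidates, "
                         "all with a nonpositive echo or outside the mask)")
    logs = np.log(np.where(vols > 0, vols, 1.0))
    te_c = te - te.mean()
    slope = logs @ te_c / np.sum(te_c ** 2)
    intercept = logs.mean(axis=-1) - slope * te.mean()
    r2star = np.where(valid, -slope, np.nan)
    s0 = np.where(valid, np.exp(intercept), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2star = np.where(r2star > 0, 1.0 / r2star, np.nan)
    valid = valid & (r2star > 0)
    return RelaxometryMaps(r2star, t2star, s0, valid)


def region_snr(volume: np.ndarray, labels: np.ndarray,
               label_names: dict[int, str] | None = None) -> list[RegionStats]:
    """Per-label mean, std and SNR = mean/std within a labelled volume.

    Labels are the positive integers in ``labels`` (0 is background and
    skipped); the std uses the population (1/n) denominator. NaN voxels are
    excluded; labels with fewer than 2 usable voxels are skipped.
    """
    if volume.shape != labels.shape:
        raise ValueError("volume and labels must share one grid")
    out = []
    for lab in np.unique(labels):
        if lab <= 0:
            continue
        vals = volume[labels == lab]
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            continue
        mean = float(np.mean(vals))
        std = float(np.std(vals))  # population denominator
        snr = mean / std if std > 0 else float("nan")
        name = (label_names or {}).get(int(lab), str(int(lab)))
        out.append(RegionStats(name, int(vals.size), mean, std, snr))
    return out


def snr_improvement(original: np.ndarray, denoised: np.ndarray,
                    labels: np.ndarray,
                    label_names: dict[int, str] | None = None) -> dict[str, float]:
    """Per-region SNR gain: snr(denoised) - snr(original).

    NaN marks regions where either side's SNR is undefined (uniform region).
    """
    if original.shape != denoised.shape or original.shape != labels.shape:
        raise ValueError("volumes and labels must share one grid")
    before = {r.label: r for r in region_snr(original, labels, label_names)}
    after = {r.label: r for r in region_snr(denoised, labels, label_names)}
    out = {}
    for label in before:
        if label not in after:
            continue
        a, b = after[label], before[label]
        out[label] = (a.snr - b.snr
                      if a.snr_defined and b.snr_defined else float("nan"))
    return out
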