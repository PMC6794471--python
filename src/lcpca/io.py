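"""Volume containers, NIfTI input/output and run logging.

Magnitude/phase pairs of co-registered 3D contrasts are the unit of input
(e.g. the five complex images of an MP2RAGEME acquisition). Phase volumes
are stored internally in radians on [-pi, pi); scanner exports that use
other conventions (integer scaling, degrees, [0, 2*pi) offsets) are
detected from their value range and rescaled on read, with the applied
rescaling logged.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger("lcpca")

TWO_PI = 2.0 * np.pi
#: slack allowed when deciding whether values already look like radians
_PHASE_RANGE_TOL = 0.01


class GridMismatchError(ValueError):
    """Volumes in one set do not share a voxel grid."""


class PhaseUnitError(ValueError):
    """Phase values not interpretable as radians under any known convention."""


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles into the half-open interval [-pi, pi)."""
    return np.mod(np.asarray(x, dtype=float) + np.pi, TWO_PI) - np.pi


@dataclass(frozen=True)
class VolumeHeader:
    """Geometry of a 3D volume: grid shape, voxel size (mm), voxel->world affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive reals, got {self.voxel_size}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or not np.allclose(aff[3], [0, 0, 0, 1]):
            raise ValueError("affine must be 4x4 with last row (0,0,0,1)")
        object.__setattr__(self, "affine", aff)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VolumeHeader":
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(tuple(int(s) for s in img.shape[:3]), zooms, np.asarray(img.affine))

    @classmethod
    def isotropic(cls, shape: Sequence[int], voxel_size: float = 0.5) -> "VolumeHeader":
        """Header with an isotropic scaled-identity affine (default 0.5 mm)."""
        aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        return cls(tuple(int(s) for s in shape), (voxel_size,) * 3, aff)

    def matches(self, other: "VolumeHeader", rtol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, rtol=rtol)


@dataclass
class ComplexImageSet:
    """M_c co-registered contrasts as paired magnitude (>=0) and phase volumes.

    Phases are radians in [-pi, pi). ``names`` are short per-contrast labels
    used to derive deterministic output filenames.
    """

    magnitudes: list[np.ndarray]
    phases: list[np.ndarray]
    header: VolumeHeader
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.magnitudes) < 1 or len(self.magnitudes) != len(self.phases):
            raise ValueError("need equal, nonzero numbers of magnitude and phase volumes")
        shp = self.header.shape
        for i, (m, p) in enumerate(zip(self.magnitudes, self.phases)):
            if m.shape != shp or p.shape != shp:
                raise GridMismatchError(
                    f"contrast {i}: volume shape {m.shape}/{p.shape} != header {shp}"
                )
            if np.any(m < 0):
                raise ValueError(f"contrast {i}: magnitude has negative values")
        if not self.names:
            self.names = [f"contrast{i + 1}" for i in range(len(self.magnitudes))]
        if len(self.names) != len(self.magnitudes):
            raise ValueError("names must match number of contrasts")

    @property
    def n_contrasts(self) -> int:
        return len(self.magnitudes)


# --- phase-unit conventions -------------------------------------------------
#
# Detected in order from the observed value range; each maps the stored
# values linearly onto radians before the final rewrap into [-pi, pi).

def _phase_to_radians(data: np.ndarray, path: str) -> np.ndarray:
    lo, hi = float(np.min(data)), float(np.max(data))
    if -np.pi - _PHASE_RANGE_TOL <= lo and hi <= np.pi + _PHASE_RANGE_TOL:
        return wrap_phase(data)
    if 0.0 <= lo and hi <= TWO_PI + _PHASE_RANGE_TOL:
        logger.info("phase %s: range [0, 2pi) detected, rewrapping", path)
        return wrap_phase(data)
    if -180.0 - _PHASE_RANGE_TOL <= lo and hi <= 180.0 + _PHASE_RANGE_TOL:
        logger.info("phase %s: degrees [-180, 180] detected, converting", path)
        return wrap_phase(np.deg2rad(data))
    if 0.0 <= lo and hi <= 360.0 + _PHASE_RANGE_TOL:
        logger.info("phase %s: degrees [0, 360] detected, converting", path)
        return wrap_phase(np.deg2rad(data))
    if 0.0 <= lo and hi < 4096.0:
        logger.info("phase %s: integer [0, 4096) scaling detected, converting", path)
        return wrap_phase(data / 4096.0 * TWO_PI - np.pi)
    if -4096.0 <= lo and hi < 4096.0:
        logger.info("phase %s: integer [-4096, 4096) scaling detected, converting", path)
        return wrap_phase(data / 4096.0 * np.pi)
    raise PhaseUnitError(
        f"phase volume {path}: value range [{lo:.3g}, {hi:.3g}] matches no known "
        "phase convention (radians, degrees, or +/-4096 integer scaling)"
    )


def read_complex_set(
    magnitude_paths: Sequence[str | Path],
    phase_paths: Sequence[str | Path],
) -> ComplexImageSet:
    """Load paired magnitude/phase NIfTI volumes into a validated set.

    All volumes must share one grid (shape and affine). Phase volumes stored
    on a non-radian convention are rescaled (see ``_phase_to_radians``).
    """
    if len(magnitude_paths) < 1 or len(magnitude_paths) != len(phase_paths):
        raise ValueError("need equal, nonzero numbers of magnitude and phase paths")
    header: VolumeHeader | None = None
    mags, phases, names = [], [], []
    for mpath, ppath in zip(magnitude_paths, phase_paths):
        mimg, pimg = nib.load(str(mpath)), nib.load(str(ppath))
        for img, path in ((mimg, mpath), (pimg, ppath)):
            h = VolumeHeader.from_nifti(img)
            if header is None:
                header = h
            elif not header.matches(h):
                raise GridMismatchError(
                    f"{path}: grid {h.shape} does not match first volume {header.shape}"
                )
        mags.append(np.asarray(mimg.get_fdata(), dtype=float))
        phases.append(_phase_to_radians(np.asarray(pimg.get_fdata(), dtype=float), str(ppath)))
        name = Path(mpath).name
        for suffix in (".nii.gz", ".nii"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        names.append(name)
    assert header is not None
    return ComplexImageSet(mags, phases, header, names)


def _save_nifti(data: np.ndarray, header: VolumeHeader, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), header.affine)
    img.header.set_zooms(header.voxel_size)
    nib.save(img, str(path))


def write_complex_set(cset: ComplexImageSet, output_dir: str | Path,
                      suffix: str = "") -> list[Path]:
    """Write one magnitude + one phase NIfTI per contrast; returns the paths."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mag, phs in zip(cset.names, cset.magnitudes, cset.phases):
        for tag, vol in (("mag", mag), ("phs", phs)):
            p = outdir / f"{name}{suffix}_{tag}.nii"
            _save_nifti(vol, cset.header, p)
            paths.append(p)
    return paths


def write_denoise_result(result, output_dir: str | Path) -> list[Path]:
    """Write a full denoising result: per-contrast magnitude and phase plus
    the two patch-averaged QC maps (local dimension, noise-fit R^2).

    ``result`` is an ``lcpca.core.LcpcaResult`` (duck-typed: needs ``images``,
    ``dimension_map`` and ``fit_map``). Filenames are deterministic from the
    input contrast names; volumes are written uncompressed so reruns are
    byte-identical.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    images: ComplexImageSet = result.images
    paths = write_complex_set(images, outdir, suffix="_lcpca")
    for tag, vol in (("dim", result.dimension_map), ("residuals", result.fit_map)):
        p = outdir / f"lcpca_{tag}.nii"
        _save_nifti(vol, images.header, p)
        paths.append(p)
    return paths


# --- run log ----------------------------------------------------------------

class RunLog:
    """Collects resolved parameters and per-stage wall time; writes one JSON
    sidecar per run so results can be traced back to their settings."""

    def __init__(self, parameters: dict):
        self.parameters = dict(parameters)
        self.timings: dict[str, float] = {}
        self._t0: dict[str, float] = {}

    def start(self, stage: str) -> None:
        self._t0[stage] = time.perf_counter()

    def stop(self, stage: str) -> None:
        self.timings[stage] = round(time.perf_counter() - self._t0.pop(stage), 4)

    def write(self, path: str | Path) -> None:
        payload = {"parameters": self.parameters, "timings_s": self.timings}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
        logger.info("run log written to %s", path)
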