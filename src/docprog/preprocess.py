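"""Resting-state preprocessing for a single BOLD run.

Stages, in the order they are applied by :func:`preprocess_run`:

1. discard the first ``k`` volumes (scanner equilibration);
2. spatial Gaussian smoothing (6 mm FWHM default);
3. nuisance regression: 6 motion parameters, their first backward
   differences, the global (within-mask) mean signal and a linear trend;
4. motion censoring: volumes bracketing any framewise displacement (FD)
   above 1.5 mm are removed; runs left with fewer than 50 volumes are
   excluded;
5. zero-phase band-pass filtering (0.01-0.08 Hz) of the surviving volumes.

FD follows the summed-absolute-derivative convention with rotations
converted to displacement at a 50 mm radius. The whole pipeline is
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage, signal

from .exceptions import ConfigurationError, PipelineError

logger = logging.getLogger(__name__)

FD_ROTATION_RADIUS_MM = 50.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BoldRun:
    """One 4D scan: data grid, repetition time, mask and motion trace.

    ``motion`` stays aligned to the current time axis of ``data``;
    ``kept_volumes`` maps the current time axis back to the original
    volume indices of the acquisition.
    """

    data: np.ndarray  # (x, y, z, t)
    tr: float
    mask: np.ndarray  # (x, y, z) boolean
    motion: np.ndarray  # (t, 6): translations mm, rotations rad
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    kept_volumes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.data.ndim != 4:
            raise ConfigurationError("data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ConfigurationError("mask shape must match the spatial grid")
        if self.motion.shape != (self.n_volumes, 6):
            raise ConfigurationError(
                f"motion must be ({self.n_volumes}, 6), got {self.motion.shape}"
            )
        if self.kept_volumes is None:
            self.kept_volumes = np.arange(self.n_volumes)
        self.kept_volumes = np.asarray(self.kept_volumes, dtype=int)
        if len(self.kept_volumes) != self.n_volumes:
            raise ConfigurationError("kept_volumes must align with the time axis")
        if np.any(np.diff(self.kept_volumes) <= 0):
            raise ConfigurationError("kept_volumes must be strictly increasing")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def take_volumes(self, idx: np.ndarray) -> "BoldRun":
        idx = np.asarray(idx, dtype=int)
        return BoldRun(
            data=self.data[..., idx],
            tr=self.tr,
            mask=self.mask,
            motion=self.motion[idx],
            affine=self.affine,
            kept_volumes=self.kept_volumes[idx],
        )


@dataclass(frozen=True)
class ExclusionSignal:
    """A run failed motion QC: too few volumes survived censoring."""

    n_remaining: int
    min_required: int
    reason: str = "insufficient volumes after motion censoring"
    subject_id: str | None = None


@dataclass(frozen=True)
class PreprocessConfig:
    drop_k: int = 5
    fwhm_mm: float = 6.0
    fd_threshold_mm: float = 1.5
    min_volumes: int = 50
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    censor_margin: int = 0  # extra volumes removed on each side of the pair
    filter_order: int = 4


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------

def drop_initial_volumes(run: BoldRun, k: int = 5) -> BoldRun:
    """Remove the first ``k`` volumes from data, motion and kept_volumes."""
    if k < 0:
        raise ConfigurationError("k must be >= 0")
    if k >= run.n_volumes:
        raise ConfigurationError(
            f"cannot drop {k} volumes from a {run.n_volumes}-volume run"
        )
    if k == 0:
        return run
    return run.take_volumes(np.arange(k, run.n_volumes))


def smooth_gaussian(run: BoldRun, fwhm_mm: float = 6.0) -> BoldRun:
    """Convolve each volume with a separable Gaussian of the given FWHM."""
    if fwhm_mm < 0:
        raise ConfigurationError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return run
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / run.voxel_sizes
    out = np.empty_like(run.data)
    for t in range(run.n_volumes):
        out[..., t] = ndimage.gaussian_filter(run.data[..., t], sigma=sigma_vox)
    return replace_data(run, out)


def replace_data(run: BoldRun, data: np.ndarray) -> BoldRun:
    return BoldRun(
        data=data,
        tr=run.tr,
        mask=run.mask,
        motion=run.motion,
        affine=run.affine,
        kept_volumes=run.kept_volumes,
    )


def compute_fd(motion: np.ndarray) -> np.ndarray:
    """Framewise displacement in mm; the first volume is defined as 0.

    FD_t = sum over translations |delta| + 50 mm * sum over rotations
    |delta| (rotations in radians converted to arc displacement at a 50 mm
    radius).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ConfigurationError("motion must be (t, 6)")
    if not np.all(np.isfinite(motion)):
        raise ConfigurationError("motion parameters contain non-finite values")
    d = np.abs(np.diff(motion, axis=0))
    fd = np.concatenate(
        [[0.0], d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)]
    )
    return fd


def censor_frames(
    run: BoldRun,
    fd: np.ndarray,
    threshold_mm: float = 1.5,
    min_remaining: int = 50,
    margin: int = 0,
) -> BoldRun | ExclusionSignal:
    """Remove the volume pair bracketing every super-threshold displacement.

    FD_t measures the t-1 -> t transition, so both endpoints (t-1 and t)
    are contaminated and removed; ``margin`` widens the window by that many
    extra volumes on each side. If fewer than ``min_remaining`` volumes
    survive, an :class:`ExclusionSignal` is returned instead of a run.
    """
    fd = np.asarray(fd, dtype=float)
    if len(fd) != run.n_volumes:
        raise ConfigurationError("fd must align with the run's volumes")
    bad = np.zeros(run.n_volumes, dtype=bool)
    for t in np.nonzero(fd > threshold_mm)[0]:
        lo = max(0, t - 1 - margin)
        hi = min(run.n_volumes, t + 1 + margin)
        bad[lo:hi] = True
    keep = np.nonzero(~bad)[0]
    if len(keep) < min_remaining:
        return ExclusionSignal(n_remaining=len(keep), min_required=min_remaining)
    return run.take_volumes(keep)


def _nuisance_design(run: BoldRun) -> np.ndarray:
    motion = run.motion
    dmotion = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    global_mean = run.data[run.mask].mean(axis=0)
    trend = np.linspace(-1.0, 1.0, run.n_volumes)
    intercept = np.ones(run.n_volumes)
    return np.column_stack([motion, dmotion, global_mean, trend, intercept])


def nuisance_regress(run: BoldRun) -> BoldRun:
    """Per-voxel least-squares residualization against the nuisance design.

    Design = [6 motion parameters, their first backward differences, the
    global within-mask mean, a linear trend, an intercept]. Collinear
    columns are dropped (with a warning) before solving, so the residuals
    are exactly orthogonal to every retained regressor.
    """
    design = _nuisance_design(run)
    Q, R = np.linalg.qr(design, mode="reduced")
    keep_cols = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())
    if not keep_cols.all():
        warnings.warn("nuisance design is rank deficient; dropping collinear columns")
        # re-orthogonalize on the independent columns found by column norm of R
        design = design[:, keep_cols]
        Q, R = np.linalg.qr(design, mode="reduced")
    series = run.data.reshape(-1, run.n_volumes).T  # (t, voxels)
    resid = series - Q @ (Q.T @ series)
    return replace_data(run, resid.T.reshape(run.data.shape))


def bandpass_filter(
    run: BoldRun,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
) -> BoldRun:
    """Zero-phase Butterworth band-pass along the (concatenated) time axis."""
    nyquist = 0.5 / run.tr
    if not (0 <= low_hz < high_hz):
        raise ConfigurationError("need 0 <= low < high")
    if high_hz >= nyquist:
        raise ConfigurationError(f"high edge {high_hz} Hz >= Nyquist {nyquist} Hz")
    if run.n_volumes < 8:
        raise ConfigurationError("need at least 8 volumes to band-pass filter")
    sos = signal.butter(
        order, [low_hz / nyquist, high_hz / nyquist], btype="band", output="sos"
    )
    padlen = min(3 * (2 * order + 1), run.n_volumes - 1)
    series = run.data.reshape(-1, run.n_volumes)
    # even-symmetric padding keeps edge transients inside the stop-band bound
    filtered = signal.sosfiltfilt(
        sos, series, axis=1, padlen=padlen, padtype="even"
    )
    return replace_data(run, filtered.reshape(run.data.shape))


def preprocess_run(
    run: BoldRun, config: PreprocessConfig | None = None
) -> BoldRun | ExclusionSignal:
    """Full per-run pipeline: discard, smooth, regress, censor, filter."""
    cfg = config or PreprocessConfig()
    run = drop_initial_volumes(run, cfg.drop_k)
    run = smooth_gaussian(run, cfg.fwhm_mm)
    run = nuisance_regress(run)
    fd = compute_fd(run.motion)
    censored = censor_frames(
        run,
        fd,
        threshold_mm=cfg.fd_threshold_mm,
        min_remaining=cfg.min_volumes,
        margin=cfg.censor_margin,
    )
    if isinstance(censored, ExclusionSignal):
        logger.info("run excluded: %d volumes remain", censored.n_remaining)
        return censored
    logger.info("censoring retained %d/%d volumes", censored.n_volumes, run.n_volumes)
    return bandpass_filter(
        censored, cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order
    )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def save_run(run: BoldRun, bold_path, mask_path=None, motion_path=None) -> None:
    """Write a run as NIfTI (+ optional mask NIfTI and 6-column motion TSV)."""
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    zooms = (*run.voxel_sizes, run.tr)
    img.header.set_zooms(zooms)
    nib.save(img, str(bold_path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(run.mask.astype(np.uint8), run.affine), str(mask_path))
    if motion_path is not None:
        np.savetxt(motion_path, run.motion, delimiter="\t", fmt="%.8f")


def load_run(bold_path, mask_path, motion_path, tr: float | None = None) -> BoldRun:
    """Load a run from NIfTI + mask NIfTI + motion TSV (mm, mm, mm, rad x3)."""
    img = nib.load(str(bold_path))
    data = np.asarray(img.dataobj, dtype=float)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ConfigurationError("TR must be positive (set it or store it in the header)")
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    motion = np.loadtxt(str(motion_path), delimiter="\t")
    if motion.ndim == 1:
        motion = motion.reshape(1, -1)
    return BoldRun(data=data, tr=tr, mask=mask, motion=motion, affine=img.affine)
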