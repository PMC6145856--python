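"""Synthetic cohorts, ROI time series, motion traces and 4D volumes.

The generator emulates the statistical structure the prognostic analysis
assumes: a cohort of chronic disorders-of-consciousness patients (plus
healthy controls) whose one-year CRS-R outcome is a sparse linear function
of imaging and clinical features; ROI time series with six-network block
covariance in which the default-mode / executive-control anti-correlation
is present only in subjects with high residual "recovery capacity"; and
head-motion traces with occasional spike displacements that exercise the
framewise-displacement censoring rule.

Everything is deterministic under the seed: the same
:class:`CohortSpec` produces bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import spawn_seed
from .exceptions import ConfigurationError, GenerationError
from .roi import NETWORKS, RoiSet, example_roiset

ETIOLOGIES = ("trauma", "stroke", "anoxia")
CLINICAL_FEATURES = ("age", "duration", "etiology_stroke", "etiology_anoxia")

#: CRS-R total score bounds.
CRSR_MIN, CRSR_MAX = 0, 23
#: Synthetic outcomes are clipped into the observed follow-up range.
CRSR_T1_LOW, CRSR_T1_HIGH = 3, 23
#: GOS >= 3 defines consciousness recovery.
GOS_RECOVERY = 3


def default_networks(roi_count: int) -> list[str]:
    """Network membership for a synthetic ROI ordering.

    For the canonical 22-ROI layout this follows the example seed set;
    otherwise networks are assigned cyclically so each of the six networks
    is populated whenever roi_count >= 6.
    """
    if roi_count == 22:
        return example_roiset().networks
    return [NETWORKS[i % len(NETWORKS)] for i in range(roi_count)]


def default_roi_names(roi_count: int) -> list[str]:
    if roi_count == 22:
        return example_roiset().names
    return [f"ROI{i:02d}" for i in range(roi_count)]


def feature_names(roi_names: Sequence[str]) -> list[str]:
    """Canonical feature ordering: resemblance, pairwise FC, clinical."""
    n = len(roi_names)
    res = [f"resemblance::{name}" for name in roi_names]
    fc = [
        f"fc::{roi_names[i]}--{roi_names[j]}"
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return res + fc + list(CLINICAL_FEATURES)


def n_features(roi_count: int) -> int:
    return roi_count + roi_count * (roi_count - 1) // 2 + len(CLINICAL_FEATURES)


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth configuration for a synthetic cohort.

    Parameters
    ----------
    n_patients, n_controls
        Cohort sizes. Defaults mirror a training cohort of 63 patients and
        30 healthy controls.
    roi_count
        Number of seed regions; 22 gives the canonical 253 imaging features.
    networks
        Per-ROI network membership (length ``roi_count``).
    effect_weights
        Sparse ground-truth linear weights over the full feature vector
        (resemblance + FC + clinical). ``None`` selects a default sparse
        pattern: positive weights on three resemblance features, a negative
        weight on the default-mode--executive connectivity, and negative
        age / anoxia effects.
    intercept, noise_sd
        CRS-R T1 = clip(round(intercept + features @ weights + noise), 3, 23).
    rho_within
        Within-network time-series correlation.
    anticorrelation_strength
        Default-mode x executive coupling at full recovery capacity; in
        [-1, 0]. Scaled by capacity so impaired subjects lose the
        anti-correlation.
    motion_spike_rate
        Per-volume probability of a spike displacement in the motion trace.
    recovery_threshold
        CRS-R T1 at or above which GOS >= 3 (recovery) is assigned.
    """

    n_patients: int = 63
    n_controls: int = 30
    roi_count: int = 22
    networks: tuple[str, ...] | None = None
    effect_weights: np.ndarray | None = None
    intercept: float = 3.0
    noise_sd: float = 2.0
    rho_within: float = 0.4
    anticorrelation_strength: float = -0.3
    motion_spike_rate: float = 0.05
    recovery_threshold: int = 14
    capacity_loading: float = 0.5
    feature_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 0:
            raise ConfigurationError("need n_patients >= 2 and n_controls >= 0")
        if self.roi_count < 2:
            raise ConfigurationError("roi_count must be >= 2")
        if not (-1.0 <= self.anticorrelation_strength <= 0.0):
            raise ConfigurationError("anticorrelation_strength must lie in [-1, 0]")
        if not (0.0 <= self.motion_spike_rate <= 1.0):
            raise ConfigurationError("motion_spike_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.networks is None:
            object.__setattr__(self, "networks", tuple(default_networks(self.roi_count)))
        if len(self.networks) != self.roi_count:
            raise ConfigurationError("networks length must equal roi_count")
        if self.effect_weights is None:
            object.__setattr__(self, "effect_weights", self._default_weights())
        w = np.asarray(self.effect_weights, dtype=float)
        if w.shape != (self.n_features,):
            raise ConfigurationError(
                f"effect_weights must have length {self.n_features}, got {w.shape}"
            )
        object.__setattr__(self, "effect_weights", w)

    @property
    def roi_names(self) -> list[str]:
        return default_roi_names(self.roi_count)

    @property
    def n_features(self) -> int:
        return n_features(self.roi_count)

    @property
    def feature_names(self) -> list[str]:
        return feature_names(self.roi_names)

    def pair_index(self) -> list[tuple[int, int]]:
        r = self.roi_count
        return [(i, j) for i in range(r) for j in range(i + 1, r)]

    def dmn_ecn_pairs(self) -> list[int]:
        """Positions (within the FC block) of default-mode x executive pairs."""
        nets = self.networks
        out = []
        for k, (i, j) in enumerate(self.pair_index()):
            pair = {nets[i], nets[j]}
            if pair == {"default_mode", "executive_control"}:
                out.append(k)
        return out

    def _default_weights(self) -> np.ndarray:
        w = np.zeros(self.n_features)
        r = self.roi_count
        # Positive weights on a few resemblance features (first three ROIs
        # spanning the default-mode / executive networks in the canonical
        # layout), a negative weight on the first DMN--ECN connectivity,
        # and negative age / anoxia effects.
        w[0] = 6.0
        w[min(1, r - 1)] = 5.0
        if r > 4:
            w[4] = 4.0
        pairs = self.dmn_ecn_pairs()
        if pairs:
            w[r + pairs[0]] = -8.0
        names = self.feature_names
        w[names.index("age")] = -0.05
        w[names.index("etiology_anoxia")] = -1.5
        return w


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical covariates and outcomes for one subject."""

    id: str
    group: str  # "patient" | "control"
    age: float
    duration: float | None  # months since insult (patients only)
    etiology: str | None  # patients only
    crsr_t0: int
    crsr_t1: int | None = None
    gos_t1: int | None = None
    latent_capacity: float = 1.0  # ground truth, synthetic only

    def __post_init__(self) -> None:
        if self.group == "patient":
            if self.etiology not in ETIOLOGIES:
                raise ConfigurationError(f"patient {self.id}: invalid etiology")
            if self.duration is None or self.duration < 0:
                raise ConfigurationError(f"patient {self.id}: invalid duration")
        for score in (self.crsr_t0, self.crsr_t1):
            if score is not None and not (CRSR_MIN <= score <= CRSR_MAX):
                raise ConfigurationError(f"subject {self.id}: CRS-R out of range")

    @property
    def recovered(self) -> bool | None:
        if self.gos_t1 is None:
            return None
        return self.gos_t1 >= GOS_RECOVERY


def _clinical_dummies(etiology: str) -> tuple[float, float]:
    # trauma is the reference level
    return (float(etiology == "stroke"), float(etiology == "anoxia"))


def gen_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], pd.DataFrame, dict]:
    """Generate a cohort: subject records, feature table and ground truth.

    Returns
    -------
    subjects
        Patients first, then controls; outcomes only for patients.
    table
        DataFrame indexed by subject id with the canonical feature columns
        (resemblance, FC, clinical), plus ``crsr_t1``, ``gos_t1``,
        ``group`` and ``latent_capacity`` bookkeeping columns.
    truth
        Ground-truth effect weights, intercept and per-subject capacity.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.roi_count
    n_fc = r * (r - 1) // 2
    names = spec.feature_names
    dmn_ecn = set(spec.dmn_ecn_pairs())
    nets = spec.networks
    pair_idx = spec.pair_index()

    subjects: list[SubjectRecord] = []
    rows = []
    n_total = spec.n_patients + spec.n_controls
    capacities = np.empty(n_total)
    for s in range(n_total):
        is_patient = s < spec.n_patients
        capacity = float(rng.uniform(0.0, 1.0)) if is_patient else 1.0
        capacities[s] = capacity
        z_cap = 2.0 * capacity - 1.0  # roughly centered/unit scale

        # Resemblance features: degrade toward 0 with lost capacity.
        resemblance = np.clip(
            0.35 + spec.capacity_loading * 0.4 * (z_cap + 1.0)
            + rng.normal(0.0, spec.feature_noise_sd, size=r),
            -1.0,
            1.0,
        )
        # FC features (Fisher z scale): within-network positive baseline,
        # DMN--ECN pairs carry the capacity-gated anti-correlation.
        fc = rng.normal(0.0, spec.feature_noise_sd, size=n_fc)
        for k, (i, j) in enumerate(pair_idx):
            if k in dmn_ecn:
                fc[k] += spec.anticorrelation_strength * capacity
            elif nets[i] == nets[j]:
                fc[k] += spec.rho_within

        age = float(rng.uniform(18.0, 71.0))
        if is_patient:
            etiology = str(rng.choice(ETIOLOGIES, p=[17 / 63, 21 / 63, 25 / 63]))
            duration = float(np.round(np.exp(rng.uniform(0.0, np.log(36.0))), 1))
            crsr_t0 = int(np.clip(np.round(3 + 10 * capacity + rng.normal(0, 2)), 3, 18))
        else:
            etiology, duration, crsr_t0 = None, None, CRSR_MAX

        dummies = _clinical_dummies(etiology) if etiology else (0.0, 0.0)
        features = np.concatenate(
            [resemblance, fc, [age, duration if duration is not None else 0.0, *dummies]]
        )
        rows.append(features)

        crsr_t1 = gos_t1 = None
        if is_patient:
            raw = spec.intercept + float(features @ spec.effect_weights)
            raw += float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
            crsr_t1 = int(np.clip(np.round(raw), CRSR_T1_LOW, CRSR_T1_HIGH))
            if crsr_t1 < spec.recovery_threshold:
                gos_t1 = 2
            elif crsr_t1 < spec.recovery_threshold + 4:
                gos_t1 = 3
            else:
                gos_t1 = 4

        subjects.append(
            SubjectRecord(
                id=f"{'sub' if is_patient else 'ctl'}-{s:03d}",
                group="patient" if is_patient else "control",
                age=age,
                duration=duration,
                etiology=etiology,
                crsr_t0=crsr_t0,
                crsr_t1=crsr_t1,
                gos_t1=gos_t1,
                latent_capacity=capacity,
            )
        )

    table = pd.DataFrame(rows, columns=names, index=[s.id for s in subjects])
    table.index.name = "id"
    table["crsr_t1"] = [s.crsr_t1 for s in subjects]
    table["gos_t1"] = [s.gos_t1 for s in subjects]
    table["group"] = [s.group for s in subjects]
    table["latent_capacity"] = capacities

    truth = {
        "effect_weights": spec.effect_weights.copy(),
        "intercept": spec.intercept,
        "feature_names": names,
        "seed": spec.seed,
    }
    return subjects, table, truth


def patient_table(table: pd.DataFrame) -> pd.DataFrame:
    """Patient rows of a cohort table (the modelling population)."""
    return table[table["group"] == "patient"]


# --------------------------------------------------------------------------
# ROI time series
# --------------------------------------------------------------------------

def block_covariance(spec: CohortSpec, capacity: float) -> np.ndarray:
    """Implied ROI x ROI covariance for a subject with given capacity.

    Unit variances; within-network correlation ``rho_within``; default-mode
    x executive blocks get ``anticorrelation_strength * g(capacity)`` with
    g(c) = clip(c, 0, 1) (monotone increasing, so low-capacity subjects
    lose the anti-correlation); all other between-network entries 0.
    """
    r = spec.roi_count
    nets = spec.networks
    cov = np.eye(r)
    gate = float(np.clip(capacity, 0.0, 1.0))
    for i in range(r):
        for j in range(i + 1, r):
            if nets[i] == nets[j]:
                val = spec.rho_within
            elif {nets[i], nets[j]} == {"default_mode", "executive_control"}:
                val = spec.anticorrelation_strength * gate
            else:
                val = 0.0
            cov[i, j] = cov[j, i] = val
    return cov


def gen_roi_timeseries(
    subject: SubjectRecord,
    spec: CohortSpec,
    n_volumes: int,
    tr: float = 2.0,
    seed: int | None = None,
) -> np.ndarray:
    """Draw an ROI x time matrix from the subject's block covariance."""
    if n_volumes < 2:
        raise ConfigurationError("n_volumes must be >= 2")
    cov = block_covariance(spec, subject.latent_capacity)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise GenerationError(
            "implied ROI covariance is not positive definite "
            f"(rho_within={spec.rho_within}, "
            f"anticorrelation={spec.anticorrelation_strength})"
        ) from exc
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    white = rng.standard_normal((spec.roi_count, n_volumes))
    return chol @ white


# --------------------------------------------------------------------------
# Motion traces
# --------------------------------------------------------------------------

def gen_motion_trace(
    n_volumes: int,
    spike_rate: float,
    spike_magnitude_mm: float = 2.0,
    seed: int = 0,
    drift_sd: float = 0.02,
) -> np.ndarray:
    """Six-column motion trace: translations (mm) then rotations (radians).

    Smooth low-amplitude drift (a lightly damped random walk) plus
    Bernoulli(spike_rate) persistent step displacements of
    ``spike_magnitude_mm`` on a random translation axis, so the framewise
    displacement exceeds the spike magnitude exactly at spiked volumes.
    """
    if n_volumes < 1:
        raise ConfigurationError("n_volumes must be >= 1")
    if not (0.0 <= spike_rate <= 1.0):
        raise ConfigurationError("spike_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, drift_sd, size=(n_volumes, 6))
    steps[:, 3:] *= 0.01  # rotations drift on a much smaller scale (rad)
    trace = np.cumsum(steps, axis=0)
    spikes = rng.random(n_volumes) < spike_rate
    spikes[0] = False  # first volume has FD 0 by definition
    for t in np.nonzero(spikes)[0]:
        axis = int(rng.integers(0, 3))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        trace[t:, axis] += sign * spike_magnitude_mm
    return trace


# --------------------------------------------------------------------------
# 4D volumes
# --------------------------------------------------------------------------

def gen_bold_nifti(
    roi_ts: np.ndarray,
    roiset: RoiSet,
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float = 3.0,
    noise_sd: float = 0.0,
    tr: float = 2.0,
    seed: int = 0,
    motion: np.ndarray | None = None,
):
    """Paint ROI time series into a 4D volume with a synthetic brain mask.

    Voxels inside ROI *i* carry ``roi_ts[i]`` plus white noise; all other
    voxels carry noise only. The brain mask is a filled ellipsoid covering
    all ROI spheres. Returns a :class:`docprog.preprocess.BoldRun`; use
    :func:`docprog.preprocess.save_run` for NIfTI output.
    """
    from .preprocess import BoldRun  # local import to avoid a cycle

    if any(d <= 0 for d in grid_shape):
        raise ConfigurationError("grid dimensions must be positive")
    roi_ts = np.asarray(roi_ts, dtype=float)
    if roi_ts.shape[0] != len(roiset):
        raise ConfigurationError("roi_ts rows must match the ROI count")
    n_vol = roi_ts.shape[1]

    centers_mm = roiset.centers
    radii = np.array([r.radius for r in roiset])
    # Affine: grid center maps to the centroid of the ROI centers.
    shape = np.asarray(grid_shape)
    centroid = centers_mm.mean(axis=0)
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_size_mm
    affine[:3, 3] = centroid - voxel_size_mm * (shape - 1) / 2.0

    # Overlap check (mm space).
    for i in range(len(roiset)):
        for j in range(i + 1, len(roiset)):
            d = np.linalg.norm(centers_mm[i] - centers_mm[j])
            if d < radii[i] + radii[j]:
                raise GenerationError(
                    f"ROI spheres overlap: {roiset[i].name} and {roiset[j].name}"
                )

    # Voxel-center coordinates in mm.
    ii, jj, kk = np.meshgrid(*(np.arange(d) for d in grid_shape), indexing="ij")
    vox = np.stack([ii, jj, kk], axis=-1).astype(float)
    mm = vox * voxel_size_mm + affine[:3, 3]

    rng = np.random.default_rng(seed)
    data = (
        rng.normal(0.0, noise_sd, size=(*grid_shape, n_vol))
        if noise_sd > 0
        else np.zeros((*grid_shape, n_vol))
    )
    for i in range(len(roiset)):
        dist = np.linalg.norm(mm - centers_mm[i], axis=-1)
        sel = dist <= radii[i]
        if not sel.any():
            raise GenerationError(
                f"grid too small: ROI {roiset[i].name} contains no voxels"
            )
        data[sel, :] += roi_ts[i]

    # Mask: filled ellipsoid around the centroid covering all ROI spheres.
    half_extent = np.abs(mm - centroid).reshape(-1, 3).max(axis=0)
    semi = np.maximum(
        np.abs(centers_mm - centroid).max(axis=0) + radii.max() + voxel_size_mm,
        voxel_size_mm,
    )
    semi = np.minimum(semi, half_extent + voxel_size_mm)
    mask = (((mm - centroid) / semi) ** 2).sum(axis=-1) <= 1.0
    # Every ROI voxel must be inside the mask.
    for i in range(len(roiset)):
        dist = np.linalg.norm(mm - centers_mm[i], axis=-1)
        mask |= dist <= radii[i]

    if motion is None:
        motion = np.zeros((n_vol, 6))
    return BoldRun(
        data=data,
        tr=tr,
        mask=mask,
        motion=np.asarray(motion, dtype=float),
        affine=affine,
    )
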