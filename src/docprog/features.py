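"""Imaging feature construction.

Two feature families are computed per subject:

* 231 pairwise functional connectivities — Fisher-z transformed Pearson
  correlations between every pair of the 22 ROI-averaged time series, in
  canonical upper-triangle order;
* 22 template-resemblance features — the spatial Pearson correlation
  between each ROI's whole-brain seed connectivity z-map and the
  healthy-control group template (one-sample t map) of that ROI's network.

Together with age, duration and two etiology dummies (trauma as the
reference level) these form the 257-long model feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from ._utils import fisher_z
from .exceptions import ConfigurationError, PipelineError
from .preprocess import BoldRun
from .roi import NETWORKS, RoiSet
from .synthetic import CLINICAL_FEATURES, SubjectRecord

#: Cap applied to degenerate one-sample t values (zero variance voxels).
T_CAP = 100.0


def roi_voxel_masks(run: BoldRun, roiset: RoiSet) -> list[np.ndarray]:
    """Boolean voxel masks (within the brain mask) for each ROI sphere."""
    shape = run.mask.shape
    idx = np.stack(
        np.meshgrid(*(np.arange(d) for d in shape), indexing="ij"), axis=-1
    ).astype(float)
    # voxel centers in mm via the affine
    mm = idx @ run.affine[:3, :3].T + run.affine[:3, 3]
    masks = []
    for roi in roiset:
        dist = np.linalg.norm(mm - np.asarray(roi.center), axis=-1)
        sel = (dist <= roi.radius) & run.mask
        if not sel.any():
            raise PipelineError(f"ROI {roi.name} contains no in-mask voxels")
        masks.append(sel)
    return masks


def extract_roi_timeseries(run: BoldRun, roiset: RoiSet) -> np.ndarray:
    """ROI x time matrix: mean over the in-mask voxels of each sphere."""
    masks = roi_voxel_masks(run, roiset)
    return np.vstack([run.data[m].mean(axis=0) for m in masks])


def pairwise_fc(ts: np.ndarray) -> np.ndarray:
    """Fisher-z pairwise correlations in canonical upper-triangle order.

    For n ROIs returns n(n-1)/2 values ordered (0,1), (0,2), ..., (n-2,n-1).
    Perfect correlations are clipped before the atanh so degenerate inputs
    stay finite.
    """
    ts = np.asarray(ts, dtype=float)
    n, t = ts.shape
    if t < 3:
        raise ConfigurationError("need at least 3 time points")
    sds = ts.std(axis=1)
    if np.any(sds == 0):
        bad = int(np.nonzero(sds == 0)[0][0])
        raise PipelineError(f"ROI index {bad} has a constant time series")
    r = np.corrcoef(ts)
    iu = np.triu_indices(n, k=1)
    return np.asarray(fisher_z(r[iu]), dtype=float)


def seed_zmap(run: BoldRun, seed_ts: np.ndarray) -> np.ndarray:
    """Whole-brain Fisher-z correlation map of a seed series.

    Returns a 3D map with z values at in-mask voxels and NaN elsewhere.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    if len(seed_ts) != run.n_volumes:
        raise ConfigurationError("seed series must align with the run's volumes")
    if seed_ts.std() == 0:
        raise PipelineError("seed series has zero variance")
    series = run.data[run.mask]  # (voxels, t)
    sc = seed_ts - seed_ts.mean()
    vc = series - series.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(vc, axis=1) * np.linalg.norm(sc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ sc) / denom
    r[denom == 0] = 0.0
    out = np.full(run.mask.shape, np.nan)
    out[run.mask] = fisher_z(r)
    return out


@dataclass(frozen=True)
class TemplateMap:
    """Per-network group connectivity template: a signed one-sample t map."""

    network: str
    tmap: np.ndarray  # 3D, NaN outside the analysis mask
    n_controls: int


def network_seed_series(run: BoldRun, roiset: RoiSet) -> dict[str, np.ndarray]:
    """Per-network seed series: the average over that network's ROI series."""
    ts = extract_roi_timeseries(run, roiset)
    out = {}
    for net in NETWORKS:
        idx = roiset.indices_of_network(net)
        if idx:
            out[net] = ts[idx].mean(axis=0)
    return out


def build_network_templates(
    control_zmaps: dict[str, list[np.ndarray]]
) -> dict[str, TemplateMap]:
    """One-sample t across controls, per network, per voxel.

    ``control_zmaps[network]`` is the list of control-subject z-maps for
    that network's averaged seed. Voxels with zero across-control variance
    get a capped t of sign(mean) * 100; the signed map is stored
    unthresholded.
    """
    templates = {}
    for net, maps in control_zmaps.items():
        if len(maps) < 3:
            raise ConfigurationError(f"network {net}: need >= 3 control maps")
        stack = np.stack(maps)
        n = stack.shape[0]
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = mean / (sd / np.sqrt(n))
        degenerate = (sd == 0) & np.isfinite(mean)
        t[degenerate] = np.sign(mean[degenerate]) * T_CAP
        t = np.clip(t, -T_CAP, T_CAP)
        templates[net] = TemplateMap(network=net, tmap=t, n_controls=n)
    return templates


def _spatial_corr(a: np.ndarray, b: np.ndarray) -> float:
    sel = np.isfinite(a) & np.isfinite(b)
    x, y = a[sel], b[sel]
    if x.size < 3:
        raise PipelineError("too few overlapping voxels for spatial correlation")
    if x.std() == 0 or y.std() == 0:
        raise PipelineError("constant map in spatial correlation")
    return float(np.corrcoef(x, y)[0, 1])


def resemblance_features(
    subject_zmaps: list[np.ndarray],
    templates: dict[str, TemplateMap],
    roiset: RoiSet,
) -> np.ndarray:
    """Spatial correlation of each ROI's z-map with its network template."""
    if len(subject_zmaps) != len(roiset):
        raise ConfigurationError("need one z-map per ROI")
    out = np.empty(len(roiset))
    for i, roi in enumerate(roiset):
        if roi.network not in templates:
            raise ConfigurationError(f"no template for network {roi.network}")
        out[i] = _spatial_corr(subject_zmaps[i], templates[roi.network].tmap)
    return out


@dataclass(frozen=True)
class ConnectivityProfile:
    """Imaging features for one subject, in canonical order."""

    subject_id: str
    fc: np.ndarray  # 231 Fisher-z connectivities
    resemblance: np.ndarray  # 22 spatial correlations

    def __post_init__(self) -> None:
        n = len(self.resemblance)
        if len(self.fc) != n * (n - 1) // 2:
            raise ConfigurationError("fc length must be n(n-1)/2")
        if np.any(np.abs(self.resemblance) > 1) or not np.all(
            np.isfinite(self.resemblance)
        ):
            raise ConfigurationError("resemblance values must be finite in [-1, 1]")


def compute_profile(
    run: BoldRun,
    roiset: RoiSet,
    templates: dict[str, TemplateMap],
    subject_id: str = "",
) -> ConnectivityProfile:
    """All imaging features for one preprocessed run."""
    ts = extract_roi_timeseries(run, roiset)
    fc = pairwise_fc(ts)
    zmaps = [seed_zmap(run, ts[i]) for i in range(len(roiset))]
    res = resemblance_features(zmaps, templates, roiset)
    return ConnectivityProfile(subject_id=subject_id, fc=fc, resemblance=res)


def assemble_feature_vector(
    profile: ConnectivityProfile, subject: SubjectRecord
) -> tuple[np.ndarray, list[str]]:
    """Full model feature vector and its canonical names.

    Order: [resemblance (22), fc (231), age, duration, dummy_stroke,
    dummy_anoxia], with trauma as the etiology reference level.
    """
    for fieldname in ("age", "duration", "etiology"):
        if getattr(subject, fieldname) is None:
            raise ConfigurationError(f"subject {subject.id}: missing {fieldname}")
    dummy_stroke = float(subject.etiology == "stroke")
    dummy_anoxia = float(subject.etiology == "anoxia")
    vec = np.concatenate(
        [
            profile.resemblance,
            profile.fc,
            [subject.age, subject.duration, dummy_stroke, dummy_anoxia],
        ]
    )
    n = len(profile.resemblance)
    names = (
        [f"resemblance::{i:02d}" for i in range(n)]
        + [
            f"fc::{i:02d}--{j:02d}"
            for i in range(n)
            for j in range(i + 1, n)
        ]
        + list(CLINICAL_FEATURES)
    )
    return vec, names


def assemble_feature_table(
    profiles: list[ConnectivityProfile],
    subjects: list[SubjectRecord],
    roiset: RoiSet,
) -> pd.DataFrame:
    """Feature table (one row per subject) with ROI-named columns."""
    names = (
        roiset.resemblance_feature_names()
        + roiset.fc_feature_names()
        + list(CLINICAL_FEATURES)
    )
    by_id = {s.id: s for s in subjects}
    rows, ids = [], []
    for p in profiles:
        subj = by_id[p.subject_id]
        vec, _ = assemble_feature_vector(p, subj)
        rows.append(vec)
        ids.append(subj.id)
    df = pd.DataFrame(rows, columns=names, index=pd.Index(ids, name="id"))
    return df


def save_templates(templates: dict[str, TemplateMap], directory, affine=None) -> None:
    """One NIfTI per network plus a manifest JSON."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    if affine is None:
        affine = np.eye(4)
    for net, tm in templates.items():
        path = directory / f"template_{net}.nii.gz"
        nib.save(nib.Nifti1Image(np.nan_to_num(tm.tmap).astype(np.float32), affine), str(path))
        manifest[net] = {"file": path.name, "n_controls": tm.n_controls}
    (directory / "templates.json").write_text(json.dumps(manifest, indent=2))
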