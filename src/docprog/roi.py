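"""Seed-region configuration.

The analysis probes six resting-state networks (default mode, executive
control, salience, sensorimotor, auditory, visual) through 22 spherical
seed regions. Seed coordinates are a user-supplied configuration; the
module ships a literature-style example set (`example_roiset`) so the
pipeline can run end-to-end, but any study should load its own table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

NETWORKS = (
    "default_mode",
    "executive_control",
    "salience",
    "sensorimotor",
    "auditory",
    "visual",
)

N_ROIS = 22
N_FC_FEATURES = N_ROIS * (N_ROIS - 1) // 2  # 231
N_IMAGING_FEATURES = N_FC_FEATURES + N_ROIS  # 253


@dataclass(frozen=True)
class Roi:
    name: str
    network: str
    center: tuple[float, float, float]  # mm, MNI convention
    radius: float = 6.0

    def __post_init__(self) -> None:
        if self.network not in NETWORKS:
            raise ValueError(f"unknown network {self.network!r} for ROI {self.name}")
        if self.radius <= 0:
            raise ValueError(f"ROI {self.name}: radius must be > 0")


@dataclass(frozen=True)
class RoiSet:
    """An ordered collection of named spherical seed regions.

    The ROI order is canonical: it fixes the ordering of the pairwise
    connectivity features (upper triangle, i < j, row-major) and hence the
    meaning of every downstream model coefficient.
    """

    rois: tuple[Roi, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i: int) -> Roi:
        return self.rois[i]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    @property
    def networks(self) -> list[str]:
        return [r.network for r in self.rois]

    @property
    def centers(self) -> np.ndarray:
        return np.array([r.center for r in self.rois], dtype=float)

    def indices_of_network(self, network: str) -> list[int]:
        return [i for i, r in enumerate(self.rois) if r.network == network]

    def network_partition(self) -> dict[str, list[int]]:
        return {net: self.indices_of_network(net) for net in NETWORKS}

    def pair_index(self) -> list[tuple[int, int]]:
        """Canonical (i, j) order of the pairwise connectivity vector."""
        n = len(self)
        return [(i, j) for i in range(n) for j in range(i + 1, n)]

    def fc_feature_names(self) -> list[str]:
        names = self.names
        return [f"fc::{names[i]}--{names[j]}" for i, j in self.pair_index()]

    def resemblance_feature_names(self) -> list[str]:
        return [f"resemblance::{r.name}" for r in self.rois]

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "network": self.networks,
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "z": self.centers[:, 2],
                "radius": [r.radius for r in self.rois],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RoiSet":
        required = {"name", "network", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"ROI table missing columns: {sorted(missing)}")
        rois = tuple(
            Roi(
                name=str(row["name"]),
                network=str(row["network"]),
                center=(float(row["x"]), float(row["y"]), float(row["z"])),
                radius=float(row.get("radius", 6.0)) if "radius" in df.columns else 6.0,
            )
            for _, row in df.iterrows()
        )
        return cls(rois)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_frame().to_dict(orient="records"), indent=2))
        else:
            self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "RoiSet":
        path = Path(path)
        if path.suffix == ".json":
            df = pd.DataFrame(json.loads(path.read_text()))
        else:
            df = pd.read_csv(path)
        return cls.from_frame(df)


def _mk(entries: Iterable[tuple[str, str, float, float, float]], radius: float) -> RoiSet:
    return RoiSet(tuple(Roi(n, net, (x, y, z), radius) for n, net, x, y, z in entries))


def example_roiset(radius: float = 6.0) -> RoiSet:
    """A literature-style example of 22 seeds covering the six networks.

    Shipped only so that examples and synthetic studies have a concrete
    geometry; coordinates approximate commonly reported network nodes and
    are NOT a validated clinical configuration.
    """
    entries = [
        ("DMN.aMPFC", "default_mode", -1.0, 55.0, -3.0),
        ("DMN.PCC", "default_mode", -5.0, -50.0, 36.0),
        ("DMN.L.LatParietal", "default_mode", -45.0, -67.0, 36.0),
        ("DMN.R.LatParietal", "default_mode", 52.0, -59.0, 36.0),
        ("ExecuContr.DMPFC", "executive_control", -1.0, 31.0, 45.0),
        ("ExecuContr.L.SupParietal", "executive_control", -38.0, -56.0, 48.0),
        ("ExecuContr.R.SupParietal", "executive_control", 42.0, -52.0, 49.0),
        ("ExecuContr.L.DLPFC", "executive_control", -44.0, 27.0, 33.0),
        ("Salience.dACC", "salience", -2.0, 19.0, 32.0),
        ("Salience.L.AntInsula", "salience", -40.0, 12.0, -4.0),
        ("Salience.R.AntInsula", "salience", 42.0, 10.0, -2.0),
        ("Salience.R.DLPFC", "salience", 44.0, 30.0, 30.0),
        ("Sensorimotor.L.M1", "sensorimotor", -39.0, -26.0, 51.0),
        ("Sensorimotor.R.M1", "sensorimotor", 38.0, -26.0, 48.0),
        ("Sensorimotor.SMA", "sensorimotor", 0.0, -21.0, 48.0),
        ("Sensorimotor.L.S2", "sensorimotor", -54.0, -22.0, 22.0),
        ("Auditory.L.A1", "auditory", -43.0, -23.0, 11.0),
        ("Auditory.R.A1", "auditory", 43.0, -23.0, 11.0),
        ("Auditory.MCC", "auditory", -1.0, -8.0, 45.0),
        ("Visual.L.V1", "visual", -8.0, -83.0, 3.0),
        ("Visual.R.V1", "visual", 10.0, -81.0, 5.0),
        ("Visual.MT", "visual", -45.0, -70.0, -2.0),
    ]
    return _mk(entries, radius)
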