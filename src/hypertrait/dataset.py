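"""Tabular container joining mean spectra to trait values and replicates."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SpectralDataset:
    """Samples x wavelengths matrix with trait values and replicate labels.

    ``X`` holds one (possibly preprocessed) spectrum per row on the common
    wavelength ``grid``; ``y`` is the trait being modelled (water % of fresh
    mass, or nitrogen % of dry mass); ``replicate`` carries the experimental
    replicate each sample belongs to, which drives the train/validation
    split; ``partition`` (if set) labels rows ``train`` or ``validation``.
    """

    X: np.ndarray
    grid: np.ndarray
    y: np.ndarray
    replicate: np.ndarray
    trait: str = ""
    sample_id: np.ndarray | None = None
    partition: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.replicate = np.asarray(self.replicate)
        n = self.X.shape[0]
        if self.X.ndim != 2 or self.grid.size != self.X.shape[1]:
            raise ValueError("grid length must equal number of spectral columns")
        if self.y.size != n or self.replicate.size != n:
            raise ValueError("y and replicate must have one entry per sample")
        if self.sample_id is None:
            self.sample_id = np.arange(n)
        self.sample_id = np.asarray(self.sample_id)
        if self.partition is not None:
            self.partition = np.asarray(self.partition)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def take(self, index: np.ndarray) -> "SpectralDataset":
        """Row subset preserving all metadata."""
        return SpectralDataset(
            X=self.X[index],
            grid=self.grid.copy(),
            y=self.y[index],
            replicate=self.replicate[index],
            trait=self.trait,
            sample_id=self.sample_id[index],
            partition=None if self.partition is None else self.partition[index],
        )

    def with_X(self, X: np.ndarray, grid: np.ndarray | None = None) -> "SpectralDataset":
        """Copy with a replaced spectral matrix (and optionally grid)."""
        return SpectralDataset(
            X=X,
            grid=self.grid.copy() if grid is None else np.asarray(grid, dtype=float),
            y=self.y.copy(),
            replicate=self.replicate.copy(),
            trait=self.trait,
            sample_id=self.sample_id.copy(),
            partition=None if self.partition is None else self.partition.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: sample id, trait/replicate columns, wavelength columns."""
        cols = {"sample_id": self.sample_id, "replicate": self.replicate}
        if self.trait:
            cols[self.trait] = self.y
        else:
            cols["y"] = self.y
        if self.partition is not None:
            cols["partition"] = self.partition
        frame = pd.DataFrame(cols)
        spec = pd.DataFrame(self.X, columns=[f"{w:.6g}" for w in self.grid])
        return pd.concat([frame, spec], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, trait: str | None = None) -> "SpectralDataset":
        frame = pd.read_csv(path)
        meta_cols = [c for c in frame.columns if not _is_number(c)]
        wl_cols = [c for c in frame.columns if _is_number(c)]
        if trait is None:
            candidates = [c for c in meta_cols if c not in ("sample_id", "replicate", "partition")]
            if len(candidates) != 1:
                raise ValueError(f"cannot infer trait column from {candidates}")
            trait = candidates[0]
        return cls(
            X=frame[wl_cols].to_numpy(dtype=float),
            grid=np.array([float(c) for c in wl_cols]),
            y=frame[trait].to_numpy(dtype=float),
            replicate=frame["replicate"].to_numpy(),
            trait=trait,
            sample_id=frame["sample_id"].to_numpy(),
            partition=frame["partition"].to_numpy() if "partition" in frame else None,
        )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
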