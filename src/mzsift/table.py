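"""The features x samples abundance table shared by all downstream stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]


@dataclass
class FeatureTable:
    """Feature abundances across samples, with feature and sample metadata.

    ``abundance``: DataFrame, rows = feature names, columns = sample ids.
    ``features``: DataFrame indexed by feature name with at least ``mz`` and
    ``rt`` (s); peak-picking adds consensus RT bounds and fill flags.
    ``samples``: DataFrame indexed by sample id with ``group``,
    ``sample_type`` and ``injection_index``.
    ``log_transformed`` records whether abundances are log10 values.
    """

    abundance: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.abundance.index.name = "feature"
        self.features.index.name = "feature"
        self.samples.index.name = "sample_id"
        if not self.abundance.index.equals(self.features.index):
            self.features = self.features.loc[self.abundance.index]
        missing = [c for c in self.abundance.columns
                   if c not in self.samples.index]
        if missing:
            raise ValueError(f"samples sidecar lacks entries for {missing}")
        self.samples = self.samples.loc[list(self.abundance.columns)]

    # -- convenience views -------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def group_columns(self, group: str) -> list[str]:
        mask = (self.samples["group"] == group)
        return list(self.samples.index[mask])

    def type_columns(self, sample_type: str) -> list[str]:
        mask = (self.samples["sample_type"] == sample_type)
        return list(self.samples.index[mask])

    @property
    def qc_mask(self) -> np.ndarray:
        return (self.samples["sample_type"] == "qc").to_numpy()

    @property
    def injection_index(self) -> np.ndarray:
        return self.samples["injection_index"].to_numpy(dtype=float)

    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)

    def subset(self, feature_names) -> "FeatureTable":
        names = list(feature_names)
        return FeatureTable(self.abundance.loc[names].copy(),
                            self.features.loc[names].copy(),
                            self.samples.copy(),
                            log_transformed=self.log_transformed)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        ids = list(sample_ids)
        return FeatureTable(self.abundance[ids].copy(),
                            self.features.copy(),
                            self.samples.loc[ids].copy(),
                            log_transformed=self.log_transformed)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.abundance.copy(), self.features.copy(),
                            self.samples.copy(),
                            log_transformed=self.log_transformed)

    # -- serialisation -----------------------------------------------------
    def to_csv(self, path: str | Path, samples_path: str | Path | None = None) -> None:
        """Write features+abundances CSV and a sample-metadata sidecar CSV."""
        path = Path(path)
        out = self.features.join(self.abundance)
        out.index.name = "feature"
        out.to_csv(path, float_format="%.10g")
        side = Path(samples_path) if samples_path else path.with_name(
            path.stem + ".samples.csv")
        samples = self.samples.copy()
        samples.index.name = "sample_id"
        samples.to_csv(side)

    @classmethod
    def from_csv(cls, path: str | Path,
                 samples_path: str | Path | None = None) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="feature")
        side = Path(samples_path) if samples_path else path.with_name(
            path.stem + ".samples.csv")
        samples = pd.read_csv(side, index_col="sample_id")
        sample_cols = [c for c in df.columns if c in samples.index]
        meta_cols = [c for c in df.columns if c not in samples.index]
        feats = df[meta_cols].copy()
        for c in ("mz", "rt", "rt_left", "rt_right"):
            if c in feats:
                feats[c] = feats[c].astype(float)
        return cls(df[sample_cols].astype(float), feats, samples)
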