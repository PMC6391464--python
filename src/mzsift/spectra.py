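"""In-memory containers for centroided LC-MS injections."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectrumRun", "SAMPLE_TYPES", "GROUPS"]

#: Incubation groups by substrate concentration (0 / 12.5 / 25 uM).
GROUPS = ("Blank", "Low", "High")

#: Sample roles within an analytical sequence.
SAMPLE_TYPES = ("incubation", "qc", "substrate_blank", "enzyme_blank")


@dataclass
class SpectrumRun:
    """One centroided LC-MS injection.

    Scans are stored column-wise: ``scan_times`` holds the retention time (s)
    of each scan, and ``scans[i]`` is a pair of equally sized arrays
    (m/z values, intensities) for scan ``i``, sorted by m/z.
    """

    sample_id: str
    group: str
    sample_type: str
    injection_index: int
    polarity: str
    scan_times: np.ndarray
    scans: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        if self.scan_times.ndim != 1 or self.scan_times.size == 0:
            raise ValueError("scan grid must be a non-empty 1-D array")
        if np.any(np.diff(self.scan_times) <= 0):
            raise ValueError("scan times must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return len(self.scan_times)

    @property
    def scan_interval(self) -> float:
        return float(np.median(np.diff(self.scan_times)))

    def n_centroids(self) -> int:
        return int(sum(len(mz) for mz, _ in self.scans))

    def flatten(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All centroids as (rt, mz, intensity) arrays, scan-ordered."""
        rts, mzs, ints = [], [], []
        for t, (mz, inten) in zip(self.scan_times, self.scans):
            if len(mz):
                rts.append(np.full(len(mz), t))
                mzs.append(mz)
                ints.append(inten)
        if not rts:
            z = np.empty(0)
            return z, z.copy(), z.copy()
        return np.concatenate(rts), np.concatenate(mzs), np.concatenate(ints)

    def eic(self, target_mz: float, ppm: float) -> np.ndarray:
        """Extracted-ion intensity on the scan grid, summing centroids
        within ``ppm`` of ``target_mz`` in each scan."""
        tol = target_mz * ppm * 1e-6
        out = np.zeros(self.n_scans)
        for i, (mz, inten) in enumerate(self.scans):
            if len(mz):
                lo = np.searchsorted(mz, target_mz - tol)
                hi = np.searchsorted(mz, target_mz + tol, side="right")
                if hi > lo:
                    out[i] = inten[lo:hi].sum()
        return out
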