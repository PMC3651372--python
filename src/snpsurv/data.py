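"""Core containers for genotype matrices and right-censored survival data."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DataError", "SurvivalData", "GenotypeMatrix"]


class DataError(ValueError):
    """Raised when an input file or array violates the expected format."""


@dataclass
class SurvivalData:
    """Right-censored follow-up data.

    Parameters
    ----------
    times
        Observed times ``X_i = min(T_i, C_i)``, non-negative, arbitrary
        time units.
    events
        Event indicators ``delta_i = I(T_i <= C_i)``; 1 for an observed
        event, 0 for censoring.
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events)
        if times.ndim != 1 or events.shape != times.shape:
            raise DataError("times and events must be 1-d arrays of equal length")
        if times.size < 2:
            raise DataError("survival data needs at least two samples")
        if not np.all(np.isfinite(times)) or np.any(times < 0):
            raise DataError("observed times must be finite and non-negative")
        if not np.isin(np.unique(events), (0, 1)).all():
            raise DataError("event indicators must be 0 (censored) or 1 (event)")
        self.times = times
        self.events = events.astype(np.int8)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.times[idx], self.events[idx])

    def __len__(self) -> int:
        return self.n


@dataclass
class GenotypeMatrix:
    """B-allele counts in {0, 1, 2}, samples x SNPs.

    ``values[i, j]`` is the number of copies of the risk (B) allele carried
    by sample ``i`` at SNP ``j``: 0, 1 or 2 for genotypes AA, AB, BB.
    """

    values: np.ndarray
    sample_ids: tuple
    snp_ids: tuple

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise DataError("genotype values must be a 2-d samples x SNPs array")
        if not np.isin(values, (0, 1, 2)).all():
            raise DataError("genotypes must take values in {0, 1, 2}")
        self.values = values.astype(np.int8)
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.snp_ids = tuple(str(s) for s in self.snp_ids)
        if len(self.sample_ids) != self.values.shape[0]:
            raise DataError("sample_ids length does not match the genotype rows")
        if len(self.snp_ids) != self.values.shape[1]:
            raise DataError("snp_ids length does not match the genotype columns")
        self._index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        """Genotype vector of one SNP across samples."""
        return self.values[:, self._index[snp_id]]

    def subset_samples(self, idx) -> "GenotypeMatrix":
        ids = tuple(np.asarray(self.sample_ids, dtype=object)[idx])
        return GenotypeMatrix(self.values[idx], ids, self.snp_ids)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        cols = [self._index[s] for s in snp_ids]
        return GenotypeMatrix(self.values[:, cols], self.sample_ids, tuple(snp_ids))
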