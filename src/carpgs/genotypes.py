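"""Dosage-coded genotype matrices.

Genotypes are stored as the count of one designated allele per biallelic
locus, so each entry is 0, 1 or 2; missing calls are coded ``MISSING`` (-1).
Rows are individuals, columns are loci.  Marker metadata (linkage group and
map position in cM) travels with the matrix so downstream stages can write
positioned output without a side table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-dosage matrix with explicit missing code.

    Parameters
    ----------
    dosages
        ``(n_samples, n_loci)`` integer array with entries in {0, 1, 2,
        ``MISSING``}.
    samples
        Individual identifiers, one per row, in row order.
    markers
        Optional marker table with columns ``marker`` (name), ``lg``
        (linkage group, int) and ``pos_cm`` (map position).  When absent a
        bare index-named table is synthesised.
    """

    dosages: np.ndarray
    samples: np.ndarray
    markers: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x loci) array")
        self.samples = np.asarray(self.samples, dtype=object)
        if self.samples.shape[0] != self.dosages.shape[0]:
            raise ValueError("sample count does not match dosage rows")
        if self.markers is None:
            self.markers = pd.DataFrame(
                {
                    "marker": [f"M{j + 1}" for j in range(self.n_loci)],
                    "lg": np.zeros(self.n_loci, dtype=int),
                    "pos_cm": np.zeros(self.n_loci, dtype=float),
                }
            )
        if len(self.markers) != self.dosages.shape[1]:
            raise ValueError("marker table length does not match dosage columns")
        bad = (self.dosages > 2) | (self.dosages < MISSING)
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or the missing code")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing calls, same shape as ``dosages``."""
        return self.dosages == MISSING

    def sample_index(self, ids) -> np.ndarray:
        """Row indices of the given sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"sample {exc.args[0]!r} not in genotype matrix") from None

    def subset_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(self.dosages[idx], self.samples[idx], self.markers.reset_index(drop=True))

    def subset_loci(self, which) -> "GenotypeMatrix":
        """Subset loci by boolean mask or integer index array."""
        which = np.asarray(which)
        if which.dtype == bool:
            which = np.flatnonzero(which)
        return GenotypeMatrix(
            self.dosages[:, which],
            self.samples,
            self.markers.iloc[which].reset_index(drop=True),
        )

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with missing entries set to NaN."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        return d

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.copy(), self.samples.copy(), self.markers.copy())
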