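"""In-memory containers for abundance tables, targets and distance matrices.

All containers validate their invariants at construction time so that
downstream numerical code can assume clean inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_REL_TOL = 1e-9


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


@dataclass
class AbundanceTable:
    """Samples x taxa table of non-negative counts or relative abundances.

    Rows are samples, columns are taxa (the n_samples x n_features
    convention of the regression stage). ``is_relative`` marks tables whose
    rows sum to one.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    is_relative: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundance table contains non-finite entries")
        neg = np.argwhere(self.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if self.is_relative:
            sums = self.values.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > _REL_TOL)[0]
            if bad.size:
                raise ValueError(
                    f"relative-abundance row {self.sample_ids[bad[0]]!r} "
                    f"sums to {sums[bad[0]]}, not 1"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def select_taxa(self, taxa: list[str]) -> "AbundanceTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return AbundanceTable(
            sample_ids=list(self.sample_ids),
            taxon_ids=list(taxa),
            values=self.values[:, idx],
            is_relative=False if not self.is_relative else self.is_relative,
        )


@dataclass
class TargetVector:
    """One numeric regression target per sample (age, BMI, CDAI, ...)."""

    sample_ids: list[str]
    y: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.y = np.asarray(self.y, dtype=float)
        _check_unique(self.sample_ids, "sample")
        if self.y.ndim != 1 or len(self.y) != len(self.sample_ids):
            raise ValueError("targets must be one value per sample")
        if not np.all(np.isfinite(self.y)):
            bad = int(np.where(~np.isfinite(self.y))[0][0])
            raise ValueError(f"non-finite target for sample {self.sample_ids[bad]!r}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "TargetVector":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return TargetVector(list(sample_ids), self.y[idx], self.units)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix over samples for one metric."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = ""
    metric_params: dict = field(default_factory=dict)

    _BOUNDED = {"jaccard", "bray_curtis", "unweighted_unifrac", "weighted_unifrac"}

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("distance matrix contains negative entries")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-12:
            raise ValueError("distance matrix is not symmetric within 1e-12")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if self.metric in self._BOUNDED and np.any(self.values > 1 + 1e-12):
            raise ValueError(f"{self.metric} distances must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        """Dense block of distances for the given integer index set."""
        idx = np.asarray(idx)
        return self.values[np.ix_(idx, idx)]
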