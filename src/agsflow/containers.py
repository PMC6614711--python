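"""Shared in-memory containers for community tables and sample metadata.

The package keeps community data in a :class:`CommunityTable`: a samples x taxa
matrix (counts or relative abundances) plus a metadata frame aligned row-by-row
with the samples.  Metadata columns follow the sampling design of a multi-reactor
granular-sludge experiment: ``reactor``, ``day``, ``fraction`` (floc | granule |
whole) and an optional ``phase`` label (transition | stable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ("reactor", "day", "fraction", "phase")


class ValidationError(ValueError):
    """Raised when a table or configuration violates its invariants."""


@dataclass
class CommunityTable:
    """Samples x taxa abundance matrix with aligned sample metadata.

    Parameters
    ----------
    values
        DataFrame with one row per sample and one column per taxon.  Entries are
        non-negative counts or proportions.
    meta
        DataFrame indexed like ``values`` with at least ``reactor`` and ``day``
        columns.  ``fraction`` defaults to ``"whole"`` when absent.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.values.index)
        if len(self.meta) != len(self.values):
            raise ValidationError(
                f"metadata has {len(self.meta)} rows but table has "
                f"{len(self.values)} samples"
            )
        if not self.meta.index.equals(self.values.index):
            raise ValidationError("metadata index does not match sample index")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate sample ids: {list(dupes)}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValidationError(f"duplicate taxon ids: {list(dupes)}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("community table contains negative entries")
        if "fraction" not in self.meta.columns:
            self.meta = self.meta.assign(fraction="whole")

    # -- convenience -------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def taxa(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def is_proportions(self, atol: float = 1e-6) -> bool:
        sums = self.values.sum(axis=1).to_numpy()
        return bool(np.allclose(sums, 1.0, atol=atol))

    def subset(self, mask) -> "CommunityTable":
        """Row-subset samples by a boolean mask or index list."""
        return CommunityTable(self.values.loc[mask].copy(), self.meta.loc[mask].copy())

    def for_reactor(self, reactor) -> "CommunityTable":
        mask = self.meta["reactor"] == reactor
        sub = self.subset(mask)
        order = np.argsort(sub.meta["day"].to_numpy(), kind="stable")
        idx = sub.values.index[order]
        return CommunityTable(sub.values.loc[idx], sub.meta.loc[idx])

    def copy(self) -> "CommunityTable":
        return CommunityTable(self.values.copy(), self.meta.copy())
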