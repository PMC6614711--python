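"""Stable-state detection on a reactor's community time series.

A sample is in the *stable state* when the maximum Bray-Curtis distance
between its community and the communities of **all later** samples falls below
a threshold (default 0.6).  The last sample's forward set is empty, so its
forward maximum is 0 and it is stable by convention.  The stable-state *onset*
is the start of the maximal all-stable suffix: isolated early stable samples
followed by a transition sample are flagged but excluded from the stable
dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CommunityTable, ValidationError
from .metrics import bray_curtis_matrix, relative_abundance

logger = logging.getLogger(__name__)

__all__ = ["StableStateResult", "flag_stable_samples", "global_max_distance"]


@dataclass
class StableStateResult:
    """Per-sample stability flags and the stable-state onset for one reactor.

    ``max_forward_distance[i]`` is ``max_{j>i} BC(i, j)`` (0 for the last
    sample).  ``onset_index`` / ``onset_day`` locate the first sample of the
    maximal suffix in which every sample is stable.
    """

    sample_ids: list
    days: np.ndarray
    stable: np.ndarray  # bool per sample
    max_forward_distance: np.ndarray
    onset_index: int
    onset_day: float
    threshold: float
    reactor: object = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "stable": self.stable,
                "max_forward_distance": self.max_forward_distance,
            },
            index=self.sample_ids,
        )

    def to_dict(self) -> dict:
        return {
            "reactor": self.reactor,
            "threshold": self.threshold,
            "onset_index": int(self.onset_index),
            "onset_day": float(self.onset_day),
            "samples": [
                {
                    "sample": str(s),
                    "day": float(d),
                    "stable": bool(f),
                    "max_forward_distance": float(m),
                }
                for s, d, f, m in zip(
                    self.sample_ids, self.days, self.stable,
                    self.max_forward_distance,
                )
            ],
        }


def _series_inputs(series, days):
    if isinstance(series, CommunityTable):
        if days is None:
            if "day" not in series.meta.columns:
                raise ValidationError("community table metadata lacks a 'day' column")
            days = series.meta["day"].to_numpy(dtype=float)
        frame = series.values
    else:
        frame = pd.DataFrame(series)
        if days is None:
            days = np.arange(len(frame), dtype=float)
    days = np.asarray(days, dtype=float)
    if len(days) != len(frame):
        raise ValidationError("days and samples have different lengths")
    if len(days) > 1 and not (np.diff(days) > 0).all():
        raise ValidationError("sampling days must be strictly increasing")
    return frame, days


def flag_stable_samples(
    series, threshold: float = 0.6, days=None, reactor=None
) -> StableStateResult:
    """Flag each sample of a time-ordered series as stable or transition.

    Sample *i* is stable iff ``max_{j>i} BC(i, j) < threshold`` on relative
    abundances.  Raising the threshold can only flip samples towards stable.
    """
    frame, day_arr = _series_inputs(series, days)
    n = len(frame)
    if n == 0:
        raise ValidationError("empty series")
    if n < 2:
        logger.warning("fewer than 2 samples: flagging all stable")
        fwd = np.zeros(n)
    else:
        dm = bray_curtis_matrix(relative_abundance(frame)).to_numpy()
        fwd = np.zeros(n)
        for i in range(n - 1):
            fwd[i] = dm[i, i + 1 :].max()
    stable = fwd < threshold
    # onset: start of the maximal all-stable suffix
    not_stable = np.flatnonzero(~stable)
    onset_index = 0 if not_stable.size == 0 else int(not_stable[-1] + 1)
    if onset_index >= n:  # every sample (incl. the vacuous last) unstable -> none
        onset_index = n - 1
    onset_day = float(day_arr[onset_index])
    return StableStateResult(
        sample_ids=list(frame.index),
        days=day_arr,
        stable=stable,
        max_forward_distance=fwd,
        onset_index=onset_index,
        onset_day=onset_day,
        threshold=threshold,
        reactor=reactor,
    )


def global_max_distance(series, days=None) -> float:
    """Maximum Bray-Curtis distance over all unordered sample pairs."""
    frame, _ = _series_inputs(series, days)
    if len(frame) < 2:
        raise ValidationError("need at least 2 samples")
    dm = bray_curtis_matrix(relative_abundance(frame)).to_numpy()
    return float(dm.max())
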