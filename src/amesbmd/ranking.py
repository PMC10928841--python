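"""Rank-ordered CED confidence intervals, overlap analysis, quartile summaries.

A lower CED means a more potent (more sensitive) assay condition, so the
ranking is ascending in CED with rank 1 the most potent.  Where two
intervals do not overlap the potency difference is resolvable; where they
do, the dose-response data do not contain enough information to separate
the conditions.  Shared endpoints count as overlapping (the conservative
choice: no potency difference is claimed).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .plate_io import Design

__all__ = [
    "RankingEntry",
    "rank_potencies",
    "overlap_matrix",
    "quartile_summary",
    "fold_range",
]


@dataclass(frozen=True)
class RankingEntry:
    """One subgroup's potency interval positioned in the ranked list."""

    design: Design
    ced: float
    cedl: float
    cedu: float  # math.inf for an unbounded upper limit
    rank: int | None = None

    @property
    def upper_unbounded(self) -> bool:
        return math.isinf(self.cedu)


def rank_potencies(entries) -> list:
    """Order entries ascending by CED; rank 1 is the most potent.

    Ties break by lower confidence bound, then by design tuple.  Entries
    with a missing or non-finite CED are excluded with a warning;
    unbounded upper limits keep their CED-based rank (flagged via
    ``upper_unbounded``).
    """
    kept = []
    for e in entries:
        if e.ced is None or not math.isfinite(e.ced):
            warnings.warn(f"excluding entry without finite CED: {e.design}",
                          stacklevel=2)
            continue
        kept.append(e)
    kept.sort(key=lambda e: (e.ced, e.cedl, e.design))
    return [replace(e, rank=i + 1) for i, e in enumerate(kept)]


def overlap_matrix(entries) -> np.ndarray:
    """Symmetric boolean matrix of closed-interval intersection.

    ``[cedl_i, cedu_i]`` and ``[cedl_j, cedu_j]`` overlap when neither lies
    strictly below the other; an unbounded upper limit behaves as +inf.
    """
    entries = list(entries)
    lo = np.array([e.cedl for e in entries])
    hi = np.array([e.cedu for e in entries])
    return (lo[:, None] <= hi[None, :]) & (lo[None, :] <= hi[:, None])


def _quartile_of_rank(rank: int, n: int) -> int:
    bounds = (math.ceil(n / 4), math.ceil(n / 2), math.ceil(3 * n / 4))
    for q, b in enumerate(bounds, start=1):
        if rank <= b:
            return q
    return 4


def quartile_summary(entries, attribute: str) -> pd.DataFrame:
    """Counts of each attribute level per rank quartile.

    ``attribute`` is one of the design fields (s9, vehicle, strain,
    method); quartiles are defined on rank positions (the top quartile of
    12 entries is ranks 1-3), and the counts sum to the number of entries.
    """
    if attribute not in Design._fields:
        raise ValueError(
            f"unknown attribute {attribute!r}; use one of {Design._fields}"
        )
    ranked = [e for e in entries if e.rank is not None] or rank_potencies(entries)
    n = len(ranked)
    if n < 4:
        raise ValueError("quartile summary needs at least 4 ranked entries")
    levels = sorted({getattr(e.design, attribute) for e in ranked})
    table = pd.DataFrame(
        0, index=pd.Index(levels, name=attribute),
        columns=[f"Q{q}" for q in (1, 2, 3, 4)],
    )
    for e in ranked:
        q = _quartile_of_rank(e.rank, n)
        table.loc[getattr(e.design, attribute), f"Q{q}"] += 1
    return table


def fold_range(entries) -> tuple:
    """Spread of ranked CEDs as (max/min ratio, its log10).

    The log10 value expresses the span in "log units" (a three-log-unit
    span is a ~1000-fold potency range).
    """
    ceds = [e.ced for e in entries if e.ced is not None and math.isfinite(e.ced)]
    if not ceds:
        raise ValueError("no finite CEDs to span")
    ratio = max(ceds) / min(ceds)
    return ratio, math.log10(ratio)
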