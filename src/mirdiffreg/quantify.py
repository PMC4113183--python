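"""RPM normalization and the abundance filter.

Two normalization modes exist. ``reads_level`` divides each count by the
pool's grand total, so RPM columns sum to exactly 10^6. ``within_library``
divides each identifier's count by the total of all identifiers assigned to
the same reference library in that pool, so RPMs are comparable within a
library's scope. The abundance filter then keeps only elements with
RPM >= 10 in at least 3 of the pools (defaults configurable).
"""
from __future__ import annotations

import pandas as pd

MODE_READS_LEVEL = "reads_level"
MODE_WITHIN_LIBRARY = "within_library"

RPM_THRESHOLD = 10.0
MIN_POOLS = 3


def to_rpm(
    matrix: pd.DataFrame,
    mode: str = MODE_READS_LEVEL,
    library_assignment: pd.Series | None = None,
) -> pd.DataFrame:
    """Normalize a counts matrix to reads per million, per pool.

    ``library_assignment`` (row id -> library label) is required for
    ``within_library`` mode; each row is scaled by the per-pool total of
    its own library. Values are plain floats, no rounding.
    """
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if mode == MODE_READS_LEVEL:
        totals = matrix.sum(axis=0)
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(f"zero total reads in pool(s): {', '.join(zero.index)}")
        return matrix / totals * 1e6
    if mode == MODE_WITHIN_LIBRARY:
        if library_assignment is None:
            raise ValueError("within_library mode requires a library assignment per row")
        assignment = library_assignment.reindex(matrix.index)
        if assignment.isna().any():
            missing = list(matrix.index[assignment.isna()])[:5]
            raise ValueError(f"rows without library assignment, e.g. {missing}")
        out = matrix.astype(float).copy()
        for library, rows in matrix.groupby(assignment).groups.items():
            totals = matrix.loc[rows].sum(axis=0)
            zero = totals[totals == 0]
            if len(zero):
                raise ValueError(
                    f"zero total reads for library {library!r} in pool(s): "
                    f"{', '.join(zero.index)}"
                )
            out.loc[rows] = matrix.loc[rows] / totals * 1e6
        return out
    raise ValueError(f"unknown normalization mode {mode!r}")


def abundance_filter(
    matrix: pd.DataFrame,
    threshold: float = RPM_THRESHOLD,
    min_pools: int = MIN_POOLS,
) -> pd.DataFrame:
    """Keep rows with RPM >= threshold in at least ``min_pools`` pools."""
    if min_pools > matrix.shape[1]:
        raise ValueError(
            f"min_pools={min_pools} exceeds the {matrix.shape[1]} available pools"
        )
    keep = (matrix >= threshold).sum(axis=1) >= min_pools
    return matrix.loc[keep]
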