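"""Profile-table CSV reading/writing and JSON report serialization.

The profile table is a CSV with header ``phi,loglik`` and one row per
Monte Carlo profile evaluation.  A third column ``se`` is reserved for
future per-point standard errors and is ignored with a logged notice.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ProfileFormatError
from .mcap import ProfilePoints

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("phi", "loglik")


def read_profile(path: str | Path) -> ProfilePoints:
    """Read a profile table, validating every row.

    Rows are parsed in order; duplicate ``phi`` values are preserved as
    replicate evaluations.  Non-numeric or non-finite rows raise a
    row-numbered error (rows counted from 1, excluding the header).
    """
    path = Path(path)
    if not path.exists():
        raise ProfileFormatError(f"profile file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ProfileFormatError(f"could not parse {path}: {exc}") from exc

    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header 'phi,loglik'"
        )
    extra = [c for c in df.columns if c not in _REQUIRED_COLUMNS]
    if "se" in extra:
        logger.info("%s: column 'se' is reserved and currently ignored", path)

    for col in _REQUIRED_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(values.to_numpy(dtype=float)))
        if bad.size:
            raise ProfileFormatError(
                f"{path}: non-numeric or non-finite '{col}' in data row(s) "
                f"{[int(i) + 1 for i in bad[:10]]}"
            )
        df[col] = values

    if len(df) < 4:
        raise ProfileFormatError(
            f"{path}: a profile needs at least 4 rows, got {len(df)}"
        )
    return ProfilePoints(df["phi"].to_numpy(), df["loglik"].to_numpy())


def write_profile(points: ProfilePoints, path: str | Path) -> None:
    """Write a profile table; round-trips exactly through ``read_profile``."""
    df = pd.DataFrame({"phi": points.phi, "loglik": points.loglik})
    # default float formatting is repr-exact, so tables round-trip bit-for-bit
    df.to_csv(path, index=False)


def write_json(record: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record, indent=2) + "\n")
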