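"""Reading and writing diagnosis-pair tables.

Pair files are UTF-8 tab-delimited with header ``pair_id  code_a  code_b``
and an optional fourth ``label`` column restricted to ``similar`` /
``discrepant``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .classification import DISCREPANT, SIMILAR
from .taxonomy import TaxonomyError

__all__ = ["read_pairs", "write_pairs"]

_REQUIRED = ["pair_id", "code_a", "code_b"]


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a pair file, validating header and label values."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise TaxonomyError(f"pair file {path} is missing columns {missing}")
    if "label" in frame.columns:
        bad = set(frame["label"].dropna()) - {SIMILAR, DISCREPANT}
        if bad:
            raise TaxonomyError(f"pair file {path} has invalid labels {sorted(bad)}")
    return frame


def write_pairs(frame: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in (*_REQUIRED, "label") if c in frame.columns]
    frame[cols].to_csv(path, sep="\t", index=False)
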