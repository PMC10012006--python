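"""Run-length utilities shared by validity classification and segmentation."""

from __future__ import annotations

import numpy as np

__all__ = ["maximal_runs"]


def maximal_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of every maximal True run in ``flags``."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    padded = np.concatenate(([False], flags, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))
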