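"""Assembly length statistics: Nx metrics and length-composition tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError


def nx_metric(lengths, fraction: float) -> int:
    """The Nx length statistic of a multiset of sequence lengths.

    Sort descending and return the first length at which the cumulative sum
    reaches ``fraction`` of the total (N50 = fraction 0.5, N90 = 0.9).  Ties
    are inclusive: the threshold is met with ``>=``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise DataError("cannot compute an Nx metric of an empty length set")
    if (arr <= 0).any():
        raise DataError("lengths must be positive")
    cumulative = np.cumsum(arr)
    threshold = fraction * cumulative[-1]
    return int(arr[np.searchsorted(cumulative, threshold, side="left")])


@dataclass
class LengthSummary:
    bins: pd.DataFrame  # columns: bin, count, percent
    count: int
    total: int
    mean: float
    min: int | None
    max: int | None


def length_summary(lengths, bin_edges: list[int]) -> LengthSummary:
    """Length-composition table over half-open bins ``[e_i, e_{i+1})`` with a
    final open-ended bin; lengths below the first edge land in an explicit
    underflow bin.  Counts partition the multiset; percents sum to 100 within
    rounding."""
    if any(a >= b for a, b in zip(bin_edges, bin_edges[1:])):
        raise ValueError(f"bin edges must be strictly ascending: {bin_edges}")
    values = np.asarray(list(lengths), dtype=np.int64)
    labels = [f"<{bin_edges[0]}"] if bin_edges else []
    labels += [f"[{a},{b})" for a, b in zip(bin_edges, bin_edges[1:])]
    if bin_edges:
        labels.append(f">={bin_edges[-1]}")
    if values.size and bin_edges:
        idx = np.digitize(values, bin_edges)  # 0 = underflow
        counts = np.bincount(idx, minlength=len(labels))
    else:
        counts = np.zeros(len(labels), dtype=int)
    n = int(values.size)
    percents = 100.0 * counts / n if n else np.zeros_like(counts, dtype=float)
    bins = pd.DataFrame({"bin": labels, "count": counts, "percent": percents})
    return LengthSummary(
        bins=bins,
        count=n,
        total=int(values.sum()) if n else 0,
        mean=float(values.mean()) if n else float("nan"),
        min=int(values.min()) if n else None,
        max=int(values.max()) if n else None,
    )
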