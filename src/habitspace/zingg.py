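"""Zingg aspect-ratio classification of particle habits.

A particle's three orthogonal extents, sorted as short (S) <= medium (M)
<= long (L), yield two aspect ratios S:M and M:L in (0, 1].  Zingg's
scheme partitions the (S:M, M:L) unit square into four habit classes by
comparing each ratio with a single threshold (0.66 here):

    block:  S:M > t and M:L > t      (near-isometric)
    needle: S:M > t and M:L <= t     (one long axis)
    plate:  S:M <= t and M:L > t     (one short axis)
    lath:   S:M <= t and M:L <= t    (all three axes distinct)

Equality at the threshold goes to the "<= t" branch: a block is defined by
both ratios strictly exceeding the threshold.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import numpy as np

#: The four habit classes, in canonical order.
CLASSES = ("block", "needle", "lath", "plate")

#: Default aspect-ratio threshold separating the classes.
DEFAULT_THRESHOLD = 0.66


def classify(s_m: float, m_l: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Classify one particle from its S:M and M:L aspect ratios.

    Parameters
    ----------
    s_m, m_l:
        Short:medium and medium:long aspect ratios, each in [0, 1].
    threshold:
        Class boundary; ratios strictly greater than it count as "large".

    Returns
    -------
    str
        One of ``"block"``, ``"needle"``, ``"lath"``, ``"plate"``.

    Raises
    ------
    ValueError
        If either ratio lies outside [0, 1].
    """
    if not (0.0 <= s_m <= 1.0) or not (0.0 <= m_l <= 1.0):
        raise ValueError(
            f"aspect ratios must lie in [0, 1]; got s_m={s_m!r}, m_l={m_l!r}"
        )
    if s_m > threshold:
        return "block" if m_l > threshold else "needle"
    return "plate" if m_l > threshold else "lath"


def classify_batch(
    records: Iterable[Sequence[float]], threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[str], dict[str, int]]:
    """Classify a sequence of (s_m, m_l) pairs.

    Returns the per-record labels and a count per class (all four classes
    always present in the counts, possibly zero).
    """
    labels = [classify(s, m, threshold) for s, m in records]
    counts = Counter(labels)
    return labels, {c: counts.get(c, 0) for c in CLASSES}


def classify_array(
    s_m: np.ndarray, m_l: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> np.ndarray:
    """Vectorized :func:`classify` over equal-length ratio arrays."""
    s_m = np.asarray(s_m, dtype=float)
    m_l = np.asarray(m_l, dtype=float)
    if np.any((s_m < 0) | (s_m > 1) | (m_l < 0) | (m_l > 1)):
        raise ValueError("aspect ratios must lie in [0, 1]")
    out = np.where(
        s_m > threshold,
        np.where(m_l > threshold, "block", "needle"),
        np.where(m_l > threshold, "plate", "lath"),
    )
    return out.astype(object)
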