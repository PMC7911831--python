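"""Windowed nucleotide-skew profiles of (circular) genomes.

The cumulative AT-skew of a phage genome typically peaks where transcription
direction flips (rightward- and leftward-facing gene blocks meeting), so the
global extremum of the cumulative series is a useful descriptive landmark.
Windows are non-overlapping tiles; the final partial window is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import GenomeRecord

__all__ = ["SkewProfile", "at_skew_profile", "gc_track", "inflection"]


@dataclass
class SkewProfile:
    window: int
    coordinates: list[int]  # 1-based start of each window
    values: list[float]
    cumulative: list[float]


def _window_counts(seq: str, window: int) -> np.ndarray:
    """(n_windows, 4) counts of A,C,G,T per tiling window."""
    if window < 1:
        raise ValueError("window must be >= 1")
    L = len(seq)
    if L < window:
        raise ValueError("sequence shorter than one window")
    n = L // window
    arr = np.frombuffer(seq[: n * window].encode(), dtype=np.uint8).reshape(n, window)
    out = np.empty((n, 4), dtype=np.int64)
    for i, b in enumerate("ACGT"):
        out[:, i] = (arr == ord(b)).sum(axis=1)
    return out


def at_skew_profile(record: GenomeRecord, window: int = 45) -> SkewProfile:
    """Per-window AT skew (A-T)/(A+T) and its exact cumulative sum.

    A window with no A or T bases contributes 0, keeping the cumulative
    series well-defined.
    """
    counts = _window_counts(record.seq, window)
    a, t = counts[:, 0].astype(float), counts[:, 3].astype(float)
    denom = a + t
    values = np.divide(a - t, denom, out=np.zeros_like(denom), where=denom > 0)
    cumulative = np.cumsum(values)
    coords = [i * window + 1 for i in range(len(values))]
    return SkewProfile(
        window=window,
        coordinates=coords,
        values=values.tolist(),
        cumulative=cumulative.tolist(),
    )


def gc_track(record: GenomeRecord, window: int = 45) -> SkewProfile:
    """Per-window GC fraction (N-free denominator per window)."""
    counts = _window_counts(record.seq, window)
    g, c = counts[:, 2].astype(float), counts[:, 1].astype(float)
    denom = counts.sum(axis=1).astype(float)
    values = np.divide(g + c, denom, out=np.zeros_like(denom), where=denom > 0)
    cumulative = np.cumsum(values)
    coords = [i * window + 1 for i in range(len(values))]
    return SkewProfile(
        window=window,
        coordinates=coords,
        values=values.tolist(),
        cumulative=cumulative.tolist(),
    )


def inflection(profile: SkewProfile) -> int:
    """Window-start coordinate of the global maximum of the cumulative series.

    Ties resolve to the smallest coordinate.
    """
    if not profile.values:
        raise ValueError("empty profile")
    i = int(np.argmax(profile.cumulative))  # argmax returns first maximum
    return profile.coordinates[i]
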