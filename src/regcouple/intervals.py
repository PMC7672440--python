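"""Minimal interval-set operations on 0-based half-open genomic intervals.

Tracks are dicts ``chrom -> (n, 2) int array`` of sorted, merged intervals.
Only the operations the epigenetic features need are provided: merge,
n-way intersection, union, subtraction and region overlap counting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

Track = dict[str, np.ndarray]


def from_frame(bed: pd.DataFrame) -> Track:
    """Build a track from a BED-like frame (chrom, start, end)."""
    track: Track = {}
    for chrom, grp in bed.groupby("chrom"):
        arr = grp[["start", "end"]].to_numpy(dtype=int)
        if (arr[:, 0] >= arr[:, 1]).any():
            raise ValueError(f"interval with start >= end on {chrom}")
        track[chrom] = merge(arr)
    return track


def to_frame(track: Track) -> pd.DataFrame:
    rows = [
        (chrom, int(s), int(e))
        for chrom in sorted(track)
        for s, e in track[chrom]
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def merge(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or touching intervals."""
    if len(arr) == 0:
        return np.empty((0, 2), dtype=int)
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    out = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=int)


def _intersect_chrom(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=int) if out else np.empty((0, 2), dtype=int)


def intersect_all(tracks: list[Track]) -> Track:
    """Intersection of several tracks (intervals present in every track)."""
    if not tracks:
        return {}
    chroms = set(tracks[0])
    for t in tracks[1:]:
        chroms &= set(t)
    out: Track = {}
    for chrom in chroms:
        cur = tracks[0][chrom]
        for t in tracks[1:]:
            cur = _intersect_chrom(cur, t[chrom])
            if len(cur) == 0:
                break
        if len(cur):
            out[chrom] = cur
    return out


def union_all(tracks: list[Track]) -> Track:
    out: Track = {}
    chroms = set().union(*[set(t) for t in tracks]) if tracks else set()
    for chrom in chroms:
        parts = [t[chrom] for t in tracks if chrom in t]
        out_c = merge(np.vstack(parts))
        if len(out_c):
            out[chrom] = out_c
    return out


def subtract(a: Track, b: Track) -> Track:
    """Portions of ``a`` not covered by ``b``."""
    out: Track = {}
    for chrom, ivs in a.items():
        cut = b.get(chrom, np.empty((0, 2), dtype=int))
        pieces = []
        for s, e in ivs:
            cur = s
            for bs, be in cut:
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    pieces.append((cur, bs))
                cur = max(cur, be)
                if cur >= e:
                    break
            if cur < e:
                pieces.append((cur, e))
        if pieces:
            out[chrom] = np.array(pieces, dtype=int)
    return out


def count_overlaps(track: Track, chrom: str, start: int, end: int) -> int:
    """Number of track intervals overlapping [start, end) by >= 1 bp."""
    ivs = track.get(chrom)
    if ivs is None or len(ivs) == 0 or start >= end:
        return 0
    return int(((ivs[:, 0] < end) & (ivs[:, 1] > start)).sum())


def any_overlap(track: Track, chrom: str, start: int, end: int) -> bool:
    return count_overlaps(track, chrom, start, end) > 0
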