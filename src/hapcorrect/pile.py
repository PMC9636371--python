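"""Read alignment piles and window segmentation.

A pile anchors every read that overlaps a chosen target read onto the
target's coordinates: each overlapping read is restricted to its overlap
interval (dangling ends outside the overlap are discarded), oriented into
target orientation, and aligned to the corresponding target substring by a
global edit-distance alignment.  The alignment traceback yields a monotone
column map from fragment positions to target coordinates, which makes
cutting the pile into non-overlapping 500-bp target windows exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .io import OverlapRecord, Read, revcomp
from .simulate import _iter_cigar


@dataclass
class PileFragment:
    """One overlapping read, trimmed to the overlap and mapped onto the target."""

    read_id: str
    orient: str                      # original strand of the overlap
    target_start: int
    target_end: int
    frag_seq: str                    # oriented subsequence within the overlap
    frag_quals: Optional[List[int]]
    colmap: np.ndarray               # fragment position -> target coordinate

    def __post_init__(self) -> None:
        if len(self.colmap) != len(self.frag_seq):
            raise ValueError("colmap length != fragment length")


@dataclass
class WindowFragment:
    read_id: str
    seq: str
    quals: Optional[List[int]]
    offset: int                      # start coordinate within the window


@dataclass
class WindowInstance:
    window_index: int
    target_start: int
    target_end: int
    target_subread: str
    target_subquals: Optional[List[int]]
    fragments: List[WindowFragment]


def _orient_overlap(target: Read, ov: OverlapRecord,
                    reads_by_id: Dict[str, Read]):
    """Return (other read, other interval, target interval, strand)."""
    if ov.tid == target.id:
        other = reads_by_id[ov.qid]
        return other, (ov.qstart, ov.qend), (ov.tstart, ov.tend), ov.strand
    if ov.qid == target.id:
        other = reads_by_id[ov.tid]
        return other, (ov.tstart, ov.tend), (ov.qstart, ov.qend), ov.strand
    raise ValueError(f"overlap {ov.qid}-{ov.tid} does not involve target {target.id}")


def build_pile(
    target: Read,
    overlaps: Sequence[OverlapRecord],
    reads_by_id: Dict[str, Read],
) -> List[PileFragment]:
    """Step 2: align every overlapping read fragment onto the target.

    One fragment per overlap; the column map is derived from the traceback
    of a global edit-distance alignment (insertions relative to the target
    map to the target position they precede).
    """
    pile: List[PileFragment] = []
    for ov in overlaps:
        other, (os_, oe), (ts, te), strand = _orient_overlap(target, ov, reads_by_id)
        if oe > len(other) or te > len(target):
            raise ValueError(f"overlap {ov.qid}-{ov.tid} outside read bounds")
        frag = other.seq[os_:oe]
        quals = other.quals[os_:oe] if other.quals is not None else None
        if strand == "-":
            frag = revcomp(frag)
            quals = quals[::-1] if quals is not None else None
        tsub = target.seq[ts:te]
        res = edlib.align(frag, tsub, task="path", mode="NW")
        colmap = _cigar_to_colmap(res["cigar"], ts, te)
        pile.append(PileFragment(
            read_id=other.id, orient=strand,
            target_start=ts, target_end=te,
            frag_seq=frag, frag_quals=quals, colmap=colmap,
        ))
    pile.sort(key=lambda f: (f.read_id, f.target_start))
    return pile


def _cigar_to_colmap(cigar: str, tstart: int, tend: int) -> np.ndarray:
    """Target coordinate for every fragment base (query of the alignment)."""
    coords: List[int] = []
    t = tstart
    for n, op in _iter_cigar(cigar):
        if op in "=X":
            coords.extend(range(t, t + n))
            t += n
        elif op == "I":           # fragment base with no target base
            coords.extend([min(t, tend - 1)] * n)
        elif op == "D":
            t += n
    return np.asarray(coords, dtype=np.int64)


def segment_windows(
    target: Read,
    pile: Sequence[PileFragment],
    window_len: int = 500,
    min_frag_len: int = 50,
    max_frags: int = 200,
) -> List[WindowInstance]:
    """Step 3: cut the pile into non-overlapping windows of the target.

    Windows tile the target exactly; only the rightmost may be shorter.
    Fragments contributing fewer than ``min_frag_len`` bases to a window
    are dropped from that window; if more than ``max_frags`` remain, the
    longest contributions are kept (ties by read id).
    """
    L = len(target)
    n_win = max(1, -(-L // window_len))
    windows: List[WindowInstance] = []
    per_win: List[List[WindowFragment]] = [[] for _ in range(n_win)]
    for frag in pile:
        w_lo = frag.target_start // window_len
        w_hi = min(n_win - 1, (frag.target_end - 1) // window_len)
        for wi in range(w_lo, w_hi + 1):
            ws, we = wi * window_len, min(L, (wi + 1) * window_len)
            i0 = int(np.searchsorted(frag.colmap, ws, side="left"))
            i1 = int(np.searchsorted(frag.colmap, we, side="left"))
            if i1 - i0 < min(min_frag_len, we - ws):
                continue
            sub = frag.frag_seq[i0:i1]
            subq = frag.frag_quals[i0:i1] if frag.frag_quals is not None else None
            per_win[wi].append(WindowFragment(
                read_id=frag.read_id, seq=sub, quals=subq,
                offset=int(frag.colmap[i0]) - ws,
            ))
    for wi in range(n_win):
        ws, we = wi * window_len, min(L, (wi + 1) * window_len)
        frags = sorted(per_win[wi], key=lambda f: (-len(f.seq), f.read_id))[:max_frags]
        frags.sort(key=lambda f: f.read_id)
        windows.append(WindowInstance(
            window_index=wi, target_start=ws, target_end=we,
            target_subread=target.seq[ws:we],
            target_subquals=target.quals[ws:we] if target.quals is not None else None,
            fragments=frags,
        ))
    return windows
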