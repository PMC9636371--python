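"""All-vs-all read overlaps and overlap filtering.

Overlap detection uses minimizer seeds (canonical k-mers, window minimum of
a mixed 64-bit hash) shared between read pairs, grouped per pair and
relative strand and kept when enough seeds cluster on a common diagonal.
This is deliberately a simple seed-and-cluster overlapper, not a full
chaining aligner: the downstream correction only needs approximate overlap
coordinates, and precomputed PAF from an external overlapper can be
substituted at any time.

Filtering implements the first-cycle criteria -- minimum overlap length,
self-overlaps, internal matches (overhang heuristic), and the mapping
length-ratio error test |1 - min(Lq,Lt)/max(Lq,Lt)| >= e -- and, for the
second cycle, a minimum base-level overlap identity delta computed by
global alignment of the mapped substrings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence

import edlib
import numpy as np

from .io import OverlapRecord, Read, revcomp
from .simulate import _iter_cigar


@dataclass
class OverlapFilterConfig:
    """Thresholds for overlap filtering.

    ``min_len``: overlaps whose mapped span does not exceed this are dropped.
    ``max_len_ratio_err``: the maximum error-rate threshold e on mapping
    length ratio.  ``min_identity``: cycle-2 identity threshold delta
    (None disables the identity criterion).
    """

    min_len: int = 500
    max_len_ratio_err: float = 0.3
    internal_match_overhang: int = 1000
    internal_match_ratio: float = 0.8
    min_identity: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.max_len_ratio_err < 1.0):
            raise ValueError("max_len_ratio_err must be in (0,1)")
        if self.min_identity is not None and not (0.5 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0.5, 1]")


# ---------------------------------------------------------------------------
# minimizer computation

_CODE = np.full(256, 255, dtype=np.uint8)
for i, ch in enumerate("ACGT"):
    _CODE[ord(ch)] = i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _mix64(x: np.ndarray) -> np.ndarray:
    """Invertible 64-bit hash mix (splitmix64 finalizer)."""
    x = x.astype(np.uint64)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def _minimizers(codes: np.ndarray, k: int, w: int):
    """(hash, pos, strand) arrays of the read's minimizers."""
    n = codes.size
    if n < k:
        return (np.empty(0, np.uint64), np.empty(0, np.int64), np.empty(0, np.int64))
    nk = n - k + 1
    fwd = np.zeros(nk, dtype=np.uint64)
    rev = np.zeros(nk, dtype=np.uint64)
    for j in range(k):
        fwd |= codes[j:j + nk].astype(np.uint64) << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - codes[j:j + nk].astype(np.uint64)) << np.uint64(2 * j)
    strand = (rev < fwd).astype(np.int64)  # 1: reverse kmer is canonical
    canon = np.where(strand == 1, rev, fwd)
    h = _mix64(canon)
    if nk <= w:
        best = int(np.argmin(h))
        return h[best:best + 1], np.array([best]), strand[best:best + 1]
    # sliding-window minimum over w consecutive kmer hashes
    nw = nk - w + 1
    stacked = np.lib.stride_tricks.sliding_window_view(h, w)
    arg = stacked.argmin(axis=1) + np.arange(nw)
    sel = np.unique(arg)
    return h[sel], sel, strand[sel]


def compute_overlaps(
    reads: Sequence[Read],
    k: int = 15,
    w: int = 5,
    min_chain: int = 4,
    max_occ: int = 120,
    diag_band: int = 500,
) -> List[OverlapRecord]:
    """Detect pairwise overlaps from shared minimizers.

    For every read pair sharing ``min_chain`` or more minimizers on one
    relative strand within ``diag_band`` of the pair's median diagonal, one
    record is emitted (the lower read index as query), spanning the
    clustered seed matches.  Seeds occurring in more than ``max_occ`` reads
    are treated as repetitive and skipped.
    """
    if not (2 <= k <= 28):
        raise ValueError("k must be in [2, 28]")
    n_reads = len(reads)
    all_h, all_r, all_p, all_s = [], [], [], []
    for ri, read in enumerate(reads):
        h, p, s = _minimizers(_encode(read.seq), k, w)
        all_h.append(h)
        all_r.append(np.full(p.size, ri, dtype=np.int64))
        all_p.append(p)
        all_s.append(s)
    h = np.concatenate(all_h)
    r = np.concatenate(all_r)
    p = np.concatenate(all_p)
    s = np.concatenate(all_s)
    order = np.argsort(h, kind="stable")
    h, r, p, s = h[order], r[order], p[order], s[order]
    bounds = np.flatnonzero(np.r_[True, h[1:] != h[:-1], True])

    pair_q, pair_t, rel, qpos, tpos = [], [], [], [], []
    for bi in range(bounds.size - 1):
        lo, hi = bounds[bi], bounds[bi + 1]
        sz = hi - lo
        if sz < 2 or sz > max_occ:
            continue
        rr, pp, ss = r[lo:hi], p[lo:hi], s[lo:hi]
        ii, jj = np.triu_indices(sz, k=1)
        keep = rr[ii] != rr[jj]
        if not keep.any():
            continue
        ii, jj = ii[keep], jj[keep]
        # orient each pair so the smaller read index is the query
        flip = rr[ii] > rr[jj]
        qi = np.where(flip, jj, ii)
        ti = np.where(flip, ii, jj)
        pair_q.append(rr[qi])
        pair_t.append(rr[ti])
        rel.append(ss[qi] ^ ss[ti])
        qpos.append(pp[qi])
        tpos.append(pp[ti])
    if not pair_q:
        return []
    pair_q = np.concatenate(pair_q)
    pair_t = np.concatenate(pair_t)
    rel = np.concatenate(rel)
    qpos = np.concatenate(qpos)
    tpos = np.concatenate(tpos)

    key = (pair_q * n_reads + pair_t) * 2 + rel
    order = np.argsort(key, kind="stable")
    key, pair_q, pair_t, rel = key[order], pair_q[order], pair_t[order], rel[order]
    qpos, tpos = qpos[order], tpos[order]
    bounds = np.flatnonzero(np.r_[True, key[1:] != key[:-1], True])

    out: List[OverlapRecord] = []
    for bi in range(bounds.size - 1):
        lo, hi = bounds[bi], bounds[bi + 1]
        if hi - lo < min_chain:
            continue
        qp, tp = qpos[lo:hi], tpos[lo:hi]
        strand = rel[lo]
        diag = qp - tp if strand == 0 else qp + tp
        keep = np.abs(diag - np.median(diag)) <= diag_band
        if keep.sum() < min_chain:
            continue
        qp, tp = qp[keep], tp[keep]
        qi, ti = int(pair_q[lo]), int(pair_t[lo])
        qread, tread = reads[qi], reads[ti]
        qlen, tlen = len(qread), len(tread)
        qs, qe = int(qp.min()), int(qp.max()) + k
        ts, te = int(tp.min()), int(tp.max()) + k
        # extend the seed-anchored span toward the read ends (dovetail
        # extension): true overlaps continue past the outermost seeds.
        # Capped so that genuine internal matches keep their overhangs.
        cap = 200
        if strand == 0:
            ext = min(qs, ts, cap)
            qs, ts = qs - ext, ts - ext
            ext = min(qlen - qe, tlen - te, cap)
            qe, te = qe + ext, te + ext
        else:
            ext = min(qs, tlen - te, cap)
            qs, te = qs - ext, te + ext
            ext = min(qlen - qe, ts, cap)
            qe, ts = qe + ext, ts - ext
        out.append(OverlapRecord(
            qid=qread.id, qlen=qlen, qstart=qs, qend=qe,
            strand="+" if strand == 0 else "-",
            tid=tread.id, tlen=tlen, tstart=ts, tend=te,
            nmatch=int(keep.sum()) * k,
            blocklen=max(qe - qs, te - ts),
        ))
    out.sort(key=lambda o: o.key())
    return out


# ---------------------------------------------------------------------------
# filtering

def _is_internal_match(ov: OverlapRecord, cfg: OverlapFilterConfig) -> bool:
    # overhang heuristic for internal (repeat-induced) matches
    if ov.strand == "+":
        overhang = min(ov.qstart, ov.tstart) + \
            min(ov.qlen - ov.qend, ov.tlen - ov.tend)
    else:
        overhang = min(ov.qstart, ov.tlen - ov.tend) + \
            min(ov.tstart, ov.qlen - ov.qend)
    maplen = max(ov.qspan, ov.tspan)
    return overhang > min(cfg.internal_match_overhang,
                          cfg.internal_match_ratio * maplen)


def filter_overlaps_cycle1(
    overlaps: Iterable[OverlapRecord],
    reads: Sequence[Read],
    cfg: OverlapFilterConfig = OverlapFilterConfig(),
) -> List[OverlapRecord]:
    """Apply the first-cycle overlap filters.

    Removes overlaps that (a) do not exceed ``min_len`` on either read,
    (b) are self-overlaps, (c) are internal matches, or (d) fail the
    length-ratio error test |1 - min(Lq,Lt)/max(Lq,Lt)| >= e.
    """
    known = {r.id for r in reads}
    kept = []
    for ov in overlaps:
        if ov.qid not in known or ov.tid not in known:
            raise ValueError(f"overlap references unknown read {ov.qid}/{ov.tid}")
        if min(ov.qspan, ov.tspan) <= cfg.min_len:
            continue
        if ov.qid == ov.tid:
            continue
        if _is_internal_match(ov, cfg):
            continue
        ratio_err = abs(1.0 - min(ov.qspan, ov.tspan) / max(ov.qspan, ov.tspan))
        if ratio_err >= cfg.max_len_ratio_err:
            continue
        kept.append(ov)
    return kept


def compute_overlap_identity(
    ov: OverlapRecord, reads_by_id: Dict[str, Read]
) -> OverlapRecord:
    """Attach base-level identity from a global alignment of the mapped substrings.

    Identity = matching columns / total alignment columns; the query
    substring is reverse-complemented for minus-strand overlaps.
    """
    qseq = reads_by_id[ov.qid].seq[ov.qstart:ov.qend]
    tseq = reads_by_id[ov.tid].seq[ov.tstart:ov.tend]
    if not qseq or not tseq:
        raise ValueError(f"empty mapped substring in overlap {ov.qid}-{ov.tid}")
    if ov.strand == "-":
        qseq = revcomp(qseq)
    res = edlib.align(qseq, tseq, task="path", mode="NW")
    cols = sum(n for n, _ in _iter_cigar(res["cigar"]))
    identity = 1.0 - res["editDistance"] / cols
    return replace(ov, identity=identity,
                   nmatch=cols - res["editDistance"], blocklen=cols)


def filter_overlaps_cycle2(
    overlaps: Iterable[OverlapRecord],
    reads: Sequence[Read],
    cfg: OverlapFilterConfig,
) -> List[OverlapRecord]:
    """Second-cycle filter: all cycle-1 criteria plus identity >= delta."""
    if cfg.min_identity is None:
        raise ValueError("cycle-2 filtering requires cfg.min_identity (delta)")
    kept = []
    for ov in filter_overlaps_cycle1(overlaps, reads, cfg):
        if ov.identity is None:
            raise ValueError(
                f"overlap {ov.qid}-{ov.tid} lacks identity; run "
                "compute_overlap_identity first")
        if ov.identity >= cfg.min_identity:
            kept.append(ov)
    return kept
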