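"""Two-cycle correction pipeline.

Cycle 1 (error removal): all-vs-all overlaps -> overlap filters -> per-target
alignment pile -> 500-bp windows -> per-window variation graph ->
Support/Confidence pruning with realignment -> optimal-path extraction of
the target subread -> concatenation.  The pre-corrected reads of all
targets are merged and fed to cycle 2.

Cycle 2 (haplotype-pure consensus): overlaps are recomputed with base-level
identity and additionally filtered at identity >= delta, so that window
piles contain same-haplotype reads only; each window graph then yields a
single heaviest-bundle consensus instead of iterative pruning.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .graph import AlignScoring, heaviest_bundle, poa_build
from .io import OverlapRecord, Read
from .overlap import (OverlapFilterConfig, compute_overlap_identity,
                      compute_overlaps, filter_overlaps_cycle1,
                      filter_overlaps_cycle2)
from .pile import WindowInstance, build_pile, segment_windows
from .pruning import (PruneConfig, compute_stats, correct_subread,
                      prune_iterative)

logger = logging.getLogger(__name__)

#: cycle-2 identity threshold presets: delta = 1 - 2 x expected residual
#: error after cycle 1 (~0.5% on simulated data, slightly more on real data)
DELTA_PRESETS = {"simulated": 0.99, "real": 0.98}


@dataclass
class RunConfig:
    """End-to-end pipeline parameters (defaults follow the method)."""

    window_len: int = 500
    scoring: AlignScoring = field(default_factory=AlignScoring)
    prune: PruneConfig = field(default_factory=PruneConfig)
    overlap1: OverlapFilterConfig = field(default_factory=OverlapFilterConfig)
    overlap2: OverlapFilterConfig = field(
        default_factory=lambda: OverlapFilterConfig(min_identity=0.99))
    k: int = 15
    w: int = 5
    min_chain: int = 4
    max_occ: int = 120
    min_window_reads: int = 4
    min_frag_len: int = 50
    max_frags: int = 200
    band: int = 75
    consolidate: bool = False
    min_out_len: int = 500
    drop_uncorrected: bool = False
    threads: int = 1
    seed: int = 0

    @classmethod
    def preset(cls, data_type: str = "simulated", **kwargs) -> "RunConfig":
        delta = DELTA_PRESETS[data_type]
        cfg = cls(**kwargs)
        cfg.overlap2 = replace(cfg.overlap2, min_identity=delta)
        return cfg


@dataclass
class CorrectionResult:
    reads: List[Read]
    cycle1_reads: List[Read]
    counters: Dict[str, int]


def _overlaps_by_read(overlaps: Sequence[OverlapRecord]) -> Dict[str, List[OverlapRecord]]:
    by_read: Dict[str, List[OverlapRecord]] = {}
    for ov in overlaps:
        by_read.setdefault(ov.qid, []).append(ov)
        by_read.setdefault(ov.tid, []).append(ov)
    return by_read


def _correct_window_cycle1(win: WindowInstance, cfg: RunConfig) -> Tuple[str, bool]:
    if len(win.fragments) < cfg.min_window_reads or not win.target_subread:
        return win.target_subread, False
    seqs = [("__target__", win.target_subread, win.target_subquals, 0)]
    seqs += [(f.read_id, f.seq, f.quals, f.offset) for f in win.fragments]
    graph = poa_build(seqs, cfg.scoring, band=cfg.band)
    pcfg = replace(cfg.prune, L=max(1, len(win.target_subread)))
    prune_iterative(graph, seqs, cfg.scoring, pcfg, band=cfg.band,
                    realign_first=cfg.consolidate)
    return correct_subread(graph, win.target_subread, win.target_subquals,
                           cfg.scoring, band=cfg.band)


def _correct_window_cycle2(win: WindowInstance, cfg: RunConfig) -> Tuple[str, bool]:
    if len(win.fragments) < cfg.min_window_reads or not win.target_subread:
        return win.target_subread, False
    seqs = [("__target__", win.target_subread, None, 0)]
    seqs += [(f.read_id, f.seq, None, f.offset) for f in win.fragments]
    graph = poa_build(seqs, cfg.scoring, band=cfg.band)
    stats = compute_stats(graph)
    consensus = heaviest_bundle(graph, stats.edge_weight_dict())
    if not consensus:
        return win.target_subread, False
    return consensus, True


def _correct_target(target: Read, overlaps: Sequence[OverlapRecord],
                    reads_by_id: Dict[str, Read], cfg: RunConfig,
                    cycle: int,
                    identity_rank: Optional[Dict[str, float]] = None
                    ) -> Tuple[Read, int, int]:
    """Correct one target read; returns (read, windows corrected, windows skipped)."""
    pile = build_pile(target, overlaps, reads_by_id)
    windows = segment_windows(target, pile, cfg.window_len,
                              cfg.min_frag_len, cfg.max_frags)
    if identity_rank:
        for win in windows:
            win.fragments.sort(
                key=lambda f: (-identity_rank.get(f.read_id, 0.0), f.read_id))
    parts: List[str] = []
    n_ok = n_skip = 0
    for win in windows:
        if cycle == 1:
            seq, ok = _correct_window_cycle1(win, cfg)
        else:
            seq, ok = _correct_window_cycle2(win, cfg)
        parts.append(seq)
        if ok:
            n_ok += 1
        else:
            n_skip += 1
    return Read(id=target.id, seq="".join(parts)), n_ok, n_skip


def _run_cycle(reads: Sequence[Read], cfg: RunConfig, cycle: int,
               targets: Optional[Sequence[str]] = None,
               overlaps: Optional[Sequence[OverlapRecord]] = None
               ) -> Tuple[List[Read], Dict[str, int]]:
    reads_by_id = {r.id: r for r in reads}
    if overlaps is None:
        overlaps = compute_overlaps(reads, k=cfg.k, w=cfg.w,
                                    min_chain=cfg.min_chain, max_occ=cfg.max_occ)
    if cycle == 1:
        overlaps = filter_overlaps_cycle1(overlaps, reads, cfg.overlap1)
    else:
        overlaps = filter_overlaps_cycle1(overlaps, reads, cfg.overlap2)
        overlaps = [compute_overlap_identity(ov, reads_by_id) for ov in overlaps]
        overlaps = filter_overlaps_cycle2(overlaps, reads, cfg.overlap2)
    by_read = _overlaps_by_read(overlaps)
    target_ids = list(targets) if targets is not None else [r.id for r in reads]
    counters = {"targets": len(target_ids), "no_overlap": 0,
                "windows_corrected": 0, "windows_skipped": 0}
    uncorrected_ids: set = set()

    def work(tid: str) -> Read:
        target = reads_by_id[tid]
        tovs = by_read.get(tid, [])
        if not tovs:
            counters["no_overlap"] += 1
            uncorrected_ids.add(tid)
            return Read(id=target.id, seq=target.seq)
        identity_rank = None
        if cycle == 2:
            identity_rank = {}
            for ov in tovs:
                other = ov.tid if ov.qid == tid else ov.qid
                ident = ov.identity or 0.0
                if ident > identity_rank.get(other, 0.0):
                    identity_rank[other] = ident
        out, n_ok, n_skip = _correct_target(target, tovs, reads_by_id, cfg,
                                            cycle, identity_rank)
        counters["windows_corrected"] += n_ok
        counters["windows_skipped"] += n_skip
        return out

    if cfg.threads > 1:
        with ThreadPoolExecutor(max_workers=cfg.threads) as pool:
            out_reads = list(pool.map(work, target_ids))
    else:
        out_reads = [work(tid) for tid in target_ids]
    return out_reads, counters, uncorrected_ids


def run_cycle1(reads: Sequence[Read], cfg: Optional[RunConfig] = None,
               targets: Optional[Sequence[str]] = None,
               overlaps: Optional[Sequence[OverlapRecord]] = None
               ) -> Tuple[List[Read], Dict[str, int]]:
    """First correction cycle: iterative graph pruning per window."""
    cfg = cfg if cfg is not None else RunConfig()
    if len(reads) < 2:
        raise ValueError("need at least 2 reads to correct")
    out, counters, _ = _run_cycle(reads, cfg, cycle=1, targets=targets,
                                  overlaps=overlaps)
    return out, counters


def run_cycle2(pre_corrected: Sequence[Read], cfg: Optional[RunConfig] = None,
               overlaps: Optional[Sequence[OverlapRecord]] = None
               ) -> Tuple[List[Read], Dict[str, int]]:
    """Second cycle: identity-filtered overlaps, heaviest-bundle consensus."""
    cfg = cfg if cfg is not None else RunConfig()
    if not pre_corrected:
        raise ValueError("cycle 2 requires a nonempty pre-corrected read set")
    out, counters, _ = _run_cycle(pre_corrected, cfg, cycle=2, overlaps=overlaps)
    return out, counters


def correct(reads: Sequence[Read], cfg: Optional[RunConfig] = None,
            targets: Optional[Sequence[str]] = None) -> CorrectionResult:
    """Run both cycles end-to-end.

    ``targets`` limits which reads are corrected (all reads still
    contribute to the piles); corrected reads shorter than
    ``cfg.min_out_len`` are dropped from the final output.
    """
    cfg = cfg if cfg is not None else RunConfig()
    if not reads:
        logger.warning("empty input read set")
        return CorrectionResult(reads=[], cycle1_reads=[], counters={})
    pre, c1_counters, unc1 = _run_cycle(reads, cfg, cycle=1, targets=targets)
    final, c2_counters, unc2 = _run_cycle(pre, cfg, cycle=2)
    counters = {f"cycle1_{k}": v for k, v in c1_counters.items()}
    counters.update({f"cycle2_{k}": v for k, v in c2_counters.items()})
    never_corrected = unc1 & unc2
    kept: List[Read] = []
    n_short = n_unc = 0
    for r in final:
        if len(r.seq) < cfg.min_out_len:
            n_short += 1
            continue
        if cfg.drop_uncorrected and r.id in never_corrected:
            n_unc += 1
            continue
        kept.append(r)
    counters["dropped_short"] = n_short
    counters["dropped_uncorrected"] = n_unc
    return CorrectionResult(reads=kept, cycle1_reads=pre, counters=counters)
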