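"""Evaluate (corrected) reads against truth haplotypes.

Each read is aligned end-to-end (free ends on the haplotype, i.e. infix
alignment) against every haplotype on both strands; the best-scoring
alignment defines its mismatch/insertion/deletion counts.  The aggregate
error rate is (mismatches + insertions + deletions) / alignment columns,
i.e. mismatch rate + indel rate.  Haplotype coverage is the fraction of
truth bases covered by at least one aligned read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np
import pandas as pd

from .io import Read, revcomp
from .simulate import HaplotypeSet, _iter_cigar, snp_loci

#: a read whose best normalized edit distance exceeds this is "unalignable"
MAX_NORM_DIST = 0.40


@dataclass
class EvalReport:
    n_reads: int
    n_unaligned: int
    error_rate: float
    mismatch_rate: float
    indel_rate: float
    haplotype_coverage: float
    per_read: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]

    def summary(self) -> Dict[str, float]:
        return {
            "n_reads": self.n_reads,
            "n_unaligned": self.n_unaligned,
            "error_rate_pct": 100.0 * self.error_rate,
            "mismatch_rate_pct": 100.0 * self.mismatch_rate,
            "indel_rate_pct": 100.0 * self.indel_rate,
            "haplotype_coverage_pct": 100.0 * self.haplotype_coverage,
        }


def _best_alignment(seq: str, haps: HaplotypeSet):
    """Best infix alignment of ``seq`` over all haplotypes and strands."""
    best = None
    for hi, (name, hseq) in enumerate(haps.haplotypes):
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            res = edlib.align(s, hseq, task="distance", mode="HW")
            d = res["editDistance"]
            if best is None or d < best[0]:
                best = (d, name, hseq, strand, s)
    d, name, hseq, strand, s = best
    res = edlib.align(s, hseq, task="path", mode="HW")
    return name, strand, res


def evaluate_corrected(reads: Sequence[Read], haps: HaplotypeSet) -> EvalReport:
    """Score a read set against truth haplotypes.

    Reads whose best normalized distance exceeds ``MAX_NORM_DIST`` are
    counted as unaligned and excluded from the rate aggregation.
    """
    rows = []
    cover: Dict[str, List[Tuple[int, int]]] = {n: [] for n in haps.names()}
    n_unaligned = 0
    for read in reads:
        if not read.seq:
            n_unaligned += 1
            continue
        name, strand, res = _best_alignment(read.seq, haps)
        if res["editDistance"] / max(1, len(read.seq)) > MAX_NORM_DIST:
            n_unaligned += 1
            continue
        nmatch = nmis = nins = ndel = 0
        for n, op in _iter_cigar(res["cigar"]):
            if op == "=":
                nmatch += n
            elif op == "X":
                nmis += n
            elif op == "I":
                nins += n
            elif op == "D":
                ndel += n
        tstart, tend_incl = res["locations"][0]
        cover[name].append((tstart, tend_incl + 1))
        cols = nmatch + nmis + nins + ndel
        rows.append({
            "id": read.id, "haplotype": name, "strand": strand,
            "aligned_len": cols, "matches": nmatch, "mismatches": nmis,
            "insertions": nins, "deletions": ndel,
        })
    per_read = pd.DataFrame(rows)
    if rows:
        tot_cols = per_read["aligned_len"].sum()
        mism = per_read["mismatches"].sum() / tot_cols
        indel = (per_read["insertions"].sum() + per_read["deletions"].sum()) / tot_cols
    else:
        mism = indel = float("nan")
    hap_cov = _coverage_fraction(cover, haps)
    return EvalReport(
        n_reads=len(rows),
        n_unaligned=n_unaligned,
        error_rate=mism + indel,
        mismatch_rate=mism,
        indel_rate=indel,
        haplotype_coverage=hap_cov,
        per_read=per_read,
    )


def _coverage_fraction(cover: Dict[str, List[Tuple[int, int]]],
                       haps: HaplotypeSet) -> float:
    covered = total = 0
    for name, hseq in haps.haplotypes:
        total += len(hseq)
        ivals = sorted(cover[name])
        end = -1
        for s, e in ivals:
            if s > end:
                covered += e - s
                end = e
            elif e > end:
                covered += e - end
                end = e
    return covered / total if total else float("nan")


def snp_concordance(
    corrected: Sequence[Read],
    haps: HaplotypeSet,
    truth: Dict[str, Tuple[str, int, int, str]],
) -> Tuple[float, int, int]:
    """Fraction of reads carrying their origin allele at every spanned SNP.

    ``truth`` maps read id -> (haplotype, start, end, strand) on the truth
    haplotype.  Only substitution loci between the first two haplotypes are
    scored (the diploid harness).  Returns (fraction, n_perfect, n_scored);
    reads spanning no SNP are not scored.
    """
    loci = snp_loci(haps, 0, 1)
    n_perfect = n_scored = 0
    for read in corrected:
        if read.id not in truth or not read.seq:
            continue
        hap, start, end, strand = truth[read.id]
        if hap not in loci:
            continue
        hseq = haps.seq(hap)
        seq = read.seq if strand == "+" else revcomp(read.seq)
        pad = 100
        ws, we = max(0, start - pad), min(len(hseq), end + pad)
        res = edlib.align(seq, hseq[ws:we], task="path", mode="HW")
        # map haplotype positions (within the aligned span) to read bases
        t0 = ws + res["locations"][0][0]
        t1 = ws + res["locations"][0][1] + 1
        base_at = _target_to_query_base(res["cigar"], seq, t0)
        spanned = [(p, a) for p, a in loci[hap] if t0 <= p < t1]
        if not spanned:
            continue
        n_scored += 1
        if all(base_at.get(p) == a for p, a in spanned):
            n_perfect += 1
    frac = n_perfect / n_scored if n_scored else float("nan")
    return frac, n_perfect, n_scored


def _target_to_query_base(cigar: str, query: str, t0: int) -> Dict[int, str]:
    """For each target position consumed by the alignment, the aligned query base
    (absent for deletions)."""
    out: Dict[int, str] = {}
    qi, ti = 0, t0
    for n, op in _iter_cigar(cigar):
        if op in "=X":
            for k in range(n):
                out[ti + k] = query[qi + k]
            qi += n
            ti += n
        elif op == "I":
            qi += n
        elif op == "D":
            ti += n
    return out
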