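"""Synthetic haplotype mixtures and error-laden long reads.

The generator emulates the study design of mixed-strain / polyploid
long-read sequencing: a handful of closely related haplotypes (ANI in the
96-99% range, i.e. 1-4% pairwise divergence), sampled at ~30x coverage per
haplotype with reads of several kbp carrying ~10% errors dominated by
indels, as is typical for PacBio CLR chemistry.

Haplotypes are produced by mutating a random ancestor: ~90% of mutation
events are substitutions and ~10% short indels (<=3 bp), reflecting that
strain divergence is substitution-dominated.  Sequencing errors are placed
i.i.d. per base with a configurable mismatch:insertion:deletion mix
(default 25:35:40, indel-dominant).  Both models are deliberately simple
and homopolymer-blind; see docs/methods.md for what this does and does not
emulate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .io import Read, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    res = edlib.align(a, b, task="distance", mode="NW")
    dist = res["editDistance"]
    # columns >= max(len); use the exact column count from the path
    res = edlib.align(a, b, task="path", mode="NW")
    cols = sum(int(n) for n, op in _iter_cigar(res["cigar"]))
    return 1.0 - dist / cols


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


@dataclass
class HaplotypeSet:
    """An ordered collection of named haplotype sequences."""

    haplotypes: List[Tuple[str, str]]
    pairwise_ani: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pairwise_ani is None:
            k = len(self.haplotypes)
            ani = np.eye(k)
            for i in range(k):
                for j in range(i + 1, k):
                    ani[i, j] = ani[j, i] = alignment_identity(
                        self.haplotypes[i][1], self.haplotypes[j][1]
                    )
            self.pairwise_ani = ani

    def names(self) -> List[str]:
        return [name for name, _ in self.haplotypes]

    def seq(self, name: str) -> str:
        for n, s in self.haplotypes:
            if n == name:
                return s
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.haplotypes)


@dataclass
class SimConfig:
    """Read-simulation parameters.

    ``error_mix`` is (mismatch, insertion, deletion) fractions of injected
    errors; the default 25:35:40 mimics CLR-like indel dominance.  Every
    emitted base gets the same Phred score Q = -10*log10(error_rate).
    """

    coverage_per_hap: float = 30.0
    error_rate: float = 0.10
    error_mix: Tuple[float, float, float] = (0.25, 0.35, 0.40)
    read_len_mean: float = 10000.0
    read_len_sd: float = 3000.0
    min_read_len: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.3):
            raise ValueError("error_rate must be in [0, 0.3]")
        if self.coverage_per_hap <= 0:
            raise ValueError("coverage_per_hap must be positive")
        mix = self.error_mix
        if any(m < 0 for m in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("error_mix must be nonnegative and sum to 1")


def generate_haplotypes(
    ancestor_len: int,
    ploidy: int,
    target_ani: float,
    seed: int,
    sub_frac: float = 0.9,
    max_indel: int = 3,
) -> HaplotypeSet:
    """Generate ``ploidy`` haplotypes around ``target_ani`` pairwise identity.

    Each haplotype receives an independent edit budget of
    ``ancestor_len * (1 - target_ani) / 2`` edited bases relative to a random
    ancestor, so that any two haplotypes diverge by ~``1 - target_ani``.
    """
    if ancestor_len < 1000:
        raise ValueError("ancestor_len must be >= 1000")
    if not (0.9 <= target_ani < 1.0):
        raise ValueError("target_ani must be in [0.9, 1.0); identical haplotypes "
                         "carry no variation to preserve")
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    rng = np.random.default_rng(seed)
    ancestor = _rand_seq(rng, ancestor_len)
    budget = ancestor_len * (1.0 - target_ani) / 2.0
    haps: List[Tuple[str, str]] = []
    for h in range(ploidy):
        seq = _mutate(rng, ancestor, budget, sub_frac, max_indel)
        haps.append((f"hap{h + 1}", seq))
    hs = HaplotypeSet(haps)
    return hs


def _mutate(rng: np.random.Generator, seq: str, edit_budget: float,
            sub_frac: float, max_indel: int) -> str:
    """Apply random mutation events totalling ~``edit_budget`` edited bases."""
    arr = list(seq)
    n = len(arr)
    events: List[Tuple[int, int, str]] = []  # (pos, kind, payload)
    used = 0.0
    taken = set()
    while used < edit_budget:
        pos = int(rng.integers(0, n))
        if pos in taken:
            continue
        taken.add(pos)
        if rng.random() < sub_frac:
            events.append((pos, 0, ""))
            used += 1
        else:
            ln = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:
                events.append((pos, 1, _rand_seq(rng, ln)))  # insertion
            else:
                events.append((pos, 2, str(ln)))  # deletion
            used += ln
    # apply right-to-left so positions stay valid
    for pos, kind, payload in sorted(events, reverse=True):
        if kind == 0:
            old = arr[pos]
            choices = [b for b in "ACGT" if b != old]
            arr[pos] = choices[int(rng.integers(0, 3))]
        elif kind == 1:
            arr[pos] = arr[pos] + payload
        else:
            ln = int(payload)
            for k in range(pos, min(pos + ln, n)):
                arr[k] = ""
    return "".join(arr)


def simulate_reads(haps: HaplotypeSet, cfg: SimConfig) -> List[Read]:
    """Simulate error-laden reads independently from each haplotype.

    The number of reads per haplotype is Poisson with mean
    ``coverage * len / read_len_mean``; starts are uniform, lengths Normal
    truncated to [min_read_len, haplotype length], strands equiprobable.
    Truth metadata (haplotype, interval, strand) is attached to every read.
    """
    rng = np.random.default_rng(cfg.seed)
    mis, ins, dele = cfg.error_mix
    if cfg.error_rate > 0:
        q = int(round(-10.0 * math.log10(cfg.error_rate)))
    else:
        q = 90
    reads: List[Read] = []
    idx = 0
    for name, hseq in haps.haplotypes:
        L = len(hseq)
        n_reads = int(rng.poisson(cfg.coverage_per_hap * L / cfg.read_len_mean))
        for _ in range(n_reads):
            ln = int(round(rng.normal(cfg.read_len_mean, cfg.read_len_sd)))
            ln = max(cfg.min_read_len, min(ln, L))
            start = int(rng.integers(0, L - ln + 1))
            template = hseq[start:start + ln]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                template = revcomp(template)
            seq = _inject_errors(rng, template, cfg.error_rate, mis, ins, dele)
            reads.append(Read(
                id=f"r{idx:05d}",
                seq=seq,
                quals=[q] * len(seq),
                truth_hap=name,
                truth_start=start,
                truth_end=start + ln,
                truth_strand=strand,
            ))
            idx += 1
    return reads


def _inject_errors(rng: np.random.Generator, template: str, rate: float,
                   mis: float, ins: float, dele: float) -> str:
    if rate <= 0:
        return template
    n = len(template)
    err_pos = np.nonzero(rng.random(n) < rate)[0]
    if err_pos.size == 0:
        return template
    kinds = rng.choice(3, size=err_pos.size, p=[mis, ins, dele])
    out = []
    prev = 0
    for pos, kind in zip(err_pos.tolist(), kinds.tolist()):
        out.append(template[prev:pos])
        base = template[pos]
        if kind == 0:  # mismatch
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(0, 3))])
        elif kind == 1:  # insertion after the base
            out.append(base)
            out.append("ACGT"[int(rng.integers(0, 4))])
        # kind == 2: deletion, emit nothing
        prev = pos + 1
    out.append(template[prev:])
    return "".join(out)


def truth_table(reads: Sequence[Read]) -> List[Tuple[str, str, int, int, str]]:
    """(read id, haplotype, start, end, strand) rows for a truth TSV."""
    rows = []
    for r in reads:
        if r.truth_hap is None:
            raise ValueError(f"read {r.id} carries no truth metadata")
        rows.append((r.id, r.truth_hap, r.truth_start, r.truth_end, r.truth_strand))
    return rows


def write_truth_tsv(reads: Sequence[Read], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\thaplotype\tstart\tend\tstrand\n")
        for row in truth_table(reads):
            fh.write("\t".join(str(x) for x in row) + "\n")


def snp_loci(haps: HaplotypeSet, a: int = 0, b: int = 1) -> Dict[str, List[Tuple[int, str]]]:
    """Substitution loci between haplotypes ``a`` and ``b``.

    Aligns the two haplotypes globally and returns, for each haplotype, the
    list of (position, allele) pairs at aligned mismatch columns -- the
    truth SNPs that distinguish the pair.
    """
    name_a, seq_a = haps.haplotypes[a]
    name_b, seq_b = haps.haplotypes[b]
    res = edlib.align(seq_a, seq_b, task="path", mode="NW")
    ia = ib = 0
    loci_a: List[Tuple[int, str]] = []
    loci_b: List[Tuple[int, str]] = []
    for n, op in _iter_cigar(res["cigar"]):
        if op == "=":
            ia += n
            ib += n
        elif op == "X":
            for k in range(n):
                loci_a.append((ia + k, seq_a[ia + k]))
                loci_b.append((ib + k, seq_b[ib + k]))
            ia += n
            ib += n
        elif op == "I":  # base in seq_a only
            ia += n
        elif op == "D":  # base in seq_b only
            ib += n
    return {name_a: loci_a, name_b: loci_b}
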