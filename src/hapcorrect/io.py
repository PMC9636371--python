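"""Sequence and overlap I/O.

Reads and writes FASTA/FASTQ (via Biopython) and PAF overlap records
(minimap2 dialect, columns 1-12 plus optional tags), and converts Phred
quality scores to error probabilities.  All coordinates are 0-based,
half-open throughout the package; PAF is natively so.

The graph alphabet downstream is exactly {A, C, G, T}: any other letter
(N, IUPAC ambiguity codes, lowercase soft-masking) is uppercased and then
mapped to ``A`` deterministically; the number of replaced bases is counted
on the record so callers can log it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: deterministic replacement for letters outside the {A,C,G,T} alphabet
_NON_ACGT_FALLBACK = "A"


def sanitize_seq(seq: str) -> tuple[str, int]:
    """Uppercase ``seq`` and replace non-ACGT letters by ``A``.

    Returns the sanitized sequence and the number of replaced positions.
    """
    up = seq.upper()
    if all(ch in "ACGT" for ch in up):
        return up, 0
    out = []
    n_replaced = 0
    for ch in up:
        if ch in "ACGT":
            out.append(ch)
        else:
            out.append(_NON_ACGT_FALLBACK)
            n_replaced += 1
    return "".join(out), n_replaced


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A sequence record with optional Phred qualities and truth metadata.

    ``truth_hap`` / ``truth_start`` / ``truth_end`` / ``truth_strand`` are
    simulation-only metadata (haplotype of origin and interval on it); they
    are never consulted by the correction pipeline itself.
    """

    id: str
    seq: str
    quals: Optional[List[int]] = None
    truth_hap: Optional[str] = None
    truth_start: Optional[int] = None
    truth_end: Optional[int] = None
    truth_strand: Optional[str] = None
    n_sanitized: int = 0

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class OverlapRecord:
    """A pairwise overlap between two reads (PAF semantics).

    Coordinates are 0-based half-open on the forward strand of each read;
    for ``strand == '-'`` the reverse complement of the query maps to the
    target, with ``qstart``/``qend`` still given on the original query.
    """

    qid: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tid: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int = 0
    blocklen: int = 0
    identity: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.qstart < self.qend <= self.qlen):
            raise ValueError(f"bad query interval in overlap {self.qid}-{self.tid}")
        if not (0 <= self.tstart < self.tend <= self.tlen):
            raise ValueError(f"bad target interval in overlap {self.qid}-{self.tid}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.identity is not None and not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")

    @property
    def qspan(self) -> int:
        return self.qend - self.qstart

    @property
    def tspan(self) -> int:
        return self.tend - self.tstart

    def key(self) -> tuple:
        return (self.qid, self.tid, self.qstart, self.qend,
                self.tstart, self.tend, self.strand)


def phred_to_error_prob(q: float) -> float:
    """Error probability ``10**(-q/10)`` for a Phred score, clamped to [0,1]."""
    if q < 0:
        raise ValueError(f"negative Phred score: {q}")
    return min(1.0, 10.0 ** (-q / 10.0))


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna"}:
        return "fasta"
    # fall back on sniffing the first byte
    with open(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def read_sequences(path, fmt: str = "auto") -> List[Read]:
    """Load FASTA/FASTQ records as :class:`Read` objects.

    Non-ACGT letters are sanitized (see :func:`sanitize_seq`); the per-read
    replacement count is kept on ``Read.n_sanitized`` and totalled in a log
    message.  FASTQ qualities are Phred+33 as decoded by Biopython.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = _detect_format(path)
    if fmt not in {"fasta", "fastq"}:
        raise ValueError(f"unknown format {fmt!r}")
    reads: List[Read] = []
    seen = set()
    total_sanitized = 0
    for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
        seq, n_rep = sanitize_seq(str(rec.seq))
        total_sanitized += n_rep
        if rec.id in seen:
            raise ValueError(f"duplicate read id {rec.id!r} at record {i}")
        seen.add(rec.id)
        quals = None
        if fmt == "fastq":
            quals = list(rec.letter_annotations["phred_quality"])
        reads.append(Read(id=rec.id, seq=seq, quals=quals, n_sanitized=n_rep))
    if total_sanitized:
        logger.info("sanitized %d non-ACGT bases in %s", total_sanitized, path)
    return reads


def write_sequences(reads: Iterable[Read], path, fmt: str = "fasta") -> int:
    """Write reads to FASTA or FASTQ; empty sequences are skipped with a warning.

    Returns the number of records written.
    """
    path = Path(path)
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            if not read.seq:
                logger.warning("skipping empty read %r on output", read.id)
                continue
            if fmt == "fasta":
                fh.write(f">{read.id}\n{read.seq}\n")
            elif fmt == "fastq":
                quals = read.quals if read.quals is not None else [30] * len(read.seq)
                qstr = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{read.id}\n{read.seq}\n+\n{qstr}\n")
            else:
                raise ValueError(f"unknown format {fmt!r}")
            n += 1
    return n


def read_paf(path) -> List[OverlapRecord]:
    """Parse a PAF file (columns 1-12; extra tag columns are ignored)."""
    records: List[OverlapRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"PAF line {lineno}: expected >=12 columns, got {len(cols)}")
            try:
                rec = OverlapRecord(
                    qid=cols[0], qlen=int(cols[1]),
                    qstart=int(cols[2]), qend=int(cols[3]),
                    strand=cols[4],
                    tid=cols[5], tlen=int(cols[6]),
                    tstart=int(cols[7]), tend=int(cols[8]),
                    nmatch=int(cols[9]), blocklen=int(cols[10]),
                )
            except ValueError as exc:
                raise ValueError(f"PAF line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_paf(overlaps: Iterable[OverlapRecord], path) -> None:
    """Write overlap records as 12-column PAF (mapping quality fixed at 255)."""
    with open(path, "w") as fh:
        for ov in overlaps:
            fh.write(
                "\t".join(str(x) for x in (
                    ov.qid, ov.qlen, ov.qstart, ov.qend, ov.strand,
                    ov.tid, ov.tlen, ov.tstart, ov.tend,
                    ov.nmatch, ov.blocklen, 255,
                )) + "\n"
            )


def paf_identity(ov: OverlapRecord) -> float:
    """Approximate identity from PAF columns, ``nmatch / blocklen``."""
    if ov.blocklen <= 0:
        raise ValueError("blocklen must be positive to derive identity")
    return ov.nmatch / ov.blocklen
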