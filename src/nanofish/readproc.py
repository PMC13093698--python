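"""Quality/length filtering, dual-barcode demultiplexing and primer trimming.

Read-level quality is aggregated on the error-probability scale (the mean of
``10^(-q/10)`` converted back to Phred), the convention of common Nanopore
filtering tools; the arithmetic mean of Phred values would overestimate
quality. Demultiplexing requires the *same* barcode found at both read ends,
which guards against between-sample chimeras formed during pooling.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import edlib

from .io import Read, revcomp
from .simulate import MIFISH_U_F, MIFISH_U_R

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    """Quality/length gate: Qscore strictly above ``min_qscore``, length
    within [min_len, max_len] (the window excludes off-target 16S products)."""

    min_qscore: float = 10.0
    min_len: int = 180
    max_len: int = 250

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_qscore < 0:
            raise ValueError("min_qscore must be >= 0")


@dataclass
class DemuxParams:
    barcodes: dict[str, str] = field(default_factory=dict)
    search_window: int = 150
    min_barcode_identity: float = 0.85

    def __post_init__(self) -> None:
        if self.barcodes:
            longest = max(len(b) for b in self.barcodes.values())
            if self.search_window < longest:
                raise ValueError("search_window shorter than longest barcode")
        if not 0.5 < self.min_barcode_identity <= 1:
            raise ValueError("min_barcode_identity must be in (0.5, 1]")


def mean_read_quality(read: Read) -> float:
    """Phred-scale read quality: −10·log10(mean per-base error probability)."""
    if not read.qualities:
        raise ValueError(f"read {read.read_id!r} is empty")
    mean_err = sum(10 ** (-q / 10) for q in read.qualities) / len(read.qualities)
    return -10.0 * math.log10(mean_err)


def filter_reads(
    reads: Iterable[Read], params: FilterParams | None = None
) -> tuple[list[Read], Counter]:
    """Apply the quality/length gate; returns kept reads and rejection tallies."""
    params = params or FilterParams()
    kept: list[Read] = []
    rejected: Counter = Counter()
    for read in reads:
        if len(read) < params.min_len:
            rejected["too_short"] += 1
        elif len(read) > params.max_len:
            rejected["too_long"] += 1
        elif mean_read_quality(read) <= params.min_qscore:
            rejected["low_quality"] += 1
        else:
            kept.append(read)
    return kept, rejected


def _best_barcode_hit(
    window: str, barcodes: dict[str, str], offset: int
) -> tuple[str | None, float, tuple[int, int] | None, bool]:
    """Best-identity barcode match (either orientation) within a window.

    Returns (barcode_id, identity, absolute half-open span, ambiguous).
    Identity is (len - edit distance) / len for the best infix alignment.
    """
    best_id, best_ident, best_span = None, -1.0, None
    ambiguous = False
    for bc_id, bc_seq in barcodes.items():
        for seq in (bc_seq, revcomp(bc_seq)):
            res = edlib.align(seq, window, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            ident = (len(seq) - res["editDistance"]) / len(seq)
            if ident > best_ident + 1e-12:
                start, end = res["locations"][0]
                best_id, best_ident = bc_id, ident
                best_span = (offset + start, offset + end + 1)
                ambiguous = False
            elif abs(ident - best_ident) <= 1e-12 and bc_id != best_id:
                ambiguous = True
    return best_id, best_ident, best_span, ambiguous


@dataclass
class DemuxResult:
    assigned: dict[str, list[Read]]
    discarded: dict[str, list[Read]]

    def counts(self) -> dict[str, int]:
        out = {k: len(v) for k, v in self.assigned.items()}
        out.update({f"discarded:{k}": len(v) for k, v in self.discarded.items()})
        return out


def demultiplex(
    reads: Iterable[Read],
    params: DemuxParams,
    sample_map: dict[str, str] | None = None,
) -> DemuxResult:
    """Assign reads to samples by identical barcodes at both ends.

    Each read end (first/last ``search_window`` bases) is searched for every
    barcode on both strands; a read is assigned only when both ends pass
    ``min_barcode_identity`` and agree on the barcode, and the barcode
    regions are trimmed off. Everything else lands in ``mismatched_pair``,
    ``unassigned`` or ``ambiguous`` bins.
    """
    if not params.barcodes:
        raise ValueError("no barcodes to demultiplex against")
    sample_map = sample_map or {bc: bc for bc in params.barcodes}
    result = DemuxResult(
        assigned={sample_map[bc]: [] for bc in params.barcodes},
        discarded={"unassigned": [], "mismatched_pair": [], "ambiguous": []},
    )
    w = params.search_window
    for n, read in enumerate(reads):
        if n and n % 100_000 == 0:
            logger.info("demultiplexed %d reads", n)
        seq = read.sequence
        front = seq[:w]
        rear_offset = max(0, len(seq) - w)
        rear = seq[rear_offset:]
        f_id, f_ident, f_span, f_amb = _best_barcode_hit(front, params.barcodes, 0)
        r_id, r_ident, r_span, r_amb = _best_barcode_hit(
            rear, params.barcodes, rear_offset
        )
        if f_amb or r_amb:
            result.discarded["ambiguous"].append(read)
            continue
        f_ok = f_id is not None and f_ident >= params.min_barcode_identity
        r_ok = r_id is not None and r_ident >= params.min_barcode_identity
        if not (f_ok and r_ok):
            result.discarded["unassigned"].append(read)
            continue
        if f_id != r_id:
            result.discarded["mismatched_pair"].append(read)
            continue
        start, end = f_span[1], r_span[0]
        if start >= end:
            result.discarded["unassigned"].append(read)
            continue
        sample_id = sample_map[f_id]
        result.assigned[sample_id].append(
            Read(
                read.read_id,
                seq[start:end],
                read.qualities[start:end],
                sample_id=sample_id,
                orientation=read.orientation,
            )
        )
    return result


def orient_and_trim_primers(
    read: Read,
    fwd_primer: str = MIFISH_U_F,
    rev_primer: str = MIFISH_U_R,
    max_mismatch: int = 3,
) -> tuple[Read | None, str]:
    """Locate the primer pair, reorient if needed, and return the insert.

    The forward primer is expected near the 5' end and the reverse complement
    of the reverse primer near the 3' end, each within ``max_mismatch`` edits;
    a read matching only on the reverse strand is reverse-complemented first.
    Returns (insert read with orientation="forward", "ok") or (None, reason).
    """
    rc_rev = revcomp(rev_primer)
    for attempt, (seq, quals) in enumerate(
        (
            (read.sequence, read.qualities),
            (revcomp(read.sequence), read.qualities[::-1]),
        )
    ):
        f = edlib.align(fwd_primer, seq, mode="HW", task="locations", k=max_mismatch)
        r = edlib.align(rc_rev, seq, mode="HW", task="locations", k=max_mismatch)
        if f["editDistance"] < 0 or r["editDistance"] < 0:
            continue
        f_end = f["locations"][0][1] + 1
        r_start = max(loc[0] for loc in r["locations"])
        if f_end >= r_start:
            continue
        return (
            Read(
                read.read_id,
                seq[f_end:r_start],
                quals[f_end:r_start],
                sample_id=read.sample_id,
                orientation="forward",
            ),
            "ok",
        )
    return None, "no_primer"


def trim_primers(
    reads: Iterable[Read],
    fwd_primer: str = MIFISH_U_F,
    rev_primer: str = MIFISH_U_R,
    max_mismatch: int = 3,
) -> tuple[list[Read], Counter]:
    """Batch wrapper over :func:`orient_and_trim_primers`."""
    kept: list[Read] = []
    rejected: Counter = Counter()
    for read in reads:
        insert, reason = orient_and_trim_primers(
            read, fwd_primer, rev_primer, max_mismatch
        )
        if insert is None:
            rejected[reason] += 1
        else:
            kept.append(insert)
    return kept, rejected
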