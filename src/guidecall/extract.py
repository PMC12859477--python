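"""Extraction of guide-capture reads into a deduplicated cell x guide UMI count matrix.

A read identifies a guide molecule when it contains both a library
protospacer and the constant capture sequence (CS1 by default, the anchor
appended to the gRNA scaffold for direct capture), each within a configurable
Hamming distance (default 1). Matching reads are sliced for cell barcode and
UMI per a configurable layout, barcodes are corrected against a whitelist,
and counts are the number of distinct UMIs per (cell, guide) after optional
directional collapse of sequencing-error UMIs.
"""

from __future__ import annotations

import gzip
import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io import BarcodeList, GuideCountMatrix, GuideLibrary

__all__ = [
    "CS1",
    "ReadLayout",
    "UmiRecord",
    "ExtractionReport",
    "hamming_find",
    "match_read",
    "correct_barcode",
    "count_guides",
    "extract_counts",
]

# Capture sequence 1: the constant anchor on direct-capture gRNA scaffolds
CS1 = "GCTTTAAGGCCGGTCCTAGCAA"

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadLayout:
    """Where in the FASTQ streams the barcode, UMI and protospacer live.

    Streams are named (e.g. "barcode", "read"); the same stream may carry
    several elements. Defaults reflect a direct-capture library on the 10x
    Multiome platform: 16 bp cell barcode at the start of its index read
    (extra cycles ignored), 12 bp UMI from the RT primer at the start of the
    guide read, and the protospacer + CS1 anchor searched anywhere in the
    guide read at up to ``d_max`` mismatches.
    """

    barcode_stream: str = "barcode"
    barcode_offset: int = 0
    barcode_length: int = 16
    umi_stream: str = "read"
    umi_offset: int = 0
    umi_length: int = 12
    protospacer_stream: str = "read"
    anchor: str = CS1
    d_max: int = 1
    barcode_reverse_complement: bool = False
    strict_layout: bool = False  # require protospacer immediately 5' of the anchor

    def __post_init__(self) -> None:
        if self.barcode_length <= 0 or self.umi_length <= 0:
            raise ValueError("barcode and UMI lengths must be positive")
        if self.d_max < 0:
            raise ValueError("d_max must be >= 0")
        bad = set(self.anchor) - _DNA
        if bad:
            raise ValueError(f"anchor contains non-ACGT characters: {sorted(bad)}")

    @property
    def stream_names(self) -> tuple[str, ...]:
        seen = dict.fromkeys((self.barcode_stream, self.umi_stream, self.protospacer_stream))
        return tuple(seen)


@dataclass(frozen=True)
class UmiRecord:
    """One matched read: captured cell barcode, identified guide, UMI."""

    cell_barcode: str
    guide_id: str
    umi: str


@dataclass
class ExtractionReport:
    """Tallies from one extraction run."""

    total_reads: int = 0
    matched_reads: int = 0
    barcode_corrected_reads: int = 0
    counted_reads: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "matched_reads": self.matched_reads,
            "barcode_corrected_reads": self.barcode_corrected_reads,
            "counted_reads": self.counted_reads,
            "dropped": dict(sorted(self.dropped.items())),
        }


def hamming_find(read: str, pattern: str, d_max: int) -> tuple[int, int] | None:
    """Leftmost alignment of ``pattern`` in ``read`` with <= ``d_max`` mismatches.

    Returns (position, mismatches) for the first (leftmost) offset whose
    Hamming distance is within ``d_max``, or None. Ambiguity characters (N)
    always count as mismatches. A pattern longer than the read never matches.
    """
    m, n = len(pattern), len(read)
    if m > n or m == 0:
        return None
    pos = read.find(pattern)  # exact occurrences located at C speed
    for i in range(n - m + 1):
        if pos != -1 and pos <= i:
            return (pos, 0)
        d = 0
        window = read[i : i + m]
        for a, b in zip(window, pattern):
            if a != b:
                d += 1
                if d > d_max:
                    break
        else:
            return (i, d)
    return None


def match_read(
    streams: dict[str, str],
    layout: ReadLayout,
    lib: GuideLibrary,
    _ps_map: dict[str, str] | None = None,
) -> tuple[UmiRecord | None, str | None]:
    """Match one read tuple against the library.

    A record is produced iff some protospacer AND the anchor each match the
    protospacer stream within ``layout.d_max``. Among multiply-matching
    protospacers the fewest-mismatch one wins; ties discard the read.

    Returns (record, drop_reason); exactly one of the two is None.
    """
    ps_map = lib.protospacer_map() if _ps_map is None else _ps_map
    ps_read = streams[layout.protospacer_stream]
    bc_read = streams[layout.barcode_stream]
    umi_read = streams[layout.umi_stream]
    if len(bc_read) < layout.barcode_offset + layout.barcode_length:
        return None, "read_too_short"
    if len(umi_read) < layout.umi_offset + layout.umi_length:
        return None, "read_too_short"

    anchor_hit = hamming_find(ps_read, layout.anchor, layout.d_max)
    if anchor_hit is None:
        return None, "no_anchor"

    if layout.strict_layout:
        # protospacer must sit immediately 5' of the anchor
        best_guide = None
        best_d = layout.d_max + 1
        tie = False
        for ps, guide_id in ps_map.items():
            start = anchor_hit[0] - len(ps)
            if start < 0:
                continue
            d = sum(a != b for a, b in zip(ps_read[start : anchor_hit[0]], ps))
            if d < best_d:
                best_guide, best_d, tie = guide_id, d, False
            elif d == best_d:
                tie = True
        if best_guide is None:
            return None, "no_protospacer"
        if tie:
            return None, "ambiguous_protospacer"
        bc = bc_read[layout.barcode_offset : layout.barcode_offset + layout.barcode_length]
        if layout.barcode_reverse_complement:
            bc = reverse_complement(bc)
        umi = umi_read[layout.umi_offset : layout.umi_offset + layout.umi_length]
        return UmiRecord(cell_barcode=bc, guide_id=best_guide, umi=umi), None

    # exact-containment fast path (C-speed substring search)
    exact = [g for ps, g in ps_map.items() if ps in ps_read]
    if len(exact) > 1:
        return None, "ambiguous_protospacer"
    if len(exact) == 1:
        best_guide, tie = exact[0], False
    else:
        best_guide = None
        best_d = layout.d_max + 1
        tie = False
        for ps, guide_id in ps_map.items():
            hit = hamming_find(ps_read, ps, layout.d_max)
            if hit is None:
                continue
            d = hit[1]
            if d < best_d:
                best_guide, best_d, tie = guide_id, d, False
            elif d == best_d:
                tie = True
    if best_guide is None:
        return None, "no_protospacer"
    if tie:
        return None, "ambiguous_protospacer"

    bc = bc_read[layout.barcode_offset : layout.barcode_offset + layout.barcode_length]
    if layout.barcode_reverse_complement:
        bc = reverse_complement(bc)
    umi = umi_read[layout.umi_offset : layout.umi_offset + layout.umi_length]
    return UmiRecord(cell_barcode=bc, guide_id=best_guide, umi=umi), None


def correct_barcode(bc: str, whitelist: BarcodeList) -> str | None:
    """Correct a captured barcode against the whitelist.

    Exact (post-translation) hits pass through; otherwise the unique
    whitelist barcode at Hamming distance 1 is returned, and ambiguity (two
    or more candidates) or no candidate yields None.
    """
    hit = whitelist.lookup(bc)
    if hit is not None:
        return hit
    candidate: str | None = None
    for i, base in enumerate(bc):
        for sub in "ACGT":
            if sub == base:
                continue
            neighbor = bc[:i] + sub + bc[i + 1 :]
            hit = whitelist.lookup(neighbor)
            if hit is not None:
                if candidate is not None and hit != candidate:
                    return None  # ambiguous
                candidate = hit
    return candidate


def _directional_collapse(umi_counts: Counter) -> int:
    """Number of UMI clusters after directional merge at Hamming distance 1.

    Higher-count UMIs absorb their distance-1 neighbours; ties absorb into
    the lexicographically smaller UMI.
    """
    # process in descending count, lexicographic tiebreak: every UMI is
    # absorbed by the first already-kept representative within distance 1
    ordered = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    kept: list[str] = []
    n_clusters = 0
    for umi in ordered:
        absorbed = False
        for rep in kept:
            if sum(a != b for a, b in zip(rep, umi)) <= 1:
                absorbed = True
                break
        if not absorbed:
            kept.append(umi)
            n_clusters += 1
    return n_clusters


def count_guides(
    records,
    cells: BarcodeList,
    lib: GuideLibrary,
    umi_collapse: str = "exact",
    report: ExtractionReport | None = None,
) -> tuple[GuideCountMatrix, ExtractionReport]:
    """Deduplicate UMI records into a cell x guide count matrix.

    ``exact`` counts distinct UMI strings per (cell, guide); ``directional``
    additionally merges UMIs within Hamming distance 1 into the
    higher-count UMI. Records whose barcode cannot be corrected to the
    whitelist are dropped.
    """
    if umi_collapse not in ("exact", "directional"):
        raise ValueError(f"unknown umi_collapse mode {umi_collapse!r}")
    report = report if report is not None else ExtractionReport()
    guide_index = {g: j for j, g in enumerate(lib.guide_ids)}
    cell_index = {b: i for i, b in enumerate(cells.barcodes)}

    per_pair: dict[tuple[int, int], Counter] = defaultdict(Counter)
    for rec in records:
        if rec.guide_id not in guide_index:
            raise KeyError(f"record guide {rec.guide_id!r} not in library")
        corrected = correct_barcode(rec.cell_barcode, cells)
        if corrected is None:
            report.drop("barcode_unmatched")
            continue
        if corrected != rec.cell_barcode:
            report.barcode_corrected_reads += 1
        per_pair[(cell_index[corrected], guide_index[rec.guide_id])][rec.umi] += 1
        report.counted_reads += 1

    rows, cols, data = [], [], []
    for (i, j), umis in per_pair.items():
        n = len(umis) if umi_collapse == "exact" else _directional_collapse(umis)
        rows.append(i)
        cols.append(j)
        data.append(n)
    mat = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(cells), lib.n_guides), dtype=np.int64
    )
    return GuideCountMatrix(mat, list(cells.barcodes), lib.guide_ids), report


def _fastq_reader(path: str | os.PathLike):
    """Yield sequences from a (gzipped) FASTQ file."""
    from Bio import SeqIO

    path = os.fspath(path)
    handle = gzip.open(path, "rt") if path.endswith(".gz") else open(path, "rt")
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            yield str(rec.seq)
    finally:
        handle.close()


def extract_counts(
    fastq_paths: dict[str, str | os.PathLike],
    layout: ReadLayout,
    lib: GuideLibrary,
    cells: BarcodeList,
    umi_collapse: str = "exact",
) -> tuple[GuideCountMatrix, ExtractionReport]:
    """Full pipeline: synchronized FASTQ streams -> UMI count matrix + report.

    ``fastq_paths`` maps each stream name the layout references to its FASTQ
    file; streams must be read-id synchronized (the usual R1/R2/I2 layout).
    """
    for name in layout.stream_names:
        if name not in fastq_paths:
            raise ValueError(f"layout references stream {name!r} with no FASTQ path")
    report = ExtractionReport()
    readers = {name: _fastq_reader(fastq_paths[name]) for name in layout.stream_names}
    ps_map = lib.protospacer_map()

    def record_stream():
        for seqs in zip(*readers.values()):
            streams = dict(zip(readers.keys(), seqs))
            report.total_reads += 1
            rec, reason = match_read(streams, layout, lib, _ps_map=ps_map)
            if rec is None:
                report.drop(reason)
                continue
            report.matched_reads += 1
            yield rec

    return count_guides(record_stream(), cells, lib, umi_collapse=umi_collapse, report=report)
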