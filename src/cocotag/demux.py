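"""Demultiplex combinatorially indexed reads into occupancy streams.

Input is a quadruple of FASTQ files in lockstep: genomic R1/R2 plus two
index reads I1/I2 carrying the Tn5-adapter and nanowell barcodes.  Each
read pair is routed to ``target1``/``target2``/``co1``/``co2`` by its
s5/s7 barcode combination and its header is rewritten to the cell barcode
``WELL+p5+p7`` so reads from the same physical cell share a barcode in
all four streams.  Keeping co1 and co2 as separate files preserves which
paired end of a co-occupancy fragment belongs to which target; for most
downstream work the two files are simply concatenated.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from cocotag.barcodes import STREAMS, UNASSIGNED, BarcodeScheme, assign_stream, cell_barcode, well_id


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Gzip-transparent text open (by suffix)."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (header, sequence, quality) records."""
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq_record(fh: IO[str], header: str, seq: str, qual: str) -> None:
    fh.write(f"@{header}\n{seq}\n+\n{qual}\n")


@dataclass
class DemuxSummary:
    """Per-stream and per-well read accounting."""

    stream_counts: Counter = field(default_factory=Counter)
    well_counts: Counter = field(default_factory=Counter)
    total: int = 0

    @property
    def assigned(self) -> int:
        return sum(self.stream_counts[s] for s in STREAMS)

    @property
    def assignment_rate(self) -> float:
        return self.assigned / self.total if self.total else 0.0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("section\tkey\tcount\n")
            fh.write(f"total\tall\t{self.total}\n")
            for s in (*STREAMS, UNASSIGNED):
                fh.write(f"stream\t{s}\t{self.stream_counts[s]}\n")
            for w, n in sorted(self.well_counts.items()):
                fh.write(f"well\t{w}\t{n}\n")


def assign_read(i1: str, i2: str, scheme: BarcodeScheme) -> tuple[str, str | None]:
    """Assign one read: returns (stream, cell_barcode or None)."""
    s5, s7, p5, p7 = scheme.parse_index_reads(i1, i2)
    if s5 is None or s7 is None or p5 is None or p7 is None:
        return UNASSIGNED, None
    stream = assign_stream(s5, s7)
    return stream, cell_barcode(well_id(s5, s7), p5, p7)


def demultiplex(
    r1: str | Path,
    r2: str | Path,
    i1: str | Path,
    i2: str | Path,
    scheme: BarcodeScheme,
    out_dir: str | Path,
    emit_unassigned: bool = False,
    gzip_output: bool = False,
) -> DemuxSummary:
    """Route read pairs into per-stream FASTQ files and rewrite barcodes.

    The output header of an assigned read is ``<cell_barcode>:<original id>``
    so the cell barcode leads the read name.  Raises ``ValueError`` with the
    record number if the four input files desynchronize.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"

    streams = list(STREAMS) + ([UNASSIGNED] if emit_unassigned else [])
    handles: dict[tuple[str, int], IO[str]] = {}
    for s in streams:
        for mate in (1, 2):
            handles[(s, mate)] = _open_text(out_dir / f"{s}_R{mate}{suffix}", "wt")

    summary = DemuxSummary()
    iters = [read_fastq(p) for p in (r1, r2, i1, i2)]
    try:
        n = 0
        while True:
            recs = []
            for it in iters:
                recs.append(next(it, None))
            live = [r is not None for r in recs]
            if not any(live):
                break
            if not all(live):
                raise ValueError(f"FASTQ inputs desynchronized at record {n + 1}")
            (h1, s1, q1), (h2, s2, q2), (_, seq_i1, _), (_, seq_i2, _) = recs
            n += 1
            summary.total += 1
            stream, barcode = assign_read(seq_i1, seq_i2, scheme)
            summary.stream_counts[stream] += 1
            if barcode is not None:
                summary.well_counts[barcode.split("+")[0]] += 1
                new1 = f"{barcode}:{h1.split()[0]}"
                new2 = f"{barcode}:{h2.split()[0]}"
            else:
                new1, new2 = h1.split()[0], h2.split()[0]
            if stream == UNASSIGNED and not emit_unassigned:
                continue
            write_fastq_record(handles[(stream, 1)], new1, s1, q1)
            write_fastq_record(handles[(stream, 2)], new2, s2, q2)
    finally:
        for fh in handles.values():
            fh.close()
    return summary
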