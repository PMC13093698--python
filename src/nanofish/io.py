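"""Core domain types and readers/writers for the formats the pipeline touches.

Sequences are stored uppercase over the alphabet {A, C, G, T, N}; ``U`` is
mapped to ``T`` on input and anything else is rejected at parse time.
Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
SAMPLE_TYPES = frozenset(
    {"environmental", "field_blank", "pcr_blank", "positive_control", "mock"}
)
BLANK_TYPES = frozenset({"field_blank", "pcr_blank"})
ACTIVITY_LEVELS = frozenset({"diurnal", "nocturnal", "both", "unknown"})

SAMPLE_SHEET_HEADER = [
    "sample_id",
    "barcode_id",
    "sample_type",
    "habitat",
    "season",
    "clock_time",
    "replicate",
    "experiment_id",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T and reject characters outside {A,C,G,T,N}."""
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(f"{context}: invalid characters {sorted(bad)!r}")
    return seq


class FormatError(ValueError):
    """A malformed input file or record."""


@dataclass
class Read:
    """One sequencing read with per-base Phred qualities.

    ``qualities`` are integer Phred scores (decoded from Phred+33 on disk);
    ``sample_id`` is filled in after demultiplexing.
    """

    read_id: str
    sequence: str
    qualities: list[int]
    sample_id: str | None = None
    orientation: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.qualities and not all(0 <= q <= 93 for q in self.qualities):
            raise FormatError(f"read {self.read_id!r}: Phred score outside [0, 93]")
        if self.orientation not in ("forward", "reverse", "unknown"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SampleRecord:
    """One row of the sample sheet: a barcoded library and its metadata."""

    sample_id: str
    barcode_id: str
    sample_type: str
    habitat: str | None = None
    season: str | None = None
    clock_time: str | None = None
    replicate: int = 1
    experiment_id: str = "default"

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise FormatError(
                f"sample {self.sample_id!r}: unknown sample_type "
                f"{self.sample_type!r} (expected one of {sorted(SAMPLE_TYPES)})"
            )
        if self.replicate < 1:
            raise FormatError(f"sample {self.sample_id!r}: replicate must be >= 1")

    @property
    def is_blank(self) -> bool:
        return self.sample_type in BLANK_TYPES


@dataclass
class ReferenceRecord:
    """A taxonomy-annotated, primer-trimmed 12S amplicon reference."""

    accession: str
    species: str
    family: str
    order: str
    class_: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"reference {self.accession!r}: empty sequence")
        for rank in ("species", "family", "order", "class_"):
            if not getattr(self, rank):
                raise FormatError(f"reference {self.accession!r}: empty {rank}")


@dataclass
class ReferencePanel:
    """An ordered collection of unique-accession reference records."""

    records: list[ReferenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.accession in seen:
                raise FormatError(f"duplicate accession {rec.accession!r}")
            seen.add(rec.accession)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def by_accession(self, accession: str) -> ReferenceRecord:
        for rec in self.records:
            if rec.accession == accession:
                return rec
        raise KeyError(accession)

    @property
    def species(self) -> list[str]:
        return [rec.species for rec in self.records]


@dataclass
class CountTable:
    """An OTU-by-sample (or species-by-sample) integer count matrix.

    ``counts`` rows are OTU/species identifiers, columns are sample ids.
    ``row_annotations`` shares the row index and carries taxonomy and
    alignment metrics; ``samples`` maps every column to its SampleRecord.
    """

    counts: pd.DataFrame
    row_annotations: pd.DataFrame
    samples: dict[str, SampleRecord]

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.row_annotations.index):
            raise ValueError("counts and row_annotations row ids differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = [c for c in self.counts.columns if c not in self.samples]
        if missing:
            raise ValueError(f"columns without a SampleRecord: {missing}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.counts.columns)

    def copy(self) -> "CountTable":
        return CountTable(
            self.counts.copy(), self.row_annotations.copy(), dict(self.samples)
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        keep = [s for s in self.col_ids if s in set(sample_ids)]
        return CountTable(
            self.counts[keep].copy(),
            self.row_annotations.copy(),
            {s: self.samples[s] for s in keep},
        )

    def environmental(self) -> "CountTable":
        return self.select_samples(
            s for s, rec in self.samples.items() if rec.sample_type == "environmental"
        )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Yield Reads from a (possibly gzipped) Phred+33 FASTQ file.

    Raises FormatError naming the 0-based record index on malformed records.
    """
    with _open_text(path) as handle:
        index = -1
        try:
            for index, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
                if len(qual) != len(seq):
                    raise FormatError(
                        f"FASTQ record {index}: quality length != sequence length"
                    )
                yield Read(
                    read_id=title.split()[0],
                    sequence=normalize_sequence(seq, context=f"FASTQ record {index}"),
                    qualities=[ord(c) - 33 for c in qual],
                )
        except ValueError as exc:  # Biopython signals truncation/mismatch
            if isinstance(exc, FormatError):
                raise
            raise FormatError(f"FASTQ record {index + 1}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def read_reference_fasta(path: str | Path) -> ReferencePanel:
    """Load a reference panel from the pipe-delimited taxonomy FASTA dialect.

    Headers look like ``>accession|species|family|order|class``.
    """
    records: list[ReferenceRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        if header is None:
            return
        fields = header.split("|")
        if len(fields) != 5:
            raise FormatError(
                f"line {line_no}: header needs 5 pipe-delimited fields, "
                f"got {len(fields)}: {header!r}"
            )
        records.append(
            ReferenceRecord(
                accession=fields[0].strip(),
                species=fields[1].strip(),
                family=fields[2].strip(),
                order=fields[3].strip(),
                class_=fields[4].strip(),
                sequence=normalize_sequence("".join(chunks), context=header),
            )
        )

    header_line = 0
    with _open_text(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(header_line)
                header, chunks, header_line = line[1:], [], line_no
            else:
                if header is None:
                    raise FormatError(f"line {line_no}: sequence before any header")
                chunks.append(line)
        flush(header_line)
    return ReferencePanel(records)


def write_reference_fasta(panel: ReferencePanel, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in panel:
            handle.write(
                f">{rec.accession}|{rec.species}|{rec.family}|{rec.order}|"
                f"{rec.class_}\n{rec.sequence}\n"
            )


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Load and validate the sample sheet CSV."""
    with _open_text(path) as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != SAMPLE_SHEET_HEADER:
            raise FormatError(
                f"sample sheet header must be {','.join(SAMPLE_SHEET_HEADER)}"
            )
        samples = []
        seen_ids: set[str] = set()
        seen_barcodes: set[str] = set()
        for row in reader:
            sid = row["sample_id"]
            if sid in seen_ids:
                raise FormatError(f"duplicate sample_id {sid!r}")
            if row["barcode_id"] in seen_barcodes:
                raise FormatError(f"duplicate barcode_id {row['barcode_id']!r}")
            seen_ids.add(sid)
            seen_barcodes.add(row["barcode_id"])
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    barcode_id=row["barcode_id"],
                    sample_type=row["sample_type"],
                    habitat=row["habitat"] or None,
                    season=row["season"] or None,
                    clock_time=row["clock_time"] or None,
                    replicate=int(row["replicate"] or 1),
                    experiment_id=row["experiment_id"] or "default",
                )
            )
    if not samples:
        raise FormatError("empty sample sheet")
    if not any(s.sample_type == "environmental" for s in samples):
        logger.warning("sample sheet contains no environmental samples")
    return samples


def write_sample_sheet(samples: Iterable[SampleRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(SAMPLE_SHEET_HEADER)
        for s in samples:
            writer.writerow(
                [
                    s.sample_id,
                    s.barcode_id,
                    s.sample_type,
                    s.habitat or "",
                    s.season or "",
                    s.clock_time or "",
                    s.replicate,
                    s.experiment_id,
                ]
            )


_TAXONOMY_RANKS = ["species", "family", "order", "class_"]
MISSING = "."


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write the count-table TSV dialect.

    Columns: ``row_id``, ``taxonomy`` (species;family;order;class),
    ``mean_bit_score``, then one column per sample. Absent annotation
    values are written as ``.``.
    """
    ann = table.row_annotations
    with _open_text(path, "wt") as handle:
        handle.write("\t".join(["row_id", "taxonomy", "mean_bit_score"] + table.col_ids))
        handle.write("\n")
        for row_id in table.row_ids:
            ranks = []
            for rank in _TAXONOMY_RANKS:
                val = ann.at[row_id, rank] if rank in ann.columns else None
                ranks.append(str(val) if val is not None and not pd.isna(val) else MISSING)
            taxonomy = ";".join(ranks)
            bit = (
                ann.at[row_id, "mean_bit_score"]
                if "mean_bit_score" in ann.columns
                else None
            )
            bit_str = MISSING if bit is None or pd.isna(bit) else repr(float(bit))
            row_counts = [str(int(v)) for v in table.counts.loc[row_id]]
            handle.write("\t".join([row_id, taxonomy, bit_str] + row_counts) + "\n")


def read_count_table(
    path: str | Path, samples: list[SampleRecord] | None = None
) -> CountTable:
    """Read the TSV written by :func:`write_count_table`.

    If ``samples`` is not given, placeholder environmental SampleRecords are
    created for every column.
    """
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:3] != ["row_id", "taxonomy", "mean_bit_score"]:
            raise FormatError("not a count-table TSV")
        col_ids = header[3:]
        row_ids, tax_rows, bits, count_rows = [], [], [], []
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            row_ids.append(fields[0])
            ranks = fields[1].split(";")
            if len(ranks) != 4:
                raise FormatError(f"row {fields[0]!r}: malformed taxonomy field")
            tax_rows.append([None if r == MISSING else r for r in ranks])
            bits.append(None if fields[2] == MISSING else float(fields[2]))
            count_rows.append([int(v) for v in fields[3:]])
    counts = pd.DataFrame(count_rows, index=row_ids, columns=col_ids, dtype=int)
    ann = pd.DataFrame(tax_rows, index=row_ids, columns=_TAXONOMY_RANKS)
    ann["mean_bit_score"] = bits
    if samples is None:
        sample_map = {
            c: SampleRecord(c, f"BC{i + 1:02d}", "environmental")
            for i, c in enumerate(col_ids)
        }
    else:
        sample_map = {s.sample_id: s for s in samples}
    return CountTable(counts, ann, sample_map)


def read_activity_traits(path: str | Path) -> dict[str, str]:
    """Load the species,activity CSV used for diel analysis."""
    traits: dict[str, str] = {}
    with _open_text(path) as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != ["species", "activity"]:
            raise FormatError("trait table header must be species,activity")
        for row in reader:
            if row["activity"] not in ACTIVITY_LEVELS:
                raise FormatError(
                    f"species {row['species']!r}: unknown activity {row['activity']!r}"
                )
            traits[row["species"]] = row["activity"]
    return traits


def write_activity_traits(traits: dict[str, str], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("species,activity\n")
        for sp, act in traits.items():
            handle.write(f"{sp},{act}\n")
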