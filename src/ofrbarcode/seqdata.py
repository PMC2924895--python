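"""Barcode sequence datasets: FASTA I/O, species/accession structure, trimming.

A *dataset* is a flat list of accession records grouped by species.  Sequences
may be gapped (aligned) or plain.  Frequency-based analyses always run on the
degapped view; alignment-based analyses (p-distance, diagnostic characters)
require records of equal gapped length.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import (
    AlignmentError,
    DuplicateRecordError,
    EmptySequenceError,
    EmptyWindowError,
    LabelError,
    ParseError,
)

#: IUPAC nucleotide one-letter codes plus the gap character.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: Default header rule: "Genus_species|accession".
DEFAULT_HEADER_REGEX = r"^(?P<species>[^|]+)\|(?P<accession>.+)$"


@dataclass(frozen=True)
class SequenceRecord:
    """One accession of one species.

    ``residues`` may contain ``-`` gap characters when the record comes from
    an alignment; ``source_length`` is always the ungapped length.
    """

    species_id: str
    accession_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptySequenceError(
                f"empty sequence for {self.species_id}|{self.accession_id}"
            )
        bad = set(self.residues) - IUPAC_CHARS
        if bad:
            raise ParseError(
                f"non-IUPAC characters {sorted(bad)} in "
                f"{self.species_id}|{self.accession_id}"
            )

    @property
    def source_length(self) -> int:
        """Ungapped length in nucleotides."""
        return len(self.residues) - self.residues.count("-")

    @property
    def gapped_length(self) -> int:
        return len(self.residues)

    @property
    def label(self) -> str:
        return f"{self.species_id}|{self.accession_id}"


def _infer_aligned(records: list[SequenceRecord]) -> bool:
    lengths = {r.gapped_length for r in records}
    has_gap = any("-" in r.residues for r in records)
    return has_gap and len(lengths) == 1


@dataclass
class BarcodeDataset:
    """Grouped accession records for one barcode locus.

    ``is_aligned`` may be forced with the ``aligned`` argument (e.g. for an
    ungapped but column-consistent alignment); by default it is inferred:
    true iff any record carries a gap and all gapped lengths are equal.
    """

    records: list[SequenceRecord]
    is_aligned: bool = field(default=False)

    def __init__(self, records: list[SequenceRecord], aligned: bool | None = None):
        if not records:
            raise ParseError("dataset has no records")
        self.records = list(records)
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            key = (r.species_id, r.accession_id)
            if key in seen:
                raise DuplicateRecordError(f"duplicate record {r.label}")
            seen.add(key)
        if aligned is None:
            self.is_aligned = _infer_aligned(self.records)
        else:
            if aligned and len({r.gapped_length for r in self.records}) != 1:
                raise AlignmentError("aligned dataset has unequal gapped lengths")
            self.is_aligned = aligned

    # -- structure ---------------------------------------------------------

    @property
    def species_index(self) -> dict[str, list[SequenceRecord]]:
        idx: dict[str, list[SequenceRecord]] = {}
        for r in self.records:
            idx.setdefault(r.species_id, []).append(r)
        return idx

    @property
    def species_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species_id)
        return list(seen)

    @property
    def species_count(self) -> int:
        return len(self.species_ids)

    @property
    def accession_counts(self) -> dict[str, int]:
        return {s: len(rs) for s, rs in self.species_index.items()}

    @property
    def average_length(self) -> float:
        """Mean ungapped length over all records (the dataset's *a*)."""
        return sum(r.source_length for r in self.records) / len(self.records)

    @property
    def alignment_width(self) -> int:
        widths = {r.gapped_length for r in self.records}
        if len(widths) != 1:
            raise AlignmentError("records have unequal gapped lengths")
        return widths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def summary(self) -> pd.DataFrame:
        """Per-species summary: accession count and length statistics."""
        rows = []
        for sp, recs in self.species_index.items():
            lens = [r.source_length for r in recs]
            rows.append(
                {
                    "species_id": sp,
                    "n_accessions": len(recs),
                    "mean_length": sum(lens) / len(lens),
                    "min_length": min(lens),
                    "max_length": max(lens),
                }
            )
        return pd.DataFrame(rows)


# -- header parsing --------------------------------------------------------


def parse_header(header: str, regex: str = DEFAULT_HEADER_REGEX) -> tuple[str, str]:
    """Split a FASTA header into (species_id, accession_id)."""
    m = re.match(regex, header.strip())
    if not m or not m.group("species").strip() or not m.group("accession").strip():
        raise LabelError(f"header {header!r} does not match the label rule")
    return m.group("species").strip(), m.group("accession").strip()


def _clean_residues(raw: str) -> str:
    # public data mixes cases and RNA annotation; normalise on ingest
    return raw.upper().replace("U", "T")


def read_fasta(
    path, label_regex: str = DEFAULT_HEADER_REGEX, aligned: bool | None = None
) -> BarcodeDataset:
    """Read a multi-FASTA file into a :class:`BarcodeDataset`.

    Headers must yield species and accession under ``label_regex`` (default
    ``Species|accession``).  Sequences are upper-cased and U is mapped to T.
    """
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if not stripped:
        raise ParseError(f"{path}: empty FASTA file")
    if not stripped.startswith(">"):
        bad_line = next(
            i + 1 for i, ln in enumerate(text.splitlines()) if ln.strip()
        )
        raise ParseError(f"{path}: line {bad_line} precedes the first header")
    records: list[SequenceRecord] = []
    for bio in SeqIO.parse(io.StringIO(text), "fasta"):
        species, accession = parse_header(bio.description, label_regex)
        seq = _clean_residues(str(bio.seq))
        if not seq:
            raise ParseError(f"{path}: record {bio.description!r} has no sequence")
        records.append(SequenceRecord(species, accession, seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return BarcodeDataset(records, aligned=aligned)


def write_fasta(ds: BarcodeDataset, path) -> None:
    """Write a dataset as FASTA with ``Species|accession`` headers."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.label, description="")
        for r in ds.records
    ]
    SeqIO.write(bio, str(path), "fasta")


# -- alignment-level operations -------------------------------------------


def trim_common_window(ds: BarcodeDataset, min_coverage: float = 1.0) -> BarcodeDataset:
    """Trim ragged alignment ends to the window covered by all records.

    Columns are retained between the first and last column at which the
    fraction of non-gap records is at least ``min_coverage`` (default: every
    record non-gap, i.e. the outermost fully covered columns).  Interior
    columns are kept regardless of coverage.
    """
    width = ds.alignment_width
    n = len(ds.records)
    coverage = [
        sum(1 for r in ds.records if r.residues[c] != "-") / n for c in range(width)
    ]
    covered = [c for c in range(width) if coverage[c] >= min_coverage]
    if not covered:
        raise EmptyWindowError("no alignment column meets the coverage requirement")
    lo, hi = covered[0], covered[-1]
    trimmed = [
        SequenceRecord(r.species_id, r.accession_id, r.residues[lo : hi + 1])
        for r in ds.records
    ]
    return BarcodeDataset(trimmed, aligned=True)


def degap(ds: BarcodeDataset) -> BarcodeDataset:
    """Remove every gap character; the result is unaligned."""
    out = []
    for r in ds.records:
        seq = r.residues.replace("-", "")
        if not seq:
            raise EmptySequenceError(f"record {r.label} is empty after degapping")
        out.append(SequenceRecord(r.species_id, r.accession_id, seq))
    return BarcodeDataset(out, aligned=False)
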