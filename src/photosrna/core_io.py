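"""Shared domain types, coordinate conventions and format readers/writers.

Conventions
-----------
* All internal coordinates are 0-based half-open ``[start, end)``.
* All emitted GFF3 (and report) coordinates are 1-based inclusive, per the
  GFF3 standard.
* Nucleotide sequences are stored upper-case in DNA space (U -> T).
* Time points of the de-etiolation design are ``W0, W1, W3, W6, W12, W24``
  (hours of white light after 4 d darkness), with three biological
  replicates each.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

TIME_POINTS = ("W0", "W1", "W3", "W6", "W12", "W24")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and map U -> T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space."""
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


class Biotype(enum.Enum):
    protein_coding = "protein_coding"
    TAS_noncoding = "TAS_noncoding"
    transposable_element = "transposable_element"
    other = "other"


class SrnaClass(enum.Enum):
    miRNA = "miRNA"
    phasiRNA = "phasiRNA"
    siRNA = "siRNA"


@dataclass(frozen=True)
class Transcript:
    """A reference sequence (mRNA, TAS precursor or TE transcript)."""

    id: str
    sequence: str
    biotype: Biotype = Biotype.protein_coding

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedRead:
    """One sRNA/degradome read placement on a reference.

    ``count`` is the collapsed read multiplicity; coordinates are 0-based
    half-open on the forward strand of the reference.
    """

    read_id: str
    sequence: str
    count: int
    ref_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.end - self.start != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: end - start = {self.end - self.start}"
                f" != sequence length {len(self.sequence)}"
            )
        if self.count < 1:
            raise ValueError(f"read {self.read_id!r}: count must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read {self.read_id!r}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SrnaCatalogEntry:
    """A mature sRNA with class and (optional) family annotation."""

    srna_id: str
    sequence: str
    srna_class: SrnaClass = SrnaClass.miRNA
    family: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DegradomeProfile:
    """Per-transcript vector of degradome 5'-end read counts.

    ``position_counts[i]`` is the number of 5' ends at 1-based transcript
    position ``i + 1``; its length equals the transcript length.
    """

    transcript_id: str
    position_counts: np.ndarray
    library_size: int = 0

    def __post_init__(self) -> None:
        self.position_counts = np.asarray(self.position_counts, dtype=np.int64)
        if (self.position_counts < 0).any():
            raise ValueError("degradome counts must be non-negative")
        if self.library_size == 0:
            self.library_size = int(self.position_counts.sum())

    def count_at(self, position: int) -> int:
        """Count at a 1-based transcript position."""
        if not 1 <= position <= len(self.position_counts):
            raise IndexError(
                f"position {position} outside transcript "
                f"{self.transcript_id!r} (length {len(self.position_counts)})"
            )
        return int(self.position_counts[position - 1])


@dataclass
class ExpressionMatrix:
    """Feature x (time point, replicate) abundance matrix.

    ``values`` is a DataFrame whose index is feature id and whose columns are
    a MultiIndex of (time_point, replicate).  ``library_totals`` maps each
    (time_point, replicate) library to its total mapped 20-24 nt read count,
    required for RPM normalization.
    """

    values: pd.DataFrame
    unit: str = "raw_count"
    library_totals: pd.Series | None = None

    _UNITS = ("raw_count", "RPM", "RPKM")

    def __post_init__(self) -> None:
        if self.unit not in self._UNITS:
            raise ValueError(f"unit must be one of {self._UNITS}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def time_points(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    @property
    def replicates(self) -> list:
        return sorted(set(self.values.columns.get_level_values(1)))

    def feature(self, feature_id: str) -> pd.DataFrame:
        """Return one feature as a time_point x replicate DataFrame."""
        row = self.values.loc[feature_id]
        return row.unstack(level=1).reindex(self.time_points)

    @classmethod
    def from_feature_table(
        cls,
        table: dict[str, dict[tuple[str, int], float]],
        unit: str = "raw_count",
        library_totals: pd.Series | None = None,
    ) -> "ExpressionMatrix":
        df = pd.DataFrame.from_dict(table, orient="index")
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["time_point", "replicate"])
        return cls(df.fillna(0.0), unit=unit, library_totals=library_totals)


# ---------------------------------------------------------------------------
# FASTA / collapsed reads
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, biotype: Biotype = Biotype.protein_coding) -> list[Transcript]:
    """Read a transcriptome FASTA into :class:`Transcript` records.

    U bases are stored as T; record order is preserved.  Duplicate ids raise
    a ``ValueError`` naming the offending id.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(Transcript(rec.id, str(rec.seq), biotype=biotype))
    return records


def read_collapsed_reads(path: str | Path) -> list[tuple[str, int]]:
    """Read a collapsed-read FASTA whose headers end in ``_<count>``.

    Returns ``(sequence, count)`` tuples, sequences upper-cased (U -> T).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        head, _, suffix = rec.id.rpartition("_")
        if not head or not suffix.isdigit():
            raise ValueError(
                f"collapsed-read header {rec.id!r} does not end in '_<integer>'"
            )
        out.append((normalize_sequence(str(rec.seq)), int(suffix)))
    return out


def read_fastq_collapsed(path: str | Path) -> list[tuple[str, int]]:
    """Read plain FASTQ and collapse identical sequences to (sequence, count)."""
    counts: Counter[str] = Counter()
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = normalize_sequence(str(rec.seq))
        if seq not in counts:
            order.append(seq)
        counts[seq] += 1
    return [(seq, counts[seq]) for seq in order]


def write_collapsed_reads(reads: Iterable[tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(reads, start=1):
            fh.write(f">r{i}_{count}\n{seq}\n")


def read_srna_catalog(
    fasta_path: str | Path, family_path: str | Path | None = None
) -> list[SrnaCatalogEntry]:
    """Read a mature-sRNA FASTA plus an optional family/class annotation TSV.

    The TSV has columns ``srna_id``, ``family`` and optionally ``class``;
    "." marks a missing family.
    """
    families: dict[str, str | None] = {}
    classes: dict[str, SrnaClass] = {}
    if family_path is not None:
        ann = pd.read_csv(family_path, sep="\t", dtype=str).fillna(".")
        for _, row in ann.iterrows():
            families[row["srna_id"]] = None if row["family"] == "." else row["family"]
            if "class" in ann.columns and row["class"] != ".":
                classes[row["srna_id"]] = SrnaClass[row["class"]]
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        out.append(
            SrnaCatalogEntry(
                rec.id,
                str(rec.seq),
                srna_class=classes.get(rec.id, SrnaClass.miRNA),
                family=families.get(rec.id),
            )
        )
    return out


# ---------------------------------------------------------------------------
# GFF3 locus reports
# ---------------------------------------------------------------------------

_GFF3_HEADER = "##gff-version 3\n"


def write_locus_gff3(calls: Sequence, path: str | Path) -> None:
    """Write PHAS locus calls as GFF3.

    Internal 0-based half-open ``[start, end)`` becomes 1-based inclusive
    columns 4 and 5.  The p-value is carried in the attributes column.
    """
    with open(path, "w") as fh:
        fh.write(_GFF3_HEADER)
        for i, call in enumerate(calls, start=1):
            attrs = (
                f"ID=phas{i};n={call.n};k={call.k};pvalue={call.p_value:.1e}"
            )
            if getattr(call, "trigger", None):
                attrs += f";trigger={call.trigger}"
            fh.write(
                "\t".join(
                    [
                        call.ref_id,
                        "photosrna",
                        "siRNA_locus",
                        str(call.start + 1),
                        str(call.end),
                        f"{call.p_value:.3e}",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_locus_gff3(path: str | Path) -> list[dict]:
    """Read a locus GFF3 back into dicts with internal 0-based coordinates."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            out.append(
                {
                    "ref_id": cols[0],
                    "start": int(cols[3]) - 1,
                    "end": int(cols[4]),
                    "n": int(attrs["n"]),
                    "k": int(attrs["k"]),
                    "p_value": float(attrs["pvalue"]),
                    "trigger": attrs.get("trigger"),
                }
            )
    return out


# ---------------------------------------------------------------------------
# Degradome profile TSV
# ---------------------------------------------------------------------------

def read_degradome_tsv(
    path: str | Path, transcripts: Sequence[Transcript]
) -> dict[str, DegradomeProfile]:
    """Load degradome profiles from a (transcript_id, position, count) TSV.

    ``position`` is 1-based.  Transcripts absent from the TSV get all-zero
    profiles; positions outside the transcript raise.
    """
    lengths = {t.id: len(t) for t in transcripts}
    counts = {tid: np.zeros(n, dtype=np.int64) for tid, n in lengths.items()}
    table = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    for _, row in table.iterrows():
        tid, pos, c = row["transcript_id"], int(row["position"]), int(row["count"])
        if tid not in counts:
            raise ValueError(f"unknown transcript id {tid!r} in {path}")
        if not 1 <= pos <= lengths[tid]:
            raise ValueError(
                f"position {pos} outside transcript {tid!r} (length {lengths[tid]})"
            )
        counts[tid][pos - 1] += c
    total = int(sum(a.sum() for a in counts.values()))
    return {
        tid: DegradomeProfile(tid, arr, library_size=total)
        for tid, arr in counts.items()
    }


def write_degradome_tsv(profiles: dict[str, DegradomeProfile], path: str | Path) -> None:
    rows = []
    for tid in sorted(profiles):
        arr = profiles[tid].position_counts
        for pos in np.flatnonzero(arr):
            rows.append((tid, int(pos) + 1, int(arr[pos])))
    pd.DataFrame(rows, columns=["transcript_id", "position", "count"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.columns = [f"{tp}.r{rep}" for tp, rep in df.columns]
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_expression_tsv(
    path: str | Path, unit: str = "raw_count", library_totals: pd.Series | None = None
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    cols = []
    for col in df.columns:
        tp, rep = col.rsplit(".r", 1)
        cols.append((tp, int(rep)))
    df.columns = pd.MultiIndex.from_tuples(cols, names=["time_point", "replicate"])
    return ExpressionMatrix(df, unit=unit, library_totals=library_totals)
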