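"""Sequence I/O and dereplication.

Reads are handled as plain ACGT strings.  Dereplication collapses identical
reads into :class:`UniqueSequence` records carrying an abundance (the number
of reads of that exact sequence), the unit everything downstream works with.
Abundance-annotated FASTA uses the usearch ``;size=N`` header dialect.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGT")

_SIZE_RE = re.compile(r";size=([^;]*)")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA records or headers."""


@dataclass(frozen=True)
class UniqueSequence:
    """A distinct read sequence with its read count.

    Parameters
    ----------
    id : str
        Stable label for the sequence.
    sequence : str
        Non-empty string over {A, C, G, T}.
    abundance : int
        Number of reads of this exact sequence (>= 1).
    """

    id: str
    sequence: str
    abundance: int

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        if not set(self.sequence) <= ALPHABET:
            bad = sorted(set(self.sequence) - ALPHABET)
            raise ValueError(f"sequence contains non-ACGT symbols: {bad}")
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")


@dataclass
class ReadSet:
    """A dereplicated sequencing data set: unique sequences with abundances."""

    members: list[UniqueSequence] = field(default_factory=list)

    def __post_init__(self):
        seqs = [m.sequence for m in self.members]
        if len(set(seqs)) != len(seqs):
            raise ValueError("ReadSet members must be pairwise distinct")

    @property
    def total_reads(self) -> int:
        return sum(m.abundance for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def parse_size_annotation(header: str) -> int:
    """Return the abundance encoded in a ``;size=N`` header suffix (1 if absent)."""
    m = _SIZE_RE.search(header)
    if m is None:
        return 1
    try:
        size = int(m.group(1))
    except ValueError as exc:
        raise FastaFormatError(
            f"non-integer size annotation in header {header!r}"
        ) from exc
    if size < 1:
        raise FastaFormatError(f"size annotation must be >= 1 in header {header!r}")
    return size


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(header, sequence)`` tuples.

    Sequences are uppercased.  Records containing symbols outside ACGT
    (e.g. ``N``) are dropped; the number of dropped records is logged.
    """
    records: list[tuple[str, str]] = []
    n_dropped = 0
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if not seq or not set(seq) <= ALPHABET:
                n_dropped += 1
                logger.debug("dropping record %s: non-ACGT symbols", rec.id)
                continue
            records.append((rec.description, seq))
    except ValueError as exc:
        raise FastaFormatError(f"malformed FASTA file {path}: {exc}") from exc
    if n_dropped:
        logger.info("read_fasta: dropped %d record(s) with non-ACGT symbols", n_dropped)
    return records


def dereplicate(reads: Sequence[str] | Sequence[tuple[str, str]]) -> ReadSet:
    """Collapse raw reads into unique sequences with abundances.

    Accepts plain sequence strings or ``(header, sequence)`` tuples; headers
    may carry ``;size=N`` annotations (pre-dereplicated input), which are
    honoured so that dereplication is idempotent.

    Members are ordered by descending abundance, ties broken lexicographically
    by sequence, and labelled ``u0, u1, ...`` in that order.
    """
    if len(reads) == 0:
        raise ValueError("dereplicate: empty input")
    counts: Counter[str] = Counter()
    for item in reads:
        if isinstance(item, str):
            header, seq = "", item
        else:
            header, seq = item
        counts[seq] += parse_size_annotation(header) if header else 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    members = [
        UniqueSequence(id=f"u{i}", sequence=seq, abundance=n)
        for i, (seq, n) in enumerate(ordered)
    ]
    return ReadSet(members=members)


def write_genotypes_fasta(path: str | Path, genotypes: Iterable[tuple[str, str, int]]) -> None:
    """Write genotypes as FASTA with ``;size=N`` abundance annotations.

    ``genotypes`` yields ``(id, sequence, abundance)``.
    """
    with open(path, "w") as fh:
        for gid, seq, size in genotypes:
            fh.write(f">{gid};size={size}\n{seq}\n")


def write_membership_tsv(path: str | Path, table: pd.DataFrame) -> None:
    """Write the per-read cluster membership table as TSV."""
    cols = [
        "read_id",
        "sequence",
        "abundance",
        "cluster_id",
        "family_signature",
        "lambda",
        "p_value",
    ]
    table.loc[:, cols].to_csv(path, sep="\t", index=False)


def write_error_rates_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
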