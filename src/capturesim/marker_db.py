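"""Marker reference database: records, count tables, and file I/O.

A marker database holds chaperonin-style reference sequences, one per
taxon, each annotated with its domain of life, chaperonin type (type I for
Bacteria/organelles, type II for Archaea and the eukaryotic cytosol), and
the coordinates of the universal target (UT) — the 549-567 bp region that
universal primers amplify and that anchors sub-OTU calling.

All coordinates are 0-based, half-open. Metadata travels as TSV with the
fixed header ``id  taxon  domain  cpn_type  ut_start  ut_end``; sequences
as plain FASTA.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import reverse_complement, validate_dna, gc_fraction  # noqa: F401 (re-export)

__all__ = [
    "Domain",
    "CpnType",
    "MarkerRecord",
    "MarkerDB",
    "ClusterCountTable",
    "read_marker_db",
    "write_marker_db",
    "read_count_table",
    "write_count_table",
    "reverse_complement",
]

METADATA_COLUMNS = ["id", "taxon", "domain", "cpn_type", "ut_start", "ut_end"]

#: default permitted UT length range for type I chaperonins (nt)
UT_LENGTH_RANGE_TYPE_I = (549, 567)


class Domain(str, enum.Enum):
    BACTERIA = "Bacteria"
    ARCHAEA = "Archaea"
    EUKARYA = "Eukarya"


class CpnType(str, enum.Enum):
    I = "I"
    II = "II"


@dataclass(frozen=True)
class MarkerRecord:
    """One reference marker sequence with taxonomy and UT interval."""

    id: str
    taxon: str
    domain: Domain
    cpn_type: CpnType
    seq: str
    ut_interval: tuple[int, int]

    def __post_init__(self) -> None:
        validate_dna(self.seq, allow_n=True)
        s, e = self.ut_interval
        if not (0 <= s < e <= len(self.seq)):
            raise ValueError(
                f"record {self.id!r}: UT interval {self.ut_interval} outside "
                f"sequence of length {len(self.seq)}"
            )

    @property
    def ut_seq(self) -> str:
        s, e = self.ut_interval
        return self.seq[s:e]

    @property
    def ut_length(self) -> int:
        s, e = self.ut_interval
        return e - s

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)


class MarkerDB:
    """Ordered, id-indexed collection of :class:`MarkerRecord`."""

    def __init__(self, records: Iterable[MarkerRecord]):
        self.records: list[MarkerRecord] = list(records)
        if not self.records:
            raise ValueError("MarkerDB must contain at least one record")
        self._index: dict[str, MarkerRecord] = {}
        for rec in self.records:
            if rec.id in self._index:
                raise ValueError(f"duplicate record id {rec.id!r}")
            self._index[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MarkerRecord]:
        return iter(self.records)

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    def __getitem__(self, rid: str) -> MarkerRecord:
        return self._index[rid]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, ids: Iterable[str]) -> "MarkerDB":
        return MarkerDB(self._index[i] for i in ids)

    def validate_ut_lengths(self, length_range: tuple[int, int] = UT_LENGTH_RANGE_TYPE_I) -> None:
        """Check that type I UT lengths fall in the configured range."""
        lo, hi = length_range
        for rec in self.records:
            if rec.cpn_type is CpnType.I and not (lo <= rec.ut_length <= hi):
                raise ValueError(
                    f"record {rec.id!r}: type I UT length {rec.ut_length} "
                    f"outside [{lo}, {hi}]"
                )


def read_marker_db(fasta_path: str | Path, metadata_path: str | Path) -> MarkerDB:
    """Load a marker database from FASTA + metadata TSV.

    FASTA ids must match metadata rows one-to-one; record order follows the
    FASTA file.
    """
    seqs: dict[str, str] = {}
    order: list[str] = []
    for sr in SeqIO.parse(str(fasta_path), "fasta"):
        if sr.id in seqs:
            raise ValueError(f"duplicate FASTA id {sr.id!r}")
        seqs[sr.id] = str(sr.seq).upper()
        order.append(sr.id)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"id": str, "taxon": str})
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ValueError(f"metadata missing column(s): {sorted(missing_cols)}")
    if meta["id"].duplicated().any():
        dupes = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate metadata id(s): {dupes}")
    meta_ids = set(meta["id"])
    fasta_ids = set(order)
    if meta_ids != fasta_ids:
        raise ValueError(
            f"FASTA/metadata id mismatch: only in FASTA {sorted(fasta_ids - meta_ids)[:5]}, "
            f"only in metadata {sorted(meta_ids - fasta_ids)[:5]}"
        )
    rows = meta.set_index("id")
    records = []
    for rid in order:
        row = rows.loc[rid]
        try:
            dom = Domain(row["domain"])
        except ValueError as exc:
            raise ValueError(
                f"record {rid!r}: domain {row['domain']!r} must be one of "
                f"{[d.value for d in Domain]}"
            ) from exc
        try:
            ctype = CpnType(str(row["cpn_type"]))
        except ValueError as exc:
            raise ValueError(f"record {rid!r}: cpn_type {row['cpn_type']!r}") from exc
        records.append(
            MarkerRecord(
                id=rid,
                taxon=str(row["taxon"]),
                domain=dom,
                cpn_type=ctype,
                seq=seqs[rid],
                ut_interval=(int(row["ut_start"]), int(row["ut_end"])),
            )
        )
    return MarkerDB(records)


def write_marker_db(db: MarkerDB, fasta_path: str | Path, metadata_path: str | Path) -> None:
    recs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in db]
    SeqIO.write(recs, str(fasta_path), "fasta")
    pd.DataFrame(
        {
            "id": [r.id for r in db],
            "taxon": [r.taxon for r in db],
            "domain": [r.domain.value for r in db],
            "cpn_type": [r.cpn_type.value for r in db],
            "ut_start": [r.ut_interval[0] for r in db],
            "ut_end": [r.ut_interval[1] for r in db],
        }
    ).to_csv(metadata_path, sep="\t", index=False)


@dataclass
class ClusterCountTable:
    """Taxonomic-cluster x sample table of mapped read-pair counts.

    One cluster per reference record; counts are non-negative integers.
    Backed by a pandas DataFrame (clusters as rows, samples as columns).
    """

    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.counts.size == 0:
            raise ValueError("empty count table")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate cluster ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        self.counts.index.name = "cluster_id"

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, sample_id: str) -> pd.Series:
        return self.counts[sample_id]

    def validate_against(self, db: MarkerDB) -> None:
        unknown = set(self.cluster_ids) - set(db.ids)
        if unknown:
            raise ValueError(f"cluster id(s) not in database: {sorted(unknown)[:5]}")

    @classmethod
    def from_columns(cls, columns: dict[str, pd.Series]) -> "ClusterCountTable":
        return cls(pd.DataFrame(columns).fillna(0).astype(np.int64))


def write_count_table(table: ClusterCountTable, path: str | Path) -> Path:
    path = Path(path)
    df = table.counts.copy()
    df.index.name = "cluster_id"
    df.to_csv(path, sep="\t")
    return path


def read_count_table(path: str | Path) -> ClusterCountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("count table cells must be non-negative integers")
    return ClusterCountTable(df)
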