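"""Tiling capture-probe (bait) design from a marker database.

Baits are fixed-length windows (default 120 nt) taken along each reference
at a fixed step (default 60 nt), so consecutive probes overlap by
window - step nt — 50% at the defaults. When the reference length is not a
multiple of the step, one extra probe is anchored at the 3' end so every
base is covered. Probes containing any non-ACGT base are discarded
(synthesizability), and exact duplicate sequences are collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .marker_db import MarkerDB, MarkerRecord

logger = logging.getLogger(__name__)

__all__ = ["ProbeDesignParams", "Probe", "ProbeSet", "tile_probes", "design_array",
           "probe_coverage_report", "write_probe_fasta", "read_probe_fasta"]


@dataclass(frozen=True)
class ProbeDesignParams:
    window: int = 120
    step: int = 60
    end_anchor: bool = True
    dedupe: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError(f"require 0 < step <= window, got step={self.step} window={self.window}")

    @property
    def overlap_fraction(self) -> float:
        """Overlap between consecutive probes as a fraction of the window."""
        return (self.window - self.step) / self.window


@dataclass(frozen=True)
class Probe:
    source_id: str
    offset: int
    seq: str

    @property
    def id(self) -> str:
        return f"{self.source_id}|{self.offset}"


@dataclass
class ProbeSet:
    probes: list[Probe]
    params: ProbeDesignParams
    stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)


def tile_offsets(length: int, window: int, step: int, end_anchor: bool) -> list[int]:
    """Window start offsets for one reference (the tiling rule itself)."""
    if length < window:
        return []
    offsets = list(range(0, length - window + 1, step))
    if end_anchor and length % step != 0:
        last = length - window
        if last not in offsets:
            offsets.append(last)
    return offsets


def tile_probes(record: MarkerRecord, params: ProbeDesignParams | None = None) -> list[Probe]:
    """Tile one record into fixed-length probes.

    Records shorter than the step are skipped (logged). Records between
    step and window long are emitted whole as a single short probe so that
    short references keep representation on the array.
    """
    params = params or ProbeDesignParams()
    L = len(record.seq)
    if L < params.step:
        logger.warning("record %s (length %d) shorter than step %d: skipped",
                       record.id, L, params.step)
        return []
    if L < params.window:
        return [Probe(record.id, 0, record.seq)]
    return [
        Probe(record.id, off, record.seq[off : off + params.window])
        for off in tile_offsets(L, params.window, params.step, params.end_anchor)
    ]


def design_array(db: MarkerDB, params: ProbeDesignParams | None = None) -> ProbeSet:
    """Tile every record, drop ambiguous windows, collapse exact duplicates."""
    params = params or ProbeDesignParams()
    probes: list[Probe] = []
    n_ambiguous = 0
    for rec in db:
        for p in tile_probes(rec, params):
            if set(p.seq) - set("ACGT"):
                n_ambiguous += 1
                continue
            probes.append(p)
    n_raw = len(probes)
    if params.dedupe:
        seen: set[str] = set()
        unique = []
        for p in probes:
            if p.seq not in seen:
                seen.add(p.seq)
                unique.append(p)
        probes = unique
    if not probes:
        raise ValueError("probe design produced no probes (all records too short or ambiguous)")
    stats = {
        "n_probes": len(probes),
        "n_raw": n_raw,
        "n_ambiguous_dropped": n_ambiguous,
        "n_duplicates_collapsed": n_raw - len(probes),
        "consecutive_overlap_fraction": params.overlap_fraction,
    }
    return ProbeSet(probes=probes, params=params, stats=stats)


def probe_coverage_report(pset: ProbeSet, db: MarkerDB) -> pd.DataFrame:
    """Per-record coverage summary: covered fraction, probe count, max gap."""
    by_source: dict[str, list[Probe]] = {}
    for p in pset:
        by_source.setdefault(p.source_id, []).append(p)
    rows = []
    for rec in db:
        L = len(rec.seq)
        plist = sorted(by_source.get(rec.id, []), key=lambda p: p.offset)
        intervals = [(p.offset, p.offset + len(p.seq)) for p in plist]
        covered = 0
        max_gap = 0
        prev_end = 0
        for s, e in intervals:
            if s > prev_end:
                max_gap = max(max_gap, s - prev_end)
            covered += max(0, min(e, L) - max(s, prev_end))
            prev_end = max(prev_end, e)
        if prev_end < L:
            max_gap = max(max_gap, L - prev_end)
        rows.append(
            {
                "record_id": rec.id,
                "length": L,
                "n_probes": len(plist),
                "covered_fraction": covered / L if L else 0.0,
                "max_gap": max_gap,
                "flagged": len(plist) == 0,
            }
        )
    return pd.DataFrame(rows).set_index("record_id")


def write_probe_fasta(pset: ProbeSet, path: str | Path) -> Path:
    recs = [SeqRecord(Seq(p.seq), id=p.id, description="") for p in pset]
    SeqIO.write(recs, str(path), "fasta")
    return Path(path)


def read_probe_fasta(path: str | Path, params: ProbeDesignParams | None = None) -> ProbeSet:
    probes = []
    for sr in SeqIO.parse(str(path), "fasta"):
        source_id, _, off = sr.id.rpartition("|")
        probes.append(Probe(source_id, int(off), str(sr.seq).upper()))
    return ProbeSet(probes=probes, params=params or ProbeDesignParams(),
                    stats={"n_probes": len(probes)})
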