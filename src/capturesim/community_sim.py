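"""Synthetic marker families, host genomes, and community designs.

This module manufactures the ground-truth side of every experiment:

* a *marker family* — records derived from one random ancestor by point
  substitution to a per-record target identity, standing in for a curated
  chaperonin reference set;
* *host genomes* — random sequence at a requested GC content with a marker
  embedded verbatim at a recorded position;
* *community designs* — an even mock community (eight bacteria at 12% each
  plus two eukaryotes at 2% each) and a spike-in dilution series (20
  plasmid members at 1e8/1e7/1e6/0 copies each in a constant carrier
  background harbouring two endogenous markers).

Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import gc_fraction, to_bytes, to_str
from .marker_db import CpnType, Domain, MarkerDB, MarkerRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerFamilySpec", "GenomeRecord", "CommunitySample", "SpikePanelSpec",
    "generate_marker_family", "embed_marker_in_genome",
    "make_even_community", "make_spike_series",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: total carrier weight (copies x nt). The high spike level carries
#: ~0.4 ng of plasmid DNA into a carrier background of order 1000 ng
#: (10 ng/uL), a ~2500:1 mass ratio; in weight units the 20-member panel
#: at 1e8 copies x ~555 nt is ~1.1e12, giving ~2.8e15 for the carrier.
DEFAULT_BACKGROUND_WEIGHT = 2.8e15


@dataclass(frozen=True)
class MarkerFamilySpec:
    """Parameters for generating a marker family from a common ancestor."""

    n_taxa: int = 8
    ut_length_range: tuple[int, int] = (549, 567)
    flank_length: int = 400
    target_identity_range: tuple[float, float] = (0.70, 0.95)
    gc_range: tuple[float, float] = (0.30, 0.70)
    seed: int = 0
    domain: Domain = Domain.BACTERIA
    cpn_type: CpnType = CpnType.I
    id_prefix: str = "taxon"

    def __post_init__(self) -> None:
        lo, hi = self.target_identity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("identities must lie in (0, 1]")
        if self.ut_length_range[0] <= 0 or self.flank_length < 0:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class GenomeRecord:
    """A synthetic host genome with embedded marker(s)."""

    id: str
    seq: str
    embedded_markers: tuple[tuple[str, int], ...] = ()
    marker_lengths: tuple[int, ...] = ()

    @property
    def gc(self) -> float:
        return gc_fraction(self.seq)

    def marker_intervals(self) -> list[tuple[str, int, int]]:
        return [
            (rid, pos, pos + ln)
            for (rid, pos), ln in zip(self.embedded_markers, self.marker_lengths)
        ]


@dataclass
class CommunitySample:
    """A community design with full ground truth.

    ``members`` maps marker record ids to abundances. In ``copies`` mode the
    abundance is an absolute template copy number (spike series); in
    ``mass`` mode it is a relative mass fraction (even community).
    ``genomes`` optionally maps a member id to the host genome carrying its
    marker; members without a genome are naked templates (e.g. plasmids
    consisting of the cloned marker). ``background`` carries
    (genome, weight) pairs constant across a series.
    """

    sample_id: str
    members: list[tuple[str, float]]
    abundance_mode: str = "copies"  # "copies" | "mass"
    genomes: dict[str, GenomeRecord] = field(default_factory=dict)
    background: list[tuple[GenomeRecord, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members and not self.background:
            raise ValueError("community must have at least one member or background entry")
        for rid, ab in self.members:
            if not np.isfinite(ab) or ab < 0:
                raise ValueError(f"member {rid!r}: abundance {ab} must be finite and >= 0")
        if self.abundance_mode not in ("copies", "mass"):
            raise ValueError(f"unknown abundance mode {self.abundance_mode!r}")

    def truth_table(self) -> dict[str, float]:
        """Relative abundance of each member (members only, sums to 1)."""
        total = sum(ab for _, ab in self.members)
        if total == 0:
            return {rid: 0.0 for rid, _ in self.members}
        return {rid: ab / total for rid, ab in self.members}


@dataclass(frozen=True)
class SpikePanelSpec:
    n_members: int = 20
    levels: tuple[float, ...] = (1e8, 1e7, 1e6, 0.0)
    background_weight: float = DEFAULT_BACKGROUND_WEIGHT
    level_names: tuple[str, ...] = ("high", "medium", "low", "unspiked")

    def __post_init__(self) -> None:
        lv = list(self.levels)
        if any(x < 0 for x in lv):
            raise ValueError("levels must be non-negative")
        nonzero = [x for x in lv if x > 0]
        decreasing = all(a > b for a, b in zip(nonzero, nonzero[1:]))
        zeros_last = lv[: len(nonzero)] == nonzero
        if not (decreasing and zeros_last):
            raise ValueError("levels must be strictly decreasing, with zero (if any) last")
        if len(self.level_names) != len(self.levels):
            raise ValueError("level_names must match levels")


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


def _mutate_to_identity(
    rng: np.random.Generator, ancestor: np.ndarray, identity: float, target_gc: float | None
) -> np.ndarray:
    """Substitute exactly round((1-identity)*L) positions of the ancestor.

    Replacement bases are drawn to differ from the original; when a target
    GC is given the replacement distribution is tilted toward it, moving
    composition as far as the substitution budget allows.
    """
    L = ancestor.size
    n_mut = int(round((1.0 - identity) * L))
    out = ancestor.copy()
    if n_mut == 0:
        return out
    pos = rng.choice(L, size=n_mut, replace=False)
    gc = 0.5 if target_gc is None else float(np.clip(target_gc, 0.05, 0.95))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for i in pos:
        orig = out[i]
        probs = p.copy()
        probs[np.flatnonzero(_BASES == orig)[0]] = 0.0
        probs /= probs.sum()
        out[i] = _BASES[rng.choice(4, p=probs)]
    return out


def generate_marker_family(spec: MarkerFamilySpec) -> MarkerDB:
    """Derive ``n_taxa`` records from one seeded ancestor by substitution.

    Each record's identity to the ancestor hits its target exactly (by
    construction; substitution-only, no indels). The UT interval sits
    between the flanks and its length is drawn per record from
    ``ut_length_range``.
    """
    rng = np.random.default_rng(spec.seed)
    lo_i, hi_i = spec.target_identity_range
    ut_max = spec.ut_length_range[1]
    anc_len = spec.flank_length * 2 + ut_max
    ancestor = _random_seq(rng, anc_len)
    records = []
    for t in range(spec.n_taxa):
        identity = float(rng.uniform(lo_i, hi_i)) if spec.n_taxa > 1 or lo_i < hi_i else lo_i
        target_gc = float(rng.uniform(*spec.gc_range))
        ut_len = int(rng.integers(spec.ut_length_range[0], spec.ut_length_range[1] + 1))
        seq = _mutate_to_identity(rng, ancestor, identity, target_gc)
        # per-record UT length: trim the tail so flanks stay symmetric-ish
        total = spec.flank_length * 2 + ut_len
        seq = seq[:total]
        records.append(
            MarkerRecord(
                id=f"{spec.id_prefix}{t:03d}",
                taxon=f"{spec.id_prefix} sp. {t:03d}",
                domain=spec.domain,
                cpn_type=spec.cpn_type,
                seq=to_str(seq),
                ut_interval=(spec.flank_length, spec.flank_length + ut_len),
            )
        )
    return MarkerDB(records)


def embed_marker_in_genome(
    record: MarkerRecord,
    genome_length: int,
    gc: float,
    seed: int,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Random genome at the target GC (+/-2% for >=10 kb) hosting the marker."""
    L_m = len(record.seq)
    if genome_length <= L_m:
        raise ValueError(f"genome_length {genome_length} must exceed marker length {L_m}")
    rng = np.random.default_rng(seed)
    backbone = _random_seq(rng, genome_length - L_m, gc=gc)
    pos = int(rng.integers(0, backbone.size + 1))
    seq = np.concatenate([backbone[:pos], to_bytes(record.seq), backbone[pos:]])
    genome = GenomeRecord(
        id=genome_id or f"genome_{record.id}",
        seq=to_str(seq),
        embedded_markers=((record.id, pos),),
        marker_lengths=(L_m,),
    )
    realized = genome.gc
    if genome_length >= 10_000 and abs(realized - gc) > 0.02:
        logger.warning("genome %s: realized GC %.3f misses target %.3f by >2%% "
                       "(fixed marker composition)", genome.id, realized, gc)
    return genome


def make_even_community(
    db: MarkerDB,
    bacterial_frac: float = 0.12,
    eukaryote_frac: float = 0.02,
    sample_id: str = "even",
    genomes: dict[str, GenomeRecord] | None = None,
    tol: float = 1e-9,
) -> CommunitySample:
    """Even mock community: each bacterial member at ``bacterial_frac`` and
    each eukaryotic member at ``eukaryote_frac`` of total mass; fractions
    must sum to 1."""
    members = []
    for rec in db:
        frac = eukaryote_frac if rec.domain is Domain.EUKARYA else bacterial_frac
        members.append((rec.id, frac))
    total = sum(f for _, f in members)
    if abs(total - 1.0) > tol:
        raise ValueError(f"member fractions sum to {total!r}, not 1")
    return CommunitySample(
        sample_id=sample_id,
        members=members,
        abundance_mode="mass",
        genomes=genomes or {},
    )


def make_spike_series(
    db: MarkerDB,
    spec: SpikePanelSpec,
    background: list[tuple[GenomeRecord, float]],
) -> list[CommunitySample]:
    """One sample per spike level; members share the level's copy number and
    the carrier background is constant across samples."""
    if spec.n_members > len(db):
        raise ValueError(f"panel of {spec.n_members} exceeds database size {len(db)}")
    if not background:
        raise ValueError("spike series requires a non-empty background")
    member_ids = db.ids[: spec.n_members]
    samples = []
    for name, copies in zip(spec.level_names, spec.levels):
        samples.append(
            CommunitySample(
                sample_id=name,
                members=[(rid, float(copies)) for rid in member_ids],
                abundance_mode="copies",
                background=list(background),
            )
        )
    return samples
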