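"""Three-arm sequencing simulation: shotgun, hybridization capture, amplicon.

The physical model, in order of application:

* ``shear`` — fragments are drawn from community sources with probability
  proportional to source weight (abundance x fragment-bearing length) and
  fragment lengths are Normal(mean, sd) truncated at >= 50 nt;
* ``hybridize`` — each fragment's best local alignment against the probe
  set yields an identity I, mapped to a capture probability by a
  piecewise-linear ramp: the off-target floor ``p_background`` below
  ``min_identity``, rising linearly to ``p_on_max`` at I = 1. One
  Bernoulli draw per fragment decides capture;
* ``amplify`` — PCR of primer-matched (UT-bearing) templates with a
  per-template efficiency penalised above 50% GC, compounded over the
  cycle count: weight proportional to (1 + efficiency(GC))^cycles;
* ``sequence_reads`` — paired 2 x 250 nt reads: mate 1 from the fragment's
  5' end, mate 2 reverse-complemented from the 3' end, i.i.d. substitution
  errors, constant quality.

Fragments live in a :class:`FragmentPool` (one concatenated byte buffer +
offset arrays) so that million-fragment pools stay cheap; a
:class:`Fragment` view is available per element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np

from ._seq import _CODE, _COMP, kmer_codes, to_bytes, to_str
from .community_sim import CommunitySample, GenomeRecord
from .marker_db import MarkerDB, MarkerRecord
from .probe_design import ProbeSet

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "SourceSeq", "Fragment", "FragmentPool", "HybridizationModel", "PcrModel",
    "ReadSimParams", "EnrichmentStats", "PairedReads", "LibraryBundle",
    "community_sources", "shear", "hybridize", "amplify", "sequence_reads",
    "build_libraries",
]


# ----------------------------------------------------------------- sources

@dataclass(frozen=True)
class SourceSeq:
    """One template molecule class entering shearing."""

    id: str
    seq: str
    weight: float                      # abundance x fragment-bearing length
    marker_intervals: tuple[tuple[str, int, int], ...] = ()  # (record_id, s, e)


def community_sources(sample: CommunitySample, db: MarkerDB) -> list[SourceSeq]:
    """Expand a community design into weighted shearing templates.

    Copy-number abundances are converted to sampling weights as
    copies x length; mass fractions are used directly (mass is already
    proportional to copies x length).
    """
    sources: list[SourceSeq] = []
    for rid, abundance in sample.members:
        if abundance <= 0:
            continue
        genome = sample.genomes.get(rid)
        if genome is not None:
            seq = genome.seq
            intervals = tuple(genome.marker_intervals())
            sid = genome.id
        else:
            rec = db[rid]
            seq = rec.seq
            intervals = ((rid, 0, len(seq)),)
            sid = rid
        w = abundance * len(seq) if sample.abundance_mode == "copies" else abundance
        sources.append(SourceSeq(id=sid, seq=seq, weight=w, marker_intervals=intervals))
    for genome, weight in sample.background:
        sources.append(
            SourceSeq(
                id=genome.id,
                seq=genome.seq,
                weight=weight,
                marker_intervals=tuple(genome.marker_intervals()),
            )
        )
    return sources


# ------------------------------------------------------------------- pools

@dataclass(frozen=True)
class Fragment:
    """Single-fragment view (0-based half-open coordinates on its source)."""

    source_id: str
    start: int
    end: int
    seq: str
    carries_marker: bool
    marker_id: str | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad fragment interval [{self.start}, {self.end})")


class FragmentPool:
    """Columnar container of fragments sharing one byte buffer."""

    def __init__(
        self,
        buffer: np.ndarray,
        offsets: np.ndarray,
        source_index: np.ndarray,
        source_ids: list[str],
        starts: np.ndarray,
        ends: np.ndarray,
        carries_marker: np.ndarray,
        marker_index: np.ndarray,
        marker_ids: list[str],
        weights: np.ndarray | None = None,
    ):
        self.buffer = buffer
        self.offsets = offsets
        self.source_index = source_index
        self.source_ids = source_ids
        self.starts = starts
        self.ends = ends
        self.carries_marker = carries_marker
        self.marker_index = marker_index        # -1 where no marker
        self.marker_ids = marker_ids
        n = len(self)
        self.weights = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    def __len__(self) -> int:
        return self.offsets.size - 1

    @property
    def lengths(self) -> np.ndarray:
        return self.offsets[1:] - self.offsets[:-1]

    def seq(self, i: int) -> str:
        return to_str(self.buffer[self.offsets[i] : self.offsets[i + 1]])

    def fragment(self, i: int) -> Fragment:
        mi = int(self.marker_index[i])
        return Fragment(
            source_id=self.source_ids[int(self.source_index[i])],
            start=int(self.starts[i]),
            end=int(self.ends[i]),
            seq=self.seq(i),
            carries_marker=bool(self.carries_marker[i]),
            marker_id=self.marker_ids[mi] if mi >= 0 else None,
            weight=float(self.weights[i]),
        )

    def __iter__(self) -> Iterator[Fragment]:
        return (self.fragment(i) for i in range(len(self)))

    def subset(self, mask_or_index: np.ndarray) -> "FragmentPool":
        idx = np.flatnonzero(mask_or_index) if mask_or_index.dtype == bool else mask_or_index
        lens = self.lengths[idx]
        new_offsets = np.concatenate([[0], np.cumsum(lens)])
        buf = np.empty(int(new_offsets[-1]), dtype=np.uint8)
        for j, i in enumerate(idx):
            buf[new_offsets[j] : new_offsets[j + 1]] = self.buffer[
                self.offsets[i] : self.offsets[i + 1]
            ]
        return FragmentPool(
            buffer=buf,
            offsets=new_offsets,
            source_index=self.source_index[idx],
            source_ids=self.source_ids,
            starts=self.starts[idx],
            ends=self.ends[idx],
            carries_marker=self.carries_marker[idx],
            marker_index=self.marker_index[idx],
            marker_ids=self.marker_ids,
            weights=self.weights[idx],
        )

    def marker_fraction(self) -> float:
        """Weight (molecule) fraction of marker-bearing fragments."""
        if len(self) == 0:
            return 0.0
        total = self.weights.sum()
        if total <= 0:
            return 0.0
        return float(self.weights[self.carries_marker].sum() / total)


# ------------------------------------------------------------------ models

@dataclass(frozen=True)
class HybridizationModel:
    """Piecewise-linear identity -> capture-probability map."""

    min_overlap: int = 40
    min_identity: float = 0.55
    p_on_max: float = 0.95
    p_background: float = 1e-4
    seed: int = 0
    seed_k: int = 11
    min_seed_votes: int = 2
    seed_stride: int = 2

    def __post_init__(self) -> None:
        if not (0 <= self.p_background < self.p_on_max <= 1):
            raise ValueError("require 0 <= p_background < p_on_max <= 1")
        if not (0 < self.min_identity < 1):
            raise ValueError("min_identity must lie in (0, 1)")

    def capture_probability(self, identity: float | np.ndarray) -> float | np.ndarray:
        """Capture probability at a given best-probe alignment identity."""
        i = np.asarray(identity, dtype=float)
        ramp = (i - self.min_identity) / (1.0 - self.min_identity)
        p = np.where(
            i < self.min_identity,
            self.p_background,
            self.p_background + (self.p_on_max - self.p_background) * ramp,
        )
        return float(p) if np.isscalar(identity) else p


@dataclass(frozen=True)
class PcrModel:
    """GC-penalised exponential amplification.

    efficiency(GC) = e0 * (1 - b * max(0, GC - 0.5)); template weight after
    ``cycles`` rounds is proportional to (1 + efficiency)^cycles.
    """

    cycles: int = 40
    base_efficiency: float = 0.95
    gc_penalty: float = 0.8

    def efficiency(self, gc: float | np.ndarray) -> float | np.ndarray:
        e = self.base_efficiency * (1.0 - self.gc_penalty * np.maximum(0.0, np.asarray(gc) - 0.5))
        if np.any(e <= 0) or np.any(e > 1):
            raise ValueError("efficiency left (0, 1]; check gc_penalty/base_efficiency")
        return float(e) if np.isscalar(gc) else e


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 250
    paired: bool = True
    substitution_error_rate: float = 0.005
    n_read_pairs: int = 50_000
    seed: int = 0


@dataclass
class EnrichmentStats:
    n_input: int
    n_captured: int
    pre_marker_fraction: float
    post_marker_fraction: float

    @staticmethod
    def _ratio(f: float) -> float:
        return f / (1.0 - f) if f < 1.0 else np.inf

    @property
    def fold_enrichment(self) -> float:
        """Fold change of the marker:non-marker fragment ratio."""
        pre = self._ratio(self.pre_marker_fraction)
        post = self._ratio(self.post_marker_fraction)
        if pre == 0:
            return np.inf if post > 0 else 1.0
        return post / pre

    @property
    def log10_fold_enrichment(self) -> float:
        return float(np.log10(self.fold_enrichment))


# ------------------------------------------------------------------- shear

def shear(
    sources: Sequence[SourceSeq],
    mean_len: float = 500.0,
    sd: float = 150.0,
    n_fragments: int = 200_000,
    seed: int = 0,
    allocation: str = "proportional",
) -> FragmentPool:
    """Randomly fragment weighted sources (sonication stand-in).

    ``allocation`` controls how the simulated fragment budget is spent:

    * ``proportional`` — fragments are drawn across sources in proportion
      to source weight and each simulated fragment has weight 1 (one
      molecule per fragment);
    * ``uniform`` — the budget is split evenly across sources and each
      fragment carries weight w_source / n_source, i.e. it stands for that
      many molecules. This is importance sampling: rare sources are
      resolved finely while a heavy carrier background is represented by
      fewer, heavier fragments. Downstream steps treat weight as molecule
      multiplicity, so count statistics are distributed as in the
      proportional scheme.
    """
    if not sources:
        raise ValueError("no sources to shear")
    if mean_len <= 2 * sd:
        logger.warning("mean fragment length %.0f <= 2*sd %.0f; heavy truncation at 50 nt",
                       mean_len, 2 * sd)
    rng = np.random.default_rng(seed)
    weights = np.array([s.weight for s in sources], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all source weights are zero")
    if allocation == "proportional":
        p = weights / weights.sum()
        src_idx = rng.choice(len(sources), size=n_fragments, p=p)
        frag_weights = np.ones(n_fragments)
    elif allocation == "uniform":
        live = np.flatnonzero(weights > 0)
        per = n_fragments // live.size
        counts_per = np.full(live.size, per, dtype=np.int64)
        counts_per[: n_fragments - per * live.size] += 1
        src_idx = np.repeat(live, counts_per)
        frag_weights = np.repeat(weights[live] / counts_per, counts_per)
        n_fragments = src_idx.size
    else:
        raise ValueError(f"unknown allocation {allocation!r}")
    src_lens = np.array([len(s.seq) for s in sources], dtype=np.int64)
    flens = np.maximum(50, np.rint(rng.normal(mean_len, sd, size=n_fragments))).astype(np.int64)
    L = src_lens[src_idx]
    flens = np.minimum(flens, L)  # fragment never exceeds source bounds
    max_start = L - flens
    starts = (rng.random(n_fragments) * (max_start + 1)).astype(np.int64)
    ends = starts + flens

    offsets = np.concatenate([[0], np.cumsum(flens)])
    buf = np.empty(int(offsets[-1]), dtype=np.uint8)
    src_bytes = [to_bytes(s.seq) for s in sources]
    order = np.argsort(src_idx, kind="stable")
    for i in order:  # grouped by source for locality; simple loop is fine here
        buf[offsets[i] : offsets[i + 1]] = src_bytes[src_idx[i]][starts[i] : ends[i]]

    # marker overlap bookkeeping
    marker_ids: list[str] = []
    marker_pos: dict[str, int] = {}
    carries = np.zeros(n_fragments, dtype=bool)
    marker_index = np.full(n_fragments, -1, dtype=np.int64)
    for si, s in enumerate(sources):
        rows = np.flatnonzero(src_idx == si)
        for rid, ms, me in s.marker_intervals:
            if rid not in marker_pos:
                marker_pos[rid] = len(marker_ids)
                marker_ids.append(rid)
            ov = np.minimum(ends[rows], me) - np.maximum(starts[rows], ms)
            hit = rows[ov > 0]
            carries[hit] = True
            marker_index[hit] = marker_pos[rid]

    return FragmentPool(
        buffer=buf,
        offsets=offsets,
        source_index=src_idx.astype(np.int64),
        source_ids=[s.id for s in sources],
        starts=starts,
        ends=ends,
        carries_marker=carries,
        marker_index=marker_index,
        marker_ids=marker_ids,
        weights=frag_weights,
    )


# --------------------------------------------------------------- hybridize
#
# Hybridization is scored on ungapped duplex identity: the best probe
# placement (a diagonal, either strand) is evaluated as the fraction of
# matching bases over the geometric probe/fragment overlap, which must span
# >= min_overlap nt. Unrelated sequences score ~0.3 under this measure,
# well below the 0.55 capture threshold, while gapped edit-style identity
# would sit near the threshold for random pairs. Candidate diagonals come
# from shared seed k-mers; requiring two seed hits on the same diagonal
# makes chance evaluations vanishingly rare.

def _probe_kmer_index(probes: ProbeSet, k: int):
    """Sorted k-mer codes with CSR expansion to (probe, position) entries."""
    codes_all, pidx_all, ppos_all = [], [], []
    for j, p in enumerate(probes):
        c = kmer_codes(to_bytes(p.seq), k)
        keep = c >= 0
        codes_all.append(c[keep])
        ppos_all.append(np.flatnonzero(keep).astype(np.int64))
        pidx_all.append(np.full(int(keep.sum()), j, dtype=np.int64))
    codes = np.concatenate(codes_all)
    pidx = np.concatenate(pidx_all)
    ppos = np.concatenate(ppos_all)
    order = np.argsort(codes, kind="stable")
    codes, pidx, ppos = codes[order], pidx[order], ppos[order]
    uniq, starts = np.unique(codes, return_index=True)
    bounds = np.concatenate([starts, [codes.size]])
    return uniq, bounds, pidx, ppos


def ungapped_overlap_identity(
    probe: str | np.ndarray, fragment: str | np.ndarray, diag: int, min_overlap: int
) -> float:
    """Match fraction of a probe placed at fragment offset ``diag``.

    The identity is computed over the geometric overlap of the placed probe
    with the fragment; overlaps shorter than ``min_overlap`` score 0.
    """
    p = to_bytes(probe) if isinstance(probe, str) else probe
    f = to_bytes(fragment) if isinstance(fragment, str) else fragment
    a = max(0, -diag)                      # probe-local overlap start
    b = min(p.size, f.size - diag)         # probe-local overlap end
    if b - a < min_overlap:
        return 0.0
    return float(np.count_nonzero(p[a:b] == f[diag + a : diag + b]) / (b - a))


def best_probe_identity(
    fragment_seq: str,
    probes: ProbeSet,
    model: HybridizationModel,
    candidates: Sequence[int] | None = None,
) -> float:
    """Best ungapped overlap identity of any probe against one fragment.

    Exhaustive over placements and both strands (brute force; the pooled
    ``hybridize`` path reaches the same placements through seed diagonals).
    """
    plist = list(probes)
    cand = range(len(plist)) if candidates is None else candidates
    frag_fwd = to_bytes(fragment_seq)
    frag_rev = _COMP[frag_fwd[::-1]]
    best = 0.0
    for j in cand:
        p = to_bytes(plist[j].seq)
        for f in (frag_fwd, frag_rev):
            for diag in range(-(p.size - model.min_overlap),
                              f.size - model.min_overlap + 1):
                ident = ungapped_overlap_identity(p, f, diag, model.min_overlap)
                if ident > best:
                    best = ident
    return best


def hybridize(
    pool: FragmentPool,
    probes: ProbeSet,
    model: HybridizationModel | None = None,
) -> tuple[FragmentPool, EnrichmentStats]:
    """Bait-capture a fragment pool; returns the captured pool and stats."""
    model = model or HybridizationModel()
    if len(probes) == 0:
        raise ValueError("probe set is empty")
    rng = np.random.default_rng(model.seed)
    k = model.seed_k
    uniq, bounds, pidx, ppos = _probe_kmer_index(probes, k)
    n = len(pool)
    identities = np.zeros(n, dtype=float)
    plen = np.array([len(p.seq) for p in probes], dtype=np.int64)
    probe_bytes = [to_bytes(p.seq) for p in probes]
    max_flen = int(pool.lengths.max()) if n else 0
    diag_span = max_flen + int(plen.max()) + 1

    # dense membership table: O(1) prescreen per sampled window
    member = np.zeros(4**k, dtype=bool)
    member[uniq] = True

    # seed prescreen over the concatenated buffer (both strands)
    for strand in (0, 1):
        buf = pool.buffer if strand == 0 else _COMP[pool.buffer[::-1]]
        offs = pool.offsets if strand == 0 else (pool.buffer.size - pool.offsets[::-1])
        base_codes = _CODE[buf]
        n_windows = max(0, buf.size - k + 1)
        keys_parts = []
        chunk = 8_000_000
        for c0 in range(0, n_windows, chunk * model.seed_stride):
            wpos = np.arange(c0, min(n_windows, c0 + chunk * model.seed_stride),
                             model.seed_stride)
            acc = np.zeros(wpos.size, dtype=np.int64)
            bad = np.zeros(wpos.size, dtype=bool)
            for j in range(k):
                b = base_codes[wpos + j]
                bad |= b == 255
                acc = (acc << 2) | (b & 3)
            frag_j = np.searchsorted(offs, wpos, side="right") - 1
            # windows spanning a fragment boundary are chimeric: drop them
            ok = ~bad & (wpos + k <= offs[frag_j + 1]) & member[acc]
            if not ok.any():
                continue
            codes_ok = acc[ok]
            local_pos = (wpos - offs[frag_j])[ok]
            frag_of = frag_j[ok] if strand == 0 else (len(pool) - 1) - frag_j[ok]
            pos = np.searchsorted(uniq, codes_ok)
            counts = bounds[pos + 1] - bounds[pos]
            total = int(counts.sum())
            flat = np.repeat(bounds[pos], counts) + (
                np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
            )
            frag_rep = np.repeat(frag_of, counts)
            local_rep = np.repeat(local_pos, counts)
            probe_rep = pidx[flat]
            diag_rep = local_rep - ppos[flat]  # probe placement offset on fragment
            keys_parts.append(
                (frag_rep * plen.size + probe_rep) * diag_span
                + (diag_rep + plen.max())
            )
        if not keys_parts:
            continue
        key_u, votes = np.unique(np.concatenate(keys_parts), return_counts=True)
        key_u = key_u[votes >= model.min_seed_votes]
        if key_u.size == 0:
            continue
        diag_u = (key_u % diag_span) - int(plen.max())
        fp = key_u // diag_span
        frag_u = fp // plen.size
        probe_u = fp % plen.size
        for fi, pj, dg in zip(frag_u.tolist(), probe_u.tolist(), diag_u.tolist()):
            fbytes = pool.buffer[pool.offsets[fi] : pool.offsets[fi + 1]]
            if strand == 1:
                fbytes = _COMP[fbytes[::-1]]
            ident = ungapped_overlap_identity(
                probe_bytes[pj], fbytes, int(dg), model.min_overlap
            )
            if ident > identities[fi]:
                identities[fi] = ident

    # one Bernoulli draw per molecule: a fragment of weight w stands for
    # round(w/q) molecules (q = smallest fragment weight), thinned with a
    # Binomial draw — identical in distribution to per-molecule Bernoulli
    p_capture = model.capture_probability(identities)
    w = pool.weights
    positive = w[w > 0]
    q = float(positive.min()) if positive.size else 1.0
    mult = np.maximum(np.rint(w / q), 0.0).astype(np.int64)
    captured_mult = rng.binomial(mult, p_capture)
    keep = captured_mult > 0
    captured = pool.subset(keep)
    captured.weights = captured_mult[keep] * q
    stats = EnrichmentStats(
        n_input=n,
        n_captured=len(captured),
        pre_marker_fraction=pool.marker_fraction(),
        post_marker_fraction=captured.marker_fraction(),
    )
    return captured, stats


# ----------------------------------------------------------------- amplify

def amplify(
    templates: FragmentPool,
    model: PcrModel | None = None,
    target_predicate: Callable[[Fragment], bool] | None = None,
) -> FragmentPool:
    """Weight primer-matched templates by GC-dependent PCR gain.

    Non-target templates get weight 0; target weights are proportional to
    (1 + efficiency(GC))^cycles, normalized to sum to 1 (computed in log
    space so large cycle counts stay finite).
    """
    model = model or PcrModel()
    if target_predicate is None:
        target_predicate = lambda f: f.carries_marker  # noqa: E731
    is_target = np.array([bool(target_predicate(f)) for f in templates], dtype=bool)
    if not is_target.any():
        raise ValueError("no primer-matched (UT-containing) template in pool")
    gcs = np.zeros(len(templates))
    for i in np.flatnonzero(is_target):
        frag = templates.buffer[templates.offsets[i] : templates.offsets[i + 1]]
        gcs[i] = np.count_nonzero((frag == ord("G")) | (frag == ord("C"))) / frag.size
    logw = np.full(len(templates), -np.inf)
    eff = model.efficiency(gcs[is_target])
    logw[is_target] = model.cycles * np.log1p(eff)
    logw[is_target] -= logw[is_target].max()
    w = np.exp(logw)
    w[~is_target] = 0.0
    w /= w.sum()
    out = templates.subset(np.arange(len(templates)))
    out.weights = w
    return out


# --------------------------------------------------------------- sequencing

class PairedReads:
    """Paired-end reads in columnar form, with ground truth attached."""

    def __init__(
        self,
        r1: np.ndarray,
        r2: np.ndarray,
        l1: np.ndarray,
        l2: np.ndarray,
        source_ids: list[str],
        source_index: np.ndarray,
        carries_marker: np.ndarray,
        ids: list[str] | None = None,
    ):
        self.r1, self.r2 = r1, r2
        self.l1, self.l2 = l1, l2
        self.source_ids = source_ids
        self.source_index = source_index
        self.carries_marker = carries_marker
        self._ids = ids

    def __len__(self) -> int:
        return self.r1.shape[0]

    @property
    def ids(self) -> list[str]:
        if self._ids is None:
            self._ids = [
                f"read{i}|{self.source_ids[int(self.source_index[i])]}"
                for i in range(len(self))
            ]
        return self._ids

    def pair(self, i: int) -> tuple[str, str, str]:
        return (
            self.ids[i],
            to_str(self.r1[i, : self.l1[i]]),
            to_str(self.r2[i, : self.l2[i]]),
        )

    def marker_fraction(self) -> float:
        return float(self.carries_marker.mean()) if len(self) else 0.0

    def to_fastq(self, r1_path: str | Path, r2_path: str | Path) -> None:
        for path, mat, lens, mate in ((r1_path, self.r1, self.l1, 1),
                                      (r2_path, self.r2, self.l2, 2)):
            with open(path, "w") as fh:
                for i in range(len(self)):
                    seq = to_str(mat[i, : lens[i]])
                    fh.write(f"@{self.ids[i]}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")

    @classmethod
    def from_fastq(cls, r1_path: str | Path, r2_path: str | Path) -> "PairedReads":
        def read_fq(path):
            ids, seqs = [], []
            with open(path) as fh:
                while True:
                    h = fh.readline()
                    if not h:
                        break
                    seq = fh.readline().strip()
                    fh.readline()
                    fh.readline()
                    ids.append(h[1:].strip().rsplit("/", 1)[0])
                    seqs.append(seq)
            return ids, seqs

        ids1, s1 = read_fq(r1_path)
        ids2, s2 = read_fq(r2_path)
        if ids1 != ids2:
            raise ValueError("mate files disagree on read ids/order")
        n = len(s1)
        m1 = max((len(s) for s in s1), default=0)
        m2 = max((len(s) for s in s2), default=0)
        r1 = np.zeros((n, m1), dtype=np.uint8)
        r2 = np.zeros((n, m2), dtype=np.uint8)
        l1 = np.zeros(n, dtype=np.int64)
        l2 = np.zeros(n, dtype=np.int64)
        for i, (a, b) in enumerate(zip(s1, s2)):
            r1[i, : len(a)] = to_bytes(a)
            r2[i, : len(b)] = to_bytes(b)
            l1[i], l2[i] = len(a), len(b)
        src = [rid.split("|", 1)[1] if "|" in rid else "?" for rid in ids1]
        uniq = sorted(set(src))
        lut = {s: j for j, s in enumerate(uniq)}
        return cls(
            r1, r2, l1, l2,
            source_ids=uniq,
            source_index=np.array([lut[s] for s in src], dtype=np.int64),
            carries_marker=np.zeros(n, dtype=bool),
            ids=ids1,
        )


def _inject_errors(mat: np.ndarray, lens: np.ndarray, rate: float,
                   rng: np.random.Generator, chunk: int = 100_000) -> None:
    if rate <= 0:
        return
    n, w = mat.shape
    col = np.arange(w)
    for s0 in range(0, n, chunk):
        sl = slice(s0, min(n, s0 + chunk))
        block = mat[sl]
        valid = col[None, :] < lens[sl, None]
        mask = (rng.random(block.shape) < rate) & valid
        rows, cols = np.nonzero(mask)
        if rows.size == 0:
            continue
        orig = _CODE[block[rows, cols]].astype(np.int64)
        shift = rng.integers(1, 4, size=rows.size)
        block[rows, cols] = _BASES[(orig + shift) % 4]


def sequence_reads(pool: FragmentPool, params: ReadSimParams | None = None) -> PairedReads:
    """Draw read pairs with replacement proportional to fragment weight."""
    params = params or ReadSimParams()
    if len(pool) == 0:
        raise ValueError("cannot sequence an empty pool")
    rng = np.random.default_rng(params.seed)
    w = pool.weights
    if w.sum() <= 0:
        raise ValueError("pool weights sum to zero")
    p = w / w.sum()
    frag_idx = rng.choice(len(pool), size=params.n_read_pairs, p=p)
    rl = params.read_length
    flens = pool.lengths[frag_idx]
    offs = pool.offsets[frag_idx]
    fends = pool.offsets[frag_idx + 1]
    col = np.arange(rl)
    n_pairs = params.n_read_pairs

    l1 = np.minimum(rl, flens)
    l2 = np.minimum(rl, flens)
    r1 = np.zeros((n_pairs, rl), dtype=np.uint8)
    r2 = np.zeros((n_pairs, rl), dtype=np.uint8)
    chunk = 100_000
    for s0 in range(0, n_pairs, chunk):
        sl = slice(s0, min(n_pairs, s0 + chunk))
        idx1 = np.minimum(offs[sl, None] + col[None, :], fends[sl, None] - 1)
        r1[sl] = pool.buffer[idx1]
        r1[sl][col[None, :] >= l1[sl, None]] = 0
        idx2 = np.maximum(fends[sl, None] - 1 - col[None, :], offs[sl, None])
        r2[sl] = _COMP[pool.buffer[idx2]]
        r2[sl][col[None, :] >= l2[sl, None]] = 0

    _inject_errors(r1, l1, params.substitution_error_rate, rng)
    _inject_errors(r2, l2, params.substitution_error_rate, rng)

    return PairedReads(
        r1=r1, r2=r2, l1=l1, l2=l2,
        source_ids=pool.source_ids,
        source_index=pool.source_index[frag_idx],
        carries_marker=pool.carries_marker[frag_idx],
    )


# ------------------------------------------------------------ orchestration

@dataclass
class LibraryBundle:
    """The three arms plus ground truth and a reproducibility manifest."""

    capture: PairedReads
    shotgun: PairedReads
    amplicon: PairedReads
    enrichment: EnrichmentStats
    truth: dict[str, float]
    manifest: dict

    @property
    def arms(self) -> dict[str, PairedReads]:
        return {"capture": self.capture, "shotgun": self.shotgun, "amplicon": self.amplicon}


def _amplicon_templates(sample: CommunitySample, db: MarkerDB) -> FragmentPool:
    """UT-region templates entering the amplicon arm, weighted by copies."""
    seqs: list[np.ndarray] = []
    ids: list[str] = []
    weights: list[float] = []
    for rid, abundance in sample.members:
        if abundance <= 0:
            continue
        seqs.append(to_bytes(db[rid].ut_seq))
        ids.append(rid)
        weights.append(abundance)
    for genome, weight in sample.background:
        for rid, _s, _e in genome.marker_intervals():
            if rid in db:
                seqs.append(to_bytes(db[rid].ut_seq))
                ids.append(rid)
                # genome copies ~ weight / genome length
                weights.append(weight / len(genome.seq))
    if not seqs:
        raise ValueError("no UT-bearing template for the amplicon arm")
    lens = np.array([s.size for s in seqs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    buf = np.concatenate(seqs)
    n = len(seqs)
    pool = FragmentPool(
        buffer=buf,
        offsets=offsets,
        source_index=np.arange(n, dtype=np.int64),
        source_ids=ids,
        starts=np.zeros(n, dtype=np.int64),
        ends=lens.copy(),
        carries_marker=np.ones(n, dtype=bool),
        marker_index=np.arange(n, dtype=np.int64),
        marker_ids=ids,
        weights=np.array(weights, dtype=float),
    )
    return pool


def build_libraries(
    sample: CommunitySample,
    db: MarkerDB,
    probes: ProbeSet,
    hyb_model: HybridizationModel | None = None,
    pcr_model: PcrModel | None = None,
    read_params: ReadSimParams | None = None,
    n_fragments: int = 200_000,
    fragment_mean: float = 500.0,
    fragment_sd: float = 150.0,
    seed: int = 0,
    allocation: str = "proportional",
) -> LibraryBundle:
    """Run all three arms for one community sample under one master seed."""
    hyb_model = hyb_model or HybridizationModel()
    pcr_model = pcr_model or PcrModel()
    read_params = read_params or ReadSimParams()
    master = np.random.default_rng(seed)
    sub = master.integers(0, 2**31 - 1, size=5)

    sources = community_sources(sample, db)
    pool = shear(sources, fragment_mean, fragment_sd, n_fragments, seed=int(sub[0]),
                 allocation=allocation)

    shotgun = sequence_reads(pool, replace(read_params, seed=int(sub[1])))

    captured, stats = hybridize(pool, probes, replace(hyb_model, seed=int(sub[2])))
    if len(captured) == 0:
        raise ValueError("capture arm produced an empty pool")
    capture_reads = sequence_reads(captured, replace(read_params, seed=int(sub[3])))

    templates = _amplicon_templates(sample, db)
    amplified = amplify(templates, pcr_model, target_predicate=lambda f: f.carries_marker)
    amplicon_reads = sequence_reads(amplified, replace(read_params, seed=int(sub[4])))

    manifest = {
        "sample_id": sample.sample_id,
        "seed": int(seed),
        "arm_seeds": {
            "shear": int(sub[0]), "shotgun": int(sub[1]), "hybridize": int(sub[2]),
            "capture_reads": int(sub[3]), "amplicon_reads": int(sub[4]),
        },
        "n_fragments": int(n_fragments),
        "allocation": allocation,
        "fragment_mean": float(fragment_mean),
        "fragment_sd": float(fragment_sd),
        "read_params": {
            "read_length": read_params.read_length,
            "substitution_error_rate": read_params.substitution_error_rate,
            "n_read_pairs": read_params.n_read_pairs,
        },
        "hybridization": {
            "min_overlap": hyb_model.min_overlap,
            "min_identity": hyb_model.min_identity,
            "p_on_max": hyb_model.p_on_max,
            "p_background": hyb_model.p_background,
        },
        "pcr": {
            "cycles": pcr_model.cycles,
            "base_efficiency": pcr_model.base_efficiency,
            "gc_penalty": pcr_model.gc_penalty,
        },
    }
    return LibraryBundle(
        capture=capture_reads,
        shotgun=shotgun,
        amplicon=amplicon_reads,
        enrichment=stats,
        truth=sample.truth_table(),
        manifest=manifest,
    )
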