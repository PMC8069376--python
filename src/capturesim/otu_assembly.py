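"""Targeted OTU assembly and sub-OTU (ASV) calling from cluster read bins.

The assembler is a small de Bruijn unitig builder, the desk-scale analogue
of a full transcriptome assembler run per taxonomic cluster: k-mers
(default k=31) from both mates and their reverse complements are counted,
low-coverage k-mers (below ``min_kmer_count``) dropped, and maximal
unambiguous paths emitted as contigs. This is method-analogous, not
tool-identical — no graph phasing, tips and bubbles are handled only
through the coverage floor, which suffices at low substitution error
rates.

Sub-OTU (sOTU / ASV) calling is likewise a simplified denoiser: reads are
anchored on the universal target (UT) start of their cluster's reference,
reverse-orientation reads are reverse-complemented, everything is trimmed
to exactly ``trim_length`` nt (default 220, i.e. UT nucleotides 1-220 in
1-based terms), and exact sequence variants are collapsed with abundance
floors. Variants differing by a single nucleotide stay distinct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter

import numpy as np

from ._align import align_local, global_identity, infix_distance
from ._seq import reverse_complement, to_bytes, to_str, _COMP
from .capture_sim import PairedReads
from .marker_db import MarkerRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AssemblyParams", "Contig", "SotuParams", "ASV",
    "assemble_cluster", "contig_identity", "trim_to_sotu", "call_asvs",
]


@dataclass(frozen=True)
class AssemblyParams:
    """De Bruijn assembly thresholds.

    ``dominance_ratio`` resolves branches caused by recurring sequencing
    errors: at a fork, the heaviest edge is followed when it outweighs
    every alternative by this factor. Genuine haplotype splits (balanced
    coverage) are never resolved and terminate the unitig.
    """

    k: int = 31
    min_kmer_count: int = 2
    min_contig_len: int = 200
    dominance_ratio: float = 10.0

    def __post_init__(self) -> None:
        if self.k < 15 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 15")


@dataclass(frozen=True)
class Contig:
    cluster_id: str
    seq: str
    mean_coverage: float
    identity_to_truth: float | None = None

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SotuParams:
    """Sub-OTU window and denoising thresholds.

    Variants are absorbed into a dominant variant when they differ by at
    most ``max_absorb_dist`` mismatches and are at least ``absorb_ratio``
    times rarer — the minimal stand-in for model-based read error
    correction. Genuine single-nucleotide variants of comparable abundance
    are never merged.
    """

    trim_length: int = 220
    min_count: int = 2
    min_fraction: float = 0.001
    max_absorb_dist: int = 1
    absorb_ratio: float = 10.0


@dataclass(frozen=True)
class ASV:
    seq: str
    abundance: int
    cluster_id: str


def _sequences_of(reads: PairedReads | list[str]) -> list[str]:
    if isinstance(reads, PairedReads):
        out = []
        for i in range(len(reads)):
            out.append(to_str(reads.r1[i, : reads.l1[i]]))
            out.append(to_str(reads.r2[i, : reads.l2[i]]))
        return out
    return list(reads)


def _kmer_code_arrays(seqs: list[str], k: int) -> np.ndarray:
    """All valid k-mer codes (both strands) across the read set."""
    from ._seq import kmer_codes

    parts = []
    for s in seqs:
        arr = to_bytes(s)
        if arr.size < k:
            continue
        for a in (arr, _COMP[arr[::-1]]):
            c = kmer_codes(a, k)
            parts.append(c[c >= 0])
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)


def _decode(code: int, k: int) -> str:
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode()


def assemble_cluster(
    reads: PairedReads | list[str],
    params: AssemblyParams | None = None,
    cluster_id: str = "cluster",
    truth: MarkerRecord | str | None = None,
) -> list[Contig]:
    """Assemble one cluster's read bin into unitig contigs, longest first."""
    params = params or AssemblyParams()
    seqs = _sequences_of(reads)
    if not seqs:
        raise ValueError("empty read bin")
    k = params.k
    codes = _kmer_code_arrays(seqs, k)
    if codes.size == 0:
        logger.warning("cluster %s: no k-mers at k=%d", cluster_id, k)
        return []
    uniq, counts = np.unique(codes, return_counts=True)
    keep = counts >= params.min_kmer_count
    uniq, counts = uniq[keep], counts[keep]
    if uniq.size == 0:
        logger.warning("cluster %s: no k-mer above coverage floor", cluster_id)
        return []
    count_of = dict(zip(uniq.tolist(), counts.tolist()))
    kmers = set(count_of)
    mask = (1 << (2 * (k - 1))) - 1

    ratio = params.dominance_ratio

    def successors(c: int) -> list[int]:
        suf = (c & mask) << 2
        return [suf | b for b in range(4) if (suf | b) in kmers]

    def predecessors(c: int) -> list[int]:
        pre = c >> 2
        return [pre | (b << (2 * (k - 1))) for b in range(4)
                if (pre | (b << (2 * (k - 1)))) in kmers]

    def resolve(cands: list[int]) -> int | None:
        """Unique neighbour, or the dominant one at an error-like fork."""
        if len(cands) == 1:
            return cands[0]
        if not cands:
            return None
        ordered = sorted(cands, key=lambda c: (-count_of[c], c))
        if count_of[ordered[0]] >= ratio * count_of[ordered[1]]:
            return ordered[0]
        return None

    visited: set[int] = set()
    contigs: list[tuple[str, float]] = []
    # walk unitigs from deterministic start nodes (sorted codes)
    for start in uniq.tolist():
        if start in visited:
            continue
        pred = resolve(predecessors(start))
        is_start = pred is None or resolve(successors(pred)) != start
        if not is_start:
            continue
        path = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = resolve(successors(cur))
            if nxt is None or nxt in visited or resolve(predecessors(nxt)) != cur:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        seq = _decode(path[0], k) + "".join(_decode(c, k)[-1] for c in path[1:])
        cov = float(np.mean([count_of[c] for c in path]))
        contigs.append((seq, cov))
    # orphan cycles (rare): emit remaining nodes as singleton paths
    for c in uniq.tolist():
        if c not in visited:
            visited.add(c)
            contigs.append((_decode(c, k), float(count_of[c])))

    # collapse strand duplicates (each unitig appears once per strand)
    seen: set[str] = set()
    out: list[Contig] = []
    for seq, cov in sorted(contigs, key=lambda t: (-len(t[0]), t[0])):
        canon = min(seq, reverse_complement(seq))
        if canon in seen:
            continue
        seen.add(canon)
        if len(seq) < params.min_contig_len:
            continue
        ident = None
        if truth is not None:
            tseq = truth.seq if isinstance(truth, MarkerRecord) else truth
            ident = contig_identity(seq, tseq)[0]
        out.append(Contig(cluster_id=cluster_id, seq=seq, mean_coverage=cov,
                          identity_to_truth=ident))
    if not out:
        logger.warning("cluster %s: no contig above %d nt", cluster_id, params.min_contig_len)
    return out


def contig_identity(contig: str | Contig, truth: str | MarkerRecord) -> tuple[float, int]:
    """Identity of a contig to its truth sequence over the aligned region.

    Local alignment on the better strand (same scoring scheme as the
    profiler); returns (identity, aligned columns). Unrelated sequences
    report whatever weak local identity exists (typically < 0.6) and are
    the caller's to flag.
    """
    cseq = contig.seq if isinstance(contig, Contig) else contig
    tseq = truth.seq if isinstance(truth, MarkerRecord) else truth
    best = (0.0, 0)
    for q in (cseq, reverse_complement(cseq)):
        res = align_local(q, tseq)
        if res is not None and res.identity * res.aligned_length > best[0] * best[1]:
            best = (res.identity, res.aligned_length)
    return best


def _locate(read: str, ref: str) -> tuple[int, int, bool] | None:
    """(ref_start, edit_distance, is_reverse) of the better-strand placement."""
    fwd = infix_distance(read, ref)
    rev = infix_distance(reverse_complement(read), ref)
    cands = []
    if fwd is not None:
        cands.append((fwd[0], fwd[1][0], False))
    if rev is not None:
        cands.append((rev[0], rev[1][0], True))
    if not cands:
        return None
    d, start, is_rev = min(cands)
    return start, d, is_rev


def trim_to_sotu(
    reads: PairedReads | list[str],
    reference: MarkerRecord,
    params: SotuParams | None = None,
    max_edit_fraction: float = 0.3,
) -> list[str]:
    """Anchor reads at the reference UT start and trim to the sOTU window.

    Reads in reverse orientation are reverse-complemented first. A read is
    kept only if its placement on the reference covers the whole window
    ``[ut_start, ut_start + trim_length)``; the emitted substring is
    exactly ``trim_length`` nt. Placement uses best-strand infix alignment;
    with a substitution-only error model read/reference offsets are exact.
    """
    params = params or SotuParams()
    ut_start = reference.ut_interval[0]
    out: list[str] = []
    for s in _sequences_of(reads):
        loc = _locate(s, reference.seq)
        if loc is None:
            continue
        start, dist, is_rev = loc
        if dist > max_edit_fraction * len(s):
            continue
        oriented = reverse_complement(s) if is_rev else s
        lo = ut_start - start
        hi = lo + params.trim_length
        if lo < 0 or hi > len(oriented):
            continue  # does not cover the full sOTU window
        out.append(oriented[lo:hi])
    return out


def call_asvs(trimmed: list[str], params: SotuParams | None = None,
              cluster_id: str = "cluster") -> list[ASV]:
    """Collapse exact sequence variants, denoise, and apply abundance floors.

    Rare variants within ``max_absorb_dist`` mismatches of a >=
    ``absorb_ratio``-fold more abundant accepted variant are folded into
    it (sequencing-error shadows); survivors below the ``min_count`` /
    ``min_fraction`` floor are dropped. Deterministic and invariant to
    read order: output sorted by descending abundance, ties by sequence.
    """
    params = params or SotuParams()
    for s in trimmed:
        if len(s) != params.trim_length:
            raise ValueError(
                f"ASV input must be exactly {params.trim_length} nt, got {len(s)}"
            )
    total = len(trimmed)
    counts = Counter(trimmed)
    variants = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    accepted: list[tuple[np.ndarray, str]] = []
    acc_counts: dict[str, int] = {}
    for seq, n in variants:
        arr = to_bytes(seq)
        absorbed = False
        for host_arr, host_seq in accepted:
            if acc_counts[host_seq] >= params.absorb_ratio * n and (
                int((host_arr != arr).sum()) <= params.max_absorb_dist
            ):
                acc_counts[host_seq] += n
                absorbed = True
                break
        if not absorbed:
            accepted.append((arr, seq))
            acc_counts[seq] = acc_counts.get(seq, 0) + n
    floor = max(params.min_count, int(np.ceil(params.min_fraction * total)))
    asvs = [
        ASV(seq=seq, abundance=n, cluster_id=cluster_id)
        for seq, n in acc_counts.items()
        if n >= floor
    ]
    asvs.sort(key=lambda a: (-a.abundance, a.seq))
    return asvs
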