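"""Read-pair classification against the marker database.

The mapper mirrors what a local paired aligner does for taxonomic
clustering, at desk scale: an exhaustive k-mer index over both strands of
every reference proposes candidate records (votes), candidate alignments
are scored with the fixed local scheme, and the pair is assigned to the
single record maximizing the summed mate score — requiring both mates to
hit the same record at >= 70% identity over >= 50 nt, ties broken by
lexicographically smallest record id. One taxonomic cluster per reference
record; unmapped is a value, not an error.

Down-sampling to a fixed depth is hypergeometric (without replacement),
matching rarefaction of a count column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._align import align_infix, approx_result_from_distance, infix_distance, AlignResult
from ._seq import _COMP, kmer_codes, to_bytes, to_str
from .capture_sim import PairedReads
from .marker_db import ClusterCountTable, MarkerDB

logger = logging.getLogger(__name__)

__all__ = [
    "AlignIndex", "AlignmentHit", "DownsampleParams", "build_index",
    "map_read_pair", "profile_sample", "downsample", "relative_abundance",
    "ProfileResult",
]

#: §2.5 inter-technique depth and §2.5/§2.9 per-method smallest-library depths
DOWNSAMPLE_PRESETS = {
    "inter_technique": 2777,
    "intra_shotgun": 2777,
    "intra_capture": 127_642,
    "intra_amplicon": 27_388,
    "spike_amplicon": 30_091,
    "spike_capture": 506_247,
}

MIN_IDENTITY = 0.7
MIN_ALIGNED = 50


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    record_id: str
    strand: str  # "+" or "-"
    score: int
    identity: float
    ref_interval: tuple[int, int]


@dataclass(frozen=True)
class DownsampleParams:
    depth: int = DOWNSAMPLE_PRESETS["inter_technique"]
    seed: int = 0


class AlignIndex:
    """Complete k-mer index over both strands of every reference."""

    def __init__(self, db: MarkerDB, k: int = 11):
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.db = db
        self.k = k
        self.record_ids: list[str] = []
        self.ref_seqs: list[str] = []
        codes_all, tag_all = [], []
        for rec in db:
            if len(rec.seq) < k:
                logger.warning("reference %s shorter than k=%d: skipped", rec.id, k)
                continue
            rid_idx = len(self.record_ids)
            self.record_ids.append(rec.id)
            self.ref_seqs.append(rec.seq)
            fwd = to_bytes(rec.seq)
            for strand, arr in ((0, fwd), (1, _COMP[fwd[::-1]])):
                c = kmer_codes(arr, k)
                c = np.unique(c[c >= 0])
                codes_all.append(c)
                tag_all.append(np.full(c.size, rid_idx * 2 + strand, dtype=np.int64))
        if not self.record_ids:
            raise ValueError("no reference long enough to index")
        codes = np.concatenate(codes_all)
        tags = np.concatenate(tag_all)
        order = np.argsort(codes, kind="stable")
        codes, tags = codes[order], tags[order]
        self._codes, starts = np.unique(codes, return_index=True)
        self._bounds = np.concatenate([starts, [codes.size]])
        self._tags = tags
        self.n_refs = len(self.record_ids)

    def n_seeds(self, record_id: str, strand: str = "+") -> int:
        """Number of distinct seed k-mers indexed for one record strand."""
        rid_idx = self.record_ids.index(record_id)
        tag = rid_idx * 2 + (0 if strand == "+" else 1)
        return int(np.count_nonzero(self._tags == tag))

    def votes_for_codes(self, codes: np.ndarray, row_of_code: np.ndarray,
                        n_rows: int) -> np.ndarray:
        """Dense (n_rows, 2*n_refs) seed-vote matrix for a code batch."""
        valid = codes >= 0
        pos = np.searchsorted(self._codes, codes[valid])
        inb = pos < self._codes.size
        pos_ok = np.zeros(pos.size, dtype=bool)
        pos_ok[inb] = self._codes[pos[inb]] == codes[valid][inb]
        rows = row_of_code[valid][pos_ok]
        vpos = pos[pos_ok]
        counts = self._bounds[vpos + 1] - self._bounds[vpos]
        total = int(counts.sum())
        if total == 0:
            return np.zeros((n_rows, 2 * self.n_refs), dtype=np.int32)
        flat = np.repeat(self._bounds[vpos], counts) + (
            np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        )
        tag_rep = self._tags[flat]
        row_rep = np.repeat(rows, counts)
        votes = np.bincount(
            row_rep * (2 * self.n_refs) + tag_rep, minlength=n_rows * 2 * self.n_refs
        )
        return votes.reshape(n_rows, 2 * self.n_refs).astype(np.int32)


def build_index(db: MarkerDB, k: int = 11) -> AlignIndex:
    return AlignIndex(db, k=k)


def _read_codes(mat: np.ndarray, lens: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Sampled k-mer codes for a padded read matrix; returns (codes, row)."""
    n, w = mat.shape
    cols = np.arange(0, max(1, w - k + 1), stride)
    out_codes = np.full((n, cols.size), -1, dtype=np.int64)
    flat = mat.reshape(-1)
    base = np.arange(n)[:, None] * w + cols[None, :]
    from ._seq import _CODE
    acc = np.zeros((n, cols.size), dtype=np.int64)
    bad = np.zeros((n, cols.size), dtype=bool)
    for j in range(k):
        b = _CODE[flat[base + j]].astype(np.int64)
        bad |= b == 255
        acc = (acc << 2) | np.where(b == 255, 0, b)
    valid_win = cols[None, :] + k <= lens[:, None]
    out_codes = np.where(valid_win & ~bad, acc, -1)
    rows = np.repeat(np.arange(n), cols.size)
    return out_codes.reshape(-1), rows


def _pair_candidates(index: AlignIndex, reads: PairedReads, stride: int,
                     min_votes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-2 candidate (record, strand-of-mate1) per pair by joint seed votes."""
    n = len(reads)
    k = index.k
    c1, r1rows = _read_codes(reads.r1, reads.l1, k, stride)
    c2, r2rows = _read_codes(reads.r2, reads.l2, k, stride)
    v1 = index.votes_for_codes(c1, r1rows, n)  # (n, 2*n_refs)
    v2 = index.votes_for_codes(c2, r2rows, n)
    nr = index.n_refs
    # mate1 on strand s pairs with mate2 on the opposite strand
    joint_fwd = v1[:, 0::2] + v2[:, 1::2]   # mate1 +, mate2 -
    joint_rev = v1[:, 1::2] + v2[:, 0::2]
    strand_is_rev = joint_rev > joint_fwd
    joint = np.where(strand_is_rev, joint_rev, joint_fwd)
    top1 = np.argmax(joint, axis=1)
    jcopy = joint.copy()
    jcopy[np.arange(n), top1] = -1
    top2 = np.argmax(jcopy, axis=1)
    votes1 = joint[np.arange(n), top1]
    votes2 = jcopy[np.arange(n), top2]
    cand = np.stack([top1, top2], axis=1)
    cand_votes = np.stack([votes1, votes2], axis=1)
    strands = np.stack(
        [strand_is_rev[np.arange(n), top1], strand_is_rev[np.arange(n), top2]], axis=1
    )
    cand_votes[cand_votes < min_votes] = -1
    return cand, cand_votes, strands


def _align_mate(seq: str, ref: str, exact_cigar: bool) -> AlignResult | None:
    if exact_cigar:
        return align_infix(seq, ref)
    hit = infix_distance(seq, ref)
    if hit is None:
        return None
    dist, interval = hit
    return approx_result_from_distance(len(seq), dist, interval)


def _assign_pair(
    index: AlignIndex,
    s1: str,
    s2: str,
    cand: np.ndarray,
    votes: np.ndarray,
    strands: np.ndarray,
    exact_cigar: bool,
) -> tuple[int, AlignResult, AlignResult, bool] | None:
    """Best concordant assignment among candidate records, or None."""
    best: tuple[int, AlignResult, AlignResult, bool] | None = None
    best_score = None
    for j in range(cand.size):
        if votes[j] < 0:
            continue
        if j > 0 and votes[j] * 2 < votes[0]:
            continue  # clearly dominated runner-up
        ri = int(cand[j])
        ref = index.ref_seqs[ri]
        rev = bool(strands[j])
        q1 = to_str(_COMP[to_bytes(s1)[::-1]]) if rev else s1
        q2 = s2 if rev else to_str(_COMP[to_bytes(s2)[::-1]])
        a1 = _align_mate(q1, ref, exact_cigar)
        a2 = _align_mate(q2, ref, exact_cigar)
        if a1 is None or a2 is None:
            continue
        if min(a1.identity, a2.identity) < MIN_IDENTITY:
            continue
        if min(a1.aligned_length, a2.aligned_length) < MIN_ALIGNED:
            continue
        score = a1.score + a2.score
        key = (-score, index.record_ids[ri])
        if best is None or key < best_score:
            best = (ri, a1, a2, rev)
            best_score = key
    return best


def map_read_pair(
    r1: str,
    r2: str,
    index: AlignIndex,
    read_id: str = "read",
    stride: int = 1,
) -> tuple[AlignmentHit, AlignmentHit] | None:
    """Map one pair; returns the mate hits or None when unmapped."""
    if not r1 or not r2:
        return None
    reads = _pair_from_strings(r1, r2)
    cand, votes, strands = _pair_candidates(index, reads, stride, min_votes=1)
    res = _assign_pair(index, r1, r2, cand[0], votes[0], strands[0], exact_cigar=True)
    if res is None:
        return None
    ri, a1, a2, rev = res
    rid = index.record_ids[ri]
    strand1 = "-" if rev else "+"
    strand2 = "+" if rev else "-"
    return (
        AlignmentHit(read_id, rid, strand1, a1.score, a1.identity, a1.target_interval),
        AlignmentHit(read_id, rid, strand2, a2.score, a2.identity, a2.target_interval),
    )


def _pair_from_strings(r1: str, r2: str) -> PairedReads:
    a, b = to_bytes(r1), to_bytes(r2)
    m1, m2 = a.size, b.size
    return PairedReads(
        r1=a.reshape(1, m1).copy(),
        r2=b.reshape(1, m2).copy(),
        l1=np.array([m1]), l2=np.array([m2]),
        source_ids=["?"], source_index=np.zeros(1, dtype=np.int64),
        carries_marker=np.zeros(1, dtype=bool),
        ids=["read"],
    )


@dataclass
class ProfileResult:
    """One sample's cluster counts plus per-read assignments."""

    column: pd.Series                 # cluster id -> mapped pair count
    assignments: np.ndarray           # per-pair record index, -1 = unmapped
    n_pairs: int

    @property
    def n_mapped(self) -> int:
        return int((self.assignments >= 0).sum())

    @property
    def n_unmapped(self) -> int:
        return self.n_pairs - self.n_mapped

    @property
    def mapped_fraction(self) -> float:
        return self.n_mapped / self.n_pairs if self.n_pairs else 0.0


def profile_sample(
    reads: PairedReads,
    index: AlignIndex,
    stride: int = 4,
    min_votes: int = 2,
    batch_size: int = 20_000,
) -> ProfileResult:
    """Assign every pair of a library to a taxonomic cluster.

    Throughput path: seed votes are sampled every ``stride`` positions and
    candidate alignments use edit distance only (substitution-dominant
    score/identity). Counts are mapped pairs; one cluster per record.
    """
    n = len(reads)
    assignments = np.full(n, -1, dtype=np.int64)
    for s0 in range(0, n, batch_size):
        sl = slice(s0, min(n, s0 + batch_size))
        batch = PairedReads(
            r1=reads.r1[sl], r2=reads.r2[sl], l1=reads.l1[sl], l2=reads.l2[sl],
            source_ids=reads.source_ids, source_index=reads.source_index[sl],
            carries_marker=reads.carries_marker[sl], ids=None,
        )
        cand, votes, strands = _pair_candidates(index, batch, stride, min_votes)
        has_cand = (votes >= 0).any(axis=1)
        for i in np.flatnonzero(has_cand):
            s1 = to_str(batch.r1[i, : batch.l1[i]])
            s2 = to_str(batch.r2[i, : batch.l2[i]])
            res = _assign_pair(index, s1, s2, cand[i], votes[i], strands[i],
                               exact_cigar=False)
            if res is not None:
                assignments[s0 + i] = res[0]
    counts = np.bincount(assignments[assignments >= 0], minlength=index.n_refs)
    column = pd.Series(counts, index=pd.Index(index.record_ids, name="cluster_id"))
    return ProfileResult(column=column, assignments=assignments, n_pairs=n)


def profile_to_table(results: dict[str, ProfileResult]) -> ClusterCountTable:
    return ClusterCountTable(pd.DataFrame({sid: r.column for sid, r in results.items()}))


def downsample(column: pd.Series, params: DownsampleParams) -> pd.Series:
    """Subsample a count column to an exact depth without replacement."""
    total = int(column.sum())
    if params.depth > total:
        raise ValueError(f"downsample depth {params.depth} exceeds column total {total}")
    if params.depth == total:
        return column.copy()
    rng = np.random.default_rng(params.seed)
    sub = rng.multivariate_hypergeometric(column.to_numpy().astype(np.int64), params.depth)
    return pd.Series(sub, index=column.index)


def relative_abundance(column: pd.Series) -> pd.Series:
    total = column.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero column")
    return column / total
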