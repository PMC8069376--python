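"""Alignment helpers shared by the hybridization model and the profiler.

Two engines, one scoring convention:

* fast path — edlib bit-vector alignment in infix ("HW") mode: the whole
  query is aligned inside the target. Identity and score are derived from
  the extended CIGAR (task="path") or, in the throughput path, from the
  edit distance alone under a substitution-dominant assumption.
* slow path — Biopython's PairwiseAligner in true local mode, used where
  infix semantics are wrong (query overhanging the target, e.g. a probe
  overlapping a fragment end) and as the exhaustive oracle in tests.

Scoring scheme (fixed): match +2, mismatch -3, gap open -5, gap extend -2
(affine; a length-g gap costs 5 + 2*(g-1)).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align

import edlib

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5
GAP_EXTEND = -2

_CIG_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class AlignResult:
    """Outcome of aligning a query inside/against a target."""

    identity: float      # matches / aligned columns
    score: int           # fixed scoring scheme
    aligned_length: int  # aligned columns (incl. gap columns)
    target_interval: tuple[int, int]  # 0-based half-open on target


def _parse_cigar(cigar: str) -> tuple[int, int, int, int, int]:
    """Return (matches, mismatches, gap_opens, gap_bases, columns)."""
    m = x = opens = gapb = 0
    for num, op in _CIG_RE.findall(cigar):
        n = int(num)
        if op == "=":
            m += n
        elif op == "X":
            x += n
        else:  # I or D
            opens += 1
            gapb += n
    return m, x, opens, gapb, m + x + gapb


def score_from_counts(matches: int, mismatches: int, gap_opens: int, gap_bases: int) -> int:
    return (
        MATCH * matches
        + MISMATCH * mismatches
        + GAP_OPEN * gap_opens
        + GAP_EXTEND * (gap_bases - gap_opens)
    )


def align_infix(query: str, target: str) -> AlignResult | None:
    """Best edit-distance alignment of the full query inside the target."""
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0:
        return None
    m, x, opens, gapb, cols = _parse_cigar(res["cigar"])
    start, end = res["locations"][0]
    return AlignResult(
        identity=m / cols if cols else 0.0,
        score=score_from_counts(m, x, opens, gapb),
        aligned_length=cols,
        target_interval=(start, end + 1),
    )


def infix_distance(query: str, target: str) -> tuple[int, tuple[int, int]] | None:
    """Edit distance + target location only (fast; no CIGAR)."""
    res = edlib.align(query, target, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return None
    start, end = res["locations"][0]
    return res["editDistance"], (start, end + 1)


def approx_result_from_distance(qlen: int, dist: int, interval: tuple[int, int]) -> AlignResult:
    """Score/identity assuming all edits are substitutions (throughput path)."""
    return AlignResult(
        identity=max(0.0, 1.0 - dist / qlen) if qlen else 0.0,
        score=MATCH * (qlen - dist) + MISMATCH * dist,
        aligned_length=qlen,
        target_interval=interval,
    )


def make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_LOCAL = make_local_aligner()


def align_local(query: str, target: str) -> AlignResult | None:
    """True Smith-Waterman local alignment (Biopython engine)."""
    if not query or not target:
        return None
    alns = _LOCAL.align(query, target)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    m, x, gapb = counts.identities, counts.mismatches, counts.gaps
    # count gap openings from the aligned blocks
    tblocks, qblocks = aln.aligned
    opens = 0
    for i in range(1, len(tblocks)):
        if tblocks[i][0] != tblocks[i - 1][1] or qblocks[i][0] != qblocks[i - 1][1]:
            opens += 1
    cols = m + x + gapb
    t0 = int(tblocks[0][0])
    t1 = int(tblocks[-1][1])
    return AlignResult(
        identity=m / cols if cols else 0.0,
        score=int(aln.score),
        aligned_length=cols,
        target_interval=(t0, t1),
    )


def global_identity(a: str, b: str) -> float:
    """Needleman-Wunsch style identity between two full sequences.

    Uses edlib in global mode; identity = matches / alignment columns.
    """
    res = edlib.align(a, b, mode="NW", task="path")
    m, x, opens, gapb, cols = _parse_cigar(res["cigar"])
    return m / cols if cols else 0.0
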