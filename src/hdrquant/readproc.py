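"""Paired-read merging and global alignment of merged reads.

Amplicons (~250 bp) are shorter than the combined length of a read pair, so
the mates overlap and can be merged into a single full-length molecule
sequence by an alignment-free overlap scan (the contract of the FLASH
merger, re-implemented here so the pipeline has no external binary
dependency).  Merged reads are then aligned end-to-end to the reference
amplicon with a Needleman-Wunsch global alignment under affine gap
penalties; defaults reproduce EMBOSS-needle scoring for DNA (match +5,
mismatch -4, a gap of length L costs 10 + 0.5*L).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .locus import ConfigurationError, revcomp

_VALID_READ = re.compile(r"[ACGTN]*")

DEFAULT_MATCH = 5.0
DEFAULT_MISMATCH = -4.0
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5
DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_DENSITY = 0.25


@dataclass(frozen=True)
class ReadPair:
    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: tuple[int, ...]
    r2_qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ConfigurationError(f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    overlap_len: int
    n_overlap_mismatches: int


@dataclass(frozen=True)
class Unmerged:
    """Flag for a pair that could not be assembled."""

    id: str
    reason: str


# -- events reported by an alignment ---------------------------------------

@dataclass(frozen=True)
class SubstitutionEvent:
    position: int  # reference coordinate
    ref: str
    alt: str


@dataclass(frozen=True)
class InsertionEvent:
    position: int  # reference coordinate the insertion precedes
    seq: str


@dataclass(frozen=True)
class DeletionEvent:
    start: int
    end: int  # half-open reference interval deleted from the query


DiffEvent = Union[SubstitutionEvent, InsertionEvent, DeletionEvent]


@dataclass(frozen=True)
class AlignmentResult:
    aligned_ref: str
    aligned_query: str
    score: float
    identity_pct: float
    diffs: tuple[DiffEvent, ...]


def merge_pair(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_density: float = DEFAULT_MAX_MISMATCH_DENSITY,
) -> MergedRead | Unmerged:
    """Assemble a read pair by scanning un-gapped overlap shifts.

    R2 is reverse-complemented, then the shift maximising overlap length
    among shifts whose mismatch density is at most ``max_mismatch_density``
    (and overlap at least ``min_overlap``) is taken.  In the overlap each
    base comes from the mate with the higher Phred quality (ties go to R1).
    """
    if not pair.r1_seq or not pair.r2_seq:
        return Unmerged(pair.id, "empty read")
    r1 = np.frombuffer(pair.r1_seq.encode(), dtype=np.uint8)
    rc2 = np.frombuffer(revcomp(pair.r2_seq).encode(), dtype=np.uint8)
    q1 = np.asarray(pair.r1_qual, dtype=np.int16)
    q2 = np.asarray(pair.r2_qual, dtype=np.int16)[::-1]  # reversed with revcomp
    n1, n2 = len(r1), len(rc2)
    # shift d = offset of rc2's first base within the merged molecule;
    # ascending d scans overlaps from largest to smallest
    for d in range(0, n1 - min_overlap + 1):
        ov = min(n1 - d, n2)
        if ov < min_overlap:
            break
        a, b = r1[d : d + ov], rc2[:ov]
        mismatch = np.count_nonzero(a != b)
        if mismatch <= max_mismatch_density * ov:
            take_r1 = q1[d : d + ov] >= q2[:ov]
            consensus = np.where(take_r1, a, b)
            merged = (
                r1[:d].tobytes() + consensus.tobytes() + rc2[ov:].tobytes()
            ).decode()
            return MergedRead(pair.id, merged, ov, int(mismatch))
    return Unmerged(pair.id, "no qualifying overlap")


def _make_matrix(match: float, mismatch: float):
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            # N never scores as a match
            m[x, y] = match if (x == y and x != "N") else mismatch
    return m


def _make_aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _make_matrix(match, mismatch)
    # EMBOSS convention: a gap of length L costs gap_open + L * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _left_normalize(ref: list[str], qry: list[str]) -> None:
    """Shift every gap run leftward through equal bases (score-preserving)."""
    for gapped, other in ((qry, ref), (ref, qry)):
        i = len(gapped) - 1
        while i >= 0:
            if gapped[i] != "-":
                i -= 1
                continue
            end = i + 1
            while i >= 0 and gapped[i] == "-":
                i -= 1
            start = i + 1
            while start > 0 and gapped[start - 1] != "-" and other[start - 1] == other[end - 1]:
                gapped[end - 1] = gapped[start - 1]
                gapped[start - 1] = "-"
                start -= 1
                end -= 1
            i = start - 1


def _extract_diffs(aref: str, aqry: str) -> tuple[list[DiffEvent], float]:
    diffs: list[DiffEvent] = []
    matches = 0
    columns = len(aref)
    rpos = 0
    ins_at: Optional[int] = None
    ins_seq: list[str] = []
    del_start: Optional[int] = None
    for rc, qc in zip(aref, aqry):
        if rc != "-" and ins_seq:
            diffs.append(InsertionEvent(ins_at, "".join(ins_seq)))
            ins_seq, ins_at = [], None
        if rc != "-" and qc != "-" and del_start is not None:
            diffs.append(DeletionEvent(del_start, rpos))
            del_start = None
        if rc == "-":
            if ins_at is None:
                ins_at = rpos
            ins_seq.append(qc)
        elif qc == "-":
            if del_start is None:
                del_start = rpos
            rpos += 1
        else:
            if rc == qc and rc != "N":
                matches += 1
            elif rc != qc:
                diffs.append(SubstitutionEvent(rpos, rc, qc))
            rpos += 1
    if ins_seq:
        diffs.append(InsertionEvent(ins_at, "".join(ins_seq)))
    if del_start is not None:
        diffs.append(DeletionEvent(del_start, rpos))
    identity = 100.0 * matches / columns if columns else 0.0
    return diffs, identity


def global_align(
    query: str,
    reference: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global alignment of ``query`` against ``reference``.

    Affine gap penalties; indels in the reported alignment are left-aligned
    for reproducible diffs.  Raises on empty or non-ACGTN input.
    """
    for name, seq in (("query", query), ("reference", reference)):
        if not seq:
            raise ConfigurationError(f"{name} is empty")
        m = _VALID_READ.match(seq)
        if m.end() != len(seq):
            raise ConfigurationError(
                f"{name} has invalid character {seq[m.end()]!r} at position {m.end()}"
            )
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(reference, query)[0]
    aref, aqry = list(aln[0]), list(aln[1])
    _left_normalize(aref, aqry)
    aref_s, aqry_s = "".join(aref), "".join(aqry)
    diffs, identity = _extract_diffs(aref_s, aqry_s)
    return AlignmentResult(aref_s, aqry_s, float(aln.score), identity, tuple(diffs))


def apply_diffs(reference: str, diffs: Sequence[DiffEvent]) -> str:
    """Regenerate the query sequence from the reference and a diff list."""
    events = sorted(
        diffs,
        key=lambda d: (getattr(d, "position", getattr(d, "start", 0)),
                       0 if isinstance(d, InsertionEvent) else 1),
    )
    out: list[str] = []
    pos = 0
    for ev in events:
        if isinstance(ev, SubstitutionEvent):
            out.append(reference[pos : ev.position])
            out.append(ev.alt)
            pos = ev.position + 1
        elif isinstance(ev, InsertionEvent):
            out.append(reference[pos : ev.position])
            out.append(ev.seq)
            pos = ev.position
        else:
            out.append(reference[pos : ev.start])
            pos = ev.end
    out.append(reference[pos:])
    return "".join(out)


def format_pairwise(result: AlignmentResult, width: int = 60,
                    ref_name: str = "reference", query_name: str = "query") -> str:
    """Human-readable pairwise dump (needle-style) for inspection."""
    lines = [f"# score: {result.score}", f"# identity: {result.identity_pct:.2f}%"]
    for i in range(0, len(result.aligned_ref), width):
        r = result.aligned_ref[i : i + width]
        q = result.aligned_query[i : i + width]
        marks = "".join("|" if a == b and a != "-" else " " for a, b in zip(r, q))
        lines += [f"{ref_name:>10} {r}", f"{'':>10} {marks}", f"{query_name:>10} {q}", ""]
    return "\n".join(lines)
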