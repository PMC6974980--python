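"""Rule-based categorisation of merged amplicon reads.

Each merged read is assigned exactly one of four categories by an ordered
cascade:

1. ``WT`` — the wild-type guide-region pattern occurs as an exact substring
   of the read (no editing at the assayed window).
2. ``Correct_HDR`` / ``Incorrect_HDR`` — the HDR pattern occurs as an exact
   substring; the read is globally aligned to the reference, the covered CDS
   window is reconstructed and translated, and the read is ``Correct_HDR``
   when the protein carries exactly the expected residue changes (extra
   synonymous nucleotide changes are allowed) and ``Incorrect_HDR``
   otherwise.
3. ``Others`` — neither pattern matches (indels over the guide region,
   unmapped sequence, ...).

The cascade is exposed as a scikit-learn style estimator
(:class:`HdrOutcomeClassifier`) so it composes with pipelines; the
module-level :func:`classify_read` is a thin wrapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .locus import (
    ConfigurationError,
    EditSpec,
    PatternSet,
    ReferenceLocus,
    derive_patterns,
    minimal_flank,
    revcomp,
    translate_frame,
)
from .readproc import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    DEFAULT_MATCH,
    DEFAULT_MAX_MISMATCH_DENSITY,
    DEFAULT_MIN_OVERLAP,
    DEFAULT_MISMATCH,
    AlignmentResult,
    MergedRead,
    ReadPair,
    Unmerged,
    global_align,
    merge_pair,
)

CATEGORIES = ("WT", "Correct_HDR", "Incorrect_HDR", "Others")
UNMERGED_LABEL = "Unmerged"


@dataclass(frozen=True)
class EditingCall:
    read_id: str
    category: str
    wt_pattern_hit: bool = False
    hdr_pattern_hit: bool = False
    orientation: str = "+"
    protein_check: str = "not_applicable"  # pass | fail | not_applicable
    reason: str = ""
    identity_pct: float = float("nan")
    diffs: tuple = ()


@dataclass(frozen=True)
class EfficiencyReport:
    condition: str
    counts: dict[str, int]
    total_assembled: int
    unmerged: int
    percentages: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "counts": dict(self.counts),
            "total_assembled": self.total_assembled,
            "unmerged": self.unmerged,
            "percentages": dict(self.percentages),
        }


class PairedReadMerger(TransformerMixin, BaseEstimator):
    """Overlap-merging of read pairs as a stateless sklearn transformer.

    ``transform`` maps a sequence of :class:`ReadPair` to a same-length list
    of :class:`MergedRead` / :class:`Unmerged`.  An optional mean-Phred floor
    discards low-quality pairs before merging (off by default).
    """

    def __init__(
        self,
        min_overlap: int = DEFAULT_MIN_OVERLAP,
        max_mismatch_density: float = DEFAULT_MAX_MISMATCH_DENSITY,
        min_mean_quality: float | None = None,
    ):
        self.min_overlap = min_overlap
        self.max_mismatch_density = max_mismatch_density
        self.min_mean_quality = min_mean_quality

    def fit(self, X=None, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X: Iterable[ReadPair]) -> list[MergedRead | Unmerged]:
        out = []
        for pair in X:
            if self.min_mean_quality is not None:
                quals = pair.r1_qual + pair.r2_qual
                if quals and sum(quals) / len(quals) < self.min_mean_quality:
                    out.append(Unmerged(pair.id, "below quality floor"))
                    continue
            out.append(
                merge_pair(pair, self.min_overlap, self.max_mismatch_density)
            )
        return out


class HdrOutcomeClassifier(BaseEstimator):
    """Categorise merged amplicon reads into WT / Correct_HDR / Incorrect_HDR / Others.

    Parameters
    ----------
    locus, edit:
        The reference locus and edit specification the patterns are derived
        from.
    flank:
        Bases added on each side of the protospacer+PAM window when building
        the patterns; ``"auto"`` picks the smallest flank containing every
        substitution of ``edit``.
    identity_floor:
        Global-alignment identity (percent) below which an unmatched read is
        reported as unmapped.
    match, mismatch, gap_open, gap_extend:
        Scoring of the global alignment used for the protein check.
    """

    def __init__(
        self,
        locus: ReferenceLocus | None = None,
        edit: EditSpec | None = None,
        flank: int | str = "auto",
        identity_floor: float = 60.0,
        match: float = DEFAULT_MATCH,
        mismatch: float = DEFAULT_MISMATCH,
        gap_open: float = DEFAULT_GAP_OPEN,
        gap_extend: float = DEFAULT_GAP_EXTEND,
    ):
        self.locus = locus
        self.edit = edit
        self.flank = flank
        self.identity_floor = identity_floor
        self.match = match
        self.mismatch = mismatch
        self.gap_open = gap_open
        self.gap_extend = gap_extend

    # -- fitting -----------------------------------------------------------

    def fit(self, X=None, y=None) -> "HdrOutcomeClassifier":
        if self.locus is None or self.edit is None:
            raise ConfigurationError("locus and edit must be provided")
        flank = (
            minimal_flank(self.locus, self.edit)
            if self.flank == "auto"
            else int(self.flank)
        )
        self.flank_ = flank
        self.patterns_: PatternSet = derive_patterns(self.locus, self.edit, flank)
        self.wt_protein_ = self.locus.wt_protein()
        self.expected_protein_ = _apply_residue_changes(
            self.wt_protein_, self.edit.expected_residue_changes
        )
        self.classes_ = np.asarray(CATEGORIES + (UNMERGED_LABEL,), dtype=object)
        return self

    # -- prediction --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        return np.asarray([c.category for c in self.classify(X)], dtype=object)

    def classify(self, X) -> list[EditingCall]:
        check_is_fitted(self, "patterns_")
        calls = []
        for i, item in enumerate(X):
            if isinstance(item, Unmerged):
                calls.append(
                    EditingCall(item.id, UNMERGED_LABEL, reason=item.reason)
                )
                continue
            if isinstance(item, MergedRead):
                read_id, seq = item.id, item.seq
            else:
                read_id, seq = f"read_{i}", str(item)
            calls.append(self.classify_one(seq, read_id))
        return calls

    def classify_one(self, seq: str, read_id: str = "read") -> EditingCall:
        check_is_fitted(self, "patterns_")
        pats = self.patterns_
        if not seq:
            return EditingCall(read_id, "Others", reason="empty read")
        if len(seq) < len(pats.wt_pattern):
            return EditingCall(read_id, "Others", reason="read shorter than pattern")
        orientations = ((seq, "+"), (revcomp(seq), "-"))
        # rule 1: exact wild-type pattern
        for oriented, orient in orientations:
            if pats.wt_pattern in oriented:
                return EditingCall(
                    read_id, "WT", wt_pattern_hit=True, orientation=orient
                )
        # rule 2: exact HDR pattern, then protein-level check
        for oriented, orient in orientations:
            if pats.hdr_pattern in oriented:
                return self._protein_rule(read_id, oriented, orient)
        # rule 3: everything else
        best: AlignmentResult | None = None
        best_orient = "+"
        for oriented, orient in orientations:
            aln = self._align(oriented)
            if best is None or aln.identity_pct > best.identity_pct:
                best, best_orient = aln, orient
            if best.identity_pct >= self.identity_floor:
                break
        reason = (
            "unmapped" if best.identity_pct < self.identity_floor else "no pattern match"
        )
        return EditingCall(
            read_id,
            "Others",
            orientation=best_orient,
            reason=reason,
            identity_pct=best.identity_pct,
            diffs=best.diffs,
        )

    def _align(self, seq: str) -> AlignmentResult:
        return global_align(
            seq,
            self.locus.amplicon_seq,
            self.match,
            self.mismatch,
            self.gap_open,
            self.gap_extend,
        )

    def _protein_rule(self, read_id: str, oriented: str, orient: str) -> EditingCall:
        aln = self._align(oriented)
        observed, covered = _observed_cds_protein(self.locus, aln)
        expected_codons = [c.codon_index for c in self.edit.expected_residue_changes]
        if covered is None or any(
            not (covered[0] <= k <= covered[1]) for k in expected_codons
        ):
            # missing evidence: neither correct nor incorrect can be asserted
            return EditingCall(
                read_id,
                "Others",
                hdr_pattern_hit=True,
                orientation=orient,
                protein_check="not_applicable",
                reason="expected change not covered by read",
                identity_pct=aln.identity_pct,
                diffs=aln.diffs,
            )
        k0, k1 = covered
        expected_window = self.expected_protein_[k0 : k1 + 1]
        ok = observed == expected_window
        return EditingCall(
            read_id,
            "Correct_HDR" if ok else "Incorrect_HDR",
            hdr_pattern_hit=True,
            orientation=orient,
            protein_check="pass" if ok else "fail",
            identity_pct=aln.identity_pct,
            diffs=aln.diffs,
        )

    def calls_to_frame(self, calls: Sequence[EditingCall]) -> pd.DataFrame:
        rows = [
            {
                "read_id": c.read_id,
                "category": c.category,
                "wt_pattern_hit": c.wt_pattern_hit,
                "hdr_pattern_hit": c.hdr_pattern_hit,
                "orientation": c.orientation,
                "protein_check": c.protein_check,
                "reason": c.reason,
                "identity_pct": c.identity_pct,
                "n_diffs": len(c.diffs),
            }
            for c in calls
        ]
        return pd.DataFrame(rows)


# -- helpers ----------------------------------------------------------------

def _apply_residue_changes(protein: str, changes) -> str:
    out = list(protein)
    for ch in changes:
        if not (0 <= ch.codon_index < len(out)):
            raise ConfigurationError(
                f"expected residue change at codon {ch.codon_index} outside CDS"
            )
        if out[ch.codon_index] != ch.ref_aa:
            raise ConfigurationError(
                f"expected residue change at codon {ch.codon_index}: "
                f"ref_aa {ch.ref_aa} does not match translation {out[ch.codon_index]}"
            )
        out[ch.codon_index] = ch.alt_aa
    return "".join(out)


def _observed_cds_protein(
    locus: ReferenceLocus, aln: AlignmentResult
) -> tuple[str, Optional[tuple[int, int]]]:
    """Translate the CDS window of the aligned query.

    Returns ``(protein, (first_codon, last_codon))`` for the fully covered
    codon range, or ``("", None)`` when not a single complete codon is
    covered.  Insertions inside the window are kept (frameshifts propagate),
    deletions shorten it.
    """
    # query characters per reference position + insertions keyed by the
    # reference position they precede
    per_ref: list[str] = [""] * len(locus.amplicon_seq)
    insertions: dict[int, str] = {}
    rpos = 0
    for rc, qc in zip(aln.aligned_ref, aln.aligned_query):
        if rc == "-":
            insertions[rpos] = insertions.get(rpos, "") + qc
        else:
            if qc != "-":
                per_ref[rpos] = qc
            rpos += 1
    covered_positions = [i for i, c in enumerate(per_ref) if c]
    if not covered_positions:
        return "", None
    span = (covered_positions[0], covered_positions[-1] + 1)
    n = locus.n_codons()
    full = [
        k
        for k in range(n)
        if span[0] <= locus.codon_interval(k).start
        and locus.codon_interval(k).end <= span[1]
    ]
    if not full:
        return "", None
    k0, k1 = full[0], full[-1]
    starts = [locus.codon_interval(k).start for k in (k0, k1)]
    ends = [locus.codon_interval(k).end for k in (k0, k1)]
    lo, hi = min(starts), max(ends)
    chunks = []
    for p in range(lo, hi):
        chunks.append(per_ref[p])  # '' where deleted
        nxt = p + 1
        if lo < nxt < hi and nxt in insertions:
            chunks.append(insertions[nxt])
    segment = "".join(chunks)
    if locus.cds_strand == "-":
        segment = revcomp(segment)
    return translate_frame(segment), (k0, k1)


# -- aggregation and statistics ---------------------------------------------

def classify_read(
    merged: MergedRead | str,
    locus: ReferenceLocus,
    patterns: PatternSet | None = None,
    edit: EditSpec | None = None,
    identity_floor: float = 60.0,
    flank: int | str = "auto",
) -> EditingCall:
    """One-shot wrapper around :class:`HdrOutcomeClassifier` for a single read."""
    clf = HdrOutcomeClassifier(
        locus=locus, edit=edit, flank=flank, identity_floor=identity_floor
    ).fit()
    if isinstance(merged, MergedRead):
        return clf.classify_one(merged.seq, merged.id)
    return clf.classify_one(str(merged))


def summarize(calls: Sequence[EditingCall | str], condition: str) -> EfficiencyReport:
    """Aggregate per-read calls into per-condition counts and percentages.

    Percent denominators are assembled reads only; unmerged pairs are
    reported separately.
    """
    labels = [c.category if isinstance(c, EditingCall) else str(c) for c in calls]
    if not labels:
        raise ConfigurationError("cannot summarize an empty list of calls")
    counts = {cat: 0 for cat in CATEGORIES}
    unmerged = 0
    for lab in labels:
        if lab == UNMERGED_LABEL:
            unmerged += 1
        elif lab in counts:
            counts[lab] += 1
        else:
            raise ConfigurationError(f"unknown category {lab!r}")
    total = sum(counts.values())
    if total == 0:
        raise ConfigurationError("no assembled reads to summarize")
    percentages = {cat: 100.0 * n / total for cat, n in counts.items()}
    return EfficiencyReport(condition, counts, total, unmerged, percentages)


def fold_change(
    report_a: EfficiencyReport, report_b: EfficiencyReport, category: str
) -> float | None:
    """Ratio of a category's percentage between two conditions (A over B).

    Returns ``None`` (undefined) when the denominator percentage is zero.
    """
    pa = report_a.percentages[category]
    pb = report_b.percentages[category]
    if pb == 0:
        return None
    return pa / pb


def chi_square_rescue(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a contingency table.

    Used for phenotype-class x condition tables (e.g. low/medium/high rescue
    counts per donor).  Returns ``(statistic, df, p)``.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ConfigurationError("contingency table must be 2-dimensional")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ConfigurationError("contingency table has a zero row or column")
    res = stats.chi2_contingency(arr, correction=False)
    if (res.expected_freq <= 0).any():
        raise ConfigurationError("expected counts must all be positive")
    return float(res.statistic), int(res.dof), float(res.pvalue)


def expected_category_probabilities(
    locus: ReferenceLocus,
    edit: EditSpec,
    patterns: PatternSet,
    class_proportions: Mapping[str, float],
    per_base_error: float,
) -> dict[str, float]:
    """Closed-form expected category frequencies under uniform per-base error.

    With error rate ``e`` and pattern length ``L``, a molecule's pattern
    survives sequencing with probability ``(1-e)^L``; a read whose pattern is
    hit leaks to ``Others``.  For correctly edited molecules an additional
    factor accounts for protein-changing errors in the CDS outside the
    pattern window, using the exact per-site fraction of nonsynonymous
    substitutions enumerated from the edited sequence.  Independent of the
    classifier implementation; used as an oracle for recovery tests.
    """
    from .locus import apply_substitutions  # local import to avoid cycle noise

    e = per_base_error
    L = len(patterns.wt_pattern)
    p_pat = (1.0 - e) ** L
    edited = apply_substitutions(locus.amplicon_seq, edit.substitutions)
    q_clean = 1.0
    for k in range(locus.n_codons()):
        iv = locus.codon_interval(k)
        for pos in range(iv.start, iv.end):
            if patterns.pattern_interval.contains(pos):
                continue
            aa0 = _codon_aa(locus, edited, k)
            n_changing = 0
            for b in "ACGT":
                if b == edited[pos]:
                    continue
                mutant = edited[:pos] + b + edited[pos + 1 :]
                if _codon_aa(locus, mutant, k) != aa0:
                    n_changing += 1
            q_clean *= 1.0 - e * n_changing / 3.0
    probs = {cat: 0.0 for cat in CATEGORIES}
    for cls, w in class_proportions.items():
        if cls == "WT":
            probs["WT"] += w * p_pat
            probs["Others"] += w * (1.0 - p_pat)
        elif cls == "Correct_HDR":
            probs["Correct_HDR"] += w * p_pat * q_clean
            probs["Incorrect_HDR"] += w * p_pat * (1.0 - q_clean)
            probs["Others"] += w * (1.0 - p_pat)
        elif cls in ("Incorrect_HDR_substitution", "Incorrect_HDR_indel"):
            probs["Incorrect_HDR"] += w * p_pat
            probs["Others"] += w * (1.0 - p_pat)
        elif cls == "NHEJ_indel":
            probs["Others"] += w
        else:
            raise ConfigurationError(f"unknown simulation class {cls!r}")
    return probs


def _codon_aa(locus: ReferenceLocus, seq: str, codon_index: int) -> str:
    iv = locus.codon_interval(codon_index)
    codon = seq[iv.start : iv.end]
    if locus.cds_strand == "-":
        codon = revcomp(codon)
    return translate_frame(codon)
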