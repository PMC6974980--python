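"""Construction and verification of HDR donor templates.

Covers the donor design space of single-stranded repair templates: long
ssDNA (lssDNA, ~300-500 nt, symmetric homology arms), short ssODN
(~100-130 nt, symmetric or asymmetric arms), silent PAM/seed alterations
that prevent re-cutting of the repaired allele, and synonymous "Coding-bar"
substitutions that plant a de-novo restriction site for genotyping without
touching the protein.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .locus import (
    SEED_LENGTH,
    ConfigurationError,
    EditSpec,
    Interval,
    ReferenceLocus,
    RestrictionEnzyme,
    Substitution,
    apply_substitutions,
    codon_for,
    derive_patterns,
    minimal_flank,
    revcomp,
    translate_frame,
)
from .restriction import find_sites


@dataclass(frozen=True)
class DonorTemplate:
    sequence: str
    donor_kind: str  # lssDNA | ssODN | dsDNA_fragment | circular_dsDNA
    left_arm_len: int
    right_arm_len: int
    strand: str  # sense | antisense (relative to amplicon)
    applied_substitutions: tuple[Substitution, ...]
    core_interval: Interval  # amplicon interval of the edited core

    def fasta_header(self) -> str:
        return (
            f"{self.donor_kind}|arms={self.left_arm_len}/{self.right_arm_len}"
            f"|strand={self.strand}|len={len(self.sequence)}"
        )


@dataclass(frozen=True)
class CodingBarCandidate:
    substitutions: tuple[Substitution, ...]
    enzyme: RestrictionEnzyme
    site_position: int
    n_changes: int


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class VerificationReport:
    checks: tuple[CheckResult, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed_checks(self) -> list[CheckResult]:
        return [c for c in self.checks if not c.passed]


def _core_interval(locus: ReferenceLocus, edit: EditSpec) -> Interval:
    """Donor core for substitution-only edits: the classifier pattern span."""
    flank = minimal_flank(locus, edit)
    return derive_patterns(locus, edit, flank).pattern_interval


def build_lssdna_donor(
    locus: ReferenceLocus,
    edit: EditSpec,
    arm_len: int,
    strand: str = "sense",
    core_interval: Interval | None = None,
) -> DonorTemplate:
    """Long ssDNA donor: symmetric homology arms around the edited core."""
    return _build_ss_donor(locus, edit, arm_len, arm_len, strand, "lssDNA", core_interval)


def build_ssodn(
    locus: ReferenceLocus,
    edit: EditSpec,
    total_len: int,
    symmetry: str = "symmetric",
    asym_split: tuple[int, int] | None = None,
    strand: str = "sense",
    core_interval: Interval | None = None,
) -> DonorTemplate:
    """Short ssODN donor of a given total length.

    ``symmetric`` splits the remaining length evenly (arms differ by at most
    1 nt); ``asymmetric`` requires an explicit ``asym_split``.
    """
    core = core_interval if core_interval is not None else _core_interval(locus, edit)
    core_len = len(core)
    if total_len < core_len + 2:
        raise ConfigurationError(
            f"total_len {total_len} leaves no room for arms around a "
            f"{core_len} nt core (need at least {core_len + 2})"
        )
    if symmetry == "symmetric":
        left = (total_len - core_len) // 2
        right = total_len - core_len - left
    elif symmetry == "asymmetric":
        if asym_split is None:
            raise ConfigurationError("asymmetric ssODN requires asym_split")
        left, right = asym_split
        if left + right + core_len != total_len:
            raise ConfigurationError(
                f"asym_split {asym_split} + core {core_len} != total_len {total_len}"
            )
    else:
        raise ConfigurationError(f"unknown symmetry {symmetry!r}")
    return _build_ss_donor(locus, edit, left, right, strand, "ssODN", core)


def _build_ss_donor(
    locus: ReferenceLocus,
    edit: EditSpec,
    left_arm: int,
    right_arm: int,
    strand: str,
    kind: str,
    core_interval: Interval | None,
) -> DonorTemplate:
    if left_arm < 1 or right_arm < 1:
        raise ConfigurationError("homology arms must be at least 1 nt")
    if strand not in ("sense", "antisense"):
        raise ConfigurationError(f"unknown strand {strand!r}")
    edit.validate_against(locus)
    core = core_interval if core_interval is not None else _core_interval(locus, edit)
    start = core.start - left_arm
    end = core.end + right_arm
    if start < 0 or end > len(locus.amplicon_seq):
        shortfall_left = max(0, -start)
        shortfall_right = max(0, end - len(locus.amplicon_seq))
        raise ConfigurationError(
            f"homology arms exceed the reference context by "
            f"{shortfall_left} nt (left) / {shortfall_right} nt (right)"
        )
    inside = [s for s in edit.substitutions if core.contains(s.position)]
    outside = [s.position for s in edit.substitutions if not core.contains(s.position)]
    if outside:
        raise ConfigurationError(
            f"substitutions at {outside} fall outside the donor core "
            f"[{core.start}, {core.end})"
        )
    seq = apply_substitutions(
        locus.amplicon_seq[start:end], inside, offset=start
    )
    if strand == "antisense":
        seq = revcomp(seq)
    return DonorTemplate(
        sequence=seq,
        donor_kind=kind,
        left_arm_len=left_arm,
        right_arm_len=right_arm,
        strand=strand,
        applied_substitutions=tuple(inside),
        core_interval=core,
    )


# -- PAM / seed silencing ----------------------------------------------------

def silence_pam(locus: ReferenceLocus, edit: EditSpec) -> list[Substitution]:
    """Minimal deterministic substitution set preventing re-cutting.

    In coding context, searches single-base synonymous substitutions that
    destroy a G of the PAM's GG dinucleotide, preferring (1) fewest changes,
    (2) wobble-position changes, (3) the lexicographically smallest resulting
    codon; falls back to synonymous substitutions in the 12 nt seed region,
    and raises when no synonymous option exists.  Outside coding sequence the
    first G of the GG is mutated to A.
    """
    if locus.protospacer_interval is None:
        raise ConfigurationError("locus has no guide annotation")
    pam = locus.pam_interval
    gg_positions = _guide_oriented_pam_gg(locus)
    coding = [p for p in gg_positions if _in_complete_codon(locus, p)]
    if not coding:
        first_g = min(gg_positions)
        ref = locus.amplicon_seq[first_g]
        return [
            Substitution(first_g, ref, "A", roles=frozenset({"pam_silencing"}))
        ]
    hit = _best_synonymous_single(locus, edit, coding)
    if hit is not None:
        return [hit]
    # seed fallback: any synonymous single-base change in the seed region
    seed = locus.seed_interval
    seed_positions = [
        p
        for p in range(seed.start, seed.end)
        if _in_complete_codon(locus, p)
    ]
    hit = _best_synonymous_single(locus, edit, seed_positions)
    if hit is not None:
        return [hit]
    raise ConfigurationError(
        "no synonymous PAM- or seed-breaking substitution exists; "
        "consider a non-coding guide or accept a coding change"
    )


def _guide_oriented_pam_gg(locus: ReferenceLocus) -> list[int]:
    """Amplicon positions of the two G bases of the NGG PAM."""
    pam = locus.pam_interval
    if locus.guide_strand == "+":
        return [pam.start + 1, pam.start + 2]
    return [pam.start, pam.start + 1]


def _in_complete_codon(locus: ReferenceLocus, pos: int) -> bool:
    for k in range(locus.n_codons()):
        if locus.codon_interval(k).contains(pos):
            return True
    return False


def _codon_index_of(locus: ReferenceLocus, pos: int) -> int:
    for k in range(locus.n_codons()):
        if locus.codon_interval(k).contains(pos):
            return k
    raise ConfigurationError(f"position {pos} not in a complete codon")


def _best_synonymous_single(
    locus: ReferenceLocus, edit: EditSpec, positions: Iterable[int]
) -> Substitution | None:
    """Best synonymous single-base change at any of ``positions``.

    Synonymy is judged on the edited (post-HDR) sequence so that silencing
    never reverts the knock-in.  Order: wobble position first, then smallest
    resulting codon, then position.
    """
    edited = apply_substitutions(locus.amplicon_seq, edit.substitutions)
    occupied = {s.position for s in edit.substitutions}
    candidates = []
    for pos in positions:
        if pos in occupied:
            continue
        k = _codon_index_of(locus, pos)
        iv = locus.codon_interval(k)
        codon = edited[iv.start : iv.end]
        strand_minus = locus.cds_strand == "-"
        oriented = revcomp(codon) if strand_minus else codon
        idx = (iv.end - 1 - pos) if strand_minus else (pos - iv.start)
        aa = translate_frame(oriented)
        for b in "ACGT":
            cur_oriented_base = oriented[idx]
            if b == cur_oriented_base:
                continue
            new_oriented = oriented[:idx] + b + oriented[idx:][1:]
            if translate_frame(new_oriented) != aa:
                continue
            is_wobble = idx == 2
            new_amp_base = revcomp(b) if strand_minus else b
            candidates.append(
                (0 if is_wobble else 1, new_oriented, pos,
                 Substitution(pos, edited[pos], new_amp_base,
                              roles=frozenset({"pam_silencing"})))
            )
    if not candidates:
        return None
    candidates.sort(key=lambda t: t[:3])
    return candidates[0][3]


# -- Coding-bar design -------------------------------------------------------

def design_coding_bar(
    locus: ReferenceLocus,
    edit: EditSpec,
    enzymes: Sequence[RestrictionEnzyme],
    window: Interval,
    max_changes: int = 2,
) -> list[CodingBarCandidate]:
    """Enumerate synonymous codon substitutions creating a de-novo enzyme site.

    All combinations of at most ``max_changes`` synonymous codon replacements
    inside ``window`` (codon-aligned, within the CDS) are applied on top of
    the edit's existing substitutions; combinations whose edited sequence
    gains a recognition site (IUPAC-aware, both strands) absent from the
    wild-type context are returned, sorted by number of nucleotide changes,
    then site position, then enzyme name.
    """
    if not enzymes:
        raise ConfigurationError("empty enzyme list")
    codons = [
        k
        for k in range(locus.n_codons())
        if window.contains(locus.codon_interval(k).start)
        and locus.codon_interval(k).end <= window.end
    ]
    if not codons:
        raise ConfigurationError("window contains no complete codon")
    base = apply_substitutions(locus.amplicon_seq, edit.substitutions)
    occupied = {s.position for s in edit.substitutions}
    max_site = max(len(e.recognition) for e in enzymes)
    scan = Interval(
        max(0, window.start - (max_site - 1)),
        min(len(locus.amplicon_seq), window.end + (max_site - 1)),
    )
    wt_scan = locus.amplicon_seq[scan.start : scan.end]
    strand_minus = locus.cds_strand == "-"

    def codon_variants(k: int) -> list[tuple[Substitution, ...]]:
        iv = locus.codon_interval(k)
        if any(p in occupied for p in range(iv.start, iv.end)):
            return []  # leave codons already touched by the edit alone
        codon = base[iv.start : iv.end]
        oriented = revcomp(codon) if strand_minus else codon
        aa = translate_frame(oriented)
        variants = []
        for alt in codon_for(aa):
            if alt == oriented:
                continue
            alt_amp = revcomp(alt) if strand_minus else alt
            subs = tuple(
                Substitution(iv.start + j, codon[j], alt_amp[j],
                             roles=frozenset({"coding_bar"}))
                for j in range(3)
                if codon[j] != alt_amp[j]
            )
            variants.append(subs)
        return variants

    per_codon = {k: codon_variants(k) for k in codons}
    out: list[CodingBarCandidate] = []
    seen: set[tuple] = set()
    for r in range(0, max_changes + 1):
        for combo in itertools.combinations(codons, r):
            variant_sets = [per_codon[k] for k in combo]
            if any(not v for v in variant_sets):
                continue
            for choice in itertools.product(*variant_sets):
                subs = tuple(s for group in choice for s in group)
                edited = apply_substitutions(base, subs)
                ed_scan = edited[scan.start : scan.end]
                for enz in enzymes:
                    wt_hits = set(find_sites(wt_scan, enz))
                    for pos in find_sites(ed_scan, enz):
                        if pos in wt_hits:
                            continue
                        key = (subs, enz.name, pos + scan.start)
                        if key in seen:
                            continue
                        seen.add(key)
                        out.append(
                            CodingBarCandidate(
                                substitutions=subs,
                                enzyme=enz,
                                site_position=pos + scan.start,
                                n_changes=len(subs),
                            )
                        )
    out.sort(key=lambda c: (c.n_changes, c.site_position, c.enzyme.name))
    return out


# -- donor verification ------------------------------------------------------

def verify_donor(
    donor: DonorTemplate, locus: ReferenceLocus, edit: EditSpec
) -> VerificationReport:
    """Consistency report for a built donor.

    Checks: homology-arm identity to the reference flanks, presence of every
    intended substitution, absence of the intact protospacer+PAM (re-cut
    guard, both strands), and protein-level agreement (the donor's CDS
    translation differs from wild type by exactly the expected residue
    changes).
    """
    checks: list[CheckResult] = []
    seq = donor.sequence if donor.strand == "sense" else revcomp(donor.sequence)
    core = donor.core_interval
    start = core.start - donor.left_arm_len
    end = core.end + donor.right_arm_len
    ref_window = locus.amplicon_seq[start:end]

    # arm identity
    mismatches = [
        i
        for i in list(range(donor.left_arm_len))
        + list(range(len(ref_window) - donor.right_arm_len, len(ref_window)))
        if seq[i] != ref_window[i]
    ]
    checks.append(
        CheckResult(
            "arm_identity",
            not mismatches,
            "" if not mismatches
            else f"arm mismatch at amplicon position(s) {[start + i for i in mismatches]}",
        )
    )

    # intended substitutions present
    missing = [
        s.position
        for s in edit.substitutions
        if not (start <= s.position < end) or seq[s.position - start] != s.alt_base
    ]
    checks.append(
        CheckResult(
            "substitutions_present",
            not missing,
            "" if not missing else f"intended substitution(s) missing at {missing}",
        )
    )

    # re-cut guard: the intact guide target must be absent from the donor
    if locus.protospacer_interval is not None:
        lo = min(locus.protospacer_interval.start, locus.pam_interval.start)
        hi = max(locus.protospacer_interval.end, locus.pam_interval.end)
        target = locus.amplicon_seq[lo:hi]
        present = target in seq or revcomp(target) in seq
        checks.append(
            CheckResult(
                "recut_prevented",
                not present,
                "" if not present else "intact protospacer+PAM present in donor",
            )
        )

    # protein check over the donor-covered complete codons
    donor_codons = [
        k
        for k in range(locus.n_codons())
        if start <= locus.codon_interval(k).start
        and locus.codon_interval(k).end <= end
    ]
    if donor_codons:
        expected = list(locus.wt_protein())
        for ch in edit.expected_residue_changes:
            expected[ch.codon_index] = ch.alt_aa
        bad = []
        for k in donor_codons:
            iv = locus.codon_interval(k)
            codon = seq[iv.start - start : iv.end - start]
            if locus.cds_strand == "-":
                codon = revcomp(codon)
            if translate_frame(codon) != expected[k]:
                bad.append(k)
        checks.append(
            CheckResult(
                "protein_identity",
                not bad,
                "" if not bad else f"unexpected residue change at codon(s) {bad}",
            )
        )
    return VerificationReport(tuple(checks))
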