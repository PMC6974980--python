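"""Reference locus, edit specification and classifier patterns.

An amplicon-sequencing experiment for a CRISPR knock-in is described by a
:class:`ReferenceLocus` (the wild-type amplicon, the coding window inside it
and the guide-RNA target) together with an :class:`EditSpec` (the intended
nucleotide substitutions and the residue change they encode).  From the two,
:func:`derive_patterns` produces the pair of exact-match classifier strings:
the wild-type sequence of the guide-covered region (``wt_pattern``) and the
same region with all intended substitutions applied (``hdr_pattern``).

Coordinates are 0-based half-open throughout; 1-based numbers appear only in
human-readable reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

_DNA_RE = re.compile(r"[ACGT]+\Z")
_DNA_N_RE = re.compile(r"[ACGTN]+\Z")

#: Codons of the standard genetic code, amino acid -> tuple of codons.
CODON_TABLE = unambiguous_dna_by_id[1]
SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TABLE.forward_table.items():
    SYNONYMOUS.setdefault(_aa, ())
    SYNONYMOUS[_aa] += (_codon,)
SYNONYMOUS["*"] = tuple(CODON_TABLE.stop_codons)

#: PAM-proximal protospacer bases most sensitive to mismatches.
SEED_LENGTH = 12


class ConfigurationError(ValueError):
    """Raised when a locus/edit description is internally inconsistent."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (gaps and N preserved)."""
    return str(Seq(seq).reverse_complement())


def translate_frame(nt: str) -> str:
    """Translate an in-frame nucleotide string with the standard code.

    Incomplete terminal codons are dropped; stop codons appear as ``*``.
    """
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    return str(Seq(nt[:usable]).translate(table=1))


def codon_for(aa: str) -> tuple[str, ...]:
    """All codons of the standard table encoding amino acid ``aa``."""
    return SYNONYMOUS[aa]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ConfigurationError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Substitution:
    """A single intended base substitution on the amplicon.

    ``roles`` tags why the substitution is in the donor: ``desired`` (the
    knock-in itself), ``coding_bar`` (synonymous genotyping barcode) or
    ``pam_silencing`` (PAM/seed alteration preventing re-cutting).  A
    substitution carries at least one role.
    """

    position: int
    ref_base: str
    alt_base: str
    roles: frozenset[str] = frozenset({"desired"})

    def __post_init__(self) -> None:
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise ConfigurationError(f"non-ACGT substitution at {self.position}")
        if self.ref_base == self.alt_base:
            raise ConfigurationError(f"substitution at {self.position} is a no-op")
        if not self.roles:
            raise ConfigurationError(f"substitution at {self.position} has no role tag")
        bad = set(self.roles) - {"desired", "coding_bar", "pam_silencing"}
        if bad:
            raise ConfigurationError(f"unknown substitution roles {sorted(bad)}")


@dataclass(frozen=True)
class ResidueChange:
    """Expected amino-acid change: codon index within the CDS, WT aa, new aa."""

    codon_index: int
    ref_aa: str
    alt_aa: str


@dataclass(frozen=True)
class RestrictionEnzyme:
    """Named recognition site with the top-strand cut offset.

    ``cut_offset_top`` is the position of the top-strand cut within the
    recognition site (0 = immediately before the first base).  ``None``
    means unknown; consumers fall back to a blunt mid-site cut.
    """

    name: str
    recognition: str
    cut_offset_top: int | None = None

    _IUPAC = set("ACGTRYSWKMBDHVN")

    def __post_init__(self) -> None:
        bad = set(self.recognition) - self._IUPAC
        if bad:
            raise ConfigurationError(
                f"enzyme {self.name}: invalid IUPAC codes {sorted(bad)}"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


@dataclass(frozen=True)
class ReferenceLocus:
    """Wild-type amplicon with its CDS window and guide-RNA annotation.

    ``cds_frame`` is the offset of the first complete codon within
    ``cds_interval`` in the reading direction of ``cds_strand``.  The PAM is
    the NGG trinucleotide adjacent to the protospacer 3' end on
    ``guide_strand``.
    """

    gene_name: str
    amplicon_seq: str
    cds_interval: Interval
    cds_frame: int = 0
    cds_strand: str = "+"
    protospacer_interval: Interval | None = None
    pam_interval: Interval | None = None
    guide_strand: str = "+"

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.amplicon_seq):
            raise ConfigurationError("amplicon must be uppercase A/C/G/T")
        n = len(self.amplicon_seq)
        for name, iv in (
            ("cds_interval", self.cds_interval),
            ("protospacer_interval", self.protospacer_interval),
            ("pam_interval", self.pam_interval),
        ):
            if iv is not None and not (0 <= iv.start and iv.end <= n):
                raise ConfigurationError(f"{name} outside amplicon [0, {n})")
        if self.cds_strand not in "+-" or self.guide_strand not in "+-":
            raise ConfigurationError("strand must be '+' or '-'")
        if self.cds_frame not in (0, 1, 2):
            raise ConfigurationError("cds_frame must be 0, 1 or 2")
        if self.protospacer_interval is not None:
            if len(self.protospacer_interval) != 20:
                raise ConfigurationError("protospacer must be 20 nt")
            if self.pam_interval is None:
                raise ConfigurationError("protospacer given without PAM")
            if len(self.pam_interval) != 3:
                raise ConfigurationError("PAM must be 3 nt")
            # PAM abuts the protospacer 3' end in guide orientation.
            if self.guide_strand == "+":
                if self.pam_interval.start != self.protospacer_interval.end:
                    raise ConfigurationError("PAM not adjacent to protospacer 3' end")
            else:
                if self.pam_interval.end != self.protospacer_interval.start:
                    raise ConfigurationError("PAM not adjacent to protospacer 3' end")
            if self.pam_guide_oriented[1:] != "GG":
                raise ConfigurationError(
                    f"PAM is {self.pam_guide_oriented}, expected NGG"
                )

    @property
    def pam_guide_oriented(self) -> str:
        """PAM bases read in guide orientation (should be NGG)."""
        raw = self.amplicon_seq[self.pam_interval.start : self.pam_interval.end]
        return raw if self.guide_strand == "+" else revcomp(raw)

    @property
    def cut_site(self) -> int:
        """Blunt Cas9 cut position, 3 bp 5' of the PAM (amplicon coordinate)."""
        if self.guide_strand == "+":
            return self.protospacer_interval.end - 3
        return self.protospacer_interval.start + 3

    @property
    def seed_interval(self) -> Interval:
        """The 12 PAM-proximal protospacer bases (amplicon coordinates)."""
        p = self.protospacer_interval
        if self.guide_strand == "+":
            return Interval(p.end - SEED_LENGTH, p.end)
        return Interval(p.start, p.start + SEED_LENGTH)

    def wt_protein(self) -> str:
        """Translation of the wild-type CDS window."""
        return translate_cds(self, self.amplicon_seq)

    def codon_interval(self, codon_index: int) -> Interval:
        """Amplicon interval of the ``codon_index``-th complete CDS codon."""
        if self.cds_strand == "+":
            s = self.cds_interval.start + self.cds_frame + 3 * codon_index
            return Interval(s, s + 3)
        e = self.cds_interval.end - self.cds_frame - 3 * codon_index
        return Interval(e - 3, e)

    def n_codons(self) -> int:
        return (len(self.cds_interval) - self.cds_frame) // 3


@dataclass(frozen=True)
class EditSpec:
    """The intended knock-in: substitutions and the residue change they encode."""

    substitutions: tuple[Substitution, ...]
    expected_residue_changes: tuple[ResidueChange, ...] = ()
    introduced_enzyme: str | None = None

    @property
    def coding_bar_substitutions(self) -> tuple[Substitution, ...]:
        return tuple(s for s in self.substitutions if "coding_bar" in s.roles)

    @property
    def pam_silencing_substitutions(self) -> tuple[Substitution, ...]:
        return tuple(s for s in self.substitutions if "pam_silencing" in s.roles)

    def validate_against(self, locus: ReferenceLocus) -> None:
        seen = set()
        for sub in self.substitutions:
            if sub.position in seen:
                raise ConfigurationError(f"duplicate substitution at {sub.position}")
            seen.add(sub.position)
            if not (0 <= sub.position < len(locus.amplicon_seq)):
                raise ConfigurationError(f"substitution at {sub.position} outside amplicon")
            actual = locus.amplicon_seq[sub.position]
            if actual != sub.ref_base:
                raise ConfigurationError(
                    f"substitution at {sub.position}: ref_base {sub.ref_base} "
                    f"does not match amplicon base {actual}"
                )


@dataclass(frozen=True)
class PatternSet:
    """Exact-match classifier strings for the guide-covered region."""

    wt_pattern: str
    hdr_pattern: str
    pattern_interval: Interval


def apply_substitutions(seq: str, subs: Iterable[Substitution], offset: int = 0) -> str:
    """Apply substitutions (amplicon coordinates) to ``seq`` starting at ``offset``."""
    out = list(seq)
    for sub in subs:
        i = sub.position - offset
        if not (0 <= i < len(out)):
            raise ConfigurationError(
                f"substitution at {sub.position} outside sequence window"
            )
        if out[i] != sub.ref_base:
            raise ConfigurationError(
                f"substitution at {sub.position}: expected {sub.ref_base}, found {out[i]}"
            )
        out[i] = sub.alt_base
    return "".join(out)


def derive_patterns(locus: ReferenceLocus, edit: EditSpec, flank: int = 0) -> PatternSet:
    """Build the WT/HDR exact-match patterns for the guide-covered region.

    The pattern interval is the union of the protospacer and PAM, extended by
    ``flank`` bases on each side and clipped to the amplicon.  Every
    substitution of ``edit`` must fall inside it (they are what the patterns
    assay); a substitution outside raises :class:`ConfigurationError`.
    """
    if flank < 0:
        raise ConfigurationError("flank must be non-negative")
    if locus.protospacer_interval is None:
        raise ConfigurationError("locus has no guide annotation")
    edit.validate_against(locus)
    lo = min(locus.protospacer_interval.start, locus.pam_interval.start) - flank
    hi = max(locus.protospacer_interval.end, locus.pam_interval.end) + flank
    iv = Interval(max(0, lo), min(len(locus.amplicon_seq), hi))
    outside = [s.position for s in edit.substitutions if not iv.contains(s.position)]
    if outside:
        raise ConfigurationError(
            f"substitutions at {outside} lie outside the pattern interval "
            f"[{iv.start}, {iv.end}); increase flank"
        )
    if not edit.substitutions:
        raise ConfigurationError("edit has no substitutions inside the pattern interval")
    wt = locus.amplicon_seq[iv.start : iv.end]
    hdr = apply_substitutions(wt, edit.substitutions, offset=iv.start)
    return PatternSet(wt_pattern=wt, hdr_pattern=hdr, pattern_interval=iv)


def minimal_flank(locus: ReferenceLocus, edit: EditSpec) -> int:
    """Smallest flank for which all edit substitutions fit the pattern interval."""
    lo = min(locus.protospacer_interval.start, locus.pam_interval.start)
    hi = max(locus.protospacer_interval.end, locus.pam_interval.end)
    flank = 0
    for s in edit.substitutions:
        if s.position < lo:
            flank = max(flank, lo - s.position)
        if s.position >= hi:
            flank = max(flank, s.position - hi + 1)
    return flank


def translate_cds(locus: ReferenceLocus, seq: str) -> str:
    """Translate the CDS window of ``seq`` (a string in amplicon coordinates).

    ``seq`` must have the same length as the amplicon; positions outside the
    sequenced/covered region may be ``-``.  Only the in-frame codons of the
    covered CDS sub-window are translated, on ``cds_strand``; incomplete
    terminal codons are dropped.  Returns ``""`` when fewer than one complete
    codon is covered.
    """
    if len(seq) != len(locus.amplicon_seq):
        raise ConfigurationError("sequence length differs from amplicon length")
    window = seq[locus.cds_interval.start : locus.cds_interval.end]
    # restrict to the contiguous covered core
    stripped = window.strip("-")
    if "-" in stripped:
        raise ConfigurationError("CDS window contains unresolved internal gaps")
    left_pad = len(window) - len(window.lstrip("-"))
    right_pad = len(window) - len(window.rstrip("-"))
    if locus.cds_strand == "+":
        skip = (locus.cds_frame - left_pad) % 3
        return translate_frame(stripped[skip:])
    skip = (locus.cds_frame - right_pad) % 3
    rc = revcomp(stripped)
    return translate_frame(rc[skip:])
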