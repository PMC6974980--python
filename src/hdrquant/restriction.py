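"""In-silico restriction genotyping (RFLP screen).

A knock-in that introduces a de-novo restriction site can be screened by
digesting the PCR amplicon: edited molecules yield the digest fragments,
wild-type molecules the uncut band.  This module finds degenerate (IUPAC)
recognition sites, predicts digestion fragments, and models the pooled-embryo
positive/negative call with a configurable band-detection floor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple

from Bio.Data.IUPACData import ambiguous_dna_values

from .locus import ConfigurationError, RestrictionEnzyme, revcomp

_IUPAC_RE = {code: f"[{bases}]" if len(bases) > 1 else bases
             for code, bases in ambiguous_dna_values.items()}


class Site(NamedTuple):
    """A recognition-site hit in top-strand coordinates."""

    position: int
    strand: str  # '+' hit of the recognition on top strand, '-' on bottom


@dataclass(frozen=True)
class DigestResult:
    label: str
    enzyme: str
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]


@dataclass(frozen=True)
class PoolCall:
    """Positive/negative genotyping call for a pooled sample."""

    pool_id: str
    edited_fraction: float
    detection_threshold: float
    call: str  # 'positive' | 'negative'
    #: (fragment length, relative abundance) of the expected gel pattern
    gel_pattern: tuple[tuple[int, float], ...]


def load_enzyme_table(path=None) -> dict[str, RestrictionEnzyme]:
    """Load the bundled (or a user-supplied) enzyme table.

    The format is a minimal REBASE-style TSV: name, IUPAC recognition,
    top-strand cut offset (blank = unknown, digest falls back to mid-site).
    """
    if path is None:
        text = resources.files("hdrquant.data").joinpath("enzymes.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, RestrictionEnzyme] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        name, recognition = fields[0], fields[1]
        offset = int(fields[2]) if len(fields) > 2 and fields[2] != "" else None
        table[name] = RestrictionEnzyme(name, recognition, offset)
    return table


def _compile(recognition: str) -> re.Pattern:
    try:
        pattern = "".join(_IUPAC_RE[c] for c in recognition)
    except KeyError as exc:
        raise ConfigurationError(f"invalid IUPAC code {exc} in {recognition}") from exc
    return re.compile(f"(?={pattern})")  # lookahead: overlapping matches


def find_sites_stranded(seq: str, enzyme: RestrictionEnzyme) -> list[Site]:
    """All recognition hits, both strands, in top-strand start coordinates.

    Palindromic recognitions are reported once (strand ``+``); for
    non-palindromic enzymes the bottom strand is scanned too and hits are
    mapped back to top-strand coordinates with strand tag ``-``.
    """
    hits = [Site(m.start(), "+") for m in _compile(enzyme.recognition).finditer(seq)]
    if not enzyme.is_palindromic:
        rc_pat = _compile(revcomp(enzyme.recognition))
        k = len(enzyme.recognition)
        for m in rc_pat.finditer(seq):
            hits.append(Site(m.start(), "-"))
    # a degenerate non-palindromic recognition can still hit both strands at
    # the same position (e.g. GACNNNGTC); report such a position once
    seen, out = set(), []
    for h in sorted(hits):
        if h.position not in seen:
            seen.add(h.position)
            out.append(h)
    return out


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Recognition-site start positions (top-strand coordinates, both strands)."""
    return [s.position for s in find_sites_stranded(seq, enzyme)]


def _cut_position(site: Site, enzyme: RestrictionEnzyme) -> int:
    k = len(enzyme.recognition)
    offset = enzyme.cut_offset_top if enzyme.cut_offset_top is not None else k // 2
    if site.strand == "+":
        return site.position + offset
    return site.position + (k - offset)


def digest(seq: str, enzyme: RestrictionEnzyme, label: str = "") -> DigestResult:
    """Predict digestion of a linear sequence.

    Fragment lengths always sum to the input length; a sequence without a
    site yields the single uncut fragment.
    """
    cuts = sorted({_cut_position(s, enzyme) for s in find_sites_stranded(seq, enzyme)})
    cuts = [c for c in cuts if 0 < c < len(seq)]
    bounds = [0] + cuts + [len(seq)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(label, enzyme.name, tuple(cuts), fragments)


def genotype_pool(
    wt_amplicon: str,
    edited_amplicon: str,
    enzyme: RestrictionEnzyme,
    edited_fraction: float,
    detection_threshold: float = 0.05,
    pool_id: str = "pool",
) -> PoolCall:
    """Model the pooled-sample RFLP screen.

    The enzyme must cut the edited amplicon and not the wild-type one
    (otherwise the assay is uninformative and an error is raised).  The call
    is positive when the fraction of edited molecules reaches the
    band-detection floor ``detection_threshold``; the expected gel pattern
    mixes the uncut wild-type band with the digest fragments at their
    relative abundances.
    """
    if not 0.0 <= edited_fraction <= 1.0:
        raise ConfigurationError("edited_fraction must be in [0, 1]")
    wt_digest = digest(wt_amplicon, enzyme, "WT")
    ed_digest = digest(edited_amplicon, enzyme, "edited")
    if wt_digest.cut_positions:
        raise ConfigurationError(
            f"assay uninformative: {enzyme.name} cuts the wild-type amplicon"
        )
    if not ed_digest.cut_positions:
        raise ConfigurationError(
            f"assay uninformative: {enzyme.name} does not cut the edited amplicon"
        )
    bands: dict[int, float] = {}
    if edited_fraction < 1.0:
        bands[len(wt_amplicon)] = 1.0 - edited_fraction
    if edited_fraction > 0.0:
        for frag in ed_digest.fragment_lengths:
            bands[frag] = bands.get(frag, 0.0) + edited_fraction
    call = "positive" if edited_fraction >= detection_threshold else "negative"
    pattern = tuple(sorted(bands.items(), key=lambda kv: -kv[0]))
    return PoolCall(pool_id, edited_fraction, detection_threshold, call, pattern)


def pool_edited_fraction(per_embryo_fractions: Iterable[float]) -> float:
    """Edited fraction of a pool of mosaic embryos = mean of member fractions."""
    fractions = list(per_embryo_fractions)
    if not fractions:
        raise ConfigurationError("empty pool")
    return sum(fractions) / len(fractions)
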