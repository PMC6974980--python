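"""Synthetic loci, edits and paired amplicon reads with known truth.

The generator emulates the statistical structure the analysis assumes: a
~250 bp amplicon containing a short CDS window with an NGG-adjacent
protospacer, an edit made of one non-synonymous substitution near the PAM
plus synonymous Coding-bar substitutions creating a de-novo restriction
site, and overlapping read pairs drawn from a configurable mixture of
molecule classes (wild type, correct HDR, HDR with a secondary substitution
or frameshift indel, NHEJ indel) with uniform per-base sequencing error.
Every emitted pair carries a truth record, so each pipeline stage can be
tested closed-loop without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .donors import design_coding_bar
from .locus import (
    ConfigurationError,
    EditSpec,
    Interval,
    ReferenceLocus,
    ResidueChange,
    Substitution,
    apply_substitutions,
    derive_patterns,
    minimal_flank,
    revcomp,
    translate_frame,
)
from .readproc import ReadPair
from .restriction import find_sites, load_enzyme_table

#: Molecule classes the generator draws from.
SIM_CLASSES = (
    "WT",
    "Correct_HDR",
    "Incorrect_HDR_substitution",
    "Incorrect_HDR_indel",
    "NHEJ_indel",
)

#: Default class mixture of the desk-scale study conditions.
DEFAULT_PROPORTIONS = {
    "WT": 0.70,
    "Correct_HDR": 0.12,
    "Incorrect_HDR_indel": 0.04,
    "Incorrect_HDR_substitution": 0.02,
    "NHEJ_indel": 0.12,
}

#: NHEJ indel length spectrum (no published spectrum for these loci; the
#: 25 echoes the 25 bp founder deletion used as the rescue model).
DEFAULT_INDEL_LENGTHS = {1: 0.3, 2: 0.2, 3: 0.15, 5: 0.1, 7: 0.1, 10: 0.1, 25: 0.05}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_reads: int = 20_000
    amplicon_len: int = 250
    read_len: int = 150
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    per_base_error: float = 0.001
    indel_len_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_LENGTHS)
    )
    quality_mean: int = 35

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"class proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(SIM_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown simulation classes {sorted(unknown)}")
        if not 0.0 <= self.per_base_error <= 0.2:
            raise ConfigurationError("per_base_error must be in [0, 0.2]")
        if self.n_reads < 1:
            raise ConfigurationError("n_reads must be positive")
        if 2 * self.read_len <= self.amplicon_len:
            raise ConfigurationError(
                "read pairs cannot overlap: 2*read_len must exceed amplicon_len"
            )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def simulate_locus(
    seed: int, amplicon_len: int = 250, max_attempts: int = 200
) -> tuple[ReferenceLocus, EditSpec]:
    """Random locus + edit with the architecture the classifier assumes.

    The amplicon carries a 45 nt CDS window (frame 0, sense strand) around
    its midpoint; a 20 nt protospacer with NGG PAM sits codon-aligned inside
    the CDS.  The edit couples one non-synonymous seed-region substitution
    (the knock-in, which also prevents re-cutting) with synonymous Coding-bar
    substitutions creating a de-novo site for a bundled enzyme that cuts the
    edited amplicon and not the wild type.  Fully reproducible from ``seed``.
    """
    if amplicon_len < 100:
        raise ConfigurationError("amplicon_len must be at least 100")
    rng = np.random.default_rng(seed)
    enzymes = list(load_enzyme_table().values())
    cds_len = 45
    cds_start = amplicon_len // 2 - 25
    proto_start = cds_start + 3
    pam_start = proto_start + 20
    for _ in range(max_attempts):
        amp = list(_random_dna(rng, amplicon_len))
        amp[pam_start + 1] = "G"
        amp[pam_start + 2] = "G"
        amplicon = "".join(amp)
        locus = ReferenceLocus(
            gene_name=f"sim{seed}",
            amplicon_seq=amplicon,
            cds_interval=Interval(cds_start, cds_start + cds_len),
            cds_frame=0,
            cds_strand="+",
            protospacer_interval=Interval(proto_start, proto_start + 20),
            pam_interval=Interval(pam_start, pam_start + 3),
            guide_strand="+",
        )
        edit = _draw_edit(rng, locus, enzymes)
        if edit is not None:
            return locus, edit
    raise ConfigurationError(
        f"no suitable locus found in {max_attempts} attempts (seed {seed})"
    )


def _draw_edit(rng, locus: ReferenceLocus, enzymes) -> EditSpec | None:
    cds_start = locus.cds_interval.start
    # non-synonymous knock-in at the middle base of a seed-region codon
    pos_ns = locus.protospacer_interval.end - 5  # codon boundary safe: see layout
    k_ns = (pos_ns - cds_start) // 3
    iv = locus.codon_interval(k_ns)
    pos = iv.start + 1  # middle base: almost always protein-changing
    codon = locus.amplicon_seq[iv.start : iv.end]
    ref_aa = translate_frame(codon)
    alts = []
    for b in "ACGT":
        if b == locus.amplicon_seq[pos]:
            continue
        new = codon[:1] + b + codon[2:]
        aa = translate_frame(new)
        if aa not in (ref_aa, "*") and ref_aa != "*":
            alts.append((b, aa))
    if not alts:
        return None
    b, alt_aa = alts[int(rng.integers(len(alts)))]
    nonsyn = Substitution(
        pos, locus.amplicon_seq[pos], b, roles=frozenset({"desired", "pam_silencing"})
    )
    edit0 = EditSpec(
        substitutions=(nonsyn,),
        expected_residue_changes=(ResidueChange(k_ns, ref_aa, alt_aa),),
    )
    # Coding-bar: synonymous substitutions inside the guide-covered codons
    window = Interval(
        locus.protospacer_interval.start,
        locus.protospacer_interval.start
        + 3 * ((len(locus.protospacer_interval) + len(locus.pam_interval)) // 3),
    )
    candidates = design_coding_bar(locus, edit0, enzymes, window, max_changes=2)
    for cand in candidates:
        subs = tuple(
            sorted(edit0.substitutions + cand.substitutions, key=lambda s: s.position)
        )
        edited = apply_substitutions(locus.amplicon_seq, subs)
        if find_sites(locus.amplicon_seq, cand.enzyme):
            continue  # enzyme must not cut anywhere in the WT amplicon
        if not find_sites(edited, cand.enzyme):
            continue
        return EditSpec(
            substitutions=subs,
            expected_residue_changes=edit0.expected_residue_changes,
            introduced_enzyme=cand.enzyme.name,
        )
    return None


def _mutate_nonsyn(rng, locus: ReferenceLocus, seq: str, exclude: Interval) -> str:
    """One protein-changing substitution at a codon middle base outside ``exclude``."""
    options = []
    for k in range(locus.n_codons()):
        iv = locus.codon_interval(k)
        mid = iv.start + 1
        if exclude.contains(mid) or exclude.overlaps(iv):
            continue
        options.append((k, mid))
    if not options:
        raise ConfigurationError("no codon outside the pattern window available")
    for _ in range(20):
        k, mid = options[int(rng.integers(len(options)))]
        iv = locus.codon_interval(k)
        codon = seq[iv.start : iv.end]
        aa = translate_frame(codon)
        b = "ACGT"[int(rng.integers(4))]
        if b == seq[mid]:
            continue
        new = codon[:1] + b + codon[2:]
        if translate_frame(new) != aa:
            return seq[:mid] + b + seq[mid + 1 :]
    raise ConfigurationError("failed to draw a non-synonymous substitution")


def _molecule(
    rng,
    cls: str,
    locus: ReferenceLocus,
    edit: EditSpec,
    pattern_interval: Interval,
    indel_lengths: tuple[np.ndarray, np.ndarray],
) -> tuple[str, str]:
    """Sequence of one sampled molecule plus a human-readable diff note."""
    wt = locus.amplicon_seq
    hdr = apply_substitutions(wt, edit.substitutions)
    if cls == "WT":
        return wt, ""
    if cls == "Correct_HDR":
        return hdr, "HDR substitutions"
    if cls == "Incorrect_HDR_substitution":
        return _mutate_nonsyn(rng, locus, hdr, pattern_interval), "HDR + extra nonsyn"
    if cls == "Incorrect_HDR_indel":
        length = 1 + int(rng.integers(2))  # 1 or 2 nt: frameshift
        start = pattern_interval.end + 2
        if start + length > locus.cds_interval.end:
            start = locus.cds_interval.end - length
        return hdr[:start] + hdr[start + length :], f"HDR + del{length}@{start}"
    if cls == "NHEJ_indel":
        lengths, probs = indel_lengths
        length = int(rng.choice(lengths, p=probs))
        cut = locus.cut_site
        if rng.random() < 0.8:  # deletion centred at the cut
            start = max(1, cut - length // 2)
            end = min(len(wt) - 1, start + length)
            return wt[:start] + wt[end:], f"del{end - start}@{start}"
        ins = _random_dna(rng, length)
        return wt[:cut] + ins + wt[cut:], f"ins{length}@{cut}"
    raise ConfigurationError(f"unknown class {cls!r}")


def _sequencing_errors(rng, seq: str, e: float) -> str:
    if e == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < e)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_reads(
    locus: ReferenceLocus, edit: EditSpec, config: SimulationConfig
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Draw read pairs from the class mixture; returns (pairs, truth table).

    Each molecule is fragmented into an R1 covering its 5' end and an R2
    covering its 3' end (reverse-complemented), overlapping in the middle;
    uniform substitution errors are injected at ``per_base_error``.  Written
    qualities are constant at ``quality_mean`` and independent of the
    injected errors.
    """
    rng = np.random.default_rng(config.seed)
    patterns = derive_patterns(locus, edit, minimal_flank(locus, edit))
    names = tuple(config.class_proportions.keys())
    probs = np.asarray([config.class_proportions[n] for n in names], dtype=float)
    draws = rng.choice(len(names), size=config.n_reads, p=probs)
    lengths = np.asarray(sorted(config.indel_len_distribution), dtype=int)
    lprobs = np.asarray(
        [config.indel_len_distribution[int(l)] for l in lengths], dtype=float
    )
    lprobs = lprobs / lprobs.sum()
    qual = (config.quality_mean,) * config.read_len
    pairs: list[ReadPair] = []
    truth_rows = []
    for i, d in enumerate(draws):
        cls = names[int(d)]
        mol, note = _molecule(
            rng, cls, locus, edit, patterns.pattern_interval, (lengths, lprobs)
        )
        rl = min(config.read_len, len(mol))
        r1 = _sequencing_errors(rng, mol[:rl], config.per_base_error)
        r2 = _sequencing_errors(
            rng, revcomp(mol[-rl:]), config.per_base_error
        )
        rid = f"sim_{i:06d}"
        pairs.append(ReadPair(rid, r1, r2, qual[:rl], qual[:rl]))
        truth_rows.append({"read_id": rid, "true_class": cls, "diffs": note})
    truth = pd.DataFrame(truth_rows)
    return pairs, truth


def expected_categories(truth: pd.DataFrame) -> pd.Series:
    """Map true molecule classes to the categories the rule cascade can express."""
    mapping = {
        "WT": "WT",
        "Correct_HDR": "Correct_HDR",
        "Incorrect_HDR_substitution": "Incorrect_HDR",
        "Incorrect_HDR_indel": "Incorrect_HDR",
        "NHEJ_indel": "Others",
    }
    return truth["true_class"].map(mapping)
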