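"""File formats: FASTQ pairs, FASTA, and YAML locus/edit configuration."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus import (
    ConfigurationError,
    EditSpec,
    Interval,
    ReferenceLocus,
    ResidueChange,
    Substitution,
)
from .readproc import ReadPair


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Iterate mate pairs from two (optionally gzipped) FASTQ files."""
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for rec1, rec2 in zip(it1, it2):
            yield ReadPair(
                id=rec1.id,
                r1_seq=str(rec1.seq).upper(),
                r2_seq=str(rec2.seq).upper(),
                r1_qual=tuple(rec1.letter_annotations["phred_quality"]),
                r2_qual=tuple(rec2.letter_annotations["phred_quality"]),
            )


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    with _open_text(r1_path, "wt") as fh1, _open_text(r2_path, "wt") as fh2:
        for pair in pairs:
            for fh, seq, qual in (
                (fh1, pair.r1_seq, pair.r1_qual),
                (fh2, pair.r2_seq, pair.r2_qual),
            ):
                rec = SeqRecord(Seq(seq), id=pair.id, description="")
                rec.letter_annotations["phred_quality"] = list(qual)
                SeqIO.write(rec, fh, "fastq")


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
            fh,
            "fasta",
        )


# -- locus / edit YAML -------------------------------------------------------

def locus_to_dict(locus: ReferenceLocus) -> dict:
    d = {
        "gene_name": locus.gene_name,
        "amplicon_seq": locus.amplicon_seq,
        "cds": {
            "start": locus.cds_interval.start,
            "end": locus.cds_interval.end,
            "frame": locus.cds_frame,
            "strand": locus.cds_strand,
        },
    }
    if locus.protospacer_interval is not None:
        d["protospacer"] = {
            "start": locus.protospacer_interval.start,
            "end": locus.protospacer_interval.end,
            "strand": locus.guide_strand,
        }
        d["pam"] = {"start": locus.pam_interval.start, "end": locus.pam_interval.end}
    return d


def locus_from_dict(d: dict, base_dir: Path | None = None) -> ReferenceLocus:
    if "amplicon_seq" in d:
        amplicon = d["amplicon_seq"].upper()
    elif "amplicon_fasta" in d:
        path = Path(d["amplicon_fasta"])
        if base_dir is not None and not path.is_absolute():
            path = base_dir / path
        records = read_fasta(path)
        if "amplicon_record" in d:
            amplicon = records[d["amplicon_record"]]
        else:
            amplicon = next(iter(records.values()))
    else:
        raise ConfigurationError("locus needs amplicon_seq or amplicon_fasta")
    cds = d["cds"]
    kwargs = {}
    if "protospacer" in d:
        proto = d["protospacer"]
        pam = d["pam"]
        kwargs = {
            "protospacer_interval": Interval(proto["start"], proto["end"]),
            "pam_interval": Interval(pam["start"], pam["end"]),
            "guide_strand": proto.get("strand", "+"),
        }
    return ReferenceLocus(
        gene_name=d.get("gene_name", "locus"),
        amplicon_seq=amplicon,
        cds_interval=Interval(cds["start"], cds["end"]),
        cds_frame=cds.get("frame", 0),
        cds_strand=cds.get("strand", "+"),
        **kwargs,
    )


def edit_to_dict(edit: EditSpec) -> dict:
    return {
        "substitutions": [
            {
                "position": s.position,
                "ref": s.ref_base,
                "alt": s.alt_base,
                "roles": sorted(s.roles),
            }
            for s in edit.substitutions
        ],
        "expected_residue_changes": [
            {"codon_index": c.codon_index, "ref_aa": c.ref_aa, "alt_aa": c.alt_aa}
            for c in edit.expected_residue_changes
        ],
        "introduced_enzyme": edit.introduced_enzyme,
    }


def edit_from_dict(d: dict) -> EditSpec:
    subs = tuple(
        Substitution(
            position=s["position"],
            ref_base=s["ref"],
            alt_base=s["alt"],
            roles=frozenset(s.get("roles", ["desired"])),
        )
        for s in d.get("substitutions", [])
    )
    changes = tuple(
        ResidueChange(c["codon_index"], c["ref_aa"], c["alt_aa"])
        for c in d.get("expected_residue_changes", [])
    )
    return EditSpec(
        substitutions=subs,
        expected_residue_changes=changes,
        introduced_enzyme=d.get("introduced_enzyme"),
    )


def load_locus(path) -> ReferenceLocus:
    path = Path(path)
    with open(path) as fh:
        return locus_from_dict(yaml.safe_load(fh), base_dir=path.parent)


def load_edit(path) -> EditSpec:
    with open(path) as fh:
        return edit_from_dict(yaml.safe_load(fh))


def dump_locus(locus: ReferenceLocus, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(locus_to_dict(locus), fh, sort_keys=False)


def dump_edit(edit: EditSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(edit_to_dict(edit), fh, sort_keys=False)
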