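"""Template parsing, T7 promoter location, run-off transcripts, terminator U-tracts.

A PLOR (position-selective labeling of RNA) experiment starts from a
double-stranded DNA template carrying a class-III T7 promoter.  This module
derives the run-off transcript from the printed template strand — scanning
both strands for the 17-nt consensus ``TAATACGACTCACTATA`` with transcription
starting at the next base (+1) — and annotates the intrinsic-terminator
U-tract that splits products into "terminated" (T) and "full-length" (FL)
species.

Coordinates are 1-based inclusive throughout; transcript position 1 is +1.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import PromoterError, SequenceError, TerminatorError

T7_PROMOTER = "TAATACGACTCACTATA"

Alphabet = Literal["DNA", "RNA"]

_DNA_SET = frozenset("ACGT")
_RNA_SET = frozenset("ACGU")


@dataclass(frozen=True)
class NucleicSequence:
    """A validated uppercase nucleic-acid sequence.

    ``residues`` is drawn from {A,C,G,T} for DNA or {A,C,G,U} for RNA; use
    :func:`normalize_sequence` to build one from raw text.
    """

    residues: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        allowed = _DNA_SET if self.alphabet == "DNA" else _RNA_SET
        if not self.residues:
            raise SequenceError("empty sequence")
        bad = next((i for i, c in enumerate(self.residues) if c not in allowed), None)
        if bad is not None:
            raise SequenceError(
                f"invalid character {self.residues[bad]!r} at position {bad + 1} "
                f"for alphabet {self.alphabet}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class PromoterSite:
    """Location of the T7 promoter consensus on a template.

    ``strand`` records whether the consensus was found on the strand as given
    or on its reverse complement; coordinates refer to that reported strand.
    ``txn_start`` is the +1 position, immediately 3' of the 17-mer.
    """

    strand: Literal["given", "reverse_complement"]
    promoter_start: int
    txn_start: int


@dataclass(frozen=True)
class Transcript:
    """A run-off transcript: RNA from +1 to the end of the coding-sense strand."""

    rna: NucleicSequence
    source_site: PromoterSite

    @property
    def length(self) -> int:
        return len(self.rna)


@dataclass(frozen=True)
class TerminatorAnnotation:
    """The terminator U-tract: a maximal run of >= min_run consecutive U.

    ``terminated_length`` is the length of the product released when the
    polymerase dissociates at the tract, i.e. the transcript truncated
    immediately before the first U of the run (u_start - 1 nt).
    """

    u_start: int
    u_end: int
    terminated_length: int


def normalize_sequence(text: str, alphabet: Alphabet) -> NucleicSequence:
    """Normalize raw sequence text to a validated :class:`NucleicSequence`.

    Whitespace and digits are stripped (so GenBank-style pasted blocks work),
    case is folded to upper, and T/U are coerced to the declared alphabet.
    Any other character raises :class:`SequenceError` naming its position.
    """
    cleaned = re.sub(r"[\s\d]+", "", text).upper()
    if not cleaned:
        raise SequenceError("empty sequence after whitespace removal")
    if alphabet == "DNA":
        cleaned = cleaned.replace("U", "T")
    elif alphabet == "RNA":
        cleaned = cleaned.replace("T", "U")
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    return NucleicSequence(cleaned, alphabet)


def reverse_complement(seq: NucleicSequence) -> NucleicSequence:
    """Watson-Crick reverse complement of a DNA sequence (an involution)."""
    if seq.alphabet != "DNA":
        raise SequenceError("reverse_complement requires a DNA sequence")
    return NucleicSequence(str(Seq(seq.residues).reverse_complement()), "DNA")


def find_t7_promoter(template: NucleicSequence) -> PromoterSite:
    """Locate the unique 17-nt T7 promoter consensus on either strand.

    Both the given strand and its reverse complement are scanned for
    ``TAATACGACTCACTATA``.  Exactly one match across both strands is required;
    zero matches raise "promoter not found" and multiple matches raise an
    ambiguity error listing every site.
    """
    if template.alphabet != "DNA":
        raise SequenceError("promoter search requires a DNA template")
    if len(template) < len(T7_PROMOTER) + 1:
        raise PromoterError(
            f"template too short ({len(template)} nt) to contain a promoter and +1 base"
        )

    hits: list[PromoterSite] = []
    for strand, residues in (
        ("given", template.residues),
        ("reverse_complement", reverse_complement(template).residues),
    ):
        start = residues.find(T7_PROMOTER)
        while start != -1:
            hits.append(
                PromoterSite(
                    strand=strand,  # type: ignore[arg-type]
                    promoter_start=start + 1,
                    txn_start=start + 1 + len(T7_PROMOTER),
                )
            )
            start = residues.find(T7_PROMOTER, start + 1)

    if not hits:
        raise PromoterError("promoter not found")
    if len(hits) > 1:
        sites = ", ".join(f"{h.strand}:{h.promoter_start}" for h in hits)
        raise PromoterError(f"ambiguous promoter: multiple consensus sites ({sites})")
    site = hits[0]
    if site.txn_start > len(template):
        raise PromoterError("promoter found at the template end: no +1 base to transcribe")
    return site


def derive_transcript(template: NucleicSequence) -> Transcript:
    """Derive the run-off transcript downstream of the T7 promoter.

    The transcript is the coding-sense strand from +1 to the template end,
    emitted as RNA.  T7 RNAP strongly prefers to initiate on G; a transcript
    that does not begin with G triggers a :class:`UserWarning`, not an error.
    """
    site = find_t7_promoter(template)
    coding = (
        template if site.strand == "given" else reverse_complement(template)
    ).residues
    rna = normalize_sequence(coding[site.txn_start - 1 :], "RNA")
    if not rna.residues.startswith("G"):
        warnings.warn(
            f"transcript starts with {rna.residues[0]}, not G; "
            "T7 RNAP initiates poorly on non-G starts",
            UserWarning,
            stacklevel=2,
        )
    return Transcript(rna=rna, source_site=site)


def annotate_terminator(tx: Transcript, min_run: int = 6) -> TerminatorAnnotation:
    """Find the terminator U-tract: the longest U-run of length >= ``min_run``.

    Ties between equally long runs are broken toward the most 3' (downstream)
    run.  The terminated product length is ``u_start - 1``, i.e. the polymerase
    is taken to release the transcript just before the first U of the tract.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    runs = [
        (m.start() + 1, m.end())
        for m in re.finditer(r"U+", tx.rna.residues)
        if m.end() - m.start() >= min_run
    ]
    if not runs:
        raise TerminatorError(f"no U-tract found (no U-run of length >= {min_run})")
    # max() keeps the later run on ties because later runs sort higher on u_start
    u_start, u_end = max(runs, key=lambda r: (r[1] - r[0], r[0]))
    return TerminatorAnnotation(u_start=u_start, u_end=u_end, terminated_length=u_start - 1)


# --- file ingestion -------------------------------------------------------

def read_fasta(path: str | Path, alphabet: Alphabet = "DNA") -> list[NucleicSequence]:
    """Read all records of a FASTA file as validated sequences."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return [normalize_sequence(str(r.seq), alphabet) for r in records]


def write_fasta(
    path: str | Path, sequences: Iterator[tuple[str, NucleicSequence]] | list[tuple[str, NucleicSequence]]
) -> None:
    """Write (description, sequence) pairs as FASTA."""
    records = [
        SeqRecord(Seq(seq.residues), id=name.split()[0], description=name)
        for name, seq in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_template(path: str | Path) -> NucleicSequence:
    """Read a single DNA template from FASTA or plain text (pasted blocks OK)."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        seqs = read_fasta(path, "DNA")
        if len(seqs) > 1:
            raise SequenceError(f"{path} contains {len(seqs)} records; expected one template")
        return seqs[0]
    return normalize_sequence(text, "DNA")
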