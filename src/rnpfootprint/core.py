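"""Ribonuclease-protection model for extracellular RNA fragments.

Secreted ribonucleases of the RNase A superfamily cleave single-stranded RNA
on the 3' side of pyrimidine residues (C, U).  When a protein complex (an Sm
ring, a splicing factor, a ribosomal protein) sits on a stretch of an RNA,
the bases underneath it are shielded, so exhaustive extracellular digestion
leaves a predictable surviving fragment: the protected interval extended on
each side up to — and including — the nearest cleavable pyrimidine outside
the complex.  This module holds that mechanistic rule and the coordinate
types everything else builds on.

Coordinates are 0-based, half-open throughout the library; conversion to
1-based inclusive (genome-browser style) happens only in human-readable
report writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

RNA_ALPHABET = frozenset("ACGU")
PYRIMIDINES = frozenset("CU")


class Tier(str, Enum):
    """Protection tier of a bound complex.

    ``CORE`` marks the tightly bound complex that survives in every digested
    particle class (the Sm heptamer); ``PERIPHERAL`` marks more loosely
    associated factors (SF3B1 on the branch site loop, SNRPA1 on stem loop
    IV) whose footprints appear only in some particle classes.
    """

    CORE = "core"
    PERIPHERAL = "peripheral"


@dataclass(frozen=True)
class Transcript:
    """A reference RNA sequence, 5'->3', alphabet {A, C, G, U}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r}: invalid bases {sorted(bad)}; "
                "expected A/C/G/U"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProtectedInterval:
    """A protein-protected interval on a transcript (0-based, half-open)."""

    transcript_id: str
    start: int
    end: int
    label: str
    tier: Tier = Tier.CORE

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"protected interval [{self.start},{self.end}) is empty "
                "or out of range"
            )
        object.__setattr__(self, "tier", Tier(self.tier))

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RNaseSpec:
    """Cleavage specificity of a single-strand endoribonuclease.

    ``target_bases`` is the set of bases after which the enzyme cuts; the cut
    falls between position ``pos`` and ``pos + 1``, i.e. on the 3' side, the
    chemistry of the RNase A superfamily (the 2',3'-cyclic-phosphate pathway
    leaves the pyrimidine's phosphate on the upstream product).
    """

    target_bases: frozenset = PYRIMIDINES
    side: str = "3prime"

    def __post_init__(self) -> None:
        bases = frozenset(self.target_bases)
        if not bases or not bases <= RNA_ALPHABET:
            raise ValueError(
                "target_bases must be a non-empty subset of {A,C,G,U}"
            )
        object.__setattr__(self, "target_bases", bases)
        if self.side != "3prime":
            raise ValueError("only 3' cleavage is modeled")


#: RNase A superfamily default: cut 3' of pyrimidines.
RNASE_A = RNaseSpec()


def is_cleavage_site(sequence: str, pos: int, spec: RNaseSpec = RNASE_A) -> bool:
    """True iff the base at ``pos`` is cleavable (cut between pos and pos+1).

    A cut after the last base of a transcript is chemically possible but has
    no effect on fragmentation; callers treat it as a no-op.
    """
    if not 0 <= pos < len(sequence):
        raise IndexError(
            f"position {pos} out of range for sequence of length {len(sequence)}"
        )
    return sequence[pos] in spec.target_bases


def validate_protections(
    transcript: Transcript, protections: Iterable[ProtectedInterval]
) -> list[ProtectedInterval]:
    """Check that intervals belong to the transcript, fit it, and do not overlap."""
    out = []
    for p in protections:
        if p.transcript_id != transcript.id:
            raise ValueError(
                f"interval {p.label!r} belongs to {p.transcript_id!r}, "
                f"not {transcript.id!r}"
            )
        if p.end > len(transcript):
            raise ValueError(
                f"interval {p.label!r} [{p.start},{p.end}) exceeds transcript "
                f"length {len(transcript)}"
            )
        out.append(p)
    out.sort(key=lambda p: p.start)
    for a, b in zip(out, out[1:]):
        if b.start < a.end:
            raise ValueError(
                f"protected intervals {a.label!r} and {b.label!r} overlap "
                f"on {transcript.id!r}"
            )
    return out


def eligible_sites(
    transcript: Transcript,
    protections: Iterable[ProtectedInterval] = (),
    spec: RNaseSpec = RNASE_A,
) -> list[int]:
    """Positions the enzyme can actually cut after: cleavable AND unprotected.

    Pyrimidines inside a protected interval are never returned, including
    interval-terminal residues such as the U's of an Sm site — the bound
    complex shields them.  Sorted ascending, no duplicates.
    """
    prots = validate_protections(transcript, protections)
    shielded = bytearray(len(transcript))
    for p in prots:
        for i in range(p.start, p.end):
            shielded[i] = 1
    targets = spec.target_bases
    return [
        i
        for i, base in enumerate(transcript.sequence)
        if base in targets and not shielded[i]
    ]


def predict_protected_fragment(
    transcript: Transcript,
    interval: ProtectedInterval,
    spec: RNaseSpec = RNASE_A,
) -> tuple[int, int]:
    """Surviving fragment of a protected interval under exhaustive digestion.

    The fragment runs from just after the nearest cleavable base strictly
    upstream of the interval (or the transcript 5' end if there is none) to
    just after the nearest cleavable base at or downstream of ``interval.end``
    (or the transcript 3' end).  The cut base itself belongs to the upstream
    product, so it is the fragment's last base.  The 3' boundary is the rule
    the biology dictates; applying the mirrored rule at the 5' boundary is an
    extension of the same chemistry and is flagged as such in report
    metadata.

    Returns a 0-based half-open interval that always contains the input
    interval.
    """
    validate_protections(transcript, [interval])
    seq = transcript.sequence
    targets = spec.target_bases

    start = 0
    for p in range(interval.start - 1, -1, -1):
        if seq[p] in targets:
            start = p + 1
            break

    end = len(seq)
    for p in range(interval.end, len(seq)):
        if seq[p] in targets:
            end = p + 1
            break

    return start, end


# ---------------------------------------------------------------------------
# BED6 interchange for protection annotations.
# Name column encodes "label:tier"; score unused; strand fixed "+" because
# protection is defined on the transcript's own (sense) coordinates.
# ---------------------------------------------------------------------------


def write_protections_bed(path, protections: Sequence[ProtectedInterval]) -> None:
    with open(path, "w") as fh:
        for p in protections:
            fh.write(
                f"{p.transcript_id}\t{p.start}\t{p.end}\t"
                f"{p.label}:{p.tier.value}\t0\t+\n"
            )


def read_protections_bed(path) -> list[ProtectedInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: need >=4 BED columns")
            name = fields[3]
            label, _, tier = name.partition(":")
            out.append(
                ProtectedInterval(
                    transcript_id=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    label=label,
                    tier=Tier(tier) if tier else Tier.CORE,
                )
            )
    return out


def read_transcripts_fasta(path) -> list[Transcript]:
    """Load transcripts from FASTA; T is accepted and converted to U."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(Transcript(rec.id, str(rec.seq).upper().replace("T", "U")))
    return out


def write_transcripts_fasta(path, transcripts: Sequence[Transcript]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")


def to_browser_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive, for human-readable reports."""
    return start + 1, end
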