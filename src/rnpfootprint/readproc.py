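"""Desk-scale small-RNA read processing against transcript references.

Adapter trimming (suffix-vs-adapter-prefix, mismatch tolerant), exhaustive
sense-strand alignment over small references (every placement scored, best
by mismatch count with leftmost/reference-order tie-breaks), and
per-transcript counting with RPM normalization.  This replaces a
Cutadapt/Bowtie2/FeatureCounts chain at transcript scale: the references
here are a handful of short RNAs, so an exhaustive scan is both exact and
fast, and there is no need for genome-scale indexing.

Identical read sequences are collapsed before trimming and alignment; each
retained alignment carries a ``weight`` equal to its read multiplicity, and
all downstream counting and coverage honors the weights.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Transcript

MIN_READ_LEN = 15  # reads shorter than this after trimming are discarded


@dataclass
class AlignedRead:
    """A sense-strand placement of a (possibly collapsed) read."""

    read_id: str
    transcript_id: str
    start: int
    end: int
    n_mismatch: int
    ambiguous: bool = False
    weight: int = 1
    sequence: str = ""


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
) -> str:
    """Remove a 3' adapter: longest read-suffix matching an adapter prefix.

    The longest suffix of the read equal to a prefix of the adapter with a
    mismatch rate <= ``max_mismatch_rate`` and overlap >= ``min_overlap`` is
    cut off; reads with no acceptable overlap are returned unchanged.
    """
    if not read:
        raise ValueError("empty read")
    if not adapter:
        raise ValueError("empty adapter")
    for k in range(min(len(read), len(adapter)), min_overlap - 1, -1):
        tail = read[len(read) - k :]
        mm = sum(a != b for a, b in zip(tail, adapter))
        if mm <= max_mismatch_rate * k:
            return read[: len(read) - k]
    return read


class ReferenceIndex:
    """Transcript references prepared for alignment (U->T, byte arrays)."""

    def __init__(self, transcripts: Sequence[Transcript]):
        if not transcripts:
            raise ValueError("need at least one reference")
        self.transcripts = list(transcripts)
        self.dna = [t.sequence.replace("U", "T") for t in self.transcripts]
        self._arrs = [
            np.frombuffer(d.encode("ascii"), dtype=np.uint8) for d in self.dna
        ]

    def __iter__(self):
        return iter(self.transcripts)


def align_read(
    read: str,
    index: ReferenceIndex,
    max_mismatches: int = 1,
    read_id: str = "",
    min_len: int = 6,
) -> AlignedRead | None:
    """Best sense-strand placement of a trimmed read, or None if unaligned.

    Best = fewest mismatches; ties broken by leftmost position then
    reference order; a tie at the best score across distinct placements sets
    ``ambiguous``.  References are compared after U->T conversion.  Reads
    shorter than ``min_len`` are a precondition violation; the processing
    pipeline additionally discards anything under 15 nt after trimming.
    """
    if len(read) < min_len:
        raise ValueError(
            f"read of length {len(read)} is below the {min_len}-nt minimum"
        )

    # exact-match fast path
    hits: list[tuple[int, int, int]] = []  # (mm, ref_idx, pos)
    for ri, dna in enumerate(index.dna):
        pos = dna.find(read)
        while pos != -1:
            hits.append((0, ri, pos))
            pos = dna.find(read, pos + 1)

    if not hits and max_mismatches > 0:
        rarr = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
        L = len(rarr)
        for ri, arr in enumerate(index._arrs):
            if len(arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mm = (windows != rarr).sum(axis=1)
            for pos in np.nonzero(mm <= max_mismatches)[0]:
                hits.append((int(mm[pos]), ri, int(pos)))

    if not hits:
        return None
    hits.sort(key=lambda h: (h[0], h[2], h[1]))  # mismatches, position, ref order
    best_mm = hits[0][0]
    best = [h for h in hits if h[0] == best_mm]
    mm, ri, pos = best[0]
    return AlignedRead(
        read_id=read_id,
        transcript_id=index.transcripts[ri].id,
        start=pos,
        end=pos + len(read),
        n_mismatch=mm,
        ambiguous=len(best) > 1,
        sequence=read,
    )


@dataclass
class ProcessResult:
    alignments: list[AlignedRead]  # collapsed, weighted; includes ambiguous
    stats: dict


def process_reads(
    reads: Iterable[tuple[str, str]],
    index: ReferenceIndex,
    adapter: str,
    min_overlap: int = 3,
    max_mismatch_rate: float = 0.1,
    max_mismatches: int = 1,
) -> ProcessResult:
    """Trim and align an iterable of (read_id, sequence) pairs.

    Reads are collapsed by sequence before trimming; the first read id seen
    for a sequence represents the collapsed group and ``weight`` carries the
    multiplicity.
    """
    counter: Counter[str] = Counter()
    first_id: dict[str, str] = {}
    n_reads = 0
    for rid, seq in reads:
        n_reads += 1
        counter[seq] += 1
        if seq not in first_id:
            first_id[seq] = rid

    alignments: list[AlignedRead] = []
    n_short = n_unaligned = n_ambiguous = n_aligned = 0
    for seq, count in counter.items():
        trimmed = trim_adapter(seq, adapter, min_overlap, max_mismatch_rate)
        if len(trimmed) < MIN_READ_LEN:
            n_short += count
            continue
        aln = align_read(trimmed, index, max_mismatches, read_id=first_id[seq])
        if aln is None:
            n_unaligned += count
            continue
        aln.weight = count
        alignments.append(aln)
        if aln.ambiguous:
            n_ambiguous += count
        else:
            n_aligned += count

    stats = {
        "n_reads": n_reads,
        "n_too_short": n_short,
        "n_unaligned": n_unaligned,
        "n_ambiguous": n_ambiguous,
        "n_aligned_unique": n_aligned,
        "n_collapsed_groups": len(alignments),
    }
    return ProcessResult(alignments=alignments, stats=stats)


def parse_fastq(path) -> Iterable[tuple[str, str]]:
    """(read_id, sequence) pairs from a FASTQ file, optionally gzipped."""
    import gzip

    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq


def process_fastq(path, index: ReferenceIndex, adapter: str, **kw) -> ProcessResult:
    return process_reads(parse_fastq(path), index, adapter, **kw)


def count_reads(
    alignments: Iterable[AlignedRead], include_ambiguous: bool = False
) -> pd.DataFrame:
    """Per-transcript counts and reads-per-million over aligned reads.

    Ambiguous placements are excluded from both counts and the RPM
    denominator unless ``include_ambiguous``; with at least one aligned read
    the RPM column sums to 1e6.  Zero aligned reads yield an empty table.
    """
    counts: Counter[str] = Counter()
    for a in alignments:
        if a.ambiguous and not include_ambiguous:
            continue
        counts[a.transcript_id] += a.weight
    if not counts:
        return pd.DataFrame(columns=["transcript_id", "count", "rpm"])
    total = sum(counts.values())
    df = pd.DataFrame(
        sorted(counts.items()), columns=["transcript_id", "count"]
    )
    df["rpm"] = df["count"] / total * 1e6
    return df


def write_sam(path, alignments: Iterable[AlignedRead], transcripts: Sequence[Transcript]) -> None:
    """Minimal SAM: @SQ per reference, mandatory 11 columns, NM tag.

    One record per collapsed read group (the weight is not expanded); POS is
    1-based per the SAM spec.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for t in transcripts:
            fh.write(f"@SQ\tSN:{t.id}\tLN:{len(t)}\n")
        for a in alignments:
            seq = a.sequence or "*"
            cigar = f"{a.end - a.start}M"
            fh.write(
                f"{a.read_id}\t0\t{a.transcript_id}\t{a.start + 1}\t255\t"
                f"{cigar}\t*\t0\t0\t{seq}\t*\tNM:i:{a.n_mismatch}\n"
            )
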