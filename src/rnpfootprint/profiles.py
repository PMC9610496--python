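"""Coverage profiles, footprint calling and terminus statistics.

A footprint shows up in small-RNA-seq as a sharp pile of reads over the
protected interval.  ``call_footprints`` formalizes reading those peaks off
a coverage track: maximal runs of positions at or above a fraction of the
profile maximum, with small gaps bridged and short runs dropped.  The
terminus statistic quantifies the cleavage chemistry directly: among reads
with an informative 3' end, what fraction end on a pyrimidine?
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import PYRIMIDINES, Transcript, to_browser_coords
from .readproc import AlignedRead


@dataclass
class CoverageProfile:
    """Per-base depth plus 5'-start and 3'-end counts for one transcript."""

    transcript_id: str
    depth: np.ndarray
    end5: np.ndarray
    end3: np.ndarray

    def total_reads(self) -> int:
        return int(self.end5.sum())


@dataclass
class PredictedMatch:
    label: str
    offset5: int
    offset3: int
    concordant: bool
    extended_5prime_rule: bool = True  # 5' boundary uses the mirrored rule


@dataclass
class FootprintCall:
    start: int
    end: int
    peak_depth: int
    mean_depth: float
    predicted_match: PredictedMatch | None = None


def compute_coverage(
    alignments: Iterable[AlignedRead],
    transcript: Transcript,
    include_ambiguous: bool = False,
) -> CoverageProfile:
    """Pileup of weighted alignments on one transcript.

    depth[i] counts alignments covering i; end3 counts each alignment at its
    last covered base.  Alignments on a different transcript raise.
    """
    n = len(transcript)
    depth = np.zeros(n, dtype=np.int64)
    end5 = np.zeros(n, dtype=np.int64)
    end3 = np.zeros(n, dtype=np.int64)
    for a in alignments:
        if a.transcript_id != transcript.id:
            raise ValueError(
                f"alignment on {a.transcript_id!r} passed with transcript "
                f"{transcript.id!r}"
            )
        if a.ambiguous and not include_ambiguous:
            continue
        depth[a.start : a.end] += a.weight
        end5[a.start] += a.weight
        end3[a.end - 1] += a.weight
    return CoverageProfile(transcript.id, depth, end5, end3)


def call_footprints(
    profile: CoverageProfile,
    theta: float = 0.5,
    min_len: int = 10,
    merge_gap: int = 2,
) -> list[FootprintCall]:
    """Peaks of the coverage track as candidate footprints.

    Positions with depth >= theta * max(depth) seed runs; runs separated by
    gaps <= merge_gap are merged; runs shorter than min_len are dropped.
    An all-zero profile yields no calls.
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must be in (0, 1]")
    d = profile.depth
    peak = int(d.max()) if d.size else 0
    if peak == 0:
        return []
    mask = d >= theta * peak

    runs: list[list[int]] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    calls = []
    for s, e in merged:
        if e - s < min_len:
            continue
        seg = d[s:e]
        calls.append(
            FootprintCall(
                start=s,
                end=e,
                peak_depth=int(seg.max()),
                mean_depth=float(seg.mean()),
            )
        )
    return calls


def terminus_pyrimidine_fraction(
    alignments: Iterable[AlignedRead],
    transcript: Transcript,
    read_len: int | None = None,
    include_ambiguous: bool = False,
) -> float:
    """Fraction of informative 3' read termini landing on a pyrimidine.

    Only internal termini count: reads ending at the transcript's last base
    are excluded (a transcript end is not evidence of cleavage), and when
    ``read_len`` is given, alignments spanning at least read_len bases are
    excluded because their insert was truncated by the sequencer and the true
    3' end is unobserved.  Returns NaN when no alignment is eligible.
    """
    num = den = 0
    last = len(transcript) - 1
    seq = transcript.sequence
    for a in alignments:
        if a.transcript_id != transcript.id:
            raise ValueError("alignment on a different transcript")
        if a.ambiguous and not include_ambiguous:
            continue
        if a.end - 1 >= last:
            continue
        if read_len is not None and a.end - a.start >= read_len:
            continue
        den += a.weight
        if seq[a.end - 1] in PYRIMIDINES:
            num += a.weight
    if den == 0:
        return float("nan")
    return num / den


def match_footprint_to_prediction(
    call: FootprintCall,
    predicted: tuple[int, int],
    tol: int = 2,
    label: str = "",
) -> PredictedMatch:
    """Boundary offsets of a called footprint against a predicted fragment.

    Offsets are called minus predicted; the call is concordant when both
    absolute offsets are within ``tol`` nt.
    """
    off5 = call.start - predicted[0]
    off3 = call.end - predicted[1]
    return PredictedMatch(
        label=label,
        offset5=off5,
        offset3=off3,
        concordant=abs(off5) <= tol and abs(off3) <= tol,
    )


def fold_change(
    rpm_a: Mapping[str, float],
    rpm_b: Mapping[str, float],
    transcript_id: str,
    pseudocount: float = 0.5,
) -> float:
    """Pseudocounted RPM ratio of one transcript between two samples."""
    if transcript_id not in rpm_a and transcript_id not in rpm_b:
        raise KeyError(f"{transcript_id!r} absent from both tables")
    a = rpm_a.get(transcript_id, 0.0)
    b = rpm_b.get(transcript_id, 0.0)
    return (a + pseudocount) / (b + pseudocount)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def write_bedgraph(profile: CoverageProfile, path, track: str = "depth") -> None:
    """One bedGraph track (depth, end5 or end3), runs of equal value collapsed."""
    values = getattr(profile, track)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{profile.transcript_id}_{track}"\n')
        i = 0
        n = len(values)
        while i < n:
            j = i
            while j < n and values[j] == values[i]:
                j += 1
            if values[i] != 0:
                fh.write(f"{profile.transcript_id}\t{i}\t{j}\t{int(values[i])}\n")
            i = j


def write_footprints_bed(path, transcript_id: str, calls: Sequence[FootprintCall]) -> None:
    with open(path, "w") as fh:
        for k, c in enumerate(calls):
            name = c.predicted_match.label if c.predicted_match else f"call{k}"
            fh.write(
                f"{transcript_id}\t{c.start}\t{c.end}\t{name}\t{c.peak_depth}\t+\n"
            )


def write_footprints_tsv(path, transcript_id: str, calls: Sequence[FootprintCall]) -> None:
    """Human-readable call table; coordinates 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tstart_1based\tend_1based\tpeak_depth\tmean_depth\t"
            "matched_label\toffset5\toffset3\tconcordant\tfive_prime_rule_extended\n"
        )
        for c in calls:
            s1, e1 = to_browser_coords(c.start, c.end)
            m = c.predicted_match
            if m is None:
                fh.write(
                    f"{transcript_id}\t{s1}\t{e1}\t{c.peak_depth}\t"
                    f"{c.mean_depth:.2f}\t.\t.\t.\t.\t.\n"
                )
            else:
                fh.write(
                    f"{transcript_id}\t{s1}\t{e1}\t{c.peak_depth}\t"
                    f"{c.mean_depth:.2f}\t{m.label}\t{m.offset5}\t{m.offset3}\t"
                    f"{str(m.concordant).lower()}\t{str(m.extended_5prime_rule).lower()}\n"
                )
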