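"""Classify coverage profiles into the three qualitative digestion regimes.

An EV- or cell-like sample spreads reads over the whole transcript
(``uniform``); an exomere-like sample shows several protected footprints
(``multi_footprint``); a supermere-like sample retains only the core
complex's footprint (``core_only``).  The classifier is intentionally
simple: a breadth cut separates uniform profiles, and the tier composition
of footprint calls concordant with the protection annotations separates the
other two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .core import (
    ProtectedInterval,
    RNaseSpec,
    RNASE_A,
    Tier,
    Transcript,
    predict_protected_fragment,
)
from .profiles import (
    CoverageProfile,
    FootprintCall,
    call_footprints,
    match_footprint_to_prediction,
)

UNIFORM = "uniform"
MULTI_FOOTPRINT = "multi_footprint"
CORE_ONLY = "core_only"
UNCLASSIFIABLE = "unclassifiable"


@dataclass
class ProfileClass:
    label: str
    breadth: float
    in_core_fraction: float
    n_concordant: dict = field(default_factory=dict)  # tier value -> count
    calls: list = field(default_factory=list)


def classify_profile(
    profile: CoverageProfile,
    transcript: Transcript,
    annotations: Sequence[ProtectedInterval],
    spec: RNaseSpec = RNASE_A,
    *,
    breadth_cut: float = 0.8,
    depth_floor: float = 0.1,
    theta: float = 0.5,
    min_len: int = 10,
    merge_gap: int = 2,
    tol: int = 2,
) -> ProfileClass:
    """Label a profile uniform / multi_footprint / core_only.

    breadth = fraction of the transcript with depth >= depth_floor * max;
    profiles with breadth >= breadth_cut are uniform.  Otherwise footprints
    are called and matched against the predicted protected fragments; if at
    least one call is concordant and every concordant call matches a
    core-tier interval the profile is core_only, else multi_footprint.
    A profile with no coverage is unclassifiable.
    """
    anns = [a for a in annotations if a.transcript_id == transcript.id]
    if not any(a.tier is Tier.CORE for a in anns):
        raise ValueError("annotations must include at least one core interval")

    d = profile.depth
    if d.sum() == 0:
        return ProfileClass(UNCLASSIFIABLE, 0.0, 0.0)

    peak = int(d.max())
    breadth = float((d >= depth_floor * peak).mean())

    predictions = {
        a: predict_protected_fragment(transcript, a, spec) for a in anns
    }
    core_mask = np.zeros(len(transcript), dtype=bool)
    for a, (s, e) in predictions.items():
        if a.tier is Tier.CORE:
            core_mask[s:e] = True
    in_core = float(d[core_mask].sum() / d.sum())

    calls = call_footprints(profile, theta=theta, min_len=min_len, merge_gap=merge_gap)
    n_concordant = {Tier.CORE.value: 0, Tier.PERIPHERAL.value: 0}
    for call in calls:
        best_ann = None
        best_score = None
        for a, pred in predictions.items():
            m = match_footprint_to_prediction(call, pred, tol=tol, label=a.label)
            score = max(abs(m.offset5), abs(m.offset3))
            if best_score is None or score < best_score:
                best_score = score
                best_ann = (a, m)
        if best_ann is not None:
            a, m = best_ann
            call.predicted_match = m
            if m.concordant:
                n_concordant[a.tier.value] += 1

    if breadth >= breadth_cut:
        label = UNIFORM
    else:
        total_conc = sum(n_concordant.values())
        if total_conc > 0 and total_conc == n_concordant[Tier.CORE.value]:
            label = CORE_ONLY
        else:
            label = MULTI_FOOTPRINT

    return ProfileClass(label, breadth, in_core, n_concordant, calls)


def profile_similarity(a: CoverageProfile, b: CoverageProfile) -> float:
    """Spearman correlation of per-base depths over covered positions.

    Positions covered in at least one profile enter the correlation; the
    value is symmetric and invariant to scaling either profile by a positive
    constant.  Returns NaN when both profiles are empty or ranks are
    degenerate.
    """
    if a.transcript_id != b.transcript_id:
        raise ValueError("profiles are on different transcripts")
    da = np.asarray(a.depth, dtype=float)
    db = np.asarray(b.depth, dtype=float)
    mask = (da > 0) | (db > 0)
    if not mask.any():
        return float("nan")
    xa, xb = da[mask], db[mask]
    if np.all(xa == xa[0]) or np.all(xb == xb[0]):
        return float("nan")
    return float(spearmanr(xa, xb).statistic)


def write_classification_tsv(path, rows) -> None:
    """rows: iterables of (sample, transcript_id, ProfileClass)."""
    with open(path, "w") as fh:
        fh.write(
            "sample\ttranscript_id\tlabel\tbreadth\tin_core_fraction\t"
            "n_concordant_core\tn_concordant_peripheral\tn_calls\n"
        )
        for sample, tid, pc in rows:
            fh.write(
                f"{sample}\t{tid}\t{pc.label}\t{pc.breadth:.4f}\t"
                f"{pc.in_core_fraction:.4f}\t"
                f"{pc.n_concordant.get('core', 0)}\t"
                f"{pc.n_concordant.get('peripheral', 0)}\t{len(pc.calls)}\n"
            )
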