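"""Synthetic data generation: digestion-shaped reads and spectral counts.

Two generators live here.

The read generator emulates small-RNA-seq libraries from four kinds of
sample.  In digested compartments (exomere- and supermere-like particles,
which are exposed to extracellular ribonucleases) each transcript molecule
is cut independently at every eligible pyrimidine with probability ``q``;
fragments passing the library size selection enter the read pool, so
protein-protected footprints dominate by survivorship.  Undigested
compartments (whole cells, extracellular vesicles whose lumen shields the
RNA) still yield short reads because library preparation itself fragments
the RNA; that step is modeled as a uniform breakpoint surrogate: a 5' start
drawn uniformly over feasible positions and a length drawn uniformly over
the size-selection window.  Degradation of unprotected fragments is implicit
in the size selection; no separate decay parameter exists.

The spectral-count generator emulates shotgun-proteomics tables in which a
protein's spectral count scales with its abundance and its length (longer
proteins yield more tryptic peptides), with per-class enrichment effects and
Poisson counting noise.

Everything is driven by one numpy Generator seeded from the parameter
objects, so identical parameters reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ProtectedInterval,
    RNaseSpec,
    RNASE_A,
    Tier,
    Transcript,
    eligible_sites,
    validate_protections,
)

DEFAULT_ADAPTER = "AGATCGGAAGAGC"  # TruSeq-style 3' adapter stub


class NoFragmentsError(RuntimeError):
    """Raised when no simulated fragment falls inside the size window."""


@dataclass
class DigestionParams:
    """Knobs of the read simulator.

    q is the per-eligible-site cleavage probability (extracellular RNase
    exposure has no measured rate, so q is a free parameter);
    min_len/max_len is the library size selection in nt; read_len the
    sequencer read length; n_molecules the number of transcript molecules
    digested to build the fragment pool.
    """

    q: float = 0.9
    n_reads: int = 10_000
    min_len: int = 15
    max_len: int = 50
    read_len: int = 50
    adapter: str = DEFAULT_ADAPTER
    n_molecules: int = 2_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.read_len < self.min_len:
            raise ValueError("read_len must be >= min_len")
        if self.n_reads < 0 or self.n_molecules <= 0:
            raise ValueError("n_reads must be >= 0 and n_molecules > 0")
        if set(self.adapter) - set("ACGTN"):
            raise ValueError("adapter must be a DNA string")


@dataclass(frozen=True)
class CompartmentModel:
    """Which digestion regime and protection tiers a sample class sees."""

    name: str
    digested: bool
    active_tiers: frozenset = frozenset({Tier.CORE, Tier.PERIPHERAL})

    def __post_init__(self) -> None:
        tiers = frozenset(Tier(t) for t in self.active_tiers)
        object.__setattr__(self, "active_tiers", tiers)


#: Cells and EVs are shielded from extracellular RNases; exomere-like
#: particles retain both core and peripheral complexes; supermere-like
#: particles retain only the core complex.
COMPARTMENTS: dict[str, CompartmentModel] = {
    "CELL": CompartmentModel("CELL", digested=False),
    "EV": CompartmentModel("EV", digested=False),
    "EXOMERE": CompartmentModel(
        "EXOMERE", digested=True, active_tiers=frozenset({Tier.CORE, Tier.PERIPHERAL})
    ),
    "SUPERMERE": CompartmentModel(
        "SUPERMERE", digested=True, active_tiers=frozenset({Tier.CORE})
    ),
}


def digest_transcript(
    transcript: Transcript,
    protections: Iterable[ProtectedInterval],
    q: float,
    rng: np.random.Generator,
    spec: RNaseSpec = RNASE_A,
    sites: Sequence[int] | None = None,
) -> list[tuple[int, int]]:
    """One stochastic digestion of one molecule.

    Each eligible site is cut independently with probability ``q``; the
    returned fragments are the maximal uncut runs and tile the transcript
    exactly (size selection is the caller's job).  ``sites`` may carry a
    precomputed ``eligible_sites`` result for speed.
    """
    if sites is None:
        sites = eligible_sites(transcript, protections, spec)
    length = len(transcript)
    if len(sites) == 0:
        return [(0, length)]
    sites_arr = np.asarray(sites)
    cut = sites_arr[rng.random(len(sites_arr)) < q]
    bounds = [0]
    for c in cut:
        b = int(c) + 1
        if b < length:  # a cut after the last base is a no-op
            bounds.append(b)
    bounds.append(length)
    return [(a, b) for a, b in zip(bounds, bounds[1:])]


def _undigested_fragment(
    length: int, min_len: int, max_len: int, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Library-prep fragmentation surrogate for shielded RNA.

    Start uniform over feasible 5' positions, fragment length uniform over
    the feasible part of the size window; returns None when the transcript
    is shorter than min_len.
    """
    if length < min_len:
        return None
    start = int(rng.integers(0, length - min_len + 1))
    hi = min(max_len, length - start)
    frag_len = int(rng.integers(min_len, hi + 1))
    return start, start + frag_len


@dataclass
class SimRead:
    read_id: str
    transcript_id: str
    start: int
    end: int
    sequence: str  # DNA, adapter appended, truncated to read_len


@dataclass
class SimulatedSample:
    compartment: str
    reads: list[SimRead]
    pool_size: int

    def fastq_text(self) -> str:
        chunks = []
        for r in self.reads:
            chunks.append(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
        return "".join(chunks)


def simulate_compartment(
    references: Sequence[Transcript],
    annotations: Sequence[ProtectedInterval],
    compartment: CompartmentModel,
    abundances: Mapping[str, float],
    params: DigestionParams,
    fastq_path=None,
    truth_bed_path=None,
    manifest_path=None,
    rng: np.random.Generator | None = None,
) -> SimulatedSample:
    """Simulate one sample: FASTQ reads plus per-read ground-truth intervals.

    Fragment pools are built from ``params.n_molecules`` abundance-weighted
    transcript molecules; reads are drawn uniformly from the surviving pool.
    Raises NoFragmentsError if reads are requested but nothing passes the
    size window.  Deterministic for fixed params/seed.
    """
    ref_by_id = {t.id: t for t in references}
    ids = [t.id for t in references]
    probs = np.array([abundances.get(i, 0.0) for i in ids], dtype=float)
    if probs.sum() <= 0 or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("abundances must sum to 1 over the references")
    for t in references:
        validate_protections(t, [a for a in annotations if a.transcript_id == t.id])

    if rng is None:
        rng = np.random.default_rng(params.seed)

    active_prots: dict[str, list[ProtectedInterval]] = {
        t.id: [
            a
            for a in annotations
            if a.transcript_id == t.id and a.tier in compartment.active_tiers
        ]
        for t in references
    }
    site_cache = {
        t.id: eligible_sites(t, active_prots[t.id]) for t in references
    }

    pool: list[tuple[str, int, int]] = []
    choices = rng.choice(len(ids), size=params.n_molecules, p=probs)
    for c in choices:
        t = references[int(c)]
        if compartment.digested:
            frags = digest_transcript(
                t, active_prots[t.id], params.q, rng, sites=site_cache[t.id]
            )
            pool.extend(
                (t.id, a, b)
                for a, b in frags
                if params.min_len <= b - a <= params.max_len
            )
        else:
            frag = _undigested_fragment(
                len(t), params.min_len, params.max_len, rng
            )
            if frag is not None:
                pool.append((t.id, frag[0], frag[1]))

    if params.n_reads > 0 and not pool:
        raise NoFragmentsError(
            f"{compartment.name}: no fragments in size window "
            f"[{params.min_len},{params.max_len}]"
        )

    reads: list[SimRead] = []
    if params.n_reads > 0:
        idx = rng.integers(0, len(pool), size=params.n_reads)
        for i, j in enumerate(idx):
            tid, s, e = pool[int(j)]
            insert = ref_by_id[tid].sequence[s:e].replace("U", "T")
            seq = (insert + params.adapter)[: params.read_len]
            reads.append(SimRead(f"{compartment.name}_{i:06d}", tid, s, e, seq))

    sample = SimulatedSample(compartment.name, reads, len(pool))

    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            fh.write(sample.fastq_text())
    if truth_bed_path is not None:
        with open(truth_bed_path, "w") as fh:
            for r in reads:
                fh.write(f"{r.transcript_id}\t{r.start}\t{r.end}\t{r.read_id}\t0\t+\n")
    if manifest_path is not None:
        import yaml

        manifest = {
            "compartment": compartment.name,
            "digested": compartment.digested,
            "active_tiers": sorted(t.value for t in compartment.active_tiers),
            "abundances": {k: float(v) for k, v in abundances.items()},
            "params": asdict(params),
            "pool_size": len(pool),
        }
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)

    return sample


# ---------------------------------------------------------------------------
# Spectral-count table generator
# ---------------------------------------------------------------------------


@dataclass
class SpectralCountParams:
    """Generative model for per-protein spectral counts.

    Mean count for protein i in class c is depth * w / sum(w) with
    w_i = length_i * abundance_i * class_effect_{c,i}; abundances are
    log-normal with log-scale spread ``abundance_sd`` and shared across
    classes and replicates (a paired design); observed counts are Poisson.
    """

    n_proteins: int = 50
    lengths: Sequence[int] | None = None
    abundance_sd: float = 1.0
    class_effect: Mapping[str, object] | None = None  # class -> scalar or array
    classes: tuple = ("exomere", "supermere")
    depth: int = 5_000
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lengths is None:
            # deterministic spread of plausible protein lengths, 80-600 aa
            self.lengths = np.rint(
                np.geomspace(80, 600, self.n_proteins)
            ).astype(int)
        self.lengths = np.asarray(self.lengths, dtype=int)
        if len(self.lengths) != self.n_proteins:
            raise ValueError("lengths must have n_proteins entries")
        if (self.lengths <= 0).any():
            raise ValueError("protein lengths must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.abundance_sd < 0:
            raise ValueError("abundance_sd must be >= 0")


def simulate_spectral_counts(
    params: SpectralCountParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Raw spectral-count table plus the generative ground truth.

    Returns a tidy DataFrame (protein_id, length_aa, class, replicate,
    raw_count) and a truth dict with per-protein abundances, per-class
    expected means and the generative Spearman correlation between expected
    count and protein length.
    """
    from scipy.stats import spearmanr

    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    lengths = np.asarray(params.lengths, dtype=float)
    abundance = rng.lognormal(mean=0.0, sigma=params.abundance_sd, size=n)

    effects = {}
    for c in params.classes:
        eff = 1.0
        if params.class_effect:
            eff = params.class_effect.get(c, 1.0)
        effects[c] = np.broadcast_to(np.asarray(eff, dtype=float), (n,)).copy()

    rows = []
    expected = {}
    gen_rho = {}
    protein_ids = [f"P{i:03d}" for i in range(n)]
    for c in params.classes:
        w = lengths * abundance * effects[c]
        mean = params.depth * w / w.sum()
        expected[c] = mean
        gen_rho[c] = float(spearmanr(mean, lengths).statistic)
        for r in range(params.n_replicates):
            counts = rng.poisson(mean)
            for i in range(n):
                rows.append(
                    (protein_ids[i], int(lengths[i]), c, r + 1, int(counts[i]))
                )

    df = pd.DataFrame(
        rows, columns=["protein_id", "length_aa", "class", "replicate", "raw_count"]
    )
    truth = {
        "abundance": abundance,
        "expected_mean": expected,
        "generative_rho": gen_rho,
        "protein_ids": protein_ids,
    }
    return df, truth


# ---------------------------------------------------------------------------
# Built-in synthetic references
# ---------------------------------------------------------------------------

def _filler(n: int, rng: np.random.Generator) -> str:
    """Aperiodic unprotected sequence: short purine runs separated by
    pyrimidines, so digestion fragments between cuts stay below the size
    selection and no 15-mer repeats elsewhere on the transcript."""
    out: list[str] = []
    while len(out) < n:
        run = int(rng.integers(2, 5))
        out.extend(rng.choice(["A", "G"], size=run))
        out.append(str(rng.choice(["C", "U"])))
    return "".join(out[:n])


def toy_u2_reference() -> tuple[Transcript, list[ProtectedInterval]]:
    """Synthetic U2-snRNA-like reference with three protected intervals.

    A ~199-nt transcript carrying, 5'->3': a branch-site-loop-like interval
    protected by a peripheral factor (SF3B1 tier), an Sm-site-like core
    interval whose protected sequence resembles the miR-1246-annotated
    fragment, and a stem-loop-IV-like interval protected by a second
    peripheral factor (SNRPA1 tier).  Purine spacers flank the protected
    intervals so predicted fragments extend a few bases to the nearest
    outside pyrimidine; unprotected filler keeps pyrimidines frequent so
    stray digestion fragments rarely pass the size selection.  This is a
    synthetic stand-in constructed for simulation; it is not the genomic
    RNU2-1 sequence.
    """
    rng = np.random.default_rng(99)  # fixed: the reference is a constant
    segments: list[tuple[str, str | None, Tier | None]] = [
        (_filler(35, rng), None, None),
        ("GGAUACCUGAAUCGCGUAAGGCAU", "SF3B1", Tier.PERIPHERAL),
        ("AAGGA", None, None),
        (_filler(25, rng), None, None),
        ("GAAGA", None, None),
        ("AAUGGAUUUUUGGAGCAGG", "Sm", Tier.CORE),
        ("AAAGGAA", None, None),
        (_filler(25, rng), None, None),
        ("GGCAUUCGAAUGCCAAGGUCUAAG", "SNRPA1", Tier.PERIPHERAL),
        ("AGGAA", None, None),
        (_filler(25, rng), None, None),
    ]
    seq_parts = []
    annotations = []
    pos = 0
    tid = "U2LIKE"
    for seq, label, tier in segments:
        if label is not None:
            annotations.append(
                ProtectedInterval(tid, pos, pos + len(seq), label, tier)
            )
        seq_parts.append(seq)
        pos += len(seq)
    transcript = Transcript(tid, "".join(seq_parts))
    validate_protections(transcript, annotations)
    return transcript, annotations


def random_transcript(
    length: int, rng: np.random.Generator, pyr_frac: float = 0.45, tid: str = "T"
) -> Transcript:
    """Random RNA with a given expected pyrimidine content."""
    p_each = [
        (1 - pyr_frac) / 2,  # A
        pyr_frac / 2,  # C
        (1 - pyr_frac) / 2,  # G
        pyr_frac / 2,  # U
    ]
    bases = rng.choice(list("ACGU"), size=length, p=p_each)
    return Transcript(tid, "".join(bases))
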