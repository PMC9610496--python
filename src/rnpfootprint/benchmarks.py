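"""End-to-end validation runs: oracle agreement, recovery, accuracy, error rates.

Each function here regenerates its inputs from a seed, runs the package's
own simulation/analysis path, and returns plain-dict metrics.  The
brute-force references in this module are deliberately written as different
algorithms from the implementations they check (cut-set arithmetic instead
of directional scans; explicit sign enumeration instead of dynamic
programming) so agreement is informative.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

from .compare import CORE_ONLY, MULTI_FOOTPRINT, UNIFORM, classify_profile
from .core import (
    PYRIMIDINES,
    ProtectedInterval,
    RNASE_A,
    Tier,
    Transcript,
    predict_protected_fragment,
)
from .profiles import (
    compute_coverage,
    call_footprints,
    fold_change,
    match_footprint_to_prediction,
    terminus_pyrimidine_fraction,
)
from .proteomics import (
    SignedRankResult,
    normalize_counts,
    paired_class_test,
    size_correlation,
    _signed_rank_exact_p,
)
from .readproc import ReferenceIndex, count_reads, process_reads
from .synth import (
    COMPARTMENTS,
    DigestionParams,
    SpectralCountParams,
    digest_transcript,
    random_transcript,
    simulate_compartment,
    simulate_spectral_counts,
    toy_u2_reference,
)


# ---------------------------------------------------------------------------
# Brute-force references
# ---------------------------------------------------------------------------


def bruteforce_protected_fragment(
    transcript: Transcript, interval: ProtectedInterval, spec=RNASE_A
) -> tuple[int, int]:
    """Cut-set reference for the surviving fragment of a protected interval.

    Enumerate every cut boundary an exhaustive digestion can realise (3' of
    each cleavable base outside the protection), then take the closest
    boundaries enclosing the interval.
    """
    seq = transcript.sequence
    cuts = [
        p + 1
        for p, base in enumerate(seq)
        if base in spec.target_bases and not (interval.start <= p < interval.end)
    ]
    start = max((c for c in cuts if c <= interval.start), default=0)
    end = min((c for c in cuts if c >= interval.end), default=len(seq))
    return start, end


def _random_case(rng: np.random.Generator, min_len=20, max_len=200):
    length = int(rng.integers(min_len, max_len + 1))
    t = random_transcript(length, rng, pyr_frac=0.45, tid="R")
    a = int(rng.integers(0, length))
    b = int(rng.integers(a + 1, length + 1))
    return t, ProtectedInterval("R", a, b, "X")


def cleavage_rule_agreement(n_cases: int = 1000, seed: int = 0) -> dict:
    """Fraction of random (transcript, interval) cases where the fragment
    prediction equals the brute-force cut-set reference."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_cases):
        t, iv = _random_case(rng)
        if predict_protected_fragment(t, iv) == bruteforce_protected_fragment(t, iv):
            agree += 1
    return {"agreement": agree / n_cases, "n": n_cases}


# ---------------------------------------------------------------------------
# Digestion laws
# ---------------------------------------------------------------------------


def digestion_law_check(
    n_transcripts: int = 500, qs=(0.2, 1.0), seed: int = 0
) -> dict:
    """Count violations of the three digestion laws over random transcripts.

    (1) pre-filter fragments tile the transcript; (2) every internal 3'
    fragment end is a pyrimidine and every internal 5' start is preceded by
    one; (3) at q = 1 the fragment containing the protected interval equals
    the predicted protected fragment.
    """
    rng = np.random.default_rng(seed)
    violations = 0
    n_checked = 0
    for _ in range(n_transcripts):
        t, iv = _random_case(rng)
        for q in qs:
            n_checked += 1
            frags = digest_transcript(t, [iv], q, rng)
            ok = True
            # tiling
            if frags[0][0] != 0 or frags[-1][1] != len(t):
                ok = False
            for (a1, b1), (a2, b2) in zip(frags, frags[1:]):
                if b1 != a2:
                    ok = False
            # terminus law
            for a, b in frags:
                if b < len(t) and t.sequence[b - 1] not in PYRIMIDINES:
                    ok = False
                if a > 0 and t.sequence[a - 1] not in PYRIMIDINES:
                    ok = False
            # q=1 oracle
            if q == 1.0:
                containing = [
                    (a, b) for a, b in frags if a <= iv.start and b >= iv.end
                ]
                if containing != [predict_protected_fragment(t, iv)]:
                    ok = False
            if not ok:
                violations += 1
    return {"violations": violations, "n": n_checked}


def small_instance_tv_distance(
    n_draws: int = 100_000, q: float = 0.5, seed: int = 0
) -> dict:
    """TV distance between simulated and enumerated fragment frequencies.

    For each short transcript (<= 12 nt), draw ``n_draws`` digestions with
    the simulator and compare the pooled fragment-interval frequencies with
    the exact distribution obtained by enumerating every subset of cut
    sites.  Returns the maximum TV distance over the fixtures.
    """
    fixtures = [
        (Transcript("S1", "ACGUACGUACGU"), []),
        (Transcript("S2", "CCUAGGAUUCGA"), []),
        (Transcript("S3", "AAGCUAAGCUAA"), [ProtectedInterval("S3", 3, 7, "P")]),
    ]
    rng = np.random.default_rng(seed)
    worst = 0.0
    for t, prots in fixtures:
        from .core import eligible_sites

        sites = eligible_sites(t, prots)
        length = len(t)

        # exact: expected per-digest count of each fragment / expected total
        exact: Counter = Counter()
        total_weight = 0.0
        for k in range(len(sites) + 1):
            for cut_set in itertools.combinations(sites, k):
                w = (q ** len(cut_set)) * ((1 - q) ** (len(sites) - len(cut_set)))
                bounds = [0] + [c + 1 for c in cut_set if c + 1 < length] + [length]
                bounds = sorted(set(bounds))
                frags = list(zip(bounds, bounds[1:]))
                for f in frags:
                    exact[f] += w
                total_weight += w * len(frags)
        exact_freq = {f: w / total_weight for f, w in exact.items()}

        emp: Counter = Counter()
        n_frags = 0
        for _ in range(n_draws):
            frags = digest_transcript(t, prots, q, rng, sites=sites)
            emp.update(frags)
            n_frags += len(frags)
        tv = 0.5 * sum(
            abs(emp.get(f, 0) / n_frags - exact_freq.get(f, 0.0))
            for f in set(emp) | set(exact_freq)
        )
        worst = max(worst, tv)
    return {"tv_distance": worst, "n": n_draws}


# ---------------------------------------------------------------------------
# Pipeline helpers
# ---------------------------------------------------------------------------


def run_sample_pipeline(
    compartment: str,
    params: DigestionParams,
    reference=None,
    annotations=None,
    abundances=None,
):
    """Simulate one toy-reference sample and push it through trim/align/pileup."""
    if reference is None:
        reference, annotations = toy_u2_reference()
    if abundances is None:
        abundances = {reference.id: 1.0}
    sample = simulate_compartment(
        [reference], annotations, COMPARTMENTS[compartment], abundances, params
    )
    index = ReferenceIndex([reference])
    res = process_reads(
        ((r.read_id, r.sequence) for r in sample.reads),
        index,
        params.adapter,
    )
    profile = compute_coverage(res.alignments, reference)
    return sample, res, profile


def footprint_recovery(
    n_replicates: int = 100, n_reads: int = 50_000, q: float = 0.9, seed: int = 0
) -> dict:
    """Supermere-regime parameter recovery on the toy U2-like reference.

    In each replicate the strongest called footprint is compared with the
    predicted core (Sm) fragment; a hit means both boundaries within 2 nt.
    """
    reference, annotations = toy_u2_reference()
    core = next(a for a in annotations if a.tier is Tier.CORE)
    predicted = predict_protected_fragment(reference, core)
    hits = 0
    for i in range(n_replicates):
        params = DigestionParams(q=q, n_reads=n_reads, seed=seed + i)
        _, _, profile = run_sample_pipeline("SUPERMERE", params, reference, annotations)
        calls = call_footprints(profile)
        if not calls:
            continue
        best = max(calls, key=lambda c: c.peak_depth)
        m = match_footprint_to_prediction(best, predicted, tol=2, label=core.label)
        hits += int(m.concordant)
    return {"hit_rate": hits / n_replicates, "n": n_replicates}


def classification_accuracy(
    n_per_class: int = 30, n_reads: int = 20_000, q: float = 0.9, seed_base: int = 1
) -> dict:
    """Accuracy of the three-way profile classifier on labeled simulations."""
    reference, annotations = toy_u2_reference()
    truth = (
        [("EV", UNIFORM)] * n_per_class
        + [("EXOMERE", MULTI_FOOTPRINT)] * n_per_class
        + [("SUPERMERE", CORE_ONLY)] * n_per_class
    )
    correct = 0
    for i, (compartment, expected) in enumerate(truth):
        params = DigestionParams(q=q, n_reads=n_reads, seed=seed_base + i)
        _, _, profile = run_sample_pipeline(compartment, params, reference, annotations)
        pc = classify_profile(profile, reference, annotations)
        correct += int(pc.label == expected)
    return {"accuracy": correct / len(truth), "n": len(truth)}


def terminus_statistics(n_reads: int = 10_000, q: float = 0.9, seed: int = 0) -> dict:
    """3'-terminus pyrimidine fractions for a digested and an EV-like sample."""
    reference, annotations = toy_u2_reference()
    params_d = DigestionParams(q=q, n_reads=n_reads, seed=seed)
    _, res_d, _ = run_sample_pipeline("SUPERMERE", params_d, reference, annotations)
    frac_digested = terminus_pyrimidine_fraction(
        res_d.alignments, reference, read_len=params_d.read_len
    )
    params_e = DigestionParams(q=q, n_reads=n_reads, seed=seed + 1)
    _, res_e, _ = run_sample_pipeline("EV", params_e, reference, annotations)
    frac_ev = terminus_pyrimidine_fraction(
        res_e.alignments, reference, read_len=params_e.read_len
    )
    content = sum(b in PYRIMIDINES for b in reference.sequence) / len(reference)
    return {
        "digested_fraction": frac_digested,
        "ev_fraction": frac_ev,
        "pyrimidine_content": content,
        "ev_abs_deviation": abs(frac_ev - content),
        "n": n_reads,
    }


def fold_change_recovery(
    n_reads: int = 100_000, spike_fold: float = 8.0, seed: int = 0
) -> dict:
    """Recover a known abundance spike from raw reads via the full pipeline.

    One transcript is 8x more abundant (relative share) in sample A than in
    sample B; both undigested samples are simulated, processed and counted,
    and the RPM fold change of the spiked transcript is returned.
    """
    rng = np.random.default_rng(seed)
    spike = random_transcript(120, rng, tid="SPIKE")
    background = random_transcript(120, rng, tid="BG")
    refs = [spike, background]
    base = 0.02
    ab_a = {"SPIKE": base * spike_fold, "BG": 1 - base * spike_fold}
    ab_b = {"SPIKE": base, "BG": 1 - base}
    index = ReferenceIndex(refs)
    rpms = []
    for ab, s_off in ((ab_a, 1), (ab_b, 2)):
        params = DigestionParams(
            q=0.0, n_reads=n_reads, n_molecules=20_000, seed=seed + s_off
        )
        sample = simulate_compartment(
            refs, [], COMPARTMENTS["EV"], ab, params
        )
        res = process_reads(
            ((r.read_id, r.sequence) for r in sample.reads), index, params.adapter
        )
        counts = count_reads(res.alignments)
        rpms.append(dict(zip(counts["transcript_id"], counts["rpm"])))
    fc = fold_change(rpms[0], rpms[1], "SPIKE")
    return {"fold_change": fc, "expected": spike_fold, "n": n_reads}


# ---------------------------------------------------------------------------
# Proteomics operating characteristics
# ---------------------------------------------------------------------------


def spearman_recovery(
    n_sims: int = 100, n_proteins: int = 50, depth: int = 5_000, seed: int = 0
) -> dict:
    """Mean absolute error of the size-correlation estimate vs its
    generative value across simulated tables."""
    errs = []
    for i in range(n_sims):
        params = SpectralCountParams(
            n_proteins=n_proteins,
            depth=depth,
            classes=("exomere",),
            seed=seed + i,
        )
        df, truth = simulate_spectral_counts(params)
        df = normalize_counts(df)
        res = size_correlation(df, sample_class="exomere")
        errs.append(res.rho - truth["generative_rho"]["exomere"])
    errs = np.asarray(errs)
    return {
        "mean_abs_error": float(np.abs(errs).mean()),
        "mean_error": float(errs.mean()),
        "n": n_sims,
    }


def _group_table(effect: float, seed: int, n_group: int = 25, n_background: int = 175,
                 depth: int = 5_000):
    # the tested group is a small fraction of the emulated proteome, as a
    # protein family is of a real spectral-count table; per-sample total
    # normalization then leaves the group's paired differences effectively
    # independent (a group occupying half the table would couple them
    # through the shared total)
    n = n_group + n_background
    eff = np.ones(n)
    eff[:n_group] = effect
    params = SpectralCountParams(
        n_proteins=n,
        depth=depth,
        classes=("exomere", "supermere"),
        class_effect={"exomere": eff},
        seed=seed,
    )
    df, truth = simulate_spectral_counts(params)
    group = truth["protein_ids"][:n_group]
    return normalize_counts(df), group


def signed_rank_operating_characteristics(
    n_null: int = 500,
    n_alt: int = 200,
    effect: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I error under the null generator and power under a group effect.

    The tested protein group has 25 members (exact signed-rank path); under
    the alternative its spectral counts are multiplied by ``effect`` in the
    exomere class before per-sample normalization.
    """
    rej_null = 0
    for i in range(n_null):
        df, group = _group_table(1.0, seed=seed + i)
        res = paired_class_test(df, "exomere", "supermere", protein_subset=group)
        rej_null += int(res.pvalue < alpha)
    rej_alt = 0
    for i in range(n_alt):
        df, group = _group_table(effect, seed=seed + 100_000 + i)
        res = paired_class_test(df, "exomere", "supermere", protein_subset=group)
        rej_alt += int(res.pvalue < alpha)
    return {
        "type1_error": rej_null / n_null,
        "power": rej_alt / n_alt,
        "n_null": n_null,
        "n_alt": n_alt,
    }


def signed_rank_enumeration_agreement(
    n_fixtures: int = 20, n: int = 10, seed: int = 0
) -> dict:
    """Max |exact-DP p minus full 2^n sign-enumeration p| on random fixtures."""
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        d = rng.normal(size=n)
        d[d == 0] = 0.1
        ranks = rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        p_dp = _signed_rank_exact_p(ranks, w_plus)

        # explicit enumeration of all sign assignments
        signs = np.array(list(itertools.product([0, 1], repeat=n)))
        dist = signs @ ranks
        p_le = float((dist <= w_plus + 1e-9).mean())
        p_ge = float((dist >= w_plus - 1e-9).mean())
        p_enum = min(1.0, 2.0 * min(p_le, p_ge))
        worst = max(worst, abs(p_dp - p_enum))
    return {"max_abs_p_difference": worst, "n": n_fixtures}


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------


def determinism_check(seed: int = 0, workdir=None) -> dict:
    """Same config + seed twice: FASTQ bytes, coverage, calls and reports
    must be identical."""
    import tempfile
    from pathlib import Path

    from .compare import write_classification_tsv
    from .profiles import write_bedgraph, write_footprints_tsv

    reference, annotations = toy_u2_reference()

    def one_run(outdir: Path) -> dict:
        params = DigestionParams(q=0.9, n_reads=10_000, seed=seed)
        fastq = outdir / "sample.fastq"
        simulate_compartment(
            [reference],
            annotations,
            COMPARTMENTS["SUPERMERE"],
            {reference.id: 1.0},
            params,
            fastq_path=fastq,
            truth_bed_path=outdir / "truth.bed",
        )
        from .readproc import process_fastq

        index = ReferenceIndex([reference])
        res = process_fastq(fastq, index, params.adapter)
        profile = compute_coverage(res.alignments, reference)
        write_bedgraph(profile, outdir / "depth.bedgraph")
        calls = call_footprints(profile)
        pc = classify_profile(profile, reference, annotations)
        write_footprints_tsv(outdir / "calls.tsv", reference.id, pc.calls)
        write_classification_tsv(
            outdir / "report.tsv", [("sample", reference.id, pc)]
        )
        return {
            p.name: p.read_bytes()
            for p in sorted(outdir.iterdir())
        }

    ctx = tempfile.TemporaryDirectory() if workdir is None else None
    base = Path(ctx.name) if ctx else Path(workdir)
    try:
        d1 = base / "run1"
        d2 = base / "run2"
        d1.mkdir(parents=True, exist_ok=True)
        d2.mkdir(parents=True, exist_ok=True)
        out1 = one_run(d1)
        out2 = one_run(d2)
        identical = out1.keys() == out2.keys() and all(
            out1[k] == out2[k] for k in out1
        )
    finally:
        if ctx:
            ctx.cleanup()
    return {"identical": bool(identical), "n": 2}
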