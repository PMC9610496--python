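"""Digestion simulator, compartment read generator, spectral-count generator."""

import numpy as np
import pytest
from scipy.stats import chisquare, spearmanr

from rnpfootprint.core import PYRIMIDINES, ProtectedInterval, Transcript
from rnpfootprint.synth import (
    COMPARTMENTS,
    CompartmentModel,
    DigestionParams,
    NoFragmentsError,
    SpectralCountParams,
    digest_transcript,
    random_transcript,
    simulate_compartment,
    simulate_spectral_counts,
    toy_u2_reference,
)
from rnpfootprint.core import predict_protected_fragment


class TestDigestTranscript:
    def test_q1_cuts_after_every_pyrimidine(self, rng):
        t = Transcript("T", "ACGU")
        frags = digest_transcript(t, [], 1.0, rng)
        assert frags == [(0, 2), (2, 4)]  # cut after terminal U is a no-op

    def test_q1_with_protection_matches_prediction(self, toy16, toy16_protection, rng):
        frags = digest_transcript(toy16, [toy16_protection], 1.0, rng)
        assert frags == [(0, 1), (1, 16)]
        surviving = [f for f in frags if f[1] - f[0] >= 10]
        assert surviving == [predict_protected_fragment(toy16, toy16_protection)]

    def test_q0_returns_whole_transcript(self, toy16, rng):
        assert digest_transcript(toy16, [], 0.0, rng) == [(0, 16)]

    def test_tiling_and_terminus_laws(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 120))
            t = random_transcript(n, rng)
            a = int(rng.integers(0, n))
            b = int(rng.integers(a + 1, n + 1))
            prots = [ProtectedInterval("T", a, b, "X")]
            q = float(rng.uniform(0, 1))
            frags = digest_transcript(t, prots, q, rng)
            assert frags[0][0] == 0 and frags[-1][1] == n
            for (a1, b1), (a2, _) in zip(frags, frags[1:]):
                assert b1 == a2
            for s, e in frags:
                if e < n:
                    assert t.sequence[e - 1] in PYRIMIDINES
                if s > 0:
                    assert t.sequence[s - 1] in PYRIMIDINES


class TestCompartmentModel:
    def test_presets_match_biology(self):
        assert not COMPARTMENTS["CELL"].digested
        assert not COMPARTMENTS["EV"].digested
        assert COMPARTMENTS["EXOMERE"].digested
        assert {t.value for t in COMPARTMENTS["EXOMERE"].active_tiers} == {
            "core",
            "peripheral",
        }
        assert {t.value for t in COMPARTMENTS["SUPERMERE"].active_tiers} == {"core"}


class TestSimulateCompartment:
    def test_supermere_q1_forced_fragment(self, toy16, toy16_protection):
        params = DigestionParams(q=1.0, n_reads=200, min_len=10, max_len=50, seed=4)
        sample = simulate_compartment(
            [toy16],
            [toy16_protection],
            COMPARTMENTS["SUPERMERE"],
            {"TOY": 1.0},
            params,
        )
        inserts = {(r.start, r.end) for r in sample.reads}
        assert inserts == {(1, 16)}
        expected = ("AAAGATTTTGAAAGC" + params.adapter)[: params.read_len]
        assert all(r.sequence == expected for r in sample.reads)

    def test_ev_starts_uniform(self, toy16):
        params = DigestionParams(q=0.9, n_reads=10_000, min_len=10, max_len=50, seed=1)
        sample = simulate_compartment(
            [toy16], [], COMPARTMENTS["EV"], {"TOY": 1.0}, params
        )
        starts = np.array([r.start for r in sample.reads])
        # feasible starts are 0..len-min_len; the surrogate draws them uniformly
        counts = np.bincount(starts, minlength=len(toy16) - params.min_len + 1)
        assert chisquare(counts).pvalue > 0.01

    def test_zero_reads_gives_empty_fastq(self, toy16):
        params = DigestionParams(q=0.5, n_reads=0, seed=0)
        sample = simulate_compartment(
            [toy16], [], COMPARTMENTS["EV"], {"TOY": 1.0}, params
        )
        assert sample.fastq_text() == ""

    def test_empty_pool_raises(self, toy16):
        params = DigestionParams(q=0.5, n_reads=10, min_len=20, max_len=30, seed=0)
        with pytest.raises(NoFragmentsError):
            simulate_compartment(
                [toy16], [], COMPARTMENTS["EV"], {"TOY": 1.0}, params
            )

    def test_abundances_must_sum_to_one(self, toy16):
        params = DigestionParams(q=0.5, n_reads=10, seed=0)
        with pytest.raises(ValueError):
            simulate_compartment(
                [toy16], [], COMPARTMENTS["EV"], {"TOY": 0.4}, params
            )

    def test_same_seed_byte_identical_fastq(self, u2, tmp_path):
        ref, anns = u2
        texts = []
        for run in range(2):
            params = DigestionParams(q=0.9, n_reads=2000, seed=77)
            sample = simulate_compartment(
                [ref], anns, COMPARTMENTS["EXOMERE"], {ref.id: 1.0}, params,
                fastq_path=tmp_path / f"r{run}.fastq",
            )
            texts.append(sample.fastq_text())
        assert texts[0] == texts[1]
        assert (tmp_path / "r0.fastq").read_bytes() == (tmp_path / "r1.fastq").read_bytes()

    def test_q1_supermere_pool_matches_prediction_on_u2(self, u2):
        ref, anns = u2
        core = next(a for a in anns if a.tier.value == "core")
        params = DigestionParams(q=1.0, n_reads=500, seed=9)
        sample = simulate_compartment(
            [ref], anns, COMPARTMENTS["SUPERMERE"], {ref.id: 1.0}, params
        )
        predicted = predict_protected_fragment(ref, core)
        covering = {
            (r.start, r.end)
            for r in sample.reads
            if r.start <= core.start and r.end >= core.end
        }
        assert covering == {predicted}


class TestSpectralCounts:
    def test_noiseless_limit_counts_monotone_in_length(self):
        params = SpectralCountParams(
            n_proteins=30,
            abundance_sd=0.0,
            depth=2_000_000,
            classes=("exomere",),
            n_replicates=1,
            seed=3,
        )
        df, _ = simulate_spectral_counts(params)
        rho = spearmanr(df["raw_count"], df["length_aa"]).statistic
        assert rho > 0.999

    def test_deterministic_per_seed(self):
        params = SpectralCountParams(seed=11)
        df1, _ = simulate_spectral_counts(params)
        df2, _ = simulate_spectral_counts(SpectralCountParams(seed=11))
        assert df1.equals(df2)

    def test_class_effect_shifts_group(self):
        eff = np.ones(40)
        eff[:20] = 2.0
        params = SpectralCountParams(
            n_proteins=40,
            depth=50_000,
            class_effect={"exomere": eff},
            classes=("exomere", "supermere"),
            seed=5,
        )
        df, truth = simulate_spectral_counts(params)
        grp = truth["protein_ids"][:20]
        m = df.groupby(["class", df["protein_id"].isin(grp)])["raw_count"].mean()
        ratio_group = m[("exomere", True)] / m[("supermere", True)]
        ratio_rest = m[("exomere", False)] / m[("supermere", False)]
        assert ratio_group > ratio_rest * 1.5

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            SpectralCountParams(n_proteins=3, lengths=[10, 20])
        with pytest.raises(ValueError):
            SpectralCountParams(depth=0)


def test_toy_reference_is_valid_and_annotated(u2):
    ref, anns = u2
    labels = {a.label: a.tier.value for a in anns}
    assert labels == {"Sm": "core", "SF3B1": "peripheral", "SNRPA1": "peripheral"}
    for a in anns:
        s, e = predict_protected_fragment(ref, a)
        assert 15 <= e - s <= 50  # every footprint is recoverable at 50-nt reads
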