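"""K-mer spectra, sliding-window scans and anomaly flagging."""

import numpy as np
import pytest

from hgtscan import (
    NucleotideSequence, flag_anomalies, kmer_spectrum,
    simulate_genome_with_island, sliding_scan,
)
from hgtscan.kmerscan import KmerSpectrum

from oracles import naive_kmer_counts


def random_genome(rng, length, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


class TestSpectrum:
    def test_homopolymer_k2(self):
        spec = kmer_spectrum("AAAA", 2)
        idx = KmerSpectrum.kmers(2).index("AA")
        assert spec.freqs[idx] == 1.0
        assert spec.freqs.sum() == pytest.approx(1.0, abs=1e-12)
        assert spec.n_counted == 3

    def test_uniform_k1(self):
        spec = kmer_spectrum("ACGT", 1)
        assert np.allclose(spec.freqs, 0.25)

    def test_matches_naive_dictionary_count(self):
        rng = np.random.default_rng(13)
        seq = random_genome(rng, 10_000)
        # sprinkle Ns: those windows must be excluded from counting
        seq = seq[:500] + "N" * 7 + seq[507:]
        for k in (1, 2, 4):
            spec = kmer_spectrum(seq, k)
            counts = naive_kmer_counts(seq, k)
            total = sum(counts.values())
            assert spec.n_counted == total
            for i, word in enumerate(KmerSpectrum.kmers(k)):
                assert spec.freqs[i] * total == pytest.approx(
                    counts.get(word, 0), abs=1e-9)

    def test_normalization_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            spec = kmer_spectrum(random_genome(rng, 2000), 4)
            assert spec.freqs.sum() == pytest.approx(1.0, abs=1e-12)
            assert (spec.freqs >= 0).all()

    def test_l2_option_unit_norm(self):
        spec = kmer_spectrum("ACGTACGTGGCC", 2, norm="l2")
        assert np.linalg.norm(spec.freqs) == pytest.approx(1.0, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            kmer_spectrum("ACG", 4)
        with pytest.raises(ValueError):
            kmer_spectrum("NNNNNNNN", 4)   # zero countable words


class TestSlidingScan:
    def test_window_count_arithmetic(self):
        rng = np.random.default_rng(1)
        g = NucleotideSequence("g", random_genome(rng, 10_000))
        scan = sliding_scan(g, k=4, window=1000, step=500)
        assert len(scan.windows) == 19
        starts = [w.start for w in scan.windows]
        assert starts == list(range(0, 9001, 500))
        assert all(w.end - w.start == 1000 for w in scan.windows)

    def test_rolling_equals_naive_recount(self):
        rng = np.random.default_rng(17)
        for rep in range(50):
            length = int(rng.integers(3000, 20_001))
            seq = random_genome(rng, length)
            if rep % 5 == 0:   # inject N runs
                pos = int(rng.integers(0, length - 200))
                seq = seq[:pos] + "N" * 150 + seq[pos + 150:]
            g = NucleotideSequence(f"g{rep}", seq)
            scan = sliding_scan(g, k=4, window=1000, step=500)
            gfreqs = scan.genome_spectrum.freqs
            for w in scan.windows:
                counts = naive_kmer_counts(seq[w.start:w.end], 4)
                total = sum(counts.values())
                if w.missing:
                    continue
                naive = np.zeros(256)
                for i, word in enumerate(KmerSpectrum.kmers(4)):
                    naive[i] = counts.get(word, 0)
                expected = np.abs(naive / total - gfreqs).sum()
                assert w.score == pytest.approx(expected, abs=1e-12)

    def test_repeat_genome_scores_zero(self):
        g = NucleotideSequence("r", "ACGT" * 2500)
        scan = sliding_scan(g, k=1, window=1000, step=500)
        assert all(w.score == pytest.approx(0.0, abs=1e-12) for w in scan.windows)

    def test_l1_score_bounded_by_two(self):
        rng = np.random.default_rng(29)
        g = NucleotideSequence(
            "g", random_genome(rng, 5000) + "G" * 2000 + random_genome(rng, 5000))
        scan = sliding_scan(g, k=4, window=1000, step=500)
        assert all(0.0 <= w.score <= 2.0 for w in scan.windows if not w.missing)

    def test_mostly_n_window_reported_missing(self):
        rng = np.random.default_rng(31)
        seq = random_genome(rng, 3000) + "N" * 1000 + random_genome(rng, 3000)
        scan = sliding_scan(NucleotideSequence("g", seq), k=4,
                            window=1000, step=500)
        assert any(w.missing for w in scan.windows)
        assert all(np.isnan(w.score) for w in scan.windows if w.missing)

    def test_window_larger_than_genome_rejected(self):
        with pytest.raises(ValueError):
            sliding_scan(NucleotideSequence("g", "ACGT" * 10), window=1000)


class TestFlagAnomalies:
    def test_constant_scores_produce_no_flags(self):
        g = NucleotideSequence("r", "ACGT" * 2500)
        scan = sliding_scan(g, k=1, window=1000, step=500)
        with pytest.warns(UserWarning, match="MAD"):
            flagged = flag_anomalies(scan)
        assert not any(w.flagged for w in flagged.windows)
        assert flagged.merged_intervals == []

    def test_infinite_cutoff_never_flags(self):
        rng = np.random.default_rng(37)
        g = NucleotideSequence("g", random_genome(rng, 20_000))
        scan = sliding_scan(g)
        flagged = flag_anomalies(scan, cutoff=float("inf"))
        assert not any(w.flagged for w in flagged.windows)

    def test_island_windows_score_above_host_maximum(self):
        sim = simulate_genome_with_island(
            50_000, (0.25,) * 4, 5000, (0.1, 0.4, 0.4, 0.1), 20_000, seed=5)
        scan = sliding_scan(sim.genome)
        inside = [w.score for w in scan.windows
                  if w.start >= sim.island_start and w.end <= sim.island_end]
        outside = [w.score for w in scan.windows
                   if w.end <= sim.island_start or w.start >= sim.island_end]
        assert min(inside) > max(outside)

    def test_recovers_inserted_island(self):
        hits = 0
        for seed in range(5):
            sim = simulate_genome_with_island(
                100_000, (0.25,) * 4, 5000, (0.1, 0.4, 0.4, 0.1),
                50_000, seed=seed)
            scan = flag_anomalies(sliding_scan(sim.genome))
            covered = sum(
                max(0, min(e, sim.island_end) - max(s, sim.island_start))
                for s, e in scan.merged_intervals)
            hits += covered >= 0.8 * (sim.island_end - sim.island_start)
        assert hits >= 4

    def test_too_few_windows_rejected(self):
        rng = np.random.default_rng(41)
        g = NucleotideSequence("g", random_genome(rng, 2000))
        scan = sliding_scan(g, window=1000, step=500)
        with pytest.raises(ValueError):
            flag_anomalies(scan)


def test_scan_deterministic_and_metadata_independent():
    rng = np.random.default_rng(43)
    seq = "".join(rng.choice(list("ACGT"), size=8000))
    s1 = sliding_scan(NucleotideSequence("a", seq))
    s2 = sliding_scan(NucleotideSequence("b", seq))
    assert [w.score for w in s1.windows] == [w.score for w in s2.windows]
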