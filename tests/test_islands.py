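"""SICER-style island caller: scoring, clustering, E-value threshold."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from chipspike.islands import (
    IslandParams,
    assemble_islands,
    background_lambda,
    call_islands,
    eligibility_threshold,
    score_threshold_mc,
    window_counts,
    window_score,
)
from chipspike.model import GenomeLayout


def fragments_at(chrom, midpoints, width=2):
    """Fragment table whose midpoints are exactly the given positions."""
    mid = np.asarray(midpoints, dtype=np.int64)
    return pd.DataFrame(
        {"chrom": chrom, "start": mid - width // 2, "end": mid + width // 2, "strand": "+"}
    )


def brute_islands(counts, lam, min_count, gap_windows, window_width, chrom, chrom_length):
    """Independent reference: scan eligibility runs with a plain loop."""
    eligible = [i for i, c in enumerate(counts) if c >= min_count]
    groups = []
    for i in eligible:
        if groups and i - groups[-1][-1] <= gap_windows + 1:
            groups[-1].append(i)
        else:
            groups.append([i])
    out = []
    for g in groups:
        score = sum(-poisson.logpmf(counts[i], lam) for i in g)
        out.append(
            (
                chrom,
                g[0] * window_width,
                min((g[-1] + 1) * window_width, chrom_length),
                score,
                int(sum(counts[g[0] : g[-1] + 1])),
            )
        )
    return out


class TestWindowCounts:
    def test_midpoint_assignment(self, small_genome):
        frags = pd.DataFrame(
            {"chrom": ["chrA"], "start": [0], "end": [200], "strand": ["+"]}
        )
        counts = window_counts(frags, small_genome, 200)
        assert counts["chrA"][0] == 1 and counts["chrA"][1:].sum() == 0

    def test_empty_input(self, small_genome):
        frags = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        counts = window_counts(frags, small_genome, 200)
        assert all(v.sum() == 0 for v in counts.values())

    def test_conservation(self, rng, small_genome):
        mids = rng.integers(10, 9990, 10_000)
        counts = window_counts(fragments_at("chrA", mids), small_genome, 200)
        assert sum(v.sum() for v in counts.values()) == 10_000


class TestWindowScore:
    def test_poisson_neg_log_pmf(self):
        # -ln(e^-1 * 1^5 / 5!) = 1 + ln(120)
        assert window_score(5, 1.0, min_count=1) == pytest.approx(1 + math.log(120), rel=1e-12)

    def test_below_eligibility_scores_zero(self):
        assert window_score(0, 1.0) == 0.0

    @pytest.mark.parametrize("lam", [0.1, 1.0, 5.0])
    def test_monotone_in_count(self, lam):
        k0 = max(eligibility_threshold(lam), math.ceil(lam))
        scores = [window_score(k, lam, min_count=k0) for k in range(k0, k0 + 10)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_rejects_nonpositive_lambda(self):
        with pytest.raises(ValueError):
            window_score(5, 0.0)


class TestEligibilityThreshold:
    def test_small_lambda(self):
        # P(X>=1) = 1 - e^-0.1 = 0.0952 < 0.2
        assert eligibility_threshold(0.1, 0.2) == 1

    def test_tiny_lambda_limit(self):
        assert eligibility_threshold(1e-9, 0.2) == 1

    @pytest.mark.parametrize("lam", [0.01, 0.1, 0.5, 1.0, 2.0, 5.0])
    def test_matches_bruteforce_tail_sums(self, lam):
        k = eligibility_threshold(lam, 0.2)

        def tail(j):  # P(X >= j) by explicit summation
            return 1.0 - sum(
                math.exp(-lam) * lam**i / math.factorial(i) for i in range(j)
            )

        assert tail(k) < 0.2
        assert k == 1 or tail(k - 1) >= 0.2


class TestAssembleIslands:
    def run(self, eligible_idx, n_windows, gap_windows):
        counts = np.zeros(n_windows, dtype=np.int64)
        counts[list(eligible_idx)] = 5
        scores = np.where(counts >= 5, 1.0, 0.0)
        return assemble_islands(
            counts >= 5, scores, counts, "chrA", n_windows * 200, 200, gap_windows
        )

    def test_gap_bridging(self):
        islands = self.run({0, 1, 5}, 10, 3)
        assert len(islands) == 1
        assert (islands[0].start, islands[0].end) == (0, 1200)

    def test_gap_exceeded_splits(self):
        islands = self.run({0, 10}, 20, 3)
        assert len(islands) == 2

    def test_random_vectors_match_bruteforce(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            counts = rng.poisson(1.0, n)
            lam, gap_w = 1.0, int(rng.integers(0, 4))
            min_count = 2
            scores = np.where(counts >= min_count, -poisson.logpmf(counts, lam), 0.0)
            got = assemble_islands(counts >= min_count, scores, counts, "chrA",
                                   n * 200, 200, gap_w)
            want = brute_islands(counts, lam, min_count, gap_w, 200, "chrA", n * 200)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert (g.chrom, g.start, g.end, g.tag_count) == (w[0], w[1], w[2], w[4])
                assert g.score == pytest.approx(w[3], rel=1e-9)

    def test_islands_disjoint_and_cover_eligible(self, rng):
        counts = rng.poisson(2.0, 200)
        scores = np.where(counts >= 4, 1.0, 0.0)
        islands = assemble_islands(counts >= 4, scores, counts, "chrA", 40_000, 200, 3)
        spans = [(i.start, i.end) for i in islands]
        assert spans == sorted(spans)
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))
        for i in np.flatnonzero(counts >= 4):
            assert any(s <= i * 200 < e for s, e in spans)


class TestScoreThreshold:
    params = IslandParams(
        window_width=200, gap=600, e_value=1.0, effective_genome_fraction=1.0,
        null_mc_draws=500, seed=42,
    )

    def test_deterministic_given_seed(self):
        genome = GenomeLayout("t", (("chrA", 400_000),))
        t1 = score_threshold_mc(self.params, genome, 20_000)
        t2 = score_threshold_mc(self.params, genome, 20_000)
        assert t1 == t2 and t1 > 0

    def test_monotone_in_e_value(self):
        genome = GenomeLayout("t", (("chrA", 400_000),))
        ts = [
            score_threshold_mc(
                IslandParams(window_width=200, gap=600, e_value=e,
                             effective_genome_fraction=1.0, null_mc_draws=500, seed=42),
                genome, 20_000)
            for e in (0.2, 1.0, 5.0)
        ]
        assert ts[0] >= ts[1] >= ts[2]

    def test_infinite_e_value_threshold_zero(self):
        genome = GenomeLayout("t", (("chrA", 400_000),))
        p = IslandParams(window_width=200, gap=600, e_value=math.inf,
                         effective_genome_fraction=1.0, null_mc_draws=500, seed=42)
        assert score_threshold_mc(p, genome, 20_000) == 0.0

    def test_tiny_genome_threshold_calibrates_against_independent_mc(self, rng):
        # 10 kb genome, 50 tags: validate the threshold with an independent
        # brute-force null simulation — islands at/above the threshold should
        # appear about e_value times per genome.
        genome = GenomeLayout("t", (("chrA", 10_000),))
        params = IslandParams(window_width=200, gap=400, e_value=1.0,
                              effective_genome_fraction=1.0, null_mc_draws=2000, seed=9)
        n_tags, n_windows = 50, 50
        threshold = score_threshold_mc(params, genome, n_tags)
        lam = n_tags / n_windows
        min_count = eligibility_threshold(lam, params.eligibility_p0)
        hits = 0
        reps = 3000
        for _ in range(reps):
            counts = np.bincount(rng.integers(0, n_windows, n_tags), minlength=n_windows)
            for isl in brute_islands(counts, lam, min_count, params.gap_windows,
                                     200, "chrA", 10_000):
                if isl[3] >= threshold:
                    hits += 1
        assert 0.6 <= hits / reps <= 1.6


class TestCallIslands:
    def test_planted_domain_recovered(self, rng):
        genome = GenomeLayout("t", (("chrA", 200_000),))
        # background ~1 tag/window, one 5-kb domain at 20x density
        bg = rng.integers(100, 199_900, 1000)
        dom = rng.integers(40_000, 45_000, 500)
        frags = fragments_at("chrA", np.concatenate([bg, dom]))
        params = IslandParams(window_width=200, gap=600, e_value=1.0,
                              effective_genome_fraction=1.0, null_mc_draws=500, seed=3)
        islands = call_islands(frags, genome, params)
        assert len(islands) >= 1
        top = max(islands, key=lambda i: i.score)
        assert abs(top.start - 40_000) <= 200
        assert abs(top.end - 45_000) <= 200
        # no other strong calls
        assert all(i.score < top.score / 5 for i in islands if i is not top)

    def test_empty_input_empty_output(self, small_genome):
        frags = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        assert call_islands(frags, small_genome) == []

    def test_matches_exhaustive_enumeration_on_small_genomes(self, rng):
        # <= 50 windows: caller output equals the brute-force reference
        for trial in range(10):
            n_windows = int(rng.integers(10, 51))
            genome = GenomeLayout("t", (("chrA", n_windows * 200),))
            n_tags = int(rng.integers(20, 200))
            mids = rng.integers(1, n_windows * 200 - 1, n_tags)
            frags = fragments_at("chrA", mids)
            params = IslandParams(window_width=200, gap=400, e_value=1.0,
                                  effective_genome_fraction=1.0,
                                  null_mc_draws=500, seed=trial)
            threshold = score_threshold_mc(params, genome, n_tags)
            got = call_islands(frags, genome, params, threshold=threshold)
            lam = background_lambda(n_tags, genome, params)
            min_count = eligibility_threshold(lam, params.eligibility_p0)
            counts = window_counts(frags, genome, 200)["chrA"]
            want = [
                isl for isl in brute_islands(counts, lam, min_count,
                                             params.gap_windows, 200, "chrA",
                                             n_windows * 200)
                if isl[3] >= threshold
            ]
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert (g.start, g.end, g.tag_count) == (w[1], w[2], w[4])
                assert g.score == pytest.approx(w[3], rel=1e-9)
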