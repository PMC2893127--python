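import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tripeak.countmodel import (
    CountHistogram,
    DegenerateHistogramError,
    GammaPoissonModel,
    PoissonModel,
    ThresholdError,
    bin_counts,
    efdr_table,
    fit_background,
    gp_tail,
    select_pbrs,
    select_threshold,
)
from tripeak.tagio import GenomeTable, TagRecord


def _hist_from_counts(counts, n_total=None):
    ks, fs = np.unique(counts, return_counts=True)
    return CountHistogram(
        {int(k): int(f) for k, f in zip(ks, fs)},
        n_total=n_total or len(counts),
    )


class TestBinCounts:
    def test_empty_genome_binning(self):
        genome = GenomeTable([("chrA", 1000)])
        per_bin, hist = bin_counts([], genome, 250)
        assert list(per_bin["chrA"]) == [0, 0, 0, 0]
        assert hist.n_total == 4 and hist.counts == {0: 4}

    def test_window_boundary_assignment(self):
        genome = GenomeTable([("chrA", 1000)])
        tags = [TagRecord("chrA", 0, "+"), TagRecord("chrA", 249, "-")]
        per_bin, _ = bin_counts(tags, genome, 250)
        assert list(per_bin["chrA"]) == [2, 0, 0, 0]

    def test_against_brute_force_tally(self, rng):
        genome = GenomeTable([("chrA", 1_000_000)])
        pos = rng.integers(0, 1_000_000, size=10_000)
        tags = [TagRecord("chrA", int(p), "+") for p in pos]
        per_bin, hist = bin_counts(tags, genome, 250)
        brute = np.zeros(4000, dtype=int)
        for p in pos:
            brute[p // 250] += 1
        assert np.array_equal(per_bin["chrA"], brute)
        # histogram mass: all windows accounted for, tags conserved
        assert sum(hist.counts.values()) == hist.n_total == 4000
        assert sum(k * f for k, f in hist.counts.items()) == len(tags)

    def test_partial_final_window_kept(self):
        genome = GenomeTable([("chrA", 260)])
        per_bin, hist = bin_counts([TagRecord("chrA", 255, "+")], genome, 250)
        assert per_bin["chrA"].size == 2 and per_bin["chrA"][1] == 1

    def test_invalid_window_size(self):
        with pytest.raises(ValueError):
            bin_counts([], GenomeTable([("c", 10)]), 0)


class TestDistributions:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0.1, 20.0), st.floats(0.05, 0.95))
    def test_truncated_pmf_sums_to_one(self, r, p):
        model = GammaPoissonModel(r, p, zero_truncated=True)
        upper = int(stats.nbinom.isf(1e-13, r, p)) + 10
        ks = np.arange(1, upper)
        assert abs(model.pmf(ks).sum() - 1.0) < 1e-9

    def test_geometric_closed_form_tail(self):
        # r = 1: Pr(X > k | X >= 1) = (1-p)^k
        p = 0.37
        model = GammaPoissonModel(1.0, p, zero_truncated=True)
        for k in range(1, 11):
            assert abs(gp_tail(model, k) - (1 - p) ** k) < 1e-12

    def test_tail_boundary_and_limits(self):
        model = GammaPoissonModel(2.0, 0.5, zero_truncated=True)
        assert gp_tail(model, 0) == 1.0  # truncated support starts at 1
        assert gp_tail(model, 500) < 1e-12
        tails = [gp_tail(model, k) for k in range(20)]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_truncated_poisson_pmf_sums_to_one(self):
        model = PoissonModel(3.2, zero_truncated=True)
        assert abs(model.pmf(np.arange(1, 200)).sum() - 1.0) < 1e-9


class TestFitBackground:
    def test_mean_identity_and_moderate_recovery(self, rng):
        draws = stats.nbinom.rvs(2.0, 0.5, size=60_000, random_state=rng)
        hist = _hist_from_counts(draws[draws > 0])
        gp, _, report = fit_background(hist)
        assert report.converged
        assert gp.mean == pytest.approx(gp.r * (1 - gp.p) / gp.p)
        assert abs(gp.r - 2.0) / 2.0 < 0.1 and abs(gp.p - 0.5) < 0.03

    def test_mle_errors_shrink_with_sample_size(self):
        # single-replicate errors are noisy (r-hat has a wide sampling
        # distribution), so compare seed-averaged errors at the two sizes
        mean_err = {}
        for n in (1_000, 100_000):
            errs = []
            for seed in range(5):
                draws = stats.nbinom.rvs(
                    2.0, 0.5, size=3 * n, random_state=123 + seed
                )
                draws = draws[draws > 0][:n]
                gp, _, _ = fit_background(_hist_from_counts(draws))
                errs.append(abs(gp.r - 2.0) / 2.0 + abs(gp.p - 0.5))
            mean_err[n] = np.mean(errs)
        assert mean_err[100_000] < mean_err[1_000]

    def test_poisson_data_makes_models_agree(self, rng):
        draws = stats.poisson.rvs(3.0, size=50_000, random_state=rng)
        hist = _hist_from_counts(draws[draws > 0])
        _, _, report = fit_background(hist)
        assert abs(report.loglik_gp - report.loglik_poisson) < 2.0

    def test_degenerate_histogram_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            fit_background(CountHistogram({1: 50}, n_total=60))


class TestEfdr:
    def test_three_line_hand_computation(self):
        hist = CountHistogram({1: 90, 2: 8, 10: 2}, n_total=100)
        model = GammaPoissonModel(2.0, 0.6, zero_truncated=True)
        table = efdr_table(model, hist)
        assert list(table["k"]) == list(range(11))
        # hand oracle: N_obs(>k) from the three frequencies, expected from
        # the model tail, efdr clipped at 1
        for _, row in table.iterrows():
            k = int(row["k"])
            n_obs = sum(f for kk, f in hist.counts.items() if kk > k)
            assert row["n_observed"] == n_obs
            expected = 100 * gp_tail(model, k)
            assert row["expected"] == pytest.approx(expected)
            if n_obs:
                assert row["efdr"] == pytest.approx(min(1.0, expected / n_obs))
            else:
                assert math.isnan(row["efdr"])

    def test_exact_expectation_gives_efdr_one(self):
        model = GammaPoissonModel(2.0, 0.6, zero_truncated=True)
        n_total = 10_000
        counts = {}
        running = 0
        for k in range(1, 8):
            f = round(n_total * float(model.pmf(k)))
            counts[k] = f
            running += f
        hist = CountHistogram(counts, n_total=n_total)
        table = efdr_table(model, hist)
        # at k=0 the observed exceedances nearly equal the expectation
        assert table["efdr"].iloc[0] == pytest.approx(1.0, abs=0.05)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(2, 50))
    def test_scale_invariance(self, factor):
        hist = CountHistogram({1: 90, 2: 8, 10: 2}, n_total=100)
        scaled = CountHistogram(
            {k: f * factor for k, f in hist.counts.items()}, n_total=100 * factor
        )
        model = GammaPoissonModel(1.7, 0.55, zero_truncated=True)
        a, b = efdr_table(model, hist), efdr_table(model, scaled)
        assert np.allclose(a["efdr"].to_numpy(), b["efdr"].to_numpy(), equal_nan=True)

    def test_efdr_clipped_on_simulated_data(self, rng):
        draws = stats.nbinom.rvs(2.0, 0.5, size=20_000, random_state=rng)
        hist = _hist_from_counts(draws)
        gp, _, _ = fit_background(
            CountHistogram({k: f for k, f in hist.counts.items() if k >= 1},
                           hist.n_total)
        )
        table = efdr_table(gp, hist)
        valid = table["efdr"].dropna()
        assert ((valid >= 0) & (valid <= 1)).all()


class TestThresholdAndPBRs:
    def _table(self, efdrs):
        import pandas as pd

        return pd.DataFrame(
            {
                "k": range(len(efdrs)),
                "n_observed": [10] * len(efdrs),
                "expected": [1.0] * len(efdrs),
                "efdr": efdrs,
            }
        )

    def test_first_crossing(self):
        assert select_threshold(self._table([0.9, 0.6, 0.4, 0.1]), 0.5) == 2

    def test_loose_alpha_selects_zero(self):
        assert select_threshold(self._table([0.9, 0.6, 0.4, 0.1]), 0.99) == 0

    def test_unreachable_alpha_errors(self):
        with pytest.raises(ThresholdError, match="larger alpha"):
            select_threshold(self._table([0.9, 0.8]), 0.5)

    def test_linear_scan_oracle(self, rng):
        efdrs = np.clip(rng.random(40).cumsum()[::-1] / 20, 0, 1)
        table = self._table(list(efdrs))
        alpha = 0.5
        oracle = min(k for k, e in enumerate(efdrs) if e <= alpha)
        assert select_threshold(table, alpha) == oracle

    def test_worked_merge(self):
        genome = GenomeTable([("chrA", 1000)])
        pbrs = select_pbrs({"chrA": np.array([7, 9, 3, 8])}, 6, 250, genome)
        assert [(p.region.start, p.region.end, p.tag_count, p.source_bins)
                for p in pbrs] == [(0, 500, 16, 2), (750, 1000, 8, 1)]

    def test_no_bin_exceeds(self):
        genome = GenomeTable([("chrA", 1000)])
        assert select_pbrs({"chrA": np.array([1, 2, 3, 4])}, 6, 250, genome) == []

    def test_run_length_encoding_oracle(self, rng):
        mask = rng.integers(0, 2, size=10_000).astype(np.int64)
        genome = GenomeTable([("chrA", 10_000 * 250)])
        pbrs = select_pbrs({"chrA": mask}, 0, 250, genome)
        # independent RLE oracle
        runs = []
        i = 0
        while i < mask.size:
            if mask[i]:
                j = i
                while j < mask.size and mask[j]:
                    j += 1
                runs.append((i * 250, j * 250))
                i = j
            else:
                i += 1
        assert [(p.region.start, p.region.end) for p in pbrs] == runs
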