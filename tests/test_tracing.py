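"""Distance matrices, contacts, Hi-C normalization and compartment scoring."""

import numpy as np
import pytest

from nucleotrace import phantoms, tracing
from nucleotrace.types import ChromatinTrace, DistanceMatrix, GenomicRegion


def trace_from(positions, cell=0, copy=0):
    return ChromatinTrace(cell_id=cell, copy_id=copy, positions=np.asarray(positions, dtype=float))


class TestMeanDistanceMatrix:
    def test_two_trace_arithmetic(self):
        t1 = trace_from([[0, 0, 0], [100, 0, 0]])
        t2 = trace_from([[0, 0, 0], [300, 0, 0]], cell=1)
        dm = tracing.mean_distance_matrix([t1, t2], min_pairs=1)
        assert dm.mean_nm[0, 1] == pytest.approx(200.0)
        assert dm.counts[0, 1] == 2

    def test_pairwise_deletion_counts(self):
        t1 = trace_from([[0, 0, 0], [100, 0, 0]])
        t2 = trace_from([[0, 0, 0], [np.nan, np.nan, np.nan]], cell=1)
        dm = tracing.mean_distance_matrix([t1, t2], min_pairs=1)
        assert dm.counts[0, 1] == 1
        assert dm.mean_nm[0, 1] == pytest.approx(100.0)

    def test_min_pairs_masks_entries(self):
        t1 = trace_from([[0, 0, 0], [100, 0, 0]])
        dm = tracing.mean_distance_matrix([t1], min_pairs=2)
        assert np.isnan(dm.mean_nm[0, 1])

    def test_symmetry_and_zero_diagonal(self, rng):
        traces = [trace_from(rng.uniform(0, 2000, size=(8, 3)), cell=i) for i in range(10)]
        dm = tracing.mean_distance_matrix(traces, min_pairs=1)
        assert np.allclose(dm.mean_nm, dm.mean_nm.T)
        assert np.all(np.diag(dm.mean_nm) == 0)

    def test_phantom_matrix_matches_planted_expectation(self, scores50):
        """Mean distances from 500 planted traces agree with the planted
        fBm expectation within sampling error (3 sigma / sqrt(n))."""
        traces = phantoms.gen_traces(
            250, scores50, polarization_strength=0.0, powerlaw_exponent=0.4,
            seed=8, dropout=0.0, noise_nm=0.0,
        )
        dm = tracing.mean_distance_matrix(traces, min_pairs=2)
        n = len(traces)
        sep = np.abs(np.subtract.outer(np.arange(50), np.arange(50)))
        expected = 400.0 * np.where(sep > 0, sep, 1) ** 0.4
        off = sep > 0
        # distances are Maxwell-ish: sd/mean ~ 0.42; compare elementwise
        tol = 3 * 0.5 * expected[off] / np.sqrt(n)
        assert np.all(np.abs(dm.mean_nm[off] - expected[off]) < 4 * tol + 0.05 * expected[off])

    def test_zero_traces_error(self):
        with pytest.raises(ValueError):
            tracing.mean_distance_matrix([])


class TestContactProbability:
    def test_all_in_contact(self):
        traces = [trace_from([[0, 0, 0], [100, 0, 0]], cell=i) for i in range(5)]
        prob, _ = tracing.contact_probability_matrix(traces, threshold_nm=150.0)
        assert prob[0, 1] == 1.0

    def test_exact_threshold_is_not_contact(self):
        traces = [trace_from([[0, 0, 0], [150.0, 0, 0]], cell=i) for i in range(5)]
        prob, _ = tracing.contact_probability_matrix(traces, threshold_nm=150.0)
        assert prob[0, 1] == 0.0

    def test_planted_loop_frequency_recovered(self, rng):
        """A locus pair planted in contact with probability 0.3 over 500
        traces is recovered within a binomial confidence band."""
        p_true, n = 0.3, 500
        traces = []
        for i in range(n):
            d = 100.0 if rng.uniform() < p_true else 400.0
            traces.append(trace_from([[0, 0, 0], [d, 0, 0]], cell=i))
        prob, counts = tracing.contact_probability_matrix(traces, 150.0)
        assert counts[0, 1] == n
        assert prob[0, 1] == pytest.approx(p_true, abs=0.05)

    def test_anchor_and_difference_modes(self, rng):
        traces_a = [trace_from([[0, 0, 0], [100, 0, 0], [500, 0, 0]], cell=i) for i in range(20)]
        traces_b = [trace_from([[0, 0, 0], [400, 0, 0], [500, 0, 0]], cell=i) for i in range(20)]
        diff = tracing.contact_probability_difference(traces_a, traces_b, anchor_region=0)
        assert diff[1] == pytest.approx(1.0)  # contact only in group A
        assert np.isnan(diff[0])


class TestHicContactFrequency:
    def regions(self, lengths):
        return [
            GenomicRegion("chr19", int(1e6 * i), int(1e6 * i) + L, f"r{i}")
            for i, L in enumerate(lengths)
        ]

    def test_length_normalization(self):
        counts = np.array([[0, 100], [100, 0]])
        freq = tracing.hic_contact_frequency(counts, self.regions([1_000_000, 2_000_000]))
        assert freq[0, 1] == pytest.approx(100 / (1e6 * 2e6))

    def test_doubling_lengths_quarters_frequency(self):
        counts = np.array([[0, 100], [100, 0]])
        f1 = tracing.hic_contact_frequency(counts, self.regions([1_000_000, 1_000_000]))
        f2 = tracing.hic_contact_frequency(counts, self.regions([2_000_000, 2_000_000]))
        assert f2[0, 1] == pytest.approx(f1[0, 1] / 4)

    def test_zero_counts_and_negative_rejection(self):
        regions = self.regions([1_000_000, 1_000_000])
        assert tracing.hic_contact_frequency(np.zeros((2, 2)), regions)[0, 1] == 0
        with pytest.raises(ValueError):
            tracing.hic_contact_frequency(np.array([[0, -1], [-1, 0]]), regions)


class TestPowerlawFit:
    def test_exact_loglinear_data(self):
        x = np.linspace(1, 10, 10)
        amp, exp, r = tracing.fit_distance_powerlaw(x, 2 * x**3)
        assert exp == pytest.approx(3.0, abs=1e-12)
        assert amp == pytest.approx(2.0, rel=1e-9)
        assert r > 0.9

    def test_constant_y_gives_zero_exponent(self):
        _, exp, _ = tracing.fit_distance_powerlaw(np.arange(1, 8), np.full(7, 5.0))
        assert exp == 0.0

    def test_nonpositive_values_excluded_with_warning(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, -1.0])
        y = np.array([1.0, 8.0, 27.0, 64.0, 10.0])
        with pytest.warns(UserWarning):
            _, exp, _ = tracing.fit_distance_powerlaw(x, y)
        assert exp == pytest.approx(3.0, abs=1e-9)
        with pytest.raises(ValueError):
            tracing.fit_distance_powerlaw(np.array([1.0, 2.0, -3.0]), np.array([1.0, -2.0, 3.0]))

    def test_planted_exponent_recovered_from_traces(self, scores50):
        """Power-law fit of mean distance vs genomic separation recovers the
        planted scaling exponent within 10%."""
        traces = phantoms.gen_traces(
            250, scores50, polarization_strength=0.0, powerlaw_exponent=0.33, seed=4
        )
        dm = tracing.mean_distance_matrix(traces, min_pairs=2)
        regions = phantoms.gen_regions(scores50, seed=4)
        sep = np.abs(
            np.subtract.outer(
                [r.midpoint for r in regions], [r.midpoint for r in regions]
            )
        )
        off = ~np.eye(50, dtype=bool)
        _, exponent, _ = tracing.fit_distance_powerlaw(sep[off], dm.mean_nm[off])
        assert exponent == pytest.approx(0.33, rel=0.10)

    def test_inverse_hic_vs_distance_powerlaw(self, scores50):
        """Synthetic contact counts sampled from traces: inverse normalized
        frequency correlates with spatial distance as a power law whose
        fitted exponent is recovered within +-0.5."""
        traces = phantoms.gen_traces(
            400, scores50, polarization_strength=0.0, powerlaw_exponent=0.33, seed=6
        )
        dm = tracing.mean_distance_matrix(traces, min_pairs=2)
        # distances at a 350-nm contact radius give informative frequencies
        counts = phantoms.gen_hic_counts(traces, contact_threshold_nm=350.0, depth=2_000_000, seed=6)
        regions = phantoms.gen_regions(scores50, seed=6)
        freq = tracing.hic_contact_frequency(counts, regions)
        off = ~np.eye(50, dtype=bool)
        ok = off & (freq > 0)
        # fit frequency ~ distance^(-k), then check inverse relation on a grid
        _, exponent, _ = tracing.fit_distance_powerlaw(dm.mean_nm[ok], freq[ok])
        assert exponent < -1.0  # frequency decays with distance
        grid = np.arange(1.0, 8.1, 0.5)
        corrs = [
            np.corrcoef(1 / freq[ok], dm.mean_nm[ok] ** k)[0, 1] for k in grid
        ]
        best = grid[int(np.argmax(corrs))]
        assert best == pytest.approx(-exponent, abs=1.0)


class TestCompartmentScores:
    def planted_dm(self, scores, shrink=0.8, seed=0):
        """Distance matrix following a power law with within-compartment
        distances shrunk below the trend."""
        n = scores.size
        rng = np.random.default_rng(seed)
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        d = 400.0 * np.where(sep > 0, sep, 1.0) ** 0.33
        same = np.sign(scores)[:, None] == np.sign(scores)[None, :]
        d = np.where(same, d * shrink, d)
        d *= rng.normal(1.0, 0.01, size=d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(mean_nm=d, counts=np.full((n, n), 100))

    def test_planted_partition_sign_recovery(self, scores50):
        """Two-block planted structure: compartment signs recovered for at
        least 48 of 50 regions."""
        dm = self.planted_dm(scores50)
        regions = phantoms.gen_regions(scores50, seed=1)
        result = tracing.compartment_scores(dm, regions)
        agree = np.sign(result.scores) == np.sign(scores50)
        assert agree.sum() >= 48
        assert result.oriented
        assert np.linalg.norm(result.scores) == pytest.approx(1.0)

    def test_orientation_follows_gene_density(self, scores50):
        dm = self.planted_dm(scores50)
        regions = phantoms.gen_regions(scores50, seed=1)
        result = tracing.compartment_scores(dm, regions)
        density = np.array([r.gene_density for r in regions])
        assert np.corrcoef(result.scores, density)[0, 1] > 0

    def test_exact_powerlaw_distances_degenerate(self, scores50):
        dm = self.planted_dm(scores50, shrink=1.0)
        # remove the residual jitter entirely: exact power law
        n = 50
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        d = 400.0 * np.where(sep > 0, sep, 1.0) ** 0.33
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(mean_nm=d, counts=np.full((n, n), 100))
        with pytest.raises(ValueError, match="constant|undefined"):
            tracing.compartment_scores(dm, phantoms.gen_regions(scores50, seed=1))

    def test_missing_entries_rejected_with_pairs(self, scores50):
        dm = self.planted_dm(scores50)
        dm.mean_nm[3, 7] = dm.mean_nm[7, 3] = np.nan
        with pytest.raises(ValueError, match="missing"):
            tracing.compartment_scores(dm, phantoms.gen_regions(scores50, seed=1))

    def test_invariant_to_global_distance_rescaling(self, scores50):
        """Scores are unchanged when all distances are rescaled: the power-law
        amplitude absorbs the factor."""
        dm = self.planted_dm(scores50)
        regions = phantoms.gen_regions(scores50, seed=1)
        base = tracing.compartment_scores(dm, regions)
        scaled = DistanceMatrix(mean_nm=3.7 * dm.mean_nm, counts=dm.counts)
        res = tracing.compartment_scores(scaled, regions)
        assert np.allclose(res.scores, base.scores, atol=1e-9)
        assert res.amplitude == pytest.approx(3.7 * base.amplitude, rel=1e-6)

    def test_correlation_matrix_symmetric(self, scores50):
        """Rows vs columns as observations is immaterial: the correlation
        matrix of the normalized matrix is symmetric."""
        dm = self.planted_dm(scores50)
        result = tracing.compartment_scores(dm, phantoms.gen_regions(scores50, seed=1))
        assert np.allclose(result.correlation, result.correlation.T)


class TestExpressionFoldVsScore:
    def test_tally_semantics(self):
        expression = {"hep": np.array([8.0, 2.0]), "ery": np.array([2.0, 2.0])}
        scores = {"hep": np.array([0.3]), "ery": np.array([0.1])}
        rows, tallies = tracing.expression_fold_vs_score_change(
            expression, scores, gene_to_region={0: 0, 1: 0}
        )
        # gene 0 hep vs ery: fold 4 with dscore +0.2 -> concordant
        assert tallies["score_up"] == 1 and tallies["score_down"] == 0

    def test_exact_threshold_fold_excluded(self):
        expression = {"a": np.array([3.0]), "b": np.array([1.0])}
        scores = {"a": np.array([0.2]), "b": np.array([0.0])}
        _, tallies = tracing.expression_fold_vs_score_change(
            expression, scores, gene_to_region={0: 0}, fold_threshold=3.0
        )
        assert tallies["score_up"] == 0 and tallies["score_down"] == 0

    def test_zero_denominator_excluded(self):
        expression = {"a": np.array([3.0]), "b": np.array([0.0])}
        scores = {"a": np.array([0.2]), "b": np.array([0.0])}
        rows, _ = tracing.expression_fold_vs_score_change(
            expression, scores, gene_to_region={0: 0}
        )
        assert all(r["from"] != "b" for r in rows)

    def test_planted_coupling_detected(self, rng):
        """Genes whose expression rises with the host-region score change
        produce a concordant majority (binomial p < 0.05 at n = 100)."""
        from scipy.stats import binomtest

        n_genes = 100
        dscore = rng.normal(scale=0.1, size=n_genes)
        expression = {
            "t2": np.exp(2.0 + 25 * dscore + rng.normal(scale=0.4, size=n_genes)),
            "t1": np.full(n_genes, np.exp(2.0)),
        }
        scores = {"t2": dscore, "t1": np.zeros(n_genes)}
        _, tallies = tracing.expression_fold_vs_score_change(
            expression, scores, gene_to_region={i: i for i in range(n_genes)}
        )
        up, down = tallies["score_up"], tallies["score_down"]
        assert up + down > 10
        assert up / (up + down) > 0.5
        assert binomtest(up, up + down, 0.5).pvalue < 0.05
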