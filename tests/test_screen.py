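"""Screen-stage contracts: normalization arithmetic, moments-based
dispersion, the two-model NB posterior, criterion filters, candidate
selection against simulator truth, and the assembly metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from zwscreen.screen import (
    FemaleSpecificScreen,
    ScreenConfig,
    assembly_coverage,
    compute_n50,
    de_posterior,
    estimate_dispersion,
    female_exclusive_filter,
    normalize_counts,
    select_candidates,
)
from zwscreen.simulate import CountMatrix, PoolDesign, simulate_count_matrix, simulate_transcriptome

SEXES = ["F"] * 6 + ["M"] * 6


def _matrix(counts, lengths, libs=None, sexes=None):
    counts = np.asarray(counts, dtype=np.int64)
    n, p = counts.shape
    return CountMatrix(
        contig_ids=[f"c{i}" for i in range(n)],
        pool_ids=[f"p{j}" for j in range(p)],
        pool_sex=sexes or (["F"] * (p // 2) + ["M"] * (p - p // 2)),
        library_size=np.asarray(libs if libs is not None else [1e6] * p, dtype=float),
        contig_length=np.asarray(lengths),
        counts=counts,
    )


class TestNormalize:
    def test_arithmetic_identity(self):
        m = _matrix([[10, 0]], [1000], libs=[1e6, 1e6])
        rates, scale = normalize_counts(m)
        assert scale == 1e6 * 1000
        assert rates[0, 0] == pytest.approx(10.0)
        assert rates[0, 1] == 0.0

    def test_doubling_library_size_halves_rates(self):
        base = _matrix([[40, 40]], [500], libs=[1e6, 2e6])
        rates, _ = normalize_counts(base)
        assert rates[0, 0] == pytest.approx(2 * rates[0, 1])

    def test_zero_library_size_names_pool(self):
        m = _matrix([[1, 1]], [100], libs=[1e6, 1e6])
        m.library_size = np.array([1e6, 0.0])  # e.g. corrupted metadata load
        with pytest.raises(ValueError, match="p1"):
            normalize_counts(m)


class TestDispersion:
    def test_zero_variance_gives_zero(self):
        phi, flag = estimate_dispersion([5, 5, 5, 5], [1e6] * 4, 1000)
        assert phi == 0.0 and not flag

    def test_hand_computed_moments(self):
        # m=10, s2=200 -> (200-10)/100 = 1.9
        phi, _ = estimate_dispersion([0, 20], [1e6, 1e6], 1000)
        assert phi == pytest.approx(1.9)

    def test_all_zero_flagged(self):
        phi, flag = estimate_dispersion([0, 0, 0], [1e6] * 3, 1000)
        assert phi == 0.0 and flag

    def test_poisson_rows_unbiased_toward_zero(self):
        """Mean MoM dispersion over Poisson data is ~0 (floored estimator)."""
        rng = np.random.default_rng(42)
        n_reps, mu = 10_000, 50.0
        raw = []
        for _ in range(n_reps):
            y = rng.poisson(mu, size=6)
            m, s2 = y.mean(), y.var(ddof=1)
            raw.append((s2 - m) / m**2)  # unfloored, to check centering
        raw = np.asarray(raw)
        assert abs(raw.mean()) < 3 * raw.std(ddof=1) / np.sqrt(n_reps)
        phi, _ = estimate_dispersion(rng.poisson(mu, 6), [1e6] * 6, 1000)
        assert phi >= 0.0


class TestDEPosterior:
    def test_flat_row_posterior_below_prior(self):
        cfg = ScreenConfig()
        res = de_posterior([30] * 12, [1e6] * 12, 1000, SEXES, cfg)
        assert res.posterior_de < cfg.prior_de

    def test_female_only_expression_near_one(self):
        y = [50, 60, 55, 45, 50, 52, 0, 0, 0, 0, 0, 0]
        res = de_posterior(y, [1e6] * 12, 1000, SEXES)
        assert res.posterior_de > 0.999
        assert res.theta_m == 0.0

    def test_agrees_with_independent_grid_evaluation(self):
        """Posterior matches a scipy.stats grid maximization of both models."""
        y = np.array([50, 60, 55, 45, 50, 52, 0, 0, 0, 0, 0, 0], dtype=float)
        offsets = np.full(12, 1e6) * 1000
        phi, _ = estimate_dispersion(y, [1e6] * 12, 1000, pool_sex=SEXES)
        cfg = ScreenConfig()

        def grid_ll(yy, oo):
            if yy.sum() == 0:
                return 0.0
            t0 = yy.sum() / oo.sum()
            thetas = t0 * np.exp(np.linspace(-2, 2, 4001))
            if phi <= 1e-12:
                lls = [stats.poisson.logpmf(yy, t * oo).sum() for t in thetas]
            else:
                r = 1.0 / phi
                lls = [
                    stats.nbinom.logpmf(yy, r, r / (r + t * oo)).sum() for t in thetas
                ]
            return max(lls)

        s0 = grid_ll(y, offsets) - 0.5 * np.log(12)
        s1 = (
            grid_ll(y[:6], offsets[:6])
            + grid_ll(y[6:], offsets[6:])
            - 1.0 * np.log(12)
        )
        w = np.array([np.log(1 - cfg.prior_de) + s0, np.log(cfg.prior_de) + s1])
        expected = np.exp(w[1] - np.logaddexp(*w))
        res = de_posterior(y, [1e6] * 12, 1000, SEXES, cfg, dispersion=phi)
        assert res.posterior_de == pytest.approx(expected, abs=1e-6)

    def test_sex_label_swap_symmetry(self):
        y = [5, 9, 7, 6, 8, 5, 40, 44, 39, 41, 43, 38]
        res = de_posterior(y, [1e6] * 12, 800, SEXES)
        swapped = de_posterior(y, [1e6] * 12, 800, ["M"] * 6 + ["F"] * 6)
        assert res.posterior_de == pytest.approx(swapped.posterior_de, rel=1e-9)
        assert res.theta_f == pytest.approx(swapped.theta_m, rel=1e-6)
        assert res.theta_m == pytest.approx(swapped.theta_f, rel=1e-6)

    def test_invariant_to_global_library_rescaling(self):
        y = [12, 9, 15, 11, 0, 1, 3, 2, 4, 1, 2, 3]
        libs = np.linspace(0.5e6, 2e6, 12)
        a = de_posterior(y, libs, 900, SEXES)
        b = de_posterior(y, libs * 7.5, 900, SEXES)
        assert a.posterior_de == pytest.approx(b.posterior_de, rel=1e-6)

    def test_single_sex_input_rejected(self):
        with pytest.raises(ValueError):
            de_posterior([1] * 6, [1e6] * 6, 500, ["F"] * 6)


class TestExclusiveFilter:
    def test_definition_edges(self):
        cfg = ScreenConfig()
        assert female_exclusive_filter([3, 0, 0, 0, 0, 0] + [0] * 6, SEXES, cfg)
        assert not female_exclusive_filter([3, 0, 0, 0, 0, 0] + [1, 0, 0, 0, 0, 0], SEXES, cfg)
        assert not female_exclusive_filter([0] * 12, SEXES, cfg)

    def test_matches_brute_force_rescan(self, demo_simulation):
        _, matrix = demo_simulation
        cfg = ScreenConfig()
        passing = {
            cid
            for cid, row in zip(matrix.contig_ids, matrix.counts)
            if female_exclusive_filter(row, matrix.pool_sex, cfg)
        }
        male_cols = [j for j, s in enumerate(matrix.pool_sex) if s == "M"]
        female_cols = [j for j, s in enumerate(matrix.pool_sex) if s == "F"]
        brute = set()
        for cid, row in zip(matrix.contig_ids, matrix.counts):
            if sum(int(row[j]) for j in male_cols) == 0 and any(
                row[j] >= 1 for j in female_cols
            ):
                brute.add(cid)
        assert passing == brute


class TestSelectCandidates:
    def test_length_exactly_500_rejected(self, tiny_matrix):
        report = select_candidates(tiny_matrix).report.set_index("contig_id")
        assert report.loc["cand_short", "exclusive"]
        assert not report.loc["cand_short", "length_ok"]
        assert not report.loc["cand_short", "final_candidate"]

    def test_single_male_read_rejected(self, tiny_matrix):
        report = select_candidates(tiny_matrix).report.set_index("contig_id")
        assert not report.loc["cand_maleread", "exclusive"]
        assert not report.loc["cand_maleread", "final_candidate"]
        assert report.loc["cand_ok", "final_candidate"]

    def test_exclusion_list_blocks_candidacy(self, tiny_matrix):
        cfg = ScreenConfig(exclusion_list=frozenset({"cand_ok"}))
        report = select_candidates(tiny_matrix, cfg).report.set_index("contig_id")
        assert report.loc["cand_ok", "excluded_as_contaminant"]
        assert not report.loc["cand_ok", "final_candidate"]

    def test_unknown_exclusion_id_warns_not_errors(self, tiny_matrix):
        cfg = ScreenConfig(exclusion_list=frozenset({"nonexistent"}))
        with pytest.warns(UserWarning, match="unknown contig"):
            select_candidates(tiny_matrix, cfg)

    def test_truth_recovery_on_simulation(self, demo_simulation):
        transcripts, matrix = demo_simulation
        results = select_candidates(matrix)
        truth_w = {t.transcript_id for t in transcripts if t.class_label == "w_linked"}
        candidates = set(results.candidates["contig_id"])
        assert truth_w <= candidates
        male = matrix.sex_mask("M")
        by_id = {t.transcript_id: t for t in transcripts}
        for i, cid in enumerate(matrix.contig_ids):
            if cid in candidates and by_id[cid].class_label == "autosomal":
                assert matrix.counts[i, male].sum() == 0  # sampling-zero male profile

    def test_row_permutation_invariance(self, tiny_matrix):
        perm = [2, 0, 3, 1]
        shuffled = CountMatrix(
            contig_ids=[tiny_matrix.contig_ids[i] for i in perm],
            pool_ids=tiny_matrix.pool_ids,
            pool_sex=tiny_matrix.pool_sex,
            library_size=tiny_matrix.library_size,
            contig_length=tiny_matrix.contig_length[perm],
            counts=tiny_matrix.counts[perm],
        )
        a = select_candidates(tiny_matrix).report
        b = select_candidates(shuffled).report
        pd.testing.assert_frame_equal(a, b)

    def test_null_calibration_posterior_pass_rate(self):
        """No-sex-effect simulations stay under the configured prior rate."""
        cfg = ScreenConfig()
        n_pass = n_total = 0
        for seed in range(100):
            design = PoolDesign(seed=seed)
            tr = simulate_transcriptome(
                100, {"autosomal": 1.0}, length_range=(600, 1200),
                seed=seed, design=design,
            )
            matrix = simulate_count_matrix(tr, design)
            report = FemaleSpecificScreen(matrix, cfg).fit().report
            n_pass += int(report["posterior_ok"].sum())
            n_total += len(report)
        assert n_total == 10_000
        assert n_pass / n_total <= cfg.prior_de


class TestAssemblyMetrics:
    @pytest.mark.parametrize(
        "gene,utr,contig,n,expected",
        [(1000, 200, 1200, 0, 1.0), (1000, 200, 1300, 100, 1.0), (900, 100, 2000, 0, 0.5)],
    )
    def test_coverage_examples(self, gene, utr, contig, n, expected):
        assert assembly_coverage(gene, utr, contig, n) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        gene=st.integers(100, 5000),
        utr=st.integers(0, 1000),
        contig=st.integers(200, 6000),
        n=st.integers(0, 199),
    )
    def test_coverage_matches_direct_formula(self, gene, utr, contig, n):
        assert assembly_coverage(gene, utr, contig, n) == pytest.approx(
            (gene + utr) / (contig - n)
        )

    def test_coverage_invalid_denominator(self):
        with pytest.raises(ValueError):
            assembly_coverage(1000, 100, 50, 50)

    @pytest.mark.parametrize(
        "lengths,expected",
        [([5, 4, 3, 2, 1], 4), ([1234], 1234), ([7, 7, 7], 7), ([2, 2, 2, 5], 2)],
    )
    def test_n50_examples(self, lengths, expected):
        assert compute_n50(lengths) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 500), min_size=1, max_size=30))
    def test_n50_matches_definition(self, lengths):
        n50 = compute_n50(lengths)
        total = sum(lengths)
        assert sum(x for x in lengths if x >= n50) * 2 >= total
        # maximality: any larger candidate length fails the half-total bound
        for cand in sorted(set(lengths)):
            if cand > n50:
                assert sum(x for x in lengths if x >= cand) * 2 < total

    def test_n50_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_n50([])
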