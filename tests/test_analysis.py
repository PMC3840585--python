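"""Monte Carlo ensembles, error analysis, rejection, reports."""

import numpy as np
import pytest

from rdcfit.analysis import (ensemble_analysis, error_analysis, full_report,
                             iterative_rejection, localized_validation,
                             monte_carlo_solutions, q_factor,
                             satisfies_within_error, FullReport)
from rdcfit.core import RDCSet
from rdcfit.io import write_redcat_file
from rdcfit.synthetic import (MEDIUM_TENSORS, make_validation_dataset,
                              make_vectors, simulate_rdc)


def _noisy_set(tensor, n=20, width=1.0, seed=0):
    return simulate_rdc(tensor, make_vectors(n), noise=("uniform", width),
                        seed=seed, error=width)


class TestMonteCarlo:
    def test_zero_errors_collapse_to_best(self, m1, fib20):
        rdcs = simulate_rdc(m1, fib20, noise=None, error=0.0)
        ensemble = monte_carlo_solutions(rdcs, n_trials=50, seed=1)
        assert ensemble.n_within_error == 50
        best = np.asarray(ensemble.best.tensor.s5)
        for tensor in ensemble.accepted:
            assert np.allclose(tensor.s5, best, atol=1e-12)

    def test_huge_errors_accept_everything(self, m1, fib20):
        """With an interpolating system (n = 5) the refit reproduces the
        perturbed data exactly, so every trial lies within the error bars of
        the unperturbed data regardless of bar width; with n > 5 the
        acceptance rate stays near-complete for error bars dwarfing the
        couplings (the residual is the projection of the perturbation, which
        can exceed a single bar only through leverage)."""
        exact = simulate_rdc(m1, make_vectors(5), noise=None, error=1e6)
        ensemble = monte_carlo_solutions(exact, n_trials=30, seed=2)
        assert ensemble.n_within_error == 30

        over = simulate_rdc(m1, fib20, noise=None, error=1e6)
        assert monte_carlo_solutions(over, n_trials=30, seed=2).n_within_error >= 27

    def test_acceptance_recount_oracle(self, m2):
        rdcs = _noisy_set(m2, seed=3)
        ensemble = monte_carlo_solutions(rdcs, n_trials=200, seed=5)
        recount = sum(satisfies_within_error(t, rdcs) for t in ensemble.accepted)
        assert recount == ensemble.n_within_error == len(ensemble.accepted)
        assert 0 < ensemble.n_within_error <= 200

    def test_seed_determinism(self, m2):
        rdcs = _noisy_set(m2, seed=3)
        a = monte_carlo_solutions(rdcs, n_trials=50, seed=9)
        b = monte_carlo_solutions(rdcs, n_trials=50, seed=9)
        assert a.n_within_error == b.n_within_error
        for ta, tb in zip(a.accepted, b.accepted):
            assert ta.s5 == tb.s5

    def test_monotone_in_error_width(self, m2, fib20):
        """Enlarging every error bar never shrinks the acceptance count
        (same seed, so the same unit draws are rescaled)."""
        base = simulate_rdc(m2, fib20, noise=("uniform", 1.0), seed=4, error=0.5)
        from dataclasses import replace

        counts = []
        for width in (0.5, 1.0, 2.0, 4.0):
            rdcs = RDCSet(
                data=[replace(d, error=width) for d in base.data],
                medium_label=base.medium_label,
            )
            counts.append(monte_carlo_solutions(rdcs, 100, seed=7).n_within_error)
        assert counts == sorted(counts)

    def test_zero_trials(self, m1, fib20):
        rdcs = simulate_rdc(m1, fib20, noise=None, error=0.0)
        ensemble = monte_carlo_solutions(rdcs, n_trials=0, seed=0)
        assert ensemble.accepted == [] and ensemble.n_within_error == 0


class TestQFactor:
    def test_perfect_agreement(self):
        assert q_factor([(1.0, 1.0), (-2.0, -2.0)]) == 0.0

    def test_zero_prediction_gives_one(self):
        assert q_factor([(1.0, 0.0), (2.0, 0.0)]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # rms(diff) = sqrt(2/3), rms(obs) = sqrt(14/3) -> Q = sqrt(2/14)
        q = q_factor([(1.0, 2.0), (2.0, 2.0), (3.0, 2.0)])
        assert q == pytest.approx(np.sqrt(2.0 / 14.0), abs=1e-12)

    def test_all_zero_observations_undefined(self):
        with pytest.raises(ZeroDivisionError):
            q_factor([(0.0, 1.0), (0.0, 2.0)])


class TestErrorAnalysis:
    def test_noise_free_data_is_clean(self, m1, clean_m1_set):
        report = error_analysis(clean_m1_set, m1)
        assert max(report.residuals.values()) < 1e-9
        assert report.violations == []
        assert report.q_factor == pytest.approx(0.0, abs=1e-9)

    def test_corrupted_datum_flagged_with_max_residual(self, m1, fib20):
        from dataclasses import replace

        rdcs = simulate_rdc(m1, fib20, noise=None, error=1.0)
        data = list(rdcs.data)
        data[6] = replace(data[6], d_obs=data[6].d_obs + 10.0)
        corrupted = RDCSet(data=data)
        report = error_analysis(corrupted, m1)
        assert report.violations == [7]
        assert max(report.residuals, key=report.residuals.get) == 7

    def test_rmsd_and_q_recomputable_from_correlation(self, m2):
        rdcs = _noisy_set(m2, seed=8)
        from rdcfit.svd import solve_rdcset

        tensor = solve_rdcset(rdcs).tensor
        report = error_analysis(rdcs, tensor)
        obs = np.array([p[0] for p in report.correlation])
        calc = np.array([p[1] for p in report.correlation])
        assert report.rmsd == pytest.approx(
            float(np.sqrt(np.mean((obs - calc) ** 2))), abs=1e-12
        )
        assert report.q_factor == pytest.approx(
            float(np.sqrt(np.mean((obs - calc) ** 2) / np.mean(obs**2))), abs=1e-12
        )


class TestIterativeRejection:
    def test_clean_data_omits_nothing(self, m1, clean_m1_set):
        solution, omitted = iterative_rejection(clean_m1_set)
        assert omitted == []
        assert np.allclose(solution.tensor.s5, m1.s5, atol=1e-10)

    def test_corrupted_region_removed_and_tensor_recovered(self, m2):
        from dataclasses import replace

        rdcs = simulate_rdc(m2, make_vectors(30), noise=None, error=0.5)
        data = list(rdcs.data)
        shifted = range(10, 16)  # corrupt equations 11..16
        for i in shifted:
            data[i] = replace(data[i], d_obs=data[i].d_obs + 6.0)
        solution, omitted = iterative_rejection(RDCSet(data=data))
        assert set(omitted) <= {i + 1 for i in shifted}
        assert np.allclose(solution.tensor.s5, m2.s5, atol=1e-8)

    def test_max_iter_zero_is_plain_solve(self, m2):
        rdcs = _noisy_set(m2, seed=12)
        from rdcfit.svd import solve_rdcset

        solution, omitted = iterative_rejection(rdcs, max_iter=0)
        assert omitted == []
        assert solution.tensor.s5 == solve_rdcset(rdcs).tensor.s5

    def test_stops_before_dropping_below_five_equations(self, m1):
        """Five equations containing an irreconcilable duplicate: the fit
        cannot interpolate, violations persist, but removal would leave
        fewer than five equations, so rejection stops with a warning."""
        from dataclasses import replace

        rdcs = simulate_rdc(m1, make_vectors(5), noise=None, error=0.1)
        data = list(rdcs.data)
        # same direction as equation 1 but a conflicting observation
        data[4] = replace(data[0], index=5, d_obs=data[0].d_obs + 5.0)
        with pytest.warns(UserWarning, match="fewer than 5"):
            _, omitted = iterative_rejection(RDCSet(data=data))
        assert omitted == []


class TestLocalizedValidation:
    def test_violations_concentrate_in_mobile_regions(self):
        """Cross-media flags land overwhelmingly inside the perturbed
        regions and post-rejection tensors match the generators."""
        ds = make_validation_dataset(seed=1)
        result = localized_validation(ds.media)
        mobile = set(ds.mobile_indices)
        jaccard = len(result.flagged & mobile) / len(result.flagged | mobile)
        assert jaccard >= 0.8
        for label, (solution, _, _) in result.per_medium.items():
            true = np.asarray(ds.tensors[label].s5)
            scale = np.abs(np.asarray(
                np.linalg.eigvalsh(ds.tensors[label].matrix))).max()
            assert np.abs(np.asarray(solution.tensor.s5) - true).max() < 0.05 * scale


class TestReports:
    def test_full_report_two_media_match_generators(self):
        media = [
            simulate_rdc(MEDIUM_TENSORS[label], make_vectors(20), noise=None,
                         error=1.0, medium_label=label)
            for label in ("M1", "M2")
        ]
        report = full_report(media, n_trials=20, seed=0)
        assert [m.medium_label for m in report.media] == ["M1", "M2"]
        assert np.allclose(report.media[0].principal, (-3e-4, -5e-4, 8e-4), atol=1e-10)
        assert np.allclose(report.media[1].principal, (2e-4, 5e-4, -7e-4), atol=1e-10)
        assert report.media[0].rhombicity == pytest.approx(1 / 6, abs=1e-10)

    def test_single_medium_zero_trials(self, clean_m1_set):
        report = full_report([clean_m1_set], n_trials=0, seed=0)
        assert report.media[0].n_within_error == 0
        # best-only ensemble still yields the 6 best-tensor SF points
        assert len(report.media[0].sf_points_2d) == 6

    def test_report_json_roundtrip(self, clean_m1_set):
        report = full_report([clean_m1_set], n_trials=5, seed=3)
        again = FullReport.from_json(report.to_json())
        assert again.to_json() == report.to_json()

    def test_unsolvable_medium_gets_error_marker(self, clean_m1_set):
        empty = clean_m1_set.with_selection(np.zeros(len(clean_m1_set), dtype=bool))
        report = full_report([clean_m1_set, empty], n_trials=0, seed=0)
        assert report.media[0].error is None
        assert report.media[1].error is not None


class TestEnsembleAnalysis:
    def test_truth_ranked_first_on_both_metrics(self, m2, tmp_path):
        from dataclasses import replace

        clean = simulate_rdc(m2, make_vectors(20), noise=None, error=1.0)
        data = list(clean.data)
        for i in range(5, 12):
            data[i] = replace(data[i], d_obs=data[i].d_obs + 4.0)
        paths = [tmp_path / "truth.rdc", tmp_path / "perturbed.rdc"]
        write_redcat_file(clean, paths[0])
        write_redcat_file(RDCSet(data=data), paths[1])
        result = ensemble_analysis([str(p) for p in paths], n_trials=0)
        assert result.ranking_by_rmsd[0] == 0
        assert result.ranking_by_q[0] == 0

    def test_empty_list(self):
        result = ensemble_analysis([])
        assert result.reports == [] and result.ranking_by_rmsd == []

    def test_same_file_twice_gives_identical_blocks(self, m1, tmp_path):
        rdcs = simulate_rdc(m1, make_vectors(12), noise=None, error=1.0)
        path = tmp_path / "a.rdc"
        write_redcat_file(rdcs, path)
        result = ensemble_analysis([str(path), str(path)], n_trials=0)
        a, b = result.reports
        assert a.media[0].tensor_s5 == b.media[0].tensor_s5

    def test_unreadable_path_reported_not_fatal(self, m1, tmp_path):
        rdcs = simulate_rdc(m1, make_vectors(12), noise=None, error=1.0)
        path = tmp_path / "a.rdc"
        write_redcat_file(rdcs, path)
        result = ensemble_analysis([str(tmp_path / "missing.rdc"), str(path)],
                                   n_trials=0)
        assert "error" in result.reports[0]
        assert result.ranking_by_rmsd == [1]
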