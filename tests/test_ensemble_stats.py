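import math

import numpy as np
import pytest

from confunnel import (
    boltzmann_percentages,
    conformer_type_census,
    pharmacology_correlation,
    population_subset,
    relative_from_values,
    stabilization_correction,
)
from confunnel.constants import R_KCAL_MOL_K
from confunnel.ensemble_stats import parse_potency

T_PHYS = 310.15
RT = R_KCAL_MOL_K * T_PHYS


def _table(values, ids=None):
    ids = ids or [f"c{i}" for i in range(len(values))]
    return relative_from_values(ids, values)


class TestBoltzmannPercentages:
    def test_single_conformer_is_everything(self):
        pop = boltzmann_percentages(_table([0.0]), T_PHYS)
        assert pop.bp == (100.0,)

    def test_degenerate_quartet_splits_evenly(self):
        pop = boltzmann_percentages(_table([0.0, 0.0, 0.0, 0.0]), T_PHYS)
        np.testing.assert_allclose(pop.bp, [25.0] * 4, atol=1e-12)

    def test_rt_ln2_gap_gives_two_to_one(self):
        gap = RT * math.log(2.0)  # ~0.427 kcal/mol at 310.15 K
        pop = boltzmann_percentages(_table([0.0, gap]), T_PHYS)
        np.testing.assert_allclose(pop.bp, [200.0 / 3.0, 100.0 / 3.0], atol=1e-9)

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = np.concatenate([[0.0], rng.uniform(0, 8, size=rng.integers(1, 40))])
            pop = boltzmann_percentages(_table(list(vals)), T_PHYS)
            assert math.isclose(sum(pop.bp), 100.0, abs_tol=1e-8)

    def test_monotone_in_delta_g(self):
        vals = [0.0, 0.5, 1.0, 3.0]
        pop = boltzmann_percentages(_table(vals), T_PHYS)
        assert all(a > b for a, b in zip(pop.bp, pop.bp[1:]))

    def test_heating_flattens_populations(self):
        table = _table([0.0, 1.0, 2.0])
        cold = boltzmann_percentages(table, T_PHYS)
        hot = boltzmann_percentages(table, 2 * T_PHYS)
        for i in (1, 2):  # every non-minimum conformer gains share
            assert hot.bp[i] > cold.bp[i]

    def test_incomplete_ensemble_refused(self):
        with pytest.raises(ValueError, match="incomplete"):
            boltzmann_percentages(_table([0.0, 1.0]), T_PHYS, complete=False)


class TestStabilization:
    def test_single_conformer_zero(self):
        res = stabilization_correction(_table([0.0]), T_PHYS)
        assert res.dg_stab == pytest.approx(0.0, abs=1e-12)

    def test_two_degenerate_minus_rt_ln2(self):
        res = stabilization_correction(_table([0.0, 0.0]), T_PHYS)
        assert res.dg_stab == pytest.approx(-RT * math.log(2.0), abs=1e-10)
        assert res.dg_stab == pytest.approx(-0.427, abs=0.001)

    def test_half_kcal_pair_closed_form(self):
        res = stabilization_correction(_table([0.0, 0.5]), T_PHYS)
        expected = -RT * math.log(1.0 + math.exp(-0.5 / RT))
        assert res.dg_stab == pytest.approx(expected, abs=1e-10)
        assert res.dg_stab == pytest.approx(-0.227, abs=0.001)

    def test_n_degenerate_minus_rt_ln_n(self):
        for n in (1, 2, 5, 17):
            res = stabilization_correction(_table([0.0] * n), T_PHYS)
            assert res.dg_stab == pytest.approx(-RT * math.log(n), abs=1e-10)

    def test_never_positive_and_non_increasing_as_ensemble_grows(self):
        rng = np.random.default_rng(2)
        vals = [0.0]
        prev = 0.0
        for _ in range(15):
            vals.append(float(rng.uniform(0, 6)))
            res = stabilization_correction(_table(vals), T_PHYS)
            assert res.dg_stab <= 0.0
            assert res.dg_stab <= prev + 1e-12
            prev = res.dg_stab

    def test_consistency_with_populations(self):
        """exp(-dG_stab/RT) equals the partition sum of the BP formula."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            vals = np.concatenate([[0.0], rng.uniform(0, 8, size=rng.integers(1, 30))])
            table = _table(list(vals))
            stab = stabilization_correction(table, T_PHYS)
            z = np.sum(np.exp(-vals / RT))
            assert math.exp(-stab.dg_stab / RT) == pytest.approx(z, rel=1e-9)


class TestPopulationSubset:
    def test_cutoff_selects_descending(self):
        pop = boltzmann_percentages(_table([0.0, 0.3, 1.5]), T_PHYS)
        assert population_subset(pop, 25.0) == ["c0", "c1"]

    def test_exact_cutoff_excluded(self):
        pop = boltzmann_percentages(_table([0.0, 0.0, 0.0, 0.0]), T_PHYS)
        assert population_subset(pop, 25.0) == []

    def test_zero_cutoff_keeps_all(self):
        pop = boltzmann_percentages(_table([0.0, 2.0, 5.0]), T_PHYS)
        assert len(population_subset(pop, 0.0)) == 3


class TestCensus:
    def test_all_cis(self):
        pop = boltzmann_percentages(_table([0.0] * 5), T_PHYS)
        labels = {f"c{i}": "cis" for i in range(5)}
        census = conformer_type_census(labels, pop, cutoff=0.5)
        assert census.counts == {"cis": 5, "trans": 0, "gauche": 0}

    def test_cutoff_above_max_bp_empties_census(self):
        pop = boltzmann_percentages(_table([0.0, 0.0]), T_PHYS)
        census = conformer_type_census({"c0": "cis", "c1": "trans"}, pop, cutoff=60.0)
        assert census.total == 0

    def test_missing_label_raises(self):
        pop = boltzmann_percentages(_table([0.0, 0.1]), T_PHYS)
        with pytest.raises(KeyError, match="c1"):
            conformer_type_census({"c0": "cis"}, pop, cutoff=0.5)


class TestPharmacologyCorrelation:
    def test_censored_parsing(self):
        assert parse_potency(">1000") == (1000.0, True)
        assert parse_potency(" > 500 ") == (500.0, True)
        assert parse_potency(32) == (32.0, False)
        assert parse_potency("4.2") == (4.2, False)

    def test_perfect_monotone_pairing(self):
        summary = {f"a{i}": float(i) for i in range(6)}
        pharm = {f"a{i}": 10.0 ** i for i in range(6)}
        report = pharmacology_correlation(summary, pharm)
        assert report.spearman_rho == pytest.approx(1.0, abs=1e-12)
        assert report.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_reversed_pairing(self):
        summary = {f"a{i}": float(i) for i in range(6)}
        pharm = {f"a{i}": 10.0 ** (5 - i) for i in range(6)}
        report = pharmacology_correlation(summary, pharm)
        assert report.spearman_rho == pytest.approx(-1.0, abs=1e-12)

    def test_too_few_shared_analogs(self):
        with pytest.raises(ValueError, match="3"):
            pharmacology_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_censored_excluded_from_pearson_tied_in_spearman(self):
        summary = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0, "e": 5.0}
        pharm = {"a": 10.0, "b": 100.0, "c": ">1000", "d": ">1000", "e": 500.0}
        report = pharmacology_correlation(summary, pharm)
        assert report.n_censored == 2
        assert set(report.analogs_pearson) == {"a", "b", "e"}
        assert set(report.analogs_spearman) == {"a", "b", "c", "d", "e"}
        # ties at the shared bound: expected ranks computed independently
        from scipy import stats

        expected = stats.spearmanr([1, 2, 3, 4, 5], [10, 100, 1000, 1000, 500]).statistic
        assert report.spearman_rho == pytest.approx(expected, abs=1e-12)

    def test_published_summary_vs_affinity_matches_independent_formula(self):
        """Stabilization free energies vs binding affinity over 34 analogs:
        the rank coefficient must agree with a from-scratch rank-formula
        evaluation (the study reported no correlation; this is descriptive)."""
        from confunnel.datasets import funnel_summary, pharmacology_table

        summary = dict(
            zip(funnel_summary()["analog"], funnel_summary()["dg_stab_kcal"])
        )
        pharm = dict(zip(pharmacology_table()["analog"], pharmacology_table()["ki_nm"]))
        report = pharmacology_correlation(summary, pharm, measure="Ki")
        assert len(report.analogs_spearman) == 34

        # independent oracle: Pearson formula applied to mid-ranks
        def midranks(values):
            order = sorted(range(len(values)), key=lambda i: values[i])
            ranks = [0.0] * len(values)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                    j += 1
                avg = (i + j) / 2.0 + 1.0
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return ranks

        analogs = report.analogs_spearman
        x = midranks([summary[a] for a in analogs])
        y = midranks([parse_potency(pharm[a])[0] for a in analogs])
        mx, my = sum(x) / len(x), sum(y) / len(y)
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
        )
        assert report.spearman_rho == pytest.approx(num / den, abs=1e-10)
        # and indeed no meaningful monotone association
        assert abs(report.spearman_rho) < 0.5
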