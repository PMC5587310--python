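"""Null EM, pruning, full maximum-likelihood fit and LRT inference."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

import xtriad as xt
from xtriad.fitcore import fit_full, fit_null, fit_window, lrt_pvalue, prune_rare
from xtriad.xmodel import (
    HaplotypeTable,
    PenetranceSpec,
    TriadConfig,
    Window,
    enumerate_configs,
    enumerate_haplotypes,
)

from conftest import make_triad


def _families(dataset, window=None):
    window = window or Window(0, dataset.map.n_markers,
                              tuple(dataset.map.marker_ids))
    haps = enumerate_haplotypes(window, dataset.map)
    fams = []
    for t in dataset.triads:
        cfgs = enumerate_configs(t, window, haps)
        if cfgs:
            fams.append((t, cfgs))
    return fams, haps, window


class TestFitNull:
    def test_complete_data_equals_allele_counting(self, balanced_null_dataset):
        """With complete data each family has one configuration, so EM
        reduces to counting haplotypes in the three slots (t, u, f)."""
        fams, haps, _ = _families(balanced_null_dataset)
        fitted, ll = fit_null(fams, haps)
        counts = np.zeros(2)
        for _, cfgs in fams:
            (c,) = cfgs
            for idx in (c.maternal_transmitted, c.maternal_untransmitted, c.paternal):
                counts[idx] += 1
        np.testing.assert_allclose(fitted.frequencies, counts / counts.sum(),
                                   atol=1e-12)
        assert ll == pytest.approx(
            float(counts @ np.log(counts / counts.sum())), rel=1e-12
        )

    def test_single_haplotype_degenerate(self, single_snp_map):
        triads = [make_triad(f"f{i}", [[0, 0]], [0], "male", [0])
                  for i in range(10)]
        ds = xt.TriadDataset(single_snp_map, triads)
        fams, haps, _ = _families(ds)
        fitted, _ = fit_null(fams, haps)
        assert fitted.frequencies[0] == pytest.approx(1.0, abs=1e-12)

    def test_em_loglik_non_decreasing_with_missing_data(self):
        spec = xt.SimSpec(
            haplotype_frequencies=(0.4, 0.2, 0.3, 0.1),
            true_rr_single_dose=(1.0, 1.0, 1.0, 1.0),
            n_triads=120, missing_rate=0.3, seed=17,
        )
        fams, haps, _ = _families(xt.simulate_triads(spec))
        _, _, trace, converged = fit_null(fams, haps, return_trace=True)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-10)
        assert converged

    def test_reference_is_most_frequent(self, males_consistent_dataset):
        fams, haps, _ = _families(males_consistent_dataset)
        fitted, _ = fit_null(fams, haps)
        assert fitted.reference_index == int(np.argmax(fitted.frequencies))


class TestPruneRare:
    def _table(self, freqs):
        n = len(freqs)
        return HaplotypeTable(
            haplotypes=[format(i, f"0{max(1, (n - 1).bit_length())}b") for i in range(n)],
            allele_codes=np.array(
                list(itertools.product([0, 1], repeat=max(1, (n - 1).bit_length())))
            )[:n],
            frequencies=np.asarray(freqs),
        )

    def test_renormalization(self):
        haps = self._table([0.70, 0.25, 0.04, 0.01])
        pruned, fams, labels = prune_rare(haps, 0.05, [])
        np.testing.assert_allclose(pruned.frequencies, [0.70 / 0.95, 0.25 / 0.95],
                                   rtol=1e-12)
        assert labels == ["10", "11"]

    def test_identity_when_all_common(self):
        haps = self._table([0.5, 0.3, 0.1, 0.1])
        pruned, _, labels = prune_rare(haps, 0.05, [])
        assert labels == []
        assert pruned is haps

    def test_uninformative_window_raises(self):
        haps = self._table([0.995, 0.005])
        with pytest.raises(xt.WindowUninformativeError):
            prune_rare(haps, 0.05, [])

    def test_config_remapping_and_family_exclusion(self):
        haps = self._table([0.60, 0.30, 0.06, 0.04])
        rec_ok = make_triad("ok", [[-1, -1], [-1, -1]], [-1, -1], "male", [-1, -1])
        rec_gone = make_triad("gone", [[-1, -1], [-1, -1]], [-1, -1], "male",
                              [-1, -1])
        fams = [
            (rec_ok, [TriadConfig(0, 1, 1, "male"), TriadConfig(2, 0, 0, "male")]),
            (rec_gone, [TriadConfig(3, 2, 2, "male")]),
        ]
        pruned, kept, labels = prune_rare(haps, 0.05, fams)
        assert labels == ["11"]
        assert len(kept) == 1
        assert kept[0][0] is rec_ok
        assert kept[0][1] == [TriadConfig(0, 1, 1, "male"),
                              TriadConfig(2, 0, 0, "male")]
        np.testing.assert_allclose(pruned.frequencies.sum(), 1.0)


class TestFitFull:
    def test_transmission_ratio_males(self, males_consistent_dataset):
        """Complete-data sex-stratified MLE: with every empirical margin at
        its model value, the fitted RR equals the transmitted/untransmitted
        variant ratio from heterozygous mothers (120/60 = 2)."""
        fit = fit_window(males_consistent_dataset, Window(0, 1, ("rs1",)),
                         PenetranceSpec("males_only"))
        assert fit.reference_index == 0
        assert fit.rr_single_dose[1] == pytest.approx(2.0, abs=1e-6)
        np.testing.assert_allclose(fit.haplotype_table.frequencies, [2 / 3, 1 / 3],
                                   atol=1e-6)

    def test_transmission_ratio_females(self, females_consistent_dataset):
        fit = fit_window(females_consistent_dataset, Window(0, 1, ("rs1",)),
                         PenetranceSpec("females_only"))
        assert fit.rr_single_dose[1] == pytest.approx(2.0, abs=1e-6)

    def test_balanced_null_gives_unit_rr_and_zero_lrt(self, balanced_null_dataset):
        fit = fit_window(balanced_null_dataset, Window(0, 1, ("rs1",)),
                         PenetranceSpec("males_only"))
        assert fit.rr_single_dose[1] == pytest.approx(1.0, abs=1e-6)
        assert fit.lrt_statistic == pytest.approx(0.0, abs=1e-8)
        assert fit.p_value == pytest.approx(1.0, abs=1e-6)

    def test_xinactivation_boy_rr_is_square(self):
        spec = xt.SimSpec(
            haplotype_frequencies=(0.8, 0.2),
            true_rr_single_dose=(1.0, 1.7),
            model=PenetranceSpec("xinactivation"),
            n_triads=400, seed=21,
        )
        data = xt.simulate_triads(spec)
        fit = fit_window(data, Window(0, 1, ("sim1",)),
                         PenetranceSpec("xinactivation"))
        np.testing.assert_allclose(fit.rr_boys, fit.rr_single_dose ** 2,
                                   rtol=1e-12)
        # printed-example sanity: a girls' single-dose RR of 0.57 implies a
        # boys'/double-dose RR of 0.57**2 = 0.32 under this coupling
        assert round(float(xt.double_dose_rr(0.57)), 2) == 0.32

    def test_no_xinactivation_boy_rr_is_single_dose(self):
        spec = xt.SimSpec(
            haplotype_frequencies=(0.8, 0.2),
            true_rr_single_dose=(1.0, 1.7),
            n_triads=400, seed=22,
        )
        data = xt.simulate_triads(spec)
        fit = fit_window(data, Window(0, 1, ("sim1",)), PenetranceSpec())
        np.testing.assert_allclose(fit.rr_boys, fit.rr_single_dose, rtol=1e-12)
        np.testing.assert_allclose(fit.rr_double_dose, fit.rr_single_dose ** 2,
                                   rtol=1e-12)

    def test_allele_relabelling_inverts_rr(self, males_consistent_dataset):
        """Swapping which allele is 'variant' inverts the fitted RR when the
        reference haplotype is pinned to the same physical allele label."""
        window = Window(0, 1, ("rs1",))
        fit = fit_window(males_consistent_dataset, window,
                         PenetranceSpec("males_only"), reference="1")
        swapped = xt.TriadDataset(
            males_consistent_dataset.map,
            [
                make_triad(
                    t.family_id,
                    1 - t.mother_genotypes,
                    1 - t.father_genotypes,
                    "male",
                    1 - t.child_genotypes,
                )
                for t in males_consistent_dataset.triads
            ],
        )
        fit_sw = fit_window(swapped, window, PenetranceSpec("males_only"),
                            reference="1")
        assert fit_sw.rr_single_dose[1] == pytest.approx(
            1.0 / fit.rr_single_dose[1], abs=1e-6
        )
        assert fit_sw.lrt_statistic == pytest.approx(fit.lrt_statistic, abs=1e-8)

    def test_monotone_nesting(self):
        for seed in range(4):
            spec = xt.SimSpec(
                haplotype_frequencies=(0.7, 0.3),
                true_rr_single_dose=(1.0, 1.0),
                n_triads=80, missing_rate=0.1, seed=seed,
            )
            data = xt.simulate_triads(spec)
            fit = fit_window(data, Window(0, 1, ("sim1",)), PenetranceSpec())
            assert fit.loglik_full >= fit.loglik_null - 1e-9

    def test_optimum_matches_dense_grid_search(self, males_consistent_dataset):
        """Brute-force oracle: the fitted optimum dominates a dense grid over
        (variant frequency, log RR) within 1e-4 log-units."""
        fams, haps, _ = _families(males_consistent_dataset)
        spec = PenetranceSpec("males_only")
        fit = fit_full(fams, haps, spec, compute_ci=False)
        best = -np.inf
        for q in np.linspace(0.05, 0.95, 61):
            for logr in np.linspace(-1.5, 1.5, 61):
                table = HaplotypeTable(
                    haps.haplotypes, haps.allele_codes,
                    np.array([1 - q, q]), reference_index=0,
                )
                params = xt.RiskParams(np.array([1.0, math.exp(logr)]), 0)
                best = max(best, xt.loglik(fams, table, params, spec))
        assert fit.loglik_full >= best - 1e-4

    def test_separation_hits_boundary_flag(self, single_snp_map):
        # variant transmitted by every het mother -> infinite MLE, capped
        triads = []
        for i in range(12):
            triads.append(make_triad(f"h{i}", [[0, 1]], [0], "male", [1]))
            triads.append(make_triad(f"r{i}", [[0, 0]], [0], "male", [0]))
        ds = xt.TriadDataset(single_snp_map, triads)
        fit = fit_window(ds, Window(0, 1, ("rs1",)), PenetranceSpec("males_only"))
        assert fit.boundary_haplotypes == ["2"]
        assert fit.rr_single_dose[1] <= math.exp(15.0) + 1e-6

    def test_wrong_sex_families_excluded(self, males_consistent_dataset):
        fams, haps, _ = _families(males_consistent_dataset)
        with pytest.raises(xt.NoDataError):
            fit_full(fams, haps, PenetranceSpec("females_only"))


class TestLrtPvalue:
    @pytest.mark.parametrize(
        "stat, df, expected, tol",
        [
            (0.0, 1, 1.0, 1e-12),
            (3.841459, 1, 0.05, 1e-6),
            (7.815, 3, 0.05, 1e-4),
        ],
    )
    def test_chi_square_reference_values(self, stat, df, expected, tol):
        p = lrt_pvalue(stat / 2.0, 0.0, df)
        assert p == pytest.approx(expected, abs=tol)

    def test_negative_statistic_rejected(self):
        with pytest.raises(AssertionError):
            lrt_pvalue(-1.0, 0.0, 1)

    def test_matches_survival_function(self):
        assert lrt_pvalue(5.0, 2.0, 3) == pytest.approx(
            stats.chi2.sf(6.0, 3), rel=1e-12
        )
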