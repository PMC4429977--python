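import numpy as np
import pandas as pd
import pytest

from coiprot import (
    CorpusConfig,
    ccdf,
    domain_average_lengths,
    ptm_abundance_test,
    r2_grid,
    sample_duals,
    species_aggregates,
    test_p1,
    test_p2,
    test_p3,
    test_p4,
    test_p5,
)
from coiprot.predictions import SpeciesAggregate, grid_to_frame


def constant_length_table(n_species=6, per_species=20, length=300, a=12):
    rows = []
    for s in range(n_species):
        for _ in range(per_species + s):  # vary n_p across species
            rows.append({"species": f"S{s}", "domain": "bacteria",
                         "t": length, "a": a, "has_ptm": False})
    return pd.DataFrame(rows)


class TestCcdf:
    def test_hand_counts(self):
        assert ccdf([3, 3, 4]) == [(3, 3), (4, 1)]
        assert ccdf([7]) == [(7, 1)]

    def test_total_at_minimum_and_monotone(self):
        values = [5, 2, 9, 2, 5, 5]
        pts = ccdf(values)
        assert pts[0] == (2, len(values))
        counts = [c for _, c in pts]
        assert counts == sorted(counts, reverse=True)


class TestP1:
    def test_recovers_equilibrium_tail_slope(self):
        cfg = CorpusConfig(m=50_000, beta=5.0)
        pairs = sample_duals(cfg, seed=3)
        fit = test_p1(pairs)
        from coiprot import equilibrium_pmf, fit_loglog_tail

        support = np.arange(20, 31)
        cum = equilibrium_pmf(5.0, support)[::-1].cumsum()[::-1]
        a = np.array([p[1] for p in pairs])
        used = sorted(set(int(v) for v in a if 20 <= v <= 30))
        noiseless = fit_loglog_tail(
            [(v, float((a >= 20).sum() * cum[v - 20])) for v in used], (20, 30)
        )
        assert abs(fit.slope - noiseless.slope) < 3 * fit.stderr

    def test_degenerate_window_errors(self):
        with pytest.raises(ValueError):
            test_p1([(100, 12)] * 50)

    def test_duplicating_every_protein_preserves_slope(self):
        cfg = CorpusConfig(m=20_000, beta=5.0)
        pairs = sample_duals(cfg, seed=4)
        fit = test_p1(pairs)
        doubled = test_p1(pairs + pairs)
        assert doubled.slope == pytest.approx(fit.slope, abs=1e-12)


class TestSpeciesAggregates:
    def test_sums_and_invariant(self, small_corpus):
        _, _, truth = small_corpus
        table = truth.rename(columns={})  # already has species/domain/t/a
        agg = species_aggregates(table)
        assert agg["n_p"].sum() == len(table)
        assert ((agg["n_p"] <= agg["l_a"]) & (agg["l_a"] <= agg["l_p"])).all()

    def test_window_filtering_drops_species(self):
        df = constant_length_table()
        assert len(species_aggregates(df, a_window=(50, 60))) == 0

    def test_aggregate_type_invariant(self):
        with pytest.raises(ValueError):
            SpeciesAggregate("s", "bacteria", n_p=5, l_p=10, l_a=20)  # l_a > l_p


class TestP2P4:
    def test_constant_length_gives_exact_line(self):
        df = constant_length_table(length=300)
        fit = test_p2(df, a_window=(1, 30))
        assert fit.slope == pytest.approx(300)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_constant_unique_count_gives_exact_line(self):
        df = constant_length_table(a=12)
        fit = test_p4(df, t_window=(100, 500))
        assert fit.slope == pytest.approx(12)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_equilibrium_corpus_is_linear(self, small_corpus):
        _, _, truth = small_corpus
        fit = test_p2(truth, a_window=(1, 30))
        assert fit.adj_r2 > 0.95
        true_mean = truth.loc[truth["a"] <= 30, "t"].mean()
        assert fit.slope == pytest.approx(true_mean, rel=0.05)
        fit4 = test_p4(truth, t_window=(100, 500))
        assert fit4.adj_r2 > 0.95

    def test_too_few_species_errors(self):
        df = constant_length_table(n_species=1)
        with pytest.raises(ValueError):
            test_p2(df)


class TestR2Grid:
    def test_single_cell_matches_direct_regression(self):
        df = constant_length_table()
        (cell,) = r2_grid(df, kind="p2", lattice=[12])
        direct = test_p2(df, a_window=(12, 12))
        assert cell.adj_r2 == pytest.approx(direct.adj_r2)
        assert cell.n_species == 6

    def test_perfect_corpus_all_cells_unity(self):
        df = constant_length_table()
        cells = r2_grid(df, kind="p2", lattice=[10, 12, 14])
        defined = [c for c in cells if c.adj_r2 is not None]
        assert defined and all(c.adj_r2 == pytest.approx(1.0) for c in defined)

    def test_sparse_cells_marked_absent_not_zero(self):
        df = constant_length_table()
        cells = r2_grid(df, kind="p2", lattice=[12, 25])
        absent = [c for c in cells if c.range_low == 25 and c.range_high == 25]
        assert absent[0].adj_r2 is None and absent[0].n_species == 0
        frame = grid_to_frame(cells)
        assert set(frame.columns) == {
            "range_low", "range_high", "adj_r2", "n_species", "mean_value"
        }


class TestP5:
    def test_full_fraction_identical_to_full_fit(self):
        rng = np.random.default_rng(5)
        lengths = rng.integers(100, 5000, size=20_000)
        from coiprot import fit_loglog_tail

        family = test_p5(lengths, fractions=(1.0,), n_rep=2, seed=9)
        full = fit_loglog_tail(ccdf(lengths), (300, 10_000))
        for fit in family.fits[1.0]:
            assert fit.slope == pytest.approx(full.slope, abs=1e-12)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        lengths = rng.integers(100, 5000, size=5000)
        fam1 = test_p5(lengths, fractions=(0.2, 0.5), n_rep=3, seed=11)
        fam2 = test_p5(lengths, fractions=(0.2, 0.5), n_rep=3, seed=11)
        for f in (0.2, 0.5):
            assert [x.slope for x in fam1.fits[f]] == [x.slope for x in fam2.fits[f]]

    def test_subsets_share_the_tail_slope(self):
        from coiprot.synthetic_corpus import sample_powerlaw_lengths

        lengths = sample_powerlaw_lengths(1.5, (100, 20_000), 50_000, seed=13)
        family = test_p5(lengths, fractions=(0.1, 0.5, 1.0), n_rep=5, seed=13)
        full_mean = family.slope_mean[1.0]
        for f in (0.1, 0.5):
            spread = max(family.slope_sd[f], 0.01)
            assert abs(family.slope_mean[f] - full_mean) < 4 * spread

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            test_p5([1, 2, 3], fractions=(0.0,))


class TestPtmAbundance:
    @staticmethod
    def pearson_chi2(table):
        """Independent oracle: textbook Pearson statistic, no correction."""
        obs = np.asarray(table, dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        return float(((obs - expected) ** 2 / expected).sum())

    def make_table(self, group_counts):
        rows = []
        for a, (with_ptm, without) in group_counts.items():
            rows += [{"species": "s", "domain": "bacteria", "t": 100, "a": a,
                      "has_ptm": True}] * with_ptm
            rows += [{"species": "s", "domain": "bacteria", "t": 100, "a": a,
                      "has_ptm": False}] * without
        return pd.DataFrame(rows)

    def test_identical_proportions_give_zero(self):
        df = self.make_table({a: (10, 30) for a in (6, 7, 8, 14, 15, 16)})
        report = ptm_abundance_test(df)
        assert report.chi2 == pytest.approx(0.0, abs=1e-12)
        assert report.p == pytest.approx(1.0)
        assert report.df == 5

    def test_two_group_statistic_matches_hand_pearson(self):
        df = self.make_table({6: (10, 90), 14: (50, 50)})
        report = ptm_abundance_test(df, low_bin=(6,), high_bin=(14,))
        oracle = self.pearson_chi2([[10, 90], [50, 50]])
        assert oracle == pytest.approx(38.0952, abs=1e-3)
        assert report.chi2 == pytest.approx(oracle)
        assert report.df == 1

    def test_statistic_grows_with_sample_size(self):
        base = {6: (30, 70), 7: (28, 72), 8: (26, 74),
                14: (10, 90), 15: (9, 91), 16: (8, 92)}
        small = ptm_abundance_test(self.make_table(base))
        big = ptm_abundance_test(
            self.make_table({a: (w * 4, wo * 4) for a, (w, wo) in base.items()})
        )
        assert big.chi2 > small.chi2
        assert big.chi2 == pytest.approx(4 * small.chi2, rel=1e-6)

    def test_empty_group_errors(self):
        df = self.make_table({6: (1, 1), 14: (1, 1)})
        with pytest.raises(ValueError):
            ptm_abundance_test(df)  # groups 7, 8, 15, 16 empty


class TestDomainAverages:
    def test_constant_length_domain_recovers_length_exactly(self):
        df = constant_length_table(length=295)
        fits = domain_average_lengths(df)
        assert fits["bacteria"].slope == pytest.approx(295)

    def test_generated_domain_mean_recovered(self, small_corpus):
        _, _, truth = small_corpus
        dom = truth["domain"].value_counts().idxmax()
        fits = domain_average_lengths(truth, length_cutoff=2000, domains=[dom])
        sub = truth[(truth["domain"] == dom) & (truth["t"] <= 2000)]
        assert fits[dom].slope == pytest.approx(sub["t"].mean(), rel=0.1)

    def test_underpopulated_domain_skipped_when_auto(self, small_corpus):
        _, _, truth = small_corpus
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            fits = domain_average_lengths(truth, length_cutoff=2000)
        assert truth["domain"].value_counts().idxmax() in fits

    def test_single_species_domain_errors_when_requested(self):
        df = constant_length_table(n_species=1)
        with pytest.raises(ValueError):
            domain_average_lengths(df, domains=["bacteria"])


class TestP3:
    def test_exact_power_law_counts(self):
        xs = np.arange(300, 1000, 50)
        from coiprot import fit_loglog_tail

        fit = fit_loglog_tail([(int(x), 1e6 * x**-2.0) for x in xs], (300, 10_000))
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)

    def test_too_few_distinct_lengths_errors(self):
        with pytest.raises(ValueError):
            test_p3([(400, 10)] * 100)
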