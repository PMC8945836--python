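import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bulkmap import genecand
from bulkmap.finemap import MarkerPanel
from bulkmap.simpop import (
    BulkSpec,
    F2Individual,
    GeneticMap,
    PhenoModel,
    build_bulks,
    gene_table_frames,
    make_finemap_fixture,
    make_gene_table_fixture,
    pool_sites,
    sample_pool_depths,
    simulate_f2,
    simulate_gametes,
)

from conftest import N_FINEMAP_INDIVIDUALS, RECOMBINANT_COUNTS


class TestGeneticMap:
    def test_rejects_unsorted_bp(self):
        with pytest.raises(ValueError):
            GeneticMap("c", ((100, 0.0), (50, 1.0)))

    def test_rejects_unsorted_cm(self):
        with pytest.raises(ValueError):
            GeneticMap("c", ((100, 1.0), (200, 0.5)))

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            GeneticMap("c", ())

    def test_uniform_spacing(self):
        m = GeneticMap.uniform("c", 100_000, 10_000, 2.0)
        assert len(m) == 10
        assert m.positions_bp[0] == 10_000
        assert m.positions_cm[-1] == pytest.approx(0.2)

    def test_interp_off_map(self):
        m = GeneticMap.uniform("c", 100_000, 10_000, 2.0)
        with pytest.raises(ValueError, match="off map"):
            m.interp_cm(500_000)


class TestPhenoModel:
    def test_default_means_respect_thresholds(self):
        m = PhenoModel()
        assert m.mu_mut < 10 < m.mu_het < 20 < m.mu_wt

    def test_rejects_bad_ordering(self):
        with pytest.raises(ValueError):
            PhenoModel(mu_wt=18.0)


class TestSimulateF2:
    def test_n_zero_empty(self):
        m = GeneticMap.uniform("c", 1_000_000, 10_000, 2.0)
        assert simulate_f2(0, m, 500_000, PhenoModel(), 1) == []

    def test_causal_off_map(self):
        m = GeneticMap.uniform("c", 1_000_000, 10_000, 2.0)
        with pytest.raises(ValueError, match="off map"):
            simulate_f2(10, m, 5_000_000, PhenoModel(), 1)

    def test_mendelian_ratio_at_causal(self):
        # F2 genotypes segregate 1:2:1; chi-square must accept at alpha=0.01
        m = GeneticMap.uniform("c", 1_000_000, 10_000, 2.0)
        causal = 500_000
        pop = simulate_f2(4000, m, causal, PhenoModel(sigma=0.0), 7)
        idx = int(np.searchsorted(m.positions_bp, causal))
        doses = np.array([p.dosage[idx] for p in pop])
        obs = np.bincount(doses, minlength=3)
        chi2, p = stats.chisquare(obs, f_exp=[1000, 2000, 1000])
        assert p > 0.01

    def test_haldane_recombinant_fraction_10cm(self):
        # closed form: r = (1 - exp(-2 * 0.1)) / 2 = 0.09063
        r_expected = (1.0 - math.exp(-0.2)) / 2.0
        g = simulate_gametes([0.0, 10.0], 5000, seed=3)
        r_obs = float(np.mean(g[:, 0] != g[:, 1]))
        se = math.sqrt(r_expected * (1 - r_expected) / 5000)
        assert abs(r_obs - r_expected) < 3 * se

    def test_adjacent_locus_correlation(self):
        # 0.01 cM apart: essentially always co-inherited
        g = simulate_gametes([0.0, 0.01], 2000, seed=5)
        assert np.mean(g[:, 0] != g[:, 1]) < 0.01

    def test_reproducible_under_seed(self):
        m = GeneticMap.uniform("c", 1_000_000, 50_000, 2.0)
        a = simulate_f2(50, m, 500_000, PhenoModel(), 42)
        b = simulate_f2(50, m, 500_000, PhenoModel(), 42)
        assert all(
            np.array_equal(x.dosage, y.dosage) and x.spad == y.spad
            for x, y in zip(a, b)
        )

    def test_pheno_class_consistent_with_spad(self):
        m = GeneticMap.uniform("c", 1_000_000, 50_000, 2.0)
        pop = simulate_f2(200, m, 500_000, PhenoModel(sigma=4.0), 9)
        from bulkmap.finemap import classify_spad

        for p in pop:
            assert p.pheno_class == classify_spad(p.spad)
            assert p.spad >= 0

    def test_causal_between_panel_loci(self):
        # off-grid causal position is interpolated, panel width unchanged
        m = GeneticMap.uniform("c", 1_000_000, 50_000, 2.0)
        pop = simulate_f2(20, m, 123_456, PhenoModel(), 2)
        assert all(p.dosage.size == len(m) for p in pop)


class TestBuildBulks:
    def _pop(self, n_wt, n_het, n_mut):
        pop = []
        specs = [("WT", 30.0, n_wt), ("HET", 15.0, n_het), ("MUT", 5.0, n_mut)]
        i = 0
        for cls, spad, count in specs:
            for _ in range(count):
                pop.append(
                    F2Individual(f"i{i}", np.zeros(3, dtype=np.int8), spad, cls)
                )
                i += 1
        return pop

    def test_exact_classes_forced(self):
        pop = self._pop(25, 10, 25)
        g, y = build_bulks(pop, BulkSpec(), 1)
        assert sorted(g) == sorted(p.id for p in pop if p.pheno_class == "WT")
        assert sorted(y) == sorted(p.id for p in pop if p.pheno_class == "MUT")
        assert not set(g) & set(y)

    def test_error_names_deficient_class(self):
        with pytest.raises(ValueError, match="MUT"):
            build_bulks(self._pop(30, 10, 3), BulkSpec(), 1)

    def test_determinism_contract(self):
        pop = self._pop(40, 10, 40)
        assert build_bulks(pop, BulkSpec(), 5) == build_bulks(pop, BulkSpec(), 5)

    def test_heterozygotes_excluded(self):
        pop = self._pop(30, 50, 30)
        g, y = build_bulks(pop, BulkSpec(), 2)
        hets = {p.id for p in pop if p.pheno_class == "HET"}
        assert not hets & (set(g) | set(y))


class TestSamplePoolDepths:
    def test_fixation_gives_all_alt(self):
        m = GeneticMap.uniform("c", 100_000, 10_000, 1.0)
        pop = [
            F2Individual(f"i{k}", np.full(len(m), 2, dtype=np.int8), 5.0, "MUT")
            for k in range(25)
        ]
        counts = sample_pool_depths(
            [p.id for p in pop], pop, m, m.positions_bp, 40.0, 3
        )
        assert np.all(counts[:, 0] == 0)  # ref depth 0 everywhere (p=1)

    def test_empty_bulk_errors(self):
        m = GeneticMap.uniform("c", 100_000, 10_000, 1.0)
        with pytest.raises(ValueError, match="empty bulk"):
            sample_pool_depths([], [], m, m.positions_bp, 40.0, 1)

    def test_unselected_bulk_mean_index_half(self):
        # 2000 unlinked sites, random bulk: E[SNP-index] = 0.5
        m = GeneticMap.uniform("c", 20_000_000, 10_000, 50.0)
        pop = simulate_f2(60, m, 10_000_000, PhenoModel(), 21)
        ids = [p.id for p in pop[:25]]  # arbitrary, not phenotype-selected
        counts = sample_pool_depths(ids, pop, m, m.positions_bp, 40.0, 22)
        idx = counts[:, 1] / counts.sum(axis=1)
        se = idx.std(ddof=1) / math.sqrt(idx.size)
        assert abs(idx.mean() - 0.5) < 3 * se

    def test_non_locus_site_rejected(self):
        m = GeneticMap.uniform("c", 100_000, 10_000, 1.0)
        pop = [F2Individual("a", np.zeros(len(m), dtype=np.int8), 30.0, "WT")]
        with pytest.raises(ValueError, match="not a map locus"):
            sample_pool_depths(["a"], pop, m, [12_345], 40.0, 1)


class TestSelectedBulkIndexes:
    """With near-perfect phenotyping the Y pool fixes the mutant allele at
    the causal site and the G pool fixes the wild-type allele."""

    def test_causal_site_indexes(self):
        m = GeneticMap.uniform("c", 10_000_000, 100_000, 20.0)
        causal = 5_000_000
        pop = simulate_f2(600, m, causal, PhenoModel(sigma=0.01), 31)
        g_ids, y_ids = build_bulks(pop, BulkSpec(), 32)
        gc = sample_pool_depths(g_ids, pop, m, [causal], 40.0, 33)
        yc = sample_pool_depths(y_ids, pop, m, [causal], 34.0, 34)
        assert yc[0, 0] == 0  # Y pool: SNP-index exactly 1
        assert gc[0, 1] == 0  # G pool: SNP-index exactly 0

    def test_off_causal_delta_mean_zero(self):
        # genome-wide (unlinked) delta has mean ~ 0 over >= 2000 sites
        # 100 cM between adjacent sites so per-site deltas are independent
        m = GeneticMap.uniform("c", 210_000_000, 100_000, 1000.0)
        causal = 105_000_000
        pop = simulate_f2(300, m, causal, PhenoModel(), 41)
        g_ids, y_ids = build_bulks(pop, BulkSpec(), 42)
        bp = m.positions_bp
        far = bp[np.abs(bp - causal) > 1_000_000]
        assert far.size >= 2000
        gc = sample_pool_depths(g_ids, pop, m, far, 40.0, 43)
        yc = sample_pool_depths(y_ids, pop, m, far, 34.0, 44)
        delta = yc[:, 1] / yc.sum(axis=1) - gc[:, 1] / gc.sum(axis=1)
        se = delta.std(ddof=1) / math.sqrt(delta.size)
        assert abs(delta.mean()) < 3 * se


class TestPoolSites:
    def test_roundtrip_shapes(self):
        m = GeneticMap.uniform("c", 100_000, 10_000, 1.0)
        g = np.tile([10, 5], (len(m), 1))
        y = np.tile([0, 20], (len(m), 1))
        sites = pool_sites(m, g, y)
        assert len(sites) == len(m)
        assert sites[0].g_ref == 10 and sites[0].y_alt == 20


class TestFinemapFixture:
    def test_paper_counts_roundtrip(self, paper_panel, finemap_fixture):
        from bulkmap.finemap import recombinants_at

        genotypes, phenos = finemap_fixture
        phen = phenos["class"].to_dict()
        for marker, expected in RECOMBINANT_COUNTS.items():
            assert len(recombinants_at(marker, genotypes, phen)) == expected
        assert len(genotypes) == N_FINEMAP_INDIVIDUALS

    def test_all_zero_counts_all_b(self, paper_panel):
        counts = {m: 0 for m in paper_panel.names}
        genotypes, _ = make_finemap_fixture(counts, 10, paper_panel, 1)
        assert (genotypes.values == "B").all()

    def test_increasing_profile_rejected(self):
        panel = MarkerPanel(("M1", "M2", "M3"), "c", (100, 200, 300))
        with pytest.raises(ValueError, match="not realizable"):
            make_finemap_fixture({"M1": 1, "M2": 2, "M3": 0}, 50, panel, 1)

    def test_no_zero_marker_rejected(self):
        panel = MarkerPanel(("M1", "M2"), "c", (100, 200))
        with pytest.raises(ValueError, match="not realizable"):
            make_finemap_fixture({"M1": 2, "M2": 1}, 50, panel, 1)

    def test_deterministic(self, paper_panel):
        a = make_finemap_fixture(RECOMBINANT_COUNTS, 100, paper_panel, 9)
        b = make_finemap_fixture(RECOMBINANT_COUNTS, 100, paper_panel, 9)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_all_individuals_mut_class(self, finemap_fixture):
        _, phenos = finemap_fixture
        assert (phenos["class"] == "MUT").all()
        assert (phenos["spad"] < 10).all()

    def test_single_breakpoint_structure(self, finemap_fixture):
        # each recombinant's non-B calls form one run anchored at an end
        genotypes, _ = finemap_fixture
        for _, row in genotypes.iterrows():
            calls = row.to_numpy()
            nb = calls != "B"
            if not nb.any():
                continue
            runs = np.flatnonzero(np.diff(nb.astype(int)) != 0)
            assert runs.size == 1
            assert nb[0] or nb[-1]


class TestGeneTableFixture:
    def test_effect_type_counts(self):
        _, effects = make_gene_table_fixture(3)
        kinds = pd.Series([e.effect for e in effects]).value_counts()
        assert kinds["frameshift"] == 2
        assert kinds["nonsynonymous"] == 3
        assert kinds["synonymous"] == 10

    def test_gene_totals(self):
        genes, effects = make_gene_table_fixture(3)
        assert len(genes) == 56
        assert len({e.gene for e in effects}) == 15
        unexpressed = [
            g for g in genes if not (g.expressed_wt or g.expressed_mut)
        ]
        assert len(unexpressed) == 2

    def test_triage_yields_single_candidate(self):
        genes, effects = make_gene_table_fixture(5)
        result = genecand.triage(genes, effects)
        assert len(result.candidates) == 1
        [cand] = result.candidates
        by_id = {g.id: g for g in genes}
        assert by_id[cand].annotation == "candidate"

    def test_byte_identical_tables(self):
        a_genes, a_eff = gene_table_frames(7)
        b_genes, b_eff = gene_table_frames(7)
        assert a_genes.to_csv() == b_genes.to_csv()
        assert a_eff.to_csv() == b_eff.to_csv()
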