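"""Simulator checks against closed-form genetic expectations."""

import numpy as np
import pytest

import hapcross as hc
from hapcross.simulate import (
    ELITE1,
    ELITE2,
    EXOTIC,
    ConfigError,
    _Genome,
    _MapLayout,
    build_map,
    meiosis,
)


def small_config(**kw):
    base = dict(n_chromosomes=3, n_markers_per_chromosome=50,
                n_elite_founders=6, n_exotic_founders=4,
                n_crosses=4, n_lines_per_cross=25)
    base.update(kw)
    return hc.SimConfig(**base)


class TestFounders:
    def test_zero_elite_divergence_gives_identical_elites(self):
        G = hc.simulate_founders(small_config(elite_divergence=0.0), seed=3)
        elites = [i for i, l in enumerate(G.line_ids) if l.startswith("EL")]
        ref = G.calls[elites[0]]
        for i in elites[1:]:
            np.testing.assert_array_equal(G.calls[i], ref)

    def test_elite_exotic_difference_rate_matches_setting(self):
        # near-zero segment scale makes marker flips independent, so the
        # plain binomial SE applies
        cfg = small_config(exotic_divergence=0.5, elite_divergence=0.0,
                           exotic_segment_cm=1e-6,
                           n_markers_per_chromosome=340)
        G = hc.simulate_founders(cfg, seed=5)
        n_mk = G.n_markers
        el = G.calls[G.line_index("EL01")]
        diffs = [
            (G.calls[G.line_index(l)] != el).mean()
            for l in G.line_ids if l.startswith("EX")
        ]
        se = np.sqrt(0.5 * 0.5 / n_mk)
        assert abs(np.mean(diffs) - 0.5) < 3 * se

    def test_same_seed_reproduces_bit_identical_panel(self):
        cfg = small_config()
        a = hc.simulate_founders(cfg, seed=11)
        b = hc.simulate_founders(cfg, seed=11)
        np.testing.assert_array_equal(a.calls, b.calls)
        assert a.alleles == b.alleles

    def test_founders_fully_homozygous(self):
        G = hc.simulate_founders(small_config(), seed=1)
        assert set(np.unique(G.calls)) <= {0, 2}

    def test_zero_markers_rejected(self):
        with pytest.raises(ConfigError):
            small_config(n_markers_per_chromosome=0)


class TestMeiosis:
    def _layout(self, cfg):
        gmap = build_map(cfg)
        markers = [m for c in gmap.chromosomes() for m in gmap.markers_on(c)]
        return gmap, _MapLayout(gmap, markers)

    def test_crossover_count_matches_poisson_mean(self):
        cfg = small_config(n_chromosomes=1, chromosome_length_cm=100.0,
                           n_markers_per_chromosome=101)
        _, layout = self._layout(cfg)
        n_mk = cfg.n_markers
        genome = _Genome(
            alleles=np.vstack([np.zeros(n_mk, np.int8), np.ones(n_mk, np.int8)]),
            ancestry=np.vstack([np.full(n_mk, EXOTIC, np.int8),
                                np.full(n_mk, ELITE1, np.int8)]))
        rng = np.random.default_rng(0)
        n_rep = 10_000
        switches = 0
        for _ in range(n_rep):
            _, anc = meiosis(genome, layout, rng)
            switches += int(np.sum(anc[1:] != anc[:-1]))
        # observable switches undercount crossovers slightly (double
        # crossovers between adjacent markers cancel); at 1 cM spacing the
        # loss is ~0.5% and well inside 3 SE of the Poisson mean 1.0
        mean = switches / n_rep
        se = np.sqrt(1.0 / n_rep)
        assert abs(mean - 1.0) < 3 * se + 0.02

    def test_zero_length_chromosome_never_recombines(self):
        cfg = small_config(n_chromosomes=1, chromosome_length_cm=1e-9,
                           n_markers_per_chromosome=1)
        # single-marker chromosome: span 0 => no crossover possible
        _, layout = self._layout(cfg)
        genome = _Genome(
            alleles=np.array([[0], [1]], np.int8),
            ancestry=np.array([[EXOTIC], [ELITE1]], np.int8))
        rng = np.random.default_rng(1)
        origins = {meiosis(genome, layout, rng)[1][0] for _ in range(50)}
        assert origins <= {EXOTIC, ELITE1}

    def test_homozygous_genome_gamete_equals_either_chromatid(self):
        cfg = small_config(n_chromosomes=2)
        _, layout = self._layout(cfg)
        hap = np.random.default_rng(2).integers(0, 2, cfg.n_markers,
                                                dtype=np.int8)
        genome = _Genome(alleles=np.vstack([hap, hap]),
                         ancestry=np.full((2, cfg.n_markers), ELITE2, np.int8))
        rng = np.random.default_rng(3)
        for _ in range(5):
            g, _ = meiosis(genome, layout, rng)
            np.testing.assert_array_equal(g, hap)


@pytest.fixture(scope="module")
def population():
    cfg = small_config()
    founders = hc.simulate_founders(cfg, seed=7)
    crosses = hc.make_default_crosses(cfg)
    return cfg, founders, *hc.simulate_topcross_population(
        founders, cfg, crosses, seed=7)


@pytest.fixture(scope="module")
def pheno_lines():
    cfg = small_config()
    founders = hc.simulate_founders(cfg, seed=13)
    return hc.simulate_topcross_population(
        founders, cfg, hc.make_default_crosses(cfg), seed=13)[0]


@pytest.fixture(scope="module")
def selection_study():
    cfg = small_config()
    founders = hc.simulate_founders(cfg, seed=17)
    G, truth, reg = hc.simulate_topcross_population(
        founders, cfg, hc.make_default_crosses(cfg), seed=17)
    return cfg, founders, G, truth, reg


class TestTopcrossPopulation:

    def test_exotic_truth_fraction_near_one_quarter(self, population):
        cfg, founders, G, truth, reg = population
        frac = truth.exotic_fraction_per_line()
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.25) < 3 * se

    def test_het_rate_at_informative_loci_matches_closed_form(self, population):
        cfg, founders, G, truth, reg = population
        # loci where exotic != elite1 = elite2, per cross
        rates = []
        for cid, (ex, e1, e2) in reg.crosses.items():
            hex_ = founders.calls[founders.line_index(ex)]
            he1 = founders.calls[founders.line_index(e1)]
            he2 = founders.calls[founders.line_index(e2)]
            informative = (he1 == he2) & (hex_ != he1)
            lines = [i for i, l in enumerate(G.line_ids)
                     if reg.membership[l] == cid]
            calls = G.calls[np.ix_(lines, np.flatnonzero(informative))]
            rates.append((calls == 1).mean())
        expected = 0.5 * 0.5 ** cfg.selfing_generations
        mean = np.mean(rates)
        se = np.sqrt(expected * (1 - expected) /
                     (len(rates) * 25 * 50))  # crude binomial SE
        assert abs(mean - expected) < 3 * se + 0.005

    def test_deep_selfing_drives_heterozygosity_to_zero(self):
        cfg = small_config(selfing_generations=20, n_crosses=2,
                           n_lines_per_cross=10)
        founders = hc.simulate_founders(cfg, seed=9)
        G, _, _ = hc.simulate_topcross_population(
            founders, cfg, hc.make_default_crosses(cfg), seed=9)
        assert G.het_rate() < 1e-3

    def test_truth_paint_rederives_calls_from_founders(self, population):
        """Ancestry conservation: calls = founder alleles at truth origins."""
        cfg, founders, G, truth, reg = population
        hap = (founders.calls == 2).astype(np.int8)
        for i, line in enumerate(G.line_ids):
            ex, e1, e2 = reg.parents_of(line)
            stack = np.vstack([hap[founders.line_index(p)]
                               for p in (ex, e1, e2)])
            cols = np.arange(G.n_markers)
            derived = (stack[truth.origins[i, 0], cols]
                       + stack[truth.origins[i, 1], cols])
            np.testing.assert_array_equal(G.calls[i], derived)

    def test_unknown_parent_id_rejected(self):
        cfg = small_config()
        founders = hc.simulate_founders(cfg, seed=1)
        reg = hc.CrossRegistry({"C1": ("NOPE", "EL01", "EL02")}, {})
        with pytest.raises(KeyError, match="NOPE"):
            hc.simulate_topcross_population(founders, cfg, reg, seed=1)

    def test_distinct_seeds_differ(self):
        cfg = small_config(n_crosses=1, n_lines_per_cross=5)
        founders = hc.simulate_founders(cfg, seed=1)
        crosses = hc.make_default_crosses(cfg)
        G1, _, _ = hc.simulate_topcross_population(founders, cfg, crosses, 1)
        G2, _, _ = hc.simulate_topcross_population(founders, cfg, crosses, 2)
        assert (G1.calls != G2.calls).any()


class TestPhenotypes:

    def test_zero_variance_no_qtl_gives_environment_means(self, pheno_lines):
        spec = hc.QTLSpec(environment_means={"heat": 42.0}, residual_var=0.0)
        tab = hc.simulate_phenotypes(pheno_lines, spec, seed=1)
        assert np.allclose(tab.records["value"], 42.0)

    def test_environment_specific_qtl_effect(self, pheno_lines):
        m = pheno_lines.marker_ids[5]
        j = pheno_lines.marker_index(m)
        target = pheno_lines.alleles[j][1]  # dosage-2 allele
        carriers = pheno_lines.calls[:, j] == 2
        assert carriers.any() and (~carriers).any()
        spec = hc.QTLSpec(
            qtls=(hc.QTL((m,), target, effect=500.0,
                         environments=("heat",)),),
            environment_means={"heat": 0.0, "irrigated": 0.0},
            residual_var=100.0)
        tab = hc.simulate_phenotypes(pheno_lines, spec, seed=2)
        for env, expect in (("heat", 500.0), ("irrigated", 0.0)):
            v = tab.vector("grain_yield", env)
            diff = (v[np.array(pheno_lines.line_ids)[carriers]].mean()
                    - v[np.array(pheno_lines.line_ids)[~carriers]].mean())
            assert diff == pytest.approx(expect, abs=3 * 10 / np.sqrt(20) * 3)

    def test_residual_variance_scales(self, pheno_lines):
        spec1 = hc.QTLSpec(environment_means={"heat": 0.0}, residual_var=1.0)
        spec2 = hc.QTLSpec(environment_means={"heat": 0.0}, residual_var=2.0)
        v1 = hc.simulate_phenotypes(pheno_lines, spec1, seed=3).records["value"].var()
        v2 = hc.simulate_phenotypes(pheno_lines, spec2, seed=3).records["value"].var()
        assert v2 / v1 == pytest.approx(2.0, rel=0.35)

    def test_qtl_on_absent_marker_rejected(self, pheno_lines):
        spec = hc.QTLSpec(qtls=(hc.QTL(("nope",), "A", 1.0, ("heat",)),))
        with pytest.raises(KeyError):
            hc.simulate_phenotypes(pheno_lines, spec, seed=1)


class TestSelection:

    def test_fraction_one_is_identity(self, selection_study):
        cfg, founders, G, truth, reg = selection_study
        spec = hc.QTLSpec(environment_means={"heat": 0.0}, residual_var=1.0)
        tab = hc.simulate_phenotypes(G, spec, seed=1)
        G2, t2, r2 = hc.apply_selection(G, truth, reg, tab, "grain_yield", 1.0)
        assert G2.line_ids == G.line_ids
        np.testing.assert_array_equal(t2.origins, truth.origins)

    def test_exact_retained_count(self, selection_study):
        cfg, founders, G, truth, reg = selection_study
        spec = hc.QTLSpec(environment_means={"heat": 0.0}, residual_var=1.0)
        tab = hc.simulate_phenotypes(G, spec, seed=2)
        G2, _, _ = hc.apply_selection(G, truth, reg, tab, "grain_yield", 0.5)
        assert G2.n_lines == G.n_lines // 2

    def test_invalid_fraction_rejected(self, selection_study):
        cfg, founders, G, truth, reg = selection_study
        spec = hc.QTLSpec(environment_means={"heat": 0.0}, residual_var=1.0)
        tab = hc.simulate_phenotypes(G, spec, seed=3)
        for frac in (0.0, 1.5):
            with pytest.raises(ValueError):
                hc.apply_selection(G, truth, reg, tab, "grain_yield", frac)

    def test_selection_for_elite_trait_reduces_exotic_fraction(self, selection_study):
        """Truncation selection on an elite-advantage trait pulls the
        retained panel's exotic genome below the Mendelian 25%."""
        cfg, founders, G, truth, reg = selection_study
        spec = hc.QTLSpec(
            qtls=tuple(_elite_qtls(founders, G, n=3)),
            environment_means={"heat": 0.0},
            residual_var=0.25)
        tab = hc.simulate_phenotypes(G, spec, seed=4)
        base = truth.exotic_fraction_per_line().mean()
        _, t2, _ = hc.apply_selection(G, truth, reg, tab, "grain_yield", 0.3)
        assert t2.exotic_fraction_per_line().mean() < base


def _elite_qtls(founders, G, n=3, effect=1.0):
    """QTLs whose favorable class is the elite-consensus allele string."""
    elites = [i for i, l in enumerate(founders.line_ids)
              if l.startswith("EL")]
    per_chrom = len(founders.marker_ids) // n
    qtls = []
    for k in range(n):
        j = k * per_chrom + per_chrom // 2
        col = founders.calls[elites, j]
        major = 0 if (col == 0).sum() >= (col == 2).sum() else 2
        allele = founders.alleles[j][major // 2]
        qtls.append(hc.QTL((founders.marker_ids[j],), allele, effect,
                           ("heat",)))
    return qtls
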