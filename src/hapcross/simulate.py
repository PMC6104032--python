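"""Forward simulation of the three-way topcross breeding scheme.

The scheme emulated: an exotic gene-bank accession is crossed to an elite
line (F1), the F1 is topcrossed to a second elite, and the topcross progeny
are advanced by single-seed descent for ``selfing_generations`` selfings
(default 4, i.e. TC1F1 -> TC1F5).  Each derived inbred line therefore carries
an expected 25% exotic genome, and at loci where the exotic allele differs
from the (identical) elite alleles the expected heterozygote rate after g
selfings is 0.5 * (1/2)**g.

Every simulated line carries per-chromatid ancestry truth (exotic / elite1 /
elite2 at every marker), so the downstream origin-tracing, block-detection
and association stages can all be checked against a known answer.

Meiosis uses the Haldane model: crossover counts are Poisson with mean
length/100 (cM -> Morgans), positions uniform on the cM axis, no
interference.  Founders are fully inbred; residual parent heterozygosity can
be injected with ``parent_het_rate`` to exercise the unidentified-origin
classification path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import (
    MISSING,
    CrossRegistry,
    GeneticMap,
    GenotypeMatrix,
    TraitTable,
)

# ancestry codes
EXOTIC, ELITE1, ELITE2 = 0, 1, 2
ORIGIN_LABELS = {EXOTIC: "X", ELITE1: "E1", ELITE2: "E2"}

_NUCS = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated topcross programme.

    Defaults mirror the emulated programme at desk scale: 21 wheat
    chromosomes, a 25-line elite pool with long shared haplotypes (low
    pairwise divergence) against a diverse exotic pool, topcross progeny
    selfed four generations to TC1F5.
    """

    n_chromosomes: int = 21
    chromosome_length_cm: float = 150.0
    n_markers_per_chromosome: int = 100
    n_elite_founders: int = 25
    n_exotic_founders: int = 10
    #: probability that two elite founders differ at a marker
    elite_divergence: float = 0.05
    #: probability that an exotic differs from the elite pool consensus
    exotic_divergence: float = 0.35
    #: haplotype segment scale (cM) of deviations from the pool consensus;
    #: long for elites (recent shared breeding ancestry), short for exotics
    #: (diverse landraces with short-range LD)
    elite_segment_cm: float = 30.0
    exotic_segment_cm: float = 3.0
    selfing_generations: int = 4
    n_lines_per_cross: int = 30
    n_crosses: int = 10
    missing_rate: float = 0.0
    parent_het_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.n_chromosomes <= 21:
            raise ConfigError("n_chromosomes must be in 1..21")
        if self.chromosome_length_cm <= 0:
            raise ConfigError("chromosome lengths must be > 0")
        if self.n_markers_per_chromosome < 1:
            raise ConfigError("need at least one marker per chromosome")
        if self.elite_segment_cm <= 0 or self.exotic_segment_cm <= 0:
            raise ConfigError("founder segment scales must be > 0")
        for name in ("elite_divergence", "exotic_divergence",
                     "missing_rate", "parent_het_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.selfing_generations < 0:
            raise ConfigError("selfing_generations must be >= 0")

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.n_markers_per_chromosome


@dataclass(frozen=True)
class QTL:
    """One planted causal haplotype: effect applies to homozygous carriers
    of ``class_string`` at ``markers``, in the listed environments only."""

    markers: tuple[str, ...]
    class_string: str
    effect: float
    environments: tuple[str, ...]


@dataclass(frozen=True)
class QTLSpec:
    trait: str = "grain_yield"
    qtls: tuple[QTL, ...] = ()
    environment_means: dict = field(default_factory=lambda: {
        "heat": 3500.0, "drought": 2500.0, "irrigated": 6000.0})
    polygenic_var: float = 0.0
    residual_var: float = 1.0

    def __post_init__(self) -> None:
        if self.polygenic_var < 0 or self.residual_var < 0:
            raise ConfigError("variances must be >= 0")
        for q in self.qtls:
            for env in q.environments:
                if env not in self.environment_means:
                    raise ConfigError(
                        f"QTL active in unknown environment {env!r}")


@dataclass
class AncestryTruth:
    """Per-line, per-chromatid, per-marker parental origin codes."""

    line_ids: list[str]
    marker_ids: list[str]
    origins: np.ndarray  # (n_lines, 2, n_markers) int8, codes EXOTIC/ELITE1/ELITE2

    def exotic_dosage(self) -> np.ndarray:
        """Per (line, marker): number of exotic chromatids (0, 1 or 2)."""
        return (self.origins == EXOTIC).sum(axis=1).astype(np.int8)

    def exotic_fraction_per_line(self) -> np.ndarray:
        return (self.origins == EXOTIC).mean(axis=(1, 2))

    def elite_fraction_per_line(self) -> np.ndarray:
        return (self.origins != EXOTIC).mean(axis=(1, 2))

    def subset(self, lines: Sequence[str]) -> "AncestryTruth":
        idx = {l: i for i, l in enumerate(self.line_ids)}
        sel = [idx[l] for l in lines]
        return AncestryTruth(list(lines), list(self.marker_ids),
                             self.origins[sel].copy())

    def to_frame(self):
        """Two-row-per-line chromatid origin table with X/E1/E2 codes."""
        import pandas as pd

        rows, index = [], []
        for i, line in enumerate(self.line_ids):
            for c in (0, 1):
                rows.append([ORIGIN_LABELS[o] for o in self.origins[i, c]])
                index.append((line, c))
        return pd.DataFrame(
            rows,
            index=pd.MultiIndex.from_tuples(index, names=["line_id", "chromatid"]),
            columns=self.marker_ids,
        )


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Child generator for a named stream; adding lines or crosses never
    perturbs the draws of existing ones."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + stream))


def build_map(config: SimConfig) -> GeneticMap:
    """Evenly spaced marker grid over the configured chromosomes."""
    from .datatypes import CHROMOSOMES

    entries: dict[str, tuple[str, float]] = {}
    n = config.n_markers_per_chromosome
    for ci in range(config.n_chromosomes):
        chrom = CHROMOSOMES[ci]
        if n == 1:
            positions = np.array([0.0])
        else:
            positions = np.linspace(0.0, config.chromosome_length_cm, n)
        for j, cm in enumerate(positions):
            entries[f"S{ci + 1:02d}_{j + 1:04d}"] = (chrom, float(cm))
    return GeneticMap(entries)


def _marker_ids(config: SimConfig, gmap: GeneticMap) -> list[str]:
    return [m for chrom in gmap.chromosomes() for m in gmap.markers_on(chrom)]


def _segment_flip_mask(cm_by_chrom: list[np.ndarray], p: float,
                       segment_cm: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Marker flip mask from a two-state jump process along the map.

    The flip state resamples (to Bernoulli(p)) at exponential(segment_cm)
    distances, so the marginal flip probability at every marker is exactly
    ``p`` while nearby markers share segments — founders deviate from the
    pool consensus in contiguous haplotype tracts rather than at
    independent sites.
    """
    parts = []
    for cm in cm_by_chrom:
        state = rng.random() < p
        out = np.empty(len(cm), dtype=bool)
        out[0] = state
        if len(cm) > 1:
            d = np.diff(cm)
            resample = rng.random(len(d)) < 1.0 - np.exp(-d / segment_cm)
            new_states = rng.random(len(d)) < p
            for k in range(len(d)):
                if resample[k]:
                    state = new_states[k]
                out[k + 1] = state
        parts.append(out)
    return np.concatenate(parts)


def simulate_founders(config: SimConfig, seed: int) -> GenotypeMatrix:
    """Fully homozygous founder panel (elite pool + exotic accessions).

    Each founder haplotype deviates from an elite-pool consensus in
    contiguous segments (scale ``elite_segment_cm`` / ``exotic_segment_cm``).
    The per-marker flip probability p_e of elites is chosen so that the
    expected pairwise elite-elite difference rate equals
    ``elite_divergence`` (2*p_e*(1-p_e) = d); exotics flip with probability
    ``exotic_divergence`` directly, so the expected elite-exotic difference
    rate equals that setting.
    """
    if config.n_markers == 0:
        raise ConfigError("zero markers configured")
    rng = _rng(seed, 0)
    n_mk = config.n_markers
    d_e = config.elite_divergence
    if d_e > 0.5:
        raise ConfigError("elite_divergence > 0.5 is not realizable pairwise")
    p_e = 0.5 * (1.0 - np.sqrt(1.0 - 2.0 * d_e))
    gmap0 = build_map(config)
    cm_by_chrom = [np.array([gmap0.position(m) for m in gmap0.markers_on(c)])
                   for c in gmap0.chromosomes()]
    consensus = rng.integers(0, 2, size=n_mk, dtype=np.int8)
    haps: list[np.ndarray] = []
    ids: list[str] = []
    for i in range(config.n_elite_founders):
        flip = _segment_flip_mask(cm_by_chrom, p_e,
                                  config.elite_segment_cm, rng)
        haps.append(np.where(flip, 1 - consensus, consensus).astype(np.int8))
        ids.append(f"EL{i + 1:02d}")
    for i in range(config.n_exotic_founders):
        flip = _segment_flip_mask(cm_by_chrom, config.exotic_divergence,
                                  config.exotic_segment_cm, rng)
        haps.append(np.where(flip, 1 - consensus, consensus).astype(np.int8))
        ids.append(f"EX{i + 1:02d}")
    calls = (2 * np.vstack(haps)).astype(np.int8)
    if config.parent_het_rate > 0:
        het = rng.random(calls.shape) < config.parent_het_rate
        calls[het] = 1
    gmap = build_map(config)
    marker_ids = _marker_ids(config, gmap)
    allele_rng = _rng(seed, 1)
    alleles = []
    for _ in range(n_mk):
        a, b = allele_rng.choice(4, size=2, replace=False)
        alleles.append((str(_NUCS[a]), str(_NUCS[b])))
    return GenotypeMatrix(ids, marker_ids, calls, alleles)


@dataclass
class _Genome:
    """Diploid genome: two chromatid allele arrays + ancestry-label arrays."""

    alleles: np.ndarray   # (2, n_markers) int8 in {0,1}
    ancestry: np.ndarray  # (2, n_markers) int8 origin codes


class _MapLayout:
    """Per-chromosome slices and cM arrays for fast meioses."""

    def __init__(self, gmap: GeneticMap, marker_ids: Sequence[str]):
        order = {m: j for j, m in enumerate(marker_ids)}
        self.slices: list[tuple[slice, np.ndarray, float]] = []
        for chrom in gmap.chromosomes():
            ms = gmap.markers_on(chrom)
            idx = [order[m] for m in ms if m in order]
            if not idx:
                continue
            if idx != list(range(idx[0], idx[0] + len(idx))):
                raise ValueError("marker ids must be in map order for meiosis")
            cm = np.array([gmap.position(m) for m in ms if m in order])
            length = float(cm[-1] - cm[0]) if len(cm) > 1 else 0.0
            self.slices.append((slice(idx[0], idx[0] + len(idx)), cm, length))


def meiosis(genome: _Genome, layout: _MapLayout,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete (alleles, ancestry) under Haldane crossing over."""
    n = genome.alleles.shape[1]
    out_a = np.empty(n, dtype=np.int8)
    out_o = np.empty(n, dtype=np.int8)
    for sl, cm, length in layout.slices:
        n_co = rng.poisson(length / 100.0) if length > 0 else 0
        start = int(rng.integers(0, 2))
        if n_co == 0:
            chromatid = np.full(len(cm), start, dtype=np.int8)
        else:
            xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_co))
            chromatid = ((start + np.searchsorted(xpos, cm, side="left")) % 2
                         ).astype(np.int8)
        cols = np.arange(sl.start, sl.stop)
        out_a[sl] = genome.alleles[chromatid, cols]
        out_o[sl] = genome.ancestry[chromatid, cols]
    return out_a, out_o


def make_default_crosses(config: SimConfig) -> CrossRegistry:
    """Round-robin cross plan: cross k uses exotic k mod n_exotic and the
    next two elites in rotation; line membership filled by the simulator."""
    crosses = {}
    for k in range(config.n_crosses):
        ex = f"EX{(k % config.n_exotic_founders) + 1:02d}"
        e1 = f"EL{(k % config.n_elite_founders) + 1:02d}"
        e2 = f"EL{((k + 1) % config.n_elite_founders) + 1:02d}"
        crosses[f"C{k + 1:02d}"] = (ex, e1, e2)
    return CrossRegistry(crosses, {})


def simulate_topcross_population(
    founders: GenotypeMatrix,
    config: SimConfig,
    crosses: CrossRegistry,
    seed: int,
) -> tuple[GenotypeMatrix, AncestryTruth, CrossRegistry]:
    """Simulate inbred topcross lines with per-chromatid ancestry truth.

    For each registered cross, ``n_lines_per_cross`` lines are produced:
    F1 = exotic x elite1, topcross individual = F1 gamete x elite2 gamete,
    then ``selfing_generations`` single-seed-descent selfings.
    """
    gmap = build_map(config)
    marker_ids = _marker_ids(config, gmap)
    if founders.marker_ids != marker_ids:
        raise ValueError("founder panel does not match the configured map")
    layout = _MapLayout(gmap, marker_ids)

    def founder_hap(fid: str) -> np.ndarray:
        try:
            i = founders.line_index(fid)
        except KeyError:
            raise KeyError(f"unknown parent id {fid!r}") from None
        calls = founders.calls[i]
        # parent het injections are a reporting artifact; the transmitted
        # haplotype takes the dosage-0 allele at injected sites
        return (calls == 2).astype(np.int8)

    line_ids: list[str] = []
    membership: dict[str, str] = {}
    all_calls: list[np.ndarray] = []
    all_origin: list[np.ndarray] = []
    cross_ids = sorted(crosses.crosses)
    for ci, cid in enumerate(cross_ids):
        ex_id, e1_id, e2_id = crosses.crosses[cid]
        hap_ex, hap_e1, hap_e2 = (founder_hap(f) for f in (ex_id, e1_id, e2_id))
        n_mk = hap_ex.size
        f1 = _Genome(
            alleles=np.vstack([hap_ex, hap_e1]),
            ancestry=np.vstack([
                np.full(n_mk, EXOTIC, np.int8),
                np.full(n_mk, ELITE1, np.int8),
            ]),
        )
        e2_genome = _Genome(
            alleles=np.vstack([hap_e2, hap_e2]),
            ancestry=np.full((2, n_mk), ELITE2, np.int8),
        )
        for li in range(config.n_lines_per_cross):
            rng = _rng(seed, 2, ci, li)
            ga, go = meiosis(f1, layout, rng)
            gb, gbo = meiosis(e2_genome, layout, rng)
            indiv = _Genome(alleles=np.vstack([ga, gb]),
                            ancestry=np.vstack([go, gbo]))
            for _ in range(config.selfing_generations):
                g1 = meiosis(indiv, layout, rng)
                g2 = meiosis(indiv, layout, rng)
                indiv = _Genome(alleles=np.vstack([g1[0], g2[0]]),
                                ancestry=np.vstack([g1[1], g2[1]]))
            lid = f"PBL_{cid}_{li + 1:03d}"
            line_ids.append(lid)
            membership[lid] = cid
            all_calls.append(indiv.alleles.sum(axis=0).astype(np.int8))
            all_origin.append(indiv.ancestry.copy())

    calls = np.vstack([c[None, :] for c in all_calls]).astype(np.int8)
    if config.missing_rate > 0:
        mrng = _rng(seed, 3)
        calls = calls.copy()
        calls[mrng.random(calls.shape) < config.missing_rate] = MISSING
    truth = AncestryTruth(line_ids, marker_ids, np.stack(all_origin))
    registry = CrossRegistry(dict(crosses.crosses), membership)
    G = GenotypeMatrix(line_ids, marker_ids, calls, list(founders.alleles))
    return G, truth, registry


def _carrier_mask(G: GenotypeMatrix, qtl: QTL) -> np.ndarray:
    """Homozygous carriers of the QTL allele string (het/missing excluded)."""
    cols = [G.marker_index(m) for m in qtl.markers]
    if len(qtl.class_string) != len(cols):
        raise ConfigError("QTL class string length != number of QTL markers")
    carrier = np.ones(G.n_lines, dtype=bool)
    for ch, j in zip(qtl.class_string, cols):
        a0, a2 = G.alleles[j]
        if ch == a0:
            carrier &= G.calls[:, j] == 0
        elif ch == a2:
            carrier &= G.calls[:, j] == 2
        else:
            raise ConfigError(
                f"QTL allele {ch!r} not among alleles {a0}/{a2} of marker "
                f"{G.marker_ids[j]}")
    return carrier


def simulate_phenotypes(G: GenotypeMatrix, qtl_spec: QTLSpec,
                        seed: int) -> TraitTable:
    """Multi-environment trait values with planted haplotype QTL.

    value = environment mean + sum of active QTL effects for homozygous
    carriers + polygenic term (marker-effect model, so its covariance is
    proportional to the realized genomic relationship) + N(0, residual_var).
    """
    import pandas as pd

    rng = _rng(seed, 4)
    n = G.n_lines
    poly = np.zeros(n)
    if qtl_spec.polygenic_var > 0:
        obs = G.calls != MISSING
        dose = np.where(obs, G.calls, 0).astype(float)
        freq = dose.sum(axis=0) / np.maximum(1, obs.sum(axis=0))
        Z = np.where(obs, G.calls, freq[None, :]) - freq[None, :]
        beta = rng.normal(size=G.n_markers)
        poly = Z @ beta
        sd = poly.std()
        if sd > 0:
            poly = poly / sd * np.sqrt(qtl_spec.polygenic_var)
    carrier_masks = [_carrier_mask(G, q) for q in qtl_spec.qtls]
    records = []
    for env, mu in qtl_spec.environment_means.items():
        y = np.full(n, float(mu)) + poly
        for q, mask in zip(qtl_spec.qtls, carrier_masks):
            if env in q.environments:
                y = y + q.effect * mask
        y = y + rng.normal(scale=np.sqrt(qtl_spec.residual_var), size=n)
        for lid, val in zip(G.line_ids, y):
            records.append((lid, qtl_spec.trait, env, float(val)))
    return TraitTable(pd.DataFrame(
        records, columns=["line_id", "trait", "environment", "value"]))


@dataclass
class PlantedScenario:
    """A full simulated study with one known rare, favorable exotic haplotype."""

    config: SimConfig
    founders: GenotypeMatrix
    genotypes: GenotypeMatrix
    truth: AncestryTruth
    registry: CrossRegistry
    gmap: GeneticMap
    qtl_spec: QTLSpec
    confounder_spec: QTLSpec
    phenotypes: TraitTable
    planted_markers: tuple[str, ...]
    planted_class: str

    def planted_block_of(self, blocks, min_shared: int = 2):
        """The detected block covering the planted segment: the one sharing
        the most planted markers (at least ``min_shared``), or None."""
        best, best_n = None, 0
        for b in blocks:
            n = len(set(b.markers) & set(self.planted_markers))
            if n > best_n:
                best, best_n = b, n
        return best if best_n >= min_shared else None

    def carrier_lines(self) -> list[str]:
        """Lines homozygous for the planted allele string."""
        mask = _carrier_mask(self.genotypes, self.qtl_spec.qtls[0])
        return [l for l, m in zip(self.genotypes.line_ids, mask) if m]


def planted_scenario(
    seed: int,
    config: SimConfig | None = None,
    effect_sd: float = 1.0,
    n_donor_exotics: int = 5,
    donor_cross_fraction: float = 0.5,
    segment_markers: int = 3,
    residual_var: float = 250_000.0,
    polygenic_var: float = 0.0,
) -> PlantedScenario:
    """Simulate a study carrying one rare exotic-private favorable haplotype.

    A private allele string over ``segment_markers`` consecutive markers on
    chromosome 2 is planted into ``n_donor_exotics`` exotic founders —
    emulating a gene-bank haplotype (e.g. an Ae. tauschii-derived tract)
    shared by several related synthetic-wheat donors but absent from every
    elite line, so the resulting haplotype class is exotic-specific by
    construction.  Donor exotics parent ``donor_cross_fraction`` of the
    crosses; at ~20% expected homozygous transmission this yields a carrier
    frequency of about 10% with the defaults.  Spreading the donors over
    many small families mirrors the real programme's structure (hundreds of
    lines from >100 crosses) and keeps the haplotype from being a proxy for
    a single family.  The haplotype raises grain yield by ``effect_sd``
    residual standard deviations under heat only; days to heading is
    simulated with no QTL at all and serves as the phenology confounder
    scan.
    """
    if config is None:
        config = SimConfig(n_chromosomes=6, n_markers_per_chromosome=200,
                           n_crosses=20, n_lines_per_cross=15)
    founders = simulate_founders(config, seed)
    gmap = build_map(config)
    # segment in the middle of chromosome 2
    chrom = gmap.chromosomes()[min(1, config.n_chromosomes - 1)]
    ms = gmap.markers_on(chrom)
    mid = len(ms) // 2
    planted = tuple(ms[mid:mid + segment_markers])
    cols = [founders.marker_index(m) for m in planted]
    n_donors = min(n_donor_exotics, config.n_exotic_founders)
    donors = [f"EX{i + 1:02d}" for i in range(n_donors)]
    calls = founders.calls.copy()
    for j in cols:
        calls[:, j] = 0
        for d in donors:
            calls[founders.line_index(d), j] = 2
    founders = GenotypeMatrix(founders.line_ids, founders.marker_ids, calls,
                              founders.alleles)
    planted_class = "".join(founders.alleles[j][1] for j in cols)
    # cross plan: donor exotics parent the first donor_cross_fraction of
    # crosses round-robin; the rest rotate over the non-donor exotics
    crosses = {}
    others = [l for l in founders.line_ids
              if l.startswith("EX") and l not in donors] or donors
    n_donor_crosses = int(round(donor_cross_fraction * config.n_crosses))
    for k in range(config.n_crosses):
        if k < n_donor_crosses:
            ex = donors[k % len(donors)]
        else:
            ex = others[k % len(others)]
        e1 = f"EL{(k % config.n_elite_founders) + 1:02d}"
        e2 = f"EL{((k + 1) % config.n_elite_founders) + 1:02d}"
        crosses[f"C{k + 1:02d}"] = (ex, e1, e2)
    registry = CrossRegistry(crosses, {})
    G, truth, registry = simulate_topcross_population(
        founders, config, registry, seed)
    qtl_spec = QTLSpec(
        trait="grain_yield",
        qtls=(QTL(planted, planted_class,
                  effect=effect_sd * float(np.sqrt(residual_var)),
                  environments=("heat",)),),
        environment_means={"heat": 3500.0, "drought": 2500.0,
                           "irrigated": 6000.0},
        polygenic_var=polygenic_var,
        residual_var=residual_var,
    )
    confounder_spec = QTLSpec(
        trait="days_to_heading",
        qtls=(),
        environment_means={"heat": 75.0, "drought": 85.0, "irrigated": 95.0},
        polygenic_var=0.0,
        residual_var=9.0,
    )
    phen = simulate_phenotypes(G, qtl_spec, seed)
    phen_conf = simulate_phenotypes(G, confounder_spec, seed + 7)
    import pandas as pd

    phenotypes = TraitTable(
        pd.concat([phen.records, phen_conf.records], ignore_index=True))
    return PlantedScenario(config, founders, G, truth, registry, gmap,
                           qtl_spec, confounder_spec, phenotypes,
                           planted, planted_class)


def apply_selection(
    G: GenotypeMatrix,
    truth: AncestryTruth,
    registry: CrossRegistry,
    traits: TraitTable,
    trait: str,
    retained_fraction: float,
    environment: str | None = None,
    direction: str = "max",
) -> tuple[GenotypeMatrix, AncestryTruth, CrossRegistry]:
    """Truncation selection on a trait; ancestry truth subset accordingly."""
    if not 0.0 < retained_fraction <= 1.0:
        raise ValueError("retained_fraction must be in (0, 1]")
    df = traits.records
    sel = df[df["trait"] == trait]
    if environment is not None:
        sel = sel[sel["environment"] == environment]
    means = sel.groupby("line_id")["value"].mean()
    missing_lines = [l for l in G.line_ids if l not in means.index]
    if missing_lines:
        raise ValueError(
            f"trait {trait!r} missing for lines {missing_lines[:5]}")
    n_keep = int(round(retained_fraction * G.n_lines))
    n_keep = max(1, min(G.n_lines, n_keep))
    ascending = direction == "min"
    ranked = means.loc[G.line_ids].sort_values(
        ascending=ascending, kind="stable")
    kept = sorted(ranked.index[:n_keep], key=G.line_index)
    reg = CrossRegistry(dict(registry.crosses),
                        {l: registry.membership[l] for l in kept})
    return G.subset(lines=kept), truth.subset(kept), reg
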