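"""Marker QC and confidence-interval D' haplotype-block construction.

A block is a run of consecutive mapped markers, no farther apart than the
LD window (default 5 cM), in which at least 95% of the informative (i.e.
non-inconclusive) pairwise D' comparisons are "strong LD".  Accepted
candidate intervals are taken greedily (most markers first) without
overlap, then named ``HB<chromosome index>.<rank>`` left to right, where
chromosome index 1 is 1A, 2 is 1B, ... 21 is 7D.

Haplotype classes are the allele strings of lines homozygous at every
member marker; heterozygous or missing lines carry no class for that block.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from math import lgamma

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import (
    GeneticMap,
    GenotypeMatrix,
    HaplotypeBlock,
    ValidationError,
)
from .ld import (
    RECOMB_HIGH,
    STRONG_LD_HIGH,
    STRONG_LD_LOW,
    DegeneratePairError,
    pair_ld,
)

__all__ = ["QCParams", "qc_filter", "hwe_exact_pvalue", "HaplotypeBlockFinder",
           "find_blocks", "assign_classes", "multiallelic_dprime",
           "DegenerateBlockError"]


class DegenerateBlockError(ValueError):
    """Between-block D' is undefined (fewer than 2 observed classes)."""


@dataclass(frozen=True)
class QCParams:
    """Marker/line quality-control thresholds.

    ``hwe_mode``: ``"apply"`` enforces the exact-test Hardy-Weinberg cutoff;
    ``"skip_inbred"`` (default) auto-disables it when the panel heterozygote
    rate is below ``inbred_het_threshold`` — a selfed topcross panel violates
    HWE at every marker, so a literal cutoff would discard the whole panel.
    """

    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    individual_missing_max: float = 0.75
    hwe_mode: str = "skip_inbred"
    ld_window_cm: float = 5.0
    inbred_het_threshold: float = 0.02

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0 <= self.hwe_p_min <= 1:
            raise ValueError("hwe_p_min must be in [0, 1]")
        if not 0 <= self.individual_missing_max <= 1:
            raise ValueError("individual_missing_max must be in [0, 1]")
        if self.hwe_mode not in ("apply", "skip_inbred"):
            raise ValueError("hwe_mode must be 'apply' or 'skip_inbred'")
        if self.ld_window_cm <= 0:
            raise ValueError("ld_window_cm must be > 0")


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of probabilities of
    heterozygote counts no more likely than the observed one)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n == 0 or n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)

    def logprob(h):
        homr = (rare - h) // 2
        homc = n - h - homr
        return (h * np.log(2) + lgamma(n + 1)
                - lgamma(h + 1) - lgamma(homr + 1) - lgamma(homc + 1)
                + lgamma(n_a + 1) + lgamma(n_b + 1) - lgamma(2 * n + 1))

    logs = np.array([logprob(int(h)) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[np.where(hets == n_ab)[0][0]]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def qc_filter(
    G: GenotypeMatrix,
    gmap: GeneticMap,
    params: QCParams = QCParams(),
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the panel QC chain and return (filtered matrix, report).

    Order: lines above the missing-data cutoff are dropped first; then
    unmapped markers, minor-allele-frequency and (optionally) HWE filters;
    finally co-positioned markers are reduced to the first in (cM, id)
    order.  Surviving markers come out in map order.
    """
    report_rows: list[dict] = []

    miss = G.missing_fraction_per_line()
    kept_lines = [l for l, f in zip(G.line_ids, miss)
                  if f <= params.individual_missing_max]
    for l, f in zip(G.line_ids, miss):
        if f > params.individual_missing_max:
            report_rows.append(dict(entity=l, kind="line",
                                    reason="missing_fraction", value=float(f),
                                    threshold=params.individual_missing_max))
    G1 = G.subset(lines=kept_lines) if len(kept_lines) < G.n_lines else G

    mapped, unmapped = [], []
    for m in G1.marker_ids:
        (mapped if m in gmap else unmapped).append(m)
    for m in unmapped:
        report_rows.append(dict(entity=m, kind="marker", reason="unmapped",
                                value=np.nan, threshold=np.nan))

    # map order: chromosome, then (cM, id)
    ordered = [m for chrom in gmap.chromosomes()
               for m in gmap.markers_on(chrom) if m in set(mapped)]
    G1 = G1.subset(markers=ordered)

    freq = G1.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.ones(G1.n_markers, dtype=bool)
    for j, m in enumerate(G1.marker_ids):
        if np.isnan(maf[j]) or maf[j] < params.maf_min:
            keep[j] = False
            report_rows.append(dict(entity=m, kind="marker", reason="maf",
                                    value=float(maf[j]),
                                    threshold=params.maf_min))

    apply_hwe = params.hwe_mode == "apply" or (
        params.hwe_mode == "skip_inbred"
        and G1.het_rate() >= params.inbred_het_threshold)
    if apply_hwe:
        for j, m in enumerate(G1.marker_ids):
            if not keep[j]:
                continue
            col = G1.calls[:, j]
            p = hwe_exact_pvalue(int((col == 0).sum()), int((col == 1).sum()),
                                 int((col == 2).sum()))
            if p < params.hwe_p_min:
                keep[j] = False
                report_rows.append(dict(entity=m, kind="marker", reason="hwe",
                                        value=p, threshold=params.hwe_p_min))

    kept_markers = [m for m, k in zip(G1.marker_ids, keep) if k]

    # co-positioned markers: keep only the first in (cM, id) order
    final: list[str] = []
    last_key: tuple[str, float] | None = None
    for m in kept_markers:
        key = (gmap.chromosome(m), gmap.position(m))
        if key == last_key:
            report_rows.append(dict(entity=m, kind="marker",
                                    reason="co_positioned", value=key[1],
                                    threshold=np.nan))
            continue
        final.append(m)
        last_key = key
    if not final:
        raise ValidationError("QC removed every marker; empty panel")
    report = pd.DataFrame(
        report_rows, columns=["entity", "kind", "reason", "value", "threshold"])
    return G1.subset(markers=final), report


def assign_classes(block: HaplotypeBlock, G: GenotypeMatrix) -> HaplotypeBlock:
    """Fill per-line haplotype classes and their frequencies.

    A line gets the allele string of its homozygous calls across all member
    markers (e.g. ``"GT"``); any heterozygous or missing member call leaves
    the line unassigned.  Frequencies are over assigned lines only.
    """
    cols = [G.marker_index(m) for m in block.markers]
    sub = G.calls[:, cols]
    ok = np.all((sub == 0) | (sub == 2), axis=1)
    letters = np.empty((len(cols), 2), dtype=object)
    for k, j in enumerate(cols):
        letters[k] = G.alleles[j]
    assignments: dict[str, str] = {}
    for i in np.flatnonzero(ok):
        s = "".join(letters[k][sub[i, k] // 2] for k in range(len(cols)))
        assignments[G.line_ids[i]] = s
    counts: dict[str, int] = {}
    for s in assignments.values():
        counts[s] = counts.get(s, 0) + 1
    total = sum(counts.values())
    classes = {s: c / total for s, c in counts.items()} if total else {}
    return dc_replace(block, classes=classes, assignments=assignments)


class HaplotypeBlockFinder(BaseEstimator):
    """Confidence-interval D' block detection over a QC-filtered panel.

    Parameters
    ----------
    ld_window_cm : float
        Maximum cM distance between any two markers of a block; only pairs
        within the window are ever compared.
    min_strong_frac : float
        Minimum fraction of informative pairs that must be strong LD.
    strong_ld_high, strong_ld_low, recomb_high : float
        CI bounds for the pairwise classification.
    ci_grid_points : int
        Resolution of the D' likelihood grid.

    Attributes
    ----------
    blocks_ : list[HaplotypeBlock]
        Accepted, named blocks with classes assigned on the fit panel.
    pair_classifications_ : dict[tuple[str, str], PairLD]
        Cached pairwise LD results (marker-id keyed).
    """

    def __init__(self, ld_window_cm: float = 5.0, min_strong_frac: float = 0.95,
                 strong_ld_high: float = STRONG_LD_HIGH,
                 strong_ld_low: float = STRONG_LD_LOW,
                 recomb_high: float = RECOMB_HIGH, ci_grid_points: int = 101):
        self.ld_window_cm = ld_window_cm
        self.min_strong_frac = min_strong_frac
        self.strong_ld_high = strong_ld_high
        self.strong_ld_low = strong_ld_low
        self.recomb_high = recomb_high
        self.ci_grid_points = ci_grid_points

    def fit(self, G: GenotypeMatrix, gmap: GeneticMap) -> "HaplotypeBlockFinder":
        """Find, select and name blocks on a QC-filtered panel."""
        self.pair_classifications_ = {}
        candidates: list[tuple[str, int, int, float, int]] = []
        chrom_markers: dict[str, list[str]] = {}
        for chrom in gmap.chromosomes():
            ms = [m for m in gmap.markers_on(chrom)
                  if m in set(G.marker_ids)]
            if len(ms) < 2:
                chrom_markers[chrom] = ms
                continue
            chrom_markers[chrom] = ms
            cm = np.array([gmap.position(m) for m in ms])
            cols = {m: G.marker_index(m) for m in ms}

            def classify(mi: str, mj: str) -> str | None:
                key = (mi, mj)
                if key not in self.pair_classifications_:
                    try:
                        res = pair_ld(
                            G.calls[:, cols[mi]], G.calls[:, cols[mj]],
                            strong_ld_high=self.strong_ld_high,
                            strong_ld_low=self.strong_ld_low,
                            recomb_high=self.recomb_high,
                            grid_points=self.ci_grid_points)
                    except DegeneratePairError:
                        res = None
                    self.pair_classifications_[key] = res
                res = self.pair_classifications_[key]
                return None if res is None else res.classification

            for i in range(len(ms) - 1):
                for j in range(i + 1, len(ms)):
                    if cm[j] - cm[i] > self.ld_window_cm:
                        break
                    n_strong = n_info = 0
                    degenerate = False
                    for a in range(i, j + 1):
                        for b in range(a + 1, j + 1):
                            c = classify(ms[a], ms[b])
                            if c is None:
                                degenerate = True
                                break
                            if c != "inconclusive":
                                n_info += 1
                                if c == "strong_LD":
                                    n_strong += 1
                        if degenerate:
                            break
                    if degenerate or n_info == 0:
                        continue
                    if n_strong / n_info >= self.min_strong_frac:
                        candidates.append(
                            (chrom, i, j, float(cm[j] - cm[i]), j - i + 1))

        # greedy: most markers, then span, then leftmost; no overlap
        candidates.sort(key=lambda c: (-c[4], -c[3],
                                       GeneticMap.chromosome_index(c[0]), c[1]))
        taken: dict[str, set[int]] = {}
        accepted: list[tuple[str, int, int]] = []
        for chrom, i, j, _, _ in candidates:
            used = taken.setdefault(chrom, set())
            if any(k in used for k in range(i, j + 1)):
                continue
            used.update(range(i, j + 1))
            accepted.append((chrom, i, j))

        blocks: list[HaplotypeBlock] = []
        accepted.sort(key=lambda c: (GeneticMap.chromosome_index(c[0]), c[1]))
        rank: dict[str, int] = {}
        for chrom, i, j in accepted:
            rank[chrom] = rank.get(chrom, 0) + 1
            ms = chrom_markers[chrom][i:j + 1]
            blk = HaplotypeBlock(
                name=f"HB{GeneticMap.chromosome_index(chrom)}.{rank[chrom]}",
                chromosome=chrom,
                markers=ms,
                start_cm=gmap.position(ms[0]),
                end_cm=gmap.position(ms[-1]),
            )
            blocks.append(assign_classes(blk, G))
        self.blocks_ = blocks
        return self

    def transform(self, G: GenotypeMatrix) -> list[HaplotypeBlock]:
        """Re-assign the fitted blocks' classes on another panel."""
        if not hasattr(self, "blocks_"):
            raise RuntimeError("call fit() first")
        return [assign_classes(b, G) for b in self.blocks_]


def find_blocks(G: GenotypeMatrix, gmap: GeneticMap,
                params: QCParams = QCParams(), **finder_kwargs
                ) -> list[HaplotypeBlock]:
    """Functional wrapper: fit a HaplotypeBlockFinder and return its blocks."""
    finder = HaplotypeBlockFinder(ld_window_cm=params.ld_window_cm,
                                  **finder_kwargs)
    return finder.fit(G, gmap).blocks_


def multiallelic_dprime(block_a: HaplotypeBlock, block_b: HaplotypeBlock,
                        G: GenotypeMatrix | None = None) -> float:
    """Multi-allelic D' between two blocks: sum_i sum_j p_i q_j |D'_ij|.

    Each class pair is collapsed to a 2x2 table (class i vs rest, class j
    vs rest) whose biallelic D' is weighted by the marginal class
    frequencies.  1 means no recombination between the blocks; values near
    0 mean free recombination.
    """
    a = assign_classes(block_a, G) if G is not None else block_a
    b = assign_classes(block_b, G) if G is not None else block_b
    common = sorted(set(a.assignments) & set(b.assignments))
    if not common:
        raise DegenerateBlockError("no lines assigned in both blocks")
    ca = [a.assignments[l] for l in common]
    cb = [b.assignments[l] for l in common]
    classes_a = sorted(set(ca))
    classes_b = sorted(set(cb))
    if len(classes_a) < 2 or len(classes_b) < 2:
        raise DegenerateBlockError(
            "need at least 2 observed classes in each block")
    n = len(common)
    joint = np.zeros((len(classes_a), len(classes_b)))
    ia = {c: k for k, c in enumerate(classes_a)}
    ib = {c: k for k, c in enumerate(classes_b)}
    for x, y in zip(ca, cb):
        joint[ia[x], ib[y]] += 1
    joint /= n
    p = joint.sum(axis=1)
    q = joint.sum(axis=0)
    total = 0.0
    for i in range(len(classes_a)):
        for j in range(len(classes_b)):
            d = joint[i, j] - p[i] * q[j]
            if d >= 0:
                dmax = min(p[i] * (1 - q[j]), (1 - p[i]) * q[j])
            else:
                dmax = min(p[i] * q[j], (1 - p[i]) * (1 - q[j]))
            if dmax > 0:
                total += p[i] * q[j] * abs(d) / dmax
    return float(min(total, 1.0))
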