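"""Parent-of-origin tracing for three-way topcross lines.

Two complementary estimators of exotic genome contribution:

* per-cross A/B/H SNP classification against the three parents (elite
  origin ``A``, exotic origin ``B``, heterozygous ``H``, unidentified ``U``,
  missing ``.``), and
* haplotype-block-map comparison flagging PBL blocks whose classes are
  private to the exotic parent panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .blocks import assign_classes
from .datatypes import (
    MISSING,
    CrossRegistry,
    GeneticMap,
    GenotypeMatrix,
    HaplotypeBlock,
)

__all__ = ["OriginClassifier", "classify_abh", "summarize_contribution",
           "ContributionSummary", "exotic_specific_blocks",
           "compare_block_maps"]

CODE_A, CODE_B, CODE_H, CODE_U, CODE_MISSING = "A", "B", "H", "U", "."


class OriginClassifier(BaseEstimator):
    """A/B/H/U parent-of-origin classifier for registered topcross lines.

    A marker is informative for a cross iff all three parents are
    homozygous, the two elite parents carry the same allele, and the exotic
    allele differs from it.  At informative markers a line call equal to
    the exotic homozygote is coded ``B``, equal to the elite homozygote
    ``A``, heterozygous ``H`` and missing ``.``; all non-informative
    markers are coded ``U`` (unidentified origin).

    Attributes
    ----------
    origin_ : pd.DataFrame
        Lines x markers code matrix for every registered line (after
        :meth:`fit`).
    """

    def fit(self, parents: GenotypeMatrix, lines: GenotypeMatrix,
            registry: CrossRegistry) -> "OriginClassifier":
        frames = []
        for cross_id in sorted(registry.crosses):
            member_lines = [l for l in lines.line_ids
                            if registry.membership.get(l) == cross_id]
            if not member_lines:
                continue
            frames.append(classify_abh(parents, lines, registry, cross_id))
        self.origin_ = (pd.concat(frames) if frames
                        else pd.DataFrame(columns=lines.marker_ids))
        return self

    def transform(self, gmap: GeneticMap | None = None,
                  registry: CrossRegistry | None = None
                  ) -> "ContributionSummary":
        if not hasattr(self, "origin_"):
            raise RuntimeError("call fit() first")
        return summarize_contribution(self.origin_, gmap, registry)


def classify_abh(parents: GenotypeMatrix, lines: GenotypeMatrix,
                 registry: CrossRegistry, cross_id: str) -> pd.DataFrame:
    """Code one cross's lines as A/B/H/U/'.' against their three parents."""
    try:
        ex_id, e1_id, e2_id = registry.crosses[cross_id]
    except KeyError:
        raise KeyError(f"unknown cross id {cross_id!r}") from None
    for pid in (ex_id, e1_id, e2_id):
        if pid not in parents.line_ids:
            raise KeyError(
                f"parent {pid!r} of cross {cross_id} absent from parent panel")
    if parents.marker_ids != lines.marker_ids:
        raise ValueError("parent and line panels must share the marker set")
    ex = parents.calls[parents.line_index(ex_id)]
    e1 = parents.calls[parents.line_index(e1_id)]
    e2 = parents.calls[parents.line_index(e2_id)]
    hom = lambda v: (v == 0) | (v == 2)
    informative = hom(ex) & hom(e1) & hom(e2) & (e1 == e2) & (ex != e1)
    member_lines = [l for l in lines.line_ids
                    if registry.membership.get(l) == cross_id]
    calls = lines.calls[[lines.line_index(l) for l in member_lines]]
    codes = np.full(calls.shape, CODE_U, dtype=object)
    info = informative[None, :]
    codes[info & (calls == ex[None, :])] = CODE_B
    codes[info & (calls == e1[None, :])] = CODE_A
    codes[info & (calls == 1)] = CODE_H
    codes[info & (calls == MISSING)] = CODE_MISSING
    return pd.DataFrame(codes, index=member_lines, columns=lines.marker_ids)


@dataclass
class ContributionSummary:
    """Raw and classified-only origin fractions at line, chromosome, cross
    and panel level.

    ``per_line`` raw columns (a, b, h, u, missing) sum to 1; the ``renorm_*``
    columns renormalize over classified (A/B/H) markers only, and
    ``exotic_estimate`` / ``elite_estimate`` add half the heterozygous
    fraction to the exotic / elite side respectively.
    """

    per_line: pd.DataFrame
    per_chromosome: pd.DataFrame | None
    per_cross: pd.DataFrame | None
    panel: pd.Series


def _fractions(codes: np.ndarray) -> dict[str, float]:
    n = codes.size
    out = {k: float((codes == c).sum()) / n for k, c in
           (("a", CODE_A), ("b", CODE_B), ("h", CODE_H), ("u", CODE_U),
            ("missing", CODE_MISSING))}
    classified = out["a"] + out["b"] + out["h"]
    if classified > 0:
        out["renorm_a"] = out["a"] / classified
        out["renorm_b"] = out["b"] / classified
        out["renorm_h"] = out["h"] / classified
        out["exotic_estimate"] = out["renorm_b"] + out["renorm_h"] / 2
        out["elite_estimate"] = out["renorm_a"] + out["renorm_h"] / 2
    else:
        for k in ("renorm_a", "renorm_b", "renorm_h", "exotic_estimate",
                  "elite_estimate"):
            out[k] = np.nan
    out["classified_fraction"] = classified
    return out


def summarize_contribution(origin: pd.DataFrame,
                           gmap: GeneticMap | None = None,
                           registry: CrossRegistry | None = None
                           ) -> ContributionSummary:
    """Aggregate an A/B/H/U/'.' code matrix into contribution fractions.

    The classified-only exotic estimate (``renorm_b`` + half the
    heterozygous fraction) is the SNP-based exotic-contribution figure;
    raw fractions keep unidentified and missing markers in the denominator
    so both conventions are always available.
    """
    codes = origin.to_numpy(dtype=object)
    per_line = pd.DataFrame(
        [_fractions(codes[i]) for i in range(len(origin))],
        index=origin.index)
    per_chrom = None
    if gmap is not None:
        rows = {}
        for chrom in gmap.chromosomes():
            ms = [m for m in gmap.markers_on(chrom) if m in origin.columns]
            if ms:
                rows[chrom] = _fractions(origin[ms].to_numpy(dtype=object))
        per_chrom = pd.DataFrame(rows).T if rows else None
    per_cross = None
    if registry is not None:
        rows = {}
        for cid in sorted(registry.crosses):
            ls = [l for l in origin.index
                  if registry.membership.get(l) == cid]
            if ls:
                rows[cid] = per_line.loc[ls].mean(numeric_only=True)
        per_cross = pd.DataFrame(rows).T if rows else None
    panel = per_line.mean(numeric_only=True)
    return ContributionSummary(per_line, per_chrom, per_cross, panel)


def exotic_specific_blocks(
    blocks_pbl: list[HaplotypeBlock],
    G_exotic: GenotypeMatrix,
    G_elite: GenotypeMatrix,
) -> tuple[list[HaplotypeBlock], float]:
    """PBL blocks whose haplotype classes are private to the exotic panel.

    A block is exotic-specific iff at least one of its classes observed in
    the PBL panel also occurs in the exotic parent panel and in zero elite
    parents.  Returns the flagged subset and the imprint fraction
    (flagged / total).
    """
    if G_elite.n_lines == 0:
        raise ValueError("empty elite panel: specificity is undefined")
    if not blocks_pbl:
        return [], float("nan")
    flagged = []
    for blk in blocks_pbl:
        pbl_classes = set(blk.classes)
        exo = set(assign_classes(blk, G_exotic).classes)
        eli = set(assign_classes(blk, G_elite).classes)
        if pbl_classes & exo - eli:
            flagged.append(blk)
    return flagged, len(flagged) / len(blocks_pbl)


def compare_block_maps(blocks_a: list[HaplotypeBlock],
                       blocks_b: list[HaplotypeBlock],
                       gmap: GeneticMap | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """cM-interval overlaps between two block sets on the same map.

    Returns (overlap table, summary).  The table has one row per
    overlapping (a, b) block pair with the number of shared member
    markers; the summary reports block counts and mean spans per panel.
    """
    rows = []
    for a in blocks_a:
        for b in blocks_b:
            if a.chromosome != b.chromosome:
                continue
            if a.start_cm <= b.end_cm and b.start_cm <= a.end_cm:
                shared = len(set(a.markers) & set(b.markers))
                rows.append(dict(
                    block_a=a.name, block_b=b.name, chromosome=a.chromosome,
                    a_start=a.start_cm, a_end=a.end_cm,
                    b_start=b.start_cm, b_end=b.end_cm,
                    shared_markers=shared))
    table = pd.DataFrame(rows, columns=[
        "block_a", "block_b", "chromosome", "a_start", "a_end",
        "b_start", "b_end", "shared_markers"])
    summary = {
        "n_blocks_a": len(blocks_a),
        "n_blocks_b": len(blocks_b),
        "mean_span_a": float(np.mean([a.span_cm for a in blocks_a]))
        if blocks_a else float("nan"),
        "mean_span_b": float(np.mean([b.span_cm for b in blocks_b]))
        if blocks_b else float("nan"),
        "n_overlaps": len(table),
    }
    return table, summary
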