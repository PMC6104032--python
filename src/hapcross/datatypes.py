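"""Core in-memory containers shared by every pipeline stage.

Dosage convention: per marker, the two homozygous states are coded 0 and 2
(allele labels ``alleles[m][0]`` and ``alleles[m][1]``), heterozygotes are 1
and missing calls are -1.  Inbred wheat panels are therefore mostly {0, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: Wheat chromosome labels in consensus-map order; index 1 = 1A, 2 = 1B,
#: 3 = 1D, ... 21 = 7D.  This bijection drives haplotype-block naming.
CHROMOSOMES = tuple(f"{n}{g}" for n in range(1, 8) for g in "ABD")
CHROM_INDEX: dict[str, int] = {c: i + 1 for i, c in enumerate(CHROMOSOMES)}


class ValidationError(ValueError):
    """Raised when an on-disk artifact or container violates its invariants."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), []
        for x in ids:
            if x in seen:
                dup.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {kind} id(s): {dup[:5]}")


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with per-marker allele labels.

    Parameters
    ----------
    line_ids, marker_ids
        Ordered unique identifiers.
    calls
        int8 array of shape (n_lines, n_markers) with values in
        {0, 1, 2, MISSING}.
    alleles
        Per marker, the two allele labels mapped to dosage 0 and 2.
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    alleles: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.alleles = [tuple(a) for a in self.alleles]
        _check_unique(self.line_ids, "line")
        _check_unique(self.marker_ids, "marker")
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} call(s) outside the 4-symbol alphabet "
                "{0,1,2,missing}"
            )
        if len(self.alleles) != len(self.marker_ids):
            raise ValidationError("one allele pair required per marker")
        for m, (a, b) in zip(self.marker_ids, self.alleles):
            if a == b:
                raise ValidationError(f"marker {m}: allele labels must differ")
        self._line_index = {l: i for i, l in enumerate(self.line_ids)}
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def line_index(self, line_id: str) -> int:
        try:
            return self._line_index[line_id]
        except KeyError:
            raise KeyError(f"unknown line id {line_id!r}") from None

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id {marker_id!r}") from None

    def subset(
        self,
        lines: Iterable[str] | None = None,
        markers: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """New matrix restricted to the given lines/markers (order preserved)."""
        li = (
            np.arange(self.n_lines)
            if lines is None
            else np.array([self.line_index(l) for l in lines], dtype=int)
        )
        mi = (
            np.arange(self.n_markers)
            if markers is None
            else np.array([self.marker_index(m) for m in markers], dtype=int)
        )
        return GenotypeMatrix(
            line_ids=[self.line_ids[i] for i in li],
            marker_ids=[self.marker_ids[j] for j in mi],
            calls=self.calls[np.ix_(li, mi)].copy(),
            alleles=[self.alleles[j] for j in mi],
        )

    def missing_fraction_per_line(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the dosage-2 allele per marker, missing excluded."""
        obs = self.calls != MISSING
        dose = np.where(obs, self.calls, 0).astype(float)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, dose.sum(axis=0) / denom, np.nan)

    def het_rate(self) -> float:
        obs = self.calls != MISSING
        n = int(obs.sum())
        return float((self.calls == 1).sum() / n) if n else 0.0


@dataclass
class GeneticMap:
    """Marker -> (chromosome, cM) with a deterministic within-chromosome order.

    Markers on a chromosome are ordered by (cM, marker id); the lexicographic
    tie-break makes co-located markers reproducibly ordered, which matters
    because only the first of a co-located group enters block construction.
    """

    entries: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        for m, (chrom, cm) in self.entries.items():
            if chrom not in CHROM_INDEX:
                raise ValidationError(
                    f"marker {m}: unknown chromosome label {chrom!r}"
                )
            if not np.isfinite(cm) or cm < 0:
                raise ValidationError(f"marker {m}: negative or non-finite cM {cm}")
        self._by_chrom: dict[str, list[str]] = {}
        for m, (chrom, cm) in self.entries.items():
            self._by_chrom.setdefault(chrom, []).append(m)
        for chrom, ms in self._by_chrom.items():
            ms.sort(key=lambda m: (self.entries[m][1], m))

    def __contains__(self, marker: str) -> bool:
        return marker in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def chromosome(self, marker: str) -> str:
        return self.entries[marker][0]

    def position(self, marker: str) -> float:
        return self.entries[marker][1]

    def chromosomes(self) -> list[str]:
        return [c for c in CHROMOSOMES if c in self._by_chrom]

    def markers_on(self, chrom: str) -> list[str]:
        """Markers on ``chrom`` in (cM, id) order."""
        return list(self._by_chrom.get(chrom, []))

    @staticmethod
    def chromosome_index(chrom: str) -> int:
        return CHROM_INDEX[chrom]


@dataclass
class TraitTable:
    """Long-format (line, trait, environment) -> replicate-mean value."""

    records: pd.DataFrame  # columns: line_id, trait, environment, value

    REQUIRED = ("line_id", "trait", "environment", "value")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing_cols = [c for c in self.REQUIRED if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"phenotype table missing columns {missing_cols}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        if np.isinf(df["value"].to_numpy(dtype=float, na_value=np.nan)).any():
            raise ValidationError("phenotype values must be finite or missing")
        key = df[["line_id", "trait", "environment"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValidationError(
                f"duplicate phenotype record for (line, trait, environment) {dup}"
            )
        self.records = df.reset_index(drop=True)

    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    def environments(self, trait: str | None = None) -> list[str]:
        df = self.records
        if trait is not None:
            df = df[df["trait"] == trait]
        return sorted(df["environment"].unique())

    def vector(self, trait: str, environment: str) -> pd.Series:
        """Series of values indexed by line id; missing values dropped."""
        df = self.records
        sel = df[(df["trait"] == trait) & (df["environment"] == environment)]
        s = sel.set_index("line_id")["value"].dropna()
        return s


@dataclass
class CrossRegistry:
    """Three-way cross registry: cross -> (exotic, elite1, elite2) + membership."""

    crosses: dict[str, tuple[str, str, str]]
    membership: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, parents in self.crosses.items():
            if len(parents) != 3:
                raise ValidationError(f"cross {cid}: need (exotic, elite1, elite2)")
        for line, cid in self.membership.items():
            if cid not in self.crosses:
                raise ValidationError(f"line {line}: unknown cross id {cid!r}")

    def parents_of(self, line_id: str) -> tuple[str, str, str]:
        cid = self.cross_of(line_id)
        return self.crosses[cid]

    def cross_of(self, line_id: str) -> str:
        try:
            return self.membership[line_id]
        except KeyError:
            raise KeyError(f"line {line_id!r} is not registered to a cross") from None

    def lines_in(self, cross_id: str) -> list[str]:
        return [l for l, c in self.membership.items() if c == cross_id]

    def exotic_parents(self) -> list[str]:
        return sorted({p[0] for p in self.crosses.values()})

    def elite_parents(self) -> list[str]:
        out: set[str] = set()
        for _, e1, e2 in self.crosses.values():
            out.update((e1, e2))
        return sorted(out)


@dataclass
class HaplotypeBlock:
    """A run of markers in strong LD treated as one multi-allelic locus.

    ``classes`` maps each observed allele string (e.g. ``"GT"``) to its
    frequency among assigned lines; ``assignments`` maps line id -> class
    string, with heterozygous/missing lines absent.
    """

    name: str
    chromosome: str
    markers: list[str]
    start_cm: float
    end_cm: float
    classes: dict[str, float] = field(default_factory=dict)
    assignments: dict[str, str] = field(default_factory=dict)

    @property
    def span_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def n_markers(self) -> int:
        return len(self.markers)
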