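"""Readers and writers for every on-disk artifact the pipeline touches.

Downstream stages consume only the containers built here; no stage re-parses
files.  Supported formats: HapMap-style genotype TSV, GT-only VCF 4.x, map
TSV, phenotype CSV, cross + membership CSVs, block/association/origin tables.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    CrossRegistry,
    GeneticMap,
    GenotypeMatrix,
    HaplotypeBlock,
    TraitTable,
    ValidationError,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_phenotypes",
    "write_phenotypes",
    "read_crosses",
    "write_crosses",
    "read_blocks",
    "write_blocks",
    "read_block_assignments",
    "write_block_assignments",
    "read_associations",
    "write_associations",
    "write_origin_matrix",
    "read_origin_matrix",
]

# IUPAC single-letter heterozygote codes accepted in HapMap input.
_IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
_MISSING_TOKENS = {"NN", "N", "--", "-", "./.", ".", "??"}


class ParseError(ValidationError):
    """Malformed file content; message carries the offending line number."""


def _decode_hapmap_call(token: str, a0: str, a2: str, where: str) -> int:
    token = token.strip().upper()
    if token in _MISSING_TOKENS:
        return MISSING
    if len(token) == 1:
        pair = _IUPAC_HET.get(token, (token, token))
    elif len(token) == 2:
        pair = (token[0], token[1])
    else:
        raise ParseError(f"{where}: unparseable genotype call {token!r}")
    counts = sorted(pair)
    if counts == sorted((a0, a0)):
        return 0
    if counts == sorted((a2, a2)):
        return 2
    if counts == sorted((a0, a2)):
        return 1
    raise ParseError(
        f"{where}: call {token!r} inconsistent with alleles {a0}/{a2}"
    )


def read_genotypes(path: str | Path, format: str = "hapmap_tsv",
                   on_multiallelic: str = "error") -> GenotypeMatrix:
    """Read a genotype matrix from disk.

    Parameters
    ----------
    format
        ``"hapmap_tsv"`` (marker rows, line columns, two-letter or IUPAC
        calls) or ``"vcf"`` (GT field only; diploid biallelic records).
    on_multiallelic
        For VCF input: ``"error"`` rejects multi-allelic records, ``"skip"``
        drops them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hapmap_tsv":
        return _read_hapmap(path)
    if format == "vcf":
        return _read_vcf(path, on_multiallelic=on_multiallelic)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_hapmap(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}:1: empty genotype file") from None
        header = [h.strip() for h in header]
        if len(header) < 5 or header[0] not in ("rs#", "rs", "marker", "marker_id"):
            raise ParseError(
                f"{path}:1: malformed HapMap header; expected "
                "'rs#\\talleles\\tchrom\\tpos\\t<line ids...>'"
            )
        # Full 11-column HapMap headers are accepted; metadata columns skipped.
        meta = {"strand", "assembly#", "center", "protLSID", "assayLSID",
                "panelLSID", "QCcode"}
        first_line_col = 4
        while first_line_col < len(header) and header[first_line_col] in meta:
            first_line_col += 1
        line_ids = header[first_line_col:]
        marker_ids: list[str] = []
        alleles: list[tuple[str, str]] = []
        rows: list[list[int]] = []
        for ln, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < first_line_col + len(line_ids):
                raise ParseError(f"{path}:{ln}: truncated row")
            mid = row[0].strip()
            allele_field = row[1].strip()
            parts = allele_field.split("/")
            if len(parts) != 2 or parts[0] == parts[1]:
                raise ParseError(
                    f"{path}:{ln}: alleles field {allele_field!r} must be "
                    "two distinct labels 'X/Y'"
                )
            a0, a2 = parts[0], parts[1]
            calls = [
                _decode_hapmap_call(tok, a0, a2, f"{path}:{ln}")
                for tok in row[first_line_col:first_line_col + len(line_ids)]
            ]
            marker_ids.append(mid)
            alleles.append((a0, a2))
            rows.append(calls)
    calls_arr = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(line_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(line_ids, marker_ids, calls_arr, alleles)


def _read_vcf(path: Path, on_multiallelic: str = "error") -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    marker_ids: list[str] = []
    alleles: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if on_multiallelic == "skip":
                continue
            raise ValidationError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; "
                "pass on_multiallelic='skip' to drop such records"
            )
        mid = var.ID or f"{var.CHROM}_{var.POS}"
        # gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=unknown
        gt = var.gt_types
        calls = np.full(len(line_ids), MISSING, dtype=np.int8)
        calls[gt == 0] = 0
        calls[gt == 1] = 1
        calls[gt == 3] = 2
        marker_ids.append(mid)
        alleles.append((var.REF, var.ALT[0]))
        rows.append(calls)
    vcf.close()
    calls_arr = (
        np.vstack(rows).T if rows else np.zeros((len(line_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(line_ids, marker_ids, calls_arr, alleles)


def write_genotypes(G: GenotypeMatrix, path: str | Path,
                    format: str = "hapmap_tsv",
                    genetic_map: GeneticMap | None = None) -> None:
    """Write a genotype matrix as HapMap TSV or GT-only VCF 4.2."""
    path = Path(path)
    if format == "hapmap_tsv":
        _write_hapmap(G, path, genetic_map)
    elif format == "vcf":
        _write_vcf(G, path, genetic_map)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _chrom_pos(G: GenotypeMatrix, genetic_map: GeneticMap | None):
    for j, m in enumerate(G.marker_ids):
        if genetic_map is not None and m in genetic_map:
            yield genetic_map.chromosome(m), genetic_map.position(m)
        else:
            yield "UN", float(j)


def _write_hapmap(G: GenotypeMatrix, path: Path,
                  genetic_map: GeneticMap | None) -> None:
    code_tokens = {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["rs#", "alleles", "chrom", "pos", *G.line_ids])
        for j, ((chrom, pos), mid) in enumerate(
            zip(_chrom_pos(G, genetic_map), G.marker_ids)
        ):
            a0, a2 = G.alleles[j]
            code_tokens = {0: a0 + a0, 1: a0 + a2, 2: a2 + a2, MISSING: "NN"}
            calls = [code_tokens[int(c)] for c in G.calls[:, j]]
            w.writerow([mid, f"{a0}/{a2}", chrom, pos, *calls])


def _write_vcf(G: GenotypeMatrix, path: Path,
               genetic_map: GeneticMap | None) -> None:
    gt_token = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(c for c, _ in _chrom_pos(G, genetic_map)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.line_ids)
            + "\n"
        )
        for j, ((chrom, pos), mid) in enumerate(
            zip(_chrom_pos(G, genetic_map), G.marker_ids)
        ):
            a0, a2 = G.alleles[j]
            # VCF POS is integer; cM positions are scaled to 0.01-cM ticks.
            ipos = int(round(pos * 100)) + 1
            gts = "\t".join(gt_token[int(c)] for c in G.calls[:, j])
            fh.write(
                f"{chrom}\t{ipos}\t{mid}\t{a0}\t{a2}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_map(path: str | Path) -> GeneticMap:
    """Read a genetic map TSV/CSV with columns marker, chromosome, cM."""
    df = _read_table(path)
    cols = _resolve_columns(
        df, {"marker": ("marker", "marker_id", "rs#", "rs"),
             "chromosome": ("chromosome", "chrom", "chr"),
             "cm": ("cm", "cM", "position", "pos")}, path)
    entries: dict[str, tuple[str, float]] = {}
    for _, row in df.iterrows():
        m = str(row[cols["marker"]])
        if m in entries:
            raise ValidationError(f"{path}: marker {m} mapped twice")
        entries[m] = (str(row[cols["chromosome"]]), float(row[cols["cm"]]))
    return GeneticMap(entries)


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    rows = [
        {"marker": m, "chromosome": chrom, "cm": gmap.position(m)}
        for chrom in gmap.chromosomes()
        for m in gmap.markers_on(chrom)
    ]
    # %.17g guarantees exact float round trips, so downstream tie-breaks
    # on cM spans are stable across write/read cycles
    pd.DataFrame(rows, columns=["marker", "chromosome", "cm"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_phenotypes(path: str | Path) -> TraitTable:
    """Read a long-format phenotype CSV (line_id, trait, environment, value)."""
    df = _read_table(path)
    cols = _resolve_columns(
        df, {"line_id": ("line_id", "line", "genotype"),
             "trait": ("trait",),
             "environment": ("environment", "env"),
             "value": ("value", "mean")}, path)
    df = df.rename(columns={v: k for k, v in cols.items()})
    return TraitTable(df[["line_id", "trait", "environment", "value"]])


def write_phenotypes(table: TraitTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)


def read_crosses(cross_path: str | Path,
                 membership_path: str | Path | None = None) -> CrossRegistry:
    """Read the cross registry (+ optional line-membership table)."""
    df = _read_table(cross_path)
    cols = _resolve_columns(
        df, {"cross_id": ("cross_id", "cross"),
             "exotic": ("exotic", "exotic_parent"),
             "elite1": ("elite1", "elite_1"),
             "elite2": ("elite2", "elite_2")}, cross_path)
    crosses = {
        str(r[cols["cross_id"]]): (
            str(r[cols["exotic"]]), str(r[cols["elite1"]]), str(r[cols["elite2"]]))
        for _, r in df.iterrows()
    }
    membership: dict[str, str] = {}
    if membership_path is not None:
        mdf = _read_table(membership_path)
        mcols = _resolve_columns(
            mdf, {"line_id": ("line_id", "line"),
                  "cross_id": ("cross_id", "cross")}, membership_path)
        for _, r in mdf.iterrows():
            line = str(r[mcols["line_id"]])
            if line in membership:
                raise ValidationError(
                    f"{membership_path}: line {line} belongs to two crosses"
                )
            membership[line] = str(r[mcols["cross_id"]])
    return CrossRegistry(crosses, membership)


def write_crosses(registry: CrossRegistry, cross_path: str | Path,
                  membership_path: str | Path | None = None) -> None:
    pd.DataFrame(
        [
            {"cross_id": cid, "exotic": p[0], "elite1": p[1], "elite2": p[2]}
            for cid, p in registry.crosses.items()
        ]
    ).to_csv(cross_path, index=False)
    if membership_path is not None:
        pd.DataFrame(
            [{"line_id": l, "cross_id": c} for l, c in registry.membership.items()]
        ).to_csv(membership_path, index=False)


_BLOCK_COLUMNS = ["chromosome", "start_cm", "end_cm", "name", "n_markers",
                  "markers", "classes"]


def write_blocks(blocks: Sequence[HaplotypeBlock], path: str | Path) -> None:
    """Write blocks as TSV; member markers ';'-joined, classes 'STR:freq'."""
    rows = []
    for b in blocks:
        total = sum(b.classes.values())
        if b.classes and not np.isclose(total, 1.0, atol=1e-9):
            raise ValidationError(
                f"block {b.name}: class frequencies sum to {total}, not 1"
            )
        rows.append({
            "chromosome": b.chromosome,
            "start_cm": b.start_cm,
            "end_cm": b.end_cm,
            "name": b.name,
            "n_markers": b.n_markers,
            "markers": ";".join(b.markers),
            "classes": ";".join(
                f"{cls}:{freq:.10g}" for cls, freq in sorted(b.classes.items())
            ),
        })
    pd.DataFrame(rows, columns=_BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_blocks(path: str | Path) -> list[HaplotypeBlock]:
    df = pd.read_csv(path, sep="\t", dtype=str)  # floats reparsed below
    missing_cols = [c for c in _BLOCK_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: block table missing columns {missing_cols}")
    blocks = []
    for _, r in df.iterrows():
        classes = {}
        if isinstance(r["classes"], str) and r["classes"]:
            for item in r["classes"].split(";"):
                cls, freq = item.rsplit(":", 1)
                classes[cls] = float(freq)
        blocks.append(HaplotypeBlock(
            name=r["name"],
            chromosome=r["chromosome"],
            markers=r["markers"].split(";") if isinstance(r["markers"], str) else [],
            start_cm=float(r["start_cm"]),
            end_cm=float(r["end_cm"]),
            classes=classes,
        ))
    return blocks


def write_block_assignments(blocks: Sequence[HaplotypeBlock],
                            path: str | Path) -> None:
    """Lines x blocks class-assignment CSV ('.' = unassigned)."""
    lines = sorted({l for b in blocks for l in b.assignments})
    df = pd.DataFrame(
        {b.name: [b.assignments.get(l, ".") for l in lines] for b in blocks},
        index=pd.Index(lines, name="line_id"),
    )
    df.to_csv(path)


def read_block_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="line_id", dtype=str)
    return df.replace(".", np.nan)


_ASSOC_COLUMNS = ["feature", "trait", "environment", "p_value", "df",
                  "effects", "threshold", "significant", "qq_deviates"]


def write_associations(results: pd.DataFrame, path: str | Path) -> None:
    """Write an association scan table (one row per feature x trait x env)."""
    out = results.copy()
    for col in _ASSOC_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out[_ASSOC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_associations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("significant", "qq_deviates"):
        if df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
        else:
            df[col] = df[col].astype(bool)
    return df


def write_origin_matrix(origin: pd.DataFrame, path: str | Path) -> None:
    """Lines x markers parent-of-origin codes (A/B/H/U/'.')."""
    origin.to_csv(path)


def read_origin_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, dtype=str)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        # round_trip parsing keeps cM coordinates bit-identical across
        # write/read cycles (span tie-breaks depend on them)
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ParseError(f"{path}: {exc}") from exc


def _resolve_columns(df: pd.DataFrame, wanted: dict[str, tuple[str, ...]],
                     path) -> dict[str, str]:
    lower = {c.lower(): c for c in df.columns}
    out = {}
    for key, candidates in wanted.items():
        for cand in candidates:
            if cand.lower() in lower:
                out[key] = lower[cand.lower()]
                break
        else:
            raise ParseError(
                f"{path}:1: missing required column {key!r} "
                f"(accepted names: {', '.join(candidates)})"
            )
    return out
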