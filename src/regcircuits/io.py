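"""Readers and writers for every external table the pipeline touches.

One TSV dialect everywhere: tab-separated, UTF-8, ``#``-prefixed comment
lines, a header row naming the columns.  Genomic tracks are BED (0-based
half-open); catalog/eQTL positions are 1-based and converted on read.

Readers validate strictly and *reject* malformed rows with the file path
and line number — they never silently coerce.  Writers emit deterministic
column order, sorted rows and fixed precision (6 significant digits), so
identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

from .intervals import GenomePosition, GenomicInterval

SOURCES = ("phewas", "gwas", "background")
SITE_KINDS = ("ligand_binding", "phosphorylation")
ELEMENT_KINDS = ("promoter", "enhancer")


class TableFormatError(ValueError):
    """A malformed row or header, pinpointed by file and line number."""

    def __init__(self, path, lineno: Optional[int], message: str):
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True)
class SnpRecord:
    """One catalog SNP-trait association."""

    snp_id: str
    position: GenomePosition
    trait: str
    p_value: float
    n_cases: Optional[int] = None
    source: str = "phewas"

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0,1], got {self.p_value}")
        if self.n_cases is not None and self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class EqtlRecord:
    snp_id: str
    gene_id: str
    tissue: str
    fdr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must be in [0,1], got {self.fdr}")


@dataclass(frozen=True)
class LdPair:
    snp_a: str
    snp_b: str
    r2: float
    distance_bp: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError(f"r2 must be in [0,1], got {self.r2}")
        if self.distance_bp < 0:
            raise ValueError("distance_bp must be non-negative")


@dataclass(frozen=True)
class ProteinSite:
    protein_id: str
    residue_index: int  # 1-based
    site_kind: str

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        if self.site_kind not in SITE_KINDS:
            raise ValueError(f"unknown site_kind {self.site_kind!r}")


@dataclass(frozen=True)
class CodingVariant:
    snp_id: str
    protein_id: str
    residue_index: int  # 1-based
    aa_change: str = ""

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")


@dataclass(frozen=True)
class NetworkEdgeRow:
    """One tissue-specific TF -> element -> target link as read from disk."""

    tf: str
    element_id: str
    element_kind: str
    target: str
    tissue: str

    def __post_init__(self) -> None:
        if self.element_kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element_kind {self.element_kind!r}")


@dataclass(frozen=True)
class GeneDiseaseRow:
    gene_id: str
    disease: str


@dataclass(frozen=True)
class SnpPosition:
    """Bare SNP coordinates (used for LD proxy SNPs)."""

    snp_id: str
    position: GenomePosition


# ---------------------------------------------------------------------------
# low-level TSV plumbing


def _rows(path) -> Iterator[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.rstrip("\n").split("\t")


def _header_map(
    path, lineno: int, fields: list[str], required: Sequence[str], optional: Sequence[str] = ()
) -> dict[str, int]:
    missing = [c for c in required if c not in fields]
    if missing:
        raise TableFormatError(path, lineno, f"missing required column(s) {missing}")
    allowed = set(required) | set(optional)
    extra = [c for c in fields if c not in allowed]
    if extra:
        raise TableFormatError(path, lineno, f"unexpected column(s) {extra}")
    return {c: fields.index(c) for c in fields}


def _float(path, lineno: int, value: str, column: str) -> float:
    try:
        x = float(value)
    except ValueError:
        raise TableFormatError(path, lineno, f"non-numeric {column} {value!r}") from None
    if math.isnan(x):
        raise TableFormatError(path, lineno, f"{column} is NaN")
    return x


def _int(path, lineno: int, value: str, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise TableFormatError(path, lineno, f"non-integer {column} {value!r}") from None


def normalize_chrom(chrom: str, style: Optional[str] = None) -> str:
    """Optionally strip/add the ``chr`` prefix; ``style`` is None (exact),
    ``"chr"`` or ``"plain"``."""
    if style is None:
        return chrom
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{bare}" if style == "chr" else bare


class _TsvReader:
    """Iterate validated field dicts from one TSV file."""

    def __init__(self, path, required: Sequence[str], optional: Sequence[str] = ()):
        self.path = path
        self.required = required
        self.optional = optional

    def __iter__(self) -> Iterator[tuple[int, dict[str, str]]]:
        colmap: Optional[dict[str, int]] = None
        n_cols = 0
        for lineno, fields in _rows(self.path):
            if colmap is None:
                colmap = _header_map(self.path, lineno, fields, self.required, self.optional)
                n_cols = len(fields)
                continue
            if len(fields) != n_cols:
                raise TableFormatError(
                    self.path, lineno, f"expected {n_cols} columns, found {len(fields)}"
                )
            yield lineno, {c: fields[i] for c, i in colmap.items()}
        if colmap is None:
            raise TableFormatError(self.path, None, "empty file (no header)")


# ---------------------------------------------------------------------------
# readers


def read_snp_catalog(path, source: str, chrom_style: Optional[str] = None) -> list[SnpRecord]:
    """Read a SNP-trait association catalog.

    Columns: ``snp_id, chrom, pos, trait, p`` and optional ``n_cases``.
    Duplicate (snp_id, trait) rows collapse to the smallest p.  ``p`` must
    lie in (0, 1]; a catalog p of exactly 0 is rejected (downstream works on
    the log scale) — supply a small floor instead.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}")
    best: dict[tuple[str, str], SnpRecord] = {}
    order: list[tuple[str, str]] = []
    for lineno, row in _TsvReader(path, ["snp_id", "chrom", "pos", "trait", "p"], ["n_cases"]):
        p = _float(path, lineno, row["p"], "p")
        if not (0.0 < p <= 1.0):
            raise TableFormatError(path, lineno, f"p {p} outside (0,1]")
        pos = _int(path, lineno, row["pos"], "pos")
        if pos < 1:
            raise TableFormatError(path, lineno, f"pos {pos} must be >= 1")
        n_cases = None
        if "n_cases" in row and row["n_cases"] not in ("", "NA", "."):
            n_cases = _int(path, lineno, row["n_cases"], "n_cases")
            if n_cases < 0:
                raise TableFormatError(path, lineno, "negative n_cases")
        rec = SnpRecord(
            snp_id=row["snp_id"],
            position=GenomePosition(normalize_chrom(row["chrom"], chrom_style), pos),
            trait=row["trait"],
            p_value=p,
            n_cases=n_cases,
            source=source,
        )
        key = (rec.snp_id, rec.trait)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.p_value < best[key].p_value:
            best[key] = rec
    return [best[k] for k in order]


def read_bed_track(path, feature_kind: str, chrom_style: Optional[str] = None) -> list[GenomicInterval]:
    """Read a BED3+ track into half-open 0-based intervals.

    Optional columns 4-6 are name, score, strand; missing strand means
    unstranded.  For motif tracks the name column carries the TF name,
    stored in ``attrs["tf"]``; occurrence ids are made unique by suffixing
    the data-row ordinal.
    """
    out: list[GenomicInterval] = []
    ordinal = 0
    for lineno, fields in _rows(path):
        if len(fields) < 3:
            raise TableFormatError(path, lineno, "BED needs >= 3 columns")
        chrom = normalize_chrom(fields[0], chrom_style)
        start = _int(path, lineno, fields[1], "start")
        end = _int(path, lineno, fields[2], "end")
        if start < 0:
            raise TableFormatError(path, lineno, f"negative start {start}")
        if start >= end:
            raise TableFormatError(path, lineno, f"start >= end ({start} >= {end})")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
        strand = fields[5] if len(fields) > 5 else "."
        if strand not in ("+", "-", "."):
            raise TableFormatError(path, lineno, f"bad strand {strand!r}")
        ordinal += 1
        if feature_kind == "motif":
            tf = name or f"TF{ordinal}"
            iv = GenomicInterval(
                chrom, start, end, strand, f"{tf}|{ordinal}", "motif", {"tf": tf}
            )
        else:
            iv = GenomicInterval(
                chrom, start, end, strand, name or f"{feature_kind}{ordinal}", feature_kind
            )
        out.append(iv)
    return out


def write_bed_track(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED6; motif names come from ``attrs["tf"]``."""
    with open(path, "w", encoding="utf-8") as fh:
        for iv in intervals:
            name = iv.attrs.get("tf", iv.feature_id) if iv.feature_kind == "motif" else iv.feature_id
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name or '.'}\t.\t{iv.strand}\n")


def read_eqtl_table(path) -> list[EqtlRecord]:
    """Columns: ``snp_id, gene_id, tissue, fdr``.  The FDR <= 0.05
    significance rule is applied downstream, not at read time."""
    out = []
    for lineno, row in _TsvReader(path, ["snp_id", "gene_id", "tissue", "fdr"]):
        fdr = _float(path, lineno, row["fdr"], "fdr")
        if not (0.0 <= fdr <= 1.0):
            raise TableFormatError(path, lineno, f"fdr {fdr} outside [0,1]")
        out.append(EqtlRecord(row["snp_id"], row["gene_id"], row["tissue"], fdr))
    return out


def read_ld_table(path) -> list[LdPair]:
    """Columns: ``snp_a, snp_b, r2, distance_bp``.  Pair symmetry (a,b) ==
    (b,a) is realized by :class:`regcircuits.ld.LdTable`."""
    out = []
    for lineno, row in _TsvReader(path, ["snp_a", "snp_b", "r2", "distance_bp"]):
        r2 = _float(path, lineno, row["r2"], "r2")
        if not (0.0 <= r2 <= 1.0):
            raise TableFormatError(path, lineno, f"r2 {r2} outside [0,1]")
        dist = _int(path, lineno, row["distance_bp"], "distance_bp")
        if dist < 0:
            raise TableFormatError(path, lineno, "negative distance_bp")
        if row["snp_a"] == row["snp_b"]:
            raise TableFormatError(path, lineno, "self-pair (snp_a == snp_b)")
        out.append(LdPair(row["snp_a"], row["snp_b"], r2, dist))
    return out


def read_protein_sites(path) -> list[ProteinSite]:
    out = []
    for lineno, row in _TsvReader(path, ["protein_id", "residue_index", "site_kind"]):
        idx = _int(path, lineno, row["residue_index"], "residue_index")
        if idx < 1:
            raise TableFormatError(path, lineno, "residue_index must be >= 1")
        if row["site_kind"] not in SITE_KINDS:
            raise TableFormatError(path, lineno, f"unknown site_kind {row['site_kind']!r}")
        out.append(ProteinSite(row["protein_id"], idx, row["site_kind"]))
    return out


def read_coding_variants(path) -> list[CodingVariant]:
    out = []
    for lineno, row in _TsvReader(
        path, ["snp_id", "protein_id", "residue_index"], ["aa_change"]
    ):
        idx = _int(path, lineno, row["residue_index"], "residue_index")
        if idx < 1:
            raise TableFormatError(path, lineno, "residue_index must be >= 1")
        out.append(
            CodingVariant(row["snp_id"], row["protein_id"], idx, row.get("aa_change", ""))
        )
    return out


def read_network(path) -> list[NetworkEdgeRow]:
    out = []
    for lineno, row in _TsvReader(path, ["tf", "element_id", "element_kind", "target", "tissue"]):
        if row["element_kind"] not in ELEMENT_KINDS:
            raise TableFormatError(path, lineno, f"unknown element_kind {row['element_kind']!r}")
        out.append(
            NetworkEdgeRow(row["tf"], row["element_id"], row["element_kind"], row["target"], row["tissue"])
        )
    return out


def read_gene_disease_table(path) -> list[GeneDiseaseRow]:
    return [
        GeneDiseaseRow(row["gene_id"], row["disease"])
        for _, row in _TsvReader(path, ["gene_id", "disease"])
    ]


def read_snp_positions(path, chrom_style: Optional[str] = None) -> list[SnpPosition]:
    """Bare SNP coordinate table (``snp_id, chrom, pos``), e.g. LD proxies."""
    out = []
    for lineno, row in _TsvReader(path, ["snp_id", "chrom", "pos"]):
        pos = _int(path, lineno, row["pos"], "pos")
        if pos < 1:
            raise TableFormatError(path, lineno, f"pos {pos} must be >= 1")
        out.append(
            SnpPosition(row["snp_id"], GenomePosition(normalize_chrom(row["chrom"], chrom_style), pos))
        )
    return out


def read_expression_matrix(matrix_path, sample_map_path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Genes x samples matrix plus companion sample -> tissue map.

    Every matrix sample must appear in the map and all values must be
    non-negative finite numbers.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()][0]
        raise TableFormatError(matrix_path, None, f"duplicate gene id {dup!r}")
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise TableFormatError(matrix_path, None, f"non-numeric expression value: {exc}") from None
    if mat.isna().any().any():
        raise TableFormatError(matrix_path, None, "missing expression values")
    if (mat.values < 0).any():
        gene = mat.index[(mat.values < 0).any(axis=1)][0]
        raise TableFormatError(matrix_path, None, f"negative expression value for gene {gene!r}")
    sample_map: dict[str, str] = {}
    for lineno, row in _TsvReader(sample_map_path, ["sample", "tissue"]):
        if row["sample"] in sample_map:
            raise TableFormatError(sample_map_path, lineno, f"duplicate sample {row['sample']!r}")
        sample_map[row["sample"]] = row["tissue"]
    missing = [s for s in mat.columns if s not in sample_map]
    if missing:
        raise TableFormatError(
            sample_map_path, None, f"sample(s) {missing[:5]} in matrix missing from tissue map"
        )
    return mat, sample_map


# ---------------------------------------------------------------------------
# writers


def fmt_num(x) -> str:
    """Fixed 6-significant-digit rendering used by every writer."""
    if x is None:
        return "NA"
    if isinstance(x, bool):
        return "1" if x else "0"
    if isinstance(x, int):
        return str(x)
    return f"{x:.6g}"


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence], sort: bool = True) -> None:
    """Write a TSV deterministically: fixed column order, sorted rows
    (lexicographic on rendered fields), 6-significant-digit numbers."""
    rendered = [[v if isinstance(v, str) else fmt_num(v) for v in row] for row in rows]
    if sort:
        rendered.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rendered:
            fh.write("\t".join(row) + "\n")


def write_snp_catalog(records: Iterable[SnpRecord], path) -> None:
    write_tsv(
        path,
        ["snp_id", "chrom", "pos", "trait", "p", "n_cases"],
        [
            [
                r.snp_id,
                r.position.chrom,
                r.position.pos,
                r.trait,
                r.p_value,
                "NA" if r.n_cases is None else r.n_cases,
            ]
            for r in records
        ],
    )


def write_json(path, payload) -> None:
    """Deterministic JSON: sorted keys, newline-terminated."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def checksum(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
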