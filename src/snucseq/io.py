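"""Readers, writers and validated domain containers shared by every analysis stage.

All genomic coordinates are stored 0-based half-open.  GTF input (1-based,
inclusive) is converted on read; BED6 is written natively.  Expression
matrices are genes-as-rows with an FPKM layer and an optional integer count
layer of identical shape.  Readers reject malformed input rather than repair
it, and every writer round-trips through its reader.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "GeneAnnotationTable",
    "GeneSetPanel",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gtf",
    "write_gtf",
    "read_panels",
    "write_panels",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_config",
    "write_config",
]

CONDITIONS = ("Sham", "TAC", "Control", "DCM", "other")
ASSAY_LEVELS = ("single_nucleus", "pooled", "bulk")


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Gene x sample FPKM grid with an optional raw-count layer.

    ``fpkm`` is a DataFrame indexed by gene id with sample ids as columns.
    ``counts``, when present, is shape- and label-matched.
    """

    fpkm: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.fpkm = pd.DataFrame(self.fpkm).astype(float)
        if self.fpkm.index.has_duplicates:
            dup = self.fpkm.index[self.fpkm.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.fpkm.columns.has_duplicates:
            dup = self.fpkm.columns[self.fpkm.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        vals = self.fpkm.to_numpy()
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite FPKM at gene {self.fpkm.index[bad[0]]!r}, "
                f"sample {self.fpkm.columns[bad[1]]!r}"
            )
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative FPKM at gene {self.fpkm.index[bad[0]]!r}, "
                f"sample {self.fpkm.columns[bad[1]]!r}"
            )
        if self.counts is not None:
            self.counts = pd.DataFrame(self.counts)
            if self.counts.shape != self.fpkm.shape:
                raise ValueError("counts layer shape does not match fpkm layer")
            if not (self.counts.index.equals(self.fpkm.index)
                    and self.counts.columns.equals(self.fpkm.columns)):
                raise ValueError("counts layer labels do not match fpkm layer")
            cvals = self.counts.to_numpy()
            if not np.isfinite(cvals).all() or (cvals < 0).any():
                raise ValueError("counts layer must be finite and non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fpkm.columns)

    @property
    def n_genes(self) -> int:
        return self.fpkm.shape[0]

    @property
    def n_samples(self) -> int:
        return self.fpkm.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.fpkm.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        counts = self.counts[list(samples)] if self.counts is not None else None
        return ExpressionMatrix(self.fpkm[list(samples)], counts)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.fpkm.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        counts = self.counts.loc[list(genes)] if self.counts is not None else None
        return ExpressionMatrix(self.fpkm.loc[list(genes)], counts)


@dataclass
class SampleTable:
    """Per-sample metadata: condition, batch, assay level, optional subgroup."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "batch", "assay_level")

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table)
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"sample table missing column {col!r}")
        if "subgroup" not in t.columns:
            t = t.assign(subgroup=pd.NA)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        bad = set(t["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition(s): {sorted(bad)}; allowed {CONDITIONS}")
        bad = set(t["assay_level"]) - set(ASSAY_LEVELS)
        if bad:
            raise ValueError(f"unknown assay level(s): {sorted(bad)}; allowed {ASSAY_LEVELS}")
        self.table = t.reset_index(drop=True)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must appear exactly once."""
        ids = set(self.table["sample_id"])
        missing = [s for s in matrix.sample_ids if s not in ids]
        if missing:
            raise ValueError(f"matrix samples missing from sample table: {missing}")

    def samples_where(self, **conditions) -> list[str]:
        t = self.table
        for col, val in conditions.items():
            t = t[t[col] == val]
        return list(t["sample_id"])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])


@dataclass
class GeneAnnotationTable:
    """Gene/transcript loci with exon chains, 0-based half-open."""

    table: pd.DataFrame  # gene_id, chrom, start, end, strand, biotype, exons, length

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table)
        required = ("gene_id", "chrom", "start", "end", "strand", "biotype", "exons")
        for col in required:
            if col not in t.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        for row in t.itertuples(index=False):
            if not row.start < row.end:
                raise ValueError(f"{row.gene_id}: start {row.start} not < end {row.end}")
            if row.strand not in ("+", "-"):
                raise ValueError(f"{row.gene_id}: bad strand {row.strand!r}")
            exons = list(row.exons)
            if sorted(exons) != exons:
                raise ValueError(f"{row.gene_id}: exons not sorted")
            for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
                if s1 < e0:
                    raise ValueError(f"{row.gene_id}: overlapping exons ({s0},{e0}) ({s1},{e1})")
            for s, e in exons:
                if s < row.start or e > row.end:
                    raise ValueError(f"{row.gene_id}: exon ({s},{e}) outside span")
        if "length" not in t.columns:
            t = t.assign(length=[sum(e - s for s, e in ex) for ex in t["exons"]])
        self.table = t.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def lengths(self) -> pd.Series:
        return self.table.set_index("gene_id")["length"]


@dataclass
class GeneSetPanel:
    """Named marker panel (e.g. proliferation, negative regulators)."""

    name: str
    role: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if not members:
            raise ValueError(f"panel {self.name!r} is empty")
        if len(set(members)) != len(members):
            raise ValueError(f"panel {self.name!r} has duplicate members")
        self.members = members


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path, fmt: str = "tsv") -> ExpressionMatrix:
    """Read a gene x sample FPKM matrix from TSV or MatrixMarket MTX.

    TSV: first column gene ids, header row sample ids. MTX: `path` plus
    sibling ``<path>.rows`` / ``<path>.cols`` index files.
    """
    path = Path(path)
    if fmt == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ncol = len(header)
            for lineno, line in enumerate(fh, start=2):
                nfields = line.count("\t") + 1
                if nfields != ncol:
                    raise ValueError(f"{path}:{lineno}: ragged row ({nfields} fields, expected {ncol})")
        df = pd.read_csv(path, sep="\t", index_col=0, na_filter=False)
        # reject non-numeric cells (e.g. "NA") explicitly rather than coerce
        for col in df.columns:
            if df[col].dtype == object:
                coerced = pd.to_numeric(df[col], errors="coerce")
                if coerced.isna().any():
                    gene = df.index[coerced.isna()][0]
                    raise ValueError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
                df[col] = coerced
        return ExpressionMatrix(df)
    if fmt == "mtx":
        raw = mmread(path)
        m = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        if len(rows) != m.shape[0] or len(cols) != m.shape[1]:
            raise ValueError(f"{path}: index files do not match matrix shape {m.shape}")
        return ExpressionMatrix(pd.DataFrame(m, index=rows, columns=cols))
    raise ValueError(f"unknown matrix format {fmt!r}")


def write_expression_matrix(matrix: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        matrix.fpkm.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.10g")
    elif fmt == "mtx":
        mmwrite(str(path), coo_matrix(matrix.fpkm.to_numpy()))
        # mmwrite appends .mtx if missing; normalise
        written = path if path.exists() else Path(str(path) + ".mtx")
        if written != path:
            written.rename(path)
        Path(str(path) + ".rows").write_text("\n".join(matrix.gene_ids) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(matrix.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attrs(s: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(s))


def read_gtf(path) -> GeneAnnotationTable:
    """Parse a GTF into a transcript-level annotation table.

    GTF 1-based inclusive coordinates become 0-based half-open.  Exons are
    grouped per transcript; transcript length is the exon-length sum.
    Validation failures (end < start, unknown strand, overlapping exons)
    raise with the offending line number.
    """
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end {end_i} < start {start_i}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            a = _parse_attrs(attrs)
            tx = a.get("transcript_id") or a.get("gene_id")
            if tx is None:
                raise ValueError(f"{path}:{lineno}: no transcript_id/gene_id attribute")
            rec = per_tx.setdefault(
                tx,
                {"gene_id": tx, "chrom": chrom, "strand": strand,
                 "biotype": a.get("gene_biotype", a.get("transcript_biotype", "other")),
                 "exons": [], "lines": []},
            )
            if feature == "exon":
                rec["exons"].append((start_i - 1, end_i))  # to 0-based half-open
                rec["lines"].append(lineno)
            elif feature in ("gene", "transcript") and not rec["exons"]:
                rec.setdefault("span", (start_i - 1, end_i))
    rows = []
    for tx, rec in per_tx.items():
        exons = sorted(rec["exons"]) or [rec.get("span", (0, 1))]
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                first = min(rec["lines"], default="?")
                raise ValueError(
                    f"{path}: transcript {tx!r} (first exon line {first}): "
                    f"overlapping exon records ({s0},{e0}) and ({s1},{e1})"
                )
        rows.append({
            "gene_id": tx, "chrom": rec["chrom"],
            "start": exons[0][0], "end": exons[-1][1],
            "strand": rec["strand"],
            "biotype": rec["biotype"] if rec["biotype"] in ("coding", "linc") else "other",
            "exons": exons,
            "length": sum(e - s for s, e in exons),
        })
    return GeneAnnotationTable(pd.DataFrame(rows))


def write_gtf(table: GeneAnnotationTable, path, source: str = "snucseq") -> None:
    """Emit transcript + exon lines; 0-based half-open back to GTF 1-based."""
    with open(path, "w") as fh:
        for row in table.table.itertuples(index=False):
            attrs = (f'gene_id "{row.gene_id}"; transcript_id "{row.gene_id}"; '
                     f'gene_biotype "{row.biotype}";')
            fh.write("\t".join([row.chrom, source, "transcript", str(row.start + 1),
                                str(row.end), ".", row.strand, ".", attrs]) + "\n")
            for s, e in row.exons:
                fh.write("\t".join([row.chrom, source, "exon", str(s + 1),
                                    str(e), ".", row.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# panels / FASTA / BED


def read_panels(path) -> list[GeneSetPanel]:
    """Panels as a line-oriented file: ``>name<TAB>role`` headers, one member per line."""
    panels: list[GeneSetPanel] = []
    name = role = None
    members: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None:
                    panels.append(GeneSetPanel(name, role, tuple(members)))
                head = line[1:].split("\t")
                name = head[0]
                role = head[1] if len(head) > 1 else name
                members = []
            else:
                members.append(line)
    if name is not None:
        panels.append(GeneSetPanel(name, role, tuple(members)))
    return panels


def write_panels(panels: Iterable[GeneSetPanel], path) -> None:
    with open(path, "w") as fh:
        for p in panels:
            fh.write(f">{p.name}\t{p.role}\n")
            for m in p.members:
                fh.write(m + "\n")


def read_fasta(path) -> dict[str, str]:
    """FASTA id → uppercase sequence; duplicate ids rejected."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bed(table: GeneAnnotationTable, path) -> None:
    """BED6: chrom, start, end, name, score '.', strand (0-based half-open)."""
    with open(path, "w") as fh:
        for row in table.table.itertuples(index=False):
            fh.write("\t".join([row.chrom, str(row.start), str(row.end),
                                row.gene_id, ".", row.strand]) + "\n")


# ---------------------------------------------------------------------------
# structured config


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
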