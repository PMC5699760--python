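"""Readers and writers for the on-disk formats, plus the packaged fixture.

Canonical tabular dialect: tab-delimited, one header row, UTF-8, "." decimal;
scientific notation is accepted on read. Gene sets use the GMT convention
(term TAB description TAB gene ...). Network edges are written both as SIF
(``geneA pp geneB``) and as a weighted three-column TSV.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneTable, SampleTable, ValidationError
from .diffexpr import DiffExprResult
from .enrichment import EnrichmentResult, GeneSetCollection

TABLE1_SHA256 = "359794283dd31ad3c38de91357baede8a08533ab0dfa692994c7568bcafa7021"


class ParseError(ValueError):
    """A file could not be parsed; the message cites file and line."""


class IntegrityError(RuntimeError):
    """A packaged data file does not match its recorded checksum."""


# ---------------------------------------------------------------- fixture


def load_table1_fixture() -> list[DiffExprResult]:
    """The packaged table of 77 sex-dimorphic hepatic DMET genes.

    Each record carries the published P-value, fold change (linear scale,
    >= 1) and bias direction; group means and t statistics were not
    published and are None. The file's checksum is verified on every load.
    """
    ref = resources.files("hepatodimorph").joinpath("data/table1_dmet.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise IntegrityError(
            f"packaged fixture checksum mismatch: expected {TABLE1_SHA256}, got {digest}"
        )
    import io as _io

    frame = pd.read_csv(_io.BytesIO(raw), sep="\t")
    records = [
        DiffExprResult(
            gene_id=row.symbol,
            symbol=row.symbol,
            fold_change=float(row.fold_change),
            bias=str(row.bias),
            p_value=float(row.p_value),
        )
        for row in frame.itertuples(index=False)
    ]
    if len(records) != 77:
        raise IntegrityError(f"fixture must have 77 records, found {len(records)}")
    return records


# ---------------------------------------------------------------- expression


def read_expression_tsv(path) -> ExpressionMatrix:
    """Genes x samples TSV: header = sample ids, first column = gene ids."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pandas raises many flavours
        raise ParseError(f"{path}: cannot parse expression TSV ({exc})") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        line = int(np.where(frame.index == dup)[0][1]) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}:{line}: duplicate gene_id {dup!r}")
    values = frame.to_numpy()
    if values.dtype.kind not in "fiu":
        bad = frame.columns[
            [frame[c].dtype.kind not in "fiu" for c in frame.columns]
        ][0]
        raise ParseError(f"{path}: non-numeric expression values in column {bad!r}")
    return ExpressionMatrix(
        [str(g) for g in frame.index], [str(s) for s in frame.columns], values
    )


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------- samples


def read_sample_sheet(path) -> SampleTable:
    """Two-column TSV: sample_id, sex (M or F)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "sex"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    for i, sex in enumerate(frame["sex"]):
        if sex not in ("M", "F"):
            raise ParseError(f"{path}:{i + 2}: sex must be M or F, got {sex!r}")
    try:
        return SampleTable(list(frame["sample_id"]), list(frame["sex"]))
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_sample_sheet(samples: SampleTable, path) -> None:
    samples.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- genes


def read_gene_table(path) -> GeneTable:
    """Gene annotation TSV: gene_id, symbol, chromosome, is_dmet [+ extras]."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    required = ("gene_id", "symbol", "chromosome", "is_dmet")
    for col in required:
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    is_dmet = [
        str(v).strip().lower() in ("1", "true", "yes") for v in frame["is_dmet"]
    ]
    extra_cols = [c for c in frame.columns if c not in required]
    try:
        return GeneTable(
            list(frame["gene_id"]),
            [str(s) for s in frame["symbol"]],
            [str(c) for c in frame["chromosome"]],
            is_dmet,
            extra=frame[extra_cols] if extra_cols else None,
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_gene_table(genes: GeneTable, path) -> None:
    genes.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- gene sets


def read_gmt(path, category: str | None = None) -> GeneSetCollection:
    """GMT file: one gene set per line (term TAB description TAB gene ...)."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs term, description and >=1 gene"
                )
            term, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in sets:
                raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = set(members)
            descriptions[term] = desc
    return GeneSetCollection(category or path.stem, sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for term in sorted(collection.sets):
            desc = collection.descriptions.get(term, "")
            members = "\t".join(sorted(collection.sets[term]))
            handle.write(f"{term}\t{desc}\t{members}\n")


# ---------------------------------------------------------------- results


def write_screen_results(results: list[DiffExprResult], path) -> None:
    """Ranked screen output mirroring the published table layout."""
    frame = pd.DataFrame(
        {
            "rank": range(1, len(results) + 1),
            "gene_id": [r.gene_id for r in results],
            "symbol": [r.symbol or r.gene_id for r in results],
            "p_value": [r.p_value for r in results],
            "fold_change": [r.fold_change for r in results],
            "bias": [r.bias for r in results],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_module_assignment(assignment, path) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": list(assignment.labels),
            "module": [assignment.labels[g] for g in assignment.labels],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_module_assignment(path):
    from .network import ModuleAssignment

    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "module"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return ModuleAssignment(dict(zip(frame["gene_id"], frame["module"])))


def write_beta_diagnostics(fits, path) -> None:
    frame = pd.DataFrame(
        {
            "beta": [f.beta for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "slope": [f.slope for f in fits],
            "signed_index": [f.signed_index for f in fits],
            "bins_used": [f.bins_used for f in fits],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dendrogram(dendrogram, path) -> None:
    frame = pd.DataFrame(
        dendrogram.merges, columns=["cluster_a", "cluster_b", "height", "size"]
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_edges_sif(edges, path, interaction: str = "pp") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for a, b, _w in edges:
            handle.write(f"{a}\t{interaction}\t{b}\n")


def write_edges_tsv(edges, path) -> None:
    frame = pd.DataFrame(edges, columns=["gene_a", "gene_b", "weight"])
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_enrichment_results(results: list[EnrichmentResult], path) -> None:
    frame = pd.DataFrame(
        {
            "module": [r.module for r in results],
            "category": [r.category for r in results],
            "term": [r.term for r in results],
            "count": [r.count for r in results],
            "percent": [round(r.percent, 2) for r in results],
            "p_value": [r.p_value for r in results],
            "p_bonferroni": [r.p_bonferroni for r in results],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
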