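"""Readers and writers for every format the toolkit touches.

All tables are tab-separated UTF-8 with a required header row; missing
values are empty strings.  Writers emit full-precision floats (Python
``repr``) so that read(write(rows)) == rows exactly.  Readers reject,
never coerce, malformed numeric cells.

Pathways are read from KGML (KEGG Markup Language) XML: gene-type entries
become gene nodes (an entry naming k genes expands to k nodes inheriting
the entry's relations), relations become undirected edges, and group
entries are flattened to their component gene entries.  Map, compound and
ortholog entries are dropped — only gene nodes can carry screen hits.
"""

from __future__ import annotations

import dataclasses
import json
import types
import typing
from pathlib import Path
from typing import Iterable, Sequence, Type, TypeVar

import pandas as pd
from lxml import etree

from .errors import FormatError
from .pathways import PathwayGraph, build_pathway_graph
from .screen import GeneScore, HitCall, NullModel, ShRNACountRecord
from .store import MutationRecord, OmicsStore, ProteinRecord

T = TypeVar("T")

DELIMITER = "\t"
MISSING = ""

#: Column order for signature tables, mirroring the published layout.
SIGNATURE_COLUMNS = (
    "gene", "quant_log", "rank", "is_hit", "expression_lfc",
    "dna_amp", "mutation", "cosmic_occurrences", "drugs",
)


# -- generic dataclass-row tables -------------------------------------------


def _cell_to_str(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, (tuple, list)):
        return ", ".join(str(v) for v in value)
    return str(value)


def _str_to_cell(text: str, annot, path: Path, row_no: int, column: str):
    origin = typing.get_origin(annot)
    if origin in (typing.Union, types.UnionType):
        args = [a for a in typing.get_args(annot) if a is not type(None)]
        if text == MISSING:
            return None
        annot, origin = args[0], typing.get_origin(args[0])
    if origin in (tuple, list):
        if text == MISSING:
            return () if origin is tuple else []
        parts = [p.strip() for p in text.split(",")]
        return tuple(parts) if origin is tuple else parts
    if annot is bool:
        if text not in ("0", "1"):
            raise FormatError(
                f"{path}: row {row_no}, column {column!r}: expected 0/1, got {text!r}"
            )
        return text == "1"
    if annot is int:
        try:
            return int(text)
        except ValueError:
            raise FormatError(
                f"{path}: row {row_no}, column {column!r}: not an integer: {text!r}"
            ) from None
    if annot is float:
        try:
            return float(text)
        except ValueError:
            raise FormatError(
                f"{path}: row {row_no}, column {column!r}: not a number: {text!r}"
            ) from None
    return text


def write_table(rows: Sequence, path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous dataclass rows as a TSV; empty input yields a
    header-only file (columns then taken from the declared order, if given)."""
    path = Path(path)
    if rows:
        row_type = type(rows[0])
        names = [f.name for f in dataclasses.fields(row_type)]
    else:
        names = list(columns) if columns else []
    if columns:
        names = list(columns)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(DELIMITER.join(names) + "\n")
        for row in rows:
            fh.write(
                DELIMITER.join(
                    _cell_to_str(getattr(row, c)) for c in names
                ) + "\n"
            )


def read_table(path, row_type: Type[T], columns: Sequence[str] | None = None) -> list[T]:
    """Read a TSV written by :func:`write_table` back into dataclass rows."""
    path = Path(path)
    hints = typing.get_type_hints(row_type)
    field_names = [f.name for f in dataclasses.fields(row_type)]
    with path.open("r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, header required")
        header = header_line.rstrip("\n").split(DELIMITER)
        for name in columns or field_names:
            if name not in header:
                raise FormatError(f"{path}: missing required column {name!r}")
        rows = []
        for row_no, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split(DELIMITER)
            if len(cells) != len(header):
                raise FormatError(
                    f"{path}: row {row_no}: expected {len(header)} cells, "
                    f"got {len(cells)}"
                )
            by_name = dict(zip(header, cells))
            kwargs = {
                name: _str_to_cell(by_name[name], hints[name], path, row_no, name)
                for name in field_names
                if name in by_name
            }
            rows.append(row_type(**kwargs))
    return rows


# -- shRNA count tables ------------------------------------------------------


def read_count_table(path) -> list[ShRNACountRecord]:
    """Read an shRNA count table (shrna_id, gene, count_ref, count_final).

    Counts must be non-negative integers; violations raise a FormatError
    citing the row number.
    """
    records = read_table(path, ShRNACountRecord)
    for i, rec in enumerate(records, start=2):
        for col in ("count_ref", "count_final"):
            if getattr(rec, col) < 0:
                raise FormatError(
                    f"{path}: row {i}: negative {col} for shRNA {rec.shrna_id!r}"
                )
        if not rec.gene:
            raise FormatError(f"{path}: row {i}: empty gene symbol")
    seen: set[str] = set()
    for rec in records:
        if rec.shrna_id in seen:
            raise FormatError(f"{path}: duplicate shrna_id {rec.shrna_id!r}")
        seen.add(rec.shrna_id)
    return records


def write_count_table(records: Sequence[ShRNACountRecord], path) -> None:
    write_table(records, path)


# -- hit calls and null models ----------------------------------------------


def write_hit_table(hits: Sequence[HitCall], path) -> None:
    write_table(hits, path, columns=("gene", "quant_log", "rank", "is_hit"))


def read_hit_table(path) -> list[HitCall]:
    return read_table(path, HitCall)


def write_null_model(null: NullModel, path) -> None:
    Path(path).write_text(
        json.dumps(dataclasses.asdict(null), indent=2) + "\n", encoding="utf-8"
    )


def read_null_model(path) -> NullModel:
    return NullModel(**json.loads(Path(path).read_text(encoding="utf-8")))


# -- KGML ---------------------------------------------------------------------


def read_kgml(path) -> PathwayGraph:
    """Parse a KGML pathway file into an undirected gene graph."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: malformed KGML XML: {exc}") from exc
    root = tree.getroot()
    pathway_id = root.get("name", "") or root.get("number", "")
    title = root.get("title", "")

    entry_genes: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        etype = entry.get("type")
        eid = entry.get("id")
        if etype == "gene":
            names = (entry.get("name") or "").split()
            entry_genes[eid] = [n.split(":", 1)[-1] for n in names]
        elif etype == "group":
            groups[eid] = [c.get("id") for c in entry.findall("component")]

    def genes_of(eid: str) -> list[str]:
        if eid in entry_genes:
            return entry_genes[eid]
        if eid in groups:
            out: list[str] = []
            for comp in groups[eid]:
                out.extend(genes_of(comp))
            return out
        return []

    edges: list[tuple[str, str]] = []
    for rel in root.findall("relation"):
        for g1 in genes_of(rel.get("entry1")):
            for g2 in genes_of(rel.get("entry2")):
                edges.append((g1, g2))
    nodes = sorted({g for genes in entry_genes.values() for g in genes})
    return build_pathway_graph(pathway_id, title, nodes, edges)


# -- omics store --------------------------------------------------------------


def _read_frame(path, required: Sequence[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=DELIMITER, dtype={"cell_line": str, "gene": str})
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return frame


def read_omics_tables(
    cna=None,
    expression=None,
    expression_dialect: str | None = None,
    mutations=None,
    oncogenes=None,
    drugs=None,
    hits: dict[str, object] | None = None,
    rppa=None,
) -> OmicsStore:
    """Assemble an :class:`OmicsStore` from per-layer TSV paths.

    Absent layers stay absent and are reported as such on query.  ``hits``
    maps cell-line name to a hit-table path.
    """
    cna_frame = _read_frame(cna, ("cell_line", "gene", "dna_amp")) if cna else None
    expr_frame = (
        _read_frame(expression, ("cell_line", "gene", "expression_lfc"))
        if expression
        else None
    )
    mutation_records = read_table(mutations, MutationRecord) if mutations else []
    oncogene_set = (
        frozenset(
            line.strip()
            for line in Path(oncogenes).read_text(encoding="utf-8").splitlines()
            if line.strip()
        )
        if oncogenes
        else None
    )
    drug_map: dict[str, tuple[str, ...]] | None = None
    if drugs:
        frame = _read_frame(drugs, ("gene", "drug"))
        drug_map = {
            gene: tuple(sub["drug"])
            for gene, sub in frame.groupby("gene", sort=True)
        }
    hit_map = {
        line: read_hit_table(path) for line, path in (hits or {}).items()
    }
    protein_records = read_table(rppa, ProteinRecord) if rppa else []
    return OmicsStore(
        cna=cna_frame,
        expression=expr_frame,
        expression_dialect=expression_dialect if expr_frame is not None else None,
        mutations=mutation_records,
        hits=hit_map,
        oncogenes=oncogene_set,
        drugs=drug_map,
        proteins=protein_records,
    )


def read_store(directory) -> OmicsStore:
    """Read the documented store-directory layout.

    Layout: cna.tsv, expr.tsv (+ meta.json carrying the expression dialect),
    mutations.tsv, oncogenes.txt, drugs.tsv, hits/<cell_line>.tsv, rppa.tsv.
    Missing files mean absent layers.
    """
    directory = Path(directory)

    def opt(name: str):
        p = directory / name
        return p if p.exists() else None

    dialect = None
    meta = directory / "meta.json"
    if meta.exists():
        dialect = json.loads(meta.read_text(encoding="utf-8")).get(
            "expression_dialect"
        )
    hits_dir = directory / "hits"
    hit_paths = (
        {p.stem: p for p in sorted(hits_dir.glob("*.tsv"))}
        if hits_dir.is_dir()
        else {}
    )
    return read_omics_tables(
        cna=opt("cna.tsv"),
        expression=opt("expr.tsv"),
        expression_dialect=dialect,
        mutations=opt("mutations.tsv"),
        oncogenes=opt("oncogenes.txt"),
        drugs=opt("drugs.tsv"),
        hits=hit_paths,
        rppa=opt("rppa.tsv"),
    )


def write_store(store: OmicsStore, directory) -> None:
    """Write a store back to the directory layout read by :func:`read_store`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if store.cna is not None:
        store.cna.to_csv(directory / "cna.tsv", sep=DELIMITER, index=False)
    if store.expression is not None:
        store.expression.to_csv(directory / "expr.tsv", sep=DELIMITER, index=False)
        (directory / "meta.json").write_text(
            json.dumps({"expression_dialect": store.expression_dialect}) + "\n",
            encoding="utf-8",
        )
    if store.mutations:
        write_table(store.mutations, directory / "mutations.tsv")
    if store.oncogenes is not None:
        (directory / "oncogenes.txt").write_text(
            "\n".join(sorted(store.oncogenes)) + "\n", encoding="utf-8"
        )
    if store.drugs is not None:
        rows = [
            (gene, drug)
            for gene in sorted(store.drugs)
            for drug in store.drugs[gene]
        ]
        pd.DataFrame(rows, columns=["gene", "drug"]).to_csv(
            directory / "drugs.tsv", sep=DELIMITER, index=False
        )
    if store.hits:
        hits_dir = directory / "hits"
        hits_dir.mkdir(exist_ok=True)
        for line, calls in store.hits.items():
            write_hit_table(calls, hits_dir / f"{line}.tsv")
    if store.proteins:
        write_table(store.proteins, directory / "rppa.tsv")
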