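"""Readers and writers for transect artifacts.

Formats handled here are deliberately plain:

* OTU tables: tab-separated text (OTUs x samples or samples x OTUs,
  orientation auto-detected from the first header cell) or BIOM 1.0 JSON
  (dense and sparse ``matrix_type``).
* Taxonomy: two-column TSV ``otu_id<TAB>lineage``.
* Metadata / environmental / qPCR tables: TSV keyed by sample or site.
* Dendrograms: newick with branch lengths.
* Options: a single YAML config file with one section per CLI command.

TSV dialect: UTF-8, tab-delimited, lines starting with ``#`` are comments
(except a classic ``#OTU ID`` header line), first header cell arbitrary.
"""

from __future__ import annotations

import json
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, ValidationError
from .tables import REQUIRED_SAMPLE_COLUMNS, CountTable, TransectMetadata

_OTU_HEADER_HINTS = {"otu_id", "otu id", "#otu id", "otu", "observation_id"}
_SAMPLE_HEADER_HINTS = {"sample_id", "sample id", "sample"}


# ---------------------------------------------------------------------------
# count tables
# ---------------------------------------------------------------------------

def _read_tsv_frame(path: str | Path) -> pd.DataFrame:
    lines = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#") and not line.lower().startswith("#otu id"):
            continue
        if line.strip() == "":
            continue
        lines.append(line)
    if not lines:
        raise ParseError(f"{path}: no content after removing comments")
    header = [c.strip() for c in lines[0].split("\t")][1:]
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ValidationError(f"{path}: duplicate header ids {dupes}")
    return pd.read_csv(StringIO("\n".join(lines)), sep="\t", dtype=str, index_col=0)


def read_count_table(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "auto",
    taxonomy: str | Path | None = None,
) -> CountTable:
    """Read and validate an OTU count table.

    Parameters
    ----------
    format
        ``"tsv"`` or ``"biom"`` (BIOM 1.0 JSON).
    orientation
        For TSV only: ``"otus_as_rows"``, ``"samples_as_rows"`` or ``"auto"``
        (decide from the first header cell; defaults to OTUs as rows, the
        classic convention).
    taxonomy
        Optional path to a two-column lineage TSV attached to the result.
    """
    if format == "biom":
        table = _read_biom_json(path)
    elif format == "tsv":
        frame = _read_tsv_frame(path)
        corner = str(frame.index.name or "").strip().lower()
        if orientation == "auto":
            if corner in _SAMPLE_HEADER_HINTS:
                orientation = "samples_as_rows"
            else:
                orientation = "otus_as_rows"
        if orientation == "otus_as_rows":
            frame = frame.T
        elif orientation != "samples_as_rows":
            raise ValueError(f"unknown orientation {orientation!r}")
        counts = _parse_count_cells(frame)
        table = CountTable(
            sample_ids=[str(s) for s in frame.index],
            otu_ids=[str(o) for o in frame.columns],
            counts=counts,
        )
    else:
        raise ValueError(f"unknown count-table format {format!r}")
    if taxonomy is not None:
        tax = read_taxonomy(taxonomy)
        table.taxonomy = {o: tax[o] for o in table.otu_ids if o in tax}
    return table


def _parse_count_cells(frame: pd.DataFrame) -> np.ndarray:
    values = np.empty(frame.shape, dtype=np.int64)
    raw = frame.to_numpy()
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            cell = str(raw[i, j]).strip()
            try:
                x = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric count {cell!r} at row {frame.index[i]!r}, "
                    f"column {frame.columns[j]!r}"
                ) from None
            if x < 0 or x != int(x):
                raise ParseError(
                    f"count must be a non-negative integer, got {cell!r} at "
                    f"row {frame.index[i]!r}, column {frame.columns[j]!r}"
                )
            values[i, j] = int(x)
    return values


def _read_biom_json(path: str | Path) -> CountTable:
    """Minimal BIOM 1.0 (JSON) reader: rows are observations, columns samples."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        otu_ids = [str(r["id"]) for r in doc["rows"]]
        sample_ids = [str(c["id"]) for c in doc["columns"]]
        matrix_type = doc.get("matrix_type", "sparse")
        shape = tuple(doc["shape"])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: not a BIOM 1.0 JSON table ({exc})") from None
    if shape != (len(otu_ids), len(sample_ids)):
        raise ValidationError(f"{path}: BIOM shape {shape} inconsistent with ids")
    mat = np.zeros(shape, dtype=np.int64)
    if matrix_type == "dense":
        mat[:, :] = np.asarray(doc["data"])
    elif matrix_type == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        raise SchemaError(f"{path}: unknown BIOM matrix_type {matrix_type!r}")
    taxonomy = {}
    for row, otu in zip(doc["rows"], otu_ids):
        meta = row.get("metadata") or {}
        lineage = meta.get("taxonomy")
        if lineage:
            if isinstance(lineage, (list, tuple)):
                lineage = ";".join(str(t) for t in lineage)
            taxonomy[otu] = str(lineage)
    return CountTable(
        sample_ids=sample_ids,
        otu_ids=otu_ids,
        counts=mat.T,
        taxonomy=taxonomy or None,
    )


def write_count_table(table: CountTable, path: str | Path, orientation: str = "otus_as_rows") -> None:
    df = table.to_dataframe()
    if orientation == "otus_as_rows":
        df = df.T
        df.index.name = "otu_id"
    else:
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    frame = _read_tsv_frame(path)
    if frame.shape[1] < 1:
        raise SchemaError(f"{path}: taxonomy file needs two columns (otu_id, lineage)")
    return {str(i): str(v) for i, v in frame.iloc[:, 0].items()}


def write_taxonomy(taxonomy: dict[str, str], path: str | Path) -> None:
    pd.Series(taxonomy, name="lineage").rename_axis("otu_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# metadata / per-site tables
# ---------------------------------------------------------------------------

def read_metadata(
    path: str | Path,
    env_path: str | Path | None = None,
    qpcr_path: str | Path | None = None,
) -> TransectMetadata:
    """Read sample metadata (and optional env/qPCR site tables).

    River sites come back sorted by distance; the lake is normalized to 0 m.
    """
    df = _read_tsv_frame(path).reset_index()
    df = df.rename(columns={df.columns[0]: "sample_id"})
    missing = [c for c in REQUIRED_SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing metadata column(s) {missing}")
    env = _read_site_table(env_path) if env_path is not None else None
    qpcr = _read_site_table(qpcr_path) if qpcr_path is not None else None
    return TransectMetadata(samples=df, env=env, qpcr=qpcr)


def _read_site_table(path: str | Path) -> pd.DataFrame:
    frame = _read_tsv_frame(path)
    frame.index.name = "site_id"
    return frame.apply(pd.to_numeric, errors="coerce")


def write_metadata(metadata: TransectMetadata, path: str | Path) -> None:
    metadata.samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# proportion tables (directory of three TSVs)
# ---------------------------------------------------------------------------

def write_proportions(props, outdir: str | Path, prefix: str = "") -> None:
    """Write a ProportionTable as proportions/detection/otu_totals TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    props.to_dataframe().rename_axis("site_id").to_csv(
        outdir / f"{prefix}proportions.tsv", sep="\t"
    )
    props.detection_frame().astype(int).rename_axis("site_id").to_csv(
        outdir / f"{prefix}detection.tsv", sep="\t"
    )
    pd.Series(props.otu_totals, index=props.otu_ids, name="total").rename_axis(
        "otu_id"
    ).to_csv(outdir / f"{prefix}otu_totals.tsv", sep="\t")


def read_proportions(outdir: str | Path, prefix: str = ""):
    from .tables import ProportionTable

    outdir = Path(outdir)
    p = pd.read_csv(outdir / f"{prefix}proportions.tsv", sep="\t", index_col=0)
    d = pd.read_csv(outdir / f"{prefix}detection.tsv", sep="\t", index_col=0)
    t = pd.read_csv(outdir / f"{prefix}otu_totals.tsv", sep="\t", index_col=0)
    otus = [str(c) for c in p.columns]
    return ProportionTable(
        site_ids=[str(s) for s in p.index],
        otu_ids=otus,
        proportions=p.to_numpy(float),
        detected=d.to_numpy(float).astype(bool),
        otu_totals=t.iloc[:, 0].reindex(otus).to_numpy(float),
        provenance=("filter_taxa", "rarefy", "duplicate_consistency", "average_duplicates"),
    )


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Serialize a UPGMA dendrogram to newick with branch lengths.

    ``tree`` is a :class:`riverdrift.community.Dendrogram`. Leaf-to-root
    distances equal half the merge dissimilarity, so the cophenetic distance
    between two leaves is recovered as their tip-to-tip path length.
    """
    labels = list(tree.labels)
    if len(labels) < 2:
        raise ValidationError("newick export needs a tree with >= 2 leaves")
    _check_unique_labels(labels)
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def _check_unique_labels(labels) -> None:
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate leaf labels in tree")


def read_newick(path: str | Path):
    """Parse a newick file into a scikit-bio ``TreeNode``."""
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a nested key-value YAML config (one section per CLI command)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: config must be a mapping of sections")
    return doc
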