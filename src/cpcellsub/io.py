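"""Readers and writers for the plain-text formats the pipeline consumes.

Supported formats: MatrixMarket triplets with gene/unit sidecar files,
dense TSV expression tables, GMT gene-set collections, TF->target edge
lists, clinical TSVs with a declared column map, and spatial coordinate
tables. All readers preserve identifier order from the file and report
row-level accounting where rows can be rejected.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data_model import (
    ClinicalCohort,
    ExpressionMatrix,
    GeneSetCollection,
    Layer,
    LoadReport,
    Network,
    RegionLabel,
    SpatialSection,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_edge_list",
    "write_edge_list",
    "read_spatial_section",
    "canonicalize_stage",
]


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    format: str = "dense_tsv",
    *,
    genes_path: str | Path | None = None,
    units_path: str | Path | None = None,
    orientation: str = "genes_by_units",
) -> ExpressionMatrix:
    """Read a counts matrix from dense TSV or MatrixMarket triplet form.

    Parameters
    ----------
    path
        For ``dense_tsv``: a TSV whose first column holds gene ids and whose
        header row holds unit ids. For ``mtx_triplet``: a MatrixMarket file;
        ``genes_path`` and ``units_path`` sidecars (one id per line) are then
        required.
    orientation
        ``genes_by_units`` (default) or ``units_by_genes``; the latter is
        transposed on load so the in-memory matrix is always genes x units.
    """
    path = Path(path)
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx_triplet":
        if genes_path is None or units_path is None:
            raise ValueError("mtx_triplet requires genes_path and units_path sidecars")
        mat = scipy.io.mmread(path)
        genes = Path(genes_path).read_text().split()
        units = Path(units_path).read_text().split()
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat)
        if mat.shape != (len(genes), len(units)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(genes)} genes, {len(units)} units)"
            )
        df = pd.DataFrame(mat, index=genes, columns=units)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if orientation == "units_by_genes":
        df = df.T
    elif orientation != "genes_by_units":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(df, layer=Layer.counts)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write as dense TSV (gene ids in first column, unit ids in header)."""
    expr.values.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

_STAGE_ROMAN = {"i": 1, "ii": 2, "iii": 3, "iv": 4}

DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "sample_id": "sample_id",
    "os_time": "os_time",
    "os_event": "os_event",
    "t_stage": "t_stage",
    "n_stage": "n_stage",
    "m_stage": "m_stage",
    "tnm_stage": "tnm_stage",
}


def canonicalize_stage(
    token: object, axis: str, *, collapse_n: bool = True
) -> float:
    """Collapse a raw stage string to its canonical ordinal code.

    Sub-stage suffixes (a/b/c, roman i/ii) collapse to the major numeral:
    ``"T1a" -> 1``, ``"Stage III" -> 3``. ``TX``/``NX``/``MX``/empty map to
    NaN (missing). N codes above 1 collapse to 1 by default, treating nodal
    involvement as a binary progression axis; pass ``collapse_n=False`` to
    retain the full ordinal.
    """
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return np.nan
    s = str(token).strip().lower()
    if s in ("", "na", "nan", "none", "unknown"):
        return np.nan
    s = re.sub(r"^stage\s*", "", s)
    prefix = axis[0].lower() if axis != "TNM" else ""
    if prefix and s.startswith(prefix):
        s = s[len(prefix):]
    if s == "x":
        return np.nan
    m = re.match(r"^(iv|iii|ii|i)", s)
    if m:
        code = float(_STAGE_ROMAN[m.group(1)])
    else:
        m = re.match(r"^(\d+)", s)
        if m is None:
            logger.warning("unrecognized %s stage token %r -> missing", axis, token)
            return np.nan
        code = float(m.group(1))
    if axis == "N" and collapse_n and code > 1:
        code = 1.0
    if axis == "M" and code > 1:
        logger.warning("M stage code %s above 1 -> missing", code)
        return np.nan
    lo, hi = {"T": (1, 4), "N": (0, 1), "M": (0, 1), "TNM": (1, 4)}[axis]
    if code < lo or code > hi:
        logger.warning("out-of-range %s stage code %s -> missing", axis, code)
        return np.nan
    return code


def read_clinical_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    time_unit: str = "days",
    collapse_n: bool = True,
) -> tuple[ClinicalCohort, LoadReport]:
    """Read a clinical TSV, canonicalizing stage strings to ordinals.

    ``column_map`` maps canonical field names (``sample_id``, ``os_time``,
    ``os_event``, ``t_stage``, ...) to the file's column names. Rows with
    unparsable or non-positive survival time are rejected and counted in the
    returned :class:`LoadReport`; unknown stage tokens become missing with a
    warning (counted as coerced).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    report = LoadReport(total=len(raw))

    rows = []
    index = []
    for _, row in raw.iterrows():
        sid = str(row[cmap["sample_id"]])
        try:
            os_time = float(row[cmap["os_time"]])
        except (TypeError, ValueError):
            os_time = np.nan
        if not np.isfinite(os_time) or os_time <= 0:
            logger.info("rejecting sample %s: invalid os_time %r", sid,
                        row.get(cmap["os_time"]))
            report.rejected["bad_os_time"] = report.rejected.get("bad_os_time", 0) + 1
            continue
        try:
            os_event = float(row[cmap["os_event"]])
        except (TypeError, ValueError):
            report.rejected["bad_os_event"] = report.rejected.get("bad_os_event", 0) + 1
            continue
        rec: dict[str, float] = {"os_time": os_time, "os_event": os_event}
        for axis, col_key in (("T", "t_stage"), ("N", "n_stage"),
                              ("M", "m_stage"), ("TNM", "tnm_stage")):
            colname = cmap.get(col_key)
            if colname is None or colname not in raw.columns:
                rec[col_key] = np.nan
                continue
            token = row[colname]
            val = canonicalize_stage(token, axis, collapse_n=collapse_n)
            if np.isnan(val) and not (
                token is None
                or (isinstance(token, float) and np.isnan(token))
                or str(token).strip() == ""
            ):
                report.coerced[col_key] = report.coerced.get(col_key, 0) + 1
            rec[col_key] = val
        rows.append(rec)
        index.append(sid)

    report.kept = len(rows)
    table = pd.DataFrame(rows, index=index)
    return ClinicalCohort(table, time_unit=time_unit), report


def write_clinical_table(cohort: ClinicalCohort, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT file: name, description, then genes, tab-separated."""
    sets: dict[str, list[str]] = {}
    provenance: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
            provenance[name] = desc
    return GeneSetCollection(sets, provenance)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, directed: bool = True) -> Network:
    """Read a 2- or 3-column (source, target[, weight]) TSV edge list.

    Self-loops are dropped (count retained on the Network); duplicate edges
    collapse with summed weights.
    """
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("source", "tf", "from"):
                continue  # header row
            if len(fields) < 2:
                raise ValueError(f"edge list line {lineno}: fewer than 2 columns")
            if len(fields) >= 3 and fields[2]:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ValueError(
                        f"edge list line {lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
            else:
                w = 1.0
            edges.append((fields[0], fields[1], w))
    net = Network(edges, directed=directed)
    if net.n_self_loops_dropped:
        logger.info("dropped %d self-loop(s) from %s", net.n_self_loops_dropped, path)
    return net


def write_edge_list(net: Network, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for s, t, w in net.edges:
            fh.write(f"{s}\t{t}\t{w:g}\n")


# ---------------------------------------------------------------------------
# spatial sections
# ---------------------------------------------------------------------------

def read_spatial_section(
    counts_path: str | Path,
    coords_path: str | Path,
    region_label: str | RegionLabel = RegionLabel.tumor_core,
    *,
    section_id: str | None = None,
    format: str = "dense_tsv",
    **reader_kwargs,
) -> SpatialSection:
    """Read spot counts plus a (spot id, x, y) coordinate TSV.

    Any spot present in exactly one of the two files is an error naming it.
    """
    counts = read_expression_matrix(counts_path, format=format, **reader_kwargs)
    coords = pd.read_csv(coords_path, sep="\t", index_col=0)
    coords.index = coords.index.astype(str)
    if not {"x", "y"}.issubset(coords.columns):
        raise ValueError("coordinate file requires 'x' and 'y' columns")
    if section_id is None:
        section_id = Path(counts_path).stem
    return SpatialSection(
        section_id=section_id,
        spots=counts,
        coordinates=coords,
        region_label=region_label,
    )
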