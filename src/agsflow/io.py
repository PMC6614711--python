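"""Readers and writers for the pipeline's on-disk formats.

Community tables are stored taxa-as-rows (the common amplicon convention):
first column ``taxon_id``, remaining columns one per sample.  Orientation is
auto-detected on read via that header sentinel, so a samples-as-rows table
with a ``sample_id`` first column also parses.  Sample metadata travels in a
separate TSV keyed by sample id.  BIOM v1 (the JSON flavour) import/export is
supported for interchange with other amplicon tools; distance matrices are
square TSVs with a shared id header row/column.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .containers import CommunityTable, ValidationError

__all__ = [
    "read_community_tsv",
    "write_community_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_biom_v1",
    "write_biom_v1",
    "read_distance_tsv",
    "write_distance_tsv",
]

_TAXON_SENTINEL = "taxon_id"
_SAMPLE_SENTINEL = "sample_id"


def write_community_tsv(table: CommunityTable, path, meta_path=None) -> None:
    """Write a community table as taxa rows x sample columns TSV."""
    frame = table.values.T
    frame.index.name = _TAXON_SENTINEL
    frame.to_csv(path, sep="\t")
    if meta_path is not None:
        write_metadata_tsv(table.meta, meta_path)


def _check_header_duplicates(path) -> None:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    ids = header[1:]
    dupes = {x for x in ids if ids.count(x) > 1}
    if dupes:
        raise ValidationError(f"duplicate id(s) in header of {path}: "
                              f"{sorted(dupes)}")


def read_community_tsv(path, meta_path=None) -> CommunityTable:
    """Read a community TSV, auto-detecting orientation from the header."""
    _check_header_duplicates(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    sentinel = (frame.index.name or "").strip().lower()
    if sentinel == _SAMPLE_SENTINEL:
        values = frame
    else:
        if sentinel != _TAXON_SENTINEL and frame.shape[0] < frame.shape[1]:
            values = frame  # heuristic: wide = samples as rows already
        else:
            values = frame.T
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique()
        raise ValidationError(f"duplicate sample id(s): {list(dupes)}")
    if values.columns.has_duplicates:
        dupes = values.columns[values.columns.duplicated()].unique()
        raise ValidationError(f"duplicate taxon id(s): {list(dupes)}")
    try:
        arr = values.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric entry in {path}: {exc}") from exc
    if np.isnan(arr).any():
        rows = values.index[np.isnan(arr).any(axis=1)]
        raise ValidationError(f"missing values in rows {list(rows)} of {path}")
    if (arr < 0).any():
        raise ValidationError(f"negative abundance in {path}")
    meta = read_metadata_tsv(meta_path) if meta_path is not None else None
    if meta is not None:
        meta = meta.reindex(values.index)
        if meta.isna().all(axis=1).any():
            missing = meta.index[meta.isna().all(axis=1)]
            raise ValidationError(f"metadata missing for samples {list(missing)}")
    return CommunityTable(values, meta)


def write_metadata_tsv(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = _SAMPLE_SENTINEL
    out.to_csv(path, sep="\t")


def read_metadata_tsv(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].unique()
        raise ValidationError(f"duplicate sample id(s) in metadata: {list(dupes)}")
    return meta


def write_biom_v1(table: CommunityTable, path, table_id: str = "agsflow") -> None:
    """Write a BIOM v1 (JSON, dense) observation table."""
    dense = table.values.T  # observations x samples
    payload = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "agsflow",
        "date": "1970-01-01T00:00:00",  # fixed for reproducible bytes
        "matrix_type": "dense",
        "matrix_element_type": "float",
        "shape": list(dense.shape),
        "rows": [{"id": str(t), "metadata": None} for t in dense.index],
        "columns": [
            {"id": str(s), "metadata": table.meta.loc[s].to_dict() or None}
            for s in dense.columns
        ],
        "data": dense.to_numpy(dtype=float).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_biom_v1(path) -> CommunityTable:
    """Read a BIOM v1 JSON table (dense or sparse) into a CommunityTable."""
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in payload:
            raise ValidationError(f"not a BIOM v1 table: missing {key!r}")
    taxa = [r["id"] for r in payload["rows"]]
    samples = [c["id"] for c in payload["columns"]]
    n_obs, n_samp = payload["shape"]
    if len(taxa) != n_obs or len(samples) != n_samp:
        raise ValidationError("BIOM shape does not match row/column lists")
    dense = np.zeros((n_obs, n_samp))
    if payload["matrix_type"] == "dense":
        dense[:] = np.asarray(payload["data"], dtype=float)
    elif payload["matrix_type"] == "sparse":
        for i, j, v in payload["data"]:
            dense[int(i), int(j)] = float(v)
    else:
        raise ValidationError(f"unknown matrix_type {payload['matrix_type']!r}")
    meta_rows = {}
    for c in payload["columns"]:
        if isinstance(c.get("metadata"), dict):
            meta_rows[c["id"]] = c["metadata"]
    values = pd.DataFrame(dense.T, index=samples, columns=taxa)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").reindex(samples) \
        if meta_rows else None
    return CommunityTable(values, meta)


def write_distance_tsv(dm: pd.DataFrame, path) -> None:
    out = dm.copy()
    out.index.name = _SAMPLE_SENTINEL
    out.to_csv(path, sep="\t")


def read_distance_tsv(path) -> pd.DataFrame:
    dm = pd.read_csv(path, sep="\t", index_col=0)
    try:
        dm.columns = dm.columns.astype(dm.index.dtype)
    except (TypeError, ValueError):
        pass
    if list(dm.index) != list(dm.columns):
        raise ValidationError("distance matrix row and column ids differ")
    return dm
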