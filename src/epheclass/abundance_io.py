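"""Reading, writing and validation of ASV/OTU count tables and sample metadata.

The on-disk formats are the ones mothur/QIIME exports produce in practice:

* a plain TSV count matrix (either orientation, tab-separated, no quoting,
  first column holding the row ids);
* BIOM v1 (JSON) and BIOM v2.1 (HDF5) count tables, where rows are
  observations (features) and columns are samples by convention;
* a TSV metadata table with columns ``sample_id``, ``label`` and optionally
  ``stratum``.

Everything is normalised into an :class:`AbundanceTable` with samples as rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, ParseError, ValidationError

logger = logging.getLogger("epheclass")

#: canonical binary phenotype labels
POSITIVE_LABEL = "D"
NEGATIVE_LABEL = "NotD"
LABELS = (POSITIVE_LABEL, NEGATIVE_LABEL)


@dataclass
class AbundanceTable:
    """A validated count table with samples as rows.

    Parameters
    ----------
    sample_ids, feature_ids
        Unique string identifiers; lengths match ``counts.shape``.
    counts
        Non-negative integer matrix, shape ``(n_samples, n_features)``.
    labels
        Optional per-sample binary phenotype in ``{"D", "NotD"}``.
    stratum
        Optional per-sample categorical stratum (e.g. collection site).
    """

    sample_ids: list[str]
    feature_ids: list[str]
    counts: np.ndarray
    labels: np.ndarray | None = None
    stratum: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValidationError("duplicate feature ids")
        if counts.size:
            if not np.issubdtype(counts.dtype, np.integer):
                as_float = counts.astype(float)
                if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                    raise ValidationError("counts must be integral")
                counts = as_float.astype(np.int64)
            if counts.min() < 0:
                raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (len(self.sample_ids),):
                raise ValidationError("labels length does not match samples")
            bad = set(self.labels) - set(LABELS)
            if bad:
                raise ValidationError(f"labels outside {LABELS}: {sorted(bad)}")
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum, dtype=object)
            if self.stratum.shape != (len(self.sample_ids),):
                raise ValidationError("stratum length does not match samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def select_samples(self, idx: np.ndarray) -> "AbundanceTable":
        """Return a new table restricted to samples ``idx`` (positional)."""
        idx = np.asarray(idx)
        return AbundanceTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            counts=self.counts[idx],
            labels=None if self.labels is None else self.labels[idx],
            stratum=None if self.stratum is None else self.stratum[idx],
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        same = (
            self.sample_ids == other.sample_ids
            and self.feature_ids == other.feature_ids
            and np.array_equal(self.counts, other.counts)
        )
        for a, b in ((self.labels, other.labels), (self.stratum, other.stratum)):
            same = same and ((a is None) == (b is None)) and (a is None or np.array_equal(a, b))
        return same


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: Path, orientation: str) -> AbundanceTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except Exception as exc:  # pandas raises many flavours
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no data columns found")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                v = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric value {raw!r} at data line {i + 2}"
                ) from None
            if v != round(v):
                raise ValidationError(
                    f"{path}: non-integer count {raw!r} at data line {i + 2}"
                )
            if v < 0:
                raise ValidationError(
                    f"{path}: negative count {raw!r} at data line {i + 2}"
                )
            values[i, j] = int(round(v))
    row_ids = [str(r) for r in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "samples_as_rows":
        return AbundanceTable(row_ids, col_ids, values)
    return AbundanceTable(col_ids, row_ids, values.T)


def _read_biom_json(path: Path) -> AbundanceTable:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    try:
        feature_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        matrix_type = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: missing BIOM field {exc}") from exc
    mat = np.zeros(shape, dtype=np.int64)
    if matrix_type == "dense":
        mat[:, :] = np.asarray(data)
    else:
        for r, c, v in data:
            if v != round(v):
                raise ValidationError(f"{path}: non-integer count {v}")
            mat[int(r), int(c)] = int(round(v))
    # BIOM rows are observations (features), columns are samples
    return AbundanceTable(sample_ids, feature_ids, mat.T)


def _read_biom_hdf5(path: Path) -> AbundanceTable:
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as h5:
        feature_ids = [x.decode() if isinstance(x, bytes) else str(x)
                       for x in h5["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x)
                      for x in h5["sample/ids"][:]]
        grp = h5["observation/matrix"]
        csr = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(feature_ids), len(sample_ids)),
        )
    dense = np.asarray(csr.todense())
    if np.any(dense != np.round(dense)):
        raise ValidationError(f"{path}: non-integer counts in BIOM matrix")
    return AbundanceTable(sample_ids, feature_ids, dense.T.astype(np.int64))


def read_table(path: str | Path, orientation: str = "samples_as_rows") -> AbundanceTable:
    """Read a count table from TSV or BIOM into samples-as-rows orientation.

    ``orientation`` applies to TSV files (which carry no convention of their
    own); BIOM files always store observations as rows and samples as columns,
    so the flag is ignored for them. If a sidecar metadata file written by
    :func:`write_table` sits next to a TSV, labels/stratum are re-attached.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("samples_as_rows", "features_as_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    if path.suffix == ".biom":
        with open(path, "rb") as fh:
            magic = fh.read(8)
        if magic.startswith(b"\x89HDF"):
            table = _read_biom_hdf5(path)
        else:
            table = _read_biom_json(path)
    else:
        table = _read_tsv(path, orientation)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        table = join_metadata(table, read_metadata(sidecar))
    return table


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a TSV metadata table with columns sample_id, label[, stratum]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "label" not in df.columns:
        raise ParseError(f"{path}: metadata needs 'sample_id' and 'label' columns")
    return df


def join_metadata(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    label_map: Mapping[str, str] | None = None,
) -> AbundanceTable:
    """Attach labels (and optional stratum) to the table's samples.

    Samples absent from the metadata are dropped with a logged count; a label
    value that ``label_map`` cannot map to {"D", "NotD"} is an error.
    """
    label_map = dict(label_map) if label_map else {}
    meta = metadata.set_index("sample_id")
    if meta.index.has_duplicates:
        raise ValidationError("duplicate sample_id in metadata")
    keep: list[int] = []
    labels: list[str] = []
    strata: list[str] = []
    has_stratum = "stratum" in meta.columns
    for i, sid in enumerate(table.sample_ids):
        if sid not in meta.index:
            continue
        raw = str(meta.at[sid, "label"])
        lab = label_map.get(raw, raw)
        if lab not in LABELS:
            raise ValidationError(
                f"label {raw!r} for sample {sid!r} is not mappable to {LABELS}"
            )
        keep.append(i)
        labels.append(lab)
        if has_stratum:
            strata.append(str(meta.at[sid, "stratum"]))
    dropped = table.n_samples - len(keep)
    if dropped:
        logger.warning("join_metadata: dropped %d samples without metadata", dropped)
    if not keep:
        raise EmptyDatasetError("no samples remain after metadata join")
    out = table.select_samples(np.asarray(keep))
    out.labels = np.asarray(labels, dtype=object)
    out.stratum = np.asarray(strata, dtype=object) if has_stratum else None
    return AbundanceTable(out.sample_ids, out.feature_ids, out.counts,
                          out.labels, out.stratum)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".metadata.tsv")


def write_table(
    table: AbundanceTable,
    path: str | Path,
    orientation: str = "samples_as_rows",
) -> Path:
    """Write the table as TSV; labels/stratum go to a sidecar metadata TSV."""
    path = Path(path)
    if table.n_features == 0 or table.n_samples == 0:
        raise EmptyDatasetError("refusing to write an empty table")
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=table.feature_ids)
    if orientation == "features_as_rows":
        df = df.T
        df.index.name = "feature_id"
    elif orientation == "samples_as_rows":
        df.index.name = "sample_id"
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t")
    if table.labels is not None:
        meta = pd.DataFrame({"sample_id": table.sample_ids, "label": table.labels})
        if table.stratum is not None:
            meta["stratum"] = table.stratum
        meta.to_csv(_sidecar_path(path), sep="\t", index=False)
    return path


def write_metadata(table: AbundanceTable, path: str | Path) -> Path:
    """Write sample_id/label[/stratum] of a labelled table as TSV."""
    if table.labels is None:
        raise ValidationError("table has no labels to write")
    meta = pd.DataFrame({"sample_id": table.sample_ids, "label": table.labels})
    if table.stratum is not None:
        meta["stratum"] = table.stratum
    meta.to_csv(path, sep="\t", index=False)
    return Path(path)
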