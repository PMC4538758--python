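"""Readers and writers for the text interchange formats used across the pipeline.

Supported formats:

* **GCT** (Gene Cluster Text, v1.2) — the canonical expression-matrix carrier.
* **PCL** (Stanford pre-clustering) — read-only; converted into :class:`GctDataset`.
* **CLS** (categorical class labels) — phenotype labels for the sample columns.
* **GMT** (gene-matrix transposed) — named gene sets, one per line.
* Flat gene lists, probe→symbol annotation tables, and the tab-delimited
  clinical table.

All readers accept Unix or Windows line endings and UTF-8 text.  Missing-value
tokens on read are the empty string, ``NA`` and ``NaN`` (case-insensitive);
on write a missing value is serialized as the empty string.  Gene symbols are
uppercased on ingestion so that expression matrices, gene sets and annotation
tables agree on membership regardless of source capitalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GctDataset",
    "ClsLabels",
    "GeneSetCollection",
    "read_gct",
    "write_gct",
    "read_pcl",
    "read_cls",
    "write_cls",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "read_annotation",
]

GCT_VERSION = "#1.2"

_MISSING_TOKENS = {"", "na", "nan"}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class GctDataset:
    """In-memory image of a GCT v1.2 file.

    ``values`` is a float matrix of shape (n_rows, n_cols); missing entries are
    ``NaN``.  ``row_ids`` are probe or gene identifiers, ``row_descriptions``
    the free-text second column.
    """

    row_ids: list[str]
    row_descriptions: list[str]
    sample_ids: list[str]
    values: np.ndarray
    version_line: str = GCT_VERSION

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise FormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.sample_ids)} samples"
            )
        if len(self.row_descriptions) != len(self.row_ids):
            raise FormatError("row_descriptions length does not match row_ids")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame indexed by row id with sample-id columns."""
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, descriptions: list[str] | None = None) -> "GctDataset":
        desc = descriptions if descriptions is not None else ["na"] * len(frame)
        return cls(
            row_ids=[str(i) for i in frame.index],
            row_descriptions=desc,
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GctDataset):
            return NotImplemented
        return (
            self.row_ids == other.row_ids
            and self.row_descriptions == other.row_descriptions
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass
class ClsLabels:
    """Categorical CLS phenotype labels."""

    class_names: list[str]
    labels: list[int]

    def __post_init__(self) -> None:
        if any(l < 0 or l >= len(self.class_names) for l in self.labels):
            raise FormatError("CLS label index out of range")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def name_per_sample(self) -> list[str]:
        return [self.class_names[i] for i in self.labels]

    def indices_of(self, class_name: str) -> list[int]:
        k = self.class_names.index(class_name)
        return [i for i, l in enumerate(self.labels) if l == k]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions; symbols uppercased."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def _is_missing(token: str) -> bool:
    return token.strip().lower() in _MISSING_TOKENS


def _parse_cell(token: str, row: int, col: int, path: Path) -> float:
    if _is_missing(token):
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}: non-numeric value {token!r} at data row {row + 1}, column {col + 1}"
        ) from None


def read_gct(path: str | Path) -> GctDataset:
    """Parse a GCT v1.2 file.

    Raises :class:`FormatError` when the declared dimensions disagree with the
    body or a data cell is neither numeric nor a missing token.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GCT file ({len(lines)} lines)")
    version = lines[0].strip()
    if not version.startswith("#"):
        raise FormatError(f"{path}: line 1 must be a GCT version tag, found {version!r}")
    dims = lines[1].split("\t")
    if len(dims) < 2:
        raise FormatError(f"{path}: line 2 must hold row and column counts")
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except ValueError:
        raise FormatError(f"{path}: non-integer dimensions on line 2: {lines[1]!r}") from None
    header = lines[2].rstrip("\n").split("\t")
    if len(header) != n_cols + 2:
        raise FormatError(
            f"{path}: header declares {len(header) - 2} sample columns, expected {n_cols}"
        )
    sample_ids = header[2:]
    body = [l for l in lines[3:] if l.strip() != ""]
    if len(body) != n_rows:
        raise FormatError(f"{path}: expected {n_rows} data rows, found {len(body)}")
    row_ids: list[str] = []
    row_desc: list[str] = []
    values = np.empty((n_rows, n_cols), dtype=float)
    for i, line in enumerate(body):
        fields = line.split("\t")
        if len(fields) != n_cols + 2:
            raise FormatError(
                f"{path}: data row {i + 1} has {len(fields) - 2} value fields, expected {n_cols}"
            )
        row_ids.append(fields[0])
        row_desc.append(fields[1])
        for j, token in enumerate(fields[2:]):
            values[i, j] = _parse_cell(token, i, j, path)
    return GctDataset(row_ids, row_desc, sample_ids, values, version_line=version)


def _format_value(v: float) -> str:
    v = float(v)
    if math.isnan(v):
        return ""
    return repr(v)


def write_gct(ds: GctDataset, path: str | Path) -> Path:
    """Write ``ds`` as GCT v1.2; ``read_gct(write_gct(ds)) == ds``."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{GCT_VERSION}\n{ds.n_rows}\t{ds.n_cols}\n")
        fh.write("NAME\tDescription\t" + "\t".join(ds.sample_ids) + "\n")
        for rid, desc, row in zip(ds.row_ids, ds.row_descriptions, ds.values):
            fh.write(rid + "\t" + desc + "\t" + "\t".join(_format_value(v) for v in row) + "\n")
    return path


def read_pcl(path: str | Path) -> GctDataset:
    """Read a Stanford PCL file into a :class:`GctDataset` (read-only support).

    The PCL header columns are ID, NAME, GWEIGHT followed by sample ids; an
    optional EWEIGHT row after the header is skipped.  GWEIGHT/EWEIGHT values
    are discarded — the GCT carrier keeps ids, descriptions and values only.
    """
    path = Path(path)
    lines = [l for l in path.read_text(encoding="utf-8").splitlines() if l.strip() != ""]
    if not lines:
        raise FormatError(f"{path}: empty PCL file")
    header = lines[0].split("\t")
    if len(header) < 4:
        raise FormatError(f"{path}: PCL header must have ID, NAME, GWEIGHT + samples")
    has_gweight = header[2].upper() == "GWEIGHT"
    n_meta = 3 if has_gweight else 2
    sample_ids = header[n_meta:]
    body = lines[1:]
    if body and body[0].split("\t")[0].upper() == "EWEIGHT":
        body = body[1:]
    row_ids, row_desc = [], []
    rows = []
    for i, line in enumerate(body):
        fields = line.split("\t")
        if len(fields) != n_meta + len(sample_ids):
            raise FormatError(f"{path}: PCL data row {i + 1} has {len(fields)} fields")
        row_ids.append(fields[0])
        row_desc.append(fields[1])
        rows.append([_parse_cell(t, i, j, path) for j, t in enumerate(fields[n_meta:])])
    return GctDataset(row_ids, row_desc, sample_ids, np.asarray(rows, dtype=float))


def read_cls(path: str | Path) -> ClsLabels:
    """Parse a categorical CLS file (three-line dialect)."""
    path = Path(path)
    lines = [l for l in path.read_text(encoding="utf-8").splitlines() if l.strip() != ""]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS file needs 3 lines, found {len(lines)}")
    head = lines[0].split()
    if len(head) < 3:
        raise FormatError(f"{path}: CLS line 1 must be 'n_samples n_classes 1'")
    n_samples, n_classes = int(head[0]), int(head[1])
    name_line = lines[1].split()
    if name_line[0] != "#":
        raise FormatError(f"{path}: CLS line 2 must begin with '#'")
    class_names = name_line[1:]
    if len(class_names) != n_classes:
        raise FormatError(
            f"{path}: declared {n_classes} classes but line 2 names {len(class_names)}"
        )
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{path}: declared {n_samples} samples but label line has {len(tokens)}"
        )
    if all(t.lstrip("-").isdigit() for t in tokens):
        labels = [int(t) for t in tokens]
    else:
        # Labels given as class names; map through the declared name order.
        try:
            labels = [class_names.index(t) for t in tokens]
        except ValueError as exc:
            raise FormatError(f"{path}: unknown class label in CLS body: {exc}") from None
    return ClsLabels(class_names, labels)


def write_cls(labels: ClsLabels, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{labels.n_samples} {labels.n_classes} 1\n")
        fh.write("# " + " ".join(labels.class_names) + "\n")
        fh.write(" ".join(str(l) for l in labels.labels) + "\n")
    return path


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT gene-set file.

    Each tab-delimited line is ``name<TAB>description<TAB>member...``.
    Duplicate members within a line are dropped with a warning; a duplicate
    set name or a line with fewer than three fields is an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if line.strip() == "":
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno} has {len(fields)} fields, expected >=3")
        name, desc, *members = fields
        if name in sets:
            raise FormatError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
        seen: dict[str, None] = {}
        dupes = 0
        for m in members:
            m = m.strip().upper()
            if not m:
                continue
            if m in seen:
                dupes += 1
            else:
                seen[m] = None
        if dupes:
            warnings.warn(
                f"{path.name}: set {name!r} had {dupes} duplicate member(s), deduplicated",
                stacklevel=2,
            )
        sets[name] = list(seen)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "na")
            fh.write(name + "\t" + desc + "\t" + "\t".join(members) + "\n")
    return path


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line, uppercased, blank lines skipped."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        sym = line.strip().upper()
        if sym:
            out.append(sym)
    return out


def read_annotation(path: str | Path) -> pd.Series:
    """Two-column tab-delimited probe→gene-symbol table.

    Returns a Series indexed by probe id with uppercased symbols.  A header
    row is detected (and skipped) when the second field of the first line is
    not a plausible symbol pairing, i.e. when it matches common header names.
    """
    path = Path(path)
    probes, symbols = [], []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if line.strip() == "":
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno} has fewer than 2 columns")
        if lineno == 1 and fields[0].lower() in {"probe", "probe_id", "id"}:
            continue
        probes.append(fields[0])
        symbols.append(fields[1].strip().upper())
    return pd.Series(symbols, index=probes, name="gene_symbol")
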