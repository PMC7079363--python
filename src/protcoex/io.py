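"""Readers and writers for the external formats the pipeline touches.

Formats handled: the wide tab-separated protein-abundance table with its
sample-metadata sidecar, GMT gene-set collections, and plain-text edge
lists (2-4 whitespace/tab-delimited columns) as used for co-expression and
knowledge networks.

Identifier conventions: protein identifiers are case-sensitive; gene-set
matching uppercases both sides, because GMT collections use uppercase human
gene symbols.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Condition labels of the three-arm oxygen/cyclosporine design.
CONDITIONS = ("O19", "O1", "O1_CyA")

RAW = "raw"
LOG2 = "log2"


@dataclass
class AbundanceMatrix:
    """Protein x sample abundance values plus per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample id.
        Non-negative on the raw scale; any real value on the log2 scale.
    sample_meta
        DataFrame indexed by sample id with columns ``condition`` (one of
        :data:`CONDITIONS` or any user-defined label) and ``replicate``
        (integer >= 1).
    scale
        ``"raw"`` or ``"log2"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate protein id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.sample_meta.index]
        if missing:
            raise ValueError(
                f"sample(s) {missing} in abundance table but not in sample metadata"
            )
        if "condition" not in self.sample_meta.columns:
            raise ValueError("sample metadata must have a 'condition' column")
        if "replicate" not in self.sample_meta.columns:
            raise ValueError("sample metadata must have a 'replicate' column")
        if (self.sample_meta.loc[list(self.values.columns), "replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("abundance values must be numeric")
        if self.scale == RAW and np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("raw-scale abundances must be non-negative")
        if np.isnan(arr).any():
            raise ValueError("missing abundance cells are not allowed")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance across samples."""
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_meta.loc[s, "condition"], None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        return [
            s
            for s in self.values.columns
            if self.sample_meta.loc[s, "condition"] == condition
        ]

    def subset(self, protein_ids: Iterable[str]) -> "AbundanceMatrix":
        ids = list(protein_ids)
        return AbundanceMatrix(self.values.loc[ids], self.sample_meta, self.scale)


@dataclass(frozen=True, order=True)
class EdgeRecord:
    """One undirected network edge, canonically ordered (node_a < node_b)."""

    node_a: str
    node_b: str
    weight: float = 1.0
    zscore: float | None = None

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ValueError(f"self-loop edge {self.node_a!r}")
        if self.node_a > self.node_b:
            raise ValueError("edge endpoints must be in lexicographic order; use make_edge")


def make_edge(u: str, v: str, weight: float = 1.0, zscore: float | None = None) -> EdgeRecord:
    """Build an :class:`EdgeRecord` with endpoints put in canonical order."""
    if u > v:
        u, v = v, u
    return EdgeRecord(u, v, float(weight), None if zscore is None else float(zscore))


@dataclass
class GeneSetCollection:
    """Named gene sets with uppercase-normalized members."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @property
    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def read_abundance_table(path, meta_path) -> AbundanceMatrix:
    """Read a wide TSV abundance table and its sample-metadata TSV.

    The table's first column holds protein ids, the remaining columns one
    sample each. The metadata file maps ``sample_id`` to ``condition`` and
    ``replicate``. Column order of the table is preserved.

    Raises
    ------
    ValueError
        On duplicate protein or sample ids (naming the offender), a sample
        missing from the metadata, or a non-numeric cell (naming its
        row/column coordinates).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    protein_col = raw.columns[0]
    ids = raw[protein_col]
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate protein id {dup.iloc[0]!r} in {path}")
    sample_cols = list(raw.columns[1:])
    values = pd.DataFrame(index=pd.Index(ids, name="protein"))
    for col in sample_cols:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell {raw[col].iloc[row]!r} at protein "
                f"{ids.iloc[row]!r}, sample {col!r} in {path}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"empty cell at protein {ids.iloc[row]!r}, sample {col!r}")
        values[col] = numeric.to_numpy()
    meta = pd.read_csv(meta_path, sep="\t", dtype={"replicate": int})
    meta = meta.set_index(meta.columns[0])
    return AbundanceMatrix(values=values, sample_meta=meta, scale=RAW)


def write_abundance_table(matrix: AbundanceMatrix, path, meta_path) -> None:
    """Write the abundance table and metadata in the format read back by
    :func:`read_abundance_table`."""
    out = matrix.values.copy()
    out.index.name = "protein"
    out.to_csv(path, sep="\t", float_format="%.17g")
    meta = matrix.sample_meta.loc[list(matrix.values.columns), ["condition", "replicate"]]
    meta.index.name = "sample"
    meta.to_csv(meta_path, sep="\t")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>member...``.

    Members are deduplicated and uppercased. A line with fewer than three
    fields is a hard error naming the line number.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has {len(fields)} fields (< 3)")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} at line {lineno}")
            members = frozenset(m.strip().upper() for m in fields[2:] if m.strip())
            if not members:
                raise ValueError(f"gene set {name!r} at line {lineno} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_list(path, header: bool | None = None) -> set[EdgeRecord]:
    """Read a whitespace/tab-delimited edge list into canonical edges.

    The file has two node columns and optional weight and z-score columns.
    ``header=None`` sniffs a header line: the first line is treated as a
    header when its third field (or, for two-column files, either field on
    the second line matching the first) is non-numeric. Self-loops are
    dropped with a warning; duplicate undirected edges collapse keeping the
    maximum weight. An unparseable line is a hard error with its number.
    """
    edges: dict[tuple[str, str], EdgeRecord] = {}
    with open(path) as fh:
        lines = [(i, ln.rstrip("\n")) for i, ln in enumerate(fh, start=1) if ln.strip()]
    if not lines:
        return set()
    first_fields = lines[0][1].split()
    if header is None:
        if len(first_fields) >= 3:
            header = not _looks_numeric(first_fields[2])
        else:
            # no weight column to sniff: assume data
            header = False
    if header:
        lines = lines[1:]
    n_self = 0
    for lineno, line in lines:
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"edge-list line {lineno} has fewer than 2 columns")
        u, v = fields[0], fields[1]
        weight = 1.0
        zscore: float | None = None
        try:
            if len(fields) >= 3:
                weight = float(fields[2])
            if len(fields) >= 4:
                zscore = None if fields[3].upper() in ("NA", "NAN") else float(fields[3])
        except ValueError as exc:
            raise ValueError(f"unreadable edge-list line {lineno}: {line!r}") from exc
        if u == v:
            n_self += 1
            continue
        edge = make_edge(u, v, weight, zscore)
        key = (edge.node_a, edge.node_b)
        prev = edges.get(key)
        if prev is None or edge.weight > prev.weight:
            edges[key] = edge
    if n_self:
        logger.warning("dropped %d self-loop edge(s) reading %s", n_self, path)
    return set(edges.values())


def write_edge_list(edges: Iterable[EdgeRecord], path) -> None:
    """Write edges as ``node_a<TAB>node_b<TAB>weight<TAB>zscore`` lines.

    Weights and z-scores use 6 decimal places ("NA" for a missing z-score);
    lines are in lexicographic edge order, so writing is deterministic and
    :func:`read_edge_list` round-trips the result. An empty edge set yields
    an empty file and a warning.
    """
    edges = sorted(edges)
    if not edges:
        logger.warning("writing empty edge list to %s", path)
    with open(path, "w") as fh:
        for e in edges:
            z = "NA" if e.zscore is None or math.isnan(e.zscore) else f"{e.zscore:.6f}"
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.weight:.6f}\t{z}\n")


def read_id_map(path) -> Mapping[str, str]:
    """Read a two-column protein-to-gene-symbol map (TSV, optional header)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError("id map must have two columns")
    first = df.iloc[0]
    if first.iloc[0].lower() in ("protein", "protein_id", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].str.upper()))
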