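"""Readers, writers and validation for the formats the pipeline touches.

Feature tables travel as TSV (QIIME2-style export: first header cell
``#ASV_ID``, one column per sample) or BIOM 1.0 JSON; trees as newick;
sample metadata as TSV. Every writer has a reader that round-trips it.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import ConsistencyError, FormatError, InputError, ParameterError

HABITATS = ("phyllosphere", "soil", "litter")
SPECIES = ("FM", "PK")
STAGES = ("NSL", "EDL", "LDL")
FRACTIONS = ("surface", "interior", "whole")

METADATA_COLUMNS = ("habitat", "species", "stage", "fraction", "altitude")


@dataclass(frozen=True)
class FeatureTable:
    """A taxa x samples matrix of non-negative integer counts.

    Rows are ASVs (amplicon sequence variants), columns are samples. The
    class is immutable; subsetting operations return new tables.
    """

    taxon_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FormatError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if counts.size == 0:
            raise FormatError("empty feature table")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                bad = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
                raise FormatError(
                    f"non-integer count for taxon {self.taxon_ids[bad[0]]!r} "
                    f"in sample {self.sample_ids[bad[1]]!r}"
                )
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count for taxon {self.taxon_ids[bad[0]]!r} "
                f"in sample {self.sample_ids[bad[1]]!r}"
            )
        for kind, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {kind} id: {i!r}")
                seen.add(i)
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))

    # -- construction ----------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureTable":
        return cls(tuple(frame.index.astype(str)), tuple(frame.columns.astype(str)), frame.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.copy(), index=list(self.taxon_ids), columns=list(self.sample_ids))

    # -- basic queries ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def taxon_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def taxon_index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.taxon_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1)."""
        totals = self.sample_sums().astype(float)
        if (totals == 0).any():
            j = int(np.argmax(totals == 0))
            raise InputError(f"sample {self.sample_ids[j]!r} has zero total count")
        return self.counts / totals

    # -- subsetting ------------------------------------------------------
    def select_samples(self, ids: Sequence[str]) -> "FeatureTable":
        idx = self.sample_index()
        missing = [s for s in ids if s not in idx]
        if missing:
            raise ConsistencyError(f"unknown sample ids: {missing}")
        cols = [idx[s] for s in ids]
        return FeatureTable(self.taxon_ids, tuple(ids), self.counts[:, cols])

    def select_taxa(self, ids: Sequence[str]) -> "FeatureTable":
        idx = self.taxon_index()
        missing = [t for t in ids if t not in idx]
        if missing:
            raise ConsistencyError(f"unknown taxon ids: {missing}")
        rows = [idx[t] for t in ids]
        return FeatureTable(tuple(ids), self.sample_ids, self.counts[rows, :])

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index()[sample_id]].copy()


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, format: str = "tsv") -> FeatureTable:
    """Read a feature table from TSV or BIOM 1.0 JSON."""
    path = Path(path)
    if format == "tsv":
        return _read_table_tsv(path)
    if format == "biom_json":
        return _read_table_biom(path)
    raise ParameterError(f"unknown feature-table format: {format!r}")


def write_feature_table(table: FeatureTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        frame = table.to_frame()
        frame.index.name = "#ASV_ID"
        frame.to_csv(path, sep="\t")
    elif format == "biom_json":
        _write_table_biom(table, path)
    else:
        raise ParameterError(f"unknown feature-table format: {format!r}")


def _read_table_tsv(path: Path) -> FeatureTable:
    try:
        frame = pd.read_csv(path, sep="\t", header=0, index_col=0, comment=None)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"could not parse {path} as TSV: {exc}") from exc
    if frame.empty:
        raise FormatError(f"{path}: empty table")
    frame.index = frame.index.astype(str)
    dup = frame.index[frame.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicated taxon row id {dup[0]!r}")
    dupc = frame.columns[frame.columns.duplicated()]
    if len(dupc):
        raise FormatError(f"{path}: duplicated sample column id {dupc[0]!r}")
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in count table")
    return FeatureTable(tuple(frame.index), tuple(frame.columns.astype(str)), values)


# BIOM 1.0 ("Biological Observation Matrix") is plain JSON; the small subset
# used here (dense or sparse OTU tables) is read and written directly.
_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"


def _read_table_biom(path: Path) -> FeatureTable:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"could not parse {path} as JSON: {exc}") from exc
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise FormatError(f"{path}: missing BIOM key {key!r}")
    n_rows, n_cols = doc["shape"]
    taxa = [str(r["id"]) for r in doc["rows"]]
    samples = [str(c["id"]) for c in doc["columns"]]
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    if doc["matrix_type"] == "dense":
        counts[:, :] = np.asarray(doc["data"])
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    else:
        raise FormatError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    return FeatureTable(tuple(taxa), tuple(samples), counts)


def _write_table_biom(table: FeatureTable, path: Path) -> None:
    rows, cols = np.nonzero(table.counts)
    doc = {
        "id": None,
        "format": _BIOM_FORMAT,
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "littersuccession",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": list(table.shape),
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [[int(i), int(j), int(table.counts[i, j])] for i, j in zip(rows, cols)],
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def validate_metadata(
    frame: pd.DataFrame,
    habitats: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Validate a metadata frame indexed by sample id.

    ``habitat`` is required for every sample; ``species``, ``stage`` and
    ``fraction`` may be missing but must come from the controlled
    vocabularies when present. ``habitats`` overrides the accepted habitat
    labels (synthetic scenarios may use more than the three field habitats).
    """
    habitats = tuple(habitats) if habitats is not None else HABITATS
    frame = frame.copy()
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate sample id in metadata: {dup!r}")
    for col in METADATA_COLUMNS:
        if col not in frame.columns:
            frame[col] = pd.NA
    bad = frame.index[~frame["habitat"].isin(habitats)]
    if len(bad):
        raise FormatError(
            f"sample {bad[0]!r}: habitat {frame.loc[bad[0], 'habitat']!r} "
            f"not in {sorted(habitats)}"
        )
    for col, vocab in (("species", SPECIES), ("stage", STAGES), ("fraction", FRACTIONS)):
        present = frame[col].notna() & (frame[col] != "")
        bad = frame.index[present & ~frame[col].isin(vocab)]
        if len(bad):
            raise FormatError(
                f"sample {bad[0]!r}: {col} {frame.loc[bad[0], col]!r} not in {sorted(vocab)}"
            )
    if frame["altitude"].notna().any():
        frame["altitude"] = pd.to_numeric(frame["altitude"], errors="raise")
    return frame[list(METADATA_COLUMNS)]


def read_metadata(path: str | Path, habitats: Iterable[str] | None = None) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise FormatError(f"could not parse {path} as metadata TSV: {exc}") from exc
    frame.index.name = "sample_id"
    return validate_metadata(frame, habitats=habitats)


def write_metadata(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 (warned)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"could not parse {path} as newick: {exc}") from exc
    return _validate_tree(tree)


def parse_tree(newick: str) -> TreeNode:
    """Parse a newick string (convenience used by tests and docs)."""
    import io as _io

    try:
        tree = TreeNode.read(_io.StringIO(newick), format="newick")
    except Exception as exc:
        raise FormatError(f"could not parse newick string: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if any(n is None for n in names):
        raise FormatError("tree has unnamed leaves")
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise FormatError(f"duplicate leaf label in tree: {n!r}")
        seen.add(n)
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(
            f"{n_missing} branch(es) had no length in the newick source; set to 0",
            stacklevel=2,
        )
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.traverse(include_self=False)))


def align_table_and_tree(
    table: FeatureTable, tree: TreeNode, policy: str = "intersect"
) -> tuple[FeatureTable, TreeNode]:
    """Reconcile a table's taxa with a tree's leaves.

    ``intersect`` prunes both to the shared taxa; ``strict`` raises on any
    mismatch. Taxa without a tip have no defined place in UniFrac or the
    phylogenetic null models, hence the intersect default.
    """
    if policy not in ("intersect", "strict"):
        raise ParameterError(f"unknown alignment policy: {policy!r}")
    table_taxa = set(table.taxon_ids)
    tree_taxa = {t.name for t in tree.tips()}
    only_table = sorted(table_taxa - tree_taxa)
    only_tree = sorted(tree_taxa - table_taxa)
    if policy == "strict" and (only_table or only_tree):
        raise ConsistencyError(
            f"table/tree taxon mismatch: {len(only_table)} only in table "
            f"{only_table[:5]}, {len(only_tree)} only in tree {only_tree[:5]}"
        )
    if not only_table and not only_tree:
        return table, tree
    shared = [t for t in table.taxon_ids if t in tree_taxa]
    if not shared:
        raise ConsistencyError("table and tree share no taxa")
    pruned_table = table.select_taxa(shared)
    pruned_tree = tree.shear(shared)
    pruned_tree.prune()
    return pruned_table, _validate_tree(pruned_tree)
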