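"""Readers and writers for expression matrices, gene-set collections and committees.

Expression matrices use a fixed CSV dialect with samples in columns and genes
in rows:

* row 1: ``ID,NAME,<sample id>,<sample id>,...``
* row 2 (training files only): ``,CLASS,<class label>,<class label>,...``
* remaining rows: ``<gene id>,<gene name>,<value>,...``

Missing expression values are written as ``NA`` and may be read from an empty
cell or the token ``NA``. Gene sets travel in Broad-style GMT (one set per
line: set id, source/description, then member gene ids, TAB-separated).
Trained committees persist as a single versioned JSON document (``.gcmt``).
"""

from __future__ import annotations

import base64
import csv
import io
import json
import logging
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import numpy as np

log = logging.getLogger("genesetcommittee")

MISSING_TOKENS = frozenset({"", "NA"})
COMMITTEE_FORMAT = "genesetcommittee/committee"
COMMITTEE_VERSION = 1


class FormatError(ValueError):
    """Malformed input file (CSV dialect or GMT violation)."""


class CommitteeIOError(ValueError):
    """Committee file could not be persisted or loaded."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with optional per-sample class labels.

    ``values`` holds floats with ``NaN`` marking missing measurements. Labels
    are absent (``None``) for diagnostic datasets of unseen samples.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    gene_names: list[str]
    values: np.ndarray
    class_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must form a 2-D matrix")
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.gene_names) != n_genes:
            raise ValueError(
                f"gene annotation length mismatch: {len(self.gene_ids)} ids, "
                f"{len(self.gene_names)} names, {n_genes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        _check_unique(self.sample_ids, "sample ID")
        _check_unique(self.gene_ids, "gene ID")
        if self.class_labels is not None and len(self.class_labels) != n_samples:
            raise ValueError("one class label per sample is required")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        """Distinct class labels in order of first appearance."""
        if self.class_labels is None:
            return []
        return list(dict.fromkeys(self.class_labels))

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label in self.class_labels or []:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def require_training(self) -> None:
        """Raise unless this dataset is usable for supervised training."""
        if self.class_labels is None:
            raise ValueError("training requires class labels for every sample")
        if len(self.classes) < 2:
            raise ValueError("training requires at least 2 distinct classes")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def feature_matrix(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Samples x features matrix restricted to ``gene_ids`` (dataset order of samples)."""
        index = self.gene_index()
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes absent from dataset: {', '.join(missing)}")
        rows = [index[g] for g in gene_ids]
        return self.values[rows, :].T.copy()

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and self.gene_names == other.gene_names
            and self.class_labels == other.class_labels
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with a provenance tag (ontology/pathway source)."""

    set_id: str
    name: str
    source: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.set_id!r} has duplicate members")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique([s.set_id for s in self.sets], "gene set ID")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    def member_union(self) -> set[str]:
        union: set[str] = set()
        for s in self.sets:
            union.update(s.members)
        return union


def _check_unique(items: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            raise FormatError(f"duplicate {kind}: {item!r}")
        seen.add(item)


# ---------------------------------------------------------------------------
# Expression-matrix CSV
# ---------------------------------------------------------------------------

def _open_text(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def read_expression_matrix(source) -> ExpressionDataset:
    """Parse an expression matrix from a path or open text stream.

    Raises :class:`FormatError` for ragged rows (with the offending row
    index), duplicate sample or gene IDs (naming the ID), and non-numeric
    expression cells (with gene/sample coordinates).
    """
    handle, close = _open_text(source)
    try:
        rows = list(csv.reader(handle))
    finally:
        if close:
            handle.close()
    rows = [r for r in rows if r]  # drop fully empty lines
    if len(rows) < 2:
        raise FormatError("expression CSV needs a header row and at least one gene row")

    header = rows[0]
    if len(header) < 3:
        raise FormatError("header row must contain ID, NAME and at least one sample")
    sample_ids = [c.strip() for c in header[2:]]
    _check_unique(sample_ids, "sample ID")
    width = len(header)

    body_start = 1
    class_labels: list[str] | None = None
    second = rows[1]
    if len(second) >= 2 and second[0].strip() == "" and second[1].strip().upper() == "CLASS":
        if len(second) != width:
            raise FormatError(f"row 2 (CLASS) has {len(second)} cells, expected {width}")
        class_labels = [c.strip() for c in second[2:]]
        body_start = 2

    gene_ids: list[str] = []
    gene_names: list[str] = []
    data: list[list[float]] = []
    for row_index, row in enumerate(rows[body_start:], start=body_start + 1):
        if len(row) != width:
            raise FormatError(f"row {row_index} has {len(row)} cells, expected {width}")
        gene_id = row[0].strip()
        gene_names.append(row[1].strip())
        gene_ids.append(gene_id)
        parsed: list[float] = []
        for col, cell in enumerate(row[2:]):
            token = cell.strip()
            if token in MISSING_TOKENS:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(token))
            except ValueError:
                raise FormatError(
                    f"non-numeric expression value {cell!r} for gene "
                    f"{gene_id!r}, sample {sample_ids[col]!r}"
                ) from None
        data.append(parsed)
    _check_unique(gene_ids, "gene ID")

    values = np.array(data, dtype=float) if data else np.empty((0, len(sample_ids)))
    return ExpressionDataset(sample_ids, gene_ids, gene_names, values, class_labels)


def write_expression_matrix(dataset: ExpressionDataset, sink) -> None:
    """Write ``dataset`` so that :func:`read_expression_matrix` reproduces it exactly."""
    handle, close = _open_text(sink, "w")
    try:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["ID", "NAME", *dataset.sample_ids])
        if dataset.class_labels is not None:
            writer.writerow(["", "CLASS", *dataset.class_labels])
        for i, (gid, gname) in enumerate(zip(dataset.gene_ids, dataset.gene_names)):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in dataset.values[i]]
            writer.writerow([gid, gname, *cells])
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gene_set_collection(source) -> GeneSetCollection:
    """Parse a GMT file: ``set_id<TAB>source<TAB>member...`` per line.

    Duplicate members within a line are dropped with a warning; a line with
    fewer than three fields or a repeated set id is a :class:`FormatError`.
    """
    handle, close = _open_text(source)
    try:
        lines = handle.read().splitlines()
    finally:
        if close:
            handle.close()

    sets: list[GeneSet] = []
    seen_ids: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line {lineno}: expected at least 3 TAB-separated fields")
        set_id, source_tag = fields[0].strip(), fields[1].strip()
        if set_id in seen_ids:
            raise FormatError(f"duplicate gene set ID: {set_id!r}")
        seen_ids.add(set_id)
        members = [m.strip() for m in fields[2:] if m.strip()]
        if not members:
            raise FormatError(f"GMT line {lineno}: gene set {set_id!r} has no members")
        unique = list(dict.fromkeys(members))
        if len(unique) != len(members):
            log.warning("gene set %s: %d duplicate member(s) dropped",
                        set_id, len(members) - len(unique))
        sets.append(GeneSet(set_id=set_id, name=set_id, source=source_tag,
                            members=tuple(unique)))
    return GeneSetCollection(sets)


def write_gene_set_collection(collection: GeneSetCollection, sink) -> None:
    handle, close = _open_text(sink, "w")
    try:
        for s in collection:
            handle.write("\t".join([s.set_id, s.source, *s.members]) + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Committee persistence (versioned JSON, extension .gcmt)
# ---------------------------------------------------------------------------

KNOWN_FAMILIES = ("knn", "decision_tree", "svm", "naive_bayes", "random_forest")


def persist_committee(committee, sink) -> None:
    """Serialize a trained committee to a single JSON document.

    Fitted scikit-learn estimators are embedded as base64 pickle payloads so
    that a reloaded committee predicts bit-identically to the in-memory one.
    """
    experts = getattr(committee, "experts", None)
    if not experts or any(e.model is None for e in experts):
        raise CommitteeIOError("cannot persist an untrained committee")
    doc = {
        "format": COMMITTEE_FORMAT,
        "version": COMMITTEE_VERSION,
        "classes": list(committee.classes),
        "gene_universe": list(committee.gene_universe),
        "training_means": {g: _json_float(v) for g, v in committee.training_means.items()},
        "metadata": committee.metadata,
        "experts": [
            {
                "expert_id": e.expert_id,
                "set_id": e.gene_set.set_id,
                "set_name": e.gene_set.name,
                "set_source": e.gene_set.source,
                "set_members": list(e.gene_set.members),
                "usable_features": list(e.usable_features),
                "family": e.config.family,
                "config_id": e.config.config_id,
                "hyperparameters": e.config.hyperparameters,
                "metrics": e.metrics,
                "model": base64.b64encode(pickle.dumps(e.model)).decode("ascii"),
            }
            for e in experts
        ],
    }
    handle, close = _open_text(sink, "w")
    try:
        json.dump(doc, handle, indent=1)
    finally:
        if close:
            handle.close()


def load_committee(source):
    """Load a committee persisted by :func:`persist_committee`."""
    from .committee import Committee, TrainedExpert
    from .evaluation import ClassifierConfig

    handle, close = _open_text(source)
    try:
        try:
            doc = json.load(handle)
        except json.JSONDecodeError as exc:
            raise CommitteeIOError(f"truncated or corrupt committee file: {exc}") from exc
    finally:
        if close:
            handle.close()

    if not isinstance(doc, dict) or doc.get("format") != COMMITTEE_FORMAT:
        raise CommitteeIOError("not a committee file")
    if doc.get("version") != COMMITTEE_VERSION:
        raise CommitteeIOError(
            f"unsupported committee file version {doc.get('version')!r} "
            f"(expected {COMMITTEE_VERSION})"
        )

    experts = []
    for entry in doc["experts"]:
        family = entry["family"]
        if family not in KNOWN_FAMILIES:
            raise CommitteeIOError(f"unknown classifier family tag: {family!r}")
        config = ClassifierConfig(
            family=family,
            hyperparameters=entry["hyperparameters"],
            config_id=entry["config_id"],
        )
        gene_set = GeneSet(
            set_id=entry["set_id"],
            name=entry["set_name"],
            source=entry["set_source"],
            members=tuple(entry["set_members"]),
        )
        model = pickle.loads(base64.b64decode(entry["model"]))
        experts.append(
            TrainedExpert(
                expert_id=entry["expert_id"],
                gene_set=gene_set,
                usable_features=tuple(entry["usable_features"]),
                config=config,
                metrics={k: _from_json_float(v) for k, v in entry["metrics"].items()},
                model=model,
            )
        )
    return Committee(
        experts=experts,
        classes=list(doc["classes"]),
        gene_universe=list(doc["gene_universe"]),
        training_means={g: _from_json_float(v) for g, v in doc["training_means"].items()},
        metadata=doc.get("metadata", {}),
    )


def _json_float(v):
    v = float(v)
    return "NaN" if np.isnan(v) else v


def _from_json_float(v):
    if v == "NaN":
        return float("nan")
    return float(v) if isinstance(v, (int, float)) else v
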