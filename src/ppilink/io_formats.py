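"""File formats: FASTA sequences, interaction-edge TSVs, split files, metrics reports.

The edge dialect follows STRING "actions" exports in minimal form: a
tab-separated table with header columns ``protein_a``, ``protein_b``,
``mode`` and one interaction-type label per row; rows for the same unordered
pair are merged by label union.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The seven interaction types, in canonical column order.
INTERACTION_TYPES = (
    "activation",
    "binding",
    "catalysis",
    "expression",
    "inhibition",
    "ptmod",
    "reaction",
)

#: Accepted spellings in edge files, mapped to canonical names.
_MODE_ALIASES = {
    **{t: t for t in INTERACTION_TYPES},
    "post-translational modification": "ptmod",
    "post_translational_modification": "ptmod",
    "posttranslational modification": "ptmod",
}


class FormatError(ValueError):
    """A file violated the expected format or an invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier with its amino-acid sequence (uppercase letters)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise FormatError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise FormatError(f"protein {self.id!r}: sequence must be non-empty")
        if not self.sequence.isalpha() or not self.sequence.isupper():
            raise FormatError(
                f"protein {self.id!r}: sequence must consist of uppercase letters"
            )


@dataclass(frozen=True)
class EdgeRecord:
    """An unordered protein pair with a subset of the 7 interaction types."""

    protein_a: str
    protein_b: str
    labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.protein_a == self.protein_b:
            raise FormatError(f"self-interaction not allowed: {self.protein_a!r}")
        object.__setattr__(self, "labels", frozenset(self.labels))
        unknown = self.labels - set(INTERACTION_TYPES)
        if unknown:
            raise FormatError(
                f"unknown interaction types {sorted(unknown)}; "
                f"accepted: {list(INTERACTION_TYPES)}"
            )

    @property
    def key(self) -> tuple:
        """Canonical unordered pair key."""
        return tuple(sorted((self.protein_a, self.protein_b)))


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords (uppercased, order preserved)."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FormatError(f"{path}: entry {i} has an empty header")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: entry {i} ({rec.id!r}) has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate protein id {rec.id!r} (entry {i})")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for j in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[j : j + 70] + "\n")


def read_edges(path) -> list[EdgeRecord]:
    """Read a (protein_a, protein_b, mode) TSV, merging unordered-pair duplicates."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"protein_a", "protein_b", "mode"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    merged: dict[tuple, set] = {}
    order: list[tuple] = []
    names: dict[tuple, tuple] = {}
    for row in df.itertuples(index=False):
        a, b, mode = row.protein_a, row.protein_b, row.mode
        if a == b:
            raise FormatError(f"{path}: self-interaction {a!r}")
        label = _MODE_ALIASES.get(str(mode).strip().lower())
        if label is None:
            raise FormatError(
                f"{path}: unknown mode {mode!r}; accepted: {list(INTERACTION_TYPES)}"
            )
        key = tuple(sorted((a, b)))
        if key not in merged:
            merged[key] = set()
            order.append(key)
            names[key] = (a, b)
        merged[key].add(label)
    return [
        EdgeRecord(names[k][0], names[k][1], frozenset(merged[k])) for k in order
    ]


def write_edges(edges: Iterable[EdgeRecord], path) -> None:
    """Write edges one (pair, label) row at a time in canonical label order."""
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tmode\n")
        for e in edges:
            for t in INTERACTION_TYPES:
                if t in e.labels:
                    fh.write(f"{e.protein_a}\t{e.protein_b}\t{t}\n")


# -- split files --------------------------------------------------------------

_SCHEMES = ("random", "bfs", "dfs")


def write_split(result, path) -> None:
    """Serialize a SplitResult as a TSV with a scheme/seed header comment."""
    with open(path, "w") as fh:
        fh.write(f"# scheme={result.scheme} seed={result.seed}\n")
        fh.write("protein_a\tprotein_b\tlabels\tpartition\n")
        for part, edges in (("train", result.train_edges), ("test", result.test_edges)):
            for e in edges:
                labels = ";".join(t for t in INTERACTION_TYPES if t in e.labels)
                fh.write(f"{e.protein_a}\t{e.protein_b}\t{labels}\t{part}\n")


def read_split(path):
    """Read a split file back into a SplitResult (strata recomputed)."""
    from .partition import SplitResult, stratify_test

    with open(path) as fh:
        header = fh.readline().strip()
    if not header.startswith("#"):
        raise FormatError(f"{path}: missing '# scheme=... seed=...' header comment")
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok)
    scheme = meta.get("scheme")
    if scheme not in _SCHEMES:
        raise FormatError(f"{path}: unknown scheme tag {scheme!r}; accepted: {_SCHEMES}")
    seed = int(meta.get("seed", 0))

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    train, test = [], []
    seen: dict[tuple, str] = {}
    for row in df.itertuples(index=False):
        labels = frozenset(str(row.labels).split(";")) if str(row.labels) != "nan" else frozenset()
        edge = EdgeRecord(row.protein_a, row.protein_b, labels)
        prev = seen.get(edge.key)
        if prev is not None and prev != row.partition:
            raise FormatError(
                f"{path}: edge {edge.key} appears in both train and test partitions"
            )
        seen[edge.key] = row.partition
        if row.partition == "train":
            train.append(edge)
        elif row.partition == "test":
            test.append(edge)
        else:
            raise FormatError(f"{path}: unknown partition {row.partition!r}")
    if not test:
        logger.warning("%s: split file has an empty test set", path)
    homologous, unknown = stratify_test(train, test)
    return SplitResult(
        scheme=scheme,
        seed=seed,
        train_edges=train,
        test_edges=test,
        test_homologous=homologous,
        test_unknown=unknown,
    )


def write_metrics_report(report, path) -> None:
    """Write a MetricsReport as JSON (precision, recall, micro_f1, per_label_counts)."""
    payload = {
        "precision": report.precision,
        "recall": report.recall,
        "micro_f1": report.micro_f1,
        "per_label_counts": report.per_label_counts,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
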