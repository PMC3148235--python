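"""Interchange formats and expression-matrix plumbing.

The pipeline talks GCT (#1.2) for expression matrices, CLS for binary class
labels, GMT for gene-set collections, and two small TSV dialects: a
sample-annotation table (sample_id, group, timepoint) and a probe-bridging
table (source probe <TAB> target probe) for cross-platform translation.

All writers terminate files with a newline.  Probe and sample identifiers
are matched case-sensitively; there is no fuzzy matching.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "BridgingMap",
    "FormatError",
    "load_expression",
    "save_expression",
    "load_gene_sets",
    "save_gene_sets",
    "load_bridge_map",
    "save_bridge_map",
    "load_cls",
    "save_cls",
    "load_annotations",
    "save_annotations",
    "map_platform",
    "subtract_control_means",
]


class FormatError(ValueError):
    """Malformed or inconsistent interchange file."""


@dataclasses.dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 expression intensities.

    ``data`` is indexed by probe identifier with one column per sample;
    ``annotations`` is indexed by sample identifier and carries at least a
    ``group`` column and, for in-vivo study designs, a ``timepoint`` column.
    Values are post-normalization log2 intensities (e.g. RMA output);
    nothing in the pipeline re-normalizes them.
    """

    data: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe identifiers: {dupes[:5]}")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes[:5]}")
        if self.annotations is not None:
            missing = [s for s in self.data.columns if s not in self.annotations.index]
            if missing:
                raise FormatError(f"samples without annotation: {missing[:5]}")
            if "group" not in self.annotations.columns:
                raise FormatError("annotations must carry a 'group' column")

    # -- convenience selections -----------------------------------------
    def groups(self) -> pd.Series:
        """Per-sample group labels, aligned to the matrix column order."""
        if self.annotations is None:
            raise ValueError("matrix has no sample annotations")
        return self.annotations.loc[self.sample_ids, "group"]

    def timepoints(self) -> pd.Series:
        if self.annotations is None or "timepoint" not in self.annotations.columns:
            raise ValueError("matrix has no timepoint annotations")
        return self.annotations.loc[self.sample_ids, "timepoint"]

    def select_samples(
        self,
        group: str | list[str] | None = None,
        timepoint: str | None = None,
    ) -> "ExpressionMatrix":
        """Column subset by group and/or timepoint, preserving sample order."""
        mask = pd.Series(True, index=self.data.columns)
        if group is not None:
            wanted = [group] if isinstance(group, str) else list(group)
            mask &= self.groups().isin(wanted).to_numpy()
        if timepoint is not None:
            mask &= (self.timepoints() == timepoint).to_numpy()
        cols = self.data.columns[mask]
        ann = None if self.annotations is None else self.annotations.loc[cols]
        return ExpressionMatrix(self.data[cols], ann)

    def copy(self) -> "ExpressionMatrix":
        ann = None if self.annotations is None else self.annotations.copy()
        return ExpressionMatrix(self.data.copy(), ann)


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets: name -> {description, members (ordered, unique)}."""

    sets: dict[str, dict]

    def __post_init__(self) -> None:
        for name, rec in self.sets.items():
            if not rec.get("members"):
                raise FormatError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return list(self.sets[name]["members"])


@dataclasses.dataclass
class BridgingMap:
    """Many-to-many probe pairs (source platform -> target platform)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise FormatError("duplicate (source, target) pairs in bridging map")

    def __len__(self) -> int:
        return len(self.pairs)

    def targets_by_source(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, []).append(t)
        return out

    def sources_by_target(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, t in self.pairs:
            out.setdefault(t, []).append(s)
        return out


# ---------------------------------------------------------------------------
# GCT
# ---------------------------------------------------------------------------

def load_expression(
    gct_path: str | Path,
    cls_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
    cls_groups: tuple[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a GCT #1.2 matrix, optionally attaching CLS / annotation labels.

    A CLS file supplies a binary group annotation (class names from its
    second line); an annotation TSV supplies (group, timepoint) per sample
    and takes precedence over the CLS when both are given.
    """
    gct_path = Path(gct_path)
    with open(gct_path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{gct_path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{gct_path}: malformed dimension line")
        n_probes, n_samples = int(dims[0]), int(dims[1])
        body = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    if "Description" in body.columns:
        body = body.drop(columns=["Description"])
    elif body.shape[1] >= 1:
        # second column is Description whatever its header says
        body = body.drop(columns=[body.columns[0]])
    if body.shape != (n_probes, n_samples):
        raise FormatError(
            f"{gct_path}: header declares {n_probes}x{n_samples} "
            f"but body is {body.shape[0]}x{body.shape[1]}"
        )
    body.index = body.index.astype(str)
    body = body.astype(float)

    annotations = None
    if cls_path is not None:
        labels, names = load_cls(cls_path)
        if len(labels) != n_samples:
            raise FormatError(
                f"CLS declares {len(labels)} samples but GCT has {n_samples}"
            )
        group = [names[i] for i in labels]
        annotations = pd.DataFrame({"group": group}, index=body.columns)
    if annotation_path is not None:
        annotations = load_annotations(annotation_path)
    return ExpressionMatrix(body, annotations)


def save_expression(matrix: ExpressionMatrix, gct_path: str | Path) -> None:
    """Write GCT #1.2; the Description column repeats the probe id."""
    matrix.validate()
    gct_path = Path(gct_path)
    with open(gct_path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_probes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for probe, row in zip(matrix.probe_ids, matrix.values):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{probe}\t{probe}\t{vals}\n")


# ---------------------------------------------------------------------------
# CLS
# ---------------------------------------------------------------------------

def load_cls(cls_path: str | Path) -> tuple[list[int], list[str]]:
    """Read a categorical CLS file -> (per-sample class index, class names)."""
    lines = [ln.strip() for ln in Path(cls_path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{cls_path}: CLS needs 3 non-empty lines")
    header = lines[0].split()
    n_samples, n_classes = int(header[0]), int(header[1])
    names = lines[1].lstrip("#").split()
    if len(names) != n_classes:
        raise FormatError(f"{cls_path}: {n_classes} classes declared, {len(names)} named")
    tokens = lines[2].split()
    if len(tokens) != n_samples:
        raise FormatError(
            f"{cls_path}: {n_samples} samples declared, {len(tokens)} labels given"
        )
    if all(t in names for t in tokens):
        labels = [names.index(t) for t in tokens]
    else:
        labels = [int(t) for t in tokens]
        if any(l < 0 or l >= n_classes for l in labels):
            raise FormatError(f"{cls_path}: class index out of range")
    return labels, names


def save_cls(labels: list[int], names: list[str], cls_path: str | Path) -> None:
    with open(cls_path, "w") as fh:
        fh.write(f"{len(labels)} {len(names)} 1\n")
        fh.write("# " + " ".join(names) + "\n")
        fh.write(" ".join(str(l) for l in labels) + "\n")


# ---------------------------------------------------------------------------
# Annotation TSV (sample_id, group, timepoint)
# ---------------------------------------------------------------------------

def load_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required.issubset(ann.columns):
        raise FormatError(f"{path}: annotation TSV needs columns {sorted(required)}")
    return ann.set_index("sample_id")


def save_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def load_gene_sets(gmt_path: str | Path) -> GeneSetCollection:
    """Read tab-delimited GMT: name, description, member, member, ...

    Member order is preserved; duplicate members within a set are dropped.
    """
    sets: dict[str, dict] = {}
    for i, line in enumerate(Path(gmt_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{gmt_path}:{i}: GMT line needs >= 3 tab-separated fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        members = list(dict.fromkeys(members))
        if name in sets:
            raise FormatError(f"{gmt_path}:{i}: duplicate set name {name!r}")
        sets[name] = {"description": desc, "members": members}
    return GeneSetCollection(sets)


def save_gene_sets(collection: GeneSetCollection, gmt_path: str | Path) -> None:
    with open(gmt_path, "w") as fh:
        for name, rec in collection.sets.items():
            fh.write("\t".join([name, rec.get("description", "")] + rec["members"]) + "\n")


# ---------------------------------------------------------------------------
# Bridging TSV
# ---------------------------------------------------------------------------

def load_bridge_map(tsv_path: str | Path) -> BridgingMap:
    """Two-column (source, target) TSV; optional 'source\\ttarget' header."""
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for i, line in enumerate(Path(tsv_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise FormatError(f"{tsv_path}:{i}: bridging row needs 2 tab-separated fields")
        src, tgt = fields[0], fields[1]
        if i == 1 and src.lower() in {"source", "source_probe"}:
            continue
        pair = (src, tgt)
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return BridgingMap(pairs)


def save_bridge_map(bridge: BridgingMap, tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("source\ttarget\n")
        for s, t in bridge.pairs:
            fh.write(f"{s}\t{t}\n")


# ---------------------------------------------------------------------------
# Cross-platform translation and control subtraction
# ---------------------------------------------------------------------------

def map_platform(matrix: ExpressionMatrix, bridge: BridgingMap) -> ExpressionMatrix:
    """Translate probe identifiers across platforms via a bridging map.

    Each output row is the arithmetic mean (on the stored log2 scale) over
    all input rows whose source probe maps to that target; source probes
    with no bridge entry are dropped.  Sample ids and annotations are
    untouched.  Averaging happens after mapping, over every source of each
    target that is present in the matrix.
    """
    present = set(matrix.probe_ids)
    groups: dict[str, list[str]] = {}
    for src, tgt in bridge.pairs:
        if src in present:
            groups.setdefault(tgt, []).append(src)
    if not groups:
        raise FormatError("no bridging source probe occurs in the matrix")
    targets = sorted(groups)
    rows = np.vstack([
        matrix.data.loc[groups[t]].to_numpy().mean(axis=0) for t in targets
    ])
    data = pd.DataFrame(rows, index=targets, columns=matrix.sample_ids)
    return ExpressionMatrix(data, matrix.annotations)


def subtract_control_means(
    matrix: ExpressionMatrix,
    control_group: str,
    timepoint: str | None = None,
) -> pd.DataFrame:
    """Per-probe exposed-minus-control group-mean differences.

    For every non-control group g present (at the given timepoint, if any):
    d(probe, g) = mean over g's samples - mean over control samples.  This
    is the control-subtracted expression level used for persistence tables.
    """
    sub = matrix if timepoint is None else matrix.select_samples(timepoint=timepoint)
    groups = sub.groups()
    if (groups == control_group).sum() == 0:
        where = f" at timepoint {timepoint!r}" if timepoint else ""
        raise ValueError(f"no samples of control group {control_group!r}{where}")
    others = [g for g in pd.unique(groups) if g != control_group]
    if not others:
        raise ValueError("no non-control group present")
    ctrl_mean = sub.data.loc[:, (groups == control_group).to_numpy()].mean(axis=1)
    out = {}
    for g in others:
        out[g] = sub.data.loc[:, (groups == g).to_numpy()].mean(axis=1) - ctrl_mean
    return pd.DataFrame(out)
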