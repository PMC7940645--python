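"""Pathway definitions and subject-by-ROI table I/O.

A *pathway* is the ROI set of one neurotransmitter projection system
(e.g. the striatocortical dopaminergic network).  The shipped default
config defines the seven networks used throughout the analysis; a user
config in the same YAML schema overrides it.  Bilateral regions expand
to one ``_left`` and one ``_right`` ROI (left before right), midline
regions to a single ROI, so pathway-definition order fixes the column
order of every downstream matrix and the dendrogram leaf order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ROI",
    "PathwayDefinition",
    "SubjectMatrix",
    "PathwayConfigError",
    "SubjectTableError",
    "load_pathway_config",
    "default_pathways",
    "read_subject_table",
    "write_subject_table",
    "extract_pathway",
]

LATERALITIES = ("left", "right", "bilateral", "midline")


class PathwayConfigError(ValueError):
    """Raised for a malformed or inconsistent pathway config."""


class SubjectTableError(ValueError):
    """Raised for a malformed subject-by-ROI table."""


@dataclass(frozen=True)
class ROI:
    """A single region of interest with its laterality tag."""

    name: str
    laterality: str = "midline"

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right", "midline"):
            raise PathwayConfigError(
                f"ROI {self.name!r}: laterality must be left/right/midline "
                f"after expansion, got {self.laterality!r}"
            )


@dataclass(frozen=True)
class PathwayDefinition:
    """Named, ordered ROI list defining one pathway network.

    The same ROI may appear in several pathways (the amygdala belongs to
    both the mesolimbic and the Ch4 lateral capsular network) but must be
    unique within a pathway.
    """

    name: str
    rois: tuple[ROI, ...]

    def __post_init__(self) -> None:
        if not self.rois:
            raise PathwayConfigError(f"pathway {self.name!r} has no ROIs")
        names = [r.name for r in self.rois]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise PathwayConfigError(
                f"pathway {self.name!r} lists duplicate ROIs: {dupes}"
            )

    @property
    def roi_names(self) -> list[str]:
        return [r.name for r in self.rois]

    def __len__(self) -> int:
        return len(self.rois)


@dataclass
class SubjectMatrix:
    """n_subjects x n_ROI table of regional metabolic values.

    Rows are subjects, columns are named ROIs; the unit of group-level
    input for all connectivity analyses.
    """

    values: np.ndarray
    roi_names: list[str]
    group_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_names = list(self.roi_names)
        if self.values.ndim != 2:
            raise SubjectTableError("values must be a 2-D array")
        if self.values.shape[1] != len(self.roi_names):
            raise SubjectTableError(
                f"{self.values.shape[1]} columns but {len(self.roi_names)} ROI names"
            )
        if len(set(self.roi_names)) != len(self.roi_names):
            raise SubjectTableError("duplicate ROI names")
        if self.n_subjects < 3:
            raise SubjectTableError(
                f"group {self.group_label!r}: {self.n_subjects} subjects; "
                "at least 3 are required for Pearson correlation "
                "(is the table transposed?)"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise SubjectTableError(
                f"non-finite value at subject row {i + 1}, ROI {self.roi_names[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.roi_names)


def _expand_roi(entry: dict) -> list[ROI]:
    try:
        name = entry["name"]
    except (KeyError, TypeError):
        raise PathwayConfigError(f"ROI entry {entry!r} lacks a 'name'") from None
    lat = entry.get("laterality", "bilateral")
    if lat not in LATERALITIES:
        raise PathwayConfigError(
            f"ROI {name!r}: unknown laterality {lat!r} (expected one of {LATERALITIES})"
        )
    if lat == "bilateral":
        return [ROI(f"{name}_left", "left"), ROI(f"{name}_right", "right")]
    return [ROI(f"{name}_{lat}", lat) if lat in ("left", "right") else ROI(name, "midline")]


def _parse_config(doc: object, source: str) -> list[PathwayDefinition]:
    if not isinstance(doc, dict) or "pathways" not in doc:
        raise PathwayConfigError(f"{source}: expected a mapping with a 'pathways' key")
    out = []
    for block in doc["pathways"]:
        if not isinstance(block, dict) or "name" not in block or "rois" not in block:
            raise PathwayConfigError(
                f"{source}: each pathway needs 'name' and 'rois', got {block!r}"
            )
        rois: list[ROI] = []
        for entry in block["rois"]:
            rois.extend(_expand_roi(entry))
        out.append(PathwayDefinition(name=str(block["name"]), rois=tuple(rois)))
    if not out:
        raise PathwayConfigError(f"{source}: no pathways defined")
    names = [p.name for p in out]
    if len(set(names)) != len(names):
        raise PathwayConfigError(f"{source}: duplicate pathway names")
    return out


def load_pathway_config(path: str | Path | None = None) -> list[PathwayDefinition]:
    """Load pathway definitions from a YAML config (default: shipped atlas).

    Schema: ``{pathways: [{name, rois: [{name, laterality}]}]}`` with
    laterality one of left/right/bilateral/midline (bilateral expands to
    a left and a right ROI).
    """
    if path is None:
        text = resources.files("phnet.data").joinpath("pathways.yaml").read_text()
        source = "default pathway config"
    else:
        path = Path(path)
        if not path.exists():
            raise PathwayConfigError(f"pathway config not found: {path}")
        text = path.read_text(encoding="utf-8")
        source = str(path)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise PathwayConfigError(f"{source}: unparseable YAML: {exc}") from exc
    return _parse_config(doc, source)


def default_pathways() -> list[PathwayDefinition]:
    """The seven shipped pathway networks."""
    return load_pathway_config(None)


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_subject_table(path: str | Path, group_label: str = "") -> SubjectMatrix:
    """Read a delimited subject-by-ROI table (header row of ROI names).

    Delimiter is sniffed from the extension (``.tsv``/``.tab`` -> tab,
    otherwise comma).  Missing or non-numeric cells and duplicate column
    names are hard errors naming the offending location; nothing is
    imputed.
    """
    path = Path(path)
    if not path.exists():
        raise SubjectTableError(f"subject table not found: {path}")
    delim = _delimiter_for(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if not rows:
        raise SubjectTableError(f"{path}: empty file")
    header = [c.strip() for c in rows[0]]
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise SubjectTableError(f"{path}: duplicate column names {dupes}")
    ncol = len(header)
    values = np.empty((len(rows) - 1, ncol))
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != ncol:
            raise SubjectTableError(
                f"{path}: row {i} has {len(row)} cells, header has {ncol}"
            )
        for j, cell in enumerate(row):
            cell = cell.strip()
            if cell == "":
                raise SubjectTableError(
                    f"{path}: missing value at row {i}, column {header[j]!r}"
                )
            try:
                values[i - 1, j] = float(cell)
            except ValueError:
                raise SubjectTableError(
                    f"{path}: non-numeric value {cell!r} at row {i}, "
                    f"column {header[j]!r}"
                ) from None
    return SubjectMatrix(values=values, roi_names=header, group_label=group_label)


def write_subject_table(matrix: SubjectMatrix, path: str | Path) -> Path:
    """Write a SubjectMatrix as delimited text (round-trips with the reader)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(path, sep=_delimiter_for(path), index=False)
    return path


def extract_pathway(matrix: SubjectMatrix, pathway: PathwayDefinition) -> SubjectMatrix:
    """Column-subset a SubjectMatrix to one pathway, in pathway order."""
    index = {name: k for k, name in enumerate(matrix.roi_names)}
    missing = [n for n in pathway.roi_names if n not in index]
    if missing:
        raise SubjectTableError(
            f"pathway {pathway.name!r}: ROIs absent from table: {missing}"
        )
    cols = [index[n] for n in pathway.roi_names]
    return SubjectMatrix(
        values=matrix.values[:, cols],
        roi_names=pathway.roi_names,
        group_label=matrix.group_label,
    )
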