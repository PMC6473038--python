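"""Activation-focus data model, table ingestion and coordinate-space handling.

A *focus* (peak) is a reported local maximum of brain activation given as a
3-D stereotactic coordinate in millimetres, tagged with the study and
contrast it came from and with a class label (e.g. ``intention`` vs
``self_agency``).  A :class:`FociDataset` is the unit of meta-analysis: an
ordered collection of foci, all normalised to MNI space at ingestion.

Talairach-reported coordinates are converted with the inverse of the
standard piecewise-linear MNI->Talairach ("Brett") approximation: two
distinct linear maps above and below the axial plane and no translation
term, so the origin is a fixed point.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DatasetError, FormatError

__all__ = [
    "Focus",
    "FociDataset",
    "PriorTable",
    "DEFAULT_LABELS",
    "DEFAULT_COLUMNS",
    "mni2tal",
    "tal2mni",
    "read_foci_table",
    "read_sleuth",
    "write_foci_table",
    "dataset_priors",
]

DEFAULT_LABELS = ("intention", "self_agency", "external_agency")

#: Default header-name mapping for delimited foci tables.
DEFAULT_COLUMNS = {
    "study": "study",
    "contrast": "contrast",
    "label": "label",
    "x": "x",
    "y": "y",
    "z": "z",
    "space": "space",
}

# Piecewise-linear MNI -> Talairach approximation (no translation).
# Row order (x, y, z); the superior map applies for MNI z >= 0.
_MNI2TAL_SUP = np.array(
    [[0.9900, 0.0, 0.0], [0.0, 0.9688, 0.0460], [0.0, -0.0485, 0.9189]]
)
_MNI2TAL_INF = np.array(
    [[0.9900, 0.0, 0.0], [0.0, 0.9688, 0.0420], [0.0, -0.0485, 0.8390]]
)
_TAL2MNI_SUP = np.linalg.inv(_MNI2TAL_SUP)
_TAL2MNI_INF = np.linalg.inv(_MNI2TAL_INF)

# Sanity bounds for MNI coordinates (mm); violations are logged, not fatal.
_SANITY_XY = 100.0
_SANITY_Z = (-80.0, 120.0)


@dataclass(frozen=True)
class Focus:
    """One activation peak.

    Attributes
    ----------
    study_id, contrast_id : str
        Opaque identifiers of the originating study and contrast.
    label : str
        Class tag of the peak (one of the dataset's label set).
    coord : tuple of 3 floats
        Stereotactic coordinate in mm.
    space : str
        ``"MNI"`` or ``"Talairach"``.
    """

    study_id: str
    contrast_id: str
    label: str
    coord: tuple[float, float, float]
    space: str = "MNI"


@dataclass(frozen=True)
class FociDataset:
    """An ordered collection of foci, the unit of meta-analysis."""

    foci: tuple[Focus, ...]
    label_set: tuple[str, ...] = DEFAULT_LABELS
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.foci) == 0:
            raise DatasetError("a FociDataset must contain at least one focus")
        bad = {f.label for f in self.foci} - set(self.label_set)
        if bad:
            raise DatasetError(f"labels outside the declared label set: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.foci)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of coordinates in mm."""
        return np.array([f.coord for f in self.foci], dtype=float)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f.label for f in self.foci)

    def label_counts(self) -> dict[str, int]:
        counts = {lab: 0 for lab in self.label_set}
        for f in self.foci:
            counts[f.label] += 1
        return counts

    def subset(self, labels: Iterable[str]) -> "FociDataset":
        """Restrict to foci whose label is in ``labels`` (order preserved)."""
        keep = tuple(f for f in self.foci if f.label in set(labels))
        return FociDataset(keep, self.label_set, self.provenance)

    def by_experiment(self) -> dict[tuple[str, str], np.ndarray]:
        """Group coordinates by (study, contrast) experiment, input order kept."""
        groups: dict[tuple[str, str], list] = {}
        for f in self.foci:
            groups.setdefault((f.study_id, f.contrast_id), []).append(f.coord)
        return {k: np.array(v, dtype=float) for k, v in groups.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study": [f.study_id for f in self.foci],
                "contrast": [f.contrast_id for f in self.foci],
                "label": [f.label for f in self.foci],
                "x": [f.coord[0] for f in self.foci],
                "y": [f.coord[1] for f in self.foci],
                "z": [f.coord[2] for f in self.foci],
                "space": [f.space for f in self.foci],
            }
        )


@dataclass(frozen=True)
class PriorTable:
    """Per-label proportions of the whole dataset (exact rationals).

    These are the success probabilities of the cluster-composition binomial
    test: the prior likelihood that a randomly drawn focus carries a label.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise DatasetError("negative label count")
        if self.total == 0:
            raise DatasetError("empty prior table")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def proportion(self, label: str) -> float:
        if label not in self.counts:
            raise ValueError(f"label {label!r} not in prior table")
        return self.counts[label] / self.total

    def exact(self, label: str) -> Fraction:
        return Fraction(self.counts[label], self.total)

    def as_dict(self) -> dict[str, float]:
        return {lab: self.proportion(lab) for lab in self.counts}


def mni2tal(coord: Sequence[float]) -> np.ndarray:
    """Forward piecewise-linear MNI -> Talairach map (superior map for z >= 0)."""
    c = np.asarray(coord, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite coordinate")
    mat = _MNI2TAL_SUP if c[2] >= 0 else _MNI2TAL_INF
    return mat @ c


def tal2mni(coord: Sequence[float]) -> np.ndarray:
    """Talairach -> MNI, inverting the piecewise map.

    The halfspace (superior/inferior linear map) is chosen by the sign of the
    *output* MNI z: the superior inverse is tried first and the inferior one
    is used if the result lands strictly below the axial plane.  z = 0 ties
    resolve to the superior map.  Round-trip with :func:`mni2tal` reproduces
    the input to well under 1e-6 mm.
    """
    c = np.asarray(coord, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite coordinate")
    out = _TAL2MNI_SUP @ c
    if out[2] < 0:
        out = _TAL2MNI_INF @ c
    return out


def _normalise_space(tag: str) -> str:
    t = str(tag).strip().lower()
    if t in {"mni", "mni152"}:
        return "MNI"
    if t in {"talairach", "tal"}:
        return "Talairach"
    raise ValueError(f"unknown coordinate-space tag: {tag!r}")


def _to_mni(focus: Focus) -> Focus:
    if focus.space == "MNI":
        return focus
    xyz = tal2mni(focus.coord)
    return replace(focus, coord=(float(xyz[0]), float(xyz[1]), float(xyz[2])), space="MNI")


def read_foci_table(
    source,
    dialect: Mapping[str, str] | None = None,
    label_set: Sequence[str] = DEFAULT_LABELS,
    sep: str | None = None,
) -> tuple[FociDataset, list[str]]:
    """Read a delimited foci table and normalise all rows to MNI space.

    Parameters
    ----------
    source : path or text handle
        CSV/TSV with a header declaring study, contrast, label, x, y, z and
        space columns (names configurable via ``dialect``).
    dialect : mapping, optional
        Maps the canonical keys of :data:`DEFAULT_COLUMNS` to the header
        names actually used in the file.
    sep : str, optional
        Field separator; inferred when omitted.

    Returns
    -------
    (FociDataset, list of str)
        The dataset (one focus per accepted row, input order) and a per-row
        ingestion log recording rejected rows and sanity warnings.

    Raises
    ------
    FormatError
        If a mandatory column is missing (the message names it).
    ValueError
        On an unknown coordinate-space tag.
    DatasetError
        If no valid rows remain.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    # coordinates are parsed below with Python's correctly-rounded float(),
    # keeping MNI rows bit-identical through a text round trip
    df = pd.read_csv(source, sep=sep, engine="python" if sep is None else "c", dtype=str)
    for key, name in cols.items():
        if name not in df.columns:
            raise FormatError(f"missing mandatory column: {name!r} (maps to {key!r})")

    log: list[str] = []
    foci: list[Focus] = []
    for i, row in df.iterrows():
        try:
            xyz = tuple(float(row[cols[a]]) for a in ("x", "y", "z"))
        except (TypeError, ValueError):
            log.append(f"row {i}: rejected (non-numeric coordinate)")
            continue
        if not all(np.isfinite(xyz)):
            log.append(f"row {i}: rejected (non-finite coordinate)")
            continue
        space = _normalise_space(row[cols["space"]])
        f = Focus(
            study_id=str(row[cols["study"]]),
            contrast_id=str(row[cols["contrast"]]),
            label=str(row[cols["label"]]),
            coord=xyz,
            space=space,
        )
        f = _to_mni(f)
        x, y, z = f.coord
        if abs(x) > _SANITY_XY or abs(y) > _SANITY_XY or not (_SANITY_Z[0] <= z <= _SANITY_Z[1]):
            log.append(f"row {i}: warning (coordinate outside MNI sanity bounds)")
        foci.append(f)
    if not foci:
        raise DatasetError("no valid foci rows in table")
    name = getattr(source, "name", str(source))
    return FociDataset(tuple(foci), tuple(label_set), provenance=f"read from {name}"), log


def write_foci_table(ds: FociDataset, target, sep: str = "\t") -> None:
    """Write a dataset back to a delimited table (lossless for MNI rows)."""
    df = ds.to_frame()
    # repr-round-trip formatting keeps coordinates bit-exact through text
    for c in ("x", "y", "z"):
        df[c] = df[c].map(repr)
    df.to_csv(target, sep=sep, index=False)


def read_sleuth(
    source,
    label: str = "intention",
    label_set: Sequence[str] = DEFAULT_LABELS,
) -> tuple[FociDataset, list[str]]:
    """Read the Sleuth/GingerALE foci text dialect.

    The format is ``// Reference=MNI`` (or Talairach) once at the top, then
    per-experiment comment blocks (``// Study: contrast`` plus any further
    ``//`` lines) each followed by whitespace-separated ``x y z`` rows.
    Sleuth files carry no class labels, so every focus receives ``label``.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    space = "MNI"
    study, contrast = "unknown", "1"
    in_header = False
    foci: list[Focus] = []
    log: list[str] = []
    for ln, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line:
            in_header = False
            continue
        if line.startswith("//"):
            body = line[2:].strip()
            if "=" in body and body.lower().startswith("reference"):
                space = _normalise_space(body.split("=", 1)[1])
                continue
            if not in_header:  # first comment line of a new experiment block
                in_header = True
                if ":" in body:
                    study, contrast = (s.strip() for s in body.split(":", 1))
                else:
                    study, contrast = body, "1"
            continue
        in_header = False
        parts = line.split()
        if len(parts) < 3:
            log.append(f"line {ln}: rejected (expected x y z)")
            continue
        try:
            xyz = tuple(float(v) for v in parts[:3])
        except ValueError:
            log.append(f"line {ln}: rejected (non-numeric coordinate)")
            continue
        foci.append(_to_mni(Focus(study, contrast, label, xyz, space)))
    if not foci:
        raise DatasetError("no foci found in Sleuth file")
    return FociDataset(tuple(foci), tuple(label_set), provenance="sleuth"), log


def dataset_priors(ds: FociDataset, labels: Sequence[str] | None = None) -> PriorTable:
    """Per-label proportions of the whole dataset.

    These exact rational proportions are the binomial success probabilities
    against which each cluster's composition is tested.  Only labels that
    occur (or are explicitly requested) enter the table, so the proportions
    sum to one.
    """
    counts = ds.label_counts()
    if labels is not None:
        bad = set(labels) - set(ds.label_set)
        if bad:
            raise ValueError(f"labels not in label set: {sorted(bad)}")
        counts = {lab: counts[lab] for lab in labels}
    else:
        counts = {lab: c for lab, c in counts.items() if c > 0}
    return PriorTable(counts)
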