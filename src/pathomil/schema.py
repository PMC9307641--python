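"""Five-class colon annotation schema and external label-scheme aggregation.

The whole pipeline trades in multilabel vectors over five diagnostic classes
(cancer, high-grade dysplasia, low-grade dysplasia, hyperplastic polyp, normal),
in that fixed canonical order.  Predictions can be aggregated onto the label
schemes of external public datasets (GlaS, CRC, UNITOPATHO, TCGA-COAD, Xu,
AIDA, IMP-CRC) via OR-semantics over scheme membership sets.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_CLASSES = 5


class SchemaError(ValueError):
    """Raised for malformed class names, labels or scheme tables."""


class AnnotationClass(enum.IntEnum):
    """The five diagnostic classes, in canonical index order."""

    cancer = 0
    high_grade_dysplasia = 1
    low_grade_dysplasia = 2
    hyperplastic_polyp = 3
    normal = 4

    @classmethod
    def from_name(cls, name: str) -> "AnnotationClass":
        try:
            return cls[name]
        except KeyError:
            raise SchemaError(
                f"unknown annotation class {name!r}; expected one of "
                f"{[c.name for c in cls]}"
            ) from None


CLASS_NAMES = tuple(c.name for c in AnnotationClass)

#: Short column names used in label CSV files, canonical order.
LABEL_COLUMNS = ("cancer", "hgd", "lgd", "hyperplastic", "normal")


def make_label(classes: Iterable[AnnotationClass | str]) -> np.ndarray:
    """Build a binary label vector with the given classes set.

    An empty input yields the all-zero (non-finalized) vector; finalization
    with the ``normal`` fallback is the labeler's job.
    """
    vec = np.zeros(N_CLASSES, dtype=np.int8)
    for c in classes:
        if isinstance(c, str):
            c = AnnotationClass.from_name(c)
        vec[int(c)] = 1
    return vec


def label_classes(label: np.ndarray) -> set[AnnotationClass]:
    """Set of classes whose indicator is on."""
    label = as_label(label)
    return {AnnotationClass(i) for i in np.flatnonzero(label)}


def as_label(label) -> np.ndarray:
    arr = np.asarray(label)
    if arr.shape != (N_CLASSES,):
        raise SchemaError(f"label vector must have shape (5,), got {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise SchemaError("label vector entries must be 0/1")
    return arr.astype(np.int8)


def union_labels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise OR of two label vectors (multilabel merge)."""
    return np.maximum(as_label(a), as_label(b))


@dataclass(frozen=True)
class ExternalScheme:
    """A partial mapping of internal classes onto an external dataset's labels.

    ``mapping`` sends an internal class to at most one external class name;
    internal classes absent from the mapping are dropped during aggregation.
    """

    name: str
    mapping: Mapping[AnnotationClass, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.mapping:
            raise SchemaError(f"scheme {self.name!r} maps no internal class")

    @property
    def external_classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ext in self.mapping.values():
            seen.setdefault(ext, None)
        return tuple(seen)

    def members(self, external_class: str) -> set[AnnotationClass]:
        return {c for c, e in self.mapping.items() if e == external_class}


def map_to_scheme(label: np.ndarray, scheme: ExternalScheme) -> set[str]:
    """Aggregate a 5-class label vector onto an external scheme.

    An external class is present iff at least one of its internal member
    classes is set.  Set internal classes without a mapping are dropped.
    """
    label = as_label(label)
    out: set[str] = set()
    for c in label_classes(label):
        ext = scheme.mapping.get(c)
        if ext is None:
            logger.debug("scheme %s drops unmapped class %s", scheme.name, c.name)
        else:
            out.add(ext)
    return out


def load_schemes(path=None) -> dict[str, ExternalScheme]:
    """Load external schemes from a TSV (scheme_name, internal_class, external_class).

    Without ``path`` the bundled table covering the seven public colon datasets
    is used.
    """
    if path is None:
        with resources.files("pathomil.data").joinpath("schemes.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t", dtype=str)
    else:
        table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"scheme_name", "internal_class", "external_class"}
    if missing := required - set(table.columns):
        raise SchemaError(f"scheme table missing columns {sorted(missing)}")
    schemes: dict[str, ExternalScheme] = {}
    for name, group in table.groupby("scheme_name", sort=False):
        mapping: dict[AnnotationClass, str] = {}
        for _, row in group.iterrows():
            cls = AnnotationClass.from_name(row["internal_class"])
            if cls in mapping:
                raise SchemaError(
                    f"scheme {name!r} maps {cls.name} to more than one external class"
                )
            mapping[cls] = row["external_class"]
        schemes[str(name)] = ExternalScheme(name=str(name), mapping=mapping)
    return schemes


# ---------------------------------------------------------------------------
# Label table IO (case_id + five 0/1 indicator columns)

def labels_to_frame(case_ids: Iterable[str], labels: np.ndarray) -> pd.DataFrame:
    labels = np.atleast_2d(np.asarray(labels, dtype=np.int8))
    frame = pd.DataFrame(labels, columns=list(LABEL_COLUMNS))
    frame.insert(0, "case_id", list(case_ids))
    return frame


def frame_to_labels(frame: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    if missing := ({"case_id", *LABEL_COLUMNS} - set(frame.columns)):
        raise SchemaError(f"label table missing columns {sorted(missing)}")
    labels = frame[list(LABEL_COLUMNS)].to_numpy(dtype=np.int8)
    return frame["case_id"].astype(str).tolist(), labels


def read_label_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    frame_to_labels(frame)  # validate
    return frame


def write_label_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
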