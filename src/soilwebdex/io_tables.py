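"""Tabular input/output and the shared data model.

All tables are delimited text (tab by default, comma via ``sep=','``),
first column ``sample_id``. Samples are always matched across tables by
``sample_id``, never by row order. Missing values are empty fields on disk
and NaN in memory; downstream statistics use pairwise deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical eight-enzyme reference profile and its class assignment
CANONICAL_ENZYME_CLASSES: dict[str, str] = {
    "AG": "C-hydrolase",
    "BG": "C-hydrolase",
    "CB": "C-hydrolase",
    "XS": "C-hydrolase",
    "NAG": "N-hydrolase",
    "LAP": "N-hydrolase",
    "PHOX": "oxidase",
    "PEOX": "oxidase",
}

ENZYME_CLASSES = frozenset({"C-hydrolase", "N-hydrolase", "oxidase"})

COMMUNITY_GROUPS = ("bacteria", "fungi", "protozoa", "nematode")

NEMATODE_TROPHIC_GROUPS = frozenset(
    {"bacterivore", "fungivore", "omnivore-predator", "herbivore"}
)
#: free-living trophic groups retained for decomposer food-web analyses
FREE_LIVING_TROPHIC_GROUPS = frozenset(
    {"bacterivore", "fungivore", "omnivore-predator"}
)
PROTOZOA_FEEDING_HABITS = frozenset({"bacterivore", "fungivore", "other"})

REQUIRED_METADATA_COLUMNS = ("treatment", "season", "plot")


class ValidationError(ValueError):
    """A table violated one of the documented data-model invariants."""


@dataclass
class ActivityTable:
    """Sample x enzyme activity matrix (nmol g^-1 soil h^-1).

    ``values`` is a DataFrame indexed by sample_id with one column per
    enzyme; ``enzyme_class`` maps every enzyme to one of
    {C-hydrolase, N-hydrolase, oxidase}.
    """

    values: pd.DataFrame
    enzyme_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        classes = dict(CANONICAL_ENZYME_CLASSES)
        classes.update(self.enzyme_class)
        for enzyme in self.values.columns:
            if enzyme not in classes:
                raise ValidationError(
                    f"enzyme {enzyme!r} has no declared class; pass class_map"
                )
            if classes[enzyme] not in ENZYME_CLASSES:
                raise ValidationError(
                    f"enzyme {enzyme!r}: unknown class {classes[enzyme]!r}"
                )
        self.enzyme_class = {e: classes[e] for e in self.values.columns}
        arr = self.values.to_numpy(dtype=float)
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative activity {arr[i, j]} for sample "
                f"{self.values.index[i]!r}, enzyme {self.values.columns[j]!r}"
            )
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate sample_id in activity table")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def enzymes(self) -> list[str]:
        return list(self.values.columns)

    def enzymes_of_class(self, *classes: str) -> list[str]:
        """Enzymes whose class is in ``classes``, in table order."""
        wanted = set(classes)
        return [e for e in self.enzymes if self.enzyme_class[e] in wanted]


@dataclass
class CommunityTable:
    """Sample x taxon count matrix for one microbiota group.

    ``annotations`` is an optional taxon-indexed DataFrame carrying
    ``feeding_habit`` (protozoa), ``trophic_group`` and ``cp_class``
    (nematodes) where applicable.
    """

    group: str
    counts: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.group not in COMMUNITY_GROUPS:
            raise ValidationError(
                f"group must be one of {COMMUNITY_GROUPS}, got {self.group!r}"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            as_float = self.counts.to_numpy(dtype=float)
            if np.any(as_float != np.floor(as_float)) or np.any(np.isnan(as_float)):
                bad = np.argwhere(
                    (as_float != np.floor(as_float)) | np.isnan(as_float)
                )[0]
                raise ValidationError(
                    f"non-integer count {as_float[bad[0], bad[1]]} for sample "
                    f"{self.counts.index[bad[0]]!r}, taxon "
                    f"{self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise ValidationError(f"negative count in {self.group} table")
        if self.annotations is not None:
            extra = self.annotations.index.difference(self.counts.columns)
            if len(extra):
                logger.warning(
                    "%s annotations: %d taxa absent from counts ignored",
                    self.group,
                    len(extra),
                )
                self.annotations = self.annotations.drop(index=extra)
            self._check_annotation_levels()

    def _check_annotation_levels(self) -> None:
        ann = self.annotations
        if self.group == "nematode" and "trophic_group" in ann.columns:
            bad = set(ann["trophic_group"].dropna()) - NEMATODE_TROPHIC_GROUPS
            if bad:
                raise ValidationError(f"unknown nematode trophic groups: {bad}")
        if self.group == "nematode" and "cp_class" in ann.columns:
            cp = ann["cp_class"].dropna()
            if not cp.isin([1, 2, 3, 4, 5]).all():
                raise ValidationError("nematode cp_class must be in 1..5")
        if self.group == "protozoa" and "feeding_habit" in ann.columns:
            bad = set(ann["feeding_habit"].dropna()) - PROTOZOA_FEEDING_HABITS
            if bad:
                raise ValidationError(f"unknown protozoa feeding habits: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def _read_table(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    logger.info("loaded %s: %d rows x %d columns", path, df.shape[0], df.shape[1])
    return df


def read_activity_table(path, class_map: dict[str, str] | None = None,
                        sep: str = "\t") -> ActivityTable:
    """Read a sample x enzyme activity TSV/CSV.

    Canonical enzymes (AG, BG, CB, XS, NAG, LAP, PHOX, PEOX) are classed
    automatically; any other enzyme must appear in ``class_map``.
    """
    return ActivityTable(_read_table(path, sep), dict(class_map or {}))


def read_community_table(path, group: str, annotations_path=None,
                         sep: str = "\t") -> CommunityTable:
    """Read a sample x taxon count table plus optional annotation sidecar.

    The sidecar is keyed by taxon in its first column; taxa listed there
    but absent from the counts are dropped with a warning.
    """
    counts = _read_table(path, sep)
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep=sep, index_col=0)
        ann.index = ann.index.astype(str)
    return CommunityTable(group=group, counts=counts, annotations=ann)


def read_metadata(path, sep: str = "\t") -> pd.DataFrame:
    """Read sample metadata (treatment, season, plot) keyed by sample_id."""
    md = _read_table(path, sep)
    for col in REQUIRED_METADATA_COLUMNS:
        if col not in md.columns:
            raise ValidationError(f"metadata missing required column {col!r}")
    if md.index.has_duplicates:
        dup = md.index[md.index.duplicated()][0]
        raise ValidationError(f"duplicate sample_id {dup!r} in metadata")
    combo = md[list(REQUIRED_METADATA_COLUMNS)]
    if combo.duplicated().any():
        raise ValidationError(
            "duplicate (treatment, season, plot) combination in metadata"
        )
    return md


def read_substrate_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read the substrate chemistry / gene-copy table keyed by sample_id."""
    sub = _read_table(path, sep)
    num = sub.select_dtypes(include=[np.number])
    if (num.to_numpy(dtype=float) <= 0).any():
        raise ValidationError("substrate table values must be > 0 where present")
    return sub


def read_index_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a per-sample index table written by :func:`write_index_table`."""
    return _read_table(path, sep)


def write_index_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a per-sample index table; full float precision round-trips.

    Missing values are written as empty fields.
    """
    if table.shape[1] == 0:
        raise ValidationError("index table has no index columns")
    # %.17g round-trips any float64 bit-identically
    table.to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")
    logger.info("wrote %s: %d rows x %d columns", path, *table.shape)


def align_samples(*tables: pd.DataFrame) -> list[pd.DataFrame]:
    """Restrict tables to their shared sample_ids, in the first table's order."""
    shared = tables[0].index
    for t in tables[1:]:
        shared = shared.intersection(t.index)
    if len(shared) == 0:
        raise ValidationError("tables share no sample_ids")
    order = [s for s in tables[0].index if s in set(shared)]
    return [t.loc[order] for t in tables]
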