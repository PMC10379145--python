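"""Core domain types, delimited-text IO, and packaged reference tables.

The toolkit operates on small urinary extracellular-vesicle (uEV) RNA-seq
datasets: a raw count matrix (features x samples), per-sample annotations
(dataset membership, storage temperature, isolation workflow, disease group),
feature panels (e.g. kidney-enriched genes, top kidney miRNAs), and a handful
of curated literature tables that ship with the package as tab-separated
fixtures:

``table2``
    miRNAs dysregulated in uEV from urine stored at -20 degC vs -80 degC,
    with raw-count and log2CPM group means +/- SEM.
``table3``
    Literature miRNAs linked to diabetic kidney disease (DKD) with evidence
    from kidney tissue or cell-line models.
``table4``
    Literature miRNAs linked to DKD with evidence from urine, urinary
    sediments or uEV.
``table5``
    Heatmap cluster-1/cluster-4 miRNAs with the direction of change observed
    in the ultracentrifugation (UC) dataset and in the literature.
``table6``
    Coefficient of variation of the candidate reference genes (plus GAPDH and
    the high-CV comparator UPK1A) across six datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "UevrnaError",
    "IdentifierError",
    "FormatError",
    "ParameterError",
    "DataError",
    "GroupingError",
    "NormalizationError",
    "DegenerateSampleError",
    "ConfigurationError",
    "MirnaParseError",
    "CountMatrix",
    "SampleAnnotation",
    "FeaturePanel",
    "DysregulatedMirnaRecord",
    "LiteratureMirnaRecord",
    "ConcordanceRecord",
    "CvFixtureTable",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_annotations",
    "read_feature_panel",
    "load_fixture",
    "FIXTURE_NAMES",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class UevrnaError(Exception):
    """Base class for all errors raised by this package."""


class IdentifierError(UevrnaError):
    """Duplicate or otherwise invalid feature/sample identifiers."""


class FormatError(UevrnaError):
    """Malformed input file (non-numeric, negative or fractional counts)."""


class ParameterError(UevrnaError, ValueError):
    """An argument is outside its documented domain."""


class DataError(UevrnaError):
    """Input data violate the contract of an operation (NaN, length mismatch)."""


class GroupingError(UevrnaError):
    """Sample groups overlap, are empty, or reference unknown samples."""


class NormalizationError(UevrnaError):
    """Scaling-factor computation failed (e.g. no shared positive features)."""


class DegenerateSampleError(NormalizationError):
    """A sample has zero total counts and no externally supplied library size."""


class ConfigurationError(UevrnaError):
    """Invalid run/scenario configuration."""


class MirnaParseError(UevrnaError):
    """A miRNA identifier string could not be parsed."""

    def __init__(self, raw: str, message: str = "") -> None:
        self.raw = raw
        super().__init__(f"cannot parse miRNA identifier {raw!r}" + (f": {message}" if message else ""))


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

class CountMatrix:
    """Raw integer counts, features as rows and samples as columns.

    Wraps a :class:`pandas.DataFrame` and enforces the invariants every
    downstream operation relies on: unique feature and sample identifiers,
    non-negative integral counts, and at least one feature and one sample.
    """

    def __init__(self, data: pd.DataFrame) -> None:
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise DataError("count matrix needs at least 1 feature and 1 sample")
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate feature identifiers: {dup}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()].unique().tolist()
            raise IdentifierError(f"duplicate sample identifiers: {dup}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("count matrix contains non-numeric cells")
        if np.isnan(values.astype(float)).any():
            r, c = np.argwhere(np.isnan(values.astype(float)))[0]
            raise FormatError(f"missing value at feature {data.index[r]!r}, sample {data.columns[c]!r}")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count {values[r, c]} at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        if not np.allclose(values, np.round(values)):
            frac = np.abs(values - np.round(values)) > 0
            r, c = np.argwhere(frac)[0]
            raise FormatError(
                f"non-integer count {values[r, c]} at feature {data.index[r]!r}, sample {data.columns[c]!r}"
            )
        self.data = data.astype(np.int64)

    # -- accessors ----------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def library_sizes(self) -> pd.Series:
        """Total counts per sample."""
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.data.loc[:, list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"CountMatrix({self.n_features} features x {self.n_samples} samples)"


# ---------------------------------------------------------------------------
# Annotations and panels
# ---------------------------------------------------------------------------

STORAGE_TEMPS = ("minus80", "minus20", "unknown")
WORKFLOWS = ("UC", "HFD", "NG", "unknown")
COLLECTIONS = ("ON", "h24", "unknown")
DISEASE_GROUPS = ("healthy", "normo", "micro", "macro", "PCa", "unknown")
SEXES = ("male", "female", "unknown")

ANNOTATION_COLUMNS = (
    "sample_id",
    "dataset_id",
    "storage_temp",
    "workflow",
    "collection",
    "precleared",
    "disease_group",
    "sex",
)


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one uEV sample. Missing fields default to "unknown"."""

    sample_id: str
    dataset_id: str
    storage_temp: str = "unknown"
    workflow: str = "unknown"
    collection: str = "unknown"
    precleared: str = "unknown"  # tri-state: "yes" / "no" / "unknown"
    disease_group: str = "unknown"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        checks = (
            ("storage_temp", STORAGE_TEMPS),
            ("workflow", WORKFLOWS),
            ("collection", COLLECTIONS),
            ("precleared", ("yes", "no", "unknown")),
            ("disease_group", DISEASE_GROUPS),
            ("sex", SEXES),
        )
        for name, allowed in checks:
            value = getattr(self, name)
            if value not in allowed:
                raise ParameterError(f"{name}={value!r} not one of {allowed}")


@dataclass(frozen=True)
class FeaturePanel:
    """A named list of feature identifiers (gene or miRNA panel)."""

    name: str
    source: str
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.feature_ids:
            raise ParameterError(f"panel {self.name!r} is empty")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise IdentifierError(f"panel {self.name!r} has duplicate feature identifiers")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in set(self.feature_ids)


# ---------------------------------------------------------------------------
# Fixture record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DysregulatedMirnaRecord:
    """A miRNA dysregulated by -20 degC urine storage, with group summaries."""

    mirna_id: str
    direction: str  # down_at_minus20 | up_at_minus20
    raw_mean_minus80: float
    raw_sem_minus80: float
    raw_mean_minus20: float
    raw_sem_minus20: float
    log2cpm_mean_minus80: float
    log2cpm_sem_minus80: float
    log2cpm_mean_minus20: float
    log2cpm_sem_minus20: float
    kidney_disease_annotation: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("down_at_minus20", "up_at_minus20"):
            raise ParameterError(f"bad direction {self.direction!r}")
        for name in (
            "raw_mean_minus80", "raw_sem_minus80", "raw_mean_minus20", "raw_sem_minus20",
            "log2cpm_sem_minus80", "log2cpm_sem_minus20",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LiteratureMirnaRecord:
    """One literature report of a DKD-linked miRNA (verbatim identifier)."""

    mirna_id_raw: str
    evidence_tier: str  # tissue_invitro | urine_sediment_uev
    direction: str  # up | down | mixed | unknown
    reference_tag: str

    def __post_init__(self) -> None:
        if not self.mirna_id_raw:
            raise ParameterError("empty miRNA identifier")
        if self.evidence_tier not in ("tissue_invitro", "urine_sediment_uev"):
            raise ParameterError(f"bad evidence tier {self.evidence_tier!r}")
        if self.direction not in ("up", "down", "mixed", "unknown"):
            raise ParameterError(f"bad direction {self.direction!r}")


@dataclass(frozen=True)
class ConcordanceRecord:
    """Direction of change for a cluster-1/cluster-4 miRNA, study vs literature."""

    mirna_id: str
    cluster: str  # c1 | c4
    direction_study: str  # up | down
    direction_literature: str  # up | down

    def __post_init__(self) -> None:
        if self.cluster not in ("c1", "c4"):
            raise ParameterError(f"bad cluster {self.cluster!r}")
        for name in ("direction_study", "direction_literature"):
            if getattr(self, name) not in ("up", "down"):
                raise DataError(f"{name} must be 'up' or 'down', got {getattr(self, name)!r}")


@dataclass(frozen=True)
class CvFixtureTable:
    """Gene x dataset CV matrix with per-gene roles.

    Roles: ``candidate`` (the 11 stable-gene candidates), ``common_reference``
    (GAPDH) and ``high_cv_comparison`` (UPK1A).
    """

    cv: pd.DataFrame  # genes x datasets
    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.cv.isna().any().any():
            raise DataError("CV fixture has missing cells")
        if (self.cv.to_numpy() < 0).any():
            raise DataError("CV values must be >= 0")
        bad = set(self.roles.values()) - {"candidate", "common_reference", "high_cv_comparison"}
        if bad:
            raise ParameterError(f"unknown roles {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cv.index)

    @property
    def dataset_ids(self) -> list[str]:
        return list(self.cv.columns)

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g in self.gene_ids if self.roles[g] == role]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_count_matrix(path: str | Path, orientation: str = "features_in_rows") -> CountMatrix:
    """Read a delimited count matrix (TSV by default, CSV by extension).

    The header row holds sample identifiers and the first column feature
    identifiers; ``orientation="samples_in_rows"`` reads the transpose.
    Duplicate identifiers raise :class:`IdentifierError`; negative,
    fractional or non-numeric cells raise :class:`FormatError` with the
    offending coordinates.
    """
    path = Path(path)
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "samples_in_rows":
        frame = frame.T
    # Non-numeric columns surface as object dtype; locate the first bad cell
    # so the error points at a row/column the user can find.
    for col in frame.columns:
        if frame[col].dtype == object:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = coerced.isna() & frame[col].notna()
            if bad.any():
                row = frame.index[bad.to_numpy().nonzero()[0][0]]
                raise FormatError(
                    f"non-numeric cell {frame.loc[row, col]!r} at feature {row!r}, sample {col!r} in {path}"
                )
            frame[col] = coerced
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return CountMatrix(frame)


def write_count_matrix(matrix: CountMatrix, path: str | Path, orientation: str = "features_in_rows") -> None:
    """Write a count matrix as delimited text (lossless round-trip)."""
    path = Path(path)
    frame = matrix.data if orientation == "features_in_rows" else matrix.data.T
    frame.to_csv(path, sep=_sep_for(path))


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read a sample-annotation TSV; absent optional columns become "unknown"."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str).fillna("unknown")
    for required in ("sample_id", "dataset_id"):
        if required not in frame.columns:
            raise FormatError(f"annotation file {path} lacks required column {required!r}")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise IdentifierError(f"duplicate sample_id in annotations: {dup}")
    records = []
    for _, row in frame.iterrows():
        kwargs = {c: row[c] for c in ANNOTATION_COLUMNS if c in frame.columns}
        records.append(SampleAnnotation(**kwargs))
    return records


def read_feature_panel(path: str | Path, name: str | None = None) -> FeaturePanel:
    """Read a feature panel: one identifier per line, or a 2-column (id, panel) TSV."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    ids: list[str] = []
    for ln in lines:
        parts = ln.split("\t")
        ids.append(parts[0].strip())
    if ids and ids[0].lower() in ("id", "feature_id", "gene_id", "mirna_id"):
        ids = ids[1:]
    seen: set[str] = set()
    unique = [i for i in ids if not (i in seen or seen.add(i))]
    return FeaturePanel(name=name or path.stem, source=str(path), feature_ids=tuple(unique))


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table2", "table3", "table4", "table5", "table6")

_DIRECTION_BY_TABLE2 = {"down": "down_at_minus20", "up": "up_at_minus20"}


def _fixture_text(filename: str) -> str:
    text = resources.files("uevrna.fixtures").joinpath(filename).read_text(encoding="utf-8")
    # The source tables print the Unicode minus (U+2212); normalize so numeric
    # fields always parse.
    return text.replace("−", "-")


def _fixture_frame(filename: str) -> pd.DataFrame:
    from io import StringIO

    return pd.read_csv(StringIO(_fixture_text(filename)), sep="\t", dtype=str).fillna("")


def load_fixture(name: str):
    """Load a packaged in-paper table as typed records.

    Returns a list of records for ``table2``/``table3``/``table4``/``table5``
    and a :class:`CvFixtureTable` for ``table6``. Unknown names raise
    :class:`KeyError`.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    if name == "table2":
        frame = _fixture_frame("table2.tsv")
        return [
            DysregulatedMirnaRecord(
                mirna_id=row["mirna_id"],
                direction=_DIRECTION_BY_TABLE2[row["direction"]],
                raw_mean_minus80=float(row["raw_mean_minus80"]),
                raw_sem_minus80=float(row["raw_sem_minus80"]),
                raw_mean_minus20=float(row["raw_mean_minus20"]),
                raw_sem_minus20=float(row["raw_sem_minus20"]),
                log2cpm_mean_minus80=float(row["log2cpm_mean_minus80"]),
                log2cpm_sem_minus80=float(row["log2cpm_sem_minus80"]),
                log2cpm_mean_minus20=float(row["log2cpm_mean_minus20"]),
                log2cpm_sem_minus20=float(row["log2cpm_sem_minus20"]),
                kidney_disease_annotation=row["kidney_disease_annotation"],
            )
            for _, row in frame.iterrows()
        ]
    if name in ("table3", "table4"):
        tier = "tissue_invitro" if name == "table3" else "urine_sediment_uev"
        frame = _fixture_frame(f"{name}.tsv")
        return [
            LiteratureMirnaRecord(
                mirna_id_raw=row["mirna_id"],
                evidence_tier=tier,
                direction=row["direction"],
                reference_tag=row["reference"],
            )
            for _, row in frame.iterrows()
        ]
    if name == "table5":
        frame = _fixture_frame("table5.tsv")
        return [
            ConcordanceRecord(
                mirna_id=row["mirna_id"],
                cluster=row["cluster"],
                direction_study=row["direction_study"],
                direction_literature=row["direction_literature"],
            )
            for _, row in frame.iterrows()
        ]
    # table6
    frame = _fixture_frame("table6.tsv")
    roles = dict(zip(frame["gene_id"], frame["role"]))
    cv = frame.drop(columns=["role"]).set_index("gene_id").astype(float)
    return CvFixtureTable(cv=cv, roles=roles)
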