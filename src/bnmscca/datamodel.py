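"""Core data containers and delimited-text IO.

The package works on subject x feature tables (one per imaging modality),
a binary diagnosis vector, a partition of the features into brain networks,
and an optional covariate table.  All on-disk formats are plain CSV/TSV so
that fixtures and results stay human-readable.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "FeatureMatrix",
    "DiagnosisVector",
    "GroupStructure",
    "CovariateTable",
    "load_feature_matrix",
    "save_feature_matrix",
    "load_diagnosis",
    "load_group_structure",
    "load_covariates",
    "default_aal_groups",
    "aal116_labels",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


@dataclass
class FeatureMatrix:
    """A subjects x features table for one imaging modality.

    ``values`` is an (n, d) float array; rows follow ``subject_ids`` and
    columns follow ``feature_labels`` (e.g. AAL region names such as
    ``"PUT.L"``).  ``modality`` is a free tag like ``"dfalff"`` or ``"gm"``.
    """

    values: np.ndarray
    subject_ids: list[str]
    feature_labels: list[str]
    modality: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.feature_labels = [str(f) for f in self.feature_labels]
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, d = self.values.shape
        if n != len(self.subject_ids):
            raise ValidationError(
                f"{n} rows but {len(self.subject_ids)} subject ids"
            )
        if d != len(self.feature_labels):
            raise ValidationError(
                f"{d} columns but {len(self.feature_labels)} feature labels"
            )
        if len(set(self.feature_labels)) != d:
            raise ValidationError("feature labels must be unique")
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicate subject ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.feature_labels
        )


@dataclass
class DiagnosisVector:
    """Binary diagnosis coded 0/1 (e.g. HC -> 0, SCZ -> 1)."""

    values: np.ndarray
    coding: dict[str, int] = field(default_factory=lambda: {"0": 0, "1": 1})

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        uniq = set(np.unique(self.values).tolist())
        if not uniq <= {0.0, 1.0}:
            raise ValidationError(f"diagnosis values must be 0/1, got {sorted(uniq)}")
        if len(set(self.coding.values())) != len(self.coding):
            raise ValidationError("coding must be one-to-one")

    @classmethod
    def from_labels(cls, labels, positive=None) -> "DiagnosisVector":
        labels = [str(x) for x in labels]
        uniq = sorted(set(labels))
        if len(uniq) != 2:
            raise ValidationError(
                f"diagnosis must have exactly two distinct labels, got {uniq}"
            )
        if positive is None:
            positive = uniq[1]
        elif str(positive) not in uniq:
            raise ValidationError(f"positive label {positive!r} not in {uniq}")
        coding = {lab: int(lab == str(positive)) for lab in uniq}
        return cls(np.array([coding[x] for x in labels], float), coding)

    @property
    def column(self) -> np.ndarray:
        """The values as an (n, 1) matrix, the shape solvers expect."""
        return self.values.reshape(-1, 1)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class GroupStructure:
    """Partition of feature labels into K brain networks.

    ``assignment`` maps every feature label to a network label; the derived
    ``index_blocks`` give, per network (ordered by first appearance), the
    column indices it occupies in a feature matrix ordered like
    ``feature_labels``.
    """

    assignment: dict[str, str]
    feature_labels: list[str]

    def __post_init__(self) -> None:
        missing = [f for f in self.feature_labels if f not in self.assignment]
        if missing:
            raise ValidationError(f"features without a network: {missing}")
        extra = [f for f in self.assignment if f not in set(self.feature_labels)]
        if extra:
            raise ValidationError(f"mapped labels absent from data: {extra}")
        self.network_labels: list[str] = []
        seen: set[str] = set()
        for f in self.feature_labels:
            g = self.assignment[f]
            if g not in seen:
                seen.add(g)
                self.network_labels.append(g)
        lookup = {g: k for k, g in enumerate(self.network_labels)}
        self.indices = np.array(
            [lookup[self.assignment[f]] for f in self.feature_labels], dtype=int
        )
        self.index_blocks = [
            np.flatnonzero(self.indices == k) for k in range(len(self.network_labels))
        ]
        if any(b.size == 0 for b in self.index_blocks):
            raise ValidationError("every network block must be non-empty")

    @property
    def K(self) -> int:
        return len(self.network_labels)

    @classmethod
    def from_labels(cls, network_per_feature, feature_labels=None) -> "GroupStructure":
        """Build from a per-feature sequence of network labels."""
        nets = [str(g) for g in network_per_feature]
        if feature_labels is None:
            feature_labels = [f"f{i}" for i in range(len(nets))]
        feature_labels = [str(f) for f in feature_labels]
        if len(feature_labels) != len(nets):
            raise ValidationError("label/network length mismatch")
        return cls(dict(zip(feature_labels, nets)), feature_labels)

    def network_of(self, label: str) -> str:
        return self.assignment[str(label)]


@dataclass
class CovariateTable:
    """Per-subject covariates (age in years, gender coded 0/1)."""

    table: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.table) != len(self.subject_ids):
            raise ValidationError("covariate rows do not match subject ids")
        if "gender" in self.table.columns:
            g = set(pd.unique(self.table["gender"]))
            if not g <= {0, 1, 0.0, 1.0}:
                raise ValidationError(f"gender must be binary 0/1, got {sorted(g)}")

    @property
    def design(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)


# ---------------------------------------------------------------------------
# readers / writers


def load_feature_matrix(path, modality: str = "generic", impute: bool = False) -> FeatureMatrix:
    """Read a delimited feature table (header = feature labels, first column
    = subject id).

    With ``impute=False`` any missing/non-numeric cell is a hard error naming
    the offending row and column; with ``impute=True`` missing cells are
    replaced by their column mean.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected subject-id column plus features")
    if df.columns[0].startswith("Unnamed") and df.shape[0] and df.iloc[0, 0] is None:
        raise FormatError(f"{path}: missing header row")
    subject_ids = df.iloc[:, 0].astype(str).tolist()
    if len(set(subject_ids)) != len(subject_ids):
        dupes = sorted({s for s in subject_ids if subject_ids.count(s) > 1})
        raise ValidationError(f"{path}: duplicate subject id(s) {dupes}")
    body = df.iloc[:, 1:]
    values = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size and not impute:
        r, c = bad[0]
        raise FormatError(
            f"{path}: non-numeric or missing cell at row {subject_ids[r]!r}, "
            f"column {body.columns[c]!r}"
        )
    if bad.size:
        col_means = np.nanmean(values, axis=0)
        values = np.where(np.isfinite(values), values, col_means[None, :])
    return FeatureMatrix(values, subject_ids, list(body.columns), modality)


def save_feature_matrix(fm: FeatureMatrix, path) -> None:
    df = fm.to_frame()
    df.index.name = "subject_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def load_diagnosis(path, positive=None) -> tuple[DiagnosisVector, list[str]]:
    """Read a two-column (subject_id, diagnosis) table; returns the coded
    vector plus the subject ids, for alignment checks by the caller."""
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected subject_id and diagnosis columns")
    return DiagnosisVector.from_labels(df.iloc[:, 1], positive), df.iloc[:, 0].tolist()


def load_group_structure(path, feature_labels, strict: bool = True) -> GroupStructure:
    """Read a two-column (feature_label, network_label) mapping.

    Labels mapped in the file but absent from ``feature_labels`` raise with
    ``strict=True`` and warn otherwise; features without a mapping always
    raise, listing the missing labels.
    """
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (feature, network)")
    assignment = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    feature_labels = [str(f) for f in feature_labels]
    extra = [f for f in assignment if f not in set(feature_labels)]
    if extra:
        if strict:
            raise ValidationError(f"{path}: mapped labels absent from data: {extra}")
        warnings.warn(f"ignoring {len(extra)} mapped labels absent from data")
        assignment = {k: v for k, v in assignment.items() if k not in set(extra)}
    missing = [f for f in feature_labels if f not in assignment]
    if missing:
        raise ValidationError(f"{path}: features without a network: {missing}")
    return GroupStructure(assignment, feature_labels)


def load_covariates(path) -> CovariateTable:
    """Read covariates CSV (subject_id, age, gender, ...); a two-level string
    gender column is auto-encoded to 0/1 by sorted label order."""
    df = pd.read_csv(path, sep=_sep_for(path), header=0)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected subject_id plus covariates")
    subject_ids = df.iloc[:, 0].astype(str).tolist()
    body = df.iloc[:, 1:].copy()
    if "gender" in body.columns and body["gender"].dtype == object:
        levels = sorted(body["gender"].astype(str).unique())
        if len(levels) != 2:
            raise ValidationError(f"gender must have two levels, got {levels}")
        body["gender"] = body["gender"].astype(str).map({levels[0]: 0, levels[1]: 1})
    return CovariateTable(body.astype(float), subject_ids)


# ---------------------------------------------------------------------------
# shipped default AAL-116 -> 15-network mapping

_DEFAULT_MAP = "aal116_networks.csv"


def _default_map_frame() -> pd.DataFrame:
    ref = importlib.resources.files("bnmscca.data").joinpath(_DEFAULT_MAP)
    with ref.open("r") as fh:
        return pd.read_csv(fh, dtype=str)


def aal116_labels() -> list[str]:
    """The 116 AAL region labels, in atlas order, as used by the default map."""
    return _default_map_frame()["roi"].tolist()


def default_aal_groups(feature_labels=None) -> GroupStructure:
    """The shipped 116-region -> 15-network partition.

    The partition follows the common practice of grouping AAL regions into
    seven functional systems per hemisphere (subcortical SN, auditory AUN,
    attention ATN, default-mode DMN, visual VIN, sensorimotor SMN) plus one
    cerebellar network per hemisphere (CN) and the vermis (VN) as its own
    network: 15 networks in total.  It is a best-effort reconstruction of a
    published grouping that is not printed anywhere in full; any user mapping
    loaded with :func:`load_group_structure` overrides it.
    """
    df = _default_map_frame()
    assignment = dict(zip(df["roi"], df["network"]))
    if feature_labels is None:
        feature_labels = df["roi"].tolist()
    return GroupStructure(assignment, [str(f) for f in feature_labels])
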