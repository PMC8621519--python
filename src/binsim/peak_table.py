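"""Peak-table data model, I/O, ppm alignment and reproducibility filters.

Direct-infusion high-resolution MS produces one peak list (m/z, intensity)
per sample.  Aligning the lists across samples yields a samples x features
intensity matrix -- the *peak table* -- in which a feature missing from a
sample is an explicit gap (NaN), not a zero.  Everything downstream
(pre-treatment, clustering, classification) consumes this object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakList",
    "PeakTable",
    "DatasetSummary",
    "TableDialect",
    "read_peak_table",
    "write_peak_table",
    "read_labels",
    "align_peak_lists",
    "filter_occurrence",
    "summarize",
]


@dataclass(frozen=True)
class PeakList:
    """One sample's centroided peaks: ascending m/z with positive intensities."""

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if mz.ndim != 1 or inten.shape != mz.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError(f"m/z values of sample {self.sample_id!r} must be strictly increasing")
        if np.any(inten <= 0) or np.any(~np.isfinite(inten)):
            raise ValueError(f"intensities of sample {self.sample_id!r} must be strictly positive")

    def __len__(self) -> int:
        return int(self.mz.size)


class PeakTable:
    """Samples x features intensity matrix with explicit missing entries.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are feature m/z values (floats).  Missing
        entries are NaN; all observed entries must be strictly positive.
    labels : mapping or pandas.Series, optional
        Class/replicate-group label per sample id.

    Features with zero occurrences are dropped at construction: they carry
    no information under any pre-treatment.
    """

    def __init__(self, data: pd.DataFrame, labels=None) -> None:
        if data.shape[0] == 0 or data.shape[1] == 0:
            raise ValueError("peak table must have at least one sample and one feature")
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        data = data.astype(float)
        cols = np.asarray(data.columns, dtype=float)
        order = np.argsort(cols, kind="stable")
        data = data.iloc[:, order]
        data.columns = cols[order]
        if np.any(np.diff(data.columns.to_numpy()) <= 0):
            raise ValueError("feature m/z values must be strictly increasing (duplicates present)")
        vals = data.to_numpy()
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("all observed intensities must be strictly positive")
        empty = data.isna().all(axis=0)
        if empty.any():
            logger.warning("dropping %d feature(s) with zero occurrences", int(empty.sum()))
            data = data.loc[:, ~empty]
            if data.shape[1] == 0:
                raise ValueError("all features have zero occurrences")
        self.data = data
        if labels is not None:
            labels = pd.Series(labels)
            missing = [s for s in data.index if s not in labels.index]
            if missing:
                raise ValueError(f"labels missing for samples: {missing}")
            labels = labels.reindex(data.index)
        self.labels = labels

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_mz(self) -> np.ndarray:
        return self.data.columns.to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def occurrence_counts(self) -> np.ndarray:
        """Number of non-missing entries per feature."""
        return self.data.notna().sum(axis=0).to_numpy()

    def missing_fraction(self) -> float:
        return float(self.data.isna().to_numpy().mean())

    def with_labels(self, labels) -> "PeakTable":
        return PeakTable(self.data.copy(), labels=labels)

    def copy_with(self, values: np.ndarray) -> "PeakTable":
        """New table with the same axes/labels and replaced values."""
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return PeakTable(df, labels=self.labels)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PeakTable({self.n_samples} samples x {self.n_features} features, "
            f"{100 * self.missing_fraction():.1f}% missing)"
        )


@dataclass(frozen=True)
class DatasetSummary:
    """Table-level characteristics: sizes, per-sample feature counts, missingness."""

    n_samples: int
    n_features: int
    features_per_sample_mean: float
    features_per_sample_min: int
    features_per_sample_max: int
    n_classes: int
    samples_per_class: dict
    missing_pct: float


@dataclass(frozen=True)
class TableDialect:
    """How a peak table is laid out on disk.

    ``orientation`` is ``"features_rows"`` (first column m/z, header row of
    sample ids -- the native layout) or ``"samples_rows"``.  Cells equal to a
    token in ``missing_tokens``, empty cells, and (by default) values <= 0
    are read as missing.
    """

    delimiter: str = "\t"
    orientation: str = "features_rows"
    missing_tokens: tuple = ("", "NA", "NaN", "nan")
    nonpositive_is_missing: bool = True


def read_peak_table(path, dialect: TableDialect = TableDialect(), labels=None) -> PeakTable:
    """Read a delimited peak table from disk into a validated :class:`PeakTable`."""
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        index_col=0,
        na_values=list(dialect.missing_tokens),
        keep_default_na=True,
    )
    if dialect.orientation == "features_rows":
        df = df.T
        df.columns = _parse_mz(df.columns, path)
    elif dialect.orientation == "samples_rows":
        df.columns = _parse_mz(df.columns, path)
    else:
        raise ValueError(f"unknown orientation {dialect.orientation!r}")
    bad = df.map(lambda v: isinstance(v, str))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"malformed numeric cell at sample {df.index[r]!r}, feature {df.columns[c]!r} in {path}"
        )
    df = df.astype(float)
    if dialect.nonpositive_is_missing:
        df = df.mask(df <= 0)
    return PeakTable(df, labels=labels)


def write_peak_table(pt: PeakTable, path, dialect: TableDialect = TableDialect()) -> None:
    """Write a peak table; missing entries become empty cells."""
    df = pt.data
    if dialect.orientation == "features_rows":
        out = df.T
        out.index.name = "mz"
    else:
        out = df.copy()
        out.index.name = "sample_id"
    out.to_csv(path, sep=dialect.delimiter, na_rep="")


def read_labels(path, delimiter: str = "\t") -> pd.Series:
    """Read a metadata table with columns ``sample_id`` and ``class``."""
    meta = pd.read_csv(path, sep=delimiter)
    if not {"sample_id", "class"}.issubset(meta.columns):
        raise ValueError("metadata file must have columns 'sample_id' and 'class'")
    return meta.set_index("sample_id")["class"]


def _parse_mz(index, path) -> np.ndarray:
    try:
        return np.asarray([float(v) for v in index])
    except ValueError as exc:
        raise ValueError(f"non-numeric m/z value in {path}: {exc}") from None


def align_peak_lists(lists, ppm_tol: float = 1.0, labels=None) -> PeakTable:
    """Merge per-sample peak lists into a peak table at a ppm m/z tolerance.

    All peaks are pooled and sorted by m/z; a greedy scan opens a new feature
    group whenever the next peak lies more than ``ppm_tol`` ppm from the
    running group centroid (mean m/z of members).  Each feature takes the
    mean m/z of its members.  Two peaks of the same sample falling into one
    group collide: the more intense one is kept and a warning logged.
    Sorting first makes the result independent of input sample order.
    """
    if len(lists) < 2:
        raise ValueError("alignment requires at least two peak lists")
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    ids = [pl.sample_id for pl in lists]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids among peak lists")

    mz = np.concatenate([pl.mz for pl in lists])
    inten = np.concatenate([pl.intensity for pl in lists])
    samp = np.concatenate([np.full(len(pl), i) for i, pl in enumerate(lists)])
    order = np.argsort(mz, kind="stable")
    mz, inten, samp = mz[order], inten[order], samp[order]

    groups: list[dict] = []
    cur: dict | None = None
    centroid = 0.0
    for m, x, s in zip(mz, inten, samp):
        if cur is not None and abs(m - centroid) <= centroid * ppm_tol * 1e-6:
            if s in cur:
                logger.warning(
                    "sample %s: peak collision near m/z %.6f; keeping the more intense peak",
                    ids[s], centroid,
                )
                if x > cur[s][1]:
                    cur[s] = (m, x)
            else:
                cur[s] = (m, x)
            centroid = float(np.mean([v[0] for v in cur.values()]))
        else:
            cur = {s: (m, x)}
            centroid = m
            groups.append(cur)

    feat_mz = np.array([np.mean([v[0] for v in g.values()]) for g in groups])
    values = np.full((len(lists), len(groups)), np.nan)
    for j, g in enumerate(groups):
        for s, (_, x) in g.items():
            values[s, j] = x
    df = pd.DataFrame(values, index=ids, columns=feat_mz)
    return PeakTable(df, labels=labels)


def filter_occurrence(pt: PeakTable, k: int, mode: str = "global", labels=None) -> PeakTable:
    """Reproducibility filter: keep features observed at least ``k`` times.

    ``mode="global"`` counts over all samples; ``mode="per_class"`` keeps a
    feature if it reaches ``k`` observations within at least one class.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    observed = pt.data.notna()
    if mode == "global":
        if k > pt.n_samples:
            raise ValueError(f"k={k} exceeds the number of samples ({pt.n_samples})")
        keep = observed.sum(axis=0) >= k
    elif mode == "per_class":
        lab = labels if labels is not None else pt.labels
        if lab is None:
            raise ValueError("per_class filtering requires sample labels")
        lab = pd.Series(lab).reindex(pt.data.index)
        if lab.isna().any():
            raise ValueError("labels missing for some samples")
        per_class = observed.groupby(lab, observed=True).sum()
        if k > int(lab.value_counts().max()):
            raise ValueError(f"k={k} exceeds the largest class size")
        keep = (per_class >= k).any(axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep.any():
        raise ValueError("occurrence filter removed every feature")
    return PeakTable(pt.data.loc[:, keep].copy(), labels=pt.labels)


def summarize(pt: PeakTable) -> DatasetSummary:
    """General characteristics of a peak table (sizes, missingness, classes)."""
    per_sample = pt.data.notna().sum(axis=1)
    if pt.labels is not None:
        counts = pt.labels.value_counts().to_dict()
    else:
        counts = {}
    total = pt.n_samples * pt.n_features
    n_missing = int(pt.data.isna().to_numpy().sum())
    return DatasetSummary(
        n_samples=pt.n_samples,
        n_features=pt.n_features,
        features_per_sample_mean=float(per_sample.mean()),
        features_per_sample_min=int(per_sample.min()),
        features_per_sample_max=int(per_sample.max()),
        n_classes=len(counts),
        samples_per_class=counts,
        missing_pct=100.0 * n_missing / total,
    )
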