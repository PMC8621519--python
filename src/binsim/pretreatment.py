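"""The seven pre-treatment pipelines for MS peak tables.

Intensity-based pipelines combine a missing-value imputation (half-minimum
or random-forest), an optional normalization (reference feature or PQN), an
optional generalized-log transform, and Pareto scaling, in that fixed order:

    P   = imputation + Pareto
    NP  = imputation + normalization + Pareto
    NGP = imputation + normalization + glog + Pareto

Binary Simplification (BinSim) replaces all of that with a single step:
encode feature presence as 1 and absence (a missing value) as 0.

Every step is a scikit-learn style transformer operating on a samples x
features ``pandas.DataFrame`` (NaN = missing; column labels are feature m/z
values) or a plain ndarray, so the pipelines compose with
``sklearn.pipeline.Pipeline``.  Module-level functions wrap the estimators
for use with :class:`~binsim.peak_table.PeakTable`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor

from .peak_table import PeakTable

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMatrix",
    "PretreatmentSpec",
    "BinSim",
    "HalfMinImputer",
    "RandomForestImputer",
    "ReferenceFeatureNormalizer",
    "PQNNormalizer",
    "GLogTransformer",
    "ParetoScaler",
    "binsim",
    "impute_half_min",
    "impute_rf",
    "normalize_reference",
    "normalize_pqn",
    "glog",
    "pareto",
    "apply_pipeline",
]


class BinaryMatrix:
    """{0,1} occurrence matrix with the same axes as a :class:`PeakTable`."""

    def __init__(self, data: pd.DataFrame, labels=None) -> None:
        vals = data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        if (vals.sum(axis=0) == 0).any():
            raise ValueError("every feature must occur in at least one sample")
        self.data = data.astype(int)
        self.labels = labels

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

    def __repr__(self) -> str:  # pragma: no cover
        return f"BinaryMatrix({self.n_samples} samples x {self.n_features} features)"


def _as_frame(X):
    """Return (DataFrame view of X, was_frame flag)."""
    if isinstance(X, pd.DataFrame):
        return X, True
    return pd.DataFrame(np.asarray(X, dtype=float)), False


def _like(result: pd.DataFrame, was_frame: bool):
    return result if was_frame else result.to_numpy()


class BinSim(TransformerMixin, BaseEstimator):
    """Binary Simplification: presence -> 1, missing -> 0.

    Stateless; replaces imputation, normalization, transformation and
    scaling in one step.
    """

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        df, was_frame = _as_frame(X)
        return _like(df.notna().astype(float), was_frame)


class HalfMinImputer(TransformerMixin, BaseEstimator):
    """Replace missing entries by half the global minimum observed intensity.

    A limit-of-detection style imputation: gaps are assumed to be values
    below the instrument's detection threshold.
    """

    def fit(self, X, y=None):
        df, _ = _as_frame(X)
        vals = df.to_numpy()
        if np.all(np.isnan(vals)):
            raise ValueError("cannot impute an all-missing matrix")
        self.fill_value_ = float(np.nanmin(vals)) / 2.0
        return self

    def transform(self, X):
        df, was_frame = _as_frame(X)
        return _like(df.fillna(self.fill_value_), was_frame)


class RandomForestImputer(TransformerMixin, BaseEstimator):
    """Iterative random-forest missing-value imputation (missForest style).

    Each feature with gaps is regressed, over the samples where it is
    observed, on its ``n_similar`` most |correlation|-similar features of the
    provisionally filled matrix; the fitted forest predicts the gaps.
    Features are visited in order of increasing missingness and sweeps repeat
    until the sum of squared changes in the imputed entries increases (the
    previous sweep's values are then kept) or ``max_sweeps`` is reached.
    Features observed in fewer than two samples fall back to half-minimum
    imputation.

    Parameters
    ----------
    n_trees : int
        Trees per regression forest.
    n_similar : int
        Number of most-correlated predictor features.
    max_sweeps : int
        Hard cap on full passes over the incomplete features.
    random_state : int
        Seed; output is bit-reproducible for a fixed seed.
    """

    def __init__(self, n_trees: int = 50, n_similar: int = 100, max_sweeps: int = 10,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.n_similar = n_similar
        self.max_sweeps = max_sweeps
        self.random_state = random_state

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        df, was_frame = _as_frame(X)
        vals = df.to_numpy(copy=True)
        n, p = vals.shape
        if p < 2:
            raise ValueError("random-forest imputation requires at least two features")
        if self.n_similar < 1:
            raise ValueError("n_similar must be >= 1")
        miss = np.isnan(vals)
        if not miss.any():
            return _like(df.copy(), was_frame)
        if np.all(miss):
            raise ValueError("cannot impute an all-missing matrix")

        half_min = np.nanmin(vals) / 2.0
        filled = np.where(miss, half_min, vals)

        n_obs = (~miss).sum(axis=0)
        sparse = np.flatnonzero((n_obs < 2) & miss.any(axis=0))
        if sparse.size:
            logger.warning(
                "%d feature(s) observed in < 2 samples: falling back to half-min imputation",
                sparse.size,
            )
        targets = [j for j in np.argsort(miss.sum(axis=0), kind="stable")
                   if miss[:, j].any() and n_obs[j] >= 2]

        rng = np.random.default_rng(self.random_state)
        prev_delta = np.inf
        snapshot = filled.copy()
        for _ in range(self.max_sweeps):
            corr = np.corrcoef(filled, rowvar=False)
            np.nan_to_num(corr, copy=False)
            delta = 0.0
            for j in targets:
                sim = np.abs(corr[j]).copy()
                sim[j] = -np.inf
                k = min(self.n_similar, p - 1)
                predictors = np.argpartition(sim, -k)[-k:]
                obs = ~miss[:, j]
                rf = RandomForestRegressor(
                    n_estimators=self.n_trees,
                    random_state=int(rng.integers(2**31)),
                )
                rf.fit(filled[obs][:, predictors], vals[obs, j])
                new = rf.predict(filled[miss[:, j]][:, predictors])
                delta += float(np.sum((new - filled[miss[:, j], j]) ** 2))
                filled[miss[:, j], j] = new
            if delta > prev_delta:
                filled = snapshot  # diverging: keep the previous sweep
                break
            snapshot = filled.copy()
            prev_delta = delta
        out = pd.DataFrame(filled, index=df.index, columns=df.columns)
        return _like(out, was_frame)


class ReferenceFeatureNormalizer(TransformerMixin, BaseEstimator):
    """Divide each sample by its intensity of a designated reference feature.

    The reference (e.g. the lock-mass standard leucine enkephalin,
    m/z 556.276575 in ESI+ or 554.262022 in ESI-) must be resolvable within
    ``ppm_tol`` of a feature m/z and observed in every sample.  Requires a
    DataFrame input whose columns are m/z values.
    """

    def __init__(self, reference_mz: float, ppm_tol: float = 1.0):
        self.reference_mz = reference_mz
        self.ppm_tol = ppm_tol

    def fit(self, X, y=None):
        df, was_frame = _as_frame(X)
        if not was_frame:
            raise ValueError("reference normalization needs a DataFrame with m/z columns")
        mz = df.columns.to_numpy(dtype=float)
        dev = np.abs(mz - self.reference_mz)
        j = int(np.argmin(dev))
        if dev[j] > self.reference_mz * self.ppm_tol * 1e-6:
            raise ValueError(
                f"no feature within {self.ppm_tol} ppm of m/z {self.reference_mz}; "
                f"nearest is {mz[j]:.6f} ({1e6 * dev[j] / self.reference_mz:.2f} ppm away)"
            )
        self.reference_index_ = j
        self.reference_feature_mz_ = float(mz[j])
        return self

    def transform(self, X):
        df, _ = _as_frame(X)
        ref = df.iloc[:, self.reference_index_]
        if ref.isna().any() or (ref <= 0).any():
            raise ValueError("reference feature must be observed and positive in every sample")
        return df.div(ref, axis=0)


class PQNNormalizer(TransformerMixin, BaseEstimator):
    """Probabilistic quotient normalization against the median spectrum.

    The reference spectrum is the feature-wise median over the fitted
    samples; each sample is divided by the median of its feature-wise
    quotients against that reference, cancelling per-sample dilution.
    Requires a fully observed matrix (run after imputation).
    """

    def fit(self, X, y=None):
        df, _ = _as_frame(X)
        if df.isna().to_numpy().any():
            raise ValueError("PQN requires a fully observed matrix; impute first")
        self.reference_ = df.median(axis=0)
        return self

    def transform(self, X):
        df, was_frame = _as_frame(X)
        quotients = df.div(self.reference_, axis=1)
        med = quotients.median(axis=1)
        if (med == 0).any() or med.isna().any():
            raise ValueError("a sample has zero/undefined median quotient")
        return _like(df.div(med, axis=0), was_frame)


class GLogTransformer(TransformerMixin, BaseEstimator):
    """Generalized logarithm x -> ln((x + sqrt(x^2 + lam)) / 2).

    Variance-stabilizing: behaves like ln(x) for x >> sqrt(lam) and flattens
    below it.  ``lam="auto"`` sets lam to the square of the matrix minimum at
    fit time, which after half-minimum imputation ties the transition region
    to the detection limit.  With lam = 0 the transform is exactly ln.
    """

    def __init__(self, lam="auto"):
        self.lam = lam

    def fit(self, X, y=None):
        df, _ = _as_frame(X)
        vals = df.to_numpy()
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("glog requires non-negative entries")
        if self.lam == "auto":
            self.lam_ = float(np.nanmin(vals)) ** 2
        else:
            if self.lam < 0:
                raise ValueError("lam must be >= 0")
            self.lam_ = float(self.lam)
        return self

    def transform(self, X):
        df, was_frame = _as_frame(X)
        vals = df.to_numpy()
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("glog requires non-negative entries")
        out = np.log((vals + np.sqrt(vals**2 + self.lam_)) / 2.0)
        return _like(pd.DataFrame(out, index=df.index, columns=df.columns), was_frame)


class ParetoScaler(TransformerMixin, BaseEstimator):
    """Mean-center each feature and divide by the square root of its sd.

    A compromise between no scaling and auto-scaling: large intensities are
    shrunk but relative magnitudes partly preserved.  The standard deviation
    uses the n-1 denominator; zero-variance features map to all-zeros.
    """

    def fit(self, X, y=None):
        df, _ = _as_frame(X)
        if df.shape[0] < 2:
            raise ValueError("Pareto scaling requires at least two samples")
        self.mean_ = df.mean(axis=0)
        self.scale_ = np.sqrt(df.std(axis=0, ddof=1))
        return self

    def transform(self, X):
        df, was_frame = _as_frame(X)
        centered = df.sub(self.mean_, axis=1)
        scale = self.scale_.replace(0.0, np.inf)  # constant columns -> 0
        return _like(centered.div(scale, axis=1), was_frame)


# --------------------------------------------------------------------------
# Pipeline specification and application
# --------------------------------------------------------------------------

@dataclass
class PretreatmentSpec:
    """One of the seven benchmark pre-treatment combinations.

    ``binsim=True`` excludes every other step.  ``normalization`` is one of
    ``"reference_feature"`` (requires ``reference_mz``), ``"pqn"``, ``"none"``.
    """

    imputation: str = "none"          # half_min | random_forest | none
    normalization: str = "none"       # reference_feature | pqn | none
    reference_mz: float | None = None
    transform: str = "none"           # glog | none
    glog_lambda: float | str = "auto"
    scaling: str = "none"             # pareto | auto | none
    binsim: bool = False

    _IMPUTATIONS = ("half_min", "random_forest", "none")
    _NORMALIZATIONS = ("reference_feature", "pqn", "none")
    _TRANSFORMS = ("glog", "none")
    _SCALINGS = ("pareto", "auto", "none")

    def __post_init__(self) -> None:
        if self.binsim and (self.imputation, self.normalization, self.transform,
                            self.scaling) != ("none", "none", "none", "none"):
            raise ValueError("binsim excludes every other pre-treatment step")
        if self.imputation not in self._IMPUTATIONS:
            raise ValueError(f"unknown imputation {self.imputation!r}")
        if self.normalization not in self._NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.transform not in self._TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.scaling not in self._SCALINGS:
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.normalization == "reference_feature" and self.reference_mz is None:
            raise ValueError("reference_feature normalization requires reference_mz")

    @classmethod
    def from_name(cls, name: str, reference_mz: float | None = None,
                  glog_lambda="auto") -> "PretreatmentSpec":
        """Parse names like ``binsim``, ``half_min-P``, ``rf-NP``, ``rf-NGP``.

        The normalization in NP/NGP is by reference feature when
        ``reference_mz`` is given, else PQN (the large-dataset convention).
        """
        if name.lower() == "binsim":
            return cls(binsim=True)
        try:
            imp_name, combo = name.split("-")
        except ValueError:
            raise ValueError(f"unrecognized pre-treatment name {name!r}") from None
        imputation = {"half_min": "half_min", "rf": "random_forest"}.get(imp_name)
        if imputation is None or combo not in ("P", "NP", "NGP"):
            raise ValueError(f"unrecognized pre-treatment name {name!r}")
        norm = "none"
        if "N" in combo:
            norm = "reference_feature" if reference_mz is not None else "pqn"
        return cls(
            imputation=imputation,
            normalization=norm,
            reference_mz=reference_mz,
            transform="glog" if "G" in combo else "none",
            glog_lambda=glog_lambda,
            scaling="pareto",
        )

    def build_steps(self, seed: int = 0) -> list:
        """Ordered (name, transformer) steps for a sklearn Pipeline."""
        if self.binsim:
            return [("binsim", BinSim())]
        steps = []
        if self.imputation == "half_min":
            steps.append(("impute", HalfMinImputer()))
        elif self.imputation == "random_forest":
            steps.append(("impute", RandomForestImputer(random_state=seed)))
        if self.normalization == "reference_feature":
            steps.append(("normalize", ReferenceFeatureNormalizer(self.reference_mz)))
        elif self.normalization == "pqn":
            steps.append(("normalize", PQNNormalizer()))
        if self.transform == "glog":
            steps.append(("glog", GLogTransformer(lam=self.glog_lambda)))
        if self.scaling == "pareto":
            steps.append(("scale", ParetoScaler()))
        elif self.scaling == "auto":
            from sklearn.preprocessing import StandardScaler
            steps.append(("scale", StandardScaler()))
        return steps


# --------------------------------------------------------------------------
# PeakTable-level convenience functions
# --------------------------------------------------------------------------

def binsim(pt: PeakTable) -> BinaryMatrix:
    """Binary Simplification of a peak table: presence 1, absence 0."""
    return BinaryMatrix(BinSim().fit_transform(pt.data).astype(int), labels=pt.labels)


def impute_half_min(pt: PeakTable) -> PeakTable:
    return pt.copy_with(HalfMinImputer().fit_transform(pt.data).to_numpy())


def impute_rf(pt: PeakTable, n_trees: int = 50, n_similar: int = 100,
              seed: int = 0) -> PeakTable:
    imp = RandomForestImputer(n_trees=n_trees, n_similar=n_similar, random_state=seed)
    return pt.copy_with(imp.fit_transform(pt.data).to_numpy())


def normalize_reference(pt: PeakTable, reference_mz: float, ppm_tol: float = 1.0) -> PeakTable:
    norm = ReferenceFeatureNormalizer(reference_mz, ppm_tol=ppm_tol)
    return pt.copy_with(norm.fit_transform(pt.data).to_numpy())


def normalize_pqn(pt: PeakTable) -> PeakTable:
    return pt.copy_with(PQNNormalizer().fit_transform(pt.data).to_numpy())


def glog(pt, lam="auto") -> pd.DataFrame:
    """Generalized-log transform a peak table.

    Returns a DataFrame (not a PeakTable): the transform maps intensities
    below 1 to negative values, which a PeakTable rejects by construction.
    """
    frame = pt.data if isinstance(pt, PeakTable) else pt
    return GLogTransformer(lam=lam).fit_transform(frame)


def pareto(pt) -> pd.DataFrame:
    """Pareto-scale a peak table (or treated DataFrame).

    Returns a DataFrame: centering produces non-positive values, which a
    PeakTable rejects by construction.
    """
    frame = pt.data if isinstance(pt, PeakTable) else pt
    return ParetoScaler().fit_transform(frame)


def apply_pipeline(pt: PeakTable, spec: PretreatmentSpec, seed: int = 0):
    """Apply a pre-treatment combination to a peak table.

    Steps run in the fixed order imputation -> normalization -> transform ->
    scaling; ``binsim`` short-circuits everything.  Returns a
    :class:`BinaryMatrix` for BinSim, else a ``pandas.DataFrame`` of treated
    intensities (scaled data may be negative).
    """
    if spec.binsim:
        return binsim(pt)
    result = pt.data
    for _, step in spec.build_steps(seed=seed):
        result = step.fit_transform(result)
    return result
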