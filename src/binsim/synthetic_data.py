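"""Synthetic direct-infusion MS peak tables with known ground truth.

The generator emulates the statistical structure of high-resolution
metabolomics benchmark data: a few replicates per class, log-normal
intensities with per-class mean shifts on shared features, class-exclusive
"biomarker" features, per-sample multiplicative dilution, a reference
(lock-mass) feature present in every sample, and missingness dominated by
intensity-threshold censoring (MNAR) with optional uniform (MCAR) deletion
on top.  Because the censoring threshold is applied after dilution,
missingness depends on dilution -- the regime in which occurrence-based
encoding carries real information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .peak_table import PeakTable

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate", "table1_like",
           "mnar_quantile_for_missing"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic peak table.

    Intensities are log-normal: a shared feature's natural-log intensity in
    sample s of class c is ``base_f + module_cf + shift_cf + eps +
    dilution_s`` with ``base_f ~ N(base_log_intensity)``,
    ``shift_cf ~ N(0, effect_sd)`` and ``eps ~ N(0, noise_sd)``.

    ``module_cf`` models metabolic modules shared by related classes: with
    probability ``module_prob`` a feature is expressed (boosted by
    ``module_effect`` log units) in a random subset of at least
    ``min_module_size`` classes.  Modules span two or more classes, so
    single-class-exclusive occurrence remains the signature of the planted
    biomarkers, which are drawn only in their class and boosted by
    ``biomarker_log_boost`` so that a class marker sits above the detection
    threshold.  MNAR censoring removes entries below the ``mnar_quantile``
    quantile of all true intensities; MCAR deletion then removes surviving
    entries uniformly at ``mcar_rate``.
    """

    n_classes: int = 5
    replicates_per_class: int = 3
    class_sizes: tuple | None = None   # overrides replicates_per_class if set
    n_shared_features: int = 500
    biomarkers_per_class: int = 10
    base_log_intensity: tuple = (13.8, 1.0)   # ~e^13.8 = 1e6 arbitrary units
    effect_sd: float = 0.2
    noise_sd: float = 0.2
    dilution_sd: float = 0.1
    module_prob: float = 0.45
    module_effect: float = 2.0
    module_noise_sd: float = 0.0
    min_module_size: int = 2
    max_module_size: int | None = None   # default: n_classes
    biomarker_log_boost: float = 2.0
    mnar_quantile: float = 0.0
    mcar_rate: float = 0.0
    reference_mz: float = 556.276575
    mz_range: tuple = (150.0, 1100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mnar_quantile < 1 or not 0 <= self.mcar_rate < 1:
            raise ValueError("mnar_quantile and mcar_rate must be in [0, 1)")
        if self.mnar_quantile + self.mcar_rate >= 1:
            raise ValueError("mnar_quantile + mcar_rate must be < 1")
        if self.n_classes < 1 or self.replicates_per_class < 1:
            raise ValueError("need at least one class and one replicate")

    @property
    def sizes(self) -> tuple:
        if self.class_sizes is not None:
            if len(self.class_sizes) != self.n_classes:
                raise ValueError("class_sizes must have n_classes entries")
            return tuple(self.class_sizes)
        return (self.replicates_per_class,) * self.n_classes

    @property
    def n_samples(self) -> int:
        return sum(self.sizes)

    @property
    def n_features(self) -> int:
        return self.n_shared_features + self.n_classes * self.biomarkers_per_class + 1


@dataclass(frozen=True)
class SyntheticTruth:
    """What the generator knows and the analyst must recover."""

    biomarker_class: dict          # feature m/z -> class label
    dilution: dict                 # sample id -> multiplicative dilution factor
    mnar_censored: dict            # (sample id, m/z) -> true intensity
    mcar_censored: dict            # (sample id, m/z) -> true intensity
    censoring_threshold: float


def structural_missing_fraction(cfg: SyntheticConfig) -> float:
    """Fraction of matrix entries that are absent by construction
    (biomarkers outside their own class)."""
    sizes = cfg.sizes
    n = cfg.n_samples
    absent = sum(cfg.biomarkers_per_class * (n - sz) for sz in sizes)
    return absent / (n * cfg.n_features)


def mnar_quantile_for_missing(cfg: SyntheticConfig, target_missing: float,
                              n_iter: int = 8) -> float:
    """Censoring quantile that lands the realized missing fraction near
    ``target_missing``.

    The realized fraction is measured on the generated table after features
    censored to zero occurrences are dropped, so the analytic relation
    between quantile and missingness does not hold; a short bisection on
    actual draws (deterministic under ``cfg.seed``) calibrates it instead.
    """
    lo, hi = 0.0, 0.995
    for _ in range(n_iter):
        q = (lo + hi) / 2
        pt, _, _ = generate(replace(cfg, mnar_quantile=q))
        if pt.missing_fraction() < target_missing:
            lo = q
        else:
            hi = q
    return (lo + hi) / 2


def generate(cfg: SyntheticConfig):
    """Draw one synthetic dataset.

    Returns ``(PeakTable, ground_truth, SyntheticTruth)`` where
    ``ground_truth`` maps sample id to class label.
    """
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sizes
    n, p = cfg.n_samples, cfg.n_features
    classes = [f"C{c + 1:02d}" for c in range(cfg.n_classes)]
    sample_ids, sample_class = [], []
    for c, sz in zip(range(cfg.n_classes), sizes):
        for r in range(sz):
            sample_ids.append(f"{classes[c]}_r{r + 1}")
            sample_class.append(c)
    sample_class = np.asarray(sample_class)

    # feature m/z values: unique draws plus the exact reference m/z
    lo, hi = cfg.mz_range
    draws = np.unique(rng.uniform(lo, hi, size=2 * p))
    draws = draws[np.abs(draws - cfg.reference_mz) > 1e-3][: p - 1]
    if draws.size < p - 1:
        raise ValueError("m/z range too narrow for the requested feature count")
    n_shared = cfg.n_shared_features
    shared_mz = draws[:n_shared]
    biomarker_mz = draws[n_shared:].reshape(cfg.n_classes, cfg.biomarkers_per_class) \
        if cfg.biomarkers_per_class else np.empty((cfg.n_classes, 0))

    mu, sd = cfg.base_log_intensity
    log_x = np.full((n, p - 1), np.nan)

    base = rng.normal(mu, sd, size=n_shared)
    shift = rng.normal(0.0, cfg.effect_sd, size=(cfg.n_classes, n_shared))
    # metabolic modules: expression boosts shared by >= min_module_size classes
    module = np.zeros((cfg.n_classes, n_shared))
    lo_size = min(cfg.min_module_size, cfg.n_classes)
    hi_size = min(cfg.max_module_size or cfg.n_classes, cfg.n_classes)
    structured = rng.random(n_shared) < cfg.module_prob
    for f in np.flatnonzero(structured):
        size = int(rng.integers(lo_size, max(lo_size, hi_size) + 1))
        members = rng.choice(cfg.n_classes, size=size, replace=False)
        module[members, f] = cfg.module_effect
    eps = rng.normal(0.0, cfg.noise_sd, size=(n, n_shared))
    if cfg.module_noise_sd > 0 and structured.any():
        # module-regulated metabolites fluctuate more around the detection limit
        eps[:, structured] += rng.normal(
            0.0, cfg.module_noise_sd, size=(n, int(structured.sum())))
    log_x[:, :n_shared] = base + module[sample_class] + shift[sample_class] + eps

    bm_class: dict = {}
    for c in range(cfg.n_classes):
        cols = slice(n_shared + c * cfg.biomarkers_per_class,
                     n_shared + (c + 1) * cfg.biomarkers_per_class)
        rows = sample_class == c
        bbase = rng.normal(mu + cfg.biomarker_log_boost, sd, size=cfg.biomarkers_per_class)
        log_x[np.ix_(rows, range(*cols.indices(p - 1)))] = (
            bbase + rng.normal(0.0, cfg.noise_sd, size=(int(rows.sum()), cfg.biomarkers_per_class))
        )
        for m in biomarker_mz[c]:
            bm_class[float(m)] = classes[c]

    dilution_log = rng.normal(0.0, cfg.dilution_sd, size=n)
    log_x += dilution_log[:, None]
    ref_log = mu + 4.0 + rng.normal(0.0, cfg.noise_sd, size=n) + dilution_log

    mz_all = np.concatenate([shared_mz, biomarker_mz.ravel(), [cfg.reference_mz]])
    x = np.empty((n, p))
    x[:, : p - 1] = np.exp(log_x)
    x[:, p - 1] = np.exp(ref_log)

    present = ~np.isnan(x)
    observed = present.copy()

    mnar_censored: dict = {}
    threshold = 0.0
    if cfg.mnar_quantile > 0:
        threshold = float(np.nanquantile(x, cfg.mnar_quantile))
        low = present & (x < threshold)
        low[:, p - 1] = False  # the reference feature is never censored
        observed &= ~low
        for i, j in zip(*np.nonzero(low)):
            mnar_censored[(sample_ids[i], float(mz_all[j]))] = float(x[i, j])

    mcar_censored: dict = {}
    if cfg.mcar_rate > 0:
        drop = observed & (rng.random(x.shape) < cfg.mcar_rate)
        drop[:, p - 1] = False
        observed &= ~drop
        for i, j in zip(*np.nonzero(drop)):
            mcar_censored[(sample_ids[i], float(mz_all[j]))] = float(x[i, j])

    if (~observed).all(axis=1).any():
        raise ValueError("configuration produced an all-missing sample")

    # identifiability of the planted ground truth: shared features whose
    # realized occurrence pattern is perfectly class-aligned (every class
    # fully present or fully absent) would be indistinguishable from planted
    # markers (or their absence counterparts), so they are rejected; planted
    # biomarkers are then the only features with class-determined occurrence
    keep = np.ones(p, dtype=bool)
    class_rows = [np.flatnonzero(sample_class == c) for c in range(cfg.n_classes)]
    for j in range(n_shared):
        if not observed[:, j].any():
            continue
        per_class = [observed[rows, j] for rows in class_rows]
        clean = all(o.all() or not o.any() for o in per_class)
        k_present = sum(o.all() for o in per_class)
        if clean and 1 <= k_present <= cfg.n_classes - 1:
            keep[j] = False

    values = np.where(observed, x, np.nan)[:, keep]
    gt = {s: classes[c] for s, c in zip(sample_ids, sample_class)}
    df = pd.DataFrame(values, index=sample_ids, columns=mz_all[keep])
    pt = PeakTable(df, labels=pd.Series(gt))
    truth = SyntheticTruth(
        biomarker_class=bm_class,
        dilution={s: float(np.exp(d)) for s, d in zip(sample_ids, dilution_log)},
        mnar_censored=mnar_censored,
        mcar_censored=mcar_censored,
        censoring_threshold=threshold,
    )
    return pt, gt, truth


_PRESETS = {
    "GD-like": dict(n_classes=11, replicates_per_class=3, n_shared_features=6200,
                    biomarkers_per_class=15, base_log_intensity=(13.8, 0.6),
                    effect_sd=0.6, noise_sd=0.2, dilution_sd=0.1,
                    module_prob=0.0, biomarker_log_boost=3.0,
                    target_missing=0.80),
    "YD-like": dict(n_classes=5, replicates_per_class=3, n_shared_features=3800,
                    biomarkers_per_class=10, base_log_intensity=(13.8, 0.6),
                    effect_sd=0.6, noise_sd=0.2, dilution_sd=0.1,
                    module_prob=0.0, biomarker_log_boost=3.0,
                    target_missing=0.65),
    "HD-like": dict(n_classes=2, class_sizes=(114, 135), replicates_per_class=124,
                    n_shared_features=12600, biomarkers_per_class=40,
                    base_log_intensity=(13.8, 0.9), effect_sd=0.15,
                    noise_sd=0.35, dilution_sd=0.15, module_prob=0.0,
                    biomarker_log_boost=2.0, target_missing=0.38),
}


def table1_like(preset: str, seed: int = 0):
    """Synthetic dataset in one of the benchmark regimes.

    ``GD-like``: 33 samples / 11 classes / ~3000 features / ~80% missing;
    ``YD-like``: 15 / 5 / ~2000 / ~65%; ``HD-like``: 249 / 2 / ~12000 / ~38%.
    The censoring quantile is calibrated by :func:`mnar_quantile_for_missing`
    so the realized missing fraction lands on the regime's target.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    params = dict(_PRESETS[preset])
    target = params.pop("target_missing")
    cfg = SyntheticConfig(**params, seed=seed)
    q = mnar_quantile_for_missing(cfg, target)
    return generate(replace(cfg, mnar_quantile=q))
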