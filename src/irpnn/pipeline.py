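"""End-to-end pipeline: simulate/load -> restrict -> extract -> train -> evaluate.

The default run mirrors the study design: a 440-sample cohort
(220 normal / 120 early / 100 advanced), a stratified 230/210
train/test split, region restriction to the 2000-650 cm^-1 fingerprint
window, db4 five-level decomposition with energy features from detail
levels 3 and 4, leave-one-out selection of the Parzen width, and a
per-class recognition report for both partitions.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureConfig, FeatureVector, extract_features, features_to_table
from .pnn import PNNModel, model_to_json, pnn_predict, pnn_train, select_sigma
from .spectra_io import Spectrum, read_spectrum_csv, restrict_region
from .synthetic_spectra import SyntheticConfig, simulate_cohort
from .tissue import CLASS_ORDER, TissueClass

__all__ = [
    "SplitPlan",
    "ClassificationReport",
    "PipelineConfig",
    "stratified_split",
    "evaluate",
    "run_pipeline",
]

logger = logging.getLogger("irpnn")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class DataError(ValueError):
    """Input data missing or malformed at the pipeline level."""


@dataclass(frozen=True)
class SplitPlan:
    """Stratified train/test allocation (defaults 230/210 of 440)."""

    n_train: int = 230
    n_test: int = 210
    stratified: bool = True
    seed: int = 0


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total`` from fractional quotas."""
    floors = np.floor(quotas).astype(int)
    short = total - floors.sum()
    # ties in the remainder go to the earlier (lower-ordinal) class
    order = np.argsort(-(quotas - floors), kind="stable")
    for i in order[:short]:
        floors[i] += 1
    return floors


def stratified_split(
    cohort: list, plan: SplitPlan
) -> tuple[list, list]:
    """Split labeled samples into disjoint train/test sets.

    Per-class train counts follow class frequency with largest-remainder
    rounding (so the totals are exactly ``n_train``/``n_test``); the
    within-class ordering is a seeded shuffle.  Works on any objects with
    a ``label`` attribute (spectra or feature vectors).
    """
    labels = [s.label for s in cohort]
    if any(lab is None for lab in labels):
        raise DataError("every cohort sample needs a label for a stratified split")
    n = len(cohort)
    if plan.n_train + plan.n_test > n:
        raise ConfigError(
            f"n_train + n_test = {plan.n_train + plan.n_test} exceeds cohort size {n}"
        )
    if plan.n_train < 1 or plan.n_test < 1:
        raise ConfigError("n_train and n_test must be >= 1")
    rng = np.random.default_rng(plan.seed)
    if not plan.stratified:
        perm = rng.permutation(n)
        train_idx = perm[: plan.n_train]
        test_idx = perm[plan.n_train : plan.n_train + plan.n_test]
        return [cohort[i] for i in train_idx], [cohort[i] for i in test_idx]

    classes = [tc for tc in CLASS_ORDER if tc in set(labels)]
    counts = np.array([labels.count(tc) for tc in classes])
    train_alloc = _largest_remainder(plan.n_train * counts / n, plan.n_train)
    test_quota = plan.n_test * counts / n
    test_alloc = np.minimum(_largest_remainder(test_quota, plan.n_test), counts - train_alloc)
    # redistribute any shortfall to classes with spare samples
    short = plan.n_test - test_alloc.sum()
    while short > 0:
        spare = counts - train_alloc - test_alloc
        i = int(np.argmax(spare))
        if spare[i] == 0:
            raise ConfigError("cannot satisfy test allocation")
        test_alloc[i] += 1
        short -= 1
    if np.any(train_alloc < 1):
        raise ConfigError(f"per-class train counts {train_alloc.tolist()} must all be >= 1")
    train, test = [], []
    for tc, n_tr, n_te in zip(classes, train_alloc, test_alloc):
        idx = [i for i, lab in enumerate(labels) if lab == tc]
        idx = [idx[j] for j in rng.permutation(len(idx))]
        train.extend(cohort[i] for i in idx[:n_tr])
        test.extend(cohort[i] for i in idx[n_tr : n_tr + n_te])
    return train, test


@dataclass
class ClassificationReport:
    """Confusion matrices and recognition rates for both partitions.

    ``confusion[partition]`` is a (true class x predicted class)
    DataFrame; recognition rate is the diagonal over the row sum, in
    percent, the per-class accuracy convention of the field.
    """

    confusion: dict[str, pd.DataFrame] = field(default_factory=dict)
    per_class_accuracy: dict[str, dict[TissueClass, float]] = field(default_factory=dict)
    overall_accuracy: dict[str, float] = field(default_factory=dict)

    def add_partition(self, name: str, model: PNNModel, data: list[FeatureVector]) -> None:
        conf, per_class, overall = evaluate(model, data)
        self.confusion[name] = conf
        self.per_class_accuracy[name] = per_class
        self.overall_accuracy[name] = overall

    def rates_frame(self) -> pd.DataFrame:
        """Recognition-rate table: rows = partitions, columns = classes (%)."""
        rows = {}
        for name, rates in self.per_class_accuracy.items():
            rows[name] = {tc.label: rates[tc] for tc in rates}
        return pd.DataFrame.from_dict(rows, orient="index")

    def summary(self) -> str:
        lines = ["Recognition rates (%)", ""]
        frame = self.rates_frame()
        lines.append(frame.round(2).to_string())
        for name, conf in self.confusion.items():
            lines += ["", f"Confusion matrix — {name} (rows: true, cols: predicted)"]
            lines.append(conf.to_string())
            lines.append(f"overall accuracy: {self.overall_accuracy[name]:.2f}%")
        return "\n".join(lines)


def evaluate(
    model: PNNModel, data: list[FeatureVector]
) -> tuple[pd.DataFrame, dict[TissueClass, float], float]:
    """Exhaustive prediction over labeled feature vectors.

    Returns the confusion matrix (true x predicted counts), per-class
    recognition rates (%), and overall accuracy (%).
    """
    if not data:
        raise DataError("cannot evaluate on an empty data set")
    labels = [fv.label for fv in data]
    for lab in labels:
        if lab is None:
            raise DataError("every evaluation sample needs a label")
        if lab not in model.classes:
            raise DataError(f"label {lab.label!r} absent from the model's classes")
    X = np.vstack([fv.values for fv in data])
    preds = pnn_predict(model, X)
    names = [tc.label for tc in model.classes]
    conf = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for true, pred in zip(labels, preds):
        conf.loc[true.label, pred.label] += 1
    per_class: dict[TissueClass, float] = {}
    for tc in model.classes:
        row_sum = int(conf.loc[tc.label].sum())
        per_class[tc] = 100.0 * conf.loc[tc.label, tc.label] / row_sum if row_sum else float("nan")
    overall = 100.0 * np.trace(conf.values) / len(data)
    return conf, per_class, overall


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a YAML document."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_dir: str | None = None  # read CSVs + manifest instead of simulating
    region_high: float = 2000.0
    region_low: float = 650.0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    split: SplitPlan = field(default_factory=SplitPlan)
    sigma_grid: tuple[float, ...] = tuple(np.geomspace(1e-3, 1.0, 31).round(12))
    error_goal: float = 0.01
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            doc = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(doc)
        try:
            if "synthetic" in kwargs:
                syn = dict(kwargs["synthetic"])
                if "class_sizes" in syn:
                    syn["class_sizes"] = {
                        TissueClass.from_label(k): int(v)
                        for k, v in dict(syn["class_sizes"]).items()
                    }
                kwargs["synthetic"] = SyntheticConfig(**syn)
            if "features" in kwargs:
                fc = dict(kwargs["features"])
                if "detail_levels" in fc:
                    fc["detail_levels"] = tuple(fc["detail_levels"])
                kwargs["features"] = FeatureConfig(**fc)
            if "split" in kwargs:
                kwargs["split"] = SplitPlan(**dict(kwargs["split"]))
            if "sigma_grid" in kwargs:
                kwargs["sigma_grid"] = tuple(float(v) for v in kwargs["sigma_grid"])
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid configuration: {exc}") from exc


def _load_cohort(config: PipelineConfig) -> list[Spectrum]:
    if config.input_dir is None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        logger.info("simulating cohort: sizes=%s seed=%d",
                    {tc.label: syn.class_sizes[tc] for tc in CLASS_ORDER}, syn.seed)
        return simulate_cohort(syn)
    root = Path(config.input_dir)
    manifest = root / "manifest.csv"
    if not root.is_dir() or not manifest.exists():
        raise DataError(f"input directory {root} with manifest.csv not found")
    table = pd.read_csv(manifest)
    cohort = []
    for _, row in table.iterrows():
        s = read_spectrum_csv(root / str(row["filename"]))
        s.label = TissueClass.from_label(str(row["label"]))
        cohort.append(s)
    if not cohort:
        raise DataError(f"manifest {manifest} lists no spectra")
    return cohort


def run_pipeline(config: PipelineConfig) -> ClassificationReport:
    """Execute the full chain and (optionally) write all artifacts.

    Stages: simulate or load the cohort; restrict to the analysis region;
    split; extract features; select sigma by leave-one-out on the training
    partition; train the exemplar PNN; evaluate both partitions.  With
    ``output_dir`` set, writes the recognition report (CSV + text
    summary), the model JSON, both feature tables, and a log of every
    seed and parameter.
    """
    out = Path(config.output_dir) if config.output_dir else None
    handler = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        logger.info("pipeline start: seed=%d region=%s-%s cm^-1 wavelet=%s levels=%d",
                    config.seed, config.region_high, config.region_low,
                    config.features.wavelet, config.features.levels)
        cohort = _load_cohort(config)
        cohort = [restrict_region(s, config.region_high, config.region_low) for s in cohort]
        plan = dataclasses.replace(config.split, seed=config.seed)
        train_spectra, test_spectra = stratified_split(cohort, plan)
        logger.info("split: %d train / %d test", len(train_spectra), len(test_spectra))
        train_features = [extract_features(s, config.features) for s in train_spectra]
        test_features = [extract_features(s, config.features) for s in test_spectra]
        sigma = select_sigma(train_features, np.asarray(config.sigma_grid), config.error_goal)
        logger.info("selected sigma=%g (grid of %d, error goal %g)",
                    sigma, len(config.sigma_grid), config.error_goal)
        model = pnn_train(train_features, sigma)
        report = ClassificationReport()
        report.add_partition("training", model, train_features)
        report.add_partition("testing", model, test_features)
        for name in ("training", "testing"):
            logger.info("%s per-class recognition: %s", name,
                        {tc.label: round(r, 2)
                         for tc, r in report.per_class_accuracy[name].items()})
        if out is not None:
            report.rates_frame().to_csv(out / "report.csv", index_label="partition")
            (out / "summary.txt").write_text(
                f"run at {datetime.datetime.now().isoformat()}\n\n" + report.summary() + "\n"
            )
            model_to_json(model, out / "model.json")
            features_to_table(train_features, out / "features_train.csv")
            features_to_table(test_features, out / "features_test.csv")
            logger.info("artifacts written to %s", out)
        return report
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
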