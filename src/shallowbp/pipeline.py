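"""End-to-end orchestration of the two-stage BP estimation method.

One call wires the stages together: condition the raw store, split
train/test (subject-disjoint when subject identities exist), train the
U-Net autoencoder on the training partition, extract bottleneck features
for both partitions, fit one regressor per BP target, predict, and score
against the full evaluation stack.  Artifacts (checkpoint, features,
predictions, rejection report, evaluation report, manifest) are written to
a work directory; a manifest records the configuration so that reruns are
reproducible bit for bit in deterministic mode.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .autoencoder import UNetFeatureExtractor
from .evaluation import EvalReport, evaluate
from .preprocess import PreprocessConfig, PreprocessResult, preprocess_store
from .regress import BloodPressureRegressor
from .segment_io import SegmentStore, write_store
from .synth import SyntheticConfig, generate

CHANNEL_ORDER = ("PPG", "VPG", "APG", "ECG")
CHANNEL_PRESETS = {
    1: ("PPG",),
    2: ("PPG", "ECG"),
    3: ("PPG", "VPG", "APG"),
    4: ("PPG", "VPG", "APG", "ECG"),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; the seed feeds every stochastic stage."""

    channels: tuple[str, ...] = CHANNEL_PRESETS[4]
    depth: int = 1
    width: int = 128
    kernel: int = 3
    n_features: int = 1024
    target: str = "ABP"
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 15
    sbp_algorithm: str = "mlp"
    dbp_algorithm: str = "mlp"
    test_fraction: float = 0.25
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.channels) - set(CHANNEL_ORDER)
        if bad:
            raise ValueError(f"unknown channels {sorted(bad)}")

    @classmethod
    def quick(cls, seed: int = 0, channels: int = 1, max_epochs: int = 10) -> "PipelineConfig":
        """Scaled-down profile for desk-sized experiments."""
        return cls(
            channels=CHANNEL_PRESETS[channels],
            width=32,
            n_features=128,
            max_epochs=max_epochs,
            patience=max_epochs,
            seed=seed,
        )


def stack_channels(store: SegmentStore, channels: Sequence[str]) -> np.ndarray:
    """Stack predictor channels into an (n, length, C) tensor in the
    declared order PPG, VPG, APG, ECG (subset preserving that order)."""
    ordered = [c for c in CHANNEL_ORDER if c in channels]
    missing = [c for c in ordered if c not in store.channel_kinds()]
    if missing:
        raise ValueError(f"store lacks channels {missing}; present: {store.channel_kinds()}")
    return np.stack([store.channel_matrix(c) for c in ordered], axis=2)


def subject_disjoint_split(
    subject_ids: Sequence[str], test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded record split that keeps each subject on one side.

    Subjects are shuffled and assigned to the test side until its record
    share reaches ``test_fraction``.  When every record belongs to one
    anonymous subject the split falls back to record level.
    """
    subject_ids = np.asarray(subject_ids)
    rng = np.random.default_rng(seed)
    n = len(subject_ids)
    unique = pd.unique(subject_ids)
    if len(unique) < 2:
        perm = rng.permutation(n)
        n_test = max(1, int(round(test_fraction * n)))
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])
    order = rng.permutation(len(unique))
    test_subjects: set = set()
    count = 0
    for j in order:
        if count >= test_fraction * n:
            break
        test_subjects.add(unique[j])
        count += int(np.sum(subject_ids == unique[j]))
    mask = np.isin(subject_ids, list(test_subjects))
    return np.where(~mask)[0], np.where(mask)[0]


@dataclass
class PipelineOutcome:
    reports: dict[str, EvalReport]
    predictions: pd.DataFrame
    baseline_mae: dict[str, float]
    extractor: UNetFeatureExtractor
    regressors: dict[str, BloodPressureRegressor]
    preprocess_result: PreprocessResult


def _targets(store: SegmentStore, cfg: PipelineConfig) -> np.ndarray:
    kind = "ABP" if cfg.target == "ABP" else "PPG"
    return store.channel_matrix(kind)


def run_pipeline(
    cfg: PipelineConfig,
    store: SegmentStore,
    workdir: str | None = None,
) -> PipelineOutcome:
    """Execute preprocess -> autoencoder -> features -> regressors -> report."""
    if "ABP" not in (set.union(*(set(r.channels) for r in store.records)) if len(store) else set()):
        raise ValueError("ABP required: input store carries no pressure channel")
    pre = preprocess_store(store, cfg.preprocess)
    labels = pre.labels.set_index("segment_id")
    clean = pre.store

    train_idx, test_idx = subject_disjoint_split(
        clean.subject_ids(), cfg.test_fraction, cfg.seed
    )
    train_store, test_store = clean.subset(train_idx), clean.subset(test_idx)

    X_train = stack_channels(train_store, cfg.channels)
    X_test = stack_channels(test_store, cfg.channels)
    Y_train = _targets(train_store, cfg)
    if cfg.target == "ABP":
        # the store was normalized by the all-accepted pressure maximum;
        # rescaling by the train partition's own maximum makes the divisor
        # a train-only statistic (exact: (x/M_all)/(M_tr/M_all) = x/M_tr)
        Y_train = Y_train / float(Y_train.max())

    extractor = UNetFeatureExtractor(
        depth=cfg.depth,
        width=cfg.width,
        kernel=cfg.kernel,
        in_channels=X_train.shape[2],
        n_features=cfg.n_features,
        target=cfg.target,
        batch_size=cfg.batch_size,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        random_state=cfg.seed,
    )
    extractor.fit(X_train, Y_train)
    F_train = extractor.transform(X_train)
    F_test = extractor.transform(X_test)

    y_train = labels.loc[train_store.segment_ids()]
    y_test = labels.loc[test_store.segment_ids()]

    reports: dict[str, EvalReport] = {}
    baseline: dict[str, float] = {}
    regressors: dict[str, BloodPressureRegressor] = {}
    pred_rows = {"segment_id": test_store.segment_ids(), "subject_id": test_store.subject_ids()}
    for target, algo in (("SBP", cfg.sbp_algorithm), ("DBP", cfg.dbp_algorithm)):
        col = target.lower()
        model = BloodPressureRegressor(algo, target, random_state=cfg.seed)
        model.fit(F_train, y_train[col].to_numpy())
        pred = model.predict(F_test)
        truth = y_test[col].to_numpy()
        reports[target] = evaluate(truth, pred, y_test["subject_id"], target)
        baseline[target] = float(np.mean(np.abs(truth - y_train[col].mean())))
        regressors[target] = model
        pred_rows[f"{col}_true"] = truth
        pred_rows[f"{col}_pred"] = pred
    predictions = pd.DataFrame(pred_rows)

    outcome = PipelineOutcome(reports, predictions, baseline, extractor, regressors, pre)
    if workdir is not None:
        _write_artifacts(cfg, outcome, train_store, workdir)
    return outcome


def _write_artifacts(
    cfg: PipelineConfig, outcome: PipelineOutcome, train_store: SegmentStore, workdir: str
) -> None:
    os.makedirs(workdir, exist_ok=True)
    outcome.extractor.model_.save(os.path.join(workdir, "autoencoder.npz"))
    np.savetxt(
        os.path.join(workdir, "features_train.csv"),
        outcome.extractor.transform(
            stack_channels(train_store, cfg.channels)
        ),
        delimiter=",",
    )
    outcome.predictions.to_csv(os.path.join(workdir, "predictions.csv"), index=False)
    outcome.preprocess_result.report.to_csv(
        os.path.join(workdir, "rejection_report.csv"), index=False
    )
    report_json = {t: r.to_dict() for t, r in outcome.reports.items()}
    with open(os.path.join(workdir, "report.json"), "w") as fh:
        json.dump(report_json, fh, indent=2, sort_keys=True)
    cfg_dict = asdict(cfg)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_train": len(train_store),
    }
    with open(os.path.join(workdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    write_store(train_store, os.path.join(workdir, "train_store.h5"))


def run_sweep(
    cfg: PipelineConfig, store: SegmentStore, grid: dict[str, Sequence]
) -> pd.DataFrame:
    """One pipeline run per grid cell; returns (axis values, SBP/DBP MAE).

    Axes: depth, width, kernel, channels (1-4 preset code), features,
    target.  Infeasible cells (e.g. input length not divisible by the
    pooling factor) are marked skipped and the sweep continues.
    """
    allowed = {"depth", "width", "kernel", "channels", "features", "target"}
    bad = set(grid) - allowed
    if bad:
        raise ValueError(f"unknown sweep axes {sorted(bad)}")
    axes = sorted(grid)
    if not axes:
        combos = [()]
    else:
        import itertools

        combos = list(itertools.product(*(grid[a] for a in axes)))
    rows = []
    from dataclasses import replace

    for combo in combos:
        cell = dict(zip(axes, combo))
        run_cfg = cfg
        if "depth" in cell:
            run_cfg = replace(run_cfg, depth=int(cell["depth"]))
        if "width" in cell:
            run_cfg = replace(run_cfg, width=int(cell["width"]))
        if "kernel" in cell:
            run_cfg = replace(run_cfg, kernel=int(cell["kernel"]))
        if "features" in cell:
            run_cfg = replace(run_cfg, n_features=int(cell["features"]))
        if "channels" in cell:
            run_cfg = replace(run_cfg, channels=CHANNEL_PRESETS[int(cell["channels"])])
        if "target" in cell:
            run_cfg = replace(run_cfg, target=str(cell["target"]))
        row = dict(cell)
        try:
            outcome = run_pipeline(run_cfg, store)
            row["sbp_mae"] = outcome.reports["SBP"].mae
            row["dbp_mae"] = outcome.reports["DBP"].mae
            row["status"] = "ok"
        except ValueError as exc:
            row["sbp_mae"] = np.nan
            row["dbp_mae"] = np.nan
            row["status"] = f"skipped: {exc}"
        rows.append(row)
    return pd.DataFrame(rows).sort_values(axes or ["status"]).reset_index(drop=True)


def run_transfer(
    cfg: PipelineConfig, train_store: SegmentStore, test_store: SegmentStore
) -> dict[str, EvalReport]:
    """Train on one corpus, test on another (cross-corpus generalization)."""
    pre_train = preprocess_store(train_store, cfg.preprocess)
    pre_test = preprocess_store(test_store, cfg.preprocess, context=pre_train.context)
    X_train = stack_channels(pre_train.store, cfg.channels)
    X_test = stack_channels(pre_test.store, cfg.channels)
    Y_train = _targets(pre_train.store, cfg)
    extractor = UNetFeatureExtractor(
        depth=cfg.depth, width=cfg.width, kernel=cfg.kernel,
        in_channels=X_train.shape[2], n_features=cfg.n_features,
        batch_size=cfg.batch_size, max_epochs=cfg.max_epochs,
        patience=cfg.patience, random_state=cfg.seed,
    )
    extractor.fit(X_train, Y_train)
    F_train, F_test = extractor.transform(X_train), extractor.transform(X_test)
    ltr = pre_train.labels.set_index("segment_id").loc[pre_train.store.segment_ids()]
    lte = pre_test.labels.set_index("segment_id").loc[pre_test.store.segment_ids()]
    reports = {}
    for target, algo in (("SBP", cfg.sbp_algorithm), ("DBP", cfg.dbp_algorithm)):
        col = target.lower()
        model = BloodPressureRegressor(algo, target, random_state=cfg.seed)
        model.fit(F_train, ltr[col].to_numpy())
        reports[target] = evaluate(
            lte[col].to_numpy(), model.predict(F_test), lte["subject_id"], target
        )
    return reports


def demo_run(
    n_records: int = 400, seed: int = 0, max_epochs: int = 5, channels: int = 1
) -> PipelineOutcome:
    """Small synthetic end-to-end run (the README worked example)."""
    store, _ = generate(SyntheticConfig(n_records=n_records, seed=seed))
    cfg = PipelineConfig.quick(seed=seed, channels=channels, max_epochs=max_epochs)
    return run_pipeline(cfg, store)
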