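"""End-to-end fusion experiment.

The full protocol: extract the 45 colour components per sample, preprocess
the spectra (SG + SNV), split each month's samples 3:1 into training and
prediction sets, reduce each modality by PCA fitted on training rows only,
pick the PC count per modality by the minimum mean RMSECV over repeated
cross-validated BPNN runs, then concatenate the optimal score blocks
(z-scored with training statistics) and calibrate a fusion BPNN.  The
report compares the sensor-only, NIR-only and fusion models over the same
split and the same sequence of initialization seeds, so the comparison is
paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from .chemometrics import (
    BPNNConfig,
    PCAModel,
    RunStats,
    derive_seeds,
    fold_assignment,
    pca_fit,
    pca_transform,
    pearson_r,
    rmse,
)
from .cohort import (
    ArrayGeometry,
    CohortConfig,
    SensitivityMatrix,
    SpectralSignature,
    StorageSample,
    default_sensitivity,
    default_signature,
    generate_cohort,
    render_sensor_pair,
    sample_seeds,
    synth_spectrum,
)
from .imaging import FEATURE_NAMES, extract_pair_features
from .spectra import Spectrum, preprocess

__all__ = [
    "SplitSpec",
    "split_by_month",
    "PCOptimization",
    "optimize_pc_count",
    "FusedFeatures",
    "fuse",
    "ModalityBlock",
    "TechniqueResult",
    "FusionReport",
    "ExperimentConfig",
    "Dataset",
    "build_synthetic_dataset",
    "load_dataset",
    "run_full_experiment",
]


# ---------------------------------------------------------------------------
# sample-set division


@dataclass(frozen=True)
class SplitSpec:
    """Monthly-stratified random split; 3:1 puts 15 of 20 in training."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split_by_month(
    cohort: Sequence[StorageSample], spec: SplitSpec
) -> tuple[list[str], list[str]]:
    """Split each month's samples into train/test at the configured ratio.

    The train count is the fraction rounded to the nearest integer,
    clamped so the training side is never smaller than the test side and
    both are non-empty.  Disjoint, exhaustive, reproducible from the seed.
    """
    by_month: dict[int, list[str]] = {}
    for s in cohort:
        by_month.setdefault(s.month, []).append(s.sample_id)
    rng = np.random.default_rng(spec.seed)
    train: list[str] = []
    test: list[str] = []
    for month in sorted(by_month):
        ids = by_month[month]
        m = len(ids)
        if m < 2:
            raise ValueError(f"month {month} has fewer than 2 samples")
        n_train = int(round(m * spec.train_fraction))
        n_train = max(n_train, m - n_train)  # train side never smaller
        n_train = min(max(n_train, 1), m - 1)
        perm = rng.permutation(m)
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# PC-count optimization (repeated cross-validated BPNN runs per k)


@dataclass(frozen=True)
class PCOptimization:
    """Outcome of the PC scan: the chosen count and the per-k table of
    mean/variance/sd of RMSECV and R_C over the repeated runs."""

    chosen_k: int
    per_k: pd.DataFrame


def _fold_net_seed(run_seed: int, fold: int) -> int:
    return int(
        np.random.SeedSequence(entropy=run_seed, spawn_key=(fold,))
        .generate_state(1)[0]
        % (2**31)
    )


def optimize_pc_count(
    X_train: np.ndarray,
    y_train: np.ndarray,
    cfg: BPNNConfig | None = None,
    k_range: Sequence[int] = tuple(range(1, 11)),
    n_runs: int = 50,
    folds: int = 5,
    seed: int = 0,
) -> PCOptimization:
    """Choose the PC count minimizing the mean RMSECV over repeated runs.

    For every candidate k the BPNN is cross-validated ``n_runs`` times
    with fresh initialization seeds (fold assignment held fixed); PCA is
    refit inside each training fold.  The chosen k is the argmin of the
    mean RMSECV, ties broken toward the smaller k.  The per-run protocol
    is identical to :func:`ricefusion.chemometrics.cross_validate` with a
    PCA reducer; all runs and folds are trained in one vectorized pass.
    """
    cfg = cfg or BPNNConfig()
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must not be empty")
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n = len(y)
    fold_seed, runs_seed = derive_seeds(seed, 2)
    labels = fold_assignment(n, folds, fold_seed)
    run_seeds = derive_seeds(runs_seed, n_runs)

    # per fold: PCA on the training partition, scores for all samples
    max_k = max(k_range)
    fold_scores: list[np.ndarray] = []
    for f in range(folds):
        tr = labels != f
        k_fit = min(max_k, int(tr.sum()) - 1, X.shape[1])
        if max_k > k_fit:
            raise ValueError(
                f"k_range up to {max_k} infeasible for fold of size "
                f"{int(tr.sum())} with {X.shape[1]} features"
            )
        pca = pca_fit(X[tr], k_fit)
        fold_scores.append(pca_transform(pca, X))

    rows = []
    best_k: int | None = None
    best_rmsecv = np.inf
    for k in k_range:
        # one network per (fold, run), all trained simultaneously; the
        # sample mask confines each network to its own training fold
        R = folds * n_runs
        d = k
        Xs = np.empty((R, n, d))
        ys = np.empty((R, n))
        mask = np.empty((R, n), dtype=bool)
        seeds = np.empty(R, dtype=object)
        y_scales = []
        for f in range(folds):
            tr = labels != f
            S = fold_scores[f][:, :k]
            x_lo, x_hi = S[tr].min(axis=0), S[tr].max(axis=0)
            y_lo, y_hi = float(y[tr].min()), float(y[tr].max())
            Ss = chem._minmax_scale(S, x_lo, x_hi)
            ysc = (y - y_lo) / (y_hi - y_lo)
            for r in range(n_runs):
                i = f * n_runs + r
                Xs[i] = Ss
                ys[i] = ysc
                mask[i] = tr
                seeds[i] = _fold_net_seed(run_seeds[r], f)
            y_scales.append((y_lo, y_hi))
        layer_dims = [d, *cfg.hidden_layers, 1]
        Ws, bs = chem._init_params(layer_dims, list(seeds))
        chem._train_core(
            Xs, ys, layer_dims, cfg.learning_rate, cfg.max_iterations,
            cfg.target_rmse, Ws, bs, mask,
        )
        out = chem._forward_many(Xs, Ws, bs)  # (R, n) scaled
        rmsecv = np.empty(n_runs)
        rc = np.empty(n_runs)
        for r in range(n_runs):
            pooled = np.empty(n)
            for j in range(n):
                f = labels[j]
                y_lo, y_hi = y_scales[f]
                pooled[j] = out[f * n_runs + r, j] * (y_hi - y_lo) + y_lo
            rmsecv[r] = rmse(y, pooled)
            rc[r] = pearson_r(y, pooled)
        rows.append(
            {
                "k": k,
                "rmsecv_mean": rmsecv.mean(),
                "rmsecv_var": rmsecv.var(ddof=1),
                "rmsecv_sd": rmsecv.std(ddof=1),
                "rc_mean": rc.mean(),
                "rc_var": rc.var(ddof=1),
                "rc_sd": rc.std(ddof=1),
            }
        )
        if rows[-1]["rmsecv_mean"] < best_rmsecv:  # strict: ties keep smaller k
            best_rmsecv = rows[-1]["rmsecv_mean"]
            best_k = k
    return PCOptimization(chosen_k=int(best_k), per_k=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# feature-level fusion


@dataclass(frozen=True)
class FusedFeatures:
    """Concatenated PC-score blocks, z-scored with training statistics."""

    matrix: np.ndarray
    train_mean: np.ndarray
    train_sd: np.ndarray

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def fuse(
    sensor_scores: np.ndarray,
    nir_scores: np.ndarray,
    train_mask: np.ndarray,
) -> FusedFeatures:
    """Concatenate two row-aligned score blocks and z-score each column
    with the training rows' mean and (n-1) standard deviation.

    Sensor and spectral PC scores live on different numeric scales;
    z-scoring puts the blocks on an equal footing before the fusion
    network sees them.
    """
    sensor_scores = np.atleast_2d(np.asarray(sensor_scores, dtype=float))
    nir_scores = np.atleast_2d(np.asarray(nir_scores, dtype=float))
    if sensor_scores.shape[1] == 0:
        sensor_scores = sensor_scores.reshape(nir_scores.shape[0], 0)
    if nir_scores.shape[1] == 0:
        nir_scores = nir_scores.reshape(sensor_scores.shape[0], 0)
    if sensor_scores.shape[0] != nir_scores.shape[0]:
        raise ValueError(
            f"row mismatch: {sensor_scores.shape[0]} vs {nir_scores.shape[0]}"
        )
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape[0] != sensor_scores.shape[0]:
        raise ValueError("train_mask length must match score rows")
    stacked = np.hstack([sensor_scores, nir_scores])
    mu = stacked[train_mask].mean(axis=0)
    sd = stacked[train_mask].std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise chem.DegenerateDataError("constant fused column on training rows")
    return FusedFeatures(
        matrix=(stacked - mu) / sd, train_mean=mu, train_sd=sd
    )


# ---------------------------------------------------------------------------
# experiment configuration and data assembly


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything the full experiment needs, reproducible from one seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    sensitivity: SensitivityMatrix = field(default_factory=default_sensitivity)
    signature: SpectralSignature = field(default_factory=default_signature)
    geometry: ArrayGeometry = field(default_factory=ArrayGeometry)
    sg_window: int = 11
    sg_order: int = 2
    bpnn: BPNNConfig = field(default_factory=BPNNConfig)
    folds: int = 5
    k_range: tuple[int, ...] = tuple(range(1, 11))
    n_runs: int = 50
    train_fraction: float = 0.75
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        """Build a config from a YAML mapping of the scalar fields.

        Recognized top-level keys: ``cohort`` (mapping of CohortConfig
        fields), ``bpnn`` (mapping of BPNNConfig fields), and the scalar
        experiment fields; instrument models keep their defaults.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**raw.pop("cohort"))
        if "bpnn" in raw:
            bp = raw.pop("bpnn")
            if "hidden_layers" in bp:
                bp["hidden_layers"] = tuple(bp["hidden_layers"])
            kwargs["bpnn"] = BPNNConfig(**bp)
        if "k_range" in raw:
            raw["k_range"] = tuple(raw.pop("k_range"))
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass(frozen=True)
class Dataset:
    """In-memory cohort with both modalities, row-aligned by sample."""

    ids: tuple[str, ...]
    months: np.ndarray
    y: np.ndarray  # fatty acid, mg/100 g
    sensor_features: np.ndarray  # n x 45 raw colour shifts
    spectra: np.ndarray  # n x 512 raw intensities
    wavelengths: np.ndarray
    samples: tuple[StorageSample, ...]

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("months", "y", "sensor_features", "spectra"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} rows do not match sample count {n}")


def build_synthetic_dataset(config: ExperimentConfig) -> Dataset:
    """Generate a cohort and measure it with both synthetic instruments,
    running the real image-extraction chain on every rendered pair."""
    samples = generate_cohort(config.cohort)
    seeds = sample_seeds(config.cohort)
    feats = np.empty((len(samples), len(FEATURE_NAMES)))
    spectra = np.empty((len(samples), config.signature.grid.size))
    for i, (s, sd) in enumerate(zip(samples, seeds)):
        before, after = render_sensor_pair(
            s, config.sensitivity, config.geometry, seed=sd["image"]
        )
        feats[i] = extract_pair_features(before, after).values
        spectra[i] = synth_spectrum(
            s.fatty_acid, config.signature, seed=sd["spectrum"]
        ).intensities
    return Dataset(
        ids=tuple(s.sample_id for s in samples),
        months=np.array([s.month for s in samples]),
        y=np.array([s.fatty_acid for s in samples]),
        sensor_features=feats,
        spectra=spectra,
        wavelengths=config.signature.grid.copy(),
        samples=tuple(samples),
    )


def load_dataset(manifest_path: str | Path) -> Dataset:
    """Assemble a dataset from an on-disk cohort (manifest + PNGs + CSVs),
    running the image-extraction chain on each pair."""
    from PIL import Image

    from .cohort import read_manifest

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = read_manifest(manifest_path)
    feats = []
    spectra = []
    wavelengths = None
    samples = []
    for _, row in manifest.iterrows():
        before = np.asarray(Image.open(root / row["before_image"]))
        after = np.asarray(Image.open(root / row["after_image"]))
        feats.append(extract_pair_features(before, after).values)
        spec = pd.read_csv(root / row["spectrum"])
        wavelengths = spec["wavelength_nm"].to_numpy()
        spectra.append(spec["intensity"].to_numpy())
        samples.append(
            StorageSample(
                sample_id=str(row["sample_id"]),
                month=int(row["month"]),
                bag=int(row["bag"]),
                fatty_acid=float(row["fatty_acid"]),
            )
        )
    return Dataset(
        ids=tuple(s.sample_id for s in samples),
        months=np.array([s.month for s in samples]),
        y=np.array([s.fatty_acid for s in samples]),
        sensor_features=np.array(feats),
        spectra=np.array(spectra),
        wavelengths=wavelengths,
        samples=tuple(samples),
    )


# ---------------------------------------------------------------------------
# the full experiment


@dataclass(frozen=True)
class ModalityBlock:
    """One modality's fitted reduction: features, train-fitted PCA, and
    the PC count chosen by the RMSECV scan."""

    name: str
    pca: PCAModel
    chosen_k: int
    optimization: PCOptimization
    evr_table: pd.DataFrame


@dataclass(frozen=True)
class TechniqueResult:
    """Repeated-run metrics for one technique row of the report."""

    name: str
    pcs: int
    stats: RunStats


@dataclass(frozen=True)
class FusionReport:
    """Comparison of the sensor-only, NIR-only and fusion calibrations."""

    techniques: tuple[TechniqueResult, ...]
    blocks: tuple[ModalityBlock, ...]
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Table of point estimates (means over runs) with dispersion.

        Columns mirror the usual comparison table: technique, PCs,
        training R_C / RMSE and prediction R_P / RMSEP, plus sample
        variance and standard deviation for each metric.
        """
        rows = []
        for t in self.techniques:
            mean, var, sd = t.stats.mean, t.stats.variance, t.stats.sd
            row: dict = {"technique": t.name, "pcs": t.pcs}
            for metric, col in [
                ("R_C", "r_c"),
                ("RMSEC", "rmsec"),
                ("R_P", "r_p"),
                ("RMSEP", "rmsep"),
            ]:
                row[metric] = mean[col]
                row[f"{metric}_var"] = var[col]
                row[f"{metric}_sd"] = sd[col]
            rows.append(row)
        return pd.DataFrame(rows)

    def technique(self, name: str) -> TechniqueResult:
        for t in self.techniques:
            if t.name == name:
                return t
        raise KeyError(name)

    def best_run(self, name: str) -> pd.Series:
        """Metrics of the single run with the lowest RMSEP."""
        v = self.technique(name).stats.values
        return v.loc[v["rmsep"].idxmin()]


def _train_eval_many(
    cfg: BPNNConfig,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Train one network per seed on (X_tr, y_tr) and evaluate on both
    partitions; identical to looping ``bpnn_train`` over the seeds."""
    x_lo, x_hi = X_tr.min(axis=0), X_tr.max(axis=0)
    y_lo, y_hi = float(y_tr.min()), float(y_tr.max())
    if y_hi == y_lo:
        raise chem.DegenerateDataError("target has zero range")
    R = len(seeds)
    Xs = np.broadcast_to(
        chem._minmax_scale(X_tr, x_lo, x_hi), (R, *X_tr.shape)
    )
    ys = np.broadcast_to((y_tr - y_lo) / (y_hi - y_lo), (R, len(y_tr)))
    layer_dims = [X_tr.shape[1], *cfg.hidden_layers, 1]
    Ws, bs = chem._init_params(layer_dims, list(seeds))
    chem._train_core(
        Xs, ys, layer_dims, cfg.learning_rate, cfg.max_iterations,
        cfg.target_rmse, Ws, bs,
    )
    pred_tr = chem._forward_many(Xs, Ws, bs) * (y_hi - y_lo) + y_lo
    Xs_te = np.broadcast_to(
        chem._minmax_scale(X_te, x_lo, x_hi), (R, *X_te.shape)
    )
    pred_te = chem._forward_many(Xs_te, Ws, bs) * (y_hi - y_lo) + y_lo
    rows = []
    for r in range(R):
        rows.append(
            {
                "r_c": pearson_r(y_tr, pred_tr[r]),
                "rmsec": rmse(y_tr, pred_tr[r]),
                "r_p": pearson_r(y_te, pred_te[r]),
                "rmsep": rmse(y_te, pred_te[r]),
            }
        )
    return pd.DataFrame(rows, index=list(seeds))


def run_full_experiment(
    config: ExperimentConfig | None = None,
    dataset: Dataset | None = None,
) -> FusionReport:
    """Run the complete fusion study and return the comparison report.

    All fitting — PCA means/loadings, min-max scalers, the PC-count
    choice — uses training rows only; prediction rows are transformed,
    never refit.  The three technique rows share the split and the
    final-model seed sequence, so their repeated-run metrics are paired.
    """
    config = config or ExperimentConfig()
    if dataset is None:
        dataset = build_synthetic_dataset(config)

    # spectral preprocessing (per spectrum, no cross-sample fitting)
    processed = np.empty_like(dataset.spectra)
    for i in range(dataset.spectra.shape[0]):
        processed[i] = preprocess(
            Spectrum(dataset.wavelengths, dataset.spectra[i]),
            window=config.sg_window,
            polyorder=config.sg_order,
        ).intensities

    split_seed, opt_sensor_seed, opt_nir_seed, final_seed = derive_seeds(
        config.seed, 4
    )
    train_ids, test_ids = split_by_month(
        dataset.samples, SplitSpec(config.train_fraction, split_seed)
    )
    id_index = {sid: i for i, sid in enumerate(dataset.ids)}
    tr_idx = np.array([id_index[s] for s in train_ids])
    te_idx = np.array([id_index[s] for s in test_ids])
    train_mask = np.zeros(len(dataset.ids), dtype=bool)
    train_mask[tr_idx] = True
    y = dataset.y

    modality_X = {"sensor": dataset.sensor_features, "nir": processed}
    opt_seeds = {"sensor": opt_sensor_seed, "nir": opt_nir_seed}
    blocks: list[ModalityBlock] = []
    scores: dict[str, np.ndarray] = {}
    for name in ("sensor", "nir"):
        X = modality_X[name]
        opt = optimize_pc_count(
            X[tr_idx],
            y[tr_idx],
            cfg=config.bpnn,
            k_range=config.k_range,
            n_runs=config.n_runs,
            folds=config.folds,
            seed=opt_seeds[name],
        )
        pca = pca_fit(X[tr_idx], opt.chosen_k)
        scores[name] = pca_transform(pca, X)
        # EVR table over the feasible spectrum of components (report analog
        # of the covariance-contribution plot)
        k_full = min(len(tr_idx) - 1, X.shape[1])
        evr = pca_fit(X[tr_idx], k_full).explained_variance_ratio
        evr_table = pd.DataFrame(
            {
                "pc": np.arange(1, k_full + 1),
                "evr": evr,
                "cumulative_evr": np.cumsum(evr),
            }
        )
        blocks.append(
            ModalityBlock(
                name=name,
                pca=pca,
                chosen_k=opt.chosen_k,
                optimization=opt,
                evr_table=evr_table,
            )
        )

    fused = fuse(scores["sensor"], scores["nir"], train_mask)
    final_run_seeds = derive_seeds(final_seed, config.n_runs)

    feature_sets = {
        "sensor": scores["sensor"],
        "nir": scores["nir"],
        "fusion": fused.matrix,
    }
    pcs = {
        "sensor": blocks[0].chosen_k,
        "nir": blocks[1].chosen_k,
        "fusion": blocks[0].chosen_k + blocks[1].chosen_k,
    }
    techniques = []
    for name, F in feature_sets.items():
        values = _train_eval_many(
            config.bpnn, F[tr_idx], y[tr_idx], F[te_idx], y[te_idx],
            final_run_seeds,
        )
        techniques.append(
            TechniqueResult(name=name, pcs=pcs[name], stats=RunStats(values))
        )
    return FusionReport(
        techniques=tuple(techniques),
        blocks=tuple(blocks),
        train_ids=tuple(train_ids),
        test_ids=tuple(test_ids),
        seed=config.seed,
    )
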