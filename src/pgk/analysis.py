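"""Field-level analysis: kernel-SVM stress classification, zone staging
and method comparison.

Classification uses a support vector machine on a precomputed kernel
under stratified k-fold cross-validation.  Everything data-dependent -
trait normalisation extrema, the median-heuristic bandwidth, grid-search
model selection - is fitted inside the training folds only, so held-out
folds never leak into model choice.

Zone staging follows the precision-agriculture reading of the kernel:
within a zone, healthy plants look alike (high mean pairwise PGK
similarity) while stress increases heterogeneity, so mean similarity
falls with severity.  Thresholding that mean at (0.80, 0.60) stages a
zone as Healthy / Mild Stress / Severe Stress.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoding import (
    CONDITIONS,
    DEFAULT_THRESHOLDS,
    RawTraitRecord,
    fit_normalization,
    normalize,
)
from .graphs import DEFAULT_EPSILON, PerceptualTraitGraph, build_deviation_graph
from .kernels import (
    embedding_matrix,
    median_sigma,
    pgk_cross,
    sp_kernel,
    wl_kernel,
)

__all__ = [
    "DEFAULT_STAGE_THRESHOLDS",
    "ClassificationResult",
    "ZoneReport",
    "FieldReport",
    "ComparisonResult",
    "compute_metrics",
    "cv_classify",
    "zone_similarity",
    "classify_zone",
    "stage_zones",
    "compare_methods",
    "field_report",
]

#: Zone staging thresholds (t_healthy, t_mild) on mean PGK similarity.
DEFAULT_STAGE_THRESHOLDS: tuple[float, float] = (0.80, 0.60)

#: Default PGK bandwidth for zone-level similarity; calibrated so the
#: synthetic generator's within-zone similarities land near the
#: reference ranges (healthy ~0.9, mild ~0.7, severe ~0.45).
DEFAULT_ZONE_SIGMA: float = 0.7

DEFAULT_C_GRID: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
DEFAULT_SIGMA_GRID: tuple = (0.1, 0.25, 0.5, 1.0, "median")
DEFAULT_H_GRID: tuple[int, ...] = (0, 1, 2)


def compute_metrics(confusion: np.ndarray) -> dict:
    """Classification metrics from a multiclass confusion matrix.

    Rows are true classes, columns predictions.  Accuracy is
    trace/total; precision, recall and F1 are computed one-vs-rest per
    class and macro-averaged.  A class with zero predicted (or actual)
    instances contributes 0 to the affected ratio.
    """
    M = np.asarray(confusion, dtype=float)
    if M.size == 0:
        raise ValueError("confusion matrix is empty")
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {M.shape}")
    if np.any(M < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    total = M.sum()
    if total == 0:
        raise ValueError("confusion matrix has no observations")
    tp = np.diag(M)
    pred = M.sum(axis=0)
    actual = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred > 0, tp / np.where(pred > 0, pred, 1), 0.0)
        recall = np.where(actual > 0, tp / np.where(actual > 0, actual, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return {
        "accuracy": float(tp.sum() / total),
        "precision": precision.tolist(),
        "recall": recall.tolist(),
        "f1": f1.tolist(),
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
    }


@dataclass
class ClassificationResult:
    """Cross-validated classification outcome."""

    kernel: str
    classes: tuple[str, ...]
    fold_confusions: list[np.ndarray]
    fold_metrics: list[dict]
    selected_params: list[dict]
    seed: int
    folds: int

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([m["accuracy"] for m in self.fold_metrics])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.fold_metrics) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        """mean +/- sd of each metric across folds."""
        rows = {}
        for key in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
            vals = np.array([m[key] for m in self.fold_metrics])
            rows[key] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        return pd.DataFrame(rows).T


def _class_order(labels: Sequence[str]) -> tuple[str, ...]:
    seen = set(labels)
    ordered = [c for c in CONDITIONS if c in seen]
    ordered += sorted(seen - set(ordered))
    return tuple(ordered)


def _confusion(y_true, y_pred, classes) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[idx[t], idx[p]] += 1
    return M


def _perceptual_vectors(
    records: Sequence[RawTraitRecord],
    train_idx: np.ndarray | None = None,
    assume_perceptual: bool = False,
):
    """Turn raw records into perceptual vectors.

    With ``assume_perceptual`` the raw values are taken as intensities
    already in [0, 1] (e.g. the synthetic generator's output) and used
    directly.  Otherwise a min-max model is fitted - on the training
    subset only when ``train_idx`` is given, so held-out records are
    clamped rather than influencing the extrema.

    Re-normalising already-perceptual values is not merely redundant:
    because the deviation embedding is invariant to the global
    inversion p -> 1 - p, stretching a symmetric class layout to the
    full [0, 1] range can alias the two extreme classes.
    """
    from .encoding import TRAIT_CODES, PerceptualTraitVector

    if assume_perceptual:
        vectors = []
        for r in records:
            vals = np.array([r.values[c] for c in TRAIT_CODES])
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(
                    f"record {r.plant_id!r} has values outside [0, 1]; "
                    "it is not already perceptual"
                )
            vectors.append(
                PerceptualTraitVector(
                    owner_id=r.plant_id,
                    intensities=vals,
                    traits=TRAIT_CODES,
                    zone_id=r.zone_id,
                )
            )
        return vectors
    fit_on = records if train_idx is None else [records[i] for i in train_idx]
    model = fit_normalization(fit_on)
    return [normalize(model, r) for r in records]


def _fold_kernels(
    records: Sequence[RawTraitRecord],
    train_idx: np.ndarray,
    kernel: str,
    epsilon: float,
    thresholds: tuple[float, float],
    augmented: bool,
    sigma_grid,
    h_grid,
    bin_width: float,
    assume_perceptual: bool = False,
):
    """Per-fold kernel construction with train-only fitting.

    Returns (param_combos, kernel_for) where ``kernel_for(combo)``
    yields the full n x n kernel matrix under that hyperparameter
    choice.  Normalisation extrema and the median-heuristic sigma are
    estimated on the training records only.
    """
    vectors = _perceptual_vectors(records, train_idx, assume_perceptual)
    if kernel in ("pgk", "pgk-linear", "wl", "sp"):
        graphs = [build_deviation_graph(v, epsilon, thresholds) for v in vectors]
    if kernel == "pgk":
        X = embedding_matrix(graphs, augmented=augmented)
        sig_med = median_sigma(X[train_idx])
        sigmas = [sig_med if s == "median" else float(s) for s in sigma_grid]
        combos = [{"sigma": s} for s in sigmas]
        cache: dict[float, np.ndarray] = {}

        def kernel_for(combo):
            s = combo["sigma"]
            if s not in cache:
                cache[s] = pgk_cross(X, X, sigma=s, variant="rbf")
            return cache[s]

    elif kernel == "pgk-linear":
        X = embedding_matrix(graphs, augmented=augmented)
        K = X @ X.T
        combos = [{}]

        def kernel_for(combo):
            return K

    elif kernel == "wl":
        mats = {h: wl_kernel(graphs, h=h, normalised=True).values for h in h_grid}
        combos = [{"h": h} for h in h_grid]

        def kernel_for(combo):
            return mats[combo["h"]]

    elif kernel == "sp":
        K = sp_kernel(graphs, bin_width=bin_width, normalised=True).values
        combos = [{"bin_width": bin_width}]

        def kernel_for(combo):
            return K

    elif kernel == "linear-traits":
        # ablation baseline: linear kernel on continuous perceptual
        # vectors, bypassing graphs and discretisation entirely
        P = np.stack([v.intensities for v in vectors])
        K = P @ P.T
        combos = [{}]

        def kernel_for(combo):
            return K

    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return combos, kernel_for


def cv_classify(
    records: Sequence[RawTraitRecord],
    kernel: str = "pgk",
    folds: int = 5,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    sigma_grid: Sequence = DEFAULT_SIGMA_GRID,
    h_grid: Sequence[int] = DEFAULT_H_GRID,
    bin_width: float = 0.1,
    inner_folds: int = 3,
    augmented: bool = False,
    labels: Sequence[str] | None = None,
    assume_perceptual: bool = False,
) -> ClassificationResult:
    """Stratified k-fold kernel-SVM classification with inner grid search.

    ``kernel`` is one of ``pgk`` (RBF on the interaction embedding,
    sigma grid-searched), ``pgk-linear``, ``wl`` (h grid-searched),
    ``sp`` or ``linear-traits`` (continuous-vector ablation baseline).
    ``labels`` overrides the records' condition labels (e.g. for
    permutation tests).  ``assume_perceptual`` skips per-fold min-max
    refitting when raw values are already intensities in [0, 1].
    Deterministic given ``seed``.
    """
    records = list(records)
    y = list(labels) if labels is not None else [r.condition for r in records]
    if any(l is None for l in y):
        raise ValueError("all records must carry a condition label")
    if len(records) < folds:
        raise ValueError(f"need at least {folds} records for {folds}-fold CV")
    classes = _class_order(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = {c: y.count(c) for c in classes}
    thin = [c for c, n in counts.items() if n < folds]
    if thin:
        raise ValueError(
            f"classes with fewer members than folds={folds}: {thin}"
        )
    y_arr = np.asarray(y)
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    inner_seed = seed + 1

    fold_confusions, fold_metrics, selected = [], [], []
    for train_idx, test_idx in outer.split(np.zeros(len(records)), y_arr):
        combos, kernel_for = _fold_kernels(
            records, train_idx, kernel, epsilon, thresholds,
            augmented, sigma_grid, h_grid, bin_width, assume_perceptual,
        )
        # inner grid search on the training fold only; grid order breaks
        # ties toward smaller C, then the earlier kernel parameter
        best, best_score = None, -np.inf
        inner = StratifiedKFold(
            n_splits=inner_folds, shuffle=True, random_state=inner_seed
        )
        inner_splits = list(inner.split(np.zeros(len(train_idx)), y_arr[train_idx]))
        for C in C_grid:
            for combo in combos:
                K = kernel_for(combo)
                scores = []
                for tr, va in inner_splits:
                    tr_i, va_i = train_idx[tr], train_idx[va]
                    clf = SVC(kernel="precomputed", C=C)
                    clf.fit(K[np.ix_(tr_i, tr_i)], y_arr[tr_i])
                    pred = clf.predict(K[np.ix_(va_i, tr_i)])
                    scores.append(float(np.mean(pred == y_arr[va_i])))
                score = float(np.mean(scores))
                if score > best_score:
                    best_score, best = score, {"C": C, **combo}
        K = kernel_for({k: v for k, v in best.items() if k != "C"})
        clf = SVC(kernel="precomputed", C=best["C"])
        clf.fit(K[np.ix_(train_idx, train_idx)], y_arr[train_idx])
        pred = clf.predict(K[np.ix_(test_idx, train_idx)])
        M = _confusion(y_arr[test_idx], pred, classes)
        fold_confusions.append(M)
        fold_metrics.append(compute_metrics(M))
        selected.append(best)

    return ClassificationResult(
        kernel=kernel,
        classes=classes,
        fold_confusions=fold_confusions,
        fold_metrics=fold_metrics,
        selected_params=selected,
        seed=seed,
        folds=folds,
    )


# ---------------------------------------------------------------------------
# Zone-level staging


def zone_similarity(
    graphs: Sequence[PerceptualTraitGraph],
    sigma: float = DEFAULT_ZONE_SIGMA,
    variant: str = "rbf",
    augmented: bool = False,
) -> float:
    """Mean pairwise PGK similarity among one zone's plant graphs."""
    if len(graphs) < 2:
        raise ValueError(
            f"zone similarity needs at least 2 plants, got {len(graphs)}"
        )
    X = embedding_matrix(list(graphs), augmented=augmented)
    K = pgk_cross(X, X, sigma=sigma, variant=variant)
    iu = np.triu_indices(len(graphs), k=1)
    return float(K[iu].mean())


def classify_zone(
    similarity: float,
    thresholds: tuple[float, float] = DEFAULT_STAGE_THRESHOLDS,
) -> str:
    """Stage a zone from its mean similarity.

    similarity >= t_healthy -> Healthy; >= t_mild -> Mild Stress;
    otherwise Severe Stress.  Boundaries are inclusive.
    """
    t_healthy, t_mild = thresholds
    if not t_healthy > t_mild:
        raise ValueError(
            f"thresholds must satisfy t_healthy > t_mild, got {thresholds}"
        )
    if similarity >= t_healthy:
        return "Healthy"
    if similarity >= t_mild:
        return "Mild Stress"
    return "Severe Stress"


@dataclass
class ZoneReport:
    """Staging outcome for one zone."""

    acre_id: str
    zone_id: str
    similarity: float
    status: str
    thresholds: tuple[float, float] = DEFAULT_STAGE_THRESHOLDS


def stage_zones(
    records: Sequence[RawTraitRecord],
    epsilon: float = DEFAULT_EPSILON,
    sigma: float = DEFAULT_ZONE_SIGMA,
    stage_thresholds: tuple[float, float] = DEFAULT_STAGE_THRESHOLDS,
    state_thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    assume_perceptual: bool = False,
) -> list[ZoneReport]:
    """Stage every zone in a trait table.

    With ``assume_perceptual`` raw values are taken as intensities in
    [0, 1] directly; otherwise a normalisation model is fitted over the
    whole table first.
    """
    records = list(records)
    vectors = _perceptual_vectors(records, None, assume_perceptual)
    by_zone: dict[tuple[str, str], list] = {}
    for rec, vec in zip(records, vectors):
        by_zone.setdefault((rec.acre_id, rec.zone_id), []).append(vec)
    reports = []
    for (acre, zone), vecs in by_zone.items():
        graphs = [build_deviation_graph(v, epsilon, state_thresholds) for v in vecs]
        sim = zone_similarity(graphs, sigma=sigma)
        reports.append(
            ZoneReport(
                acre_id=acre,
                zone_id=zone,
                similarity=sim,
                status=classify_zone(sim, stage_thresholds),
                thresholds=stage_thresholds,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Method comparison


@dataclass
class ComparisonResult:
    """Paired comparison of classification methods."""

    table: pd.DataFrame
    pvalues: dict[tuple[str, str], float]
    test: str
    n: int
    low_power: bool


def _paired_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    diff = a - b
    if np.all(diff == 0):
        return 1.0
    if test == "wilcoxon":
        return float(stats.wilcoxon(a, b).pvalue)
    if test == "ttest":
        return float(stats.ttest_rel(a, b).pvalue)
    raise ValueError(f"unknown test {test!r}")


def compare_methods(
    results: Mapping[str, Sequence],
    test: str = "wilcoxon",
) -> ComparisonResult:
    """Compare methods evaluated on identical seed/partition sequences.

    ``results`` maps method name to a sequence of per-seed outcomes,
    either :class:`ClassificationResult` objects or plain mean-accuracy
    floats.  Returns the mean +/- sd table and paired two-sided p-values
    per method pair; fewer than 6 paired observations raises the
    ``low_power`` flag.
    """
    if len(results) < 2:
        raise ValueError("need at least two methods to compare")
    accs: dict[str, np.ndarray] = {}
    seeds: dict[str, tuple] = {}
    for name, seq in results.items():
        seq = list(seq)
        if seq and isinstance(seq[0], ClassificationResult):
            accs[name] = np.array([r.mean_accuracy for r in seq])
            seeds[name] = tuple(r.seed for r in seq)
        else:
            accs[name] = np.asarray(seq, dtype=float)
            seeds[name] = ()
    lengths = {len(a) for a in accs.values()}
    if len(lengths) > 1:
        raise ValueError("methods were evaluated on different numbers of runs")
    seed_seqs = {s for s in seeds.values() if s}
    if len(seed_seqs) > 1:
        raise ValueError("methods were evaluated on mismatched seed partitions")
    n = lengths.pop()
    table = pd.DataFrame(
        {
            name: {"mean": float(a.mean()), "sd": float(a.std(ddof=1)) if n > 1 else 0.0}
            for name, a in accs.items()
        }
    ).T
    pvalues = {
        (a, b): _paired_p(accs[a], accs[b], test)
        for a, b in combinations(accs, 2)
    }
    return ComparisonResult(
        table=table, pvalues=pvalues, test=test, n=n, low_power=n < 6
    )


# ---------------------------------------------------------------------------
# Field report


@dataclass
class FieldReport:
    """Acre x zone status grid plus the underlying table."""

    table: pd.DataFrame

    def status_grid(self) -> pd.DataFrame:
        return self.table.pivot(index="acre_id", columns="zone_id", values="status")

    def similarity_grid(self) -> pd.DataFrame:
        return self.table.pivot(
            index="acre_id", columns="zone_id", values="similarity"
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def heatmap(self, path) -> None:
        """Save a similarity heatmap annotated with statuses."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        grid = self.similarity_grid()
        fig, ax = plt.subplots(figsize=(1.2 * max(grid.shape[1], 3), 2.5))
        im = ax.imshow(grid.to_numpy(), cmap="RdYlGn", vmin=0.0, vmax=1.0)
        ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=45, ha="right")
        ax.set_yticks(range(grid.shape[0]), grid.index)
        fig.colorbar(im, ax=ax, label="mean PGK similarity")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def field_report(zone_reports: Sequence[ZoneReport]) -> FieldReport:
    """Assemble zone reports into a field-level grid; each (acre, zone)
    may appear only once."""
    seen = set()
    rows = []
    for zr in zone_reports:
        key = (zr.acre_id, zr.zone_id)
        if key in seen:
            raise ValueError(f"duplicate zone in report: {key}")
        seen.add(key)
        rows.append(
            {
                "acre_id": zr.acre_id,
                "zone_id": zr.zone_id,
                "similarity": zr.similarity,
                "status": zr.status,
            }
        )
    columns = ["acre_id", "zone_id", "similarity", "status"]
    return FieldReport(table=pd.DataFrame(rows, columns=columns))
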