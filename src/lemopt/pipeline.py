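"""miRNA-expression subtype classification pipeline.

Stages, in the order they run:

1. load an expression table (samples x features, one label column),
2. preprocess: drop zero-variance genes, log2(x + 1) transform,
3. pairwise differential expression over all unordered class pairs
   (Welch two-sample t per gene on the log2 scale, Benjamini-Hochberg
   within contrast; a gene is selected when BH-adjusted p < 0.05 and
   |log2FC| > 1 in at least one contrast),
4. stratified 80/20 train/test split with train-fitted standardisation,
5. AHALA-tuned multilayer-perceptron classifier — the optimizer searches
   (learning rate, batch size, hidden size) and the fitness is validation
   accuracy of a net early-stopped on validation loss,
6. one-vs-rest multi-class evaluation (TPR/FPR/precision/F1 per class,
   overall accuracy, ROC/PRC AUCs, confusion matrix) plus permutation
   feature importance and label-specific median imputation for external
   cohorts missing some features.

The differential-expression statistic is a self-contained unequal-variance
two-sample t test; a moderated (empirical-Bayes) linear model would share
information across genes and can select slightly different gene sets on the
same thresholds.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix as _sk_confusion,
    log_loss,
    roc_auc_score,
)
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .optimizer import AHALAConfig, OptimizationTrace, SearchSpace, run_ahala

__all__ = [
    "ExpressionDataset",
    "ContrastResult",
    "ClassMetrics",
    "SplitData",
    "HYPERPARAM_SPACE",
    "load_expression",
    "preprocess",
    "pairwise_dge",
    "selected_features",
    "benjamini_hochberg",
    "split_and_standardize",
    "decode_hyperparams",
    "dnn_fitness",
    "train_classifier",
    "optimize_hyperparams",
    "classification_metrics",
    "feature_importance",
    "impute_missing_features",
    "run_subtype_pipeline",
    "PipelineResult",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Samples x features expression matrix with per-sample class labels."""

    X: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.X.columns.duplicated().any():
            dup = self.X.columns[self.X.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name: {dup!r}")
        if not self.labels.index.equals(self.X.index):
            self.labels = self.labels.reindex(self.X.index)
            if self.labels.isna().any():
                raise ValueError("labels do not cover all samples")
        if self.labels.nunique() < 2:
            raise ValueError("need at least 2 classes")

    @property
    def class_names(self) -> List[str]:
        """Class labels in lexicographic order (the encoding order)."""
        return sorted(self.labels.unique())

    @property
    def feature_names(self) -> List[str]:
        return list(self.X.columns)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class ContrastResult:
    """Per-gene differential-expression statistics for one class pair.

    ``table`` is indexed by feature with columns ``log2fc`` (mean class-A
    minus mean class-B on the log2 scale), ``pvalue``, ``adj_pvalue``
    (Benjamini-Hochberg within this contrast) and the boolean ``is_deg``
    (adjusted p < alpha and |log2FC| > the fold-change threshold).
    """

    contrast: Tuple[str, str]
    table: pd.DataFrame
    alpha: float = 0.05
    lfc_threshold: float = 1.0


@dataclass
class SplitData:
    """Standardised design matrix with integer-encoded labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: List[str]
    class_names: List[str]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# Loading and preprocessing
# ---------------------------------------------------------------------------

def load_expression(path: str, label_column: str = "subtype") -> ExpressionDataset:
    """Read a CSV/TSV expression table (samples x features + label column).

    The delimiter is taken from the extension (``.tsv``/``.txt`` -> tab).
    The first column is used as the sample index.  Missing or non-numeric
    expression cells raise a parse error naming the offending row/column.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if label_column not in df.columns:
        raise ValueError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {list(df.columns[:5])}...)"
        )
    labels = df[label_column].astype(str)
    X = df.drop(columns=[label_column])
    for col in X.columns:
        numeric = pd.to_numeric(X[col], errors="coerce")
        bad = numeric.isna() & X[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"{path}: non-numeric value {X.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        if numeric.isna().any():
            row = numeric.isna().idxmax()
            raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
        X[col] = numeric
    return ExpressionDataset(X=X, labels=labels)


def preprocess(
    ds: ExpressionDataset,
    low_variance_quantile: Optional[float] = None,
) -> ExpressionDataset:
    """Drop zero-variance genes and log2(x + 1)-transform the matrix.

    Expression values must be nonnegative.  ``low_variance_quantile``
    optionally drops the given lowest-variance fraction of the remaining
    genes (off by default: zero-variance filtering only).
    """
    if (ds.X.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    variances = ds.X.var(axis=0, ddof=0)
    keep = variances > 0
    X = ds.X.loc[:, keep]
    if low_variance_quantile:
        cutoff = X.var(axis=0, ddof=0).quantile(low_variance_quantile)
        X = X.loc[:, X.var(axis=0, ddof=0) > cutoff]
    X = np.log2(X + 1.0)
    return ExpressionDataset(X=X, labels=ds.labels.copy())


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    ``adj[i] = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j)``,
    capped at 1, returned in the original order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def pairwise_dge(
    ds: ExpressionDataset,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> List[ContrastResult]:
    """Differential expression for every unordered class pair.

    Expects a preprocessed (log2-scale) dataset.  Per gene and contrast
    (A, B): log2FC = mean_A - mean_B and p from Welch's unequal-variance
    two-sample t; BH adjustment is applied within each contrast.  Genes
    with an undefined statistic (both groups constant) get p = 1.
    Contrasts where either class has fewer than 2 samples are skipped with
    a warning.
    """
    results: List[ContrastResult] = []
    X = ds.X
    for a, b in combinations(ds.class_names, 2):
        A = X[ds.labels == a].to_numpy()
        B = X[ds.labels == b].to_numpy()
        if len(A) < 2 or len(B) < 2:
            warnings.warn(
                f"contrast ({a}, {b}) skipped: a class has < 2 samples",
                stacklevel=2,
            )
            continue
        log2fc = A.mean(axis=0) - B.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(A, B, axis=0, equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        adj = benjamini_hochberg(pvals)
        table = pd.DataFrame(
            {
                "log2fc": log2fc,
                "pvalue": pvals,
                "adj_pvalue": adj,
                "is_deg": (adj < alpha) & (np.abs(log2fc) > lfc_threshold),
            },
            index=X.columns,
        )
        results.append(
            ContrastResult(contrast=(a, b), table=table, alpha=alpha, lfc_threshold=lfc_threshold)
        )
    return results


def selected_features(contrasts: Sequence[ContrastResult]) -> List[str]:
    """Union of genes flagged in at least one contrast, in matrix order."""
    flagged: set = set()
    order: List[str] = []
    for cr in contrasts:
        for feat in cr.table.index[cr.table["is_deg"]]:
            if feat not in flagged:
                flagged.add(feat)
                order.append(feat)
    # keep a deterministic order: as first flagged across contrasts would
    # depend on contrast order; sort by the first contrast's feature order
    if contrasts:
        ref = [f for f in contrasts[0].table.index if f in flagged]
        extra = [f for f in order if f not in set(ref)]
        return ref + extra
    return order


# ---------------------------------------------------------------------------
# Split and standardisation
# ---------------------------------------------------------------------------

def split_and_standardize(
    ds: ExpressionDataset,
    train_frac: float = 0.8,
    seed: int = 42,
    features: Optional[Sequence[str]] = None,
) -> Tuple[SplitData, SplitData, StandardScaler]:
    """Stratified train/test split with train-fitted standardisation.

    Class labels are encoded to integers 0..K-1 in lexicographic order.
    The scaler (zero mean, unit variance per feature) is fitted on the
    training portion only and applied to both.  231 samples at the default
    80% fraction yield 184 train / 47 test.
    """
    counts = ds.class_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes too small to stratify: {small}")
    classes = ds.class_names
    X = ds.X[list(features)] if features is not None else ds.X
    code = {c: i for i, c in enumerate(classes)}
    y = ds.labels.map(code).to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X.to_numpy(), y, train_size=train_frac, stratify=y, random_state=seed
    )
    scaler = StandardScaler().fit(X_tr)
    feat = list(X.columns)
    train = SplitData(scaler.transform(X_tr), y_tr, feat, classes)
    test = SplitData(scaler.transform(X_te), y_te, feat, classes)
    return train, test, scaler


# ---------------------------------------------------------------------------
# Hyperparameter space and the neural-network fitness
# ---------------------------------------------------------------------------

#: (learning rate, batch size, hidden size); the last two decode as integers
HYPERPARAM_SPACE = SearchSpace(
    lb=np.array([0.0001, 16.0, 64.0]),
    ub=np.array([0.01, 128.0, 512.0]),
    integer_mask=np.array([False, True, True]),
)


def decode_hyperparams(
    x: Sequence[float], space: SearchSpace = HYPERPARAM_SPACE
) -> Tuple[float, int, int]:
    """Clamp a raw search vector into bounds and round integer dimensions."""
    x = np.clip(np.asarray(x, dtype=float), space.lb, space.ub)
    x[space.integer_mask] = np.rint(x[space.integer_mask])
    lr, batch, hidden = x
    return float(lr), int(batch), int(hidden)


def _train_mlp(
    params: Tuple[float, int, int],
    train: SplitData,
    val: SplitData,
    seed: int,
    max_epochs: int = 100,
    patience: int = 10,
) -> Tuple[MLPClassifier, float]:
    """Train the MLP with Adam + cross-entropy and val-loss early stopping.

    Architecture: three fully connected extractor layers of widths
    (h, h/2, h/4) with ReLU, then a two-layer classifier head
    (h/4 -> h/4 -> K).  Returns the fitted net (best-validation-loss
    weights restored) and its validation accuracy.
    """
    lr, batch, hidden = params
    n_classes = len(train.class_names)
    if hidden // 4 < n_classes:
        warnings.warn(
            f"hidden size {hidden} too narrow for {n_classes} classes; widened",
            stacklevel=2,
        )
        hidden = 4 * n_classes
    batch = min(batch, train.n_samples)  # cap at the training-set size
    layers = (hidden, max(hidden // 2, 2), max(hidden // 4, 2), max(hidden // 4, 2))
    clf = MLPClassifier(
        hidden_layer_sizes=layers,
        activation="relu",
        solver="adam",
        learning_rate_init=lr,
        max_iter=1,
        random_state=seed,
    )
    rng = np.random.default_rng(seed)
    classes = np.arange(n_classes)
    best_loss = np.inf
    best_weights = None
    stall = 0
    n = train.n_samples
    for _epoch in range(max_epochs):
        idx = rng.permutation(n)
        for start in range(0, n, batch):
            sl = idx[start : start + batch]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # per-minibatch convergence chatter
                clf.partial_fit(train.X[sl], train.y[sl], classes=classes)
        val_loss = log_loss(val.y, clf.predict_proba(val.X), labels=classes)
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_weights = (
                [c.copy() for c in clf.coefs_],
                [b.copy() for b in clf.intercepts_],
            )
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    if best_weights is not None:
        clf.coefs_, clf.intercepts_ = best_weights
    acc = float((clf.predict(val.X) == val.y).mean())
    return clf, acc


def dnn_fitness(
    params: Tuple[float, int, int],
    train: SplitData,
    val: SplitData,
    seed: int = 42,
    max_epochs: int = 100,
    patience: int = 10,
) -> float:
    """Validation accuracy of the net trained under ``params`` (in [0, 1]).

    Deterministic under a fixed seed.  This is the quantity the optimizer
    maximises (it is negated internally for the minimisation convention).
    """
    _, acc = _train_mlp(params, train, val, seed, max_epochs, patience)
    return acc


def train_classifier(
    params: Tuple[float, int, int],
    train: SplitData,
    val: SplitData,
    seed: int = 42,
    max_epochs: int = 100,
    patience: int = 10,
) -> MLPClassifier:
    """Fit and return the MLP under the given hyperparameters."""
    clf, _ = _train_mlp(params, train, val, seed, max_epochs, patience)
    return clf


def optimize_hyperparams(
    train: SplitData,
    val: SplitData,
    config: AHALAConfig,
    space: SearchSpace = HYPERPARAM_SPACE,
    max_epochs: int = 100,
    patience: int = 10,
) -> Tuple[Tuple[float, int, int], float, OptimizationTrace]:
    """AHALA search over (learning rate, batch size, hidden size).

    Returns the decoded best configuration, its validation accuracy and
    the optimization trace (best-so-far curve on the negated-accuracy
    scale).  The fitness budget is ``N*(Tmax+1) + floor(Tmax/k)*M*n_elite``
    network trainings.
    """

    def objective(x: np.ndarray) -> float:
        decoded = decode_hyperparams(x, space)
        return -dnn_fitness(decoded, train, val, seed=config.seed,
                            max_epochs=max_epochs, patience=patience)

    z_best, f_best, trace = run_ahala(objective, space, config)
    return decode_hyperparams(z_best, space), -f_best, trace


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    """One-vs-rest multi-class evaluation report.

    ``per_class`` has one row per class with TP/FP/TN/FN counts, TPR
    (recall), FPR, precision, F1 and — when probability scores were given —
    one-vs-rest ROC AUC and average precision.  Classes absent from the
    true labels get NaN metrics.
    """

    per_class: pd.DataFrame
    accuracy: float
    confusion: pd.DataFrame
    macro_roc_auc: float = float("nan")
    macro_pr_auc: float = float("nan")
    micro_pr_auc: float = float("nan")

    def normalized_confusion(self) -> pd.DataFrame:
        row_sums = self.confusion.sum(axis=1).replace(0, np.nan)
        return self.confusion.div(row_sums, axis=0)


def classification_metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    scores: Optional[np.ndarray] = None,
    class_names: Optional[Sequence[str]] = None,
) -> ClassMetrics:
    """Compute the one-vs-rest evaluation suite.

    ``scores`` (samples x classes predicted probabilities) enables the
    ROC/PRC AUCs; without it only the count-based metrics are filled.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    if class_names is None:
        K = int(max(y_true.max(), y_pred.max())) + 1
        class_names = [str(c) for c in range(K)]
    K = len(class_names)
    cm = _sk_confusion(y_true, y_pred, labels=np.arange(K))
    N = cm.sum()
    rows = []
    for c in range(K):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = N - tp - fn - fp
        support = tp + fn
        if support == 0:
            rows.append(dict(TP=tp, FP=fp, TN=tn, FN=fn, TPR=np.nan, FPR=np.nan,
                             precision=np.nan, F1=np.nan, support=0))
            continue
        tpr = tp / support
        fpr = fp / (fp + tn) if (fp + tn) else np.nan
        prec = tp / (tp + fp) if (tp + fp) else np.nan
        if np.isnan(prec):
            f1 = np.nan
        elif prec + tpr == 0:
            f1 = 0.0
        else:
            f1 = 2 * prec * tpr / (prec + tpr)
        rows.append(dict(TP=tp, FP=fp, TN=tn, FN=fn, TPR=tpr, FPR=fpr,
                         precision=prec, F1=f1, support=support))
    per_class = pd.DataFrame(rows, index=list(class_names))
    accuracy = float(np.trace(cm) / N)
    confusion = pd.DataFrame(cm, index=list(class_names), columns=list(class_names))

    macro_roc = macro_pr = micro_pr = float("nan")
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        roc, pr = [], []
        onehot = np.zeros_like(scores)
        onehot[np.arange(y_true.size), y_true] = 1.0
        for c in range(K):
            pos = y_true == c
            if pos.any() and (~pos).any():
                roc.append(roc_auc_score(pos, scores[:, c]))
                pr.append(average_precision_score(pos, scores[:, c]))
                per_class.loc[class_names[c], "roc_auc"] = roc[-1]
                per_class.loc[class_names[c], "pr_auc"] = pr[-1]
            else:
                per_class.loc[class_names[c], "roc_auc"] = np.nan
                per_class.loc[class_names[c], "pr_auc"] = np.nan
        macro_roc = float(np.mean(roc)) if roc else float("nan")
        macro_pr = float(np.mean(pr)) if pr else float("nan")
        micro_pr = float(
            average_precision_score(onehot.ravel(), scores.ravel())
        )
    return ClassMetrics(
        per_class=per_class,
        accuracy=accuracy,
        confusion=confusion,
        macro_roc_auc=macro_roc,
        macro_pr_auc=macro_pr,
        micro_pr_auc=micro_pr,
    )


def feature_importance(
    model,
    X_val: np.ndarray,
    y_val: np.ndarray,
    feature_names: Sequence[str],
    n_repeats: int = 10,
    seed: int = 42,
) -> pd.DataFrame:
    """Permutation importance: accuracy drop when one feature is shuffled.

    Returns a DataFrame (feature, importance) sorted descending by the
    mean accuracy drop over ``n_repeats`` shuffles.  Reproducible under a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val)
    base = float((model.predict(X_val) == y_val).mean())
    importances = np.zeros(X_val.shape[1])
    for j in range(X_val.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Xp = X_val.copy()
            Xp[:, j] = Xp[rng.permutation(X_val.shape[0]), j]
            drops.append(base - float((model.predict(Xp) == y_val).mean()))
        importances[j] = np.mean(drops)
    out = pd.DataFrame({"feature": list(feature_names), "importance": importances})
    return out.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)


def impute_missing_features(
    external_X: pd.DataFrame,
    external_labels: pd.Series,
    reference: ExpressionDataset,
    missing: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fill features absent from an external cohort with label-specific medians.

    Each missing cell receives the median of that feature over reference
    samples of the *same class*; present features are untouched.  The
    returned frame carries the reference feature order.  An external class
    absent from the reference raises an error.
    """
    if missing is None:
        missing = [f for f in reference.feature_names if f not in external_X.columns]
    unknown = set(external_labels.unique()) - set(reference.class_names)
    if unknown:
        raise ValueError(f"classes absent from the reference: {sorted(unknown)}")
    out = external_X.copy()
    for feat in missing:
        if feat not in reference.X.columns:
            raise ValueError(f"feature {feat!r} not present in the reference")
        medians = reference.X[feat].groupby(reference.labels).median()
        out[feat] = external_labels.map(medians).to_numpy()
    return out[[f for f in reference.feature_names if f in out.columns]]


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    contrasts: List[ContrastResult]
    selected: List[str]
    best_params: Tuple[float, int, int]
    val_accuracy: float
    test_metrics: ClassMetrics
    importance: pd.DataFrame
    trace: OptimizationTrace
    model: MLPClassifier = field(repr=False, default=None)


def run_subtype_pipeline(
    ds: ExpressionDataset,
    config: Optional[AHALAConfig] = None,
    seed: int = 42,
    val_frac: float = 0.2,
    importance_repeats: int = 5,
) -> PipelineResult:
    """Run the full pipeline on a raw (nonnegative) expression dataset.

    Preprocess, select genes by pairwise differential expression, split
    80/20 (stratified), carve a further stratified validation fold (20% of
    the training portion) for early stopping and the optimizer fitness,
    tune (learning rate, batch size, hidden size) with AHALA, refit under
    the best configuration and evaluate once on the held-out test set.
    """
    if config is None:
        config = AHALAConfig(N=10, Tmax=20, seed=seed)
    prepped = preprocess(ds)
    contrasts = pairwise_dge(prepped)
    genes = selected_features(contrasts)
    if not genes:
        raise ValueError("no differentially expressed genes selected")
    train_full, test, _scaler = split_and_standardize(
        prepped, train_frac=0.8, seed=seed, features=genes
    )
    X_fit, X_val, y_fit, y_val = train_test_split(
        train_full.X, train_full.y, train_size=1.0 - val_frac,
        stratify=train_full.y, random_state=seed,
    )
    fit = SplitData(X_fit, y_fit, genes, train_full.class_names)
    val = SplitData(X_val, y_val, genes, train_full.class_names)
    best_params, val_acc, trace = optimize_hyperparams(fit, val, config)
    model = train_classifier(best_params, fit, val, seed=config.seed)
    scores = model.predict_proba(test.X)
    metrics = classification_metrics(
        test.y, model.predict(test.X), scores=scores, class_names=test.class_names
    )
    importance = feature_importance(
        model, val.X, val.y, genes, n_repeats=importance_repeats, seed=seed
    )
    return PipelineResult(
        contrasts=contrasts,
        selected=genes,
        best_params=best_params,
        val_accuracy=val_acc,
        test_metrics=metrics,
        importance=importance,
        trace=trace,
        model=model,
    )
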