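"""Species classification from elliptic Fourier features.

The identification model is a soft-margin multi-class SVM (C-SVC,
one-vs-one) with an RBF kernel whose two hyperparameters (penalty C and
kernel width gamma) are found by a genetic algorithm maximizing stratified
k-fold cross-validation accuracy on the training split.  Validation repeats
the whole procedure over several random stratified 1:1 train/test splits and
aggregates per-run CV/test accuracy, pooled per-species accuracy, and the
pairwise misidentification-rate matrix

    P_e(A -> B) = 100 * (sum over runs of E_AB) / S_A,

where E_AB counts test specimens of species A predicted as B in one run and
S_A is, by default, the total number of A specimens tested across runs (the
only divisor under which per-species accuracy and misidentification rates
partition 100%); a whole-sample divisor is available behind
``misid_denominator='global'``.

Feature tables throughout are pandas DataFrames with a ``label`` column,
optional ``source`` column, and one column per descriptor coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import RunConfig
from .errors import ModelError, WingidError
from .ga import ga_maximize

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

__all__ = [
    "ClassifierModel",
    "EvaluationResult",
    "ValidationReport",
    "PCAEmbedding",
    "feature_columns",
    "split_train_test",
    "ga_optimize",
    "train_model",
    "evaluate",
    "run_repeated_validation",
    "misidentification_rate",
    "pca_overlap",
    "hierarchical_train",
    "save_model",
    "load_model",
]

_META_COLUMNS = ("label", "source", "group", "path")


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Feature column names: everything except the metadata columns."""
    return [c for c in df.columns if c not in _META_COLUMNS]


def _matrix(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = feature_columns(df)
    if not cols:
        raise WingidError("feature table has no feature columns")
    return df[cols].to_numpy(dtype=float), df["label"].to_numpy()


@dataclass
class ClassifierModel:
    """A fitted identification model plus everything needed to reuse it.

    ``scaler_mean``/``scaler_scale`` are the training-set standardization
    statistics (applied before the SVM, persisted with the model);
    ``svm`` is None for a trivial single-class group model.
    """

    svm: SVC | None
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    classes: tuple
    n_features: int
    params: tuple  # (C, gamma)
    group_id: str | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ModelError(
                f"feature length {X.shape[-1]} does not match the model's {self.n_features}"
            )
        return (X - self.scaler_mean) / self.scaler_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.transform(X)
        if self.svm is None:
            return np.full(len(Xs), self.classes[0], dtype=object)
        return self.svm.predict(Xs)

    def decision_scores(self, X: np.ndarray) -> pd.DataFrame:
        """Per-class one-vs-rest decision values (single-class: all zero)."""
        Xs = self.transform(X)
        if self.svm is None:
            return pd.DataFrame({self.classes[0]: np.zeros(len(Xs))})
        scores = self.svm.decision_function(Xs)
        if scores.ndim == 1:  # binary: expand to two columns
            scores = np.column_stack([-scores, scores])
        return pd.DataFrame(scores, columns=list(self.svm.classes_))


@dataclass
class EvaluationResult:
    """Per-species accuracies, confusion counts and the raw prediction log."""

    accuracy: float  # overall %, all species pooled
    per_species: pd.Series  # species -> %
    confusion: pd.DataFrame  # rows true, cols predicted, counts
    predictions: pd.DataFrame  # columns: source, true, predicted


@dataclass
class ValidationReport:
    """Aggregate of repeated randomized train/test validation.

    ``runs`` has one row per randomized run (cv_accuracy, test_accuracy, C,
    gamma); ``per_species_accuracy`` pools correct/tested over all runs;
    ``misid_matrix`` holds P_e percentages (rows: true species, columns:
    predicted-as species, NaN where the denominator is zero); ``predictions``
    is the full per-specimen log every aggregate is recomputable from.
    """

    runs: pd.DataFrame
    mean_cv: float
    mean_test: float
    per_species_accuracy: pd.Series
    misid_matrix: pd.DataFrame
    predictions: pd.DataFrame
    n_runs: int
    S: int

    def write(self, out_dir) -> None:
        """Write runs/per-species/misidentification/prediction tables as CSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        runs = self.runs.copy()
        runs.loc["mean"] = {
            "run": "mean",
            "cv_accuracy": self.mean_cv,
            "test_accuracy": self.mean_test,
        }
        runs.to_csv(out / "runs.csv", index=False)
        self.per_species_accuracy.rename("accuracy_pct").to_csv(out / "per_species.csv")
        rows = []
        for a in self.misid_matrix.index:
            for b in self.misid_matrix.columns:
                rate = self.misid_matrix.loc[a, b]
                if a != b and pd.notna(rate) and rate > 0:
                    rows.append({"actual_species": a, "identified_as": b, "rate_pct": rate})
        pd.DataFrame(rows, columns=["actual_species", "identified_as", "rate_pct"]).to_csv(
            out / "misidentification.csv", index=False
        )
        self.predictions.to_csv(out / "predictions.csv", index=False)


@dataclass
class PCAEmbedding:
    """First two principal components of a feature table."""

    scores: np.ndarray  # (n, 2)
    explained_fraction: float  # variance fraction of PC1+PC2
    labels: np.ndarray
    explained_ratios: np.ndarray  # all components; sums to 1


# ---------------------------------------------------------------------------
# splitting / CV plumbing
# ---------------------------------------------------------------------------

def split_train_test(df: pd.DataFrame, ratio: float = 0.5, seed: int = 0):
    """Stratified random split; odd class counts send the extra specimen to train."""
    if not (0.0 < ratio < 1.0):
        raise WingidError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label, group in df.groupby("label", sort=True):
        if len(group) < 2:
            raise WingidError(f"class {label!r} has a single specimen; cannot split")
        perm = rng.permutation(len(group))
        n_train = int(np.ceil(len(group) * ratio))
        idx = group.index.to_numpy()
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    return df.loc[train_idx].copy(), df.loc[test_idx].copy()


def _cv_accuracy(X: np.ndarray, y: np.ndarray, folds, C: float, gamma: float) -> float:
    """Mean stratified k-fold accuracy of scale->SVC, with minimal overhead."""
    correct = total = 0
    for tr, te in folds:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        svm = SVC(C=C, gamma=gamma, kernel="rbf")
        svm.fit((X[tr] - mu) / sd, y[tr])
        pred = svm.predict((X[te] - mu) / sd)
        correct += int(np.sum(pred == y[te]))
        total += len(te)
    return 100.0 * correct / total


def ga_optimize(train: pd.DataFrame, config: RunConfig = RunConfig(), seed: int = 0):
    """GA search for (C, gamma) maximizing k-fold CV accuracy on the training set.

    The search runs over ``log2 C`` and ``log2 gamma`` boxes from the config.
    The initial population is seeded with the conventional default
    ``(C=1, gamma=1/n_features)``, so with elitism the returned parameters
    never score below that default on the same folds.

    Returns ``(C, gamma, cv_accuracy_pct)``.
    """
    X, y = _matrix(train)
    counts = pd.Series(y).value_counts()
    if counts.min() < config.cv_folds:
        raise WingidError(
            f"class {counts.idxmin()!r} has {counts.min()} training specimens, "
            f"fewer than cv_folds={config.cv_folds}"
        )
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed % 2**31)
    folds = list(skf.split(X, y))
    bounds = [
        (config.ga_log2c_min, config.ga_log2c_max),
        (config.ga_log2gamma_min, config.ga_log2gamma_max),
    ]
    default = (0.0, float(np.log2(1.0 / X.shape[1])))

    def fitness(genome):
        return _cv_accuracy(X, y, folds, C=2.0 ** genome[0], gamma=2.0 ** genome[1])

    rng = np.random.default_rng(seed + 1)
    best, best_fit, _ = ga_maximize(
        fitness,
        bounds,
        rng,
        population=config.ga_population,
        generations=config.ga_generations,
        crossover_rate=config.ga_crossover,
        mutation_rate=config.ga_mutation,
        include=[default],
    )
    return 2.0 ** best[0], 2.0 ** best[1], best_fit


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

def train_model(train: pd.DataFrame, params, group_id: str | None = None) -> ClassifierModel:
    """Fit standardization + one-vs-one C-SVC with the given (C, gamma)."""
    X, y = _matrix(train)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise WingidError("training a multi-class model requires >= 2 classes")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    C, gamma = params
    svm = SVC(C=C, gamma=gamma, kernel="rbf")
    svm.fit((X - mu) / sd, y)
    return ClassifierModel(
        svm=svm, scaler_mean=mu, scaler_scale=sd, classes=classes,
        n_features=X.shape[1], params=(float(C), float(gamma)), group_id=group_id,
    )


def _single_class_model(train: pd.DataFrame, group_id: str | None = None) -> ClassifierModel:
    X, y = _matrix(train)
    return ClassifierModel(
        svm=None, scaler_mean=np.zeros(X.shape[1]), scaler_scale=np.ones(X.shape[1]),
        classes=(y[0],), n_features=X.shape[1], params=(np.nan, np.nan), group_id=group_id,
    )


def evaluate(model: ClassifierModel, test: pd.DataFrame) -> EvaluationResult:
    """Predict the test set; per-species accuracy and full confusion counts."""
    X, y = _matrix(test)
    pred = model.predict(X)
    labels = sorted(set(y) | set(pred))
    confusion = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for yt, yp in zip(y, pred):
        confusion.loc[yt, yp] += 1
    tested = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_species = 100.0 * pd.Series(np.diag(confusion), index=labels) / tested
    per_species = per_species[tested > 0]
    sources = test["source"] if "source" in test.columns else pd.Series(test.index.astype(str), index=test.index)
    predictions = pd.DataFrame({"source": sources.to_numpy(), "true": y, "predicted": pred})
    return EvaluationResult(
        accuracy=100.0 * float(np.mean(pred == y)),
        per_species=per_species,
        confusion=confusion,
        predictions=predictions,
    )


def misidentification_rate(
    confusion_sum: pd.DataFrame,
    denominator: str = "per_species",
    total_tested: int | None = None,
) -> pd.DataFrame:
    """P_e matrix (%) from confusion counts summed over runs.

    ``denominator='per_species'`` divides row A by the total tested specimens
    of A (so accuracy + misidentification rates partition 100% per species);
    ``'global'`` divides everything by ``total_tested`` (the whole tested
    sample).  Rows with a zero denominator become NaN.
    """
    counts = confusion_sum.astype(float)
    if denominator == "per_species":
        denom = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pe = 100.0 * counts.div(denom.replace(0, np.nan), axis=0)
    elif denominator == "global":
        if total_tested is None:
            total_tested = int(counts.to_numpy().sum())
        if total_tested <= 0:
            raise WingidError("global misidentification denominator is zero")
        pe = 100.0 * counts / total_tested
    else:
        raise WingidError("denominator must be 'per_species' or 'global'")
    np.fill_diagonal(pe.to_numpy(), 0.0)  # diagonal is accuracy, not misidentification
    return pe


# ---------------------------------------------------------------------------
# repeated validation
# ---------------------------------------------------------------------------

def _run_seeds(master_seed: int, n_runs: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_runs)]


def run_repeated_validation(
    df: pd.DataFrame,
    config: RunConfig = RunConfig(),
    seed: int | None = None,
    group_of: dict | None = None,
) -> ValidationReport:
    """Repeat (stratified 1:1 split -> GA -> train -> test) and aggregate.

    With ``group_of`` (species -> group label), each run trains one
    independent model per group on that group's species only and evaluates
    each test specimen with its own group's model — emulating a taxonomist
    pre-sorting specimens by a human-visible character before the outline
    classifier runs.  Cross-group confusion is structurally impossible.
    """
    seed = config.seed if seed is None else seed
    if group_of is not None:
        missing = set(df["label"]) - set(group_of)
        if missing:
            raise WingidError(f"species without a group assignment: {sorted(missing)}")
    run_rows, prediction_frames = [], []
    confusion_total: pd.DataFrame | None = None
    for run, run_seed in enumerate(_run_seeds(seed, config.n_runs), start=1):
        train, test = split_train_test(df, ratio=config.split_ratio, seed=run_seed)
        if group_of is None:
            C, gamma, cv_acc = ga_optimize(train, config, seed=run_seed)
            model = train_model(train, (C, gamma))
            result = evaluate(model, test)
        else:
            C = gamma = np.nan
            cv_acc, result = _grouped_run(train, test, group_of, config, run_seed)
        log = result.predictions.assign(run=run)
        prediction_frames.append(log)
        confusion_total = (
            result.confusion if confusion_total is None
            else confusion_total.add(result.confusion, fill_value=0).fillna(0).astype(int)
        )
        run_rows.append({
            "run": run, "cv_accuracy": cv_acc, "test_accuracy": result.accuracy,
            "C": C, "gamma": gamma,
        })
    runs = pd.DataFrame(run_rows)
    predictions = pd.concat(prediction_frames, ignore_index=True)
    tested = confusion_total.sum(axis=1)
    per_species = (100.0 * pd.Series(np.diag(confusion_total), index=confusion_total.index)
                   / tested.replace(0, np.nan)).dropna()
    misid = misidentification_rate(
        confusion_total,
        denominator=config.misid_denominator,
        total_tested=int(tested.sum()),
    )
    return ValidationReport(
        runs=runs,
        mean_cv=float(runs["cv_accuracy"].mean()),
        mean_test=float(runs["test_accuracy"].mean()),
        per_species_accuracy=per_species,
        misid_matrix=misid,
        predictions=predictions,
        n_runs=config.n_runs,
        S=len(df),
    )


def _grouped_run(train, test, group_of, config, run_seed):
    """One validation run with an independent model per group."""
    groups = sorted(set(group_of.values()))
    cv_parts, results = [], []
    for gi, group in enumerate(groups):
        species = [s for s, g in group_of.items() if g == group]
        tr = train[train["label"].isin(species)]
        te = test[test["label"].isin(species)]
        if tr.empty:
            continue
        if tr["label"].nunique() < 2:
            logger.warning("group %r has a single species; using a trivial assigner", group)
            model = _single_class_model(tr, group_id=group)
            cv = 100.0
        else:
            C, gamma, cv = ga_optimize(tr, config, seed=run_seed + gi)
            model = train_model(tr, (C, gamma), group_id=group)
        cv_parts.append((cv, len(tr)))
        if not te.empty:
            results.append(evaluate(model, te))
    cv_acc = float(np.average([c for c, _ in cv_parts], weights=[n for _, n in cv_parts]))
    confusion = None
    preds = []
    for r in results:
        confusion = (r.confusion if confusion is None
                     else confusion.add(r.confusion, fill_value=0).fillna(0).astype(int))
        preds.append(r.predictions)
    predictions = pd.concat(preds, ignore_index=True)
    accuracy = 100.0 * float(np.mean(predictions["true"] == predictions["predicted"]))
    labels = sorted(set(predictions["true"]) | set(predictions["predicted"]))
    confusion = confusion.reindex(index=labels, columns=labels, fill_value=0).astype(int)
    tested = confusion.sum(axis=1)
    per_species = (100.0 * pd.Series(np.diag(confusion), index=labels) / tested.replace(0, np.nan)).dropna()
    result = EvaluationResult(accuracy=accuracy, per_species=per_species,
                              confusion=confusion, predictions=predictions)
    return cv_acc, result


def hierarchical_train(
    df: pd.DataFrame,
    group_of: dict,
    config: RunConfig = RunConfig(),
    seed: int | None = None,
) -> dict:
    """Fit one final model per group on all of that group's specimens.

    Prediction with these models requires the caller to supply each
    specimen's group (a human-judged character); single-species groups get a
    trivial constant assigner and a logged warning.
    """
    seed = config.seed if seed is None else seed
    missing = set(df["label"]) - set(group_of)
    if missing:
        raise WingidError(f"species without a group assignment: {sorted(missing)}")
    models = {}
    for gi, group in enumerate(sorted(set(group_of.values()))):
        species = [s for s, g in group_of.items() if g == group]
        sub = df[df["label"].isin(species)]
        if sub.empty:
            continue
        if sub["label"].nunique() < 2:
            logger.warning("group %r has fewer than 2 species; trivial single-class assigner", group)
            models[group] = _single_class_model(sub, group_id=group)
        else:
            C, gamma, _ = ga_optimize(sub, config, seed=seed + gi)
            models[group] = train_model(sub, (C, gamma), group_id=group)
    return models


# ---------------------------------------------------------------------------
# PCA diagnostic
# ---------------------------------------------------------------------------

def pca_overlap(df: pd.DataFrame) -> PCAEmbedding:
    """Centered PCA of the feature table (no re-scaling beyond normalization).

    The first-two-component scatter shows which species' outlines overlap
    and therefore where the classifier's confusion will concentrate.
    """
    X, y = _matrix(df)
    if len(X) < 3:
        raise WingidError("PCA diagnostic needs at least 3 specimens")
    pca = PCA()
    scores = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    return PCAEmbedding(
        scores=scores[:, :2],
        explained_fraction=float(ratios[:2].sum()),
        labels=y,
        explained_ratios=ratios,
    )


def plot_pca(embedding: PCAEmbedding, path) -> None:
    """Species-coloured scatter of the first two principal components."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 5))
    ax = fig.add_subplot(111)
    for label in sorted(set(embedding.labels)):
        m = embedding.labels == label
        ax.scatter(embedding.scores[m, 0], embedding.scores[m, 1], s=18, label=str(label))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(f"PC1+PC2 explain {100 * embedding.explained_fraction:.1f}% of variance")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(path, models, n_harmonics: int, extra: dict | None = None) -> None:
    """Persist one model or a {group: model} dict as a single versioned file."""
    if isinstance(models, ClassifierModel):
        models = {None: models}
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_harmonics": int(n_harmonics),
        "models": models,
        "extra": extra or {},
    }
    joblib.dump(payload, path)


def load_model(path) -> dict:
    """Load a persisted model container; checks the format version."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # joblib raises various things on corrupt input
        raise ModelError(f"cannot load model {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelError(f"{path} is not a supported model container")
    return payload
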