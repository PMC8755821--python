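"""Pseudo-population decoding with linear discriminant analysis and
permutation resampling.

Units are recorded one session at a time, so their single-trial responses
cannot be combined into true simultaneous population vectors.  Surrogate
("pseudo-population") vectors are therefore assembled by independently
shuffling each unit's trial order within a stimulus grouping and
concatenating the i-th shuffled trial of every unit into population vector
i — any within-session trial-to-trial covariance is destroyed by
construction, leaving only the tuning structure.

The decoding statistic is the one-vs-rest area under the ROC curve per
grouping, computed from the decision scores of a linear discriminant
classifier on a held-out stratified test split.  The whole construction is
repeated ``n_resamples`` times (default 1200) with fresh shuffles to give a
labelled performance distribution, and again with grouping labels permuted
across rows to give a "no information" null distribution.  The permutation
p-value per grouping is the add-one estimator

    p = (1 + #{null >= median(labelled)}) / (1 + n_resamples)

with binomial standard error sqrt(p (1 - p) / n_resamples); it can never
be exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .session_synth import ValidationError

__all__ = [
    "PseudoPopulation",
    "DecodingResult",
    "build_pseudopopulation",
    "decode_once",
    "permutation_analysis",
    "held_out_generalization",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PseudoPopulation:
    """Surrogate population matrix: rows = pseudo-trials, cols = units."""

    X: np.ndarray
    y: np.ndarray                  # grouping label per row
    image_id: np.ndarray | None    # set when built exemplar-resolved
    neuron_ids: tuple
    resample_index: int = 0
    rng_seed: int = 0


@dataclass(frozen=True)
class DecodingResult:
    """Per-grouping labelled and null performance distributions + p-values."""

    groupings: tuple
    labelled: np.ndarray       # (n_resamples, n_groupings)
    null: np.ndarray           # (n_resamples, n_groupings)
    p_values: np.ndarray
    p_errors: np.ndarray
    n_resamples: int
    classifier: str = "lda"

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grouping": self.groupings,
                "median_performance": np.median(self.labelled, axis=0),
                "median_null": np.median(self.null, axis=0),
                "p_value": self.p_values,
                "p_error": self.p_errors,
            }
        )


class _RateCube:
    """Per-(unit, cell) stimulus rates truncated to a common trial count.

    ``by="grouping"`` pools all exemplars of a grouping into one cell;
    ``by="image"`` keeps cells exemplar-resolved so held-out-image vectors
    are well defined.
    """

    def __init__(self, trials: pd.DataFrame, by: str = "grouping") -> None:
        if by not in ("grouping", "image"):
            raise ValidationError("by must be 'grouping' or 'image'")
        self.by = by
        key = "grouping" if by == "grouping" else "image_id"
        cells = sorted(trials[key].unique())
        neuron_ids = sorted(trials["neuron_id"].astype(str).unique())
        if len(cells) < 2 and by == "grouping":
            raise ValidationError("need >= 2 stimulus groupings")

        per_cell: dict = {}
        counts: dict = {}
        grouped = trials.copy()
        grouped["neuron_id"] = grouped["neuron_id"].astype(str)
        pivot = {
            (nid, cell): sub["rate_stim_hz"].to_numpy()
            for (nid, cell), sub in grouped.groupby(["neuron_id", key], sort=True)
        }
        keep = []
        for nid in neuron_ids:
            n_per = [len(pivot.get((nid, c), ())) for c in cells]
            if min(n_per) == 0:
                logger.warning("neuron %s: empty stimulus cell, excluded", nid)
                continue
            keep.append(nid)
        if not keep:
            raise ValidationError("no neuron covers every stimulus cell")
        k = min(len(pivot[(nid, c)]) for nid in keep for c in cells)
        for c in cells:
            per_cell[c] = np.stack([pivot[(nid, c)][:k] for nid in keep])
        self.cells = cells
        self.k = k
        self.neuron_ids = tuple(keep)
        self.rates = per_cell            # cell -> (n_neurons, k)
        if by == "image":
            self.cell_grouping = {
                c: int(trials.loc[trials["image_id"] == c, "grouping"].iloc[0])
                for c in cells
            }

    def sample(self, rng: np.random.Generator, cells=None) -> tuple:
        """One surrogate draw: independently permute each unit's trials
        within each cell and stack the aligned columns into vectors."""
        cells = self.cells if cells is None else cells
        blocks, labels, images = [], [], []
        for c in cells:
            shuffled = rng.permuted(self.rates[c], axis=1)  # rows independent
            blocks.append(shuffled.T)                       # (k, n_neurons)
            lab = c if self.by == "grouping" else self.cell_grouping[c]
            labels.extend([lab] * self.k)
            if self.by == "image":
                images.extend([c] * self.k)
        X = np.vstack(blocks)
        y = np.asarray(labels)
        img = np.asarray(images) if self.by == "image" else None
        return X, y, img


def build_pseudopopulation(
    trials: pd.DataFrame,
    seed: int = 0,
    by: str = "grouping",
    resample_index: int = 0,
) -> PseudoPopulation:
    """Assemble one pseudo-population from per-unit trial tables.

    ``trials`` is a session table (one or many units).  Trial lists are
    truncated to the minimum per-cell count across units so every unit
    contributes equally; units missing a cell entirely are excluded with a
    warning.  Deterministic in ``seed``.
    """
    cube = _RateCube(trials, by=by)
    rng = np.random.default_rng(seed)
    X, y, img = cube.sample(rng)
    return PseudoPopulation(
        X=X, y=y, image_id=img, neuron_ids=cube.neuron_ids,
        resample_index=resample_index, rng_seed=seed,
    )


def _fit_lda(X_train: np.ndarray, y_train: np.ndarray) -> LinearDiscriminantAnalysis:
    """LDA with automatic shrinkage when the within-class scatter may be
    singular (more features than training rows per class)."""
    n, d = X_train.shape
    if n - len(np.unique(y_train)) <= d:
        logger.info("shrinkage-regularized LDA (n=%d rows, %d features)", n, d)
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    else:
        clf = LinearDiscriminantAnalysis(solver="svd")
    clf.fit(X_train, y_train)
    return clf


def _per_class_auc(
    clf: LinearDiscriminantAnalysis, X_test: np.ndarray, y_test: np.ndarray,
    classes: np.ndarray,
) -> np.ndarray:
    """One-vs-rest ROC area per class from decision scores; 0.5 when the
    test split lacks positives or negatives for a class."""
    scores = clf.decision_function(X_test)
    if scores.ndim == 1:  # binary: score for classes_[1]
        scores = np.column_stack([-scores, scores])
    col = {c: i for i, c in enumerate(clf.classes_)}
    out = np.full(len(classes), 0.5)
    for i, c in enumerate(classes):
        pos = y_test == c
        if c not in col or pos.all() or not pos.any():
            continue
        out[i] = roc_auc_score(pos, scores[:, col[c]])
    return out


def decode_once(
    pop: PseudoPopulation,
    train_fraction: float = 0.75,
    seed: int = 0,
    permute_labels: bool = False,
) -> np.ndarray:
    """Fit LDA on a stratified train split; per-grouping one-vs-rest AUC on
    the held-out rows.  ``permute_labels`` shuffles the grouping labels
    across rows before the split (the "no information" control)."""
    classes = np.unique(pop.y)
    if len(classes) < 2:
        raise ValidationError("decoding needs >= 2 groupings")
    rng = np.random.default_rng(seed)
    y = rng.permutation(pop.y) if permute_labels else pop.y
    X_tr, X_te, y_tr, y_te = train_test_split(
        pop.X, y,
        train_size=train_fraction,
        stratify=y,
        random_state=int(rng.integers(2**31)),
    )
    clf = _fit_lda(X_tr, y_tr)
    return _per_class_auc(clf, X_te, y_te, classes)


def permutation_analysis(
    trials: pd.DataFrame,
    n_resamples: int = 1200,
    seed: int = 0,
    train_fraction: float = 0.75,
) -> DecodingResult:
    """Full permutation-resampling decoding analysis of a session.

    Each resample rebuilds the pseudo-population with a fresh within-
    grouping shuffle and decodes it; the null repeats this with labels
    permuted across rows before training.  Reproducible from
    ``(trials, seed, n_resamples)``.
    """
    if n_resamples < 100:
        logger.warning("n_resamples=%d < 100: p-values will be unstable", n_resamples)
    cube = _RateCube(trials, by="grouping")
    classes = np.unique(np.asarray(cube.cells))
    rng = np.random.default_rng(seed)
    labelled = np.empty((n_resamples, len(classes)))
    null = np.empty((n_resamples, len(classes)))
    for r in range(n_resamples):
        for arr, permute in ((labelled, False), (null, True)):
            X, y, _ = cube.sample(rng)
            pop = PseudoPopulation(
                X=X, y=y, image_id=None, neuron_ids=cube.neuron_ids,
                resample_index=r, rng_seed=seed,
            )
            arr[r] = decode_once(
                pop,
                train_fraction=train_fraction,
                seed=int(rng.integers(2**31)),
                permute_labels=permute,
            )
    observed = np.median(labelled, axis=0)
    exceed = (null >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_resamples)
    p_err = np.sqrt(p * (1.0 - p) / n_resamples)
    return DecodingResult(
        groupings=tuple(classes.tolist()),
        labelled=labelled,
        null=null,
        p_values=p,
        p_errors=p_err,
        n_resamples=n_resamples,
    )


def held_out_generalization(
    trials: pd.DataFrame,
    n_resamples: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Decoding generalization to held-out exemplars.

    For each exemplar fold, the classifier trains on pseudo-vectors built
    only from the other exemplars of every grouping and is tested on
    vectors built from the held-out exemplars.  Per-grouping one-vs-rest
    AUC is averaged over folds and resamples.  Groupings with a single
    exemplar cannot be held out and are skipped with a warning.
    """
    cube = _RateCube(trials, by="image")
    groupings = sorted({g for g in cube.cell_grouping.values()})
    exemplars: dict = {}
    for img, g in cube.cell_grouping.items():
        exemplars.setdefault(g, []).append(img)
    n_ex = {g: len(v) for g, v in exemplars.items()}
    usable = [g for g in groupings if n_ex[g] >= 2]
    for g in groupings:
        if n_ex[g] < 2:
            logger.warning("grouping %s has a single exemplar: skipped", g)
    if not usable:
        raise ValidationError("no grouping with >= 2 exemplars")
    max_folds = min(n_ex[g] for g in usable)

    rng = np.random.default_rng(seed)
    classes = np.asarray(usable)
    perf = np.zeros((n_resamples, max_folds, len(classes)))
    for r in range(n_resamples):
        for fold in range(max_folds):
            held = {exemplars[g][fold] for g in usable}
            train_cells = [c for c in cube.cells if c not in held]
            test_cells = [c for c in cube.cells if c in held]
            X_tr, y_tr, _ = cube.sample(rng, cells=train_cells)
            X_te, y_te, _ = cube.sample(rng, cells=test_cells)
            clf = _fit_lda(X_tr, y_tr)
            perf[r, fold] = _per_class_auc(clf, X_te, y_te, classes)
    mean_perf = perf.mean(axis=(0, 1))
    return pd.DataFrame(
        {
            "grouping": usable,
            "held_out_performance": mean_perf,
            "n_exemplars": [n_ex[g] for g in usable],
        }
    )
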