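"""Partial least squares correlation (PLSC) between an FC block and a symptom block.

The model: with ``X`` (n subjects x p FC edges) and ``Y`` (n x q mood items)
column-standardized, the cross-covariance ``R = Y' X / (n - 1)`` is decomposed
by SVD, ``R = U S V'``.  Each latent component (LC) pairs a mood salience
(column of ``U``), an FC salience (column of ``V``) and a singular value;
components are ranked by the covariance they explain, ``s_k^2 / sum(s^2)``.
Subject-level FC and mood scores are the projections of the standardized
blocks onto the saliences, and loadings — the interpretable quantity — are
Pearson correlations between each original variable and the component score.

The 37-item mood symptom profile is 10 PANAS positive-affect items, 10 PANAS
negative-affect items (each rated 1-5) and the 17 clinician-rated HRSD-17
items (item-specific ordinal maxima, total 0-52), in that fixed order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PANAS_PA_ITEMS",
    "PANAS_NA_ITEMS",
    "HRSD17_ITEMS",
    "SYMPTOM_ITEMS",
    "SYMPTOM_ITEM_RANGES",
    "DataBlocks",
    "PlsModel",
    "ScoreSet",
    "LoadingSet",
    "residualize",
    "fit_pls",
    "compute_scores",
    "compute_loadings",
]

# ---------------------------------------------------------------------------
# Symptom instrument layout: fixed, documented item order
# ---------------------------------------------------------------------------

PANAS_PA_ITEMS: tuple[str, ...] = (
    "Interested", "Excited", "Strong", "Enthusiastic", "Proud",
    "Alert", "Inspired", "Determined", "Attentive", "Active",
)
PANAS_NA_ITEMS: tuple[str, ...] = (
    "Distressed", "Upset", "Guilty", "Scared", "Hostile",
    "Irritable", "Ashamed", "Nervous", "Jittery", "Afraid",
)
# HRSD-17 items: nine rated 0-4, eight rated 0-2 (maximum total score 52)
_HRSD17: tuple[tuple[str, int], ...] = (
    ("Depressed_Mood", 4), ("Guilt", 4), ("Suicide", 4),
    ("Insomnia_E", 2), ("Insomnia_M", 2), ("Insomnia_L", 2),
    ("Work_Activities", 4), ("Retardation", 4), ("Agitation", 4),
    ("Anxiety_P", 4), ("Anxiety_S", 4),
    ("Gastrointestinal_S", 2), ("General_S", 2), ("Genital_S", 2),
    ("Hypochondriasis", 4), ("Weight_Loss", 2), ("Insight", 2),
)
HRSD17_ITEMS: tuple[str, ...] = tuple(f"HRSD_{name}" for name, _ in _HRSD17)

SYMPTOM_ITEMS: tuple[str, ...] = (
    tuple(f"PA_{x}" for x in PANAS_PA_ITEMS)
    + tuple(f"NA_{x}" for x in PANAS_NA_ITEMS)
    + HRSD17_ITEMS
)
#: (low, high) inclusive rating range for each of the 37 items, in order
SYMPTOM_ITEM_RANGES: tuple[tuple[int, int], ...] = (
    ((1, 5),) * 10 + ((1, 5),) * 10 + tuple((0, hi) for _, hi in _HRSD17)
)
assert len(SYMPTOM_ITEMS) == 37 and len(SYMPTOM_ITEM_RANGES) == 37


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class DataBlocks:
    """Paired FC and symptom blocks with aligned rows.

    ``X`` is n x p (FC edges, p = 1431 for the 54-region parcellation), ``Y``
    is n x q (symptom items, q = 37).  Missing values are refused unless
    ``impute_mean=True``, which replaces NaN by the column mean.
    """

    X: np.ndarray
    Y: np.ndarray
    subject_ids: list[str] | None = None
    x_names: list[str] | None = None
    y_names: list[str] | None = None
    covariates: np.ndarray | None = None
    covariate_names: list[str] | None = None
    impute_mean: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D matrices")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"row mismatch: X has {self.X.shape[0]} subjects, "
                f"Y has {self.Y.shape[0]}"
            )
        n = self.X.shape[0]
        if self.subject_ids is not None and len(self.subject_ids) != n:
            raise ValueError("subject_ids length must match row count")
        if self.x_names is not None and len(self.x_names) != self.X.shape[1]:
            raise ValueError("x_names length must match X columns")
        if self.y_names is not None and len(self.y_names) != self.Y.shape[1]:
            raise ValueError("y_names length must match Y columns")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows must match subject count")
        for name in ("X", "Y"):
            block = getattr(self, name)
            if np.isnan(block).any():
                if not self.impute_mean:
                    raise ValueError(
                        f"{name} contains missing values; pass impute_mean=True "
                        "to accept per-column mean imputation"
                    )
                col_mean = np.nanmean(block, axis=0)
                idx = np.where(np.isnan(block))
                block[idx] = np.take(col_mean, idx[1])
            if not np.all(np.isfinite(block)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class PlsModel:
    """Fitted PLSC model: saliences, singular values and training statistics."""

    fc_saliences: np.ndarray        # p x k
    mood_saliences: np.ndarray      # q x k
    singular_values: np.ndarray     # k
    explained_cov: np.ndarray       # k, sums to 1
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    standardize: str = "zscore"
    n_train: int = 0
    x_names: list[str] | None = None
    y_names: list[str] | None = None
    # filled at fit time for convenience (training-sample quantities)
    fc_loadings: np.ndarray | None = None
    mood_loadings: np.ndarray | None = None
    training_fc_scores: np.ndarray | None = None
    training_mood_scores: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.singular_values.size

    @property
    def p(self) -> int:
        return self.fc_saliences.shape[0]

    @property
    def q(self) -> int:
        return self.mood_saliences.shape[0]


@dataclass
class ScoreSet:
    """Subject-level projections onto the saliences (n x k per block)."""

    fc_scores: np.ndarray
    mood_scores: np.ndarray

    def __post_init__(self) -> None:
        self.fc_scores = np.atleast_2d(np.asarray(self.fc_scores, dtype=float))
        self.mood_scores = np.atleast_2d(np.asarray(self.mood_scores, dtype=float))
        if self.fc_scores.shape != self.mood_scores.shape:
            raise ValueError("fc and mood score shapes must match")


@dataclass
class LoadingSet:
    """Pearson correlations of original variables with component scores."""

    fc_loadings: np.ndarray     # p x k
    mood_loadings: np.ndarray   # q x k
    fc_ci_low: np.ndarray | None = None
    fc_ci_high: np.ndarray | None = None
    mood_ci_low: np.ndarray | None = None
    mood_ci_high: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def residualize(block: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Replace each column by its OLS residual on the covariates plus intercept.

    With no covariates (``None`` or zero columns) this reduces to column
    centering.  Raises on rank-deficient covariates.
    """
    b = np.asarray(block, dtype=float)
    n = b.shape[0]
    if covariates is None:
        design = np.ones((n, 1))
    else:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if c.shape[0] != n:
            raise ValueError("covariate rows must match block rows")
        design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix (plus intercept) is rank deficient")
    coef, *_ = np.linalg.lstsq(design, b, rcond=None)
    return b - design @ coef


def _standardize(block: np.ndarray, mode: str, names: list[str] | None):
    mean = block.mean(axis=0)
    if mode == "zscore":
        sd = block.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            label = names[zero[0]] if names else f"column {zero[0]}"
            raise ValueError(f"zero-variance column: {label}")
    elif mode == "center":
        sd = np.ones(block.shape[1])
    else:
        raise ValueError(f"unknown standardization mode: {mode!r}")
    return (block - mean) / sd, mean, sd


def _apply_sign_convention(U: np.ndarray, V: np.ndarray) -> None:
    """Resolve per-component sign indeterminacy in place.

    Both saliences of a component are flipped jointly, which leaves the score
    covariance (the singular value, hence non-negative) untouched; the
    largest-magnitude mood-salience entry is made positive.
    """
    for k in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] *= -1.0
            V[:, k] *= -1.0


def fit_pls(
    blocks: DataBlocks,
    standardize: str = "zscore",
    residualize_covariates: bool = False,
    attach_training_outputs: bool = True,
) -> PlsModel:
    """Fit the symmetric PLS correlation model.

    Both blocks are column-standardized with training statistics (z-scoring
    by default; ``standardize='center'`` for centering only), the
    cross-covariance ``R = Y' X / (n-1)`` is formed and decomposed by SVD,
    and ``k = min(p, q, n-1)`` components are retained.  With
    ``residualize_covariates=True`` both blocks are first residualized on
    ``blocks.covariates`` (confound control: age, sex, education, BMI, head
    motion in the intended application).
    """
    n = blocks.n
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    X, Y = blocks.X, blocks.Y
    if residualize_covariates:
        if blocks.covariates is None:
            raise ValueError("residualize_covariates=True but no covariates given")
        X = residualize(X, blocks.covariates)
        Y = residualize(Y, blocks.covariates)

    Xs, x_mean, x_sd = _standardize(X, standardize, blocks.x_names)
    Ys, y_mean, y_sd = _standardize(Y, standardize, blocks.y_names)

    R = Ys.T @ Xs / (n - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    k = min(X.shape[1], Y.shape[1], n - 1)
    U, s, V = U[:, :k], s[:k], V[:, :k]
    _apply_sign_convention(U, V)

    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("cross-covariance is identically zero; no components")
    model = PlsModel(
        fc_saliences=V,
        mood_saliences=U,
        singular_values=s,
        explained_cov=s**2 / total,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        standardize=standardize,
        n_train=n,
        x_names=list(blocks.x_names) if blocks.x_names else None,
        y_names=list(blocks.y_names) if blocks.y_names else None,
    )
    if attach_training_outputs:
        scores = ScoreSet(fc_scores=Xs @ V, mood_scores=Ys @ U)
        model.training_fc_scores = scores.fc_scores
        model.training_mood_scores = scores.mood_scores
        train_blocks = DataBlocks(X=X, Y=Y)
        loadings = compute_loadings(train_blocks, scores)
        model.fc_loadings = loadings.fc_loadings
        model.mood_loadings = loadings.mood_loadings
    return model


def compute_scores(model: PlsModel, blocks: DataBlocks) -> ScoreSet:
    """Project subjects onto the saliences using the model's stored statistics.

    ``fc_score = X_std @ fc_saliences`` and likewise for the mood block, where
    standardization uses the training mean/SD.  Re-projecting the training
    sample reproduces the fit-time scores exactly.
    """
    if blocks.X.shape[1] != model.p or blocks.Y.shape[1] != model.q:
        raise ValueError(
            f"feature dimension mismatch: model expects p={model.p}, q={model.q}; "
            f"got p={blocks.X.shape[1]}, q={blocks.Y.shape[1]}"
        )
    Xs = (blocks.X - model.x_mean) / model.x_sd
    Ys = (blocks.Y - model.y_mean) / model.y_sd
    return ScoreSet(fc_scores=Xs @ model.fc_saliences,
                    mood_scores=Ys @ model.mood_saliences)


def _column_correlations(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r between every block column and every score column."""
    n = block.shape[0]
    bc = block - block.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    b_sd = bc.std(axis=0)
    s_sd = sc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (bc.T @ sc) / n / np.outer(b_sd, s_sd)
    corr[np.broadcast_to((b_sd == 0)[:, None], corr.shape)] = np.nan
    return corr


def compute_loadings(blocks: DataBlocks, scores: ScoreSet) -> LoadingSet:
    """Pearson correlations of original variables with the component scores.

    A constant column has no defined correlation; its loadings are recorded
    as NaN with a warning rather than raising.
    """
    if blocks.n < 3:
        raise ValueError("need at least 3 subjects to compute loadings")
    if scores.fc_scores.shape[0] != blocks.n:
        raise ValueError("score rows must match block rows")
    fc = _column_correlations(blocks.X, scores.fc_scores)
    mood = _column_correlations(blocks.Y, scores.mood_scores)
    n_const = int(np.isnan(fc[:, 0]).sum() + np.isnan(mood[:, 0]).sum())
    if n_const:
        warnings.warn(
            f"{n_const} constant column(s): loadings recorded as NaN",
            UserWarning,
            stacklevel=2,
        )
    return LoadingSet(fc_loadings=fc, mood_loadings=mood)
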