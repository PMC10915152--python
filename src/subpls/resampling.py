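"""Permutation significance and bootstrap reliability for PLSC components.

Significance of each latent component is assessed by permuting the rows of
the symptom block (breaking the FC-symptom coupling while preserving each
block's internal covariance), refitting, and comparing null singular values
to the observed ones; p = (1 + #null >= observed) / (1 + B), which can never
be exactly zero.

Reliability of individual salience entries is assessed by bootstrap
resampling of subjects: the bootstrap ratio (BSR) divides each observed
salience entry by its bootstrap standard deviation and behaves like a
z-statistic (|BSR| > 2 roughly corresponds to p < 0.05).  Percentile
bootstrap confidence intervals on the loadings flag "significant" variables
(95% CI excluding zero).

Components of a resampled solution are only identified up to rotation and
sign, so each resampled solution is aligned to the observed one by an
orthogonal Procrustes rotation (computed on the mood saliences, applied to
both blocks and, for permutations, to the singular values) before
aggregation.  Without this step axis flips inflate bootstrap SDs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls import DataBlocks, PlsModel, ScoreSet, _column_correlations, _standardize, fit_pls

__all__ = [
    "PermutationResult",
    "BootstrapResult",
    "EdgeSelection",
    "procrustes_rotation",
    "permutation_test",
    "bootstrap",
    "select_edges",
]


@dataclass
class PermutationResult:
    observed_singulars: np.ndarray   # k
    null_singulars: np.ndarray       # B x k
    p_values: np.ndarray             # k, in (0, 1]
    B: int
    seed: int


@dataclass
class BootstrapResult:
    bsr_fc: np.ndarray               # p x k
    bsr_mood: np.ndarray             # q x k
    fc_salience_sd: np.ndarray       # p x k bootstrap SDs
    mood_salience_sd: np.ndarray     # q x k
    fc_loading_ci_low: np.ndarray | None
    fc_loading_ci_high: np.ndarray | None
    mood_loading_ci_low: np.ndarray | None
    mood_loading_ci_high: np.ndarray | None
    B: int
    seed: int
    n_redrawn: int = 0
    degenerate_sd_fc: np.ndarray | None = None
    degenerate_sd_mood: np.ndarray | None = None


@dataclass
class EdgeSelection:
    """Edges retained at the two reliability tiers.

    ``reliable_edges``: |BSR| above the base threshold and loading CI
    excluding zero.  ``robust_edges``: additionally |BSR| above the high
    threshold and ranked in the top fraction by absolute loading; a subset of
    the reliable set whenever the high threshold dominates the base one.
    """

    reliable_edges: set = field(default_factory=set)
    robust_edges: set = field(default_factory=set)


def procrustes_rotation(reference: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Orthogonal R minimizing ||reference - target R||_F (includes sign flips)."""
    A, _, Bt = np.linalg.svd(target.T @ reference)
    return A @ Bt


def permutation_test(
    blocks: DataBlocks,
    B: int = 5000,
    seed: int = 0,
    standardize: str = "zscore",
    align: bool = False,
) -> PermutationResult:
    """Permutation test of the latent components' singular values.

    Rows of Y are permuted uniformly at random with X fixed; each null
    cross-covariance is decomposed and its singular values compared,
    rank for rank, with the observed ones.  For the first component this
    matches observed and null maxima and holds the nominal type-I error
    under the null (verified by simulation in the test suite).

    ``align=True`` instead Procrustes-rotates each null solution onto the
    observed mood saliences and takes per-component column norms of the
    rotated, scaled solution.  Alignment is essential for bootstrap SDs but
    grossly anti-conservative here: rotating an unrelated null solution
    toward the observed one spreads singular-value energy evenly across
    components, so the null first-component value systematically undershoots
    the observed maximum.  It is therefore off by default and offered for
    comparison only.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    model = fit_pls(blocks, standardize=standardize, attach_training_outputs=False)
    n, k = blocks.n, model.k
    # z-scores are invariant under row permutation, so standardize once
    Xs, *_ = _standardize(blocks.X, standardize, blocks.x_names)
    Ys, *_ = _standardize(blocks.Y, standardize, blocks.y_names)
    U_obs = model.mood_saliences

    rng = np.random.default_rng(seed)
    null = np.empty((B, k))
    for b in range(B):
        perm = rng.permutation(n)
        Rb = Ys[perm].T @ Xs / (n - 1)
        Ub, sb, _ = np.linalg.svd(Rb, full_matrices=False)
        Ub, sb = Ub[:, :k], sb[:k]
        if align:
            rot = procrustes_rotation(U_obs, Ub)
            null[b] = np.linalg.norm((Ub * sb) @ rot, axis=0)
        else:
            null[b] = sb
    exceed = (null >= model.singular_values).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + B)
    return PermutationResult(
        observed_singulars=model.singular_values,
        null_singulars=null,
        p_values=p,
        B=B,
        seed=seed,
    )


def bootstrap(
    blocks: DataBlocks,
    B: int = 5000,
    seed: int = 0,
    standardize: str = "zscore",
    align: bool = True,
    compute_loading_ci: bool = True,
    ci_percentiles: tuple[float, float] = (2.5, 97.5),
    max_redraw_factor: int = 10,
    resample_indices: list[np.ndarray] | None = None,
) -> BootstrapResult:
    """Bootstrap reliability of saliences (BSR) and percentile loading CIs.

    Subjects are resampled with replacement; each resampled model is
    Procrustes-aligned to the observed solution before aggregating.
    Alignment follows the singular-value-scaled convention: the resampled
    solution ``(U_b S_b) R`` / ``(V_b S_b) R`` (rotation ``R`` fitted on the
    mood side, applied to both blocks) is accumulated, and BSR divides the
    observed scaled salience by the bootstrap SD of its aligned scaled
    counterparts.  Scaling matters: with as many components as mood items
    the mood-side rotation alone is a complete basis change, and the scaled
    aligned FC solution reduces to ``R_b' U_0`` — a fixed-direction
    projection of each resample's cross-covariance, which is what makes the
    BSR behave like a z-statistic (under the null, about 5% of entries
    exceed |BSR| = 2 when pooled over features and components; the first
    component alone runs higher because its direction is estimated from the
    same data).

    An SD of exactly zero yields an infinite BSR, flagged in
    ``degenerate_sd_*`` rather than raising.  Resamples that leave a column
    with zero variance are redrawn (counted and warned), up to
    ``max_redraw_factor * B`` attempts in total.

    ``resample_indices`` overrides the random resampling with an explicit
    list of index arrays — a hook for deterministic degenerate-case tests.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    model = fit_pls(blocks, standardize=standardize)
    n, k = blocks.n, model.k
    U0, V0 = model.mood_saliences, model.fc_saliences
    rng = np.random.default_rng(seed)

    sum_u = np.zeros_like(U0)
    sumsq_u = np.zeros_like(U0)
    sum_v = np.zeros_like(V0)
    sumsq_v = np.zeros_like(V0)
    fc_loads = np.empty((B, model.p, k)) if compute_loading_ci else None
    mood_loads = np.empty((B, model.q, k)) if compute_loading_ci else None

    n_redrawn = 0
    attempts_left = max_redraw_factor * B
    b = 0
    while b < B:
        if resample_indices is not None:
            idx = np.asarray(resample_indices[b])
        else:
            idx = rng.integers(0, n, size=n)
        Xb, Yb = blocks.X[idx], blocks.Y[idx]
        attempts_left -= 1
        if (standardize == "zscore"
                and (np.any(Xb.std(axis=0) == 0) or np.any(Yb.std(axis=0) == 0))):
            n_redrawn += 1
            if resample_indices is not None:
                raise ValueError("supplied resample has a zero-variance column")
            if attempts_left <= 0:
                raise ValueError(
                    "too many degenerate bootstrap resamples "
                    f"(redrew {n_redrawn} of {max_redraw_factor * B} attempts)"
                )
            continue
        Xbs, *_ = _standardize(Xb, standardize, None)
        Ybs, *_ = _standardize(Yb, standardize, None)
        Rb = Ybs.T @ Xbs / (n - 1)
        Ub, sb, Vbt = np.linalg.svd(Rb, full_matrices=False)
        Ub, sb, Vb = Ub[:, :k], sb[:k], Vbt.T[:, :k]
        if align:
            rot = procrustes_rotation(U0, Ub)
            Ub_s = (Ub * sb) @ rot
            Vb_s = (Vb * sb) @ rot
            Ub_dir, Vb_dir = Ub @ rot, Vb @ rot
        else:
            Ub_s, Vb_s = Ub * sb, Vb * sb
            Ub_dir, Vb_dir = Ub, Vb
        sum_u += Ub_s
        sumsq_u += Ub_s**2
        sum_v += Vb_s
        sumsq_v += Vb_s**2
        if compute_loading_ci:
            sc = ScoreSet(fc_scores=Xbs @ Vb_dir, mood_scores=Ybs @ Ub_dir)
            fc_loads[b] = _column_correlations(Xb, sc.fc_scores)
            mood_loads[b] = _column_correlations(Yb, sc.mood_scores)
        b += 1

    if n_redrawn:
        warnings.warn(
            f"redrew {n_redrawn} degenerate bootstrap resample(s)",
            UserWarning,
            stacklevel=2,
        )

    def _sd(total, total_sq):
        var = (total_sq - total**2 / B) / (B - 1)
        return np.sqrt(np.clip(var, 0.0, None))

    sd_u = _sd(sum_u, sumsq_u)
    sd_v = _sd(sum_v, sumsq_v)
    s0 = model.singular_values
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr_mood = (U0 * s0) / sd_u
        bsr_fc = (V0 * s0) / sd_v

    lo, hi = ci_percentiles
    if compute_loading_ci:
        fc_lo = np.nanpercentile(fc_loads, lo, axis=0)
        fc_hi = np.nanpercentile(fc_loads, hi, axis=0)
        mood_lo = np.nanpercentile(mood_loads, lo, axis=0)
        mood_hi = np.nanpercentile(mood_loads, hi, axis=0)
    else:
        fc_lo = fc_hi = mood_lo = mood_hi = None

    return BootstrapResult(
        bsr_fc=bsr_fc,
        bsr_mood=bsr_mood,
        fc_salience_sd=sd_v,
        mood_salience_sd=sd_u,
        fc_loading_ci_low=fc_lo,
        fc_loading_ci_high=fc_hi,
        mood_loading_ci_low=mood_lo,
        mood_loading_ci_high=mood_hi,
        B=B,
        seed=seed,
        n_redrawn=n_redrawn,
        degenerate_sd_fc=(sd_v == 0),
        degenerate_sd_mood=(sd_u == 0),
    )


def select_edges(
    bsr: np.ndarray,
    loadings: np.ndarray,
    ci_low: np.ndarray,
    ci_high: np.ndarray,
    labels: list | None = None,
    bsr_threshold: float = 2.0,
    high_threshold: float = 3.0,
    top_fraction: float = 0.05,
) -> EdgeSelection:
    """Two-tier edge selection for one component.

    ``reliable``: |BSR| > ``bsr_threshold`` and the loading CI excludes zero.
    ``robust``: |BSR| > ``high_threshold``, significant loading, and within
    the top ``ceil(top_fraction * n)`` edges by absolute loading.  Empty
    selections are legitimate results, not errors.
    """
    if bsr_threshold <= 0 or high_threshold <= 0 or top_fraction <= 0:
        raise ValueError("thresholds must be positive")
    bsr = np.asarray(bsr, dtype=float).ravel()
    loadings = np.asarray(loadings, dtype=float).ravel()
    ci_low = np.asarray(ci_low, dtype=float).ravel()
    ci_high = np.asarray(ci_high, dtype=float).ravel()
    p = bsr.size
    if labels is None:
        labels = list(range(p))
    if not (loadings.size == ci_low.size == ci_high.size == p == len(labels)):
        raise ValueError("bsr, loadings, CIs and labels must have equal length")

    significant = (ci_low > 0) | (ci_high < 0)
    with np.errstate(invalid="ignore"):
        reliable_mask = (np.abs(bsr) > bsr_threshold) & significant
        high_mask = (np.abs(bsr) > high_threshold) & significant
    n_top = math.ceil(top_fraction * p)
    order = np.argsort(-np.abs(loadings), kind="stable")
    in_top = np.zeros(p, dtype=bool)
    in_top[order[:n_top]] = True
    robust_mask = high_mask & in_top

    return EdgeSelection(
        reliable_edges={labels[i] for i in np.flatnonzero(reliable_mask)},
        robust_edges={labels[i] for i in np.flatnonzero(robust_mask)},
    )
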