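"""Synthetic cohorts with a planted FC-mood latent component and outcomes.

The generator emulates the statistical structure the analysis assumes, at
the geometry of a naturalistic depression cohort: n = 135 subjects, a
54-region subcortical parcellation giving p = 1431 FC edges, a q = 37-item
mood profile (10 PANAS-PA + 10 PANAS-NA + 17 HRSD-17 items), roughly 62% of
subjects completing the 8-week follow-up, and a posttreatment outcome driven
by the latent FC score.

One latent component is planted: with subject factor ``t ~ N(0, 1)``,

    X_i = gamma_x * t_i * u' + noise,   Y*_i = gamma_y * t_i * v' + noise,

where ``u`` (sparse, non-negative — higher connectivity loads with greater
negative affect) and ``v`` (negative on positive-affect items, positive on
negative-affect and depression items) are unit-norm saliences.  Continuous
item values ``Y*`` are mapped onto each instrument's ordinal range by
monotone quantile discretization.  Outcomes: baseline HRSD-17 totals are
drawn over the moderate-to-severe inclusion range (14-33); the posttreatment
total increases with ``t`` (higher latent score, worse outcome); an optional
binary outcome with a planted log odds ratio per unit of the (standardized)
FC projection supports odds-ratio recovery studies.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .connectivity import RoiTimeSeries, devectorize, make_pair_labels, n_edges
from .pls import SYMPTOM_ITEMS, SYMPTOM_ITEM_RANGES, DataBlocks

__all__ = ["SyntheticConfig", "OutcomeConfig", "generate_cohort", "generate_timeseries",
           "default_region_labels"]

_SUBCORTEX = ("HP", "THA", "AMG", "PUT", "CAU", "NAc", "GP")


def default_region_labels(n_regions: int = 54) -> list[str]:
    """Synthetic parcel names patterned on a 54-subregion subcortical atlas."""
    labels = []
    i = 0
    while len(labels) < n_regions:
        struct = _SUBCORTEX[i % len(_SUBCORTEX)]
        hemi = "lh" if (i // len(_SUBCORTEX)) % 2 == 0 else "rh"
        labels.append(f"{struct}-{i // (2 * len(_SUBCORTEX)) + 1}-{hemi}")
        i += 1
    return labels


@dataclass
class OutcomeConfig:
    """Posttreatment outcome model.

    ``post = clip(round(beta0 + beta_score * t + noise), 0, 52)``; response
    and remission follow from the standard definitions.  ``log_or`` (if set)
    additionally generates a binary outcome by a logistic model on the
    standardized FC projection, with the stated log odds ratio per score
    unit.
    """

    beta0: float = 8.0
    beta_score: float = 3.0
    outcome_noise_sd: float = 5.0
    log_or: float | None = None
    logit_intercept: float = 0.0


@dataclass
class SyntheticConfig:
    """Study-geometry defaults: 135 subjects, 1431 edges, 37 items."""

    n: int = 135
    p: int = n_edges(54)
    q: int = 37
    fc_sparsity: float = 0.05       # fraction of edges carrying the planted signal
    # signal scales (SD units of the noise), calibrated so the first latent
    # component explains roughly half of the cross-covariance at n = 135 —
    # the regime of the moderate-to-severe depression cohorts this emulates
    gamma_x: float = 4.2
    gamma_y: float = 4.2
    noise_sd: float = 1.0
    completer_fraction: float = 84 / 135
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    seed: int = 0
    structure_seed: int | None = None   # share planted saliences across cohorts
    # time-series mode
    timeseries_mode: bool = False
    n_frames: int = 240
    n_regions: int = 54
    ts_edge_strength: float = 0.15  # planted per-edge correlation shift per unit t

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3 subjects")
        if not 0 < self.completer_fraction <= 1:
            raise ValueError("completer_fraction must be in (0, 1]")


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("salience vector is identically zero")
    return v / norm


def _fc_salience(rng: np.random.Generator, p: int, sparsity: float) -> np.ndarray:
    # equal positive weight on a random sparse support (FC up with negative
    # affect); uniform magnitudes keep the planted direction invariant to
    # per-column standardization, so it is the recoverable ground truth
    k = max(1, round(sparsity * p))
    u = np.zeros(p)
    u[rng.choice(p, size=k, replace=False)] = 1.0
    return _unit(u)


def _mood_salience(rng: np.random.Generator, q: int) -> np.ndarray:
    v = np.abs(rng.normal(loc=1.0, scale=0.3, size=q))
    if q == 37:
        v[:10] *= -1.0  # positive-affect items load negatively
    else:
        v[: q // 3] *= -1.0
    return _unit(v)


def _discretize_items(y_cont: np.ndarray, ranges) -> np.ndarray:
    """Monotone quantile mapping of each continuous column onto its ordinal range."""
    n, q = y_cont.shape
    out = np.empty((n, q))
    for j in range(q):
        lo, hi = ranges[j % len(ranges)]
        n_levels = hi - lo + 1
        ranks = y_cont[:, j].argsort().argsort()  # 0..n-1, monotone in value
        out[:, j] = lo + np.minimum((ranks * n_levels) // n, n_levels - 1)
    return out


def generate_cohort(config: SyntheticConfig) -> tuple[DataBlocks, pd.DataFrame, dict]:
    """One cohort: FC block, subject/outcome table, and the planted ground truth.

    Returns ``(blocks, subjects, ground_truth)`` where ``subjects`` holds the
    covariates and outcomes (posttreatment scores are NaN for
    non-completers) and ``ground_truth`` holds the planted saliences, latent
    factor and effect sizes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.gamma_x == 0 or cfg.gamma_y == 0:
        warnings.warn(
            "zero planted signal: recovery tests on this cohort are uninformative",
            UserWarning,
            stacklevel=2,
        )
    struct_rng = (rng if cfg.structure_seed is None
                  else np.random.default_rng(cfg.structure_seed))
    u = _fc_salience(struct_rng, cfg.p, cfg.fc_sparsity)
    v = _mood_salience(struct_rng, cfg.q)
    t = rng.normal(size=cfg.n)

    X = cfg.gamma_x * np.outer(t, u) + rng.normal(scale=cfg.noise_sd, size=(cfg.n, cfg.p))
    y_cont = cfg.gamma_y * np.outer(t, v) + rng.normal(scale=cfg.noise_sd, size=(cfg.n, cfg.q))
    ranges = SYMPTOM_ITEM_RANGES if cfg.q == 37 else ((1, 5),) * cfg.q
    Y = _discretize_items(y_cont, ranges)

    subject_ids = [f"sub-{i + 1:04d}" for i in range(cfg.n)]
    if cfg.p == n_edges(54):
        x_names = [f"{a}|{b}" for a, b in make_pair_labels(default_region_labels(54))]
    else:
        x_names = [f"edge_{j:05d}" for j in range(cfg.p)]
    y_names = list(SYMPTOM_ITEMS) if cfg.q == 37 else [f"item_{j:02d}" for j in range(cfg.q)]

    # demographic covariates at naturalistic-cohort scale
    age = np.clip(rng.normal(29.4, 8.4, cfg.n), 18, 55)
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": np.round(age, 1),
            "sex": rng.binomial(1, 0.689, cfg.n),  # 1 = female
            "education_years": np.round(np.clip(rng.normal(15.8, 2.2, cfg.n), 6, 22), 1),
            "bmi": np.round(np.clip(rng.normal(22.0, 3.3, cfg.n), 15, 35), 1),
            "head_motion": np.round(rng.lognormal(np.log(0.12), 0.4, cfg.n), 4),
            "age_of_onset": np.round(np.minimum(np.clip(rng.normal(27.7, 8.8, cfg.n), 12, 55), age), 1),
            "episode_duration": np.round(rng.lognormal(np.log(3.5), 0.9, cfg.n), 1),
        }
    )

    # outcomes: inclusion requires moderate-to-severe baseline severity
    oc = cfg.outcome
    baseline = rng.integers(14, 34, size=cfg.n)
    post = np.clip(
        np.round(oc.beta0 + oc.beta_score * t + rng.normal(scale=oc.outcome_noise_sd, size=cfg.n)),
        0, 52,
    ).astype(int)
    n_completers = max(1, round(cfg.completer_fraction * cfg.n))
    completers = np.zeros(cfg.n, dtype=bool)
    completers[rng.choice(cfg.n, size=n_completers, replace=False)] = True
    subjects["baseline_hrsd"] = baseline
    subjects["post_hrsd"] = np.where(completers, post, np.nan)

    ground_truth = {
        "true_fc_salience": u,
        "true_mood_salience": v,
        "latent_factor": t,
        "gamma_x": cfg.gamma_x,
        "gamma_y": cfg.gamma_y,
        "completers": completers,
        "outcome": asdict(oc),
        "seed": cfg.seed,
    }
    if oc.log_or is not None:
        # FC projection on the standardized block — the scale on which the
        # pipeline's fitted FC scores live
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        fc_proxy = Xs @ u
        logits = oc.logit_intercept + oc.log_or * fc_proxy
        subjects["binary_outcome"] = rng.binomial(1, 1.0 / (1.0 + np.exp(-logits)))
        ground_truth["fc_proxy_score"] = fc_proxy
        ground_truth["planted_log_or"] = oc.log_or

    blocks = DataBlocks(
        X=X,
        Y=Y,
        subject_ids=subject_ids,
        x_names=x_names,
        y_names=y_names,
        covariates=subjects[["age", "sex", "education_years", "bmi", "head_motion"]].to_numpy(),
        covariate_names=["age", "sex", "education_years", "bmi", "head_motion"],
    )
    return blocks, subjects, ground_truth


# ---------------------------------------------------------------------------
# Time-series mode
# ---------------------------------------------------------------------------


def _nearest_correlation(mat: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a valid (positive-definite) correlation matrix.

    Eigenvalue clipping followed by diagonal renormalization; shrinks toward
    the identity if clipping alone does not produce a usable matrix.
    """
    m = (mat + mat.T) / 2
    for shrink in (0.0, 0.1, 0.3, 0.5):
        cand = (1 - shrink) * m + shrink * np.eye(m.shape[0])
        w, q = np.linalg.eigh(cand)
        cand = (q * np.clip(w, eps, None)) @ q.T
        d = np.sqrt(np.diag(cand))
        cand = cand / np.outer(d, d)
        np.fill_diagonal(cand, 1.0)
        if np.linalg.eigvalsh(cand).min() > 0:
            return cand
    raise ValueError("could not project to a positive-definite correlation matrix")


def generate_timeseries(config: SyntheticConfig) -> tuple[list[RoiTimeSeries], dict]:
    """Per-subject multivariate-normal ROI series with a planted edge pattern.

    Each subject's correlation matrix is ``base + t_i * strength * pattern``
    (projected to the nearest valid correlation matrix), where the sparse
    symmetric ``pattern`` marks the planted edges; feeding the series through
    ``compute_fc`` therefore recovers an FC block whose planted component
    scales with the subject factor ``t``.  Framewise-displacement traces are
    attached (low-motion baseline) so scrubbing can be exercised end to end.
    """
    cfg = config
    if not cfg.timeseries_mode:
        raise ValueError("config.timeseries_mode is off")
    if cfg.n_frames < 120:
        raise ValueError("need at least 120 frames per subject")
    rng = np.random.default_rng(cfg.seed)
    d = cfg.n_regions
    labels = default_region_labels(d)

    # shared base connectivity: weak random factor structure
    loadings = rng.normal(scale=0.4, size=(d, 3))
    base = _nearest_correlation(loadings @ loadings.T + 0.7 * np.eye(d))

    p = n_edges(d)
    struct_rng = (rng if cfg.structure_seed is None
                  else np.random.default_rng(cfg.structure_seed))
    u = _fc_salience(struct_rng, p, cfg.fc_sparsity)
    pattern = devectorize((u > 0).astype(float))
    t = rng.normal(size=cfg.n)

    series = []
    for i in range(cfg.n):
        target = base + cfg.ts_edge_strength * t[i] * pattern
        np.fill_diagonal(target, 1.0)
        corr = _nearest_correlation(target)
        chol = np.linalg.cholesky(corr)
        frames = rng.normal(size=(cfg.n_frames, d)) @ chol.T
        fd = rng.lognormal(np.log(0.1), 0.35, size=cfg.n_frames)
        series.append(
            RoiTimeSeries(
                subject_id=f"sub-{i + 1:04d}",
                data=frames,
                region_labels=labels,
                fd=fd,
            )
        )
    ground_truth = {
        "true_fc_salience": u,
        "planted_edges": set(np.flatnonzero(u > 0).tolist()),
        "latent_factor": t,
        "base_correlation": base,
        "seed": cfg.seed,
    }
    return series, ground_truth
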