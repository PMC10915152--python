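"""Generalization of a fitted PLSC model to an independent cohort.

Two complementary checks: (1) loading similarity — the Pearson correlation
between the component's loading vectors estimated independently in each
cohort; (2) score agreement — predicted scores, obtained by projecting the
new cohort onto the training saliences, correlated with the scores of the
cohort's own fit.  The new cohort is standardized with its own column
statistics before projection, which removes scanner/site scale effects.
Components of independent fits are identified only up to sign, so each
metric is computed after sign alignment (similarity reported with the sign
that maximizes it, and recorded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pls import DataBlocks, PlsModel, ScoreSet, _standardize, compute_scores

__all__ = ["ReplicationReport", "project_external", "compare_models"]


@dataclass
class ReplicationReport:
    fc_loading_similarity: float
    mood_loading_similarity: float
    fc_score_agreement: float
    mood_score_agreement: float
    fc_loading_p: float
    mood_loading_p: float
    fc_score_p: float
    mood_score_p: float
    component: int = 0
    sign_flipped: bool = False


def _check_feature_match(model: PlsModel, blocks: DataBlocks) -> None:
    if blocks.X.shape[1] != model.p or blocks.Y.shape[1] != model.q:
        raise ValueError(
            f"feature dimension mismatch: model p={model.p}, q={model.q}; "
            f"cohort p={blocks.X.shape[1]}, q={blocks.Y.shape[1]}"
        )
    for model_names, block_names, what in (
        (model.x_names, blocks.x_names, "FC pair"),
        (model.y_names, blocks.y_names, "symptom item"),
    ):
        if model_names is not None and block_names is not None:
            bad = [
                (i, a, b)
                for i, (a, b) in enumerate(zip(model_names, block_names))
                if a != b
            ]
            if bad:
                head = "; ".join(
                    f"position {i}: model={a!r} cohort={b!r}" for i, a, b in bad[:5]
                )
                raise ValueError(f"{what} label mismatch ({len(bad)} total): {head}")


def project_external(model: PlsModel, new_blocks: DataBlocks) -> ScoreSet:
    """Predicted scores of an external cohort under the training saliences.

    The new blocks are standardized with the *new cohort's own* column
    statistics (matching the training-time mode), then multiplied by the
    training saliences.  Feature ordering must match the model exactly;
    label mismatches raise with the first offending positions listed.
    """
    _check_feature_match(model, new_blocks)
    Xs, *_ = _standardize(new_blocks.X, model.standardize, new_blocks.x_names)
    Ys, *_ = _standardize(new_blocks.Y, model.standardize, new_blocks.y_names)
    return ScoreSet(fc_scores=Xs @ model.fc_saliences,
                    mood_scores=Ys @ model.mood_saliences)


def _aligned_corr(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """Pearson r after sign alignment; returns (|best| r, p, flipped)."""
    r, p = stats.pearsonr(a, b)
    if r < 0:
        return -float(r), float(p), True
    return float(r), float(p), False


def compare_models(
    model_a: PlsModel,
    model_b: PlsModel,
    blocks_b: DataBlocks,
    component: int = 0,
) -> ReplicationReport:
    """Cross-cohort agreement between two independently fitted models.

    ``model_a`` is the training (main-sample) model, ``model_b`` the model
    fitted on the replication cohort ``blocks_b``.  Loading similarities
    correlate the two fits' loading vectors for the chosen component
    (default: the first); score agreements correlate the predicted scores
    (``project_external(model_a, blocks_b)``) with the replication fit's own
    scores.  All metrics are sign-aligned; one joint flip indicator is
    derived from the mood-loading alignment and applied consistently.
    """
    _check_feature_match(model_a, blocks_b)
    if model_a.p != model_b.p or model_a.q != model_b.q:
        raise ValueError("models were fitted on differing feature spaces")
    if model_a.fc_loadings is None or model_b.fc_loadings is None:
        raise ValueError("both models must carry training loadings (fit with "
                         "attach_training_outputs=True)")
    c = component
    fc_r, fc_p, _ = _aligned_corr(model_a.fc_loadings[:, c], model_b.fc_loadings[:, c])
    mood_r, mood_p, flipped = _aligned_corr(
        model_a.mood_loadings[:, c], model_b.mood_loadings[:, c]
    )

    predicted = project_external(model_a, blocks_b)
    observed = compute_scores(model_b, blocks_b)
    fc_sr, fc_sp, _ = _aligned_corr(predicted.fc_scores[:, c], observed.fc_scores[:, c])
    mood_sr, mood_sp, _ = _aligned_corr(
        predicted.mood_scores[:, c], observed.mood_scores[:, c]
    )
    return ReplicationReport(
        fc_loading_similarity=fc_r,
        mood_loading_similarity=mood_r,
        fc_score_agreement=fc_sr,
        mood_score_agreement=mood_sr,
        fc_loading_p=fc_p,
        mood_loading_p=mood_p,
        fc_score_p=fc_sp,
        mood_score_p=mood_sp,
        component=c,
        sign_flipped=flipped,
    )
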