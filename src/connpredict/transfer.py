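"""Cross-cohort transfer of frozen predictive models.

A model fitted once on the full discovery cohort is applied to an external
cohort as a pure dot product — ``intercept + X_new @ coefficients`` — with no
refitting and no recentering on external statistics.  Because external
cohorts typically lack the discovery battery's cognitive scores, validation
correlates the model-predicted score with the external cohort's age,
partialling out mean framewise displacement, under Bonferroni correction
across all models applied to that cohort (nine by default: age plus eight
cognitive metrics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import IncompatibleFeatureSpaceError, InvalidParameterError
from .prediction import PLSResults, partial_accuracy

__all__ = [
    "TransferResult",
    "apply_model",
    "load_model",
    "save_model",
    "validate_transfer",
]


@dataclass(frozen=True)
class TransferResult:
    """External-validation outcome for one frozen model."""

    target_name: str
    partial_r: float
    p: float
    bonferroni_alpha: float
    passed: bool


def apply_model(
    model: PLSResults, X_new, *, atlas_hash: str | None = None
) -> np.ndarray:
    """Predict scores for an external cohort from a frozen model.

    ``atlas_hash`` (when provided, e.g. read from the external connectome
    file's provenance) must match the hash recorded at training; a mismatch
    means the edge orderings cannot be assumed compatible.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.params.shape[0]:
        raise IncompatibleFeatureSpaceError(
            f"external edge matrix has {X_new.shape[1] if X_new.ndim == 2 else '?'}"
            f" edges; model expects {model.params.shape[0]}"
        )
    if (
        atlas_hash is not None
        and model.atlas_hash is not None
        and atlas_hash != model.atlas_hash
    ):
        raise IncompatibleFeatureSpaceError(
            f"atlas hash mismatch: model {model.atlas_hash}, data {atlas_hash}"
        )
    return X_new @ model.params + model.intercept


def validate_transfer(
    predicted,
    external_age,
    external_fd,
    *,
    n_models_tested: int = 9,
    alpha: float = 0.05,
    target_name: str = "target",
) -> TransferResult:
    """Partial correlation of predicted scores with external age, Bonferroni.

    The sign convention is preserved: an age model should transfer with a
    positive partial r, cognition models (scores declining with age) with a
    negative one.  ``passed`` requires ``p < alpha / n_models_tested``.
    """
    if n_models_tested < 1:
        raise InvalidParameterError("n_models_tested must be >= 1")
    r, p = partial_accuracy(external_age, predicted, external_fd)
    threshold = alpha / n_models_tested
    return TransferResult(
        target_name=target_name,
        partial_r=r,
        p=p,
        bonferroni_alpha=threshold,
        passed=bool(p < threshold),
    )


def save_model(model: PLSResults, path) -> None:
    """Serialize a frozen model (metadata + coefficient vector) as JSON."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def load_model(path) -> PLSResults:
    """Load a model saved by :func:`save_model`."""
    return PLSResults.from_dict(json.loads(Path(path).read_text()))
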