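"""Sensitivity and PPV of predicted structures with slippage tolerance.

A predicted pair (i, j) counts as correct if the known structure contains
(i, j), (i-1, j), (i+1, j), (i, j-1) or (i, j+1) — a single-position
slippage allowance reflecting uncertainty in comparative structure
determination and thermal fluctuation.  Sensitivity counts known pairs
matched by at least one predicted pair under the mirrored rule; PPV counts
predicted pairs matched by at least one known pair.  A ratio with a zero
denominator is reported as 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import FormatError, SecondaryStructure

__all__ = ["PredictionScore", "score_structure"]


@dataclass(frozen=True)
class PredictionScore:
    sensitivity: float
    ppv: float
    n_known: int
    n_predicted: int
    n_correct: int
    empty_known: bool = False
    empty_prediction: bool = False

    @property
    def f_measure(self) -> float:
        s, p = self.sensitivity, self.ppv
        return 0.0 if s + p == 0 else 2 * s * p / (s + p)


def _slip_matches(pair: tuple, other: frozenset) -> bool:
    i, j = pair
    return any(
        cand in other
        for cand in ((i, j), (i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1))
    )


def score_structure(
    predicted: SecondaryStructure, known: SecondaryStructure
) -> PredictionScore:
    """Score a prediction against a known structure on the same sequence."""
    if predicted.sequence_length != known.sequence_length:
        raise FormatError(
            f"sequence length mismatch: predicted {predicted.sequence_length}, "
            f"known {known.sequence_length}"
        )
    n_pred = len(predicted.pairs)
    n_known = len(known.pairs)
    n_correct = sum(1 for p in predicted.pairs if _slip_matches(p, known.pairs))
    n_found = sum(1 for k in known.pairs if _slip_matches(k, predicted.pairs))
    return PredictionScore(
        sensitivity=n_found / n_known if n_known else 0.0,
        ppv=n_correct / n_pred if n_pred else 0.0,
        n_known=n_known,
        n_predicted=n_pred,
        n_correct=n_correct,
        empty_known=n_known == 0,
        empty_prediction=n_pred == 0,
    )
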