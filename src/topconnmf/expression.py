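"""The in-memory container for expression data.

An :class:`ExpressionMatrix` holds a nonnegative ``g x s`` matrix of
expression values (``g`` samples in rows, ``s`` biomarkers in columns)
together with the per-sample metadata the downstream analysis needs: a
class label (``control`` / ``diseased``) and a nonnegative time index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

CONTROL = "control"
DISEASED = "diseased"
VALID_CLASSES = (CONTROL, DISEASED)


@dataclass
class ExpressionMatrix:
    """Nonnegative samples-by-biomarkers expression matrix with metadata.

    Parameters
    ----------
    values
        ``g x s`` array, all entries finite and ``>= 0``.
    feature_ids
        ``s`` unique biomarker identifiers (column names).
    sample_class
        ``g`` labels, each ``"control"`` or ``"diseased"``.
    sample_time
        ``g`` nonnegative time indices (equally spaced collection
        points; the unit is whatever the study design uses).
    sample_ids
        Optional ``g`` unique sample identifiers; generated if omitted.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_class: list[str]
    sample_time: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at sample row {i}, feature column {j}"
            )
        g, s = self.values.shape
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != s:
            raise ValidationError(
                f"expected {s} feature ids, got {len(self.feature_ids)}"
            )
        if len(set(self.feature_ids)) != s:
            raise ValidationError("feature ids must be unique")
        self.sample_class = [str(c) for c in self.sample_class]
        if len(self.sample_class) != g:
            raise ValidationError(f"expected {g} class labels, got {len(self.sample_class)}")
        bad = sorted(set(self.sample_class) - set(VALID_CLASSES))
        if bad:
            raise ValidationError(f"unknown class labels {bad}; expected {VALID_CLASSES}")
        self.sample_time = np.asarray(self.sample_time, dtype=float)
        if self.sample_time.shape != (g,):
            raise ValidationError(f"expected {g} time indices")
        if np.any(self.sample_time < 0) or not np.all(np.isfinite(self.sample_time)):
            raise ValidationError("time indices must be finite and nonnegative")
        if not self.sample_ids:
            self.sample_ids = [f"sample_{i:04d}" for i in range(g)]
        self.sample_ids = [str(i) for i in self.sample_ids]
        if len(self.sample_ids) != g or len(set(self.sample_ids)) != g:
            raise ValidationError("sample ids must be unique, one per row")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_mask(self, label: str) -> np.ndarray:
        """Boolean mask over samples belonging to ``label``."""
        return np.asarray([c == label for c in self.sample_class])


def as_values(X) -> np.ndarray:
    """Accept an :class:`ExpressionMatrix` or a bare array; return the array."""
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)
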