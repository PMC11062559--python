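"""Scikit-learn estimator view of template matching.

:class:`TemplateMatcher` is a nearest-template classifier: ``fit`` learns
one trial-averaged population template per condition, ``transform`` maps
trials to their Pearson correlations with each template, and ``predict``
assigns the condition whose template correlates best. It composes with
sklearn pipelines and model selection, and backs the module-level
:func:`templatest.metrics.specificity_index` for the two-template case.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import ValidationError
from .metrics import row_correlations
from .session import ConditionTemplate

__all__ = ["TemplateMatcher"]


class TemplateMatcher(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Nearest trial-averaged-template classifier with correlation features.

    Parameters
    ----------
    None; the estimator is parameter-free — its behaviour is fully
    determined by the training data.

    Attributes
    ----------
    classes_ : ndarray of shape (n_classes,)
        Condition labels, sorted.
    templates_ : ndarray of shape (n_classes, n_features)
        Per-condition mean population vectors λ.
    counts_ : ndarray of shape (n_classes,)
        Trials averaged per template.
    n_features_in_ : int

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[0., 1, 2], [0, 1, 3], [3, 1, 0], [2, 1, 0]])
    >>> y = np.array(["up", "up", "down", "down"])
    >>> tm = TemplateMatcher().fit(X, y)
    >>> tm.predict([[0, 1, 2.5]])
    array(['up'], dtype='<U4')
    """

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_features=2)
        self.classes_, inverse = np.unique(y, return_inverse=True)
        if self.classes_.size < 1:
            raise ValidationError("need at least one class")
        n_classes = self.classes_.size
        self.templates_ = np.empty((n_classes, X.shape[1]))
        self.counts_ = np.empty(n_classes, dtype=int)
        for k in range(n_classes):
            mask = inverse == k
            self.counts_[k] = mask.sum()
            self.templates_[k] = X[mask].mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Correlation of each trial with each class template.

        Returns an ``(n_trials, n_classes)`` matrix; NaN where a trial or
        template has zero variance.
        """
        check_is_fitted(self, "templates_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return np.column_stack(
            [row_correlations(X, t) for t in self.templates_]
        )

    def predict(self, X):
        corr = self.transform(X)
        # undefined correlations never win the argmax
        corr = np.nan_to_num(corr, nan=-np.inf)
        return self.classes_[np.argmax(corr, axis=1)]

    def decision_function(self, X):
        """Two-class case: cor(template_1) − cor(template_0) per trial."""
        corr = self.transform(X)
        if corr.shape[1] != 2:
            raise ValidationError("decision_function requires exactly 2 classes")
        return corr[:, 1] - corr[:, 0]

    def specificity(self, X, correct_labels, wrong_labels):
        """ρ per trial: cor(λ_correct, r) − cor(λ_wrong, r).

        ``correct_labels`` / ``wrong_labels`` are per-trial class labels
        (broadcast from scalars).
        """
        corr = self.transform(X)
        n = corr.shape[0]
        correct_labels = np.broadcast_to(np.asarray(correct_labels), (n,))
        wrong_labels = np.broadcast_to(np.asarray(wrong_labels), (n,))
        class_index = {c: k for k, c in enumerate(self.classes_)}
        try:
            ci = np.array([class_index[c] for c in correct_labels])
            wi = np.array([class_index[c] for c in wrong_labels])
        except KeyError as exc:
            raise ValidationError(f"unknown class label: {exc.args[0]!r}") from exc
        rows = np.arange(n)
        return corr[rows, ci] - corr[rows, wi]

    def templates_as_dict(self, neuron_ids=None) -> dict[str, ConditionTemplate]:
        """Fitted templates as the package's domain objects."""
        check_is_fitted(self, "templates_")
        return {
            str(c): ConditionTemplate(
                condition=str(c), mean_vector=self.templates_[k], n_trials=int(self.counts_[k])
            )
            for k, c in enumerate(self.classes_)
        }

    @classmethod
    def from_templates(cls, templates: dict[str, ConditionTemplate]) -> "TemplateMatcher":
        """Build a fitted matcher directly from precomputed templates."""
        if not templates:
            raise ValidationError("need at least one template")
        obj = cls()
        labels = sorted(templates)
        vecs = [np.asarray(templates[c].mean_vector, dtype=float) for c in labels]
        lengths = {v.size for v in vecs}
        if len(lengths) != 1:
            raise ValidationError("templates have inconsistent lengths")
        obj.classes_ = np.asarray(labels)
        obj.templates_ = np.vstack(vecs)
        obj.counts_ = np.asarray([templates[c].n_trials for c in labels], dtype=int)
        obj.n_features_in_ = vecs[0].size
        return obj
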