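"""Model/Results interface over the functional pipeline.

``BloodPLSClassifier`` holds a preprocessed samples x probes matrix and the
dummy-coded case/control response; ``fit()`` runs the inner analysis
(LOO-CV model-order choice, jackknife probe selection, refit) and returns a
``BloodPLSResults`` carrying the selected signature, coefficient estimates
with jackknife uncertainties, and a ``summary()`` table.  Validation
(double cross-validation, permutation null, learning curve) hangs off the
model; score prediction, the global test of the signature and plotting hang
off the results.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import globaltest as _gt
from . import validate as _val
from .containers import (
    BloodsigError,
    ExpressionMatrix,
    SampleAnnotation,
    response_from_labels,
)
from .pls import classify, predict_score
from .plsjack import SelectionResult, default_a_max, select_and_refit


class BloodPLSClassifier:
    """PLS1 case/control classifier with jackknife feature selection.

    Parameters
    ----------
    endog : response; either +-1 codes or class-label strings.
    exog : samples x probes matrix (preprocessed: complete, standardized).
    probe_ids, array_ids : optional identifiers.
    alpha : jackknife selection threshold (p <= alpha keeps a probe).
    a_max : cap on the number of latent components (default min(30, n-2)).
    """

    def __init__(
        self,
        endog,
        exog,
        probe_ids: Optional[Sequence] = None,
        array_ids: Optional[Sequence] = None,
        alpha: float = 0.05,
        a_max: Optional[int] = None,
    ) -> None:
        endog = np.asarray(endog)
        if endog.dtype.kind in "OU":
            self.endog = response_from_labels(endog)
        else:
            endog = endog.astype(float)
            if not set(np.unique(endog)) <= {-1.0, 1.0}:
                raise BloodsigError("numeric endog must be coded -1/+1")
            self.endog = endog
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != len(self.endog):
            raise BloodsigError("exog must be samples x probes matching endog")
        n, p = self.exog.shape
        self.probe_ids = (
            np.array([f"p{i}" for i in range(p)], dtype=object)
            if probe_ids is None
            else np.asarray(probe_ids, dtype=object)
        )
        self.array_ids = (
            np.array([f"s{i}" for i in range(n)], dtype=object)
            if array_ids is None
            else np.asarray(array_ids, dtype=object)
        )
        self.alpha = alpha
        self.a_max = default_a_max(n) if a_max is None else a_max

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_expression(
        cls,
        matrix: ExpressionMatrix,
        annot: SampleAnnotation,
        **kwargs,
    ) -> "BloodPLSClassifier":
        """Build from a preprocessed probes x arrays matrix and annotation."""
        annot.check_matches(matrix)
        aligned = annot.aligned_to(matrix.array_ids)
        y = response_from_labels(aligned["class_label"])
        return cls(
            endog=y,
            exog=matrix.values.T,
            probe_ids=matrix.probe_ids,
            array_ids=matrix.array_ids,
            **kwargs,
        )

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, labels: Sequence[str], **kwargs
    ) -> "BloodPLSClassifier":
        """Build from a samples x probes DataFrame and per-sample labels."""
        return cls(
            endog=np.asarray(labels, dtype=object),
            exog=frame.to_numpy(dtype=float),
            probe_ids=frame.columns.to_numpy(dtype=object),
            array_ids=frame.index.to_numpy(dtype=object),
            **kwargs,
        )

    # -- estimation ----------------------------------------------------------
    def fit(self) -> "BloodPLSResults":
        sel = select_and_refit(
            self.exog,
            self.endog,
            alpha=self.alpha,
            A_max=self.a_max,
            probe_ids=self.probe_ids,
        )
        return BloodPLSResults(self, sel)

    # -- validation ----------------------------------------------------------
    def cross_validate(self, store_selected: bool = False) -> _val.CVResult:
        """Outer leave-one-out double cross-validation."""
        return _val.double_cv(
            self.exog,
            self.endog,
            alpha=self.alpha,
            A_max=self.a_max,
            probe_ids=self.probe_ids,
            array_ids=self.array_ids,
            store_selected=store_selected,
        )

    def permutation_test(self, k: int, seed: int, observed=None) -> _val.PermutationResult:
        return _val.permutation_test(
            self.exog,
            self.endog,
            k=k,
            seed=seed,
            alpha=self.alpha,
            A_max=self.a_max,
            observed=observed,
        )

    def learning_curve(
        self, fractions: Sequence[float], reps: int, seed: int
    ) -> _val.LearningCurveResult:
        return _val.learning_curve(
            self.exog,
            self.endog,
            fractions=fractions,
            reps=reps,
            seed=seed,
            alpha=self.alpha,
            A_max=self.a_max,
        )


class BloodPLSResults:
    """Fitted signature: selected probes, coefficients, uncertainties."""

    def __init__(self, model: BloodPLSClassifier, selection: SelectionResult):
        self.model = model
        self.selection = selection

    # convenience accessors
    @property
    def selected_probe_ids(self) -> np.ndarray:
        return self.selection.selected_probe_ids

    @property
    def n_selected(self) -> int:
        return len(self.selection.selected_probe_ids)

    @property
    def n_components(self) -> int:
        return self.selection.a_opt2

    @property
    def params(self) -> pd.Series:
        """Regression coefficients of the refitted model (selected probes)."""
        m = self.selection.model
        return pd.Series(
            m.B[:, m.A - 1], index=self.selected_probe_ids, name="coef"
        )

    @property
    def jackknife_table(self) -> pd.DataFrame:
        jk = self.selection.jackknife
        return pd.DataFrame(
            {
                "coef": jk.b_full,
                "se": jk.se,
                "t": jk.t,
                "p": jk.p,
                "selected": np.isin(
                    self.model.probe_ids, self.selected_probe_ids
                ),
            },
            index=self.model.probe_ids,
        )

    # prediction ------------------------------------------------------------
    def predict(self, X_new, a: Optional[int] = None) -> np.ndarray:
        """Raw prediction scores for new samples over the selected probes.

        ``X_new`` may be a DataFrame keyed by probe id (any superset of the
        signature) or an array over the full original probe set.
        """
        if isinstance(X_new, pd.DataFrame):
            return predict_score(self.selection.model, X_new, a)
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] == len(self.model.probe_ids):
            X_new = X_new[:, self.selection.selected_idx]
        return predict_score(self.selection.model, X_new, a)

    def classify(self, X_new, a: Optional[int] = None):
        return classify(self.predict(X_new, a))

    # signature characterisation ---------------------------------------------
    def global_test(self, B: int = 10_000, seed: int = 0) -> _gt.GlobalTestResult:
        """Permutation global test of the selected signature."""
        X = self.model.exog[:, self.selection.selected_idx]
        return _gt.null_calibrate(
            X, self.model.endog, B=B, seed=seed, probe_ids=self.selected_probe_ids
        )

    def summary(self) -> str:
        sel = self.selection
        n, p = self.model.exog.shape
        err1 = sel.err1[sel.a_opt1 - 1]
        err2 = sel.err2[sel.a_opt2 - 1]
        lines = [
            "PLS1 whole-blood signature (jackknife-selected)",
            "=" * 52,
            f"samples:                    {n}",
            f"probes offered:             {p}",
            f"probes selected (p<={self.model.alpha:g}): {self.n_selected}",
            f"components, first LOO-CV:   {sel.a_opt1}"
            f"  (CV misclassification {err1:.3f})",
            f"components, refit LOO-CV:   {sel.a_opt2}"
            f"  (CV misclassification {err2:.3f})",
        ]
        if sel.fallback_used:
            lines.append("note: no probe passed; smallest-p fallback used")
        top = self.jackknife_table.query("selected").nsmallest(10, "p")
        lines.append("")
        lines.append("top probes by jackknife p:")
        lines.append(
            top[["coef", "se", "t", "p"]].to_string(float_format="%.4g")
        )
        return "\n".join(lines)

    # plotting ----------------------------------------------------------------
    def plot_scores(self, cv: Optional[_val.CVResult] = None, ax=None):
        """Sorted raw prediction scores, cases vs healthy (bar plot)."""
        import matplotlib.pyplot as plt

        if cv is None:
            scores = self.predict(self.model.exog)
            y = self.model.endog
        else:
            scores, y = cv.scores, cv.y_true
        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(-scores)
        colors = np.where(y[order] > 0, "firebrick", "forestgreen")
        ax.bar(np.arange(len(scores)), scores[order], color=list(colors), width=1.0)
        ax.axhline(0.0, color="black", lw=0.8)
        ax.set_xlabel("samples (sorted by score)")
        ax.set_ylabel("raw prediction score")
        return ax

    def plot_roc(self, cv: _val.CVResult, ax=None):
        import matplotlib.pyplot as plt

        auc, curve = _val.roc_auc(cv.scores, cv.y_true)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve[:, 0], curve[:, 1], drawstyle="steps-post")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"AUC = {auc:.2f}")
        return ax
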