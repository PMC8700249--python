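"""Mixed descriptive-inferential sequential feature selection.

Stage 1 (descriptive): rank every feature by the absolute point-biserial
correlation between the feature and the binary grade label. The
point-biserial coefficient is numerically identical to the Pearson
correlation with the labels coded 0/1.

Stage 2 (inferential): walk the ranking. At step k a logistic regression of
the label on the top-k features is fitted and its likelihood-ratio p-value
against the intercept-only model recorded; the walk stops at the first step
whose p-value fails to decrease strictly, and the features accumulated
before that step are selected (at least one is always kept). The cumulative
(nested-model) variant is the default because only nested fits give the
p-value sequence a monotone interpretation; a per-feature univariate variant
is available via ``mode="univariate"``.

No post-hoc p < 0.05 filter is applied: features whose step p-value exceeds
0.05 remain selected if the sequence was still decreasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["SelectionResult", "point_biserial", "rank_by_point_biserial", "sequential_select"]


class SelectionError(ValueError):
    """The inputs cannot support a correlation/selection computation."""


@dataclass
class SelectionResult:
    ranking: list[str]
    pbc_values: dict[str, float]
    step_pvalues: list[float]
    selected: list[str]
    stop_step: int
    mode: str = "cumulative"
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ranking": self.ranking,
            "pbc_values": self.pbc_values,
            "step_pvalues": self.step_pvalues,
            "selected": self.selected,
            "stop_step": self.stop_step,
            "mode": self.mode,
            "warnings": self.warnings,
        }


def point_biserial(feature: np.ndarray, labels: np.ndarray) -> float:
    """Point-biserial correlation between a numeric feature and 0/1 labels.

    ``r = (M1 - M0)/s * sqrt(n1 n0 / n^2)`` with ``s`` the population
    standard deviation of the feature; identical to the Pearson correlation
    of the feature with the 0/1 coding.
    """
    x = np.asarray(feature, dtype=np.float64)
    y = np.asarray(labels)
    if x.shape != y.shape or x.ndim != 1:
        raise SelectionError("feature and labels must be equal-length 1-D vectors")
    if set(np.unique(y)) != {0, 1}:
        raise SelectionError("labels must contain both classes coded 0/1")
    s = x.std()  # population (ddof=0) standard deviation
    if s == 0:
        raise SelectionError("feature is constant; correlation undefined")
    n = x.size
    n1 = int((y == 1).sum())
    n0 = n - n1
    m1 = x[y == 1].mean()
    m0 = x[y == 0].mean()
    return float((m1 - m0) / s * np.sqrt(n1 * n0 / n**2))


def rank_by_point_biserial(
    X: pd.DataFrame, labels: np.ndarray
) -> tuple[list[str], dict[str, float]]:
    """Feature names sorted by descending |pbc|.

    Constant features get r = 0 and therefore sort last; ties keep the
    frozen column order (stable sort). "Constant" is judged with a relative
    tolerance so that columns equal up to float rounding (e.g. a shape index
    of identically shaped regions) do not pick up a spurious correlation
    from their last bits.
    """
    pbc: dict[str, float] = {}
    for name in X.columns:
        x = X[name].to_numpy(dtype=np.float64)
        if x.std() <= 1e-12 * max(1.0, float(np.abs(x).max())):
            pbc[name] = 0.0
            continue
        try:
            pbc[name] = point_biserial(x, labels)
        except SelectionError:
            pbc[name] = 0.0
    order = sorted(range(len(X.columns)), key=lambda i: -abs(pbc[X.columns[i]]))
    return [X.columns[i] for i in order], pbc


def _logit_pvalue(X: np.ndarray, y: np.ndarray) -> tuple[float, str | None]:
    """Likelihood-ratio p-value of a logistic fit vs the intercept-only model.

    Non-convergent or perfectly separated fits are treated as p = 0 (the
    model explains the labels arbitrarily well) with a warning message.
    """
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        last: Exception | None = None
        # newton first; BFGS handles rank-deficient designs (collinear
        # columns), where the rank-based model df keeps the LRT honest
        for method in ("newton", "bfgs"):
            try:
                res = sm.Logit(y, design).fit(disp=0, maxiter=500, method=method)
                p = float(res.llr_pvalue)
                if not np.isfinite(p):
                    return 0.0, "non-finite likelihood-ratio p-value; treated as 0"
                return p, None
            except Exception as exc:  # perfect separation and friends
                last = exc
        return 0.0, f"logistic fit failed ({type(last).__name__}); p-value treated as 0"


def sequential_select(
    X: pd.DataFrame,
    labels: np.ndarray,
    mode: str = "cumulative",
) -> SelectionResult:
    """Run the full two-stage selection on a feature matrix.

    Parameters
    ----------
    X
        One column per candidate feature, one row per observation.
    labels
        Binary grade labels (0 low, 1 high), one per row.
    mode
        ``"cumulative"`` fits the label on the top-k features at step k
        (default); ``"univariate"`` fits on the k-th ranked feature alone.
    """
    if X.shape[1] < 2:
        raise SelectionError("need at least two candidate features")
    y = np.asarray(labels)
    if set(np.unique(y)) != {0, 1}:
        raise SelectionError("labels must contain both classes coded 0/1")
    if mode not in ("cumulative", "univariate"):
        raise SelectionError(f"unknown selection mode {mode!r}")
    ranking, pbc = rank_by_point_biserial(X, y)
    # standardize columns: keeps the logistic optimizer well-conditioned
    # without changing likelihood-ratio p-values
    Xs = X[ranking].to_numpy(dtype=np.float64)
    sd = Xs.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xs - Xs.mean(axis=0)) / sd

    step_pvalues: list[float] = []
    notes: list[str] = []
    prev = np.inf
    n_selected = len(ranking)  # reached only if the sequence never stops decreasing
    stop = len(ranking)
    for k in range(1, len(ranking) + 1):
        cols = Xs[:, k - 1 : k] if mode == "univariate" else Xs[:, :k]
        p, note = _logit_pvalue(cols, y)
        if note:
            notes.append(f"step {k}: {note}")
            logger.warning("selection step %d: %s", k, note)
        step_pvalues.append(p)
        if p >= prev:  # strict decrease required to continue
            stop = k
            n_selected = max(1, k - 1)
            break
        prev = p
    return SelectionResult(
        ranking=ranking,
        pbc_values=pbc,
        step_pvalues=step_pvalues,
        selected=ranking[:n_selected],
        stop_step=stop,
        mode=mode,
        warnings=notes,
    )
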