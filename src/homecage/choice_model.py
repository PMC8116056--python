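"""Logistic choice-strategy model with history regressors.

Choice on each trial is modeled as ``P(left) = 1 / (1 + exp(-z))`` with

    z = b_S0*S0 + sum_i b_Si*Si + sum_i b_Ai*Ai + sum_i b_Ri*Ri
        + b_Savg*Savg + b_WSLS*WSLS + b0

where S0 is the current stimulus (+1 = lick-left-instructing pole position),
S1..S5 / A1..A5 / R1..R5 are the stimulus, choice and reward histories over
the last five trials (+1 = left / rewarded), Savg is the mean stimulus over
the last 20 trials, and WSLS = A1*R1 is a win-stay-lose-switch regressor.
P(left) > 0.5 predicts a left lick.

Model weights are maximum-likelihood fits with a small ridge (1e-4) on the
non-bias weights to stabilize separable windows.  Prediction accuracy is
assessed with a history-excluding cross-validation: within a 500-trial
window, nine 60-trial test blocks are placed with evenly spaced starts, and
each block's training set excludes the block plus 20 trials on either side,
guaranteeing that no training trial's history overlaps a test trial.  The
contribution of each regressor is measured by zeroing its fitted weight
(partial model) and bootstrapping the test set 1000 times; p is the fraction
of resamples where the partial model predicts better than the full model
(reported both with the strict rule and with ties counted half).  A
regressor significant (p < 0.05) in five consecutive 500-trial windows
(100-trial steps) marks a strategy the subject relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .trial_engine import Choice, Outcome, PolePosition, TrialRecord

__all__ = [
    "REGRESSOR_NAMES",
    "HISTORY_DEPTH",
    "SAVG_WINDOW",
    "ChoiceDesign",
    "ModelFit",
    "PartialModelResult",
    "build_design",
    "fit_logistic",
    "predict_left",
    "crossval_predict",
    "cv_blocks",
    "partial_model_pvalue",
    "sliding_window_analysis",
    "regressor_reliance",
    "shuffle_control",
    "penalized_loglik",
]

HISTORY_DEPTH = 5
SAVG_WINDOW = 20
RIDGE_DEFAULT = 1e-4

REGRESSOR_NAMES = (
    ["S0"]
    + [f"S{i}" for i in range(1, HISTORY_DEPTH + 1)]
    + [f"A{i}" for i in range(1, HISTORY_DEPTH + 1)]
    + [f"R{i}" for i in range(1, HISTORY_DEPTH + 1)]
    + ["Savg", "WSLS"]
)

CV_WINDOW = 500
CV_BLOCK = 60
CV_GUARD = 20
CV_REPEATS = 9


@dataclass
class ChoiceDesign:
    """Design matrix (one row per analyzable scored trial) and responses."""

    X: np.ndarray  # (n, n_regressors)
    y: np.ndarray  # (n,) 1 = left, 0 = right
    columns: list[str]
    trial_indices: np.ndarray  # original trial_index of each row

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, regressors: Sequence[str]) -> "ChoiceDesign":
        """Design restricted to the named regressors (reduced models)."""
        idx = [self.columns.index(r) for r in regressors]
        return ChoiceDesign(
            X=self.X[:, idx].copy(),
            y=self.y.copy(),
            columns=list(regressors),
            trial_indices=self.trial_indices.copy(),
        )

    def rows(self, idx: np.ndarray) -> "ChoiceDesign":
        return ChoiceDesign(
            X=self.X[idx], y=self.y[idx], columns=self.columns,
            trial_indices=self.trial_indices[idx],
        )

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.X, columns=self.columns)
        df.insert(0, "trial_index", self.trial_indices)
        df["y"] = self.y
        return df


@dataclass
class ModelFit:
    """Fitted weights and evaluation results for one window."""

    beta: np.ndarray  # per-regressor weights, order = columns
    intercept: float  # bias term b0
    columns: list[str]
    window_start: Optional[int] = None  # 1-based first trial of the window
    cv_accuracy: Optional[float] = None
    pvalues: dict = field(default_factory=dict)  # regressor -> PartialModelResult
    saturated: bool = False
    shuffled: bool = False
    reduced: bool = False

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])


@dataclass(frozen=True)
class PartialModelResult:
    """Bootstrap comparison of a partial model against the full model."""

    regressor: str
    p_strict: float  # fraction of resamples where partial strictly better
    p_mid: float  # ties counted half
    tie_fraction: float
    full_accuracy: float
    partial_accuracy: float


def _coded_stimulus(trial: TrialRecord) -> float:
    return 1.0 if trial.pole_position is PolePosition.ANTERIOR else -1.0


def build_design(trials: Sequence[TrialRecord],
                 regressors: Optional[Sequence[str]] = None) -> ChoiceDesign:
    """Build the regressor matrix from a temporally ordered trial sequence.

    Ignore trials carry no choice and are dropped from the responses; the
    history regressors are built over scored trials only, so A1/R1 refer to
    the last trial on which the animal actually chose.  Rows exist only for
    scored trials with at least 20 scored predecessors.
    """
    scored = [t for t in trials if t.choice is not Choice.IGNORE]
    S, A, R = [], [], []
    for t in scored:
        S.append(_coded_stimulus(t))
        A.append(1.0 if t.choice is Choice.LEFT else -1.0)
        R.append(1.0 if t.outcome is Outcome.CORRECT else -1.0)
    S, A, R = np.asarray(S), np.asarray(A), np.asarray(R)

    rows, ys, idxs = [], [], []
    for i in range(SAVG_WINDOW, len(scored)):
        hist_s = [S[i - k] for k in range(1, HISTORY_DEPTH + 1)]
        hist_a = [A[i - k] for k in range(1, HISTORY_DEPTH + 1)]
        hist_r = [R[i - k] for k in range(1, HISTORY_DEPTH + 1)]
        savg = float(np.mean(S[i - SAVG_WINDOW:i]))
        wsls = hist_a[0] * hist_r[0]
        rows.append([S[i], *hist_s, *hist_a, *hist_r, savg, wsls])
        ys.append(1 if A[i] > 0 else 0)
        idxs.append(scored[i].trial_index)

    X = np.asarray(rows, dtype=float).reshape(len(rows), len(REGRESSOR_NAMES))
    design = ChoiceDesign(
        X=X,
        y=np.asarray(ys, dtype=int),
        columns=list(REGRESSOR_NAMES),
        trial_indices=np.asarray(idxs, dtype=int),
    )
    if regressors is not None:
        design = design.subset(regressors)
    return design


def fit_logistic(design: ChoiceDesign, ridge: float = RIDGE_DEFAULT) -> ModelFit:
    """Maximum-likelihood weights for the logistic choice model.

    Minimizes the negative log-likelihood plus ``ridge * ||beta||^2`` over
    the non-bias weights (the intercept is unpenalized).  Deterministic for
    a given design.  A one-class response cannot be fit; it returns a
    bias-saturated fit with a warning.
    """
    if len(design) == 0:
        raise ValueError("empty design")
    classes = np.unique(design.y)
    if classes.size == 1:
        warnings.warn("one-class response; returning bias-saturated fit")
        sign = 1.0 if classes[0] == 1 else -1.0
        return ModelFit(
            beta=np.zeros(design.X.shape[1]),
            intercept=sign * 20.0,
            columns=list(design.columns),
            saturated=True,
        )
    clf = LogisticRegression(
        C=1.0 / (2.0 * ridge),
        solver="lbfgs",
        max_iter=2000,
        tol=1e-8,
    )
    clf.fit(design.X, design.y)
    return ModelFit(
        beta=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        columns=list(design.columns),
    )


def predict_left(X: np.ndarray, fit: ModelFit,
                 zero_regressor: Optional[str] = None) -> np.ndarray:
    """Predicted choice (1 = left) under a fit, optionally zeroing one weight."""
    beta = fit.beta.copy()
    if zero_regressor is not None:
        beta[fit.columns.index(zero_regressor)] = 0.0
    z = X @ beta + fit.intercept
    return (z > 0).astype(int)  # P(left) > 0.5  <=>  z > 0


def penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                     intercept: float, ridge: float = RIDGE_DEFAULT) -> float:
    """Ridge-penalized Bernoulli log-likelihood (the fitting objective)."""
    z = X @ beta + intercept
    ll = np.sum(y * z - np.logaddexp(0.0, z))
    return float(ll - ridge * np.dot(beta, beta))


def cv_blocks(n_rows: int, n_blocks: int = CV_REPEATS, block: int = CV_BLOCK,
              guard: int = CV_GUARD) -> list[tuple[np.ndarray, np.ndarray]]:
    """History-excluding CV splits over consecutive design rows.

    Test blocks of ``block`` consecutive trials start at evenly spaced
    positions; each training set excludes the block plus ``guard`` trials on
    either side, so no training trial lies within ``guard`` trials of any
    test trial.
    """
    min_rows = block + guard + 30
    if n_rows < min_rows:
        raise ValueError(f"need >= {min_rows} design rows for CV, got {n_rows}")
    starts = np.unique(np.linspace(0, n_rows - block, n_blocks).round().astype(int))
    splits = []
    rows = np.arange(n_rows)
    for s in starts:
        test = rows[s:s + block]
        train = rows[(rows < s - guard) | (rows >= s + block + guard)]
        splits.append((test, train))
    return splits


def crossval_predict(design: ChoiceDesign, n_blocks: int = CV_REPEATS,
                     block: int = CV_BLOCK, guard: int = CV_GUARD,
                     ridge: float = RIDGE_DEFAULT,
                     return_details: bool = False):
    """Cross-validated choice-prediction accuracy for one window.

    Returns the accuracy averaged over test blocks; with
    ``return_details=True`` also returns per-block (fit, test_idx,
    correct_mask) tuples for downstream partial-model tests.
    """
    splits = cv_blocks(len(design), n_blocks, block, guard)
    accs, details = [], []
    for test, train in splits:
        fit = fit_logistic(design.rows(train), ridge=ridge)
        pred = predict_left(design.X[test], fit)
        correct = pred == design.y[test]
        accs.append(float(np.mean(correct)))
        details.append((fit, test, correct))
    acc = float(np.mean(accs))
    if return_details:
        return acc, details
    return acc


def partial_model_pvalue(design: ChoiceDesign, regressor: str,
                         n_boot: int = 1000,
                         rng: Optional[np.random.Generator] = None,
                         n_blocks: int = CV_REPEATS, block: int = CV_BLOCK,
                         guard: int = CV_GUARD,
                         ridge: float = RIDGE_DEFAULT) -> PartialModelResult:
    """Bootstrap test of one regressor's contribution to prediction.

    For each CV block the full model is fit on the training set; the partial
    model is the same fit with the regressor's weight set to zero.  The
    pooled test-set correctness indicators are resampled with replacement
    ``n_boot`` times; p is the fraction of resamples where the partial model
    predicts strictly better (``p_strict``), with ties counted half in
    ``p_mid``.
    """
    if rng is None:
        rng = np.random.default_rng()
    splits = cv_blocks(len(design), n_blocks, block, guard)
    full_c, part_c = [], []
    for test, train in splits:
        fit = fit_logistic(design.rows(train), ridge=ridge)
        full_c.append(predict_left(design.X[test], fit) == design.y[test])
        part_c.append(
            predict_left(design.X[test], fit, zero_regressor=regressor) == design.y[test]
        )
    full_c = np.concatenate(full_c).astype(int)
    part_c = np.concatenate(part_c).astype(int)
    n = full_c.size
    d = part_c - full_c  # +1 where only the partial model is right
    idx = rng.integers(0, n, size=(n_boot, n))
    sums = d[idx].sum(axis=1)
    p_strict = float(np.mean(sums > 0))
    ties = float(np.mean(sums == 0))
    p_mid = p_strict + 0.5 * ties
    return PartialModelResult(
        regressor=regressor,
        p_strict=p_strict,
        p_mid=p_mid,
        tie_fraction=ties,
        full_accuracy=float(np.mean(full_c)),
        partial_accuracy=float(np.mean(part_c)),
    )


def sliding_window_analysis(trials: Sequence[TrialRecord], window: int = CV_WINDOW,
                            step: int = 100,
                            compute_pvalues: bool = False,
                            regressors: Optional[Sequence[str]] = None,
                            n_boot: int = 1000,
                            rng: Optional[np.random.Generator] = None,
                            ridge: float = RIDGE_DEFAULT) -> list[ModelFit]:
    """Fit the choice model in sliding windows of trials.

    ``floor((N - window) / step) + 1`` windows; each yields a full-model fit
    on the window's design, its cross-validated accuracy, and (optionally)
    partial-model p-values for the requested regressors.  Fewer than
    ``window`` trials yields an empty list with a warning.
    """
    trials = list(trials)
    n = len(trials)
    if n < window:
        warnings.warn(f"{n} trials < window {window}; no fits")
        return []
    if compute_pvalues and rng is None:
        rng = np.random.default_rng()
    fits = []
    for start in range(0, n - window + 1, step):
        chunk = trials[start:start + window]
        design = build_design(chunk)
        fit = fit_logistic(design, ridge=ridge)
        fit.window_start = start + 1
        fit.cv_accuracy = crossval_predict(design, ridge=ridge)
        if compute_pvalues:
            for reg in (regressors or design.columns):
                fit.pvalues[reg] = partial_model_pvalue(
                    design, reg, n_boot=n_boot, rng=rng, ridge=ridge
                )
        fits.append(fit)
    return fits


def regressor_reliance(pvalue_series: Sequence[dict], alpha: float = 0.05,
                       n_consecutive: int = 5) -> dict[str, bool]:
    """Flag regressors significant in five consecutive windows.

    ``pvalue_series`` is one dict per window mapping regressor name to a
    p-value (floats or PartialModelResult, in which case ``p_strict`` is
    used).
    """
    if len(pvalue_series) < n_consecutive:
        raise ValueError(f"need >= {n_consecutive} windows")
    names = set()
    for d in pvalue_series:
        names.update(d.keys())
    out = {}
    for name in sorted(names):
        run = best = 0
        for d in pvalue_series:
            p = d.get(name)
            if p is None:
                run = 0
                continue
            if isinstance(p, PartialModelResult):
                p = p.p_strict
            run = run + 1 if p < alpha else 0
            best = max(best, run)
        out[name] = best >= n_consecutive
    return out


def shuffle_control(design: ChoiceDesign, rng: np.random.Generator) -> ChoiceDesign:
    """Shuffle choices across trials, keeping all regressor columns intact."""
    perm = rng.permutation(len(design))
    return replace(design, X=design.X.copy(), y=design.y[perm].copy(),
                   columns=list(design.columns),
                   trial_indices=design.trial_indices.copy())
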