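"""Leave-one-out naive-Bayes surgical-outcome model and its statistics.

The headline model predicts good (Class-1) versus poor (Class-3+) surgical
outcome in the definitive-surgery group from the four CReP30 features
(fLAN-OUT, uLAN-EIG, FCN-EIG, HFO-RATE). A Gaussian naive Bayes is fitted
with leave-one-out cross-validation; the held-out posterior probabilities
feed a ROC curve, the Hanley-McNeil AUC confidence interval, a bootstrap
test of AUC = 0.5, a calibration curve and positive predictive value at a
posterior-certainty threshold. Group differences in the feature vectors are
tested with a two-sample Hotelling T^2 followed by per-feature t-tests.

The modelling surface follows the fitted-model idiom:
``SurgicalOutcomeModel(features, labels).fit()`` returns a
:class:`SurgicalOutcomeResults` carrying estimates, uncertainties,
diagnostics and a ``summary()`` table; the underlying statistics are also
exposed as plain functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.naive_bayes import GaussianNB

POSITIVE = "Class-1"
NEGATIVE = "Class-3+"


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ClassifierResult:
    """Held-out posteriors and derived discrimination statistics."""

    posteriors: np.ndarray          # per-patient held-out P(Class-1)
    labels: np.ndarray              # boolean, True = Class-1
    roc_points: np.ndarray          # (FPR, TPR) rows
    auc: float
    auc_ci: tuple[float, float]
    auc_p: float
    calibration: list[tuple[float, float]]
    ppv_at: dict[float, tuple[float, int, int]]   # thresh -> (ppv, tp, n_pred)


@dataclass
class GroupTestResult:
    """Hotelling T^2 omnibus test with optional per-feature post hocs."""

    t2: float
    f_stat: float
    p_global: float
    per_feature: list[tuple[float, float]] = field(default_factory=list)
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and AUC; AUC equals the Mann-Whitney probability with ties
    counted one half."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(y, s)
    pos, neg = s[y], s[~y]
    # Mann-Whitney form: exact AUC with ties counted 1/2
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (greater + 0.5 * ties) / (len(pos) * len(neg))
    return np.column_stack([fpr, tpr]), float(auc)


def hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int,
                     level: float = 0.95) -> tuple[float, float]:
    """Hanley-McNeil confidence interval for an AUC.

    Uses the closed-form variance with ``Q1 = A/(2-A)`` and
    ``Q2 = 2A^2/(1+A)``. Bounds are deliberately not clamped to [0, 1]: the
    interval is a normal approximation and may extend past 1 for large AUCs.
    """
    if not (0.0 <= auc <= 1.0):
        raise ValueError("auc must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both groups must be nonempty")
    a = auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return float(a - z * se), float(a + z * se)


def bootstrap_auc_test(scores: np.ndarray, labels: np.ndarray,
                       n_boot: int = 10_000, seed: int = 0) -> float:
    """One-sided test of AUC = 0.5 by label permutation.

    The null distribution resamples labels without replacement; the p-value
    is the fraction of null AUCs at least as large as the observed one, with
    add-one continuity so p is never exactly 0.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    _, obs = roc_auc(s, y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        perm = rng.permutation(y)
        _, a = roc_auc(s, perm)
        if a >= obs:
            count += 1
    return (count + 1) / (n_boot + 1)


def ppv_at_threshold(posteriors: np.ndarray, labels: np.ndarray,
                     thresh: float = 0.8) -> tuple[float, int, int]:
    """Positive predictive value at a posterior-certainty threshold.

    A patient is predicted Class-1 iff the posterior is at least ``thresh``.
    Returns ``(ppv, tp, n_pred)``; with no predicted positives the PPV is
    undefined and returned as ``nan``.
    """
    post = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pred = post >= thresh
    n_pred = int(pred.sum())
    tp = int((pred & y).sum())
    ppv = tp / n_pred if n_pred else float("nan")
    return ppv, tp, n_pred


def permutation_ppv_test(pred_a: np.ndarray, pred_b: np.ndarray,
                         labels: np.ndarray, n_perm: int = 10_000,
                         seed: int = 0) -> float:
    """Paired permutation test comparing two prediction rules' PPVs.

    The statistic is ``PPV_a - PPV_b``; the null swaps the two rules'
    binary predictions independently within each patient. Two-sided p with
    add-one continuity; a permutation in which either PPV is undefined
    contributes a statistic of 0.
    """
    a = np.asarray(pred_a, dtype=bool)
    b = np.asarray(pred_b, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("both rules must be evaluated on the same patients")

    def _ppv_diff(pa, pb):
        na, nb = pa.sum(), pb.sum()
        if na == 0 or nb == 0:
            return 0.0
        return (pa & y).sum() / na - (pb & y).sum() / nb

    obs = _ppv_diff(a, b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(len(y)) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        if abs(_ppv_diff(pa, pb)) >= abs(obs):
            count += 1
    return (count + 1) / (n_perm + 1)


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray,
                 alpha: float = 0.05) -> GroupTestResult:
    """Two-sample Hotelling T^2 with pooled covariance and F-transform p.

    If the omnibus p-value falls below ``alpha``, per-feature two-tailed
    equal-variance t-tests are run as post hocs. A singular pooled
    covariance falls back to the pseudo-inverse with a warning.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the feature dimension")
    d = A.shape[1]
    if d == 0:
        raise ValueError("at least one feature required")
    na, nb = A.shape[0], B.shape[0]
    n = na + nb
    if n - 2 <= d:
        raise ValueError("need n_a + n_b - 2 > d for the F transform")
    diff = A.mean(axis=0) - B.mean(axis=0)
    Sa = np.cov(A, rowvar=False, ddof=1) if na > 1 else np.zeros((d, d))
    Sb = np.cov(B, rowvar=False, ddof=1) if nb > 1 else np.zeros((d, d))
    Sp = ((na - 1) * np.atleast_2d(Sa) + (nb - 1) * np.atleast_2d(Sb)) / (n - 2)
    try:
        sol = np.linalg.solve(Sp, diff)
    except np.linalg.LinAlgError:
        import warnings
        warnings.warn("singular pooled covariance: using pseudo-inverse")
        sol = np.linalg.pinv(Sp) @ diff
    t2 = float(na * nb / n * diff @ sol)
    f = (n - d - 1) / (d * (n - 2)) * t2
    p = float(stats.f.sf(f, d, n - d - 1))
    res = GroupTestResult(t2=t2, f_stat=float(f), p_global=p, alpha=alpha)
    if p < alpha:
        for k in range(d):
            t, pk = stats.ttest_ind(A[:, k], B[:, k], equal_var=True)
            res.per_feature.append((float(t), float(pk)))
    return res


def calibration_curve(posteriors: np.ndarray, labels: np.ndarray,
                      n_bins: int = 5) -> list[tuple[float, float]]:
    """Equal-width calibration bins: (mean posterior, observed Class-1 rate).

    Empty bins are omitted. The final bin is closed at 1.
    """
    post = np.asarray(posteriors, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if np.any((post < 0) | (post > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    edges = np.linspace(0, 1, n_bins + 1)
    out = []
    for k in range(n_bins):
        hi_closed = k == n_bins - 1
        mask = (post >= edges[k]) & ((post <= edges[k + 1]) if hi_closed
                                     else (post < edges[k + 1]))
        if mask.any():
            out.append((float(post[mask].mean()), float(y[mask].mean())))
    return out


# ---------------------------------------------------------------------------
# leave-one-out naive Bayes
# ---------------------------------------------------------------------------

def loo_naive_bayes(
    features: np.ndarray,
    labels: np.ndarray,
    thresholds: tuple[float, ...] = (0.8,),
    n_boot: int = 10_000,
    n_bins: int = 5,
    seed: int = 0,
) -> tuple[ClassifierResult, list[GaussianNB]]:
    """Leave-one-out Gaussian naive Bayes with full discrimination readout.

    ``labels`` is boolean (True = Class-1). Each of the n folds fits a
    Gaussian naive Bayes (empirical class priors; variance floored at
    1e-9 x the largest feature variance) on the other n-1 patients and
    records the held-out posterior P(Class-1). Posteriors are sorted back to
    the input patient order, so results are invariant to row order.

    Returns the :class:`ClassifierResult` and the list of fold models (for
    scoring held-out Class-2 patients).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels, dtype=bool)
    if X.shape[0] != len(y):
        raise ValueError("features and labels must have one row per patient")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    n = len(y)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 patients per class for leave-one-out")

    posteriors = np.empty(n)
    fold_models: list[GaussianNB] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        yt = y[mask]
        if yt.all() or not yt.any():
            raise ValueError(f"fold {i}: a class is absent from the training split")
        model = GaussianNB()
        model.fit(X[mask], yt.astype(int))
        pos_col = list(model.classes_).index(1)
        posteriors[i] = model.predict_proba(X[i:i + 1])[0, pos_col]
        fold_models.append(model)

    roc_points, auc = roc_auc(posteriors, y)
    ci = hanley_mcneil_ci(auc, int(y.sum()), int((~y).sum()))
    p = bootstrap_auc_test(posteriors, y, n_boot=n_boot, seed=seed)
    cal = calibration_curve(posteriors, y, n_bins=n_bins)
    ppvs = {t: ppv_at_threshold(posteriors, y, t) for t in thresholds}
    result = ClassifierResult(posteriors, y, roc_points, auc, ci, p, cal, ppvs)
    return result, fold_models


def apply_to_heldout(fold_models: list[GaussianNB],
                     heldout_features: np.ndarray) -> list[tuple[float, float]]:
    """Score held-out patients against every leave-one-out fold model.

    Returns per patient the mean and SD of the P(Class-1) posteriors over
    all fold models.
    """
    if not fold_models:
        raise ValueError("at least one fitted fold model required")
    X = np.atleast_2d(np.asarray(heldout_features, dtype=float))
    if X.shape[1] != fold_models[0].theta_.shape[1]:
        raise ValueError("held-out feature dimension does not match the fold models")
    scores = np.empty((X.shape[0], len(fold_models)))
    for k, model in enumerate(fold_models):
        pos_col = list(model.classes_).index(1)
        scores[:, k] = model.predict_proba(X)[:, pos_col]
    return [(float(m), float(s)) for m, s in zip(scores.mean(axis=1), scores.std(axis=1))]


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class SurgicalOutcomeModel:
    """Leave-one-out naive-Bayes model of surgical outcome.

    Parameters
    ----------
    features
        Patients x features array (the default analysis uses the four
        CReP30 columns).
    labels
        Boolean per patient, True = good outcome (Class-1).
    feature_names
        Optional column names for the summary table.
    """

    def __init__(self, features, labels, feature_names: list[str] | None = None):
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.labels = np.asarray(labels, dtype=bool)
        self.feature_names = list(feature_names) if feature_names is not None else [
            f"x{k}" for k in range(self.features.shape[1])]

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame,
                       feature_cols: list[str] | None = None,
                       label_col: str = "class_group") -> "SurgicalOutcomeModel":
        """Build from a feature table (Class-2 rows are dropped).

        By default uses the four CReP30 columns as features and maps
        ``class_group`` to the boolean label.
        """
        if feature_cols is None:
            feature_cols = [c for c in table.columns if c.endswith("_CReP30")]
            if not feature_cols:
                raise ValueError("no CReP30 columns found; pass feature_cols")
        sub = table[table[label_col] != "Class-2"]
        labels = (sub[label_col] == POSITIVE).to_numpy()
        return cls(sub[feature_cols].to_numpy(), labels, feature_cols)

    def fit(self, thresholds: tuple[float, ...] = (0.8,), n_boot: int = 10_000,
            n_bins: int = 5, seed: int = 0) -> "SurgicalOutcomeResults":
        result, fold_models = loo_naive_bayes(
            self.features, self.labels, thresholds=thresholds,
            n_boot=n_boot, n_bins=n_bins, seed=seed)
        # the F transform needs n - 2 > d; on smaller cohorts the omnibus
        # test is undefined and reported as None
        if len(self.labels) - 2 > self.features.shape[1]:
            group_test = hotelling_t2(self.features[self.labels],
                                      self.features[~self.labels])
        else:
            group_test = None
        return SurgicalOutcomeResults(self, result, fold_models, group_test)


class SurgicalOutcomeResults:
    """Fitted results: posteriors, ROC/AUC with CI, calibration, PPV and the
    Hotelling T^2 group comparison."""

    def __init__(self, model: SurgicalOutcomeModel, classifier: ClassifierResult,
                 fold_models: list[GaussianNB], group_test: GroupTestResult):
        self.model = model
        self.classifier = classifier
        self.fold_models = fold_models
        self.group_test = group_test

    # convenience accessors
    @property
    def posteriors(self) -> np.ndarray:
        return self.classifier.posteriors

    @property
    def auc(self) -> float:
        return self.classifier.auc

    @property
    def auc_ci(self) -> tuple[float, float]:
        return self.classifier.auc_ci

    @property
    def auc_p(self) -> float:
        return self.classifier.auc_p

    def predict_heldout(self, heldout_features) -> list[tuple[float, float]]:
        """Mean and SD posterior of held-out patients over all fold models."""
        return apply_to_heldout(self.fold_models, heldout_features)

    def summary(self) -> str:
        c = self.classifier
        g = self.group_test
        n_pos = int(c.labels.sum())
        n_neg = int((~c.labels).sum())
        lines = [
            "Leave-one-out Gaussian naive Bayes — surgical outcome",
            "=" * 56,
            f"patients                {len(c.labels)}  ({n_pos} Class-1, {n_neg} Class-3+)",
            f"features                {', '.join(self.model.feature_names)}",
            f"AUC                     {c.auc:.3f}",
            f"95% CI (Hanley-McNeil)  ({c.auc_ci[0]:.3f}, {c.auc_ci[1]:.3f})",
            f"P(AUC = 0.5), bootstrap {c.auc_p:.4f}",
        ]
        for t, (ppv, tp, npred) in sorted(c.ppv_at.items()):
            shown = f"{ppv:.2f} ({tp}/{npred})" if npred else "undefined (0 predicted)"
            lines.append(f"PPV at posterior >= {t:.2f}  {shown}")
        if g is not None:
            lines.append(f"Hotelling T2            {g.t2:.3f}  "
                         f"(F = {g.f_stat:.3f}, p = {g.p_global:.4g})")
            for name, (t, p) in zip(self.model.feature_names, g.per_feature):
                lines.append(f"  post hoc {name:<18} t = {t:+.3f}, p = {p:.4g}")
        else:
            lines.append("Hotelling T2            not computed (n - 2 <= d)")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the held-out posteriors."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        pts = self.classifier.roc_points
        ax.plot(pts[:, 0], pts[:, 1], drawstyle="steps-post",
                label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def plot_calibration(self, ax=None):
        """Predicted posterior vs observed Class-1 rate per bin."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        cal = np.array(self.classifier.calibration)
        ax.plot(cal[:, 0], cal[:, 1], "o-")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("predicted P(Class-1)")
        ax.set_ylabel("observed Class-1 rate")
        return ax
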