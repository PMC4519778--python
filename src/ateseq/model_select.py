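"""Five-model Bayesian selection on isoform proportions in a 2x2 design.

For each transcript (or event) the vector of per-sample proportions is
logit-transformed and confronted with five nested Gaussian linear models over
the factors LPS treatment and macrophage type:

====  =========================  ==============================
M0    intercept                  no difference (null)
M1    + LPS                      LPS effect
M2    + MF                       macrophage type effect
M3    + LPS + MF                 both effects, independent
M4    + LPS + MF + LPS:MF        interaction (type-specific LPS response)
====  =========================  ==============================

Model evidence uses Zellner's g-prior on the non-intercept coefficients with
a reference (flat / Jeffreys) prior on intercept and variance, which yields
the closed-form log Bayes factor against the null

    log BF_k = (n - 1 - k)/2 * log(1 + g) - (n - 1)/2 * log(1 + g (1 - R_k^2))

where k is the number of non-intercept columns and R_k^2 the coefficient of
determination of model k on the centred response. Posterior model
probabilities combine these evidences with the prior vector
(0.6, 0.1, 0.1, 0.1, 0.1), encoding that most transcripts are not expected
to change; a transcript is called significantly changed when the posterior
probability of the null model drops below 0.05.

The default g equals the number of samples (unit-information prior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

DEFAULT_PRIOR = (0.6, 0.1, 0.1, 0.1, 0.1)
DEFAULT_P_NULL_THRESHOLD = 0.05
DEFAULT_EPS = 1e-3

MODEL_NAMES = ("M0", "M_LPS", "M_MF", "M_both", "M_int")
EFFECT_CLASSES = ("null", "LPS", "MF_type", "both_same", "opposite")


def logit_transform(p, eps: float = DEFAULT_EPS):
    """Logit with clamping of p into [eps, 1 - eps]."""
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    return np.log(p / (1 - p))


def design_matrices(lps: np.ndarray, mf: np.ndarray) -> list[np.ndarray]:
    """The five nested design matrices (each includes an intercept column)."""
    n = len(lps)
    one = np.ones(n)
    lps = np.asarray(lps, dtype=float)
    mf = np.asarray(mf, dtype=float)
    return [
        np.column_stack([one]),
        np.column_stack([one, lps]),
        np.column_stack([one, mf]),
        np.column_stack([one, lps, mf]),
        np.column_stack([one, lps, mf, lps * mf]),
    ]


def marginal_likelihood(y: np.ndarray, X: np.ndarray, g: float) -> float:
    """Log model evidence relative to the intercept-only model.

    Gaussian linear model, g-prior on non-intercept coefficients, reference
    prior on intercept and variance. ``X`` must contain the intercept as its
    first column and be of full column rank. For the intercept-only model the
    value is exactly 0, so differences of returned values are log Bayes
    factors.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y and X have incompatible shapes")
    k = p - 1
    if n <= p:
        raise ValueError(f"need more samples ({n}) than parameters ({p})")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    if k == 0:
        return 0.0
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0.0:
        # constant response: the extra coefficients explain nothing (R^2 = 0
        # limit), so richer models are penalised by their g-prior dimension
        r2 = 0.0
    else:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        r2 = max(0.0, 1.0 - rss / tss)
    return 0.5 * (n - 1 - k) * np.log1p(g) - 0.5 * (n - 1) * np.log1p(g * (1 - r2))


@dataclass
class ModelPosterior:
    """Posterior over the five effect models for one transcript or event."""

    posterior: np.ndarray  # length 5, sums to 1
    prior: np.ndarray
    log_evidence: np.ndarray
    skipped: bool = False

    @property
    def p_null(self) -> float:
        return float(self.posterior[0])

    @property
    def best_model(self) -> str:
        return MODEL_NAMES[int(np.argmax(self.posterior))]

    def significant(self, threshold: float = DEFAULT_P_NULL_THRESHOLD) -> bool:
        return not self.skipped and self.p_null < threshold


class BayesianModelSelector(BaseEstimator):
    """Per-feature five-model selection on proportions across samples.

    Parameters
    ----------
    prior : sequence of 5 floats, sums to 1
        Prior model probabilities (null, LPS, MF, both, interaction).
    g : float or "n"
        Zellner g; "n" uses the number of usable samples per feature.
    eps : float
        Logit clamp for proportions at 0 or 1.
    alpha : float
        Threshold on the posterior null probability to call a change.
    min_per_group : int
        Minimum non-missing samples per condition group; features below it
        are skipped (flagged, not errored).

    Attributes (after ``fit``)
    --------------------------
    posterior_ : (n_features, 5) array of posterior model probabilities
    p_null_ : (n_features,) posterior probability of the null model
    best_model_ : (n_features,) best model names
    effect_class_ : (n_features,) effect-class labels (see
        :func:`classify_effect`)
    skipped_ : (n_features,) bool mask of under-replicated features
    """

    def __init__(
        self,
        prior=DEFAULT_PRIOR,
        g="n",
        eps: float = DEFAULT_EPS,
        alpha: float = DEFAULT_P_NULL_THRESHOLD,
        min_per_group: int = 2,
    ):
        self.prior = prior
        self.g = g
        self.eps = eps
        self.alpha = alpha
        self.min_per_group = min_per_group

    def _prior(self) -> np.ndarray:
        prior = np.asarray(self.prior, dtype=float)
        if prior.shape != (5,) or not np.isclose(prior.sum(), 1.0):
            raise ValueError("prior must be 5 probabilities summing to 1")
        return prior

    def fit(self, X, y):
        """Fit one model comparison per feature.

        Parameters
        ----------
        X : (n_samples, n_features) proportions in [0, 1]; NaN = missing
        y : (n_samples, 2) binary factor matrix, columns (lps, mf), or a
            metadata DataFrame with ``treatment`` and ``mf_type`` columns.
        """
        X = np.atleast_2d(np.asarray(self._to_array(X), dtype=float))
        lps, mf = self._factors(y)
        if X.shape[0] != len(lps):
            raise ValueError("X rows must match the sample factors")
        prior = self._prior()
        log_prior = np.log(prior)
        nfeat = X.shape[1]
        self.posterior_ = np.full((nfeat, 5), np.nan)
        self.log_evidence_ = np.full((nfeat, 5), np.nan)
        self.skipped_ = np.zeros(nfeat, dtype=bool)
        self.delta_lps_mdm_ = np.full(nfeat, np.nan)
        self.delta_lps_ipsdm_ = np.full(nfeat, np.nan)
        for j in range(nfeat):
            col = X[:, j]
            ok = ~np.isnan(col)
            if not self._replicated(lps[ok], mf[ok]):
                self.skipped_[j] = True
                self.posterior_[j] = prior
                self.log_evidence_[j] = 0.0
                continue
            yv = logit_transform(col[ok], self.eps)
            designs = design_matrices(lps[ok], mf[ok])
            g = float(len(yv)) if self.g == "n" else float(self.g)
            logml = np.array([marginal_likelihood(yv, D, g) for D in designs])
            w = log_prior + logml
            w -= w.max()
            post = np.exp(w)
            post /= post.sum()
            self.posterior_[j] = post
            self.log_evidence_[j] = logml
            self.delta_lps_mdm_[j] = _lps_delta(col[ok], lps[ok], mf[ok], mf_level=0)
            self.delta_lps_ipsdm_[j] = _lps_delta(col[ok], lps[ok], mf[ok], mf_level=1)
        self.p_null_ = self.posterior_[:, 0]
        self.best_model_ = np.array(
            [MODEL_NAMES[i] for i in np.argmax(self.posterior_, axis=1)]
        )
        self.effect_class_ = np.array(
            [
                _effect_class(
                    self.posterior_[j],
                    self.skipped_[j],
                    self.delta_lps_mdm_[j],
                    self.delta_lps_ipsdm_[j],
                    self.alpha,
                )
                for j in range(nfeat)
            ]
        )
        self.n_features_in_ = nfeat
        return self

    def predict(self, X=None):
        """Effect-class labels of the fitted features."""
        check_is_fitted(self, "effect_class_")
        return self.effect_class_

    def results_frame(self, index=None) -> pd.DataFrame:
        """Tabular results: p_null, posteriors, best model, effect class."""
        check_is_fitted(self, "posterior_")
        df = pd.DataFrame(
            self.posterior_,
            columns=[f"posterior_{i}" for i in range(5)],
            index=index,
        )
        df.insert(0, "p_null", self.p_null_)
        df["best_model"] = self.best_model_
        df["effect_class"] = self.effect_class_
        df["skipped"] = self.skipped_
        return df

    @staticmethod
    def _to_array(X):
        return X.values if isinstance(X, pd.DataFrame) else X

    def _replicated(self, lps: np.ndarray, mf: np.ndarray) -> bool:
        for a in (0, 1):
            for b in (0, 1):
                if np.sum((lps == a) & (mf == b)) < self.min_per_group:
                    return False
        return True

    @staticmethod
    def _factors(y):
        if isinstance(y, pd.DataFrame):
            lps = (y["treatment"].to_numpy() == "LPS").astype(float)
            mf = (y["mf_type"].to_numpy() == "IPSDM").astype(float)
        else:
            arr = np.asarray(y, dtype=float)
            lps, mf = arr[:, 0], arr[:, 1]
        return lps, mf


def _lps_delta(props, lps, mf, mf_level: int) -> float:
    sel = mf == mf_level
    on = props[sel & (lps == 1)]
    off = props[sel & (lps == 0)]
    if len(on) == 0 or len(off) == 0:
        return np.nan
    return float(np.mean(on) - np.mean(off))


def _effect_class(posterior, skipped, d_mdm, d_ipsdm, alpha) -> str:
    if skipped or posterior[0] >= alpha:
        return "null"
    best = int(np.argmax(posterior[1:])) + 1
    if best == 1:
        return "LPS"
    if best == 2:
        return "MF_type"
    if best == 3:
        return "both_same"
    # interaction model: opposite only if the LPS response flips sign
    if np.isfinite(d_mdm) and np.isfinite(d_ipsdm) and np.sign(d_mdm) != np.sign(d_ipsdm):
        return "opposite"
    return "both_same"


def select_model(
    y,
    metadata: pd.DataFrame,
    prior=DEFAULT_PRIOR,
    g="n",
    eps: float = DEFAULT_EPS,
    alpha: float = DEFAULT_P_NULL_THRESHOLD,
) -> ModelPosterior:
    """Model selection for a single vector of per-sample proportions."""
    sel = BayesianModelSelector(prior=prior, g=g, eps=eps, alpha=alpha).fit(
        np.asarray(y, dtype=float).reshape(-1, 1), metadata
    )
    return ModelPosterior(
        posterior=sel.posterior_[0],
        prior=np.asarray(prior, dtype=float),
        log_evidence=sel.log_evidence_[0],
        skipped=bool(sel.skipped_[0]),
    )


def classify_effect(
    result: ModelPosterior,
    y,
    metadata: pd.DataFrame,
    alpha: float = DEFAULT_P_NULL_THRESHOLD,
) -> str:
    """Effect class of a fitted transcript/event.

    ``null`` when the null model keeps posterior >= alpha; otherwise the best
    non-null model maps to LPS / MF_type / both_same, with the interaction
    model split into ``opposite`` when the LPS response changes sign between
    macrophage types and ``both_same`` otherwise.
    """
    lps, mf = BayesianModelSelector._factors(metadata)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    d_mdm = _lps_delta(y[ok], lps[ok], mf[ok], 0)
    d_ipsdm = _lps_delta(y[ok], lps[ok], mf[ok], 1)
    return _effect_class(result.posterior, result.skipped, d_mdm, d_ipsdm, alpha)
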