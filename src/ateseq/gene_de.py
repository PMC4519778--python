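"""Two-factor gene-level differential expression on the 2x2 design.

Counts are normalised by median-of-ratios size factors and modelled per gene
by an ordinary linear model on log2(normalised count + 0.5) with LPS,
macrophage-type and interaction terms. This is a deliberately simple
log-normal working model — not a negative-binomial Wald test with dispersion
shrinkage — whose job is to flag genes with treatment, cell-type or
interaction effects at the configured thresholds (defaults: FDR < 0.01 and
fold change > 2 for the main effects; FDR < 0.1 and a fold-change difference
> 2 between the two cell types' LPS responses for the interaction rule).

Fits are vectorised across genes (one shared design matrix, per-gene OLS via
the hat matrix), so tens of thousands of genes fit in well under a second.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR = 0.01
DEFAULT_FC = 2.0
DEFAULT_INTERACTION_FDR = 0.1
DEFAULT_FC_DIFF = 2.0
PSEUDOCOUNT = 0.5


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median of count / geometric-mean-count over those genes.
    """
    arr = counts.to_numpy(dtype=float)
    all_nonzero = (arr > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "consider a pseudo-reference sample"
        )
    sub = arr[all_nonzero]
    log_geo_mean = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo_mean)
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class TwoFactorDE(BaseEstimator):
    """Gene-wise linear model over LPS, macrophage type and their interaction.

    Parameters
    ----------
    fdr, fc : main-effect thresholds (BH FDR and fold change).
    interaction_fdr, fc_diff : interaction-rule thresholds (BH FDR on the
        interaction term and fold-change *difference* between the two cell
        types' LPS responses).
    pseudocount : added before the log2 transform.

    Attributes (after ``fit``)
    --------------------------
    size_factors_ : per-sample normalisation factors
    results_ : DataFrame indexed by gene with log2 fold changes, raw p and
        BH-adjusted FDR per term, and significance flags.
    """

    def __init__(
        self,
        fdr: float = DEFAULT_FDR,
        fc: float = DEFAULT_FC,
        interaction_fdr: float = DEFAULT_INTERACTION_FDR,
        fc_diff: float = DEFAULT_FC_DIFF,
        pseudocount: float = PSEUDOCOUNT,
    ):
        self.fdr = fdr
        self.fc = fc
        self.interaction_fdr = interaction_fdr
        self.fc_diff = fc_diff
        self.pseudocount = pseudocount

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        """Fit per-gene models.

        Parameters
        ----------
        X : counts DataFrame, rows = genes, columns = samples.
        y : metadata DataFrame with sample_id / mf_type / treatment rows
            matching the columns of ``X``.
        """
        counts = X
        meta = y.set_index("sample_id").loc[list(counts.columns)]
        lps = (meta["treatment"].to_numpy() == "LPS").astype(float)
        mf = (meta["mf_type"].to_numpy() == "IPSDM").astype(float)
        groups = {(a, b): (lps == a) & (mf == b) for a in (0, 1) for b in (0, 1)}
        if any(m.sum() < 2 for m in groups.values()):
            raise ValueError("each condition group needs >= 2 samples")

        self.size_factors_ = size_factors(counts)
        norm = counts / self.size_factors_
        Y = np.log2(norm.to_numpy(dtype=float) + self.pseudocount)

        # treatment-coded design: intercept, LPS (in MDM), MF, LPS:MF
        D = np.column_stack([np.ones_like(lps), lps, mf, lps * mf])
        n, p = D.shape
        XtX_inv = np.linalg.inv(D.T @ D)
        B = Y @ (XtX_inv @ D.T).T  # genes x 4 coefficients
        resid = Y - B @ D.T
        dof = n - p
        sigma2 = (resid**2).sum(axis=1) / dof

        # contrasts of interest (rows: coefficient weights)
        contrasts = {
            "LPS_MDM": np.array([0.0, 1.0, 0.0, 0.0]),
            "LPS_IPSDM": np.array([0.0, 1.0, 0.0, 1.0]),
            "LPS": np.array([0.0, 1.0, 0.0, 0.5]),  # pooled LPS effect
            "MF": np.array([0.0, 0.0, 1.0, 0.5]),  # pooled cell-type effect
            "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
        }
        res = pd.DataFrame(index=counts.index)
        for name, c in contrasts.items():
            est = B @ c
            se = np.sqrt(sigma2 * float(c @ XtX_inv @ c))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
            pval = 2 * stats.t.sf(np.abs(t), dof)
            res[f"log2FC_{name}"] = est
            res[f"p_{name}"] = pval
        for term in ("LPS", "MF", "interaction"):
            res[f"fdr_{term}"] = bh_fdr(res[f"p_{term}"].to_numpy())
        lfc = np.log2(self.fc)
        res["significant_LPS"] = (res["fdr_LPS"] < self.fdr) & (
            res["log2FC_LPS"].abs() > lfc
        )
        res["significant_MF"] = (res["fdr_MF"] < self.fdr) & (
            res["log2FC_MF"].abs() > lfc
        )
        res["fc_diff_LPS"] = res["log2FC_LPS_IPSDM"] - res["log2FC_LPS_MDM"]
        res["significant_interaction"] = (
            res["fdr_interaction"] < self.interaction_fdr
        ) & (res["fc_diff_LPS"].abs() > np.log2(self.fc_diff))
        self.results_ = res
        self.n_features_in_ = counts.shape[0]
        return self

    def predict(self, X=None) -> pd.DataFrame:
        check_is_fitted(self, "results_")
        return self.results_


def fit_two_factor(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    fdr: float = DEFAULT_FDR,
    fc: float = DEFAULT_FC,
    interaction_fdr: float = DEFAULT_INTERACTION_FDR,
    fc_diff: float = DEFAULT_FC_DIFF,
) -> pd.DataFrame:
    """Functional wrapper over :class:`TwoFactorDE`; returns the results table."""
    de = TwoFactorDE(
        fdr=fdr, fc=fc, interaction_fdr=interaction_fdr, fc_diff=fc_diff
    ).fit(counts, metadata)
    return de.results_


def differential_response(
    results: pd.DataFrame,
    fdr_threshold: float = DEFAULT_INTERACTION_FDR,
    fc_diff_threshold: float = DEFAULT_FC_DIFF,
) -> pd.DataFrame:
    """Genes whose LPS response differs between cell types, with direction.

    Selects genes with interaction FDR below ``fdr_threshold`` and an
    absolute log2 fold-change difference above log2(``fc_diff_threshold``),
    labelling each by the more strongly induced cell type.
    """
    sel = (results["fdr_interaction"] < fdr_threshold) & (
        results["fc_diff_LPS"].abs() > np.log2(fc_diff_threshold)
    )
    out = results.loc[sel, ["log2FC_LPS_MDM", "log2FC_LPS_IPSDM", "fc_diff_LPS",
                            "fdr_interaction"]].copy()
    out["direction"] = np.where(out["fc_diff_LPS"] > 0, "IPSDM", "MDM")
    return out
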