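"""Downstream summaries: proportion PCA, 3' UTR asymmetry, enrichment tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import condition_groups

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray


def proportion_pca(top_props: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of top-transcript proportions (genes x samples).

    Genes with any missing sample are dropped (logged). Columns (samples) are
    the observations: the matrix is transposed, column-centred per gene and
    decomposed by SVD. Component signs are fixed so the largest-magnitude
    loading of each component is positive, making results deterministic.
    """
    if top_props.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    complete = top_props.dropna(axis=0)
    dropped = top_props.shape[0] - complete.shape[0]
    if dropped:
        logger.info("proportion_pca: dropped %d genes with missing samples", dropped)
    X = complete.to_numpy(dtype=float).T  # samples x genes
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign fix: largest-|loading| entry positive per component
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    total = float((S**2).sum())
    var_frac = (S**2) / total if total > 0 else np.zeros_like(S)
    k = n_components or len(S)
    comp_names = [f"PC{i + 1}" for i in range(len(S))][:k]
    return PCAResult(
        scores=pd.DataFrame(
            (U * S)[:, :k], index=top_props.columns, columns=comp_names
        ),
        loadings=pd.DataFrame(Vt[:k].T, index=complete.index, columns=comp_names),
        variance_fraction=var_frac[:k],
    )


def utr_asymmetry(
    event_table: pd.DataFrame,
    event_props: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    effect_classes: tuple[str, ...] = ("MF_type", "LPS", "both_same"),
) -> pd.DataFrame:
    """Mean relative expression of the long-3'-UTR alternative per condition.

    For every UTR-only alternative-3'-end event (``utr_class`` of long_ref or
    long_alt), the proportion of the long alternative is averaged within each
    of the four condition groups; rows are events, grouped by effect class.
    """
    groups = condition_groups(metadata)
    rows = []
    utr_events = event_table[
        event_table["utr_class"].isin(["long_ref", "long_alt"])
        & event_table["effect_class"].isin(effect_classes)
    ]
    for _, ev in utr_events.iterrows():
        props = event_props[ev["event_id"]]
        long_row = "ref" if ev["utr_class"] == "long_ref" else "alt"
        rec = {"event_id": ev["event_id"], "effect_class": ev["effect_class"]}
        for (mf, tr), samples in groups.items():
            rec[f"{mf}_{tr}"] = float(props.loc[long_row, samples].mean())
        rows.append(rec)
    cols = ["event_id", "effect_class"] + [f"{mf}_{tr}" for mf, tr in groups]
    return pd.DataFrame(rows, columns=cols)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value by the probability-mass rule."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def hypergeom_overlap(overlap: int, set1: int, set2: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) for the overlap of two gene sets.

    ``set1`` (K) and ``set2`` (n) are drawn from ``universe`` (N) genes.
    """
    if not (0 <= overlap <= min(set1, set2)):
        raise ValueError("overlap must satisfy 0 <= k <= min(K, n)")
    if set1 > universe or set2 > universe:
        raise ValueError("set sizes cannot exceed the universe")
    return float(sps.hypergeom.sf(overlap - 1, universe, set1, set2))


def pc_weight_enrichment(
    loadings: pd.Series, flagged_genes, n_bins: int = 10
) -> tuple[float, float]:
    """Chi-square goodness-of-fit of flagged genes' |loading| deciles.

    Absolute loadings of all genes are binned into deciles; the decile counts
    of the flagged subset are tested against a uniform expectation
    (chi-square GOF, n_bins - 1 df). With fewer than ``n_bins`` flagged genes
    an exact multinomial p-value is computed instead (warned).

    Returns (statistic, p_value).
    """
    flagged = [g for g in flagged_genes if g in loadings.index]
    if not flagged or len(flagged) >= len(loadings):
        raise ValueError("flagged subset must be non-empty and smaller than universe")
    absw = loadings.abs()
    # decile bins over the whole universe; duplicate edges merged defensively
    deciles = pd.qcut(absw.rank(method="first"), n_bins, labels=False)
    obs = np.bincount(deciles.loc[flagged].to_numpy(), minlength=n_bins).astype(float)
    exp = np.full(n_bins, len(flagged) / n_bins)
    stat = float(((obs - exp) ** 2 / exp).sum())
    if len(flagged) < n_bins:
        logger.warning(
            "pc_weight_enrichment: only %d flagged genes; using exact multinomial",
            len(flagged),
        )
        p = _multinomial_gof_exact(obs.astype(int), n_bins)
    else:
        p = float(sps.chi2.sf(stat, df=n_bins - 1))
    return stat, p


def _multinomial_gof_exact(obs: np.ndarray, n_bins: int) -> float:
    """Exact multinomial GOF p: total probability of outcomes no more likely
    than the observed one, under equal bin probabilities."""
    from itertools import product

    n = int(obs.sum())
    p_obs = sps.multinomial.pmf(obs, n, [1 / n_bins] * n_bins)
    total = 0.0
    for counts in _compositions(n, n_bins):
        p = sps.multinomial.pmf(counts, n, [1 / n_bins] * n_bins)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return min(1.0, float(total))


def _compositions(n: int, k: int):
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first, *rest)
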