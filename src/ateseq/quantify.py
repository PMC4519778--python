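"""Expression arithmetic: TPM, transcript/event proportions and filters.

Expression matrices are plain pandas DataFrames (rows = transcripts, genes or
event alternatives; columns = samples). Sample metadata is a DataFrame with
columns ``sample_id``, ``mf_type`` (MDM / IPSDM), ``treatment`` (naive / LPS)
and ``donor``; the four mf_type x treatment combinations are the experimental
condition groups used throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation import GeneModel, restrict_intervals
from .events import EventAnnotation

logger = logging.getLogger(__name__)

MF_TYPES = ("MDM", "IPSDM")
TREATMENTS = ("naive", "LPS")
METADATA_COLUMNS = ("sample_id", "mf_type", "treatment", "donor")


def validate_metadata(metadata: pd.DataFrame, min_per_group: int = 2) -> pd.DataFrame:
    """Check the sample table covers the 2x2 design with enough replicates."""
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks columns: {missing}")
    if metadata["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    bad = set(metadata["mf_type"]) - set(MF_TYPES)
    if bad:
        raise ValueError(f"unknown mf_type values: {bad}")
    bad = set(metadata["treatment"]) - set(TREATMENTS)
    if bad:
        raise ValueError(f"unknown treatment values: {bad}")
    counts = metadata.groupby(["mf_type", "treatment"], observed=True).size()
    if len(counts) < 4 or (counts < min_per_group).any():
        raise ValueError(
            f"each mf_type x treatment group needs >= {min_per_group} samples; "
            f"got {counts.to_dict()}"
        )
    return metadata


def condition_groups(metadata: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Sample ids per (mf_type, treatment) group, in fixed order."""
    out = {}
    for mf in MF_TYPES:
        for tr in TREATMENTS:
            sel = metadata[(metadata.mf_type == mf) & (metadata.treatment == tr)]
            out[(mf, tr)] = list(sel.sample_id)
    return out


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from counts and per-row lengths in bp.

    TPM_rs = (counts_rs / length_r) / sum_r'(counts_r's / length_r') * 1e6,
    so every expressed column sums to 1e6. All-zero columns stay zero and are
    logged.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"no length for rows: {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("all row lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum == 0
    if zero_cols.any():
        logger.warning("all-zero columns in counts: %s", list(colsum.index[zero_cols]))
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1) * 1e6
    return tpm.fillna(0.0)


def transcript_proportions(
    tpm: pd.DataFrame, gene_of: pd.Series
) -> pd.DataFrame:
    """Per-sample transcript proportions within each gene.

    ``gene_of`` maps transcript id -> gene id and must cover every row.
    Samples where a gene is entirely unexpressed get NaN (flagged missing).
    """
    gene_of = gene_of.reindex(tpm.index)
    if gene_of.isna().any():
        unknown = list(gene_of.index[gene_of.isna()])[:5]
        raise ValueError(f"transcripts with unknown gene: {unknown} ...")
    gene_sums = tpm.groupby(gene_of).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        props = tpm / gene_sums.replace(0, np.nan)
    return props


def gene_tpm(tpm: pd.DataFrame, gene_of: pd.Series) -> pd.DataFrame:
    """Gene-level TPM = sum of the gene's transcript TPMs."""
    return tpm.groupby(gene_of.reindex(tpm.index)).sum()


def top_transcript(tpm: pd.DataFrame, gene: GeneModel) -> str:
    """The gene's most highly expressed transcript by mean TPM over all samples.

    The identity is fixed across conditions so that one transcript represents
    the gene's transcriptional make-up everywhere. Ties break to the
    lexicographically smallest id (logged).
    """
    ids = [t.transcript_id for t in gene.transcripts]
    means = tpm.loc[ids].mean(axis=1)
    if (means == 0).all():
        raise KeyError(f"{gene.gene_id}: gene entirely unexpressed")
    best = means.max()
    winners = sorted(means.index[means == best])
    if len(winners) > 1:
        logger.warning(
            "%s: tie for top transcript among %s, picking %s",
            gene.gene_id, winners, winners[0],
        )
    return winners[0]


def filter_expressed(
    tpm: pd.DataFrame,
    gene_of: pd.Series,
    metadata: pd.DataFrame,
    threshold: float = 2.0,
    mode: str = "all_conditions",
) -> list[str]:
    """Gene ids whose condition-group mean TPM exceeds ``threshold``.

    The mean gene TPM is computed within each of the four mf_type x treatment
    groups; ``all_conditions`` requires mean > threshold (strict) in every
    group, ``any_condition`` in at least one.
    """
    if mode not in ("all_conditions", "any_condition"):
        raise ValueError(f"unknown mode {mode!r}")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    gt = gene_tpm(tpm, gene_of)
    group_means = pd.DataFrame(
        {
            grp: gt[samples].mean(axis=1)
            for grp, samples in condition_groups(metadata).items()
        }
    )
    if mode == "all_conditions":
        keep = (group_means > threshold).all(axis=1)
    else:
        keep = (group_means > threshold).any(axis=1)
    return sorted(gt.index[keep])


def quantify_event(
    annotation: EventAnnotation, gene: GeneModel, tpm: pd.DataFrame
) -> pd.DataFrame:
    """Event proportions by structural compatibility of annotated transcripts.

    Each transcript of the gene is assigned to the ref alternative, the alt
    alternative, or neither: its exonic structure restricted to the event's
    genomic span must equal that alternative's structure. Alternative
    expression is the summed TPM of its compatible transcripts; the returned
    frame has rows ``ref``/``alt`` holding proportions ref/(ref+alt) and
    alt/(ref+alt), NaN where both are zero.

    This aggregation stands in for re-estimating expression on the reduced
    event annotation: it is identical in expectation when the transcript-level
    estimates are unbiased.
    """
    span = annotation.span
    ref_struct = annotation.ref_transcript.exons
    alt_struct = annotation.alt_transcript.exons
    ref_ids, alt_ids = [], []
    for t in gene.transcripts:
        restricted = restrict_intervals(t.exons, span)
        is_ref = restricted == ref_struct
        is_alt = restricted == alt_struct
        if is_ref and is_alt:
            raise AssertionError(
                f"{t.transcript_id} compatible with both alternatives of "
                f"{annotation.event.event_id}"
            )
        if is_ref:
            ref_ids.append(t.transcript_id)
        elif is_alt:
            alt_ids.append(t.transcript_id)
    ref_expr = tpm.loc[ref_ids].sum(axis=0) if ref_ids else 0.0 * tpm.iloc[0]
    alt_expr = tpm.loc[alt_ids].sum(axis=0) if alt_ids else 0.0 * tpm.iloc[0]
    total = ref_expr + alt_expr
    zero = total == 0
    if zero.any():
        logger.info(
            "%s: %d sample(s) with zero event expression flagged missing",
            annotation.event.event_id, int(zero.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ref_prop = ref_expr / total.replace(0, np.nan)
    out = pd.DataFrame(
        {"ref": ref_prop, "alt": 1.0 - ref_prop}
    ).T
    out.columns = tpm.columns
    return out
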