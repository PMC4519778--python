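"""Two-step alternative-transcription-event pipeline over the 2x2 design.

Step 1 screens annotated transcripts: TPM normalisation, the expressed-gene
filter (group mean TPM > 2 in all four conditions), transcript proportions,
and five-model selection per transcript. For every gene whose most
significantly changed transcript clears the posterior-null threshold and
differs from its most highly expressed transcript, the (top, changed) pair is
passed on.

Step 2 decomposes each pair into positional events, builds reduced two-
alternative event annotations, re-quantifies each event by structural
compatibility, reruns model selection on the event proportions, and keeps
events that stay significant and move at least 10% in proportion in one of
the three design contrasts (naive MDM vs naive IPSDM; naive vs LPS within
either cell type). This second pass separates events genuinely supported by
the data from events dragged along on a shared transcript with a causal one.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel, write_gtf
from .events import ATEvent, EventAnnotation, build_event_annotation, classify_utr_length, find_events
from .gene_de import TwoFactorDE, differential_response
from .model_select import (
    DEFAULT_P_NULL_THRESHOLD,
    DEFAULT_PRIOR,
    BayesianModelSelector,
)
from .quantify import (
    condition_groups,
    counts_to_tpm,
    filter_expressed,
    gene_tpm,
    quantify_event,
    top_transcript,
    transcript_proportions,
    validate_metadata,
)
from .stats import hypergeom_overlap, proportion_pca, utr_asymmetry

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every threshold of the analysis, with the study's defaults."""

    tpm_threshold: float = 2.0
    tpm_filter_mode: str = "all_conditions"
    prior: tuple = DEFAULT_PRIOR
    p_null_threshold: float = DEFAULT_P_NULL_THRESHOLD
    delta_prop: float = 0.10
    cds_bp: int = 100
    flank_exons: int = 1
    de_fdr: float = 0.01
    de_fc: float = 2.0
    interaction_fdr: float = 0.1
    fc_diff: float = 2.0
    g: object = "n"
    eps: float = 1e-3
    min_per_group: int = 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prior"] = list(d["prior"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "prior" in d:
            d["prior"] = tuple(d["prior"])
        return cls(**d)


@dataclass
class Step1Result:
    transcript_results: pd.DataFrame  # per-transcript model selection
    pairs: pd.DataFrame  # gene_id, top_transcript, changed_transcript
    kept_genes: list
    tpm: pd.DataFrame
    proportions: pd.DataFrame
    gene_of: pd.Series


@dataclass
class Step2Result:
    events: pd.DataFrame  # retained events with classification
    all_events: pd.DataFrame  # every tested event, pre-filter
    event_props: dict  # event_id -> 2 x samples proportion frame
    annotations: list  # retained EventAnnotation objects


def contrast_deltas(props: pd.Series, metadata: pd.DataFrame) -> dict[str, float]:
    """Mean-proportion differences for the three design contrasts."""
    groups = condition_groups(metadata)
    mean = {
        grp: float(props[samples].mean()) for grp, samples in groups.items()
    }
    return {
        "naive_MF": mean[("IPSDM", "naive")] - mean[("MDM", "naive")],
        "LPS_in_MDM": mean[("MDM", "LPS")] - mean[("MDM", "naive")],
        "LPS_in_IPSDM": mean[("IPSDM", "LPS")] - mean[("IPSDM", "naive")],
    }


def max_abs_delta(props: pd.Series, metadata: pd.DataFrame) -> float:
    return max(abs(v) for v in contrast_deltas(props, metadata).values())


def _most_significant(sub: pd.DataFrame, rtol: float = 1e-6) -> str:
    """Most significantly changed transcript of one gene.

    Minimum p_null; ties (within relative tolerance, so that the exactly
    mirrored proportions of a 2-isoform gene compare equal despite rounding)
    broken by larger proportion change, then lexicographically smallest id.
    """
    p = sub["p_null"]
    cand = sub[p <= p.min() * (1 + rtol) + 1e-300]
    d = cand["max_delta"]
    cand = cand[d >= d.max() * (1 - rtol) - 1e-300]
    return sorted(cand.index)[0]


def run_step1(
    genes: list[GeneModel],
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> Step1Result:
    """Transcript-level screen producing (top, changed) transcript pairs."""
    config = config or PipelineConfig()
    validate_metadata(metadata, config.min_per_group)
    gene_of = pd.Series(
        {t.transcript_id: g.gene_id for g in genes for t in g.transcripts}
    )
    lengths = pd.Series(
        {t.transcript_id: t.length for g in genes for t in g.transcripts}
    )
    counts = counts.loc[:, list(metadata.sample_id)]
    tpm = counts_to_tpm(counts, lengths)
    kept = filter_expressed(
        tpm, gene_of, metadata, config.tpm_threshold, config.tpm_filter_mode
    )
    kept_set = set(kept)
    genes_by_id = {g.gene_id: g for g in genes}
    multi = [
        gid for gid in kept if len(genes_by_id[gid].transcripts) >= 2
    ]
    tids = [
        t.transcript_id for gid in multi for t in genes_by_id[gid].transcripts
    ]
    props = transcript_proportions(tpm, gene_of).loc[tids]

    selector = BayesianModelSelector(
        prior=config.prior,
        g=config.g,
        eps=config.eps,
        alpha=config.p_null_threshold,
        min_per_group=config.min_per_group,
    ).fit(props.T, metadata)
    results = selector.results_frame(index=props.index)
    results.insert(0, "gene_id", gene_of.loc[props.index].to_numpy())
    results["max_delta"] = [
        max_abs_delta(props.loc[tid], metadata) for tid in props.index
    ]

    pair_rows = []
    for gid in multi:
        sub = results[results.gene_id == gid]
        top = top_transcript(tpm, genes_by_id[gid])
        ms = _most_significant(sub)
        if sub.loc[ms, "p_null"] >= config.p_null_threshold:
            continue  # nothing significant in this gene
        if ms == top:
            continue  # no pair to compare
        pair_rows.append(
            {"gene_id": gid, "top_transcript": top, "changed_transcript": ms}
        )
    pairs = pd.DataFrame(
        pair_rows, columns=["gene_id", "top_transcript", "changed_transcript"]
    )
    logger.info(
        "step1: %d/%d genes expressed, %d pairs selected",
        len(kept), len(genes), len(pairs),
    )
    return Step1Result(
        transcript_results=results,
        pairs=pairs,
        kept_genes=kept,
        tpm=tpm,
        proportions=props,
        gene_of=gene_of,
    )


def run_step2(
    step1: Step1Result,
    genes: list[GeneModel],
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> Step2Result:
    """Event decomposition, re-quantification and final filtering."""
    config = config or PipelineConfig()
    genes_by_id = {g.gene_id: g for g in genes}
    selector_kwargs = dict(
        prior=config.prior,
        g=config.g,
        eps=config.eps,
        alpha=config.p_null_threshold,
        min_per_group=config.min_per_group,
    )
    rows, props_by_event, kept_annotations = [], {}, []
    for _, pair in step1.pairs.iterrows():
        gene = genes_by_id[pair.gene_id]
        reference = gene.transcript(pair.top_transcript)
        changed = gene.transcript(pair.changed_transcript)
        for event in find_events(reference, changed):
            ann = build_event_annotation(
                event, reference, changed, config.flank_exons
            )
            eprops = quantify_event(ann, gene, step1.tpm)
            sel = BayesianModelSelector(**selector_kwargs).fit(
                eprops.loc[["ref"]].T, metadata
            )
            ref_props = eprops.loc["ref"]
            deltas = contrast_deltas(ref_props, metadata)
            max_delta = max(abs(v) for v in deltas.values())
            p_null = float(sel.p_null_[0])
            retained = (
                not sel.skipped_[0]
                and p_null < config.p_null_threshold
                and max_delta >= config.delta_prop
            )
            rows.append(
                {
                    "event_id": event.event_id,
                    "gene_id": event.gene_id,
                    "event_type": event.event_type,
                    "positional_class": event.positional_class,
                    "cds_change_bp": event.cds_change_bp,
                    "coding": event.coding,
                    "ref_transcript": pair.top_transcript,
                    "changed_transcript": pair.changed_transcript,
                    "p_null": p_null,
                    "best_model": sel.best_model_[0],
                    "effect_class": sel.effect_class_[0],
                    "utr_class": classify_utr_length(event),
                    "delta_naive_MF": deltas["naive_MF"],
                    "delta_LPS_in_MDM": deltas["LPS_in_MDM"],
                    "delta_LPS_in_IPSDM": deltas["LPS_in_IPSDM"],
                    "max_delta": max_delta,
                    "retained": retained,
                }
            )
            props_by_event[event.event_id] = eprops
            if retained:
                kept_annotations.append(ann)
    all_events = pd.DataFrame(
        rows,
        columns=[
            "event_id", "gene_id", "event_type", "positional_class",
            "cds_change_bp", "coding", "ref_transcript", "changed_transcript",
            "p_null", "best_model", "effect_class", "utr_class",
            "delta_naive_MF", "delta_LPS_in_MDM", "delta_LPS_in_IPSDM",
            "max_delta", "retained",
        ],
    )
    events = all_events[all_events.retained].drop(columns="retained").reset_index(
        drop=True
    )
    logger.info(
        "step2: %d events tested, %d retained in %d genes",
        len(all_events), len(events), events.gene_id.nunique() if len(events) else 0,
    )
    return Step2Result(
        events=events,
        all_events=all_events,
        event_props=props_by_event,
        annotations=kept_annotations,
    )


def run_gene_de(
    counts_gene: pd.DataFrame,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Two-factor gene-level DE on gene counts."""
    config = config or PipelineConfig()
    de = TwoFactorDE(
        fdr=config.de_fdr,
        fc=config.de_fc,
        interaction_fdr=config.interaction_fdr,
        fc_diff=config.fc_diff,
    ).fit(counts_gene, metadata)
    return de.results_


def run_summaries(
    step1: Step1Result,
    step2: Step2Result,
    metadata: pd.DataFrame,
    genes: list[GeneModel],
    de_results: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Downstream bundle: PCA, event counts, UTR asymmetry, overlaps."""
    config = config or PipelineConfig()
    genes_by_id = {g.gene_id: g for g in genes}
    top_rows = {}
    for gid in step1.kept_genes:
        gene = genes_by_id[gid]
        if len(gene.transcripts) < 2:
            continue
        top = top_transcript(step1.tpm, gene)
        top_rows[gid] = step1.proportions.loc[top]
    top_props = pd.DataFrame(top_rows).T
    pca = proportion_pca(top_props) if len(top_props) >= 2 else None

    events = step2.events
    count_table = (
        events.groupby(["event_type", "effect_class"], observed=True)
        .size()
        .unstack(fill_value=0)
        if len(events)
        else pd.DataFrame()
    )
    asym = utr_asymmetry(events, step2.event_props, metadata) if len(events) else pd.DataFrame()

    overlaps = {}
    if de_results is not None and len(events):
        universe = [g for g in step1.kept_genes if g in de_results.index]
        ate_lps = set(
            events.loc[
                events.effect_class.isin(["LPS", "both_same", "opposite"]), "gene_id"
            ]
        ) & set(universe)
        de_lps = set(de_results.index[de_results.significant_LPS]) & set(universe)
        ate_mf = set(
            events.loc[
                events.effect_class.isin(["MF_type", "both_same"]), "gene_id"
            ]
        ) & set(universe)
        de_mf = set(de_results.index[de_results.significant_MF]) & set(universe)
        for name, a, b in (("LPS", de_lps, ate_lps), ("MF_type", de_mf, ate_mf)):
            if a and b:
                k = len(a & b)
                p = hypergeom_overlap(k, len(a), len(b), len(universe))
                overlaps[name] = {
                    "overlap": k, "de_genes": len(a), "ate_genes": len(b),
                    "universe": len(universe), "p_value": p,
                }
                logger.info(
                    "overlap %s: k=%d K=%d n=%d N=%d p=%.3g",
                    name, k, len(a), len(b), len(universe), p,
                )
    return {
        "pca": pca,
        "top_proportions": top_props,
        "event_counts": count_table,
        "utr_asymmetry": asym,
        "overlaps": overlaps,
        "differential_response": differential_response(
            de_results, config.interaction_fdr, config.fc_diff
        )
        if de_results is not None
        else None,
    }


# ---------------------------------------------------------------------------
# file-level orchestration
# ---------------------------------------------------------------------------

def write_manifest(path, config: PipelineConfig, extra: dict | None = None) -> None:
    payload = {"config": config.to_dict()}
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_event_outputs(step2: Step2Result, outdir, config: PipelineConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    step2.events.to_csv(outdir / "events.tsv", sep="\t", index=False, float_format="%.6g")
    step2.all_events.to_csv(
        outdir / "events_all.tsv", sep="\t", index=False, float_format="%.6g"
    )
    event_genes = {}
    for ann in step2.annotations:
        gid = ann.event.gene_id
        event_genes.setdefault(gid, []).extend(
            [ann.ref_transcript, ann.alt_transcript]
        )
    gene_models = [
        GeneModel(gene_id=gid, transcripts=ts) for gid, ts in event_genes.items()
    ]
    write_gtf(gene_models, outdir / "events.gtf")
    write_manifest(outdir / "manifest.json", config, {"n_events": len(step2.events)})
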