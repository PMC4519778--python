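"""Ground-truth simulator for the 2x2 macrophage design.

Generates multi-isoform genes whose two transcripts differ by exactly one
alternative transcription event (promoter switch, cassette exon, or 3' end
change), together with negative-binomial transcript counts across naive and
LPS-stimulated MDM and IPSDM samples (5 and 4 donors respectively, both
treatments). Each gene carries one effect class controlling how the focal
transcript's proportion moves between condition groups:

- ``null``      constant proportion everywhere
- ``LPS``       shift after LPS stimulation in both cell types
- ``MF_type``   shift between MDM and IPSDM at both treatments
- ``both_same`` additive LPS and cell-type shifts
- ``opposite``  LPS response of opposite sign in the two cell types

Counts are drawn per transcript as NB(mean, dispersion) with mean =
gene total x proportion x (transcript length / mean gene transcript length),
so the counts -> TPM -> proportion path is exercised non-trivially. The truth
table records event class, effect class and the true proportion differences
per contrast, closing the loop for end-to-end recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    Interval,
    TranscriptModel,
    interval_length,
    symmetric_difference_intervals,
)

EVENT_CLASSES = ("promoter", "splicing", "threeprime", "none")
EFFECT_CLASSES = ("null", "LPS", "MF_type", "both_same", "opposite")

GENE_SPACING = 100_000  # bp between simulated gene starts on the chromosome
_STRUCT_SPAN = 5_000  # local coordinate span of the simulated gene structures


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort."""

    n_genes: int = 200
    event_fractions: dict = field(
        default_factory=lambda: {
            "promoter": 0.3,
            "splicing": 0.3,
            "threeprime": 0.3,
            "none": 0.1,
        }
    )
    effect_fractions: dict = field(
        default_factory=lambda: {
            "null": 0.4,
            "LPS": 0.2,
            "MF_type": 0.15,
            "both_same": 0.2,
            "opposite": 0.05,
        }
    )
    effect_size: float = 0.3  # delta proportion, natural scale
    baseline_proportion: float = 0.5  # focal-transcript proportion at baseline
    dispersion: float = 0.05  # NB dispersion (var = mu + disp * mu^2)
    expr_log_mean: float = np.log(500.0)  # log-normal gene total counts
    expr_log_sd: float = 0.8
    n_mdm_donors: int = 5
    n_ipsdm_donors: int = 4
    cds_changing_3prime_fraction: float = 0.25  # 3' events altering >100 bp CDS
    de_lps_fraction: float = 0.15  # genes whose total expression responds to LPS
    de_fold: float = 4.0  # fold change of those genes (half up, half down)
    donor_sd: float = 0.0  # optional donor random effect on the logit scale
    seed: int = 0

    def __post_init__(self) -> None:
        for fam, keys in (
            (self.event_fractions, EVENT_CLASSES),
            (self.effect_fractions, EFFECT_CLASSES),
        ):
            if set(fam) != set(keys):
                raise ValueError(f"fractions must cover exactly {keys}")
            if not np.isclose(sum(fam.values()), 1.0):
                raise ValueError("fractions must sum to 1")
        if self.n_genes < 1 or self.dispersion <= 0:
            raise ValueError("n_genes must be >= 1 and dispersion > 0")


# ---------------------------------------------------------------------------
# transcript structures, defined in transcript (5'->3') orientation and
# mirrored onto the genome for minus-strand genes
# ---------------------------------------------------------------------------

def _mirror(ivs: list[Interval], span: int) -> list[Interval]:
    return sorted((span - e, span - s) for s, e in ivs)


def _structures(event_class: str) -> tuple[dict, dict, int]:
    """Exon/CDS layouts of the two isoforms in transcript orientation.

    Returns (t1, t2, cds_change_bp) where each isoform is a dict with
    ``exons`` and ``cds`` lists; t2 is the focal isoform.
    """
    A, B, C = (1000, 1200), (2000, 2200), (3000, 3200)
    D = (4000, 4300)
    common_cds = [(1100, 1200), (3000, 3200), (4000, 4100)]
    if event_class == "promoter":
        t1 = {"exons": [A, B, C, D], "cds": [(1100, 1200), (2000, 2200)] + common_cds[1:]}
        t2 = {"exons": [(0, 200), B, C, D], "cds": [(2000, 2200)] + common_cds[1:]}
        return t1, t2, 100  # first-exon CDS part (1100,1200) lost
    if event_class in ("splicing", "none"):
        cds1 = [(1100, 1200), (2000, 2200), (3000, 3200), (4000, 4100)]
        cds2 = [(1100, 1200), (3000, 3200), (4000, 4100)]
        t1 = {"exons": [A, B, C, D], "cds": cds1}
        t2 = {"exons": [A, C, D], "cds": cds2}
        return t1, t2, 200  # cassette exon is fully coding
    if event_class == "threeprime":
        # UTR-only terminal extension: identical CDS, longer 3' UTR on t1
        t1 = {"exons": [A, B, C, (4000, 4600)], "cds": common_cds}
        t2 = {"exons": [A, B, C, (4000, 4300)], "cds": common_cds}
        return t1, t2, 0
    if event_class == "threeprime_coding":
        t1 = {"exons": [A, B, C, (4000, 4600)],
              "cds": common_cds[:-1] + [(4000, 4300)]}
        t2 = {"exons": [A, B, C, (4000, 4150)],
              "cds": common_cds[:-1] + [(4000, 4100)]}
        return t1, t2, 150
    raise ValueError(f"unknown event class {event_class!r}")


def _allocate(n: int, fractions: dict, order: tuple, rng) -> np.ndarray:
    """Integer class counts matching the fractions, assigned in random order."""
    counts = np.floor(np.array([fractions[c] for c in order]) * n).astype(int)
    # distribute the remainder to the largest fractional parts
    frac = np.array([fractions[c] for c in order]) * n - counts
    for i in np.argsort(-frac)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.array(order, dtype=object), counts)
    return labels[rng.permutation(n)]


def simulate_annotation(cfg: SimulationConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Simulate gene structures and the truth-table skeleton.

    Each gene gets two isoforms differing by exactly its assigned event
    class; strands alternate between genes. ``none`` genes reuse the cassette
    structure but will keep constant proportions. The focal (proportion-
    shifted, higher-expressed) isoform is named ``<gene>.t2`` so that its id
    sorts after the non-focal ``<gene>.t1``.
    """
    rng = np.random.default_rng(cfg.seed)
    event_of = _allocate(cfg.n_genes, cfg.event_fractions, EVENT_CLASSES, rng)
    has_event = event_of != "none"
    effect_of = np.array(["null"] * cfg.n_genes, dtype=object)
    idx = np.flatnonzero(has_event)
    if len(idx):
        effect_of[idx] = _allocate(
            len(idx), cfg.effect_fractions, EFFECT_CLASSES, rng
        )
    coding_3p = rng.random(cfg.n_genes) < cfg.cds_changing_3prime_fraction
    # independent gene-level LPS response (total expression, not proportions)
    de_lps = rng.random(cfg.n_genes) < cfg.de_lps_fraction
    de_sign = np.where(rng.random(cfg.n_genes) < 0.5, 1.0, -1.0)

    genes, rows = [], []
    for i in range(cfg.n_genes):
        gid = f"G{i:05d}"
        ev = event_of[i]
        struct_class = ev
        if ev == "threeprime" and coding_3p[i]:
            struct_class = "threeprime_coding"
        t1s, t2s, cds_bp = _structures(struct_class)
        strand = "+" if i % 2 == 0 else "-"
        offset = 1000 + i * GENE_SPACING
        transcripts = []
        for tid, st in ((f"{gid}.t1", t1s), (f"{gid}.t2", t2s)):
            exons, cds = st["exons"], st["cds"]
            if strand == "-":
                exons = _mirror(exons, _STRUCT_SPAN)
                cds = _mirror(cds, _STRUCT_SPAN)
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom="chr1",
                    strand=strand,
                    exons=[(s + offset, e + offset) for s, e in sorted(exons)],
                    cds=[(s + offset, e + offset) for s, e in sorted(cds)],
                )
            )
        genes.append(GeneModel(gene_id=gid, transcripts=transcripts))
        div_bp = interval_length(
            symmetric_difference_intervals(
                transcripts[0].exons, transcripts[1].exons
            )
        )
        rows.append(
            {
                "gene_id": gid,
                "event_class": ev,
                "effect_class": effect_of[i],
                "effect_size": cfg.effect_size if effect_of[i] != "null" else 0.0,
                "focal_transcript": f"{gid}.t2",
                "strand": strand,
                "divergent_bp": div_bp,
                "cds_change_bp": cds_bp if ev != "none" else cds_bp,
                "coding": cds_bp > 100,
                "de_lps": bool(de_lps[i]),
                "de_lps_log2fc": float(
                    de_sign[i] * np.log2(cfg.de_fold) * de_lps[i]
                ),
            }
        )
    truth = pd.DataFrame(rows).set_index("gene_id")
    return genes, truth


def make_metadata(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample sheet for the 2x2 design: each donor contributes both treatments."""
    rows = []
    donor = 0
    for mf, n in (("MDM", cfg.n_mdm_donors), ("IPSDM", cfg.n_ipsdm_donors)):
        for _ in range(n):
            donor += 1
            for tr in ("naive", "LPS"):
                rows.append(
                    {
                        "sample_id": f"{mf}_d{donor}_{tr}",
                        "mf_type": mf,
                        "treatment": tr,
                        "donor": f"d{donor}",
                    }
                )
    return pd.DataFrame(rows)


def true_proportion(effect_class: str, baseline: float, delta: float,
                    is_lps: bool, is_ipsdm: bool) -> float:
    """Focal-transcript proportion for one condition group."""
    p = baseline
    if effect_class == "LPS":
        p += delta * is_lps
    elif effect_class == "MF_type":
        p += delta * is_ipsdm
    elif effect_class == "both_same":
        p += delta * is_lps + delta * is_ipsdm
    elif effect_class == "opposite":
        p += delta * is_lps * (1 if not is_ipsdm else -1)
    return float(np.clip(p, 0.02, 0.98))


def simulate_counts(
    genes: list[GeneModel], truth: pd.DataFrame, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw transcript-level NB counts for every sample of the 2x2 design."""
    rng = np.random.default_rng(cfg.seed + 1)
    metadata = make_metadata(cfg)
    is_lps = (metadata.treatment == "LPS").to_numpy()
    is_ipsdm = (metadata.mf_type == "IPSDM").to_numpy()
    donors = metadata.donor.to_numpy()
    donor_ids = sorted(set(donors))

    rows, index = [], []
    size = 1.0 / cfg.dispersion
    for gene in genes:
        tr = truth.loc[gene.gene_id]
        total = float(rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd))
        total_s = total * np.where(is_lps, 2.0 ** tr["de_lps_log2fc"], 1.0)
        lengths = np.array([t.length for t in gene.transcripts], dtype=float)
        len_factor = lengths / lengths.mean()
        donor_shift = (
            dict(zip(donor_ids, rng.normal(0.0, cfg.donor_sd, len(donor_ids))))
            if cfg.donor_sd > 0
            else None
        )
        p_focal = np.array(
            [
                true_proportion(
                    tr["effect_class"],
                    cfg.baseline_proportion,
                    tr["effect_size"],
                    bool(l),
                    bool(m),
                )
                for l, m in zip(is_lps, is_ipsdm)
            ]
        )
        if donor_shift is not None:
            z = np.log(p_focal / (1 - p_focal))
            z += np.array([donor_shift[d] for d in donors])
            p_focal = 1.0 / (1.0 + np.exp(-z))
        for k, t in enumerate(gene.transcripts):
            p_t = p_focal if t.transcript_id == tr["focal_transcript"] else 1 - p_focal
            mu = total_s * p_t * len_factor[k]
            prob = size / (size + np.maximum(mu, 1e-12))
            counts = rng.negative_binomial(size, prob)
            rows.append(counts)
            index.append(t.transcript_id)
    counts = pd.DataFrame(
        np.vstack(rows), index=index, columns=list(metadata.sample_id)
    )
    counts.index.name = "transcript_id"
    return counts, metadata


def transcript_lengths(genes: list[GeneModel]) -> pd.Series:
    return pd.Series(
        {t.transcript_id: t.length for g in genes for t in g.transcripts},
        name="length",
    )


def gene_map(genes: list[GeneModel]) -> pd.Series:
    return pd.Series(
        {t.transcript_id: g.gene_id for g in genes for t in g.transcripts},
        name="gene_id",
    )
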