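"""Stage 2→3 bridge — promoter-level candidate nomination.

Clustered genes are filtered on promoter evidence in the reference pair
(by default at least two promoter CpGs each showing a 40% methylation
difference), and summarised by a promoter methylation score: 100 x the mean
beta of the gene's differentially methylated promoter probes.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import pandas as pd

from .data_io import PROMOTER_GROUPS, BetaMatrix, ProbeAnnotation, annotation_frame
from .diffcall import ProbeDelta


@dataclasses.dataclass(frozen=True)
class PromoterScore:
    """Promoter methylation score (percent) for one gene in one line."""

    gene: str
    line: str
    score_pct: float
    n_probes_used: int
    diff_pct: Optional[float] = None  # aggressive - parental, percentage points


def _promoter_probes(gene: str, ann: Sequence[ProbeAnnotation]) -> set[str]:
    af = annotation_frame(ann)
    sub = af[(af["gene"] == gene) & af["region_group"].isin(PROMOTER_GROUPS)]
    return set(sub["probe_id"])


def promoter_filter(
    gene_set: Sequence[str],
    deltas: Sequence[ProbeDelta],
    ann: Sequence[ProbeAnnotation],
    min_promoter_cpgs: int = 2,
    min_diff: float = 0.40,
    diff_mode: str = "per-cpg",
) -> list[str]:
    """Retain genes with strong promoter hypermethylation in the reference pair.

    ``per-cpg`` (default): at least ``min_promoter_cpgs`` promoter probes
    each with delta >= ``min_diff``.  ``promoter-mean``: at least
    ``min_promoter_cpgs`` hyper promoter probes and a mean delta over the
    gene's differentially methylated promoter probes >= ``min_diff``.
    """
    if diff_mode not in ("per-cpg", "promoter-mean"):
        raise ValueError(f"unknown diff_mode {diff_mode!r}")
    af = annotation_frame(ann)
    prom = af[af["region_group"].isin(PROMOTER_GROUPS)]
    by_probe = {d.probe_id: d for d in deltas}
    out = []
    for gene in sorted(set(gene_set)):
        probes = prom.loc[prom["gene"] == gene, "probe_id"].unique()
        ds = [by_probe[p] for p in probes if p in by_probe and by_probe[p].passes_detection]
        if diff_mode == "per-cpg":
            strong = [d for d in ds if d.delta >= min_diff]
            if len(strong) >= min_promoter_cpgs:
                out.append(gene)
        else:
            hyper = [d for d in ds if d.hyper]
            if len(hyper) >= min_promoter_cpgs:
                mean_delta = sum(d.delta for d in hyper) / len(hyper)
                if mean_delta >= min_diff:
                    out.append(gene)
    return out


def promoter_methylation_score(
    gene: str,
    bm: BetaMatrix,
    deltas: Sequence[ProbeDelta],
    ann: Sequence[ProbeAnnotation],
    line: str,
) -> Optional[PromoterScore]:
    """100 x mean replicate-median beta over the gene's differentially
    methylated promoter probes in ``line``; None if no probe qualifies."""
    qualifying = _qualifying_probes(gene, deltas, ann)
    if not qualifying:
        return None
    samples = bm.samples_of(line)
    medians = bm.beta.loc[sorted(qualifying), samples].median(axis=1)
    return PromoterScore(
        gene=gene,
        line=line,
        score_pct=float(medians.mean() * 100.0),
        n_probes_used=len(qualifying),
    )


def _qualifying_probes(
    gene: str, deltas: Sequence[ProbeDelta], ann: Sequence[ProbeAnnotation]
) -> set[str]:
    prom = _promoter_probes(gene, ann)
    return {d.probe_id for d in deltas if d.hyper and d.probe_id in prom}


def promoter_score_table(
    genes: Sequence[str],
    bm: BetaMatrix,
    deltas: Sequence[ProbeDelta],
    ann: Sequence[ProbeAnnotation],
    parental: str,
    aggressive: str,
) -> pd.DataFrame:
    """Promoter scores for both lines and their difference, one row per gene."""
    rows = []
    for gene in genes:
        sp = promoter_methylation_score(gene, bm, deltas, ann, parental)
        sa = promoter_methylation_score(gene, bm, deltas, ann, aggressive)
        if sp is None or sa is None:
            continue
        rows.append(
            {
                "gene": gene,
                "score_parental_pct": sp.score_pct,
                "score_aggressive_pct": sa.score_pct,
                "diff_pct": sa.score_pct - sp.score_pct,
                "n_probes_used": sa.n_probes_used,
            }
        )
    return pd.DataFrame(rows, columns=[
        "gene", "score_parental_pct", "score_aggressive_pct", "diff_pct", "n_probes_used"
    ])


def rank_candidates(
    scores: pd.DataFrame,
    functional_list: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Sort candidates by promoter-score difference, flag functional overlap.

    ``functional_list`` stands in for an externally derived functional gene
    list (e.g. pathway-analysis output); when given, candidates present in
    it are flagged ``in_functional_list``.
    """
    out = scores.sort_values("diff_pct", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
    flagged = set(functional_list) if functional_list else set()
    out["in_functional_list"] = out["gene"].isin(flagged)
    return out
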