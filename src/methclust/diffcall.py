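"""Stage 1 — differential hypermethylation calling between paired lines.

A probe is called hypermethylated in the aggressive line when the difference
of replicate-median beta values (aggressive minus parental) reaches the
differential threshold (default 0.2, the smallest difference detectable with
99% confidence on Infinium arrays) and every replicate of both lines passes
the detection p-value cutoff (default 0.01).  Genes are called when at least
``min_cpgs`` (default 3) of their probes are hypermethylated, and the genes
shared by all pairs form the common hypermethylated set.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import PROMOTER_GROUPS, BetaMatrix, ProbeAnnotation, annotation_frame


@dataclasses.dataclass(frozen=True)
class ProbeDelta:
    """Replicate-median beta difference for one probe in one pair."""

    probe_id: str
    median_parental: float
    median_aggressive: float
    delta: float
    passes_detection: bool
    hyper: bool


@dataclasses.dataclass(frozen=True)
class GeneCall:
    """Per-gene hypermethylation call for one cell-line pair."""

    gene: str
    pair: str
    n_hyper_cpgs: int
    hyper_gene: bool
    hyper_probe_ids: tuple[str, ...]


def probe_deltas(
    bm: BetaMatrix,
    parental: str,
    aggressive: str,
    delta_threshold: float = 0.2,
    detp_max: float = 0.01,
) -> list[ProbeDelta]:
    """Per-probe replicate-median differences with detection filtering.

    A probe fails detection if *any* sample of either line has detection
    p >= ``detp_max``; failing probes can never be hyper.
    """
    par_samples = bm.samples_of(parental)
    agg_samples = bm.samples_of(aggressive)
    med_par = bm.beta[par_samples].median(axis=1)
    med_agg = bm.beta[agg_samples].median(axis=1)
    detp = bm.detect_p[par_samples + agg_samples].to_numpy()
    # NaN detection p counts as failing (comparison with NaN is False)
    passes = np.all(detp < detp_max, axis=1)
    delta = (med_agg - med_par).to_numpy()
    # tiny slack so a difference that is exactly the threshold up to float
    # representation (e.g. 0.30 - 0.10) still qualifies
    hyper = passes & (delta >= delta_threshold - 1e-12)
    return [
        ProbeDelta(
            probe_id=pid,
            median_parental=float(mp),
            median_aggressive=float(ma),
            delta=float(d),
            passes_detection=bool(p),
            hyper=bool(h),
        )
        for pid, mp, ma, d, p, h in zip(
            bm.probe_ids, med_par.to_numpy(), med_agg.to_numpy(), delta, passes, hyper
        )
    ]


def aggregate_genes(
    deltas: Sequence[ProbeDelta],
    ann: Sequence[ProbeAnnotation],
    min_cpgs: int = 3,
    promoter_only: bool = False,
    pair: str = "pair",
) -> list[GeneCall]:
    """Count hyper probes per gene and call genes with >= ``min_cpgs``.

    With ``promoter_only``, only probes annotated to the gene through a
    promoter region group (TSS1500/TSS200/5'UTR/1st exon) are counted.
    Returns one call per gene that has at least one hyper probe.
    """
    af = annotation_frame(ann)
    known = set(af["probe_id"])
    hyper_ids = [d.probe_id for d in deltas if d.hyper]
    unknown = [pid for pid in (d.probe_id for d in deltas) if pid not in known]
    if unknown:
        raise KeyError(f"probes absent from annotation: {unknown[:5]}")
    sub = af[af["probe_id"].isin(set(hyper_ids))]
    if promoter_only:
        sub = sub[sub["region_group"].isin(PROMOTER_GROUPS)]
    calls = []
    for gene, grp in sub.groupby("gene", sort=True):
        probe_ids = tuple(sorted(set(grp["probe_id"])))
        n = len(probe_ids)
        calls.append(
            GeneCall(
                gene=gene,
                pair=pair,
                n_hyper_cpgs=n,
                hyper_gene=n >= min_cpgs,
                hyper_probe_ids=probe_ids,
            )
        )
    return calls


def intersect_pairs(
    calls_by_pair: Mapping[str, Sequence[GeneCall]],
) -> dict[str, dict[str, tuple[str, ...]]]:
    """Genes hypermethylated in every pair, with per-pair supporting probes.

    Returns ``{gene: {pair: hyper probe ids}}`` for the common set.
    """
    if not calls_by_pair:
        raise ValueError("no pairs supplied")
    if len(calls_by_pair) == 1:
        warnings.warn("single pair supplied; intersection is degenerate", stacklevel=2)
    per_pair: dict[str, dict[str, GeneCall]] = {
        pair: {c.gene: c for c in calls if c.hyper_gene}
        for pair, calls in calls_by_pair.items()
    }
    common = set.intersection(*(set(d) for d in per_pair.values()))
    return {
        gene: {pair: per_pair[pair][gene].hyper_probe_ids for pair in calls_by_pair}
        for gene in sorted(common)
    }


def region_breakdown(
    gene_set: Sequence[str],
    deltas: Sequence[ProbeDelta],
    ann: Sequence[ProbeAnnotation],
) -> pd.DataFrame:
    """Distribution of hyper CpGs of a gene set over region classes.

    Classes are promoter (TSS1500/TSS200/5'UTR/1st exon), gene body and
    3'UTR.  A probe annotated to multiple genes of the set counts once per
    class membership; fractions sum to 1 over the three classes (when any
    CpG is classified).
    """
    genes = set(gene_set)
    hyper_ids = {d.probe_id for d in deltas if d.hyper}
    af = annotation_frame(ann)
    sub = af[af["gene"].isin(genes) & af["probe_id"].isin(hyper_ids)].copy()
    sub["region_class"] = np.where(
        sub["region_group"].isin(PROMOTER_GROUPS),
        "promoter",
        np.where(sub["region_group"] == "Body", "body", "3UTR"),
    )
    counts = {
        cls: int(sub.loc[sub["region_class"] == cls, "probe_id"].nunique())
        for cls in ("promoter", "body", "3UTR")
    }
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "count": pd.Series(counts),
            "fraction": pd.Series(
                {k: (v / total if total else 0.0) for k, v in counts.items()}
            ),
        }
    )


# ---------------------------------------------------------------------------
# Nearest centroid marker classifier
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CentroidModel:
    """Nearest-centroid methylation marker classifier.

    Markers are probes whose group centroids (mean beta) differ by at least
    ``threshold`` and for which at most ``max_misclassified`` training
    samples sit nearer the opposite centroid.  The direction vector is a
    signed z-score: centroid difference over the pooled standard deviation,
    positive when hypermethylated in the second phenotype.
    """

    phenotypes: tuple[str, str]
    marker_probes: tuple[str, ...]
    z_scores: pd.Series  # signed z per marker probe
    centroids: pd.DataFrame  # marker probes x the two phenotypes

    def assign(self, betas: pd.Series | pd.DataFrame) -> str | list[str]:
        """Assign sample(s) to the nearest centroid (mean absolute beta
        distance over marker probes); ties go to the first phenotype."""
        if isinstance(betas, pd.Series):
            return self._assign_one(betas)
        return [self._assign_one(betas[c]) for c in betas.columns]

    def _assign_one(self, beta: pd.Series) -> str:
        v = beta.reindex(self.centroids.index)
        d0 = float((v - self.centroids[self.phenotypes[0]]).abs().mean())
        d1 = float((v - self.centroids[self.phenotypes[1]]).abs().mean())
        return self.phenotypes[1] if d1 < d0 else self.phenotypes[0]


def centroid_classifier(
    bm: BetaMatrix,
    groups: tuple[str, str],
    candidate_probes: Optional[Sequence[str]] = None,
    threshold: float = 0.2,
    max_misclassified: int = 0,
) -> CentroidModel:
    """Select marker probes separating two phenotypes and build a classifier.

    Zero pooled variance at a probe yields a signed-infinite z-score; the
    probe is retained if the centroid test passes.
    """
    g0, g1 = groups
    s0, s1 = bm.samples_of(g0), bm.samples_of(g1)
    if len(s0) < 2 or len(s1) < 2:
        raise ValueError("need >= 2 samples per phenotype")
    probes = list(candidate_probes) if candidate_probes is not None else bm.probe_ids
    b0 = bm.beta.loc[probes, s0]
    b1 = bm.beta.loc[probes, s1]
    m0, m1 = b0.mean(axis=1), b1.mean(axis=1)
    diff = m1 - m0
    n0, n1 = len(s0), len(s1)
    pooled_var = ((n0 - 1) * b0.var(axis=1, ddof=1) + (n1 - 1) * b1.var(axis=1, ddof=1)) / (
        n0 + n1 - 2
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / np.sqrt(pooled_var)
    # variance below float-noise level counts as zero -> signed-infinite z
    z = z.where(np.sqrt(pooled_var) > 1e-9, np.sign(diff) * np.inf)
    z = z.where(diff != 0, 0.0)

    # per-probe training misclassifications: sample nearer the wrong centroid
    mis0 = (b0.sub(m0, axis=0).abs() > b0.sub(m1, axis=0).abs()).sum(axis=1)
    mis1 = (b1.sub(m1, axis=0).abs() > b1.sub(m0, axis=0).abs()).sum(axis=1)
    is_marker = (diff.abs() >= threshold) & ((mis0 + mis1) <= max_misclassified)
    markers = tuple(diff.index[is_marker])
    centroids = pd.DataFrame({g0: m0[is_marker], g1: m1[is_marker]})
    return CentroidModel(
        phenotypes=(g0, g1),
        marker_probes=markers,
        z_scores=z[is_marker],
        centroids=centroids,
    )
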