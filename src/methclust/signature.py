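"""The 0–4 per-patient methylation score and risk group.

Four genes enter the signature — MYH1 (one CpG, hypomethylated in
aggressive tumours), PCDHB16 and PCDHB15 (one CpG each, hypermethylated)
and BCL2L10 (two adjacent CpGs averaged, hypermethylated).  Each gene
scores 1 when the patient's methylation deviates from the primary-cohort
median by at least 15 percentage points in the gene's aggressive direction;
the total is the sum over the four genes (0–4) and patients with total >= 2
form the high-risk group.
"""
from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .data_io import PatientRecord


@dataclasses.dataclass(frozen=True)
class SignatureEntry:
    gene: str
    cpgs: tuple[str, ...]
    direction: str  # "hypo" | "hyper"
    combine: str  # "single" | "mean"

    def __post_init__(self) -> None:
        if self.direction not in ("hypo", "hyper"):
            raise ValueError(f"{self.gene}: direction must be hypo/hyper")
        if self.combine not in ("single", "mean"):
            raise ValueError(f"{self.gene}: combine must be single/mean")
        if self.combine == "single" and len(self.cpgs) != 1:
            raise ValueError(f"{self.gene}: combine='single' needs exactly one CpG")


@dataclasses.dataclass(frozen=True)
class SignatureSpec:
    entries: tuple[SignatureEntry, ...]
    deviation_threshold_pct: float = 15.0
    score_cutoff: int = 2
    strict_threshold: bool = False  # ">" instead of ">=" at the boundary

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    @property
    def cpg_ids(self) -> list[str]:
        return [c for e in self.entries for c in e.cpgs]


def default_signature_spec(**overrides) -> SignatureSpec:
    """The four-gene, five-CpG melanoma aggressiveness signature."""
    return SignatureSpec(
        entries=(
            SignatureEntry("MYH1", ("cpg_MYH1_1",), "hypo", "single"),
            SignatureEntry("PCDHB16", ("cpg_PCDHB16_1",), "hyper", "single"),
            SignatureEntry("PCDHB15", ("cpg_PCDHB15_1",), "hyper", "single"),
            SignatureEntry("BCL2L10", ("cpg_BCL2L10_1", "cpg_BCL2L10_2"), "hyper", "mean"),
        ),
        **overrides,
    )


@dataclasses.dataclass
class SignatureResult:
    patient_id: str
    gene_values: dict[str, float]  # combined methylation percent per gene
    gene_scores: dict[str, int]
    total: int
    high_risk: bool
    incomplete: bool = False  # some gene had missing CpGs (scored 0)
    n_missing_genes: int = 0


def _combine(patient: PatientRecord, entry: SignatureEntry) -> float:
    vals = [patient.cpg_meth.get(c, float("nan")) for c in entry.cpgs]
    arr = np.asarray(vals, dtype=float)
    if np.isnan(arr).any():
        return float("nan")
    return float(arr.mean()) if entry.combine == "mean" else float(arr[0])


def reference_medians(
    patients: Sequence[PatientRecord],
    spec: SignatureSpec,
    reference: str = "primaries",
) -> dict[str, float]:
    """Per-gene reference medians over the cohort.

    The gene's combine rule (mean of the two BCL2L10 CpGs) is applied per
    patient first, then the median is taken over the reference set —
    ``primaries`` (default) or ``metastases``.
    """
    if reference not in ("primaries", "metastases"):
        raise ValueError(f"unknown reference {reference!r}")
    wanted = "primary" if reference == "primaries" else "metastatic"
    ref = [p for p in patients if p.sample_type == wanted]
    if not ref:
        raise ValueError(f"no {wanted} patients in cohort")
    out: dict[str, float] = {}
    for entry in spec.entries:
        vals = [_combine(p, entry) for p in ref]
        vals = [v for v in vals if not np.isnan(v)]
        if not vals:
            raise ValueError(
                f"signature CpGs for {entry.gene} missing in every {wanted} patient"
            )
        out[entry.gene] = float(np.median(vals))
    return out


def gene_subscore(
    patient_value: float,
    median: float,
    direction: str,
    threshold_pct: float = 15.0,
    strict: bool = False,
) -> int:
    """1 when the value deviates from the median by >= threshold (percentage
    points) in the gene's aggressive direction, else 0."""
    if np.isnan(patient_value):
        return 0
    dev = (median - patient_value) if direction == "hypo" else (patient_value - median)
    return int(dev > threshold_pct if strict else dev >= threshold_pct)


def signature_score(
    patient: PatientRecord,
    medians: Mapping[str, float],
    spec: SignatureSpec,
) -> SignatureResult:
    """Score one patient against the cohort medians.

    A gene whose CpGs are missing contributes 0 and marks the result
    incomplete.
    """
    gene_values: dict[str, float] = {}
    gene_scores: dict[str, int] = {}
    n_missing = 0
    for entry in spec.entries:
        v = _combine(patient, entry)
        gene_values[entry.gene] = v
        if np.isnan(v):
            n_missing += 1
            gene_scores[entry.gene] = 0
            continue
        gene_scores[entry.gene] = gene_subscore(
            v,
            medians[entry.gene],
            entry.direction,
            spec.deviation_threshold_pct,
            spec.strict_threshold,
        )
    if n_missing:
        warnings.warn(
            f"patient {patient.patient_id}: {n_missing} signature gene(s) missing; "
            "scored 0 for those genes",
            stacklevel=2,
        )
    total = sum(gene_scores.values())
    return SignatureResult(
        patient_id=patient.patient_id,
        gene_values=gene_values,
        gene_scores=gene_scores,
        total=total,
        high_risk=total >= spec.score_cutoff,
        incomplete=n_missing > 0,
        n_missing_genes=n_missing,
    )


def score_cohort(
    patients: Sequence[PatientRecord],
    spec: SignatureSpec,
    reference: str = "primaries",
) -> list[SignatureResult]:
    """Reference medians + per-patient scores in one call."""
    medians = reference_medians(patients, spec, reference=reference)
    return [signature_score(p, medians, spec) for p in patients]


def independence_test(
    results: Sequence[SignatureResult],
    n_sim: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise association of the per-gene sub-scores.

    For each gene pair the 2x2 table of {0,1} sub-scores is summarised by
    the chi-square statistic (no continuity correction); the p-value comes
    from a seeded Monte-Carlo permutation of one margin, which remains valid
    at the small counts typical of these cohorts.  Pairs where a gene is
    constant are reported untestable.
    """
    genes = sorted({g for r in results for g in r.gene_scores})
    cols = {g: np.array([r.gene_scores.get(g, 0) for r in results]) for g in genes}
    rng = np.random.default_rng(seed)
    rows = []
    for ga, gb in itertools.combinations(genes, 2):
        a, b = cols[ga], cols[gb]
        if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
            rows.append({"gene_a": ga, "gene_b": gb, "chi2": np.nan,
                         "p_value": np.nan, "testable": False})
            continue
        obs = _chi2_stat(a, b)
        perm = np.empty(n_sim)
        for s in range(n_sim):
            perm[s] = _chi2_stat(a, rng.permutation(b))
        p = (1.0 + np.sum(perm >= obs - 1e-12)) / (n_sim + 1.0)
        rows.append({"gene_a": ga, "gene_b": gb, "chi2": obs,
                     "p_value": float(p), "testable": True})
    return pd.DataFrame(rows)


def _chi2_stat(a: np.ndarray, b: np.ndarray) -> float:
    table = pd.crosstab(a, b).to_numpy()
    if table.shape != (2, 2):
        # a permutation can empty a cell's row/column; pad to 2x2
        full = np.zeros((2, 2))
        t = pd.crosstab(a, b)
        for i in t.index:
            for j in t.columns:
                full[int(i), int(j)] = t.loc[i, j]
        table = full
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return 0.0
    stat, _p, _dof, _exp = chi2_contingency(table, correction=False)
    return float(stat)


def results_frame(results: Sequence[SignatureResult]) -> pd.DataFrame:
    """Flat per-patient table of gene sub-scores, total and risk group."""
    rows = []
    for r in results:
        row = {"patient_id": r.patient_id, "total": r.total,
               "high_risk": r.high_risk, "incomplete": r.incomplete}
        for g, s in r.gene_scores.items():
            row[f"score_{g}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
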