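"""Synthetic genomes, paired cell-line beta matrices, and patient cohorts.

The generator emulates the study design the pipeline targets: three pairs of
cell lines (a parental line and an aggressive derivative, three replicates
each) profiled on a 450K-style array, with a set of genes hypermethylated in
the aggressive member of *every* pair — some of them arranged in genomic
clusters — plus pair-specific hypermethylation that must not survive the
intersection.  A separate cohort generator produces patients whose CpG
methylation percentages and survival times carry a planted aggressiveness
signal, so each downstream stage can be checked against ground truth.

All randomness flows through ``numpy.random.default_rng`` seeded with
integer seed sequences, so a fixed seed reproduces outputs bit-identically
across runs and platforms.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_io import (
    PROMOTER_GROUPS,
    REGION_GROUPS,
    BetaMatrix,
    PatientRecord,
    ProbeAnnotation,
)

# Region labels cycle promoter-first so every gene with >=4 probes has >=3
# promoter CpGs (needed for the planted shift to be callable at min_cpgs=3).
_REGION_CYCLE = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")


@dataclasses.dataclass
class SynthDesign:
    """Layout and planted structure for the paired cell-line experiment."""

    n_chromosomes: int = 20
    genes_per_chrom: int = 150
    probes_per_gene: int = 6
    chrom_length_bp: int = 150_000_000
    n_pairs: int = 3
    n_replicates: int = 3
    planted_common_genes: tuple[str, ...] = ()
    planted_cluster_spans: tuple[tuple[str, tuple[int, int]], ...] = ()
    planted_pair_specific: tuple[tuple[str, ...], ...] = ()
    delta_hyper: float = 0.35
    noise_sd: float = 0.02
    fraction_detp_fail: float = 0.0
    include_sex: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_hyper <= 0.2:
            raise ValueError(
                "delta_hyper must exceed 0.2 so planted genes clear the "
                "differential-methylation threshold"
            )
        if self.genes_per_chrom * self.probes_per_gene == 0:
            raise ValueError("genes_per_chrom and probes_per_gene must be positive")
        if not 1 <= self.n_chromosomes <= 22:
            raise ValueError("n_chromosomes must be in 1..22 (autosome labels)")

    @property
    def chromosomes(self) -> list[str]:
        chroms = [str(i) for i in range(1, self.n_chromosomes + 1)]
        if self.include_sex:
            chroms += ["X", "Y"]
        return chroms

    def gene_name(self, chrom: str, idx: int) -> str:
        return f"G{chrom}_{idx:03d}"

    @property
    def gene_universe(self) -> set[str]:
        return {
            self.gene_name(c, i)
            for c in self.chromosomes
            for i in range(self.genes_per_chrom)
        }


@dataclasses.dataclass
class SurvivalDesign:
    """Cohort layout and planted survival effect for the patient generator.

    Survival times are exponential under proportional hazards: the baseline
    median fixes the rate for non-aggressive patients and the hazard of a
    planted-aggressive patient is multiplied by ``effect_hr``, so a Cox fit
    on the true labels recovers ``effect_hr``.  Censoring is an independent
    uniform time calibrated numerically to the requested overall rate.
    """

    n_primary: int = 49
    n_metastatic: int = 10
    effect_hr: float = 3.4
    baseline_median_months: float = 51.0
    censor_rate: float = 0.15
    meth_shift_pct: float = 25.0
    noise_sd_pct: float = 5.0
    aggressive_frac: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_hr <= 0:
            raise ValueError("effect_hr must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.meth_shift_pct <= 15:
            warnings.warn(
                "meth_shift_pct <= 15: planted effect at or below the score's "
                "deviation threshold; the signature will not detect it reliably",
                stacklevel=2,
            )


def default_design(seed: int = 0, **overrides) -> SynthDesign:
    """The standard planted layout: 50 common hyper genes, 9 clusters on 6
    chromosomes (30 clustered genes + 20 scattered singletons), and 25
    pair-specific extra genes per pair.
    """
    spans = (
        ("1", (10, 13)),
        ("1", (40, 42)),
        ("2", (20, 22)),
        ("2", (60, 61)),
        ("3", (30, 35)),
        ("4", (50, 51)),
        ("5", (70, 73)),
        ("6", (80, 82)),
        ("6", (100, 102)),
    )
    design = SynthDesign(seed=seed, **overrides)
    common: list[str] = []
    for chrom, (lo, hi) in spans:
        common += [design.gene_name(chrom, i) for i in range(lo, hi + 1)]
    # 20 scattered singletons on chromosomes 7..16, far apart in both index
    # and distance so they never satisfy the linkage rule.
    for c in range(7, 17):
        common += [design.gene_name(str(c), 20), design.gene_name(str(c), 90)]
    pair_specific = tuple(
        tuple(design.gene_name(str(17 + p), 5 * i) for i in range(25))
        for p in range(design.n_pairs)
    )
    return dataclasses.replace(
        design,
        planted_common_genes=tuple(common),
        planted_cluster_spans=spans,
        planted_pair_specific=pair_specific,
    )


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def make_genome(design: SynthDesign) -> tuple[list[ProbeAnnotation], pd.DataFrame]:
    """Lay out genes and probes deterministically.

    Returns the probe annotations and a gene catalogue DataFrame with
    columns ``gene, chrom, pos`` (pos = TSS, strictly increasing per
    chromosome; genes evenly spaced along the chromosome).
    """
    universe = design.gene_universe
    missing = [g for g in design.planted_common_genes if g not in universe]
    if missing:
        raise ValueError(f"planted genes not in generated universe: {missing[:5]}")
    for extras in design.planted_pair_specific:
        missing = [g for g in extras if g not in universe]
        if missing:
            raise ValueError(f"planted pair-specific genes not in universe: {missing[:5]}")

    spacing = design.chrom_length_bp // (design.genes_per_chrom + 1)
    ann: list[ProbeAnnotation] = []
    catalogue_rows = []
    for chrom in design.chromosomes:
        for gi in range(design.genes_per_chrom):
            gene = design.gene_name(chrom, gi)
            tss = spacing * (gi + 1)
            catalogue_rows.append((gene, chrom, tss))
            for pi in range(design.probes_per_gene):
                ann.append(
                    ProbeAnnotation(
                        probe_id=f"cg_{gene}_{pi}",
                        chrom=chrom,
                        pos=tss + 50 * pi,
                        genes=(gene,),
                        region_groups=(_REGION_CYCLE[pi % len(_REGION_CYCLE)],),
                    )
                )
    catalogue = pd.DataFrame(catalogue_rows, columns=["gene", "chrom", "pos"])
    return ann, catalogue


def _promoter_probe_indices(design: SynthDesign) -> np.ndarray:
    """Within-gene probe offsets that carry the planted promoter shift."""
    offs = [
        pi
        for pi in range(design.probes_per_gene)
        if _REGION_CYCLE[pi % len(_REGION_CYCLE)] in PROMOTER_GROUPS
    ]
    return np.asarray(offs, dtype=int)


def simulate_pair_betas(design: SynthDesign, pair_index: int) -> BetaMatrix:
    """Simulate one parental/aggressive pair with planted hypermethylation.

    Parental replicates scatter around a per-probe baseline beta; aggressive
    replicates additionally gain ``delta_hyper`` at every promoter probe of
    each gene planted for this pair.  Noise is truncated normal on [0, 1].
    """
    if not 0 <= pair_index < design.n_pairs:
        raise IndexError(f"pair_index {pair_index} out of range 0..{design.n_pairs - 1}")
    ann, _cat = make_genome(design)
    rng = np.random.default_rng([design.seed, 101, pair_index])

    n_probes = len(ann)
    probe_ids = [a.probe_id for a in ann]
    # Baseline drawn once per probe; headroom so the planted shift does not
    # saturate at 1 and bias the recovered delta.
    baseline = rng.uniform(0.05, 0.55, size=n_probes)

    shifted_genes = set(design.planted_common_genes)
    if design.planted_pair_specific:
        shifted_genes |= set(design.planted_pair_specific[pair_index])
    prom_offs = set(_promoter_probe_indices(design).tolist())
    shift = np.zeros(n_probes)
    for i, a in enumerate(ann):
        gene = a.genes[0]
        if gene in shifted_genes and int(a.probe_id.rsplit("_", 1)[1]) in prom_offs:
            shift[i] = design.delta_hyper

    parental = f"par{pair_index + 1}"
    aggressive = f"agg{pair_index + 1}"
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, tuple[str, int]] = {}
    for line, mean in ((parental, baseline), (aggressive, baseline + shift)):
        for rep in range(design.n_replicates):
            sid = f"{line}_r{rep + 1}"
            noise = rng.normal(0.0, design.noise_sd, size=n_probes) if design.noise_sd > 0 else 0.0
            cols[sid] = np.clip(mean + noise, 0.0, 1.0)
            groups[sid] = (line, rep + 1)

    beta = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
    detp_vals = rng.uniform(0.0, 0.005, size=beta.shape)
    if design.fraction_detp_fail > 0:
        fail = rng.random(size=beta.shape) < design.fraction_detp_fail
        detp_vals = np.where(fail, rng.uniform(0.01, 0.05, size=beta.shape), detp_vals)
    detp = pd.DataFrame(detp_vals, index=beta.index, columns=beta.columns)
    return BetaMatrix(beta=beta, detect_p=detp, sample_groups=groups)


# ---------------------------------------------------------------------------
# Patient cohort
# ---------------------------------------------------------------------------

def _uniform_censor_horizon(rates: np.ndarray, target: float) -> float:
    """Horizon c of a U(0, c) censoring time giving the requested overall
    censoring fraction against exponential event times with the given rates."""

    def expected_censored(c: float) -> float:
        lam = rates
        return float(np.mean((1.0 - np.exp(-lam * c)) / (lam * c)))

    return brentq(lambda c: expected_censored(c) - target, 1e-9, 1e9)


def simulate_cohort(
    sdesign: SurvivalDesign,
    signature_spec,
) -> tuple[list[PatientRecord], dict[str, bool]]:
    """Simulate a patient cohort with a planted aggressiveness signature.

    ``signature_spec`` is a :class:`methclust.signature.SignatureSpec` (or
    anything with ``entries`` of (gene, cpgs, direction, combine)).  A latent
    aggressive indicator is drawn per primary patient; aggressive patients'
    signature CpGs deviate from the cohort baseline by ``meth_shift_pct`` in
    each gene's aggressive direction, and their hazard is multiplied by
    ``effect_hr``.  Metastatic patients get aggressive-like methylation and
    hazard.  Returns the records and the ground-truth label map.
    """
    rng = np.random.default_rng([sdesign.seed, 202])

    # Baseline (non-aggressive) mean percent per gene; values chosen so a
    # +/- meth_shift_pct excursion stays well inside [0, 100].
    base_means = {"hypo": 60.0, "hyper": 25.0}

    n_pri, n_met = sdesign.n_primary, sdesign.n_metastatic
    aggressive_pri = rng.random(n_pri) < sdesign.aggressive_frac
    is_aggressive = np.concatenate([aggressive_pri, np.ones(n_met, dtype=bool)])
    sample_type = ["primary"] * n_pri + ["metastatic"] * n_met
    ids = [f"P{i + 1:03d}" for i in range(n_pri)] + [f"M{i + 1:03d}" for i in range(n_met)]
    n = n_pri + n_met

    cpg_meth: list[dict[str, float]] = [dict() for _ in range(n)]
    for entry in signature_spec.entries:
        base = base_means[entry.direction]
        sign = -1.0 if entry.direction == "hypo" else 1.0
        for cpg in entry.cpgs:
            mean = np.where(is_aggressive, base + sign * sdesign.meth_shift_pct, base)
            vals = np.clip(rng.normal(mean, sdesign.noise_sd_pct), 0.0, 100.0)
            for i in range(n):
                cpg_meth[i][cpg] = float(vals[i])

    lam0 = math.log(2.0) / sdesign.baseline_median_months
    rates = np.where(is_aggressive, lam0 * sdesign.effect_hr, lam0)
    event_t = rng.exponential(1.0 / rates)
    if sdesign.censor_rate > 0:
        horizon = _uniform_censor_horizon(rates, sdesign.censor_rate)
        censor_t = rng.uniform(0.0, horizon, size=n)
        observed = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
    else:
        observed = event_t
        event = np.ones(n, dtype=int)

    # Breslow depth correlates with aggressiveness (lognormal around 1.5 mm
    # for indolent, 3.5 mm for aggressive tumours); T stage derived from it.
    depth = np.exp(rng.normal(np.where(is_aggressive, math.log(3.5), math.log(1.5)), 0.35))
    t_stage = np.select(
        [depth < 1.0, depth < 2.0, depth < 4.0], ["T1", "T2", "T3"], default="T4"
    )

    patients: list[PatientRecord] = []
    truth: dict[str, bool] = {}
    for i in range(n):
        patients.append(
            PatientRecord(
                patient_id=ids[i],
                sample_type=sample_type[i],
                cpg_meth=cpg_meth[i],
                os_months=float(observed[i]),
                event=int(event[i]),
                t_stage=str(t_stage[i]),
                breslow_mm=float(depth[i]),
            )
        )
        truth[ids[i]] = bool(is_aggressive[i])
    return patients, truth


def write_truth_table(truth: dict[str, bool], path) -> None:
    """Sidecar ground-truth labels for a simulated cohort."""
    pd.DataFrame(
        {"patient_id": list(truth), "aggressive": [int(v) for v in truth.values()]}
    ).to_csv(path, index=False)
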