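"""Readers and writers for the tabular formats the pipeline touches.

All files are plain delimited text (comma or tab, auto-detected).  Internal
genomic coordinates are 1-based, matching Illumina array manifests; the only
conversion to 0-based half-open coordinates happens at BED export.  Missing
beta values are represented as NaN, never as 0 (0 is a meaningful
methylation value).
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

#: The six Illumina gene-region annotation groups.
REGION_GROUPS = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

#: Region groups that make up the promoter (TSS1500-TSS200-5'UTR-first exon).
PROMOTER_GROUPS = frozenset({"TSS1500", "TSS200", "5UTR", "1stExon"})

SEX_CHROMOSOMES = frozenset({"X", "Y"})

#: Default thresholds for every tunable stage; a YAML config file with the
#: same nested layout can override any subset (see :func:`load_config`).
DEFAULT_CONFIG: dict = {
    "diffcall": {
        "delta_threshold": 0.2,
        "detp_max": 0.01,
        "min_cpgs": 3,
        "promoter_only": False,
    },
    "clusters": {
        "max_gap_mb": 3.0,
        "n_sim": 1000,
        "include_sex": False,
    },
    "candidates": {
        "min_promoter_cpgs": 2,
        "min_diff": 0.40,
        "diff_mode": "per-cpg",
    },
    "signature": {
        "deviation_threshold_pct": 15.0,
        "score_cutoff": 2,
        "strict_threshold": False,
        "reference": "primaries",
    },
}


class DataFormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ProbeAnnotation:
    """One array probe with its genomic location and gene assignments.

    ``genes`` and ``region_groups`` are parallel lists: a probe annotated to
    several genes carries one region label per gene and counts toward each.
    """

    probe_id: str
    chrom: str
    pos: int
    genes: tuple[str, ...]
    region_groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataFormatError(f"probe {self.probe_id}: pos must be >= 1, got {self.pos}")
        if len(self.genes) != len(self.region_groups):
            raise DataFormatError(
                f"probe {self.probe_id}: genes ({len(self.genes)}) and region_groups "
                f"({len(self.region_groups)}) must be parallel lists"
            )
        for grp in self.region_groups:
            if grp not in REGION_GROUPS:
                raise DataFormatError(
                    f"probe {self.probe_id}: unknown region group {grp!r}; "
                    f"expected one of {REGION_GROUPS}"
                )


@dataclasses.dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with detection p-values.

    ``beta`` and ``detect_p`` are equally shaped DataFrames indexed by probe
    id with sample-id columns; ``sample_groups`` maps each sample id to its
    (cell line, replicate index) pair.
    """

    beta: pd.DataFrame
    detect_p: pd.DataFrame
    sample_groups: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        if self.beta.shape != self.detect_p.shape:
            raise DataFormatError("beta and detect_p must have identical shapes")
        if not self.beta.index.equals(self.detect_p.index) or not self.beta.columns.equals(
            self.detect_p.columns
        ):
            raise DataFormatError("beta and detect_p must share probe/sample labels")
        missing = [s for s in self.sample_groups if s not in self.beta.columns]
        if missing:
            raise DataFormatError(f"samples in design absent from matrix: {missing}")
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            r, c = np.argwhere(bad & ~np.isnan(vals))[0]
            raise DataFormatError(
                f"beta outside [0,1] at probe {self.beta.index[r]!r}, "
                f"sample {self.beta.columns[c]!r} (value {vals[r, c]})"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for line, _rep in self.sample_groups.values():
            seen.setdefault(line, None)
        return list(seen)

    def samples_of(self, line: str) -> list[str]:
        """Sample ids belonging to one cell line, in column order."""
        members = {s for s, (ln, _r) in self.sample_groups.items() if ln == line}
        out = [s for s in self.beta.columns if s in members]
        if not out:
            raise KeyError(f"unknown cell line {line!r}; lines present: {self.lines()}")
        return out


@dataclasses.dataclass
class PatientRecord:
    """One patient: CpG methylation percentages, survival and staging."""

    patient_id: str
    sample_type: str  # "primary" | "metastatic"
    cpg_meth: dict[str, float]  # CpG id -> percent in [0, 100]
    os_months: float
    event: int  # 1 = death observed, 0 = censored
    t_stage: str = "unknown"  # T1..T4 or "unknown"
    breslow_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sample_type not in ("primary", "metastatic"):
            raise DataFormatError(
                f"patient {self.patient_id}: sample_type must be primary/metastatic"
            )
        if self.os_months < 0:
            raise DataFormatError(f"patient {self.patient_id}: negative os_months")
        if self.event not in (0, 1):
            raise DataFormatError(f"patient {self.patient_id}: event must be 0/1")
        for cpg, v in self.cpg_meth.items():
            if not math.isnan(v) and not (0.0 <= v <= 100.0):
                raise DataFormatError(
                    f"patient {self.patient_id}: methylation percent for {cpg} "
                    f"outside [0,100] ({v})"
                )
        if self.t_stage not in ("T1", "T2", "T3", "T4", "unknown"):
            raise DataFormatError(f"patient {self.patient_id}: bad t_stage {self.t_stage!r}")


@dataclasses.dataclass
class ClusterCall:
    """A detected run of hypermethylated genes on one chromosome."""

    chrom: str
    member_genes: tuple[str, ...]
    start: int  # 1-based position of the first member gene
    end: int  # 1-based position of the last member gene
    p_value: Optional[float] = None

    @property
    def n_members(self) -> int:
        return len(self.member_genes)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def annotation_frame(ann: Sequence[ProbeAnnotation]) -> pd.DataFrame:
    """Expand annotations to one (probe, gene, region) row per assignment."""
    rows = []
    for a in ann:
        for gene, grp in zip(a.genes, a.region_groups):
            rows.append((a.probe_id, a.chrom, a.pos, gene, grp))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "gene", "region_group"])


def _read_table(path) -> pd.DataFrame:
    # sep=None + python engine sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python", dtype=str)


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise DataFormatError(f"{path}: missing required column {c!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_manifest(path) -> list[ProbeAnnotation]:
    """Read a probe annotation manifest.

    Expected header columns: ``probe_id, chrom, pos, genes, region_groups``
    with ``genes`` and ``region_groups`` ``;``-separated parallel lists.
    """
    df = _read_table(path)
    _require_columns(df, ["probe_id", "chrom", "pos", "genes", "region_groups"], path)
    out: list[ProbeAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        try:
            pos = int(str(row.pos))
        except (TypeError, ValueError):
            raise DataFormatError(f"{path}: line {i}: pos {row.pos!r} is not an integer")
        genes = tuple(g for g in str(row.genes).split(";") if g) if pd.notna(row.genes) else ()
        groups = (
            tuple(g for g in str(row.region_groups).split(";") if g)
            if pd.notna(row.region_groups)
            else ()
        )
        try:
            out.append(
                ProbeAnnotation(
                    probe_id=str(row.probe_id),
                    chrom=str(row.chrom),
                    pos=pos,
                    genes=genes,
                    region_groups=groups,
                )
            )
        except DataFormatError as exc:
            raise DataFormatError(f"{path}: line {i}: {exc}") from exc
    return out


def read_beta_matrix(
    path_beta,
    path_detp,
    design: Mapping[str, tuple[str, int]],
) -> BetaMatrix:
    """Read paired beta-value and detection p-value matrices.

    Both files have a ``probe_id`` first column and one column per sample;
    ``design`` maps each sample id to its (cell line, replicate index).
    Betas outside [0,1] are rejected; missing values stay NaN.
    """
    beta = _read_table(path_beta).set_index("probe_id").astype(float)
    detp = _read_table(path_detp).set_index("probe_id").astype(float)
    missing = [s for s in design if s not in beta.columns]
    if missing:
        raise DataFormatError(f"{path_beta}: samples in design absent from file: {missing}")
    missing_p = [s for s in design if s not in detp.columns]
    if missing_p:
        raise DataFormatError(f"{path_detp}: samples in design absent from file: {missing_p}")
    beta = beta[list(design)]
    detp = detp.reindex(index=beta.index)[list(design)]
    vals = beta.to_numpy()
    bad = np.argwhere((vals < 0) | (vals > 1))
    if len(bad):
        cells = [f"({beta.index[r]}, {beta.columns[c]})" for r, c in bad[:5]]
        raise DataFormatError(f"{path_beta}: beta outside [0,1] at {', '.join(cells)}")
    return BetaMatrix(beta=beta, detect_p=detp, sample_groups=dict(design))


def read_patient_table(path, cpg_prefix: str = "cpg_") -> list[PatientRecord]:
    """Read a patient table; CpG columns are detected by ``cpg_prefix``."""
    df = _read_table(path)
    _require_columns(df, ["patient_id", "sample_type", "os_months", "event"], path)
    cpg_cols = [c for c in df.columns if c.startswith(cpg_prefix)]
    out: list[PatientRecord] = []
    for i, row in df.iterrows():
        cpgs = {}
        for c in cpg_cols:
            v = row[c]
            cpgs[c] = float(v) if pd.notna(v) and str(v) != "" else float("nan")
        t_stage = row.get("t_stage")
        t_stage = str(t_stage) if pd.notna(t_stage) and str(t_stage).strip() else "unknown"
        breslow = row.get("breslow_mm")
        breslow = float(breslow) if pd.notna(breslow) and str(breslow).strip() else None
        out.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                sample_type=str(row["sample_type"]),
                cpg_meth=cpgs,
                os_months=float(row["os_months"]),
                event=int(float(row["event"])),
                t_stage=t_stage,
                breslow_mm=breslow,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Writers (round-trip counterparts + BED export)
# ---------------------------------------------------------------------------

def write_manifest(ann: Sequence[ProbeAnnotation], path) -> None:
    rows = [
        {
            "probe_id": a.probe_id,
            "chrom": a.chrom,
            "pos": a.pos,
            "genes": ";".join(a.genes),
            "region_groups": ";".join(a.region_groups),
        }
        for a in ann
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_beta_matrix(bm: BetaMatrix, path_beta, path_detp) -> None:
    bm.beta.rename_axis("probe_id").to_csv(path_beta)
    bm.detect_p.rename_axis("probe_id").to_csv(path_detp)


def write_patient_table(patients: Sequence[PatientRecord], path) -> None:
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "sample_type": p.sample_type,
            "os_months": p.os_months,
            "event": p.event,
            "t_stage": p.t_stage if p.t_stage != "unknown" else "",
            "breslow_mm": "" if p.breslow_mm is None else p.breslow_mm,
        }
        row.update(p.cpg_meth)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_clusters_bed(clusters: Sequence[ClusterCall], path) -> None:
    """Write clusters as BED6 (0-based half-open; score = -log10 p, cap 1000)."""
    with open(path, "w") as fh:
        for c in clusters:
            if c.p_value is None:
                score = 0.0
            elif c.p_value <= 0.0:  # underflowed p: cap directly
                score = 1000.0
            else:
                score = min(1000.0, -math.log10(c.p_value))
            fh.write(
                f"{c.chrom}\t{c.start - 1}\t{c.end}\t{'|'.join(c.member_genes)}"
                f"\t{score:g}\t.\n"
            )


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def _deep_update(base: dict, upd: Mapping) -> dict:
    for k, v in upd.items():
        if isinstance(v, Mapping) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path=None) -> dict:
    """Load the pipeline config, overlaying a YAML file onto the defaults."""
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise DataFormatError(f"{path}: config must be a mapping of sections")
        _deep_update(cfg, user)
    return cfg
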