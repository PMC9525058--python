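import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methclust import BetaMatrix, ProbeAnnotation

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_bm(values: dict[str, list[float]], probe_ids, groups, detp=0.001):
    """Hand-build a BetaMatrix: values maps sample id -> betas per probe."""
    beta = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), dtype=float)
    if np.isscalar(detp):
        dp = pd.DataFrame(detp, index=beta.index, columns=beta.columns, dtype=float)
    else:
        dp = pd.DataFrame(detp, index=beta.index, columns=beta.columns, dtype=float)
    return BetaMatrix(beta=beta, detect_p=dp, sample_groups=dict(groups))


@pytest.fixture
def pair_groups():
    """3 + 3 replicate design for a parental/aggressive pair."""
    g = {}
    for r in (1, 2, 3):
        g[f"par_r{r}"] = ("par", r)
        g[f"agg_r{r}"] = ("agg", r)
    return g


@pytest.fixture
def simple_ann():
    """Two genes x three promoter + one body probe each, on chromosome 1."""
    ann = []
    for gi, gene in enumerate(["GA", "GB"]):
        for pi, grp in enumerate(["TSS200", "TSS1500", "1stExon", "Body"]):
            ann.append(
                ProbeAnnotation(
                    probe_id=f"cg{gene}{pi}",
                    chrom="1",
                    pos=1_000_000 * (gi + 1) + 100 * pi,
                    genes=(gene,),
                    region_groups=(grp,),
                )
            )
    return ann


def constant_pair_bm(pair_groups, probe_ids, par_beta, agg_beta, detp=0.001):
    """Noise-free pair matrix: every parental replicate = par_beta etc."""
    values = {}
    for s, (line, _r) in pair_groups.items():
        base = par_beta if line == "par" else agg_beta
        values[s] = list(base)
    return make_bm(values, probe_ids, pair_groups, detp=detp)
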