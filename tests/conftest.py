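import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from methylsel.cgmap import SITE_INDEX_NAMES, SampleMeta, SiteMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(cells: dict[str, dict[tuple, tuple]], meta: list[SampleMeta]) -> SiteMatrix:
    """Build a SiteMatrix from {sample: {(chrom,pos,base): (c, n)}}.

    Sites absent from a sample's dict are missing cells.
    """
    all_sites = sorted({k for d in cells.values() for k in d})
    idx = pd.MultiIndex.from_tuples(all_sites, names=SITE_INDEX_NAMES)
    meth = pd.DataFrame(index=idx, columns=[m.sample_id for m in meta], dtype=float)
    depth = meth.copy()
    for sid, d in cells.items():
        for site, (c, n) in d.items():
            meth.loc[site, sid] = c
            depth.loc[site, sid] = n
    return SiteMatrix(meth, depth, meta)


@pytest.fixture
def pool_meta():
    return [
        SampleMeta("FE_pool", "FE", "", "pool", "SEL"),
        SampleMeta("SE_pool", "SE", "", "pool", "SEL"),
    ]


@pytest.fixture
def paired_meta():
    metas = []
    for f in range(1, 9):
        for grp in ("FE", "SE"):
            metas.append(SampleMeta(f"fam{f:02d}_{grp}", grp, f"fam{f:02d}",
                                    "individual", "F2C"))
    return metas


@pytest.fixture
def paired_cohort():
    """Small well-specified paired cohort shared by slower tests."""
    from methylsel.simulate import SimConfig, simulate_cohort, simulate_genome

    cfg = SimConfig(
        design="paired_individuals", n_cpg_sites=300, n_genes=10,
        low_weight=0.0, tss_enriched_fraction=0.0,
        sigma_fam=0.5, sigma_ind=0.0, coverage_mean=20.0, coverage_dispersion=30.0,
    )
    genome = simulate_genome(cfg, 123)
    return simulate_cohort(cfg, genome, 123)
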