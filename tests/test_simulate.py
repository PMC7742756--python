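import numpy as np
import pytest

from methylsel.cgmap import SiteRecord
from methylsel.simulate import (
    Genome,
    SimConfig,
    logit_shift_for_difference,
    matrix_to_records,
    pool_samples,
    rrbs_preset,
    simulate_cohort,
    simulate_genome,
    write_cohort,
    write_gff3,
)


def test_genome_reproducible_byte_for_byte(tmp_path):
    cfg = SimConfig(n_chromosomes=1, n_genes=10, n_cpg_sites=500)
    g1 = simulate_genome(cfg, 1)
    g2 = simulate_genome(cfg, 1)
    p1, p2 = tmp_path / "a.gff3", tmp_path / "b.gff3"
    write_gff3(g1, p1)
    write_gff3(g2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert g1.cpgs.equals(g2.cpgs)
    assert len(g1.cpgs) == 500 and len(g1.genes) == 10
    # different seed, different draws
    assert not simulate_genome(cfg, 2).cpgs.equals(g1.cpgs)


def test_genome_genes_non_overlapping_within_chromosome():
    g = simulate_genome(SimConfig(n_chromosomes=2, n_genes=30, n_cpg_sites=100), 3)
    for chrom, sub in g.genes.groupby("chrom"):
        sub = sub.sort_values("start")
        assert (sub.start.to_numpy()[1:] > sub.end.to_numpy()[:-1]).all()
        assert (sub.start >= 1).all()
    assert set(g.genes.strand) <= {"+", "-"}


def test_genome_zero_genes_all_intergenic():
    g = simulate_genome(SimConfig(n_genes=0, n_cpg_sites=100), 1)
    assert g.genes.empty
    assert not g.cpgs.tss_proximal.any()


def test_genome_infeasible_config_errors():
    with pytest.raises(ValueError, match="cannot place"):
        simulate_genome(
            SimConfig(n_chromosomes=1, chromosome_length=10_000, n_genes=50,
                      n_cpg_sites=10), 1
        )


def test_cohort_reproducible_and_truth_matches(tmp_path):
    cfg = SimConfig(n_cpg_sites=200, n_genes=5, dmc_fraction=0.05)
    genome = simulate_genome(cfg, 7)
    c1 = simulate_cohort(cfg, genome, 7)
    c2 = simulate_cohort(cfg, genome, 7)
    assert c1.matrix.meth.equals(c2.matrix.meth)
    assert c1.matrix.depth.equals(c2.matrix.depth)
    assert c1.truth.sites.equals(c2.truth.sites)
    d1, d2 = tmp_path / "c1", tmp_path / "c2"
    for cohort, d in ((c1, d1), (c2, d2)):
        write_cohort(cohort, d)
    for f in sorted(p.name for p in d1.iterdir()):
        assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f
    assert c1.truth.sites.is_true_dmc.sum() == round(0.05 * 200)


def test_paired_design_shape_and_labels():
    cfg = SimConfig(n_cpg_sites=50, n_genes=2, n_families=8)
    cohort = simulate_cohort(cfg, simulate_genome(cfg, 1), 1)
    meta = cohort.matrix.meta
    assert len(meta) == 16
    fams = {m.family_id for m in meta}
    assert len(fams) == 8
    for f in fams:
        groups = sorted(m.group for m in meta if m.family_id == f)
        assert groups == ["FE", "SE"]


def test_degenerate_config_matches_binomial_noise():
    # sigma_fam = sigma_ind = 0, delta = 0, fixed-ish coverage 50:
    # every sample's ratio is binomial around the shared baseline
    cfg = SimConfig(n_cpg_sites=300, n_genes=0, sigma_fam=0.0, sigma_ind=0.0,
                    coverage_mean=50.0, coverage_dispersion=1e6,
                    low_weight=0.0, tss_enriched_fraction=0.0)
    cohort = simulate_cohort(cfg, simulate_genome(cfg, 2), 2)
    ratios = cohort.matrix.ratios().to_numpy()
    base = cohort.truth.sites.baseline.to_numpy()
    resid = ratios - base[:, None]
    sd = np.sqrt(base * (1 - base) / 50)
    assert np.mean(np.abs(resid) < 3 * sd[:, None]) > 0.99
    assert abs(resid.mean()) < 0.01


def test_pool_design_counts_are_member_sums():
    cfg = SimConfig(n_cpg_sites=80, n_genes=2, design="pooled", pool_size=6)
    genome = simulate_genome(cfg, 5)
    cohort = simulate_cohort(cfg, genome, 5)
    assert cohort.matrix.samples == ["FE_pool", "SE_pool"]
    # pooled coverage ~ pool_size * member coverage
    assert cohort.matrix.depth.mean().mean() == pytest.approx(
        6 * cfg.coverage_mean, rel=0.15
    )


def test_pool_samples_additivity_and_partial_presence():
    a = SiteRecord("chr1", 10, "C", "CG", "CG", 0.3, 3, 10)
    b = SiteRecord("chr1", 10, "C", "CG", "CG", 0.7, 7, 10)
    only = SiteRecord("chr1", 99, "C", "CG", "CG", 1.0, 2, 2)
    pooled = pool_samples([[a, only], [b]])
    by_pos = {r.position: r for r in pooled}
    assert (by_pos[10].c_count, by_pos[10].total_count) == (10, 20)
    assert by_pos[10].meth_ratio == 0.5
    assert (by_pos[99].c_count, by_pos[99].total_count) == (2, 2)
    with pytest.raises(ValueError, match="empty"):
        pool_samples([])


def test_logit_shift_helper_round_trips():
    from scipy.special import expit, logit

    for base, diff in [(0.5, 0.30), (0.2, 0.15), (0.8, -0.25)]:
        d = logit_shift_for_difference(base, diff)
        assert expit(logit(base) + d) - base == pytest.approx(diff, abs=1e-12)
    with pytest.raises(ValueError):
        logit_shift_for_difference(0.9, 0.2)


def test_artefact_sites_injected_for_filters():
    cfg = SimConfig(n_cpg_sites=200, n_genes=0, invariant_fraction=0.1,
                    extreme_coverage_fraction=0.05)
    cohort = simulate_cohort(cfg, simulate_genome(cfg, 6), 6)
    sites = cohort.truth.sites
    assert (sites.artefact == "invariant0").sum() == 10
    assert (sites.artefact == "invariant1").sum() == 10
    assert (sites.artefact == "extreme_cov").sum() == 10
    ratios = cohort.matrix.ratios().to_numpy()
    inv0 = (sites.artefact == "invariant0").to_numpy()
    inv1 = (sites.artefact == "invariant1").to_numpy()
    assert np.nanmax(ratios[inv0]) == 0.0
    assert np.nanmin(ratios[inv1]) == 1.0
    depth = cohort.matrix.depth.to_numpy()
    ext = (sites.artefact == "extreme_cov").to_numpy()
    assert np.nanmean(depth[ext]) > 10 * np.nanmean(depth[~ext])


def test_rrbs_preset_hits_target_mean_methylation():
    cfg = rrbs_preset(n_cpg_sites=3000)
    cohort = simulate_cohort(cfg, simulate_genome(cfg, 3), 3)
    mean = cohort.matrix.ratios().mean().mean()
    assert mean == pytest.approx(0.16, abs=0.02)


def test_adding_samples_preserves_earlier_draws():
    # same seed, more families: the first families' counts are unchanged
    cfg8 = SimConfig(n_cpg_sites=100, n_genes=2, n_families=8)
    cfg10 = SimConfig(n_cpg_sites=100, n_genes=2, n_families=10)
    genome = simulate_genome(cfg8, 9)
    m8 = simulate_cohort(cfg8, genome, 9).matrix
    m10 = simulate_cohort(cfg10, genome, 9).matrix
    shared = m8.samples
    assert m8.meth[shared].equals(m10.meth[shared])


def test_missingness_dropout():
    cfg = SimConfig(n_cpg_sites=400, n_genes=0, missing_probability=0.2)
    cohort = simulate_cohort(cfg, simulate_genome(cfg, 4), 4)
    miss_frac = 1 - cohort.matrix.present().to_numpy().mean()
    assert miss_frac == pytest.approx(0.2, abs=0.03)
    recs = matrix_to_records(cohort.matrix, cohort.matrix.samples[0])
    assert len(recs) == cohort.matrix.present().iloc[:, 0].sum()
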