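"""Synthetic bisulfite-count cohorts emulating a selection-line methylation study.

The generator produces everything the analysis pipeline consumes — CGmap
files, a sample sheet, a GFF3 gene annotation and a ground-truth table —
for two study designs:

* ``paired_individuals``: n_families families, each contributing one
  fast-exploring (FE) and one slow-exploring (SE) extreme sibling
  (default 8 families / 16 RRBS-like libraries);
* ``pooled``: one FE and one SE pool, each the count-wise sum of
  ``pool_size`` member libraries (default 6, WGBS-like).

Per-site counts follow a binomial logit-normal hierarchy: individual j in
family f at site s is methylated with probability

    p = expit(alpha_s + u_{f,s} + e_{j,s} + delta_s * I[group == FE])

with u ~ N(0, sigma_fam^2) shared by siblings, e ~ N(0, sigma_ind^2)
per library, coverage n drawn negative-binomial (clamped to >= 1) and
c ~ Binomial(n, p).  Baseline levels alpha_s reproduce the bimodal
vertebrate methylation landscape: TSS-proximal CpGs are hypomethylated
(Beta component near 0) and the remainder sit near 50%; the RRBS preset
weights the low component so the cohort-mean methylation is ~16%, as
observed for CpG-enriched reduced-representation libraries.

Randomness discipline: one root seed; every stream (genome, site
parameters, each sample) draws from ``SeedSequence(root, spawn_key=(k,))``
with a fixed per-stream key, so adding samples never perturbs earlier
draws and identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cgmap import SampleMeta, SiteMatrix, SiteRecord, write_cgmap, write_sample_sheet

__all__ = [
    "SimConfig",
    "Genome",
    "Cohort",
    "TruthTable",
    "rrbs_preset",
    "wgbs_pool_preset",
    "logit_shift_for_difference",
    "simulate_genome",
    "write_gff3",
    "simulate_cohort",
    "pool_samples",
    "write_cohort",
]

# fixed spawn keys for independent random streams
_STREAM_GENOME = 0
_STREAM_SITES = 1
_STREAM_SPIKES = 2
_STREAM_SAMPLE_BASE = 100


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; every field has a study-scale default."""

    # genome
    n_chromosomes: int = 2
    chromosome_length: int = 1_000_000
    n_genes: int = 40
    n_cpg_sites: int = 2_000
    tss_enriched_fraction: float = 0.3  # CpGs placed near TSSs
    tss_proximal_bp: int = 500  # window calling a site TSS-proximal

    # design
    design: str = "paired_individuals"  # or "pooled"
    n_families: int = 8
    pool_size: int = 6

    # methylation landscape (Beta components on the ratio scale)
    low_beta: tuple[float, float] = (0.4, 12.0)  # hypomethylated, mean ~0.03
    mid_beta: tuple[float, float] = (8.0, 8.0)  # intermediate, mean 0.5
    target_mean_methylation: float | None = None  # if set, solves the low/mid weight
    low_weight: float = 0.35  # P(low component) for non-TSS-proximal sites

    # random effects (logit scale)
    sigma_fam: float = 0.5
    sigma_ind: float = 0.3

    # coverage
    coverage_mean: float = 15.0  # matches 10-18x library averages
    coverage_dispersion: float = 8.0  # NB size parameter
    missing_probability: float = 0.0  # per (site, sample) dropout

    # spiked signal and filter-exercising artefacts
    dmc_fraction: float = 0.0
    spike_differences: tuple[float, ...] = (0.10, 0.18, 0.25, 0.30, 0.36)
    invariant_fraction: float = 0.0  # all-0 / all-1 sites
    extreme_coverage_fraction: float = 0.0
    extreme_coverage_factor: float = 25.0

    dataset: str = "SIM"

    def validate(self) -> None:
        for name in (
            "tss_enriched_fraction",
            "low_weight",
            "missing_probability",
            "dmc_fraction",
            "invariant_fraction",
            "extreme_coverage_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.sigma_fam < 0 or self.sigma_ind < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.design not in ("paired_individuals", "pooled"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.coverage_mean < 1:
            raise ValueError("coverage_mean must be >= 1")


def rrbs_preset(**overrides) -> SimConfig:
    """Paired-sibling cohort emulating CpG-enriched RRBS libraries.

    The low/mid mixture weight is solved so the expected cohort mean
    methylation is ~16%, the level reported for such libraries.
    """
    cfg = SimConfig(
        design="paired_individuals",
        tss_enriched_fraction=0.5,
        target_mean_methylation=0.16,
        dataset="F2C-RRBS",
    )
    return replace(cfg, **overrides)


def wgbs_pool_preset(**overrides) -> SimConfig:
    """Two 6-member pools emulating whole-genome libraries (~50% plateau)."""
    cfg = SimConfig(design="pooled", tss_enriched_fraction=0.15, low_weight=0.2,
                    dataset="SEL-WGBS")
    return replace(cfg, **overrides)


def logit_shift_for_difference(baseline: float, difference: float) -> float:
    """Logit effect delta such that expit(logit(b) + delta) - b == difference."""
    target = baseline + difference
    if not (0.0 < baseline < 1.0) or not (0.0 < target < 1.0):
        raise ValueError(
            f"baseline {baseline} with difference {difference} leaves (0,1)"
        )
    return float(logit(target) - logit(baseline))


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class Genome:
    """Simulated gene models and CpG coordinate list."""

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand (1-based inclusive)
    cpgs: pd.DataFrame  # chrom, pos, strand_base, tss_proximal

    @property
    def n_sites(self) -> int:
        return len(self.cpgs)


def simulate_genome(config: SimConfig, seed: int) -> Genome:
    """Draw non-overlapping gene models and CpG positions (TSS-enriched)."""
    config.validate()
    rng = _rng(seed, _STREAM_GENOME)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    lengths = {c: config.chromosome_length for c in chroms}

    # genes: round-robin over chromosomes, one gene per equal slot
    per_chrom = np.zeros(config.n_chromosomes, dtype=int)
    for i in range(config.n_genes):
        per_chrom[i % config.n_chromosomes] += 1
    gene_rows = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        n = per_chrom[ci]
        if n == 0:
            continue
        slot = lengths[chrom] // n
        min_len, pad = 1_000, 200
        if slot < min_len + 2 * pad:
            raise ValueError(
                f"cannot place {n} genes on {chrom}: slot {slot} bp too small"
            )
        for k in range(n):
            max_len = min(10_000, slot - 2 * pad)
            glen = int(rng.integers(min_len, max_len + 1))
            start = slot * k + int(rng.integers(pad, slot - glen - pad + 1)) + 1
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append(
                {
                    "gene_id": f"gene{gid:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + glen - 1,
                    "strand": strand,
                }
            )
            gid += 1
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )

    # CpG positions: a TSS-enriched fraction scattered around gene starts,
    # the rest uniform; proportional allocation over chromosomes
    site_rows: list[tuple[str, int, str]] = []
    total_len = sum(lengths.values())
    tss_by_chrom = {
        c: (
            genes.loc[genes.chrom == c]
            .apply(lambda g: g.start if g.strand == "+" else g.end, axis=1)
            .to_numpy(dtype=int)
            if len(genes) and (genes.chrom == c).any()
            else np.array([], dtype=int)
        )
        for c in chroms
    }
    remaining = config.n_cpg_sites
    for ci, chrom in enumerate(chroms):
        n_here = (
            remaining
            if ci == config.n_chromosomes - 1
            else int(round(config.n_cpg_sites * lengths[chrom] / total_len))
        )
        remaining -= n_here
        tsss = tss_by_chrom[chrom]
        n_tss = int(round(config.tss_enriched_fraction * n_here)) if len(tsss) else 0
        chosen: set[int] = set()
        while len(chosen) < n_tss:
            anchor = tsss[rng.integers(0, len(tsss))]
            pos = int(anchor + round(rng.normal(0.0, 250.0)))
            if 2 <= pos <= lengths[chrom] - 1:
                chosen.add(pos)
        while len(chosen) < n_here:
            chosen.add(int(rng.integers(2, lengths[chrom])))
        strands = rng.random(len(chosen)) < 0.5
        for pos, is_c in zip(sorted(chosen), strands):
            site_rows.append((chrom, pos, "C" if is_c else "G"))

    cpgs = pd.DataFrame(site_rows, columns=["chrom", "pos", "strand_base"])
    prox = np.zeros(len(cpgs), dtype=bool)
    for chrom, tsss in tss_by_chrom.items():
        if not len(tsss):
            continue
        mask = cpgs.chrom.to_numpy() == chrom
        pos = cpgs.pos.to_numpy()[mask]
        dist = np.min(np.abs(pos[:, None] - tsss[None, :]), axis=1)
        prox[mask] = dist <= config.tss_proximal_bp
    cpgs["tss_proximal"] = prox
    return Genome(lengths, genes, cpgs)


def write_gff3(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in genome.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genome.genes.itertuples():
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.gene_id.upper()}\n"
            )


@dataclass
class TruthTable:
    """Ground truth of a simulated cohort, regenerable from (config, seed).

    ``sites`` holds per-site parameters (baseline logit, spiked group
    effect, flags); ``family_effects`` the u_{f,s} draws (families x sites)
    and ``coverage`` the n draws (samples x sites, 0 where dropped).
    """

    sites: pd.DataFrame
    family_effects: np.ndarray
    coverage: np.ndarray
    sample_ids: list[str]

    def to_tsv(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class Cohort:
    matrix: SiteMatrix
    truth: TruthTable
    genome: Genome
    config: SimConfig


def _draw_site_params(config: SimConfig, genome: Genome, seed: int) -> pd.DataFrame:
    rng = _rng(seed, _STREAM_SITES)
    n = genome.n_sites
    prox = genome.cpgs.tss_proximal.to_numpy()
    f_prox = prox.mean() if n else 0.0

    low_w = config.low_weight
    if config.target_mean_methylation is not None:
        lo = config.low_beta[0] / sum(config.low_beta)
        mid = config.mid_beta[0] / sum(config.mid_beta)
        w = (mid - config.target_mean_methylation) / (mid - lo)
        w = float(np.clip(w, 0.0, 1.0))
        # TSS-proximal sites are always low; spread the remainder
        low_w = 0.0 if f_prox >= w else (w - f_prox) / (1.0 - f_prox)
    is_low = prox | (rng.random(n) < low_w)
    base = np.where(
        is_low,
        rng.beta(*config.low_beta, size=n),
        rng.beta(*config.mid_beta, size=n),
    )
    base = np.clip(base, 5e-4, 1.0 - 5e-4)

    df = genome.cpgs[["chrom", "pos", "strand_base"]].copy()
    df["baseline"] = base
    df["alpha_logit"] = logit(base)
    df["component"] = np.where(is_low, "low", "mid")

    srng = _rng(seed, _STREAM_SPIKES)
    delta = np.zeros(n)
    is_dmc = np.zeros(n, dtype=bool)
    if config.dmc_fraction > 0:
        n_dmc = int(round(config.dmc_fraction * n))
        idx = srng.choice(n, size=n_dmc, replace=False)
        for i in idx:
            diff = float(srng.choice(config.spike_differences))
            sign = 1.0 if srng.random() < 0.5 else -1.0
            b = base[i]
            # keep the shifted mean inside (0,1)
            if b + sign * diff <= 0.005 or b + sign * diff >= 0.995:
                sign = -sign
            if 0.005 < b + sign * diff < 0.995:
                delta[i] = logit_shift_for_difference(b, sign * diff)
                is_dmc[i] = True
    df["delta_logit"] = delta
    df["is_true_dmc"] = is_dmc

    flag = np.zeros(n, dtype=int)  # 0 normal, 1 invariant-0, 2 invariant-1, 3 extreme cov
    if config.invariant_fraction > 0:
        n_inv = int(round(config.invariant_fraction * n))
        idx = srng.choice(np.flatnonzero(flag == 0), size=n_inv, replace=False)
        flag[idx[: n_inv // 2]] = 1
        flag[idx[n_inv // 2:]] = 2
    if config.extreme_coverage_fraction > 0:
        n_ext = int(round(config.extreme_coverage_fraction * n))
        idx = srng.choice(np.flatnonzero(flag == 0), size=n_ext, replace=False)
        flag[idx] = 3
    df["artefact"] = np.array(["none", "invariant0", "invariant1", "extreme_cov"])[flag]
    return df


def _nb_coverage(rng: np.random.Generator, config: SimConfig, n: int,
                 extreme: np.ndarray) -> np.ndarray:
    k = config.coverage_dispersion
    mean = np.full(n, float(config.coverage_mean))
    mean[extreme] *= config.extreme_coverage_factor
    p = k / (k + mean)
    cov = rng.negative_binomial(k, p)
    return np.maximum(cov, 1)


def _members(config: SimConfig) -> list[SampleMeta]:
    if config.design == "paired_individuals":
        metas = []
        for f in range(config.n_families):
            fam = f"fam{f + 1:02d}"
            for grp in ("FE", "SE"):
                metas.append(
                    SampleMeta(f"{fam}_{grp}", grp, fam, "individual", config.dataset)
                )
        return metas
    # pooled: unrelated members, each carries its own family-scale draw
    metas = []
    for grp in ("FE", "SE"):
        for i in range(config.pool_size):
            metas.append(
                SampleMeta(f"{grp}_member{i + 1}", grp, "", "individual", config.dataset)
            )
    return metas


def simulate_cohort(config: SimConfig, genome: Genome, seed: int) -> Cohort:
    """Draw per-sample binomial counts for every CpG under the configured design.

    For the pooled design the returned matrix contains the two summed
    pools (FE_pool / SE_pool); member draws still each get an independent
    family-scale effect because pool members are unrelated birds.
    """
    config.validate()
    sites = _draw_site_params(config, genome, seed)
    n_sites = len(sites)
    members = _members(config)
    alpha = sites.alpha_logit.to_numpy()
    delta = sites.delta_logit.to_numpy()
    artefact = sites.artefact.to_numpy()
    extreme = artefact == "extreme_cov"

    paired = config.design == "paired_individuals"
    families = sorted({m.family_id for m in members if m.family_id})
    fam_index = {f: i for i, f in enumerate(families)}
    n_fam_draws = len(families) if paired else len(members)
    fam_rng = _rng(seed, _STREAM_SITES + 10)
    fam_eff = fam_rng.normal(0.0, config.sigma_fam, size=(n_fam_draws, n_sites))

    meth = np.zeros((n_sites, len(members)))
    depth = np.zeros((n_sites, len(members)))
    present = np.ones((n_sites, len(members)), dtype=bool)
    for j, m in enumerate(members):
        rng = _rng(seed, _STREAM_SAMPLE_BASE + j)
        u = fam_eff[fam_index[m.family_id] if paired else j]
        e = rng.normal(0.0, config.sigma_ind, size=n_sites)
        eta = alpha + u + e + (delta if m.group == "FE" else 0.0)
        p = expit(eta)
        p[artefact == "invariant0"] = 0.0
        p[artefact == "invariant1"] = 1.0
        n_cov = _nb_coverage(rng, config, n_sites, extreme)
        c = rng.binomial(n_cov, p)
        if config.missing_probability > 0:
            drop = rng.random(n_sites) < config.missing_probability
            present[:, j] = ~drop
        meth[:, j] = c
        depth[:, j] = n_cov

    coverage = np.where(present, depth, 0).astype(int).T  # samples x sites
    truth = TruthTable(sites, fam_eff, coverage, [m.sample_id for m in members])

    idx = pd.MultiIndex.from_frame(
        sites[["chrom", "pos", "strand_base"]]
    )
    meth_df = pd.DataFrame(meth, index=idx, columns=[m.sample_id for m in members])
    depth_df = pd.DataFrame(depth, index=idx, columns=[m.sample_id for m in members])
    meth_df = meth_df.where(pd.DataFrame(present, index=idx, columns=meth_df.columns))
    depth_df = depth_df.where(pd.DataFrame(present, index=idx, columns=depth_df.columns))
    matrix = SiteMatrix(meth_df.sort_index(), depth_df.sort_index(), list(members))

    if config.design == "pooled":
        matrix = _pool_matrix(matrix, config)
    return Cohort(matrix, truth, genome, config)


def _pool_matrix(member_matrix: SiteMatrix, config: SimConfig) -> SiteMatrix:
    metas, meth_cols, depth_cols = [], {}, {}
    for grp in ("FE", "SE"):
        cols = [m.sample_id for m in member_matrix.meta if m.group == grp]
        pid = f"{grp}_pool"
        meth_cols[pid] = member_matrix.meth[cols].sum(axis=1, min_count=1)
        depth_cols[pid] = member_matrix.depth[cols].sum(axis=1, min_count=1)
        metas.append(SampleMeta(pid, grp, "", "pool", config.dataset))
    return SiteMatrix(pd.DataFrame(meth_cols), pd.DataFrame(depth_cols), metas)


def pool_samples(
    member_records: Sequence[Sequence[SiteRecord]], pool_id: str = "pool"
) -> list[SiteRecord]:
    """Sum member CGmap records site-wise into one pooled record stream.

    A site present in only some members contributes those members' counts;
    the pooled ratio is recomputed from the summed counts.
    """
    if not member_records:
        raise ValueError("empty member list")
    acc: dict[tuple, list] = {}
    for stream in member_records:
        for rec in stream:
            key = (rec.chrom, rec.position, rec.watson_base)
            if key in acc:
                entry = acc[key]
                entry[0] += rec.c_count
                entry[1] += rec.total_count
            else:
                acc[key] = [rec.c_count, rec.total_count, rec.context, rec.dinucleotide]
    out = []
    for (chrom, pos, base), (c, n, ctx, dinuc) in sorted(acc.items()):
        ratio = c / n if n else 0.0
        out.append(SiteRecord(chrom, pos, base, ctx, dinuc, ratio, c, n))
    return out


def matrix_to_records(matrix: SiteMatrix, sample_id: str) -> list[SiteRecord]:
    """Extract one sample's non-missing cells as CGmap records."""
    c = matrix.meth[sample_id]
    n = matrix.depth[sample_id]
    out = []
    for (chrom, pos, base), ci, ni in zip(matrix.meth.index, c, n):
        if np.isnan(ni):
            continue
        ci, ni = int(ci), int(ni)
        ratio = ci / ni if ni else 0.0
        out.append(SiteRecord(chrom, pos, base, "CG", "CG", ratio, ci, ni))
    return out


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write CGmap files, sample sheet, GFF3 and truth TSV; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for m in cohort.matrix.meta:
        p = outdir / f"{m.sample_id}.cgmap"
        write_cgmap(matrix_to_records(cohort.matrix, m.sample_id), p)
        paths[m.sample_id] = p
    sheet = outdir / "samples.tsv"
    write_sample_sheet(cohort.matrix.meta, sheet)
    paths["sample_sheet"] = sheet
    gff = outdir / "genes.gff3"
    write_gff3(cohort.genome, gff)
    paths["gff3"] = gff
    truth = outdir / "truth.tsv"
    cohort.truth.to_tsv(truth)
    paths["truth"] = truth
    return paths
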