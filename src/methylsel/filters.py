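"""Site-retention filters applied, in order, before differential testing.

The pipeline order is fixed: minimum coverage -> removal of sites
invariant at 0%/100% across all libraries -> per-library coverage
percentile cut (high-coverage sites are enriched for technical artefacts
such as collapsed repeats, and show spuriously strong differential
signal) -> presence requirements (pool intersection for pooled designs;
family/individual presence for the paired-sibling design).

Every filter returns a new :class:`~methylsel.cgmap.SiteMatrix` whose
sites are a subset of its input, and is idempotent.  ``FilterReport``
records the surviving-site count after each stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cgmap import SampleMeta, SiteMatrix

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_min_coverage",
    "filter_invariant_extremes",
    "filter_coverage_percentile",
    "filter_presence",
    "apply_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    min_coverage: int = 10
    keep_fraction: float = 0.999
    presence_mode: str = "pool_intersection"  # or "family_presence"
    min_families: int = 7
    min_individuals: int = 14

    def validate(self) -> None:
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError(f"keep_fraction must be in (0,1], got {self.keep_fraction}")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")
        if self.presence_mode not in ("pool_intersection", "family_presence"):
            raise ValueError(f"unknown presence mode {self.presence_mode!r}")


@dataclass
class FilterReport:
    """Surviving-site counts per stage, serializable as a TSV run log."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, stage: str, n_sites: int) -> None:
        self.stages.append((stage, n_sites))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_sites"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_min_coverage(matrix: SiteMatrix, min_coverage: int = 10) -> SiteMatrix:
    """Mask cells below ``min_coverage`` reads; drop sites missing everywhere."""
    keep_cell = matrix.depth >= min_coverage
    meth = matrix.meth.where(keep_cell)
    depth = matrix.depth.where(keep_cell)
    any_present = depth.notna().any(axis=1)
    return SiteMatrix(meth.loc[any_present], depth.loc[any_present], matrix.meta)


def filter_invariant_extremes(matrix: SiteMatrix) -> SiteMatrix:
    """Drop sites whose ratio is 0 in every library, or 1 in every library.

    A site mixing 0% and 100% across libraries is *not* uniform and is
    retained.
    """
    r = matrix.ratios()
    present = r.notna()
    n_present = present.sum(axis=1)
    all_zero = ((r == 0) | ~present).all(axis=1) & (n_present > 0)
    all_one = ((r == 1) | ~present).all(axis=1) & (n_present > 0)
    keep = ~(all_zero | all_one)
    return matrix.subset_sites(keep[keep].index)


def filter_coverage_percentile(
    matrix: SiteMatrix, keep_fraction: float = 0.999
) -> SiteMatrix:
    """Per library, keep the ``ceil(keep_fraction * N)`` lowest-coverage sites.

    N counts the sites present in that library.  Ties at the cut are
    broken by genomic (chrom, pos) order, so the retained count is exact.
    A site survives overall only if it survives in every library in which
    it is present.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0,1]")
    survive = pd.DataFrame(True, index=matrix.depth.index, columns=matrix.samples)
    positions = np.arange(len(matrix.depth))  # index order == (chrom, pos) order
    for s in matrix.samples:
        cov = matrix.depth[s].to_numpy()
        present = ~np.isnan(cov)
        n = int(present.sum())
        if n == 0:
            continue
        m = math.ceil(keep_fraction * n)
        idx_present = np.flatnonzero(present)
        # stable sort on (coverage, genomic order)
        order = idx_present[np.lexsort((positions[idx_present], cov[idx_present]))]
        dropped = order[m:]
        col = survive[s].to_numpy()
        col[dropped] = False
        survive[s] = col
    keep = survive.to_numpy().all(axis=1)
    return matrix.subset_sites(matrix.depth.index[keep])


def filter_presence(
    matrix: SiteMatrix,
    meta: Sequence[SampleMeta] | None = None,
    config: FilterConfig = FilterConfig(),
) -> SiteMatrix:
    """Apply the design's presence rule.

    ``pool_intersection``: keep sites non-missing in every library.
    ``family_presence``: keep sites with >= ``min_individuals`` non-missing
    libraries AND non-missing in >= ``min_families`` *complete* families
    (a family counts only when both its FE and SE sibling are present).
    """
    config.validate()
    meta = list(meta) if meta is not None else matrix.meta
    present = matrix.present()
    if config.presence_mode == "pool_intersection":
        keep = present.all(axis=1)
        return matrix.subset_sites(present.index[keep])

    by_id = {m.sample_id: m for m in meta}
    fams: dict[str, list[str]] = {}
    for s in matrix.samples:
        m = by_id.get(s)
        if m is None or not m.family_id:
            raise ValueError(
                f"family_presence filtering needs a family_id for sample {s}"
            )
        fams.setdefault(m.family_id, []).append(s)
    n_ind = present.sum(axis=1)
    complete = sum(
        (present[cols].all(axis=1)).astype(int) for cols in fams.values()
    )
    keep = (n_ind >= config.min_individuals) & (complete >= config.min_families)
    return matrix.subset_sites(present.index[keep])


def apply_filters(
    matrix: SiteMatrix,
    config: FilterConfig = FilterConfig(),
    meta: Sequence[SampleMeta] | None = None,
) -> tuple[SiteMatrix, FilterReport]:
    """Run the full fixed-order filter pipeline, logging stage counts."""
    config.validate()
    report = FilterReport()
    report.add("input", matrix.n_sites)
    matrix = filter_min_coverage(matrix, config.min_coverage)
    report.add(f"min_coverage>={config.min_coverage}", matrix.n_sites)
    matrix = filter_invariant_extremes(matrix)
    report.add("drop_invariant_0_100", matrix.n_sites)
    matrix = filter_coverage_percentile(matrix, config.keep_fraction)
    report.add(f"coverage_percentile<={config.keep_fraction}", matrix.n_sites)
    matrix = filter_presence(matrix, meta, config)
    report.add(f"presence[{config.presence_mode}]", matrix.n_sites)
    return matrix, report
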