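"""CGmap methylation-call IO and multi-sample count-matrix assembly.

A CGmap file is the tab-separated per-cytosine output of bisulfite
methylation callers: one line per called cytosine with

    chrom  watson_base  position  context  dinucleotide  meth_ratio  c_count  total_count

``watson_base`` is C for a cytosine called on the Watson strand and G for
one on the Crick strand; ``c_count`` is the number of methylated reads
(unconverted C) and ``total_count`` the read depth, so the unmethylated
count is ``total_count - c_count``.

Sites are keyed throughout by ``(chrom, position, watson_base)`` with
1-based inclusive coordinates; Watson/Crick calls of a symmetric CpG are
kept as separate sites unless explicitly merged with
:func:`merge_symmetric_cpgs`.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteRecord",
    "SampleMeta",
    "SiteMatrix",
    "CGmapFormatError",
    "read_cgmap",
    "write_cgmap",
    "read_sample_sheet",
    "write_sample_sheet",
    "assemble_matrix",
    "merge_symmetric_cpgs",
]

SITE_INDEX_NAMES = ("chrom", "pos", "strand_base")


class CGmapFormatError(ValueError):
    """Raised for malformed CGmap / sample-sheet content (carries line number)."""


@dataclass(frozen=True, slots=True)
class SiteRecord:
    """One called cytosine: coordinates, context and methylation counts."""

    chrom: str
    position: int
    watson_base: str
    context: str
    dinucleotide: str
    meth_ratio: float
    c_count: int
    total_count: int

    @property
    def t_count(self) -> int:
        """Unmethylated read count."""
        return self.total_count - self.c_count

    def validate(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not (0 <= self.c_count <= self.total_count):
            raise ValueError(
                f"invalid counts c={self.c_count}, total={self.total_count} "
                f"at {self.chrom}:{self.position}"
            )
        if self.total_count > 0:
            expected = self.c_count / self.total_count
            if abs(self.meth_ratio - expected) > 1e-2:
                raise ValueError(
                    f"meth_ratio {self.meth_ratio} inconsistent with counts "
                    f"{self.c_count}/{self.total_count} at {self.chrom}:{self.position}"
                )


@dataclass(frozen=True, slots=True)
class SampleMeta:
    """Sample-sheet row: phenotype group, family and dataset role of a library."""

    sample_id: str
    group: str  # "FE" (fast-exploring) or "SE" (slow-exploring)
    family_id: str = ""  # empty for unrelated pool members
    role: str = "individual"  # "pool" or "individual"
    dataset: str = ""

    def __post_init__(self) -> None:
        if self.group not in ("FE", "SE"):
            raise ValueError(f"group must be FE or SE, got {self.group!r}")
        if self.role not in ("pool", "individual"):
            raise ValueError(f"role must be pool or individual, got {self.role!r}")


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_cgmap(
    path: str | Path,
    context_filter: frozenset[str] | set[str] | None = frozenset({"CG"}),
    strict_ratio: bool = False,
) -> Iterator[SiteRecord]:
    """Stream :class:`SiteRecord` from a (possibly gzipped) CGmap file.

    Records whose context is not in ``context_filter`` are skipped
    (``None`` keeps every context).  Malformed lines raise
    :class:`CGmapFormatError` naming the offending line number.
    """
    known_contexts = {"CG", "CHG", "CHH"}
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise CGmapFormatError(
                    f"{path}: line {lineno}: expected 8 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, base, pos_s, context, dinuc, ratio_s, c_s, n_s = fields
            try:
                position = int(pos_s)
                ratio = float(ratio_s)
                c_count = int(c_s)
                total = int(n_s)
            except ValueError as exc:
                raise CGmapFormatError(
                    f"{path}: line {lineno}: non-numeric field ({exc})"
                ) from None
            if context not in known_contexts:
                # unrecognised context (e.g. '--'): not an error in callers'
                # output, just not analysable here
                import logging

                logging.getLogger(__name__).warning(
                    "%s: line %d: unknown context %r skipped", path, lineno, context
                )
                continue
            if context_filter is not None and context not in context_filter:
                continue
            record = SiteRecord(
                chrom, position, base, context, dinuc, ratio, c_count, total
            )
            try:
                record.validate()
            except ValueError as exc:
                if strict_ratio or "counts" in str(exc) or "position" in str(exc):
                    raise CGmapFormatError(
                        f"{path}: line {lineno}: {exc}"
                    ) from None
            yield record


def write_cgmap(records: Iterable[SiteRecord], path: str | Path) -> None:
    """Write records to a CGmap file (gzipped iff the path ends in .gz).

    Counts are authoritative; the ratio column is printed with 4 decimals.
    """
    with _open_maybe_gzip(path, "wt") as handle:
        for rec in records:
            handle.write(
                f"{rec.chrom}\t{rec.watson_base}\t{rec.position}\t{rec.context}\t"
                f"{rec.dinucleotide}\t{rec.meth_ratio:.4f}\t{rec.c_count}\t"
                f"{rec.total_count}\n"
            )


SHEET_COLUMNS = ["sample_id", "group", "family_id", "role", "dataset"]


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a header-bearing TSV sample sheet into SampleMeta rows."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(SHEET_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise CGmapFormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    metas = [
        SampleMeta(
            sample_id=row["sample_id"],
            group=row["group"],
            family_id=row.get("family_id", ""),
            role=row.get("role", "individual") or "individual",
            dataset=row.get("dataset", ""),
        )
        for row in df.to_dict("records")
    ]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise CGmapFormatError(f"{path}: duplicate sample_id in sample sheet")
    return metas


def write_sample_sheet(metas: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "group": m.group,
                "family_id": m.family_id,
                "role": m.role,
                "dataset": m.dataset,
            }
            for m in metas
        ],
        columns=SHEET_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def check_paired_families(metas: Sequence[SampleMeta]) -> dict[str, tuple[str, str]]:
    """For a paired design, map family_id -> (FE sample, SE sample).

    Raises if any family does not have exactly one FE and one SE member.
    """
    fams: dict[str, dict[str, list[str]]] = {}
    for m in metas:
        if not m.family_id:
            raise ValueError(f"sample {m.sample_id} has no family_id in paired design")
        fams.setdefault(m.family_id, {"FE": [], "SE": []})[m.group].append(m.sample_id)
    out = {}
    for fam, groups in fams.items():
        if len(groups["FE"]) != 1 or len(groups["SE"]) != 1:
            raise ValueError(
                f"family {fam} must have exactly one FE and one SE member, "
                f"got FE={groups['FE']}, SE={groups['SE']}"
            )
        out[fam] = (groups["FE"][0], groups["SE"][0])
    return out


@dataclass
class SiteMatrix:
    """Per-site methylated/total counts across samples.

    ``meth`` and ``depth`` are float DataFrames indexed by the MultiIndex
    ``(chrom, pos, strand_base)`` and with one column per sample, aligned
    to ``meta`` order.  Missing cells (site not called in that library)
    are NaN — distinct from observed zero counts.
    """

    meth: pd.DataFrame
    depth: pd.DataFrame
    meta: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.depth.index):
            raise ValueError("meth/depth site indexes differ")
        if list(self.meth.columns) != list(self.depth.columns):
            raise ValueError("meth/depth sample columns differ")
        if self.meta and [m.sample_id for m in self.meta] != list(self.meth.columns):
            raise ValueError("meta order does not match matrix columns")

    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def n_sites(self) -> int:
        return len(self.meth)

    def ratios(self) -> pd.DataFrame:
        """Per-cell methylation ratio (NaN where missing)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.meth / self.depth
        return r

    def present(self) -> pd.DataFrame:
        """Boolean mask of non-missing cells."""
        return self.depth.notna()

    def subset_sites(self, keep: pd.Index | np.ndarray) -> "SiteMatrix":
        return SiteMatrix(self.meth.loc[keep], self.depth.loc[keep], self.meta)

    def meta_for(self, sample_id: str) -> SampleMeta:
        for m in self.meta:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as a wide TSV with <sample>.meth / <sample>.depth columns."""
        out = pd.DataFrame(index=self.meth.index)
        for s in self.samples:
            out[f"{s}.meth"] = self.meth[s]
            out[f"{s}.depth"] = self.depth[s]
        out.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, meta: Sequence[SampleMeta] | None = None) -> "SiteMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index(list(SITE_INDEX_NAMES))
        samples = [c[:-5] for c in df.columns if c.endswith(".meth")]
        meth = df[[f"{s}.meth" for s in samples]]
        meth.columns = samples
        depth = df[[f"{s}.depth" for s in samples]]
        depth.columns = samples
        return cls(meth, depth, list(meta) if meta else [])


def assemble_matrix(
    per_sample_records: Mapping[str, Iterable[SiteRecord]],
    meta: Sequence[SampleMeta],
) -> SiteMatrix:
    """Union all samples' records into one :class:`SiteMatrix`.

    Site order is deterministic: sorted by (chrom, pos, strand_base).
    A site listed twice within one sample is an error.
    """
    missing_streams = [m.sample_id for m in meta if m.sample_id not in per_sample_records]
    if missing_streams:
        raise ValueError(f"no record stream for samples: {missing_streams}")
    frames_c: dict[str, pd.Series] = {}
    frames_n: dict[str, pd.Series] = {}
    for m in meta:
        keys, cs, ns = [], [], []
        for rec in per_sample_records[m.sample_id]:
            keys.append((rec.chrom, rec.position, rec.watson_base))
            cs.append(rec.c_count)
            ns.append(rec.total_count)
        idx = pd.MultiIndex.from_tuples(keys, names=SITE_INDEX_NAMES) if keys else (
            pd.MultiIndex.from_arrays([[], [], []], names=SITE_INDEX_NAMES)
        )
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"sample {m.sample_id}: duplicate site entry {dup}")
        frames_c[m.sample_id] = pd.Series(cs, index=idx, dtype=float)
        frames_n[m.sample_id] = pd.Series(ns, index=idx, dtype=float)
    union = None
    for s in frames_c.values():
        union = s.index if union is None else union.union(s.index)
    union = union.sort_values()
    meth = pd.DataFrame(
        {sid: frames_c[sid].reindex(union) for sid in (m.sample_id for m in meta)}
    )
    depth = pd.DataFrame(
        {sid: frames_n[sid].reindex(union) for sid in (m.sample_id for m in meta)}
    )
    meth.index.names = depth.index.names = SITE_INDEX_NAMES
    return SiteMatrix(meth, depth, list(meta))


def merge_symmetric_cpgs(matrix: SiteMatrix) -> SiteMatrix:
    """Optionally merge Watson (C at pos) and Crick (G at pos+1) CpG calls.

    Off by default in the pipeline: each called cytosine is its own site.
    Merged counts are summed; the merged site keeps the Watson coordinate
    with strand_base 'C'.
    """
    idx = matrix.meth.index.to_frame(index=False)
    # Crick G at position p pairs with Watson C at p-1
    anchor_pos = np.where(idx["strand_base"].to_numpy() == "G", idx["pos"] - 1, idx["pos"])
    key = pd.MultiIndex.from_arrays(
        [idx["chrom"], anchor_pos, np.repeat("C", len(idx))], names=SITE_INDEX_NAMES
    )
    meth = matrix.meth.set_axis(key).groupby(level=[0, 1, 2]).sum(min_count=1)
    depth = matrix.depth.set_axis(key).groupby(level=[0, 1, 2]).sum(min_count=1)
    order = meth.index.sort_values()
    return SiteMatrix(meth.loc[order], depth.loc[order], matrix.meta)
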