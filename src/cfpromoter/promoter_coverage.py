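"""Fragment counting over promoter windows and coverage normalization.

For each sample, the number of cfDNA fragments overlapping each 2 kb pTSS
window is divided by (total mapped fragments x window length):

    normalized = count / (total_mapped * 2000)

so values are in fragments per (mapped fragment x bp), typically ~1e-8 at
0.3x depth.  A fragment counts in a window if the two intervals share at
least one base (any-overlap rule); windows must be disjoint within a
chromosome so each fragment contributes to at most one window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_regions import PtssRegion

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageMatrix",
    "NormalizedMatrix",
    "read_fragments_bed",
    "count_fragments_in_regions",
    "build_coverage_matrix",
    "normalize_ptss",
]

#: Eq.-style constant window length in bp.
REGION_LENGTH = 2000


@dataclass
class CoverageMatrix:
    """Raw per-window fragment counts, samples x genes.

    ``counts`` is indexed by sample_id with one column per gene_id;
    ``total_mapped`` gives each sample's genome-wide fragment count.
    """

    counts: pd.DataFrame
    total_mapped: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be >= 0")
        if not self.counts.index.equals(self.total_mapped.index):
            raise ValueError("counts and total_mapped must share the sample index")
        if (self.total_mapped <= 0).any():
            empty = self.total_mapped.index[self.total_mapped <= 0].tolist()
            raise ValueError(f"total_mapped must be > 0; offending sample(s): {empty}")

    @property
    def samples(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def genes(self) -> list[str]:
        return self.counts.columns.tolist()


@dataclass
class NormalizedMatrix:
    """Normalized promoter coverage, samples x genes (see module docstring)."""

    values: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def genes(self) -> list[str]:
        return self.values.columns.tolist()


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3+ column BED of fragments into a (chrom, start, end) DataFrame."""
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    if (df["start"] >= df["end"]).any() or (df["start"] < 0).any():
        raise ValueError(f"{path}: fragments must satisfy 0 <= start < end")
    return df


def _check_disjoint(regions: Sequence[PtssRegion]) -> None:
    by_chrom: dict[str, list[PtssRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"regions overlap on {chrom}: {a.gene_id} [{a.start},{a.end}) and "
                    f"{b.gene_id} [{b.start},{b.end}); merge or drop overlapping windows"
                )


def count_fragments_in_regions(
    fragments: pd.DataFrame, regions: Sequence[PtssRegion]
) -> tuple[np.ndarray, int]:
    """Count fragments overlapping each region by >= 1 bp.

    Returns counts aligned with ``regions`` plus the genome-wide total
    fragment count.  Intervals are 0-based half-open, so a fragment ending
    exactly where a region starts does not count.  Regions must be disjoint
    within each chromosome.
    """
    _check_disjoint(regions)
    total_mapped = len(fragments)
    counts = np.zeros(len(regions), dtype=np.int64)
    region_idx_by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        region_idx_by_chrom.setdefault(r.chrom, []).append(i)
    for chrom, group in fragments.groupby("chrom", sort=False):
        idx = region_idx_by_chrom.get(chrom)
        if not idx:
            continue
        starts = np.sort(group["start"].to_numpy())
        ends = np.sort(group["end"].to_numpy())
        r_start = np.array([regions[i].start for i in idx])
        r_end = np.array([regions[i].end for i in idx])
        # overlap iff frag.start < r.end and frag.end > r.start; the two
        # excluded tails are disjoint, so subtraction counts exactly once
        counts[idx] = np.searchsorted(starts, r_end, side="left") - np.searchsorted(
            ends, r_start, side="right"
        )
    return counts, total_mapped


def build_coverage_matrix(
    fragment_sources: Mapping[str, pd.DataFrame | str | Path],
    regions: Sequence[PtssRegion],
) -> CoverageMatrix:
    """Assemble the samples x genes count matrix from per-sample fragments.

    ``fragment_sources`` maps sample_id to either an in-memory fragment
    DataFrame or a BED path.
    """
    gene_ids = [r.gene_id for r in regions]
    rows, totals = {}, {}
    for sid, src in fragment_sources.items():
        frags = src if isinstance(src, pd.DataFrame) else read_fragments_bed(src)
        counts, total = count_fragments_in_regions(frags, regions)
        if total == 0:
            raise ValueError(f"sample {sid!r} has an empty fragment file")
        rows[sid] = counts
        totals[sid] = total
    counts_df = pd.DataFrame.from_dict(rows, orient="index", columns=gene_ids)
    return CoverageMatrix(counts_df, pd.Series(totals, name="total_mapped"))


def normalize_ptss(matrix: CoverageMatrix, region_length: int = REGION_LENGTH) -> NormalizedMatrix:
    """Normalize counts to fragments per (mapped fragment x bp).

    value[s, g] = counts[s, g] / (total_mapped[s] * region_length); no other
    scaling is applied, so values stay on the raw ~1e-8 scale.
    """
    if region_length <= 0:
        raise ValueError("region_length must be > 0")
    values = matrix.counts.div(matrix.total_mapped * float(region_length), axis=0)
    return NormalizedMatrix(values)


def write_matrix_tsv(values: pd.DataFrame, path: str | Path) -> Path:
    """Write a samples x genes matrix as genes-in-rows TSV (first column gene_id)."""
    out = values.T
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    return Path(path)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-in-rows TSV back into a samples x genes DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def coverage_qc(matrix: CoverageMatrix) -> pd.DataFrame:
    """Per-sample QC: total fragments and the fraction falling in windows."""
    in_windows = matrix.counts.sum(axis=1)
    return pd.DataFrame(
        {
            "sample_id": matrix.samples,
            "total_mapped": matrix.total_mapped.values,
            "fraction_in_windows": (in_windows / matrix.total_mapped).values,
        }
    )
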