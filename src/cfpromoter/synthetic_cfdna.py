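"""Synthetic cfDNA cohorts with nucleosome-footprint promoter depletion.

Maternal plasma cfDNA is nucleosome-bound: fragments average ~167 bp (one
nucleosome core plus linker), and promoters of transcriptionally active genes
are nucleosome-depleted, so active promoters show *reduced* cfDNA coverage.
This module generates toy single-chromosome genomes and per-sample fragment
sets in which fragment midpoints are placed uniformly along the chromosome and
then thinned inside each gene's +/-1000 bp promoter window by a per-gene
depletion fraction ``d_g`` in [0, 1].  Case/control cohorts plant a set of
promoters whose depletion differs between groups, and carry the ground truth
needed to score downstream discovery and classification.

Everything is a pure function of its arguments including the seed, so any
downstream result is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Gene",
    "ToyGenome",
    "SampleProfile",
    "SimTruth",
    "FragmentRecord",
    "SimulatedCohort",
    "simulate_genome",
    "simulate_fragments",
    "simulate_cohort",
    "write_fragments_bed",
]

#: Default mean fragment length in bp (mononucleosome + linker).
DEFAULT_FRAGMENT_LENGTH_MEAN = 167.0
#: Default fragment length SD in bp.
DEFAULT_FRAGMENT_LENGTH_SD = 10.0
#: Hard lower bound on simulated fragment length in bp.
MIN_FRAGMENT_LENGTH = 50
#: Half-width of the promoter window around the TSS, bp.
PROMOTER_FLANK = 1000


@dataclass(frozen=True)
class Gene:
    gene_id: str
    tss: int  # 0-based bp
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned cfDNA fragment as a 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ToyGenome:
    """A single-chromosome genome with TSS-annotated genes.

    Promoter windows ``[tss - 1000, tss + 1000)`` of neighbouring genes never
    overlap by construction (see :func:`simulate_genome`).
    """

    chrom_name: str
    chrom_length: int
    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        tss = self.tss_positions()
        if len(set(g.gene_id for g in self.genes)) != len(self.genes):
            raise ValueError("gene_ids must be unique")
        if np.any(np.diff(tss) <= 0):
            raise ValueError("TSS positions must be strictly increasing")
        if len(tss) and (tss[0] < PROMOTER_FLANK or tss[-1] >= self.chrom_length - PROMOTER_FLANK):
            raise ValueError("every TSS must lie in [1000, chrom_length - 1000)")

    def tss_positions(self) -> np.ndarray:
        return np.array([g.tss for g in self.genes], dtype=np.int64)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass(frozen=True)
class SampleProfile:
    """Generative parameters for one sample's fragment set.

    ``depletion`` maps gene_id -> d_g, the fractional thinning of fragment
    midpoints inside that gene's promoter window; ``depth`` is mean genome
    coverage in x (total fragment bases / chromosome length).
    """

    sample_id: str
    depletion: Mapping[str, float]
    depth: float = 0.3
    fragment_length_mean: float = DEFAULT_FRAGMENT_LENGTH_MEAN
    fragment_length_sd: float = DEFAULT_FRAGMENT_LENGTH_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.fragment_length_mean <= 0:
            raise ValueError("fragment_length_mean must be > 0")
        bad = {g: d for g, d in self.depletion.items() if not 0.0 <= d <= 1.0}
        if bad:
            raise ValueError(f"depletion outside [0, 1] for genes: {sorted(bad)}")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated cohort: which promoters were planted."""

    planted_genes: frozenset[str]
    effect: float  # case-minus-control difference in d_g at planted genes
    base_depletion: float
    seed: int

    def to_frame(self, gene_ids: list[str]) -> pd.DataFrame:
        planted = [int(g in self.planted_genes) for g in gene_ids]
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "planted": planted,
                "effect": [self.effect if p else 0.0 for p in planted],
            }
        )


@dataclass
class SimulatedCohort:
    """Fragments, design table and ground truth for one simulated cohort."""

    fragments: dict[str, pd.DataFrame]  # sample_id -> (chrom, start, end)
    design: pd.DataFrame  # sample_id, label, cohort, gestational_week, fetal_sex
    truth: SimTruth
    genome: ToyGenome = field(repr=False, default=None)


def simulate_genome(n_genes: int, spacing: int = 5000, seed: int = 0) -> ToyGenome:
    """Lay out ``n_genes`` TSSs at jittered multiples of ``spacing`` on one chromosome.

    ``spacing`` must be >= 4000 so that the 2 kb promoter windows of adjacent
    genes can never overlap (jitter is bounded by (spacing - 4000) / 2).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if spacing < 4000:
        raise ValueError("spacing must be >= 4000 bp so promoter windows stay disjoint")
    rng = np.random.default_rng(seed)
    jitter_max = (spacing - 4000) // 2
    base = PROMOTER_FLANK + spacing // 2 + np.arange(n_genes, dtype=np.int64) * spacing
    jitter = rng.integers(-jitter_max, jitter_max + 1, size=n_genes) if jitter_max > 0 else 0
    tss = base + jitter
    strands = rng.choice(["+", "-"], size=n_genes)
    chrom_length = int(n_genes * spacing + 2 * PROMOTER_FLANK + spacing)
    width = len(str(n_genes))
    genes = tuple(
        Gene(f"g{i + 1:0{width}d}", int(t), str(s)) for i, (t, s) in enumerate(zip(tss, strands))
    )
    return ToyGenome("chr1", chrom_length, genes)


def _promoter_windows(genome: ToyGenome) -> tuple[np.ndarray, np.ndarray]:
    tss = genome.tss_positions()
    return tss - PROMOTER_FLANK, tss + PROMOTER_FLANK


def simulate_fragments(genome: ToyGenome, profile: SampleProfile) -> pd.DataFrame:
    """Draw one sample's fragments as a (chrom, start, end) DataFrame.

    The number of fragments is Poisson with mean ``depth * chrom_length /
    fragment_length_mean`` (so expected total bases ~= depth * chrom_length);
    midpoints are uniform on the chromosome, then a midpoint falling inside
    gene g's promoter window survives with probability ``1 - d_g``.  Lengths
    are normal(mean, sd) floored at 50 bp; fragments are shifted to stay
    within chromosome bounds.
    """
    unknown = set(profile.depletion) - set(genome.gene_ids())
    if unknown:
        raise ValueError(f"depletion references unknown gene_ids: {sorted(unknown)}")
    rng = np.random.default_rng(profile.seed)
    length = genome.chrom_length
    n = rng.poisson(profile.depth * length / profile.fragment_length_mean)
    midpoints = rng.uniform(0.0, length, size=n)

    win_start, win_end = _promoter_windows(genome)
    d = np.array([profile.depletion.get(g, 0.0) for g in genome.gene_ids()])
    idx = np.searchsorted(win_start, midpoints, side="right") - 1
    in_window = (idx >= 0) & (midpoints < win_end[np.clip(idx, 0, None)])
    thin = np.zeros(n)
    thin[in_window] = d[idx[in_window]]
    keep = rng.uniform(size=n) >= thin
    midpoints = midpoints[keep]

    lengths = rng.normal(profile.fragment_length_mean, profile.fragment_length_sd, size=keep.sum())
    lengths = np.maximum(np.rint(lengths), MIN_FRAGMENT_LENGTH).astype(np.int64)
    starts = np.rint(midpoints).astype(np.int64) - lengths // 2
    # shift (never truncate) fragments that stick out past either end
    starts = np.clip(starts, 0, np.maximum(length - lengths, 0))
    ends = starts + lengths
    order = np.argsort(starts, kind="stable")
    return pd.DataFrame(
        {
            "chrom": genome.chrom_name,
            "start": starts[order],
            "end": ends[order],
        }
    )


def simulate_cohort(
    genome: ToyGenome,
    n_cases: int = 47,
    n_controls: int = 47,
    n_planted: int = 50,
    effect: float = 0.8 / 3,
    base_depletion: float = 0.2,
    depth: float = 0.3,
    seed: int = 0,
    cohort: str = "training",
    planted_genes: frozenset[str] | None = None,
    fragment_length_mean: float = DEFAULT_FRAGMENT_LENGTH_MEAN,
    fragment_length_sd: float = DEFAULT_FRAGMENT_LENGTH_SD,
) -> SimulatedCohort:
    """Simulate a matched case/control cohort with planted differential promoters.

    Cases receive ``d_g = base_depletion + effect`` at planted genes; controls
    (and every non-planted gene in both groups) receive ``base_depletion``.
    With the defaults the expected window-count ratio at planted genes is
    ``(1 - base) / (1 - base - effect) = 1.5``.  ``effect=0`` yields a null
    cohort whose two groups share one generative law.  Gestational week
    (uniform integer 12..27) and fetal sex are attached for matching.

    ``planted_genes`` pins the planted set (e.g. to reuse the truth of a
    previously simulated cohort); otherwise it is drawn from the genome.
    """
    gene_ids = genome.gene_ids()
    if n_planted > len(gene_ids):
        raise ValueError("n_planted exceeds number of genes")
    d_case = base_depletion + effect
    if not (0.0 <= base_depletion <= 1.0 and 0.0 <= d_case <= 1.0):
        raise ValueError(
            f"base_depletion={base_depletion} with effect={effect} pushes d_g outside [0, 1]"
        )
    rng = np.random.default_rng(seed)
    if planted_genes is None:
        planted = frozenset(rng.choice(gene_ids, size=n_planted, replace=False).tolist())
    else:
        unknown = set(planted_genes) - set(gene_ids)
        if unknown:
            raise ValueError(f"planted_genes not in genome: {sorted(unknown)}")
        planted = frozenset(planted_genes)

    control_dep = {g: base_depletion for g in gene_ids}
    case_dep = {g: (d_case if g in planted else base_depletion) for g in gene_ids}

    n = n_cases + n_controls
    labels = ["macrosomia"] * n_cases + ["control"] * n_controls
    sample_ids = [f"{cohort}_MA{i + 1:03d}" for i in range(n_cases)] + [
        f"{cohort}_CT{i + 1:03d}" for i in range(n_controls)
    ]
    weeks = rng.integers(12, 28, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    fragments: dict[str, pd.DataFrame] = {}
    for sid, label, child in zip(sample_ids, labels, child_seeds):
        profile = SampleProfile(
            sample_id=sid,
            depletion=case_dep if label == "macrosomia" else control_dep,
            depth=depth,
            fragment_length_mean=fragment_length_mean,
            fragment_length_sd=fragment_length_sd,
            seed=int(child),
        )
        fragments[sid] = simulate_fragments(genome, profile)

    design = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "label": labels,
            "cohort": cohort,
            "gestational_week": weeks.astype(float),
            "fetal_sex": sexes,
        }
    )
    truth = SimTruth(planted, float(effect), float(base_depletion), int(seed))
    return SimulatedCohort(fragments, design, truth, genome)


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path, force: bool = False) -> Path:
    """Write fragments as 3-column BED (0-based half-open), sorted by (chrom, start)."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    out = fragments.sort_values(["chrom", "start"], kind="stable")
    out.to_csv(path, sep="\t", header=False, index=False, columns=["chrom", "start", "end"])
    return path


def write_cohort(cohort: SimulatedCohort, outdir: str | Path, force: bool = False) -> Path:
    """Write a cohort's per-sample BEDs, design TSV and truth TSV under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "fragments").mkdir(parents=True, exist_ok=True)
    for sid, frags in cohort.fragments.items():
        write_fragments_bed(frags, outdir / "fragments" / f"{sid}.bed", force=force)
    cohort.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    cohort.truth.to_frame(cohort.genome.gene_ids()).to_csv(
        outdir / "truth.tsv", sep="\t", index=False
    )
    return outdir


def merge_cohorts(cohorts: list[SimulatedCohort]) -> SimulatedCohort:
    """Concatenate cohorts that share a genome and truth into one object."""
    if not cohorts:
        raise ValueError("no cohorts to merge")
    base = cohorts[0]
    fragments: dict[str, pd.DataFrame] = {}
    for c in cohorts:
        overlap = fragments.keys() & c.fragments.keys()
        if overlap:
            raise ValueError(f"duplicate sample_ids across cohorts: {sorted(overlap)}")
        fragments.update(c.fragments)
    design = pd.concat([c.design for c in cohorts], ignore_index=True)
    return SimulatedCohort(fragments, design, base.truth, base.genome)
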