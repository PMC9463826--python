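"""Discovery stage: per-promoter case/control comparison.

Each gene's normalized promoter coverage is compared between groups with the
two-sided Wilcoxon rank-sum (Mann-Whitney U) test; p-values are adjusted with
Benjamini-Hochberg across all tested genes, and a promoter is called
significant when both the symmetrized fold change of group means is >= 1.3
and the FDR is <= 0.05 (both thresholds inclusive and configurable).
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .promoter_coverage import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "wilcoxon_rank_sum",
    "benjamini_hochberg",
    "fold_change",
    "run_discovery",
]

#: Largest combined sample size for which the exact null distribution is used.
EXACT_MAX_N = 12


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of x vs y.

    Returns (U statistic for x, two-sided p).  The exact permutation null is
    used when n1 + n2 <= 12 and there are no ties; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Degenerate input (all values identical) returns p = 1.0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(case_values: Sequence[float], control_values: Sequence[float]) -> tuple[float, str]:
    """Symmetrized ratio of group means and its direction (case vs control).

    Returns (max(r, 1/r), "up"/"down") where r = mean(case) / mean(control);
    a zero control mean yields (+inf, "up").  Both means zero is undefined and
    raises ValueError — callers exclude such genes.
    """
    mean_case = float(np.mean(case_values))
    mean_control = float(np.mean(control_values))
    if mean_case == 0.0 and mean_control == 0.0:
        raise ValueError("fold change undefined: both group means are zero")
    if mean_control == 0.0:
        return math.inf, "up"
    r = mean_case / mean_control
    return (r, "up") if r > 1 else (1.0 / r if r > 0 else math.inf, "down")


def run_discovery(
    norm: NormalizedMatrix,
    design: pd.DataFrame,
    fc_threshold: float = 1.3,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every promoter for a case/control coverage difference.

    ``design`` must carry ``sample_id`` and ``label`` ("macrosomia"/"control")
    for every sample in ``norm``.  Genes whose coverage is zero in all samples
    are excluded before testing (their count is logged).  The result has one
    row per tested gene — columns gene_id, mean_case, mean_control,
    fold_change, direction, p_value, fdr, significant — sorted by FDR then by
    fold change, descending.
    """
    labels = design.set_index("sample_id")["label"]
    missing = set(norm.samples) - set(labels.index)
    if missing:
        raise ValueError(f"design is missing samples: {sorted(missing)}")
    labels = labels.loc[norm.samples]
    case_ids = labels.index[labels == "macrosomia"]
    control_ids = labels.index[labels == "control"]
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("each group needs >= 2 samples")

    values = norm.values
    nonzero = values.columns[(values != 0).any(axis=0)]
    n_dropped = values.shape[1] - len(nonzero)
    if n_dropped:
        logger.info("excluded %d gene(s) with zero coverage in every sample", n_dropped)

    case = values.loc[case_ids, nonzero].to_numpy()
    control = values.loc[control_ids, nonzero].to_numpy()

    rows = []
    for j, gene in enumerate(nonzero):
        fc, direction = fold_change(case[:, j], control[:, j])
        _, p = wilcoxon_rank_sum(case[:, j], control[:, j])
        rows.append((gene, case[:, j].mean(), control[:, j].mean(), fc, direction, p))
    result = pd.DataFrame(
        rows, columns=["gene_id", "mean_case", "mean_control", "fold_change", "direction", "p_value"]
    )
    result["fdr"] = benjamini_hochberg(result["p_value"].to_numpy())
    result["significant"] = (result["fold_change"] >= fc_threshold) & (
        result["fdr"] <= fdr_threshold
    )
    result = result.sort_values(
        ["fdr", "fold_change"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return result


def significant_genes(discovery: pd.DataFrame) -> list[str]:
    """Gene ids of the significant promoters, in the discovery sort order."""
    return discovery.loc[discovery["significant"], "gene_id"].tolist()
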