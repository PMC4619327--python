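"""Per-cell signal aggregation and reproducibility metrics.

Nuclear reporter signal arrives as per-timepoint traces (mean 3D pixel
intensity per nucleus plus a local non-nuclear background estimate).  The
per-cell summary statistic is the lifetime mean of the background-subtracted
intensity ("blot"); when nuclear volume is available a total amount
(concentration x volume) is carried alongside, which stays roughly constant
as nuclei shrink while concentration rises.

Reproducibility is summarised as Pearson correlation of concentrations over
shared cells between replicate embryos, and as the cross-reporter
correlation of per-division mean sister asymmetries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from wntlineage.lineage_model import LineageTree, polarity_char

__all__ = [
    "NucleusTracePoint",
    "aggregate_cell",
    "replicate_correlation",
    "group_mean_correlation",
    "cross_reporter_division_correlation",
    "lifetime_profile",
]


@dataclass(frozen=True)
class NucleusTracePoint:
    """One timepoint of a tracked nucleus."""

    time: float
    mean_intensity: float
    local_background: float
    volume: Optional[float] = None

    def __post_init__(self) -> None:
        if self.volume is not None and self.volume <= 0:
            raise ValueError("nucleus volume must be positive")


def aggregate_cell(
    trace: Sequence[NucleusTracePoint],
) -> tuple[float, Optional[float]]:
    """Lifetime summary of one nucleus trace.

    Returns ``(blot, total)``: blot is the unweighted mean over timepoints
    of (mean_intensity - local_background); total is the mean of
    concentration x volume when every point carries a volume, else None.
    All timepoints are weighted equally (constant acquisition interval).
    """
    if not trace:
        raise ValueError("empty nucleus trace")
    conc = np.array([p.mean_intensity - p.local_background for p in trace])
    blot = float(conc.mean())
    if all(p.volume is not None for p in trace):
        vols = np.array([p.volume for p in trace])
        return blot, float((conc * vols).mean())
    return blot, None


def _shared_blots(
    tree_a: LineageTree, tree_b: LineageTree
) -> tuple[np.ndarray, np.ndarray]:
    shared = sorted(set(tree_a.cells) & set(tree_b.cells))
    a = np.array([tree_a[c].blot for c in shared])
    b = np.array([tree_b[c].blot for c in shared])
    keep = ~(np.isnan(a) | np.isnan(b))
    return a[keep], b[keep]


def replicate_correlation(
    tree_a: LineageTree, tree_b: LineageTree, method: str = "pearson"
) -> float:
    """Correlation of nuclear concentrations over cells shared between two
    replicate embryos.  Requires at least 3 shared cells with blot values."""
    a, b = _shared_blots(tree_a, tree_b)
    if len(a) < 3:
        raise ValueError(
            f"only {len(a)} shared cells between {tree_a.embryo_id!r} and "
            f"{tree_b.embryo_id!r}; need >= 3"
        )
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def group_mean_correlation(
    trees: Sequence[LineageTree], method: str = "pearson"
) -> float:
    """Mean pairwise replicate correlation over all embryo pairs in a group."""
    if len(trees) < 2:
        raise ValueError("need >= 2 embryos for a replicate group")
    rs = [
        replicate_correlation(a, b, method=method)
        for a, b in combinations(trees, 2)
    ]
    return float(np.mean(rs))


def cross_reporter_division_correlation(
    asym_a: dict, asym_b: dict, method: str = "pearson"
) -> float:
    """Correlation between two reporters' per-division mean sister
    asymmetries, over divisions measured in both groups.

    ``asym_a``/``asym_b`` map division parent name -> mean asymmetry (as
    produced by :func:`wntlineage.asymmetry.division_table`).
    """
    shared = sorted(set(asym_a) & set(asym_b))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} divisions shared; need >= 3")
    a = np.array([asym_a[d] for d in shared])
    b = np.array([asym_b[d] for d in shared])
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def lifetime_profile(
    trees: Iterable[LineageTree],
    bin_minutes: float = 1.0,
    drop_first_points: int = 0,
    high_char: str = "p",
) -> pd.DataFrame:
    """Mean concentration versus minutes since division, by polarity class.

    Pools every cell trace across embryos, aligned to the cell's birth
    (anaphase origin); cells are split into anterior-class and
    posterior-class daughters by their birth polarity character.  The first
    one or two timepoints of a cell correspond to anaphase/telophase and can
    be dropped via ``drop_first_points`` (kept by default).

    Returns a tidy frame with columns
    ``polarity_class, t, mean, sem, n``.
    """
    rows = []
    for tree in trees:
        for name, rec in tree.cells.items():
            if rec.trace is None:
                continue
            pc = polarity_char(name)
            if pc is None:
                continue
            cls = "posterior" if pc == high_char else "anterior"
            for t, conc in rec.trace[drop_first_points:]:
                rows.append((cls, t - rec.birth_time, conc))
    if not rows:
        raise ValueError("no per-timepoint traces available in these trees")
    df = pd.DataFrame(rows, columns=["polarity_class", "dt", "conc"])
    df["t"] = (df["dt"] / bin_minutes).round().astype(int) * bin_minutes
    prof = (
        df.groupby(["polarity_class", "t"])["conc"]
        .agg(mean="mean", sem="sem", n="size")
        .reset_index()
    )
    return prof
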