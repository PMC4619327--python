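"""Subtree-activity metrics for stable, lagged transcriptional reporters.

POPTOP-family reporters drive a stable histone-fluorophore from multimerised
TCF sites, so transcription in one cell is detected minutes later in its
descendants.  "Activity" of a cell is therefore the mean reporter level over
the cell and all of its recorded descendants; the difference in activity
between sister subtrees isolates the contribution of a single division.
Expression-initiating cells are inferred as ancestors of fully-expressing
clades, shifted earlier along the lineage by the fluorophore maturation lag
(~30 min for mCherry).

High-High fractions and per-gene High-High scores (fraction of a gene's
expression-initiating lineages that are SYS-1 High-High) connect reporter
activity back to beta-catenin signaling history, and an ancestor-dose linear
model tests whether activity rises with the number of High-High ancestors
beyond what the total number of High ancestors explains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from wntlineage.lineage_model import CellName, Division, LineageTree, parse_name

__all__ = [
    "ActivityResult",
    "HHFraction",
    "GeneHHScore",
    "subtree_activity",
    "activity_table",
    "activity_sister_asymmetry",
    "infer_initiating_cells",
    "hh_fraction",
    "gene_hh_score",
    "ancestor_dose_model",
    "compare_regulation_classes",
]

logger = logging.getLogger(__name__)

REGULATION_CLASSES = ("activated", "repressed", "dual", "unregulated", "indirect")


@dataclass(frozen=True)
class ActivityResult:
    cell: CellName
    activity: float
    n_cells: int
    sister_asymmetry: Optional[float] = None
    cohort: Optional[str] = None


def subtree_activity(tree: LineageTree, cell: CellName | str) -> float:
    """Unweighted mean blot over a cell and every recorded descendant.

    A leaf's activity is its own blot.  Satisfies the recursion
    ``activity(c) * size(c) = blot(c) + sum_d activity(d) * size(d)``.
    """
    cn = parse_name(cell)
    if cn not in tree.cells:
        raise KeyError(f"{cn} not in tree")
    vals = [tree[n].blot for n in tree.subtree(cn)]
    return float(np.mean(vals))


def activity_table(tree: LineageTree) -> pd.DataFrame:
    """Activity of every recorded cell, computed in one bottom-up pass."""
    sums: dict[CellName, float] = {}
    sizes: dict[CellName, int] = {}
    for name in sorted(tree.cells, key=lambda n: (-n.depth, n)):
        s, k = tree[name].blot, 1
        for d in tree.daughters(name):
            s += sums[d]
            k += sizes[d]
        sums[name], sizes[name] = s, k
    rows = [
        (str(n), sums[n] / sizes[n], sizes[n], tree[n].birth_time)
        for n in sorted(tree.cells)
    ]
    return pd.DataFrame(rows, columns=["cell", "activity", "n_cells", "birth_time"])


def activity_sister_asymmetry(
    tree: LineageTree, division: Division
) -> Optional[float]:
    """Activity of the second-listed (posterior) sister subtree minus the
    first-listed (anterior); None (logged) when a subtree is unrecorded."""
    if division.daughter1 not in tree.cells or division.daughter2 not in tree.cells:
        logger.info("%s: division %s lacks a recorded sister subtree",
                    tree.embryo_id, division.parent)
        return None
    return subtree_activity(tree, division.daughter2) - subtree_activity(
        tree, division.daughter1
    )


def infer_initiating_cells(
    tree: LineageTree,
    onset_threshold: float,
    lag_minutes: float = 30.0,
) -> list[CellName]:
    """Expression-initiating cells of a stable lagged reporter.

    Finds maximal clades in which every recorded cell exceeds
    ``onset_threshold``, then shifts each clade root earlier by
    ``lag_minutes`` along the unique ancestor path: the initiating cell is
    the ancestor alive at (clade-root birth time - lag).  Returns an empty
    list when the threshold excludes all cells.  Idempotent: re-running on
    an inferred clade returns the same ancestor.
    """
    expressing = {
        n for n, rec in tree.cells.items()
        if not np.isnan(rec.blot) and rec.blot > onset_threshold
    }
    # all_above[c]: entire recorded subtree of c exceeds the threshold
    all_above: dict[CellName, bool] = {}
    for name in sorted(tree.cells, key=lambda n: (-n.depth, n)):
        ok = name in expressing
        for d in tree.daughters(name):
            ok = ok and all_above[d]
        all_above[name] = ok

    out = []
    for name in sorted(tree.cells):
        if not all_above[name]:
            continue
        parent = tree.parent(name)
        if parent is not None and all_above[parent]:
            continue  # not maximal
        out.append(_lag_ancestor(tree, name, lag_minutes))
    return sorted(set(out))


def _lag_ancestor(tree: LineageTree, cell: CellName, lag: float) -> CellName:
    """Ancestor of ``cell`` alive at (cell's birth - lag)."""
    target = tree[cell].birth_time - lag
    cur = cell
    while tree[cur].birth_time > target:
        parent = tree.parent(cur)
        if parent is None:
            break
        cur = parent
    return cur


@dataclass(frozen=True)
class HHFraction:
    fraction: float
    n_hh: int
    n_counted: int
    n_excluded: int


def hh_fraction(
    initiating_cells: Iterable[CellName | str],
    labels: Mapping[str, str],
) -> HHFraction:
    """Fraction of initiating cells whose SYS-1 history label is HH.

    ``labels`` maps cell name -> 2-division shorthand ('HH', 'LH', ...),
    typically from a SYS-1 reference group via
    :func:`wntlineage.history_enrichment.label_history`.  Cells without a
    label are excluded and counted.  Invariant to list order; in [0, 1].
    """
    n_hh = n_counted = n_excluded = 0
    for cell in initiating_cells:
        key = str(parse_name(cell))
        lab = labels.get(key)
        if lab is None:
            n_excluded += 1
            continue
        n_counted += 1
        if lab == "HH":
            n_hh += 1
    frac = n_hh / n_counted if n_counted else float("nan")
    return HHFraction(frac, n_hh, n_counted, n_excluded)


@dataclass(frozen=True)
class GeneHHScore:
    """Per-gene High-High lineage score.

    ``hh_score`` is the fraction of the gene's expression-initiating
    lineages that are SYS-1 High-High; the regulation class (activated /
    repressed / dual / unregulated / indirect) is a user-supplied annotation
    from perturbation experiments, never inferred here.
    """

    gene: str
    initiating_cells: tuple[str, ...]
    hh_score: float
    regulation_class: str = "unregulated"

    def __post_init__(self) -> None:
        if self.regulation_class not in REGULATION_CLASSES:
            raise ValueError(f"unknown regulation class {self.regulation_class!r}")
        if not (0.0 <= self.hh_score <= 1.0 or np.isnan(self.hh_score)):
            raise ValueError("hh_score must lie in [0, 1]")


def gene_hh_score(
    gene: str,
    initiating_cells: Sequence[CellName | str],
    labels: Mapping[str, str],
    regulation_class: str = "unregulated",
) -> GeneHHScore:
    frac = hh_fraction(initiating_cells, labels)
    return GeneHHScore(
        gene=gene,
        initiating_cells=tuple(str(parse_name(c)) for c in initiating_cells),
        hh_score=frac.fraction,
        regulation_class=regulation_class,
    )


def ancestor_dose_model(
    activities: Sequence[float],
    hh_ancestor_counts: Sequence[int],
    high_ancestor_counts: Sequence[int],
) -> dict:
    """Linear model: activity ~ n_HH_ancestors + n_High_ancestors.

    Returns the HH-ancestor coefficient and its p-value after accounting
    for the total number of High ancestors, plus the full fit.  A large
    design condition number logs a collinearity warning.
    """
    y = np.asarray(activities, dtype=float)
    X = np.column_stack([
        np.asarray(hh_ancestor_counts, dtype=float),
        np.asarray(high_ancestor_counts, dtype=float),
    ])
    X = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, X).fit()
    if fit.condition_number > 1e8:
        logger.warning("ancestor covariates nearly collinear (cond=%.3g)",
                       fit.condition_number)
    return {
        "hh_coef": float(fit.params[1]),
        "hh_p": float(fit.pvalues[1]),
        "high_coef": float(fit.params[2]),
        "condition_number": float(fit.condition_number),
        "fit": fit,
    }


def compare_regulation_classes(
    gene_scores: Iterable[GeneHHScore],
    class_a: str = "activated",
    class_b: str = "repressed",
) -> dict:
    """Wilcoxon rank-sum comparison of hh_score between two regulation
    classes.  Uses the exact null distribution for small samples without
    ties (automatic in scipy), the normal approximation otherwise."""
    scores = {class_a: [], class_b: []}
    for gs in gene_scores:
        if gs.regulation_class in scores and not np.isnan(gs.hh_score):
            scores[gs.regulation_class].append(gs.hh_score)
    a, b = scores[class_a], scores[class_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 genes per regulation class")
    if sorted(a) == sorted(b):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return {
        "p": p,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": len(a),
        "n_b": len(b),
    }
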