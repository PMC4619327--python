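"""Lineage-history labels and transmitotic cousin enrichment.

A cell's High/Low history over its last ``k`` divisions records whether it
(and its ancestors) were the reporter-High daughter at each division.  For
the posterior-localising beta-catenins (SYS-1, WRM-1) High means posterior
('p' suffix); for the anterior-localising TCF (POP-1) High means anterior
('a').  "High-High" (HH) cells were the High daughter at two consecutive
divisions; their matched "Low-High" (LH) cousins share the grandparent but
had a Low parent.

Cousin enrichment is the additional nuclear concentration in HH cells over
their LH cousins.  It is quantified per grandparent quartet and summarised
as the percent increase of HH over LH group means with a Wilcoxon
signed-rank p over matched pairs.  Triple-history contrasts (HHH vs LHH,
LHH vs HLH) distinguish one-division from two-division memory, and the
SYS-1-per-POP-1 ratio of a history class is estimated as the slope of a
best-fit line through that class's (POP-1, SYS-1) concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from wntlineage.lineage_model import (
    CellName,
    LineageTree,
    cousin_pair,
    parse_name,
)

__all__ = [
    "HistoryLabel",
    "CousinPairResult",
    "CousinEnrichment",
    "high_char",
    "label_history",
    "cousin_enrichment",
    "triple_history_contrast",
    "ratio_slope",
    "slope_fold",
]

logger = logging.getLogger(__name__)

_HIGH_CHAR = {"SYS-1": "p", "WRM-1": "p", "POP-1": "a"}


def high_char(reporter: str) -> str:
    """Suffix character of the reporter-High daughter: 'p' for SYS-1/WRM-1,
    'a' for POP-1.  Matches on family substring."""
    for family, c in _HIGH_CHAR.items():
        if family in reporter:
            return c
    raise ValueError(f"unknown reporter family for {reporter!r}")


@dataclass(frozen=True)
class HistoryLabel:
    """High/Low labels over a cell's last divisions, oldest first."""

    cell: CellName
    reporter: str
    labels: tuple[str, ...]  # each 'H' or 'L'
    truncated: bool = False  # fewer divisions available than requested

    @property
    def shorthand(self) -> str:
        return "".join(self.labels)


def _measured_high(tree: LineageTree, cell: CellName) -> Optional[bool]:
    """Whether ``cell`` had the greater blot of its sibling pair.  Ties
    break to Low with a warning; None when the pair is unmeasurable."""
    parent = tree.parent(cell)
    if parent is None:
        return None
    sibs = tree.daughters(parent)
    if len(sibs) != 2:
        return None
    other = sibs[0] if sibs[1] == cell else sibs[1]
    b_self, b_other = tree[cell].blot, tree[other].blot
    if np.isnan(b_self) or np.isnan(b_other):
        return None
    if b_self == b_other:
        logger.warning("%s: tie between %s and %s; labeled Low",
                       tree.embryo_id, cell, other)
        return False
    return b_self > b_other


def label_history(
    tree: LineageTree,
    cell: CellName | str,
    reporter: str,
    k: int = 2,
    mode: str = "by-name",
    reversed_divisions: Iterable[str] = (),
) -> Optional[HistoryLabel]:
    """High/Low history of a cell over its last ``k`` divisions.

    ``by-name``: High at a division iff the cell (or ancestor) carries the
    reporter's High-polarity suffix character; only a-p divisions can be
    labeled by name — l-r/d-v divisions always fall back to measurement.
    ``by-measurement``: High iff that cell had the greater blot of the two
    daughters (ties to Low, logged).

    Cells whose labeled divisions include a reversed-polarity division
    (parents listed in ``reversed_divisions``) return None under by-name
    labeling.  Shorter histories than ``k`` are returned flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("by-name", "by-measurement"):
        raise ValueError(f"unknown mode {mode!r}")
    cn = parse_name(cell)
    hc = high_char(reporter)
    reversed_set = {str(parse_name(r)) for r in reversed_divisions}

    labels: list[str] = []
    cur = cn
    for _ in range(k):
        if not cur.suffix:
            break  # founder: no further suffix history
        ch = cur.suffix[-1]
        parent = CellName(cur.founder, cur.suffix[:-1])
        use_measurement = mode == "by-measurement" or ch not in ("a", "p")
        if use_measurement:
            hi = _measured_high(tree, cur)
            if hi is None:
                break
            labels.append("H" if hi else "L")
        else:
            if str(parent) in reversed_set:
                return None
            labels.append("H" if ch == hc else "L")
        cur = parent
    if not labels:
        return HistoryLabel(cn, reporter, (), truncated=True)
    labels.reverse()  # oldest first
    return HistoryLabel(cn, reporter, tuple(labels), truncated=len(labels) < k)


@dataclass(frozen=True)
class CousinPairResult:
    """One matched High-High / Low-High cousin pair within one embryo."""

    hh_cell: CellName
    lh_cell: CellName
    hh_conc: float
    lh_conc: float
    embryo_id: str

    @property
    def ratio(self) -> Optional[float]:
        return self.hh_conc / self.lh_conc if self.lh_conc > 0 else None


@dataclass
class CousinEnrichment:
    """Group summary of cousin enrichment for one reporter/condition."""

    pairs: list[CousinPairResult]
    mean_ratio: Optional[float]
    percent_increase: float
    percent_increase_pairs: Optional[float]
    p: float
    n_pairs: int


def _enumerate_pairs(
    tree: LineageTree,
    reporter: str,
    mode: str,
    reversed_divisions: Iterable[str],
) -> list[CousinPairResult]:
    hc = high_char(reporter)
    out = []
    seen_hh: set[CellName] = set()
    for cell in sorted(tree.cells):
        lab = label_history(tree, cell, reporter, k=2, mode=mode,
                            reversed_divisions=reversed_divisions)
        if lab is None or lab.shorthand != "HH" or lab.truncated:
            continue
        if mode == "by-name":
            if len(cell.suffix) < 2 or cell.suffix[-2:] != hc * 2:
                continue  # HH via measurement fallback on non-a-p axes
            lh = cousin_pair(cell, hc)
        else:
            lh = _measured_cousin(tree, cell)
            if lh is None:
                continue
        lh_rec = tree.get(lh)
        if lh_rec is None or np.isnan(lh_rec.blot) or np.isnan(tree[cell].blot):
            continue
        if cell in seen_hh:
            continue
        seen_hh.add(cell)
        out.append(
            CousinPairResult(cell, lh, tree[cell].blot, lh_rec.blot, tree.embryo_id)
        )
    return out


def _measured_cousin(tree: LineageTree, hh_cell: CellName) -> Optional[CellName]:
    """Measured-High daughter of the Low sibling of the HH cell's parent."""
    parent = tree.parent(hh_cell)
    if parent is None:
        return None
    gp = tree.parent(parent)
    if gp is None:
        return None
    aunts = [d for d in tree.daughters(gp) if d != parent]
    if len(aunts) != 1:
        return None
    nieces = tree.daughters(aunts[0])
    if len(nieces) != 2:
        return None
    hi = _measured_high(tree, nieces[0])
    if hi is None:
        return None
    return nieces[0] if hi else nieces[1]


def cousin_enrichment(
    trees: Sequence[LineageTree],
    reporter: Optional[str] = None,
    mode: str = "by-name",
    reversed_divisions: Iterable[str] = (),
    test: str = "signed-rank",
) -> CousinEnrichment:
    """Cousin enrichment of a reporter over a group of embryos.

    Enumerates every grandparent quartet with measurable HH and LH members
    (each HH cell appears in at most one pair).  The headline percent
    increase pools cells by class across embryos:
    ``(mean_HH - mean_LH) / mean_LH x 100``; a mean of per-pair ratios is
    reported alongside (undefined — None — when the LH mean is <= 0, since
    background-subtracted concentrations can be negative).  Significance is
    a Wilcoxon signed-rank over matched pairs by default (``test``:
    ``'signed-rank'`` or ``'rank-sum'``).
    """
    if reporter is None:
        reporter = trees[0].reporter
    pairs: list[CousinPairResult] = []
    for tree in trees:
        pairs.extend(_enumerate_pairs(tree, reporter, mode, reversed_divisions))
    if not pairs:
        raise ValueError("no measurable cousin quartets in this group")
    hh = np.array([p.hh_conc for p in pairs])
    lh = np.array([p.lh_conc for p in pairs])
    if lh.mean() > 0:
        pct = float((hh.mean() - lh.mean()) / lh.mean() * 100)
    else:
        pct = float("nan")
    ratios = [p.ratio for p in pairs if p.ratio is not None]
    mean_ratio = float(np.mean(ratios)) if ratios else None
    pct_pairs = (
        float((np.mean(ratios) - 1) * 100) if ratios and len(ratios) == len(pairs) else None
    )
    diffs = hh - lh
    if test == "signed-rank":
        p = 1.0 if np.all(diffs == 0) else float(stats.wilcoxon(diffs).pvalue)
    elif test == "rank-sum":
        p = float(stats.mannwhitneyu(hh, lh, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return CousinEnrichment(
        pairs=pairs,
        mean_ratio=mean_ratio,
        percent_increase=pct,
        percent_increase_pairs=pct_pairs,
        p=p,
        n_pairs=len(pairs),
    )


_CONTRASTS = {
    "HHH vs LHH": ("HHH", "LHH"),
    "LHH vs HLH": ("LHH", "HLH"),
}


def triple_history_contrast(
    trees: Sequence[LineageTree],
    reporter: Optional[str] = None,
    contrast: str = "HHH vs LHH",
    mode: str = "by-name",
    reversed_divisions: Iterable[str] = (),
) -> tuple[float, float, int, int]:
    """Percent difference in mean concentration between two 3-division
    history classes, plus rank-sum p.

    Returns ``(percent_difference, p, n_first, n_second)`` where the percent
    difference is of the first-named class's mean over the second's.
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(_CONTRASTS)}")
    cls_a, cls_b = _CONTRASTS[contrast]
    if reporter is None:
        reporter = trees[0].reporter
    groups: dict[str, list[float]] = {cls_a: [], cls_b: []}
    for tree in trees:
        for cell in tree.cells:
            lab = label_history(tree, cell, reporter, k=3, mode=mode,
                                reversed_divisions=reversed_divisions)
            if lab is None or lab.truncated:
                continue
            if lab.shorthand in groups and not np.isnan(tree[cell].blot):
                groups[lab.shorthand].append(tree[cell].blot)
    for cls, vals in groups.items():
        if not vals:
            raise ValueError(f"no cells in history class {cls}")
    a, b = np.array(groups[cls_a]), np.array(groups[cls_b])
    pct = float((a.mean() - b.mean()) / abs(b.mean()) * 100)
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return pct, p, len(a), len(b)


def ratio_slope(
    sys1: Sequence[float],
    pop1: Sequence[float],
    fit_intercept: bool = True,
) -> float:
    """Ordinary-least-squares slope of SYS-1 concentration against POP-1
    concentration for one history class: SYS-1 per unit POP-1.

    Fitted with an intercept by default; a through-origin variant is
    available.  A zero-variance predictor raises.
    """
    y = np.asarray(sys1, dtype=float)
    x = np.asarray(pop1, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 matched (POP-1, SYS-1) points")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: POP-1 values have zero variance")
    if fit_intercept:
        return float(np.polyfit(x, y, 1)[0])
    return float(np.dot(x, y) / np.dot(x, x))


def slope_fold(slope_a: float, slope_b: float) -> float:
    """Fold-difference between two groups' SYS-1-per-POP-1 slopes."""
    if slope_b == 0:
        raise ValueError("reference slope is zero")
    return slope_a / slope_b
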