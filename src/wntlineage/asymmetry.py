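"""Per-division sister-asymmetry statistics.

Sister asymmetry is the difference in background-subtracted nuclear
concentration between the two daughters of a division — posterior minus
anterior on the a-p axis, and second-listed minus first-listed daughter
(r-l, v-d) on the other axes.  SYS-1/WRM-1-type reporters are expected
posterior-positive; POP-1-type reporters use the same formula and are
expected negative (anterior-high).

Per-division significance is a two-sided one-sample test of the mean
asymmetry across replicate embryos, corrected over divisions by
Benjamini-Hochberg FDR.  Divisions are classified as normal / low / none /
reversed against thresholds derived from an untreated wild-type reference
group (low cutoff at the bottom 5th percentile of wild-type asymmetries;
none cutoff from known-unpolarized divisions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from wntlineage.lineage_model import Division, LineageTree

__all__ = [
    "PolarityThresholds",
    "sister_asymmetry",
    "collect_asymmetries",
    "test_asymmetry",
    "division_table",
    "derive_thresholds",
    "classify_division",
    "orientation_deviation",
    "compare_groups",
    "expected_sign",
]

logger = logging.getLogger(__name__)

#: Expected sign of (posterior - anterior) asymmetry per reporter family.
#: Configuration, never inferred from data.
REPORTER_SIGN = {
    "SYS-1": +1,
    "WRM-1": +1,
    "POP-1": -1,
}


def expected_sign(reporter: str) -> int:
    """+1 for posterior-high reporters (SYS-1, WRM-1), -1 for anterior-high
    (POP-1).  Matches on family substring so 'Venus::SYS-1' works."""
    for family, sign in REPORTER_SIGN.items():
        if family in reporter:
            return sign
    raise ValueError(f"unknown reporter family for {reporter!r}")


@dataclass(frozen=True)
class PolarityThresholds:
    """Classification cutoffs derived from an untreated wild-type group.

    ``low_cutoff``: 5th percentile of wild-type signed asymmetries — below
    it (but still in the expected direction) a division is 'low'.
    ``none_cutoff``: maximum |asymmetry| among wild-type known-unpolarized
    divisions — inside +/- this band a division is 'none'; beyond it in the
    unexpected direction it is 'reversed'.
    ``orientation_cutoff``: wild-type 5th-percentile bound on division-
    orientation deviation, degrees.
    """

    low_cutoff: float
    none_cutoff: float
    orientation_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.none_cutoff < 0:
            raise ValueError("none_cutoff must be >= 0")


def sister_asymmetry(tree: LineageTree, division: Division) -> Optional[float]:
    """Second-listed (posterior/right/ventral) daughter blot minus
    first-listed daughter blot; None (logged) when either blot is missing."""
    rec2 = tree.get(division.daughter2)
    rec1 = tree.get(division.daughter1)
    if rec1 is None or rec2 is None or np.isnan(rec1.blot) or np.isnan(rec2.blot):
        logger.info(
            "%s: division %s skipped (missing daughter measurement)",
            tree.embryo_id,
            division.parent,
        )
        return None
    return rec2.blot - rec1.blot


def collect_asymmetries(
    trees: Sequence[LineageTree],
) -> pd.DataFrame:
    """Per-embryo sister asymmetries for every division observed in a group.

    Returns a tidy frame: ``division`` (parent name, str), ``axis``,
    ``embryo_id``, ``asym``, ``parent_birth``, ``division_time``.
    """
    rows = []
    for tree in trees:
        for div in tree.divisions():
            a = sister_asymmetry(tree, div)
            if a is None:
                continue
            rows.append(
                (
                    str(div.parent),
                    div.axis,
                    tree.embryo_id,
                    a,
                    tree[div.parent].birth_time,
                    div.time,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["division", "axis", "embryo_id", "asym", "parent_birth", "division_time"],
    )


def test_asymmetry(
    asyms: pd.DataFrame,
    method: str = "ttest",
    min_embryos: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided one-sample test of mean sister asymmetry != 0 per division.

    ``asyms`` is the frame from :func:`collect_asymmetries`.  ``method`` is
    ``'ttest'`` (default), ``'wilcoxon'`` (signed-rank) or ``'sign-perm'``
    (exact sign-flip permutation).  Divisions with fewer than
    ``min_embryos`` observations are excluded and counted in the
    ``excluded`` attribute of the returned frame.  q-values are
    Benjamini-Hochberg over all tested divisions.
    """
    rows = []
    excluded = 0
    for (division, axis), grp in asyms.groupby(["division", "axis"], sort=True):
        vals = grp["asym"].to_numpy()
        if len(vals) < min_embryos:
            excluded += 1
            continue
        if method == "ttest":
            if np.allclose(vals, vals[0]):
                p = 1.0 if vals[0] == 0 else 0.0
            else:
                p = float(stats.ttest_1samp(vals, 0.0).pvalue)
        elif method == "wilcoxon":
            p = 1.0 if np.all(vals == 0) else float(stats.wilcoxon(vals).pvalue)
        elif method == "sign-perm":
            p = _sign_permutation_p(vals)
        else:
            raise ValueError(f"unknown test method {method!r}")
        rows.append(
            {
                "division": division,
                "axis": axis,
                "n_embryos": len(vals),
                "asym_mean": float(vals.mean()),
                "asym_sd": float(vals.std(ddof=1)),
                "p_nominal": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_fdr"] = multipletests(df["p_nominal"], method="fdr_bh")[1]
        df["significant"] = df["p_nominal"] < alpha
    else:
        df["q_fdr"] = []
        df["significant"] = []
    df.attrs["excluded"] = excluded
    df.attrs["n_significant"] = int(df["significant"].sum()) if len(df) else 0
    df.attrs["n_tested"] = len(df)
    return df


def _sign_permutation_p(vals: np.ndarray, max_exact: int = 20) -> float:
    """Exact two-sided sign-flip permutation p for a one-sample location test."""
    n = len(vals)
    obs = abs(vals.sum())
    if n > max_exact:
        raise ValueError(f"sign permutation is exact only; n={n} too large")
    total = 1 << n
    count = 0
    for mask in range(total):
        s = 0.0
        for i in range(n):
            s += vals[i] if (mask >> i) & 1 else -vals[i]
        if abs(s) >= obs - 1e-12:
            count += 1
    return count / total


def division_table(
    trees: Sequence[LineageTree],
    method: str = "ttest",
    min_embryos: int = 3,
    thresholds: Optional[PolarityThresholds] = None,
    reporter_sign: Optional[int] = None,
) -> pd.DataFrame:
    """One row per division: mean asymmetry, p, q, and (when thresholds and
    the reporter's expected sign are given) the polarity class."""
    df = test_asymmetry(collect_asymmetries(trees), method=method, min_embryos=min_embryos)
    if thresholds is not None:
        if reporter_sign is None:
            reporter_sign = expected_sign(trees[0].reporter)
        df["polarity_class"] = [
            classify_division(a, thresholds, reporter_sign) for a in df["asym_mean"]
        ]
    return df


def derive_thresholds(
    wildtype_table: pd.DataFrame,
    unpolarized_divisions: Iterable[str],
    reporter_sign: int,
    percentile: float = 5.0,
    orientation_deviations: Optional[Sequence[float]] = None,
) -> PolarityThresholds:
    """Thresholds from an untreated wild-type division table.

    ``low_cutoff`` is the ``percentile``-th percentile (default bottom 5%)
    of the signed wild-type asymmetries; ``none_cutoff`` is the largest
    |mean asymmetry| among the named known-unpolarized divisions (a required
    input list — the choice of unpolarized reference divisions is a study
    design decision, not inferred).
    """
    unpol = set(unpolarized_divisions)
    signed = wildtype_table["asym_mean"] * reporter_sign
    polarized = signed[~wildtype_table["division"].isin(unpol)]
    if not len(polarized):
        raise ValueError("no polarized wild-type divisions to derive low_cutoff")
    ref = wildtype_table.loc[wildtype_table["division"].isin(unpol), "asym_mean"]
    if not len(ref):
        raise ValueError("no known-unpolarized divisions found in wild-type table")
    ori = None
    if orientation_deviations is not None and len(orientation_deviations):
        ori = float(np.percentile(orientation_deviations, 100 - percentile))
    return PolarityThresholds(
        low_cutoff=float(np.percentile(polarized, percentile)),
        none_cutoff=float(ref.abs().max()),
        orientation_cutoff=ori,
    )


def classify_division(
    asym: float, thresholds: PolarityThresholds, reporter_sign: int
) -> str:
    """Polarity class of one division's mean asymmetry.

    'none' inside the +/- none_cutoff band (boundary closed on the 'none'
    side); 'reversed' beyond the band opposite the reporter's expected sign;
    'low' in the expected direction but at or below the low cutoff; else
    'normal'.
    """
    signed = asym * reporter_sign
    if abs(asym) <= thresholds.none_cutoff:
        return "none"
    if signed < 0:
        return "reversed"
    if signed <= thresholds.low_cutoff:
        return "low"
    return "normal"


def orientation_deviation(
    test_vector: Sequence[float],
    reference_vectors: Sequence[Sequence[float]],
    cutoff_degrees: Optional[float] = None,
) -> tuple[float, Optional[bool]]:
    """Angle (degrees) between a division vector and the mean wild-type
    vector for the same named division, plus a defective flag when a cutoff
    is supplied.

    Division vectors run from the first-listed daughter's birth position to
    the second-listed daughter's.  Reference vectors are normalised before
    averaging so embryos contribute direction, not magnitude.
    """
    v = np.asarray(test_vector, dtype=float)
    refs = np.asarray(reference_vectors, dtype=float)
    if refs.ndim == 1:
        refs = refs[None, :]
    norms = np.linalg.norm(refs, axis=1)
    if np.any(norms == 0) or np.linalg.norm(v) == 0:
        raise ValueError("zero-length division vector")
    mean_ref = (refs / norms[:, None]).mean(axis=0)
    if np.linalg.norm(mean_ref) == 0:
        raise ValueError("reference vectors cancel; no mean direction")
    cosang = np.dot(v, mean_ref) / (np.linalg.norm(v) * np.linalg.norm(mean_ref))
    angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    flag = None if cutoff_degrees is None else angle > cutoff_degrees
    return angle, flag


def division_vector(
    tree: LineageTree, division: Division
) -> Optional[np.ndarray]:
    """Birth-position vector from first- to second-listed daughter, or None
    (logged) when positions are absent — never fabricated."""
    r1, r2 = tree.get(division.daughter1), tree.get(division.daughter2)
    if r1 is None or r2 is None or r1.pos_birth is None or r2.pos_birth is None:
        logger.info(
            "%s: no positions for division %s", tree.embryo_id, division.parent
        )
        return None
    return np.asarray(r2.pos_birth, dtype=float) - np.asarray(r1.pos_birth, dtype=float)


def compare_groups(
    asyms_a: pd.DataFrame,
    asyms_b: pd.DataFrame,
    stratifier: Optional[Callable[[pd.Series], str]] = None,
    classes_a: Optional[Sequence[str]] = None,
    classes_b: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Effect size and Wilcoxon rank-sum p between two condition groups.

    ``asyms_a``/``asyms_b`` are tidy per-embryo asymmetry frames
    (:func:`collect_asymmetries`); the comparison is on the pooled ``asym``
    values, optionally per stratum (``stratifier`` maps a row to a stratum
    label, e.g. before/after the 28-cell stage by parent birth time;
    boundary divisions go to the earlier stratum by the stratifier's own
    rule).  Reported per stratum: percent difference of group means
    ((B - A)/|A| x 100) and two-sided rank-sum p.  When polarity-class
    lists are supplied, a chi-square (or Fisher exact for 2x2) contingency
    test over class counts is appended as a ``classes`` stratum.
    """
    a = asyms_a.copy()
    b = asyms_b.copy()
    if stratifier is None:
        a["stratum"] = "all"
        b["stratum"] = "all"
    else:
        a["stratum"] = a.apply(stratifier, axis=1)
        b["stratum"] = b.apply(stratifier, axis=1)
    rows = []
    for stratum in sorted(set(a["stratum"]) | set(b["stratum"])):
        va = a.loc[a["stratum"] == stratum, "asym"].to_numpy()
        vb = b.loc[b["stratum"] == stratum, "asym"].to_numpy()
        if len(va) == 0 or len(vb) == 0:
            rows.append(
                {"stratum": stratum, "n_a": len(va), "n_b": len(vb),
                 "percent_diff": np.nan, "p": np.nan}
            )
            continue
        pct = (vb.mean() - va.mean()) / abs(va.mean()) * 100 if va.mean() != 0 else np.nan
        p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
        rows.append(
            {"stratum": stratum, "n_a": len(va), "n_b": len(vb),
             "percent_diff": float(pct), "p": p}
        )
    out = pd.DataFrame(rows)
    if classes_a is not None and classes_b is not None:
        out.attrs["class_test"] = _class_contingency(classes_a, classes_b)
    return out


def _class_contingency(
    classes_a: Sequence[str], classes_b: Sequence[str]
) -> dict:
    labels = sorted(set(classes_a) | set(classes_b))
    table = np.array(
        [
            [sum(c == lab for c in classes_a) for lab in labels],
            [sum(c == lab for c in classes_b) for lab in labels],
        ]
    )
    if table.shape == (2, 2):
        p = float(stats.fisher_exact(table)[1])
        test = "fisher"
    else:
        p = float(stats.chi2_contingency(table).pvalue)
        test = "chi2"
    return {"labels": labels, "table": table.tolist(), "p": p, "test": test}
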