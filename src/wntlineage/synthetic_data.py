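"""Synthetic multi-embryo lineage datasets with known ground truth.

The generator emulates the statistical structure of lineage-traced nuclear
reporter data, not its biophysics: an invariant binary lineage expanded from
P0, per-cell background-subtracted concentrations with posterior-biased
sister asymmetry, history-dependent (cousin) enrichment with one- or
two-division memory, reversed-polarity divisions, multiplicative per-embryo
replicate scaling, and — for POPTOP-like reporters — stable lagged
accumulation in the descendants of activating cells.

The generative model for an instant (concentration) reporter is

    High daughter:  blot = mu + alpha * gamma**m + noise
    Low daughter:   blot = mu - alpha/2 + noise

where ``m`` counts consecutive reporter-High ancestors (capped at the
memory depth), so ``gamma`` is the cousin-enrichment factor: with memory 1
and no noise the HH-over-LH percent increase is exactly
``100 * alpha * (gamma - 1) / (mu + alpha)``.  All blots are scaled by a
per-embryo lognormal factor, and negative values arise naturally — the
generator never clips.

Ground truth (per-cell High/Low labels, consecutive-High depth, activation
and initiation flags, true means) is stored alongside every simulated
dataset so recovery tests can compare pipeline output to planted values.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from wntlineage.io_tables import (
    EmbryoManifest,
    TableDialect,
    write_cell_table,
    write_manifest,
)
from wntlineage.lineage_model import (
    EARLY_DAUGHTERS,
    OPPOSITE_CHAR,
    CellName,
    CellRecord,
    LineageTree,
    daughters_of,
    parse_name,
)

__all__ = [
    "SynthParams",
    "make_tree",
    "simulate_reporter",
    "simulate_reporter_pair",
    "simulate_dataset",
    "expected_percent_increase",
    "stage_at",
    "stage_time",
    "ground_truth_frame",
]

_AXIS_UNIT = {"a-p": (1.0, 0.0, 0.0), "l-r": (0.0, 1.0, 0.0), "d-v": (0.0, 0.0, 1.0)}


@dataclass(frozen=True)
class SynthParams:
    """Generative parameters for one simulated reporter condition.

    Defaults are the wild-type SYS-1-like study condition: 350-cell stage,
    baseline ``mu`` = 40 a.u., posterior boost ``alpha`` = 60 a.u. (three
    noise SDs), per-cell noise ``sigma`` = 20 a.u., 10% multiplicative
    replicate scaling, ~5% of divisions on l-r/d-v axes, and ``gamma``
    calibrated so the planted cousin enrichment is a 74% HH-over-LH
    increase.  ``polarity`` is 'posterior-high' (SYS-1/WRM-1) or
    'anterior-high' (POP-1).  ``mode`` 'stable-lagged' switches to a
    POPTOP-like stable reporter that accumulates in descendants of cells
    whose consecutive-High depth reaches ``activation_depth``, visible only
    ``lag_minutes`` after activation.
    """

    stage: int = 350
    mu: float = 40.0
    alpha: float = 60.0
    gamma: float = 1.0 + 0.74 * (40.0 + 60.0) / 60.0  # planted 74% enrichment
    memory: int = 1
    sigma: float = 20.0
    embryo_scale_sd: float = 0.1
    lr_dv_fraction: float = 0.05
    reversed_divisions: tuple[str, ...] = ()
    polarity: str = "posterior-high"
    mode: str = "instant"
    lag_minutes: float = 30.0
    activation_depth: int = 2
    expr_level: float = 200.0
    alpha_early_factor: float = 1.0  # scales alpha for divisions before 28-cell stage
    base_cycle: float = 25.0
    cycle_jitter: float = 0.1
    with_positions: bool = False
    trace_points: int = 0
    trace_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.lag_minutes < 0:
            raise ValueError("lag_minutes must be >= 0")
        if self.memory not in (1, 2):
            raise ValueError("memory depth must be 1 or 2")
        if self.polarity not in ("posterior-high", "anterior-high"):
            raise ValueError(f"invalid polarity {self.polarity!r}")
        if self.mode not in ("instant", "stable-lagged"):
            raise ValueError(f"invalid mode {self.mode!r}")

    @property
    def high_char(self) -> str:
        return "p" if self.polarity == "posterior-high" else "a"


def expected_percent_increase(params: SynthParams) -> float:
    """Closed-form planted HH-over-LH percent increase (memory 1, no noise):
    ``100 * alpha * (gamma - 1) / (mu + alpha)``."""
    return 100.0 * params.alpha * (params.gamma - 1.0) / (params.mu + params.alpha)


def make_tree(
    stage: int,
    seed: int,
    base_cycle: float = 25.0,
    cycle_jitter: float = 0.1,
    lr_dv_fraction: float = 0.0,
    embryo_id: str = "",
) -> LineageTree:
    """Canonical lineage skeleton expanded from P0 to ``stage`` live cells.

    Cells divide in birth-time order with cycle lengths jittered around
    ``base_cycle`` minutes; the early P0..P4 cleavages follow the fixed
    founder table and Z2/Z3 (germline) never divide.  A configurable
    fraction of later divisions is assigned to the l-r or d-v axis.
    Deterministic for a given seed.
    """
    if not (4 <= stage <= 600):
        raise ValueError("stage must be between 4 and 600 cells")
    rng = np.random.default_rng(seed)
    tree = LineageTree(embryo_id=embryo_id)
    root = CellName("P0", "")
    tree.add(CellRecord(root, birth_time=0.0))
    # heap of (division_time, tiebreak, name)
    heap: list[tuple[float, str, CellName]] = []

    def schedule(cell: CellName, birth: float) -> None:
        if not cell.suffix and cell.founder in ("Z2", "Z3"):
            return
        cycle = base_cycle * (1.0 + cycle_jitter * rng.standard_normal())
        cycle = max(cycle, base_cycle * 0.3)
        heapq.heappush(heap, (birth + cycle, str(cell), cell))

    schedule(root, 0.0)
    alive = 1
    while alive < stage and heap:
        t, _, cell = heapq.heappop(heap)
        if cell.suffix or cell.founder not in EARLY_DAUGHTERS:
            axis = "a-p"
            if cell.suffix and rng.random() < lr_dv_fraction:
                axis = "l-r" if rng.random() < 0.5 else "d-v"
        else:
            axis = "a-p"
        d1, d2 = daughters_of(cell, axis)
        tree.cells[cell].end_time = t
        for d in (d1, d2):
            tree.add(CellRecord(d, birth_time=t))
            schedule(d, t)
        alive += 1
    # undivided leaves observed to the end of the recording
    t_end = max((rec.birth_time for rec in tree.cells.values()), default=0.0) + base_cycle
    for rec in tree.cells.values():
        if math.isnan(rec.end_time):
            rec.end_time = t_end
    return tree


def stage_at(tree: LineageTree, time: float) -> int:
    """Number of cells alive at ``time``: 1 + divisions completed before it."""
    return 1 + sum(
        1 for rec in tree.cells.values()
        if rec.end_time < time and len(tree.daughters(rec.cell)) == 2
    )


def stage_time(tree: LineageTree, n_cells: int) -> float:
    """Time at which the embryo first reaches ``n_cells`` live cells
    (the (n-1)th division time); inf if never reached."""
    if n_cells <= 1:
        return 0.0
    div_times = sorted(
        rec.end_time for rec in tree.cells.values()
        if len(tree.daughters(rec.cell)) == 2
    )
    if len(div_times) < n_cells - 1:
        return float("inf")
    return div_times[n_cells - 2]


def _twentyeight_cell_time(tree: LineageTree) -> float:
    return stage_time(tree, 28)


def _assign_truth(
    tree: LineageTree, params: SynthParams, rng: np.random.Generator
) -> dict[CellName, dict]:
    """Per-cell ground truth: High/Low at birth, consecutive-High depth."""
    hc = params.high_char
    reversed_set = {str(parse_name(r)) for r in params.reversed_divisions}
    truth: dict[CellName, dict] = {}
    for name in sorted(tree.cells, key=lambda n: (n.depth, n)):
        parent = tree.parent(name)
        if parent is None:
            truth[name] = {"high": None, "depth": 0}
            continue
        sibs = tree.daughters(parent)
        if len(sibs) != 2:
            truth[name] = {"high": None, "depth": 0}
            continue
        # designated High daughter: the one with the reporter's polarity
        # character (a-p axes) or the second-listed daughter (l-r, d-v);
        # reversed divisions swap the designation
        if name.suffix and name.suffix[-1] in ("a", "p"):
            high = name.suffix[-1] == hc
        elif name.suffix:
            high = name == sibs[1]
        else:  # founder division: second-listed daughter is posterior-equivalent
            high = (name == sibs[1]) == (hc == "p")
        if str(parent) in reversed_set:
            high = not high
        pdepth = truth[parent]["depth"]
        depth = (pdepth + 1) if high else 0
        truth[name] = {"high": high, "depth": depth}
    return truth


def simulate_reporter(
    skeleton: LineageTree,
    params: SynthParams,
    seed: int,
    reporter: str = "Venus::SYS-1",
    condition: str = "wild type",
    cell_scale: Optional[dict[CellName, float]] = None,
    division_effect: Optional[dict[CellName, float]] = None,
) -> tuple[LineageTree, pd.DataFrame]:
    """Populate a skeleton with reporter blot values.

    Returns the measured tree and a per-cell ground-truth frame (columns
    ``cell, high, depth, true_mean, activated, initiating``).  Instant mode
    draws concentrations from the generative model in the module docstring;
    stable-lagged mode instead gives ``expr_level`` to every cell born at
    least ``lag_minutes`` after an activating ancestor (consecutive-High
    depth >= ``activation_depth``) and baseline noise to everything else.

    ``cell_scale`` optionally multiplies each cell's mean by a shared latent
    factor (detection/size variation); passing the same map to two reporters
    couples their per-cell signals, as co-measured reporters are in vivo.
    ``division_effect`` (keyed by division parent) multiplies the boost
    ``alpha`` at that division; sharing it between reporters plants a
    cross-reporter correlation of per-division asymmetries.
    """
    rng = np.random.default_rng(seed)
    truth = _assign_truth(skeleton, params, rng)
    scale = float(np.exp(params.embryo_scale_sd * rng.standard_normal())) \
        if params.embryo_scale_sd > 0 else 1.0
    t28 = _twentyeight_cell_time(skeleton)

    # activation truth for the stable-lagged mode
    activation_time: dict[CellName, Optional[float]] = {}
    activator: dict[CellName, Optional[CellName]] = {}
    initiating: set[CellName] = set()
    if params.mode == "stable-lagged":
        for name in sorted(skeleton.cells, key=lambda n: (n.depth, n)):
            parent = skeleton.parent(name)
            inherited = activation_time.get(parent) if parent is not None else None
            if inherited is not None:
                activation_time[name] = inherited
                activator[name] = activator[parent]
            elif truth[name]["depth"] >= params.activation_depth:
                activation_time[name] = skeleton.cells[name].birth_time
                activator[name] = name
            else:
                activation_time[name] = None
                activator[name] = None
        # an activation counts as initiating only if it becomes visible:
        # some cell of the clade is born after the maturation lag
        for name, at in activation_time.items():
            if at is None:
                continue
            if skeleton.cells[name].birth_time >= at + params.lag_minutes:
                initiating.add(activator[name])

    tree = LineageTree(
        embryo_id=skeleton.embryo_id, reporter=reporter, condition=condition
    )
    rows = []
    for name in sorted(skeleton.cells, key=lambda n: (n.depth, n)):
        src = skeleton.cells[name]
        rec = CellRecord(
            name, birth_time=src.birth_time, end_time=src.end_time
        )
        high = truth[name]["high"]
        depth = truth[name]["depth"]
        if params.mode == "instant":
            alpha = params.alpha
            if src.birth_time <= t28:
                alpha = alpha * params.alpha_early_factor
            parent = skeleton.parent(name)
            if division_effect is not None and parent is not None:
                alpha = alpha * division_effect.get(parent, 1.0)
            if high is None:
                mean = params.mu
            elif high:
                m = min(max(depth - 1, 0), params.memory)
                mean = params.mu + alpha * params.gamma**m
            else:
                mean = params.mu - alpha / 2.0
        else:
            at = activation_time[name]
            expressing = at is not None and src.birth_time >= at + params.lag_minutes
            mean = params.expr_level if expressing else 0.0
        if cell_scale is not None:
            mean = mean * cell_scale.get(name, 1.0)
        noise = params.sigma * rng.standard_normal()
        rec.blot = scale * mean + noise
        if params.trace_points > 0:
            dur = max(src.end_time - src.birth_time, 1.0)
            times = np.linspace(src.birth_time, src.end_time, params.trace_points)
            mid = (src.birth_time + src.end_time) / 2.0
            rec.trace = [
                (float(t), rec.blot + params.trace_slope * (t - mid)) for t in times
            ]
        tree.add(rec)
        rows.append(
            {
                "cell": str(name),
                "high": "" if high is None else ("H" if high else "L"),
                "depth": depth,
                "true_mean": scale * mean,
                "activated": name in activation_time and activation_time[name] is not None,
                "initiating": name in initiating,
            }
        )
    if params.with_positions:
        _add_positions(tree, rng)
    return tree, pd.DataFrame(rows)


def _add_positions(tree: LineageTree, rng: np.random.Generator) -> None:
    """Birth positions accumulated along division axes with angular noise."""
    for name in sorted(tree.cells, key=lambda n: (n.depth, n)):
        rec = tree.cells[name]
        parent = tree.parent(name)
        if parent is None:
            rec.pos_birth = (0.0, 0.0, 0.0)
            continue
        sibs = tree.daughters(parent)
        if name.suffix:
            axis = {"a": "a-p", "p": "a-p", "l": "l-r", "r": "l-r",
                    "d": "d-v", "v": "d-v"}[name.suffix[-1]]
        else:
            axis = "a-p"
        unit = np.array(_AXIS_UNIT[axis])
        sign = 1.0 if (len(sibs) == 2 and name == sibs[1]) else -1.0
        offset = sign * unit * 2.0 + 0.3 * rng.standard_normal(3)
        ppos = np.array(tree.cells[parent].pos_birth or (0.0, 0.0, 0.0))
        rec.pos_birth = tuple(float(x) for x in ppos + offset)


def simulate_reporter_pair(
    skeleton: LineageTree,
    sys_params: SynthParams,
    pop_params: SynthParams,
    seed: int,
    cell_scale_sd: float = 0.3,
    division_effect_sd: float = 0.25,
) -> tuple[tuple[LineageTree, pd.DataFrame], tuple[LineageTree, pd.DataFrame]]:
    """Two reporters measured over one skeleton with shared latents.

    The reporters share the lineage (hence the same division structure and,
    when polarities oppose, opposite High/Low designations), a common
    per-cell lognormal latent scale (SD ``cell_scale_sd``; makes signals
    covary within a history class so the best-fit slope of one
    concentration against the other estimates that class's mean ratio) and
    a common per-division lognormal boost effect (SD ``division_effect_sd``;
    plants a cross-reporter correlation of per-division asymmetries), while
    measurement noise stays independent — emulating joint SYS-1/POP-1 or
    SYS-1/WRM-1 analyses.
    """
    rng = np.random.default_rng(seed)
    scale = None
    if cell_scale_sd > 0:
        scale = {
            name: float(np.exp(cell_scale_sd * rng.standard_normal()))
            for name in sorted(skeleton.cells)
        }
    effects = None
    if division_effect_sd > 0:
        effects = {
            name: float(np.exp(division_effect_sd * rng.standard_normal()))
            for name in sorted(skeleton.cells)
            if len(skeleton.daughters(name)) == 2
        }
    sys_out = simulate_reporter(
        skeleton, sys_params, seed + 10_000, reporter="Venus::SYS-1",
        cell_scale=scale, division_effect=effects,
    )
    pop_out = simulate_reporter(
        skeleton, pop_params, seed + 20_000, reporter="GFP::POP-1",
        cell_scale=scale, division_effect=effects,
    )
    return sys_out, pop_out


def simulate_dataset(
    params: SynthParams,
    n_embryos: int,
    seed: int,
    outdir: Optional[str | Path] = None,
    reporter: str = "Venus::SYS-1",
    condition: str = "wild type",
    dialect: TableDialect = TableDialect(),
) -> tuple[list[LineageTree], pd.DataFrame, Optional[Path]]:
    """Simulate a replicate group of embryos, optionally written to disk.

    Every embryo shares the same skeleton parameters but has its own seed
    (spawned deterministically from ``seed``), its own lognormal scale and
    noise.  When ``outdir`` is given, writes one per-cell table per embryo
    in the standard dialect, a ``manifest.csv`` and a ``ground_truth.tsv``
    sidecar, and returns the manifest path; regeneration with the same seed
    is byte-identical.
    """
    if n_embryos < 1:
        raise ValueError("need n_embryos >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_embryos)
    trees: list[LineageTree] = []
    truths = []
    for i in range(n_embryos):
        skel = make_tree(
            params.stage,
            seed=int(seeds[2 * i] % (2**31)),
            base_cycle=params.base_cycle,
            cycle_jitter=params.cycle_jitter,
            lr_dv_fraction=params.lr_dv_fraction,
            embryo_id=f"emb{i + 1:02d}",
        )
        tree, truth = simulate_reporter(
            skel,
            params,
            seed=int(seeds[2 * i + 1] % (2**31)),
            reporter=reporter,
            condition=condition,
        )
        truth.insert(0, "embryo_id", tree.embryo_id)
        trees.append(tree)
        truths.append(truth)
    truth_all = pd.concat(truths, ignore_index=True)

    manifest_path = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifests = []
        for tree in trees:
            fname = f"{tree.embryo_id}.csv"
            write_cell_table(tree.cells.values(), outdir / fname, dialect)
            manifests.append(
                EmbryoManifest(
                    embryo_id=tree.embryo_id,
                    path=fname,
                    strain="synthetic",
                    reporter=reporter,
                    condition=condition,
                )
            )
        manifest_path = outdir / "manifest.csv"
        write_manifest(manifests, manifest_path)
        truth_all.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return trees, truth_all, manifest_path


def ground_truth_frame(truth: pd.DataFrame) -> pd.DataFrame:
    """Convenience view: one row per (embryo, cell) with H/L and depth."""
    return truth[["embryo_id", "cell", "high", "depth", "true_mean"]].copy()
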