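#!/usr/bin/env python
"""Flexibility profiling of the parent/mutant toy complexes.

Computes block-averaged RMSF per bead, radius-of-gyration series, and the
interface salt-bridge distance distribution, writing tables under
results/flexibility/. The headline observation: the mutant's planted
tighter salt bridge shows up as a shifted distance distribution with much
higher occupancy below 0.45 nm, at unchanged overall flexibility.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mdnetics.core import select
from mdnetics.flexibility import residue_pair_distances, rg_series, rmsf_blocked
from mdnetics.pipeline import RunConfig, _toy_systems

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/flexibility"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

cfg = RunConfig(seed=args.seed)
systems = _toy_systems(cfg)

rows, dist_rows = [], []
for name, (top, ens) in systems.items():
    sel = select(top, "all")
    prof = rmsf_blocked(ens, sel, block_ns=cfg.flexibility["block_ns"])
    for r, v, e in zip(prof.residue_indices, prof.rmsf, prof.rmsf_sem):
        rows.append((name, int(r), top.residue_label(int(r)), v, e))
    rg = rg_series(ens, sel)
    series = residue_pair_distances(ens, 0, 3, threshold=0.45)
    for rep_i, d in enumerate(series.per_replica_distances):
        for v in d:
            dist_rows.append((name, rep_i + 1, v))
    print(f"{name}: mean Rg {np.mean([s.mean() for s in rg]):.4f} nm; "
          f"salt-bridge occupancy (<= 0.45 nm) {series.occupancy:.3f}")

pd.DataFrame(rows, columns=["system", "residue", "label", "rmsf_nm", "sem_nm"]) \
    .to_csv(args.outdir / "rmsf.csv", index=False)
pd.DataFrame(dist_rows, columns=["system", "replica", "distance_nm"]) \
    .to_csv(args.outdir / "salt_bridge_distances.csv", index=False)
print(f"wrote {args.outdir}/rmsf.csv and salt_bridge_distances.csv")
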