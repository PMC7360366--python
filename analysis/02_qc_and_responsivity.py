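"""Unit stability QC and per cell-odor responsivity across brain states.

Loads the saved sessions (run 01_simulate_sessions.py first, or this
script regenerates them), applies the cross-state stability criteria,
computes auROC response indices with rank-sum significance over the
first sniff, classifies robust vs state-specific responses, and
summarizes lifetime/population sparseness with bootstrap confidence
intervals.
"""

from pathlib import Path

import numpy as np

import odorstate as od
from odorstate import pipeline as pl

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "analysis"
SEED = 11


def load_or_simulate(profile: str, seed: int):
    sdir = ROOT / "sessions" / profile
    if sdir.exists():
        bundle, _ = od.load_session(sdir)
        return bundle
    bundle, _ = od.generate_session(od.SimConfig(n_cells_per_region=60),
                                    profile, seed=seed)
    return bundle


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, profile in enumerate(("ob", "pcx")):
        bundle = load_or_simulate(profile, SEED + i)
        qc = od.apply_stability_criteria(bundle.units)
        feats = od.extract_features(bundle)
        res = pl.stage_responsivity(feats)
        table, cross = res["table"], res["cross_state"]
        table.to_csv(OUT / f"{profile}_responsivity.csv", index=False)
        cross.to_csv(OUT / f"{profile}_cross_state_labels.csv", index=False)
        spars = pl.stage_sparseness(feats)
        spars.to_csv(OUT / f"{profile}_sparseness.csv", index=False)

        print(f"\n== {profile} ==")
        print(f"QC: {int((~qc.keep).sum())}/{len(qc)} units discarded")
        for state in ("awake", "kx"):
            sub = table[table.state == state]
            act = (sub["class"] == "activated").mean()
            sup = (sub["class"] == "suppressed").mean()
            print(f"  {state:5s}: {act:.1%} activated, {sup:.1%} suppressed "
                  f"(n={len(sub)} cell-odor pairs)")
        print(f"  robust (activated in both states): "
              f"{(cross.label == 'robust').mean():.1%}")
        # bootstrap contrast of the activated fraction across states
        per_cell = table.pivot_table(index="unit_id", columns="state",
                                     values="class",
                                     aggfunc=lambda c: (c == "activated").mean())
        bt = od.bootstrap_difference_test(per_cell["awake"], per_cell["kx"],
                                          seed=SEED)
        print(f"  awake-vs-k/x activated fraction: "
              f"diff={bt['difference']:+.3f}, bootstrap p={bt['p']:.3f}")
        lt = spars[spars.kind == "lifetime"]
        print("  lifetime sparseness: " + ", ".join(
            f"{s} {lt.loc[lt.state == s, 'sparseness'].mean():.3f}"
            for s in ("awake", "kx")))


if __name__ == "__main__":
    main()
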