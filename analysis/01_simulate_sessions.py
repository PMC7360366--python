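"""Simulate one ground-truthed session per region profile and save the
bundles to disk.

The three profiles encode the circuit hypotheses under study: "ob"
(olfactory bulb: odor responses largely awake-specific), "pcx" (piriform
cortex: a robust core of responses preserved under ketamine/xylazine),
and "telc" (piriform with recurrent output blocked: PCx-like feedforward
input, no robust amplification, no trial-by-trial stabilization).
"""

from pathlib import Path

import odorstate as od

OUT = Path(__file__).resolve().parents[1] / "results" / "sessions"
SEED = 11


def main() -> None:
    cfg = od.SimConfig(n_cells_per_region=60)
    for i, profile in enumerate(("ob", "pcx", "telc")):
        bundle, gt = od.generate_session(cfg, profile, seed=SEED + i)
        outdir = od.save_session(bundle, OUT / profile, ground_truth=gt)
        n_spikes = sum(len(s) for s in bundle.spikes.values())
        frac_responsive = (gt.cell_odor["class"] != "none").mean()
        print(f"{profile:5s}: {len(bundle.unit_ids)} units, "
              f"{len(bundle.trials)} trials, {n_spikes} spikes, "
              f"{frac_responsive:.0%} of cell-odor pairs responsive "
              f"-> {outdir}")
    print("\nEach directory holds manifest.json, spikes.csv, trials.csv, "
          "respiration.csv and ground_truth.json.")


if __name__ == "__main__":
    main()
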