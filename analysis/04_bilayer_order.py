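#!/usr/bin/env python
"""Chain order vs. diplopterol concentration in toy Δ9 / Δ11 bilayers.

Generates toy bilayers at the four simulated compositions (95:5, 85:15,
70:30, 50:50 PC:Dpop) with prescribed per-carbon order parameters whose
plateau rises with Dpop content — more steeply for Δ11 than for Δ9 —
and recovers the S_CD profile and plateau through the trajectory analysis.
Writes results/bilayer_order.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from terpord import synth, trajectory as tj
from terpord.topology import load_topology

# prescribed plateau S_CD per composition: Dpop orders the Δ11 chain more
# effectively than Δ9 at every concentration
PLATEAU_TARGETS = {
    "D9PC": {"95:5": 0.160, "85:15": 0.170, "70:30": 0.182, "50:50": 0.196},
    "D11PC": {"95:5": 0.165, "85:15": 0.190, "70:30": 0.220, "50:50": 0.250},
}


def profile_for(chain, plateau_target):
    """Scale the default decaying shape so the carbon 4-8 mean hits the target."""
    shape = {k: max(0.1, 1.0 - 0.055 * abs(k - 6)) for k in chain.indices}
    plateau_shape = sum(shape[k] for k in range(4, 9)) / 5.0
    return {k: plateau_target * shape[k] / plateau_shape for k in chain.indices}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--lipids", type=int, default=50, help="Per leaflet.")
    parser.add_argument("--frames", type=int, default=10)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    registry = load_topology()
    rows = []
    for pc, by_comp in PLATEAU_TARGETS.items():
        chain = registry.chain_for(pc)
        for comp, target in by_comp.items():
            model = synth.bilayer_preset(
                "dpop_" + pc[:-2].lower(), composition=comp, seed=args.seed,
                n_lipids_per_leaflet=args.lipids,
                target_scd=profile_for(chain, target),
            )
            frames = synth.gen_bilayer(model, n_frames=args.frames)
            prof = tj.scd_profile(frames, pc, chain)
            rows.append({"pc_isomer": pc, "composition": comp,
                         "dpop_fraction": model.sterol_fraction,
                         "plateau_scd": prof.plateau, "target_plateau": target})

    table = pd.DataFrame(rows)
    out = args.out / "bilayer_order.csv"
    table.to_csv(out, index=False)
    print(table.round(4).to_string(index=False))
    print("\nPlateau S_CD (carbons 4-8) rises with Dpop content and is higher")
    print(f"for Δ11 than Δ9 at matched composition. Wrote {out}")


if __name__ == "__main__":
    main()
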