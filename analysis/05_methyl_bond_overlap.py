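#!/usr/bin/env python
"""Where do PC double bonds sit relative to diplopterol's methyl groups?

Generates toy Δ9 and Δ11 bilayers with Dpop, builds one-sided z-histograms
(bin width 0.87 Å) of each Dpop methyl group M1-M6 and of the PC
double-bond midpoint, and quantifies their colocalization with the overlap
coefficient Σ min(p₁, p₂)·Δz. Writes results/methyl_bond_overlap.csv.

Under the default geometry the Δ9 bond (|z| ≈ 8.5 Å) coincides with methyl
M2, while the Δ11 bond (≈ 6.5 Å) falls between M3 and M4 — the packing
picture behind diplopterol's isomer-selective condensation.
"""

import argparse
from pathlib import Path

import pandas as pd

from terpord import synth, trajectory as tj
from terpord.topology import load_topology


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--lipids", type=int, default=60, help="Per leaflet.")
    parser.add_argument("--frames", type=int, default=20)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    registry = load_topology()
    rows = []
    for pc in ("D9PC", "D11PC"):
        model = synth.bilayer_preset(
            "dpop_" + pc[:-2].lower(), composition="70:30", seed=args.seed,
            n_lipids_per_leaflet=args.lipids,
        )
        frames = synth.gen_bilayer(model, n_frames=args.frames)
        chain = registry.chain_for(pc)
        h_bond = tj.double_bond_positions(frames, pc, chain)
        for label, atom in registry.sterol_for("DPOP").methyls.items():
            h_methyl = tj.z_distribution(frames, "DPOP", [atom])
            rows.append({
                "pc_isomer": pc, "methyl": label,
                "methyl_mean_z_A": h_methyl.mean(),
                "bond_mean_z_A": h_bond.mean(),
                "overlap": tj.overlap_coefficient(h_methyl, h_bond),
            })

    table = pd.DataFrame(rows)
    out = args.out / "methyl_bond_overlap.csv"
    table.to_csv(out, index=False)
    print(table.round(3).to_string(index=False))
    best = table.loc[table.groupby("pc_isomer")["overlap"].idxmax()]
    print("\nHighest-overlap methyl per isomer:")
    print(best[["pc_isomer", "methyl", "overlap"]].round(3).to_string(index=False))
    print(f"Wrote {out}")


if __name__ == "__main__":
    main()
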