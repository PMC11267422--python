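#!/usr/bin/env python
"""Condensation effect of cholesterol and diplopterol on PC isomer films.

Generates calibrated isotherm replicates for the three PC double-bond
isomers (noiseless MMA at 30 mN/m: 65.3 / 66.0 / 64.3 Å²/molecule for
Δ6 / Δ9 / Δ11) plus pure terpenoid films, builds 2:1 PC:terpenoid binary
mixtures with an injected excess area encoding the expected interaction
pattern, and computes the condensation effect at 30 mN/m with propagated
uncertainty. Writes results/monolayer_condensation.csv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from terpord import monolayer as ml
from terpord import synth

# injected excess area at 30 mN/m (Å²/molecule): cholesterol condenses all
# three isomers increasingly as the bond moves from the headgroup; diplopterol
# leaves Δ6 ideal, expands Δ9, and condenses only Δ11
EXCESS = {
    ("chol", "d6pc"): -2.0,
    ("chol", "d9pc"): -2.5,
    ("chol", "d11pc"): -3.0,
    ("dpop", "d6pc"): 0.0,
    ("dpop", "d9pc"): +1.5,
    ("dpop", "d11pc"): -2.0,
}

TERPENOID_MMA_30 = {"chol": 38.0, "dpop": 40.0}


def terpenoid_model(name: str, seed: int) -> synth.IsothermModel:
    c1, c2 = -0.45, 0.004
    c0 = TERPENOID_MMA_30[name] - (c1 * 30.0 + c2 * 900.0)
    return synth.IsothermModel(name, c0, c1, c2, noise_sd=0.3, n_replicates=3, seed=seed)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    warnings.simplefilter("ignore", UserWarning)  # noisy replicates wiggle
    pc_models = synth.reference_isotherm_models(noise_sd=0.3, seed=args.seed)
    rows = []
    for (terp, pc), d_area in EXCESS.items():
        mix = ml.MixtureSpec((pc, terp), (2 / 3, 1 / 3))
        t_model = terpenoid_model(terp, args.seed + {"chol": 11, "dpop": 22}[terp])
        excess = synth.MixtureExcessModel("constant", amplitude=d_area)
        reps, meta = synth.gen_mixture_isotherm(
            pc_models[pc], t_model, mix, excess,
            noise_sd=0.3, n_replicates=3, seed=args.seed + 77,
        )
        a0 = ml.mma_at_pressure(ml.mean_isotherm(reps), 30.0)
        a1 = ml.mma_at_pressure(ml.mean_isotherm(synth.gen_isotherms(pc_models[pc])), 30.0)
        a2 = ml.mma_at_pressure(ml.mean_isotherm(synth.gen_isotherms(t_model)), 30.0)
        res = ml.condensation_effect(a0, a1, a2, mix)
        i30 = int((meta["pressures"] == 30.0).argmax())
        rows.append({
            "terpenoid": terp, "pc_isomer": pc,
            "condensation_pct": res.c, "sd_pct": res.sd,
            "true_condensation_pct": meta["true_condensation_pct"][i30],
            "mma_mixture": a0.value, "mma_pc": a1.value, "mma_terpenoid": a2.value,
        })

    table = pd.DataFrame(rows)
    out = args.out / "monolayer_condensation.csv"
    table.to_csv(out, index=False)
    print(table.round(3).to_string(index=False))
    print(f"\nCholesterol condenses every isomer (c > 0, growing Δ6→Δ11);")
    print("diplopterol expands the Δ9 film (c < 0), is near-ideal with Δ6,")
    print(f"and condenses only Δ11 — recovered within noise. Wrote {out}")


if __name__ == "__main__":
    main()
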