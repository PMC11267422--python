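# Atom-naming registry for chain and ring-lipid topologies.
#
# Chains may be given compactly (last_carbon + double_bond + naming scheme,
# expanded in code) or as an explicit `carbons:` list of
# {index, name, hydrogens} entries for force fields with other conventions.
# Chain carbon numbers count from 2 (the carbon alpha to the carbonyl);
# a Δn double bond joins carbons n and n+1, which carry one olefinic
# hydrogen each.
#
# Sterol/hopanoid entries name the hydroxyl oxygen (o3), the tail atom
# defining the orientation vector (c24), and map methyl labels to atom
# names. The mapping of ring methyls to M1..M6 labels is editable here:
# the defaults use literal M* atom names as emitted by the toy generator;
# for force-field trajectories, point the labels at the real methyl carbon
# names (e.g. C18/C19 on cholesterol).

chains:
  "18:1d6":
    chain: sn-2
    carbon_prefix: "2"
    last_carbon: 18
    double_bond: [6, 7]
  "18:1d9":
    chain: sn-2
    carbon_prefix: "2"
    last_carbon: 18
    double_bond: [9, 10]
  "18:1d11":
    chain: sn-2
    carbon_prefix: "2"
    last_carbon: 18
    double_bond: [11, 12]
  "16:0":
    chain: sn-1
    carbon_prefix: "3"
    last_carbon: 16
    hydrogen_suffixes: [X, Y, Z]

sterols:
  CHL1:
    o3: O3
    c24: C24
    methyls: {M1: M1, M2: M2}
  DPOP:
    o3: O3
    c24: C24
    methyls: {M1: M1, M2: M2, M3: M3, M4: M4, M5: M5, M6: M6}

species:
  D6PC:
    kind: phospholipid
    chains: ["18:1d6"]
  D9PC:
    kind: phospholipid
    chains: ["18:1d9"]
  D11PC:
    kind: phospholipid
    chains: ["18:1d11"]
  POPC:
    kind: phospholipid
    chains: ["16:0", "18:1d9"]
  CHL1:
    kind: sterol
    sterol: CHL1
  DPOP:
    kind: sterol
    sterol: DPOP
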