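"""Chain and sterol/hopanoid topologies: which atoms form each acyl chain,
where its double bond sits, and which atoms anchor a ring lipid.

Topologies are loaded from a YAML registry (a copy ships with the package,
see :data:`DEFAULT_TOPOLOGY_FILE`) so that atom naming can be adapted to any
force field without touching code. A chain entry may either spell out every
carbon with its bonded hydrogens, or give a compact naming scheme that is
expanded here (carbon ``C{prefix}{k}`` for chain carbon number ``k``,
two hydrogens per methylene, one per olefinic carbon, three on the terminal
methyl).

Carbon numbering follows the acyl-chain convention: the carbonyl carbon is
C1, so the first chain carbon carrying hydrogens is number 2, and a Δn
double bond joins carbons n and n+1.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .errors import TerpordError

DEFAULT_TOPOLOGY_FILE = "topology.yaml"


@dataclass(frozen=True)
class CarbonSite:
    index: int  # chain carbon number (2 = alpha to the carbonyl)
    name: str  # atom name in coordinate files
    hydrogens: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.hydrogens) <= 3:
            raise TerpordError(
                f"carbon {self.name}: expected 1-3 hydrogens, got {self.hydrogens}"
            )


@dataclass(frozen=True)
class ChainTopology:
    """One acyl chain: ordered carbons, their hydrogens, the double bond."""

    key: str
    chain_label: str  # "sn-1" | "sn-2"
    carbons: tuple[CarbonSite, ...]
    double_bond: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        idx = [c.index for c in self.carbons]
        if idx != list(range(2, 2 + len(idx))):
            raise TerpordError(
                f"chain {self.key}: carbon numbers must be contiguous from 2, got {idx}"
            )
        if self.double_bond is not None:
            i, j = self.double_bond
            if j != i + 1 or i not in idx or j not in idx:
                raise TerpordError(
                    f"chain {self.key}: double bond {self.double_bond} must join "
                    "adjacent declared carbons"
                )

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(c.index for c in self.carbons)

    def carbon(self, index: int) -> CarbonSite:
        for c in self.carbons:
            if c.index == index:
                return c
        raise TerpordError(f"chain {self.key} has no carbon number {index}")


@dataclass(frozen=True)
class SterolTopology:
    """Ring lipid (sterol or hopanoid) anchor atoms and methyl labels."""

    key: str
    o3: str  # hydroxyl oxygen, headgroup-side anchor
    c24: str  # tail-side atom; O3-C24 defines the orientation vector
    methyls: dict[str, str]  # label (M1...) -> atom name


@dataclass(frozen=True)
class SpeciesInfo:
    resname: str
    kind: str  # "phospholipid" | "sterol"
    chains: tuple[str, ...] = ()  # chain topology keys (phospholipid)
    sterol: str | None = None  # sterol topology key


@dataclass(frozen=True)
class TopologyRegistry:
    chains: dict[str, ChainTopology]
    sterols: dict[str, SterolTopology]
    species: dict[str, SpeciesInfo]

    def chain_for(self, species: str, chain: str | None = None) -> ChainTopology:
        """Resolve the chain topology for a phospholipid species.

        ``chain`` may be a chain key or an sn-label; defaults to the
        species' first declared chain.
        """
        info = self.species_info(species)
        if info.kind != "phospholipid":
            raise TerpordError(f"{species} is not a phospholipid")
        if chain is None:
            return self.chains[info.chains[0]]
        if chain in self.chains and chain in info.chains:
            return self.chains[chain]
        for key in info.chains:
            if self.chains[key].chain_label == chain:
                return self.chains[key]
        raise TerpordError(f"species {species} has no chain {chain!r}")

    def sterol_for(self, species: str) -> SterolTopology:
        info = self.species_info(species)
        if info.kind != "sterol" or info.sterol is None:
            raise TerpordError(f"{species} is not a sterol/hopanoid species")
        return self.sterols[info.sterol]

    def species_info(self, species: str) -> SpeciesInfo:
        try:
            return self.species[species]
        except KeyError:
            raise TerpordError(
                f"unknown species {species!r}; known: {sorted(self.species)}"
            ) from None


def _expand_chain(key: str, entry: dict) -> ChainTopology:
    label = entry.get("chain", "sn-2")
    db = entry.get("double_bond")
    db = tuple(db) if db else None
    if "carbons" in entry:
        carbons = tuple(
            CarbonSite(int(c["index"]), str(c["name"]), tuple(c["hydrogens"]))
            for c in entry["carbons"]
        )
        return ChainTopology(key, label, carbons, db)
    # compact scheme: generate names C{prefix}{k} / H{k}{suffix}
    prefix = str(entry.get("carbon_prefix", "2"))
    h_suffixes = tuple(entry.get("hydrogen_suffixes", ["R", "S", "T"]))
    last = int(entry["last_carbon"])
    olefinic = set(db) if db else set()
    carbons = []
    for k in range(2, last + 1):
        if k in olefinic:
            hyds = (f"H{k}{h_suffixes[0]}",)
        elif k == last:
            hyds = tuple(f"H{k}{s}" for s in h_suffixes[:3])
        else:
            hyds = tuple(f"H{k}{s}" for s in h_suffixes[:2])
        carbons.append(CarbonSite(k, f"C{prefix}{k}", hyds))
    return ChainTopology(key, label, tuple(carbons), db)


def load_topology(path: str | Path | None = None) -> TopologyRegistry:
    """Load the topology registry from YAML (package default if no path)."""
    if path is None:
        text = (
            resources.files("terpord").joinpath("data", DEFAULT_TOPOLOGY_FILE).read_text()
        )
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    chains = {k: _expand_chain(k, v) for k, v in raw.get("chains", {}).items()}
    sterols = {
        k: SterolTopology(
            key=k,
            o3=str(v.get("o3", "O3")),
            c24=str(v.get("c24", "C24")),
            methyls={str(lbl): str(at) for lbl, at in v.get("methyls", {}).items()},
        )
        for k, v in raw.get("sterols", {}).items()
    }
    species = {}
    for resname, v in raw.get("species", {}).items():
        kind = v["kind"]
        info = SpeciesInfo(
            resname=resname,
            kind=kind,
            chains=tuple(v.get("chains", ())),
            sterol=v.get("sterol"),
        )
        for ck in info.chains:
            if ck not in chains:
                raise TerpordError(f"species {resname}: unknown chain {ck!r}")
        if kind == "sterol" and info.sterol not in sterols:
            raise TerpordError(f"species {resname}: unknown sterol {info.sterol!r}")
        species[resname] = info
    return TopologyRegistry(chains=chains, sterols=sterols, species=species)
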