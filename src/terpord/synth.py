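"""Synthetic-data generators with known ground truth.

Every input the analysis stages consume can be generated here: Langmuir
isotherm replicates for pure films and binary mixtures with an injected
excess area, toy bilayer frames whose order parameters, group z-positions
and tilt angles are prescribed exactly, and plate-reader growth/lysis
traces. The generators' metadata records the ground truth, which the test
suite uses as its oracle.

The toy bilayer realizes a target order parameter S at a carbon by placing
its C-H bond vectors at the exact polar angle φ solving ½(3cos²φ − 1) = S,
with uniform random azimuth about the membrane normal; the expected S_CD is
therefore exact by construction. This deliberately emulates only the
observables the analyses measure, not lipid conformational statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .assays import GrowthCurve, LysisSeries
from .errors import TerpordError
from .monolayer import Isotherm, MixtureSpec
from .topology import ChainTopology, TopologyRegistry, load_topology
from .trajectory import BilayerFrame

DEFAULT_PRESSURE_GRID = np.arange(0.5, 40.0 + 1e-9, 0.5)  # mN/m

#: Reference monolayer calibration: noiseless mean molecular area at
#: 30 mN/m equals 65.3 / 66.0 / 64.3 Å²/molecule for the Δ6-, Δ9- and
#: Δ11-PC isomers respectively (published monolayer values for these films).
REFERENCE_MMA_30 = {"d6pc": 65.3, "d9pc": 66.0, "d11pc": 64.3}


# ---------------------------------------------------------------------------
# Isotherms


@dataclass(frozen=True)
class IsothermModel:
    """Quadratic area law A(Π) = c0 + c1·Π + c2·Π² with Gaussian area noise.

    Valid over Π ∈ [0.5, 40] mN/m; the model must be positive and strictly
    compressing (dA/dΠ < 0) over that range.
    """

    name: str
    c0: float  # Å²/molecule
    c1: float  # Å²·m/(molecule·mN)
    c2: float  # Å²·m²/(molecule·mN²)
    noise_sd: float = 0.3  # Å²/molecule
    n_replicates: int = 3
    seed: int = 0
    pressure_grid: np.ndarray = field(
        default_factory=lambda: DEFAULT_PRESSURE_GRID.copy()
    )

    def __post_init__(self) -> None:
        p = np.asarray(self.pressure_grid, dtype=float)
        a = self.area(p)
        if np.any(a <= 0):
            raise TerpordError(f"{self.name}: A(Π) must be positive on the grid")
        slope = self.c1 + 2.0 * self.c2 * p
        if np.any(slope >= 0):
            raise TerpordError(f"{self.name}: A(Π) must be strictly decreasing")
        if self.noise_sd < 0:
            raise TerpordError("noise_sd must be non-negative")

    def area(self, pressure) -> np.ndarray:
        p = np.asarray(pressure, dtype=float)
        return self.c0 + self.c1 * p + self.c2 * p**2


def reference_isotherm_models(
    noise_sd: float = 0.3, n_replicates: int = 3, seed: int = 0
) -> dict[str, IsothermModel]:
    """Isotherm models for the three PC double-bond isomers, calibrated so
    the noiseless MMA at 30 mN/m reproduces the reference values
    (:data:`REFERENCE_MMA_30`)."""
    c1, c2 = -0.9, 0.008  # shared compressibility shape
    out = {}
    for i, (name, target) in enumerate(REFERENCE_MMA_30.items()):
        c0 = target - (c1 * 30.0 + c2 * 30.0**2)
        out[name] = IsothermModel(
            name=name, c0=c0, c1=c1, c2=c2, noise_sd=noise_sd,
            n_replicates=n_replicates, seed=seed + i,  # independent noise per film
        )
    return out


def gen_isotherms(model: IsothermModel) -> list[Isotherm]:
    """Replicate isotherms on the model grid with i.i.d. Gaussian area noise."""
    rng = np.random.default_rng(model.seed)
    p = np.asarray(model.pressure_grid, dtype=float)
    clean = model.area(p)
    composition = MixtureSpec((model.name,), (1.0,))
    out = []
    for i in range(model.n_replicates):
        noise = rng.normal(0.0, model.noise_sd, size=p.shape) if model.noise_sd else 0.0
        out.append(
            Isotherm(
                pressures=p.copy(),
                areas=clean + noise,
                replicate_id=f"{model.name}_rep{i + 1}",
                composition=composition,
            )
        )
    return out


@dataclass(frozen=True)
class MixtureExcessModel:
    """Ground-truth excess area ΔA(Π) injected into a synthetic mixture.

    ``kind``: ``zero``, ``constant`` (ΔA ≡ amplitude), or ``hump``
    (Gaussian bump amplitude·exp(−(Π−center)²/2width²)).
    """

    kind: str = "zero"
    amplitude: float = 0.0  # Å²/molecule
    center: float = 15.0  # mN/m
    width: float = 5.0  # mN/m

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "constant", "hump"):
            raise TerpordError(f"unknown excess kind {self.kind!r}")

    def __call__(self, pressure) -> np.ndarray:
        p = np.asarray(pressure, dtype=float)
        if self.kind == "zero":
            return np.zeros_like(p)
        if self.kind == "constant":
            return np.full_like(p, self.amplitude)
        return self.amplitude * np.exp(-((p - self.center) ** 2) / (2 * self.width**2))


def gen_mixture_isotherm(
    pure1: IsothermModel,
    pure2: IsothermModel,
    mix: MixtureSpec,
    excess: MixtureExcessModel,
    *,
    noise_sd: float = 0.3,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[list[Isotherm], dict]:
    """Binary-mixture isotherm A_mix = X₁A₁ + X₂A₂ + ΔA + noise.

    Returns the replicates and a metadata dict holding the noiseless
    ground truth, including the true condensation
    c(Π) = 100·(−ΔA)/(X₁A₁ + X₂A₂) on the grid.
    """
    p = np.asarray(pure1.pressure_grid, dtype=float)
    if not np.array_equal(p, np.asarray(pure2.pressure_grid, dtype=float)):
        raise TerpordError("pure components must share a pressure grid")
    ideal = mix.x1 * pure1.area(p) + mix.x2 * pure2.area(p)
    da = excess(p)
    if np.any(np.abs(da) > 0.2 * ideal):
        raise TerpordError("excess area exceeds 20% of the ideal area")
    clean = ideal + da
    if np.any(clean <= 0):
        raise TerpordError("excess area drives the mixture area non-positive")
    rng = np.random.default_rng(seed)
    reps = []
    for i in range(n_replicates):
        noise = rng.normal(0.0, noise_sd, size=p.shape) if noise_sd else 0.0
        reps.append(
            Isotherm(
                pressures=p.copy(),
                areas=clean + noise,
                replicate_id=f"mix_rep{i + 1}",
                composition=mix,
            )
        )
    meta = {
        "pressures": p,
        "ideal_area": ideal,
        "excess_area": da,
        "true_condensation_pct": 100.0 * (-da) / ideal,
        "mixture": mix,
    }
    return reps, meta


# ---------------------------------------------------------------------------
# Toy bilayer


#: Default |z| of the double-bond midpoint (mean, sd in Å) per chain key:
#: the Δ11 bond sits deeper (closer to the bilayer centre) than Δ9.
DEFAULT_DB_Z = {
    "18:1d6": (11.0, 1.2),
    "18:1d9": (8.5, 1.2),
    "18:1d11": (6.5, 1.2),
}

#: Default |z| (mean, sd in Å) of ring-lipid methyl groups.
DEFAULT_METHYL_Z = {
    "DPOP": {
        "M1": (12.5, 1.0), "M2": (8.5, 1.0), "M3": (7.2, 1.0),
        "M4": (5.8, 1.0), "M5": (4.5, 1.0), "M6": (3.2, 1.0),
    },
    "CHL1": {"M1": (9.5, 1.0), "M2": (8.0, 1.0)},
}


def _default_scd_profile(indices: Sequence[int]) -> dict[int, float]:
    # plateau-like: most ordered near carbons 4-8, melting toward the tail
    return {k: max(0.02, 0.22 - 0.012 * abs(k - 6)) for k in indices}


@dataclass(frozen=True)
class ToyBilayerModel:
    """Prescribes every observable of a toy planar bilayer.

    Defaults: 100 lipids per leaflet on a jittered lattice (a reduced-size
    stand-in for simulation-scale systems of ~550 per leaflet), sterol
    fraction 0.3, phosphate anchors at |z| = 20 Å, and per-carbon order
    targets with a plateau near carbons 4-8.
    """

    phospholipid: str = "D9PC"
    sterol: str | None = "DPOP"
    sterol_fraction: float = 0.3
    n_lipids_per_leaflet: int = 100
    box_xy: float | None = None  # Å; derived from the lattice if None
    lz: float = 100.0  # Å
    head_z: float = 20.0  # Å, anchor |z|
    tail_z: float = 4.0  # Å, |z| of the last chain carbon
    target_scd: float | Mapping[int, float] | None = None
    methyl_z: Mapping[str, tuple[float, float]] | None = None  # label -> (mean, sd)
    double_bond_z: tuple[float, float] | None = None  # (mean, sd) of |z| midpoint
    tilt_deg: tuple[float, float] = (15.0, 5.0)  # (mean, sd); sd 0 = fixed
    z_offset: float = 0.0  # rigid shift of the whole bilayer
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet < 4:
            raise TerpordError("need at least 4 lipids per leaflet")
        if not 0.0 <= self.sterol_fraction < 1.0:
            raise TerpordError("sterol_fraction must be in [0, 1)")
        if self.methyl_z is not None and any(sd <= 0 for _, sd in self.methyl_z.values()):
            raise TerpordError("methyl z sds must be positive")
        if self.double_bond_z is not None and self.double_bond_z[1] <= 0:
            raise TerpordError("double-bond z sd must be positive")


def _resolve_targets(
    model: ToyBilayerModel, chain: ChainTopology
) -> dict[int, float]:
    t = model.target_scd
    if t is None:
        targets = _default_scd_profile(chain.indices)
    elif isinstance(t, Mapping):
        targets = {int(k): float(v) for k, v in t.items()}
        missing = set(chain.indices) - set(targets)
        if missing:
            raise TerpordError(f"target_scd missing carbons {sorted(missing)}")
    else:
        targets = {k: float(t) for k in chain.indices}
    for k, s in targets.items():
        if not -0.5 <= s <= 1.0:
            raise TerpordError(f"target S_CD {s} at carbon {k} outside [-0.5, 1]")
    return targets


def _ch_polar_angle(s: float) -> float:
    """Polar angle φ (rad) with ½(3cos²φ − 1) = s."""
    return math.acos(math.sqrt((2.0 * s + 1.0) / 3.0))


def gen_bilayer(model: ToyBilayerModel, n_frames: int = 50,
                registry: TopologyRegistry | None = None) -> list[BilayerFrame]:
    """Generate toy bilayer frames realizing the model's observables.

    Residue identities, lattice sites and atom names are fixed across
    frames; positions, C-H azimuths, methyl/double-bond z draws and tilt
    draws are resampled each frame. Deterministic under the model seed.
    """
    registry = registry or load_topology()
    pc_info = registry.species_info(model.phospholipid)
    if pc_info.kind != "phospholipid":
        raise TerpordError(f"{model.phospholipid} is not a phospholipid species")
    chains = [registry.chains[k] for k in pc_info.chains]
    targets = {ch.key: _resolve_targets(model, ch) for ch in chains}

    sterol_top = None
    methyl_z: dict[str, tuple[float, float]] = {}
    if model.sterol is not None:
        sterol_top = registry.sterol_for(model.sterol)
        methyl_z = dict(
            model.methyl_z
            if model.methyl_z is not None
            else DEFAULT_METHYL_Z.get(model.sterol, {})
        )
        unknown = set(methyl_z) - set(sterol_top.methyls)
        if unknown:
            raise TerpordError(f"methyl labels {sorted(unknown)} not in topology")

    db_z: dict[str, tuple[float, float]] = {}
    for ch in chains:
        if ch.double_bond is not None:
            db_z[ch.key] = (
                model.double_bond_z
                if model.double_bond_z is not None
                else DEFAULT_DB_Z.get(ch.key, (8.0, 1.2))
            )

    n = model.n_lipids_per_leaflet
    side = math.ceil(math.sqrt(n))
    box_xy = model.box_xy if model.box_xy is not None else side * 8.0
    spacing = box_xy / side
    sites = np.array(
        [((i + 0.5) * spacing, (j + 0.5) * spacing) for i in range(side) for j in range(side)]
    )[:n]
    n_sterol = int(round(model.sterol_fraction * n)) if model.sterol else 0
    # evenly interleave sterols over lattice sites, fixed across frames
    sterol_flag = np.zeros(n, dtype=bool)
    if n_sterol:
        sterol_flag[np.linspace(0, n - 1, n_sterol).round().astype(int)] = True

    rng = np.random.default_rng(model.seed)
    box = np.array([box_xy, box_xy, model.lz])
    tilt_mean, tilt_sd = model.tilt_deg
    ch_bond = 1.09  # Å
    frames = []
    for _ in range(n_frames):
        resnames, resids, names, pos = [], [], [], []
        rid = 0
        for s in (+1, -1):
            for isite in range(n):
                rid += 1
                x0, y0 = sites[isite] + rng.uniform(-1.5, 1.5, size=2)
                if sterol_flag[isite]:
                    resname = model.sterol
                    atoms = _sterol_atoms(
                        sterol_top, methyl_z, x0, y0, s, model, tilt_mean, tilt_sd, rng
                    )
                else:
                    resname = model.phospholipid
                    atoms = _phospholipid_atoms(
                        chains, targets, db_z, x0, y0, s, model, ch_bond, rng
                    )
                for nm, xyz in atoms:
                    resnames.append(resname)
                    resids.append(rid)
                    names.append(nm)
                    pos.append(xyz)
        positions = np.asarray(pos, dtype=float)
        positions[:, 2] += model.z_offset
        # keep coordinates inside a box spanning z ∈ [-Lz/2, Lz/2]
        frames.append(
            BilayerFrame(
                box=box.copy(),
                resnames=np.array(resnames),
                resids=np.array(resids),
                names=np.array(names),
                positions=positions,
            )
        )
    return frames


def _phospholipid_atoms(chains, targets, db_z, x0, y0, s, model, ch_bond, rng):
    atoms = []
    atoms.append(("P", np.array([x0, y0, s * (model.head_z + rng.normal(0, 0.3))])))
    # glycerol reference triad, centroid exactly (x0, y0)
    ref_z = s * (model.head_z - 2.0)
    atoms.append(("C2", np.array([x0 + 0.5, y0, ref_z])))
    atoms.append(("C21", np.array([x0 - 0.25, y0 + 0.433, ref_z - 0.3 * s])))
    atoms.append(("C31", np.array([x0 - 0.25, y0 - 0.433, ref_z + 0.3 * s])))
    for ichain, chain in enumerate(chains):
        xoff = (ichain - (len(chains) - 1) / 2.0) * 2.0
        last = chain.indices[-1]
        drop = (model.head_z - 3.0 - model.tail_z) / max(last - 2, 1)
        db_mid = None
        if chain.double_bond is not None:
            mean, sd = db_z[chain.key]
            db_mid = rng.normal(mean, sd)
        for carbon in chain.carbons:
            k = carbon.index
            if chain.double_bond is not None and k in chain.double_bond:
                zabs = db_mid + (0.65 if k == chain.double_bond[0] else -0.65)
            else:
                zabs = model.head_z - 3.0 - drop * (k - 2)
            c_xyz = np.array(
                [x0 + xoff + rng.normal(0, 0.3), y0 + rng.normal(0, 0.3), s * zabs]
            )
            atoms.append((carbon.name, c_xyz))
            phi = _ch_polar_angle(targets[chain.key][k])
            for hname in carbon.hydrogens:
                psi = rng.uniform(0.0, 2.0 * np.pi)
                d = np.array(
                    [
                        math.sin(phi) * math.cos(psi),
                        math.sin(phi) * math.sin(psi),
                        s * math.cos(phi),
                    ]
                )
                atoms.append((hname, c_xyz + ch_bond * d))
    return atoms


def _sterol_atoms(sterol_top, methyl_z, x0, y0, s, model, tilt_mean, tilt_sd, rng):
    atoms = []
    o3 = np.array([x0, y0, s * (model.head_z - 2.5)])
    atoms.append((sterol_top.o3, o3))
    theta = math.radians(
        float(np.clip(rng.normal(tilt_mean, tilt_sd) if tilt_sd > 0 else tilt_mean, 0.0, 90.0))
    )
    psi = rng.uniform(0.0, 2.0 * np.pi)
    u = np.array(
        [math.sin(theta) * math.cos(psi), math.sin(theta) * math.sin(psi), s * math.cos(theta)]
    )
    atoms.append((sterol_top.c24, o3 - 5.0 * u))
    for label, atom_name in sterol_top.methyls.items():
        if label not in methyl_z:
            continue
        mean, sd = methyl_z[label]
        atoms.append(
            (
                atom_name,
                np.array(
                    [
                        x0 + rng.normal(0, 0.5),
                        y0 + rng.normal(0, 0.5),
                        s * rng.normal(mean, sd),
                    ]
                ),
            )
        )
    return atoms


# presets mirroring the simulated binary mixtures (compositions 95:5,
# 85:15, 70:30, 50:50 of phospholipid:ring-lipid)
PRESET_COMPOSITIONS = {"95:5": 0.05, "85:15": 0.15, "70:30": 0.30, "50:50": 0.50}


def bilayer_preset(
    name: str, composition: str = "70:30", seed: int = 0, **overrides
) -> ToyBilayerModel:
    """Named presets: ``{dpop,chol}_{d6,d9,d11}`` at a given composition."""
    try:
        sterol_key, pc_key = name.split("_")
    except ValueError:
        raise TerpordError(f"preset {name!r} not of the form sterol_lipid") from None
    sterol = {"dpop": "DPOP", "chol": "CHL1"}.get(sterol_key)
    pc = {"d6": "D6PC", "d9": "D9PC", "d11": "D11PC"}.get(pc_key)
    if sterol is None or pc is None:
        raise TerpordError(f"unknown preset {name!r}")
    if composition not in PRESET_COMPOSITIONS:
        raise TerpordError(
            f"unknown composition {composition!r}; choose from {sorted(PRESET_COMPOSITIONS)}"
        )
    return ToyBilayerModel(
        phospholipid=pc,
        sterol=sterol,
        sterol_fraction=PRESET_COMPOSITIONS[composition],
        seed=seed,
        **overrides,
    )


# ---------------------------------------------------------------------------
# Plate-reader traces


def gen_growth_curve(
    rate: float,
    od_start: float = 0.85,
    noise_sd: float = 0.0,
    seed: int = 0,
    times: Sequence[float] | None = None,
    label: str = "",
) -> GrowthCurve:
    """Linear OD562 decay od_start − rate·t with Gaussian noise.

    ``rate`` is the ground-truth growth rate (1/h): the phenol-red readout
    falls as the culture grows, so the fitted slope is −rate.
    """
    if rate < 0:
        raise TerpordError("rate must be non-negative")
    if times is None:
        t_end = (od_start - 0.2) / rate if rate > 0 else 24.0
        times = np.arange(0.0, t_end + 1e-9, 0.5)
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    od = od_start - rate * t
    if noise_sd:
        od = od + rng.normal(0.0, noise_sd, size=t.shape)
    return GrowthCurve(times=t, od562=np.clip(od, 0.0, None), diet=label)


def gen_lysis_series(
    true_fractions: Mapping[float, float],
    intact_level: float = 100.0,
    lysed_level: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 1,
) -> list[LysisSeries]:
    """Propidium-iodide plate wells over wash-buffer dilutions.

    ``true_fractions`` maps buffer % to the true lysed fraction; anchors at
    0% (fully lysed) and 100% (intact) are added if absent. Fluorescence is
    intact + f·(lysed − intact) + noise.
    """
    if abs(lysed_level - intact_level) < 1e-12:
        raise TerpordError("anchor levels must be distinct")
    fr = {float(k): float(v) for k, v in true_fractions.items()}
    fr.setdefault(0.0, 1.0)
    fr.setdefault(100.0, 0.0)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_replicates):
        pct = np.array(sorted(fr))
        f = np.array([fr[p] for p in pct])
        signal = intact_level + f * (lysed_level - intact_level)
        if noise_sd:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
        out.append(
            LysisSeries(
                buffer_fractions=pct, fluorescence=signal, replicate_id=f"rep{i + 1}"
            )
        )
    return out
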