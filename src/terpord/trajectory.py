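"""Bilayer trajectory observables.

Implements the standard per-frame reductions for a planar bilayer simulated
with its normal along the laboratory z axis:

* deuterium order parameters  S_CD = ½⟨3cos²φ − 1⟩  per chain carbon, where
  φ is the angle between each C-H bond and the membrane normal, plus the
  "plateau" average over the most-ordered carbons (4-8 by convention);
* density histograms of atom groups along the normal, relative to the
  bilayer centre (bin width 0.87 Å by default, leaflets folded onto one
  side);
* tilt-angle distributions of ring lipids, from the C24→O3 vector against
  the outward leaflet normal;
* per-lipid areas from a periodic Voronoi tessellation of in-plane
  reference points (phospholipids: centroid of the C2/C21/C31 glycerol
  atoms; sterols/hopanoids: the O3 atom);
* an overlap coefficient between two normalized histograms,
  Σ min(p₁, p₂)·Δz ∈ [0, 1].

Periodic boundaries are orthorhombic; bond vectors are unwrapped by the
minimum-image convention before any angle is computed, and the Voronoi
construction tiles the box 3×3 so every central cell is closed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Voronoi

from .errors import DegeneracyError, TerpordError
from .topology import ChainTopology, SterolTopology, TopologyRegistry, load_topology

logger = logging.getLogger(__name__)

DEFAULT_Z_BIN_WIDTH = 0.87  # Å
DEFAULT_TILT_BIN_WIDTH = 2.0  # degrees
DEFAULT_PLATEAU_RANGE = (4, 8)  # chain carbon numbers, inclusive
ANCHOR_ATOM = "P"  # phosphate anchor used to define the bilayer midplane


# ---------------------------------------------------------------------------
# Frame container


@dataclass
class BilayerFrame:
    """One snapshot: orthorhombic box plus flat per-atom records."""

    box: np.ndarray  # (3,) Lx, Ly, Lz in Å
    resnames: np.ndarray  # (N,) species label per atom
    resids: np.ndarray  # (N,) residue index per atom
    names: np.ndarray  # (N,) atom name per atom
    positions: np.ndarray  # (N, 3) Å

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.resnames = np.asarray(self.resnames)
        self.resids = np.asarray(self.resids, dtype=int)
        self.names = np.asarray(self.names)
        n = len(self.positions)
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise TerpordError(f"box must be 3 positive lengths, got {self.box}")
        for arr, label in ((self.resnames, "resnames"), (self.resids, "resids"), (self.names, "names")):
            if len(arr) != n:
                raise TerpordError(f"{label} length {len(arr)} != n_atoms {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def atom_index(self) -> dict[tuple[int, str], int]:
        """Map (resid, atom name) -> row; atom names unique within a residue."""
        out: dict[tuple[int, str], int] = {}
        for i, (rid, nm) in enumerate(zip(self.resids.tolist(), self.names.tolist())):
            key = (rid, nm)
            if key in out:
                raise TerpordError(f"duplicate atom {nm!r} in residue {rid}")
            out[key] = i
        return out

    def residues_of(self, species: str) -> np.ndarray:
        """Sorted unique resids of a species."""
        return np.unique(self.resids[self.resnames == species])


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the primary image (orthorhombic box)."""
    return d - box * np.round(d / box)


# ---------------------------------------------------------------------------
# I/O via MDAnalysis


def load_frames(
    paths: str | Path | Sequence[str | Path],
    *,
    registry: TopologyRegistry | None = None,
    validate: bool = True,
) -> list[BilayerFrame]:
    """Read coordinate/trajectory files (PDB, GRO, ...) into frames.

    Every frame of every file is loaded. When ``validate`` is on, each
    residue whose species is in the topology registry is checked for its
    required atoms (chain carbons + hydrogens + the C2/C21/C31 reference
    atoms for phospholipids; O3 and C24 for ring lipids).
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, Path)):
        paths = [paths]
    registry = registry or load_topology()
    frames: list[BilayerFrame] = []
    for path in paths:
        u = mda.Universe(str(path))
        resnames = u.atoms.resnames.astype(str)
        resids = u.atoms.resids.astype(int)
        names = u.atoms.names.astype(str)
        # multi-model PDBs carry one header CRYST1; the per-frame reader
        # only sees CRYST1 records inside MODEL blocks, so fall back to the
        # header record when a frame reports no box
        header_box = _header_cryst1(path)
        for _ in u.trajectory:
            dims = u.dimensions
            if dims is None and header_box is not None:
                dims = header_box
            if dims is None or np.any(dims[:3] <= 0):
                raise TerpordError(f"{path}: no box dimensions recorded")
            frames.append(
                BilayerFrame(
                    box=np.asarray(dims[:3], dtype=float).copy(),
                    resnames=resnames.copy(),
                    resids=resids.copy(),
                    names=names.copy(),
                    positions=u.atoms.positions.astype(float).copy(),
                )
            )
    if validate and frames:
        validate_frame(frames[0], registry)
    return frames


def _header_cryst1(path: str | Path) -> np.ndarray | None:
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    vals = [line[6:15], line[15:24], line[24:33],
                            line[33:40], line[40:47], line[47:54]]
                    return np.array([float(v) for v in vals])
                if line.startswith(("ATOM", "HETATM")):
                    break
    except (OSError, UnicodeDecodeError, ValueError):
        return None
    return None


def validate_frame(frame: BilayerFrame, registry: TopologyRegistry) -> None:
    """Check that every known residue carries its required atoms."""
    index = frame.atom_index()
    seen = {}
    for rid, rn in zip(frame.resids.tolist(), frame.resnames.tolist()):
        seen.setdefault(rid, rn)
    for rid, rn in seen.items():
        if rn not in registry.species:
            continue
        info = registry.species[rn]
        if info.kind == "phospholipid":
            required = ["C2", "C21", "C31"]
            for ck in info.chains:
                for carbon in registry.chains[ck].carbons:
                    required.append(carbon.name)
                    required.extend(carbon.hydrogens)
        else:
            st = registry.sterols[info.sterol]
            required = [st.o3, st.c24]
        for name in required:
            if (rid, name) not in index:
                raise TerpordError(
                    f"residue {rn} {rid} is missing required atom {name!r}"
                )


def write_frames(frames: Sequence[BilayerFrame], path: str | Path) -> Path:
    """Write frames as a multi-model PDB (text, standard reader support)."""
    import MDAnalysis as mda

    path = Path(path)
    first = frames[0]
    n = first.n_atoms
    _, res_first = np.unique(first.resids, return_index=True)
    res_order = np.sort(res_first)
    resids = first.resids[res_order]
    resnames = first.resnames[res_order]
    resid_to_idx = {rid: i for i, rid in enumerate(resids.tolist())}
    atom_resindex = np.array([resid_to_idx[r] for r in first.resids.tolist()])
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(resids),
        atom_resindex=atom_resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", first.names)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("elements", [_guess_element(nm) for nm in first.names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDB writer warns about absent attrs
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for fr in frames:
                u.atoms.positions = fr.positions
                u.dimensions = [*fr.box, 90.0, 90.0, 90.0]
                w.write(u.atoms)
    return path


def _guess_element(name: str) -> str:
    if name.startswith("M"):  # methyl pseudo-carbons M1..M6
        return "C"
    return name[0]


# ---------------------------------------------------------------------------
# Bilayer centre and leaflets


def bilayer_center(frame: BilayerFrame, anchor: str = ANCHOR_ATOM) -> float:
    """Midplane z₀: midpoint of the two leaflets' mean anchor-atom z."""
    z = frame.positions[frame.names == anchor, 2]
    if len(z) == 0:
        raise TerpordError(f"no anchor atoms named {anchor!r} in frame")
    split = float(z.mean())
    upper = z[z >= split]
    lower = z[z < split]
    if len(upper) == 0 or len(lower) == 0:
        raise TerpordError("one leaflet has no anchor atoms")
    return float((upper.mean() + lower.mean()) / 2.0)


def residue_leaflets(
    frame: BilayerFrame,
    z0: float,
    anchor_names: Sequence[str] = (ANCHOR_ATOM, "O3"),
) -> dict[int, int]:
    """Leaflet sign (+1 upper / −1 lower) per residue, by anchor-atom z."""
    out: dict[int, int] = {}
    for anchor in anchor_names:
        mask = frame.names == anchor
        for rid, z in zip(frame.resids[mask].tolist(), frame.positions[mask, 2]):
            out.setdefault(rid, 1 if z >= z0 else -1)
    return out


# ---------------------------------------------------------------------------
# Order parameters


@dataclass
class OrderProfile:
    """Signed S_CD per chain carbon, with sample counts."""

    chain: str
    carbon_index: np.ndarray  # (K,) chain carbon numbers
    scd: np.ndarray  # (K,) signed S_CD
    n_samples: np.ndarray  # (K,) C-H bond samples per carbon
    plateau_range: tuple[int, int] = DEFAULT_PLATEAU_RANGE

    def __post_init__(self) -> None:
        if np.any(self.scd < -0.5 - 1e-9) or np.any(self.scd > 1.0 + 1e-9):
            raise TerpordError("S_CD out of the physical range [-0.5, 1]")

    @property
    def plateau(self) -> float:
        """Mean S_CD over the plateau carbons (4-8 by default)."""
        lo, hi = self.plateau_range
        mask = (self.carbon_index >= lo) & (self.carbon_index <= hi)
        if not mask.any():
            raise TerpordError(f"no carbons in plateau range {self.plateau_range}")
        return float(self.scd[mask].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"carbon": self.carbon_index, "scd": self.scd, "n_samples": self.n_samples}
        )


def _bond_indices(
    frame: BilayerFrame, species: str, topology: ChainTopology
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per carbon number: (carbon rows, hydrogen rows), aligned pairwise."""
    index = frame.atom_index()
    resids = frame.residues_of(species)
    if len(resids) == 0:
        raise TerpordError(f"no residues of species {species!r}")
    out = {}
    for carbon in topology.carbons:
        c_rows, h_rows = [], []
        for rid in resids.tolist():
            ci = index.get((rid, carbon.name))
            if ci is None:
                raise TerpordError(
                    f"residue {species} {rid} is missing atom {carbon.name!r}"
                )
            for hname in carbon.hydrogens:
                hi = index.get((rid, hname))
                if hi is None:
                    raise TerpordError(
                        f"residue {species} {rid} is missing atom {hname!r}"
                    )
                c_rows.append(ci)
                h_rows.append(hi)
        if not c_rows:
            warnings.warn(
                f"carbon {carbon.name} has no hydrogens; skipped", stacklevel=2
            )
            continue
        out[carbon.index] = (np.array(c_rows), np.array(h_rows))
    return out


def scd_profile(
    frames: Iterable[BilayerFrame],
    species: str,
    topology: ChainTopology,
    plateau_range: tuple[int, int] = DEFAULT_PLATEAU_RANGE,
) -> OrderProfile:
    """Per-carbon S_CD = ½⟨3cos²φ − 1⟩ averaged over bonds, residues, frames.

    φ is the angle between each C-H bond vector (minimum-image unwrapped)
    and the membrane normal (laboratory z). The estimate is signed; no
    absolute value is taken.
    """
    frames = list(frames)
    if not frames:
        raise TerpordError("no frames")
    bonds = _bond_indices(frames[0], species, topology)
    ref_names = frames[0].names
    sums = {k: 0.0 for k in bonds}
    counts = {k: 0 for k in bonds}
    for fr in frames:
        if fr.names is not ref_names and not np.array_equal(fr.names, ref_names):
            bonds = _bond_indices(fr, species, topology)
            ref_names = fr.names
        for k, (ci, hi) in bonds.items():
            d = minimum_image(fr.positions[hi] - fr.positions[ci], fr.box)
            norm = np.linalg.norm(d, axis=1)
            ok = norm > 1e-12
            cos2 = (d[ok, 2] / norm[ok]) ** 2
            sums[k] += float(np.sum(0.5 * (3.0 * cos2 - 1.0)))
            counts[k] += int(ok.sum())
    ks = sorted(bonds)
    scd = np.array([sums[k] / counts[k] for k in ks])
    return OrderProfile(
        chain=topology.key,
        carbon_index=np.array(ks),
        scd=scd,
        n_samples=np.array([counts[k] for k in ks]),
        plateau_range=plateau_range,
    )


# ---------------------------------------------------------------------------
# Histograms along z and tilt


@dataclass
class Histogram1D:
    """Normalized 1-d histogram: Σ density·width = 1."""

    edges: np.ndarray  # (B+1,)
    densities: np.ndarray  # (B,) probability per unit of the axis
    label: str = ""

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if len(self.edges) != len(self.densities) + 1:
            raise TerpordError("edges must be one longer than densities")
        if np.any(self.densities < 0):
            raise TerpordError("densities must be non-negative")
        total = float(np.sum(self.densities * np.diff(self.edges)))
        if abs(total - 1.0) > 1e-9:
            raise TerpordError(f"histogram does not integrate to 1: {total}")

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def mean(self) -> float:
        return float(np.sum(self.centers * self.densities * self.widths))

    def mode(self) -> float:
        return float(self.centers[int(np.argmax(self.densities))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.edges[:-1],
                "bin_right": self.edges[1:],
                "density": self.densities,
            }
        )


class ZHistogram(Histogram1D):
    """Distribution along the membrane normal, relative to bilayer centre."""


class TiltHistogram(Histogram1D):
    """Distribution of tilt angles in degrees, [0, 180]."""


def _histogram(values: np.ndarray, edges: np.ndarray, cls, label: str):
    counts, _ = np.histogram(values, bins=edges)
    total = counts.sum()
    if total == 0:
        raise TerpordError("no samples fall inside the histogram range")
    dens = counts / (total * np.diff(edges))
    return cls(edges=edges, densities=dens, label=label)


def _z_edges(values: np.ndarray, width: float, fold: bool) -> np.ndarray:
    if fold:
        nbins = max(1, int(np.ceil((values.max() + 1e-9) / width)))
        return np.arange(nbins + 1) * width
    half = max(1, int(np.ceil((np.abs(values).max() + 1e-9) / width)))
    return np.arange(-half, half + 1) * width


def collect_z(
    frames: Iterable[BilayerFrame],
    species: str,
    atom_names: Sequence[str],
    anchor: str = ANCHOR_ATOM,
) -> np.ndarray:
    """All z − z₀ samples for the named atoms of a species, over frames."""
    samples = []
    for fr in frames:
        z0 = bilayer_center(fr, anchor)
        mask = (fr.resnames == species) & np.isin(fr.names, atom_names)
        if not mask.any():
            raise TerpordError(
                f"no atoms {list(atom_names)} of species {species!r} in frame"
            )
        samples.append(fr.positions[mask, 2] - z0)
    return np.concatenate(samples)


def z_distribution(
    frames: Iterable[BilayerFrame],
    species: str,
    atom_names: Sequence[str],
    bin_width: float = DEFAULT_Z_BIN_WIDTH,
    fold: bool = True,
    anchor: str = ANCHOR_ATOM,
) -> ZHistogram:
    """Histogram of atom-group positions along the normal.

    ``fold`` maps both leaflets onto |z − z₀| (the one-sided convention);
    bins are anchored at the bilayer centre so the default width of 0.87 Å
    tiles outward from z = 0.
    """
    frames = list(frames)
    z = collect_z(frames, species, atom_names, anchor)
    if fold:
        z = np.abs(z)
    edges = _z_edges(z, bin_width, fold)
    label = f"{species}:{'+'.join(atom_names)}"
    return _histogram(z, edges, ZHistogram, label)


def double_bond_positions(
    frames: Iterable[BilayerFrame],
    species: str,
    topology: ChainTopology,
    bin_width: float = DEFAULT_Z_BIN_WIDTH,
    fold: bool = True,
    anchor: str = ANCHOR_ATOM,
) -> ZHistogram:
    """z-histogram of the midpoint of the two double-bond carbons."""
    if topology.double_bond is None:
        raise TerpordError(f"chain {topology.key} declares no double bond")
    i, j = topology.double_bond
    name_i = topology.carbon(i).name
    name_j = topology.carbon(j).name
    frames = list(frames)
    samples = []
    for fr in frames:
        z0 = bilayer_center(fr, anchor)
        index = fr.atom_index()
        for rid in fr.residues_of(species).tolist():
            try:
                pi = fr.positions[index[(rid, name_i)]]
                pj = fr.positions[index[(rid, name_j)]]
            except KeyError as exc:
                raise TerpordError(
                    f"residue {species} {rid} is missing a double-bond carbon"
                ) from exc
            mid = pi + minimum_image(pj - pi, fr.box) / 2.0
            samples.append(mid[2] - z0)
    z = np.asarray(samples)
    if fold:
        z = np.abs(z)
    edges = _z_edges(z, bin_width, fold)
    return _histogram(z, edges, ZHistogram, f"{species}:double-bond")


def tilt_distribution(
    frames: Iterable[BilayerFrame],
    species: str,
    sterol: SterolTopology,
    bin_width: float = DEFAULT_TILT_BIN_WIDTH,
    anchor: str = ANCHOR_ATOM,
) -> TiltHistogram:
    """Tilt of the C24→O3 vector against the outward leaflet normal.

    Upright molecules score near 0° in both leaflets.
    """
    angles = []
    for fr in frames:
        z0 = bilayer_center(fr, anchor)
        index = fr.atom_index()
        for rid in fr.residues_of(species).tolist():
            o3 = fr.positions[index[(rid, sterol.o3)]]
            c24 = fr.positions[index[(rid, sterol.c24)]]
            v = minimum_image(o3 - c24, fr.box)
            norm = np.linalg.norm(v)
            if norm < 1e-12:
                warnings.warn(
                    f"zero-length orientation vector on residue {rid}; skipped",
                    stacklevel=2,
                )
                continue
            outward = 1.0 if o3[2] >= z0 else -1.0
            cosang = np.clip(outward * v[2] / norm, -1.0, 1.0)
            angles.append(np.degrees(np.arccos(cosang)))
    if not angles:
        raise TerpordError(f"no usable orientation vectors for {species!r}")
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    return _histogram(np.asarray(angles), edges, TiltHistogram, f"{species}:tilt")


# ---------------------------------------------------------------------------
# Reference points and Voronoi areas


@dataclass
class ReferencePoints:
    """Labeled in-plane reference points of one leaflet."""

    resids: np.ndarray  # (M,)
    species: np.ndarray  # (M,)
    xy: np.ndarray  # (M, 2), wrapped into [0, L)
    box_xy: np.ndarray  # (2,) Lx, Ly
    leaflet: int  # +1 upper / −1 lower


@dataclass
class VoronoiResult:
    """Per-residue Voronoi cell areas of one leaflet."""

    points: ReferencePoints
    areas: np.ndarray  # (M,) Å²

    def __post_init__(self) -> None:
        if np.any(self.areas <= 0):
            raise TerpordError("Voronoi areas must be positive")

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def species_stats(self) -> pd.DataFrame:
        df = pd.DataFrame({"species": self.points.species, "area": self.areas})
        out = df.groupby("species")["area"].agg(["mean", "std", "count"])
        return out.rename(columns={"mean": "mean_area", "std": "sd_area", "count": "n"})


def lipid_reference_points(
    frame: BilayerFrame,
    leaflet: int,
    registry: TopologyRegistry | None = None,
    anchor: str = ANCHOR_ATOM,
) -> ReferencePoints:
    """One in-plane point per residue of a leaflet.

    Phospholipids: unweighted centroid of C2, C21, C31 (minimum-image
    consistent); ring lipids: the O3 atom. Coordinates wrapped into [0, L).
    """
    registry = registry or load_topology()
    z0 = bilayer_center(frame, anchor)
    leaflets = residue_leaflets(frame, z0)
    index = frame.atom_index()
    box_xy = frame.box[:2]
    resids, species, pts = [], [], []
    seen: dict[int, str] = {}
    for rid, rn in zip(frame.resids.tolist(), frame.resnames.tolist()):
        seen.setdefault(rid, rn)
    for rid, rn in seen.items():
        if rn not in registry.species or leaflets.get(rid) != leaflet:
            continue
        info = registry.species[rn]
        if info.kind == "phospholipid":
            try:
                rows = [index[(rid, nm)] for nm in ("C2", "C21", "C31")]
            except KeyError as exc:
                raise TerpordError(
                    f"residue {rn} {rid} is missing reference atom {exc.args[0][1]!r}"
                ) from None
            p = frame.positions[rows]
            rel = minimum_image(p[1:] - p[0], frame.box)
            point = p[0, :2] + rel[:, :2].sum(axis=0) / 3.0
        else:
            st = registry.sterols[info.sterol]
            try:
                point = frame.positions[index[(rid, st.o3)], :2]
            except KeyError:
                raise TerpordError(
                    f"residue {rn} {rid} is missing reference atom {st.o3!r}"
                ) from None
        resids.append(rid)
        species.append(rn)
        pts.append(np.mod(point, box_xy))
    if not pts:
        raise TerpordError(f"no reference points in leaflet {leaflet:+d}")
    return ReferencePoints(
        resids=np.array(resids),
        species=np.array(species),
        xy=np.asarray(pts, dtype=float),
        box_xy=np.asarray(box_xy, dtype=float),
        leaflet=leaflet,
    )


def voronoi_areas(points: ReferencePoints) -> VoronoiResult:
    """Periodic Voronoi tessellation: 3×3 image tiling, central cells kept.

    Cell areas partition the box: Σ areas = Lx·Ly. Coincident points are
    separated by a deterministic 1e-6 Å jitter (warned).
    """
    xy = points.xy.copy()
    box = points.box_xy
    m = len(xy)
    if m < 3:
        raise TerpordError("need at least 3 points for a Voronoi tessellation")
    # deterministic de-duplication
    _, first_idx, inverse, counts = np.unique(
        np.round(xy, 9), axis=0, return_index=True, return_inverse=True, return_counts=True
    )
    if np.any(counts > 1):
        warnings.warn("coincident reference points jittered by 1e-6 Å", stacklevel=2)
        rank = np.zeros(m, dtype=int)
        tally: dict[int, int] = {}
        for i, g in enumerate(inverse.tolist()):
            rank[i] = tally.get(g, 0)
            tally[g] = rank[i] + 1
        ang = 2.0 * np.pi * rank / np.maximum(counts[inverse], 1)
        xy = xy + 1e-6 * rank[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
    offsets = np.array(
        [[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1) if (i, j) != (0, 0)]
    )
    tiled = np.vstack([xy] + [xy + off * box for off in offsets])
    vor = Voronoi(tiled)
    areas = np.empty(m)
    for i in range(m):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise DegeneracyError(
                f"unbounded Voronoi cell for point {i}; box tiling failed"
            )
        verts = vor.vertices[region]
        areas[i] = ConvexHull(verts).volume  # 2-d hull volume == polygon area
    return VoronoiResult(points=points, areas=areas)


# ---------------------------------------------------------------------------
# Histogram overlap


def _rebin(hist: Histogram1D, edges: np.ndarray) -> np.ndarray:
    """Linear mass assignment of a histogram onto new edges; returns densities."""
    mass = hist.densities * hist.widths
    out = np.zeros(len(edges) - 1)
    for m, lo, hi in zip(mass, hist.edges[:-1], hist.edges[1:]):
        if m == 0:
            continue
        left = np.clip(np.maximum(edges[:-1], lo), lo, hi)
        right = np.clip(np.minimum(edges[1:], hi), lo, hi)
        frac = np.maximum(right - left, 0.0) / (hi - lo)
        out += m * frac
    return out / np.diff(edges)


def overlap_coefficient(h1: Histogram1D, h2: Histogram1D) -> float:
    """Overlap Σ min(p₁, p₂)·Δx ∈ [0, 1]; 1 for identical distributions.

    Histograms with different binning are rebinned onto a common grid by
    linear mass assignment; disjoint supports give 0.
    """
    if len(h1.edges) == len(h2.edges) and np.allclose(h1.edges, h2.edges):
        e = h1.edges
        d1, d2 = h1.densities, h2.densities
    else:
        width = min(h1.widths.min(), h2.widths.min())
        lo = min(h1.edges[0], h2.edges[0])
        hi = max(h1.edges[-1], h2.edges[-1])
        nbins = max(1, int(np.ceil((hi - lo) / width - 1e-9)))
        e = lo + np.arange(nbins + 1) * width
        d1 = _rebin(h1, e)
        d2 = _rebin(h2, e)
    return float(np.sum(np.minimum(d1, d2) * np.diff(e)))
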