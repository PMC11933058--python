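"""Coarse-grained surface representation of an Fv (or antigen) domain.

A structure is reduced to one representative bead per residue (side-chain
centroid, C-alpha for glycine). On this bead model the package computes
relative side-chain accessibility (RSA) by sphere sampling, partitions the
surface into N centroids by seeded k-means, attaches physicochemical
properties (Kyte-Doolittle hydrophobicity weighted by exposure, formal
charge, screened Coulomb potential with a distance-dependent dielectric
eps(r) = 4r, and signed local curvature from a best-fit sphere), and detects
connected patches of extreme property values against reference-panel
quantile thresholds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .errors import ConfigurationError, FormatError
from .liabilities import RESIDUE_CHARGE

logger = logging.getLogger(__name__)

PropertyName = Literal["hydrophobicity", "charge", "potential", "curvature"]
PROPERTY_NAMES: tuple[PropertyName, ...] = ("hydrophobicity", "charge", "potential", "curvature")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Approximate side-chain volumes (cubic Angstrom) used to size the beads.
SIDECHAIN_VOLUME = {
    "A": 27.0, "R": 105.0, "N": 58.0, "D": 54.0, "C": 44.0, "Q": 80.0,
    "E": 77.0, "G": 18.0, "H": 79.0, "I": 93.0, "L": 93.0, "K": 100.0,
    "M": 94.0, "F": 103.0, "P": 57.0, "S": 31.0, "T": 51.0, "V": 71.0,
    "W": 130.0, "Y": 111.0,
}

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

PROBE_RADIUS = 1.4
COULOMB_CONSTANT = 332.0  # kcal * Angstrom / (mol * e^2)
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


def bead_radius(restype: str) -> float:
    """Sphere radius of a residue bead from its side-chain volume."""
    try:
        volume = SIDECHAIN_VOLUME[restype]
    except KeyError:
        raise ValueError(f"unknown residue type {restype!r}") from None
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class Residue:
    chain: str
    index: int  # author residue number
    restype: str  # one-letter code
    coord: tuple[float, float, float]


@dataclass
class Centroid:
    id: int
    position: np.ndarray
    members: list[int]  # residue indices into CoarseStructure.residues
    hydrophobicity: float | None = None
    charge: float | None = None
    potential: float | None = None
    curvature: float | None = None

    def property_value(self, name: PropertyName) -> float:
        value = getattr(self, name)
        if value is None:
            raise ValueError(f"centroid {self.id}: property {name!r} not computed")
        return value


@dataclass
class CoarseStructure:
    residues: list[Residue]
    rsa: np.ndarray | None = None
    centroids: list[Centroid] | None = None
    surface_rsa_cutoff: float = 0.05

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.coord for r in self.residues], dtype=float)

    @property
    def n_centroids(self) -> int:
        return 0 if self.centroids is None else len(self.centroids)

    def surface_indices(self) -> np.ndarray:
        if self.rsa is None:
            raise ValueError("RSA not computed")
        return np.where(self.rsa > self.surface_rsa_cutoff)[0]

    def sequence_by_chain(self) -> dict[str, str]:
        chains: dict[str, list[str]] = {}
        for r in self.residues:
            chains.setdefault(r.chain, []).append(r.restype)
        return {c: "".join(s) for c, s in chains.items()}

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CoarseStructure":
        """Rigid copy: coordinates (residues and centroids) moved, properties kept."""
        new_coords = self.coords @ rotation.T + translation
        residues = [Residue(r.chain, r.index, r.restype, tuple(c))
                    for r, c in zip(self.residues, new_coords)]
        out = CoarseStructure(residues, rsa=None if self.rsa is None else self.rsa.copy(),
                              surface_rsa_cutoff=self.surface_rsa_cutoff)
        if self.centroids is not None:
            out.centroids = [Centroid(c.id, c.position @ rotation.T + translation,
                                      list(c.members), c.hydrophobicity, c.charge,
                                      c.potential, c.curvature)
                             for c in self.centroids]
        return out


@dataclass(frozen=True)
class Patch:
    property: PropertyName
    centroid_ids: tuple[int, ...]
    intensity: Literal["moderate", "intense"]
    n_member_residues: int


@dataclass(frozen=True)
class PatchThresholds:
    """Per-property (moderate, intense) cutoffs from a reference panel."""

    moderate: dict[str, float]
    intense: dict[str, float]


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def load_structure(path: str | Path) -> CoarseStructure:
    """Reduce a PDB file to one representative bead per residue.

    The representative is the side-chain heavy-atom centroid, or C-alpha for
    glycine and side-chain-less residues. Alternate locations take conformer
    'A'; residues with no usable atoms are skipped with a warning.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if not st or len(st) == 0:
        raise FormatError(f"{path}: no models")
    residues: list[Residue] = []
    model = st[0]
    if len(model) == 0:
        raise FormatError(f"{path}: no chains")
    for chain in model:
        for res in chain:
            one = THREE_TO_ONE.get(res.name.upper())
            if one is None:
                logger.warning("%s: skipping unknown residue %s %s%d",
                               path, res.name, chain.name, res.seqid.num)
                continue
            side, ca = [], None
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                if atom.name == "CA":
                    ca = atom.pos
                elif atom.name not in BACKBONE_ATOMS and atom.element.name != "H":
                    side.append([atom.pos.x, atom.pos.y, atom.pos.z])
            if side and one != "G":
                coord = tuple(np.mean(np.array(side), axis=0))
            elif ca is not None:
                coord = (ca.x, ca.y, ca.z)
            else:
                logger.warning("%s: residue %s %s%d has no usable atoms, skipped",
                               path, res.name, chain.name, res.seqid.num)
                continue
            residues.append(Residue(chain.name, res.seqid.num, one, coord))
    if not residues:
        raise FormatError(f"{path}: no residues parsed")
    return CoarseStructure(residues)


# ---------------------------------------------------------------------------
# Relative solvent accessibility (sphere-sampling SASA on the bead model)
# ---------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def compute_rsa(structure: CoarseStructure, n_points: int = 512,
                probe_radius: float = PROBE_RADIUS) -> np.ndarray:
    """Relative side-chain accessibility per residue bead, in [0, 1].

    Shrake-Rupley style: sample points on each bead's solvent-expanded sphere
    and count the fraction not buried inside any neighbouring bead's expanded
    sphere. In a one-bead representation nothing occludes an isolated residue,
    so the per-type maximum is the full sphere and the accessible point
    fraction is itself the relative accessibility.
    """
    coords = structure.coords
    radii = np.array([bead_radius(r.restype) for r in structure.residues])
    expanded = radii + probe_radius
    unit = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = float(expanded.max())
    rsa = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_reach)
                      if j != i]
        if not neighbours:
            rsa[i] = 1.0
            continue
        diff = pts[:, None, :] - coords[neighbours][None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        buried = (d2 < (expanded[neighbours] ** 2)[None, :]).any(axis=1)
        rsa[i] = 1.0 - buried.mean()
    structure.rsa = rsa
    return rsa


# ---------------------------------------------------------------------------
# Centroids and properties
# ---------------------------------------------------------------------------

def build_centroids(structure: CoarseStructure, n: int = 150, seed: int = 0) -> CoarseStructure:
    """Partition the surface residues (rsa > cutoff) into `n` spatial centroids.

    Seeded k-means on the representative coordinates; every surface residue is
    assigned to exactly one centroid and centroid positions are the member
    means.
    """
    surface = structure.surface_indices()
    if not 1 <= n <= len(surface):
        raise ValueError(f"n = {n} outside [1, {len(surface)}] surface residues")
    coords = structure.coords[surface]
    km = KMeans(n_clusters=n, random_state=seed, n_init=4).fit(coords)
    centroids = []
    for cid in range(n):
        members = surface[km.labels_ == cid].tolist()
        position = coords[km.labels_ == cid].mean(axis=0)
        centroids.append(Centroid(cid, position, members))
    structure.centroids = centroids
    return structure


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit; returns (center, radius)."""
    a = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = np.einsum("ij,ij->i", points, points)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    radius = math.sqrt(max(sol[3] + center @ center, 0.0))
    return center, radius


def centroid_properties(structure: CoarseStructure, centroid: Centroid,
                        neighbourhood_radius: float = 10.0) -> Centroid:
    """Attach hydrophobicity, charge, potential and curvature to one centroid.

    - hydrophobicity: RSA-weighted mean Kyte-Doolittle value of the members;
    - charge: sum of member formal charges (elementary charges);
    - potential: sum over all charged non-member residues of
      q * 332 / (eps(r) * r) with eps(r) = 4r, in kcal/mol/e;
    - curvature: signed inverse radius of the best-fit sphere to the
      surface-residue neighbourhood within `neighbourhood_radius`; positive
      when the protein interior lies inside the sphere (convex).
    """
    if structure.rsa is None:
        raise ValueError("RSA required before centroid properties")
    coords = structure.coords
    members = np.asarray(centroid.members, dtype=int)
    weights = structure.rsa[members]
    kd = np.array([KYTE_DOOLITTLE[structure.residues[i].restype] for i in members])
    if weights.sum() > 0:
        centroid.hydrophobicity = float(np.average(kd, weights=weights))
    else:
        centroid.hydrophobicity = float(kd.mean())
    centroid.charge = float(sum(
        RESIDUE_CHARGE.get(structure.residues[i].restype, 0.0) for i in members))

    member_set = set(centroid.members)
    potential = 0.0
    for i, res in enumerate(structure.residues):
        q = RESIDUE_CHARGE.get(res.restype, 0.0)
        if q == 0.0 or i in member_set:
            continue
        r = float(np.linalg.norm(coords[i] - centroid.position))
        r = max(r, 1.0)  # avoid the singularity for coincident points
        potential += q * COULOMB_CONSTANT / (4.0 * r * r)
    centroid.potential = potential

    surface = structure.surface_indices()
    d = np.linalg.norm(coords[surface] - centroid.position, axis=1)
    neighbourhood = coords[surface[d <= neighbourhood_radius]]
    if len(neighbourhood) < 4:
        logger.warning("centroid %d: degenerate neighbourhood (<4 points), curvature 0",
                       centroid.id)
        centroid.curvature = 0.0
        return centroid
    # coplanar neighbourhoods make the algebraic sphere fit ill-posed (the
    # centre collapses into the plane); a flat patch has curvature 0
    centred = neighbourhood - neighbourhood.mean(axis=0)
    normal = np.linalg.svd(centred, full_matrices=False)[2][-1]
    if np.abs(centred @ normal).max() < 0.15:
        centroid.curvature = 0.0
        return centroid
    center, radius = _fit_sphere(neighbourhood)
    if radius <= 0 or not np.isfinite(radius):
        centroid.curvature = 0.0
        return centroid
    interior = coords.mean(axis=0)
    to_interior = interior - centroid.position
    to_center = center - centroid.position
    sign = 1.0 if float(to_interior @ to_center) >= 0 else -1.0
    centroid.curvature = float(sign / radius)
    return centroid


def compute_all_properties(structure: CoarseStructure,
                           neighbourhood_radius: float = 10.0) -> CoarseStructure:
    if structure.centroids is None:
        raise ValueError("build centroids first")
    for c in structure.centroids:
        centroid_properties(structure, c, neighbourhood_radius)
    return structure


# ---------------------------------------------------------------------------
# Patch detection
# ---------------------------------------------------------------------------

def property_magnitude(name: PropertyName, value: float) -> float:
    """The scale on which a property is thresholded for patch detection.

    Hydrophobicity and curvature are directional (hydrophobic / convex ends
    are the risky ones); charge and potential are risky at either sign, so
    their magnitude is used.
    """
    if name in ("charge", "potential"):
        return abs(value)
    return value


def thresholds_from_reference(values_by_property: dict[str, Sequence[float]],
                              q_moderate: float = 0.93,
                              q_intense: float = 0.99) -> PatchThresholds:
    """Quantile thresholds from pooled reference-panel centroid values."""
    moderate, intense = {}, {}
    for name in PROPERTY_NAMES:
        if name not in values_by_property:
            raise ConfigurationError(f"reference centroid values missing for {name!r}")
        mags = [property_magnitude(name, v) for v in values_by_property[name]]
        moderate[name] = float(np.quantile(mags, q_moderate))
        intense[name] = float(np.quantile(mags, q_intense))
    return PatchThresholds(moderate=moderate, intense=intense)


def reference_centroid_values(structures: Sequence[CoarseStructure]) -> dict[str, list[float]]:
    """Pool centroid property values across a reference panel."""
    pooled: dict[str, list[float]] = {name: [] for name in PROPERTY_NAMES}
    for st in structures:
        if st.centroids is None:
            raise ValueError("reference structure lacks centroids")
        for c in st.centroids:
            for name in PROPERTY_NAMES:
                pooled[name].append(c.property_value(name))
    return pooled


def detect_patches(centroids: Sequence[Centroid], property: PropertyName,
                   thresholds: PatchThresholds | None,
                   adjacency_cutoff: float = 10.0,
                   min_centroids: int = 3) -> list[Patch]:
    """Connected components of centroids above the moderate threshold.

    A surface *region* must span at least `min_centroids` mutually adjacent
    extreme centroids; smaller components are chance excursions of the
    quantile tail, not patches. A component is `intense` when its mean
    (magnitude) value exceeds the intense threshold. Output order is
    deterministic: by decreasing member count, then smallest centroid id.
    """
    if thresholds is None:
        raise ConfigurationError("patch detection needs reference-panel thresholds")
    mags = np.array([property_magnitude(property, c.property_value(property))
                     for c in centroids])
    hot = [i for i in range(len(centroids)) if mags[i] > thresholds.moderate[property]]
    if not hot:
        return []
    positions = np.array([centroids[i].position for i in hot])
    tree = cKDTree(positions)
    pairs = tree.query_pairs(adjacency_cutoff)
    # union-find over the hot centroids
    parent = list(range(len(hot)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(len(hot)):
        groups.setdefault(find(i), []).append(i)
    patches = []
    for group in groups.values():
        if len(group) < min_centroids:
            continue
        ids = tuple(sorted(centroids[hot[i]].id for i in group))
        mean_mag = float(mags[[hot[i] for i in group]].mean())
        intensity = "intense" if mean_mag > thresholds.intense[property] else "moderate"
        n_res = sum(len(centroids[hot[i]].members) for i in group)
        patches.append(Patch(property=property, centroid_ids=ids,
                             intensity=intensity, n_member_residues=n_res))
    patches.sort(key=lambda p: (-p.n_member_residues, p.centroid_ids[0]))
    return patches
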