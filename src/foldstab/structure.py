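"""Protein structures, solvent accessibility and core/surface classification.

The model needs three things from a 3D structure: the absolute solvent
accessible surface area (SASA) of the mutated residue, its relative
accessibility against an extended-tripeptide reference, and a binary
core/surface label (relative SASA < 0.2 means buried in the core).

SASA is computed with the Shrake-Rupley algorithm on heavy atoms with a
1.4 A water probe.  The sphere grid is deterministic (Fibonacci spiral),
and by default it is oriented in the structure's principal-axes frame so
that results are invariant under rigid rotation and translation of the
input coordinates.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import tables
from .errors import (
    ChainNotFoundError,
    EmptyStructureError,
    FormatError,
    ValidationError,
)

BURIAL_THRESHOLD = 0.2  # relative SASA below which a residue is core (COR)

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class Atom:
    """A heavy (or hydrogen) atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def vdw_radius(self) -> float:
        return tables.VDW_RADII.get(self.element.upper(), tables.DEFAULT_VDW_RADIUS)


@dataclass
class Residue:
    """A standard amino-acid residue addressed by author numbering + insertion code."""

    chain_id: str
    number: int
    icode: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]

    def get_atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureMeta:
    method: str | None = None
    resolution: float | None = None


@dataclass
class Structure:
    """Parsed chains of standard residues (first NMR model only)."""

    id: str
    chains: dict[str, list[Residue]]
    meta: StructureMeta = field(default_factory=StructureMeta)

    def residues(self, chains: Sequence[str] | None = None) -> Iterator[Residue]:
        for cid, reslist in self.chains.items():
            if chains is not None and cid not in chains:
                continue
            yield from reslist

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def get_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for res in self.chains.get(chain_id, []):
            if res.number == number and res.icode == icode:
                return res
        from .errors import ResidueNotFoundError

        raise ResidueNotFoundError(
            f"residue {chain_id}:{number}{icode} not found in structure {self.id}"
        )

    def sequence(self, chains: Sequence[str] | None = None) -> str:
        """One-letter sequence of the assigned chains, concatenated in chain order."""
        return "".join(r.aa for r in self.residues(chains))

    def seq_index(self, chain_id: str, number: int, icode: str = "") -> int:
        """1-based index of a residue within :meth:`sequence` over all chains."""
        for i, res in enumerate(self.residues(), start=1):
            if res.key == (chain_id, number, icode):
                return i
        from .errors import ResidueNotFoundError

        raise ResidueNotFoundError(f"residue {chain_id}:{number}{icode} not in structure")

    def copy(self) -> "Structure":
        chains = {
            cid: [
                Residue(r.chain_id, r.number, r.icode, r.aa,
                        [replace(a, coords=a.coords.copy()) for a in r.atoms])
                for r in reslist
            ]
            for cid, reslist in self.chains.items()
        }
        return Structure(self.id, chains, StructureMeta(self.meta.method, self.meta.resolution))


def parse_pdb(source, chains: Sequence[str] | None = None, id: str | None = None) -> Structure:
    """Parse a PDB file (path, text or file-like) into a :class:`Structure`.

    Only ATOM records of the 20 standard amino acids are kept (plus
    selenomethionine, normalized to MET).  Waters and other heteroatoms are
    dropped; for alternate locations the highest-occupancy conformer is kept
    (first-listed wins ties); only the first model of an NMR ensemble is read.
    Experimental method and resolution are captured from the header when
    present.
    """
    from Bio.PDB import PDBParser

    if hasattr(source, "read"):
        handle, label = source, id or "structure"
    else:
        text = str(source)
        if "\n" in text or (len(text) > 260 and not os.path.exists(text)):
            handle, label = io.StringIO(text), id or "structure"
        else:
            path = Path(text)
            if not path.exists():
                raise FormatError(f"no such PDB file: {path}")
            handle, label = io.StringIO(path.read_text()), id or path.stem

    parser = PDBParser(QUIET=True)
    try:
        bio_structure = parser.get_structure(label, handle)
    except Exception as exc:  # Bio.PDB raises bare exceptions on malformed input
        raise FormatError(f"unparsable PDB input: {exc}") from exc

    header = bio_structure.header or {}
    meta = StructureMeta(
        method=(header.get("structure_method") or None),
        resolution=header.get("resolution"),
    )
    if meta.resolution is not None and meta.resolution <= 0:
        meta.resolution = None

    models = list(bio_structure)
    if not models:
        raise EmptyStructureError("PDB input contains no model")
    model = models[0]

    available = [c.id for c in model]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise ChainNotFoundError(
                f"chain(s) {missing} not present (available: {available})"
            )

    out_chains: dict[str, list[Residue]] = {}
    for bio_chain in model:
        if chains is not None and bio_chain.id not in chains:
            continue
        residues = []
        for bio_res in bio_chain:
            hetflag, number, icode = bio_res.id
            resname = bio_res.get_resname().strip()
            if resname == "MSE":
                aa = "M"
            elif hetflag.strip():
                continue
            elif resname in tables.AA3TO1:
                aa = tables.AA3TO1[resname]
            else:
                continue
            atoms = []
            for bio_atom in bio_res:  # disordered atoms yield the selected altloc only
                element = (bio_atom.element or "").strip()
                if not element:
                    element = bio_atom.get_name().strip()[:1]
                occ = bio_atom.get_occupancy()
                atoms.append(
                    Atom(
                        name=bio_atom.get_name().strip(),
                        element=element,
                        coords=np.asarray(bio_atom.get_coord(), dtype=float),
                        occupancy=1.0 if occ is None else float(occ),
                        altloc=bio_atom.get_altloc().strip(),
                    )
                )
            if atoms:
                residues.append(Residue(bio_chain.id, number, icode.strip(), aa, atoms))
        if residues:
            out_chains[bio_chain.id] = residues

    if not out_chains:
        raise EmptyStructureError("no standard amino-acid residues found")
    return Structure(label, out_chains, meta)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = 2.0 * math.pi * i * (1.0 - 1.0 / ((1 + math.sqrt(5)) / 2))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _canonical_rotation(coords: np.ndarray) -> np.ndarray:
    """Rotation onto the principal axes of the atom cloud, with signs fixed by
    third moments, so any rigid transform of the input yields the same frame."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1].T  # rows: principal axes, descending variance
    for k in range(3):
        proj = centered @ axes[k]
        skew = float(np.sum(proj**3))
        if abs(skew) < 1e-9:
            skew = float(proj[np.argmax(np.abs(proj))]) if len(proj) else 1.0
        if skew < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    radii: dict[str, float] | None = None,
    canonical_frame: bool = True,
) -> np.ndarray:
    """Shrake-Rupley solvent accessible surface area, per residue (A^2).

    Returns an array aligned with ``list(structure.residues())``.  Hydrogens
    are ignored.  ``sphere_points`` controls the angular resolution (error
    roughly O(1/sqrt(n))); with ``canonical_frame`` the grid is expressed in
    the structure's principal-axes frame, making the result independent of
    the input's rigid-body orientation.
    """
    residues = list(structure.residues())
    atom_coords, atom_radii, atom_res = [], [], []
    for ri, res in enumerate(residues):
        heavy = res.heavy_atoms()
        if not heavy:
            raise ValidationError(f"residue {res.key} has no heavy atoms")
        for a in heavy:
            if not np.all(np.isfinite(a.coords)):
                raise ValidationError(f"non-finite coordinates in residue {res.key}")
            atom_coords.append(a.coords)
            if radii is not None:
                atom_radii.append(radii.get(a.element.upper(), tables.DEFAULT_VDW_RADIUS))
            else:
                atom_radii.append(a.vdw_radius)
            atom_res.append(ri)
    coords = np.asarray(atom_coords, dtype=float)
    rads = np.asarray(atom_radii, dtype=float)
    res_idx = np.asarray(atom_res)

    if canonical_frame and len(coords) > 1:
        rot = _canonical_rotation(coords)
        coords = (coords - coords.mean(axis=0)) @ rot.T

    units = _fibonacci_sphere(sphere_points)
    extended = rads + probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * extended.max()
    n_atoms = len(coords)

    # A grid point u on atom i (at c_i + E_i*u) lies inside neighbor j iff
    # u . (c_j - c_i) > (E_i^2 + D^2 - E_j^2) / (2 E_i): a half-space test,
    # so occlusion for all (atom, neighbor) pairs is one matrix product.
    sym = tree.query_pairs(max_reach, output_type="ndarray")
    exposed = np.full(n_atoms, sphere_points, dtype=int)
    if len(sym):
        ii = np.r_[sym[:, 0], sym[:, 1]]
        jj = np.r_[sym[:, 1], sym[:, 0]]
        dvec = coords[jj] - coords[ii]
        dist2 = np.einsum("ij,ij->i", dvec, dvec)
        overlap = dist2 < (extended[ii] + extended[jj]) ** 2
        ii, jj, dvec, dist2 = ii[overlap], jj[overlap], dvec[overlap], dist2[overlap]
        order = np.argsort(ii, kind="stable")
        pair_i = ii[order]
        pair_vec = dvec[order]
        pair_thresh = (extended[pair_i] ** 2 + dist2[order] - extended[jj[order]] ** 2) / (
            2 * extended[pair_i]
        )
        # process in pair-chunks aligned to atom boundaries to bound memory
        starts = np.flatnonzero(np.r_[True, np.diff(pair_i) != 0])
        boundaries = np.r_[starts, len(pair_i)]
        chunk_limit = 20000
        s = 0
        while s < len(starts):
            e = s
            while e < len(starts) and boundaries[e + 1] - boundaries[s] <= chunk_limit:
                e += 1
            e = max(e, s + 1)
            lo, hi = boundaries[s], boundaries[e]
            dots = units @ pair_vec[lo:hi].T
            buried = dots > pair_thresh[lo:hi]
            local_starts = boundaries[s:e] - lo
            per_atom = np.logical_or.reduceat(buried, local_starts, axis=1)
            atoms_here = pair_i[boundaries[s:e]]
            exposed[atoms_here] = sphere_points - per_atom.sum(axis=0)
            s = e

    areas = 4.0 * math.pi * extended**2 * exposed / sphere_points
    out = np.zeros(len(residues))
    np.add.at(out, res_idx, areas)
    return out


def relative_sasa(abs_sasa: float, aa: str, reference_table: dict[str, float] | None = None) -> float:
    """Ratio of absolute SASA to the extended-tripeptide reference for ``aa``.

    May exceed 1 for unusually exposed conformations.
    """
    table = reference_table if reference_table is not None else tables.MAX_ASA
    ref = tables.scale_value(table, aa, what="tripeptide SASA")
    if ref <= 0:
        raise ValidationError(f"reference SASA for {aa} must be positive")
    if abs_sasa < 0:
        raise ValidationError("absolute SASA cannot be negative")
    return abs_sasa / ref


def classify_location(ratio: float) -> str:
    """COR (core) if relative SASA < 0.2, else SUR (surface); strict boundary."""
    if ratio < 0:
        raise ValidationError("relative SASA cannot be negative")
    return "COR" if ratio < BURIAL_THRESHOLD else "SUR"


@dataclass
class SasaProfile:
    """Per-residue SASA, relative SASA and COR/SUR location for one structure."""

    keys: list[tuple[str, int, str]]
    aas: list[str]
    abs_sasa: np.ndarray
    rel_sasa: np.ndarray
    locations: list[str]

    def __post_init__(self):
        self._index = {k: i for i, k in enumerate(self.keys)}

    def index_of(self, chain_id: str, number: int, icode: str = "") -> int:
        try:
            return self._index[(chain_id, number, icode)]
        except KeyError:
            from .errors import ResidueNotFoundError

            raise ResidueNotFoundError(
                f"residue {chain_id}:{number}{icode} not covered by SASA profile"
            ) from None

    def for_residue(self, chain_id: str, number: int, icode: str = "") -> tuple[float, float, str]:
        i = self.index_of(chain_id, number, icode)
        return float(self.abs_sasa[i]), float(self.rel_sasa[i]), self.locations[i]

    def __len__(self) -> int:
        return len(self.keys)


def sasa_profile(
    structure: Structure,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    reference_table: dict[str, float] | None = None,
    **kwargs,
) -> SasaProfile:
    """Compute absolute SASA, relative SASA and burial labels for every residue."""
    residues = list(structure.residues())
    abs_sasa = compute_sasa(structure, probe_radius, sphere_points, **kwargs)
    rel = np.array(
        [relative_sasa(s, r.aa, reference_table) for s, r in zip(abs_sasa, residues)]
    )
    locations = [classify_location(x) for x in rel]
    return SasaProfile(
        keys=[r.key for r in residues],
        aas=[r.aa for r in residues],
        abs_sasa=abs_sasa,
        rel_sasa=rel,
        locations=locations,
    )


def write_sasa_tsv(profile: SasaProfile, path: str | Path) -> None:
    """Write the profile as TSV: chain, resnum, icode, aa, sasa_A2, rsa, location."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\ticode\taa\tsasa_A2\trsa\tlocation\n")
        for (chain, num, icode), aa, s, r, loc in zip(
            profile.keys, profile.aas, profile.abs_sasa, profile.rel_sasa, profile.locations
        ):
            fh.write(f"{chain}\t{num}\t{icode}\t{aa}\t{s:.3f}\t{r:.4f}\t{loc}\n")
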