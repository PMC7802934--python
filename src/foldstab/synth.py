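"""Synthetic fixtures: toy structures, PSSMs, conservation scores and ddG.

Everything the pipeline consumes from the outside world (PDB structures,
PSI-BLAST profiles, conservation scores, experimental ddG tables) can be
generated here so the package builds, trains and validates fully offline.

Toy proteins are ideal alpha-helices (phi = -57, psi = -47, trans peptide)
built residue-by-residue with the NeRF internal-coordinate construction,
carrying backbone, C-beta and one or two pseudo side-chain carbons so that
burial, SASA and the naive mutator all have something to act on.  Synthetic
ddG values come from a known linear generating function of the ten features
plus Gaussian noise; the reverse half of each dataset is exactly the
negated forward half, and reverse features are computed on mutated
structures and sequences — the same contract the real pipeline uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables
from .datasets import (
    MutationDataset,
    MutationRecord,
    augment_with_reverse,
    write_mutation_table,
)
from .errors import ValidationError
from .features import (
    FEATURE_NAMES,
    ConservationTable,
    PssmProfile,
    build_feature_vector,
    feature_frame,
    mutate_structure_naive,
    read_psiblast_pssm,
)
from .structure import SasaProfile, Structure, parse_pdb, sasa_profile

# ideal backbone geometry (lengths in A, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF: position atom D from three predecessors + internal coordinates."""
    angle, torsion = math.radians(angle), math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Place C-beta at idealized tetrahedral geometry around C-alpha."""
    v1 = n - ca
    v2 = c - ca
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    bisector = -(v1 + v2)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(v2, v1)
    perp /= np.linalg.norm(perp)
    theta = math.radians(54.75)
    return ca + _B_CA_CB * (bisector * math.cos(theta) + perp * math.sin(theta))


_BULKY = frozenset("RKEQWFYMIL")  # residues given a second pseudo side-chain atom

_HAIRPIN_MIN = 20  # chains at least this long fold back into a two-helix hairpin
_HAIRPIN_SEPARATION = 10.0  # axis-to-axis distance of the packed helices (A)
_CA_STEP = 3.8


def _helix_backbone(n: int) -> tuple[list, list, list]:
    """Ideal alpha-helical N/CA/C coordinates for ``n`` residues via NeRF."""
    n_xyz = [np.array([0.0, 0.0, 0.0])]
    ca_xyz = [np.array([_B_N_CA, 0.0, 0.0])]
    c0 = ca_xyz[0] + _B_CA_C * np.array(
        [math.cos(math.radians(180 - _A_N_CA_C)), math.sin(math.radians(180 - _A_N_CA_C)), 0.0]
    )
    c_xyz = [c0]
    for _ in range(1, n):
        ni = _place(n_xyz[-1], ca_xyz[-1], c_xyz[-1], _B_C_N, _A_CA_C_N, _PSI)
        cai = _place(ca_xyz[-1], c_xyz[-1], ni, _B_N_CA, _A_C_N_CA, _OMEGA)
        ci = _place(c_xyz[-1], ni, cai, _B_CA_C, _A_N_CA_C, _PHI)
        n_xyz.append(ni)
        ca_xyz.append(cai)
        c_xyz.append(ci)
    return n_xyz, ca_xyz, c_xyz


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector a onto unit vector b (Rodrigues)."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate pi about any perpendicular axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _toy_backbone(n: int) -> tuple[list, list, list]:
    """Backbone for a toy protein: a single ideal helix for short chains, an
    antiparallel two-helix hairpin (packed at ~10 A) for n >= 20 so that
    inner-facing residues are genuinely buried."""
    if n < _HAIRPIN_MIN:
        return _helix_backbone(n)
    n_loop = 3
    n1 = (n - n_loop) // 2
    n2 = n - n_loop - n1

    N1, CA1, C1 = _helix_backbone(n1)
    u = CA1[-1] - CA1[0]
    u /= np.linalg.norm(u)
    v = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(v) < 1e-6:
        v = np.cross(u, [0.0, 1.0, 0.0])
    v /= np.linalg.norm(v)

    # start of helix 2: perpendicular offset + along-axis advance such that the
    # 4 CA-CA steps through the loop are each ~3.8 A on a straight line
    along = math.sqrt(max((4 * _CA_STEP) ** 2 - _HAIRPIN_SEPARATION**2, 1.0))
    start2 = CA1[-1] + _HAIRPIN_SEPARATION * v + along * u

    N2, CA2, C2 = _helix_backbone(n2)
    u2 = CA2[-1] - CA2[0]
    u2 /= np.linalg.norm(u2)
    rot = _rotation_between(u2, -u)
    origin = CA2[0].copy()
    transform = lambda p: rot @ (p - origin) + start2
    N2 = [transform(p) for p in N2]
    CA2 = [transform(p) for p in CA2]
    C2 = [transform(p) for p in C2]

    # straight loop with ideal CA spacing; N/C placed off-axis so that the
    # O/CB construction stays numerically well conditioned
    step = (start2 - CA1[-1]) / 4.0
    dnext = step / np.linalg.norm(step)
    w = np.cross(dnext, [0.0, 0.0, 1.0])
    if np.linalg.norm(w) < 1e-6:
        w = np.cross(dnext, [0.0, 1.0, 0.0])
    w /= np.linalg.norm(w)
    N_loop, CA_loop, C_loop = [], [], []
    for k in range(1, n_loop + 1):
        ca = CA1[-1] + k * step
        N_loop.append(ca - _B_N_CA * (0.9 * dnext + 0.436 * w))
        CA_loop.append(ca)
        C_loop.append(ca + _B_CA_C * (0.9 * dnext - 0.436 * w))
    return N1 + N_loop + N2, CA1 + CA_loop + CA2, C1 + C_loop + C2


def make_toy_structure(
    n_residues: int | None = None,
    sequence: str | None = None,
    seed: int = 0,
    chain_id: str = "A",
    structure_id: str = "TOY",
) -> str:
    """PDB text for an ideal alpha-helical toy protein.

    Either ``sequence`` or ``n_residues`` must be given (a random sequence is
    drawn for the latter).  Coordinates get a tiny seeded jitter (0.02 A) to
    break exact symmetries; the same seed reproduces the file byte for byte.
    """
    rng = np.random.default_rng(seed)
    if sequence is None:
        if n_residues is None:
            raise ValidationError("give either n_residues or sequence")
        sequence = "".join(rng.choice(list(tables.AMINO_ACIDS), size=n_residues))
    sequence = sequence.upper()
    if n_residues is not None and len(sequence) != n_residues:
        raise ValidationError("sequence length disagrees with n_residues")
    if len(sequence) < 3:
        raise ValidationError("need at least 3 residues")
    for aa in sequence:
        if aa not in tables.AA1TO3:
            raise ValidationError(f"unknown residue code {aa!r}")

    n_xyz, ca_xyz, c_xyz = _toy_backbone(len(sequence))

    lines = [
        f"HEADER    SYNTHETIC HELIX                         01-JAN-20   {structure_id[:4]:<4s}",
        "EXPDTA    X-RAY DIFFRACTION",
        "REMARK   2 RESOLUTION.    1.50 ANGSTROMS.",
    ]
    serial = 1

    def atom_line(name, resname, resseq, xyz, element):
        nonlocal serial
        pname = f" {name:<3s}" if len(name) < 4 else name
        line = (
            f"ATOM  {serial:5d} {pname}{'':1s}{resname:>3s} {chain_id}{resseq:4d}{'':1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2s}"
        )
        serial += 1
        return line

    jitter = lambda: rng.normal(0.0, 0.02, size=3)
    for i, aa in enumerate(sequence):
        resname = tables.AA1TO3[aa]
        resseq = i + 1
        n_i, ca_i, c_i = n_xyz[i] + jitter(), ca_xyz[i] + jitter(), c_xyz[i] + jitter()
        o_i = _place(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, _PSI + 180.0)
        lines.append(atom_line("N", resname, resseq, n_i, "N"))
        lines.append(atom_line("CA", resname, resseq, ca_i, "C"))
        lines.append(atom_line("C", resname, resseq, c_i, "C"))
        lines.append(atom_line("O", resname, resseq, o_i, "O"))
        if aa != "G":
            cb = _cb_position(n_i, ca_i, c_i)
            lines.append(atom_line("CB", resname, resseq, cb, "C"))
            if aa != "A":
                direction = cb - ca_i
                direction /= np.linalg.norm(direction)
                cg = cb + 1.52 * direction + jitter()
                lines.append(atom_line("CG", resname, resseq, cg, "C"))
                if aa in _BULKY:
                    cd = cg + 1.52 * direction + jitter()
                    lines.append(atom_line("CD", resname, resseq, cd, "C"))
    lines.append(f"TER   {serial:5d}      {tables.AA1TO3[sequence[-1]]:>3s} {chain_id}{len(sequence):4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_synthetic_pssm(
    sequence: str,
    conservation_strength: float = 5.0,
    seed: int = 0,
    dialect: str = "full",
) -> str:
    """PSI-BLAST-style ASCII PSSM text for a sequence.

    Scores are integers drawn around zero; the native residue's column is
    raised by ``conservation_strength``, so high strengths make the native
    residue the row maximum nearly everywhere.  ``dialect`` is ``"full"``
    (40 columns plus information columns, like psiblast output) or
    ``"short"`` (log-odds block only).
    """
    rng = np.random.default_rng(seed)
    L = len(sequence)
    scores = np.rint(rng.normal(0.0, 2.0, size=(L, 20))).astype(int)
    for i, aa in enumerate(sequence):
        col = tables.PSSM_ALPHABET.find(aa)
        if col < 0:
            raise ValidationError(f"unknown residue code {aa!r}")
        scores[i, col] += int(round(conservation_strength))

    letters = "  ".join(tables.PSSM_ALPHABET)
    lines = ["", "Last position-specific scoring matrix computed, weighted observed "
                 "percentages rounded down, information per position, and relative "
                 "weight of gapless real matches to pseudocounts"]
    if dialect == "full":
        lines.append(f"            {letters}   {letters}")
    else:
        lines.append(f"            {letters}")
    pct = np.rint(rng.uniform(0, 10, size=(L, 20))).astype(int)
    for i, aa in enumerate(sequence):
        row = "".join(f"{v:4d}" for v in scores[i])
        if dialect == "full":
            extra = "".join(f"{v:4d}" for v in pct[i])
            lines.append(f"{i + 1:5d} {aa}  {row} {extra}  {0.36:5.2f} {0.09:5.2f}")
        else:
            lines.append(f"{i + 1:5d} {aa}  {row}")
    if dialect == "full":
        lines += ["", "                      K         Lambda",
                  "Standard Ungapped    0.1340     0.3180"]
    return "\n".join(lines) + "\n"


DEFAULT_COEFFICIENTS = {
    # signs follow the destabilizing-positive convention: mutations away from
    # conserved/hydrophobic residues raise ddG
    "pssm": -0.25,
    "delta_cs": -0.30,
    "delta_omh": -0.80,
    "sasa_pro": -0.004,
    "sasa_sol": 0.002,
    "p_fwy": 2.0,
    "p_rkde": -2.0,
    "p_l": 1.0,
    "n_hydro": 0.02,
    "n_charg": -0.02,
}


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic training bundle."""

    n_proteins: int = 12
    residues_per_protein: int = 60
    mutations_per_protein: int = 84
    composition: dict[str, float] | None = None
    coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    noise_sd: float = 0.5
    conservation_strength: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValidationError("need at least one protein")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        missing = set(FEATURE_NAMES) - set(self.coefficients)
        if missing:
            raise ValidationError(f"coefficients missing for features: {sorted(missing)}")
        if not all(np.isfinite(v) for v in self.coefficients.values()):
            raise ValidationError("coefficients must be finite")


@dataclass
class Bundle:
    """A complete synthetic study: structures, profiles, dataset and features."""

    spec: SyntheticSpec
    structures: dict[str, Structure]
    pdb_texts: dict[str, str]
    pssm_texts: dict[str, str]
    pssms: dict[str, PssmProfile]
    sasa: dict[str, SasaProfile]
    conservation: ConservationTable
    dataset: MutationDataset
    features: pd.DataFrame  # rows aligned with dataset.records
    locations: list[str]  # COR/SUR of the mutated site per record


def make_training_bundle(spec: SyntheticSpec | None = None) -> Bundle:
    """Generate a full training study from a :class:`SyntheticSpec`.

    Forward ddG = coefficients . features + N(0, noise_sd); the dataset is
    then reverse-augmented so each pair sums to zero exactly, and reverse
    features are computed on the naively mutated structure and sequence.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    coeffs = np.array([spec.coefficients[f] for f in FEATURE_NAMES])

    aa_list = list(tables.AMINO_ACIDS)
    weights = None
    if spec.composition:
        weights = np.array([spec.composition.get(a, 0.0) for a in aa_list], dtype=float)
        weights /= weights.sum()

    structures, pdb_texts, pssm_texts, pssms, sasa_profiles = {}, {}, {}, {}, {}
    conservation = ConservationTable()
    forward_records: list[MutationRecord] = []
    forward_features: dict[tuple, np.ndarray] = {}

    for p in range(spec.n_proteins):
        pid = f"SYN{p:03d}"
        sub_seed = int(rng.integers(0, 2**31))
        seq = "".join(np.random.default_rng(sub_seed).choice(aa_list, size=spec.residues_per_protein, p=weights))
        pdb = make_toy_structure(sequence=seq, seed=sub_seed, structure_id=pid[:4])
        structure = parse_pdb(pdb, id=pid)
        profile_text = make_synthetic_pssm(seq, spec.conservation_strength, seed=sub_seed)
        profile = read_psiblast_pssm(profile_text)
        sasa = sasa_profile(structure)

        structures[pid], pdb_texts[pid] = structure, pdb
        pssm_texts[pid], pssms[pid] = profile_text, profile
        sasa_profiles[pid] = sasa

        # distinct mutation sites/targets for this protein
        chosen: set[tuple[int, str]] = set()
        attempts = 0
        while len(chosen) < spec.mutations_per_protein and attempts < 50 * spec.mutations_per_protein:
            attempts += 1
            pos = int(rng.integers(1, len(seq) + 1))
            mut = str(rng.choice(aa_list))
            if mut == seq[pos - 1]:
                continue
            chosen.add((pos, mut))
        for pos, mut in sorted(chosen):
            wt = seq[pos - 1]
            record = MutationRecord(
                protein_id=pid, chain="A", position=pos, wt=wt, mut=mut,
                structure_id=pid,
            )
            # conservation change correlates with the PSSM change (realistic,
            # non-orthogonal design) and is exactly antisymmetric
            pssm_diff = profile.score(pos, mut) - profile.score(pos, wt)
            dcs = 0.5 * pssm_diff + rng.normal(0.0, 1.0)
            conservation.set(pid, pos, wt, mut, dcs)
            conservation.set(pid, pos, mut, wt, -dcs)
            forward_records.append(record)

    # forward features and generated ddG
    forward_with_ddg = []
    for rec in forward_records:
        fv = build_feature_vector(
            rec, structures[rec.protein_id], sasa_profiles[rec.protein_id],
            pssms[rec.protein_id], conservation,
        )
        x = fv.to_array()
        forward_features[rec.site_key] = x
        ddg = float(coeffs @ x + rng.normal(0.0, spec.noise_sd))
        forward_with_ddg.append(MutationRecord(
            protein_id=rec.protein_id, chain=rec.chain, position=rec.position,
            wt=rec.wt, mut=rec.mut, icode=rec.icode, structure_id=rec.structure_id,
            ddg=ddg,
        ))

    dataset = augment_with_reverse(MutationDataset("synthetic", forward_with_ddg))

    rows, locations = [], []
    for rec in dataset.records:
        wt_structure = structures[rec.protein_id]
        if rec.direction == "forward":
            x = forward_features[rec.site_key]
            _, _, loc = sasa_profiles[rec.protein_id].for_residue(rec.chain, rec.position, rec.icode)
        else:
            mutant = mutate_structure_naive(
                wt_structure, rec.chain, rec.position, wt=rec.mut, mut=rec.wt, icode=rec.icode
            )
            mutant_sasa = sasa_profile(mutant)
            fv = build_feature_vector(
                rec, mutant, mutant_sasa, pssms[rec.protein_id], conservation,
            )
            x = fv.to_array()
            _, _, loc = mutant_sasa.for_residue(rec.chain, rec.position, rec.icode)
        rows.append(x)
        locations.append(loc)

    features = pd.DataFrame(np.vstack(rows), columns=list(FEATURE_NAMES))
    return Bundle(
        spec=spec, structures=structures, pdb_texts=pdb_texts,
        pssm_texts=pssm_texts, pssms=pssms, sasa=sasa_profiles,
        conservation=conservation, dataset=dataset, features=features,
        locations=locations,
    )


def write_bundle(bundle: Bundle, directory: str | Path) -> None:
    """Materialize a bundle as the file tree the real pipeline reads:
    structures/<id>.pdb, pssm/<id>.pssm, conservation.tsv, mutations.csv,
    features.csv."""
    directory = Path(directory)
    (directory / "structures").mkdir(parents=True, exist_ok=True)
    (directory / "pssm").mkdir(exist_ok=True)
    for pid, text in bundle.pdb_texts.items():
        (directory / "structures" / f"{pid}.pdb").write_text(text)
    for pid, text in bundle.pssm_texts.items():
        (directory / "pssm" / f"{pid}.pssm").write_text(text)
    bundle.conservation.to_tsv(directory / "conservation.tsv")
    write_mutation_table(bundle.dataset, directory / "mutations.csv")
    out = bundle.features.copy()
    out.insert(0, "mutation", [r.label for r in bundle.dataset.records])
    out["ddg"] = bundle.dataset.ddg_array()
    out["direction"] = [r.direction for r in bundle.dataset.records]
    out["location"] = bundle.locations
    out.to_csv(directory / "features.csv", index=False)
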