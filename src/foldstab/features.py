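"""The ten-feature descriptor of a missense mutation.

The scoring function sees each mutation through ten numbers in six groups:

==============  ===============================================================
feature         meaning
==============  ===============================================================
pssm            change in PSI-BLAST log-odds at the site (mut - wt by default)
delta_cs        change of a PROVEAN-style conservation score upon mutation
delta_omh       hydrophobicity-scale difference, OMH[mut] - OMH[wt]
sasa_pro        absolute SASA (A^2) of the mutated residue in the structure
sasa_sol        SASA of the wild-type residue in an extended tripeptide (A^2)
p_fwy           fraction of residues that are buried aromatics (F/W/Y)
p_rkde          fraction of residues that are buried charged (R/K/D/E)
p_l             fraction of residues that are buried leucines
n_hydro         hydrophobic residues (VILFMWYC) in a 23-residue window
n_charg         charged residues (RKDE) in the same window
==============  ===============================================================

Forward mutations are featurized on the wild-type structure and sequence;
reverse mutations on the (naively) mutated structure and mutant sequence,
reusing the wild-type protein's PSSM with the roles of the two residues
swapped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import tables
from .errors import (
    ConsistencyError,
    FormatError,
    MissingFeatureError,
    ValidationError,
)
from .structure import BACKBONE_ATOMS, Residue, SasaProfile, Structure

FEATURE_NAMES = (
    "pssm",
    "delta_cs",
    "delta_omh",
    "sasa_pro",
    "sasa_sol",
    "p_fwy",
    "p_rkde",
    "p_l",
    "n_hydro",
    "n_charg",
)

WINDOW_HALF_WIDTH = 11  # 23 sites centered on the mutated position

PSSM_CONVENTIONS = ("diff", "wt", "mut")


@dataclass
class PssmProfile:
    """Per-position log-odds scores from a PSI-BLAST ASCII PSSM."""

    sequence: str
    scores: np.ndarray  # (L, 20) in tables.PSSM_ALPHABET column order

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sequence), 20):
            raise FormatError(
                f"PSSM shape {self.scores.shape} does not match sequence length "
                f"{len(self.sequence)}"
            )

    def score(self, position: int, aa: str) -> float:
        """Log-odds of ``aa`` at 1-based ``position``."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside profile of length {len(self.sequence)}")
        col = tables.PSSM_ALPHABET.find(aa)
        if col < 0:
            from .errors import AminoAcidError

            raise AminoAcidError(f"unknown amino acid {aa!r}")
        return float(self.scores[position - 1, col])


def read_psiblast_pssm(source) -> PssmProfile:
    """Parse the ASCII PSSM emitted by ``psiblast -out_ascii_pssm``.

    Handles both the 40-column dialect (log-odds block followed by weighted
    percentages) and files carrying only the 20 log-odds columns; only the
    log-odds block is retained.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if text and "\n" not in text:
            p = Path(text)
            if p.is_file():
                text = p.read_text()
    lines = text.splitlines()

    header_cols: list[str] | None = None
    rows: list[tuple[int, str, list[int]]] = []
    row_re = re.compile(r"^\s*(\d+)\s+([A-Z])\s+(-?\d+(?:\s+-?\d+)*)")
    for line in lines:
        stripped = line.strip()
        if header_cols is None:
            parts = stripped.split()
            if len(parts) >= 20 and all(p in tables.PSSM_ALPHABET and len(p) == 1 for p in parts[:20]):
                header_cols = parts[:20]
            continue
        m = row_re.match(line)
        if not m:
            if rows:
                break  # footer (K, lambda...) reached
            continue
        pos = int(m.group(1))
        aa = m.group(2)
        values = [int(v) for v in m.group(3).split()]
        if len(values) < 20:
            raise FormatError(f"PSSM row {pos} has {len(values)} scores, expected >= 20")
        rows.append((pos, aa, values[:20]))

    if header_cols is None or not rows:
        raise FormatError("not a PSI-BLAST ASCII PSSM (no alphabet header or score rows)")

    order = [header_cols.index(a) for a in tables.PSSM_ALPHABET]
    seq = "".join(aa for _, aa, _ in rows)
    mat = np.array([[vals[j] for j in order] for _, _, vals in rows], dtype=float)
    expected = list(range(1, len(rows) + 1))
    if [p for p, _, _ in rows] != expected:
        raise FormatError("PSSM positions are not consecutive from 1")
    return PssmProfile(sequence=seq, scores=mat)


def pssm_feature(
    profile: PssmProfile,
    position: int,
    wt: str,
    mut: str,
    convention: str = "diff",
    expect: str | None = None,
) -> float:
    """PSSM feature at a 1-based sequence position.

    ``convention`` selects what is extracted: ``"diff"`` (default) is
    score(mut) - score(wt); ``"wt"`` and ``"mut"`` return the single scores.
    ``expect`` overrides the residue checked against the profile sequence
    (used for reverse mutations, whose profile is the wild-type protein's).
    """
    if convention not in PSSM_CONVENTIONS:
        raise ValueError(f"unknown PSSM convention {convention!r}")
    check = wt if expect is None else expect
    if profile.sequence[position - 1] != check:
        raise ConsistencyError(
            f"profile sequence has {profile.sequence[position - 1]!r} at position "
            f"{position}, expected {check!r}"
        )
    if convention == "wt":
        return profile.score(position, wt)
    if convention == "mut":
        return profile.score(position, mut)
    return profile.score(position, mut) - profile.score(position, wt)


def delta_omh(wt: str, mut: str, scale: dict[str, float] | None = None) -> float:
    """Hydrophobicity change, scale(mut) - scale(wt); antisymmetric by construction."""
    table = scale if scale is not None else tables.OMH
    return tables.scale_value(table, mut, what="OMH") - tables.scale_value(table, wt, what="OMH")


@dataclass
class ConservationTable:
    """(protein, position, wt, mut) -> change-of-conservation score.

    ``default`` (when set) is returned for mutations absent from the table,
    which large scans (e.g. alanine scanning) typically need.
    """

    data: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    default: float | None = None

    def get(self, protein: str, position: int, wt: str, mut: str) -> float:
        try:
            value = self.data[(protein, position, wt, mut)]
        except KeyError:
            if self.default is not None:
                return float(self.default)
            raise MissingFeatureError(
                "conservation",
                f"no conservation score for {protein} {wt}{position}{mut}",
            ) from None
        if not np.isfinite(value):
            raise ValidationError("conservation scores must be finite")
        return float(value)

    def set(self, protein: str, position: int, wt: str, mut: str, value: float) -> None:
        self.data[(protein, position, wt, mut)] = float(value)

    @classmethod
    def from_tsv(cls, path) -> "ConservationTable":
        df = pd.read_csv(path, sep="\t")
        required = {"protein", "pos", "wt", "mut", "score"}
        missing = required - set(df.columns)
        if missing:
            from .errors import SchemaError

            raise SchemaError(f"conservation table missing columns: {sorted(missing)}")
        table = cls()
        for row in df.itertuples(index=False):
            table.set(str(row.protein), int(row.pos), str(row.wt), str(row.mut), float(row.score))
        return table

    def to_tsv(self, path) -> None:
        rows = [
            {"protein": p, "chain": "", "pos": pos, "wt": wt, "mut": mut, "score": v}
            for (p, pos, wt, mut), v in sorted(self.data.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class BurialComposition:
    """Counts and fractions of core-buried aromatic/charged/leucine residues."""

    n_all: int
    n_fwy: int
    n_rkde: int
    n_l: int

    @property
    def p_fwy(self) -> float:
        return self.n_fwy / self.n_all

    @property
    def p_rkde(self) -> float:
        return self.n_rkde / self.n_all

    @property
    def p_l(self) -> float:
        return self.n_l / self.n_all


def burial_composition(structure: Structure, sasa: SasaProfile) -> BurialComposition:
    """Fractions of buried aromatic (F/W/Y), charged (R/K/D/E) and leucine residues
    over all residues of the assigned chains."""
    n_all = n_fwy = n_rkde = n_l = 0
    for res in structure.residues():
        _, _, loc = sasa.for_residue(*res.key)
        n_all += 1
        if loc == "COR":
            if res.aa in tables.AROMATIC:
                n_fwy += 1
            if res.aa in tables.CHARGED:
                n_rkde += 1
            if res.aa == "L":
                n_l += 1
    if n_all == 0:
        raise ValidationError("structure has no residues")
    return BurialComposition(n_all, n_fwy, n_rkde, n_l)


def window_counts(sequence: str, position: int) -> tuple[int, int]:
    """Hydrophobic and charged residue counts in the 23-site window centred on
    1-based ``position``; the window truncates at the termini."""
    if not 1 <= position <= len(sequence):
        raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
    lo = max(0, position - 1 - WINDOW_HALF_WIDTH)
    hi = min(len(sequence), position + WINDOW_HALF_WIDTH)
    window = sequence[lo:hi]
    n_hydro = sum(1 for c in window if c in tables.HYDROPHOBIC)
    n_charg = sum(1 for c in window if c in tables.CHARGED)
    return n_hydro, n_charg


def mutate_structure_naive(
    structure: Structure,
    chain: str,
    position: int,
    wt: str,
    mut: str,
    icode: str = "",
) -> Structure:
    """Relabel a residue and truncate its side chain beyond C-beta.

    This is a deliberately minimal mutant-structure builder: the backbone and
    C-beta are kept in place (for a glycine target everything beyond C-alpha
    is dropped), no repacking is attempted.  An externally modelled mutant
    structure can be supplied instead wherever a Structure is accepted.
    """
    res = structure.get_residue(chain, position, icode)
    if res.aa != wt:
        raise ConsistencyError(
            f"wild-type mismatch at {chain}:{position}{icode}: structure has "
            f"{res.aa}, mutation says {wt}"
        )
    mutated = structure.copy()
    target = mutated.get_residue(chain, position, icode)
    target.aa = mut
    if wt == mut:
        return mutated
    keep = set(BACKBONE_ATOMS)
    if mut != "G":
        keep.add("CB")
    target.atoms = [a for a in target.atoms if a.name in keep]
    return mutated


@dataclass
class FeatureVector:
    """The ten model features for one mutation."""

    pssm: float
    delta_cs: float
    delta_omh: float
    sasa_pro: float
    sasa_sol: float
    p_fwy: float
    p_rkde: float
    p_l: float
    n_hydro: int
    n_charg: int

    def __post_init__(self):
        values = self.to_array()
        if not np.all(np.isfinite(values)):
            raise ValidationError("feature vector contains non-finite values")
        if not (0 <= self.n_hydro <= 23 and 0 <= self.n_charg <= 23):
            raise ValidationError("window counts must be in [0, 23]")
        for frac in (self.p_fwy, self.p_rkde, self.p_l):
            if not 0 <= frac <= 1:
                raise ValidationError("burial fractions must be in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}


def build_feature_vector(
    mutation,
    structure: Structure,
    sasa: SasaProfile,
    pssm: PssmProfile | None,
    conservation: ConservationTable | None,
    pssm_convention: str = "diff",
    sequence: str | None = None,
) -> FeatureVector:
    """Assemble the ten features for one mutation record.

    ``mutation`` needs attributes protein_id, chain, position, icode, wt, mut
    and direction.  ``structure``/``sasa`` must already be the appropriate
    ones for the record's direction (wild-type for forward, mutant for
    reverse).  ``sequence`` overrides the sequence used for window counts and
    conservation positions (default: the structure's own residue sequence).
    """
    res = structure.get_residue(mutation.chain, mutation.position, mutation.icode)
    if res.aa != mutation.wt:
        raise ConsistencyError(
            f"wild-type mismatch at {mutation.chain}:{mutation.position}"
            f"{mutation.icode}: structure has {res.aa}, record says {mutation.wt}"
        )
    try:
        abs_sasa, _, _ = sasa.for_residue(*res.key)
    except Exception as exc:
        raise MissingFeatureError("sasa", str(exc)) from exc

    seq = sequence if sequence is not None else structure.sequence()
    seq_pos = structure.seq_index(mutation.chain, mutation.position, mutation.icode)
    if seq[seq_pos - 1] != mutation.wt:
        raise ConsistencyError(
            f"sequence has {seq[seq_pos - 1]!r} at index {seq_pos}, record says {mutation.wt!r}"
        )

    if pssm is None:
        raise MissingFeatureError("pssm")
    expect = mutation.mut if getattr(mutation, "direction", "forward") == "reverse" else None
    pssm_score = pssm_feature(
        pssm, seq_pos, mutation.wt, mutation.mut, convention=pssm_convention, expect=expect
    )

    if conservation is None:
        raise MissingFeatureError("conservation")
    dcs = conservation.get(mutation.protein_id, seq_pos, mutation.wt, mutation.mut)

    comp = burial_composition(structure, sasa)
    n_hydro, n_charg = window_counts(seq, seq_pos)

    return FeatureVector(
        pssm=pssm_score,
        delta_cs=dcs,
        delta_omh=delta_omh(mutation.wt, mutation.mut),
        sasa_pro=float(abs_sasa),
        sasa_sol=tables.scale_value(tables.MAX_ASA, mutation.wt, what="tripeptide SASA"),
        p_fwy=comp.p_fwy,
        p_rkde=comp.p_rkde,
        p_l=comp.p_l,
        n_hydro=n_hydro,
        n_charg=n_charg,
    )


def feature_frame(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into a DataFrame with the canonical column order."""
    return pd.DataFrame([v.to_dict() for v in vectors], columns=list(FEATURE_NAMES))


def featurize_dataset(
    dataset,
    structures: dict[str, Structure],
    pssms: dict[str, PssmProfile],
    conservation: ConservationTable,
    pssm_convention: str = "diff",
    sphere_points: int = 960,
):
    """Featurize every record of a mutation dataset.

    Forward records are computed on the wild-type structure (SASA profiles
    cached per protein); reverse records on a naively mutated copy.  Records
    whose providers fail are skipped and reported.

    Returns ``(X, kept_indices, locations, errors)`` where ``X`` is a
    DataFrame of the kept rows, ``locations`` the COR/SUR label of each kept
    mutated site, and ``errors`` a list of (record, reason) pairs.
    """
    from .structure import sasa_profile as _sasa_profile

    wt_sasa_cache: dict[str, SasaProfile] = {}
    rows, kept, locations, errors = [], [], [], []
    for i, rec in enumerate(dataset.records):
        try:
            structure = structures[rec.protein_id]
        except KeyError:
            errors.append((rec, "no structure for protein"))
            continue
        try:
            pssm = pssms[rec.protein_id]
        except KeyError:
            errors.append((rec, "no PSSM for protein"))
            continue
        try:
            if rec.direction == "reverse":
                target = mutate_structure_naive(
                    structure, rec.chain, rec.position, wt=rec.mut, mut=rec.wt,
                    icode=rec.icode,
                )
                sasa = _sasa_profile(target, sphere_points=sphere_points)
            else:
                target = structure
                if rec.protein_id not in wt_sasa_cache:
                    wt_sasa_cache[rec.protein_id] = _sasa_profile(
                        structure, sphere_points=sphere_points
                    )
                sasa = wt_sasa_cache[rec.protein_id]
            fv = build_feature_vector(
                rec, target, sasa, pssm, conservation, pssm_convention=pssm_convention
            )
            _, _, loc = sasa.for_residue(rec.chain, rec.position, rec.icode)
        except Exception as exc:
            errors.append((rec, str(exc)))
            continue
        rows.append(fv.to_dict())
        kept.append(i)
        locations.append(loc)
    X = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    return X, kept, locations, errors
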