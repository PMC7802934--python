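"""Bundled amino-acid reference tables.

Three small per-residue tables drive the scoring function:

* ``MAX_ASA`` — solvent accessible surface area (A^2) of residue X in an
  extended Gly-X-Gly tripeptide (Miller, Janin, Lesk & Chothia, J Mol Biol
  1987).  Used as the denominator of relative SASA and directly as the
  SASA_sol feature.
* ``OMH`` — observed/optimal matching hydrophobicity scale (Sweet &
  Eisenberg, J Mol Biol 1983), derived from observed replacement
  frequencies in homologous structures.  The dOMH feature is
  ``OMH[mut] - OMH[wt]``.
* ``VDW_RADII`` — per-element van der Waals radii (A) used by the
  Shrake-Rupley SASA implementation (Bondi-style values).

Each table can be overridden from a two-column TSV or a JSON object via
:func:`load_scale`.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import AminoAcidError, FormatError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: column order of a PSI-BLAST ASCII PSSM log-odds block
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}

# residue classes used by the composition and window features
AROMATIC = frozenset("FWY")
CHARGED = frozenset("RKDE")
HYDROPHOBIC = frozenset("VILFMWYC")

# Miller et al. 1987, extended Gly-X-Gly tripeptide ASA (A^2)
MAX_ASA = {
    "A": 113.0, "R": 241.0, "N": 158.0, "D": 151.0, "C": 140.0,
    "Q": 189.0, "E": 183.0, "G": 85.0, "H": 194.0, "I": 182.0,
    "L": 180.0, "K": 211.0, "M": 204.0, "F": 218.0, "P": 143.0,
    "S": 122.0, "T": 146.0, "W": 259.0, "Y": 229.0, "V": 160.0,
}

# Sweet & Eisenberg 1983, optimal matching hydrophobicity
OMH = {
    "A": -0.40, "R": -0.59, "N": -0.92, "D": -1.31, "C": 0.17,
    "Q": -0.91, "E": -1.22, "G": -0.67, "H": -0.64, "I": 1.25,
    "L": 1.22, "K": -0.67, "M": 1.02, "F": 1.92, "P": -0.49,
    "S": -0.55, "T": -0.28, "W": 0.50, "Y": 1.67, "V": 0.91,
}

# heavy-atom van der Waals radii (A); hydrogens are ignored for SASA
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75,
    "BR": 1.85, "I": 1.98, "H": 1.20, "D": 1.20,
}
DEFAULT_VDW_RADIUS = 1.70


def scale_value(scale: dict, aa: str, *, what: str = "scale") -> float:
    """Look up ``aa`` in a per-residue table, raising :class:`AminoAcidError` if absent."""
    try:
        return scale[aa]
    except KeyError:
        raise AminoAcidError(f"amino acid {aa!r} not in {what} table") from None


def load_scale(path: str | Path) -> dict[str, float]:
    """Read a per-amino-acid table from JSON (``{"A": 113.0, ...}``) or
    two-column whitespace/tab-separated text."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json" or text.lstrip().startswith("{"):
        data = json.loads(text)
        return {str(k): float(v) for k, v in data.items()}
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"bad scale line in {path}: {line!r}")
        table[parts[0]] = float(parts[1])
    if not table:
        raise FormatError(f"no entries found in scale file {path}")
    return table
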