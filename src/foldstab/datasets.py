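"""Mutation/ddG datasets and their curation.

Implements the bookkeeping around experimental stability data: reading
mutation tables, doubling a forward set with its thermodynamic reverse
(ddG_F + ddG_R = 0), splitting by sign, merging overlapping test sets with
a conflict window, and clustering proteins by sequence identity for
leave-cluster-out validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

Key = tuple[str, str, int, str, str, str, str]  # protein, chain, pos, icode, wt, mut, direction


@dataclass
class MutationRecord:
    """A single missense mutation, optionally with its measured ddG (kcal/mol,
    positive = destabilizing)."""

    protein_id: str
    chain: str
    position: int
    wt: str
    mut: str
    icode: str = ""
    structure_id: str | None = None
    ddg: float | None = None
    direction: str = "forward"
    pair_id: int | None = None

    def __post_init__(self):
        if self.wt == self.mut:
            raise ValidationError(f"wt and mut are both {self.wt!r}")
        if self.direction not in ("forward", "reverse"):
            raise ValidationError(f"bad direction {self.direction!r}")

    @property
    def key(self) -> Key:
        # structure_id deliberately excluded: the same mutation mapped to two
        # structures is one mutation for dedup purposes
        return (self.protein_id, self.chain, self.position, self.icode,
                self.wt, self.mut, self.direction)

    @property
    def site_key(self) -> tuple[str, str, int, str, str, str]:
        """Key ignoring direction (used for overlap removal)."""
        return (self.protein_id, self.chain, self.position, self.icode, self.wt, self.mut)

    @property
    def label(self) -> str:
        return f"{self.protein_id}/{self.chain}:{self.wt}{self.position}{self.icode}{self.mut}"


@dataclass
class MutationDataset:
    name: str
    records: list[MutationRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for r in self.records:
            if r.key in seen:
                raise SchemaError(f"duplicate mutation key: {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def proteins(self) -> list[str]:
        return sorted({r.protein_id for r in self.records})

    def forward(self) -> "MutationDataset":
        return MutationDataset(self.name, [r for r in self.records if r.direction == "forward"],
                               list(self.provenance))

    def ddg_array(self) -> np.ndarray:
        values = []
        for r in self.records:
            if r.ddg is None:
                raise ValidationError(f"record {r.label} has no experimental ddG")
            values.append(r.ddg)
        return np.asarray(values, dtype=float)


DEFAULT_COLUMNS = {
    "protein": "protein",
    "chain": "chain",
    "position": "position",
    "wt": "wt",
    "mut": "mut",
    "ddg": "ddg",
}


def read_mutation_table(
    source,
    name: str = "dataset",
    columns: dict[str, str] | None = None,
    sep: str | None = None,
    sign_flip: bool = False,
    on_duplicate: str = "error",
) -> MutationDataset:
    """Read a CSV/TSV mutation table into a :class:`MutationDataset`.

    ``columns`` remaps logical column names (protein, chain, position, wt,
    mut, ddg) onto the file's headers.  ``sign_flip`` negates ddG for tables
    using the opposite sign convention.  ``on_duplicate`` is ``"error"``,
    ``"first"`` or ``"mean"``.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    if sep is None:
        sep = "\t" if str(source).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(source, sep=sep)
    required = [colmap[k] for k in ("protein", "chain", "position", "wt", "mut")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table missing columns: {missing}")
    has_ddg = colmap["ddg"] in df.columns

    records: dict[Key, list[MutationRecord]] = {}
    for row in df.itertuples(index=False):
        row = row._asdict()
        pos_raw = str(row[colmap["position"]]).strip()
        icode = ""
        if pos_raw and pos_raw[-1].isalpha():
            pos_raw, icode = pos_raw[:-1], pos_raw[-1]
        try:
            position = int(float(pos_raw))
        except ValueError:
            raise SchemaError(f"unparseable position {row[colmap['position']]!r}") from None
        ddg = None
        if has_ddg and not pd.isna(row[colmap["ddg"]]):
            try:
                ddg = float(row[colmap["ddg"]])
            except (TypeError, ValueError):
                raise ValidationError(f"unparseable ddG value {row[colmap['ddg']]!r}") from None
            if sign_flip:
                ddg = -ddg
        rec = MutationRecord(
            protein_id=str(row[colmap["protein"]]),
            chain=str(row[colmap["chain"]]),
            position=position,
            icode=icode,
            wt=str(row[colmap["wt"]]).strip().upper(),
            mut=str(row[colmap["mut"]]).strip().upper(),
            structure_id=str(row["structure"]) if "structure" in row else None,
            ddg=ddg,
        )
        records.setdefault(rec.key, []).append(rec)

    out: list[MutationRecord] = []
    for key, group in records.items():
        if len(group) == 1:
            out.append(group[0])
        elif on_duplicate == "error":
            raise SchemaError(f"duplicate mutation key in table: {key}")
        elif on_duplicate == "first":
            out.append(group[0])
        elif on_duplicate == "mean":
            ddgs = [g.ddg for g in group if g.ddg is not None]
            merged = replace(group[0], ddg=float(np.mean(ddgs)) if ddgs else None)
            out.append(merged)
        else:
            raise ValueError(f"unknown duplicate policy {on_duplicate!r}")
    return MutationDataset(name, out, [f"read from {source}"])


def write_mutation_table(dataset: MutationDataset, path: str | Path) -> None:
    rows = [
        {
            "protein": r.protein_id, "structure": r.structure_id or "",
            "chain": r.chain, "position": f"{r.position}{r.icode}",
            "wt": r.wt, "mut": r.mut,
            "ddg": "" if r.ddg is None else r.ddg,
            "direction": r.direction,
            "pair_id": "" if r.pair_id is None else r.pair_id,
        }
        for r in dataset.records
    ]
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_augmented_table(path, name: str = "dataset") -> MutationDataset:
    """Read back a table written by :func:`write_mutation_table`, preserving
    direction and forward/reverse pair linkage."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"protein", "chain", "position", "wt", "mut"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"mutation table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pos_raw = str(row.position).strip()
        icode = ""
        if pos_raw and pos_raw[-1].isalpha():
            pos_raw, icode = pos_raw[:-1], pos_raw[-1]
        ddg = getattr(row, "ddg", None)
        ddg = None if ddg is None or pd.isna(ddg) else float(ddg)
        pair = getattr(row, "pair_id", None)
        pair = None if pair is None or pd.isna(pair) else int(pair)
        structure = getattr(row, "structure", None)
        records.append(MutationRecord(
            protein_id=str(row.protein), chain=str(row.chain),
            position=int(float(pos_raw)), icode=icode,
            wt=str(row.wt).strip().upper(), mut=str(row.mut).strip().upper(),
            structure_id=None if structure is None or pd.isna(structure) else str(structure),
            ddg=ddg,
            direction=str(getattr(row, "direction", "forward")),
            pair_id=pair,
        ))
    return MutationDataset(name, records, [f"read from {path}"])


def augment_with_reverse(dataset: MutationDataset) -> MutationDataset:
    """Double a forward dataset with reverse mutations.

    Each forward record gains a partner with wt/mut swapped and ddG negated,
    linked through ``pair_id``; output size is exactly twice the input.
    """
    if any(r.direction != "forward" for r in dataset.records):
        raise ValidationError("dataset already contains reverse records; cannot augment again")
    out: list[MutationRecord] = []
    for pair_id, rec in enumerate(dataset.records):
        fwd = replace(rec, pair_id=pair_id)
        rev = replace(
            rec,
            wt=rec.mut,
            mut=rec.wt,
            ddg=None if rec.ddg is None else -rec.ddg,
            direction="reverse",
            pair_id=pair_id,
        )
        out.extend([fwd, rev])
    return MutationDataset(
        dataset.name + "+reverse", out, dataset.provenance + ["reverse-augmented"]
    )


def split_by_sign(dataset: MutationDataset) -> tuple[MutationDataset, MutationDataset]:
    """Partition into destabilizing (ddG >= 0) and stabilizing (ddG < 0) subsets."""
    destab, stab = [], []
    for r in dataset.records:
        if r.ddg is None:
            raise ValidationError(f"record {r.label} has no ddG; cannot split by sign")
        (destab if r.ddg >= 0 else stab).append(r)
    return (
        MutationDataset(dataset.name + ":destabilizing", destab),
        MutationDataset(dataset.name + ":stabilizing", stab),
    )


def merge_test_sets(
    sets: Sequence[MutationDataset],
    training: MutationDataset,
    conflict_window: float = 1.0,
    name: str = "merged",
) -> MutationDataset:
    """Union independent test sets into one, resolving repeated measurements.

    A mutation measured several times is kept at the mean ddG only if the
    spread (max - min) is strictly below ``conflict_window`` kcal/mol;
    otherwise all its entries are dropped.  Any mutation present in
    ``training`` (either direction) is removed.
    """
    train_keys = {r.site_key for r in training.records}
    groups: dict[tuple, list[MutationRecord]] = {}
    order: list[tuple] = []
    for ds in sets:
        for r in ds.records:
            k = r.site_key
            if k not in groups:
                groups[k] = []
                order.append(k)
            groups[k].append(r)

    out: list[MutationRecord] = []
    for k in order:
        if k in train_keys:
            continue
        group = groups[k]
        ddgs = sorted({g.ddg for g in group if g.ddg is not None})
        if len(ddgs) <= 1:
            rec = group[0]
            if ddgs:
                rec = replace(rec, ddg=ddgs[0])
            out.append(rec)
            continue
        if max(ddgs) - min(ddgs) < conflict_window:
            out.append(replace(group[0], ddg=float(np.mean(ddgs))))
        # else: conflicting measurements, drop all entries
    return MutationDataset(name, out, [f"merged {len(sets)} sets, window {conflict_window}"])


@dataclass
class ProteinCluster:
    cluster_id: int
    members: list[str]


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


@dataclass
class AlignmentStats:
    """Summary of one global pairwise alignment."""

    identity: float  # identical pairs / aligned (ungapped) columns
    coverage_a: float  # aligned columns / len(a)
    coverage_b: float  # aligned columns / len(b)
    score: float  # BLOSUM62 alignment score


def pairwise_identity(seq_a: str, seq_b: str) -> AlignmentStats:
    """Global-alignment identity, mutual coverage and score.

    BLOSUM62 with affine gaps (-11/-1).  Note that optimal alignments of
    *unrelated* random sequences still reach ~20-25% identity, so identity
    alone cannot attest homology; the alignment score does (negative for
    unrelated pairs), and clustering requires it to be positive.
    """
    from Bio.Align import PairwiseAligner, substitution_matrices

    if not seq_a or not seq_b:
        raise ValidationError("cannot align an empty sequence")
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    alignment = aligner.align(seq_a, seq_b)[0]
    identities = mismatches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            if seq_a[i] == seq_b[j]:
                identities += 1
            else:
                mismatches += 1
    aligned_cols = identities + mismatches
    if aligned_cols == 0:
        return AlignmentStats(0.0, 0.0, 0.0, float(alignment.score))
    return AlignmentStats(
        identity=identities / aligned_cols,
        coverage_a=aligned_cols / len(seq_a),
        coverage_b=aligned_cols / len(seq_b),
        score=float(alignment.score),
    )


def cluster_proteins(
    sequences: dict[str, str],
    identity_threshold: float = 0.25,
    coverage_threshold: float = 0.5,
) -> list[ProteinCluster]:
    """Single-linkage clusters of proteins sharing > ``identity_threshold``
    sequence identity with mutual coverage >= ``coverage_threshold``.

    A pair is linked when identity and both coverages pass their thresholds
    *and* the global BLOSUM62 score is positive (a significance guard:
    unrelated random sequences reach ~25% identity by optimal alignment but
    always score negative).  The partition is independent of input order:
    edges are evaluated for every unordered pair and clusters are numbered
    by their lexicographically smallest member.
    """
    if not sequences:
        raise ValidationError("no sequences to cluster")
    for pid, seq in sequences.items():
        if not seq:
            raise ValidationError(f"empty sequence for protein {pid!r}")
    names = sorted(sequences)
    uf = _UnionFind(names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            stats = pairwise_identity(sequences[a], sequences[b])
            if (
                stats.identity > identity_threshold
                and stats.coverage_a >= coverage_threshold
                and stats.coverage_b >= coverage_threshold
                and stats.score > 0
            ):
                uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(uf.find(n), []).append(n)
    clusters = [
        ProteinCluster(cid, sorted(members))
        for cid, (_, members) in enumerate(sorted(groups.items()))
    ]
    return clusters


def write_clusters_tsv(clusters: Sequence[ProteinCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tcluster\n")
        for c in clusters:
            for m in c.members:
                fh.write(f"{m}\t{c.cluster_id}\n")


def read_clusters_tsv(path: str | Path) -> list[ProteinCluster]:
    df = pd.read_csv(path, sep="\t")
    if not {"protein", "cluster"} <= set(df.columns):
        raise SchemaError("cluster file needs 'protein' and 'cluster' columns")
    groups: dict[int, list[str]] = {}
    for row in df.itertuples(index=False):
        groups.setdefault(int(row.cluster), []).append(str(row.protein))
    return [ProteinCluster(cid, sorted(members)) for cid, members in sorted(groups.items())]


@dataclass
class StructureCandidate:
    """Metadata for ranking alternative structures of the same protein."""

    structure_id: str
    oligomeric_state: str = "monomer"  # monomer | homomer | heteromer
    is_wild_type: bool = True
    n_ligands: int = 0
    method: str = "xray"  # xray | nmr | cryoem
    resolution: float | None = None


def rank_structure_candidates(
    candidates: Sequence[StructureCandidate],
    max_resolution: float = 3.0,
) -> list[StructureCandidate]:
    """Order candidate structures best-first by the curation criteria:
    monomer/homomer over heteromer, wild type over mutant, fewer ligands,
    crystal over NMR, then higher (numerically smaller) resolution; crystal
    structures worse than ``max_resolution`` sort after everything eligible."""
    def sort_key(c: StructureCandidate):
        hetero = 1 if c.oligomeric_state == "heteromer" else 0
        mutant = 0 if c.is_wild_type else 1
        is_nmr = 1 if c.method == "nmr" else 0
        res = c.resolution if c.resolution is not None else float("inf")
        too_low = 1 if (c.method != "nmr" and res > max_resolution) else 0
        return (too_low, hetero, mutant, c.n_ligands, is_nmr, res, c.structure_id)

    return sorted(candidates, key=sort_key)
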