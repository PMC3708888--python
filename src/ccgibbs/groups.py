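"""Group incidence matrices and (optional) structure decomposition.

The group-contribution layer approximates a compound's formation energy as a
sum of energies of structural subgroups.  The chemistry — which subgroups
exist and how a structure decomposes into them — is a pluggable input here:
a group incidence matrix G (compounds × groups, integer counts) is read from
a TSV, or produced by a pattern-matching backend (RDKit SMARTS) when compound
structures are available.  The regression mathematics never depends on the
particular group table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ReactionVector

__all__ = [
    "GroupIncidence",
    "GroupDefinitionTable",
    "load_group_incidence",
    "write_group_incidence",
    "reaction_group_change",
    "decompose_structure",
    "UndecomposableError",
]


class UndecomposableError(KeyError):
    """A reaction involves compounds with no group decomposition."""


@dataclass(frozen=True)
class GroupDefinitionTable:
    """Ordered group definitions: (group_id, description, SMARTS pattern)."""

    rows: tuple[tuple[str, str, str], ...]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate group ids in definition table")

    @property
    def group_ids(self) -> list[str]:
        return [r[0] for r in self.rows]


@dataclass
class GroupIncidence:
    """Compounds × groups incidence matrix with index bookkeeping.

    ``undecomposable`` flags compounds that have no decomposition; their rows
    are all-zero and any query touching them (without cancellation) falls on
    the infinite-uncertainty path of the estimator.
    """

    G: np.ndarray
    compound_index: list[str]
    group_index: list[str]
    undecomposable: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (len(self.compound_index), len(self.group_index)):
            raise ValueError("G shape inconsistent with indices")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G contains non-finite entries")
        if not np.allclose(self.G, np.round(self.G)):
            raise ValueError("G entries must be integers")

    def row(self, compound_id: str) -> np.ndarray:
        try:
            i = self.compound_index.index(compound_id)
        except ValueError:
            raise KeyError(f"compound {compound_id!r} not in group incidence") from None
        return self.G[i]


def load_group_incidence(path, compound_index: list[str]) -> GroupIncidence:
    """Read a long-format incidence TSV (compound_id, group_id, count).

    The matrix is aligned to ``compound_index``; compounds absent from the
    file are flagged undecomposable (all-zero row).  Duplicate
    (compound, group) pairs are an input error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        group_ids: list[str] = []
        G = np.zeros((len(compound_index), 0))
        return GroupIncidence(G, list(compound_index), group_ids, set(compound_index))
    required = {"compound_id", "group_id", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"group incidence table needs columns {sorted(required)}")
    dup = df.duplicated(subset=["compound_id", "group_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["compound_id", "group_id"]].drop_duplicates()
        raise ValueError(
            "duplicate (compound, group) rows: "
            + "; ".join(f"{r.compound_id}/{r.group_id}" for r in pairs.itertuples())
        )
    group_ids = sorted(df["group_id"].astype(str).unique())
    gpos = {g: j for j, g in enumerate(group_ids)}
    cpos = {c: i for i, c in enumerate(compound_index)}
    G = np.zeros((len(compound_index), len(group_ids)))
    seen: set[str] = set()
    for row in df.itertuples():
        cid = str(row.compound_id)
        if cid not in cpos:
            continue  # compounds outside the training index are ignored
        G[cpos[cid], gpos[str(row.group_id)]] = float(row.count)
        seen.add(cid)
    undecomposable = set(compound_index) - seen
    return GroupIncidence(G, list(compound_index), group_ids, undecomposable)


def write_group_incidence(path, gi: GroupIncidence, header: str | None = None) -> None:
    rows = []
    for i, cid in enumerate(gi.compound_index):
        if cid in gi.undecomposable:
            continue
        for j, gid in enumerate(gi.group_index):
            if gi.G[i, j] != 0:
                rows.append({"compound_id": cid, "group_id": gid, "count": int(gi.G[i, j])})
            # all-zero decomposable compounds still need one marker row
        if not np.any(gi.G[i]):
            rows.append({"compound_id": cid, "group_id": gi.group_index[0] if gi.group_index else "g0", "count": 0})
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=["compound_id", "group_id", "count"]).to_csv(
            fh, sep="\t", index=False
        )


def reaction_group_change(gi: GroupIncidence, x: ReactionVector) -> np.ndarray:
    """Net group change Gᵀx of a reaction (length = number of groups).

    Raises :class:`UndecomposableError` naming the offending compounds if any
    reactant lacks a decomposition.
    """
    bad = [c for c in x.compounds() if c in gi.undecomposable]
    if bad:
        raise UndecomposableError(
            "undecomposable compound(s) in reaction: " + ", ".join(sorted(bad))
        )
    out = np.zeros(len(gi.group_index))
    for cid, coeff in x.coefficients:
        out += coeff * gi.row(cid)
    return out


def decompose_structure(structure: str, defs: GroupDefinitionTable, backend: str = "rdkit") -> np.ndarray:
    """Count substructure-pattern matches of each group in a molecule.

    ``structure`` is a SMILES string and the patterns are SMARTS; counting
    uses the backend's unique-match semantics.  Raises a capability error if
    the backend is unavailable — the rest of the package functions without
    structure decomposition.
    """
    if backend != "rdkit":
        raise NotImplementedError(f"unknown decomposition backend {backend!r}")
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - rdkit present in CI env
        raise RuntimeError(
            "structure decomposition requires rdkit; install the 'chem' extra"
        ) from exc
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {structure!r}")
    counts = np.zeros(len(defs.rows), dtype=int)
    for k, (_, _, pattern) in enumerate(defs.rows):
        patt = Chem.MolFromSmarts(pattern)
        if patt is None:
            raise ValueError(f"invalid SMARTS pattern {pattern!r}")
        counts[k] = len(mol.GetSubstructMatches(patt, uniquify=True))
    return counts
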