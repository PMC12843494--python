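"""Monte Carlo tree search for minimal predictive substructures (rationales).

Starting from the full molecule, the search deletes one peripheral fragment
at a time: any non-ring bond of the current subgraph may be cut, and either
resulting component becomes a child state.  Because only non-ring bonds are
ever deleted, ring systems are never fragmented — a terminal ring attached
through a single linker bond is removed whole, and fused systems travel
together.  Node value is the classifier's probability for the target class
on the substructure SMILES; selection uses a PUCT-style upper-confidence
bound with the node's own score as prior.

Returned rationales are all visited connected subgraphs inside the
[min_atoms, max_atoms] window whose score clears ``prop_delta``; on small
molecules a modest rollout budget enumerates the whole reachable space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import SmilesParseError

logger = logging.getLogger(__name__)

# scorer: substructure SMILES -> class-probability vector over {0,1,2}
Scorer = Callable[[str], Sequence[float]]


@dataclass
class MCTSConfig:
    """Search budget and rationale window."""

    rollouts: int = 20
    c_puct: float = 10.0
    max_atoms: int = 20
    min_atoms: int = 8
    prop_delta: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.min_atoms > self.max_atoms:
            raise ValueError("min_atoms must not exceed max_atoms")
        if not 0.0 < self.prop_delta < 1.0:
            raise ValueError("prop_delta must lie in (0,1)")


@dataclass(frozen=True)
class Rationale:
    """A connected substructure that keeps the target-class score high."""

    parent_id: str
    smiles: str
    atoms: frozenset[int]
    score: float
    target_class: int


class _Node:
    __slots__ = ("atoms", "smiles", "score", "children", "N", "W")

    def __init__(self, atoms: frozenset[int], smiles: str, score: float):
        self.atoms = atoms
        self.smiles = smiles
        self.score = score
        self.children: list["_Node"] | None = None  # None = unexpanded
        self.N = 0
        self.W = 0.0

    @property
    def Q(self) -> float:
        return self.W / self.N if self.N else 0.0


def _subgraph_smiles(mol: Chem.Mol, atoms: frozenset[int]) -> str:
    return Chem.MolFragmentToSmiles(mol, atomsToUse=sorted(atoms), canonical=True)


def _components(adj: dict[int, set[int]], atoms: frozenset[int],
                cut: tuple[int, int] | None = None) -> list[frozenset[int]]:
    """Connected components of the induced subgraph, optionally minus one bond."""
    remaining = set(atoms)
    comps = []
    while remaining:
        start = min(remaining)
        stack, comp = [start], set()
        while stack:
            a = stack.pop()
            if a in comp:
                continue
            comp.add(a)
            for b in adj[a]:
                if b not in atoms or b in comp:
                    continue
                if cut and {a, b} == set(cut):
                    continue
                stack.append(b)
        comps.append(frozenset(comp))
        remaining -= comp
    return comps


def _child_atom_sets(mol: Chem.Mol, adj: dict[int, set[int]],
                     atoms: frozenset[int]) -> list[frozenset[int]]:
    """Delete each peripheral (non-ring) bond; both components are children."""
    children: set[frozenset[int]] = set()
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i not in atoms or j not in atoms or bond.IsInRing():
            continue
        for comp in _components(adj, atoms, cut=(i, j)):
            if comp != atoms:
                children.add(comp)
    return sorted(children, key=lambda s: (len(s), sorted(s)))


def mcts_rationales(scorer: Scorer, smiles: str, target_class: int,
                    cfg: MCTSConfig | None = None, parent_id: str = "") -> set[Rationale]:
    """Search one molecule for rationales of the target class.

    Deterministic for a given config (tie-breaks are ordered); returns the
    empty set when no reachable subgraph in the size window clears
    ``prop_delta``.  Scorer failures prune the offending branch with a
    logged warning.
    """
    cfg = cfg or MCTSConfig()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    adj = {a.GetIdx(): {n.GetIdx() for n in a.GetNeighbors()} for a in mol.GetAtoms()}

    def score_atoms(atoms: frozenset[int]) -> tuple[str, float] | None:
        sub = _subgraph_smiles(mol, atoms)
        try:
            probs = scorer(sub)
            return sub, float(probs[target_class])
        except Exception as exc:  # scorer contract breach on this substructure
            logger.warning("scorer failed on %r (%s); branch pruned", sub, exc)
            return None

    all_atoms = frozenset(range(mol.GetNumAtoms()))
    rooted = score_atoms(all_atoms)
    if rooted is None:
        return set()
    root = _Node(all_atoms, *rooted)
    nodes: dict[frozenset[int], _Node] = {all_atoms: root}

    def expand(node: _Node):
        node.children = []
        for atoms in _child_atom_sets(mol, adj, node.atoms):
            if len(atoms) < 1:
                continue
            child = nodes.get(atoms)
            if child is None:
                scored = score_atoms(atoms)
                if scored is None:
                    continue
                child = _Node(atoms, *scored)
                nodes[atoms] = child
            node.children.append(child)

    for _ in range(cfg.rollouts):
        path = [root]
        node = root
        while True:
            if node.children is None:
                expand(node)
            if not node.children or len(node.atoms) <= cfg.min_atoms:
                break
            total_n = sum(c.N for c in node.children)
            node = max(
                node.children,
                key=lambda c: (c.Q + cfg.c_puct * c.score * math.sqrt(total_n) / (1 + c.N),
                               -len(c.atoms)),
            )
            path.append(node)
        value = node.score
        for n in path:
            n.N += 1
            n.W += value

    return {
        Rationale(parent_id, n.smiles, atoms, n.score, target_class)
        for atoms, n in nodes.items()
        if cfg.min_atoms <= len(atoms) <= cfg.max_atoms and n.score >= cfg.prop_delta
    }


def aggregate_rationales(rationales: Iterable[Rationale]) -> pd.DataFrame:
    """Group rationales by (class, canonical substructure).

    Returns a table with columns target_class, smiles, count, mean_score,
    sorted by count then mean score, both descending, within each class.
    Canonical-SMILES grouping is exact by design (reproducible clustering).
    """
    rows = [
        {
            "target_class": r.target_class,
            "smiles": Chem.CanonSmiles(r.smiles),
            "score": r.score,
        }
        for r in rationales
    ]
    if not rows:
        return pd.DataFrame(columns=["target_class", "smiles", "count", "mean_score"])
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["target_class", "smiles"], as_index=False)
        .agg(count=("score", "size"), mean_score=("score", "mean"))
        .sort_values(
            ["target_class", "count", "mean_score", "smiles"],
            ascending=[True, False, False, True],
        )
        .reset_index(drop=True)
    )
    return agg
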