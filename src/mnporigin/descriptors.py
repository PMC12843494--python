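"""Physicochemical profiling, scaffolds, fingerprint clustering, overlap counts.

Six drug-likeness descriptors (MW, AlogP, HBD, HBA, rotatable bonds, TPSA),
Murcko scaffold extraction (ring systems + inter-ring linkers), Morgan
fingerprints at a configurable environment radius, PCA + K-means structural
grouping, three-set Venn region counting, and per-kingdom top-N scaffold
frequency tables.

The Morgan radius defaults to 6 — an unusually wide environment radius kept
as an explicit knob (typical ECFP work uses radius 2–3).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .chem_io import LABELS, LabeledDataset, SmilesParseError


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def physchem_profile(ds: LabeledDataset) -> pd.DataFrame:
    """Six-descriptor table, one row per compound (index = compound id).

    Columns: MW (Da), AlogP, HBD, HBA, RotB (counts), PSA (Å²).
    """
    rows = {}
    for r in ds:
        mol = _mol(r.smiles)
        rows[r.id] = {
            "MW": Descriptors.MolWt(mol),
            "AlogP": Crippen.MolLogP(mol),
            "HBD": rdMolDescriptors.CalcNumHBD(mol),
            "HBA": rdMolDescriptors.CalcNumHBA(mol),
            "RotB": rdMolDescriptors.CalcNumRotatableBonds(mol),
            "PSA": rdMolDescriptors.CalcTPSA(mol),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df


def murcko_scaffold(smiles: str) -> str:
    """Murcko scaffold SMILES: all rings plus inter-ring linkers, side chains
    removed.  Acyclic molecules yield the empty string."""
    mol = _mol(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold.GetNumAtoms() else ""


def morgan_fp(smiles: str, nbits: int = 1024, radius: int = 6) -> np.ndarray:
    """Binary Morgan (ECFP-style) fingerprint of length ``nbits``."""
    mol = _mol(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return gen.GetFingerprintAsNumPy(mol).astype(np.uint8)


def morgan_fp_table(ds: LabeledDataset, nbits: int = 1024, radius: int = 6) -> pd.DataFrame:
    """Fingerprint matrix for a dataset (rows indexed by compound id)."""
    mat = np.vstack([morgan_fp(s, nbits, radius) for s in ds.smiles])
    return pd.DataFrame(mat, index=pd.Index(ds.ids, name="id"))


@dataclass
class ClusterAssignment:
    """K-means structural-group assignment over PCA-compressed fingerprints."""

    assignment: dict[str, int]
    k: int
    seed: int


def cluster_fingerprints(
    fps: pd.DataFrame,
    pca_dims: int = 85,
    k: int | str = 5000,
    seed: int = 0,
) -> ClusterAssignment:
    """PCA-compress fingerprints to ``pca_dims`` then K-means into ``k`` groups.

    ``k="auto"`` clamps to floor(n/2) for small inputs.  For explicit ``k``
    exceeding the number of points an error proposes that clamp.
    Deterministic for a fixed seed.
    """
    n = len(fps)
    if k == "auto":
        k = max(1, n // 2)
    k = int(k)
    if n < k:
        raise ValueError(
            f"cannot form k={k} clusters from n={n} points; try k={n // 2}"
        )
    dims = min(pca_dims, n, fps.shape[1])
    X = fps.to_numpy(dtype=float)
    if dims < X.shape[1]:
        X = PCA(n_components=dims, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    return ClusterAssignment(
        assignment={cid: int(lab) for cid, lab in zip(fps.index, labels)},
        k=k,
        seed=seed,
    )


_VENN_REGIONS = ("0", "1", "2", "01", "02", "12", "012")


def overlap_counts(sets_by_class: dict[int, set]) -> dict[str, int]:
    """Exclusive three-set Venn region counts.

    Keys are sorted label strings ("0", "01", "012", ...); each element of
    the union is counted in exactly one region, so the counts sum to the
    union's cardinality.
    """
    missing = set(LABELS) - set(sets_by_class)
    if missing:
        raise ValueError(f"need sets for all three classes; missing {sorted(missing)}")
    s0, s1, s2 = (sets_by_class[lab] for lab in LABELS)
    counts = {region: 0 for region in _VENN_REGIONS}
    for item in s0 | s1 | s2:
        region = "".join(
            str(lab) for lab, s in zip(LABELS, (s0, s1, s2)) if item in s
        )
        counts[region] += 1
    return counts


def top_scaffolds(
    ds: LabeledDataset, n: int = 20
) -> dict[int, list[tuple[str, int]]]:
    """Per-kingdom top-``n`` Murcko scaffolds as (scaffold, count) lists.

    Sorted by count descending with lexicographic tie-break on the canonical
    scaffold SMILES; acyclic (empty-scaffold) compounds are excluded as the
    "no ring" pseudo-scaffold carries no origin signal.
    """
    out: dict[int, list[tuple[str, int]]] = {}
    for label in LABELS:
        counter: Counter[str] = Counter()
        for r in ds:
            if r.label != label:
                continue
            scaf = murcko_scaffold(r.smiles)
            if scaf:
                counter[scaf] += 1
        ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        out[label] = ranked[:n]
    return out


def scaffold_sets(ds: LabeledDataset) -> dict[int, set]:
    """Per-kingdom sets of distinct non-empty Murcko scaffolds (Venn input)."""
    sets: dict[int, set] = {lab: set() for lab in LABELS}
    for r in ds:
        scaf = murcko_scaffold(r.smiles)
        if scaf:
            sets[r.label].add(scaf)
    return sets


def cluster_sets(ds: LabeledDataset, clusters: ClusterAssignment) -> dict[int, set]:
    """Per-kingdom sets of occupied fingerprint-cluster ids (Venn input)."""
    sets: dict[int, set] = {lab: set() for lab in LABELS}
    for r in ds:
        sets[r.label].add(clusters.assignment[r.id])
    return sets
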