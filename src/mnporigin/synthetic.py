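"""Synthetic marine-natural-product stand-in generator.

Real origin-annotated compound sets (CMNPD-style exports) are not
redistributable, so every downstream stage is exercised on generated
molecules built from a small template grammar:

* class 0 ("animal-like")   — saturated fused carbocycles (decalin-,
  steroid-flavoured cores) with alkyl/hydroxyl decoration;
* class 1 ("bacterial-like") — aromatic nitrogen heterocycles with
  amide/amine decoration;
* class 2 ("fungal-like")    — lactones and ester/ketone-rich chains,
  polyketide-flavoured.

Molecules are assembled by attaching substituent fragments to template
cores, so every SMILES is valid by construction and generation is fully
deterministic for a given seed.  ``inject_label_noise`` plants the
symbiosis misannotation mechanism: a fraction of microbial compounds
(labels 1/2) relabeled as Animalia (0), one-way, never the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import CompoundRecord, LabeledDataset, MICROBIAL_LABELS

# Template cores per class.  All parse and sanitize; attachment points are
# carbons with at least one implicit hydrogen.
_CORES = {
    0: [  # saturated fused/bridged carbocycles
        "C1CCC2CCCCC2C1",              # decalin
        "C1CCC2C(C1)CCC1CCCCC21",      # perhydrophenanthrene
        "C1CC2CCC1CC2",                # bicyclo[2.2.2]octane
        "C1CCC2(CC1)CCCCC2",           # spiro[5.5]undecane
        "C1CCC2C(C1)CCC1C2CCC2CCCCC12",  # perhydro tetracycle (steroid-like)
        "C1CCC2CCCC2C1",               # hydrindane
    ],
    1: [  # aromatic N-heterocycles
        "c1ccncc1",                    # pyridine
        "c1cncnc1",                    # pyrimidine
        "c1ccc2[nH]ccc2c1",            # indole
        "c1ccc2ncccc2c1",              # quinoline
        "c1ccc2nccnc2c1",              # quinoxaline
        "c1c[nH]cn1",                  # imidazole
        "c1cc[nH]c1",                  # pyrrole
    ],
    2: [  # lactones / ester- and ketone-rich chains
        "O=C1CCCO1",                   # gamma-butyrolactone
        "O=C1CCCCO1",                  # delta-valerolactone
        "O=C1CCCCCCO1",                # 7-membered lactone
        "CCOC(=O)CCC(C)=O",            # keto-ester chain
        "COC(=O)CC(=O)CC",             # beta-keto diester flavour
        "CC(=O)CC(=O)OC1CCOC1=O",      # lactone + keto-ester
    ],
}

_SUBSTITUENTS = {
    0: ["C", "CC", "CCC", "O", "C(C)C", "CO"],
    1: ["C(N)=O", "NC(C)=O", "N", "C(=O)NC", "C", "CN"],
    2: ["C(C)=O", "OC(C)=O", "C(=O)OC", "O", "C", "CC(C)=O"],
}


@dataclass
class GrammarParams:
    """Substituent-sampling controls for the template grammar."""

    min_substituents: int = 1
    max_substituents: int = 3
    max_tries_per_molecule: int = 200


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_per_class: dict[int, int]
    noise_rate: float = 0.0
    seed: int = 0
    grammar_params: GrammarParams = field(default_factory=GrammarParams)

    def __post_init__(self):
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError(f"noise_rate must be in [0,1]; got {self.noise_rate}")
        for lab, n in self.n_per_class.items():
            if n < 0:
                raise ValueError(f"n_per_class[{lab}] must be >= 0; got {n}")


def _attach(core: Chem.Mol, sub_smiles: str, atom_idx: int) -> Chem.Mol | None:
    """Attach a substituent fragment to ``atom_idx`` of ``core`` by a single bond."""
    sub = Chem.MolFromSmiles(sub_smiles)
    combined = Chem.RWMol(Chem.CombineMols(core, sub))
    combined.AddBond(atom_idx, core.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(combined)
    except Exception:
        return None
    return combined.GetMol()


def _sample_molecule(rng: np.random.Generator, label: int, gp: GrammarParams) -> str | None:
    core = Chem.MolFromSmiles(_CORES[label][rng.integers(len(_CORES[label]))])
    n_sub = int(rng.integers(gp.min_substituents, gp.max_substituents + 1))
    mol = core
    for _ in range(n_sub):
        candidates = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
        ]
        if not candidates:
            break
        idx = int(candidates[rng.integers(len(candidates))])
        sub = _SUBSTITUENTS[label][rng.integers(len(_SUBSTITUENTS[label]))]
        attached = _attach(mol, sub, idx)
        if attached is not None:
            mol = attached
    smi = Chem.MolToSmiles(mol)
    return smi if Chem.MolFromSmiles(smi) is not None else None


def generate_dataset(spec: SyntheticSpec) -> LabeledDataset:
    """Generate a labeled dataset under ``spec``; same seed → identical SMILES.

    All structures are unique within the dataset.  Raises if the grammar
    cannot supply the requested number of distinct molecules for a class.
    """
    rng = np.random.default_rng(spec.seed)
    gp = spec.grammar_params
    records: list[CompoundRecord] = []
    prefix = {0: "A", 1: "B", 2: "F"}
    seen: set[str] = set()
    for label in sorted(spec.n_per_class):
        need = spec.n_per_class[label]
        made = 0
        tries = 0
        budget = max(need, 1) * gp.max_tries_per_molecule
        while made < need:
            if tries >= budget:
                raise RuntimeError(
                    f"could only generate {made}/{need} distinct class-{label} "
                    "molecules; increase grammar_params.max_substituents or "
                    "max_tries_per_molecule to enlarge the template grammar"
                )
            tries += 1
            smi = _sample_molecule(rng, label, gp)
            if smi is None or smi in seen:
                continue
            seen.add(smi)
            made += 1
            records.append(
                CompoundRecord(
                    id=f"{prefix[label]}{made:05d}",
                    smiles=smi,
                    label=label,
                    source="synthetic",
                )
            )
    return LabeledDataset(records)


def inject_label_noise(
    ds: LabeledDataset, rate: float, seed: int
) -> tuple[LabeledDataset, set[str]]:
    """Relabel a seeded fraction of microbial compounds as Animalia.

    Exactly ``round(rate * n_microbial)`` records with label 1 or 2 receive
    label 0 (the symbiosis misannotation direction); flips are one-way and
    reproducible for a given seed.  Returns the noisy dataset and the set of
    flipped ids (the planted truth for scoring recovery downstream).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0,1]; got {rate}")
    microbial_ids = [r.id for r in ds if r.label in MICROBIAL_LABELS]
    n_flips = round(rate * len(microbial_ids))
    rng = np.random.default_rng(seed)
    flips = set(rng.choice(microbial_ids, size=n_flips, replace=False).tolist()) if n_flips else set()
    noisy = ds.with_labels({cid: 0 for cid in flips})
    return noisy, flips
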