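"""Directed message-passing molecular encoder and training scheme.

A molecule is encoded as a directed bond graph (each bond contributes two
directed edges).  Messages live on directed edges; at step t+1 the message
on edge v→w aggregates the step-t messages on edges k→v for k ≠ w, which
prevents immediate echo back along the reverse edge:

    h0_vw   = relu(W_i [x_v ; e_vw])
    h_vw^t  = relu(h0_vw + W_h Σ_{k∈N(v)\\w} h_kv^{t-1})
    h_v     = relu(W_o [x_v ; Σ_{k∈N(v)} h_kv^T])
    z_mol   = Σ_v h_v                       (sum readout → MPN embedding)

A feed-forward head maps z_mol to three kingdom logits; the activation of
its final hidden layer is the last_FFN representation, the primary learned
structural fingerprint used downstream.

Training is two-stage: joint pretraining of encoder + head on Animalia plus
an equal-sized microbial sample (3-class cross-entropy), then fine-tuning
with the encoder frozen — only the head updates, so the encoder weights are
bit-identical before and after.

Everything here is plain NumPy with hand-derived gradients and Adam, which
keeps the model single-process, CPU-friendly and exactly reproducible for a
given seed.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem_io import LabeledDataset, SmilesParseError, canonicalize_smiles

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# featurization

_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B"]  # + other
_MAX_DEGREE = 5
_CHARGES = [-2, -1, 0, 1, 2]
_MAX_NUM_H = 4

ATOM_FDIM = len(_ELEMENTS) + 1 + (_MAX_DEGREE + 1) + len(_CHARGES) + (_MAX_NUM_H + 1) + 2
BOND_FDIM = 4 + 2  # order one-hot + conjugated + in-ring


@dataclass(frozen=True)
class MolGraph:
    """Directed-edge graph of one molecule (atom order canonicalized)."""

    n_atoms: int
    atom_feats: np.ndarray          # (n_atoms, ATOM_FDIM)
    bond_feats: np.ndarray          # (n_edges, BOND_FDIM), n_edges = 2 × bonds
    src: np.ndarray                 # (n_edges,) source atom of each directed edge
    dst: np.ndarray                 # (n_edges,)
    rev: np.ndarray                 # (n_edges,) index of the reverse edge

    @property
    def n_edges(self) -> int:
        return len(self.src)


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    f = np.zeros(ATOM_FDIM)
    sym = atom.GetSymbol()
    f[_ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
    off = len(_ELEMENTS) + 1
    f[off + min(atom.GetDegree(), _MAX_DEGREE)] = 1.0
    off += _MAX_DEGREE + 1
    charge = atom.GetFormalCharge()
    if charge in _CHARGES:
        f[off + _CHARGES.index(charge)] = 1.0
    off += len(_CHARGES)
    f[off + min(atom.GetTotalNumHs(), _MAX_NUM_H)] = 1.0
    off += _MAX_NUM_H + 1
    f[off] = float(atom.GetIsAromatic())
    f[off + 1] = float(atom.IsInRing())
    return f


_BOND_ORDERS = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}


def _bond_features(bond: Chem.Bond) -> np.ndarray:
    f = np.zeros(BOND_FDIM)
    f[_BOND_ORDERS.get(bond.GetBondType(), 0)] = 1.0
    f[4] = float(bond.GetIsConjugated())
    f[5] = float(bond.IsInRing())
    return f


@lru_cache(maxsize=200_000)
def featurize(smiles: str) -> MolGraph:
    """Build the directed-edge graph for a SMILES string.

    Atoms are renumbered by canonical rank and directed edges sorted by
    (src, dst), so any SMILES writing of the same molecule produces a
    bit-identical graph (and hence bit-identical embeddings downstream).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    # Re-parse the canonical SMILES so atom and bond order depend only on
    # the molecule, never on how the input string was written.
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    n = mol.GetNumAtoms()
    atom_feats = np.vstack([_atom_features(a) for a in mol.GetAtoms()]) if n else np.zeros((0, ATOM_FDIM))
    edges, feats = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        edges.append((i, j))
        feats.append(bf)
        edges.append((j, i))
        feats.append(bf)
    if edges:
        idx = sorted(range(len(edges)), key=lambda e: edges[e])
        edges = [edges[e] for e in idx]
        feats = [feats[e] for e in idx]
        pos = {e: i for i, e in enumerate(edges)}
        src = np.array([e[0] for e in edges], dtype=np.intp)
        dst = np.array([e[1] for e in edges], dtype=np.intp)
        rev = np.array([pos[(d, s)] for s, d in edges], dtype=np.intp)
        bond_feats = np.vstack(feats)
    else:
        src = dst = rev = np.zeros(0, dtype=np.intp)
        bond_feats = np.zeros((0, BOND_FDIM))
    return MolGraph(n, atom_feats, bond_feats, src, dst, rev)


@dataclass
class _Batch:
    atom_feats: np.ndarray
    bond_feats: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    rev: np.ndarray
    mol_index: np.ndarray   # (n_atoms,) molecule id per atom
    n_mols: int


def _batch_graphs(graphs: list[MolGraph]) -> _Batch:
    atom_feats, bond_feats, srcs, dsts, revs, mol_idx = [], [], [], [], [], []
    a_off = e_off = 0
    for m, g in enumerate(graphs):
        atom_feats.append(g.atom_feats)
        bond_feats.append(g.bond_feats)
        srcs.append(g.src + a_off)
        dsts.append(g.dst + a_off)
        revs.append(g.rev + e_off)
        mol_idx.append(np.full(g.n_atoms, m, dtype=np.intp))
        a_off += g.n_atoms
        e_off += g.n_edges
    return _Batch(
        np.concatenate(atom_feats) if atom_feats else np.zeros((0, ATOM_FDIM)),
        np.concatenate(bond_feats) if bond_feats else np.zeros((0, BOND_FDIM)),
        np.concatenate(srcs).astype(np.intp),
        np.concatenate(dsts).astype(np.intp),
        np.concatenate(revs).astype(np.intp),
        np.concatenate(mol_idx).astype(np.intp),
        len(graphs),
    )


# ---------------------------------------------------------------------------
# model


@dataclass
class EncoderConfig:
    """Hyperparameters for the encoder + head.

    ``hidden_dim`` defaults to 1100 (the full-scale embedding width); all
    desk-scale work runs at 64.  ``ffn_hidden_dim`` defaults to the encoder
    width when unset.
    """

    hidden_dim: int = 1100
    ffn_hidden_dim: int | None = None
    message_steps: int = 3
    ffn_layers: int = 1
    dropout: float = 0.0
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 50
    seed: int = 0
    n_classes: int = 3

    def __post_init__(self):
        if self.hidden_dim < 1 or self.message_steps < 1 or self.ffn_layers < 1:
            raise ValueError("hidden_dim, message_steps and ffn_layers must be >= 1")

    @property
    def ffn_dim(self) -> int:
        return self.ffn_hidden_dim if self.ffn_hidden_dim is not None else self.hidden_dim


_ENCODER_KEYS = ("Wi", "Wh", "Wo")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=(fan_in, fan_out))


def _init_params(config: EncoderConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    h, f = config.hidden_dim, config.ffn_dim
    params = {
        "Wi": _glorot(rng, ATOM_FDIM + BOND_FDIM, h),
        "Wh": _glorot(rng, h, h),
        "Wo": _glorot(rng, ATOM_FDIM + h, h),
    }
    prev = h
    for layer in range(config.ffn_layers):
        params[f"Wf{layer}"] = _glorot(rng, prev, f)
        params[f"bf{layer}"] = np.zeros(f)
        prev = f
    params["Wout"] = _glorot(rng, prev, config.n_classes)
    params["bout"] = np.zeros(config.n_classes)
    return params


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(params, batch: _Batch, config: EncoderConfig, cache: dict | None = None):
    """Forward pass; fills ``cache`` with intermediates when provided."""
    X, Bf = batch.atom_feats, batch.bond_feats
    src, dst, rev = batch.src, batch.dst, batch.rev
    n_atoms = len(X)
    h = config.hidden_dim
    if batch.src.size:
        In = np.concatenate([X[src], Bf], axis=1)
        H0 = np.maximum(In @ params["Wi"], 0.0)
        H = H0
        Ms, Hs = [], []
        for _ in range(1, config.message_steps):
            S = np.zeros((n_atoms, h))
            np.add.at(S, dst, H)
            M = S[src] - H[rev]
            H = np.maximum(H0 + M @ params["Wh"], 0.0)
            Ms.append(M)
            Hs.append(H)
        A = np.zeros((n_atoms, h))
        np.add.at(A, dst, H)
    else:
        In = np.zeros((0, ATOM_FDIM + BOND_FDIM))
        H0 = np.zeros((0, h))
        Ms, Hs = [], []
        A = np.zeros((n_atoms, h))
    AtomIn = np.concatenate([X, A], axis=1)
    Hatom = np.maximum(AtomIn @ params["Wo"], 0.0)
    mol = np.zeros((batch.n_mols, h))
    np.add.at(mol, batch.mol_index, Hatom)
    acts = [mol]
    cur = mol
    for layer in range(config.ffn_layers):
        cur = np.maximum(cur @ params[f"Wf{layer}"] + params[f"bf{layer}"], 0.0)
        acts.append(cur)
    logits = cur @ params["Wout"] + params["bout"]
    probs = _softmax(logits)
    if cache is not None:
        cache.update(
            In=In, H0=H0, Ms=Ms, Hs=Hs, A=A, AtomIn=AtomIn, Hatom=Hatom,
            acts=acts, probs=probs,
        )
    return probs, cur, mol  # (class probabilities, last_ffn, MPN embedding)


def _backward(params, batch: _Batch, config: EncoderConfig, cache, dlogits,
              trainable: set[str]) -> dict[str, np.ndarray]:
    grads = {k: np.zeros_like(v) for k, v in params.items() if k in trainable}
    acts = cache["acts"]
    last = acts[-1]
    if "Wout" in trainable:
        grads["Wout"] = last.T @ dlogits
        grads["bout"] = dlogits.sum(axis=0)
    dcur = dlogits @ params["Wout"].T
    for layer in range(config.ffn_layers - 1, -1, -1):
        dZ = dcur * (acts[layer + 1] > 0)
        if f"Wf{layer}" in trainable:
            grads[f"Wf{layer}"] = acts[layer].T @ dZ
            grads[f"bf{layer}"] = dZ.sum(axis=0)
        dcur = dZ @ params[f"Wf{layer}"].T
    if not (set(_ENCODER_KEYS) & trainable):
        return grads
    # into the encoder
    dmol = dcur
    dHatom = dmol[batch.mol_index]
    dZo = dHatom * (cache["Hatom"] > 0)
    grads["Wo"] = cache["AtomIn"].T @ dZo
    h = config.hidden_dim
    if batch.src.size:
        dA = dZo @ params["Wo"][ATOM_FDIM:, :].T
        dH = dA[batch.dst]
        dH0 = np.zeros_like(cache["H0"])
        grads["Wh"] = np.zeros_like(params["Wh"])
        n_atoms = len(batch.atom_feats)
        for t in range(len(cache["Hs"]) - 1, -1, -1):
            dZ = dH * (cache["Hs"][t] > 0)
            dH0 += dZ
            grads["Wh"] += cache["Ms"][t].T @ dZ
            dM = dZ @ params["Wh"].T
            G = np.zeros((n_atoms, h))
            np.add.at(G, batch.src, dM)
            dH = G[batch.dst] - dM[batch.rev]
        dH0 += dH  # H at level 0 is H0 itself
        dZ0 = dH0 * (cache["H0"] > 0)
        grads["Wi"] = cache["In"].T @ dZ0
    else:
        grads["Wh"] = np.zeros_like(params["Wh"])
        grads["Wi"] = np.zeros_like(params["Wi"])
    return grads


class _Adam:
    def __init__(self, keys, params, lr):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(params[k]) for k in keys}
        self.v = {k: np.zeros_like(params[k]) for k in keys}

    def step(self, params, grads):
        self.t += 1
        for k in self.m:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class OriginModel:
    """Encoder + head weights with config, freeze flag and loss history."""

    params: dict[str, np.ndarray]
    config: EncoderConfig
    frozen: bool = False
    loss_trace: list[float] = field(default_factory=list)
    info: dict = field(default_factory=dict)  # e.g. pretraining sample bookkeeping

    def predict_proba(self, smiles: list[str]) -> np.ndarray:
        """Class-probability matrix (n, 3) for a list of SMILES."""
        out = []
        for chunk_start in range(0, len(smiles), 512):
            chunk = smiles[chunk_start:chunk_start + 512]
            batch = _batch_graphs([featurize(s) for s in chunk])
            probs, _, _ = _forward(self.params, batch, self.config)
            out.append(probs)
        return np.vstack(out) if out else np.zeros((0, self.config.n_classes))

    def encoder_checksum(self) -> str:
        """SHA-256 over the encoder weight bytes (freeze-contract witness)."""
        digest = hashlib.sha256()
        for k in _ENCODER_KEYS:
            digest.update(np.ascontiguousarray(self.params[k]).tobytes())
        return digest.hexdigest()

    def save(self, path: str | Path) -> Path:
        """Single-file checkpoint: config JSON + weights (npz archive)."""
        path = Path(path)
        meta = {"config": self.config.__dict__, "frozen": self.frozen,
                "loss_trace": self.loss_trace}
        arrays = dict(self.params)
        arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "OriginModel":
        data = np.load(path)
        meta = json.loads(bytes(data["_meta"]).decode())
        params = {k: data[k] for k in data.files if k != "_meta"}
        return cls(params, EncoderConfig(**meta["config"]), meta["frozen"],
                   meta["loss_trace"])


def init_model(config: EncoderConfig) -> OriginModel:
    """Seeded fresh model; same config (incl. seed) → identical weights."""
    return OriginModel(_init_params(config), config)


def forward(model: OriginModel, graph: MolGraph) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities over {0,1,2} and the last_FFN vector for one molecule."""
    batch = _batch_graphs([graph])
    probs, last_ffn, _ = _forward(model.params, batch, model.config)
    return probs[0], last_ffn[0]


def encode_mpn(model: OriginModel, graph: MolGraph) -> np.ndarray:
    """Molecule-level MPN embedding (sum readout over atom states)."""
    batch = _batch_graphs([graph])
    _, _, mol = _forward(model.params, batch, model.config)
    return mol[0]


def _train(model: OriginModel, ds: LabeledDataset, config: EncoderConfig,
           trainable: set[str]) -> list[float]:
    graphs = [featurize(s) for s in ds.smiles]
    labels = np.array([r.label for r in ds], dtype=np.intp)
    n = len(graphs)
    rng = np.random.default_rng(config.seed + 1)
    onehot = np.eye(config.n_classes)
    opt = _Adam(trainable, model.params, config.lr)
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = _batch_graphs([graphs[i] for i in idx])
            y = labels[idx]
            cache: dict = {}
            if config.dropout > 0:
                # inverted dropout on the final FFN activation
                probs, last, _ = _forward(model.params, batch, config, cache)
                mask = (rng.random(last.shape) >= config.dropout) / (1 - config.dropout)
                cache["acts"][-1] = cache["acts"][-1] * mask
                logits = cache["acts"][-1] @ model.params["Wout"] + model.params["bout"]
                probs = _softmax(logits)
            else:
                probs, _, _ = _forward(model.params, batch, config, cache)
            Y = onehot[y]
            loss = -np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)))
            epoch_loss += loss * len(y)
            dlogits = (probs - Y) / len(y)
            grads = _backward(model.params, batch, config, cache, dlogits, trainable)
            opt.step(model.params, grads)
        trace.append(epoch_loss / n)
    return trace


def pretrain(animalia: LabeledDataset, microbial_pool: LabeledDataset,
             config: EncoderConfig) -> OriginModel:
    """Joint pretraining on Animalia plus an equal-sized microbial sample.

    The microbial subset is drawn uniformly (seeded) from ``microbial_pool``;
    if the pool is smaller than the Animalia set the whole pool is used with
    a warning.  Encoder and head train jointly on the 3-class objective.
    """
    if len(animalia) == 0 or len(microbial_pool) == 0:
        raise ValueError("pretraining requires non-empty Animalia and microbial sets")
    n = len(animalia)
    rng = np.random.default_rng(config.seed)
    pool_ids = microbial_pool.ids
    if len(pool_ids) < n:
        warnings.warn(
            f"microbial pool ({len(pool_ids)}) smaller than Animalia set ({n}); "
            "sampling at pool size", stacklevel=2)
        sample = pool_ids
    else:
        sample = rng.choice(pool_ids, size=n, replace=False).tolist()
    combined = LabeledDataset(list(animalia) + list(microbial_pool.subset(sample)))
    model = init_model(config)
    model.info = {
        "pretrain_n_animalia": n,
        "pretrain_n_microbial": len(sample),
        "pretrain_microbial_ids": sorted(sample),
        "pretrain_total": len(combined),
    }
    model.loss_trace = _train(model, combined, config, set(model.params))
    return model


def finetune(model: OriginModel, train: LabeledDataset,
             config: EncoderConfig | None = None) -> OriginModel:
    """Head-only training with the encoder frozen.

    The returned model shares the encoder arrays of ``model`` bit-for-bit;
    only the FFN head weights are re-fit on ``train``.
    """
    config = config or model.config
    new_params = {
        k: (v if k in _ENCODER_KEYS else v.copy()) for k, v in model.params.items()
    }
    tuned = OriginModel(new_params, config, frozen=True)
    head_keys = {k for k in new_params if k not in _ENCODER_KEYS}
    tuned.loss_trace = _train(tuned, train, config, head_keys)
    return tuned


def train_from_scratch(ds: LabeledDataset, config: EncoderConfig) -> OriginModel:
    """Joint (unfrozen) training on one dataset — the no-pretraining baseline."""
    model = init_model(config)
    model.loss_trace = _train(model, ds, config, set(model.params))
    return model


# ---------------------------------------------------------------------------
# embedding tables


@dataclass
class EmbeddingTable:
    """Per-compound real vectors of one representation kind."""

    kind: str                    # map4like | mpn | last_ffn
    ids: list[str]
    vectors: np.ndarray          # (n, d)

    def __post_init__(self):
        if len(self.ids) != len(self.vectors):
            raise ValueError("ids and vectors disagree in length")
        if len(self.vectors) and not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1] if self.vectors.ndim == 2 else 0

    def __getitem__(self, cid: str) -> np.ndarray:
        return self.vectors[self.ids.index(cid)]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# kind={self.kind}\n")
            cols = ",".join(f"v{i}" for i in range(self.dim))
            fh.write(f"id,{cols}\n")
            for cid, vec in zip(self.ids, self.vectors):
                fh.write(cid + "," + ",".join(repr(float(x)) for x in vec) + "\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmbeddingTable":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip()
            kind = header.split("kind=")[1] if "kind=" in header else "unknown"
            fh.readline()  # column names
            ids, rows = [], []
            for line in fh:
                parts = line.strip().split(",")
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(kind, ids, np.array(rows))


def extract_embeddings(model: OriginModel, ds: LabeledDataset,
                       kind: str = "last_ffn") -> EmbeddingTable:
    """One embedding vector per compound; ``kind`` ∈ {mpn, last_ffn}."""
    if kind not in ("mpn", "last_ffn"):
        raise ValueError(f"kind must be 'mpn' or 'last_ffn'; got {kind!r}")
    vecs = []
    for start in range(0, len(ds), 512):
        chunk = ds.smiles[start:start + 512]
        batch = _batch_graphs([featurize(s) for s in chunk])
        _, last_ffn, mol = _forward(model.params, batch, model.config)
        vecs.append(mol if kind == "mpn" else last_ffn)
    mat = np.vstack(vecs) if vecs else np.zeros((0, model.config.hidden_dim))
    return EmbeddingTable(kind, ds.ids, mat)


# ---------------------------------------------------------------------------
# MinHashed atom-pair fingerprint ("map4like")

_MINHASH_PRIME = np.uint64((1 << 61) - 1)
_minhash_rng = np.random.default_rng(0xC0FFEE)
_MINHASH_A = {}
_MINHASH_B = {}


def _minhash_coeffs(dims: int) -> tuple[np.ndarray, np.ndarray]:
    if dims not in _MINHASH_A:
        rng = np.random.default_rng(0xC0FFEE + dims)
        _MINHASH_A[dims] = rng.integers(1, 1 << 61, size=dims, dtype=np.uint64)
        _MINHASH_B[dims] = rng.integers(0, 1 << 61, size=dims, dtype=np.uint64)
    return _MINHASH_A[dims], _MINHASH_B[dims]


def _shingle_hash(s: str) -> np.uint64:
    return np.uint64(int.from_bytes(hashlib.sha1(s.encode()).digest()[:8], "little"))


def _atom_env(mol: Chem.Mol, idx: int, radius: int) -> str:
    env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, idx)
    if env:
        amap: dict[int, int] = {}
        sub = Chem.PathToSubmol(mol, env, atomMap=amap)
        return Chem.MolToSmiles(sub, rootedAtAtom=amap[idx], canonical=True)
    atom = mol.GetAtomWithIdx(idx)
    return f"{atom.GetSymbol()}H{atom.GetTotalNumHs()}d{atom.GetDegree()}"


def map4like_fp(smiles: str, dims: int = 1024) -> np.ndarray:
    """MinHashed atom-pair fingerprint over circular-environment shingles.

    For every atom pair, shingles combine the two atoms' circular
    environments (radius 1 and 2) keyed by their topological distance; the
    shingle set is min-hashed into ``dims`` slots.  Single-atom molecules
    hash singleton shingles.  Invariant to SMILES rewriting (environments
    are canonical rooted SMILES) and fully deterministic.
    """
    can = canonicalize_smiles(smiles)
    mol = Chem.MolFromSmiles(can)
    n = mol.GetNumAtoms()
    envs = {r: [_atom_env(mol, i, r) for i in range(n)] for r in (1, 2)}
    shingles: set[str] = set()
    if n == 1:
        for r in (1, 2):
            e = envs[r][0]
            shingles.add(f"{e}|0|{e}")
    else:
        dist = Chem.GetDistanceMatrix(mol)
        for i in range(n):
            for j in range(i + 1, n):
                d = int(dist[i, j])
                for r in (1, 2):
                    a, b = sorted((envs[r][i], envs[r][j]))
                    shingles.add(f"{a}|{d}|{b}")
    A, B = _minhash_coeffs(dims)
    mins = np.full(dims, np.iinfo(np.uint64).max, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for s in shingles:
            h = _shingle_hash(s)
            vals = (A * h + B) % _MINHASH_PRIME
            np.minimum(mins, vals, out=mins)
    return mins.astype(np.int64)


def map4like_table(ds: LabeledDataset, dims: int = 1024) -> EmbeddingTable:
    """MinHash fingerprint table for a dataset (float vectors for reuse in
    the same downstream heads as the learned embeddings)."""
    mat = np.vstack([map4like_fp(s, dims) for s in ds.smiles]).astype(float)
    return EmbeddingTable("map4like", ds.ids, mat)
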