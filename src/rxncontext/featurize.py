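"""Reaction difference fingerprints.

Each molecule is encoded as 1024 bits: a 512-bit extended-connectivity
(circular, radius 3) fingerprint concatenated with a 512-bit linear-path
fingerprint (maximum path length 7 bonds). The reaction fingerprint is the
product fingerprint minus the sum of the reactant fingerprints, kept as a
signed integer vector: negative entries are substructure environments lost in
the reaction (e.g. the C-halide environment of an aryl halide), positive
entries are environments gained (e.g. the new C-N environment). Context
species never enter the computation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import rdkit
from rdkit.Chem import rdFingerprintGenerator

from .datamodel import mol_from_smiles

FP_LENGTH = 1024


@dataclass(frozen=True)
class FingerprintConfig:
    """Fingerprint hyper-parameters; pinned to a toolkit version.

    Bit identities are toolkit-specific, so a model bundle refuses inputs
    featurized under a different configuration or toolkit version.
    """

    circular_bits: int = 512
    circular_radius: int = 3
    path_bits: int = 512
    max_path_length: int = 7
    use_chirality: bool = False
    toolkit: str = f"rdkit-{rdkit.__version__}"

    @property
    def n_bits(self) -> int:
        return self.circular_bits + self.path_bits

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FingerprintConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


DEFAULT_FP_CONFIG = FingerprintConfig()

_GENERATOR_CACHE: dict = {}


def _generators(cfg: FingerprintConfig):
    key = (cfg.circular_bits, cfg.circular_radius, cfg.path_bits,
           cfg.max_path_length, cfg.use_chirality)
    if key not in _GENERATOR_CACHE:
        morgan = rdFingerprintGenerator.GetMorganGenerator(
            radius=cfg.circular_radius,
            fpSize=cfg.circular_bits,
            includeChirality=cfg.use_chirality,
        )
        path = rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=cfg.max_path_length,
            fpSize=cfg.path_bits,
        )
        _GENERATOR_CACHE[key] = (morgan, path)
    return _GENERATOR_CACHE[key]


def molecule_fp(
    smiles: str, cfg: FingerprintConfig = DEFAULT_FP_CONFIG
) -> np.ndarray:
    """Binary fingerprint of one molecule (circular half + path half)."""
    mol = mol_from_smiles(smiles)
    morgan, path = _generators(cfg)
    bits = np.zeros(cfg.n_bits, dtype=np.int16)
    bits[: cfg.circular_bits] = np.frombuffer(
        morgan.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
    ) - ord("0")
    bits[cfg.circular_bits:] = np.frombuffer(
        path.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
    ) - ord("0")
    return bits


def reaction_fp(
    reactants: list[str],
    product: str,
    cfg: FingerprintConfig = DEFAULT_FP_CONFIG,
    _cache: dict | None = None,
) -> np.ndarray:
    """Difference fingerprint: fp(product) − Σ fp(reactant).

    Entries lie in ``[-R, 1]`` for ``R`` reactants. Reordering the reactants
    leaves the result unchanged.
    """
    if not reactants:
        raise ValueError("at least one reactant is required")

    def fp(s: str) -> np.ndarray:
        if _cache is None:
            return molecule_fp(s, cfg)
        if s not in _cache:
            _cache[s] = molecule_fp(s, cfg)
        return _cache[s]

    out = fp(product).astype(np.int16).copy()
    for r in reactants:
        out -= fp(r)
    return out


def featurize_examples(
    examples, cfg: FingerprintConfig = DEFAULT_FP_CONFIG
) -> np.ndarray:
    """Difference-fingerprint matrix for a list of labeled examples.

    Per-molecule fingerprints are cached across rows, so repeated reactants
    (common in ELN-like data) are computed once.
    """
    cache: dict[str, np.ndarray] = {}
    X = np.zeros((len(examples), cfg.n_bits), dtype=np.float32)
    for i, ex in enumerate(examples):
        X[i] = reaction_fp(list(ex.reactants), ex.product, cfg, _cache=cache)
    return X


def save_features(path_prefix: str, X: np.ndarray,
                  cfg: FingerprintConfig) -> None:
    """Persist a feature matrix with a JSON sidecar describing its config."""
    np.save(f"{path_prefix}.npy", X)
    cfg.to_json(f"{path_prefix}.json")


def load_features(path_prefix: str) -> tuple[np.ndarray, FingerprintConfig]:
    X = np.load(f"{path_prefix}.npy")
    cfg = FingerprintConfig.from_json(f"{path_prefix}.json")
    if X.shape[1] != cfg.n_bits:
        raise ValueError(
            f"feature width {X.shape[1]} does not match config ({cfg.n_bits})"
        )
    return X, cfg
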