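"""Per-drug features and pair-vector assembly.

A drug pair is described by concatenating each drug's hashed circular
(Morgan/ECFP-style) fingerprint with its knowledge-graph embedding:
``[fp(a) | fp(b) | emb(a) | emb(b)]``, length 2(B + d) — 2176 at the default
B = 1024 bits and d = 64 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class FeatureError(ValueError):
    """Fatal featurization input error."""


@dataclass
class FingerprintSet:
    """Fixed-width binary fingerprints keyed by drug id (or name)."""

    width: int
    vectors: dict = field(repr=False)

    def __post_init__(self):
        for k, v in self.vectors.items():
            v = np.asarray(v)
            if v.shape != (self.width,):
                raise FeatureError(f"fingerprint for {k!r} has shape {v.shape}, expected ({self.width},)")
            if not np.isin(v, (0, 1)).all():
                raise FeatureError(f"fingerprint for {k!r} contains non-binary entries")
            self.vectors[k] = v.astype(np.float64)

    def __contains__(self, key):
        return key in self.vectors

    def __getitem__(self, key) -> np.ndarray:
        if key not in self.vectors:
            raise FeatureError(f"no fingerprint for drug {key!r}")
        return self.vectors[key]

    def relabel(self, mapping: dict) -> "FingerprintSet":
        """Re-key vectors (e.g. drug name -> entity id); unmapped keys dropped."""
        return FingerprintSet(
            self.width, {mapping[k]: v for k, v in self.vectors.items() if k in mapping}
        )


@dataclass
class EmbeddingSet:
    """Fixed-dimension real embeddings keyed by entity id (or name)."""

    dim: int
    vectors: dict = field(repr=False)

    def __post_init__(self):
        for k, v in self.vectors.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (self.dim,):
                raise FeatureError(f"embedding for {k!r} has shape {v.shape}, expected ({self.dim},)")
            if not np.isfinite(v).all():
                raise FeatureError(f"embedding for {k!r} contains non-finite entries")
            self.vectors[k] = v

    def __contains__(self, key):
        return key in self.vectors

    def __getitem__(self, key) -> np.ndarray:
        if key not in self.vectors:
            raise FeatureError(f"no embedding for entity {key!r}")
        return self.vectors[key]

    def relabel(self, mapping: dict) -> "EmbeddingSet":
        return EmbeddingSet(
            self.dim, {mapping[k]: v for k, v in self.vectors.items() if k in mapping}
        )


@dataclass
class PairExample:
    """An ordered drug pair with label, optional interaction type, and features."""

    drug_a: int
    drug_b: int
    label: int | None = None  # 1 positive, 0 negative, None unlabeled
    itype: str | None = None  # "increase" | "decrease"
    features: np.ndarray | None = None


def compute_fingerprints(smiles_path, width: int = 1024, radius: int = 2):
    """Hash Morgan circular fingerprints (radius 2 = ECFP4) from a SMILES TSV.

    Rows are ``drug_name<TAB>SMILES``. Returns ``(FingerprintSet keyed by
    name, rejected)`` where ``rejected`` lists (name, smiles) rows RDKit
    could not parse — reported, never silently dropped.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import rdFingerprintGenerator

    RDLogger.DisableLog("rdApp.error")
    if width < 8:
        raise FeatureError("fingerprint width must be >= 8")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=width)
    vectors: dict[str, np.ndarray] = {}
    rejected: list[tuple[str, str]] = []
    with open(smiles_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FeatureError(f"{smiles_path}: line {lineno} must be name<TAB>SMILES")
            name, smiles = parts
            if name in vectors or name in {n for n, _ in rejected}:
                raise FeatureError(f"duplicate drug name {name!r} at line {lineno}")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                rejected.append((name, smiles))
                continue
            fp = gen.GetFingerprintAsNumPy(mol)
            vectors[name] = np.asarray(fp, dtype=np.float64)
    if not vectors:
        raise FeatureError(f"{smiles_path}: no parseable SMILES rows")
    return FingerprintSet(width, vectors), rejected


def load_fingerprints(fp_path) -> FingerprintSet:
    """Load ``drug_name<TAB>bitstring`` TSV; all bitstrings must share one width."""
    vectors: dict[str, np.ndarray] = {}
    width = None
    with open(fp_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FeatureError(f"{fp_path}: line {lineno} must be name<TAB>bitstring")
            name, bits = parts
            if set(bits) - {"0", "1"}:
                raise FeatureError(f"{fp_path}: line {lineno} ({name!r}): non-binary bitstring")
            if width is None:
                width = len(bits)
            elif len(bits) != width:
                raise FeatureError(
                    f"{fp_path}: line {lineno} ({name!r}): width {len(bits)} != {width}"
                )
            if name in vectors:
                raise FeatureError(f"duplicate drug name {name!r} at line {lineno}")
            vectors[name] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    if not vectors:
        raise FeatureError(f"{fp_path}: empty fingerprint file")
    return FingerprintSet(width, {k: v.astype(np.float64) for k, v in vectors.items()})


def write_fingerprints(fps: FingerprintSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, v in fps.vectors.items():
            bits = "".join("1" if b else "0" for b in v.astype(int))
            fh.write(f"{name}\t{bits}\n")


def load_embeddings(path) -> EmbeddingSet:
    """Load ``name<TAB>v1<TAB>...<TAB>vd`` TSV."""
    vectors: dict[str, np.ndarray] = {}
    dim = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name, vals = parts[0], parts[1:]
            if dim is None:
                dim = len(vals)
            elif len(vals) != dim:
                raise FeatureError(f"{path}: line {lineno}: dimension {len(vals)} != {dim}")
            vectors[name] = np.array([float(x) for x in vals])
    if not vectors:
        raise FeatureError(f"{path}: empty embedding file")
    return EmbeddingSet(dim, vectors)


def write_embeddings(embs: EmbeddingSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, v in embs.vectors.items():
            fh.write(str(name) + "\t" + "\t".join(f"{x:.8g}" for x in v) + "\n")


def pair_vector(
    a,
    b,
    fps: FingerprintSet,
    embs: EmbeddingSet | None,
    allow_missing_embedding: bool = False,
) -> np.ndarray:
    """Assemble the ordered pair feature ``[fp(a) | fp(b) | emb(a) | emb(b)]``.

    Length is 2(B + d). ``allow_missing_embedding`` supports cold-start
    inference on drugs absent from the trained embedding vocabulary: their
    embedding block is zeroed (fingerprints remain mandatory).
    """
    if a == b:
        raise FeatureError(f"pair ({a!r}, {b!r}): a drug cannot pair with itself")
    fp_a, fp_b = fps[a], fps[b]
    if embs is None:
        return np.concatenate([fp_a, fp_b])

    def emb_of(drug):
        if drug in embs:
            return embs[drug]
        if allow_missing_embedding:
            return np.zeros(embs.dim)
        raise FeatureError(f"no embedding for drug {drug!r}")

    return np.concatenate([fp_a, fp_b, emb_of(a), emb_of(b)])
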