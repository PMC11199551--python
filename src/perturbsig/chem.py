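"""Compound featurisation: ECFP4 fingerprints, external embedding tables
and Tanimoto similarity utilities for train/test similarity binning."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ECFP4_RADIUS = 2
ECFP4_NBITS = 2048

#: dimension of externally supplied pretrained graph-transformer embeddings
KPGT_DIM = 2034


class SmilesError(ValueError):
    """A SMILES string could not be parsed into a molecule."""


@dataclass
class CompoundTable:
    """Compound id -> (optional SMILES, optional fixed-length feature vector).

    Every entry carries at least one of the two; all feature vectors share
    ``feature_dim``.
    """

    smiles: dict[str, str]
    features: dict[str, np.ndarray]
    feature_dim: int | None = None

    def __post_init__(self) -> None:
        dims = {v.shape[0] for v in self.features.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent feature dimensions: {sorted(dims)}")
        if dims:
            d = dims.pop()
            if self.feature_dim is not None and self.feature_dim != d:
                raise ValueError(
                    f"feature_dim {self.feature_dim} != vectors' {d}")
            self.feature_dim = d
        empty = [c for c in self.ids
                 if c not in self.smiles and c not in self.features]
        if empty:
            raise ValueError(f"entries with neither smiles nor features: "
                             f"{empty[:5]}")

    @property
    def ids(self) -> list[str]:
        return sorted(set(self.smiles) | set(self.features))

    def feature_matrix(self, ids) -> np.ndarray:
        """Stack feature vectors for ``ids``; ECFP4 computed on demand when
        only SMILES is stored."""
        rows = []
        for c in ids:
            if c in self.features:
                rows.append(self.features[c])
            elif c in self.smiles:
                rows.append(ecfp4(self.smiles[c]).astype(float))
            else:
                raise KeyError(f"unknown compound {c!r}")
        return np.vstack(rows)


def ecfp4(smiles: str) -> np.ndarray:
    """Morgan/circular fingerprint, radius 2, folded to 2048 bits.

    Identical molecules give identical fingerprints irrespective of the
    SMILES spelling; sanitisation follows the toolkit defaults.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=ECFP4_RADIUS, fpSize=ECFP4_NBITS)
    fp = gen.GetFingerprintAsNumPy(mol)
    return fp.astype(np.uint8)


def load_feature_table(path, expected_dim: int | None = None) -> CompoundTable:
    """Load a compound CSV with columns compound_id[, smiles][, f_0...f_{d-1}].

    ``expected_dim`` (e.g. 2034 for pretrained graph-transformer embeddings)
    is enforced when given.  Duplicate compound ids are an error.
    """
    df = pd.read_csv(path)
    if "compound_id" not in df.columns:
        raise ValueError(f"{path}: missing compound_id column")
    if df["compound_id"].duplicated().any():
        dups = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
        raise ValueError(f"{path}: duplicate compound ids {dups[:5]}")
    feat_cols = [c for c in df.columns if c not in ("compound_id", "smiles")]
    if feat_cols and df[feat_cols].isna().any().any():
        bad = df[df[feat_cols].isna().any(axis=1)]["compound_id"].tolist()
        raise ValueError(f"{path}: rows with missing feature values (wrong "
                         f"column count?) for compounds {bad[:5]}")
    smiles = {}
    if "smiles" in df.columns:
        smiles = {r.compound_id: r.smiles for r in df.itertuples()
                  if isinstance(r.smiles, str) and r.smiles}
    features = {}
    if feat_cols:
        if expected_dim is not None and len(feat_cols) != expected_dim:
            raise ValueError(f"{path}: expected {expected_dim} feature "
                             f"columns, found {len(feat_cols)}")
        mat = df[feat_cols].to_numpy(dtype=float)
        features = {c: mat[i] for i, c in enumerate(df["compound_id"])}
    return CompoundTable(smiles=smiles, features=features)


def write_feature_table(table: CompoundTable, path) -> None:
    """Write a :class:`CompoundTable` back to the CSV interchange format."""
    ids = table.ids
    data = {"compound_id": ids}
    if table.smiles:
        data["smiles"] = [table.smiles.get(c, "") for c in ids]
    df = pd.DataFrame(data)
    if table.features:
        mat = np.vstack([table.features[c] for c in ids])
        feats = pd.DataFrame(mat, columns=[f"f_{j}"
                                           for j in range(mat.shape[1])])
        df = pd.concat([df, feats], axis=1)
    df.to_csv(path, index=False)


def tanimoto(a, b) -> float:
    """Jaccard similarity |a AND b| / |a OR b| of two binary vectors.

    Defined as 0 when both vectors are all-zero.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def max_similarity_to_train(test_fps: dict[str, np.ndarray],
                            train_fps: dict[str, np.ndarray]) -> dict[str, float]:
    """Per test compound, the maximum Tanimoto to any training compound.

    The standard covariate for similarity-binned evaluation of virtual
    screening models (bins such as (0.0, 0.3] of max train similarity).
    """
    if not train_fps:
        raise ValueError("empty training set")
    train_mat = np.vstack([np.asarray(v, dtype=float) != 0
                           for v in train_fps.values()]).astype(np.int64)
    train_counts = train_mat.sum(axis=1)
    out = {}
    for cid, fp in test_fps.items():
        fp = (np.asarray(fp, dtype=float) != 0).astype(np.int64)
        inter = train_mat @ fp
        union = train_counts + fp.sum() - inter
        sims = np.where(union == 0, 0.0, inter / np.maximum(union, 1))
        out[cid] = float(sims.max())
    return out


def fingerprints_for(table: CompoundTable, ids) -> dict[str, np.ndarray]:
    """ECFP4 fingerprints for a set of ids (requires SMILES)."""
    missing = [c for c in ids if c not in table.smiles]
    if missing:
        raise ValueError(f"no SMILES for compounds {missing[:5]}")
    return {c: ecfp4(table.smiles[c]) for c in ids}
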