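"""Synthetic L1000-like paired perturbation datasets with known ground truth.

The generator emulates the structure of plate-based landmark-gene profiling:
each cell line has its own basal mean profile (log-expression scale around
7 +/- 1); every plate carries DMSO control wells and compound-treated wells;
a compound's transcriptional effect is a low-rank linear function of its
binary feature vector, effect(m) = s * B @ A @ f(m), shared across cell
lines; and replicate plates re-measure the same compound/cell combinations
with independent Gaussian noise.  Because the planted effects are stored,
model recovery, screening and repurposing pipelines can all be evaluated
against exact ground truth.

Downstream labels are generated from the same planted effects: activity
labels from the cosine of the effect against a target direction, and
dose-response AUCs that decrease with the projection of the effect onto a
cell-death signature (smaller AUC = more sensitive), clipped to [0, 8].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import CompoundTable
from .profiles import ExpressionMatrix, META_COLUMNS

RESISTANT_CEILING = 7.5  # AUC of a compound with no aligned effect
AUC_SPAN = 4.0           # AUC drop from zero projection to the strongest


@dataclass
class SyntheticConfig:
    n_genes: int = 978
    n_cells: int = 3
    n_compounds: int = 300
    n_replicates: int = 3
    feature_dim: int = 256
    effect_rank: int = 10
    noise_sd_basal: float = 0.2
    noise_sd_pert: float = 0.25
    effect_scale: float = 1.0
    n_controls_per_plate: int = 3
    feature_density: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_compounds", "n_replicates",
                     "feature_dim", "effect_rank", "n_controls_per_plate"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd_basal < 0 or self.noise_sd_pert < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the planted signal exactly."""

    cell_means: np.ndarray          # n_cells x n_genes
    effect_basis: np.ndarray        # B: n_genes x r
    loading_map: np.ndarray         # A: r x feature_dim
    effect_norm: float              # global scale s of B @ A
    effect_scale: float
    compound_features: np.ndarray   # n_compounds x feature_dim, binary
    compound_ids: list[str]
    cell_ids: list[str]
    sensitivity_direction: np.ndarray  # per-dataset cell-death signature

    def effect(self, compound) -> np.ndarray:
        """Planted expression effect of one compound (id or index)."""
        i = (self.compound_ids.index(compound)
             if isinstance(compound, str) else int(compound))
        f = self.compound_features[i]
        return (self.effect_scale * self.effect_norm
                * self.effect_basis @ (self.loading_map @ f))

    def effect_matrix(self) -> np.ndarray:
        """All planted effects, n_compounds x n_genes."""
        raw = self.compound_features @ self.loading_map.T @ self.effect_basis.T
        return self.effect_scale * self.effect_norm * raw


def generate(config: SyntheticConfig) -> tuple[ExpressionMatrix, CompoundTable,
                                               GroundTruth]:
    """Generate a plate-structured paired dataset from a config.

    Per cell line and replicate there is one plate holding
    ``n_controls_per_plate`` DMSO wells plus one well per compound; compound
    wells are the plate's basal draw plus the planted effect plus
    perturbation noise, all at the canonical 24 h / 10 uM condition.
    Fully deterministic given ``config.seed``.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    cell_ids = [f"CELL{i:02d}" for i in range(c.n_cells)]
    compound_ids = [f"CPD{i:04d}" for i in range(c.n_compounds)]

    cell_means = 7.0 + rng.standard_normal((c.n_cells, c.n_genes))
    features = (rng.random((c.n_compounds, c.feature_dim))
                < c.feature_density).astype(float)
    # make sure no compound is featureless
    for i in np.flatnonzero(features.sum(axis=1) == 0):
        features[i, rng.integers(c.feature_dim)] = 1.0
    basis = rng.standard_normal((c.n_genes, c.effect_rank))
    loading = rng.standard_normal((c.effect_rank, c.feature_dim))
    raw = features @ loading.T @ basis.T
    # global scale so the planted effects have unit RMS amplitude per gene
    norm = 1.0 / max(float(np.sqrt(np.mean(raw ** 2))), 1e-12)
    death_dir = rng.standard_normal(c.n_genes)
    gt = GroundTruth(cell_means=cell_means, effect_basis=basis,
                     loading_map=loading, effect_norm=norm,
                     effect_scale=c.effect_scale,
                     compound_features=features, compound_ids=compound_ids,
                     cell_ids=cell_ids, sensitivity_direction=death_dir)
    effects = gt.effect_matrix()

    rows, meta = [], []
    for ci, cell in enumerate(cell_ids):
        for rep in range(c.n_replicates):
            plate = f"{cell}_P{rep:02d}"
            for w in range(c.n_controls_per_plate):
                x = cell_means[ci] + c.noise_sd_basal \
                    * rng.standard_normal(c.n_genes)
                rows.append(x)
                meta.append((f"{plate}_DMSO{w:02d}", plate, cell, "DMSO",
                             "dmso_control", np.nan, 24.0))
            for mi, cmpd in enumerate(compound_ids):
                x1 = cell_means[ci] + c.noise_sd_basal \
                    * rng.standard_normal(c.n_genes)
                x2 = x1 + effects[mi] + c.noise_sd_pert \
                    * rng.standard_normal(c.n_genes)
                rows.append(x2)
                meta.append((f"{plate}_{cmpd}", plate, cell, cmpd,
                             "compound", 10.0, 24.0))
    samples = pd.DataFrame(meta, columns=list(META_COLUMNS))
    matrix = ExpressionMatrix(
        gene_ids=[f"G{i:04d}" for i in range(c.n_genes)],
        values=np.vstack(rows), samples=samples)
    compounds = CompoundTable(
        smiles={}, features={cid: features[i]
                             for i, cid in enumerate(compound_ids)})
    return matrix, compounds, gt


def generate_knockdown(config: SyntheticConfig) -> ExpressionMatrix:
    """Generate shRNA-style pairs for VAE pretraining.

    Same plate structure as :func:`generate` but perturbagens are labelled
    as shRNA with empty-vector controls and carry no dose.
    """
    matrix, _, _ = generate(config)
    meta = matrix.samples.copy()
    is_ctrl = meta["pert_type"] == "dmso_control"
    meta.loc[is_ctrl, "pert_type"] = "empty_vector_control"
    meta.loc[is_ctrl, "perturbagen_id"] = "EMPTY"
    meta.loc[~is_ctrl, "pert_type"] = "shrna"
    meta.loc[~is_ctrl, "perturbagen_id"] = "sh" + \
        meta.loc[~is_ctrl, "perturbagen_id"]
    meta.loc[~is_ctrl, "dose_um"] = np.nan
    return ExpressionMatrix(gene_ids=matrix.gene_ids, values=matrix.values,
                            samples=meta)


def generate_disease_direction(gt: GroundTruth, seed: int = 0) -> np.ndarray:
    """A planted disease expression direction, unit RMS per gene.

    Drawn inside the low-rank response space spanned by the effect basis, so
    the disease state is one that compound effects can actually mimic or
    reverse -- the premise of signature-reversal repurposing.
    """
    rng = np.random.default_rng(seed)
    d = gt.effect_basis @ rng.standard_normal(gt.effect_basis.shape[1])
    return d / max(float(np.sqrt(np.mean(d ** 2))), 1e-12)


def generate_activity_labels(gt: GroundTruth, target_direction: np.ndarray,
                             threshold: float = 0.3) -> dict[str, int]:
    """Active iff cosine(effect(m), target_direction) > threshold.

    Separable by construction: activity is a deterministic function of the
    planted effect, so a learner on good effect estimates can recover it.
    """
    target = np.asarray(target_direction, dtype=float)
    if target.shape[0] != gt.cell_means.shape[1]:
        raise ValueError("target direction length != n_genes")
    tnorm = np.linalg.norm(target)
    labels = {}
    for i, cid in enumerate(gt.compound_ids):
        e = gt.effect(i)
        denom = np.linalg.norm(e) * tnorm
        cos = float(e @ target / denom) if denom > 0 else 0.0
        labels[cid] = int(cos > threshold)
    return labels


def generate_response_aucs(gt: GroundTruth, cell: str | None = None,
                           death_signature: np.ndarray | None = None,
                           noise_sd: float = 0.0,
                           seed: int = 0) -> dict[str, float]:
    """Dose-response AUC per compound, in [0, 8]; smaller = more sensitive.

    The AUC decreases linearly with the projection of the planted effect on
    the cell-death signature (default: the ground truth's stored
    sensitivity direction), from a resistant ceiling of 7.5, plus optional
    Gaussian noise, clipped to [0, 8].  A zero-effect compound sits at the
    ceiling; the most strongly aligned compound attains the batch minimum.
    """
    sig = gt.sensitivity_direction if death_signature is None \
        else np.asarray(death_signature, dtype=float)
    effects = gt.effect_matrix()
    proj = effects @ (sig / np.linalg.norm(sig))
    top = max(float(np.abs(proj).max()), 1e-12)
    rng = np.random.default_rng(seed)
    noise = noise_sd * rng.standard_normal(len(proj)) if noise_sd > 0 else 0.0
    aucs = np.clip(RESISTANT_CEILING - AUC_SPAN * proj / top + noise, 0.0, 8.0)
    return {cid: float(a) for cid, a in zip(gt.compound_ids, aucs)}
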