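"""Expression-profile handling: I/O, condition filtering, plate-matched
control pairing, MODZ replicate aggregation and train/val/test splitting.

The in-memory container is :class:`ExpressionMatrix`: a samples x genes value
matrix over the 978 L1000 landmark genes plus a per-sample metadata table
(plate, cell line, perturbagen, dose, time).  Compound-treated profiles (X2)
are paired with the DMSO vehicle profiles measured on the same physical plate
(X1), which minimises batch effects between case and control.  Replicate
pairs for one compound x cell-line combination are collapsed to a single pair
with the moderated-Z (MODZ) weighted average used by the Connectivity Map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

logger = logging.getLogger("perturbsig")

N_LANDMARK_GENES = 978

#: metadata columns, in canonical on-disk order
META_COLUMNS = ("sample_id", "plate_id", "cell_line", "perturbagen_id",
                "pert_type", "dose_um", "time_h")

PERT_TYPES = ("compound", "dmso_control", "shrna", "empty_vector_control")
CONTROL_TYPES = ("dmso_control", "empty_vector_control")


class AlignmentError(ValueError):
    """Sample ids of the value matrix and the metadata table disagree."""


class ParseError(ValueError):
    """A cell of the expression TSV could not be parsed as a number."""


@dataclass
class ExpressionMatrix:
    """Expression values (samples x genes) with per-sample metadata.

    ``values[i, j]`` is the expression of gene ``gene_ids[j]`` in the sample
    described by row ``i`` of ``samples``.
    """

    gene_ids: list[str]
    values: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.gene_ids):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes")
        if len(self.samples) != self.values.shape[0]:
            raise ValueError("metadata row count != value row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        missing = set(META_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset(self, row_mask: np.ndarray) -> "ExpressionMatrix":
        """Row subset preserving sample order."""
        idx = np.flatnonzero(np.asarray(row_mask))
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            values=self.values[idx],
            samples=self.samples.iloc[idx].reset_index(drop=True),
        )


@dataclass
class PairedSample:
    """One basal/perturbed profile pair -- the training and inference atom."""

    x1: np.ndarray
    x2: np.ndarray
    compound_id: str
    cell_line: str
    plate_id: str = "aggregated"

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape != self.x2.shape:
            raise ValueError("x1 and x2 must share gene order and length")
        if not (np.all(np.isfinite(self.x1)) and np.all(np.isfinite(self.x2))):
            raise ValueError("paired profiles must be finite")

    @property
    def delta(self) -> np.ndarray:
        """Measured differential expression, x2 - x1."""
        return self.x2 - self.x1


@dataclass
class SplitSpec:
    """Disjoint train/val/test id sets at compound or cell-line level."""

    mode: str
    train_ids: frozenset
    val_ids: frozenset
    test_ids: frozenset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("chemical_blind", "cell_blind"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        sets = (self.train_ids, self.val_ids, self.test_ids)
        if (self.train_ids & self.val_ids or self.train_ids & self.test_ids
                or self.val_ids & self.test_ids):
            raise ValueError("split id sets must be pairwise disjoint")
        self.train_ids, self.val_ids, self.test_ids = map(frozenset, sets)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path, metadata_path, *,
                        allow_any_gene_count: bool = False) -> ExpressionMatrix:
    """Read a gene x sample expression TSV and its sample-metadata TSV.

    On disk the matrix is genes in rows (first column ``gene_id``) and
    samples in columns; in memory it is transposed to samples x genes.
    Samples are aligned to metadata by ``sample_id``; a sample present in
    only one of the two files is an :class:`AlignmentError`.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id', "
                         f"got {raw.columns[0]!r}")
    gene_ids = raw["gene_id"].tolist()
    if not allow_any_gene_count and len(gene_ids) != N_LANDMARK_GENES:
        raise ValueError(
            f"{path}: expected {N_LANDMARK_GENES} landmark genes, found "
            f"{len(gene_ids)} (pass allow_any_gene_count=True for subsets)")
    body = raw.drop(columns="gene_id")
    try:
        mat = body.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell for the error message
        for j, col in enumerate(body.columns):
            for i, cell in enumerate(body[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric value {cell!r} at gene "
                        f"{gene_ids[i]!r} (row {i + 2}), sample {col!r} "
                        f"(column {j + 2})") from None
        raise
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str,
                       keep_default_na=False)
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"{metadata_path}: missing columns {sorted(missing)}")
    meta = meta.copy()
    for col in ("dose_um", "time_h"):
        meta[col] = pd.to_numeric(meta[col].replace("", np.nan))

    expr_ids = list(body.columns)
    meta_ids = meta["sample_id"].tolist()
    only_expr = [s for s in expr_ids if s not in set(meta_ids)]
    only_meta = [s for s in meta_ids if s not in set(expr_ids)]
    if only_expr or only_meta:
        raise AlignmentError(
            f"sample ids differ between files: missing from metadata "
            f"{only_expr}, missing from expression matrix {only_meta}")
    # order samples as in the metadata table
    order = [expr_ids.index(s) for s in meta_ids]
    return ExpressionMatrix(gene_ids=gene_ids, values=mat.T[order],
                            samples=meta)


def write_expression_tsv(m: ExpressionMatrix, path, metadata_path) -> None:
    """Inverse of :func:`read_expression_tsv`; values to 6 decimals."""
    out = pd.DataFrame(m.values.T, columns=m.samples["sample_id"].tolist())
    out.insert(0, "gene_id", m.gene_ids)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = m.samples.copy()
    for col in ("dose_um", "time_h"):
        meta[col] = meta[col].map(
            lambda v: "" if pd.isna(v) else f"{float(v):g}")
    meta[list(META_COLUMNS)].to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and pairing
# ---------------------------------------------------------------------------

def filter_conditions(m: ExpressionMatrix, time_h: float | None = 24.0,
                      dose_um: float | None = 10.0) -> ExpressionMatrix:
    """Keep perturbation samples at the given time/dose plus all controls.

    The canonical condition is 24 h treatment at 10 uM.  Controls carry no
    dose constraint and are always retained.  Passing ``None`` for either
    argument disables that constraint (e.g. shRNA profiles have no dose).
    """
    meta = m.samples
    is_control = meta["pert_type"].isin(CONTROL_TYPES).to_numpy()
    keep = is_control.copy()
    pert = ~is_control
    match = pert.copy()
    if time_h is not None:
        match &= (meta["time_h"].to_numpy(dtype=float) == float(time_h))
    if dose_um is not None:
        match &= (meta["dose_um"].to_numpy(dtype=float) == float(dose_um))
    keep |= match
    out = m.subset(keep)
    n_kept = int(match.sum())
    if n_kept == 0:
        logger.info("filter_conditions: no perturbation samples match "
                    "time=%s h dose=%s uM; controls retained", time_h, dose_um)
    return out


def modz_aggregate(replicates) -> np.ndarray:
    """Moderated-Z weighted average of replicate profiles.

    One replicate is returned verbatim and two are averaged equally.  For
    k >= 3 each replicate is weighted by the sum of its Spearman correlations
    to the other replicates, every pairwise correlation floored at 0.01 so
    that weights stay positive, and the weights normalised to sum to one.
    The result is invariant to replicate order.
    """
    reps = [np.asarray(r, dtype=float) for r in replicates]
    if len(reps) == 0:
        raise ValueError("modz_aggregate requires at least one replicate")
    n = reps[0].shape[0]
    if any(r.ndim != 1 or r.shape[0] != n for r in reps):
        raise ValueError("replicates must be 1-D vectors of equal length")
    k = len(reps)
    if k == 1:
        return reps[0].copy()
    if k == 2:
        return (reps[0] + reps[1]) / 2.0
    mat = np.vstack(reps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant replicate -> nan rho
        corr = spearmanr(mat, axis=1).statistic
    corr = np.atleast_2d(np.nan_to_num(corr, nan=1.0))
    np.fill_diagonal(corr, 0.0)
    corr = np.maximum(corr, 0.01)
    np.fill_diagonal(corr, 0.0)
    w = corr.sum(axis=1)
    w = w / w.sum()
    return w @ mat


def pair_with_controls(m: ExpressionMatrix) -> list[PairedSample]:
    """Pair each perturbation sample with its plate-matched vehicle profile.

    The basal profile x1 of a pair is the MODZ aggregate of all control
    samples on the perturbation sample's plate (a single control is used
    verbatim).  Plates carrying perturbation samples but no control are
    dropped with a warning rather than an error.
    """
    meta = m.samples
    is_control = meta["pert_type"].isin(CONTROL_TYPES).to_numpy()
    control_by_plate: dict[str, np.ndarray] = {}
    for plate, grp in meta[is_control].groupby("plate_id", sort=False):
        control_by_plate[plate] = modz_aggregate(
            [m.values[i] for i in grp.index])
    pairs: list[PairedSample] = []
    for i in np.flatnonzero(~is_control):
        row = meta.iloc[i]
        plate = row["plate_id"]
        if plate not in control_by_plate:
            logger.warning("plate %s has perturbation sample %s but no "
                           "control; sample dropped", plate, row["sample_id"])
            continue
        pairs.append(PairedSample(
            x1=control_by_plate[plate], x2=m.values[i],
            compound_id=row["perturbagen_id"], cell_line=row["cell_line"],
            plate_id=plate))
    return pairs


def collapse_repeats(pairs: list[PairedSample]) -> list[PairedSample]:
    """Collapse replicate pairs to one pair per (compound, cell line).

    x1 and x2 are MODZ-aggregated independently over the replicate group.
    Output order is stable, sorted by (compound_id, cell_line).
    """
    groups: dict[tuple[str, str], list[PairedSample]] = {}
    for p in pairs:
        groups.setdefault((p.compound_id, p.cell_line), []).append(p)
    out = []
    for (cmpd, cell) in sorted(groups):
        grp = groups[(cmpd, cell)]
        plate = grp[0].plate_id if len(grp) == 1 else "aggregated"
        out.append(PairedSample(
            x1=modz_aggregate([g.x1 for g in grp]),
            x2=modz_aggregate([g.x2 for g in grp]),
            compound_id=cmpd, cell_line=cell, plate_id=plate))
    return out


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(pairs: list[PairedSample], mode: str,
                  fractions=(0.8, 0.1, 0.1), seed: int = 0) -> SplitSpec:
    """Partition compound ids (chemical-blind) or cell lines (cell-blind).

    Ids are shuffled under ``seed``; test and val receive floor(f * N) ids
    each and the remainder goes to train, so held-out perturbagens or cell
    lines never appear in training.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if mode == "chemical_blind":
        ids = sorted({p.compound_id for p in pairs})
    elif mode == "cell_blind":
        ids = sorted({p.cell_line for p in pairs})
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    n_parts = sum(1 for f in fractions if f > 0)
    if len(ids) < n_parts:
        raise ValueError(f"only {len(ids)} distinct ids for {n_parts} "
                         "requested partitions")
    rng = np.random.default_rng(seed)
    ids = list(rng.permutation(ids))
    n = len(ids)
    n_test = int(np.floor(fractions[2] * n))
    n_val = int(np.floor(fractions[1] * n))
    test = frozenset(ids[:n_test])
    val = frozenset(ids[n_test:n_test + n_val])
    train = frozenset(ids[n_test + n_val:])
    return SplitSpec(mode=mode, train_ids=train, val_ids=val, test_ids=test,
                     seed=seed)


def apply_split(pairs: list[PairedSample], spec: SplitSpec):
    """Materialise (train, val, test) pair lists from a :class:`SplitSpec`."""
    key = (lambda p: p.compound_id) if spec.mode == "chemical_blind" \
        else (lambda p: p.cell_line)
    train = [p for p in pairs if key(p) in spec.train_ids]
    val = [p for p in pairs if key(p) in spec.val_ids]
    test = [p for p in pairs if key(p) in spec.test_ids]
    return train, val, test


def prepare_pairs(m: ExpressionMatrix, time_h: float | None = 24.0,
                  dose_um: float | None = 10.0) -> list[PairedSample]:
    """Full preprocessing chain: filter -> plate-pair -> collapse repeats."""
    return collapse_repeats(pair_with_controls(
        filter_conditions(m, time_h=time_h, dose_um=dose_um)))
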