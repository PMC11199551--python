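"""Connectivity scoring of differential-expression signatures.

A query phenotype is expressed as an up-regulated and a down-regulated gene
set.  Each reference signature is ranked by its delta values (rank 1 = most
up-regulated) and a Kolmogorov-Smirnov-style running-sum enrichment score
(ES) in [-1, 1] measures whether a gene set concentrates at the top or the
bottom of that ranking.  The two-tailed connectivity score combines the ES
of the up set and the down set: a positive score means the reference mimics
the query phenotype, a negative score means it reverses it, and same-sign
enrichment of both sets cancels to zero.

The literal two-set combination spans [-2, 2]; the conventional score is
reported on [-1, 1], so both the raw and the halved (normalised) values are
exposed and ranking uses the normalised one.

Also here: projection of 978-gene landmark signatures to the 10,174-gene
space (978 landmark + 9196 inferred genes) through an affine weight matrix,
repurposing rank strategies, and screening evaluation against sensitivity
labels (hits = the 20% of compounds with the lowest response AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

N_FULL_GENES = 10174
N_INFERRED_GENES = 9196


@dataclass
class Signature:
    """A differential-expression vector with gene identifiers."""

    gene_ids: list[str]
    delta: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if len(self.gene_ids) != self.delta.shape[0]:
            raise ValueError("gene_ids and delta lengths differ")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")


@dataclass
class GeneSet:
    """A set of gene identifiers with a regulation direction."""

    ids: frozenset
    direction: str = "up"

    def __post_init__(self) -> None:
        self.ids = frozenset(self.ids)
        if len(self.ids) < 1:
            raise ValueError("gene set must be nonempty")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, "
                             f"got {self.direction!r}")

    @property
    def size(self) -> int:
        return len(self.ids)


@dataclass
class ConnectivityResult:
    es_up: float
    es_down: float
    raw_score: float
    normalized_score: float


def enrichment_score(sig: Signature, gs: GeneSet) -> float:
    """Enrichment of a gene set at the top/bottom of a ranked signature.

    Genes are ranked by delta descending (ties by gene index).  With V(j)
    the rank of the j-th set gene (set genes in ascending rank order),
    t the set size and n the signature length::

        a  = max_j [ j/t - V(j)/n ]
        b  = max_j [ V(j)/n - (j-1)/t ]
        ES = a if a > b else -b

    so ES > 0 indicates concentration at the top (up-regulated end) and
    ES < 0 at the bottom.
    """
    missing = sorted(gs.ids - set(sig.gene_ids))
    if missing:
        raise ValueError(f"gene set members absent from signature: "
                         f"{missing[:10]}")
    n = len(sig.gene_ids)
    # rank 1 = most up-regulated; stable sort breaks ties by gene index
    order = np.argsort(-sig.delta, kind="stable")
    rank_of = {sig.gene_ids[g]: pos + 1 for pos, g in enumerate(order)}
    v = np.sort([rank_of[g] for g in gs.ids])
    t = v.shape[0]
    j = np.arange(1, t + 1)
    a = np.max(j / t - v / n)
    b = np.max(v / n - (j - 1) / t)
    return float(a if a > b else -b)


def connectivity_score(es_up: float, es_down: float) -> ConnectivityResult:
    """Two-tailed combination of up-set and down-set enrichment scores.

    ``raw = es_up - es_down`` when the two scores have opposite signs and 0
    otherwise; the normalised score is ``raw / 2`` so complete reversal of
    the query maps to -1 and complete mimicry to +1.
    """
    if not (-1 <= es_up <= 1 and -1 <= es_down <= 1):
        raise ValueError("enrichment scores must lie in [-1, 1]")
    raw = es_up - es_down if np.sign(es_up) != np.sign(es_down) else 0.0
    return ConnectivityResult(es_up=es_up, es_down=es_down, raw_score=raw,
                              normalized_score=raw / 2.0)


def score_library(references: list[Signature], up: GeneSet,
                  down: GeneSet) -> dict[str, ConnectivityResult]:
    """Connectivity of a query (up, down) gene-set pair against each
    reference signature."""
    out = {}
    for sig in references:
        out[sig.source_id] = connectivity_score(
            enrichment_score(sig, up), enrichment_score(sig, down))
    return out


def query_sets_from_signature(sig: Signature, top: int = 50) -> tuple[GeneSet, GeneSet]:
    """Build (up, down) query gene sets from a signature's extremes.

    Takes the ``top`` most up-regulated and most down-regulated genes;
    the standard way to turn a drug or disease signature into a
    connectivity query.
    """
    order = np.argsort(-sig.delta, kind="stable")
    up = frozenset(sig.gene_ids[i] for i in order[:top])
    down = frozenset(sig.gene_ids[i] for i in order[-top:])
    return GeneSet(up, "up"), GeneSet(down, "down")


def combine_scores(tables: list[dict[str, ConnectivityResult]]) -> dict[str, float]:
    """Mean normalised score per compound over several query signatures."""
    if not tables:
        raise ValueError("no score tables to combine")
    ids = set(tables[0])
    for t in tables[1:]:
        if set(t) != ids:
            raise ValueError("score tables cover different compounds")
    return {c: float(np.mean([t[c].normalized_score for t in tables]))
            for c in sorted(ids)}


def rank_for_repurposing(scores, mode: str = "disease") -> list[str]:
    """Order compounds for repurposing.

    ``mode='drug'``: most positive normalised score first (mimics approved
    drugs).  ``mode='disease'``: most negative first (reverses the disease
    signature).  ``scores`` may be one score table, a list of tables (mean
    normalised score per compound is taken first), or a plain id -> float
    mapping.  Ties break lexicographically by id.
    """
    if not scores:
        raise ValueError("nonempty scores required")
    if isinstance(scores, list):
        flat = combine_scores(scores)
    else:
        flat = {k: (v.normalized_score if isinstance(v, ConnectivityResult)
                    else float(v)) for k, v in scores.items()}
    if mode == "drug":
        return sorted(flat, key=lambda c: (-flat[c], c))
    if mode == "disease":
        return sorted(flat, key=lambda c: (flat[c], c))
    raise ValueError(f"mode must be drug/disease, got {mode!r}")


def project_landmark_to_full(delta978: np.ndarray, weights: np.ndarray,
                             bias: np.ndarray) -> np.ndarray:
    """Affine projection from 978 landmark genes to the 10,174-gene space.

    The output concatenates the unchanged landmark block with the inferred
    block ``W @ delta978 + bias`` (9196 genes), mirroring the L1000
    landmark-to-transcriptome inference matrix.
    """
    delta978 = np.asarray(delta978, dtype=float)
    weights = np.asarray(weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if weights.ndim != 2 or weights.shape[1] != delta978.shape[0]:
        raise ValueError(f"weight matrix {weights.shape} incompatible with "
                         f"signature length {delta978.shape[0]}")
    if bias.shape[0] != weights.shape[0]:
        raise ValueError("bias length != weight row count")
    return np.concatenate([delta978, weights @ delta978 + bias])


def evaluate_screen(ranking: list[str],
                    auc_labels: dict[str, float]) -> tuple[set, float]:
    """Score a compound ranking against response-AUC ground truth.

    Hits are the floor(0.2 * N) compounds with the lowest response AUC
    (greatest sensitivity; ties by id).  Returns the hit set and the AUROC
    of recovering hits from the ranking order (rank 1 scored highest).
    """
    missing = [c for c in ranking if c not in auc_labels]
    if missing:
        raise ValueError(f"compounds without AUC label: {missing[:10]}")
    n = len(ranking)
    n_hits = int(np.floor(0.2 * n))
    by_auc = sorted(ranking, key=lambda c: (auc_labels[c], c))
    hits = set(by_auc[:n_hits])
    y_true = np.array([c in hits for c in ranking], dtype=int)
    y_score = -np.arange(n, dtype=float)  # earlier rank = higher score
    return hits, float(roc_auc_score(y_true, y_score))


# ---------------------------------------------------------------------------
# File formats: GMT gene sets, signature TSV, projection-weight TSV
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    from gseapy.parser import read_gmt as _read
    return _read(str(path))


def read_signatures_tsv(path) -> list[Signature]:
    """Read signatures from a TSV with gene_id rows and source_id columns."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = df.index.astype(str).tolist()
    return [Signature(gene_ids=genes, delta=df[c].to_numpy(dtype=float),
                      source_id=str(c)) for c in df.columns]


def read_projection_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a landmark-to-full-gene weight TSV (last column = bias)."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy(dtype=float)
    return mat[:, :-1], mat[:, -1]
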