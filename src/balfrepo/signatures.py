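"""Compound-protein interaction scores and drug interaction signatures.

Each compound-protein score is a bioanalytic-docking surrogate for
binding likelihood: for every predicted binding site of the protein the
candidate score is ``PScore * CScore``, where PScore is the site's
confidence and CScore is the Sorensen-Dice similarity between the query
compound's substructure fingerprint and the site's co-crystallized
template ligand. The reported score is the best candidate over the
protein's sites (aggregation is configurable; ``max`` is the default
and the winning site is recorded as provenance).

Restricting the score matrix columns to the differentially expressed
protein subset yields one *interaction signature* per compound — the
vector compared across compounds by the ranking stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CompoundLibrary, SiteTable

AGGREGATIONS = ("max", "mean", "sum")


def dice_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Sorensen-Dice coefficient of two equal-length bit vectors.

    ``2|a AND b| / (|a| + |b|)``; defined as 0 when both vectors are
    all-zero.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def score_interaction(
    compound_fp: np.ndarray,
    sites: list[tuple[float, np.ndarray]],
    aggregation: str = "max",
) -> tuple[float, int | None]:
    """Interaction score of one compound against one protein's sites.

    Each site contributes ``pscore * dice(compound, ligand)``. Returns
    (score, winning site index) under ``max`` aggregation, or
    (aggregate, None) for ``mean``/``sum``. A protein with no sites
    scores 0.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    if not sites:
        return 0.0, None
    candidates = []
    for pscore, ligand in sites:
        if not 0.0 <= pscore <= 1.0:
            raise ValueError(f"PScore {pscore} outside [0, 1]")
        candidates.append(pscore * dice_similarity(compound_fp, ligand))
    if aggregation == "max":
        best = int(np.argmax(candidates))
        return float(candidates[best]), best
    if aggregation == "mean":
        return float(np.mean(candidates)), None
    return float(np.sum(candidates)), None


@dataclass
class InteractionMatrix:
    """Compound x protein interaction scores with per-entry provenance.

    ``scores``: DataFrame, rows = compound IDs, columns = protein IDs,
    entries in [0, 1] (for max/mean aggregation). ``site_index`` /
    ``cscore`` / ``pscore`` hold, per entry, the winning site's global
    index in the site table and its two factors (max aggregation only;
    otherwise None).
    """

    scores: pd.DataFrame
    site_index: pd.DataFrame | None = None
    cscore: pd.DataFrame | None = None
    pscore: pd.DataFrame | None = None
    aggregation: str = "max"

    @property
    def compounds(self) -> list[str]:
        return list(self.scores.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.scores.rename_axis("compound_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="compound_id"))


def build_matrix(
    library: CompoundLibrary,
    sites: SiteTable,
    aggregation: str = "max",
) -> InteractionMatrix:
    """Dense interaction matrix over all compounds x library proteins.

    Vectorized: Dice numerators for all compound-site pairs come from a
    single bit-matrix product; per-protein aggregation then reduces the
    site axis.
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    if (sites.pscores < 0).any() or (sites.pscores > 1).any():
        raise ValueError("PScore outside [0, 1] in site table")
    if sites.ligand_fps.shape[1] != library.n_bits:
        raise ValueError("fingerprint length mismatch between compounds and ligands")

    # sort sites by protein so each protein's sites are one contiguous block
    order = np.argsort(np.asarray(sites.protein_ids, dtype=object), kind="stable")
    prot_sorted = np.asarray(sites.protein_ids, dtype=object)[order]
    ligands = sites.ligand_fps[order].astype(np.float64)
    pscores = sites.pscores[order]

    comp = library.fingerprints.astype(np.float64)
    inter = comp @ ligands.T                         # (n_comp, n_sites)
    pop_c = comp.sum(axis=1)[:, None]
    pop_l = ligands.sum(axis=1)[None, :]
    denom = pop_c + pop_l
    with np.errstate(invalid="ignore", divide="ignore"):
        dice = np.where(denom > 0, 2.0 * inter / denom, 0.0)
    cand = dice * pscores[None, :]                   # (n_comp, n_sites)

    proteins, starts = np.unique(prot_sorted, return_index=True)
    if aggregation == "max":
        agg = np.maximum.reduceat(cand, starts, axis=1)
        # winning site per (compound, protein): argmax within each block
        win = np.empty_like(agg, dtype=np.int64)
        for k, s in enumerate(starts):
            e = starts[k + 1] if k + 1 < len(starts) else cand.shape[1]
            local = np.argmax(cand[:, s:e], axis=1)
            win[:, k] = order[s + local]
        site_index = pd.DataFrame(win, index=library.ids, columns=proteins)
        flat = win.ravel()
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        cscore = pd.DataFrame(
            np.take_along_axis(dice, inv[flat].reshape(win.shape), axis=1),
            index=library.ids,
            columns=proteins,
        )
        pscore = pd.DataFrame(
            sites.pscores[flat].reshape(win.shape), index=library.ids, columns=proteins
        )
    elif aggregation == "mean":
        sums = np.add.reduceat(cand, starts, axis=1)
        counts = np.diff(np.append(starts, cand.shape[1]))
        agg = sums / counts[None, :]
        site_index = cscore = pscore = None
    else:
        agg = np.add.reduceat(cand, starts, axis=1)
        site_index = cscore = pscore = None

    scores = pd.DataFrame(agg, index=library.ids, columns=proteins)
    return InteractionMatrix(
        scores,
        site_index=site_index,
        cscore=cscore,
        pscore=pscore,
        aggregation=aggregation,
    )


@dataclass
class SignatureSet:
    """Interaction signatures of all compounds over a fixed protein subset.

    ``signatures``: rows = compound IDs, columns = the ordered protein
    subset. ``n_missing``: how many requested proteins were absent from
    the interaction matrix (e.g. DE proteins without structural
    coverage).
    """

    signatures: pd.DataFrame
    subset: list[str]
    n_missing: int
    missing: list[str]

    @property
    def compounds(self) -> list[str]:
        return list(self.signatures.index)

    def vector(self, compound_id: str) -> np.ndarray:
        return self.signatures.loc[compound_id].to_numpy(dtype=float)


def restrict_to_subset(
    matrix: InteractionMatrix, protein_subset: list[str]
) -> SignatureSet:
    """Signatures over the intersection of a protein subset with the matrix.

    The subset typically comes from the differential-expression stage;
    proteins absent from the matrix columns (no structural coverage)
    are dropped and counted.
    """
    requested = list(dict.fromkeys(protein_subset))  # de-dup, keep order
    cols = [p for p in requested if p in matrix.scores.columns]
    missing = [p for p in requested if p not in matrix.scores.columns]
    if not cols:
        raise ValueError("no requested protein is present in the interaction matrix")
    return SignatureSet(
        signatures=matrix.scores[cols].copy(),
        subset=cols,
        n_missing=len(missing),
        missing=missing,
    )
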