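"""Consensus top-k ranking of repurposing candidates by signature similarity.

For each known-treatment drug, all other compounds are ranked by cosine
similarity of their interaction signatures and the top ``k`` (default
30) most similar are recorded. A candidate compound (not itself a known
treatment) is credited once per list it appears in, together with its
position. Candidates are then ordered by consensus count (how many
lists, descending) and, within equal counts, by average position
(ascending): compounds resembling *many* known treatments rank first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signatures import SignatureSet


def cosine_signature_similarity(s1: np.ndarray, s2: np.ndarray) -> float:
    """Cosine similarity of two signatures over the same ordered protein subset.

    A pair involving an all-zero signature returns 0 (no direction to
    compare) with a warning.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"signature subset mismatch: {s1.shape} vs {s2.shape}")
    n1 = np.linalg.norm(s1)
    n2 = np.linalg.norm(s2)
    if n1 == 0 or n2 == 0:
        warnings.warn("zero-vector signature in cosine similarity", stacklevel=2)
        return 0.0
    return float(s1 @ s2 / (n1 * n2))


@dataclass
class ConsensusRanking:
    """Result of the consensus protocol.

    ``table`` (index = candidate compound ID): consensus_count,
    average_rank, overall_rank — sorted by (count desc, average rank
    asc, ID asc). ``ranks`` holds each candidate's within-list
    positions (1-based), one per known-drug list that contains it.
    """

    table: pd.DataFrame
    ranks: dict[str, list[int]] = field(default_factory=dict)
    top_k: int = 30
    known_ids: list[str] = field(default_factory=list)
    tie_break: str = "compound_id"

    def candidates(self, min_count: int = 1) -> pd.DataFrame:
        return self.table[self.table["consensus_count"] >= min_count]

    def to_tsv(self, path: str | Path) -> None:
        self.table.rename_axis("compound_id").to_csv(path, sep="\t")


def top_k_list(
    similarities: pd.Series, query: str, top_k: int, exclude: set[str] | None = None
) -> list[str]:
    """The ``top_k`` most similar compounds to ``query`` (query excluded).

    Ties in similarity are broken by compound ID (ascending) so the
    ranking is deterministic and independent of input order.
    """
    sims = similarities.drop(index=query, errors="ignore")
    if exclude:
        sims = sims.drop(index=[c for c in exclude if c != query], errors="ignore")
    order = sorted(sims.index, key=lambda c: (-sims[c], c))
    return order[:top_k]


def consensus_rank(
    signatures: SignatureSet,
    known_ids: list[str],
    top_k: int = 30,
    exclude_known_from_lists: bool = False,
) -> ConsensusRanking:
    """Run the consensus top-k protocol over a signature set.

    ``known_ids`` are the known-treatment drugs iterated over; they are
    never credited as candidates. By default they still occupy slots
    inside each top-k list; ``exclude_known_from_lists=True`` removes
    them from the lists entirely so all ``top_k`` slots go to
    candidates.
    """
    if not known_ids:
        raise ValueError("known_ids must be nonempty")
    missing = [k for k in known_ids if k not in signatures.signatures.index]
    if missing:
        raise ValueError(f"known drugs absent from signature set: {missing}")

    sig = signatures.signatures
    known_set = set(known_ids)
    n_available = len(sig) - 1 - (len(known_set) - 1 if exclude_known_from_lists else 0)
    if n_available < top_k:
        warnings.warn(
            f"only {n_available} comparable compounds; top-{top_k} lists clipped",
            stacklevel=2,
        )

    # row-normalized signature matrix -> all cosines in one product
    mat = sig.to_numpy(dtype=float)
    norms = np.linalg.norm(mat, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero signature(s); their similarities are 0",
            stacklevel=2,
        )
    unit = np.where(zero[:, None], 0.0, mat / np.where(zero, 1.0, norms)[:, None])
    ids = list(sig.index)
    idx = {c: i for i, c in enumerate(ids)}

    ranks: dict[str, list[int]] = {}
    for known in sorted(known_ids):
        sims = pd.Series(unit @ unit[idx[known]], index=ids)
        exclude = known_set if exclude_known_from_lists else None
        for pos, comp in enumerate(top_k_list(sims, known, top_k, exclude), start=1):
            if comp in known_set:
                continue
            ranks.setdefault(comp, []).append(pos)

    rows = {
        comp: (len(r), float(np.mean(r))) for comp, r in ranks.items()
    }
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["consensus_count", "average_rank"]
    )
    table = table.loc[
        sorted(
            table.index,
            key=lambda c: (-table.at[c, "consensus_count"], table.at[c, "average_rank"], c),
        )
    ]
    table["overall_rank"] = np.arange(1, len(table) + 1)
    return ConsensusRanking(
        table, ranks=ranks, top_k=top_k, known_ids=sorted(known_ids)
    )
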