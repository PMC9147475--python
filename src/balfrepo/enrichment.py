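"""Drug and drug-combination enrichment against the idealized vector.

Each drug is a signed vector D over the network entities (+1 promotes,
-1 inhibits, 0 no documented interaction). The enrichment score of a
drug (or of a combination's net-effect vector, the element-wise sign of
the member sum) is its cosine similarity to the idealized intervention
vector M:

    Sc(D, M) = D . M / (||D|| ||M||)

Sc = 1 means the drug does exactly what the network calls for; -1 means
it does exactly the opposite. Significance is empirical: the observed
Sc is ranked against a null sample of Sc values from same-size
combinations of background drugs (each interacting with at least one
network entity), with

    p_hat = (r + 1) / (n + 1)

where r counts null values strictly greater than the observed score.
The +1 terms make p_hat achievable no smaller than 1/(n+1) and keep it
valid (super-uniform) under the null.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import IdealizedVector
from .synthetic import INHIBIT, PROMOTE

_EFFECT_SIGN = {PROMOTE: 1, INHIBIT: -1, "1": 1, "-1": -1, 1: 1, -1: -1}


def drug_vector(
    drug: str,
    effects: pd.DataFrame,
    entity_order: list[str],
) -> np.ndarray:
    """Signed effect vector of one drug over the network entities.

    ``effects`` columns: drug, protein, effect (promote/inhibit).
    Effects on entities outside the network are skipped with a warning;
    contradictory documented effects on the same entity cancel to 0.
    """
    idx = {e: i for i, e in enumerate(entity_order)}
    vec = np.zeros(len(entity_order), dtype=np.int8)
    seen: dict[int, set[int]] = {}
    mine = effects[effects["drug"] == drug]
    for row in mine.itertuples(index=False):
        target = str(row.protein)
        try:
            sign = _EFFECT_SIGN[row.effect]
        except KeyError:
            raise ValueError(f"unknown effect label {row.effect!r}") from None
        if target not in idx:
            warnings.warn(
                f"{drug}: effect on unknown entity {target!r} skipped", stacklevel=2
            )
            continue
        seen.setdefault(idx[target], set()).add(sign)
    for i, signs in seen.items():
        if len(signs) > 1:
            warnings.warn(
                f"{drug}: conflicting documented effects on "
                f"{entity_order[i]!r} resolved to 0",
                stacklevel=2,
            )
            vec[i] = 0
        else:
            vec[i] = signs.pop()
    return vec


def cosine_enrichment(d: np.ndarray, m: np.ndarray | IdealizedVector) -> float:
    """Sc(D, M): cosine similarity of a drug vector with the idealized vector."""
    if isinstance(m, IdealizedVector):
        m = m.to_numpy()
    d = np.asarray(d, dtype=float)
    m = np.asarray(m, dtype=float)
    if d.shape != m.shape:
        raise ValueError(f"vector length mismatch: {d.shape} vs {m.shape}")
    nd2 = float(d @ d)
    nm2 = float(m @ m)
    if nd2 == 0 or nm2 == 0:
        raise ValueError("zero vector is ineligible for enrichment scoring")
    # single sqrt of the squared-norm product keeps D = +-M exactly at +-1
    return float(np.clip(d @ m / np.sqrt(nd2 * nm2), -1.0, 1.0))


def net_effect(vectors: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Element-wise sign of the sum of member drug vectors (sgn(0) = 0)."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] < 1:
        raise ValueError("need at least one drug vector")
    return np.sign(arr.sum(axis=0)).astype(np.int8)


def null_distribution(
    background: np.ndarray,
    m: np.ndarray | IdealizedVector,
    combo_size: int,
    n_samples: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null Sc sample from size-``combo_size`` background combinations.

    ``background``: (n_drugs, n_entities) signed matrix, every row
    nonzero. All combinations are enumerated when there are at most
    ``n_samples`` of them; otherwise ``n_samples`` subsets are drawn
    uniformly (with replacement across draws, without within a draw).
    Zero net-effect combinations contribute Sc = NaN and are dropped.
    """
    if isinstance(m, IdealizedVector):
        m = m.to_numpy()
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ValueError("background must be a nonempty (drugs x entities) matrix")
    if (np.abs(bg).sum(axis=1) == 0).any():
        raise ValueError("background contains an all-zero drug vector")
    nb = bg.shape[0]
    if combo_size > nb:
        raise ValueError("combo_size exceeds background size")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    n_total = math.comb(nb, combo_size)
    if n_total <= n_samples:
        subsets = np.array(
            list(itertools.combinations(range(nb), combo_size)), dtype=int
        )
    else:
        subsets = np.empty((n_samples, combo_size), dtype=int)
        for i in range(n_samples):
            subsets[i] = rng.choice(nb, size=combo_size, replace=False)

    nets = np.sign(bg[subsets].sum(axis=1))          # (n, entities)
    norms2 = (nets * nets).sum(axis=1)
    mvec = np.asarray(m, dtype=float)
    nm2 = float(mvec @ mvec)
    if nm2 == 0:
        raise ValueError("idealized vector is zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        # same sqrt(|D|^2 |M|^2) form as cosine_enrichment so ties are exact
        sc = (nets @ mvec) / np.sqrt(norms2 * nm2)
    return sc[norms2 > 0]


def empirical_p(sc_obs: float, null_sample: np.ndarray) -> float:
    """p_hat = (r + 1) / (n + 1), r = #{null Sc strictly greater than observed}."""
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("null sample is empty")
    r = int((null_sample > sc_obs).sum())
    n = null_sample.size
    return (r + 1) / (n + 1)


@dataclass
class EnrichmentReport:
    """Scored singles and combinations, plus drug frequencies among hits.

    ``table`` columns: members (tuple of drug IDs), size, Sc, p_hat,
    significant — sorted by (Sc desc, p_hat asc, size asc, members).
    ``frequencies``: per drug, its appearance count among significant
    *pairs* and the fraction of significant pairs containing it.
    """

    table: pd.DataFrame
    frequencies: pd.DataFrame
    alpha: float
    null_sizes: dict[int, int] = field(default_factory=dict)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def significant_pairs(self) -> pd.DataFrame:
        return self.table[(self.table["size"] == 2) & self.table["significant"]]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["members"] = out["members"].map(lambda m: "+".join(m))
        out.to_csv(path, sep="\t", index=False)


def enrich_combinations(
    candidates: dict[str, np.ndarray],
    m: np.ndarray | IdealizedVector,
    background: dict[str, np.ndarray] | None = None,
    max_size: int = 2,
    alpha: float = 0.05,
    n_null_samples: int = 10_000,
    seed: int = 0,
) -> EnrichmentReport:
    """Score every candidate single and combination up to ``max_size``.

    ``candidates`` maps drug ID -> signed effect vector (zero vectors
    are ineligible and rejected). The null for size-k combinations is
    drawn from size-k combinations of the background (default: the
    candidates themselves). Combinations whose net effect cancels to
    the zero vector get Sc = NaN and are never significant.
    """
    if isinstance(m, IdealizedVector):
        m = m.to_numpy()
    if not candidates:
        raise ValueError("no eligible candidate drugs")
    for drug, vec in candidates.items():
        if np.abs(np.asarray(vec)).sum() == 0:
            raise ValueError(f"candidate {drug!r} has an all-zero effect vector")
    bg_map = background if background is not None else candidates
    bg = np.stack([np.asarray(v, dtype=float) for _, v in sorted(bg_map.items())])

    rng = np.random.default_rng(seed)
    rows = []
    null_sizes: dict[int, int] = {}
    names = sorted(candidates)
    for size in range(1, max_size + 1):
        if size > len(names):
            break
        null = null_distribution(bg, m, size, n_samples=n_null_samples, seed=rng)
        null_sizes[size] = null.size
        for members in itertools.combinations(names, size):
            net = net_effect([candidates[d] for d in members])
            if np.abs(net).sum() == 0:
                rows.append((members, size, np.nan, np.nan, False))
                continue
            sc = cosine_enrichment(net, m)
            p = empirical_p(sc, null)
            rows.append((members, size, sc, p, p < alpha))

    table = pd.DataFrame(
        rows, columns=["members", "size", "Sc", "p_hat", "significant"]
    )
    table = table.sort_values(
        by=["Sc", "p_hat", "size", "members"],
        ascending=[False, True, True, True],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)

    sig_pairs = table[(table["size"] == 2) & table["significant"]]
    counts: dict[str, int] = {}
    for members in sig_pairs["members"]:
        for d in members:
            counts[d] = counts.get(d, 0) + 1
    n_pairs = len(sig_pairs)
    freq = pd.DataFrame(
        {
            "count": pd.Series(counts, dtype=int),
            "fraction": pd.Series(
                {d: c / n_pairs for d, c in counts.items()} if n_pairs else {},
                dtype=float,
            ),
        }
    ).sort_values(by=["count"], ascending=False)
    freq = freq.loc[sorted(freq.index, key=lambda d: (-freq.at[d, "count"], d))]
    return EnrichmentReport(table, freq, alpha=alpha, null_sizes=null_sizes)


DESIRED = "desired"
UNDESIRED = "undesired"
UNKNOWN = "unknown"


def classify_drug_effects(
    drugs: list[str],
    m: IdealizedVector,
    effects: pd.DataFrame,
) -> pd.DataFrame:
    """Per (drug, hub) label: does the documented effect match the ideal?

    desired = documented sign equals the idealized sign at that hub;
    undesired = opposite; unknown = no documented effect. The summary
    column ``any_undesired`` flags drugs documented to work against at
    least one hub.
    """
    hubs = m.hubs
    rows = []
    for drug in drugs:
        vec = drug_vector(drug, effects, m.entities)
        series = pd.Series(vec, index=m.entities)
        for h in hubs:
            doc = int(series[h])
            ideal = int(m.values[h])
            label = UNKNOWN if doc == 0 else DESIRED if doc == ideal else UNDESIRED
            rows.append((drug, h, label))
    out = pd.DataFrame(rows, columns=["drug", "hub", "label"])
    any_und = out[out["label"] == UNDESIRED].groupby("drug").size()
    out["any_undesired"] = out["drug"].map(lambda d: bool(any_und.get(d, 0)))
    return out
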