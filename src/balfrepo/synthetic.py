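"""Synthetic pipeline inputs with planted ground truth.

Every downstream stage of the pipeline (differential expression,
interaction signatures, consensus ranking, network hubs, enrichment)
is exercised against data generated here, where the truth is known by
construction:

* a log-normal intensity table with planted differential proteins
  (half up, half down in the case group) and an albumin row whose
  observed intensity tracks a per-sample recovery factor;
* a compound library of random substructure bit vectors with a set of
  flagged known-treatment drugs and one *clone* compound whose
  fingerprint is copied from a known drug (a ranking stage must
  recover it at position 1);
* a binding-site table (protein, site confidence score, co-crystal
  ligand fingerprint);
* a signed regulatory graph built as clique communities chained by
  planted bridge hubs, so the hubs provably dominate betweenness; and
* a signed drug-protein effect list containing one *ideal* drug whose
  effects equal the idealized intervention vector on the planted hubs
  and one *anti-ideal* drug with every sign flipped.

Identical config (including seed) reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import DOWN, UP, QuantTable

PROMOTE = "promote"
INHIBIT = "inhibit"


# ---------------------------------------------------------------------------
# config


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study.

    Defaults reproduce the benchmark conditions used throughout the test
    suite: 10 samples per group, 40 of 200 proteins differential at a
    log2 effect of 2 with 5% within-group CV.
    """

    n_proteins: int = 200
    n_per_group: int = 10
    n_de_true: int = 40
    log2_effect: float = 2.0
    cv_noise: float = 0.05
    recovery_cv: float = 0.0
    missing_fraction: float = 0.0

    n_compounds: int = 120
    n_known_drugs: int = 10
    fingerprint_bits: int = 128
    bit_density: float = 0.15

    n_sites_per_protein: tuple[int, int] = (1, 3)
    n_library_proteins: int = 80
    n_de_in_library: int | None = None  # None -> min(30, n_de_true, n_library_proteins)

    n_hub_planted: int = 2
    isolated_fraction: float = 0.2
    edge_sign_neg_fraction: float = 0.5
    n_effect_drugs: int = 20

    seed: int = 0

    albumin_id: str = "ALB"

    def __post_init__(self) -> None:
        if self.n_de_true > self.n_proteins:
            raise ValueError("n_de_true must be <= n_proteins")
        if self.n_known_drugs >= self.n_compounds:
            raise ValueError("n_known_drugs must be < n_compounds")
        if self.fingerprint_bits < 8:
            raise ValueError("fingerprint_bits must be >= 8")
        for name in ("n_proteins", "n_per_group", "n_compounds", "n_known_drugs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.isolated_fraction < 1:
            raise ValueError("isolated_fraction must be in [0, 1)")
        lo, hi = self.n_sites_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("n_sites_per_protein must be a range with 1 <= lo <= hi")
        if self.n_de_in_library is None:
            self.n_de_in_library = min(30, self.n_de_true, self.n_library_proteins)
        if self.n_de_in_library > min(self.n_de_true, self.n_library_proteins):
            raise ValueError("n_de_in_library exceeds planted DE or library size")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per logical stream, stable across calls."""
        return np.random.default_rng([int(self.seed), stream])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_sites_per_protein"] = list(self.n_sites_per_protein)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "n_sites_per_protein" in d:
            d["n_sites_per_protein"] = tuple(d["n_sites_per_protein"])
        return cls(**d)


# ---------------------------------------------------------------------------
# fingerprint helpers


def fp_to_hex(bits: np.ndarray) -> str:
    return np.packbits(bits.astype(np.uint8)).tobytes().hex()

def fp_from_hex(s: str, n_bits: int) -> np.ndarray:
    return np.unpackbits(np.frombuffer(bytes.fromhex(s), dtype=np.uint8))[:n_bits]


@dataclass
class CompoundLibrary:
    """Fixed-length substructure bit vectors with known-treatment flags."""

    ids: list[str]
    is_known: np.ndarray          # bool, shape (n,)
    fingerprints: np.ndarray      # uint8 {0,1}, shape (n, bits)

    @property
    def n_bits(self) -> int:
        return self.fingerprints.shape[1]

    @property
    def known_ids(self) -> list[str]:
        return [c for c, k in zip(self.ids, self.is_known) if k]

    def fingerprint(self, compound_id: str) -> np.ndarray:
        return self.fingerprints[self.ids.index(compound_id)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_bits": self.n_bits,
            "compounds": [
                {"id": c, "known": bool(k), "fp": fp_to_hex(f)}
                for c, k, f in zip(self.ids, self.is_known, self.fingerprints)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CompoundLibrary":
        payload = json.loads(Path(path).read_text())
        n_bits = payload["n_bits"]
        rows = payload["compounds"]
        return cls(
            ids=[r["id"] for r in rows],
            is_known=np.array([r["known"] for r in rows], dtype=bool),
            fingerprints=np.stack([fp_from_hex(r["fp"], n_bits) for r in rows]),
        )


@dataclass
class SiteTable:
    """Predicted binding sites: confidence score + template-ligand fingerprint."""

    protein_ids: list[str]        # one entry per site
    pscores: np.ndarray           # float in (0, 1], shape (n_sites,)
    ligand_fps: np.ndarray        # uint8 {0,1}, shape (n_sites, bits)

    @property
    def proteins(self) -> list[str]:
        return sorted(set(self.protein_ids))

    def sites_for(self, protein_id: str) -> list[tuple[float, np.ndarray]]:
        return [
            (float(self.pscores[i]), self.ligand_fps[i])
            for i, p in enumerate(self.protein_ids)
            if p == protein_id
        ]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "protein_id": self.protein_ids,
                "site_id": [f"{p}_s{i}" for i, p in enumerate(self.protein_ids)],
                "pscore": self.pscores,
                "ligand_fp": [fp_to_hex(f) for f in self.ligand_fps],
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, n_bits: int) -> "SiteTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            protein_ids=df["protein_id"].tolist(),
            pscores=df["pscore"].to_numpy(dtype=float),
            ligand_fps=np.stack([fp_from_hex(s, n_bits) for s in df["ligand_fp"]]),
        )


# ---------------------------------------------------------------------------
# generators


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def generate_quant_table(cfg: SyntheticConfig) -> tuple[QuantTable, dict]:
    """Log-normal intensity table with planted differential proteins.

    Planted proteins get a group-mean difference of exactly
    ``+-log2_effect`` on the log2 scale (first half up in case, second
    half down). Within-group noise is normal on the log2 scale with sd
    matched to ``cv_noise`` on the linear scale. A per-sample recovery
    factor (``recovery_cv``) multiplies every intensity including the
    albumin row, so albumin normalization removes it exactly.

    Returns the table and a truth dict: planted directions, albumin id,
    recovery factors.
    """
    rng = cfg.rng(1)
    pids = _protein_ids(cfg.n_proteins)
    n = 2 * cfg.n_per_group
    samples = [f"COPD{i:02d}" for i in range(cfg.n_per_group)] + [
        f"CTRL{i:02d}" for i in range(cfg.n_per_group)
    ]
    groups = pd.Series(
        ["case"] * cfg.n_per_group + ["control"] * cfg.n_per_group, index=samples
    )

    base_log2 = rng.uniform(16.0, 26.0, size=cfg.n_proteins)
    de_idx = rng.choice(cfg.n_proteins, size=cfg.n_de_true, replace=False)
    n_up = cfg.n_de_true // 2 + cfg.n_de_true % 2
    directions = {}
    shift = np.zeros(cfg.n_proteins)
    for j, i in enumerate(de_idx):
        if j < n_up:
            shift[i] = cfg.log2_effect
            directions[pids[i]] = UP
        else:
            shift[i] = -cfg.log2_effect
            directions[pids[i]] = DOWN

    # linear CV -> log-scale sd: cv^2 = exp(sigma^2) - 1
    sd_log2 = np.sqrt(np.log1p(cfg.cv_noise**2)) / np.log(2)
    means = base_log2[:, None] + np.where(
        groups.to_numpy() == "case", shift[:, None], 0.0
    )
    log2_intens = means + rng.normal(0.0, sd_log2, size=(cfg.n_proteins, n))

    recovery = np.ones(n)
    if cfg.recovery_cv > 0:
        sd_rec = np.sqrt(np.log1p(cfg.recovery_cv**2))
        recovery = np.exp(rng.normal(0.0, sd_rec, size=n))

    intens = 2.0**log2_intens * recovery[None, :]

    # albumin reference row: constant true concentration, scaled by recovery
    alb = pd.DataFrame(
        (2.0**24 * recovery)[None, :], index=[cfg.albumin_id], columns=samples
    )
    table = pd.concat([pd.DataFrame(intens, index=pids, columns=samples), alb])

    if cfg.missing_fraction > 0:
        mask = rng.random(size=(cfg.n_proteins, n)) < cfg.missing_fraction
        vals = table.to_numpy()
        vals[:-1][mask] = 0.0
        table = pd.DataFrame(vals, index=table.index, columns=table.columns)

    truth = {
        "de_directions": directions,
        "albumin_id": cfg.albumin_id,
        "recovery": dict(zip(samples, recovery.tolist())),
    }
    return QuantTable(table, groups, albumin_id=cfg.albumin_id), truth


def _random_fingerprints(
    rng: np.random.Generator, n: int, bits: int, density: float
) -> np.ndarray:
    fps = (rng.random(size=(n, bits)) < density).astype(np.uint8)
    empty = fps.sum(axis=1) == 0
    for i in np.flatnonzero(empty):  # every fingerprint carries >=1 substructure
        fps[i, rng.integers(bits)] = 1
    return fps


def generate_compound_library(cfg: SyntheticConfig) -> tuple[CompoundLibrary, dict]:
    """Compound library with known-drug flags and a planted clone.

    The clone is a non-known compound whose fingerprint is copied bit
    for bit from the first known drug; signature-similarity ranking
    must place it at position 1 in that drug's neighbour list.
    """
    rng = cfg.rng(2)
    ids = [f"C{i:04d}" for i in range(cfg.n_compounds)]
    fps = _random_fingerprints(
        rng, cfg.n_compounds, cfg.fingerprint_bits, cfg.bit_density
    )
    known_idx = rng.choice(cfg.n_compounds, size=cfg.n_known_drugs, replace=False)
    is_known = np.zeros(cfg.n_compounds, dtype=bool)
    is_known[known_idx] = True

    template_idx = int(known_idx[0])
    candidates = np.flatnonzero(~is_known)
    clone_idx = int(rng.choice(candidates))
    fps[clone_idx] = fps[template_idx]

    truth = {"clone": ids[clone_idx], "clone_template": ids[template_idx]}
    return CompoundLibrary(ids=ids, is_known=is_known, fingerprints=fps), truth


def library_proteins(cfg: SyntheticConfig, de_truth: dict) -> list[str]:
    """Protein universe covered by the binding-site library.

    Contains ``n_de_in_library`` of the planted DE proteins plus
    non-DE quant proteins up to ``n_library_proteins`` (models the
    partial overlap between the measured proteome and the structure
    library: some DE proteins have no structural coverage).
    """
    rng = cfg.rng(3)
    de = sorted(de_truth["de_directions"])
    non_de = sorted(set(_protein_ids(cfg.n_proteins)) - set(de))
    chosen_de = sorted(rng.choice(de, size=cfg.n_de_in_library, replace=False))
    n_extra = cfg.n_library_proteins - cfg.n_de_in_library
    chosen_extra = sorted(rng.choice(non_de, size=n_extra, replace=False))
    return sorted(chosen_de + chosen_extra)


def generate_binding_sites(
    cfg: SyntheticConfig, proteins: list[str] | None = None, de_truth: dict | None = None
) -> SiteTable:
    """Binding sites for each library protein: PScore in (0,1] + ligand fingerprint."""
    if proteins is None:
        if de_truth is None:
            raise ValueError("pass either an explicit protein list or de_truth")
        proteins = library_proteins(cfg, de_truth)
    rng = cfg.rng(4)
    lo, hi = cfg.n_sites_per_protein
    pids: list[str] = []
    for p in proteins:
        pids.extend([p] * int(rng.integers(lo, hi + 1)))
    pscores = 1.0 - rng.random(len(pids))  # uniform on (0, 1]
    fps = _random_fingerprints(rng, len(pids), cfg.fingerprint_bits, cfg.bit_density)
    return SiteTable(protein_ids=pids, pscores=pscores, ligand_fps=fps)


def generate_knowledge_graph(
    cfg: SyntheticConfig,
    de_truth: dict,
    library: CompoundLibrary,
    clone_id: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Signed regulatory edges over the planted DE proteins + drug effects.

    Topology: the non-isolated DE proteins are split into
    ``n_hub_planted + 1`` clique communities chained by the planted hub
    nodes; hub *i* is adjacent to every member of communities *i* and
    *i+1* and communities share no other vertex, so every
    cross-community shortest path passes through a hub and the hubs
    dominate betweenness by construction. A configured fraction of
    nodes stays isolated (mirrors DE proteins with no documented
    regulatory partner).

    Drug effects: the *ideal* drug (the clone compound unless
    ``clone_id`` overridden) carries exactly the idealized intervention
    signs on the hubs — promote hubs that are down in the case group,
    inhibit hubs that are up; the *anti-ideal* drug carries the
    opposite signs; further background drugs get random signed effects.

    Returns (edges, effects, truth): edge table (source, target, sign,
    refs), effect table (drug, protein, effect), and planted truth
    (hubs, communities, isolated nodes, ideal/anti-ideal drug, the
    idealized vector itself).
    """
    rng = cfg.rng(5)
    nodes = sorted(de_truth["de_directions"])
    n = len(nodes)
    if n < cfg.n_hub_planted * 3 + 3:
        raise ValueError("too few DE proteins for the requested hub count")

    perm = rng.permutation(n)
    n_iso = int(round(cfg.isolated_fraction * n))
    iso = sorted(nodes[i] for i in perm[:n_iso])
    connected = [nodes[i] for i in perm[n_iso:]]
    hubs = sorted(connected[: cfg.n_hub_planted])
    members = connected[cfg.n_hub_planted :]
    n_comm = cfg.n_hub_planted + 1
    communities = [sorted(members[k::n_comm]) for k in range(n_comm)]

    rows = []
    def add_edge(u: str, v: str) -> None:
        sign = -1 if rng.random() < cfg.edge_sign_neg_fraction else 1
        rows.append((u, v, sign, int(rng.integers(1, 5))))

    for comm in communities:
        for i in range(len(comm)):
            for j in range(i + 1, len(comm)):
                add_edge(comm[i], comm[j])
    for k, hub in enumerate(hubs):
        for member in communities[k] + communities[k + 1]:
            add_edge(hub, member)
    edges = pd.DataFrame(rows, columns=["source", "target", "sign", "refs"])

    directions = de_truth["de_directions"]
    ideal_vec = {h: (1 if directions[h] == DOWN else -1) for h in hubs}

    ideal_id = clone_id or f"C{cfg.n_compounds - 1:04d}"
    non_known = [c for c, k in zip(library.ids, library.is_known) if not k]
    pool = [c for c in non_known if c != ideal_id]
    anti_id = str(rng.choice(pool))
    pool.remove(anti_id)

    fx_rows = [
        (ideal_id, h, PROMOTE if s > 0 else INHIBIT) for h, s in ideal_vec.items()
    ] + [(anti_id, h, INHIBIT if s > 0 else PROMOTE) for h, s in ideal_vec.items()]

    n_bg = min(cfg.n_effect_drugs - 2, len(pool))
    bg_drugs = sorted(rng.choice(pool, size=n_bg, replace=False))
    entities = hubs + [m for comm in communities for m in comm]
    for d in bg_drugs:
        k = int(rng.integers(1, 5))
        targets = rng.choice(entities, size=min(k, len(entities)), replace=False)
        for t in targets:
            fx_rows.append((d, str(t), PROMOTE if rng.random() < 0.5 else INHIBIT))
    effects = pd.DataFrame(fx_rows, columns=["drug", "protein", "effect"])

    truth = {
        "hubs": hubs,
        "communities": communities,
        "isolated": iso,
        "ideal_drug": ideal_id,
        "anti_ideal_drug": anti_id,
        "background_drugs": list(bg_drugs),
        "idealized_vector": ideal_vec,
    }
    return edges, effects, truth


# ---------------------------------------------------------------------------
# one-call generation + file output


@dataclass
class SyntheticStudy:
    """All five pipeline inputs plus the planted truth."""

    quant: QuantTable
    library: CompoundLibrary
    sites: SiteTable
    edges: pd.DataFrame
    effects: pd.DataFrame
    truth: dict
    config: SyntheticConfig = field(repr=False, default=None)


def generate_study(cfg: SyntheticConfig) -> SyntheticStudy:
    quant, qtruth = generate_quant_table(cfg)
    library, ctruth = generate_compound_library(cfg)
    sites = generate_binding_sites(cfg, de_truth=qtruth)
    edges, effects, gtruth = generate_knowledge_graph(
        cfg, qtruth, library, clone_id=ctruth["clone"]
    )
    truth = {**qtruth, **ctruth, **gtruth}
    return SyntheticStudy(quant, library, sites, edges, effects, truth, cfg)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the five input files + truth.json sidecar; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "quant": out / "quant.tsv",
        "samples": out / "samples.tsv",
        "compounds": out / "compounds.json",
        "sites": out / "sites.tsv",
        "edges": out / "edges.tsv",
        "effects": out / "effects.tsv",
        "truth": out / "truth.json",
    }
    study.quant.to_tsv(paths["quant"], paths["samples"])
    study.library.to_json(paths["compounds"])
    study.sites.to_tsv(paths["sites"])
    study.edges.to_csv(paths["edges"], sep="\t", index=False)
    study.effects.to_csv(paths["effects"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(study.truth, indent=1, sort_keys=True))
    return paths
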