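"""End-to-end orchestration: quant table -> ranked drugs -> enriched combinations.

Stage order mirrors the analysis chain: (1) albumin normalization +
differential test, (2) interaction matrix + DE-restricted signatures,
(3) consensus top-k candidate ranking, (4) regulatory graph,
betweenness hubs and idealized vector, (5) combination enrichment and
effect classification. Every stage artifact is written as plain
TSV/JSON into the run directory together with a manifest recording
parameters, seeds and a SHA-256 checksum per file — two runs with the
same config produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr as de
from . import enrichment as en
from . import network as net
from . import ranking as rk
from . import signatures as sg
from .synthetic import SyntheticConfig, SyntheticStudy, generate_study, write_study


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    alpha: float = 0.05
    fc_threshold: float = 1.5
    normalize_albumin: bool = True
    top_k: int = 30
    min_consensus_count: int = 1
    hub_threshold: float = 0.25
    hub_rule: str = "fraction_of_max"
    max_combo_size: int = 2
    enrichment_alpha: float = 0.05
    n_null_samples: int = 10_000
    seed: int = 0
    synthetic: SyntheticConfig | None = None

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1")
        if self.top_k < 1 or self.max_combo_size < 1:
            raise ValueError("top_k and max_combo_size must be >= 1")
        if not 0 <= self.hub_threshold <= 1:
            raise ValueError("hub_threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k != "synthetic"
        }
        d["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        return d


@dataclass
class PipelineResult:
    """In-memory handles to every stage output of one run."""

    config: RunConfig
    study: SyntheticStudy
    diff: de.DifferentialTable
    matrix: sg.InteractionMatrix
    signatures: sg.SignatureSet
    ranking: rk.ConsensusRanking
    graph: net.RegulatoryGraph
    centrality: net.CentralityTable
    ideal: net.IdealizedVector
    report: en.EnrichmentReport
    classification: pd.DataFrame
    candidates: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    cfg: RunConfig,
    out_dir: str | Path | None = None,
    study: SyntheticStudy | None = None,
) -> PipelineResult:
    """Run every stage on a synthetic (or supplied) study.

    When ``out_dir`` is given, all inputs and stage outputs are written
    there along with ``manifest.json``.
    """
    cfg.validate()
    if study is None:
        syn = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
        study = generate_study(syn)

    # stage 1: normalization + differential test
    qt = study.quant
    if cfg.normalize_albumin and qt.albumin_id is not None:
        qt = de.normalize_to_albumin(qt)
    diff = de.differential_test(qt, alpha=cfg.alpha, fc_threshold=cfg.fc_threshold)
    de_proteins = sorted(diff.directions())

    # stage 2: interaction matrix + signatures on the DE subset
    matrix = sg.build_matrix(study.library, study.sites)
    signatures = sg.restrict_to_subset(matrix, de_proteins)

    # stage 3: consensus ranking
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipped lists expected at toy scale
        ranking = rk.consensus_rank(
            signatures, study.library.known_ids, top_k=cfg.top_k
        )
    ranked_candidates = list(
        ranking.candidates(min_count=cfg.min_consensus_count).index
    )

    # stage 4: regulatory network, hubs, idealized vector
    graph = net.build_graph(study.edges, diff)
    centrality = net.betweenness(graph)
    centrality = net.select_hubs(
        centrality,
        threshold=cfg.hub_threshold,
        rule=cfg.hub_rule,
        de_directions=graph.de_directions,
    )
    ideal = net.idealized_vector(centrality.hubs, graph.de_directions, graph.nodes)

    # stage 5: enrichment over candidates with documented effects
    effect_drugs = sorted(set(study.effects["drug"]))
    vectors = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # effects outside the graph are expected
        for drug in effect_drugs:
            vec = en.drug_vector(drug, study.effects, ideal.entities)
            if np.abs(vec).sum() > 0:
                vectors[drug] = vec
    candidates = {
        d: v for d, v in vectors.items() if d in set(ranked_candidates)
    }
    if not candidates:
        raise RuntimeError(
            "enrichment stage: no consensus candidate has documented effects"
        )
    background = dict(vectors)  # candidates + graph-eligible drugs
    report = en.enrich_combinations(
        candidates,
        ideal,
        background=background,
        max_size=cfg.max_combo_size,
        alpha=cfg.enrichment_alpha,
        n_null_samples=cfg.n_null_samples,
        seed=cfg.seed,
    )
    classification = en.classify_drug_effects(sorted(candidates), ideal, study.effects)

    result = PipelineResult(
        config=cfg,
        study=study,
        diff=diff,
        matrix=matrix,
        signatures=signatures,
        ranking=ranking,
        graph=graph,
        centrality=centrality,
        ideal=ideal,
        report=report,
        classification=classification,
        candidates=sorted(candidates),
    )
    if out_dir is not None:
        result.manifest = _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    write_study(result.study, out / "inputs")
    files = {
        "differential.tsv": lambda p: result.diff.to_tsv(p),
        "interaction_matrix.tsv": lambda p: result.matrix.to_tsv(p),
        "ranking.tsv": lambda p: result.ranking.to_tsv(p),
        "centrality.tsv": lambda p: result.centrality.to_tsv(p),
        "idealized_vector.json": lambda p: result.ideal.to_json(p),
        "enrichment.tsv": lambda p: result.report.to_tsv(p),
        "frequencies.tsv": lambda p: result.report.frequencies.rename_axis(
            "drug"
        ).to_csv(p, sep="\t"),
        "classification.tsv": lambda p: result.classification.to_csv(
            p, sep="\t", index=False
        ),
    }
    for name, writer in files.items():
        writer(out / name)

    checksums = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config": result.config.to_dict(),
        "summary": {
            "de": result.diff.summary(),
            "de_in_library": len(result.signatures.subset),
            "de_not_in_library": result.signatures.n_missing,
            "n_candidates_ranked": len(result.ranking.table),
            "connectivity": result.graph.connectivity_report(),
            "hubs": result.centrality.hubs,
            "n_significant_combos": int(result.report.table["significant"].sum()),
        },
        "checksums": checksums,
        "versions": _versions(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _versions() -> dict:
    import networkx
    import scipy

    import balfrepo

    return {
        "balfrepo": balfrepo.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
    }
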