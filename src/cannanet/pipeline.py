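"""End-to-end pipeline: ingest → tag → count → test → build → report.

`run_pipeline` chains the stages over files and writes all exports plus a
run manifest (config, input checksums, package versions) so a run can be
reproduced byte-for-byte; `run_pipeline_in_memory` is the same chain over
loaded objects, for embedding and testing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from . import __version__
from .association import decide_edges, write_association_report
from .cooccurrence import CooccurrenceCounts, accumulate
from .corpus import Document, is_english, paragraph_stream, read_corpus
from .graph import (
    add_strain_edges,
    build_graph,
    graph_summary,
    validate_graph,
    write_edgelist,
    write_graphml,
    write_json_graph,
)
from .lexicon import Lexicon, load_lexicon, match_entities

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_in_memory"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, with documented defaults."""

    stopword_ratio_min: float = 0.15   # language filter threshold
    include_abstract: bool = False     # abstracts as co-occurrence paragraphs
    embedding_dim: int = 100
    embedding_window: int = 5
    embedding_min_count: int = 5
    embedding_epochs: int = 5
    expansion_threshold: float = 0.7   # cosine radius for lexicon expansion
    expansion_top_k: int = 10
    alpha: float = 0.05                # LLR significance level
    tau: float = 0.8                   # direction-class ratio threshold
    min_pair_count: int = 1            # min co-occurring paragraphs per edge
    bonferroni: bool = False
    mode: str = "permissive"           # or "significant_only"
    include_isolated_entities: bool = False
    protect_anchors: bool = True
    hops: int = 1
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key = value config file; unknown keys are rejected."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            current = getattr(cls, key)
            if isinstance(current, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif isinstance(current, int):
                kwargs[key] = int(value)
            elif isinstance(current, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    start = time.perf_counter()

    def done(detail: str = "") -> None:
        log.info("stage %-10s %6.2fs %s", name, time.perf_counter() - start, detail)

    return done


def run_pipeline_in_memory(
    docs: Sequence[Document],
    lexicon: Lexicon,
    config: PipelineConfig = PipelineConfig(),
    strain_table: Sequence[tuple[str, str]] | None = None,
) -> tuple[nx.Graph, list, dict]:
    """Run the full chain on loaded objects.

    Returns (graph, association results, summary dict).
    """
    done = _stage("filter")
    kept = [d for d in docs if is_english(d, config.stopword_ratio_min)]
    done(f"{len(kept)}/{len(docs)} documents kept")

    done = _stage("count")
    counts = CooccurrenceCounts()
    n_paras = 0
    for para in paragraph_stream(kept, include_abstract=config.include_abstract):
        accumulate(counts, match_entities(para, lexicon))
        n_paras += 1
    done(f"{n_paras} paragraphs, {len(counts.occ)} entities, {len(counts.pair_occ)} pairs")

    done = _stage("test")
    results = decide_edges(
        counts,
        alpha=config.alpha,
        tau=config.tau,
        min_pair_count=config.min_pair_count,
        bonferroni=config.bonferroni,
    )
    done(f"{len(results)} pairs scored, {sum(r.significant for r in results)} significant")

    done = _stage("build")
    citations = {d.doc_id: d.citation for d in kept}
    graph = build_graph(
        counts,
        results,
        mode=config.mode,
        include_isolated_entities=config.include_isolated_entities,
        citations=citations,
    )
    if strain_table:
        add_strain_edges(graph, strain_table)
    validate_graph(graph)
    summary = graph_summary(graph)
    done(f"{summary['node_count']} nodes, {summary['edge_count']} edges")
    return graph, results, summary


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    corpus_path: str | Path,
    lexicon_paths: Sequence[str | Path],
    out_dir: str | Path,
    strain_table_path: str | Path | None = None,
    corpus_format: str = "jsonl",
) -> dict:
    """File-level pipeline entry point; writes all exports and a manifest."""
    corpus_path = Path(corpus_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in [corpus_path, *map(Path, lexicon_paths)]:
        if not p.exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
    if strain_table_path is not None and not Path(strain_table_path).exists():
        raise FileNotFoundError(f"pipeline input missing: {strain_table_path}")

    docs = read_corpus(corpus_path, format=corpus_format)
    lexicon = Lexicon()
    for p in lexicon_paths:
        lexicon = lexicon.merge(load_lexicon(p))
    strain_rows = None
    graph, results, summary = run_pipeline_in_memory(docs, lexicon, config)
    if strain_table_path is not None:
        add_strain_edges(graph, strain_table_path)
        validate_graph(graph)
        summary = graph_summary(graph)

    write_graphml(graph, out / "graph.graphml")
    write_edgelist(graph, out / "edges.tsv")
    write_json_graph(graph, out / "graph.json")
    write_association_report(results, out / "associations.tsv")
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    inputs = {str(corpus_path): _sha256(corpus_path)}
    for p in lexicon_paths:
        inputs[str(p)] = _sha256(Path(p))
    if strain_table_path is not None:
        inputs[str(strain_table_path)] = _sha256(Path(strain_table_path))
    manifest = {
        "config": config.to_dict(),
        "inputs": inputs,
        "versions": {"cannanet": __version__, "networkx": nx.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return summary
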