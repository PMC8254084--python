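"""End-to-end pipeline: counts -> pan-DEGs -> GO -> clusters -> motifs.

Stages run in a fixed order, each writing its artifacts (TSV plus JSON)
into its own subdirectory of the output tree together with a snapshot of
the configuration, so a run is reproducible from the snapshot alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import de, motif as mo, ontology as onto, pandeg
from .matrix import CountMatrix

log = logging.getLogger("gocentric")


@dataclass
class RunConfig:
    """All tunables of a pipeline run; serialised beside every output."""

    # DE thresholds
    fdr: float = 0.01
    lfc: float = 1.0
    min_total: int = 10
    prior_count: float = 0.5
    dispersion_prior_weight: float = 10.0
    # k-means baseline
    k_min: int = 5
    k_max: int = 10
    kmeans_restarts: int = 25
    seed: int = 0
    # GO
    go_algorithm: str = "classic"  # or "elim"
    elim_cutoff: float = 0.01
    min_node_size: int = 10
    n_top_terms: int = 6
    # GO-centric / motif
    subcluster_k: int = 2
    upstream: int = 500
    downstream: int = 100
    motif_threshold: float = 0.8
    # inputs
    counts: str = ""
    meta: str = ""
    obo: str = ""
    annotations: str = ""
    fasta: str = ""
    bed: str = ""
    jaspar: str = ""

    def validate(self) -> None:
        if not (0 < self.fdr <= 1) or self.lfc <= 0 or self.min_total < 0:
            raise ValueError("invalid DE thresholds")
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("invalid k-means range")
        if self.go_algorithm not in {"classic", "elim"}:
            raise ValueError("go_algorithm must be 'classic' or 'elim'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def snapshot(self, outdir: Path) -> None:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(json.dumps(dataclasses.asdict(self), indent=1))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s started", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise StageError(name, exc) from exc
            log.info("stage %s finished in %.1fs", name, time.time() - t0)
            return result

        return inner

    return wrap


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline produced."""

    filtered: CountMatrix
    factors: np.ndarray
    de_results: dict[tuple[str, str], de.DEResult]
    calls: list[de.DEGCall]
    pan: pandeg.PanDEGSet
    enrichment: pd.DataFrame
    top: pd.DataFrame
    chosen_k: int
    silhouette_table: pd.DataFrame
    assignment: cl.ClusterAssignment
    cluster_enrichments: dict[int, pd.DataFrame]
    go_centric: dict[str, cl.GOCentricResult]
    motif_tables: dict[str, dict[int, pd.DataFrame]]
    sample_tree: cl.SampleDendrogram
    universe: set[str]


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.snapshot(out)

    cm = _load_counts(config)
    filtered, factors = _filter_and_norm(cm, config, out)
    sample_tree = _sample_stage(filtered, factors, out)
    de_results, calls = _de_stage(filtered, factors, config, out)
    pan = _pan_stage(calls, config, out)
    dag, ann, universe, enrichment, top = _go_stage(filtered, pan, config, out)
    chosen_k, sil_table, assignment, cluster_enr = _cluster_stage(
        filtered, factors, pan, ann, dag, config, out
    )
    go_centric, motif_tables = _gocentric_stage(
        filtered, factors, pan, ann, top, universe, config, out
    )
    return PipelineResult(
        filtered,
        factors,
        de_results,
        calls,
        pan,
        enrichment,
        top,
        chosen_k,
        sil_table,
        assignment,
        cluster_enr,
        go_centric,
        motif_tables,
        sample_tree,
        universe,
    )


@_stage("load")
def _load_counts(config: RunConfig) -> CountMatrix:
    if not config.counts or not config.meta:
        raise FileNotFoundError("counts/meta paths not configured")
    return CountMatrix.read_tsv(config.counts, config.meta)


@_stage("filter")
def _filter_and_norm(cm: CountMatrix, config: RunConfig, out: Path | None):
    filtered = de.filter_low_counts(cm, config.min_total)
    factors = de.tmm_norm_factors(filtered)
    if out is not None:
        d = out / "01_filter"
        d.mkdir(exist_ok=True)
        pd.DataFrame(
            {"sample": filtered.samples, "lib_size": filtered.lib_sizes, "tmm_factor": factors}
        ).to_csv(d / "norm_factors.tsv", sep="\t", index=False)
        _json(d / "summary.json", {"genes_kept": filtered.n_genes, "genes_in": cm.n_genes})
    return filtered, factors


@_stage("samples")
def _sample_stage(cm: CountMatrix, factors, out: Path | None) -> cl.SampleDendrogram:
    tree = cl.sample_dendrogram(cm, factors)
    if out is not None:
        d = out / "02_samples"
        d.mkdir(exist_ok=True)
        (d / "samples.nwk").write_text(tree.to_newick() + "\n")
        _json(d / "monophyly.json", tree.monophyly)
    return tree


@_stage("de")
def _de_stage(cm: CountMatrix, factors, config: RunConfig, out: Path | None):
    disp = de.estimate_dispersion(
        cm, factors=factors, prior_weight=config.dispersion_prior_weight
    )
    results: dict[tuple[str, str], de.DEResult] = {}
    calls: list[de.DEGCall] = []
    d = None
    if out is not None:
        d = out / "03_de"
        d.mkdir(exist_ok=True)
        _json(d / "dispersion.json", {"common": disp.common})
    for a, b in pandeg.enumerate_pairs(cm.timepoint_order):
        res = de.nb_exact_test(
            cm, a, b, disp, factors=factors, prior_count=config.prior_count
        )
        call = de.call_degs(res, config.fdr, config.lfc)
        results[(a, b)] = res
        calls.append(call)
        if d is not None:
            de.write_de_tsv(res, call, d / f"de_{a}_vs_{b}.tsv")
    return results, calls


@_stage("pandeg")
def _pan_stage(calls, config: RunConfig, out: Path | None) -> pandeg.PanDEGSet:
    pan = pandeg.build_pan_deg(calls)
    if out is not None:
        d = out / "04_pandeg"
        d.mkdir(exist_ok=True)
        pandeg.write_pan_deg_tsv(pan, d / "pan_degs.tsv")
        summary = pandeg.pan_deg_summary(pan)
        summary.to_csv(d / "summary.tsv", sep="\t", index=False)
        _json(d / "summary.json", {
            "union_size": len(pan),
            "per_comparison": summary.to_dict(orient="records"),
        })
    return pan


@_stage("enrich")
def _go_stage(cm: CountMatrix, pan: pandeg.PanDEGSet, config: RunConfig, out: Path | None):
    if not config.obo or not config.annotations:
        raise FileNotFoundError("OBO/annotation paths not configured")
    dag = onto.parse_obo(config.obo)
    direct = onto.read_annotations(config.annotations)
    ann = onto.propagate(dag, direct)
    universe = onto.feasible_universe(cm.gene_ids, ann)
    study = set(pan.genes) & universe
    if not study:
        raise ValueError("no annotated pan-DEG: cannot run enrichment")
    if config.go_algorithm == "elim":
        enr = onto.elim_fisher(
            study, universe, ann, dag, config.elim_cutoff, config.min_node_size
        )
    else:
        enr = onto.classic_fisher(study, universe, ann, dag, config.min_node_size)
    top = onto.top_terms(enr, config.n_top_terms, config.go_algorithm)
    if out is not None:
        d = out / "05_enrich"
        d.mkdir(exist_ok=True)
        enr.to_csv(d / "enrichment.tsv", sep="\t", index=False)
        top.to_csv(d / "top_terms.tsv", sep="\t", index=False)
    return dag, ann, universe, enr, top


@_stage("cluster")
def _cluster_stage(cm, factors, pan, ann, dag, config: RunConfig, out: Path | None):
    ep = cl.build_profiles(cm, pan.genes, factors)
    ks = range(config.k_min, config.k_max + 1)
    chosen, table, fits = cl.select_k(ep, ks, seed=config.seed, restarts=config.kmeans_restarts)
    assignment = fits[chosen]
    cluster_universe = set(pan.genes) & onto.feasible_universe(pan.genes, ann)
    enrichments = cl.cluster_enrichment(
        assignment, cluster_universe, ann, dag, config.min_node_size
    )
    if out is not None:
        d = out / "06_cluster"
        d.mkdir(exist_ok=True)
        table.to_csv(d / "silhouette_by_k.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"cluster": assignment.labels, "silhouette": assignment.silhouette}
        ).to_csv(d / "clusters.tsv", sep="\t")
        for label, enr in enrichments.items():
            enr.to_csv(d / f"enrichment_cluster{label}.tsv", sep="\t", index=False)
        _json(d / "summary.json", {
            "chosen_k": chosen,
            "cluster_sizes": assignment.labels.value_counts().sort_index().to_dict(),
        })
    return chosen, table, assignment, enrichments


@_stage("gocentric")
def _gocentric_stage(cm, factors, pan, ann, top, universe, config: RunConfig, out: Path | None):
    promoters = None
    pwms = None
    if config.fasta and config.bed and config.jaspar:
        pwms = mo.read_jaspar(config.jaspar, config.motif_threshold)
        promoters = mo.extract_promoters(
            sorted(universe), config.bed, config.fasta, config.upstream, config.downstream
        )
    go_centric: dict[str, cl.GOCentricResult] = {}
    motif_tables: dict[str, dict[int, pd.DataFrame]] = {}
    for term in top["term"]:
        genes = sorted(ann.term_genes[term] & set(pan.genes))
        if len(genes) < 2:
            continue
        ep = cl.build_profiles(cm, genes, factors)
        gr = cl.cut_subclusters(cl.hier_cluster(ep, term), config.subcluster_k)
        gr.subcluster_means = cl.subcluster_means(gr, ep)
        go_centric[term] = gr
        if promoters is not None and pwms is not None:
            motif_tables[term] = {}
            for label in gr.top_two:
                sub = [g for g in genes if gr.subclusters[g] == label]
                targets = promoters.subset([g for g in sub if g in promoters.sequences])
                bg_genes = [g for g in promoters.sequences if g not in set(sub)]
                background = promoters.subset(bg_genes)
                motif_tables[term][label] = mo.motif_enrichment(targets, background, pwms)
        if out is not None:
            d = out / "07_gocentric" / term.replace(":", "_")
            d.mkdir(parents=True, exist_ok=True)
            (d / "dendrogram.nwk").write_text(gr.to_newick() + "\n")
            gr.subclusters.to_frame().to_csv(d / "subclusters.tsv", sep="\t")
            gr.subcluster_means.to_csv(d / "subcluster_means.tsv", sep="\t")
            for label, table in motif_tables.get(term, {}).items():
                table.to_csv(d / f"motifs_subcluster{label}.tsv", sep="\t", index=False)
    return go_centric, motif_tables


def _json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=1, default=str))


def report(outdir: str | Path) -> dict:
    """Summarise a finished (possibly partial) run from its artifacts."""
    out = Path(outdir)
    rep: dict = {"outdir": str(out), "warnings": []}
    pan_json = out / "04_pandeg" / "summary.json"
    if pan_json.exists():
        rep["pan_deg"] = json.loads(pan_json.read_text())
        if rep["pan_deg"]["union_size"] == 0:
            rep["warnings"].append("pan-DEG set empty; downstream sections skipped")
            return rep
    else:
        rep["warnings"].append("pan-DEG stage outputs missing")
    top_tsv = out / "05_enrich" / "top_terms.tsv"
    if top_tsv.exists():
        rep["top_terms"] = pd.read_csv(top_tsv, sep="\t").to_dict(orient="records")
    cluster_json = out / "06_cluster" / "summary.json"
    if cluster_json.exists():
        rep["clusters"] = json.loads(cluster_json.read_text())
    moto = sorted(out.glob("07_gocentric/*/motifs_subcluster*.tsv"))
    if moto:
        rep["motif_tables"] = [str(p.relative_to(out)) for p in moto]
    mono = out / "02_samples" / "monophyly.json"
    if mono.exists():
        rep["sample_monophyly"] = json.loads(mono.read_text())
    return rep
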