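"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates a 4-time-point x 3-replicate bulk RNA-seq time
course: NB-distributed counts with planted expression patterns, a toy GO
DAG with planted functional modules (including a deliberately "diluted"
module split 50/50 between opposite patterns), and a toy genome whose
promoters carry planted TFBS motifs.  Every output is a pure function of
(parameters, seed), and the truth object records exactly what was planted
so recovery can be scored without external data.

Expression patterns (per-time-point log2 offsets from baseline, default
amplitude 2):

* ``flat``           — no change (non-DEG background);
* ``step_up/down``   — shift from the second time point onward;
* ``transient_up/down`` — shift at the second time point only;
* ``gradual_up/down``   — linear drift of 0.7 log2 units per step, below
  a |log2FC| > 1 cutoff between neighbours but above it across two steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CountMatrix
from .motif import PWM, write_jaspar

STEP_AMPLITUDE = 2.0
GRADUAL_STEP = 0.7

DEFAULT_TIMEPOINTS = ("0h", "24h", "48h", "72h")
#: Share of DEGs per planted pattern: two dominant opposite sustained
#: responses plus minor transient and gradual classes.
DEFAULT_PATTERN_MIX = {
    "induced": 0.44,
    "repressed": 0.44,
    "transient_up": 0.03,
    "transient_down": 0.03,
    "gradual_up": 0.03,
    "gradual_down": 0.03,
}


def pattern_offsets(pattern: str, n_timepoints: int, amplitude: float = STEP_AMPLITUDE) -> tuple[float, ...]:
    """Per-time-point log2 offsets for a named pattern.

    ``induced``/``repressed`` jump by ``amplitude`` at the second time
    point and keep drifting by 0.7 per step, so every later time point
    stays distinguishable from its neighbours (sub-cutoff drift, but
    enough correlation signal for sample-level clustering).
    """
    i = np.arange(n_timepoints, dtype=float)
    if pattern == "flat":
        off = np.zeros(n_timepoints)
    elif pattern in ("induced", "repressed"):
        off = np.where(i >= 1, amplitude + GRADUAL_STEP * np.maximum(i - 1, 0), 0.0)
        if pattern == "repressed":
            off = -off
    elif pattern == "step_up":
        off = np.where(i >= 1, amplitude, 0.0)
    elif pattern == "step_down":
        off = np.where(i >= 1, -amplitude, 0.0)
    elif pattern == "transient_up":
        off = np.where(i == 1, amplitude, 0.0)
    elif pattern == "transient_down":
        off = np.where(i == 1, -amplitude, 0.0)
    elif pattern == "gradual_up":
        off = GRADUAL_STEP * i
    elif pattern == "gradual_down":
        off = -GRADUAL_STEP * i
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return tuple(float(x) for x in off)


@dataclass
class PlantedModule:
    """One synthetic GO term and the expression patterns of its genes."""

    term_id: str
    name: str
    genes_by_pattern: dict[str, list[str]]

    @property
    def genes(self) -> list[str]:
        return [g for gs in self.genes_by_pattern.values() for g in gs]


@dataclass
class MotifPlant:
    """A PWM planted into a fraction of the designated promoters."""

    pwm: PWM
    genes: list[str]
    fraction: float = 0.8


@dataclass
class SyntheticTruth:
    """Everything that was planted, keyed the way tests need it."""

    seed: int
    timepoints: list[str]
    n_reps: int
    dispersion: float
    patterns: dict[str, str] = field(default_factory=dict)  # gene -> pattern
    offsets: dict[str, list[float]] = field(default_factory=dict)
    baselines: dict[str, float] = field(default_factory=dict)
    lib_factors: list[float] = field(default_factory=list)
    modules: list[PlantedModule] = field(default_factory=list)
    planted_sites: dict[str, list[dict]] = field(default_factory=dict)  # motif -> plants

    def genes_with_pattern(self, *patterns: str) -> list[str]:
        return [g for g, p in self.patterns.items() if p in patterns]

    @property
    def deg_genes(self) -> list[str]:
        return [g for g, p in self.patterns.items() if p != "flat"]

    def module(self, term_id: str) -> PlantedModule:
        for m in self.modules:
            if m.term_id == term_id:
                return m
        raise KeyError(term_id)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, PWM):
        return {"name": obj.name, "consensus": obj.consensus}
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(type(obj))


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    digest = sum(ord(c) * 31**i for i, c in enumerate(label)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence((int(seed) % (2**31), digest)))


def simulate_counts(
    n_genes: int = 2000,
    timepoints: tuple[str, ...] = DEFAULT_TIMEPOINTS,
    n_reps: int = 3,
    dispersion: float = 0.1,
    deg_fraction: float = 0.17,
    pattern_mix: dict[str, float] | None = None,
    lib_size_range: tuple[float, float] = (0.7, 1.3),
    baseline_range: tuple[float, float] = (20.0, 2000.0),
    low_count_fraction: float = 0.05,
    amplitude: float = STEP_AMPLITUDE,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """NB count time course with planted DEG patterns.

    Counts for gene g, time t, replicate r are NB with mean
    ``baseline_g * 2^offset_g(t) * libfactor_{t,r}`` and common dispersion
    ``phi`` (``phi = 0`` means Poisson).  Baselines are log-uniform over
    ``baseline_range``; a ``low_count_fraction`` tranche of non-DEG genes
    gets near-zero baselines so the low-count filter has work to do, and
    library-size factors vary over ``lib_size_range`` so normalisation does
    too.  DEG patterns are assigned to the first ``deg_fraction`` of genes
    according to ``pattern_mix`` (largest-remainder rounding).
    """
    if pattern_mix is None:
        pattern_mix = DEFAULT_PATTERN_MIX
    if deg_fraction > 0 and abs(sum(pattern_mix.values()) - 1.0) > 1e-9:
        raise ValueError("pattern_mix must sum to 1")
    if dispersion < 0 or n_reps < 1 or n_genes < 1:
        raise ValueError("parameters must be positive")
    rng = _substream(seed, "counts")
    T = len(timepoints)
    genes = [f"g{i:05d}" for i in range(n_genes)]

    n_deg = int(round(deg_fraction * n_genes))
    counts_per_pattern = _largest_remainder(pattern_mix, n_deg)
    patterns = []
    for name, k in counts_per_pattern.items():
        patterns.extend([name] * k)
    patterns.extend(["flat"] * (n_genes - n_deg))

    baselines = np.exp(
        rng.uniform(np.log(baseline_range[0]), np.log(baseline_range[1]), n_genes)
    )
    n_low = int(round(low_count_fraction * (n_genes - n_deg)))
    if n_low:
        # near-zero tranche drawn from the tail of the non-DEG block
        low_idx = np.arange(n_genes - n_low, n_genes)
        baselines[low_idx] = rng.uniform(0.05, 0.8, n_low)

    offsets = np.array([pattern_offsets(p, T, amplitude) for p in patterns])
    lib_factors = rng.uniform(*lib_size_range, size=T * n_reps)

    means = baselines[:, None] * 2.0 ** np.repeat(offsets, n_reps, axis=1) * lib_factors[None, :]
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + means))
    else:
        counts = rng.poisson(means)

    samples = [f"{t}_r{r + 1}" for t in timepoints for r in range(n_reps)]
    cm = CountMatrix(
        genes,
        counts.astype(np.int64),
        samples,
        [t for t in timepoints for _ in range(n_reps)],
        [r + 1 for _ in timepoints for r in range(n_reps)],
    )
    truth = SyntheticTruth(
        seed=seed,
        timepoints=list(timepoints),
        n_reps=n_reps,
        dispersion=dispersion,
        patterns=dict(zip(genes, patterns)),
        offsets={g: list(map(float, o)) for g, o in zip(genes, offsets)},
        baselines={g: float(b) for g, b in zip(genes, baselines)},
        lib_factors=[float(f) for f in lib_factors],
    )
    return cm, truth


def _largest_remainder(mix: dict[str, float], total: int) -> dict[str, int]:
    raw = {k: v * total for k, v in mix.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    leftover = total - sum(base.values())
    order = sorted(mix, key=lambda k: (-(raw[k] - base[k]), k))
    for k in order[:leftover]:
        base[k] += 1
    return base


def simulate_go(
    genes: list[str],
    planted_modules: list[tuple[str, dict[str, list[str]]]] | None = None,
    n_terms: int = 30,
    depth: int = 3,
    term_size_range: tuple[int, int] = (10, 40),
    seed: int = 0,
) -> tuple[str, pd.DataFrame, list[PlantedModule]]:
    """Toy GO DAG (OBO text) plus direct gene annotations.

    The DAG has one biological_process root, ``depth`` levels of background
    terms, one two-parent diamond, and one planted term per requested
    module annotating exactly the module's genes.  Background terms
    annotate random gene subsets and every gene receives at least one
    direct annotation, so the feasible universe spans the gene list.
    """
    if depth < 1 or n_terms < 1:
        raise ValueError("depth and n_terms must be >= 1")
    rng = _substream(seed, "go")
    genes = list(genes)
    pool = set(genes)
    for _, by_pattern in planted_modules or []:
        module_genes = [g for gs in by_pattern.values() for g in gs]
        missing = set(module_genes) - pool
        if missing:
            raise ValueError(f"planted module genes outside gene pool: {sorted(missing)[:5]}")

    root = "GO:0000001"
    terms: dict[str, dict] = {root: {"name": "biological_process", "parents": []}}
    levels: list[list[str]] = [[root]]
    tid = 1
    per_level = max(1, n_terms // depth)
    for level in range(1, depth + 1):
        ids = []
        n_here = per_level if level < depth else n_terms - per_level * (depth - 1)
        for _ in range(max(1, n_here)):
            tid += 1
            term = f"GO:{tid:07d}"
            parent = levels[level - 1][int(rng.integers(len(levels[level - 1])))]
            terms[term] = {"name": f"synthetic process {tid}", "parents": [("is_a", parent)]}
            ids.append(term)
        levels.append(ids)
    # one diamond: last leaf gains a second parent via part_of
    if len(levels) > 2 and len(levels[1]) > 1:
        leaf = levels[-1][-1]
        extra = levels[1][0]
        if ("is_a", extra) not in terms[leaf]["parents"]:
            terms[leaf]["parents"].append(("part_of", extra))

    annotations: list[tuple[str, str]] = []
    background_terms = [t for lvl in levels[1:] for t in lvl]
    for term in background_terms:
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            annotations.append((str(g), term))
    annotated = {g for g, _ in annotations}
    for g in genes:
        if g not in annotated:
            term = background_terms[int(rng.integers(len(background_terms)))]
            annotations.append((g, term))

    modules: list[PlantedModule] = []
    for i, (name, by_pattern) in enumerate(planted_modules or []):
        term = f"GO:{1000001 + i:07d}"
        parent = levels[1][int(rng.integers(len(levels[1])))]
        terms[term] = {"name": name, "parents": [("is_a", parent)]}
        module = PlantedModule(term, name, {p: list(gs) for p, gs in by_pattern.items()})
        modules.append(module)
        for g in module.genes:
            annotations.append((g, term))

    obo = _write_obo(terms)
    ann_df = pd.DataFrame(sorted(set(annotations)), columns=["gene", "term"])
    return obo, ann_df, modules


def _write_obo(terms: dict[str, dict]) -> str:
    lines = ["format-version: 1.2", "ontology: go", ""]
    for term_id in sorted(terms):
        meta = terms[term_id]
        lines += ["[Term]", f"id: {term_id}", f"name: {meta['name']}", "namespace: biological_process"]
        for rel, parent in meta.get("parents", []):
            if rel == "is_a":
                lines.append(f"is_a: {parent} ! {terms[parent]['name']}")
            else:
                lines.append(f"relationship: {rel} {parent} ! {terms[parent]['name']}")
        lines.append("")
    return "\n".join(lines)


#: Built-in planted motifs: sharply peaked 8-mers that are neither
#: palindromic nor reverse complements of each other.
def planted_pwms(peak: float = 0.9) -> list[PWM]:
    def pwm_from_consensus(name: str, consensus: str) -> PWM:
        off = (1.0 - peak) / 3.0
        mat = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus):
            mat[i, "ACGT".index(b)] = peak
        return PWM(name, mat)

    return [
        pwm_from_consensus("SYN_UP_MOTIF", "TGACGTCA"),
        pwm_from_consensus("SYN_DOWN_MOTIF", "CCGGAAGT"),
    ]


def simulate_genome(
    genes: list[str],
    plants: list[MotifPlant] | None = None,
    upstream: int = 500,
    downstream: int = 100,
    gene_body: int = 200,
    spacing: int = 150,
    seed: int = 0,
) -> tuple[str, pd.DataFrame, dict[str, list[dict]]]:
    """Toy genome FASTA text + BED6 models with motifs planted in promoters.

    Genes are laid head-to-tail on one contig with random strands; the
    background sequence is i.i.d. uniform ACGT.  For each plant, the PWM
    consensus (or its reverse complement, random strand) is written at a
    random offset inside the promoter window of the designated fraction of
    genes.  Returns FASTA text, the BED table and the planted-site truth
    ``{motif: [{gene, offset, strand}]}`` with offsets in promoter-local
    coordinates.
    """
    rng = _substream(seed, "genome")
    genes = list(genes)
    window = upstream + downstream
    # each gene's slot holds a full promoter window on either side of the
    # body so neighbouring windows can never overlap, whatever the strands
    slot = 2 * window + gene_body + spacing
    margin = window
    total = margin + slot * len(genes) + margin
    chrom = "chr1"
    seq = rng.integers(0, 4, size=total)

    rows = []
    coords: dict[str, tuple[int, str]] = {}
    for i, gene in enumerate(genes):
        strand = "+" if rng.random() < 0.5 else "-"
        region = margin + slot * i
        if strand == "+":
            tss = region + window
            start, end = tss, tss + gene_body
        else:
            start = region + window
            end = start + gene_body
            tss = end - 1
        rows.append((chrom, start, end, gene, 0, strand))
        coords[gene] = (tss, strand)

    truth: dict[str, list[dict]] = {}
    for plant in plants or []:
        consensus = plant.pwm.consensus
        enc = np.array(["ACGT".index(b) for b in consensus])
        chosen = [g for g in plant.genes if rng.random() < plant.fraction] if plant.fraction < 1 else list(plant.genes)
        sites = []
        for gene in chosen:
            tss, strand = coords[gene]
            local = int(rng.integers(0, window - len(consensus) + 1))
            site_strand = "+" if rng.random() < 0.5 else "-"
            site = enc if site_strand == "+" else 3 - enc[::-1]
            if strand == "+":
                gstart = tss - upstream + local
                seq[gstart : gstart + len(consensus)] = site
            else:
                # promoter-local coordinates run against the reference
                gend = tss + upstream - local
                seq[gend - len(consensus) : gend] = (3 - site[::-1])
            sites.append({"gene": gene, "offset": local, "strand": site_strand})
        truth.setdefault(plant.pwm.name, []).extend(sites)

    bases = np.array(list("ACGT"))
    fasta_seq = "".join(bases[seq])
    fasta = f">{chrom}\n" + "\n".join(
        fasta_seq[i : i + 80] for i in range(0, len(fasta_seq), 80)
    ) + "\n"
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    return fasta, bed, truth


@dataclass
class Scenario:
    """All synthetic inputs of the default end-to-end study."""

    counts: CountMatrix
    truth: SyntheticTruth
    obo_text: str
    annotations: pd.DataFrame
    fasta_text: str
    bed: pd.DataFrame
    pwms: list[PWM]
    dilution_term: str


def default_scenario(seed: int = 0, dilution_module_size: int = 40) -> Scenario:
    """The standard study: counts + GO DAG with a dilution module + genome.

    The dilution module draws half of its genes from the ``step_up`` and
    half from the ``step_down`` pattern, mirroring a functional category
    whose members move in opposite directions and therefore scatter across
    expression clusters.  Two motifs are planted: one in 80% of the
    module's up-gene promoters, one in 80% of its down-gene promoters,
    each at 5% elsewhere.
    """
    cm, truth = simulate_counts(seed=seed)
    rng = _substream(seed, "scenario")
    half = dilution_module_size // 2
    up = [str(g) for g in rng.choice(truth.genes_with_pattern("induced"), half, replace=False)]
    down = [str(g) for g in rng.choice(truth.genes_with_pattern("repressed"), half, replace=False)]
    obo, ann, modules = simulate_go(
        cm.gene_ids,
        planted_modules=[("diluted opposite-response module", {"induced": up, "repressed": down})],
        seed=seed,
    )
    truth.modules = modules
    pwms = planted_pwms()
    others = [g for g in cm.gene_ids if g not in set(up) | set(down)]
    bg_up = [str(g) for g in rng.choice(others, max(1, len(others) // 20), replace=False)]
    bg_down = [str(g) for g in rng.choice(others, max(1, len(others) // 20), replace=False)]
    plants = [
        # 80% of the respective module subcluster, ~5% of everything else
        MotifPlant(pwms[0], up, fraction=0.8),
        MotifPlant(pwms[0], bg_up, fraction=1.0),
        MotifPlant(pwms[1], down, fraction=0.8),
        MotifPlant(pwms[1], bg_down, fraction=1.0),
    ]
    fasta, bed, sites = simulate_genome(cm.gene_ids, plants, seed=seed)
    truth.planted_sites = sites
    return Scenario(cm, truth, obo, ann, fasta, bed, pwms, modules[0].term_id)


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Serialise a scenario to the plain-text formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "meta": outdir / "samples.tsv",
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "fasta": outdir / "genome.fa",
        "bed": outdir / "genes.bed",
        "jaspar": outdir / "motifs.jaspar",
        "truth": outdir / "truth.json",
    }
    scenario.counts.write_tsv(paths["counts"], paths["meta"])
    paths["obo"].write_text(scenario.obo_text)
    scenario.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    paths["fasta"].write_text(scenario.fasta_text)
    scenario.bed.to_csv(paths["bed"], sep="\t", index=False, header=False)
    write_jaspar(scenario.pwms, paths["jaspar"])
    scenario.truth.to_json(paths["truth"])
    return paths
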