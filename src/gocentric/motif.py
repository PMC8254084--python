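"""Promoter extraction, PWM scanning and TFBS motif enrichment.

Promoters are strand-resolved windows around the TSS taken from a genome
FASTA and BED6 gene models.  Each position-weight matrix is scanned on
both strands with log-odds scores against a background base composition;
a promoter "has" a motif when some window reaches a fixed fraction
(default 0.8) of the motif's maximum achievable score.  Enrichment of a
target promoter set against a background set counts each promoter at most
once (ZOOPS) and applies the one-sided hypergeometric test on the pooled
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta
from scipy.stats import hypergeom

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position probability matrix (rows = positions, columns = A,C,G,T)."""

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_frac: float = 0.8

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be L x 4")
        if len(self.probs) < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")

    def __len__(self) -> int:
        return len(self.probs)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background); an extra zero column handles N bases."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background)
        lo[self.probs == 0] = -np.inf
        return np.hstack([lo, np.zeros((len(self), 1))])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.25, **kw) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(name, c / c.sum(axis=1, keepdims=True), **kw)


def read_jaspar(path: str | Path, threshold_frac: float = 0.8) -> list[PWM]:
    """Read JASPAR-format count matrices into probability PWMs."""
    out = []
    with open(path) as handle:
        for record in bio_motifs.parse(handle, "jaspar"):
            counts = np.column_stack([record.counts[b] for b in _BASES])
            name = record.name or record.matrix_id
            out.append(PWM.from_counts(name, counts, threshold_frac=threshold_frac))
    return out


def write_jaspar(pwms: list[PWM], path: str | Path, scale: int = 100) -> None:
    lines = []
    for i, pwm in enumerate(pwms):
        lines.append(f">SYN{i + 1:04d} {pwm.name}")
        counts = np.rint(pwm.probs * scale).astype(int)
        for j, base in enumerate(_BASES):
            row = " ".join(str(v) for v in counts[:, j])
            lines.append(f"{base}  [ {row} ]")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class Hit:
    position: int  # 0-based start on the forward sequence
    strand: str
    score: float


@dataclass
class ScanResult:
    best_score: float
    hits: list[Hit]

    @property
    def has_hit(self) -> bool:
        return bool(self.hits)


def _strand_scores(encoded: np.ndarray, lo: np.ndarray) -> np.ndarray:
    length = len(lo)
    n_off = len(encoded) - length + 1
    scores = np.zeros(n_off)
    for i in range(length):
        scores += lo[i, encoded[i : i + n_off]]
    return scores


def scan_pwm(seq: str, pwm: PWM, threshold_frac: float | None = None) -> ScanResult:
    """Score every offset on both strands; report windows above threshold.

    N bases contribute a log-odds of 0.  Minus-strand hit positions refer
    to the forward-strand start of the matched window.
    """
    frac = pwm.threshold_frac if threshold_frac is None else threshold_frac
    length = len(pwm)
    if len(seq) < length:
        raise ValueError("sequence shorter than the motif")
    lo = pwm.log_odds
    threshold = frac * pwm.max_score
    hits: list[Hit] = []
    best = -np.inf
    fwd = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    rev = _CODE[np.frombuffer(reverse_complement(seq).encode("ascii"), dtype=np.uint8)]
    for strand, enc in (("+", fwd), ("-", rev)):
        scores = _strand_scores(enc, lo)
        best = max(best, float(scores.max()))
        for off in np.flatnonzero(scores >= threshold - 1e-9):
            pos = int(off) if strand == "+" else len(seq) - length - int(off)
            hits.append(Hit(pos, strand, float(scores[off])))
    return ScanResult(float(best), hits)


@dataclass
class PromoterSet:
    """Strand-resolved promoter sequences keyed by gene."""

    sequences: dict[str, str]
    upstream: int
    downstream: int
    clipped: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, genes) -> "PromoterSet":
        genes = list(genes)
        missing = [g for g in genes if g not in self.sequences]
        if missing:
            raise KeyError(f"genes without promoters: {missing[:5]}")
        return PromoterSet(
            {g: self.sequences[g] for g in genes},
            self.upstream,
            self.downstream,
            self.clipped & set(genes),
        )


def read_bed6(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if bed["strand"].isna().any() or not set(bed["strand"]) <= {"+", "-"}:
        raise ValueError("BED6 with explicit +/- strand required")
    return bed


def extract_promoters(
    genes: list[str],
    gene_bed: str | Path | pd.DataFrame,
    genome_fasta: str | Path,
    upstream: int = 500,
    downstream: int = 100,
) -> PromoterSet:
    """Cut TSS windows out of the genome, reverse-complemented on minus genes.

    Plus strand: genomic ``[TSS - upstream, TSS + downstream)`` with TSS at
    the BED start.  Minus strand: TSS is the last base (``end - 1``) and
    the window is the reverse complement of
    ``[TSS - downstream, TSS + upstream)``.  Windows truncated at a contig
    edge are flagged in ``clipped``.
    """
    bed = gene_bed if isinstance(gene_bed, pd.DataFrame) else read_bed6(gene_bed)
    by_name = bed.set_index("name")
    fasta = Fasta(str(genome_fasta))
    sequences: dict[str, str] = {}
    clipped: set[str] = set()
    for gene in genes:
        if gene not in by_name.index:
            raise KeyError(f"gene {gene!r} absent from BED")
        row = by_name.loc[gene]
        chrom = str(row["chrom"])
        if chrom not in fasta:
            raise KeyError(f"contig {chrom!r} absent from FASTA")
        contig_len = len(fasta[chrom])
        if row["strand"] == "+":
            tss = int(row["start"])
            lo, hi = tss - upstream, tss + downstream
        else:
            tss = int(row["end"]) - 1
            lo, hi = tss - downstream, tss + upstream
        clo, chi = max(0, lo), min(contig_len, hi)
        if (clo, chi) != (lo, hi):
            clipped.add(gene)
        seq = str(fasta[chrom][clo:chi]).upper()
        if row["strand"] == "-":
            seq = reverse_complement(seq)
        sequences[gene] = seq
    return PromoterSet(sequences, upstream, downstream, clipped)


def motif_enrichment(
    targets: PromoterSet,
    background: PromoterSet,
    pwms: list[PWM],
    threshold_frac: float | None = None,
) -> pd.DataFrame:
    """ZOOPS hypergeometric enrichment of targets vs background promoters.

    Promoters present in both sets are removed from the background.  For
    each motif, p = P(X >= targets_with_hit) when drawing |targets| from
    the pooled promoters of which K carry the motif.
    """
    if len(targets) == 0:
        raise ValueError("empty target promoter set")
    overlap = set(targets.sequences) & set(background.sequences)
    if overlap:
        warnings.warn(f"{len(overlap)} promoters in both sets; dropped from background")
        background = PromoterSet(
            {g: s for g, s in background.sequences.items() if g not in overlap},
            background.upstream,
            background.downstream,
            background.clipped - overlap,
        )
    n_t, n_b = len(targets), len(background)
    rows = []
    for pwm in pwms:
        t_hits = sum(
            scan_pwm(s, pwm, threshold_frac).has_hit for s in targets.sequences.values()
        )
        b_hits = sum(
            scan_pwm(s, pwm, threshold_frac).has_hit for s in background.sequences.values()
        )
        pooled = t_hits + b_hits
        p = float(hypergeom.sf(t_hits - 1, n_t + n_b, pooled, n_t))
        target_rate = t_hits / n_t
        pooled_rate = pooled / (n_t + n_b)
        fold = target_rate / pooled_rate if pooled_rate > 0 else np.nan
        rows.append(
            {
                "motif": pwm.name,
                "targets_with_hit": t_hits,
                "n_targets": n_t,
                "background_with_hit": b_hits,
                "n_background": n_b,
                "fold": fold,
                "p": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(["p", "motif"], kind="mergesort").reset_index(drop=True)
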