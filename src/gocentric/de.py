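"""Negative-binomial differential-expression testing between two time points.

The model is the classic exact-test family for overdispersed count data:
counts for gene *g* in library *j* are NB distributed with mean
``mu_gj = lambda_g * L_j`` and dispersion ``phi_g`` (variance
``mu + phi * mu^2``).  Libraries are brought to a common effective size by
TMM normalisation plus rescaling, replicate counts are summed within each
group, and the two group sums are compared conditionally on their total:
under the null the group-A sum given the total follows a (Poisson limit:
binomial) NB-convolution law that can be enumerated exactly.  Two-sided
p-values use the minimum-likelihood rule; Benjamini-Hochberg controls the
FDR across genes, and a gene is called differentially expressed when
``padj <= fdr`` and ``|log2FC| > lfc`` (defaults 0.01 and 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix, EmptyMatrixError

UP = "up"
DOWN = "down"
NOT_DE = "not_de"

_DEFAULT_PHI_GRID = np.concatenate([[0.0], np.logspace(-4, 1, 100)])


@dataclass
class DEResult:
    """Per-gene statistics for one pairwise comparison (B vs A)."""

    comparison: tuple[str, str]
    table: pd.DataFrame  # index gene; log2fc, logcpm, pvalue, padj, dispersion, zero_total

    def __post_init__(self) -> None:
        required = {"log2fc", "logcpm", "pvalue", "padj", "dispersion"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")


@dataclass
class DEGCall:
    """Up/down/not_de status per gene for one comparison."""

    comparison: tuple[str, str]
    status: pd.Series  # index gene, values in {up, down, not_de}

    @property
    def up_genes(self) -> list[str]:
        return list(self.status.index[self.status == UP])

    @property
    def down_genes(self) -> list[str]:
        return list(self.status.index[self.status == DOWN])


@dataclass
class DispersionEstimate:
    common: float
    per_gene: pd.Series  # index gene


def filter_low_counts(
    cm: CountMatrix, min_total: int = 10, per_sample: bool = False
) -> CountMatrix:
    """Drop weakly covered genes before testing.

    By default a gene is kept when its total count summed over *all*
    samples is at least ``min_total``; with ``per_sample=True`` every
    sample individually must reach ``min_total``.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    if per_sample:
        keep = (cm.counts >= min_total).all(axis=1)
    else:
        keep = cm.counts.sum(axis=1) >= min_total
    if not keep.any():
        raise EmptyMatrixError("no gene passed the low-count filter")
    genes = [g for g, k in zip(cm.gene_ids, keep) if k]
    return CountMatrix(genes, cm.counts[keep], cm.samples, cm.timepoints, cm.replicates)


def tmm_norm_factors(
    cm: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05
) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    Each sample's factor multiplies its library size to give the effective
    library size used everywhere downstream.  M (log ratio) values are
    trimmed by ``trim_m`` and A (log abundance) values by ``trim_a`` on
    each side; the surviving M values are combined with inverse-variance
    (delta-method binomial) weights.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = cm.lib_sizes.astype(float)
    if np.any(lib == 0):
        raise ValueError("sample with zero library size")
    cpm = cm.counts / lib * 1e6
    # reference column: upper quartile closest to the mean upper quartile
    uq = np.array([np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0 for c in cpm.T])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(cm.n_samples)
    yr, nr = cm.counts[:, ref].astype(float), lib[ref]
    for j in range(cm.n_samples):
        if j == ref:
            continue
        yj, nj = cm.counts[:, j].astype(float), lib[j]
        ok = (yj > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(f"no gene expressed in both sample {j} and reference")
        m = np.log2((yj[ok] / nj) / (yr[ok] / nr))
        a = 0.5 * np.log2((yj[ok] / nj) * (yr[ok] / nr))
        var = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        w = 1.0 / np.maximum(var, 1e-12)
        keep = np.ones(ok.sum(), dtype=bool)
        for vals, frac in ((m, trim_m), (a, trim_a)):
            lo, hi = np.quantile(vals, [frac, 1.0 - frac])
            keep &= (vals >= lo) & (vals <= hi)
        if not keep.any():  # degenerate trim: fall back to untrimmed
            keep[:] = True
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def effective_lib_sizes(cm: CountMatrix, factors: np.ndarray | None = None) -> np.ndarray:
    if factors is None:
        factors = tmm_norm_factors(cm)
    return cm.lib_sizes * np.asarray(factors, dtype=float)


def equalize_counts(
    cm: CountMatrix, factors: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Rescale counts to the geometric-mean effective library size.

    Returns the rounded pseudo-count matrix and the common library size.
    Summing such pseudo-counts within replicate groups is what makes the
    conditional exact test applicable.
    """
    eff = effective_lib_sizes(cm, factors)
    target = float(np.exp(np.mean(np.log(eff))))
    pseudo = np.rint(cm.counts * (target / eff)).astype(np.int64)
    return pseudo, target


def _conditional_loglik(pseudo: np.ndarray, group_cols: list[list[int]], phi: float) -> np.ndarray:
    """Per-gene NB conditional log-likelihood at dispersion ``phi``.

    Conditions each replicate group on its sum; library sizes are assumed
    equalised.  ``phi = 0`` is the Poisson/multinomial limit.
    """
    total = np.zeros(pseudo.shape[0])
    for cols in group_cols:
        n = len(cols)
        if n < 2:
            continue
        y = pseudo[:, cols].astype(float)
        s = y.sum(axis=1)
        if phi <= 0:
            total += gammaln(s + 1) - gammaln(y + 1).sum(axis=1) - s * np.log(n)
        else:
            r = 1.0 / phi
            total += (
                (gammaln(y + r) - gammaln(y + 1)).sum(axis=1)
                - len(cols) * gammaln(r)
                - (gammaln(s + n * r) - gammaln(s + 1) - gammaln(n * r))
            )
    return total


def estimate_dispersion(
    cm: CountMatrix,
    groups: list[list[int]] | None = None,
    factors: np.ndarray | None = None,
    prior_weight: float = 10.0,
    phi_grid: np.ndarray | None = None,
) -> DispersionEstimate:
    """Common and per-gene (shrunken) NB dispersion by conditional likelihood.

    The common value maximises the summed conditional log-likelihood over a
    dispersion grid; per-gene values maximise the gene's own conditional
    log-likelihood plus ``prior_weight`` times the gene-averaged one, which
    shrinks noisy per-gene estimates toward the common value (the weight is
    expressed in "equivalent genes"; 10 by default).
    """
    if groups is None:
        groups = [cm.samples_at(t) for t in cm.timepoint_order]
    if not any(len(g) >= 2 for g in groups):
        raise ValueError(
            "no replicated group: cannot estimate dispersion; supply phi explicitly"
        )
    if phi_grid is None:
        phi_grid = _DEFAULT_PHI_GRID
    pseudo, _ = equalize_counts(cm, factors)
    ll = np.stack([_conditional_loglik(pseudo, groups, p) for p in phi_grid], axis=1)
    common = float(phi_grid[int(np.argmax(ll.sum(axis=0)))])
    mean_ll = ll.mean(axis=0)
    weighted = ll + prior_weight * mean_ll[None, :]
    per_gene = phi_grid[np.argmax(weighted, axis=1)]
    return DispersionEstimate(common, pd.Series(per_gene, index=cm.gene_ids, name="phi"))


def _exact_pvalue(sa: int, sb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided conditional exact p for group sums ``sa`` vs ``sb``.

    Enumerates the distribution of the group-A sum given the total under
    equal per-library means; outcomes whose point probability does not
    exceed the observed one are accumulated (minimum-likelihood rule).
    """
    t = sa + sb
    if t == 0:
        return 1.0
    a = np.arange(t + 1)
    if phi <= 1e-10:  # Poisson limit; avoids overflow of r = 1/phi
        logw = binom.logpmf(a, t, na / (na + nb))
    else:
        ra, rb = na / phi, nb / phi
        logw = (
            gammaln(a + ra)
            - gammaln(a + 1)
            + gammaln(t - a + rb)
            - gammaln(t - a + 1)
        )
        logw -= logsumexp(logw)
    w = np.exp(logw)
    p = float(w[w <= w[sa] * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def nb_exact_test(
    cm: CountMatrix,
    group_a: list[int] | str,
    group_b: list[int] | str,
    dispersion: DispersionEstimate | pd.Series | float,
    factors: np.ndarray | None = None,
    prior_count: float = 0.5,
    comparison: tuple[str, str] | None = None,
) -> DEResult:
    """Exact NB test of group B vs group A (log2FC is B over A).

    ``group_a``/``group_b`` may be time-point labels or lists of column
    indices.  ``dispersion`` is a scalar, a per-gene Series, or a
    :class:`DispersionEstimate` (its per-gene values are used).
    """
    if isinstance(group_a, str):
        comparison = comparison or (group_a, group_b)  # type: ignore[assignment]
        group_a = cm.samples_at(group_a)
    if isinstance(group_b, str):
        group_b = cm.samples_at(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if comparison is None:
        comparison = ("A", "B")
    if isinstance(dispersion, DispersionEstimate):
        phi = dispersion.per_gene.reindex(cm.gene_ids).to_numpy(float)
    elif isinstance(dispersion, pd.Series):
        phi = dispersion.reindex(cm.gene_ids).to_numpy(float)
    else:
        phi = np.full(cm.n_genes, float(dispersion))
    if np.any(np.isnan(phi)) or np.any(phi < 0):
        raise ValueError("dispersion must be >= 0 for every gene")

    pseudo, target = equalize_counts(cm, factors)
    na, nb = len(group_a), len(group_b)
    sa = pseudo[:, group_a].sum(axis=1)
    sb = pseudo[:, group_b].sum(axis=1)

    pvals = np.ones(cm.n_genes)
    for i in range(cm.n_genes):
        if sa[i] + sb[i] > 0:
            pvals[i] = _exact_pvalue(int(sa[i]), int(sb[i]), na, nb, phi[i])

    mean_a = sa / na
    mean_b = sb / nb
    log2fc = np.log2(mean_b + prior_count) - np.log2(mean_a + prior_count)
    zero = (sa + sb) == 0
    log2fc[zero] = 0.0
    logcpm = np.log2((sa + sb) / (na + nb) / target * 1e6 + prior_count)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "logcpm": logcpm,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
            "dispersion": phi,
            "zero_total": zero,
        },
        index=pd.Index(cm.gene_ids, name="gene"),
    )
    return DEResult(tuple(comparison), table)


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-value passed to bh_adjust")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(de: DEResult, fdr: float = 0.01, lfc: float = 1.0) -> DEGCall:
    """Apply the DEG rule: ``padj <= fdr`` and ``log2FC`` beyond ``+/-lfc``."""
    if fdr <= 0 or lfc <= 0:
        raise ValueError("thresholds must be positive")
    t = de.table
    sig = t["padj"] <= fdr
    status = pd.Series(NOT_DE, index=t.index, name="status")
    status[sig & (t["log2fc"] > lfc)] = UP
    status[sig & (t["log2fc"] < -lfc)] = DOWN
    return DEGCall(de.comparison, status)


def write_de_tsv(de: DEResult, call: DEGCall, path) -> None:
    out = de.table.copy()
    out["status"] = call.status
    out.to_csv(path, sep="\t")
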