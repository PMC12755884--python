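"""Synonymous diversity, polymorphic-site fractions, and Poisson backbone
fits.

All synonymous statistics are computed over fourfold-degenerate (4D) sites:
third codon positions whose first two consensus bases make any third base
code for the same amino acid.  The 4D set is called per species from the
species consensus, so sequencing of nonsynonymous differences between species
does not contaminate within-species synonymous diversity.

The "ancestral backbone" test asks whether per-gene counts of polymorphic 4D
sites are consistent with mutation accumulation alone: under a uniform
mutation rate the counts are Poisson, fitted either from the zero class
(lambda = -ln p0) or from the mean.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GeneAlignment, consensus_sequence

#: Codon prefixes whose third position is fourfold degenerate (standard code).
FOURFOLD_PREFIXES = {b"TC", b"CT", b"CC", b"CG", b"AC", b"GT", b"GC", b"GG"}


def fourfold_sites(aln: GeneAlignment, cell_ids=None,
                   max_gap_frac: float = 0.5,
                   consensus: np.ndarray | None = None) -> np.ndarray:
    """Positions of scorable 4D sites, from the (species) consensus frame.

    A third-codon position is 4D when the consensus first two bases of its
    codon form a fourfold-degenerate prefix; columns missing in more than
    *max_gap_frac* of the subset's cells are excluded.
    """
    sub = aln if cell_ids is None else aln.subset(cell_ids)
    if consensus is None:
        consensus = consensus_sequence(sub)
    off = aln.frame_offset
    L = aln.length
    out = []
    gap_frac = 1.0 - sub.coverage_mask().mean(axis=0) if sub.n_seqs else np.ones(L)
    for start in range(off, L - 2, 3):
        prefix = consensus[start] + consensus[start + 1]
        third = start + 2
        if prefix in FOURFOLD_PREFIXES and gap_frac[third] <= max_gap_frac:
            out.append(third)
    return np.array(out, dtype=int)


def pi_synonymous(aln: GeneAlignment, cell_ids=None, sites=None) -> float:
    """Mean pairwise difference per 4D site, pairwise-complete per pair.

    Averages over all sequence pairs the ratio (4D mismatches / 4D sites
    jointly covered by the pair); pairs with no shared scorable site are
    skipped.  Returns NaN (undefined) with fewer than two sequences.
    """
    sub = aln if cell_ids is None else aln.subset(cell_ids)
    if sub.n_seqs < 2:
        return float("nan")
    if sites is None:
        sites = fourfold_sites(sub)
    if sites.size == 0:
        return float("nan")
    mat = sub.matrix[:, sites]
    cov = sub.coverage_mask()[:, sites]
    vals = []
    for i in range(sub.n_seqs):
        both = cov[i] & cov[i + 1:]
        nb = both.sum(axis=1)
        diff = ((mat[i] != mat[i + 1:]) & both).sum(axis=1)
        ok = nb > 0
        vals.extend(diff[ok] / nb[ok])
    return float(np.mean(vals)) if vals else float("nan")


def fraction_polymorphic_4d(aln: GeneAlignment, cell_ids=None,
                            min_cov: int = 2,
                            sites=None) -> tuple[int, int, float]:
    """(k_poly, n_4D, f_p): polymorphic fraction of scorable 4D sites.

    A site is polymorphic when at least two alleles each appear in at least
    one covered cell; sites covered by fewer than *min_cov* cells are
    excluded from n_4D.
    """
    sub = aln if cell_ids is None else aln.subset(cell_ids)
    if sites is None:
        sites = fourfold_sites(sub)
    if sites.size == 0:
        return 0, 0, float("nan")
    mat = sub.matrix[:, sites]
    cov = sub.coverage_mask()[:, sites]
    bases = np.frombuffer(b"ACGT", dtype="S1")
    counts = np.stack([((mat == b) & cov).sum(axis=0) for b in bases])
    covered = cov.sum(axis=0)
    scorable = covered >= min_cov
    poly = ((counts > 0).sum(axis=0) >= 2) & scorable
    n4d = int(scorable.sum())
    k = int(poly.sum())
    return k, n4d, (k / n4d if n4d else float("nan"))


@dataclass
class GeneDiversity:
    gene_id: str
    n_4d: int
    k_poly: int
    f_p: float
    pi_s: float


def gene_diversity_table(alignments, cell_ids, min_cov: int = 2) -> pd.DataFrame:
    """Per-gene 4D diversity summary for one species' cells."""
    rows = []
    for gene_id, aln in sorted(alignments.items()):
        sub = aln.subset(cell_ids)
        sites = fourfold_sites(sub)
        k, n, fp = fraction_polymorphic_4d(sub, sites=sites, min_cov=min_cov)
        pi = pi_synonymous(sub, sites=sites)
        rows.append({"gene_id": gene_id, "n_4D": n, "k_poly": k,
                     "f_p": fp, "pi_S": pi})
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Poisson fits of polymorphic-site counts
# ---------------------------------------------------------------------------

@dataclass
class PoissonFit:
    """Poisson fit of per-gene polymorphic 4D-site counts."""

    lambda_hat: float
    method: str                # "zero_class" or "mean"
    chi2: float
    pvalue: float
    dof: int
    n_genes: int


def _poisson_goodness(k: np.ndarray, lam: float) -> tuple[float, float, int]:
    """Chi-square over count classes, pooling the tail so expected >= 5."""
    n = k.size
    if lam == 0:
        return 0.0, 1.0, 0
    kmax = int(k.max())
    classes = np.arange(kmax + 1)
    expected = stats.poisson.pmf(classes, lam) * n
    tail = n * stats.poisson.sf(kmax, lam)
    observed = np.bincount(k, minlength=kmax + 1).astype(float)
    expected = np.append(expected, tail)
    observed = np.append(observed, 0.0)
    # pool from the right until the last class expectation reaches 5
    while expected.size > 2 and expected[-1] < 5:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected, observed = expected[:-1], observed[:-1]
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = max(expected.size - 2, 1)  # one fitted parameter
    return chi2, float(stats.chi2.sf(chi2, dof)), dof


def fit_poisson_zero_class(k_poly) -> PoissonFit:
    """Fit lambda from the fraction of genes without any polymorphic site.

    With p0 the zero-class fraction, lambda = -ln p0.  Raises when no gene
    has k=0 (use :func:`fit_poisson_mean` instead).
    """
    k = np.asarray(k_poly, dtype=int)
    if k.size == 0:
        raise ValueError("no genes supplied")
    p0 = float((k == 0).mean())
    if p0 == 0:
        raise ValueError("no zero-polymorphism genes; use the mean-based fit")
    lam = -np.log(p0)
    chi2, p, dof = _poisson_goodness(k, lam)
    return PoissonFit(float(lam), "zero_class", chi2, p, dof, k.size)


def fit_poisson_mean(k_poly) -> PoissonFit:
    """Fit lambda as the arithmetic mean of the counts."""
    k = np.asarray(k_poly, dtype=int)
    if k.size == 0:
        raise ValueError("no genes supplied")
    lam = float(k.mean())
    chi2, p, dof = _poisson_goodness(k, lam)
    return PoissonFit(lam, "mean", chi2, p, dof, k.size)


def partition_backbone_hybrid(f_p, f_cut: float = 0.05) -> pd.Series:
    """Label genes ``backbone`` (f_p < f_cut, strict) or ``hybrid``.

    Genes with undefined f_p are labelled ``unscored``.
    """
    f = pd.Series(f_p, dtype=float)
    labels = pd.Series("unscored", index=f.index, dtype=object)
    labels[f < f_cut] = "backbone"
    labels[f >= f_cut] = "hybrid"
    return labels


# ---------------------------------------------------------------------------
# Marker vs genome divergence
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    slope: float
    intercept: float
    pvalue: float
    n: int
    flag: str = ""


def marker_genome_correlation(marker_div, genome_div) -> CorrelationResult:
    """Pearson R and regression slope of marker-gene vs whole-genome
    divergence over the same cell pairs.

    A degenerate (constant) input leaves R undefined and is flagged rather
    than raising, mirroring how a monomorphic 16S locus would behave.
    """
    x = np.asarray(marker_div, dtype=float)
    y = np.asarray(genome_div, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >=3 cell pairs for a correlation")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return CorrelationResult(float("nan"), float("nan"), float("nan"),
                                 float("nan"), x.size, "constant_input")
    res = stats.linregress(x, y)
    return CorrelationResult(float(res.rvalue), float(res.slope),
                             float(res.intercept), float(res.pvalue), x.size)
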