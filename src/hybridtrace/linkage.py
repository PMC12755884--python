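"""Linkage disequilibrium statistics for incomplete single-cell alignments.

The central statistic is sigma_d^2, the ratio-of-expectations form of linkage
disequilibrium,

    sigma_d^2 = < D^2 > / < f_a (1 - f_a) f_b (1 - f_b) >,   D = f_ab - f_a f_b,

with the averages taken across site pairs *before* the ratio.  In an asexual
population under conventional demographic drift sigma_d^2 = 5/11 independent
of the separation between sites; recombination unlinks sites and drives the
statistic toward the finite-sample baseline measured by a fully unlinked
permutation control.  All per-pair frequencies are computed over the cells
that are non-missing at both sites, which makes the statistic well defined
under gene-wise SAG missingness.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io_core import GeneAlignment

#: Default per-pair minimum number of jointly covered cells.
DEFAULT_MIN_JOINT = 10
#: Default minor-allele-count filter for SNP columns.
DEFAULT_MIN_MAC = 2


@dataclass
class SitePairStats:
    """Allele/haplotype frequencies for one pair of bi-allelic sites.

    ``x`` is the separation in bp for within-gene pairs and ``None`` for pairs
    drawn from different genes.
    """

    f_a: float
    f_b: float
    f_ab: float
    n_joint: int
    x: int | None = None

    @property
    def d(self) -> float:
        return self.f_ab - self.f_a * self.f_b

    @property
    def denom(self) -> float:
        return self.f_a * (1 - self.f_a) * self.f_b * (1 - self.f_b)


def sigma_d_squared(pairs) -> float:
    """Ratio-of-expectations sigma_d^2 over a collection of site pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("sigma_d_squared requires at least one site pair")
    num = sum(p.d ** 2 for p in pairs)
    den = sum(p.denom for p in pairs)
    if den == 0:
        raise ValueError("all pairs monomorphic: zero denominator")
    return num / den


def r_squared(pair: SitePairStats) -> float:
    """D^2 / (f_a(1-f_a) f_b(1-f_b)) for a single pair."""
    if pair.denom == 0:
        raise ValueError("r^2 undefined: site monomorphic among joint cells")
    return pair.d ** 2 / pair.denom


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

@dataclass
class SNPTable:
    """Bi-allelic SNP columns of one alignment, in genomic order.

    ``codes`` is (n_cells, n_snps) int8 with 0 = major allele, 1 = minor
    allele, -1 = missing.  ``alleles`` stores the (major, minor) bases.
    """

    gene_id: str
    cell_ids: list[str]
    positions: np.ndarray
    codes: np.ndarray
    alleles: list[tuple[bytes, bytes]]
    n_multiallelic: int = 0

    @property
    def n_snps(self) -> int:
        return self.positions.size


def snp_table(aln: GeneAlignment, cell_ids=None,
              min_mac: int = DEFAULT_MIN_MAC) -> SNPTable:
    """Extract bi-allelic SNP columns (minor-allele count >= *min_mac*).

    Columns with three or more alleles among covered cells are excluded and
    counted in ``n_multiallelic``.
    """
    sub = aln if cell_ids is None else aln.subset(cell_ids)
    cov = sub.coverage_mask()
    bases = np.frombuffer(b"ACGT", dtype="S1")
    counts = np.stack([((sub.matrix == b) & cov).sum(axis=0) for b in bases])
    n_alleles = (counts > 0).sum(axis=0)
    order = np.argsort(counts, axis=0)
    major_i, minor_i = order[-1], order[-2]
    mac = np.take_along_axis(counts, minor_i[None, :], axis=0)[0]
    keep = (n_alleles == 2) & (mac >= min_mac)
    n_multi = int((n_alleles > 2).sum())
    positions = np.flatnonzero(keep)
    codes = np.full((sub.n_seqs, positions.size), -1, dtype=np.int8)
    alleles = []
    for j, pos in enumerate(positions):
        major = bases[major_i[pos]]
        minor = bases[minor_i[pos]]
        col = sub.matrix[:, pos]
        codes[col == major, j] = 0
        codes[col == minor, j] = 1
        alleles.append((major, minor))
    return SNPTable(sub.gene_id, list(sub.cell_ids), positions, codes,
                    alleles, n_multi)


def pair_stats_from_codes(codes: np.ndarray, i: int, j: int,
                          x=None) -> SitePairStats | None:
    """Joint frequencies of columns *i*, *j* over jointly covered cells."""
    a, b = codes[:, i], codes[:, j]
    joint = (a >= 0) & (b >= 0)
    n = int(joint.sum())
    if n == 0:
        return None
    fa = float((a[joint] == 1).mean())
    fb = float((b[joint] == 1).mean())
    fab = float(((a == 1) & (b == 1) & joint).sum()) / n
    return SitePairStats(fa, fb, fab, n, x)


def site_pairs(aln: GeneAlignment, cell_ids=None,
               min_joint: int = DEFAULT_MIN_JOINT,
               min_mac: int = DEFAULT_MIN_MAC) -> list[SitePairStats]:
    """All within-gene SNP pairs with at least *min_joint* shared cells."""
    tab = snp_table(aln, cell_ids, min_mac)
    out = []
    for i in range(tab.n_snps):
        for j in range(i + 1, tab.n_snps):
            p = pair_stats_from_codes(
                tab.codes, i, j, x=int(tab.positions[j] - tab.positions[i])
            )
            if p is not None and p.n_joint >= min_joint:
                out.append(p)
    return out


# ---------------------------------------------------------------------------
# Decay curves and controls
# ---------------------------------------------------------------------------

@dataclass
class LinkageCurve:
    """Distance-binned sigma_d^2 plus genome-wide and control values."""

    bin_edges: np.ndarray
    sigma_d2: np.ndarray          # NaN where a bin holds no pairs
    n_pairs: np.ndarray
    genome_wide: float = float("nan")
    genome_wide_n: int = 0
    control: float = float("nan")

    def bin_centers(self) -> np.ndarray:
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])


def _pair_sums(codes, ii, jj):
    """Vectorised D^2 and variance-product sums over column index pairs."""
    A = codes[:, ii]
    B = codes[:, jj]
    joint = (A >= 0) & (B >= 0)
    nj = joint.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = ((A == 1) & joint).sum(axis=0) / nj
        fb = ((B == 1) & joint).sum(axis=0) / nj
        fab = ((A == 1) & (B == 1) & joint).sum(axis=0) / nj
    d2 = (fab - fa * fb) ** 2
    den = fa * (1 - fa) * fb * (1 - fb)
    return d2, den, nj


def _stack_tables(alignments, cell_ids, min_mac):
    """Concatenate per-gene SNP codes onto a common cell axis."""
    cell_ids = list(cell_ids)
    pos_in = {c: i for i, c in enumerate(cell_ids)}
    mats, gene_idx, positions = [], [], []
    for gi, (gene_id, aln) in enumerate(sorted(alignments.items())):
        tab = snp_table(aln, cell_ids, min_mac)
        if tab.n_snps == 0:
            continue
        full = np.full((len(cell_ids), tab.n_snps), -1, dtype=np.int8)
        rows = [pos_in[c] for c in tab.cell_ids]
        full[rows] = tab.codes
        mats.append(full)
        gene_idx.append(np.full(tab.n_snps, gi))
        positions.append(tab.positions)
    if not mats:
        raise ValueError("no qualifying SNP columns in any alignment")
    return (np.concatenate(mats, axis=1), np.concatenate(gene_idx),
            np.concatenate(positions))


def linkage_decay_curve(alignments, cell_ids, bin_edges=None,
                        min_joint: int = DEFAULT_MIN_JOINT,
                        min_mac: int = DEFAULT_MIN_MAC,
                        max_cross_pairs: int = 100_000,
                        seed: int = 0) -> LinkageCurve:
    """sigma_d^2 as a function of SNP separation, pooled across genes.

    Within-gene pairs are binned by separation x (log-spaced bins from 1 bp to
    the longest gene by default); pairs in different genes are pooled into the
    genome-wide estimate (subsampled to *max_cross_pairs* with a seeded RNG).
    Pooling is done before the ratio at every level.
    """
    codes, gene_idx, positions = _stack_tables(alignments, cell_ids, min_mac)
    if bin_edges is None:
        max_len = max(a.length for a in alignments.values())
        bin_edges = np.unique(
            np.round(np.geomspace(1, max(max_len, 2), num=12)).astype(int)
        ).astype(float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    nbins = bin_edges.size - 1
    num = np.zeros(nbins)
    den = np.zeros(nbins)
    cnt = np.zeros(nbins, dtype=int)
    # within-gene pairs, gene by gene
    for gi in np.unique(gene_idx):
        cols = np.flatnonzero(gene_idx == gi)
        if cols.size < 2:
            continue
        ii, jj = np.triu_indices(cols.size, k=1)
        ii, jj = cols[ii], cols[jj]
        d2, dd, nj = _pair_sums(codes, ii, jj)
        x = np.abs(positions[jj] - positions[ii]).astype(float)
        ok = nj >= min_joint
        b = np.digitize(x[ok], bin_edges) - 1
        inside = (b >= 0) & (b < nbins)
        np.add.at(num, b[inside], d2[ok][inside])
        np.add.at(den, b[inside], dd[ok][inside])
        np.add.at(cnt, b[inside], 1)
    if cnt.sum() == 0:
        raise ValueError("no qualifying within-gene SNP pairs")
    with np.errstate(invalid="ignore", divide="ignore"):
        sig = np.where(den > 0, num / den, np.nan)
    sig[cnt == 0] = np.nan
    gw, gw_n = _genome_wide(codes, gene_idx, min_joint, max_cross_pairs, seed)
    return LinkageCurve(bin_edges, sig, cnt, gw, gw_n)


def _genome_wide(codes, gene_idx, min_joint, max_cross_pairs, seed):
    rng = np.random.default_rng(seed)
    S = codes.shape[1]
    if S < 2 or np.unique(gene_idx).size < 2:
        return float("nan"), 0
    n_draw = int(max_cross_pairs * 1.3) + 100
    ii = rng.integers(0, S, n_draw)
    jj = rng.integers(0, S, n_draw)
    keep = gene_idx[ii] != gene_idx[jj]
    ii, jj = ii[keep][:max_cross_pairs], jj[keep][:max_cross_pairs]
    if ii.size == 0:
        return float("nan"), 0
    d2, dd, nj = _pair_sums(codes, ii, jj)
    ok = nj >= min_joint
    if dd[ok].sum() == 0:
        return float("nan"), 0
    return float(d2[ok].sum() / dd[ok].sum()), int(ok.sum())


def unlinked_control(alignments, cell_ids, seed: int = 0,
                     min_joint: int = DEFAULT_MIN_JOINT,
                     min_mac: int = DEFAULT_MIN_MAC,
                     max_cross_pairs: int = 100_000) -> float:
    """Fully unlinked permutation control for the genome-wide sigma_d^2.

    Each SNP column's observed alleles are independently permuted across the
    covered cells, preserving the per-site allele frequency and the
    missingness pattern exactly, and the genome-wide statistic is recomputed
    on the permuted table.
    """
    codes, gene_idx, _ = _stack_tables(alignments, cell_ids, min_mac)
    rng = np.random.default_rng(seed)
    perm = codes.copy()
    for j in range(perm.shape[1]):
        covered = np.flatnonzero(perm[:, j] >= 0)
        perm[covered, j] = rng.permutation(perm[covered, j])
    gw, _ = _genome_wide(perm, gene_idx, min_joint, max_cross_pairs,
                         seed + 1)
    return gw


# ---------------------------------------------------------------------------
# Decay-model fit
# ---------------------------------------------------------------------------

def decay_model(x, rho):
    """sigma_d^2(x) = (10 + rho x) / (22 + 13 rho x + (rho x)^2).

    At rho*x = 0 this equals 10/22 = 5/11, the asexual drift limit; as
    rho*x -> infinity it decays to 0.
    """
    rx = rho * np.asarray(x, dtype=float)
    return (10 + rx) / (22 + 13 * rx + rx ** 2)


def fit_decay_model(curve: LinkageCurve) -> tuple[float, dict]:
    """Least-squares fit of the decay model; returns (rho_hat, diagnostics)."""
    x = curve.bin_centers()
    y = curve.sigma_d2
    ok = np.isfinite(y) & (curve.n_pairs > 0)
    if ok.sum() < 3:
        raise ValueError("fit_decay_model needs >=3 bins with finite sigma_d^2")
    x, y = x[ok], y[ok]
    p0 = 1.0 / max(float(np.median(x)), 1.0)
    try:
        popt, pcov = curve_fit(decay_model, x, y, p0=[p0],
                               bounds=(0, np.inf), maxfev=10_000)
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise ValueError(f"decay-model fit did not converge: {exc}") from exc
    rho = float(popt[0])
    resid = y - decay_model(x, rho)
    diag = {"rho_se": float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan"),
            "rss": float((resid ** 2).sum()), "n_bins": int(ok.sum())}
    return rho, diag
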