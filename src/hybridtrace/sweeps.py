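"""Divergence troughs and hard/soft sweep classification.

A full gene sweep of a hybrid allele through a host species collapses the
synonymous divergence between species at that locus from its typical value
(tens of percent) down to within-species levels.  Runs of consecutive loci
whose mean cross-species synonymous divergence falls below ``d_trough`` are
therefore the footprints of full gene sweeps.

Whether a sweep was hard or soft is read from the diversity among the hybrid
alleles in the recipient: a single founder allele leaves zero synonymous
diversity (hard), while multiple independently transferred founders leave
donor-like diversity, orders of magnitude above the recipient's
mutation-accumulation backbone (soft).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import fourfold_sites, pi_synonymous
from .io_core import GeneAlignment, pairwise_divergence

DEFAULT_D_TROUGH = 0.2
DEFAULT_SOFT_FACTOR = 10.0

HARD = "hard"
SOFT = "soft"
AMBIGUOUS = "ambiguous"


@dataclass
class DivergenceProfile:
    """Ordered per-locus cross-species synonymous divergence (mean/min/max)."""

    table: pd.DataFrame   # columns: gene_id, mean_div, min_div, max_div, n_pairs

    def __post_init__(self):
        t = self.table
        bad = t[(t.min_div > t.mean_div + 1e-12) |
                (t.mean_div > t.max_div + 1e-12)]
        if len(bad):
            raise ValueError(f"profile violates min<=mean<=max at "
                             f"{list(bad.gene_id)[:3]}")


@dataclass
class Trough:
    start_index: int            # first locus index in the ordered profile
    end_index: int              # past-the-end locus index
    gene_ids: list[str]

    @property
    def n_genes(self) -> int:
        return self.end_index - self.start_index


@dataclass
class SweepCall:
    gene_id: str
    mode: str
    pi_s_hybrid: float
    backbone_rate: float
    n_alleles: int
    reason: str = ""


def interspecies_divergence_profile(alignments, gene_order, cells_a, cells_b,
                                    max_gap_frac: float = 0.5
                                    ) -> DivergenceProfile:
    """Per-locus mean/min/max synonymous divergence between two species.

    4D sites are those fourfold degenerate in *both* species' consensus;
    divergences are pairwise-complete over all cross-species sequence pairs.
    Loci where either species lacks coverage are skipped with a warning.
    """
    rows = []
    set_a, set_b = set(cells_a), set(cells_b)
    for gene_id in gene_order:
        aln = alignments[gene_id]
        sub_a = aln.subset([c for c in aln.cell_ids if c in set_a])
        sub_b = aln.subset([c for c in aln.cell_ids if c in set_b])
        if sub_a.n_seqs == 0 or sub_b.n_seqs == 0:
            warnings.warn(f"gene {gene_id}: one species absent, skipped")
            continue
        sites = np.intersect1d(
            fourfold_sites(sub_a, max_gap_frac=max_gap_frac),
            fourfold_sites(sub_b, max_gap_frac=max_gap_frac))
        if sites.size == 0:
            warnings.warn(f"gene {gene_id}: no shared 4D sites, skipped")
            continue
        divs = []
        for i in range(sub_a.n_seqs):
            for j in range(sub_b.n_seqs):
                d = pairwise_divergence(sub_a.matrix[i], sub_b.matrix[j],
                                        sites=sites)
                if not np.isnan(d):
                    divs.append(d)
        if not divs:
            warnings.warn(f"gene {gene_id}: no comparable cross pairs, skipped")
            continue
        rows.append({"gene_id": gene_id, "mean_div": float(np.mean(divs)),
                     "min_div": float(np.min(divs)),
                     "max_div": float(np.max(divs)), "n_pairs": len(divs)})
    return DivergenceProfile(pd.DataFrame(rows))


def detect_troughs(profile: DivergenceProfile,
                   d_trough: float = DEFAULT_D_TROUGH,
                   min_genes: int = 1) -> list[Trough]:
    """Maximal runs of consecutive loci with mean divergence < d_trough.

    Runs separated by even a single above-cutoff locus are not merged.
    """
    t = profile.table
    below = (t.mean_div < d_trough).to_numpy()
    out = []
    i = 0
    while i < below.size:
        if below[i]:
            j = i
            while j < below.size and below[j]:
                j += 1
            if j - i >= min_genes:
                out.append(Trough(i, j, list(t.gene_id.iloc[i:j])))
            i = j
        else:
            i += 1
    return out


def classify_sweep_mode(aln: GeneAlignment, carrier_cells, backbone_rate: float,
                        soft_factor: float = DEFAULT_SOFT_FACTOR,
                        max_hard_mismatches: int = 0) -> SweepCall:
    """Hard/soft call from synonymous diversity among the hybrid alleles.

    ``hard``: the carriers' alleles are identical at 4D sites (up to the
    configured sequencing-error allowance); ``soft``: pi_S among carriers
    exceeds *soft_factor* times the backbone per-site rate; otherwise
    ``ambiguous``.  Fewer than two carriers with coverage -> ambiguous.
    """
    sub = aln.subset(carrier_cells)
    if sub.n_seqs < 2:
        return SweepCall(aln.gene_id, AMBIGUOUS, float("nan"), backbone_rate,
                         sub.n_seqs, "fewer than two hybrid alleles")
    sites = fourfold_sites(sub)
    pi = pi_synonymous(sub, sites=sites)
    if np.isnan(pi):
        return SweepCall(aln.gene_id, AMBIGUOUS, pi, backbone_rate,
                         sub.n_seqs, "no scorable 4D sites")
    # max pairwise 4D mismatch count for the zero-diversity (hard) test
    mat = sub.matrix[:, sites]
    cov = sub.coverage_mask()[:, sites]
    max_mm = 0
    for i in range(sub.n_seqs):
        both = cov[i] & cov[i + 1:]
        mm = ((mat[i] != mat[i + 1:]) & both).sum(axis=1)
        if mm.size:
            max_mm = max(max_mm, int(mm.max()))
    if max_mm <= max_hard_mismatches:
        return SweepCall(aln.gene_id, HARD, pi, backbone_rate, sub.n_seqs)
    if pi > soft_factor * backbone_rate:
        return SweepCall(aln.gene_id, SOFT, pi, backbone_rate, sub.n_seqs)
    return SweepCall(aln.gene_id, AMBIGUOUS, pi, backbone_rate, sub.n_seqs,
                     "diversity between hard and soft thresholds")
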