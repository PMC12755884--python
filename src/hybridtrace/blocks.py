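"""Detection of perfectly linked SNP blocks and inter-block linkage.

A short donor segment introduced by recombination and spread by hitchhiking
leaves a run of consecutive bi-allelic SNPs carried by exactly two
haplotypes: the host's and the donor's.  Blocks are found by greedy extension
of runs of SNPs in perfect linkage (identical cell partitions up to allele
relabeling among jointly covered cells).  Each emitted block's haplotypes are
mapped to the other species' consensus to identify the donor, and linkage
between blocks is compared to a fully unlinked permutation null.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import GeneAlignment, consensus_sequence
from .linkage import SNPTable, snp_table

DEFAULT_MIN_SNPS = 3
DEFAULT_MIN_CELLS = 3
DEFAULT_MIN_JOINT = 10
DEFAULT_MAX_GAP_BP = 300


@dataclass
class SNPBlock:
    """A maximal run of consecutive perfectly linked SNPs.

    ``columns`` are alignment positions (genomic order); ``haplotype_1`` and
    ``haplotype_2`` are the two allele vectors over those columns;
    ``cells_h1``/``cells_h2`` partition the cells assignable to a haplotype
    (cells whose covered columns all agree with exactly one haplotype).
    ``d_to_other`` maps species -> (divergence of h1, divergence of h2) from
    that species' consensus over the block columns.
    """

    gene_id: str
    columns: np.ndarray
    haplotype_1: np.ndarray
    haplotype_2: np.ndarray
    cells_h1: list[str]
    cells_h2: list[str]
    d_to_other: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return self.columns.size

    @property
    def start(self) -> int:
        return int(self.columns[0])

    @property
    def end(self) -> int:
        return int(self.columns[-1]) + 1

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    def assignment(self) -> dict[str, int]:
        out = {c: 0 for c in self.cells_h1}
        out.update({c: 1 for c in self.cells_h2})
        return out


def biallelic_snp_table(aln: GeneAlignment, cell_ids=None,
                        min_mac: int = 2) -> SNPTable:
    """Ordered bi-allelic SNP columns (minor-allele count >= min_mac) for a
    species subset; tri-allelic columns are excluded and counted."""
    return snp_table(aln, cell_ids, min_mac)


def find_snp_blocks(table: SNPTable, min_snps: int = DEFAULT_MIN_SNPS,
                    min_cells: int = DEFAULT_MIN_CELLS,
                    min_joint: int = DEFAULT_MIN_JOINT,
                    max_gap_bp: int = DEFAULT_MAX_GAP_BP) -> list[SNPBlock]:
    """Greedy extension of perfect-linkage runs over the ordered SNP table.

    A run grows while the next SNP (in SNP order, with at most *max_gap_bp*
    between adjacent block SNPs) shows exactly two joint haplotypes whose
    cell partition matches the block's, up to allele relabeling, over at
    least *min_joint* jointly covered cells.  Runs are maximal and therefore
    disjoint; emitted blocks need >= *min_snps* SNPs and >= *min_cells* cells
    per haplotype.
    """
    C = table.codes
    pos = table.positions
    S = table.n_snps
    blocks: list[SNPBlock] = []
    s = 0
    while s < S:
        assign = C[:, s].astype(np.int8)      # 0 = major side, 1 = minor side
        cols = [s]
        side_alleles = [(0, 1)]               # (code of side0, side1) per col
        t = s + 1
        while t < S:
            if pos[t] - pos[cols[-1]] > max_gap_bp:
                break
            a = C[:, t]
            joint = (assign >= 0) & (a >= 0)
            j0 = joint & (assign == 0)
            j1 = joint & (assign == 1)
            if int(joint.sum()) < min_joint or not j0.any() or not j1.any():
                break
            v0 = np.unique(a[j0])
            v1 = np.unique(a[j1])
            if v0.size != 1 or v1.size != 1 or v0[0] == v1[0]:
                break
            cols.append(t)
            side_alleles.append((int(v0[0]), int(v1[0])))
            new = (assign < 0) & (a >= 0)
            assign[new & (a == v0[0])] = 0
            assign[new & (a == v1[0])] = 1
            t += 1
        if len(cols) >= min_snps:
            n0 = int((assign == 0).sum())
            n1 = int((assign == 1).sum())
            if n0 >= min_cells and n1 >= min_cells:
                hap0 = np.array([table.alleles[c][s0]
                                 for c, (s0, _) in zip(cols, side_alleles)],
                                dtype="S1")
                hap1 = np.array([table.alleles[c][s1]
                                 for c, (_, s1) in zip(cols, side_alleles)],
                                dtype="S1")
                ids = table.cell_ids
                blocks.append(SNPBlock(
                    table.gene_id, pos[np.array(cols)], hap0, hap1,
                    [ids[i] for i in np.flatnonzero(assign == 0)],
                    [ids[i] for i in np.flatnonzero(assign == 1)]))
        s = t if t > s + len(cols) - 1 else s + len(cols)
    return blocks


def block_haplotype_consensus(block: SNPBlock, aln: GeneAlignment,
                              species_cells: dict[str, list[str]]) -> dict:
    """Map block haplotypes onto other species' majority-rule consensus.

    For each species with coverage at the block columns, computes the
    consensus base per column and the divergence (mismatches / columns) of
    each haplotype from it; fills ``block.d_to_other`` and returns it.
    Species with no coverage are omitted.
    """
    for sp, cells in species_cells.items():
        sub = aln.subset(cells)
        if sub.n_seqs == 0:
            continue
        cons = consensus_sequence(sub)[block.columns]
        scorable = cons != b"N"
        n = int(scorable.sum())
        if n == 0:
            continue
        d1 = float((block.haplotype_1[scorable] != cons[scorable]).sum()) / n
        d2 = float((block.haplotype_2[scorable] != cons[scorable]).sum()) / n
        block.d_to_other[sp] = (d1, d2)
    return block.d_to_other


@dataclass
class BlockLinkage:
    """r^2 between haplotype-membership indicators for block pairs, plus the
    fully unlinked permutation control over the same pairs."""

    data_r2: np.ndarray
    control_r2: np.ndarray

    @property
    def mean_data(self) -> float:
        return float(np.mean(self.data_r2))

    @property
    def mean_control(self) -> float:
        return float(np.mean(self.control_r2))

    @property
    def se_data(self) -> float:
        return float(np.std(self.data_r2, ddof=1) / np.sqrt(self.data_r2.size))

    @property
    def se_control(self) -> float:
        return float(np.std(self.control_r2, ddof=1)
                     / np.sqrt(self.control_r2.size))


def _indicator_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    if x.std() == 0 or y.std() == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def inter_block_linkage(blocks, min_joint: int = DEFAULT_MIN_JOINT,
                        seed: int = 0, n_perm: int = 10,
                        same_gene: bool = True) -> BlockLinkage:
    """r^2 between haplotype indicators for every qualifying block pair.

    The control permutes each block's cell partition independently
    (preserving haplotype frequencies and per-cell coverage) *n_perm* times
    and pools the resulting r^2 values.  Set ``same_gene=False`` to restrict
    to block pairs from different genes.
    """
    rng = np.random.default_rng(seed)
    assigns = [b.assignment() for b in blocks]
    pairs = []
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            if not same_gene and blocks[i].gene_id == blocks[j].gene_id:
                continue
            shared = sorted(set(assigns[i]) & set(assigns[j]))
            if len(shared) >= min_joint:
                pairs.append((i, j, shared))
    if not pairs:
        raise ValueError("no block pairs with enough jointly covered cells")
    data = []
    for i, j, shared in pairs:
        x = np.array([assigns[i][c] for c in shared], dtype=float)
        y = np.array([assigns[j][c] for c in shared], dtype=float)
        r2 = _indicator_r2(x, y)
        if r2 is not None:
            data.append(r2)
    control = []
    for _ in range(n_perm):
        perm = []
        for b, a in zip(blocks, assigns):
            cells = list(a)
            vals = rng.permutation([a[c] for c in cells])
            perm.append(dict(zip(cells, vals)))
        for i, j, shared in pairs:
            x = np.array([perm[i][c] for c in shared], dtype=float)
            y = np.array([perm[j][c] for c in shared], dtype=float)
            r2 = _indicator_r2(x, y)
            if r2 is not None:
                control.append(r2)
    if not data or not control:
        raise ValueError("all qualifying pairs degenerate (constant indicator)")
    return BlockLinkage(np.array(data), np.array(control))
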