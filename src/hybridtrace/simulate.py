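"""Forward simulator for a multi-species bacterial population with
hybridization, selective sweeps, and single-cell (SAG) missingness.

The scenario: a common ancestor diverged into 2-4 species during spatial
isolation; the species later colonized the same habitat and began exchanging
core-gene sequence by homologous recombination.  Each simulated gene carries

* between-species divergence from independent substitutions on a star-like
  species tree (all-site target ``between_div``, fourfold-degenerate-site
  target ``between_div_syn``);
* within-species diversity from a per-species, per-gene Kingman coalescent
  whose mutations are restricted to fourfold-degenerate sites, so synonymous
  diversity targets are exact;
* optional planted whole-gene transfers, sub-gene transfers, and hard/soft
  selective sweeps, all recorded in a :class:`TruthTable`;
* gene-wise missingness: each gene is observed in a cell independently with
  probability equal to the cell's completeness.

Everything is deterministic given the seed.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .classify import TransferEvent
from .diversity import FOURFOLD_PREFIXES
from .io_core import (CellRecord, GeneAlignment, SPECIES_NAMES,
                      write_cells_tsv, write_gene_alignments)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_PREFIXES = sorted(FOURFOLD_PREFIXES)


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Study-condition parameters for :func:`simulate_population`.

    Divergence scales: ``within_div`` is the target synonymous (4D-site)
    diversity within a species; ``between_div`` the all-site divergence
    between species; ``between_div_syn`` the 4D-site divergence between
    species (synonymous sites diverge faster because nonsynonymous changes
    are purged, and the trough cutoff d_trough acts on this scale).
    """

    n_species: int = 2
    n_genes: int = 100
    gene_length_bp: int = 300
    within_div: float = 0.04
    between_div: float = 0.15
    between_div_syn: float = 0.30
    backbone_frac: float = 0.0
    backbone_ratio: float = 0.01     # backbone theta = within_div * this
    n_cells_per_species: tuple = (30, 30)
    completeness_mean: float = 0.3
    completeness_range: tuple = (0.05, 0.95)
    whole_gene_transfer_rate: float = 0.0   # per-gene probability
    subgene_transfer_rate: float = 0.0      # per-gene expected event count
    transfer_freq_range: tuple = (0.1, 0.9)
    subgene_len_range: tuple = (30, 300)
    sweep_spec: tuple = ()           # (gene_index, "hard"|"soft", n_founders)
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 2 <= self.n_species <= 4:
            raise ValueError(f"n_species must be in 2..4, got {self.n_species}")
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be positive, got {self.n_genes}")
        if self.gene_length_bp % 3 != 0 or self.gene_length_bp < 3:
            raise ValueError(
                f"gene_length_bp must be a positive multiple of 3, got "
                f"{self.gene_length_bp}")
        for name in ("within_div", "between_div", "between_div_syn",
                     "backbone_frac", "backbone_ratio", "error_rate",
                     "whole_gene_transfer_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.subgene_transfer_rate < 0:
            raise ValueError("subgene_transfer_rate must be >= 0")
        if self.between_div <= self.within_div:
            raise ValueError(
                f"between_div ({self.between_div}) must exceed within_div "
                f"({self.within_div})")
        if 3 * self.between_div < self.between_div_syn:
            raise ValueError(
                "between_div_syn exceeds 3*between_div: nonsynonymous rate "
                "would be negative")
        counts = self.cells_per_species()
        if len(counts) != self.n_species or any(c < 1 for c in counts):
            raise ValueError(
                f"n_cells_per_species must give >=1 cell for each of "
                f"{self.n_species} species, got {self.n_cells_per_species}")
        lo, hi = self.completeness_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(
                f"completeness_range must satisfy 0<=lo<=hi<=1, got {lo},{hi}")
        if not lo <= self.completeness_mean <= hi:
            raise ValueError(
                f"completeness_mean {self.completeness_mean} outside "
                f"completeness_range {self.completeness_range}")
        for locus, mode, nf in self.sweep_spec:
            if mode not in ("hard", "soft"):
                raise ValueError(f"sweep_spec: unknown mode {mode!r}")
            if mode == "hard" and nf != 1:
                raise ValueError("sweep_spec: hard sweep requires n_founders=1")
            if mode == "soft" and nf < 2:
                raise ValueError("sweep_spec: soft sweep requires n_founders>=2")
            if not 0 <= locus < self.n_genes:
                raise ValueError(f"sweep_spec: locus {locus} out of range")

    def cells_per_species(self) -> tuple:
        c = self.n_cells_per_species
        if isinstance(c, int):
            return (c,) * self.n_species
        return tuple(c)


@dataclass
class BlockTruth:
    gene_id: str
    start: int
    end: int
    donor: str
    carriers: list[str]


@dataclass
class SweepTruth:
    gene_id: str
    mode: str
    n_founders: int
    donor: str
    recipient: str


@dataclass
class TruthTable:
    """Ground truth of a simulation: per-(cell, gene) ancestry segments plus
    every planted transfer, sweep, and sub-gene block.

    Segments are 0-based half-open bp intervals that tile [0, gene_length)
    without overlap for every (cell, gene).
    """

    segments: dict = field(default_factory=dict)   # (cell,gene) -> [(s,e,sp)]
    transfers: list = field(default_factory=list)
    sweeps: list = field(default_factory=list)
    blocks: list = field(default_factory=list)

    def set_ancestry(self, cell: str, gene: str, start: int, end: int,
                     origin: str) -> None:
        """Overwrite [start, end) of a cell's gene with a new origin."""
        if start >= end:
            return
        key = (cell, gene)
        segs = self.segments.get(key, [])
        out = []
        for s, e, sp in segs:
            if e <= start or s >= end:
                out.append((s, e, sp))
            else:
                if s < start:
                    out.append((s, start, sp))
                if e > end:
                    out.append((end, e, sp))
        out.append((start, end, origin))
        out.sort()
        # merge adjacent same-origin segments
        merged = [out[0]]
        for s, e, sp in out[1:]:
            ps, pe, psp = merged[-1]
            if s == pe and sp == psp:
                merged[-1] = (ps, e, sp)
            else:
                merged.append((s, e, sp))
        self.segments[key] = merged

    def to_json(self, path) -> None:
        payload = {
            "segments": {f"{c}|{g}": [list(s) for s in segs]
                         for (c, g), segs in sorted(self.segments.items())},
            "transfers": [
                {"gene_id": t.gene_id, "donor": t.donor,
                 "recipient": t.recipient, "carriers": t.carriers,
                 "frequency": t.frequency, "flags": t.flags}
                for t in self.transfers],
            "sweeps": [asdict(s) for s in self.sweeps],
            "blocks": [asdict(b) for b in self.blocks],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        tt = cls()
        for key, segs in payload["segments"].items():
            c, g = key.split("|")
            tt.segments[(c, g)] = [tuple(s) for s in segs]
        tt.transfers = [TransferEvent(**t) for t in payload["transfers"]]
        tt.sweeps = [SweepTruth(**s) for s in payload["sweeps"]]
        tt.blocks = [BlockTruth(**b) for b in payload["blocks"]]
        return tt


# ---------------------------------------------------------------------------
# Low-level building blocks
# ---------------------------------------------------------------------------

def _branch_substitution_prob(d: float) -> float:
    """Per-branch substitution probability giving observed pairwise
    divergence *d* between two star-tree branches (coincident-hit aware)."""
    if d == 0:
        return 0.0
    disc = 4.0 - 16.0 * d / 3.0
    if disc < 0:
        raise ValueError(f"target divergence {d} not attainable")
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def _mutate_bases(current: np.ndarray, rng) -> np.ndarray:
    """Random base different from each current base."""
    idx = np.searchsorted(_BASES, current)
    return _BASES[(idx + rng.integers(1, 4, size=current.shape)) % 4]


def coalescent_branches(n: int, rng) -> tuple[list, np.ndarray]:
    """Branches of a Kingman coalescent genealogy for *n* samples.

    Returns (leaf index arrays, branch lengths in coalescent units); the root
    lineage is omitted (mutations above the root are invisible).
    """
    leaves = [np.array([i]) for i in range(n)]
    acc = [0.0] * n
    out_leaves: list[np.ndarray] = []
    out_lens: list[float] = []
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        for i in range(k):
            acc[i] += t
        i, j = sorted(rng.choice(k, size=2, replace=False))
        out_leaves.append(leaves[i]); out_lens.append(acc[i])
        out_leaves.append(leaves[j]); out_lens.append(acc[j])
        leaves[i] = np.concatenate([leaves[i], leaves[j]])
        acc[i] = 0.0
        del leaves[j]; del acc[j]
        k -= 1
    return out_leaves, np.asarray(out_lens)


def _fourfold_positions(seq: np.ndarray) -> np.ndarray:
    """Third-codon positions with fourfold-degenerate prefix in *seq*."""
    L = seq.size
    out = []
    for start in range(0, L - 2, 3):
        if seq[start] + seq[start + 1] in FOURFOLD_PREFIXES:
            out.append(start + 2)
    return np.asarray(out, dtype=int)


def _coalescent_matrix(consensus: np.ndarray, n: int, theta: float,
                       sites: np.ndarray, rng) -> np.ndarray:
    """Per-cell sequences: consensus + coalescent mutations at *sites*."""
    mat = np.tile(consensus, (n, 1))
    if n < 2 or theta <= 0 or sites.size == 0:
        return mat
    br_leaves, br_lens = coalescent_branches(n, rng)
    total = float(br_lens.sum())
    n_mut = rng.poisson(theta / 2.0 * total * sites.size)
    if n_mut == 0:
        return mat
    which = rng.choice(len(br_lens), size=n_mut, p=br_lens / total)
    where = rng.choice(sites, size=n_mut)
    for b, pos in zip(which, where):
        derived = _mutate_bases(consensus[pos:pos + 1], rng)[0]
        mat[br_leaves[b], pos] = derived
    return mat


# ---------------------------------------------------------------------------
# Planted events (public operations)
# ---------------------------------------------------------------------------

def inject_transfer(aln: GeneAlignment, donor_species: str, recipient_cells,
                    interval: tuple[int, int], species_of, rng,
                    truth: TruthTable | None = None) -> GeneAlignment:
    """Copy a donor allele over *interval* (0-based half-open) into the
    recipient cells, in place.

    A whole-gene transfer is an interval covering the full gene.  The donor
    allele is one randomly chosen donor-species sequence from the alignment.
    Empty recipient sets and zero-length intervals are no-ops (warned).
    """
    start, end = interval
    if not 0 <= start <= end <= aln.length:
        raise ValueError(f"interval {interval} outside gene of length "
                         f"{aln.length}")
    recipient_cells = list(recipient_cells)
    if not recipient_cells:
        warnings.warn(f"gene {aln.gene_id}: empty recipient set, no-op")
        return aln
    if start == end:
        return aln
    idx = aln.row_index()
    donors = [c for c in aln.cell_ids if species_of.get(c) == donor_species]
    if not donors:
        raise ValueError(f"gene {aln.gene_id}: no {donor_species} sequence "
                         "to donate")
    founder = donors[rng.integers(0, len(donors))]
    allele = aln.matrix[idx[founder], start:end].copy()
    for cell in recipient_cells:
        aln.matrix[idx[cell], start:end] = allele
        if truth is not None:
            truth.set_ancestry(cell, aln.gene_id, start, end, donor_species)
    if truth is not None:
        recipients = sorted({species_of.get(c, "?") for c in recipient_cells})
        event = TransferEvent(aln.gene_id, donor_species, recipients[0],
                              sorted(recipient_cells))
        if (start, end) == (0, aln.length):
            event.flags.append("whole_gene")
            truth.transfers.append(event)
        else:
            truth.blocks.append(BlockTruth(aln.gene_id, start, end,
                                           donor_species,
                                           sorted(recipient_cells)))
    return aln


def apply_sweep(aln: GeneAlignment, donor_species: str, recipient_species: str,
                mode: str, n_founders: int, species_of, rng,
                post_sweep_mut_rate: float = 0.0,
                truth: TruthTable | None = None) -> GeneAlignment:
    """Sweep donor alleles through every recipient-species cell, in place.

    All recipient cells end up descending from *n_founders* distinct donor
    alleles (mode ``hard`` requires exactly one founder, ``soft`` at least
    two), plus optional post-sweep per-site mutations.  A hard sweep with
    zero post-sweep mutation leaves pi_S = 0 among recipients.
    """
    if mode == "hard" and n_founders != 1:
        raise ValueError("hard sweep requires n_founders=1")
    if mode == "soft" and n_founders < 2:
        raise ValueError("soft sweep requires n_founders>=2")
    idx = aln.row_index()
    donors = [c for c in aln.cell_ids if species_of.get(c) == donor_species]
    recipients = [c for c in aln.cell_ids
                  if species_of.get(c) == recipient_species]
    if n_founders > len(donors):
        raise ValueError(
            f"gene {aln.gene_id}: n_founders={n_founders} exceeds donor "
            f"sample size {len(donors)}")
    founders = rng.choice(len(donors), size=n_founders, replace=False)
    alleles = [aln.matrix[idx[donors[f]]].copy() for f in founders]
    assignment = rng.integers(0, n_founders, size=len(recipients))
    for cell, a in zip(recipients, assignment):
        row = alleles[a].copy()
        if post_sweep_mut_rate > 0:
            hit = rng.random(row.size) < post_sweep_mut_rate
            row[hit] = _mutate_bases(row[hit], rng)
        aln.matrix[idx[cell]] = row
        if truth is not None:
            truth.set_ancestry(cell, aln.gene_id, 0, aln.length, donor_species)
    if truth is not None:
        truth.sweeps.append(SweepTruth(aln.gene_id, mode, n_founders,
                                       donor_species, recipient_species))
        truth.transfers.append(TransferEvent(
            aln.gene_id, donor_species, recipient_species, sorted(recipients),
            1.0, flags=["sweep", mode]))
    return aln


def sample_sags(alignments, completeness: dict[str, float],
                seed: int = 0) -> dict[str, GeneAlignment]:
    """Gene-wise SAG missingness: each gene is retained in each cell
    independently with probability equal to the cell's completeness."""
    for c, v in completeness.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"cell {c}: completeness {v} not in [0,1]")
    rng = np.random.default_rng(seed)
    out = {}
    for gene_id in sorted(alignments):
        aln = alignments[gene_id]
        keep = [c for c in aln.cell_ids
                if rng.random() < completeness.get(c, 0.0)]
        out[gene_id] = aln.subset(keep)
    return out


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------

def _draw_completeness(cfg: SimConfig, n: int, rng) -> np.ndarray:
    lo, hi = cfg.completeness_range
    if hi == lo:
        return np.full(n, lo)
    mean_unit = (cfg.completeness_mean - lo) / (hi - lo)
    conc = 4.0  # moderate spread, emulating the observed completeness range
    a = max(mean_unit * conc, 1e-6)
    b = max((1 - mean_unit) * conc, 1e-6)
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def simulate_population(cfg: SimConfig):
    """Simulate the full scenario; returns (alignments, cells, truth).

    The returned alignments are the *observed* (SAG-sampled) ones; set
    ``completeness_range=(1, 1)`` for fully observed genomes.  Byte-identical
    output is guaranteed for identical (config, seed).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    species = SPECIES_NAMES[:cfg.n_species]
    counts = cfg.cells_per_species()
    L = cfg.gene_length_bp

    cells: list[CellRecord] = []
    for sp, n in zip(species, counts):
        comp = _draw_completeness(cfg, n, rng)
        for i in range(n):
            cells.append(CellRecord(f"{sp}_{i:03d}", f"S{i % 2 + 1}", sp,
                                    float(comp[i])))
    species_of = {c.cell_id: c.species for c in cells}
    cells_by_sp = {sp: [c.cell_id for c in cells if c.species == sp]
                   for sp in species}

    d_syn = cfg.between_div_syn
    d_ns = max((3.0 * cfg.between_div - d_syn) / 2.0, 0.0)
    p_syn = _branch_substitution_prob(d_syn)
    p_ns = _branch_substitution_prob(d_ns)

    n_backbone = int(round(cfg.backbone_frac * cfg.n_genes))
    backbone = set(rng.choice(cfg.n_genes, size=n_backbone, replace=False))
    sweeps_at = {locus: (mode, nf) for locus, mode, nf in cfg.sweep_spec}

    truth = TruthTable()
    alignments: dict[str, GeneAlignment] = {}
    for g in range(cfg.n_genes):
        gene_id = f"{g:04d}"
        # ancestral gene: every codon fourfold degenerate at position 3
        n_codons = L // 3
        pref = rng.integers(0, len(_PREFIXES), size=n_codons)
        anc = np.empty(L, dtype="S1")
        for k, p in enumerate(pref):
            anc[3 * k] = _PREFIXES[p][0:1]
            anc[3 * k + 1] = _PREFIXES[p][1:2]
        anc[2::3] = _BASES[rng.integers(0, 4, size=n_codons)]

        mats = []
        for si, sp in enumerate(species):
            cons = anc.copy()
            hit = rng.random(L) < p_ns
            hit[2::3] = False
            cons[hit] = _mutate_bases(cons[hit], rng)
            sites4d = _fourfold_positions(cons)
            hit_syn = rng.random(sites4d.size) < p_syn
            cons[sites4d[hit_syn]] = _mutate_bases(cons[sites4d[hit_syn]], rng)
            theta = cfg.within_div
            if si == 0 and g in backbone:
                theta *= cfg.backbone_ratio
            mats.append(_coalescent_matrix(cons, counts[si], theta,
                                           _fourfold_positions(cons), rng))
        cell_ids = [c for sp in species for c in cells_by_sp[sp]]
        aln = GeneAlignment(gene_id, cell_ids, np.vstack(mats))
        for c in cell_ids:
            truth.segments[(c, gene_id)] = [(0, L, species_of[c])]

        if g in sweeps_at:
            mode, nf = sweeps_at[g]
            apply_sweep(aln, species[1], species[0], mode, nf, species_of,
                        rng, truth=truth)
        else:
            if rng.random() < cfg.whole_gene_transfer_rate:
                _plant_transfer(aln, species, cells_by_sp, species_of,
                                cfg, (0, L), rng, truth)
            for _ in range(rng.poisson(cfg.subgene_transfer_rate)):
                lo, hi = cfg.subgene_len_range
                length = int(rng.integers(lo, min(hi, L) + 1))
                start = int(rng.integers(0, L - length + 1))
                _plant_transfer(aln, species, cells_by_sp, species_of,
                                cfg, (start, start + length), rng, truth)
        if cfg.error_rate > 0:
            hit = rng.random(aln.matrix.shape) < cfg.error_rate
            aln.matrix[hit] = _mutate_bases(aln.matrix[hit], rng)
        alignments[gene_id] = aln

    completeness = {c.cell_id: c.completeness for c in cells}
    observed = sample_sags(alignments, completeness,
                           seed=int(rng.integers(0, 2 ** 31)))
    return observed, cells, truth


def _plant_transfer(aln, species, cells_by_sp, species_of, cfg, interval,
                    rng, truth):
    donor, recipient = rng.choice(len(species), size=2, replace=False)
    donor, recipient = species[donor], species[recipient]
    recip_cells = cells_by_sp[recipient]
    lo, hi = cfg.transfer_freq_range
    freq = rng.uniform(lo, hi)
    n_carr = max(1, int(round(freq * len(recip_cells))))
    carriers = [recip_cells[i] for i in
                rng.choice(len(recip_cells), size=n_carr, replace=False)]
    inject_transfer(aln, donor, carriers, interval, species_of, rng, truth)
    if interval == (0, aln.length) and truth.transfers:
        truth.transfers[-1].frequency = n_carr / len(recip_cells)


def write_simulation(out_dir, alignments, cells, truth,
                     cfg: SimConfig | None = None) -> None:
    """Write FASTA-per-gene, cells.tsv, truth.json (and config.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_alignments(alignments, out / "alignments")
    write_cells_tsv(cells, out / "cells.tsv")
    truth.to_json(out / "truth.json")
    if cfg is not None:
        payload = asdict(cfg)
        (out / "config.json").write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Neutral-coalescent linkage anchor
# ---------------------------------------------------------------------------

def simulate_neutral_ld(n_loci: int, sample_size: int, theta: float = 3.0,
                        seed: int = 0, cross_locus: bool = False) -> float:
    """sigma_d^2 for tightly linked site pairs under the neutral coalescent.

    Simulates *n_loci* independent non-recombining loci (Kingman genealogy
    plus infinite-sites Poisson mutations with per-locus theta), pools all
    within-locus segregating-site pairs, and returns sigma_d^2 as a ratio of
    averages.  Converges to 5/11 as n_loci grows.  With ``cross_locus=True``
    sites are instead paired across consecutive independent loci, giving the
    finite-sample unlinked baseline.
    """
    if n_loci < 1 or sample_size < 2:
        raise ValueError("need n_loci >= 1 and sample_size >= 2")
    rng = np.random.default_rng(seed)
    num = den = 0.0
    n_pairs = 0
    prev = None
    for _ in range(n_loci):
        br_leaves, br_lens = coalescent_branches(sample_size, rng)
        total = float(br_lens.sum())
        S = rng.poisson(theta / 2.0 * total)
        if S == 0:
            continue
        M = np.zeros((sample_size, S), dtype=bool)
        which = rng.choice(len(br_lens), size=S, p=br_lens / total)
        for col, b in enumerate(which):
            M[br_leaves[b], col] = True
        f = M.mean(axis=0)
        if cross_locus:
            if prev is not None:
                fp = prev.mean(axis=0)
                fab = (prev.astype(np.float64).T @ M) / sample_size
                D = fab - np.outer(fp, f)
                num += float((D ** 2).sum())
                den += float(np.outer(fp * (1 - fp), f * (1 - f)).sum())
                n_pairs += D.size
            prev = M
            continue
        if S < 2:
            continue
        fab = (M.astype(np.float64).T @ M) / sample_size
        D = fab - np.outer(f, f)
        iu = np.triu_indices(S, k=1)
        num += float((D[iu] ** 2).sum())
        pq = f * (1 - f)
        den += float(np.outer(pq, pq)[iu].sum())
        n_pairs += iu[0].size
    if n_pairs == 0 or den == 0:
        raise ValueError(
            "no segregating site pairs; increase n_loci or theta")
    return num / den
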