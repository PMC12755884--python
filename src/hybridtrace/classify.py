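"""Per-gene species clustering and hybrid-locus classification.

Within one orthogroup alignment, sequences from asexually diverged species
form well-separated clusters: intra-cluster divergence at the within-species
level (~2%) and inter-cluster divergence at the between-species level
(~15%).  Clusters are cut from an average-linkage dendrogram at d_c = 0.075,
the gap observed between the two scales, and accepted only if internally
tight (< d_c) and separated from every other cluster (>= d_c).

Loci are then classified as

* ``non_hybrid``     -- 2-3 accepted clusters, each pure-species, with sizes
                        roughly proportional to the species' expected counts;
* ``simple_hybrid``  -- distinct clusters but at least one mixes species
                        (a whole-gene transfer), or a surplus cluster from an
                        unknown donor;
* ``mosaic_hybrid``  -- no distinct species clusters (sub-gene mixing), or a
                        single dominant mixed cluster.

Transfer direction follows the majority species of the host cluster:
minority-species members are inferred to carry a sequence donated by the
majority species.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_core import GeneAlignment, divergence_matrix

DEFAULT_D_C = 0.075
DEFAULT_MOSAIC_FRAC = 0.8
DEFAULT_SIZE_SIGMAS = 3.0

NON_HYBRID = "non_hybrid"
SIMPLE_HYBRID = "simple_hybrid"
MOSAIC_HYBRID = "mosaic_hybrid"

UNKNOWN_DONOR = "X"


@dataclass
class GeneClusterSet:
    """Accepted species clusters of one gene alignment."""

    gene_id: str
    clusters: list[list[str]]
    max_intra: list[float]
    min_inter: np.ndarray          # pairwise min divergence between clusters
    unassigned: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def n_clustered(self) -> int:
        return sum(len(c) for c in self.clusters)


@dataclass
class LocusClass:
    gene_id: str
    locus_class: str
    flags: list[str] = field(default_factory=list)


@dataclass
class TransferEvent:
    """One inferred (or planted) whole-gene hybridization event."""

    gene_id: str
    donor: str
    recipient: str
    carriers: list[str]
    frequency: float = float("nan")
    flags: list[str] = field(default_factory=list)

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


def cluster_gene(aln: GeneAlignment, d_c: float = DEFAULT_D_C,
                 min_cluster: int = 2, method: str = "average",
                 sites=None) -> GeneClusterSet:
    """Average-linkage hierarchical clustering of pairwise divergences,
    cut at *d_c*.

    Clusters are accepted when their maximum intra-cluster divergence is
    below d_c and their minimum divergence to every other accepted cluster is
    at least d_c; sequences in rejected or undersized clusters are flagged
    unassigned.  When every pairwise divergence is below d_c a single cluster
    is returned.
    """
    if aln.n_seqs < 2:
        return GeneClusterSet(aln.gene_id, [list(aln.cell_ids)], [0.0],
                              np.zeros((1, 1)))
    d = divergence_matrix(aln, sites=sites)
    # sort order-independence: cluster on the matrix, not the input order
    condensed = squareform(d, checks=False)
    Z = linkage(condensed, method=method)
    labels = fcluster(Z, t=d_c, criterion="distance")
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    # deterministic ordering: largest first, ties by smallest member index
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    accepted, intra, unassigned = [], [], []
    for g in ordered:
        if len(g) < min_cluster:
            unassigned.extend(g)
            continue
        sub = d[np.ix_(g, g)]
        mx = float(sub.max())
        if mx >= d_c:
            unassigned.extend(g)
            continue
        accepted.append(g)
        intra.append(mx)
    # separation constraint between accepted clusters
    changed = True
    while changed and len(accepted) > 1:
        changed = False
        for a in range(len(accepted)):
            for b in range(a + 1, len(accepted)):
                inter = d[np.ix_(accepted[a], accepted[b])].min()
                if inter < d_c:
                    # drop the smaller (later-ordered) cluster
                    unassigned.extend(accepted.pop(b))
                    intra.pop(b)
                    changed = True
                    break
            if changed:
                break
    k = len(accepted)
    min_inter = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            v = float(d[np.ix_(accepted[a], accepted[b])].min())
            min_inter[a, b] = min_inter[b, a] = v
    ids = aln.cell_ids
    return GeneClusterSet(
        aln.gene_id,
        [[ids[i] for i in g] for g in accepted],
        intra,
        min_inter,
        [ids[i] for i in sorted(unassigned)],
    )


def expected_cluster_sizes(aln: GeneAlignment, cells) -> dict[str, float]:
    """Expected per-species sequence counts at a gene: the sum of the
    species' cells' completeness (gene presence probability proxy)."""
    out: dict[str, float] = {}
    for c in cells:
        out[c.species] = out.get(c.species, 0.0) + c.completeness
    return out


def _majority_species(members, species_of) -> str | None:
    """Majority (>50%) species of a cluster, or None on a tie."""
    counts: dict[str, int] = {}
    for m in members:
        sp = species_of.get(m, "unassigned")
        counts[sp] = counts.get(sp, 0) + 1
    best = max(counts.values())
    winners = [sp for sp, n in counts.items() if n == best]
    if len(winners) > 1 or best * 2 <= len(members):
        return None
    return winners[0]


def classify_locus(clusters: GeneClusterSet, species_of,
                   expected_sizes: dict[str, float],
                   mosaic_frac: float = DEFAULT_MOSAIC_FRAC,
                   size_sigmas: float = DEFAULT_SIZE_SIGMAS) -> LocusClass:
    """Classify one core gene as non-hybrid / simple hybrid / mosaic hybrid."""
    gene = clusters.gene_id
    total = clusters.n_clustered + len(clusters.unassigned)
    k = clusters.n_clusters
    flags: list[str] = []
    if total == 0 or k == 0:
        return LocusClass(gene, MOSAIC_HYBRID, ["no_accepted_clusters"])
    largest = max(clusters.clusters, key=len)
    largest_mixed = len({species_of.get(m) for m in largest}) > 1
    if k == 1:
        # no distinct species structure: a single (dominant) cluster, with
        # any remaining sequences unassigned scatter
        flag = ("dominant_mixed_cluster"
                if largest_mixed and len(largest) >= mosaic_frac * total
                else "single_cluster")
        return LocusClass(gene, MOSAIC_HYBRID, [flag])
    if k > 4:
        warnings.warn(f"gene {gene}: {k} clusters, unclassifiable; "
                      "treated as mosaic")
        return LocusClass(gene, MOSAIC_HYBRID, ["fragmented"])
    mixed = [len({species_of.get(m) for m in c}) > 1 for c in clusters.clusters]
    majorities = [_majority_species(c, species_of) for c in clusters.clusters]
    if any(mixed):
        return LocusClass(gene, SIMPLE_HYBRID, [])
    # all clusters pure: surplus clusters of an already-seen species point to
    # an unknown donor (still a simple hybrid locus)
    seen: set[str] = set()
    surplus = False
    for sp in majorities:
        if sp in seen:
            surplus = True
        seen.add(sp)
    if surplus or k == 4:
        return LocusClass(gene, SIMPLE_HYBRID, ["surplus_cluster"])
    for c, sp in zip(clusters.clusters, majorities):
        exp = expected_sizes.get(sp, 0.0)
        tol = size_sigmas * math.sqrt(max(exp, 1.0))
        if abs(len(c) - exp) > tol:
            flags.append(f"size_mismatch:{sp}")
    return LocusClass(gene, NON_HYBRID, flags)


def infer_transfers(clusters: GeneClusterSet, species_of,
                    expected_sizes: dict[str, float] | None = None,
                    gamma_species: str = "gamma") -> list[TransferEvent]:
    """Infer transfer direction and donor for a simple hybrid locus.

    Minority-species members of a majority-s cluster become an event with
    donor s.  A cluster containing the (single-cell) gamma species donates to
    every other member with the direction flagged unresolved.  A surplus
    pure cluster whose species already owns its own cluster is assigned to an
    unknown donor X.
    """
    events: list[TransferEvent] = []
    majorities = [_majority_species(c, species_of) for c in clusters.clusters]
    # canonical cluster per species = the largest one with that majority
    canonical: dict[str, int] = {}
    for i, sp in enumerate(majorities):
        if sp is None:
            continue
        if sp not in canonical or len(clusters.clusters[i]) > len(
                clusters.clusters[canonical[sp]]):
            canonical[sp] = i
    for i, (members, majority) in enumerate(
            zip(clusters.clusters, majorities)):
        has_gamma = any(species_of.get(m) == gamma_species for m in members)
        if has_gamma:
            carriers = [m for m in members
                        if species_of.get(m) != gamma_species]
            by_sp: dict[str, list[str]] = {}
            for m in carriers:
                by_sp.setdefault(species_of.get(m, "unassigned"), []).append(m)
            for sp, carr in sorted(by_sp.items()):
                events.append(TransferEvent(
                    clusters.gene_id, gamma_species, sp, sorted(carr),
                    flags=["direction_unresolved"]))
            continue
        if majority is None:
            warnings.warn(
                f"gene {clusters.gene_id}: cluster {i} has no majority "
                "species; event dropped")
            continue
        if canonical.get(majority) != i:
            # surplus cluster: unknown-donor hybridization into its species
            events.append(TransferEvent(
                clusters.gene_id, UNKNOWN_DONOR, majority, sorted(members)))
            continue
        by_sp = {}
        for m in members:
            sp = species_of.get(m, "unassigned")
            if sp != majority:
                by_sp.setdefault(sp, []).append(m)
        for sp, carr in sorted(by_sp.items()):
            events.append(TransferEvent(
                clusters.gene_id, majority, sp, sorted(carr)))
    return events


def hybrid_allele_frequency(event: TransferEvent, matrix, species_of) -> float:
    """Carriers / recipient-species cells with the gene present.

    *matrix* is an :class:`~hybridtrace.io_core.OrthogroupMatrix`.  Singleton
    events (one carrier) are flagged.  Returns NaN (undefined) when no
    recipient-species cell covers the gene.
    """
    if event.gene_id not in matrix.presence.index:
        raise KeyError(f"gene {event.gene_id} not in orthogroup matrix")
    row = matrix.presence.loc[event.gene_id]
    covered = [c for c in row.index
               if row[c] and species_of.get(c) == event.recipient]
    if not covered:
        return float("nan")
    freq = event.n_carriers / len(covered)
    if event.n_carriers == 1:
        event.flags.append("singleton")
    return float(freq)
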