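"""Alignment and metadata I/O, the orthogroup presence matrix, core-gene
calling, and whole-cell species assignment.

The atomic data unit throughout the package is a :class:`GeneAlignment`: one
per-orthogroup multiple-sequence alignment over single cells.  Because the
input genomes are single-amplified genomes (SAGs) with mean completeness
around 0.3, every per-gene alignment contains only a subset of the cells, and
all downstream statistics are written to tolerate that gene-wise missingness.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

#: Characters treated as missing data in alignment columns.
MISSING_CHARS = (b"-", b"N")

#: Canonical species labels, in the order the simulator creates them.
SPECIES_NAMES = ("alpha", "beta", "gamma", "delta")

#: Label for cells that are far from every supplied reference.
NOVEL_SPECIES = "novel"
UNASSIGNED = "unassigned"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def seq_to_array(seq) -> np.ndarray:
    """Convert a string/Seq to a 1-D byte array (dtype ``S1``), uppercased."""
    return np.frombuffer(str(seq).upper().encode("ascii"), dtype="S1").copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class GeneAlignment:
    """A per-orthogroup alignment: rows are cells, columns are positions.

    ``matrix`` has dtype ``S1`` over the alphabet {A,C,G,T,-,N}.  Coordinates
    are 0-based, half-open.  Duplicate ``cell_ids`` are permitted at read time
    (they are the evidence used to flag multi-copy orthogroups) but most
    statistics assume single-copy genes.
    """

    gene_id: str
    cell_ids: list[str]
    matrix: np.ndarray
    frame_offset: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise ValueError(f"gene {self.gene_id}: matrix must be 2-D")
        if len(self.cell_ids) != self.matrix.shape[0]:
            raise ValueError(
                f"gene {self.gene_id}: {len(self.cell_ids)} cell ids for "
                f"{self.matrix.shape[0]} rows"
            )

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def sequences(self) -> dict[str, str]:
        return {c: array_to_seq(row) for c, row in zip(self.cell_ids, self.matrix)}

    def coverage_mask(self) -> np.ndarray:
        """Boolean (n_seqs, length) array: True where a real base is present."""
        m = np.ones(self.matrix.shape, dtype=bool)
        for ch in MISSING_CHARS:
            m &= self.matrix != ch
        return m

    def duplicated_cells(self) -> set[str]:
        seen, dup = set(), set()
        for c in self.cell_ids:
            (dup if c in seen else seen).add(c)
        return dup

    def row_index(self) -> dict[str, int]:
        """cell_id -> first row index."""
        idx: dict[str, int] = {}
        for i, c in enumerate(self.cell_ids):
            idx.setdefault(c, i)
        return idx

    def subset(self, cell_ids) -> "GeneAlignment":
        """Restrict to the given cells (those present in the alignment)."""
        idx = self.row_index()
        keep = [c for c in cell_ids if c in idx]
        rows = [idx[c] for c in keep]
        return GeneAlignment(
            self.gene_id, keep, self.matrix[rows].copy(), self.frame_offset
        )

    @classmethod
    def from_sequences(cls, gene_id: str, mapping, frame_offset: int = 0):
        cell_ids = list(mapping)
        arrs = [seq_to_array(mapping[c]) for c in cell_ids]
        lengths = {a.size for a in arrs}
        if len(lengths) > 1:
            raise ValueError(f"gene {gene_id}: ragged sequence lengths {lengths}")
        return cls(gene_id, cell_ids, np.vstack(arrs), frame_offset)


@dataclass
class CellRecord:
    """One single-amplified genome: identity, sample, species, completeness."""

    cell_id: str
    sample_id: str
    species: str
    completeness: float

    def __post_init__(self):
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError(
                f"cell {self.cell_id}: completeness {self.completeness} not in [0,1]"
            )


def species_map(cells) -> dict[str, str]:
    """cell_id -> species label from a list of CellRecords."""
    return {c.cell_id: c.species for c in cells}


def cells_of_species(cells, species: str) -> list[str]:
    return [c.cell_id for c in cells if c.species == species]


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

def read_gene_alignments(directory) -> dict[str, GeneAlignment]:
    """Read one FASTA per gene from *directory* (``gene_<id>.fasta``).

    Sequences are uppercased and validated for equal length; a ragged file
    raises a ValueError naming the file and offending record.  An empty
    directory returns an empty dict with a warning.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"alignment directory not found: {directory}")
    paths = sorted(directory.glob("*.fasta")) + sorted(directory.glob("*.fa"))
    if not paths:
        warnings.warn(f"no FASTA files found in {directory}")
        return {}
    alignments: dict[str, GeneAlignment] = {}
    for path in paths:
        gene_id = path.stem
        if gene_id.startswith("gene_"):
            gene_id = gene_id[len("gene_"):]
        cell_ids, rows = [], []
        length = None
        for rec in SeqIO.parse(str(path), "fasta"):
            arr = seq_to_array(rec.seq)
            if length is None:
                length = arr.size
            elif arr.size != length:
                raise ValueError(
                    f"{path}: record '{rec.id}' has length {arr.size}, "
                    f"expected {length}"
                )
            cell_ids.append(rec.id)
            rows.append(arr)
        if not rows:
            warnings.warn(f"{path}: empty FASTA, skipped")
            continue
        alignments[gene_id] = GeneAlignment(gene_id, cell_ids, np.vstack(rows))
    return alignments


def write_gene_alignments(alignments, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for gene_id, aln in alignments.items():
        records = [
            SeqRecord(Seq(array_to_seq(row)), id=cell, description="")
            for cell, row in zip(aln.cell_ids, aln.matrix)
        ]
        SeqIO.write(records, str(directory / f"gene_{gene_id}.fasta"), "fasta")


def read_cells_tsv(path) -> list[CellRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str})
    return [
        CellRecord(r.cell_id, r.sample_id, r.species, float(r.completeness))
        for r in df.itertuples()
    ]


def write_cells_tsv(cells, path) -> None:
    pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "sample_id": [c.sample_id for c in cells],
            "species": [c.species for c in cells],
            "completeness": [c.completeness for c in cells],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Orthogroup presence matrix and core-gene calling
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupMatrix:
    """Binary genes x cells presence matrix plus per-cell completeness."""

    presence: pd.DataFrame          # bool, index gene_id, columns cell_id
    completeness: pd.Series         # index cell_id

    def __post_init__(self):
        missing = set(self.presence.columns) - set(self.completeness.index)
        if missing:
            raise ValueError(f"cells without completeness: {sorted(missing)[:5]}")


def build_orthogroup_matrix(alignments, cells) -> OrthogroupMatrix:
    cell_ids = [c.cell_id for c in cells]
    data = {
        g: [c in set(a.cell_ids) for c in cell_ids] for g, a in alignments.items()
    }
    presence = pd.DataFrame.from_dict(data, orient="index", columns=cell_ids)
    completeness = pd.Series(
        {c.cell_id: c.completeness for c in cells}, name="completeness"
    )
    return OrthogroupMatrix(presence, completeness)


def call_core_genes(matrix: OrthogroupMatrix, alpha_core: float = 1e-3,
                    multi_copy_genes=()) -> list[str]:
    """Call core genes from occupancy with a one-parameter binomial fit.

    A single-copy gene present in every genome is observed in each cell
    independently with probability equal to that cell's completeness; with n
    cells of mean completeness c-bar the observed count K is approximately
    Binomial(n, c-bar).  A gene is core iff its lower tail probability
    P(K <= k) >= *alpha_core*, i.e. the count is not significantly below the
    single-copy expectation.  Genes with multi-copy evidence (duplicated cell
    ids in the alignment) are excluded regardless of occupancy.
    """
    n = matrix.presence.shape[1]
    if n == 0:
        raise ValueError("orthogroup matrix has no cells")
    cbar = float(matrix.completeness.loc[matrix.presence.columns].mean())
    counts = matrix.presence.sum(axis=1)
    multi = set(multi_copy_genes)
    core = [
        g
        for g, k in counts.items()
        if g not in multi and stats.binom.cdf(k, n, cbar) >= alpha_core
    ]
    return sorted(core)


# ---------------------------------------------------------------------------
# Pairwise divergence and species assignment
# ---------------------------------------------------------------------------

def pairwise_divergence(a: np.ndarray, b: np.ndarray, sites=None) -> float:
    """Mismatches / compared sites, skipping positions where either sequence
    is '-' or 'N'.  Returns NaN when no site is comparable."""
    if sites is not None:
        a, b = a[sites], b[sites]
    ok = np.ones(a.shape, dtype=bool)
    for ch in MISSING_CHARS:
        ok &= (a != ch) & (b != ch)
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    return float((a[ok] != b[ok]).sum()) / n


def divergence_matrix(aln: GeneAlignment, sites=None,
                      fill_value: float = 1.0) -> np.ndarray:
    """Dense pairwise divergence matrix; incomparable pairs get *fill_value*."""
    n = aln.n_seqs
    cov = aln.coverage_mask()
    mat = aln.matrix
    if sites is not None:
        cov, mat = cov[:, sites], mat[:, sites]
    d = np.zeros((n, n))
    for i in range(n):
        both = cov[i] & cov[i + 1:]
        diff = (mat[i] != mat[i + 1:]) & both
        nb = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = diff.sum(axis=1) / nb
        vals = np.where(nb > 0, vals, fill_value)
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return d


def consensus_sequence(aln: GeneAlignment, cell_ids=None) -> np.ndarray:
    """Majority-rule consensus (ties broken alphabetically; all-missing
    columns become 'N')."""
    sub = aln if cell_ids is None else aln.subset(cell_ids)
    counts = np.stack([(sub.matrix == b).sum(axis=0) for b in _BASES])
    best = counts.argmax(axis=0)  # argmax takes the first (alphabetical) max
    cons = _BASES[best]
    cons = np.where(counts.sum(axis=0) == 0, np.array(b"N", dtype="S1"), cons)
    return cons


def assign_cell_species(alignments, references: dict[str, dict[str, object]],
                        d_split: float = 0.075) -> pd.DataFrame:
    """Assign each cell to the nearest reference genome, or flag it as novel.

    *references* maps species name -> {gene_id -> sequence}.  For each cell
    the mean per-gene divergence to each reference over shared genes is
    computed; the cell is labelled with the nearest reference if that
    divergence is below *d_split*, as ``novel`` if it is at least *d_split*
    from every reference, and ``unassigned`` when no gene is shared.
    """
    ref_arrays = {
        sp: {g: seq_to_array(s) if not isinstance(s, np.ndarray) else s
             for g, s in genes.items()}
        for sp, genes in references.items()
    }
    per_cell: dict[str, dict[str, list[float]]] = {}
    for gene_id, aln in alignments.items():
        idx = aln.row_index()
        for cell, row in idx.items():
            seq = aln.matrix[row]
            for sp, genes in ref_arrays.items():
                ref = genes.get(gene_id)
                if ref is None or ref.size != seq.size:
                    continue
                d = pairwise_divergence(seq, ref)
                if not np.isnan(d):
                    per_cell.setdefault(cell, {}).setdefault(sp, []).append(d)
    rows = []
    species_names = sorted(references)
    for cell, divs in sorted(per_cell.items()):
        means = {sp: float(np.mean(divs[sp])) if sp in divs else float("nan")
                 for sp in species_names}
        finite = {sp: v for sp, v in means.items() if not np.isnan(v)}
        if not finite:
            label = UNASSIGNED
        else:
            nearest = min(finite, key=finite.get)
            label = nearest if finite[nearest] < d_split else NOVEL_SPECIES
        rows.append({"cell_id": cell, "species": label,
                     **{f"div_{sp}": means[sp] for sp in species_names}})
    return pd.DataFrame(rows).set_index("cell_id")
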