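"""sigma_d^2 / r^2 against an exact rational brute-force oracle, decay
curves, permutation controls, and the decay-model fit."""
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hybridtrace.linkage as lk
from hybridtrace.io_core import GeneAlignment, cells_of_species
from hybridtrace.simulate import SimConfig, simulate_population
from .conftest import make_alignment

MISSING = (b"-", b"N")


# ---------------------------------------------------------------------------
# Brute-force oracle: exact rational haplotype enumeration
# ---------------------------------------------------------------------------

def brute_force_sigma_d2(rows, min_mac=1, min_joint=1):
    """Enumerate haplotypes of every bi-allelic column pair with Fractions."""
    mat = np.array([list(r.encode()) for r in rows], dtype=np.uint8)
    mat = mat.view("S1")
    n, L = mat.shape
    cols = []
    for j in range(L):
        col = mat[:, j]
        covered = [i for i in range(n) if col[i] not in MISSING]
        alleles = sorted({bytes(col[i]) for i in covered})
        if len(alleles) != 2:
            continue
        minor = min(sum(bytes(col[i]) == a for i in covered)
                    for a in alleles)
        if minor < min_mac:
            continue
        cols.append((j, alleles[0]))
    num = Fraction(0)
    den = Fraction(0)
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            (ja, aa), (jb, ab) = cols[a], cols[b]
            joint = [i for i in range(n)
                     if mat[i, ja] not in MISSING and mat[i, jb] not in MISSING]
            if len(joint) < min_joint:
                continue
            m = len(joint)
            fa = Fraction(sum(bytes(mat[i, ja]) == aa for i in joint), m)
            fb = Fraction(sum(bytes(mat[i, jb]) == ab for i in joint), m)
            fab = Fraction(sum(bytes(mat[i, ja]) == aa
                               and bytes(mat[i, jb]) == ab for i in joint), m)
            num += (fab - fa * fb) ** 2
            den += fa * (1 - fa) * fb * (1 - fb)
    return num, den


def random_toy(rng, n_cells, n_sites, missing_frac=0.15):
    """Random toy alignment (<=10 cells x <=20 sites) with missingness."""
    bases = np.array([b"A", b"C"])
    mat = bases[rng.integers(0, 2, (n_cells, n_sites))]
    miss = rng.random((n_cells, n_sites)) < missing_frac
    mat[miss] = b"-"
    return ["".join(x.decode() for x in row) for row in mat]


class TestSigmaD2Oracle:
    def pairs_from_rows(self, rows, min_mac=1, min_joint=1):
        aln = make_alignment("t", {f"c{i}": r for i, r in enumerate(rows)})
        return lk.site_pairs(aln, min_joint=min_joint, min_mac=min_mac)

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_agreement_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_toy(rng, int(rng.integers(4, 11)),
                          int(rng.integers(4, 21)))
        num, den = brute_force_sigma_d2(rows)
        pairs = self.pairs_from_rows(rows)
        if den == 0:
            if pairs:
                with pytest.raises(ValueError):
                    lk.sigma_d_squared(pairs)
            return
        assert lk.sigma_d_squared(pairs) == pytest.approx(
            float(num / den), abs=1e-12)

    def test_perfect_linkage_single_pair(self):
        p = lk.SitePairStats(0.5, 0.5, 0.5, 8)   # AB=4, ab=4
        assert lk.sigma_d_squared([p]) == pytest.approx(1.0)
        assert lk.r_squared(p) == pytest.approx(1.0)

    def test_independent_pair_is_zero(self):
        p = lk.SitePairStats(0.5, 0.5, 0.25, 8)  # f_ab = f_a f_b
        assert lk.sigma_d_squared([p]) == 0.0
        assert lk.r_squared(p) == 0.0

    def test_hand_enumerated_pair(self):
        # counts AB=3, Ab=1, aB=1, ab=3: D = 3/8 - 1/4 = 1/8
        p = lk.SitePairStats(0.5, 0.5, Fraction(3, 8), 8)
        assert lk.sigma_d_squared([p]) == pytest.approx(0.25)
        assert lk.r_squared(p) == pytest.approx(0.25)

    def test_monomorphic_pair_errors(self):
        p = lk.SitePairStats(0.0, 0.5, 0.0, 8)
        with pytest.raises(ValueError):
            lk.sigma_d_squared([p])
        with pytest.raises(ValueError):
            lk.r_squared(p)

    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6),
           st.integers(0, 6))
    @settings(derandomize=True, max_examples=200)
    def test_bounds_hold_for_any_haplotype_counts(self, nab, naB, nAb, nAB):
        n = nab + naB + nAb + nAB
        if n == 0:
            return
        fa = (nAB + nAb) / n
        fb = (nAB + naB) / n
        p = lk.SitePairStats(fa, fb, nAB / n, n)
        if p.denom == 0:
            return
        assert 0.0 <= lk.r_squared(p) <= 1.0 + 1e-12
        assert 0.0 <= lk.sigma_d_squared([p]) <= 1.0 + 1e-12


class TestSNPTable:
    def test_triallelic_excluded(self):
        aln = make_alignment("g", {"a": "AAA", "b": "ACA", "c": "AGA",
                                   "d": "ACA"})
        tab = lk.snp_table(aln, min_mac=1)
        assert tab.n_snps == 0 and tab.n_multiallelic == 1

    def test_mac_filter(self):
        aln = make_alignment("g", {"a": "AA", "b": "AC", "c": "AC",
                                   "d": "CA"})
        # col0: minor C x1 (dropped at mac=2); col1: minor C x2 (kept)
        assert lk.snp_table(aln, min_mac=2).n_snps == 1
        assert lk.snp_table(aln, min_mac=1).n_snps == 2


class TestCurveAndControls:
    def test_clonal_data_flat_at_high_linkage(self):
        # two clonal lineages, no recombination: every SNP pair is perfectly
        # linked so sigma_d^2 is flat in x at ~1
        rng = np.random.default_rng(0)
        L = 400
        bases = np.frombuffer(b"ACGT", dtype="S1")
        h1 = bases[rng.integers(0, 4, L)]
        h2 = h1.copy()
        hit = rng.random(L) < 0.1
        h2[hit] = bases[(np.searchsorted(bases, h2[hit]) + 1) % 4]
        seqs = {f"a{i}": h1.tobytes().decode() for i in range(10)}
        seqs.update({f"b{i}": h2.tobytes().decode() for i in range(10)})
        aln = make_alignment("g", seqs)
        curve = lk.linkage_decay_curve({"g": aln}, list(seqs), seed=0)
        vals = curve.sigma_d2[curve.n_pairs > 0]
        assert np.allclose(vals, 1.0)

    def test_planted_subgene_transfers_decay(self, sim_blocks):
        cfg, alns, cells, truth = sim_blocks
        alpha = cells_of_species(cells, "alpha")
        curve = lk.linkage_decay_curve(alns, alpha, seed=0)
        centers = curve.bin_centers()
        short = curve.sigma_d2[centers <= 16]
        long = curve.sigma_d2[centers >= 200]
        assert np.nanmean(long) < np.nanmean(short)

    def test_control_preserves_site_frequencies(self, sim_blocks):
        cfg, alns, cells, truth = sim_blocks
        alpha = cells_of_species(cells, "alpha")
        codes, gene_idx, _ = lk._stack_tables(alns, alpha, 2)
        rng = np.random.default_rng(5)
        perm = codes.copy()
        for j in range(perm.shape[1]):
            cov = np.flatnonzero(perm[:, j] >= 0)
            perm[cov, j] = rng.permutation(perm[cov, j])
        assert ((perm == 1).sum(axis=0) == (codes == 1).sum(axis=0)).all()
        assert ((perm >= 0) == (codes >= 0)).all()

    def test_perfectly_linked_data_vs_control(self):
        rng = np.random.default_rng(1)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        alns = {}
        carriers = rng.random(40) < 0.5   # same partition in every gene
        for g in range(6):
            L = 200
            h1 = bases[rng.integers(0, 4, L)]
            h2 = h1.copy()
            hit = rng.random(L) < 0.15
            h2[hit] = bases[(np.searchsorted(bases, h2[hit]) + 1) % 4]
            seqs = {f"c{i}": (h2 if carriers[i] else h1).tobytes().decode()
                    for i in range(40)}
            alns[f"g{g}"] = make_alignment(f"g{g}", seqs)
        cells = [f"c{i}" for i in range(40)]
        curve = lk.linkage_decay_curve(alns, cells, seed=2)
        control = lk.unlinked_control(alns, cells, seed=3)
        assert curve.genome_wide == pytest.approx(1.0)
        assert control < 0.1

    def test_control_seeds_agree_within_mc_error(self, sim_blocks):
        cfg, alns, cells, truth = sim_blocks
        alpha = cells_of_species(cells, "alpha")
        c1 = lk.unlinked_control(alns, alpha, seed=11)
        c2 = lk.unlinked_control(alns, alpha, seed=12)
        assert c1 == pytest.approx(c2, abs=0.02)


class TestDecayModel:
    def test_asexual_limit_value(self):
        assert lk.decay_model(0.0, 1.0) == pytest.approx(5 / 11)

    def test_full_decay_limit(self):
        assert lk.decay_model(1e12, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_flat_curve_gives_rho_zero(self):
        edges = np.geomspace(1, 1000, 12)
        curve = lk.LinkageCurve(edges, np.full(11, 5 / 11),
                                np.ones(11, dtype=int))
        rho, _ = lk.fit_decay_model(curve)
        assert rho == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_parameter_recovery_within_20pct(self, seed):
        rng = np.random.default_rng(seed)
        edges = np.geomspace(1, 3000, 16)
        curve = lk.LinkageCurve(edges, np.zeros(15), np.ones(15, dtype=int))
        x = curve.bin_centers()
        y = lk.decay_model(x, 0.01) * (1 + 0.01 * rng.standard_normal(15))
        rho, _ = lk.fit_decay_model(
            lk.LinkageCurve(edges, y, np.ones(15, dtype=int)))
        assert rho == pytest.approx(0.01, rel=0.2)

    def test_too_few_bins_rejected(self):
        edges = np.geomspace(1, 10, 3)
        curve = lk.LinkageCurve(edges, np.array([0.4, 0.3]),
                                np.ones(2, dtype=int))
        with pytest.raises(ValueError, match="bins"):
            lk.fit_decay_model(curve)
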