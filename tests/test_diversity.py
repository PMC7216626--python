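import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitopop.diversity import (Alignment, AlignmentError, ConcordanceResult,
                               DistanceMatrix, cadm_w, clade_divergence_table,
                               compute_dnds, compute_pi, distance_matrix,
                               kendall_w, nj_tree, pairwise_dnds,
                               tree_path_lengths)


def _random_alignment(rng, n, L, maf=0.1):
    base = rng.choice(list("ACGT"), size=L)
    seqs = {}
    for i in range(n):
        row = base.copy()
        hit = rng.random(L) < maf
        row[hit] = rng.choice(list("ACGT"), size=hit.sum())
        seqs[f"s{i}"] = "".join(row)
    return Alignment.from_sequences("g", seqs)


# ---------------------------------------------------------------------------
# pi


def test_pi_two_sequences_single_difference():
    a = Alignment.from_sequences("g", {"x": "ACGTACGTAC", "y": "ACGTACGTAT"})
    assert compute_pi(a).pi == pytest.approx(0.1, abs=1e-15)


def test_pi_zero_for_identical_sequences():
    a = Alignment.from_sequences("g", {f"s{i}": "ACGTACGT" for i in range(5)})
    assert compute_pi(a).pi == 0.0


def test_pi_requires_two_sequences():
    a = Alignment.from_sequences("g", {"x": "ACGT"})
    with pytest.raises(AlignmentError):
        compute_pi(a)


def test_pi_equals_brute_force_all_pairs_recount():
    """pi must equal an independent double loop over all 190 pairs."""
    rng = np.random.default_rng(17)
    aln = _random_alignment(rng, 20, 500)
    got = compute_pi(aln).pi
    seqs = ["".join("ACGT-N"[c] for c in aln.matrix[i]) for i in range(20)]
    total, npairs = 0.0, 0
    for i in range(20):
        for j in range(i + 1, 20):
            comp = diff = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "ACGT" and b in "ACGT":
                    comp += 1
                    diff += a != b
            total += diff / comp
            npairs += 1
    assert npairs == 190
    assert got == pytest.approx(total / npairs, abs=1e-12)


def test_pi_pairwise_deletion_and_indel_column_exclusion():
    a = Alignment.from_sequences("g", {"x": "ACGTA-GG", "y": "ACNTAAGC"})
    stats = compute_pi(a)
    # column 5 has a gap (excluded, counted); column 2 N deleted pairwise
    assert stats.n_indel_positions == 1
    # comparable: 6 sites, 1 difference (last column)
    assert stats.pi == pytest.approx(1 / 6, abs=1e-12)


@settings(deadline=None, max_examples=15)
@given(st.integers(0, 2**31 - 1))
def test_pi_invariant_under_row_permutation(seed):
    rng = np.random.default_rng(seed)
    aln = _random_alignment(rng, 6, 60)
    perm = rng.permutation(6)
    shuffled = Alignment(gene="g", ids=[aln.ids[k] for k in perm],
                         matrix=aln.matrix[perm])
    assert compute_pi(aln).pi == pytest.approx(compute_pi(shuffled).pi, abs=1e-15)


def test_pi_of_pair_equals_their_distance():
    rng = np.random.default_rng(23)
    aln = _random_alignment(rng, 2, 300)
    d = distance_matrix([aln])
    assert compute_pi(aln).pi == pytest.approx(d.values[0, 1], abs=1e-15)


# ---------------------------------------------------------------------------
# dN/dS (NG86, yeast mitochondrial code)


def test_dnds_zero_for_identical_alignment():
    a = Alignment.from_sequences("g", {f"s{i}": "ATGGCTAAATAA" for i in range(4)})
    med, excl = compute_dnds(a, "s0")
    assert med == 0.0 and excl == 0


def test_single_synonymous_third_position_change_gives_zero():
    # TTA -> TTG is Leu -> Leu under the yeast mitochondrial code
    r, dn, ds = pairwise_dnds("TTAGCTAAT", "TTGGCTAAT")
    assert r == 0.0 and dn == 0.0 and ds > 0.0


def test_ng86_toy_matches_hand_computed_site_counts():
    """30-codon toy, 1 synonymous + 2 non-synonymous single-base changes.

    Hand-derived NG86 site counts under translation table 3:
    S(TTA)=S(TTG)=1/3, S(GCT)=1, S(GAT)=1/3, S(AAT)=1/3, S(ACT)=1,
    S(GGG)=1 -> S = 1/3 + 2/3 + 2/3 + 27 = 86/3, N = 90 - 86/3 = 184/3.
    """
    s1 = "TTA" + "GCT" + "AAT" + "GGG" * 27
    s2 = "TTG" + "GAT" + "ACT" + "GGG" * 27
    S, N, Sd, Nd = 86 / 3, 184 / 3, 1.0, 2.0
    jc = lambda p: -0.75 * math.log(1 - 4 * p / 3)
    expected = jc(Nd / N) / jc(Sd / S)
    r, _, _ = pairwise_dnds(s1, s2)
    assert r == pytest.approx(expected, abs=1e-9)


def test_nonsynonymous_only_pair_is_excluded_and_counted():
    # GCT -> GAT is Ala -> Asp (non-synonymous); no synonymous change
    a = Alignment.from_sequences("g", {"ref": "GCTGCTGCT", "x": "GATGCTGCT"})
    med, excl = compute_dnds(a, "ref")
    assert excl == 1
    r, dn, ds = pairwise_dnds("GCTGCTGCT", "GATGCTGCT")
    assert r is None and ds == 0.0 and dn > 0.0


def test_dnds_frame_violation_rejected():
    a = Alignment.from_sequences("g", {"ref": "ACGTA", "x": "ACGTT"})
    with pytest.raises(AlignmentError, match="divisible by 3"):
        compute_dnds(a, "ref")


# ---------------------------------------------------------------------------
# distances


def test_distance_matrix_trivial_cases():
    a = Alignment.from_sequences("g", {"x": "A" * 500, "y": "A" * 500})
    assert distance_matrix([a]).values[0, 1] == 0.0
    seq = list("A" * 500)
    for k in range(5):
        seq[k * 100] = "C"
    b = Alignment.from_sequences("g", {"x": "A" * 500, "y": "".join(seq)})
    assert distance_matrix([b]).values[0, 1] == pytest.approx(0.01, abs=1e-15)


def test_distance_matrix_matches_brute_force(population, reference):
    from mitopop.sim import CANONICAL_GENES
    genomes, _ = population
    sub = genomes[:10]
    alns = [Alignment.from_sequences(
        g, {x.isolate_id: x.spliced_cds(g) for x in sub})
        for g in CANONICAL_GENES]
    d = distance_matrix(alns)
    cat = {x.isolate_id: "".join(x.spliced_cds(g) for g in CANONICAL_GENES)
           for x in sub}
    for i, a in enumerate(d.ids):
        for j, b in enumerate(d.ids):
            if i < j:
                brute = np.mean([u != v for u, v in zip(cat[a], cat[b])])
                assert d.values[i, j] == pytest.approx(brute, abs=1e-12)


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(ids=["a", "b"], values=np.array([[0, .1], [.2, 0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(ids=["a", "b"], values=np.array([[.1, .2], [.2, 0]]))


# ---------------------------------------------------------------------------
# neighbour joining


def _additive_matrix():
    # tree ((A:0.10,B:0.20):0.05,C:0.15,D:0.30)
    paths = {("A", "B"): 0.30, ("A", "C"): 0.30, ("A", "D"): 0.45,
             ("B", "C"): 0.40, ("B", "D"): 0.55, ("C", "D"): 0.45}
    ids = list("ABCD")
    D = np.zeros((4, 4))
    for (a, b), v in paths.items():
        i, j = ids.index(a), ids.index(b)
        D[i, j] = D[j, i] = v
    return DistanceMatrix(ids=ids, values=D), paths


def test_nj_recovers_additive_distances_exactly():
    dm, paths = _additive_matrix()
    tree = nj_tree(dm)
    pl = tree_path_lengths(tree)
    for (a, b), v in paths.items():
        assert pl.loc[a, b] == pytest.approx(v, abs=1e-9)


def test_nj_three_taxa_unique_topology():
    dm = DistanceMatrix(ids=list("ABC"),
                        values=np.array([[0, .2, .3], [.2, 0, .4], [.3, .4, 0]]))
    tree = nj_tree(dm)
    pl = tree_path_lengths(tree)
    assert pl.loc["A", "B"] == pytest.approx(0.2, abs=1e-9)
    assert pl.loc["A", "C"] == pytest.approx(0.3, abs=1e-9)
    assert pl.loc["B", "C"] == pytest.approx(0.4, abs=1e-9)


def test_nj_matches_scikit_bio_on_random_matrix():
    """Cross-check topology against an independent NJ implementation."""
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(31)
    n = 8
    # additive matrix from random tree distances: perturbed ultrametric
    coords = rng.random((n, 3))
    D = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1)) / 4
    np.fill_diagonal(D, 0)
    ids = [f"t{i}" for i in range(n)]
    ours = nj_tree(DistanceMatrix(ids=ids, values=D))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
    from mitopop.diversity import _bipartitions
    import dendropy
    theirs_dp = dendropy.Tree.get(data=str(theirs), schema="newick")
    theirs_dp.is_rooted = False
    assert _bipartitions(ours) == _bipartitions(theirs_dp)


def test_nj_bootstrap_supports_clear_split():
    rng = np.random.default_rng(37)
    # two clearly separated groups of 3
    seqs = {}
    a = rng.choice(list("ACGT"), size=400)
    b = a.copy()
    flip = rng.choice(400, size=80, replace=False)
    for k in flip:
        b[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[k]]
    for i in range(3):
        row = a.copy()
        hit = rng.choice(400, 4, replace=False)
        row[hit] = rng.choice(list("ACGT"), size=4)
        seqs[f"a{i}"] = "".join(row)
        row = b.copy()
        hit = rng.choice(400, 4, replace=False)
        row[hit] = rng.choice(list("ACGT"), size=4)
        seqs[f"b{i}"] = "".join(row)
    aln = Alignment.from_sequences("g", seqs)
    d = distance_matrix([aln])
    tree = nj_tree(d, bootstrap_n=50, seed=7, alignments=[aln])
    supports = [float(n.label) for n in tree.preorder_node_iter()
                if n.label is not None and not n.is_leaf()]
    assert supports and max(supports) > 0.9


def test_nj_rejects_degenerate_input():
    with pytest.raises(ValueError, match="3 taxa"):
        nj_tree(DistanceMatrix(ids=["a", "b"], values=np.zeros((2, 2))))


# ---------------------------------------------------------------------------
# CADM


def test_cadm_identity_is_exactly_one():
    dm, _ = _additive_matrix()
    res = cadm_w([dm, dm], n_permutations=9, seed=0)
    assert res.W == 1.0


def test_cadm_matches_textbook_formula_on_three_matrices():
    """W from explicit rank sums: W = 12*S / (m^2 (n^3 - n)) without ties."""
    rng = np.random.default_rng(41)
    n = 5
    ids = [f"i{k}" for k in range(n)]
    mats = []
    for _ in range(3):
        M = np.round(rng.random((n, n)) * 0.8, 6)
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        mats.append(DistanceMatrix(ids=ids, values=M))
    res = cadm_w(mats, n_permutations=0, seed=0)
    # brute force: rank the 10 upper-triangle entries of each matrix
    from scipy.stats import rankdata
    iu = np.triu_indices(n, 1)
    ranks = np.vstack([rankdata(m.values[iu]) for m in mats])
    m, nn = ranks.shape
    R = ranks.sum(axis=0)
    S = ((R - R.mean()) ** 2).sum()
    W_direct = 12 * S / (m**2 * (nn**3 - nn))  # no ties with random floats
    assert res.W == pytest.approx(W_direct, abs=1e-12)


def test_cadm_reversed_rankings_hit_closed_form():
    """Two matrices with exactly reversed rankings: W = (1 + rho)/2 at
    rho = -1, i.e. W = 0 for the tie-free case."""
    dm, _ = _additive_matrix()
    rev = DistanceMatrix(ids=dm.ids, values=(0.6 - dm.values) * (1 - np.eye(4)))
    res = cadm_w([dm, rev], n_permutations=0, seed=0)
    assert res.W == pytest.approx(0.0, abs=1e-12)


def test_cadm_invariant_under_common_reordering():
    rng = np.random.default_rng(43)
    n = 6
    ids = [f"i{k}" for k in range(n)]
    def rand_dm(perm=None):
        M = rng.random((n, n)) * 0.5
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        return M
    m1, m2 = rand_dm(), rand_dm()
    a = cadm_w([DistanceMatrix(ids=ids, values=m1),
                DistanceMatrix(ids=ids, values=m2)], n_permutations=0, seed=0)
    perm = rng.permutation(n)
    ids_p = [ids[k] for k in perm]
    b = cadm_w([DistanceMatrix(ids=ids_p, values=m1[np.ix_(perm, perm)]),
                DistanceMatrix(ids=ids_p, values=m2[np.ix_(perm, perm)])],
               n_permutations=0, seed=0)
    assert a.W == pytest.approx(b.W, abs=1e-12)


def test_cadm_rejects_mismatched_isolates():
    dm, _ = _additive_matrix()
    other = DistanceMatrix(ids=list("ABCE"), values=dm.values)
    with pytest.raises(ValueError, match="different isolate sets"):
        cadm_w([dm, other])


# ---------------------------------------------------------------------------
# clade divergence


def test_clade_divergence_intra_and_singleton_handling():
    ids = ["a1", "a2", "b1"]
    D = np.array([[0, 0.0, .2], [0.0, 0, .2], [.2, .2, 0]])
    dm = DistanceMatrix(ids=ids, values=D)
    table = clade_divergence_table(dm, dm, {"a1": "A", "a2": "A", "b1": "B"})
    intra_a = table[(table.clade_a == "A") & (table.kind == "intra")]
    assert intra_a.mean_mito_distance.iloc[0] == 0.0
    intra_b = table[(table.clade_a == "B") & (table.kind == "intra")]
    assert np.isnan(intra_b.mean_mito_distance.iloc[0])  # singleton clade
    inter = table[table.kind == "inter"]
    assert inter.mean_mito_distance.iloc[0] == pytest.approx(0.2)


def test_clade_divergence_recovers_planted_between_group_divergence():
    cfg_rng = np.random.default_rng(47)
    base = cfg_rng.choice(list("ACGT"), size=1000)
    seqs = {}
    other = base.copy()
    flip = cfg_rng.choice(1000, size=100, replace=False)
    for k in flip:
        other[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[k]]
    for i in range(4):
        seqs[f"a{i}"] = "".join(base)
        seqs[f"b{i}"] = "".join(other)
    aln = Alignment.from_sequences("g", seqs)
    d = distance_matrix([aln])
    clades = {i: i[0].upper() for i in d.ids}
    table = clade_divergence_table(d, d, clades)
    inter = table[table.kind == "inter"].iloc[0]
    assert inter.mean_mito_distance == pytest.approx(0.1, abs=1e-12)
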