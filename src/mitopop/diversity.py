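"""Diversity statistics, distance matrices, neighbour joining and
congruence among distance matrices (CADM).

π is the average over all unordered sequence pairs of the proportion of
differing comparable sites; a site is comparable for a pair iff neither
member carries N there (pairwise deletion), and columns containing a gap
are tallied as indel positions and excluded from π altogether.

dN/dS follows Nei & Gojobori (1986) pathway counting with Jukes-Cantor
correction under the yeast mitochondrial genetic code (NCBI translation
table 3), each isolate compared against a designated reference row, with
the median over pairs reported (an all-pairs mode is available).

The neighbour-joining implementation is the Saitou-Nei algorithm with
ties in the Q-matrix broken by lowest index pair and negative branch
lengths clamped to zero (counted); bootstrap support is the fraction of
column-resampled replicates containing each bipartition.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy.stats import rankdata

_CODE = {"-": 4, "N": 5}
_ALPHABET = "ACGT-N"
_LUT = np.full(256, 255, np.uint8)
for _i, _b in enumerate(_ALPHABET):
    _LUT[ord(_b)] = _i


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Equal-length rows over {A,C,G,T,N,-} keyed by isolate id."""

    gene: str
    ids: list[str]
    matrix: np.ndarray  # uint8 codes into _ALPHABET, shape (n, L)

    @classmethod
    def from_sequences(cls, gene: str, seqs: dict[str, str]) -> "Alignment":
        ids = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"{gene}: rows have unequal lengths {lengths}")
        mat = np.vstack([_LUT[np.frombuffer(seqs[i].upper().encode(), np.uint8)]
                         for i in ids])
        if (mat == 255).any():
            raise AlignmentError(f"{gene}: illegal alignment character")
        return cls(gene=gene, ids=ids, matrix=mat)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def row(self, isolate: str) -> np.ndarray:
        return self.matrix[self.ids.index(isolate)]

    def column_classes(self) -> dict[str, np.ndarray]:
        """Boolean masks: indel (any gap), ambiguous (any N), polymorphic /
        monomorphic among non-indel columns (N ignored)."""
        m = self.matrix
        indel = (m == _CODE["-"]).any(axis=0)
        ambig = (m == _CODE["N"]).any(axis=0)
        poly = np.zeros(self.length, bool)
        for j in np.flatnonzero(~indel):
            col = m[:, j]
            bases = np.unique(col[col < 4])
            poly[j] = bases.size >= 2
        return {"indel": indel, "ambiguous": ambig,
                "polymorphic": poly & ~indel,
                "monomorphic": ~poly & ~indel}


@dataclass
class DiversityStats:
    gene: str
    n_sequences: int
    alignment_length: int
    n_polymorphic: int
    n_indel_positions: int
    pi: float
    dnds_median: float | None = None
    n_dnds_excluded: int = 0


def _pair_counts(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(comparable site counts, matching site counts) for all row pairs,
    computed over columns already filtered; N is deleted pairwise."""
    valid = (mat < 4).astype(np.float64)
    comparable = valid @ valid.T
    matches = np.zeros_like(comparable)
    for b in range(4):
        ab = ((mat == b) & (mat < 4)).astype(np.float64)
        matches += ab @ ab.T
    return comparable, matches


def compute_pi(aln: Alignment, indel_policy: str = "exclude_columns"
               ) -> DiversityStats:
    """Average pairwise diversity per comparable site.

    ``indel_policy``: "exclude_columns" removes every column containing a
    gap before the pairwise scan (gap columns are reported as indel
    positions); "pairwise" instead deletes gaps per pair like N.
    """
    if aln.n < 2:
        raise AlignmentError("need at least 2 sequences for pi")
    classes = aln.column_classes()
    n_indel = int(classes["indel"].sum())
    if indel_policy == "exclude_columns":
        mat = aln.matrix[:, ~classes["indel"]]
    elif indel_policy == "pairwise":
        mat = np.where(aln.matrix == _CODE["-"], _CODE["N"], aln.matrix)
    else:
        raise ValueError(f"unknown indel_policy {indel_policy!r}")
    comparable, matches = _pair_counts(mat)
    iu = np.triu_indices(aln.n, k=1)
    comp, match = comparable[iu], matches[iu]
    with np.errstate(invalid="ignore"):
        frac = np.where(comp > 0, (comp - match) / np.maximum(comp, 1), np.nan)
    pi = float(np.nanmean(frac))
    return DiversityStats(
        gene=aln.gene, n_sequences=aln.n, alignment_length=aln.length,
        n_polymorphic=int(classes["polymorphic"].sum()),
        n_indel_positions=n_indel, pi=pi)


# ---------------------------------------------------------------------------
# Nei-Gojobori dN/dS under the yeast mitochondrial code

_TABLE3 = CodonTable.unambiguous_dna_by_id[3]
_STOPS = set(_TABLE3.stop_codons)


def _aa(codon: str) -> str | None:
    if codon in _STOPS:
        return None
    return _TABLE3.forward_table[codon]


def _syn_fraction(codon: str) -> np.ndarray:
    """Per-position fraction of non-stop single-base changes that are
    synonymous (NG86 site counting)."""
    out = np.zeros(3)
    ref_aa = _aa(codon)
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in _STOPS:
                continue
            tot += 1
            if _aa(alt) == ref_aa:
                syn += 1
        out[pos] = syn / tot if tot else 0.0
    return out


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons,
    averaged over all mutational pathways that avoid stop codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                break
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:  # all pathways hit a stop; fall back to including them
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if _aa(cur) is not None and _aa(nxt) is not None and _aa(cur) == _aa(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            results.append((sd, nd))
    sd = float(np.mean([r[0] for r in results]))
    nd = float(np.mean([r[1] for r in results]))
    return sd, nd


def _jc(p: float) -> float | None:
    if p < 1e-12:
        return 0.0
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pairwise_dnds(seq1: str, seq2: str) -> tuple[float | None, float, float]:
    """NG86 dN/dS for one aligned coding pair.

    Returns (ratio, dN, dS); ratio is None when dS = 0 while dN > 0
    (undefined), and 0.0 when both are 0. Codons containing N, a gap or a
    stop in either sequence are skipped.
    """
    if len(seq1) != len(seq2):
        raise AlignmentError("dN/dS pair rows differ in length")
    S = N = Sd = Nd = 0.0
    usable = 0
    for i in range(0, len(seq1) - len(seq1) % 3, 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if any(ch not in "ACGT" for ch in c1 + c2):
            continue
        if c1 in _STOPS or c2 in _STOPS:
            continue
        usable += 1
        s_sites = (_syn_fraction(c1) + _syn_fraction(c2)) / 2.0
        S += float(s_sites.sum())
        N += float(3.0 - s_sites.sum())
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    if usable == 0:
        raise AlignmentError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = _jc(pS), _jc(pN)
    if dS is None or dN is None:  # saturated; treat as undefined
        return None, float("nan"), float("nan")
    if dS == 0.0:
        return (0.0, dN, dS) if dN == 0.0 else (None, dN, dS)
    return dN / dS, dN, dS


def compute_dnds(aln: Alignment, reference_row: str,
                 mode: str = "vs_reference") -> tuple[float, int]:
    """Median pairwise dN/dS for an in-frame CDS alignment.

    ``mode`` "vs_reference": each other isolate against ``reference_row``;
    "all_pairs": every unordered pair. Pairs with dS = 0 and dN > 0 are
    excluded from the median and counted. Returns (median, n_excluded).
    """
    seqs = {i: "".join(_ALPHABET[c] for c in aln.matrix[k])
            for k, i in enumerate(aln.ids)}
    ref = seqs[reference_row]
    if len(ref.replace("-", "")) % 3 != 0:
        raise AlignmentError(f"{aln.gene}: reference CDS length not divisible by 3")
    if mode == "vs_reference":
        pairs = [(reference_row, i) for i in aln.ids if i != reference_row]
    elif mode == "all_pairs":
        pairs = list(itertools.combinations(aln.ids, 2))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ratios, excluded = [], 0
    for a, b in pairs:
        r, _dn, _ds = pairwise_dnds(seqs[a], seqs[b])
        if r is None:
            excluded += 1
        else:
            ratios.append(r)
    med = float(np.median(ratios)) if ratios else 0.0
    return med, excluded


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.values = v

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids=list(ids), values=self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(ids=list(df.index), values=df.to_numpy(float))


def concatenate(alignments: list[Alignment],
                isolates: list[str] | None = None) -> Alignment:
    """Concatenate per-gene alignments over their shared isolates.

    Isolates missing from any gene are dropped with a warning.
    """
    if not alignments:
        raise AlignmentError("no alignments to concatenate")
    shared = set(alignments[0].ids)
    for a in alignments[1:]:
        shared &= set(a.ids)
    order = [i for i in (isolates or alignments[0].ids) if i in shared]
    dropped = set(isolates or alignments[0].ids) - shared
    if dropped:
        warnings.warn(f"{len(dropped)} isolate(s) missing a gene, excluded: "
                      f"{sorted(dropped)[:5]}...")
    mats = [a.matrix[[a.ids.index(i) for i in order]] for a in alignments]
    return Alignment(gene="concat", ids=order, matrix=np.hstack(mats))


def distance_matrix(alignments: list[Alignment],
                    isolates: list[str] | None = None) -> DistanceMatrix:
    """Pairwise proportion of differing comparable sites over the
    concatenated CDS (indel columns excluded, N deleted pairwise)."""
    cat = concatenate(alignments, isolates)
    indel = (cat.matrix == _CODE["-"]).any(axis=0)
    mat = cat.matrix[:, ~indel]
    comparable, matches = _pair_counts(mat)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(comparable > 0, (comparable - matches) / np.maximum(comparable, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(ids=cat.ids, values=d)


# ---------------------------------------------------------------------------
# neighbour joining


class _Node:
    __slots__ = ("label", "children", "lengths")

    def __init__(self, label=None):
        self.label = label
        self.children: list[_Node] = []
        self.lengths: list[float] = []

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{l:.12g}"
                         for c, l in zip(self.children, self.lengths))
        return f"({inner})"


def nj_tree(d: DistanceMatrix, bootstrap_n: int = 0,
            seed: int | None = None,
            alignments: list[Alignment] | None = None) -> dendropy.Tree:
    """Saitou-Nei neighbour joining; returns an unrooted dendropy tree.

    With ``bootstrap_n`` > 0 the concatenated ``alignments`` columns are
    resampled with replacement; internal-node labels carry the fraction of
    replicates containing the corresponding bipartition.
    """
    if len(d.ids) < 3:
        raise ValueError("need at least 3 taxa")
    tree = _nj_once(d)
    if bootstrap_n > 0:
        if alignments is None:
            raise ValueError("bootstrap requires the source alignments")
        rng = np.random.default_rng(seed)
        cat = concatenate(alignments, d.ids)
        L = cat.length
        counts: dict[frozenset, int] = {}
        for _ in range(bootstrap_n):
            cols = rng.integers(0, L, size=L)
            rep_aln = Alignment(gene="bs", ids=cat.ids, matrix=cat.matrix[:, cols])
            rep_d = distance_matrix([rep_aln])
            rep_t = _nj_once(rep_d)
            for bp in _bipartitions(rep_t):
                counts[bp] = counts.get(bp, 0) + 1
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            support = counts.get(_canon(leaves, set(d.ids)), 0) / bootstrap_n
            node.label = f"{support:.3f}"
    return tree


def _nj_once(d: DistanceMatrix) -> dendropy.Tree:
    n = len(d.ids)
    D = d.values.astype(float).copy()
    nodes = [_Node(label=i) for i in d.ids]
    active = list(range(n))
    n_clamped = 0
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie break: argmin on flattened row-major array
        k = int(np.argmin(Q))
        i, j = divmod(k, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            n_clamped += 1
            li = 0.0
        if lj < 0:
            n_clamped += 1
            lj = 0.0
        new = _Node()
        ai, aj = active[i], active[j]
        new.children = [nodes[ai], nodes[aj]]
        new.lengths = [li, lj]
        # distances from the new node to the rest
        newrow = np.zeros(D.shape[0] + 1)
        for t, at in enumerate(active):
            if t in (i, j):
                continue
            newrow[at] = 0.5 * (sub[i, t] + sub[j, t] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newrow[:-1]
        D[:-1, -1] = newrow[:-1]
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [D.shape[0] - 1]
    a, b = active
    root = _Node()
    dab = max(D[a, b], 0.0)
    root.children = [nodes[a], nodes[b]]
    root.lengths = [dab / 2.0, dab / 2.0]
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} negative NJ branch length(s) to 0")
    newick = root.newick() + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _canon(leafset: frozenset, all_taxa: set) -> frozenset:
    other = frozenset(all_taxa - leafset)
    return min(leafset, other, key=lambda s: (len(s), sorted(s)))


def _bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    taxa = {l.taxon.label for l in tree.leaf_node_iter()}
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(leaves) < len(taxa) - 1:
            out.add(_canon(leaves, taxa))
    return out


def tree_path_lengths(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    ids = sorted(t.label for t in tree.taxon_namespace)
    vals = np.zeros((len(ids), len(ids)))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                vals[i, j] = vals[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
    return pd.DataFrame(vals, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# CADM


@dataclass
class ConcordanceResult:
    W: float
    p_value: float
    n_permutations: int
    seed: int | None


def kendall_w(rank_rows: np.ndarray) -> float:
    """Kendall's coefficient of concordance with tie correction.

    ``rank_rows``: m x n matrix, each row the ranks one matrix assigns to
    the n objects (mean ranks on ties).
    """
    m, n = rank_rows.shape
    R = rank_rows.sum(axis=0)
    S = float(((R - R.mean()) ** 2).sum())
    T = 0.0
    for row in rank_rows:
        _, counts = np.unique(row, return_counts=True)
        T += float((counts ** 3 - counts).sum())
    denom = m * m * (n ** 3 - n) - m * T
    if denom <= 0:
        return 1.0
    return 12.0 * S / denom


def cadm_w(matrices: list[DistanceMatrix], n_permutations: int = 999,
           seed: int | None = None) -> ConcordanceResult:
    """Congruence among distance matrices: Kendall W over the ranked
    upper triangles, with a permutation null that relabels the isolates
    of every matrix except the first."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    ids = matrices[0].ids
    for m in matrices[1:]:
        if set(m.ids) != set(ids):
            raise ValueError("matrices cover different isolate sets")
    aligned = [m.reorder(ids) for m in matrices]
    ranks = np.vstack([rankdata(m.condensed()) for m in aligned])
    W = kendall_w(ranks)
    rng = np.random.default_rng(seed)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_permutations):
        rows = [ranks[0]]
        for m in aligned[1:]:
            perm = rng.permutation(n)
            shuffled = m.values[np.ix_(perm, perm)][iu]
            rows.append(rankdata(shuffled))
        if kendall_w(np.vstack(rows)) >= W:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return ConcordanceResult(W=W, p_value=p, n_permutations=n_permutations,
                             seed=seed)


# ---------------------------------------------------------------------------
# clade-level divergence


def clade_divergence_table(d_mito: DistanceMatrix, d_nuclear: DistanceMatrix,
                           clades: dict[str, str]) -> pd.DataFrame:
    """Mean inter-/intra-clade distances for both matrices.

    Rows with clade_a == clade_b are intra-clade means (NaN for singleton
    clades); others are inter-clade means.
    """
    missing = set(d_mito.ids) - set(clades)
    if missing:
        raise ValueError(f"clade labels missing for {sorted(missing)[:5]}")
    d_nuc = d_nuclear.reorder(d_mito.ids)
    ids = d_mito.ids
    by_clade: dict[str, list[int]] = {}
    for idx, iso in enumerate(ids):
        by_clade.setdefault(clades[iso], []).append(idx)
    rows = []
    names = sorted(by_clade)
    for a in names:
        for b in names:
            if a > b:
                continue
            ia, ib = by_clade[a], by_clade[b]
            if a == b:
                if len(ia) < 2:
                    mito = nuc = float("nan")
                else:
                    iu = np.triu_indices(len(ia), k=1)
                    mito = float(d_mito.values[np.ix_(ia, ia)][iu].mean())
                    nuc = float(d_nuc.values[np.ix_(ia, ia)][iu].mean())
            else:
                mito = float(d_mito.values[np.ix_(ia, ib)].mean())
                nuc = float(d_nuc.values[np.ix_(ia, ib)].mean())
            rows.append({"clade_a": a, "clade_b": b,
                         "kind": "intra" if a == b else "inter",
                         "mean_mito_distance": mito,
                         "mean_nuclear_distance": nuc})
    return pd.DataFrame(rows)
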