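"""Interspecies introgression calling from a major-allele marker catalogue.

Markers are positions, in reference CDS coordinates, where the major
allele of the recipient-species panel differs from the major allele of
the donor-species panel. Isolates are painted marker-by-marker
(conspecific / foreign / other / missing) and foreign segments are called
as runs of consecutive foreign markers, with boundaries placed at the
midpoint between the outermost foreign marker and the nearest flanking
conspecific marker — reflecting that the true crossover can lie anywhere
in the inter-marker gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .alleles import CdsStatus
from .diversity import Alignment

_BASE = "ACGT-N"


class MarkerState(Enum):
    CONSPECIFIC = "conspecific"
    FOREIGN = "foreign"
    OTHER = "other"
    MISSING = "missing"


@dataclass
class Marker:
    gene: str
    offset: int          # 0-based within the gene's spliced CDS
    allele1: str         # recipient-species major allele
    af1: float
    allele2: str         # donor-species major allele
    af2: float


@dataclass
class MarkerCatalogue:
    markers: list[Marker]
    gene_order: list[str]
    gene_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for m in self.markers:
            if m.allele1 == m.allele2:
                raise ValueError(f"marker {m.gene}:{m.offset} majors identical")
        order = {g: i for i, g in enumerate(self.gene_order)}
        self.markers.sort(key=lambda m: (order[m.gene], m.offset))

    def __len__(self) -> int:
        return len(self.markers)

    def concat_positions(self) -> np.ndarray:
        """Marker positions in concatenated-CDS coordinates."""
        offset, base = {}, 0
        for g in self.gene_order:
            offset[g] = base
            base += self.gene_lengths[g]
        return np.array([offset[m.gene] + m.offset for m in self.markers])

    @property
    def total_length(self) -> int:
        return sum(self.gene_lengths[g] for g in self.gene_order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "gene": m.gene, "offset": m.offset,
            "species1_major": m.allele1, "AF1": m.af1,
            "species2_major": m.allele2, "AF2": m.af2,
        } for m in self.markers])


def _major_allele(col: np.ndarray) -> tuple[str | None, float]:
    """Most frequent non-N, non-gap base; ties broken A<C<G<T."""
    counts = np.array([(col == b).sum() for b in range(4)])
    tot = counts.sum()
    if tot == 0:
        return None, 0.0
    best = int(np.argmax(counts))  # argmax takes the first max: A<C<G<T
    return _BASE[best], counts[best] / tot


def derive_markers(aln_sp1: dict[str, Alignment],
                   aln_sp2: dict[str, Alignment],
                   gene_order: list[str]) -> MarkerCatalogue:
    """Diagnostic positions where the two species' major alleles differ.

    Both species' per-gene alignments must share reference coordinates.
    Candidate positions are those that are not invariant across the union
    of the two panels (covering both within-species polymorphisms and
    fixed interspecies differences).
    """
    markers = []
    gene_lengths = {}
    for gene in gene_order:
        if gene not in aln_sp1 or gene not in aln_sp2:
            raise ValueError(f"gene {gene} absent from a species panel")
        a1, a2 = aln_sp1[gene], aln_sp2[gene]
        if a1.n == 0 or a2.n == 0:
            raise ValueError(f"gene {gene}: empty species alignment")
        if a1.length != a2.length:
            raise ValueError(f"gene {gene}: species alignments differ in length")
        gene_lengths[gene] = a1.length
        both = np.vstack([a1.matrix, a2.matrix])
        for j in range(a1.length):
            col = both[:, j]
            bases = np.unique(col[col < 4])
            if bases.size < 2:
                continue
            m1, af1 = _major_allele(a1.matrix[:, j])
            m2, af2 = _major_allele(a2.matrix[:, j])
            if m1 is None or m2 is None or m1 == m2:
                continue
            markers.append(Marker(gene=gene, offset=j, allele1=m1, af1=af1,
                                  allele2=m2, af2=af2))
    return MarkerCatalogue(markers=markers, gene_order=list(gene_order),
                           gene_lengths=gene_lengths)


@dataclass
class MarkerPainting:
    isolate: str
    states: list[MarkerState]

    def fraction_foreign(self) -> float:
        known = [s for s in self.states if s is not MarkerState.MISSING]
        if not known:
            return float("nan")
        return sum(s is MarkerState.FOREIGN for s in known) / len(known)


def paint_isolate(isolate: str, cds_map: dict[str, str | CdsStatus],
                  catalogue: MarkerCatalogue) -> MarkerPainting:
    """Assign each marker a state for one isolate's extracted CDSs."""
    states = []
    for m in catalogue.markers:
        seq = cds_map.get(m.gene)
        if not isinstance(seq, str) or m.offset >= len(seq) or seq[m.offset] == "N":
            states.append(MarkerState.MISSING)
            continue
        base = seq[m.offset]
        if base == m.allele1:
            states.append(MarkerState.CONSPECIFIC)
        elif base == m.allele2:
            states.append(MarkerState.FOREIGN)
        else:
            states.append(MarkerState.OTHER)
    return MarkerPainting(isolate=isolate, states=states)


@dataclass
class IntrogressionSegment:
    isolate: str
    start_boundary: float   # concatenated-CDS coordinates, half-open
    end_boundary: float
    n_foreign_markers: int
    first_marker: int       # catalogue indices of the outermost foreign markers
    last_marker: int
    genes: dict[str, str] = field(default_factory=dict)  # gene -> none/partial/full


def call_segments(p: MarkerPainting, catalogue: MarkerCatalogue,
                  min_run: int = 5) -> list[IntrogressionSegment]:
    """Maximal runs of >= ``min_run`` consecutive foreign markers.

    Missing markers are transparent (they neither break nor extend a run);
    'other' and conspecific states break it. Boundaries are the midpoints
    between the outermost foreign markers and the nearest flanking
    non-missing broken-state markers; a run touching a catalogue end takes
    the concatenated-CDS end as its boundary.
    """
    pos = catalogue.concat_positions()
    runs: list[tuple[int, int, int]] = []  # (first_idx, last_idx, n_foreign)
    cur_first = cur_last = None
    n_f = 0
    for i, s in enumerate(p.states):
        if s is MarkerState.FOREIGN:
            if cur_first is None:
                cur_first = i
            cur_last = i
            n_f += 1
        elif s is MarkerState.MISSING:
            continue
        else:
            if cur_first is not None and n_f >= min_run:
                runs.append((cur_first, cur_last, n_f))
            cur_first = cur_last = None
            n_f = 0
    if cur_first is not None and n_f >= min_run:
        runs.append((cur_first, cur_last, n_f))

    segments = []
    for first, last, n_f in runs:
        # nearest non-missing, non-foreign markers flanking the run
        left = next((k for k in range(first - 1, -1, -1)
                     if p.states[k] is not MarkerState.MISSING), None)
        right = next((k for k in range(last + 1, len(p.states))
                      if p.states[k] is not MarkerState.MISSING), None)
        start = 0.0 if left is None else (pos[left] + pos[first]) / 2.0
        end = float(catalogue.total_length) if right is None \
            else (pos[last] + pos[right]) / 2.0
        genes = {}
        for g in catalogue.gene_order:
            idx = [k for k, m in enumerate(catalogue.markers) if m.gene == g]
            if not idx:
                continue
            inside = [k for k in idx if first <= k <= last]
            if not inside:
                genes[g] = "none"
            elif len(inside) == len(idx):
                genes[g] = "full"
            else:
                genes[g] = "partial"
        segments.append(IntrogressionSegment(
            isolate=p.isolate, start_boundary=float(start),
            end_boundary=float(end), n_foreign_markers=n_f,
            first_marker=first, last_marker=last, genes=genes))
    return segments


def segments_to_frame(segments: list[IntrogressionSegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "isolate": s.isolate, "start": s.start_boundary, "end": s.end_boundary,
        "n_foreign_markers": s.n_foreign_markers,
        "genes": ";".join(f"{g}={c}" for g, c in s.genes.items() if c != "none"),
    } for s in segments])


def foreign_fraction_vs_nuclear(paintings: list[MarkerPainting],
                                nuclear_counts: dict[str, int],
                                n_permutations: int = 999,
                                seed: int | None = None
                                ) -> tuple[pd.DataFrame, float, float]:
    """Percent foreign markers per isolate vs nuclear introgressed-ORF
    counts; Spearman correlation with a permutation p-value."""
    shared = [p for p in paintings if p.isolate in nuclear_counts]
    table = pd.DataFrame({
        "isolate": [p.isolate for p in shared],
        "pct_foreign_markers": [100.0 * p.fraction_foreign() for p in shared],
        "nuclear_introgressed_orfs": [nuclear_counts[p.isolate] for p in shared],
    })
    x = table["pct_foreign_markers"].to_numpy()
    y = table["nuclear_introgressed_orfs"].to_numpy(float)
    rho = spearmanr(x, y).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        r = spearmanr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(rho):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return table, float(rho), float(p)
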