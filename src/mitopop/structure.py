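"""Gene-order inversion detection and genome-size decomposition.

Rearrangements are detected by loss of synteny on the signed permutation
of annotated features (protein-coding, rRNA and tRNA genes). The query
order is decomposed greedily into maximal blocks collinear with the
reference; a block that is reference-collinear when reversed and
strand-flipped is an inversion. Breakpoints are reported as the flanking
intergenic intervals, never points: the repeat-rich AT intergenic DNA
where real breakpoints fall does not admit precise delimitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .io import GeneAnnotation, MitoGenome

ANCHOR_KINDS = ("CDS", "rRNA", "tRNA")


@dataclass
class GeneOrder:
    isolate: str
    order: list[tuple[str, str]]  # (feature name, strand) along the genome
    spans: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.order]
        if len(names) != len(set(names)):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"{self.isolate}: duplicate features {dupes}")

    @classmethod
    def from_genome(cls, genome: MitoGenome,
                    kinds: tuple[str, ...] = ANCHOR_KINDS) -> "GeneOrder":
        feats = sorted((f for f in genome.features if f.kind in kinds),
                       key=lambda f: f.start)
        return cls(isolate=genome.isolate_id,
                   order=[(f.name, f.strand) for f in feats],
                   spans={f.name: (f.start, f.end) for f in feats})


@dataclass
class InversionCall:
    isolate: str
    block: list[tuple[str, str]]      # inverted sublist as observed in query
    query_indices: tuple[int, int]    # half-open sublist range in query order
    left_breakpoint: tuple[int, int] | None   # intergenic interval (coords)
    right_breakpoint: tuple[int, int] | None
    strand_flip: bool = True


def apply_inversion(order: GeneOrder, call: InversionCall) -> GeneOrder:
    """Reverse the called block (order and strands); used for round-trips."""
    i, j = call.query_indices
    flipped = [(n, "+" if s == "-" else "-") for n, s in reversed(order.order[i:j])]
    return GeneOrder(isolate=order.isolate,
                     order=order.order[:i] + flipped + order.order[j:],
                     spans=order.spans)


def detect_inversions(ref_order: GeneOrder, query_order: GeneOrder
                      ) -> list[InversionCall]:
    """Greedy decomposition of the query's signed permutation into maximal
    reference-collinear blocks; reversed blocks are reported as inversions.

    Features present in only one order are dropped pairwise (warned).
    Blocks that are neither collinear nor cleanly reversed are reported
    with ``strand_flip=False`` and should be treated as complex/unresolved.
    """
    ref_names = [n for n, _ in ref_order.order]
    q_names = [n for n, _ in query_order.order]
    shared = set(ref_names) & set(q_names)
    droppedd = (set(ref_names) | set(q_names)) - shared
    if droppedd:
        warnings.warn(f"{len(droppedd)} feature(s) present in only one order, "
                      f"dropped: {sorted(droppedd)[:5]}")
    ref = [(n, s) for n, s in ref_order.order if n in shared]
    qry = [(n, s) for n, s in query_order.order if n in shared]
    ref_idx = {n: i for i, (n, _) in enumerate(ref)}
    ref_strand = {n: s for n, s in ref}
    # signed permutation: sign is + when query strand matches reference
    perm = [(ref_idx[n], 1 if s == ref_strand[n] else -1) for n, s in qry]

    calls = []
    i = 0
    while i < len(perm):
        idx, sign = perm[i]
        j = i
        if sign == 1:
            while (j + 1 < len(perm) and perm[j + 1][1] == 1
                   and perm[j + 1][0] == perm[j][0] + 1):
                j += 1
            # collinear block: no call
        else:
            while (j + 1 < len(perm) and perm[j + 1][1] == -1
                   and perm[j + 1][0] == perm[j][0] - 1):
                j += 1
            calls.append(_make_call(query_order, qry, i, j + 1, flip=True))
        i = j + 1
    return calls


def _make_call(query_order: GeneOrder, qry: list[tuple[str, str]],
               i: int, j: int, flip: bool) -> InversionCall:
    spans = query_order.spans or {}
    block = qry[i:j]

    def gap(left_name: str | None, right_name: str | None):
        if left_name is None or right_name is None:
            return None
        if left_name not in spans or right_name not in spans:
            return None
        return (spans[left_name][1], spans[right_name][0])

    left_nb = qry[i - 1][0] if i > 0 else None
    right_nb = qry[j][0] if j < len(qry) else None
    return InversionCall(
        isolate=query_order.isolate, block=list(block), query_indices=(i, j),
        left_breakpoint=gap(left_nb, block[0][0]),
        right_breakpoint=gap(block[-1][0], right_nb),
        strand_flip=flip)


# ---------------------------------------------------------------------------
# size decomposition


def size_decomposition(genomes: list[MitoGenome]) -> tuple[pd.DataFrame, dict]:
    """Per-genome length components and population-level r² of total
    length against each component (ordinary least squares).

    Components: exonic CDS, intron, other genic (rRNA/tRNA/elements/GC
    clusters outside genes), intergenic (remainder). r² is NaN when a
    component (or the total) has zero variance.
    """
    rows = []
    for g in genomes:
        if not g.features:
            warnings.warn(f"{g.isolate_id}: unannotated genome excluded")
            continue
        total = len(g.sequence)
        cds_spans = [(f.start, f.end) for f in g.features if f.kind == "CDS"]
        rrna_spans = [(f.start, f.end) for f in g.features if f.kind == "rRNA"]

        def nested(f, spans):
            return any(s <= f.start and f.end <= e for s, e in spans)

        intron_in_cds = sum(f.length for f in g.features
                            if f.kind == "intron" and nested(f, cds_spans))
        intron_in_rrna = sum(f.length for f in g.features
                             if f.kind == "intron" and nested(f, rrna_spans))
        cds_exonic = sum(e - s for s, e in cds_spans) - intron_in_cds
        standalone = sum(f.length for f in g.features
                         if f.kind in ("tRNA", "element", "GC_cluster")
                         and not nested(f, cds_spans + rrna_spans))
        other_genic = (sum(e - s for s, e in rrna_spans) - intron_in_rrna
                       + standalone)
        intron = intron_in_cds + intron_in_rrna
        intergenic = total - cds_exonic - other_genic - intron
        rows.append({"isolate": g.isolate_id, "total": total,
                     "cds_exonic": cds_exonic, "intron": intron,
                     "other_genic": other_genic, "intergenic": intergenic})
    df = pd.DataFrame(rows)
    r2 = {}
    for comp in ("cds_exonic", "intron", "intergenic"):
        x = df[comp].to_numpy(float)
        y = df["total"].to_numpy(float)
        if len(df) < 3 or np.std(x) == 0 or np.std(y) == 0:
            r2[comp] = float("nan")
        else:
            r2[comp] = float(linregress(x, y).rvalue ** 2)
    return df, r2
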