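"""CDS extraction, the non-redundant allele database, and detection of
mobile elements and GC clusters.

Extraction prefers annotations (introns spliced out by concatenating exon
intervals); when a genome carries no annotation for a gene, an infix
alignment search (edlib) against the reference coding sequence locates it,
on either strand. Sequences containing N are flagged ambiguous rather than
entering the allele database, mirroring the practice of restricting
profile analysis to isolates without ambiguous bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import MitoGenome


class CdsStatus(Enum):
    MISSING = "missing"
    AMBIGUOUS = "ambiguous"


MISSING = CdsStatus.MISSING
AMBIGUOUS = CdsStatus.AMBIGUOUS


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _best_hit(genome_seq: str, query: str) -> tuple[float, int, int, str]:
    """Best infix alignment of the full query on either strand.

    Returns (identity, start, end, strand) where identity is
    1 - edit_distance / len(query), and [start, end) is the aligned target
    interval on the forward genome.
    """
    best = (-1.0, 0, 0, "+")
    for strand, q in (("+", query), ("-", _revcomp(query))):
        res = edlib.align(q, genome_seq, mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        ident = 1.0 - res["editDistance"] / len(query)
        if ident > best[0]:
            s, e = res["locations"][0]
            best = (ident, s, e + 1, strand)
    return best


def extract_cds(genome: MitoGenome, reference_genes: dict[str, str],
                min_identity: float = 0.70) -> dict[str, str | CdsStatus]:
    """Extract each reference gene's coding sequence from a genome.

    Annotated genes are sliced and spliced directly; unannotated ones are
    located by full-CDS infix alignment against the reference gene (this
    search cannot bridge introns, so intron-containing genes in
    unannotated genomes come back missing — supply annotations for those).
    """
    out: dict[str, str | CdsStatus] = {}
    for gene, ref_seq in reference_genes.items():
        if not ref_seq:
            raise ValueError(f"reference sequence for {gene} is empty")
        seq = genome.spliced_cds(gene)
        if seq is None and genome.sequence:
            ident, s, e, strand = _best_hit(genome.sequence, ref_seq)
            if ident >= min_identity:
                seq = genome.sequence[s:e]
                if strand == "-":
                    seq = _revcomp(seq)
        if seq is None:
            out[gene] = MISSING
        elif "N" in seq:
            out[gene] = AMBIGUOUS
        else:
            out[gene] = seq
    return out


@dataclass
class AlleleDB:
    """Per-gene catalogue of distinct CDS alleles, IDs in first-seen order."""

    alleles: dict[str, list[str]] = field(default_factory=dict)

    def allele_id(self, gene: str, seq: str) -> int | None:
        try:
            return self.alleles[gene].index(seq) + 1
        except (KeyError, ValueError):
            return None

    def add(self, gene: str, seq: str) -> int:
        seqs = self.alleles.setdefault(gene, [])
        try:
            return seqs.index(seq) + 1
        except ValueError:
            seqs.append(seq)
            return len(seqs)

    def n_alleles(self, gene: str) -> int:
        return len(self.alleles.get(gene, []))

    def write_fasta(self, outdir) -> None:
        """One multi-FASTA per gene; headers are geneName_alleleID."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for gene, seqs in self.alleles.items():
            with open(outdir / f"{gene}.alleles.fasta", "w") as fh:
                for i, s in enumerate(seqs, 1):
                    fh.write(f">{gene}_{i}\n")
                    for j in range(0, len(s), 70):
                        fh.write(s[j:j + 70] + "\n")


@dataclass
class CDSProfile:
    """Per-isolate vector of allele IDs (or missing/ambiguous status)."""

    isolate_id: str
    genes: dict[str, int | CdsStatus]

    @property
    def complete(self) -> bool:
        return all(isinstance(v, int) for v in self.genes.values())

    def key(self) -> tuple:
        return tuple((g, v if isinstance(v, int) else v.value)
                     for g, v in sorted(self.genes.items()))


def build_allele_db(cds_maps: dict[str, dict[str, str | CdsStatus]]
                    ) -> tuple[AlleleDB, list[CDSProfile]]:
    """Build the non-redundant allele database and per-isolate profiles.

    ``cds_maps`` maps isolate id to the output of :func:`extract_cds`.
    Identical sequences share an ID; IDs are 1-based in first-seen order
    over the given isolate iteration order.
    """
    db = AlleleDB()
    profiles = []
    for iso, cds in cds_maps.items():
        genes: dict[str, int | CdsStatus] = {}
        for gene, seq in cds.items():
            if isinstance(seq, CdsStatus):
                genes[gene] = seq
            else:
                genes[gene] = db.add(gene, seq)
        profiles.append(CDSProfile(isolate_id=iso, genes=genes))
    return db, profiles


def unique_profile_count(profiles: list[CDSProfile]) -> tuple[int, int]:
    """(number of distinct complete profiles, number of complete isolates)."""
    complete = [p for p in profiles if p.complete]
    return len({p.key() for p in complete}), len(complete)


def profiles_to_frame(profiles: list[CDSProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"isolate": p.isolate_id, "complete": p.complete}
        for g, v in p.genes.items():
            row[g] = v if isinstance(v, int) else v.value
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# element and GC-cluster detection


@dataclass
class ElementHit:
    present: bool
    start: int = 0
    end: int = 0
    strand: str = "+"
    identity: float = 0.0


def detect_element(genome: MitoGenome, query: str,
                   min_identity: float = 0.90,
                   min_coverage: float = 0.90) -> ElementHit:
    """Presence of a mobile element / intron by similarity search.

    Present iff the best full-length infix alignment of the query reaches
    ``min_identity``. Full-length alignment means query coverage is 1 by
    construction (unaligned query ends are charged to the edit distance),
    so the identity threshold subsumes any ``min_coverage`` <= 1.
    """
    if not query:
        raise ValueError("empty query sequence")
    if not genome.sequence or len(genome.sequence) < 1:
        return ElementHit(present=False)
    ident, s, e, strand = _best_hit(genome.sequence, query)
    if ident < 0:
        return ElementHit(present=False)
    return ElementHit(present=ident >= min_identity, start=s, end=e,
                      strand=strand, identity=max(ident, 0.0))


@dataclass
class GcCluster:
    start: int
    end: int
    gc_fraction: float
    strand: str = "+"
    tandem: bool = False


def detect_gc_clusters(gene_sequence: str, window: int = 20,
                       min_gc: float = 0.70,
                       motif: str | None = None) -> list[GcCluster]:
    """Find GC-rich clusters inside an AT-rich gene.

    Maximal runs of length-``window`` windows whose GC fraction reaches
    ``min_gc`` are merged into clusters. When a ``motif`` is supplied, the
    cluster's orientation is the strand of its best motif alignment, and a
    cluster containing two or more non-overlapping motif copies is flagged
    as a tandem duplication.
    """
    n = len(gene_sequence)
    if n < window:
        raise ValueError(f"sequence shorter ({n}) than window ({window})")
    is_gc = np.frombuffer(gene_sequence.encode(), np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
    frac = np.convolve(is_gc, np.ones(window), "valid") / window
    hot = frac >= min_gc
    clusters = []
    i = 0
    while i < hot.size:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < hot.size and hot[j + 1]:
            j += 1
        start, end = i, j + window  # span of all qualifying windows
        sub = gene_sequence[start:end]
        gc = (sub.count("G") + sub.count("C")) / len(sub)
        strand, tandem = "+", False
        if motif:
            fwd = edlib.align(motif, sub, mode="HW")["editDistance"]
            rev = edlib.align(_revcomp(motif), sub, mode="HW")["editDistance"]
            strand = "+" if fwd <= rev else "-"
            q = motif if strand == "+" else _revcomp(motif)
            k = max(1, int(0.25 * len(motif)))
            res = edlib.align(q, sub, mode="HW", task="locations", k=k)
            locs = res["locations"] or []
            # count non-overlapping motif copies
            copies, last_end = 0, -1
            for s0, e0 in sorted(locs):
                if s0 > last_end:
                    copies += 1
                    last_end = e0
            tandem = copies >= 2
        clusters.append(GcCluster(start=start, end=end, gc_fraction=gc,
                                  strand=strand, tandem=tandem))
        i = j + 1
    return clusters
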