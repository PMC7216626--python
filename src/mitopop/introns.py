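"""Intron presence/absence matrices, frequencies, mutual exclusivity and
exon boundary-mutation scans.

COX1 and COB carry self-splicing group introns at named sites; presence
is called by similarity search of a reference intron sequence within the
host gene span (90% identity over 90% of the query by default). Exon
sequence flanking an insertion site is scanned for elevated minor-allele
frequencies, summarized as the ratio of mean minor-allele frequency in
the 20-nt windows adjacent to the boundary over the remaining flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .alleles import detect_element
from .diversity import Alignment
from .io import MitoGenome
from .sim import INTRON_SITES, host_gene

PRESENT, ABSENT, UNKNOWN = "present", "absent", "unknown"


def intron_matrix(genomes: list[MitoGenome], intron_refs: dict[str, str],
                  min_identity: float = 0.90,
                  min_coverage: float = 0.90) -> pd.DataFrame:
    """Isolates x intron sites matrix of {present, absent, unknown}.

    A cell is unknown when the host gene is missing from the genome.
    Sites outside the declared registry are still scanned if supplied, but
    callers should treat them as a separate report.
    """
    rows = {}
    for g in genomes:
        row = {}
        for site, ref_seq in intron_refs.items():
            gene = host_gene(site) if site in INTRON_SITES else None
            span = g.feature(gene) if gene else None
            if gene is not None and span is None:
                row[site] = UNKNOWN
                continue
            region = g.sequence[span.start:span.end] if span else g.sequence
            if not region:
                row[site] = UNKNOWN
                continue
            sub = MitoGenome(isolate_id=g.isolate_id, sequence=region)
            hit = detect_element(sub, ref_seq, min_identity=min_identity,
                                 min_coverage=min_coverage)
            row[site] = PRESENT if hit.present else ABSENT
        rows[g.isolate_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def intron_frequencies(matrix: pd.DataFrame,
                       clades: dict[str, str] | None = None
                       ) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-site population frequency = present / (present + absent).

    Unknown cells are excluded; an all-unknown column yields NaN. With
    clade labels, a per-clade frequency table is also returned.
    """
    def freq(col: pd.Series) -> float:
        n_p = (col == PRESENT).sum()
        n_a = (col == ABSENT).sum()
        return n_p / (n_p + n_a) if (n_p + n_a) else float("nan")

    pop = matrix.apply(freq, axis=0)
    per_clade = None
    if clades is not None:
        labels = pd.Series({i: clades[i] for i in matrix.index})
        per_clade = matrix.groupby(labels).agg(lambda c: freq(c))
    return pop, per_clade


@dataclass
class ExclusivePair:
    site_i: str
    site_j: str
    n_i: int
    n_j: int
    n_both: int
    p_value: float  # hypergeometric P(0 co-occurrences | marginals)


def exclusive_pairs(matrix: pd.DataFrame) -> list[ExclusivePair]:
    """Site pairs never observed together despite both occurring.

    For each such pair, the hypergeometric probability of drawing zero
    co-occurrences given the marginals quantifies how surprising the
    exclusivity is (small p = unlikely under independence).
    """
    out = []
    sites = list(matrix.columns)
    for a_i in range(len(sites)):
        for a_j in range(a_i + 1, len(sites)):
            si, sj = sites[a_i], sites[a_j]
            known = matrix[(matrix[si] != UNKNOWN) & (matrix[sj] != UNKNOWN)]
            n = len(known)
            if n == 0:
                continue
            n_i = int((known[si] == PRESENT).sum())
            n_j = int((known[sj] == PRESENT).sum())
            n_both = int(((known[si] == PRESENT) & (known[sj] == PRESENT)).sum())
            if n_i > 0 and n_j > 0 and n_both == 0:
                p = float(hypergeom.pmf(0, n, n_i, n_j))
                out.append(ExclusivePair(site_i=si, site_j=sj, n_i=n_i,
                                         n_j=n_j, n_both=0, p_value=p))
    return out


@dataclass
class BoundaryScanResult:
    site: str
    positions: np.ndarray   # offsets relative to the boundary (negative = 5')
    maf: np.ndarray         # minor-allele frequency per position
    near_mean: float
    far_mean: float
    ratio: float            # near/far; NaN when far_mean is 0
    p_value: float


def _column_maf(col: np.ndarray) -> float:
    counts = np.array([(col == b).sum() for b in range(4)])
    tot = counts.sum()
    if tot == 0:
        return float("nan")
    return 1.0 - counts.max() / tot


def boundary_scan(alignment: Alignment, insertion_offsets: dict[str, int],
                  flank: int = 70, near: int = 20,
                  n_permutations: int = 999,
                  seed: int | None = None) -> list[BoundaryScanResult]:
    """Scan exon alignment columns flanking intron insertion sites.

    ``insertion_offsets`` maps each intron site to its insertion boundary
    in the exon alignment's coordinates (column index; the intron sits
    between columns offset-1 and offset). For each site, the minor-allele
    frequency of every column within ``flank`` positions of the boundary
    is computed; the summary is mean MAF over the ``near``-window adjacent
    to the boundary divided by mean MAF over the remaining flank, with a
    permutation p-value obtained by shuffling the near/far position
    labels.
    """
    rng = np.random.default_rng(seed)
    L = alignment.length
    results = []
    for site, off in insertion_offsets.items():
        lo = max(0, off - flank)
        hi = min(L, off + flank)
        if off - flank < 0 or off + flank > L:
            import warnings
            warnings.warn(f"{site}: flank truncated to [{lo},{hi})")
        positions = np.arange(lo, hi)
        rel = np.where(positions < off, positions - off, positions - off + 1)
        maf = np.array([_column_maf(alignment.matrix[:, j]) for j in positions])
        near_mask = np.abs(rel) <= near
        near_vals = maf[near_mask & ~np.isnan(maf)]
        far_vals = maf[~near_mask & ~np.isnan(maf)]
        near_mean = float(near_vals.mean()) if near_vals.size else float("nan")
        far_mean = float(far_vals.mean()) if far_vals.size else float("nan")
        if not np.isfinite(far_mean) or far_mean == 0.0:
            ratio, p = float("nan"), float("nan")
        else:
            ratio = near_mean / far_mean
            valid = maf[~np.isnan(maf)]
            labels = near_mask[~np.isnan(maf)]
            n_near = int(labels.sum())
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(valid.size)[:n_near]
                sel = np.zeros(valid.size, bool)
                sel[perm] = True
                fm = valid[~sel].mean()
                if fm > 0 and valid[sel].mean() / fm >= ratio:
                    count += 1
            p = (count + 1) / (n_permutations + 1)
        results.append(BoundaryScanResult(
            site=site, positions=rel, maf=maf, near_mean=near_mean,
            far_mean=far_mean, ratio=ratio, p_value=p))
    return results
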