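"""Synthetic mitochondrial populations with known ground truth.

The generator emulates the salient features of budding-yeast mtDNA: a
~85 kb AT-rich genome carrying the eight canonical protein-coding genes
(ATP6, ATP8, ATP9, COB, COX1, COX2, COX3, VAR1) at their S288C lengths,
two rRNAs, 24 tRNAs, homing-endonuclease elements, optional group introns
at the named COX1/COB sites, GC-cluster insertions in intergenic DNA,
multi-lineage population structure with single-generation admixture
crossovers, planted donor-species introgression blocks, and Poisson read
depth scaling with ploidy x copy number (including rho-/rho0 petites).

Internally every simulated haplotype lives on one fixed-length "master"
coordinate grid: the reference genome with *every* registry intron present.
Mutations, crossovers and introgression replacements are applied on that
grid; intron absence is an excision performed only when a genome is
emitted. This keeps all haplotypes colinear and makes ground truth exact.

Randomness: one root seed; independent child streams are spawned in a
fixed, documented order (0 = master/reference, 1 = population, 2 = donor,
3 = coverage, 4 = cohort truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .io import GeneAnnotation, MitoGenome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

#: S288C coding-sequence lengths (nt) of the eight canonical genes
CDS_LENGTHS = {
    "ATP6": 780, "ATP8": 147, "ATP9": 231, "COB": 1158,
    "COX1": 1605, "COX2": 756, "COX3": 810, "VAR1": 1197,
}
CANONICAL_GENES = tuple(CDS_LENGTHS)

#: named optional intron sites (site registry); host gene is implied by prefix
COX1_INTRON_SITES = ("ai1", "ai2", "ai3α", "ai3β",
                     "ai4α", "ai4β", "ai5α", "ai5β")
COB_INTRON_SITES = ("bi1α", "bi1β", "bi2", "bi3", "bi4", "bi5")
INTRON_SITES = COX1_INTRON_SITES + COB_INTRON_SITES


def host_gene(site: str) -> str:
    return "COX1" if site.startswith("a") else "COB"


#: yeast-mitochondrial-like gene order used for the synthetic reference
#: (protein-coding genes all on '+', mimicking the single-strand rule)
_TRNAS = ("trnP", "trnW", "trnE", "trnR1", "trnF", "trnT1", "trnV", "trnS1",
          "trnT2", "trnC", "trnH", "trnL", "trnQ", "trnK", "trnG", "trnD",
          "trnS2", "trnR2", "trnA", "trnI", "trnY", "trnN", "trnM1", "trnM2")
GENE_ORDER = (
    "trnP", "rns", "trnW", "trnE", "COX1", "ATP8", "ATP6", "trnR1", "COB",
    "trnF", "trnT1", "trnV", "ATP9", "trnS1", "VAR1", "rnl", "trnT2", "trnC",
    "trnH", "trnL", "trnQ", "trnK", "trnG", "trnD", "trnS2", "trnR2", "trnA",
    "trnI", "trnY", "trnN", "trnM1", "COX2", "trnM2", "COX3",
    "F-SceI", "RF2", "F-SceIII",
)
_RRNA_LEN = {"rns": 1600, "rnl": 4400}
_ELEMENT_LEN = {"F-SceI": 1502, "RF2": 1484, "F-SceIII": 1490, "F-SceIV": 1143}
_INTRON_LEN = {s: 1300 if s in COX1_INTRON_SITES else 900 for s in INTRON_SITES}

NUCLEAR_CHROMOSOMES = tuple(f"chr{r}" for r in (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI"))


class ConfigError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study population.

    Rates are per-site substitution probabilities on a lineage branch;
    ``donor_divergence`` is the CDS substitution rate separating the donor
    species from the recipient reference and must exceed the intraspecific
    rates for diagnostic markers to be derivable.
    """

    seed: int = 0
    n_lineages: int = 5
    isolates_per_lineage: int = 10
    per_site_mutation_rate_cds: float = 0.00425
    per_site_mutation_rate_intergenic: float = 0.0085
    within_lineage_rate_scale: float = 0.1
    admixed_fraction: float = 0.2
    admixture_events: int = 1
    donor_divergence: float = 0.02
    intron_gain_rate: float = 0.1
    intron_loss_rate: float = 0.1
    reference_intron_probability: float = 1.0
    per_haploid_cn_mean: float = 18.0
    per_haploid_cn_cv: float = 0.25
    nuclear_depth_per_haploid: float = 30.0
    petite_fraction: float = 0.015
    rho_minus_fraction: float = 0.13
    noise_depth: float = 0.05
    ploidy_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.7, 3: 0.07, 4: 0.03})
    genome_length: int = 85_000
    intergenic_at_fraction: float = 0.82
    n_gc_clusters: int = 10

    def validate(self) -> None:
        probs = {
            "per_site_mutation_rate_cds": self.per_site_mutation_rate_cds,
            "per_site_mutation_rate_intergenic": self.per_site_mutation_rate_intergenic,
            "admixed_fraction": self.admixed_fraction,
            "donor_divergence": self.donor_divergence,
            "intron_gain_rate": self.intron_gain_rate,
            "intron_loss_rate": self.intron_loss_rate,
            "reference_intron_probability": self.reference_intron_probability,
            "petite_fraction": self.petite_fraction,
            "rho_minus_fraction": self.rho_minus_fraction,
            "intergenic_at_fraction": self.intergenic_at_fraction,
        }
        for k, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{k} must be a probability in [0,1], got {v}")
        for k in ("n_lineages", "isolates_per_lineage"):
            if getattr(self, k) < 1:
                raise ConfigError(f"{k} must be >= 1")
        if self.admixture_events < 0:
            raise ConfigError("admixture_events must be >= 0")
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        if self.donor_divergence <= self.per_site_mutation_rate_cds:
            raise ConfigError(
                "donor_divergence must exceed the intraspecific CDS rate")
        tot = sum(self.ploidy_distribution.values())
        if not np.isclose(tot, 1.0) or any(p < 1 for p in self.ploidy_distribution):
            raise ConfigError("ploidy_distribution must map ploidies >=1 to "
                              "probabilities summing to 1")

    def _streams(self) -> list[np.random.Generator]:
        # fixed stream order: 0 master, 1 population, 2 donor, 3 coverage,
        # 4 cohort truth, 5 reference intron presence
        ss = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(c) for c in ss.spawn(6)]


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated population."""

    lineage: dict[str, int] = field(default_factory=dict)
    admixture: dict[str, dict] = field(default_factory=dict)
    intron_presence: dict[str, dict[str, bool]] = field(default_factory=dict)
    introgressions: list[dict] = field(default_factory=list)
    ploidy: dict[str, int] = field(default_factory=dict)
    per_haploid_cn: dict[str, float] = field(default_factory=dict)
    rho_status: dict[str, str] = field(default_factory=dict)
    retained_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# master genome construction (stream 0)


def _random_cds(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random AT-leaning coding sequence: ATG start, TAA stop, no internal
    stops under the yeast mitochondrial code (TAA/TAG are stops; TGA = Trp)."""
    assert length % 3 == 0
    stops = {(3, 0, 0), (3, 0, 2)}  # TAA, TAG
    codons = [(a, b, c) for a in range(4) for b in range(4) for c in range(4)
              if (a, b, c) not in stops]
    at = np.array([sum(x in (_A, _T) for x in cod) for cod in codons], float)
    w = (1.0 + at) ** 2
    w /= w.sum()
    n_mid = length // 3 - 2
    picks = rng.choice(len(codons), size=n_mid, p=w)
    body = np.array([b for i in picks for b in codons[i]], dtype=np.uint8)
    return np.concatenate([np.array([_A, _T, _G], np.uint8), body,
                           np.array([3, 0, 0], np.uint8)])


def _random_seq(rng: np.random.Generator, length: int, at: float) -> np.ndarray:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return arr


@dataclass
class _Master:
    """Reference coordinate grid with every registry intron present."""

    arr: np.ndarray
    features: list[GeneAnnotation]
    cds_mask: np.ndarray       # True on exonic CDS sites
    intron_spans: dict[str, tuple[int, int]]
    intron_seqs: dict[str, str]

    @property
    def length(self) -> int:
        return self.arr.size


def build_master(config: SimConfig) -> _Master:
    """Deterministically build the all-introns master genome (stream 0)."""
    config.validate()
    rng = config._streams()[0]

    # per-feature sequences
    parts: list[tuple[str, str, np.ndarray, list[tuple[str, int, np.ndarray]]]] = []
    for name in GENE_ORDER:
        if name in CDS_LENGTHS:
            seq = _random_cds(rng, CDS_LENGTHS[name])
            introns = []
            if name in ("COX1", "COB"):
                sites = [s for s in INTRON_SITES if host_gene(s) == name]
                # insertion offsets: interior codon boundaries, evenly spread
                n_codons = CDS_LENGTHS[name] // 3
                offs = np.linspace(0.12, 0.88, len(sites))
                for s, fr in zip(sites, offs):
                    off = 3 * int(fr * n_codons)
                    iseq = _random_seq(rng, _INTRON_LEN[s], at=0.78)
                    introns.append((s, off, iseq))
            parts.append((name, "CDS", seq, introns))
        elif name in _RRNA_LEN:
            seq = _random_seq(rng, _RRNA_LEN[name], at=0.75)
            introns = []
            if name == "rnl":  # omega intron carries the F-SceIV endonuclease
                iseq = _random_seq(rng, _ELEMENT_LEN["F-SceIV"], at=0.70)
                introns.append(("F-SceIV", _RRNA_LEN[name] // 2, iseq))
            parts.append((name, "rRNA", seq, introns))
        elif name in _ELEMENT_LEN:
            parts.append((name, "element", _random_seq(rng, _ELEMENT_LEN[name], at=0.70), []))
        else:  # tRNA
            parts.append((name, "tRNA", _random_seq(rng, 73, at=0.72), []))

    genic_len = sum(p[2].size + sum(i[2].size for i in p[3]) for p in parts)
    n_gaps = len(parts) + 1
    intergenic_total = config.genome_length - genic_len
    if intergenic_total < n_gaps * 20:
        raise ConfigError(
            f"genome_length {config.genome_length} too small for gene content "
            f"({genic_len} nt genic)")
    gap_w = rng.dirichlet(np.full(n_gaps, 3.0))
    gap_lens = np.maximum((gap_w * intergenic_total).astype(int), 20)
    gc_slots = rng.choice(n_gaps, size=min(config.n_gc_clusters, n_gaps), replace=False)

    chunks: list[np.ndarray] = []
    features: list[GeneAnnotation] = []
    pos = 0

    def _push_gap(i: int) -> None:
        nonlocal pos
        gap = _random_seq(rng, int(gap_lens[i]), at=config.intergenic_at_fraction)
        if i in gc_slots and gap.size > 60:
            ins = rng.integers(10, gap.size - 50)
            gc = rng.choice(4, size=36, p=[0.075, 0.425, 0.425, 0.075]).astype(np.uint8)
            gap = np.concatenate([gap[:ins], gc, gap[ins:]])
            features.append(GeneAnnotation(f"gc{i}", pos + ins, pos + ins + 36,
                                           "+", "GC_cluster"))
        chunks.append(gap)
        pos += gap.size

    intron_spans: dict[str, tuple[int, int]] = {}
    intron_seqs: dict[str, str] = {}
    for i, (name, kind, seq, introns) in enumerate(parts):
        _push_gap(i)
        start = pos
        cursor = 0
        gene_chunks = []
        for site, off, iseq in sorted(introns, key=lambda t: t[1]):
            gene_chunks.append(seq[cursor:off])
            pos += off - cursor
            if site in INTRON_SITES:  # F-SceIV (omega) is fixed, never excised
                intron_spans[site] = (pos, pos + iseq.size)
            intron_seqs[site] = _decode(iseq)
            features.append(GeneAnnotation(site, pos, pos + iseq.size, "+", "intron"))
            gene_chunks.append(iseq)
            pos += iseq.size
            cursor = off
        gene_chunks.append(seq[cursor:])
        pos += seq.size - cursor
        chunks.extend(gene_chunks)
        features.append(GeneAnnotation(name, start, pos, "+", kind))
    _push_gap(len(parts))

    arr = np.concatenate(chunks)
    cds_mask = np.zeros(arr.size, bool)
    for f in features:
        if f.kind == "CDS":
            cds_mask[f.start:f.end] = True
    for f in features:
        if f.kind == "intron":
            cds_mask[f.start:f.end] = False
    return _Master(arr=arr, features=sorted(features, key=lambda f: f.start),
                   cds_mask=cds_mask, intron_spans=intron_spans,
                   intron_seqs=intron_seqs)


def _excise(arr: np.ndarray, features: list[GeneAnnotation],
            drop_spans: list[tuple[int, int]],
            drop_names: set[str]) -> tuple[str, list[GeneAnnotation]]:
    """Remove intervals from a master-grid sequence, shifting coordinates."""
    drop_spans = sorted(drop_spans)
    keep = np.ones(arr.size, bool)
    for s, e in drop_spans:
        keep[s:e] = False
    starts = np.array([s for s, _ in drop_spans])
    lens = np.array([e - s for s, e in drop_spans])
    cum = np.cumsum(lens)

    def shift(x: int) -> int:
        i = np.searchsorted(starts, x, side="right") - 1
        removed = cum[i] if i >= 0 else 0
        return x - removed

    out_feats = []
    for f in features:
        if f.name in drop_names:
            continue
        if any(s <= f.start and f.end <= e for s, e in drop_spans):
            continue
        out_feats.append(GeneAnnotation(f.name, shift(f.start), shift(f.end),
                                        f.strand, f.kind))
    return _decode(arr[keep]), out_feats


def _emit(master: _Master, arr: np.ndarray, isolate_id: str,
          present: dict[str, bool]) -> MitoGenome:
    drop = [(s, master.intron_spans[s][0], master.intron_spans[s][1])
            for s in INTRON_SITES if not present.get(s, True)]
    seq, feats = _excise(arr, master.features,
                         [(s0, e0) for _, s0, e0 in drop],
                         {s for s, _, _ in drop})
    return MitoGenome(isolate_id=isolate_id, sequence=seq, features=feats)


def simulate_reference(config: SimConfig) -> MitoGenome:
    """Build the synthetic reference genome ("S288C-like").

    Carries the eight canonical CDSs at their S288C lengths; each registry
    intron is present with ``reference_intron_probability`` (drawn on the
    master stream, so the reference is a pure function of the config).
    """
    master = build_master(config)
    return _emit(master, master.arr, "REF", _reference_presence(config))


def _reference_presence(config: SimConfig) -> dict[str, bool]:
    rng = config._streams()[5]
    return {s: bool(rng.random() < config.reference_intron_probability)
            for s in INTRON_SITES}


# ---------------------------------------------------------------------------
# population (stream 1)


def _mutate(rng: np.random.Generator, arr: np.ndarray, cds_mask: np.ndarray,
            rate_cds: float, rate_other: float) -> np.ndarray:
    """Independent per-site substitution; AT-biased replacement outside CDS."""
    out = arr.copy()
    rate = np.where(cds_mask, rate_cds, rate_other)
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size == 0:
        return out
    # replacement base drawn among the three alternatives; outside CDS the
    # draw is AT-biased to preserve base composition at equilibrium
    for pos in idx:
        cur = out[pos]
        alts = [b for b in range(4) if b != cur]
        if cds_mask[pos]:
            out[pos] = rng.choice(alts)
        else:
            w = np.array([0.41 if b in (_A, _T) else 0.09 for b in alts])
            out[pos] = rng.choice(alts, p=w / w.sum())
    return out


def simulate_population(ref: MitoGenome, config: SimConfig
                        ) -> tuple[list[MitoGenome], TruthRecord]:
    """Simulate a structured population descended from ``ref``.

    Founder lineages diverge from the reference by independent mutations;
    each isolate adds within-lineage mutations; a configurable fraction of
    isolates are single-generation crossovers between two lineage
    haplotypes at uniformly drawn breakpoints. Intron gain/loss happens on
    the star lineage tree. Ploidy, per-haploid copy number and rho status
    are drawn per isolate and recorded in the truth record.
    """
    config.validate()
    master = build_master(config)
    if len(ref.sequence) > master.length:
        raise ConfigError("reference does not match the config's master genome")
    rng = config._streams()[1]
    L = master.length
    nlin = config.n_lineages

    ref_present = _reference_presence(config)
    lin_haplo = []
    lin_intron = []
    for _ in range(nlin):
        lin_haplo.append(_mutate(rng, master.arr, master.cds_mask,
                                 config.per_site_mutation_rate_cds,
                                 config.per_site_mutation_rate_intergenic))
        pres = {}
        for s in INTRON_SITES:
            if ref_present[s]:
                pres[s] = not (rng.random() < config.intron_loss_rate)
            else:
                pres[s] = bool(rng.random() < config.intron_gain_rate)
        lin_intron.append(pres)

    truth = TruthRecord()
    genomes: list[MitoGenome] = []
    n_iso = nlin * config.isolates_per_lineage
    sc = config.within_lineage_rate_scale
    for i in range(n_iso):
        iso = f"iso{i:03d}"
        lin = i % nlin
        admixed = (config.admixture_events > 0
                   and nlin >= 2
                   and rng.random() < config.admixed_fraction)
        if admixed:
            other = int(rng.choice([l for l in range(nlin) if l != lin]))
            bps = sorted(int(b) for b in rng.integers(0, L, size=config.admixture_events))
            hap = lin_haplo[lin].copy()
            pres = dict(lin_intron[lin])
            donors = [lin, other]
            edges = [0] + bps + [L]
            for seg_i, (s, e) in enumerate(zip(edges, edges[1:])):
                src = donors[seg_i % 2]
                hap[s:e] = lin_haplo[src][s:e]
                for site, (ss, _se) in master.intron_spans.items():
                    if s <= ss < e:
                        pres[site] = lin_intron[src][site]
            truth.admixture[iso] = {"lineages": donors, "breakpoints": bps}
        else:
            hap = lin_haplo[lin].copy()
            pres = dict(lin_intron[lin])
        if sc > 0:
            hap = _mutate(rng, hap, master.cds_mask,
                          config.per_site_mutation_rate_cds * sc,
                          config.per_site_mutation_rate_intergenic * sc)
        truth.lineage[iso] = lin
        truth.intron_presence[iso] = {s: bool(v) for s, v in pres.items()}
        genomes.append(_emit(master, hap, iso, pres))

        # per-isolate cellular state
        pl_vals = sorted(config.ploidy_distribution)
        pl_p = [config.ploidy_distribution[v] for v in pl_vals]
        ploidy = int(rng.choice(pl_vals, p=np.array(pl_p) / np.sum(pl_p)))
        cv = config.per_haploid_cn_cv
        if cv > 0:
            shape = 1.0 / cv**2
            cn = float(rng.gamma(shape, config.per_haploid_cn_mean / shape))
        else:
            cn = float(config.per_haploid_cn_mean)
        if rng.random() < config.petite_fraction:
            if rng.random() < config.rho_minus_fraction:
                status = "rho_minus"
                k = int(rng.integers(1, 3))
                retained = sorted(rng.choice(CANONICAL_GENES, size=k, replace=False))
            else:
                status, retained = "rho_zero", []
        else:
            status, retained = "rho_plus", list(CANONICAL_GENES)
        truth.ploidy[iso] = ploidy
        truth.per_haploid_cn[iso] = cn
        truth.rho_status[iso] = status
        truth.retained_genes[iso] = [str(g) for g in retained]
    return genomes, truth


def simulate_donor(config: SimConfig) -> MitoGenome:
    """Donor-species genome: the master evolved at ``donor_divergence``
    (stream 2); all registry introns present."""
    master = build_master(config)
    rng = config._streams()[2]
    arr = _mutate(rng, master.arr, master.cds_mask,
                  config.donor_divergence,
                  min(1.0, config.donor_divergence * 2.0))
    return _emit(master, arr, "DONOR", {s: True for s in INTRON_SITES})


# ---------------------------------------------------------------------------
# introgression planting


def plant_introgressions(genomes: list[MitoGenome], donor: MitoGenome,
                         spec: Sequence[tuple[str, str, int, int]]
                         ) -> tuple[list[MitoGenome], TruthRecord]:
    """Replace spliced-CDS intervals with donor sequence.

    ``spec`` rows are (isolate_id, gene, start, end) with start/end 0-based
    half-open offsets in the gene's spliced coding sequence. Both recipient
    and donor must be annotated and gene-wise colinear (equal spliced CDS
    lengths, as produced by this simulator).
    """
    by_id = {g.isolate_id: g for g in genomes}
    truth = TruthRecord()
    out = {g.isolate_id: g for g in genomes}
    for iso, gene, start, end in spec:
        if iso not in by_id:
            raise KeyError(f"unknown isolate {iso}")
        g = out[iso]
        feat = g.feature(gene)
        donor_cds = donor.spliced_cds(gene)
        if feat is None or donor_cds is None:
            raise ValueError(f"gene {gene} not annotated in {iso} or donor")
        own_cds = g.spliced_cds(gene)
        if len(own_cds) != len(donor_cds):
            raise ValueError(f"gene {gene}: recipient/donor CDS lengths differ")
        if not (0 <= start < end <= len(own_cds)):
            raise ValueError(
                f"interval [{start},{end}) outside gene {gene} "
                f"(spliced length {len(own_cds)})")
        # map spliced offsets to genomic positions (exon coordinates)
        positions = []
        pos = feat.start
        for i in g.introns_of(gene):
            positions.extend(range(pos, i.start))
            pos = i.end
        positions.extend(range(pos, feat.end))
        seq = list(g.sequence)
        for k in range(start, end):
            seq[positions[k]] = donor_cds[k]
        out[iso] = MitoGenome(isolate_id=g.isolate_id, sequence="".join(seq),
                              features=list(g.features), circular=g.circular)
        truth.introgressions.append(
            {"isolate": iso, "gene": gene, "start": int(start), "end": int(end)})
    return [out[g.isolate_id] for g in genomes], truth


# ---------------------------------------------------------------------------
# coverage (streams 3 and 4)


def simulate_cohort_truth(config: SimConfig, n_isolates: int) -> TruthRecord:
    """Sample ploidy / copy number / rho status for a cohort without
    simulating sequences (stream 4); used for depth-only experiments."""
    config.validate()
    rng = config._streams()[4]
    truth = TruthRecord()
    pl_vals = sorted(config.ploidy_distribution)
    pl_p = np.array([config.ploidy_distribution[v] for v in pl_vals])
    pl_p = pl_p / pl_p.sum()
    for i in range(n_isolates):
        iso = f"iso{i:03d}"
        truth.ploidy[iso] = int(rng.choice(pl_vals, p=pl_p))
        cv = config.per_haploid_cn_cv
        if cv > 0:
            shape = 1.0 / cv**2
            truth.per_haploid_cn[iso] = float(
                rng.gamma(shape, config.per_haploid_cn_mean / shape))
        else:
            truth.per_haploid_cn[iso] = float(config.per_haploid_cn_mean)
        if rng.random() < config.petite_fraction:
            if rng.random() < config.rho_minus_fraction:
                truth.rho_status[iso] = "rho_minus"
                k = int(rng.integers(1, 3))
                truth.retained_genes[iso] = sorted(
                    rng.choice(CANONICAL_GENES, size=k, replace=False))
            else:
                truth.rho_status[iso] = "rho_zero"
                truth.retained_genes[iso] = []
        else:
            truth.rho_status[iso] = "rho_plus"
            truth.retained_genes[iso] = list(CANONICAL_GENES)
        truth.lineage[iso] = 0
    return truth


def simulate_coverage(truth: TruthRecord, config: SimConfig):
    """Per-feature median read depth from the cellular state in ``truth``.

    Mitochondrial feature depth ~ median of per-site Poisson draws with
    mean ``nuclear_depth_per_haploid x ploidy x per_haploid_cn`` (so the
    mito/nuclear depth ratio equals the per-haploid copy number); nuclear
    chromosome depth ~ Poisson with mean depth x ploidy. rho0 isolates sit
    at the noise floor on every mitochondrial feature; rho- only on the
    genes they lost. Depth medians are taken over per-site draws (feature
    length sites for CDSs, a 2000-site sample per nuclear chromosome).
    """
    from .io import CoverageTable

    config.validate()
    rng = config._streams()[3]
    d = config.nuclear_depth_per_haploid
    mito_rows, nuc_rows = [], []
    for iso in truth.ploidy:
        ploidy = truth.ploidy[iso]
        cn = truth.per_haploid_cn[iso]
        status = truth.rho_status.get(iso, "rho_plus")
        retained = set(truth.retained_genes.get(iso, CANONICAL_GENES))
        for gene in CANONICAL_GENES:
            if status == "rho_zero" or (status == "rho_minus" and gene not in retained):
                lam = config.noise_depth
            else:
                lam = d * ploidy * cn
            depth = float(np.median(rng.poisson(lam, size=CDS_LENGTHS[gene])))
            mito_rows.append((iso, gene, depth))
        for chrom in NUCLEAR_CHROMOSOMES:
            depth = float(np.median(rng.poisson(d * ploidy, size=2000)))
            nuc_rows.append((iso, chrom, depth))
    import pandas as pd
    return CoverageTable(
        mito=pd.DataFrame(mito_rows, columns=["isolate", "feature", "median_depth"]),
        nuclear=pd.DataFrame(nuc_rows, columns=["isolate", "chromosome", "median_depth"]),
        ploidy=dict(truth.ploidy),
    )
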