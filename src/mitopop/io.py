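"""Readers/writers for external formats and the core genome containers.

Internal coordinates are 0-based half-open everywhere; GFF3 is the only
1-based inclusive surface and the conversion happens exactly once, here.
Readers validate strictly and reject rather than silently repair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: feature kinds understood by the pipeline, mapped to GFF3 type strings
FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "intron", "element", "GC_cluster")
_GFF_TYPE = {
    "CDS": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "intron": "intron",
    "element": "mobile_genetic_element",
    "GC_cluster": "sequence_feature",
}
_GFF_TYPE_REV = {v: k for k, v in _GFF_TYPE.items()}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GeneAnnotation:
    """One annotated feature on a mitochondrial genome.

    ``start``/``end`` are 0-based half-open offsets on the linearized
    sequence; ``kind`` is one of :data:`FEATURE_KINDS`.
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "CDS"

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"feature {self.name}: need 0 <= start < end, got "
                             f"[{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.name}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MitoGenome:
    """One isolate's mitochondrial sequence plus feature annotations."""

    isolate_id: str
    sequence: str
    features: list[GeneAnnotation] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise FormatError(
                f"{self.isolate_id}: illegal character {self.sequence[pos]!r} "
                f"at offset {pos}")
        self.validate_features()

    def validate_features(self) -> None:
        n = len(self.sequence)
        cds = []
        for f in self.features:
            if f.end > n:
                raise FormatError(
                    f"{self.isolate_id}: feature {f.name} [{f.start},{f.end}) "
                    f"exceeds sequence length {n}")
            if f.kind == "CDS":
                cds.append(f)
        cds.sort(key=lambda f: f.start)
        for a, b in zip(cds, cds[1:]):
            if b.start < a.end:
                raise FormatError(
                    f"{self.isolate_id}: CDS features {a.name} and {b.name} overlap")
        # introns must nest within their host gene span
        genic = [f for f in self.features if f.kind in ("CDS", "rRNA")]
        for f in self.features:
            if f.kind == "intron":
                if not any(g.start <= f.start and f.end <= g.end for g in genic):
                    raise FormatError(
                        f"{self.isolate_id}: intron {f.name} not nested in any gene")

    def feature(self, name: str) -> GeneAnnotation | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def features_of_kind(self, kind: str) -> list[GeneAnnotation]:
        return sorted((f for f in self.features if f.kind == kind),
                      key=lambda f: f.start)

    def introns_of(self, gene: str) -> list[GeneAnnotation]:
        """Intron features nested within the named gene's span, in order."""
        g = self.feature(name=gene)
        if g is None:
            return []
        return sorted((f for f in self.features
                       if f.kind == "intron" and g.start <= f.start and f.end <= g.end),
                      key=lambda f: f.start)

    def spliced_cds(self, gene: str) -> str | None:
        """Coding sequence of ``gene`` with nested introns removed.

        Returns None when the gene is not annotated. Minus-strand genes are
        reverse-complemented into coding orientation.
        """
        g = self.feature(gene)
        if g is None:
            return None
        introns = self.introns_of(gene)
        parts, pos = [], g.start
        for i in introns:
            parts.append(self.sequence[pos:i.start])
            pos = i.end
        parts.append(self.sequence[pos:g.end])
        seq = "".join(parts)
        if g.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class CoverageTable:
    """Per-(isolate, feature) and per-(isolate, chromosome) median depths.

    ``mito`` columns: isolate, feature, median_depth (0-based half-open
    BED-like convention applies to any interval columns).  ``nuclear``
    columns: isolate, chromosome, median_depth.  ``ploidy`` maps isolate to
    its integer ploidy.
    """

    mito: pd.DataFrame
    nuclear: pd.DataFrame
    ploidy: dict[str, int]

    def __post_init__(self) -> None:
        if (self.mito["median_depth"] < 0).any() or (self.nuclear["median_depth"] < 0).any():
            raise FormatError("coverage depths must be non-negative")
        if any(p < 1 for p in self.ploidy.values()):
            raise FormatError("ploidy must be >= 1")

    def isolates(self) -> list[str]:
        return sorted(set(self.mito["isolate"]))

    def write(self, mito_path, nuclear_path, ploidy_path) -> None:
        self.mito.to_csv(mito_path, sep="\t", index=False)
        self.nuclear.to_csv(nuclear_path, sep="\t", index=False)
        pd.DataFrame({"isolate": list(self.ploidy), "ploidy": list(self.ploidy.values())}
                     ).to_csv(ploidy_path, sep="\t", index=False)

    @classmethod
    def read(cls, mito_path, nuclear_path, ploidy_path) -> "CoverageTable":
        mito = pd.read_csv(mito_path, sep="\t")
        nuc = pd.read_csv(nuclear_path, sep="\t")
        pl = pd.read_csv(ploidy_path, sep="\t")
        for df, cols in ((mito, {"isolate", "feature", "median_depth"}),
                         (nuc, {"isolate", "chromosome", "median_depth"})):
            if not cols <= set(df.columns):
                raise FormatError(f"coverage table missing columns {cols - set(df.columns)}")
        return cls(mito=mito, nuclear=nuc,
                   ploidy=dict(zip(pl["isolate"], pl["ploidy"].astype(int))))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[MitoGenome]:
    """Read a multi-record FASTA into genomes (sequences only, uppercased)."""
    genomes, seen = [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        genomes.append(MitoGenome(isolate_id=rec.id, sequence=seq))
    return genomes


def write_fasta(genomes: list[MitoGenome], path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.isolate_id, description="")
               for g in genomes]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (strict 9-column subset; the single 1-based surface)


def write_gff(genomes: list[MitoGenome], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genomes:
            fh.write(f"##sequence-region {g.isolate_id} 1 {len(g.sequence)}\n")
            for f in sorted(g.features, key=lambda f: (f.start, f.end)):
                fh.write("\t".join([
                    g.isolate_id, "mitopop", _GFF_TYPE[f.kind],
                    str(f.start + 1), str(f.end), ".", f.strand, ".",
                    f"ID={f.name};Name={f.name}",
                ]) + "\n")


def read_gff(path, genomes: list[MitoGenome]) -> list[MitoGenome]:
    """Attach GFF3 features to ``genomes`` (matched by seqid), in place."""
    by_id = {g.isolate_id: g for g in genomes}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if seqid not in by_id:
                raise FormatError(f"{path}:{lineno}: unknown seqid {seqid!r}")
            if ftype not in _GFF_TYPE_REV:
                raise FormatError(f"{path}:{lineno}: unknown feature type {ftype!r}")
            name = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    name = kv[3:]
            if name is None:
                raise FormatError(f"{path}:{lineno}: feature lacks ID attribute")
            g = by_id[seqid]
            s, e = int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open
            if e > len(g.sequence) or s < 0:
                raise FormatError(
                    f"{path}:{lineno}: feature {name} [{start},{end}] outside "
                    f"sequence {seqid} of length {len(g.sequence)}")
            g.features.append(GeneAnnotation(
                name=name, start=s, end=e, strand=strand, kind=_GFF_TYPE_REV[ftype]))
    for g in genomes:
        g.validate_features()
    return genomes


# ---------------------------------------------------------------------------
# newick (via dendropy)


def read_newick(path_or_str) -> dendropy.Tree:
    if isinstance(path_or_str, (str, Path)) and Path(str(path_or_str)).exists():
        data = Path(path_or_str).read_text()
    else:
        data = str(path_or_str)
    try:
        return dendropy.Tree.get(data=data, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"malformed newick: {exc}") from exc


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


# ---------------------------------------------------------------------------
# TSV/JSON helpers


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
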