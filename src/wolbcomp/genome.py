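"""Annotated-genome domain types and FASTA/GFF3/GenBank plumbing.

Coordinates follow the usual dual convention: annotation files (GFF3,
GenBank) are 1-based inclusive; internally every feature is stored 0-based
half-open, and reported intervals are re-emitted 1-based.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation
from Bio.SeqRecord import SeqRecord

from ._codons import revcomp

CATEGORIES = ("core", "phage", "repeat", "hypothetical", "pseudogene")

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


class GenomeError(ValueError):
    """Raised on malformed or inconsistent genome input."""


@dataclass
class GeneFeature:
    """A single-interval CDS feature.

    ``start``/``end`` are 0-based half-open on the scaffold; ``cds_seq`` is
    strand-resolved (5'->3' of the coding strand).
    """

    locus_tag: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    category: str = "hypothetical"
    cds_seq: str = ""
    frame_warning: bool = False

    @property
    def start1(self) -> int:
        """1-based inclusive start, as written to annotation files."""
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end

    def __len__(self) -> int:
        return self.end - self.start

    def validate(self) -> None:
        if self.end < self.start:
            raise GenomeError(f"{self.locus_tag}: end < start")
        if self.strand not in "+-":
            raise GenomeError(f"{self.locus_tag}: bad strand {self.strand!r}")
        if self.category not in CATEGORIES:
            raise GenomeError(f"{self.locus_tag}: bad category {self.category!r}")
        if not _VALID_SEQ.match(self.cds_seq):
            raise GenomeError(f"{self.locus_tag}: cds_seq has non-ACGTN characters")
        if self.cds_seq and len(self.cds_seq) != len(self):
            raise GenomeError(f"{self.locus_tag}: cds_seq length != span")


@dataclass
class AnnotatedGenome:
    genome_id: str
    scaffolds: list[tuple[str, str]]
    features: list[GeneFeature] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def scaffold_seq(self, scaffold_id: str) -> str:
        for sid, seq in self.scaffolds:
            if sid == scaffold_id:
                return seq
        raise GenomeError(f"unknown scaffold {scaffold_id!r}")

    @property
    def scaffold_ids(self) -> list[str]:
        return [sid for sid, _ in self.scaffolds]

    def feature(self, locus_tag: str) -> GeneFeature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def features_by_tag(self) -> dict[str, GeneFeature]:
        return {f.locus_tag: f for f in self.features}

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.scaffolds)

    def gene_order(self) -> list[GeneFeature]:
        """Features in genome order: scaffold appearance order, then start."""
        rank = {sid: i for i, (sid, _) in enumerate(self.scaffolds)}
        return sorted(self.features, key=lambda f: (rank[f.scaffold_id], f.start))

    def validate(self) -> None:
        ids = set()
        for sid, _ in self.scaffolds:
            if sid in ids:
                raise GenomeError(f"duplicate scaffold id {sid!r}")
            ids.add(sid)
        tags = set()
        last: dict[str, int] = {}
        for f in self.features:
            f.validate()
            if f.locus_tag in tags:
                raise GenomeError(f"duplicate locus_tag {f.locus_tag}")
            tags.add(f.locus_tag)
            if f.scaffold_id not in ids:
                raise GenomeError(
                    f"feature {f.locus_tag} placed on missing scaffold "
                    f"{f.scaffold_id!r}"
                )
            if f.end > len(self.scaffold_seq(f.scaffold_id)):
                raise GenomeError(f"{f.locus_tag}: extends past scaffold end")
            if f.scaffold_id in last and f.start < last[f.scaffold_id]:
                raise GenomeError(
                    f"{f.locus_tag}: features not sorted by start on "
                    f"{f.scaffold_id}"
                )
            last[f.scaffold_id] = f.start


def _category_from_note(note: str | None, key: str = "category") -> str | None:
    if not note:
        return None
    m = re.search(rf"{key}:(\w+)", note)
    return m.group(1) if m else None


def _extract_cds(scaffold_seq: str, start: int, end: int, strand: str) -> str:
    s = scaffold_seq[start:end].upper()
    return revcomp(s) if strand == "-" else s


def _load_gff3(path: str | os.PathLike, category_key: str) -> list[dict]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        tag = (feat.attributes.get("locus_tag") or feat.attributes.get("ID"))
        note = ";".join(feat.attributes.get("note", []))
        rows.append(
            dict(
                locus_tag=tag[0] if tag else feat.id,
                scaffold_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                product=";".join(feat.attributes.get("product", [])),
                category=_category_from_note(note, category_key),
            )
        )
    return rows


def _load_genbank(path: str | os.PathLike, category_key: str) -> list[dict]:
    rows = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if isinstance(feat.location, CompoundLocation):
                tag = feat.qualifiers.get("locus_tag", ["?"])[0]
                raise GenomeError(
                    f"joined CDS location not supported (locus {tag})"
                )
            note = ";".join(feat.qualifiers.get("note", []))
            rows.append(
                dict(
                    locus_tag=feat.qualifiers.get("locus_tag", [None])[0]
                    or f"{rec.id}_{int(feat.location.start)}",
                    scaffold_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    product=feat.qualifiers.get("product", [""])[0],
                    category=_category_from_note(note, category_key),
                )
            )
    return rows


def load_genome(
    fasta_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    genome_id: str | None = None,
    category_key: str = "category",
) -> AnnotatedGenome:
    """Load a FASTA + (GFF3 or GenBank) annotation into an AnnotatedGenome.

    Minus-strand CDS are reverse-complemented into ``cds_seq``. A CDS whose
    length is not a multiple of 3 is kept but flagged ``frame_warning``. A
    feature referencing a scaffold absent from the FASTA is fatal, naming the
    locus tag. The feature ``category`` is read from a ``note=category:<x>``
    qualifier (key configurable); absent categories default to hypothetical.
    """
    scaffolds = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if not scaffolds:
        raise GenomeError(f"no sequences in {fasta_path}")
    apath = str(annotation_path)
    if apath.endswith((".gb", ".gbk", ".gbff", ".genbank")):
        rows = _load_genbank(apath, category_key)
    else:
        rows = _load_gff3(apath, category_key)
    seq_by_id = dict(scaffolds)
    features = []
    for r in rows:
        cat = r.pop("category") or "hypothetical"
        if r["scaffold_id"] not in seq_by_id:
            raise GenomeError(
                f"feature {r['locus_tag']} placed on missing scaffold "
                f"{r['scaffold_id']!r}"
            )
        cds = _extract_cds(seq_by_id[r["scaffold_id"]], r["start"], r["end"], r["strand"])
        features.append(
            GeneFeature(
                **r, category=cat, cds_seq=cds, frame_warning=bool(len(cds) % 3)
            )
        )
    g = AnnotatedGenome(
        genome_id=genome_id or os.path.splitext(os.path.basename(str(fasta_path)))[0],
        scaffolds=scaffolds,
        features=sorted(
            features,
            key=lambda f: (list(seq_by_id).index(f.scaffold_id), f.start),
        ),
    )
    g.validate()
    return g


def write_genome(
    g: AnnotatedGenome, fasta_path: str | os.PathLike, gff_path: str | os.PathLike
) -> None:
    """Write scaffolds as FASTA and features as GFF3 (category in `note`)."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in g.scaffolds
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, seq in g.scaffolds:
            fh.write(f"##sequence-region {sid} 1 {len(seq)}\n")
        for f in g.gene_order():
            attrs = (
                f"ID={f.locus_tag};locus_tag={f.locus_tag};"
                f"product={f.product or 'hypothetical protein'};"
                f"note=category:{f.category}"
            )
            fh.write(
                f"{f.scaffold_id}\twolbcomp\tCDS\t{f.start1}\t{f.end1}\t.\t"
                f"{f.strand}\t0\t{attrs}\n"
            )


def genome_summary(g: AnnotatedGenome) -> dict:
    """Genome-level statistics: size, CDS count/length, intergenic gaps, GC%.

    GC% is (G+C)/(A+C+G+T)*100 over all scaffolds with N excluded from the
    denominator. Mean intergenic length is taken between consecutive features
    on the same scaffold; it is None when no scaffold has two features.
    """
    if not g.scaffolds or g.total_length() == 0:
        raise GenomeError("empty genome")
    gc = at = 0
    for _, seq in g.scaffolds:
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    gaps = []
    prev: dict[str, GeneFeature] = {}
    for f in g.gene_order():
        if f.scaffold_id in prev:
            gaps.append(max(0, f.start - prev[f.scaffold_id].end))
        prev[f.scaffold_id] = f
    n_cds = len(g.features)
    return {
        "genome_id": g.genome_id,
        "size_bp": g.total_length(),
        "n_scaffolds": len(g.scaffolds),
        "n_cds": n_cds,
        "mean_cds_length": (
            sum(len(f) for f in g.features) / n_cds if n_cds else None
        ),
        "mean_intergenic_length": sum(gaps) / len(gaps) if gaps else None,
        "gc_percent": 100.0 * gc / (gc + at) if gc + at else None,
    }


def locus_number(tag: str) -> int:
    """Numeric suffix of a locus tag (WD_0276 -> 276)."""
    m = re.search(r"(\d+)$", tag)
    if not m:
        raise ValueError(f"locus tag {tag!r} has no numeric suffix")
    return int(m.group(1))


def locus_range_count(start_tag: str, end_tag: str) -> int:
    """Number of loci in a consecutively numbered tag interval, inclusive.

    Relies on the standard convention that locus-tag numbering follows gene
    order (WD_0276..WD_0296 -> 21).
    """
    n = locus_number(end_tag) - locus_number(start_tag) + 1
    if n < 1:
        raise ValueError("end tag precedes start tag")
    return n
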