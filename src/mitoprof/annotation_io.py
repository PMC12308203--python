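"""Reading and writing annotated mitogenomes.

The in-memory model mirrors the tabular form in which mitogenome structure
is conventionally published: one row per gene with a strand token (J =
majority strand, N = minority strand), 1-based inclusive coordinates on the
circular genome, and — for tRNAs — the anticodon triplet and its location.

Coordinates are 1-based inclusive everywhere in the public API. A feature
whose end coordinate is numerically smaller than its start is interpreted
as wrapping the circular origin and must be flagged as such.
"""

from __future__ import annotations

import csv
import io
import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from ._util import VALID_RESIDUES, normalize_residues, revcomp

PCG_NAMES = frozenset(
    {"COI", "COII", "COIII", "ATP6", "ATP8", "ND1", "ND2", "ND3", "ND4",
     "ND4L", "ND5", "ND6", "cytb"}
)
RRNA_NAMES = frozenset({"srRNA", "lrRNA"})

_TRNA_RE = re.compile(r"^trn[A-Z](1|2)?$")


class AnnotationError(ValueError):
    """Malformed annotation input."""


class FastaFormatError(ValueError):
    """Malformed FASTA input."""


def feature_class_for(name: str) -> str:
    if name in PCG_NAMES:
        return "PCG"
    if name in RRNA_NAMES:
        return "rRNA"
    if _TRNA_RE.match(name):
        return "tRNA"
    return "other"


@dataclass(frozen=True)
class SequenceRecord:
    """A plain DNA sequence with an identifier and topology flag."""

    identifier: str
    residues: str
    topology: str = "circular"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the circular genome."""

    name: str
    strand: str  # "J" or "N"
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    feature_class: str = ""
    anticodon: Optional[str] = None
    anticodon_span: Optional[tuple[int, int]] = None
    wraps_origin: bool = False
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self):
        if self.strand not in ("J", "N"):
            raise AnnotationError(f"unknown strand token {self.strand!r} for {self.name}")
        if self.start < 1:
            raise AnnotationError(f"{self.name}: start {self.start} < 1")
        if self.end < self.start and not self.wraps_origin:
            raise AnnotationError(
                f"{self.name}: end {self.end} < start {self.start} without wraps_origin"
            )
        if not self.feature_class:
            object.__setattr__(self, "feature_class", feature_class_for(self.name))

    def length(self, genome_length: Optional[int] = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if genome_length is None:
            raise AnnotationError(f"{self.name} wraps the origin; genome length required")
        return genome_length - self.start + 1 + self.end

    def extract(self, residues: str, genome_length: Optional[int] = None) -> str:
        """Sense-strand sequence of this gene from the J-strand genome string."""
        L = genome_length or len(residues)
        if self.wraps_origin:
            raw = residues[self.start - 1:L] + residues[:self.end]
        else:
            raw = residues[self.start - 1:self.end]
        return revcomp(raw) if self.strand == "N" else raw


@dataclass(frozen=True)
class MitoAnnotation:
    """An ordered, strand-aware gene table for one (usually circular) genome."""

    genome_length: int
    features: tuple[GeneFeature, ...]
    topology: str = "circular"

    def __post_init__(self):
        object.__setattr__(
            self, "features", tuple(sorted(self.features, key=lambda f: f.start))
        )
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise AnnotationError(f"duplicate gene names: {sorted(dupes)}")
        for f in self.features:
            bound = f.start if f.wraps_origin else f.end
            if bound > self.genome_length:
                raise AnnotationError(
                    f"{f.name} extends to {bound} beyond genome length {self.genome_length}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def by_class(self, feature_class: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.feature_class == feature_class)

    @property
    def pcgs(self) -> tuple[GeneFeature, ...]:
        return self.by_class("PCG")

    @property
    def trnas(self) -> tuple[GeneFeature, ...]:
        return self.by_class("tRNA")

    @property
    def rrnas(self) -> tuple[GeneFeature, ...]:
        return self.by_class("rRNA")

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)


# ---------------------------------------------------------------------------
# gene-name normalization

def _load_synonyms() -> dict[str, str]:
    table = {}
    text = resources.files("mitoprof.data").joinpath("gene_synonyms.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("raw\t"):
            continue
        raw, canonical = line.split("\t")
        table[raw.strip().upper()] = canonical.strip()
    return table


_SYNONYMS: Optional[dict[str, str]] = None

_CANONICAL = {n.upper(): n for n in PCG_NAMES | RRNA_NAMES}


def normalize_gene_name(raw: str) -> str:
    """Map a pipeline/GenBank gene label onto the controlled vocabulary.

    Unmappable labels are returned unchanged with a warning, so foreign
    annotations degrade gracefully rather than being silently dropped.
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    key = re.sub(r"[-_\s]", "", raw).upper()
    if key in _CANONICAL:
        return _CANONICAL[key]
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    m = re.match(r"^TRN([A-Z])([12])?$", key)
    if m:
        return f"trn{m.group(1)}{m.group(2) or ''}"
    if feature_class_for(raw) != "other":
        return raw
    warnings.warn(f"gene label {raw!r} not in the controlled vocabulary; kept as-is")
    return raw


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file of DNA sequences.

    Residues are uppercased and U is mapped to T. A residue outside
    {A,C,G,T,N,U} raises FastaFormatError naming the offending line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not any(l.strip() for l in lines):
        raise FastaFormatError(f"{path}: empty file")
    for lineno, line in enumerate(lines, 1):
        s = line.strip()
        if not s or s.startswith(">"):
            continue
        bad = set(normalize_residues(s)) - VALID_RESIDUES
        if bad:
            raise FastaFormatError(
                f"{path}:{lineno}: non-IUPAC residue(s) {sorted(bad)}"
            )
    for rec in SeqIO.parse(io.StringIO("".join(lines)), "fasta"):
        records.append(SequenceRecord(rec.id, normalize_residues(str(rec.seq))))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# tabular feature table

_RANGE_SEP = re.compile(r"[–\-:]|\.\.")

_STRAND_ALIASES = {"J": "J", "N": "N", "+": "J", "-": "N", "−": "N", "1": "J", "-1": "N"}


def _parse_span(text: str) -> tuple[int, int]:
    parts = [p for p in _RANGE_SEP.split(text.strip()) if p]
    if len(parts) != 2:
        raise AnnotationError(f"cannot parse coordinate range {text!r}")
    return int(parts[0]), int(parts[1])


def _opt(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.strip()
    return value if value and value != "-" else None


def read_feature_table(path, genome_length: Optional[int] = None) -> MitoAnnotation:
    """Read a tab- or comma-separated gene table.

    Required columns: gene, strand, and either ``location`` ("start–end",
    en dash or hyphen) or separate ``start``/``end``. Optional columns:
    anticodon (+ location), start_codon, stop_codon, wraps_origin.
    Strand accepts J/N and the +/− aliases. If ``genome_length`` is not
    given it is taken from a ``# genome_length=`` header line or defaults
    to the largest end coordinate.
    """
    path = Path(path)
    text = path.read_text()
    header_gl = re.search(r"genome[ _]length[^0-9]*([\d,]+)", text[:2000], re.I)
    if genome_length is None and header_gl:
        genome_length = int(header_gl.group(1).replace(",", ""))
    lines = [l for l in text.splitlines() if l.strip() and not l.lstrip().startswith("#")]
    if not lines:
        raise AnnotationError(f"{path}: no rows")
    dialect_sep = "\t" if "\t" in lines[0] else ","
    reader = csv.DictReader(lines, delimiter=dialect_sep)
    if reader.fieldnames is None or "gene" not in [f.lower() for f in reader.fieldnames]:
        raise AnnotationError(f"{path}: missing 'gene' column")
    features = []
    for row in reader:
        row = {k.lower().strip(): (v.strip() if isinstance(v, str) else v)
               for k, v in row.items()}
        name = normalize_gene_name(row["gene"])
        strand_token = row.get("strand", "J")
        if strand_token not in _STRAND_ALIASES:
            raise AnnotationError(f"{name}: unknown strand token {strand_token!r}")
        strand = _STRAND_ALIASES[strand_token]
        if "location" in row and _opt(row.get("location")):
            start, end = _parse_span(row["location"])
        else:
            start, end = int(row["start"]), int(row["end"])
        wraps = str(row.get("wraps_origin", "")).lower() in ("1", "true", "yes")
        if end < start and not wraps:
            raise AnnotationError(f"{name}: start {start} > end {end} and not flagged as wrapping")
        anticodon = _opt(row.get("anticodon"))
        ac_span = None
        if anticodon:
            if _opt(row.get("anticodon_start")) and _opt(row.get("anticodon_end")):
                ac_span = (int(row["anticodon_start"]), int(row["anticodon_end"]))
            elif _opt(row.get("anticodon_location")):
                ac_span = _parse_span(row["anticodon_location"])
        features.append(GeneFeature(
            name=name, strand=strand, start=start, end=end, wraps_origin=wraps,
            anticodon=anticodon, anticodon_span=ac_span,
            start_codon=_opt(row.get("start_codon")),
            stop_codon=_opt(row.get("stop_codon")),
        ))
    if genome_length is None:
        genome_length = max(f.end for f in features)
    return MitoAnnotation(genome_length=genome_length, features=tuple(features))


def write_feature_table(path, annotation: MitoAnnotation) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genome_length={annotation.genome_length}\n")
        fh.write("gene\tstrand\tstart\tend\tanticodon\tanticodon_start\t"
                 "anticodon_end\tstart_codon\tstop_codon\twraps_origin\n")
        for f in annotation.features:
            ac = f.anticodon or "-"
            acs, ace = (f.anticodon_span or ("-", "-"))
            fh.write(f"{f.name}\t{f.strand}\t{f.start}\t{f.end}\t{ac}\t{acs}\t{ace}\t"
                     f"{f.start_codon or '-'}\t{f.stop_codon or '-'}\t"
                     f"{int(f.wraps_origin)}\n")


# ---------------------------------------------------------------------------
# GenBank

_GB_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path) -> tuple[SequenceRecord, MitoAnnotation]:
    """Read a GenBank flat file into the internal sequence + annotation pair.

    GenBank locations arrive zero-based half-open from the parser and are
    converted to the 1-based inclusive convention; ``complement()`` becomes
    strand N; labels are normalized via the synonym table.
    """
    rec = SeqIO.read(str(path), "genbank")
    topology = rec.annotations.get("topology", "circular")
    residues = normalize_residues(str(rec.seq))
    features = []
    seen = set()
    for feat in rec.features:
        if feat.type not in _GB_CLASS:
            continue
        raw_name = (feat.qualifiers.get("gene") or feat.qualifiers.get("product")
                    or [feat.type])[0]
        name = normalize_gene_name(raw_name)
        if name in seen:
            continue
        seen.add(name)
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        if end > len(residues):
            raise AnnotationError(
                f"{name}: feature end {end} beyond LOCUS length {len(residues)}"
            )
        strand = "N" if feat.location.strand == -1 else "J"
        anticodon = None
        ac_span = None
        note = feat.qualifiers.get("anticodon", [None])[0]
        if note:
            m = re.search(r"pos:(\d+)\.\.(\d+).*?seq:([a-zA-Z]{3})", note)
            if m:
                ac_span = (int(m.group(1)), int(m.group(2)))
                anticodon = normalize_residues(m.group(3))
        features.append(GeneFeature(
            name=name, strand=strand, start=start, end=end,
            anticodon=anticodon, anticodon_span=ac_span,
        ))
    annotation = MitoAnnotation(
        genome_length=len(residues), features=tuple(features), topology=topology
    )
    return SequenceRecord(rec.id, residues, topology), annotation


def write_genbank(path, record: SequenceRecord, annotation: MitoAnnotation) -> None:
    """Write the sequence + annotation pair as a GenBank flat file."""
    rec = BioSeqRecord(
        Seq(record.residues), id=record.identifier, name=record.identifier[:16],
        description="synthetic mitogenome",
        annotations={"molecule_type": "DNA", "topology": record.topology},
    )
    for f in annotation.features:
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}.get(f.feature_class)
        if ftype is None:
            continue
        loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "N" else 1)
        quals = {"gene": [f.name]}
        if f.anticodon and f.anticodon_span:
            quals["anticodon"] = [
                f"(pos:{f.anticodon_span[0]}..{f.anticodon_span[1]},"
                f"aa:Xaa,seq:{f.anticodon.lower()})"
            ]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# gene order extraction and the tabular report

def extract_gene_order(annotation: MitoAnnotation, taxon: str = ""):
    """Signed circular gene order in start-coordinate order.

    Sign is + for J-strand genes and − for N-strand genes; control regions
    are unannotated gaps and therefore never appear.
    """
    from .gene_order import GeneOrder  # local import to avoid a cycle

    if not annotation.features:
        raise AnnotationError("empty annotation has no gene order")
    genes = tuple(
        (f.name, 1 if f.strand == "J" else -1) for f in annotation.features
    )
    return GeneOrder(taxon=taxon, genes=genes)


def write_annotation_report(annotation: MitoAnnotation, geometry=None) -> str:
    """Render the annotation as the conventional published gene table.

    Columns: gene, strand, location, length, anticodon and its location,
    start/stop codon, and the signed intergenic spacer to the previous
    feature (negative = overlap). The first row's intergenic entry is 0 by
    convention: the gap closing the circle is reported with the geometry's
    control regions instead.
    """
    if geometry is None and annotation.features:
        from .genome_stats import compute_geometry
        geometry = compute_geometry(annotation)
    lines = ["gene\tstrand\tlocation\tlength\tanticodon\tanticodon_location\t"
             "start_codon\tstop_codon\tintergenic"]
    if not annotation.features:
        return "\n".join(lines) + "\n"
    spacer_before = {s.downstream: s.length for s in geometry.spacers}
    first = annotation.features[0].name
    for f in annotation.features:
        ig = 0 if f.name == first else spacer_before.get(f.name, 0)
        ac = f.anticodon or "-"
        ac_loc = (f"{f.anticodon_span[0]}-{f.anticodon_span[1]}"
                  if f.anticodon_span else "-")
        lines.append(
            f"{f.name}\t{f.strand}\t{f.start}-{f.end}\t"
            f"{f.length(annotation.genome_length)}\t{ac}\t{ac_loc}\t"
            f"{f.start_codon or '-'}\t{f.stop_codon or '-'}\t{ig}"
        )
    return "\n".join(lines) + "\n"
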