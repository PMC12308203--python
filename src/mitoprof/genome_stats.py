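"""Nucleotide composition, strand skews, and gene geometry.

Composition is summarized per partition (whole genome, protein-coding
genes, codon positions, tRNAs, rRNAs, and the same split by coding
strand) the way mitogenome studies tabulate it: percentages of T/C/A/G to
one decimal, A+T content, and the two strand-asymmetry skews

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

to three decimals. Geometry covers per-gene lengths and the signed
spacer between consecutive features on the circle (negative = overlap,
zero = abutting); spacers at least ``control_region_min`` long are
classified as control regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from ._util import round_half_up, revcomp
from .annotation_io import AnnotationError, GeneFeature, MitoAnnotation


@dataclass(frozen=True)
class CompositionProfile:
    """Base composition of one sequence partition (raw, unrounded values)."""

    label: str
    n: int          # residues counted (N excluded)
    pct_t: float
    pct_c: float
    pct_a: float
    pct_g: float

    @property
    def pct_at(self) -> float:
        return self.pct_a + self.pct_t

    @property
    def at_skew(self) -> Optional[float]:
        return at_skew(self.pct_a, self.pct_t)

    @property
    def gc_skew(self) -> Optional[float]:
        return gc_skew(self.pct_g, self.pct_c)

    def rounded(self) -> dict:
        """Reporting row: percentages to 1 decimal, skews to 3 decimals."""
        sk_at, sk_gc = self.at_skew, self.gc_skew
        return {
            "partition": self.label,
            "pct_t": round_half_up(self.pct_t, 1),
            "pct_c": round_half_up(self.pct_c, 1),
            "pct_a": round_half_up(self.pct_a, 1),
            "pct_g": round_half_up(self.pct_g, 1),
            "pct_at": round_half_up(self.pct_at, 1),
            "at_skew": None if sk_at is None else round_half_up(sk_at, 3),
            "gc_skew": None if sk_gc is None else round_half_up(sk_gc, 3),
        }


def at_skew(a: float, t: float) -> Optional[float]:
    """(A − T)/(A + T); accepts counts or percentages. None when A + T = 0."""
    if a + t == 0:
        return None
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> Optional[float]:
    """(G − C)/(G + C); accepts counts or percentages. None when G + C = 0."""
    if g + c == 0:
        return None
    return (g - c) / (g + c)


def base_composition(residues: str, label: str = "") -> CompositionProfile:
    """Percent A/T/G/C over the counted residues; N excluded from the denominator."""
    if not residues:
        raise ValueError("empty sequence")
    seq = residues.upper()
    counts = {b: seq.count(b) for b in "TCAG"}
    n = sum(counts.values())
    if n == 0:
        raise ValueError(f"{label or 'sequence'}: no unambiguous residues")
    return CompositionProfile(
        label=label, n=n,
        pct_t=100 * counts["T"] / n, pct_c=100 * counts["C"] / n,
        pct_a=100 * counts["A"] / n, pct_g=100 * counts["G"] / n,
    )


def _pcg_sense_sequences(
    annotation: MitoAnnotation, residues: str, strand_filter: Optional[str]
) -> list[tuple[GeneFeature, str]]:
    out = []
    for f in annotation.pcgs:
        if strand_filter and f.strand != strand_filter:
            continue
        seq = f.extract(residues, annotation.genome_length)
        if len(seq) % 3:
            raise AnnotationError(f"{f.name}: length {len(seq)} not divisible by 3")
        out.append((f, seq))
    return out


def codon_position_composition(
    annotation: MitoAnnotation,
    residues: str,
    strand_filter: Optional[str] = None,
    label_prefix: str = "",
) -> list[CompositionProfile]:
    """Composition at codon positions 1/2/3 pooled over protein-coding genes.

    Counting is on each gene's sense strand (N-strand genes are
    reverse-complemented first). ``strand_filter`` restricts to genes
    encoded on one strand ("J" or "N").
    """
    picks = _pcg_sense_sequences(annotation, residues, strand_filter)
    if not picks:
        raise AnnotationError("no protein-coding genes selected")
    pooled = ["", "", ""]
    for _, seq in picks:
        for p in range(3):
            pooled[p] += seq[p::3]
    return [
        base_composition(pooled[p], f"{label_prefix}pos{p + 1}") for p in range(3)
    ]


def strand_class_composition(
    annotation: MitoAnnotation, residues: str, feature_class: str,
    strand: Optional[str] = None, label: str = "",
) -> CompositionProfile:
    """Pooled sense-strand composition of all features of one class.

    Each gene contributes its own coding-strand sequence; grouping by the
    encoding strand reproduces the published N-strand GC-skew sign flip.
    """
    seqs = [
        f.extract(residues, annotation.genome_length)
        for f in annotation.by_class(feature_class)
        if strand is None or f.strand == strand
    ]
    if not seqs:
        raise AnnotationError(f"no {feature_class} features on strand {strand}")
    return base_composition("".join(seqs), label)


def composition_table(annotation: MitoAnnotation, residues: str) -> pd.DataFrame:
    """The full published-style composition table (17 partitions)."""
    profiles: list[CompositionProfile] = [base_composition(residues, "whole_genome")]
    profiles.append(strand_class_composition(annotation, residues, "PCG", None, "pcg"))
    profiles += codon_position_composition(annotation, residues, None, "pcg_")
    for strand in ("J", "N"):
        profiles.append(
            strand_class_composition(annotation, residues, "PCG", strand, f"pcg_{strand}")
        )
        profiles += codon_position_composition(
            annotation, residues, strand, f"pcg_{strand}_"
        )
    profiles.append(strand_class_composition(annotation, residues, "tRNA", None, "trna"))
    for strand in ("J", "N"):
        profiles.append(
            strand_class_composition(annotation, residues, "tRNA", strand, f"trna_{strand}")
        )
    profiles.append(strand_class_composition(annotation, residues, "rRNA", None, "rrna"))
    return pd.DataFrame([p.rounded() for p in profiles])


# ---------------------------------------------------------------------------
# geometry

@dataclass(frozen=True)
class SpacerRecord:
    """Signed gap between two consecutive features on the circle."""

    upstream: str
    downstream: str
    length: int  # negative = overlap, 0 = abutting, positive = spacer
    is_control_region: bool = False


@dataclass(frozen=True)
class GeometryReport:
    genome_length: int
    gene_lengths: dict
    spacers: tuple[SpacerRecord, ...]
    control_region_min: int

    @property
    def overlaps(self) -> tuple[SpacerRecord, ...]:
        return tuple(s for s in self.spacers if s.length < 0)

    @property
    def intergenic_spacers(self) -> tuple[SpacerRecord, ...]:
        return tuple(
            s for s in self.spacers if s.length > 0 and not s.is_control_region
        )

    @property
    def control_regions(self) -> tuple[SpacerRecord, ...]:
        return tuple(s for s in self.spacers if s.is_control_region)

    @property
    def overlap_range(self) -> Optional[tuple[int, int]]:
        ls = [-s.length for s in self.overlaps]
        return (min(ls), max(ls)) if ls else None

    @property
    def spacer_range(self) -> Optional[tuple[int, int]]:
        ls = [s.length for s in self.intergenic_spacers]
        return (min(ls), max(ls)) if ls else None

    def spacer_between(self, upstream: str, downstream: str) -> SpacerRecord:
        for s in self.spacers:
            if s.upstream == upstream and s.downstream == downstream:
                return s
        raise KeyError((upstream, downstream))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"upstream": s.upstream, "downstream": s.downstream,
              "length": s.length, "is_control_region": s.is_control_region}
             for s in self.spacers]
        )


def gene_length(feature: GeneFeature, genome_length: int) -> int:
    """end − start + 1, wrapping through the origin when flagged."""
    return feature.length(genome_length)


def compute_geometry(
    annotation: MitoAnnotation, control_region_min: int = 1000
) -> GeometryReport:
    """Signed spacers for every consecutive feature pair on the circle.

    For features u (earlier start) and v (next), the spacer is
    ``v.start − u.end − 1``; the pair closing the circle (last feature →
    first feature) wraps through the origin. Non-negative spacers of at
    least ``control_region_min`` bp are flagged as control regions.
    """
    if annotation.genome_length <= 0:
        raise AnnotationError("genome length not set")
    feats = annotation.features
    if not feats:
        return GeometryReport(annotation.genome_length, {}, (), control_region_min)
    lengths = {f.name: f.length(annotation.genome_length) for f in feats}
    spacers: list[SpacerRecord] = []
    n = len(feats)
    circular = annotation.topology == "circular"
    pairs = range(n if circular and n > 1 else n - 1)
    for i in pairs:
        u, v = feats[i], feats[(i + 1) % n]
        if i + 1 < n:
            gap = v.start - u.end - 1
        else:  # wrap-around pair
            u_end = u.end if not u.wraps_origin else u.end  # wrap end is linear end
            gap = (annotation.genome_length - u.end) + (v.start - 1)
        spacers.append(SpacerRecord(
            upstream=u.name, downstream=v.name, length=gap,
            is_control_region=gap >= control_region_min,
        ))
    return GeometryReport(
        genome_length=annotation.genome_length,
        gene_lengths=lengths,
        spacers=tuple(spacers),
        control_region_min=control_region_min,
    )
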