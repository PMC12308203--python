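"""Synthetic mitogenomes and codon sequences with known ground truth.

The generator emulates the statistical structure of a strongly AT-biased
scale-insect mitogenome so that every analysis stage can be exercised
against exact, generator-recorded ground truth: a circular ~19 kb genome
with 37 genes on two strands, protein-coding genes drawn from an
empirical codon-frequency table with ATN starts and TAA stops, tRNAs
built from cloverleaf templates of a requested completeness class,
requested overlap/spacer geometry realized by coordinate adjustment, and
two large AT-rich control regions that absorb the remaining length.

Overlapping genes share sequence: the downstream gene owns the shared
bases. Overlaps are therefore only placed where the upstream feature
tolerates tail replacement — a tRNA (short overlaps confined to its
acceptor 3' side, which cannot change its arm class) or an rRNA (any
length) — and the generator re-verifies every sequence-level ground
truth on the assembled genome, redrawing the rare tRNA whose damaged
tail happens to mimic an extra arm.

One integer seed drives one named substream per sub-generator, so adding
a generator never shifts another's draws; identical configs give
byte-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from ._util import revcomp
from .annotation_io import GeneFeature, MitoAnnotation, SequenceRecord
from .codon_usage import DEFAULT_CODE, CodonCountTable, GeneticCode, codon_bias_metrics
from .datasets import (
    load_reference_annotation,
    load_reference_codon_frame,
)
from .gene_order import GeneOrder
from .selection import CodonAlignmentPair
from .trna_structure import DEFAULT_PARAMS, ArmParams, detect_arms

START_CODONS = ("ATT", "ATA", "ATG")
STOP_CODON = "TAA"

# completeness classes of the reference genome's 22 tRNAs
REFERENCE_TRNA_CLASSES: dict[str, str] = {
    **{g: "full" for g in ("trnA", "trnH", "trnI", "trnL1", "trnL2", "trnM",
                           "trnK", "trnV")},
    **{g: "T-armless" for g in ("trnR", "trnD", "trnE", "trnG", "trnF", "trnP",
                                "trnT", "trnW")},
    **{g: "D-armless" for g in ("trnN", "trnQ", "trnS1", "trnS2", "trnY")},
    "trnC": "minimal",
}


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible substream keyed by (seed, name)."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the mitogenome generator; defaults mirror the reference
    genome (18,830 bp, 90.7% A+T, 37 genes, 15 overlaps of 1–22 bp, 14
    spacers of 1–72 bp, two >2 kb control regions, 8/8/5/1 tRNA classes)."""

    seed: int = 0
    genome_length: int = 18_830
    at_content: float = 0.907
    gene_order: Optional[GeneOrder] = None          # default: reference order
    n_overlaps: int = 15
    overlap_range: tuple[int, int] = (1, 22)
    n_spacers: int = 14
    spacer_range: tuple[int, int] = (1, 72)
    control_region_length: int = 2350               # second one absorbs the rest
    control_region_min: int = 1000
    codon_frequencies: Optional[Mapping[str, float]] = None   # default: reference
    trna_classes: Optional[Mapping[str, str]] = None          # gene -> class
    pcg_lengths: Optional[Mapping[str, int]] = None           # default: reference
    identifier: str = "synthetic_mitogenome"
    max_trna_overlap: int = 4      # tail bases a tRNA may cede to the next gene

    def __post_init__(self):
        if not (0.0 < self.at_content < 1.0):
            raise ValueError("at_content must be in (0, 1)")
        if self.overlap_range[0] < 1 or self.spacer_range[0] < 1:
            raise ValueError("overlap/spacer lengths must be positive")


@dataclass
class SimulatedGenome:
    record: SequenceRecord
    annotation: MitoAnnotation
    ground_truth: dict


class SizingError(ValueError):
    """The requested genes do not fit the requested genome length."""


# ---------------------------------------------------------------------------
# sequence pieces

def default_codon_frequencies(code: GeneticCode = DEFAULT_CODE) -> dict[str, float]:
    """Sense-codon frequencies from the packaged reference codon counts."""
    df = load_reference_codon_frame()
    counts = {}
    for codon, n in zip(df["codon"], df["count"]):
        dna = codon.replace("U", "T")
        if dna in code.stop_codons:
            continue
        counts[dna] = int(n)
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}


def _sample_codons(rng, freqs: Mapping[str, float], n: int) -> list[str]:
    codons = sorted(freqs)
    p = np.array([freqs[c] for c in codons])
    p = p / p.sum()
    return [codons[i] for i in rng.choice(len(codons), size=n, p=p)]


def make_pcg(length: int, rng, freqs: Mapping[str, float]) -> str:
    """A CDS of ``length`` bp: ATN start, TAA stop, interior from ``freqs``.

    Stop codons are absent from ``freqs``, so no internal stops arise.
    """
    if length % 3:
        raise ValueError(f"CDS length {length} not divisible by 3")
    n_codons = length // 3
    if n_codons < 2:
        raise ValueError("CDS needs at least start + stop")
    start = START_CODONS[rng.integers(len(START_CODONS))]
    interior = _sample_codons(rng, freqs, n_codons - 2)
    return start + "".join(interior) + STOP_CODON


def _random_at(rng, n: int, at: float) -> str:
    p = np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])


def _complement_strand(seq: str) -> str:
    return revcomp(seq)[::-1]  # plain complement, same orientation


_TRNA_LAYOUTS = {
    # (d_arm, t_arm)
    "full": (True, True),
    "T-armless": (True, False),
    "D-armless": (False, True),
    "minimal": (False, False),
}


def make_trna(
    completeness: str,
    anticodon: str,
    rng,
    params: ArmParams = DEFAULT_PARAMS,
    max_tries: int = 80,
) -> tuple[str, tuple[int, int]]:
    """A tRNA gene sequence of the requested cloverleaf class.

    Returns the 5'→3' sequence and the 1-based span of the anticodon
    triplet. Arms that should be absent are replaced by unpaired runs too
    short to hold a hairpin, so their absence is guaranteed; the whole
    candidate is re-verified with the arm detector and redrawn until the
    detected class matches (random loops occasionally fold spuriously).
    """
    if completeness not in _TRNA_LAYOUTS:
        raise ValueError(f"unknown tRNA class {completeness!r}")
    d_arm, t_arm = _TRNA_LAYOUTS[completeness]
    anticodon = anticodon.upper().replace("U", "T")

    def stem(n):
        # AT-leaning but mixed stems pair reliably
        side = _random_at(rng, n, 0.7)
        return side, revcomp(side)

    for _ in range(max_tries):
        acc5, acc3 = stem(7)
        ac5, ac3 = stem(5)
        ac_loop = _random_at(rng, 2, 0.9) + anticodon + _random_at(rng, 2, 0.9)
        if d_arm:
            d5, d3 = stem(4)
            d_part = d5 + _random_at(rng, 7, 0.9) + d3
        else:
            d_part = "A" * 5
        if t_arm:
            t5, t3 = stem(5)
            t_part = t5 + _random_at(rng, 7, 0.9) + t3
            var = _random_at(rng, 4, 0.9)
        else:
            t_part = "A" * 6
            var = ""
        seq = acc5 + "A" + d_part + "A" + ac5 + ac_loop + ac3 + var + t_part + acc3 + "A"
        ac_start = len(acc5) + 1 + len(d_part) + 1 + len(ac5) + 2 + 1  # 1-based
        span = (ac_start, ac_start + 2)
        model = detect_arms(seq, span, params)
        if model.completeness == completeness and model.acceptor_pairs >= params.min_acceptor_pairs:
            return seq, span
    raise RuntimeError(f"could not realize a {completeness} tRNA in {max_tries} draws")


# ---------------------------------------------------------------------------
# genome assembly

def _gap_plan(order, feats_meta, cfg: SimulationConfig, rng) -> list[int]:
    """Signed gap after each feature (index i = boundary feature i → i+1).

    The boundary into the last rRNA (mimicking the pre-srRNA control
    region) gets the fixed control region; the wrap-around boundary is
    left to absorb the remaining length. Overlaps go to boundaries whose
    upstream feature tolerates tail loss.
    """
    n = len(order)
    gaps = [0] * n
    reserved = {n - 1}  # wrap-around boundary = closing control region

    cr_boundary = None
    for i in range(n - 1):
        if feats_meta[i + 1]["class"] == "rRNA":
            cr_boundary = i
    if cr_boundary is None or cr_boundary in reserved:
        cr_boundary = next(i for i in range(n - 1) if i not in reserved)
    gaps[cr_boundary] = cfg.control_region_length
    reserved.add(cr_boundary)

    eligible = [
        i for i in range(n - 1)
        if i not in reserved and feats_meta[i]["class"] in ("tRNA", "rRNA")
    ]
    if len(eligible) < cfg.n_overlaps:
        raise SizingError(
            f"only {len(eligible)} boundaries can host overlaps; "
            f"{cfg.n_overlaps} requested"
        )
    overlap_at = sorted(rng.choice(eligible, size=cfg.n_overlaps, replace=False))
    lo, hi = cfg.overlap_range
    for i in overlap_at:
        cap = hi if feats_meta[i]["class"] == "rRNA" else min(hi, cfg.max_trna_overlap)
        cap = min(cap, feats_meta[i]["length"] - 1, feats_meta[i + 1]["length"] - 1)
        gaps[i] = -int(rng.integers(lo, max(lo, cap) + 1))
        reserved.add(i)

    free = [i for i in range(n - 1) if i not in reserved]
    if len(free) < cfg.n_spacers:
        raise SizingError("not enough boundaries left for the requested spacers")
    spacer_at = sorted(rng.choice(free, size=cfg.n_spacers, replace=False))
    s_lo, s_hi = cfg.spacer_range
    for i in spacer_at:
        gaps[i] = int(rng.integers(s_lo, s_hi + 1))
    return gaps


def simulate_mitogenome(config: SimulationConfig) -> SimulatedGenome:
    """Generate a circular annotated mitogenome plus its ground truth."""
    cfg = config
    code = DEFAULT_CODE
    freqs = dict(cfg.codon_frequencies) if cfg.codon_frequencies else \
        default_codon_frequencies(code)

    reference = load_reference_annotation()
    if cfg.gene_order is None:
        order = tuple(
            (f.name, 1 if f.strand == "J" else -1) for f in reference.features
        )
    else:
        order = cfg.gene_order.genes
    pcg_lengths = dict(cfg.pcg_lengths) if cfg.pcg_lengths else {
        f.name: f.length(reference.genome_length) for f in reference.pcgs
    }
    rrna_lengths = {f.name: f.length(reference.genome_length)
                    for f in reference.rrnas}
    anticodons = {f.name: f.anticodon for f in reference.trnas}
    trna_classes = dict(cfg.trna_classes) if cfg.trna_classes else \
        dict(REFERENCE_TRNA_CLASSES)

    from .annotation_io import feature_class_for

    rng_pcg = _stream(cfg.seed, "pcg")
    rng_trna = _stream(cfg.seed, "trna")
    rng_rrna = _stream(cfg.seed, "rrna")
    rng_layout = _stream(cfg.seed, "layout")
    rng_fill = _stream(cfg.seed, "fill")

    # 1. per-gene sense sequences + metadata
    feats_meta = []
    for name, sign in order:
        fclass = feature_class_for(name)
        meta = {"name": name, "sign": sign, "class": fclass}
        if fclass == "PCG":
            length = pcg_lengths.get(name)
            if length is None:
                raise SizingError(f"no length for protein-coding gene {name}")
            meta["seq"] = make_pcg(length, rng_pcg, freqs)
        elif fclass == "tRNA":
            cls = trna_classes.get(name, "full")
            ac = anticodons.get(name) or "CAT"
            seq, span = make_trna(cls, ac, rng_trna)
            meta.update(seq=seq, trna_class=cls, ac_span=span)
        elif fclass == "rRNA":
            length = rrna_lengths.get(name, 800)
            meta["seq"] = _random_at(rng_rrna, length, min(cfg.at_content + 0.01, 0.98))
        else:
            raise SizingError(f"cannot simulate feature {name!r}")
        meta["length"] = len(meta["seq"])
        feats_meta.append(meta)

    # 2. coordinate layout
    gaps = _gap_plan(order, feats_meta, cfg, rng_layout)
    features: list[GeneFeature] = []
    pos = 1
    for i, meta in enumerate(feats_meta):
        start = pos
        end = start + meta["length"] - 1
        kwargs = {}
        if meta["class"] == "tRNA":
            rs, re_ = meta["ac_span"]
            if meta["sign"] > 0:
                kwargs["anticodon_span"] = (start + rs - 1, start + re_ - 1)
            else:
                kwargs["anticodon_span"] = (end - re_ + 1, end - rs + 1)
            kwargs["anticodon"] = anticodons.get(meta["name"]) or "CAT"
        if meta["class"] == "PCG":
            kwargs["start_codon"] = meta["seq"][:3]
            kwargs["stop_codon"] = meta["seq"][-3:]
        features.append(GeneFeature(
            name=meta["name"], strand="J" if meta["sign"] > 0 else "N",
            start=start, end=end, **kwargs,
        ))
        if i < len(feats_meta) - 1:
            pos = end + gaps[i] + 1

    last_end = features[-1].end
    closing_gap = cfg.genome_length - last_end
    if closing_gap < cfg.control_region_min:
        raise SizingError(
            f"genes + spacers occupy {last_end} bp, leaving {closing_gap} bp "
            f"(< {cfg.control_region_min}) for the closing control region"
        )
    gaps[-1] = closing_gap

    # 3. assemble: fill background, then write genes in start order so the
    # downstream gene always owns any overlapped bases
    background = list(_random_at(rng_fill, cfg.genome_length, cfg.at_content))
    meta_by_name = {m["name"]: m for m in feats_meta}

    def assemble() -> list[str]:
        genome = list(background)
        for meta, feat in zip(feats_meta, features):
            seq = meta["seq"] if feat.strand == "J" else revcomp(meta["seq"])
            genome[feat.start - 1:feat.end] = list(seq)
        return genome

    genome = assemble()

    # steer overall A+T to the target by refilling the two control regions;
    # the fill is computed once so later tRNA redraws stay reproducible
    noncoding = []
    for i, feat in enumerate(features):
        if gaps[i] >= cfg.control_region_min:
            noncoding.append((feat.end, gaps[i]))  # 0-based start just past feature
    cr_positions = {p for s, g in noncoding for p in range(s, s + g)}
    coding_at = sum(
        base in "AT" for i, base in enumerate(genome) if i not in cr_positions
    )
    cr_total = sum(g for _, g in noncoding)
    cr_fills: list[tuple[int, str]] = []
    if cr_total:
        need = cfg.at_content * cfg.genome_length - coding_at
        cr_at = min(max(need / cr_total, 0.05), 0.99)
        cr_fills = [(s, _random_at(rng_fill, g, cr_at)) for s, g in noncoding]
    for s, fill in cr_fills:
        background[s:s + len(fill)] = list(fill)

    genome = assemble()
    residues = "".join(genome)
    annotation = MitoAnnotation(
        genome_length=cfg.genome_length, features=tuple(features)
    )

    # 4. self-verification against ground truth: a tRNA whose ceded tail (or
    # chance context) changes its detected class is redrawn and the genome
    # reassembled, so overlap ownership stays consistent throughout
    from .trna_structure import classify_annotation

    rng_retry = _stream(cfg.seed, "trna-retry")
    wanted = {m["name"]: m["trna_class"] for m in feats_meta
              if m["class"] == "tRNA"}
    for _ in range(60):
        table, _hist = classify_annotation(annotation, residues)
        bad = [row["gene"] for _, row in table.iterrows()
               if wanted.get(row["gene"]) and row["class"] != wanted[row["gene"]]]
        if not bad:
            break
        for gene in bad:
            seq, span = make_trna(wanted[gene], anticodons.get(gene) or "CAT",
                                  rng_retry)
            meta_by_name[gene]["seq"] = seq  # template lengths are class-fixed
        genome = assemble()
        residues = "".join(genome)
    else:
        raise RuntimeError("tRNA class ground truth could not be stabilized")

    for feat in annotation.pcgs:
        cds = feat.extract(residues, cfg.genome_length)
        assert cds[:3] in START_CODONS and cds[-3:] == STOP_CODON, feat.name

    from collections import Counter

    histogram = Counter(m["trna_class"] for m in feats_meta if m["class"] == "tRNA")
    overlap_lengths = sorted(-g for g in gaps[:-1] if g < 0)
    spacer_lengths = sorted(g for g in gaps[:-1] if 0 < g < cfg.control_region_min)
    cr_lengths = sorted(
        [g for g in gaps[:-1] if g >= cfg.control_region_min] + [gaps[-1]]
    )
    ground_truth = {
        "genome_length": cfg.genome_length,
        "at_target": cfg.at_content,
        "n_features": len(features),
        "n_pcg": sum(1 for m in feats_meta if m["class"] == "PCG"),
        "n_trna": sum(1 for m in feats_meta if m["class"] == "tRNA"),
        "n_rrna": sum(1 for m in feats_meta if m["class"] == "rRNA"),
        "overlap_lengths": overlap_lengths,
        "spacer_lengths": spacer_lengths,
        "control_region_lengths": cr_lengths,
        "trna_classes": {m["name"]: m["trna_class"] for m in feats_meta
                         if m["class"] == "tRNA"},
        "trna_class_histogram": dict(histogram),
        "pcg_lengths": {m["name"]: m["length"] for m in feats_meta
                        if m["class"] == "PCG"},
        "gene_order": ",".join(
            f"{'-' if s < 0 else ''}{g}" for g, s in order
        ),
        "stop_codon": STOP_CODON,
    }
    record = SequenceRecord(cfg.identifier, residues, "circular")
    return SimulatedGenome(record=record, annotation=annotation,
                           ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# codon-pair evolution for Ka/Ks testing

def evolve_codon_pair(
    n_codons: int,
    omega: float,
    t: float,
    kappa: float = 2.0,
    seed: int = 0,
    code: GeneticCode = DEFAULT_CODE,
    gene: str = "sim",
    codon_frequencies: Optional[Mapping[str, float]] = None,
) -> CodonAlignmentPair:
    """Ancestor/descendant codon pair under a continuous-time codon model.

    Single-nucleotide exchanges only; transitions are scaled by ``kappa``
    and amino-acid-changing exchanges by ``omega``; exchanges into stop
    codons have rate zero. ``t`` is raw rate × time, roughly the expected
    number of exchange events per codon per unit neutral rate.
    """
    if omega < 0 or t < 0:
        raise ValueError("omega and t must be non-negative")
    rng = _stream(seed, f"codon-evolve-{gene}")
    freqs = dict(codon_frequencies) if codon_frequencies else \
        default_codon_frequencies(code)
    ancestor = _sample_codons(rng, freqs, n_codons)

    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

    def neighbor_rates(codon):
        out = []
        aa = code.forward[codon]
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                nxt = codon[:pos] + b + codon[pos + 1:]
                if nxt in code.stop_codons:
                    continue
                rate = kappa if (codon[pos], b) in transitions else 1.0
                if code.forward[nxt] != aa:
                    rate *= omega
                if rate > 0:
                    out.append((nxt, rate))
        return out

    descendant = []
    for codon in ancestor:
        current = codon
        elapsed = 0.0
        while True:
            moves = neighbor_rates(current)
            total = sum(r for _, r in moves)
            if total == 0:
                break
            elapsed += rng.exponential(1.0 / total)
            if elapsed >= t:
                break
            pick = rng.random() * total
            acc = 0.0
            for nxt, r in moves:
                acc += r
                if pick <= acc:
                    current = nxt
                    break
        descendant.append(current)
    # append a shared terminal stop so the pair looks like a complete CDS
    a = "".join(ancestor) + STOP_CODON
    b = "".join(descendant) + STOP_CODON
    return CodonAlignmentPair(gene, a, b, code)


# ---------------------------------------------------------------------------
# gene-order perturbation

def perturb_gene_order(
    order: GeneOrder,
    k_events: int,
    event_mix: tuple[float, float] = (0.7, 0.3),  # (transposition, inversion)
    seed: int = 0,
    max_segment: int = 3,
) -> tuple[GeneOrder, list[dict]]:
    """Apply ``k_events`` random transpositions/inversions to a circular order."""
    if k_events < 0:
        raise ValueError("k_events must be >= 0")
    rng = _stream(seed, "order-perturb")
    genes = list(order.genes)
    log: list[dict] = []
    p_trans = event_mix[0] / (event_mix[0] + event_mix[1])
    for _ in range(k_events):
        n = len(genes)
        seg_len = int(rng.integers(1, max_segment + 1))
        i = int(rng.integers(0, n))
        segment = [genes[(i + j) % n] for j in range(seg_len)]
        if rng.random() < p_trans:
            from .gene_order import adjacencies

            before = adjacencies(GeneOrder("t", tuple(genes)))
            remaining = [g for g in genes if g not in segment]
            for _ in range(20):  # avoid circular-identity insertions
                j = int(rng.integers(0, len(remaining) + 1))
                candidate = remaining[:j] + segment + remaining[j:]
                if adjacencies(GeneOrder("t", tuple(candidate))) != before:
                    break
            genes = candidate
            log.append({"event": "transposition", "segment": [g for g, _ in segment],
                        "insert_before": j})
        else:
            flipped = [(g, -s) for g, s in reversed(segment)]
            for j in range(seg_len):
                genes[(i + j) % n] = flipped[j]
            log.append({"event": "inversion", "segment": [g for g, _ in segment]})
    return GeneOrder(taxon=order.taxon, genes=tuple(genes)), log


# ---------------------------------------------------------------------------
# codon-usage bias gradient for the correlation analysis

def simulate_codon_usage_panel(
    n_genomes: int,
    at_span: tuple[float, float] = (0.75, 0.92),
    n_codons: int = 3500,
    seed: int = 0,
    code: GeneticCode = DEFAULT_CODE,
):
    """Codon-bias metrics for genomes along an A+T-content gradient.

    Codon usage is drawn with per-base probabilities set by each genome's
    A+T level, so stronger AT bias concentrates usage on AT-rich codons —
    the mechanism behind the expected sign pattern of the bias
    correlations (ENC rises with GC, CBI falls with GC, ENC and CBI are
    anticorrelated).
    """
    import pandas as pd

    rng = _stream(seed, "bias-panel")
    ats = np.linspace(at_span[0], at_span[1], n_genomes)
    rows = []
    sense = [c for c in code.sense_codons]
    for i, at in enumerate(ats):
        base_p = {"A": at / 2, "T": at / 2, "G": (1 - at) / 2, "C": (1 - at) / 2}
        w = np.array([np.prod([base_p[b] for b in codon]) for codon in sense])
        w = w / w.sum()
        draws = rng.multinomial(n_codons, w)
        table = CodonCountTable(dict(zip(sense, draws.tolist())), code)
        m = codon_bias_metrics(table, label=f"genome{i+1}")
        rows.append({"label": m.label, "at": at, "enc": m.enc, "cbi": m.cbi,
                     "gc": m.gc, "gc3": m.gc3})
    return pd.DataFrame(rows)
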