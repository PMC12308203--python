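"""Pairwise Ka/Ks estimation by Nei–Gojobori (1986) counting.

For each codon the number of synonymous sites is the sum over the three
positions of the fraction of single-nucleotide changes at that position
that preserve the amino acid (changes to stop codons are excluded from
the denominator). Differences between aligned codons are classified by
averaging over all minimal substitution pathways with equal weight,
excluding pathways that pass through a stop codon (unless every pathway
does). Proportions are corrected for multiple hits with the
Jukes–Cantor formula d = −3/4 · ln(1 − 4p/3); p ≥ 3/4 is reported as
saturated (NaN) rather than a number.

Ka/Ks < 1 indicates purifying selection on the protein. The estimator is
a counting method: unlike codon-model maximum likelihood it makes no
correction for mutational bias, which matters for strongly AT-biased
genomes; see the package methods note for the trade-off.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping

import pandas as pd

from ._util import normalize_residues
from .codon_usage import DEFAULT_CODE, GeneticCode

_BASES = "ACGT"


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two gap-free, codon-aligned sense-strand CDSs for one gene."""

    gene: str
    seq_a: str
    seq_b: str
    code: GeneticCode = DEFAULT_CODE

    def __post_init__(self):
        a = normalize_residues(self.seq_a)
        b = normalize_residues(self.seq_b)
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError(f"{self.gene}: unequal lengths {len(a)} vs {len(b)}")
        if len(a) % 3:
            raise ValueError(f"{self.gene}: length {len(a)} not divisible by 3")
        for label, seq in (("a", a), ("b", b)):
            codons = [seq[i:i + 3] for i in range(0, len(seq) - 3, 3)]
            if any(c in self.code.stop_codons for c in codons):
                raise ValueError(f"{self.gene}: internal stop codon in sequence {label}")

    def codons(self) -> list[tuple[str, str]]:
        a, b = self.seq_a, self.seq_b
        return [(a[i:i + 3], b[i:i + 3]) for i in range(0, len(a), 3)]


@dataclass(frozen=True)
class SelectionEstimate:
    """Ka, Ks and their ratio for one aligned gene pair."""

    gene: str
    n_sites: float       # nonsynonymous sites N
    s_sites: float       # synonymous sites S
    n_diffs: float       # Nd
    s_diffs: float       # Sd
    ka: float
    ks: float

    @property
    def ratio(self) -> float:
        """Ka/Ks; NaN when Ks is zero or either rate is saturated."""
        if not (self.ks > 0) or math.isnan(self.ka) or math.isnan(self.ks):
            return float("nan")
        return self.ka / self.ks


def ng86_sites(codon: str, code: GeneticCode = DEFAULT_CODE) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Per position, the synonymous fraction is computed over the three
    single-nucleotide neighbors that are not stop codons; the two counts
    always sum to 3.
    """
    codon = normalize_residues(codon)
    if codon in code.stop_codons:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = code.forward[codon]
    syn = 0.0
    for pos in range(3):
        syn_n = valid = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            neighbor = codon[:pos] + b + codon[pos + 1:]
            if neighbor in code.stop_codons:
                continue
            valid += 1
            if code.forward[neighbor] == aa:
                syn_n += 1
        if valid:
            syn += syn_n / valid
    return syn, 3.0 - syn


def _pathway_counts(
    codon_a: str, codon_b: str, code: GeneticCode
) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair, averaging minimal substitution pathways.

    Pathways through stop codons are excluded; if every pathway hits a
    stop, all are used (standard fallback so the pair still contributes).
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_positions):
        current = codon_a
        steps = []
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in code.stop_codons:
                hit_stop = True
            steps.append((current, nxt))
            current = nxt
        pathways.append((hit_stop, steps))
    usable = [steps for hit, steps in pathways if not hit] or [s for _, s in pathways]
    sd = nd = 0.0
    for steps in usable:
        for before, after in steps:
            before_aa = "*" if before in code.stop_codons else code.forward[before]
            after_aa = "*" if after in code.stop_codons else code.forward[after]
            if before_aa == after_aa:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction; NaN at or beyond the p = 3/4 saturation bound."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(pair: CodonAlignmentPair) -> SelectionEstimate:
    """Nei–Gojobori Ka, Ks and Ka/Ks for one codon-aligned pair.

    Sites are averaged over the two sequences, so the estimate is
    symmetric in its arguments. N + S equals the nucleotide length.
    """
    code = pair.code
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in pair.codons():
        sa = ng86_sites(ca, code) if ca not in code.stop_codons else None
        sb = ng86_sites(cb, code) if cb not in code.stop_codons else None
        if sa is None and sb is None:
            continue  # terminal stop in both: contributes no sites
        if sa is None:
            sa = sb
        if sb is None:
            sb = sa
        s_sites += (sa[0] + sb[0]) / 2
        n_sites += (sa[1] + sb[1]) / 2
        d_s, d_n = _pathway_counts(ca, cb, code)
        sd += d_s
        nd += d_n
    ks = jukes_cantor(sd / s_sites) if s_sites > 0 else float("nan")
    ka = jukes_cantor(nd / n_sites) if n_sites > 0 else float("nan")
    return SelectionEstimate(
        gene=pair.gene, n_sites=n_sites, s_sites=s_sites,
        n_diffs=nd, s_diffs=sd, ka=ka, ks=ks,
    )


def trim_to_codon_alignment(gene: str, seq_a: str, seq_b: str,
                            code: GeneticCode = DEFAULT_CODE,
                            quiet: bool = False) -> CodonAlignmentPair:
    """Naive equal-length trim to the shorter multiple of 3.

    Suitable only for simulated, indel-free sequences; real orthologs
    must be codon-aligned properly first, hence the loud warning.
    """
    if not quiet:
        warnings.warn(
            f"{gene}: trimming sequences to equal length without alignment — "
            "only valid for indel-free (simulated) data"
        )
    n = min(len(seq_a), len(seq_b)) // 3 * 3
    a, b = normalize_residues(seq_a)[:n], normalize_residues(seq_b)[:n]
    # drop a trailing aligned stop codon so internal-stop validation applies
    return CodonAlignmentPair(gene, a, b, code)


def kaks_panel(
    cds_by_taxon: Mapping[str, Mapping[str, str]],
    reference: str,
    code: GeneticCode = DEFAULT_CODE,
    pre_aligned: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-taxon Ka/Ks against one reference taxon.

    ``cds_by_taxon`` maps taxon → {gene → sense-strand CDS}. Genes are
    matched by label. Returns a long-format table with a ``ratio``
    column (NaN where undefined) ready for the "<1 means purifying"
    summary.
    """
    if reference not in cds_by_taxon:
        raise KeyError(f"reference taxon {reference!r} not in panel")
    ref = cds_by_taxon[reference]
    rows = []
    for taxon, genes in cds_by_taxon.items():
        if taxon == reference:
            continue
        for gene, seq in genes.items():
            if gene not in ref:
                continue
            if pre_aligned:
                pair = CodonAlignmentPair(gene, seq, ref[gene], code)
            else:
                pair = trim_to_codon_alignment(gene, seq, ref[gene], code, quiet=True)
            est = ng86_kaks(pair)
            rows.append({
                "taxon": taxon, "gene": gene, "ka": est.ka, "ks": est.ks,
                "ratio": est.ratio, "n_sites": est.n_sites, "s_sites": est.s_sites,
                "n_diffs": est.n_diffs, "s_diffs": est.s_diffs,
            })
    return pd.DataFrame(rows)
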