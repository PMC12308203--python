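"""Codon counting and codon-usage-bias metrics.

Implements the classical descriptive statistics of codon bias on top of
an explicit genetic-code object:

* RSCU — relative synonymous codon usage, a codon's count divided by its
  family's mean count; uniform usage gives 1 for every codon.
* ENC — Wright's effective number of codons, generalized to the family
  structure of the genetic code in use (under the invertebrate
  mitochondrial code the synonymous families are twelve 2-fold, six
  4-fold, one 6-fold Leu and one 8-fold Ser family; ENC therefore ranges
  from 20, one codon per amino acid, to 62, uniform usage).
* CBI — codon bias index, the excess usage of a set of "optimal" codons
  beyond random expectation.
* GC / GC3 — G+C fraction over all codon positions and over third
  positions, stop codons excluded.

The default code is NCBI translation table 5 (invertebrate
mitochondrial), under which UGA encodes Trp and AGA/AGG join the Ser
family.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from Bio.Data import CodonTable

from ._util import normalize_residues, round_half_up


@dataclass(frozen=True)
class GeneticCode:
    """A codon → amino-acid map plus its derived synonymous-family partition."""

    table_id: int
    forward: Mapping[str, str]        # DNA codon -> one-letter amino acid
    stop_codons: frozenset
    families: Mapping[str, tuple]     # amino acid -> sense codons

    @classmethod
    def from_ncbi_id(cls, table_id: int = 5) -> "GeneticCode":
        t = CodonTable.unambiguous_dna_by_id[table_id]
        fams = defaultdict(list)
        for codon, aa in sorted(t.forward_table.items()):
            fams[aa].append(codon)
        return cls(
            table_id=table_id,
            forward=dict(t.forward_table),
            stop_codons=frozenset(t.stop_codons),
            families={aa: tuple(c) for aa, c in fams.items()},
        )

    def translate(self, codon: str) -> str:
        codon = normalize_residues(codon)
        if codon in self.stop_codons:
            return "*"
        return self.forward[codon]

    def family_of(self, codon: str) -> tuple:
        """All codons synonymous with ``codon`` (stops form their own family)."""
        codon = normalize_residues(codon)
        if codon in self.stop_codons:
            return tuple(sorted(self.stop_codons))
        return self.families[self.forward[codon]]

    @property
    def sense_codons(self) -> tuple:
        return tuple(sorted(self.forward))


DEFAULT_CODE = GeneticCode.from_ncbi_id(5)


@dataclass
class CodonCountTable:
    """Integer codon counts (DNA alphabet keys) under a genetic code."""

    counts: dict
    code: GeneticCode = field(default_factory=lambda: DEFAULT_CODE)
    source_genes: tuple = ()

    def __post_init__(self):
        clean = {}
        for codon, n in self.counts.items():
            codon = normalize_residues(codon)
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise ValueError(f"not a codon: {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            clean[codon] = clean.get(codon, 0) + int(n)
        self.counts = clean

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(normalize_residues(codon), 0)

    def family_total(self, codon: str) -> int:
        return sum(self.get(c) for c in self.code.family_of(codon))


def count_codons(
    cds_sequences: Iterable[str] | Mapping[str, str],
    code: GeneticCode = DEFAULT_CODE,
) -> CodonCountTable:
    """Count codons, stop codons included, over sense-strand CDS sequences.

    Each CDS must have length divisible by 3. An in-frame stop before the
    final codon triggers a warning naming the gene (complete mitochondrial
    CDSs are expected to carry a single terminal stop).
    """
    if isinstance(cds_sequences, Mapping):
        items = list(cds_sequences.items())
    else:
        items = [(f"cds{i+1}", s) for i, s in enumerate(cds_sequences)]
    counts: dict = {}
    for name, seq in items:
        seq = normalize_residues(seq)
        if len(seq) % 3:
            raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
        codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        for j, codon in enumerate(codons):
            if codon in code.stop_codons and j < len(codons) - 1:
                warnings.warn(f"{name}: internal stop codon {codon} at codon {j + 1}")
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(counts, code, tuple(n for n, _ in items))


def rscu(table: CodonCountTable, ndigits: Optional[int] = None) -> dict:
    """RSCU per codon: count × family size / family total.

    Families with zero total map to None (undefined). With ``ndigits``
    set, values are half-up rounded for reporting.
    """
    if table.total == 0:
        raise ValueError("empty codon count table")
    code = table.code
    out: dict = {}
    families = list(code.families.values()) + [tuple(sorted(code.stop_codons))]
    for family in families:
        total = sum(table.get(c) for c in family)
        for codon in family:
            if total == 0:
                out[codon] = None
            else:
                value = table.get(codon) * len(family) / total
                out[codon] = round_half_up(value, ndigits) if ndigits else value
    return out


def _family_homozygosity(counts: Sequence[int]) -> Optional[float]:
    """Wright's F̂ = (n·Σp̂² − 1)/(n − 1) for one synonymous family."""
    n = sum(counts)
    if n < 2:
        return None
    p2 = sum((c / n) ** 2 for c in counts)
    return (n * p2 - 1) / (n - 1)


def enc(table: CodonCountTable) -> float:
    """Wright's effective number of codons for this code's family structure.

    Per-family homozygosities are averaged within family-size classes and
    ENC = Σ_classes N_c / F̄_c. Families too sparse to estimate (n < 2)
    are imputed with their size class's mean; an entirely missing class
    is dropped and the total rescaled. Stop codons are excluded. The
    result is capped at the number of sense codons.
    """
    code = table.code
    by_size: dict = defaultdict(list)      # size -> list of F̂ or None
    for aa, family in code.families.items():
        f_hat = _family_homozygosity([table.get(c) for c in family])
        by_size[len(family)].append(f_hat)
    n_classes = {size: len(fs) for size, fs in by_size.items()}
    total_families = sum(n_classes.values())
    value = 0.0
    represented = 0
    for size, fs in by_size.items():
        observed = [f for f in fs if f is not None and f > 0]
        if not observed:
            continue  # class dropped; rescaled below
        f_bar = sum(observed) / len(observed)
        value += n_classes[size] / f_bar
        represented += n_classes[size]
    if represented == 0:
        raise ValueError("no synonymous family has two or more codons counted")
    value *= total_families / represented
    return min(value, len(code.sense_codons))


def optimal_codons(table: CodonCountTable) -> frozenset:
    """Per-family most frequent codons (ties broken alphabetically)."""
    best = []
    for family in table.code.families.values():
        best.append(max(sorted(family), key=table.get))
    return frozenset(best)


def cbi(table: CodonCountTable, optimal: Optional[frozenset] = None) -> float:
    """Codon bias index: (N_opt − N_rand) / (N_tot − N_rand).

    N_rand = Σ_families N_family / k_family is the expected optimal-codon
    count under uniform usage. 0 for uniform usage, 1 when only optimal
    codons are used. Stop codons excluded.
    """
    if optimal is None:
        optimal = optimal_codons(table)
    n_opt = n_tot = n_rand = 0.0
    for family in table.code.families.values():
        fam_total = sum(table.get(c) for c in family)
        n_tot += fam_total
        n_rand += fam_total / len(family)
        n_opt += sum(table.get(c) for c in family if c in optimal)
    if n_tot == n_rand:
        return 0.0
    return (n_opt - n_rand) / (n_tot - n_rand)


def gc_content(table: CodonCountTable) -> tuple[float, float]:
    """(GC over all codon positions, GC at third positions); stops excluded."""
    gc_all = pos_all = gc3 = pos3 = 0
    for codon, n in table.counts.items():
        if codon in table.code.stop_codons:
            continue
        gc_all += n * sum(b in "GC" for b in codon)
        pos_all += 3 * n
        gc3 += n * (codon[2] in "GC")
        pos3 += n
    if pos_all == 0:
        raise ValueError("no sense codons counted")
    return gc_all / pos_all, gc3 / pos3


@dataclass(frozen=True)
class CodonBiasMetrics:
    label: str
    enc: float
    cbi: float
    gc: float
    gc3: float


def codon_bias_metrics(table: CodonCountTable, label: str = "") -> CodonBiasMetrics:
    gc, gc3 = gc_content(table)
    return CodonBiasMetrics(label=label, enc=enc(table), cbi=cbi(table), gc=gc, gc3=gc3)


_PAIRS = [("enc", "gc"), ("enc", "gc3"), ("cbi", "gc"), ("cbi", "gc3"), ("enc", "cbi")]


def bias_correlations(metrics: pd.DataFrame, method: str = "spearman") -> pd.DataFrame:
    """Pairwise bias-metric correlations across genomes.

    ``metrics`` needs columns enc, cbi, gc, gc3 (one row per genome, ≥3
    rows). Default is rank-based (Spearman); "pearson" is available.
    Degenerate (constant) inputs yield NaN coefficients, not errors.
    """
    if len(metrics) < 3:
        raise ValueError("need at least 3 genomes for correlation")
    fn = {"spearman": _scipy_stats.spearmanr, "pearson": _scipy_stats.pearsonr}[method]
    rows = []
    for x, y in _PAIRS:
        xs, ys = metrics[x].to_numpy(float), metrics[y].to_numpy(float)
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            rho, p = float("nan"), float("nan")
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, p = fn(xs, ys)
        sign = "" if np.isnan(rho) else ("+" if rho > 0 else "-" if rho < 0 else "0")
        rows.append({"x": x, "y": y, "coefficient": float(rho),
                     "p_value": float(p), "sign": sign, "method": method})
    return pd.DataFrame(rows)
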