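"""Heuristic tRNA cloverleaf-completeness classification.

Mitochondrial tRNAs of many insect lineages lose one or both of the side
hairpins of the canonical cloverleaf: the DHU (D) arm 5' of the
anticodon arm, or the TΨC (T) arm 3' of it. Given a tRNA gene sequence
and its annotated anticodon position, this module anchors the anticodon
loop (7 nt centered on the triplet), seeks the anticodon stem as
complementary pairs flanking that loop, the acceptor stem as pairing
between the 5' and 3' ends, and a D- and T-hairpin in the regions
between — and classifies each gene as

    full / D-armless / T-armless / minimal (both side arms missing).

This is a transparent structural heuristic for sequences whose anticodon
is already known, not a general-purpose tRNA detector. G·U wobble pairs
count as pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from ._util import revcomp
from .annotation_io import MitoAnnotation

_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}

CLASSES = ("full", "D-armless", "T-armless", "minimal")


@dataclass(frozen=True)
class ArmParams:
    """Tunable thresholds of the arm finder."""

    min_stem_pairs: int = 3
    min_acceptor_pairs: int = 4
    loop_min: int = 3
    loop_max: int = 11
    allow_gu: bool = True
    max_discriminator: int = 3  # unpaired 3' overhang tried for the acceptor stem


DEFAULT_PARAMS = ArmParams()


@dataclass(frozen=True)
class TrnaModel:
    """Detected arm structure for one tRNA gene sequence."""

    name: str
    length: int
    acceptor_pairs: int
    anticodon_stem_pairs: int
    d_arm: bool
    d_stem_pairs: int
    t_arm: bool
    t_stem_pairs: int

    @property
    def completeness(self) -> str:
        if self.d_arm and self.t_arm:
            return "full"
        if self.t_arm:
            return "D-armless"
        if self.d_arm:
            return "T-armless"
        return "minimal"


def _is_pair(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _PAIRS or (allow_gu and (a, b) in _WOBBLE)


def _stem_run(seq: str, left: int, right: int, params: ArmParams) -> int:
    """Pairs formed walking outward from (left, right) toward the ends."""
    run = 0
    while left >= 0 and right < len(seq) and _is_pair(seq[left], seq[right], params.allow_gu):
        run += 1
        left -= 1
        right += 1
    return run


def _best_hairpin(region: str, params: ArmParams) -> int:
    """Longest stem of any hairpin (stem-loop-stem) inside ``region``.

    Returns 0 if no hairpin with >= min_stem_pairs and a loop within
    bounds fits in the region.
    """
    n = len(region)
    best = 0
    for stem in range(params.min_stem_pairs, n // 2 + 1):
        for loop in range(params.loop_min, params.loop_max + 1):
            span = 2 * stem + loop
            if span > n:
                break
            for i in range(n - span + 1):
                ok = all(
                    _is_pair(region[i + k], region[i + span - 1 - k], params.allow_gu)
                    for k in range(stem)
                )
                if ok:
                    best = max(best, stem)
                    break
    return best


def detect_arms(
    sequence: str,
    anticodon_span: tuple[int, int],
    params: ArmParams = DEFAULT_PARAMS,
    name: str = "",
) -> TrnaModel:
    """Detect acceptor, anticodon, D and T arms in a 5'→3' tRNA sequence.

    ``anticodon_span`` is the 1-based inclusive position of the anticodon
    triplet within ``sequence``. Sequences down to ~38 nt are handled;
    regions too short to hold a hairpin simply yield absent arms.
    """
    seq = sequence.upper().replace("U", "T")
    ac_start, ac_end = anticodon_span
    if not (1 <= ac_start <= ac_end <= len(seq)) or ac_end - ac_start != 2:
        raise ValueError(f"{name or 'tRNA'}: anticodon span {anticodon_span} "
                         f"invalid for length {len(seq)}")
    # anticodon loop: 7 nt with the triplet at its center
    loop_lo = ac_start - 3        # 0-based index of loop start
    loop_hi = ac_end + 2          # 0-based index one past loop end
    ac_stem = _stem_run(seq, loop_lo - 1, loop_hi, params)
    ac_stem_ok = ac_stem >= params.min_stem_pairs

    # acceptor stem: 5' end pairing with the 3' end, allowing a short
    # unpaired discriminator overhang at the 3' terminus
    acc_best = 0
    acc_disc = 0
    for disc in range(params.max_discriminator + 1):
        run = 0
        left, right = 0, len(seq) - 1 - disc
        while left < right and _is_pair(seq[left], seq[right], params.allow_gu):
            run += 1
            left += 1
            right -= 1
        if run > acc_best:
            acc_best, acc_disc = run, disc

    stem_used = ac_stem if ac_stem_ok else 0
    d_region = seq[acc_best:max(loop_lo - stem_used, acc_best)]
    t_region = seq[loop_hi + stem_used:len(seq) - acc_disc - acc_best]
    d_stem = _best_hairpin(d_region, params)
    t_stem = _best_hairpin(t_region, params)

    return TrnaModel(
        name=name, length=len(seq),
        acceptor_pairs=acc_best, anticodon_stem_pairs=ac_stem,
        d_arm=d_stem >= params.min_stem_pairs, d_stem_pairs=d_stem,
        t_arm=t_stem >= params.min_stem_pairs, t_stem_pairs=t_stem,
    )


def _relative_anticodon_span(feature, genome_length: int) -> Optional[tuple[int, int]]:
    if feature.anticodon_span is None:
        return None
    a, b = feature.anticodon_span
    if feature.strand == "J":
        return a - feature.start + 1, b - feature.start + 1
    # on the minority strand the gene runs 3'→5' in genome coordinates
    return feature.end - b + 1, feature.end - a + 1


def classify_annotation(
    annotation: MitoAnnotation,
    residues: str,
    params: ArmParams = DEFAULT_PARAMS,
) -> tuple[pd.DataFrame, Counter]:
    """Classify every annotated tRNA; returns (per-gene table, class histogram).

    N-strand tRNAs are classified on their reverse complement, so the
    result is strand-invariant. tRNAs without an annotated anticodon are
    reported with class "unknown" and excluded from the histogram.
    """
    rows = []
    histogram: Counter = Counter()
    for f in annotation.trnas:
        seq = f.extract(residues, annotation.genome_length)
        span = _relative_anticodon_span(f, annotation.genome_length)
        if span is None:
            rows.append({"gene": f.name, "length": len(seq), "class": "unknown",
                         "d_arm": None, "t_arm": None, "acceptor_pairs": None})
            continue
        model = detect_arms(seq, span, params, name=f.name)
        histogram[model.completeness] += 1
        rows.append({
            "gene": f.name, "length": model.length, "class": model.completeness,
            "d_arm": model.d_arm, "t_arm": model.t_arm,
            "acceptor_pairs": model.acceptor_pairs,
        })
    return pd.DataFrame(rows), histogram
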