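"""Circular signed gene-order comparison.

A mitogenome's gene order is modelled as a circular signed permutation
of gene labels (sign = coding strand). The module provides a canonical
form (rotation- and reflection-stable), the breakpoint distance (number
of signed adjacencies of one order absent from the other, with the
adjacency x→y identified with −y→−x), contiguous-cluster search with
inverted occurrences, a presence/absence scan for clade-diagnostic
clusters, and a neighbor-joining tree on the breakpoint-distance matrix
as descriptive plumbing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

SignedGene = tuple[str, int]  # (label, +1 for J / -1 for N)

# ND2-flanking tRNA clusters discussed for scale-insect mitogenomes: the
# ancestral arrangement retained by non-neococcoid families, and the
# derived arrangements regarded as neococcoid apomorphies.
ANCESTRAL_ND2_CLUSTER: tuple[SignedGene, ...] = (("trnM", 1), ("ND2", 1), ("trnW", 1))
NEOCOCCOID_ND2_CLUSTERS: dict[str, tuple[SignedGene, ...]] = {
    "trnI-ND2-trnY": (("trnI", 1), ("ND2", 1), ("trnY", -1)),
    "trnY-ND2-trnW": (("trnY", -1), ("ND2", 1), ("trnW", 1)),
    "trnI-ND2-trnW": (("trnI", 1), ("ND2", 1), ("trnW", 1)),
    "trnQ-ND2-trnW": (("trnQ", -1), ("ND2", 1), ("trnW", 1)),
}


@dataclass(frozen=True)
class GeneOrder:
    """A circular signed gene order for one taxon."""

    taxon: str
    genes: tuple[SignedGene, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("empty gene order")
        labels = [g for g, _ in self.genes]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"{self.taxon}: duplicate gene labels {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def labels(self) -> frozenset:
        return frozenset(g for g, _ in self.genes)

    def index_of(self, label: str) -> int:
        for i, (g, _) in enumerate(self.genes):
            if g == label:
                return i
        raise KeyError(label)

    def format(self) -> str:
        return ",".join(f"{'-' if s < 0 else ''}{g}" for g, s in self.genes)

    @classmethod
    def parse(cls, text: str, taxon: str = "") -> "GeneOrder":
        genes = []
        for token in text.strip().split(","):
            token = token.strip()
            if token.startswith("-") or token.startswith("−"):
                genes.append((token[1:], -1))
            elif token.startswith("+"):
                genes.append((token[1:], 1))
            else:
                genes.append((token, 1))
        return cls(taxon=taxon, genes=tuple(genes))


def _flip(order: Sequence[SignedGene]) -> tuple[SignedGene, ...]:
    """Read the circle from the opposite strand: reverse and negate signs."""
    return tuple((g, -s) for g, s in reversed(order))


def canonicalize(order: GeneOrder, anchor: str = "COI") -> GeneOrder:
    """Rotate to start at ``anchor`` with positive orientation.

    If the anchor is on the negative strand the whole order is flipped
    first, so two orders equal up to rotation and reflection share one
    canonical form.
    """
    genes = order.genes
    try:
        i = order.index_of(anchor)
    except KeyError:
        raise KeyError(f"{order.taxon or 'order'}: anchor gene {anchor!r} absent")
    if genes[i][1] < 0:
        genes = _flip(genes)
        i = next(j for j, (g, _) in enumerate(genes) if g == anchor)
    rotated = genes[i:] + genes[:i]
    return GeneOrder(taxon=order.taxon, genes=rotated)


def adjacencies(order: GeneOrder) -> frozenset:
    """Signed circular adjacency set; x→y is identified with −y→−x."""
    out = set()
    n = len(order.genes)
    for i in range(n):
        x = order.genes[i]
        y = order.genes[(i + 1) % n]
        forward = (x, y)
        backward = ((y[0], -y[1]), (x[0], -x[1]))
        out.add(min(forward, backward))
    return frozenset(out)


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` not present in ``b``.

    Restricted to the shared label set (with a warning) when the two
    orders do not carry the same genes; symmetric on equal label sets.
    """
    if a.labels != b.labels:
        shared = a.labels & b.labels
        if not shared:
            raise ValueError("orders share no gene labels")
        warnings.warn(
            f"orders {a.taxon!r}/{b.taxon!r} differ in gene content; "
            f"restricting to {len(shared)} shared labels"
        )
        a = GeneOrder(a.taxon, tuple(g for g in a.genes if g[0] in shared))
        b = GeneOrder(b.taxon, tuple(g for g in b.genes if g[0] in shared))
    return len(adjacencies(a) - adjacencies(b))


@dataclass(frozen=True)
class ClusterMatch:
    position: int      # index in the order where the match starts
    inverted: bool


def find_cluster(
    order: GeneOrder,
    pattern: Sequence[SignedGene],
    orientation_sensitive: bool = True,
) -> list[ClusterMatch]:
    """Contiguous circular occurrences of a signed gene pattern.

    With ``orientation_sensitive`` the reverse-complement of the pattern
    (reversed order, flipped signs) is also sought and reported as an
    inverted occurrence. Without it, signs are ignored entirely.
    """
    pattern = tuple(pattern)
    if len(pattern) < 2:
        raise ValueError("cluster patterns need at least 2 genes")
    n, k = len(order.genes), len(pattern)
    if k > n:
        return []
    doubled = order.genes + order.genes[:k - 1]

    def matches(window, pat, signed):
        if signed:
            return all(w == p for w, p in zip(window, pat))
        return all(w[0] == p[0] for w, p in zip(window, pat))

    out = []
    inv = _flip(pattern)
    for i in range(n):
        window = doubled[i:i + k]
        if matches(window, pattern, orientation_sensitive):
            out.append(ClusterMatch(position=i, inverted=False))
        elif matches(window, inv, orientation_sensitive):
            out.append(ClusterMatch(position=i, inverted=True))
    return out


def apomorphy_scan(
    orders_by_group: Mapping[str, Sequence[GeneOrder]],
    patterns: Mapping[str, Sequence[SignedGene]],
    count_inverted: bool = True,
) -> pd.DataFrame:
    """Presence/absence of candidate diagnostic clusters per clade.

    Returns one row per (pattern, group) with the presence fraction,
    plus two flags per pattern: ``fixed_in`` names a group where the
    pattern occurs in every member while being absent from all other
    groups; ``diagnostic_for`` only requires presence in at least one
    member and absence everywhere else — the form in which derived gene
    clusters are usually cited as clade apomorphies, since rearrangement
    hotspots keep even diagnostic clusters from being universal.
    """
    if len(orders_by_group) < 2:
        raise ValueError("need at least two groups")
    all_labels = set()
    for orders in orders_by_group.values():
        for o in orders:
            all_labels |= o.labels
    rows = []
    for pname, pattern in patterns.items():
        for g, _ in pattern:
            if g not in all_labels:
                raise ValueError(f"pattern {pname!r} references unknown gene {g!r}")
        presence = {}
        for group, orders in orders_by_group.items():
            hits = []
            for o in orders:
                ms = find_cluster(o, pattern)
                if not count_inverted:
                    ms = [m for m in ms if not m.inverted]
                hits.append(bool(ms))
            presence[group] = sum(hits) / len(hits) if hits else 0.0
        present_groups = [g for g, frac in presence.items() if frac > 0]
        diagnostic = present_groups[0] if len(present_groups) == 1 else None
        fixed = (
            diagnostic
            if diagnostic is not None and presence[diagnostic] == 1.0
            else None
        )
        for group, frac in presence.items():
            rows.append({
                "pattern": pname, "group": group, "presence_fraction": frac,
                "diagnostic_for": diagnostic, "fixed_in": fixed,
            })
    return pd.DataFrame(rows)


def order_distance_matrix(orders: Sequence[GeneOrder]) -> pd.DataFrame:
    """Symmetric breakpoint-distance matrix over a set of orders."""
    if len(orders) < 2:
        raise ValueError("need at least two orders")
    names = [o.taxon or f"order{i+1}" for i, o in enumerate(orders)]
    if len(set(names)) != len(names):
        raise ValueError("taxon labels must be unique")
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i, a in enumerate(orders):
        for j in range(i + 1, len(orders)):
            d = breakpoint_distance(a, orders[j])
            mat.iat[i, j] = mat.iat[j, i] = d
    return mat


def nj_tree(matrix: pd.DataFrame) -> str:
    """Neighbor-joining tree (newick text) from a distance matrix.

    Negative branch lengths produced by NJ on non-additive matrices are
    clamped to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    import io

    dm = DistanceMatrix(matrix.to_numpy(dtype=float), ids=list(matrix.index))
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def read_orders(path) -> tuple[dict[str, GeneOrder], dict[str, str]]:
    """Read the gene-order exchange format.

    One taxon per line: ``taxon<TAB>[group<TAB>]order`` with the order
    as comma-separated signed labels ("-trnY" = minority strand).
    Returns (orders by taxon, group by taxon; group empty if absent).
    """
    orders: dict[str, GeneOrder] = {}
    groups: dict[str, str] = {}
    text = path if isinstance(path, str) and "\n" in path else open(path).read()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("taxon\t"):
            continue
        parts = line.split("\t")
        if len(parts) == 2:
            taxon, group, order_text = parts[0], "", parts[1]
        elif len(parts) == 3:
            taxon, group, order_text = parts
        else:
            raise ValueError(f"cannot parse gene-order line: {line[:60]!r}")
        orders[taxon] = GeneOrder.parse(order_text, taxon=taxon)
        groups[taxon] = group
    if not orders:
        raise ValueError("no gene orders found")
    return orders, groups


def load_reference_orders() -> tuple[dict[str, GeneOrder], dict[str, str]]:
    """The packaged scale-insect order set (ancestor + 18 taxa).

    Partly synthetic: only the ancestral and Putoidae orders and the
    literature-stated diagnostic clusters are real; see the fixture
    header and the methods note.
    """
    text = (
        resources.files("mitoprof.data")
        .joinpath("coccoid_gene_orders_synthetic.tsv")
        .read_text()
    )
    return read_orders(text)
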