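"""Small sequence utilities: substitution classification between coding
haplotypes, isoelectric point, Jukes-Cantor distance and neighbor joining.

Substitution counting is codon-level and observational: aligned in-frame CDS
pairs are compared codon by codon, and the nucleotide differences in a codon
are classified as nonsynonymous when the translated amino acids differ and
synonymous otherwise.  This mirrors how observed substitution counts between
sequenced haplotypes are reported, not a per-path evolutionary estimate.

The isoelectric point solves net charge(pH) = 0 by bisection with
Henderson-Hasselbalch charges for the termini and the ionizable side chains
(D, E, C, Y, H, K, R) under the EMBOSS pKa set:

    N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "count_substitutions",
    "isoelectric_point",
    "jc_distance",
    "nj_tree",
    "bootstrap_support",
    "EMBOSS_PKA",
]

EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "C", "D", "E", "Y")

_NUCS = set("ACGTN")


def _check_cds(seq: str, name: str) -> str:
    s = seq.upper().replace("U", "T")
    if len(s) % 3 != 0:
        raise ValueError(f"{name}: length not divisible by 3")
    if set(s) - _NUCS:
        raise ValueError(f"{name}: non-ACGTN characters")
    return s


def count_substitutions(a: str, b: str) -> tuple[int, int, int]:
    """(total, synonymous, nonsynonymous) nucleotide differences between two
    aligned in-frame CDSs.

    A codon pair differing at one or more positions contributes its
    nucleotide differences as nonsynonymous if the translated amino acids
    differ, else synonymous.  Codons containing N are skipped.
    """
    a = _check_cds(a, "a")
    b = _check_cds(b, "b")
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    total = syn = nonsyn = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "N" in ca or "N" in cb:
            continue
        nd = sum(x != y for x, y in zip(ca, cb))
        if nd == 0:
            continue
        total += nd
        if str(Seq(ca).translate()) == str(Seq(cb).translate()):
            syn += nd
        else:
            nonsyn += nd
    return total, syn, nonsyn


def _net_charge(ph: float, counts: dict[str, int]) -> float:
    q = 0.0
    for grp in _POSITIVE:
        n = 1 if grp == "Nterm" else counts.get(grp, 0)
        q += n / (1.0 + 10.0 ** (ph - EMBOSS_PKA[grp]))
    for grp in _NEGATIVE:
        n = 1 if grp == "Cterm" else counts.get(grp, 0)
        q -= n / (1.0 + 10.0 ** (EMBOSS_PKA[grp] - ph))
    return q


def isoelectric_point(protein: str, tol: float = 1e-4) -> float:
    """pH at which the net protein charge is zero (bisection to ``tol``)."""
    seq = protein.upper().strip("*")
    if not seq:
        raise ValueError("empty sequence")
    counts = {aa: seq.count(aa) for aa in "CDEHKRY"}
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge(mid, counts) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def jc_distance(a: str, b: str) -> float:
    """Jukes-Cantor corrected distance d = -(3/4) ln(1 - (4/3) p-hat).

    Sites where either sequence has N are excluded from the comparison.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    pairs = [(x, y) for x, y in zip(a, b) if x != "N" and y != "N"]
    if not pairs:
        raise ValueError("no comparable sites")
    p = sum(x != y for x, y in pairs) / len(pairs)
    if p >= 0.75:
        raise ValueError("proportion of differences >= 3/4; "
                         "JC distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    label: str | None
    children: list[tuple["_Node", float]]

    def leaves(self) -> frozenset:
        if self.label is not None and not self.children:
            return frozenset([self.label])
        out = frozenset()
        for ch, _ in self.children:
            out |= ch.leaves()
        return out

    def newick(self, support: dict[frozenset, float] | None = None) -> str:
        if not self.children:
            return self.label
        parts = []
        for ch, bl in self.children:
            s = ch.newick(support)
            if support is not None and ch.children:
                sup = support.get(ch.leaves())
                if sup is not None:
                    s += f"{sup:.2f}"
            parts.append(f"{s}:{bl:.6g}")
        return "(" + ",".join(parts) + ")"


def _min_label(node: _Node) -> str:
    return min(node.leaves())


def nj_tree(dist: np.ndarray, labels: list[str], outgroup: str | None = None
            ) -> tuple[str, _Node]:
    """Neighbor joining on a distance matrix; returns (newick, root node).

    Standard Q-criterion joins; ties resolve to the lexicographically
    smallest label pair (labels compared by the smallest leaf under each
    node).  Negative branch lengths are clamped to zero with the excess
    moved to the sister branch.  With an outgroup the tree is rooted on its
    pendant edge; otherwise the final three-way join is the (unrooted) root.
    """
    D = np.asarray(dist, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0) or np.any(D < 0):
        raise ValueError("need zero diagonal and nonnegative distances")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [_Node(lbl, []) for lbl in labels]
    D = D.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = [(i, j) for i in range(m) for j in range(i + 1, m)
                if Q[i, j] <= qmin + 1e-10]
        cand.sort(key=lambda ij: tuple(sorted(
            (_min_label(nodes[active[ij[0]]]),
             _min_label(nodes[active[ij[1]]])))))
        i, j = cand[0]
        gi, gj = active[i], active[j]
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        # clamp negatives, moving the excess to the sister branch
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        new = _Node(None, [(nodes[gi], vi), (nodes[gj], vj)])
        nodes.append(new)
        gn = len(nodes) - 1
        newrow = np.zeros(len(nodes))
        D = np.pad(D, ((0, 1), (0, 1)))
        for t in range(m):
            if t in (i, j):
                continue
            gt = active[t]
            D[gn, gt] = D[gt, gn] = 0.5 * (sub[i, t] + sub[j, t] - dij)
        active = [a for a in active if a not in (gi, gj)] + [gn]
    # final three-way join
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    branches = []
    for node_i, v in ((a, va), (b, vb), (c, vc)):
        branches.append((nodes[node_i], max(v, 0.0)))
    root = _Node(None, branches)
    if outgroup is not None:
        root = _root_on_outgroup(root, outgroup)
    return root.newick() + ";", root


def _root_on_outgroup(root: _Node, outgroup: str) -> _Node:
    """Re-root on the outgroup's pendant edge (split its branch in half)."""
    for idx, (ch, bl) in enumerate(root.children):
        if ch.label == outgroup and not ch.children:
            rest = [c for k, c in enumerate(root.children) if k != idx]
            ingroup = _Node(None, rest)
            return _Node(None, [(ch, bl / 2.0), (ingroup, bl / 2.0)])
    # outgroup deeper in the tree: leave the trifurcating root (documented)
    return root


def _bipartitions(root: _Node, all_leaves: frozenset) -> set[frozenset]:
    out = set()

    def walk(node):
        for ch, _ in node.children:
            if ch.children:
                side = ch.leaves()
                out.add(min(side, all_leaves - side, key=sorted))
            walk(ch)

    walk(root)
    return out


def bootstrap_support(alignment: dict[str, str], n_reps: int = 100,
                      seed: int = 0) -> tuple[str, dict[frozenset, float]]:
    """NJ tree with bootstrap support from column resampling.

    Replicates resample alignment columns with replacement, recompute JC
    distances and the NJ topology, and record bipartition frequencies; the
    support values annotate the tree built from the original alignment.
    """
    labels = sorted(alignment)
    seqs = [alignment[l] for l in labels]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("alignment sequences must have equal length")
    cols = np.array([list(s) for s in seqs])  # taxa x sites

    def dist_from(c):
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = jc_distance("".join(c[i]), "".join(c[j]))
        return D

    newick, root = nj_tree(dist_from(cols), labels)
    all_leaves = frozenset(labels)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        _, rep_root = nj_tree(dist_from(cols[:, idx]), labels)
        for bp in _bipartitions(rep_root, all_leaves):
            counts[bp] = counts.get(bp, 0) + 1
    support = {bp: c / n_reps for bp, c in counts.items()}
    # annotate the main tree's internal splits
    annotated = {}
    for bp in _bipartitions(root, all_leaves):
        annotated[bp] = support.get(bp, 0.0)
    # map annotated canonical splits back to clade leaf-sets for newick
    clade_support = {}

    def walk(node):
        for ch, _ in node.children:
            if ch.children:
                side = ch.leaves()
                canon = min(side, all_leaves - side, key=sorted)
                clade_support[side] = support.get(canon, 0.0)
            walk(ch)

    walk(root)
    return root.newick(clade_support) + ";", annotated
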