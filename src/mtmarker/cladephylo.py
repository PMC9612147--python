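"""Distance-based phylogenetics for marker resolution and clade typing.

Intra-species panels of near-identical sequences are compared with
p-distances (pairwise deletion of ambiguous columns, optional JC69
correction) and clustered with Saitou-Nei neighbor joining.  Marker
resolution is quantified as normalized Robinson-Foulds congruence between
the marker-only tree and the whole-genome tree; clades are delimited by
single-linkage clustering at a p-distance cutoff, and environmental
amplicons are typed to the clade of their nearest haplotype.

Neighbor joining is implemented here (deterministic tie-breaks, negative
branch lengths clamped to zero with the deficit moved to the sister
branch, zero-length internal edges collapsed to polytomies); tree
comparison is delegated to dendropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.calculate import treecompare

from mtmarker.seqcore import CircularGenome
from mtmarker.markerdesign import smith_waterman

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)

_ZERO_EDGE = 1e-12  # internal edges at/below this are collapsed to polytomies


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


def _pairwise_p(a: np.ndarray, b: np.ndarray, ok_a: np.ndarray, ok_b: np.ndarray) -> float:
    both = ok_a & ok_b
    n = int(both.sum())
    if n == 0:
        raise ValueError("sequence pair with zero comparable positions")
    return float(((a != b) & both).sum()) / n


def p_distance_matrix(
    aligned_seqs: Mapping[str, str], jc69: bool = False
) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of ambiguity/gap columns.

    With ``jc69`` the Jukes-Cantor transform -(3/4) ln(1 - 4p/3) is
    applied; it is undefined at p >= 0.75.
    """
    labels = list(aligned_seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    L = len(next(iter(aligned_seqs.values())))
    arrs, oks = {}, {}
    for lab, s in aligned_seqs.items():
        if len(s) != L:
            raise ValueError(f"sequence {lab!r} length {len(s)} != {L}")
        arr = np.frombuffer(s.upper().encode(), dtype=np.uint8)
        arrs[lab], oks[lab] = arr, np.isin(arr, _ACGT)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        p = _pairwise_p(arrs[labels[i]], arrs[labels[j]], oks[labels[i]], oks[labels[j]])
        if jc69:
            if p >= 0.75:
                raise ValueError(f"JC69 undefined at p = {p:.4f} >= 0.75")
            p = -0.75 * math.log1p(-4.0 * p / 3.0)
        d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# neighbor joining


class _Node:
    __slots__ = ("children", "leaf", "tag")

    def __init__(self, leaf: str | None, children=None, tag: str = ""):
        self.leaf = leaf
        self.children: list[tuple[_Node, float]] = children or []
        self.tag = tag if leaf is None else leaf  # smallest leaf label beneath

    def newick(self) -> str:
        if self.leaf is not None:
            return self.leaf
        parts = [f"{c.newick()}:{l:.10g}" for c, l in self.children]
        return "(" + ",".join(parts) + ")"


def _collapse_zero_edges(node: _Node) -> None:
    """Promote children across internal edges of (near-)zero length."""
    changed = True
    while changed:
        changed = False
        new_children = []
        for child, length in node.children:
            if child.leaf is None and length <= _ZERO_EDGE:
                new_children.extend(child.children)
                changed = True
            else:
                new_children.append((child, length))
        node.children = new_children
    for child, _ in node.children:
        if child.leaf is None:
            _collapse_zero_edges(child)


def nj_tree(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    The pair minimising Q_ij = (n-2) d_ij - r_i - r_j is joined at each
    step, ties broken by the lexicographically smallest label pair (an
    internal node is labelled by the smallest leaf beneath it).  Negative
    branch lengths are clamped to zero with the deficit moved to the
    sister branch; zero-length internal edges are collapsed, so an
    all-zero matrix yields a star tree.
    """
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    nodes: list[_Node] = [_Node(leaf=lab) for lab in dm.labels]
    D: dict[tuple[int, int], float] = {}
    ids = list(range(len(nodes)))
    for i, j in combinations(ids, 2):
        D[(i, j)] = D[(j, i)] = float(dm.d[i, j])
    next_id = len(nodes)
    node_of = {i: nodes[i] for i in ids}

    while len(ids) > 3:
        n = len(ids)
        r = {i: sum(D[(i, k)] for k in ids if k != i) for i in ids}
        best = None
        for i, j in combinations(ids, 2):
            q = (n - 2) * D[(i, j)] - r[i] - r[j]
            li, lj = sorted((node_of[i].tag, node_of[j].tag))
            key = (q, li, lj)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = D[(i, j)]
        vi = dij / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        vj = dij - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        a, b = node_of[i], node_of[j]
        if (b.tag, a.tag) < (a.tag, b.tag):
            a, b, vi, vj = b, a, vj, vi
        new = _Node(leaf=None, children=[(a, vi), (b, vj)], tag=min(a.tag, b.tag))
        u = next_id
        next_id += 1
        node_of[u] = new
        for k in ids:
            if k in (i, j):
                continue
            duk = 0.5 * (D[(i, k)] + D[(j, k)] - dij)
            D[(u, k)] = D[(k, u)] = duk
        ids = [k for k in ids if k not in (i, j)] + [u]

    (x, y, z) = ids
    dxy, dxz, dyz = D[(x, y)], D[(x, z)], D[(y, z)]
    vx = max((dxy + dxz - dyz) / 2.0, 0.0)
    vy = max((dxy + dyz - dxz) / 2.0, 0.0)
    vz = max((dxz + dyz - dxy) / 2.0, 0.0)
    trio = sorted(
        [(node_of[x], vx), (node_of[y], vy), (node_of[z], vz)],
        key=lambda t: t[0].tag,
    )
    root = _Node(leaf=None, children=trio, tag=trio[0][0].tag)
    _collapse_zero_edges(root)
    return root.newick() + ";"


def rf_distance(newick1: str, newick2: str) -> int:
    """Robinson-Foulds (symmetric bipartition difference) of unrooted trees."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    t1.is_rooted = t2.is_rooted = False
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(treecompare.symmetric_difference(t1, t2))


@dataclass
class ResolutionResult:
    score: float
    marker_tree: str
    genome_tree: str
    rf: int
    warning: str | None = None


def resolution_score(
    marker_alignment: Mapping[str, str], genome_alignment: Mapping[str, str]
) -> ResolutionResult:
    """Marker resolution as normalized RF congruence with the genome tree.

    score = 1 - RF / (2 (n-3)) for n >= 4 taxa; a 3-taxon comparison has a
    single unrooted topology and scores 1.  A marker alignment without any
    variable site yields a star tree and a warning.
    """
    if set(marker_alignment) != set(genome_alignment):
        raise ValueError("marker and genome alignments cover different strains")
    n = len(marker_alignment)
    if n < 3:
        raise ValueError("resolution needs >= 3 strains")
    marker_nwk = nj_tree(p_distance_matrix(marker_alignment))
    genome_nwk = nj_tree(p_distance_matrix(genome_alignment))
    warning = None
    seqs = list(marker_alignment.values())
    if all(s == seqs[0] for s in seqs):
        warning = "uninformative marker: no variable site in the marker alignment"
    if n == 3:
        score, rf = 1.0, 0
    else:
        rf = rf_distance(marker_nwk, genome_nwk)
        score = 1.0 - rf / (2.0 * (n - 3))
    return ResolutionResult(
        score=score, marker_tree=marker_nwk, genome_tree=genome_nwk, rf=rf,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# clade delimitation and amplicon typing


@dataclass
class CladeModel:
    tree: str | None  # Newick; None when fewer than 3 taxa
    clade_of: dict[str, int]
    n_clades: int


def assign_clades(
    aligned_seqs: Mapping[str, str], linkage_cutoff: float = 0.005
) -> CladeModel:
    """Single-linkage clades on p-distance.

    Two sequences join the same clade iff they are connected by a chain of
    pairs at distance strictly below the cutoff (default 0.005
    substitutions/site, i.e. 2 differences over a 400-nt marker separate
    clades).  Clades are numbered 1..k by their smallest member label.
    """
    labels = sorted(aligned_seqs)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    dm = p_distance_matrix({l: aligned_seqs[l] for l in labels})
    parent = {l: l for l in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(range(len(labels)), 2):
        if dm.d[i, j] < linkage_cutoff:
            parent[find(labels[i])] = find(labels[j])
    groups: dict[str, list[str]] = {}
    for l in labels:
        groups.setdefault(find(l), []).append(l)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    clade_of = {l: k + 1 for k, g in enumerate(ordered) for l in g}
    tree = nj_tree(dm) if len(labels) >= 3 else None
    return CladeModel(tree=tree, clade_of=clade_of, n_clades=len(ordered))


@dataclass
class AmpliconTyping:
    per_amplicon: pd.DataFrame  # amplicon, site, region, clade, distance
    region_clade_matrix: pd.DataFrame  # regions x clades, assigned counts
    combined_tree: str | None


def _amplicon_distance(amp: str, hap: str) -> float:
    if len(amp) == len(hap):
        a = np.frombuffer(amp.upper().encode(), dtype=np.uint8)
        h = np.frombuffer(hap.upper().encode(), dtype=np.uint8)
        return _pairwise_p(a, h, np.isin(a, _ACGT), np.isin(h, _ACGT))
    # coverage-weighted: unaligned amplicon tails count against identity,
    # so a short perfect sub-hit cannot tie a full-length near-match
    aln = smith_waterman(amp, hap)
    return 1.0 - aln.matches / len(amp)


def classify_amplicons(
    amplicons: Sequence[CircularGenome],
    metadata: pd.DataFrame,
    clade_haplotypes: Mapping[str, str],
    reject_threshold: float = 0.15,
) -> AmpliconTyping:
    """Type each amplicon to the clade of its nearest haplotype.

    Equal-length amplicons are compared by p-distance in the marker frame;
    length-discordant ones are locally aligned first.  Equidistant nearest
    haplotypes from different clades give "ambiguous"; a nearest distance
    above ``reject_threshold`` gives "unassigned" (possible off-target).
    The combined tree joins strain haplotypes with all same-length
    amplicons.
    """
    if not clade_haplotypes:
        raise ValueError("no clade haplotypes supplied")
    meta = metadata.set_index("amplicon")
    missing = [a.id for a in amplicons if a.id not in meta.index]
    if missing:
        raise ValueError(f"amplicons absent from metadata: {missing[:5]}")
    clades = sorted(clade_haplotypes)
    rows = []
    for amp in amplicons:
        dists = {c: _amplicon_distance(amp.seq, clade_haplotypes[c]) for c in clades}
        dmin = min(dists.values())
        nearest = [c for c in clades if abs(dists[c] - dmin) <= 1e-12]
        if dmin > reject_threshold:
            call = "unassigned"
        elif len(nearest) > 1:
            call = "ambiguous"
        else:
            call = nearest[0]
        rows.append(
            {
                "amplicon": amp.id,
                "site": meta.loc[amp.id, "site"],
                "region": meta.loc[amp.id, "region"],
                "clade": call,
                "distance": dmin,
            }
        )
    per_amp = pd.DataFrame(rows, columns=["amplicon", "site", "region", "clade", "distance"])
    regions = list(dict.fromkeys(meta["region"]))
    mat = pd.DataFrame(0, index=regions, columns=clades)
    for _, r in per_amp.iterrows():
        if r["clade"] in clades:
            mat.loc[r["region"], r["clade"]] += 1
    combined = {f"hap_{c}": clade_haplotypes[c] for c in clades}
    hap_len = len(next(iter(clade_haplotypes.values())))
    for amp in amplicons:
        if len(amp.seq) == hap_len:
            combined[amp.id] = amp.seq
    tree = nj_tree(p_distance_matrix(combined)) if len(combined) >= 3 else None
    return AmpliconTyping(
        per_amplicon=per_amp, region_clade_matrix=mat, combined_tree=tree
    )
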