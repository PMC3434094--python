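"""Signed gene-order rearrangement engine.

Mitochondrial gene orders are modeled as signed permutations: every genome
carries the same gene set exactly once, a gene's sign giving its strand.
Pairwise comparison is driven by *common intervals* — gene sets occupying
consecutive positions in both orders — whose overlap-free members (*strong
intervals*) form a laminar family, hence a tree.  Each inner node of that
strong interval tree is classified by the order its child blocks take in the
second genome (the quotient permutation): identity -> linear increasing,
reversal -> linear decreasing, anything else -> prime.

From the classified tree a rearrangement scenario is read off using four
operation kinds: inversion, transposition, inverse transposition, and
tandem-duplication-random-loss (TDRL).  The scenario is a heuristic (global
minimality is not guaranteed) but every returned scenario is *replay valid*:
applying its operations in order to the source permutation yields the target.
Prime nodes are resolved by TDRLs realizing the quotient in the provable
minimum number of whole-region duplication-loss steps.

Ancestral gene orders on a rooted tree are assigned bottom-up, choosing for
each internal node the candidate order (children's orders plus intermediates
along the inter-child scenario) minimizing the summed scenario length to its
children and nearest resolved context.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

from .io_formats import GeneOrderRecord

__all__ = [
    "GENE_ALPHABET",
    "SITNode",
    "RearrangementOp",
    "Scenario",
    "AncestralAssignment",
    "canonicalize",
    "encode",
    "decode",
    "apply_operation",
    "invert_segment",
    "common_intervals",
    "build_strong_interval_tree",
    "crex_scenario",
    "crex_scenario_records",
    "tdrl_lower_bound",
    "reconstruct_ancestral",
    "group_identical",
]

#: default mitochondrial gene alphabet: 14 OXPHOS proteins, rps3, both rRNAs
GENE_ALPHABET: tuple[str, ...] = (
    "atp6", "atp8", "atp9", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "rps3", "rnl", "rns",
)

SignedPerm = tuple[int, ...]


# ---------------------------------------------------------------------------
# Encoding between gene space and signed-integer space

def _split_sign(gene: str) -> tuple[int, str]:
    return (-1, gene[1:]) if gene.startswith("-") else (1, gene)


def canonicalize(record: GeneOrderRecord, anchor: str = "rns") -> GeneOrderRecord:
    """Linearize a circular gene order: rotate so ``anchor`` comes first; if
    the anchor is on the reverse strand, reflect the whole order (reverse and
    flip every sign) so the result starts with ``+anchor``.  Idempotent."""
    genes = list(record.genes)
    idx = sign = None
    for i, g in enumerate(genes):
        s, mag = _split_sign(g)
        if mag == anchor:
            idx, sign = i, s
            break
    if idx is None:
        raise ValueError(f"anchor {anchor!r} absent from taxon {record.taxon!r}")
    if sign < 0:
        genes = [("-" + g if not g.startswith("-") else g[1:])
                 for g in reversed(genes)]
        idx = len(genes) - 1 - idx
    rotated = tuple(genes[idx:] + genes[:idx])
    return GeneOrderRecord(taxon=record.taxon, genes=rotated,
                           alphabet=record.alphabet)


def encode(record: GeneOrderRecord, alphabet: Sequence[str]) -> SignedPerm:
    """Map a gene order onto signed integers via the alphabet (1-based)."""
    index = {g: i + 1 for i, g in enumerate(alphabet)}
    out = []
    for g in record.genes:
        s, mag = _split_sign(g)
        if mag not in index:
            raise ValueError(f"gene {mag!r} not in alphabet")
        out.append(s * index[mag])
    if len(out) != len(alphabet):
        raise ValueError(
            f"taxon {record.taxon!r}: unequal gene content "
            f"({len(out)} genes vs alphabet of {len(alphabet)})")
    return tuple(out)


def decode(perm: SignedPerm, alphabet: Sequence[str], taxon: str = ""
           ) -> GeneOrderRecord:
    genes = tuple(
        (alphabet[abs(v) - 1] if v > 0 else "-" + alphabet[abs(v) - 1])
        for v in perm
    )
    return GeneOrderRecord(taxon=taxon, genes=genes, alphabet=tuple(alphabet))


# ---------------------------------------------------------------------------
# Rearrangement operations

def invert_segment(seg: Sequence[int]) -> tuple[int, ...]:
    return tuple(-x for x in reversed(seg))


@dataclass(frozen=True)
class RearrangementOp:
    """One rearrangement, positionally addressed (0-based, half-open).

    * inversion: reverse ``[start, end)`` flipping signs.
    * transposition: exchange adjacent blocks ``[start, mid)`` / ``[mid, end)``.
    * inverse_transposition: same exchange, but the block named by
      ``invert_first`` is additionally inverted.
    * tdrl: duplicate ``[start, end)`` in tandem; first copy keeps elements
      with magnitude in ``keep_first`` (original order), second copy keeps
      ``keep_second``; the keep-sets partition the region.
    """

    kind: str
    start: int
    end: int
    mid: int | None = None
    invert_first: bool = True
    keep_first: frozenset[int] = frozenset()
    keep_second: frozenset[int] = frozenset()

    def to_dict(self, alphabet: Sequence[str] | None = None) -> dict:
        d: dict = {"kind": self.kind, "start": self.start, "end": self.end}
        if self.kind in ("transposition", "inverse_transposition"):
            d["mid"] = self.mid
        if self.kind == "inverse_transposition":
            d["invert_first"] = self.invert_first
        if self.kind == "tdrl":
            def names(s: frozenset[int]) -> list:
                if alphabet is None:
                    return sorted(s)
                return sorted(alphabet[m - 1] for m in s)
            d["keep_first"] = names(self.keep_first)
            d["keep_second"] = names(self.keep_second)
        return d


OP_KINDS = ("inversion", "transposition", "inverse_transposition", "tdrl")


def apply_operation(p: Sequence[int], op: RearrangementOp) -> SignedPerm:
    """Apply one operation to a signed permutation."""
    p = tuple(p)
    s, e = op.start, op.end
    if not (0 <= s < e <= len(p)):
        raise ValueError(f"operation span [{s},{e}) invalid for n={len(p)}")
    seg = p[s:e]
    if op.kind == "inversion":
        new = invert_segment(seg)
    elif op.kind == "transposition":
        m = op.mid
        if m is None or not (s < m < e):
            raise ValueError("transposition needs interior split point")
        new = seg[m - s:] + seg[:m - s]
    elif op.kind == "inverse_transposition":
        m = op.mid
        if m is None or not (s < m < e):
            raise ValueError("inverse transposition needs interior split point")
        a, b = seg[:m - s], seg[m - s:]
        new = (b + invert_segment(a)) if op.invert_first else (invert_segment(b) + a)
    elif op.kind == "tdrl":
        mags = {abs(x) for x in seg}
        if (op.keep_first | op.keep_second) != mags or (op.keep_first & op.keep_second):
            raise ValueError("tdrl keep-sets must partition the region")
        first = tuple(x for x in seg if abs(x) in op.keep_first)
        second = tuple(x for x in seg if abs(x) in op.keep_second)
        new = first + second
    else:
        raise ValueError(f"unknown operation kind {op.kind!r}")
    return p[:s] + new + p[e:]


def apply_scenario(p: Sequence[int], ops: Iterable[RearrangementOp]) -> SignedPerm:
    cur = tuple(p)
    for op in ops:
        cur = apply_operation(cur, op)
    return cur


# ---------------------------------------------------------------------------
# Common intervals and strong interval trees

def _check_same_content(p: SignedPerm, q: SignedPerm) -> None:
    if {abs(x) for x in p} != {abs(x) for x in q} or len(p) != len(q):
        raise ValueError("unequal gene content")
    if len({abs(x) for x in p}) != len(p):
        raise ValueError("duplicated gene in permutation")


def common_intervals(p: SignedPerm, q: SignedPerm) -> set[frozenset[int]]:
    """All gene sets contiguous in both orders (signs ignored).

    Exhaustive enumeration over the O(n^2) intervals of ``p``; includes all
    singletons and the full set.
    """
    p, q = tuple(p), tuple(q)
    _check_same_content(p, q)
    pos_q = {abs(x): i for i, x in enumerate(q)}
    n = len(p)
    out: set[frozenset[int]] = set()
    for i in range(n):
        lo = hi = pos_q[abs(p[i])]
        for j in range(i, n):
            pj = pos_q[abs(p[j])]
            lo, hi = min(lo, pj), max(hi, pj)
            if hi - lo == j - i:  # contiguous in q as well
                out.add(frozenset(abs(x) for x in p[i:j + 1]))
    return out


def strong_intervals(p: SignedPerm, q: SignedPerm) -> list[frozenset[int]]:
    """Common intervals overlapping no other common interval."""
    cis = sorted(common_intervals(p, q), key=len)
    strong = []
    for a in cis:
        ok = True
        for b in cis:
            if a is b:
                continue
            inter = a & b
            if inter and not (a <= b or b <= a):
                ok = False
                break
        if ok:
            strong.append(a)
    return strong


@dataclass
class SITNode:
    genes: frozenset[int]
    children: list["SITNode"] = field(default_factory=list)
    node_class: str = "linear_increasing"

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self) -> Iterable["SITNode"]:
        yield self
        for c in self.children:
            yield from c.iter_nodes()


def build_strong_interval_tree(p: SignedPerm, q: SignedPerm) -> SITNode:
    """Laminar containment tree of the strong intervals of (p, q).

    Children are ordered by position in ``p``; inner nodes are classified by
    the quotient (children's order in ``q``): identity -> linear_increasing,
    reversal -> linear_decreasing, else prime.  A singleton leaf is classified
    by whether its sign agrees between the two orders.
    """
    p, q = tuple(p), tuple(q)
    strong = sorted(strong_intervals(p, q), key=len, reverse=True)
    pos_p = {abs(x): i for i, x in enumerate(p)}
    pos_q = {abs(x): i for i, x in enumerate(q)}
    sign_p = {abs(x): (1 if x > 0 else -1) for x in p}
    sign_q = {abs(x): (1 if x > 0 else -1) for x in q}

    nodes = [SITNode(genes=s) for s in strong]
    roots: list[SITNode] = []
    # strong intervals sorted by decreasing size nest greedily
    for i, node in enumerate(nodes):
        parent = None
        for j in range(i - 1, -1, -1):
            if node.genes <= nodes[j].genes:
                parent = nodes[j]
                break
        if parent is None:
            roots.append(node)
        else:
            parent.children.append(node)
    (root,) = roots

    for node in root.iter_nodes():
        if node.is_leaf:
            (g,) = node.genes
            node.node_class = ("linear_increasing"
                               if sign_p[g] == sign_q[g] else "linear_decreasing")
            continue
        node.children.sort(key=lambda c: min(pos_p[g] for g in c.genes))
        order_q = sorted(range(len(node.children)),
                         key=lambda k: min(pos_q[g] for g in node.children[k].genes))
        ranks = [0] * len(order_q)
        for rank, k in enumerate(order_q):
            ranks[k] = rank
        if ranks == sorted(ranks):
            node.node_class = "linear_increasing"
        elif ranks == sorted(ranks, reverse=True):
            node.node_class = "linear_decreasing"
        else:
            node.node_class = "prime"
    return root


# ---------------------------------------------------------------------------
# TDRL machinery

def _run_labels(perm: Sequence[int]) -> dict[int, int]:
    """Greedy labels over values 1..k: label increases each time value v+1
    sits left of value v.  Stable LSD radix by these labels sorts the
    permutation; the label count is the minimal number of whole-region TDRLs
    rounded through ceil(log2)."""
    pos = {v: i for i, v in enumerate(perm)}
    values = sorted(pos)
    labels = {values[0]: 0}
    for a, b in zip(values, values[1:]):
        labels[b] = labels[a] + (1 if pos[b] < pos[a] else 0)
    return labels


def tdrl_lower_bound(quotient: Sequence[int]) -> int:
    """Minimum number of whole-region TDRLs sorting an unsigned permutation.

    Equals ceil(log2 r) with r the number of maximal ascending runs of the
    position sequence read in value order (r = 1 + the count of values whose
    successor lies to their left); 0 for the identity.
    """
    quotient = tuple(quotient)
    if any(v < 0 for v in quotient):
        raise ValueError("tdrl bound is defined on unsigned permutations")
    if not quotient:
        return 0
    r = max(_run_labels(quotient).values()) + 1
    return math.ceil(math.log2(r)) if r > 1 else 0


# ---------------------------------------------------------------------------
# CREx-style scenario construction (sort-space: target renamed to identity)

@dataclass
class _SNode:
    lo: int            # value range [lo, hi] (1-based, inclusive)
    hi: int
    start: int         # positional span [start, end) in the source
    end: int
    children: list["_SNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


def _iter_snodes(node: _SNode) -> Iterable[_SNode]:
    yield node
    for c in node.children:
        yield from _iter_snodes(c)


def _build_sort_tree(sp: SignedPerm) -> _SNode:
    ident = tuple(range(1, len(sp) + 1))
    strong = sorted(strong_intervals(sp, ident), key=len, reverse=True)
    pos = {abs(x): i for i, x in enumerate(sp)}
    nodes = []
    for s in strong:
        vals = sorted(s)
        ps = [pos[v] for v in vals]
        nodes.append(_SNode(lo=vals[0], hi=vals[-1],
                            start=min(ps), end=max(ps) + 1))
    roots: list[_SNode] = []
    for i, node in enumerate(nodes):
        parent = None
        for j in range(i - 1, -1, -1):
            if nodes[j].lo <= node.lo and node.hi <= nodes[j].hi \
                    and (nodes[j].hi - nodes[j].lo) > (node.hi - node.lo):
                parent = nodes[j]
                break
        if parent is None:
            roots.append(node)
        else:
            parent.children.append(node)
    (root,) = roots
    for n in _iter_snodes(root):
        n.children.sort(key=lambda c: c.start)
    return root


# routes, in the fixed precedence order used for cost ties
_TRP, _INV, _ITRP_A, _ITRP_B, _TDRL = range(5)


class _Sorter:
    """Transforms a signed permutation into the identity, recording ops.

    Orientation ``+1`` sorts a node's segment ascending/positive, ``-1``
    descending/negative (the form an enclosing inversion will flip).  Costs
    are memoized first; emission then replays the optimal plan.  Ties between
    equal-cost routes follow the precedence transposition > inversion >
    inverse transposition > TDRL, mirroring the transposition-dominated
    regime reported for fungal mitogenomes.
    """

    def __init__(self, sp: SignedPerm):
        self.sp = tuple(sp)
        self.sign = {abs(x): (1 if x > 0 else -1) for x in sp}
        self.root = _build_sort_tree(self.sp)
        self._cost: dict[tuple[int, int, int], int] = {}

    # ---- costs -----------------------------------------------------------
    def cost(self, node: _SNode, o: int) -> int:
        key = (node.lo, node.hi, o)
        if key in self._cost:
            return self._cost[key]
        if node.is_leaf:
            c = 0 if self.sign[node.lo] == o else 1
        else:
            c = min(r[0] for r in self._routes(node, o))
        self._cost[key] = c
        return c

    def _value_order(self, node: _SNode) -> list[_SNode]:
        return sorted(node.children, key=lambda c: c.lo)

    def _routes(self, node: _SNode, o: int) -> list[tuple[int, int]]:
        """(cost, route) candidates for an inner node, cheapest plan wins,
        ties resolved by the route precedence order."""
        kids = node.children
        val = self._value_order(node)
        desired = val if o == 1 else list(reversed(val))
        if kids == desired:
            return [(sum(self.cost(c, o) for c in kids), -1)]
        routes: list[tuple[int, int]] = []
        if kids == list(reversed(desired)):
            if len(kids) == 2:
                c1, c2 = kids
                routes = [
                    (self.cost(c1, o) + self.cost(c2, o) + 1, _TRP),
                    (self.cost(c1, -o) + self.cost(c2, -o) + 1, _INV),
                    (self.cost(c1, -o) + self.cost(c2, o) + 1, _ITRP_A),
                    (self.cost(c1, o) + self.cost(c2, -o) + 1, _ITRP_B),
                ]
            else:
                routes = [(sum(self.cost(c, -o) for c in kids) + 1, _INV)]
                if o == 1:
                    n_tdrl = tdrl_lower_bound(self._quotient(node))
                    routes.append(
                        (sum(self.cost(c, 1) for c in kids) + n_tdrl, _TDRL))
        else:  # prime
            base = sum(self.cost(c, 1) for c in kids) \
                + max(1, tdrl_lower_bound(self._quotient(node)))
            routes = [(base + (0 if o == 1 else 1), _TDRL)]
        routes.sort(key=lambda r: (r[0], r[1]))
        return routes

    def _quotient(self, node: _SNode) -> tuple[int, ...]:
        val = self._value_order(node)
        rank = {id(c): i + 1 for i, c in enumerate(val)}
        return tuple(rank[id(c)] for c in node.children)

    # ---- emission --------------------------------------------------------
    def run(self) -> list[RearrangementOp]:
        ops: list[RearrangementOp] = []
        self._emit(self.root, 1, ops)
        return ops

    def _emit(self, node: _SNode, o: int, ops: list[RearrangementOp]) -> None:
        if node.is_leaf:
            if self.sign[node.lo] != o:
                ops.append(RearrangementOp("inversion", node.start, node.end))
            return
        kids = node.children
        val = self._value_order(node)
        desired = val if o == 1 else list(reversed(val))
        if kids == desired:
            for c in kids:
                self._emit(c, o, ops)
            return
        route = min(self._routes(node, o), key=lambda r: (r[0], r[1]))[1]
        if kids == list(reversed(desired)):
            if len(kids) == 2:
                c1, c2 = kids
                s, m, e = c1.start, c2.start, c2.end
                if route == _TRP:
                    self._emit(c1, o, ops)
                    self._emit(c2, o, ops)
                    ops.append(RearrangementOp("transposition", s, e, mid=m))
                elif route == _INV:
                    self._emit(c1, -o, ops)
                    self._emit(c2, -o, ops)
                    ops.append(RearrangementOp("inversion", s, e))
                elif route == _ITRP_A:
                    self._emit(c1, -o, ops)
                    self._emit(c2, o, ops)
                    ops.append(RearrangementOp("inverse_transposition", s, e,
                                               mid=m, invert_first=True))
                else:
                    self._emit(c1, o, ops)
                    self._emit(c2, -o, ops)
                    ops.append(RearrangementOp("inverse_transposition", s, e,
                                               mid=m, invert_first=False))
            elif route == _INV:
                for c in kids:
                    self._emit(c, -o, ops)
                ops.append(RearrangementOp("inversion", node.start, node.end))
            else:
                for c in kids:
                    self._emit(c, 1, ops)
                self._emit_tdrls(node, ops)
            return
        # prime
        for c in kids:
            self._emit(c, 1, ops)
        self._emit_tdrls(node, ops)
        if o == -1:
            ops.append(RearrangementOp("inversion", node.start, node.end))

    def _emit_tdrls(self, node: _SNode, ops: list[RearrangementOp]) -> None:
        """Realize the node's quotient by stable radix passes over the run
        labels; each pass is one whole-region TDRL."""
        quotient = self._quotient(node)
        labels = _run_labels(quotient)
        n_bits = max(1, math.ceil(math.log2(max(labels.values()) + 1)))
        block_mags = [frozenset(range(c.lo, c.hi + 1)) for c in node.children]
        for bit in range(n_bits):
            keep1: set[int] = set()
            keep2: set[int] = set()
            for rank, mags in zip(quotient, block_mags):
                if (labels[rank] >> bit) & 1:
                    keep2 |= mags
                else:
                    keep1 |= mags
            ops.append(RearrangementOp("tdrl", node.start, node.end,
                                       keep_first=frozenset(keep1),
                                       keep_second=frozenset(keep2)))


# ---------------------------------------------------------------------------
# Scenario API

@dataclass
class Scenario:
    source: SignedPerm
    target: SignedPerm
    ops: list[RearrangementOp]

    def __len__(self) -> int:
        return len(self.ops)

    def replay(self) -> SignedPerm:
        return apply_scenario(self.source, self.ops)

    @property
    def op_kinds(self) -> list[str]:
        return [op.kind for op in self.ops]

    def op_tally(self) -> Counter:
        return Counter(self.op_kinds)

    def intermediates(self) -> list[SignedPerm]:
        """Source, every prefix image, target (inclusive both ends)."""
        out = [self.source]
        cur = self.source
        for op in self.ops:
            cur = apply_operation(cur, op)
            out.append(cur)
        return out

    def to_dict(self, alphabet: Sequence[str] | None = None) -> dict:
        return {
            "n_ops": len(self.ops),
            "ops": [op.to_dict(alphabet) for op in self.ops],
        }


def crex_scenario(p: Sequence[int], q: Sequence[int]) -> Scenario:
    """Derive a replay-valid rearrangement scenario transforming ``p`` to ``q``.

    The target is renamed to the identity, the strong interval tree of the
    renamed source is walked, and operations are read off node by node (see
    module docstring).  Deterministic given its inputs.
    """
    p, q = tuple(p), tuple(q)
    _check_same_content(p, q)
    if p == q:
        return Scenario(source=p, target=q, ops=[])
    # rename: value of element x = its (1-based) position in q, sign adjusted
    pos_q = {abs(x): i + 1 for i, x in enumerate(q)}
    sign_q = {abs(x): (1 if x > 0 else -1) for x in q}
    sp = tuple((1 if x > 0 else -1) * sign_q[abs(x)] * pos_q[abs(x)] for x in p)
    sorter = _Sorter(sp)
    sort_ops = sorter.run()
    assert apply_scenario(sp, sort_ops) == tuple(range(1, len(p) + 1))
    # translate tdrl keep-sets back to gene magnitudes; positions carry over
    back = {i + 1: abs(x) for i, x in enumerate(q)}
    ops = []
    for op in sort_ops:
        if op.kind == "tdrl":
            op = RearrangementOp(
                "tdrl", op.start, op.end,
                keep_first=frozenset(back[v] for v in op.keep_first),
                keep_second=frozenset(back[v] for v in op.keep_second))
        ops.append(op)
    scn = Scenario(source=p, target=q, ops=ops)
    if scn.replay() != q:  # defensive: THE defining contract
        raise AssertionError("scenario failed replay validation")
    return scn


def crex_scenario_records(a: GeneOrderRecord, b: GeneOrderRecord,
                          alphabet: Sequence[str] = GENE_ALPHABET,
                          anchor: str = "rns") -> Scenario:
    """Scenario between two (circular) gene-order records, after anchoring
    both at ``+anchor``."""
    pa = encode(canonicalize(a, anchor), alphabet)
    pb = encode(canonicalize(b, anchor), alphabet)
    return crex_scenario(pa, pb)


# ---------------------------------------------------------------------------
# Ancestral reconstruction

@dataclass
class AncestralAssignment:
    tree: dendropy.Tree
    node_orders: dict[str, SignedPerm]
    edge_scenarios: dict[tuple[str, str], Scenario]
    reliability: dict[str, str]          # node label -> consistent | fallback

    def op_tally(self) -> Counter:
        tally: Counter = Counter()
        for scn in self.edge_scenarios.values():
            tally.update(scn.op_kinds)
        return tally


def _node_label(node: dendropy.Node, counter: list[int]) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    counter[0] += 1
    node.label = f"N{counter[0]}"
    return node.label


def _subtree_representative(node: dendropy.Node,
                            leaf_orders: Mapping[str, SignedPerm]) -> SignedPerm:
    """Most frequent leaf order below ``node`` (ties: first encountered)."""
    orders = [leaf_orders[lf.taxon.label] for lf in node.leaf_iter()]
    counts = Counter(orders)
    best = max(counts.values())
    for o in orders:
        if counts[o] == best:
            return o
    raise AssertionError


def _candidate_orders(neighbors: Sequence[SignedPerm]) -> list[SignedPerm]:
    """Neighbor orders plus every intermediate along the pairwise scenarios
    (both directions), deduplicated, in deterministic order."""
    candidates: list[SignedPerm] = []
    for o in neighbors:
        if o not in candidates:
            candidates.append(o)
    for a in neighbors:
        for b in neighbors:
            if a == b:
                continue
            for mid in crex_scenario(a, b).intermediates():
                if mid not in candidates:
                    candidates.append(mid)
    return candidates


def reconstruct_ancestral(tree: dendropy.Tree,
                          leaf_orders: Mapping[str, Sequence[int]],
                          max_sweeps: int = 10,
                          ) -> AncestralAssignment:
    """Assign a gene order to every internal node of a rooted tree.

    Two phases.  Bottom-up: a node whose children agree inherits their
    shared order; otherwise candidates are the children's orders plus every
    intermediate order along the inter-child scenarios (both directions),
    scored by total scenario length to the children and to the
    sibling-subtree context.  Refinement: sweeps re-optimize each internal
    node against its assigned neighbors (children and parent), accepting
    strict improvements of the summed edge-scenario length, until a sweep
    changes nothing.  A node is flagged ``consistent`` when its final
    minimizer is unique.
    """
    leaf_orders = {k: tuple(v) for k, v in leaf_orders.items()}
    contents = {frozenset(abs(x) for x in o) for o in leaf_orders.values()}
    if len(contents) != 1:
        raise ValueError("unequal gene content among leaf orders")
    counter = [0]
    node_orders: dict[str, SignedPerm] = {}
    reliability: dict[str, str] = {}
    dist_cache: dict[tuple[SignedPerm, SignedPerm], int] = {}

    def dist(a: SignedPerm, b: SignedPerm) -> int:
        key = (a, b)
        if key not in dist_cache:
            dist_cache[key] = len(crex_scenario(a, b))
        return dist_cache[key]

    for node in tree.postorder_node_iter():
        label = _node_label(node, counter)
        if node.is_leaf():
            if label not in leaf_orders:
                raise ValueError(f"no gene order for leaf {label!r}")
            node_orders[label] = leaf_orders[label]
            continue
        child_orders = [node_orders[_node_label(c, counter)]
                        for c in node.child_nodes()]
        if len(set(child_orders)) == 1:
            node_orders[label] = child_orders[0]
            reliability[label] = "consistent"
            continue
        context: SignedPerm | None = None
        parent = node.parent_node
        if parent is not None:
            sibs = [c for c in parent.child_nodes() if c is not node]
            if sibs:
                context = _subtree_representative(sibs[0], leaf_orders)
        candidates = _candidate_orders(child_orders)

        def score(cand: SignedPerm) -> int:
            total = sum(dist(cand, o) for o in child_orders)
            if context is not None:
                total += dist(cand, context)
            return total

        scores = [score(c) for c in candidates]
        best = min(scores)
        winners = [c for c, s in zip(candidates, scores) if s == best]
        if len(winners) > 1:
            # tie-break toward the majority order among the subtree's leaves
            below = Counter(leaf_orders[lf.taxon.label]
                            for lf in node.leaf_iter())
            winners.sort(key=lambda c: -below.get(c, 0))
        node_orders[label] = winners[0]
        reliability[label] = "consistent" if len(winners) == 1 else "fallback"

    # refinement sweeps against assigned neighbors
    internal = [n for n in tree.postorder_internal_node_iter()]
    for _ in range(max_sweeps):
        changed = False
        for node in internal:
            label = node.label
            neighbor_labels = [_node_label(c, counter)
                               for c in node.child_nodes()]
            if node.parent_node is not None:
                neighbor_labels.append(_node_label(node.parent_node, counter))
            neighbors = [node_orders[l] for l in neighbor_labels]
            candidates = _candidate_orders(neighbors)
            cur_order = node_orders[label]
            if cur_order not in candidates:
                candidates.append(cur_order)

            def local(cand: SignedPerm) -> int:
                return sum(dist(cand, o) for o in neighbors)

            scores = [local(c) for c in candidates]
            best = min(scores)
            if best < local(cur_order):
                winners = [c for c, s in zip(candidates, scores) if s == best]
                node_orders[label] = winners[0]
                reliability[label] = ("consistent" if len(winners) == 1
                                      else "fallback")
                changed = True
        if not changed:
            break

    edge_scenarios: dict[tuple[str, str], Scenario] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            key = (node.label if not node.is_leaf() else node.taxon.label,
                   child.label if not child.is_leaf() else child.taxon.label)
            edge_scenarios[key] = crex_scenario(
                node_orders[key[0]], node_orders[key[1]])
    return AncestralAssignment(tree=tree, node_orders=node_orders,
                               edge_scenarios=edge_scenarios,
                               reliability=reliability)


# ---------------------------------------------------------------------------
# Identity grouping

def group_identical(orders: Sequence[GeneOrderRecord],
                    anchor: str = "rns") -> list[list[str]]:
    """Partition taxa into classes of exactly identical (canonicalized,
    signed) gene orders; groups numbered by first appearance."""
    groups: dict[tuple[str, ...], list[str]] = {}
    order_keys: list[tuple[str, ...]] = []
    for rec in orders:
        key = canonicalize(rec, anchor).genes
        if key not in groups:
            groups[key] = []
            order_keys.append(key)
        groups[key].append(rec.taxon)
    return [groups[k] for k in order_keys]
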