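"""Seeded generators for every input shape the pipeline consumes.

Each generator is a pure function of (parameters, seed) and returns, beside
the dataset itself, a machine-readable truth log so recovery tests can
compare inferred structure against what was planted.  Defaults emulate the
study system: a ~44 kb AT-rich (72%) circular fungal mitochondrial genome, a
17-gene mitochondrial gene order evolving mostly by transpositions, and
multi-locus panels of eight closely related species with within-species
polymorphism on top of fixed between-species differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .annotation import TT4_STOPS
from .gene_order import (
    GENE_ALPHABET, RearrangementOp, SignedPerm, apply_operation, decode,
)
from .io_formats import Feature, GeneOrderRecord, GenomeRecord

__all__ = [
    "SimTruth",
    "simulate_gene_order_evolution",
    "simulate_species_loci",
    "synthesize_genome",
    "random_signed_permutation",
    "random_operation",
    "random_tree",
]

DEFAULT_REARRANGEMENT_RATES: dict[str, float] = {
    # sparse, transposition-dominated regime as observed in Pezizomycotina
    # mitogenomes (roughly a dozen events across a 22-taxon tree): ~0.25
    # expected events per edge, mostly transpositions, occasional TDRL,
    # inversions/inverse transpositions rare
    "transposition": 0.2,
    "inversion": 0.01,
    "inverse_transposition": 0.01,
    "tdrl": 0.03,
}


@dataclass
class SimTruth:
    seed: int
    data: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"seed": self.seed, **self.data}


# ---------------------------------------------------------------------------
# Random rearrangement primitives

def random_signed_permutation(rng: np.random.Generator, n: int) -> SignedPerm:
    vals = rng.permutation(n) + 1
    signs = rng.choice((-1, 1), size=n)
    return tuple(int(s * v) for s, v in zip(signs, vals))


def random_operation(rng: np.random.Generator, n: int, kind: str,
                     forbidden: Sequence[tuple[int, int]] = (),
                     max_tries: int = 200) -> RearrangementOp:
    """Draw an operation uniformly over valid operands; optionally resample
    until its span is disjoint from ``forbidden`` spans (well-separated
    events)."""
    for _ in range(max_tries):
        if kind == "inversion":
            s = int(rng.integers(0, n))
            e = int(rng.integers(s + 1, n + 1))
            op = RearrangementOp("inversion", s, e)
        elif kind in ("transposition", "inverse_transposition"):
            s = int(rng.integers(0, n - 1))
            e = int(rng.integers(s + 2, n + 1))
            m = int(rng.integers(s + 1, e))
            if kind == "transposition":
                op = RearrangementOp("transposition", s, e, mid=m)
            else:
                op = RearrangementOp("inverse_transposition", s, e, mid=m,
                                     invert_first=bool(rng.integers(0, 2)))
        elif kind == "tdrl":
            s = int(rng.integers(0, n - 1))
            e = int(rng.integers(s + 2, n + 1))
            op = None  # keep-sets drawn against the current permutation later
            return _random_tdrl(rng, s, e, forbidden)
        else:
            raise ValueError(f"unknown op kind {kind!r}")
        if all(e <= fs or s >= fe for fs, fe in forbidden):
            return op
    return op  # give up on separation, keep validity


def _random_tdrl(rng: np.random.Generator, s: int, e: int,
                 forbidden: Sequence[tuple[int, int]]) -> RearrangementOp:
    # placeholder marker op: keep-sets are bound to the permutation at
    # application time by bind_tdrl
    return RearrangementOp("tdrl", s, e)


def bind_tdrl(rng: np.random.Generator, p: SignedPerm,
              op: RearrangementOp) -> RearrangementOp:
    """Fill a TDRL's keep-sets with a uniform non-trivial bipartition of the
    region's gene content as it stands in ``p``."""
    mags = [abs(x) for x in p[op.start:op.end]]
    while True:
        mask = rng.integers(0, 2, size=len(mags))
        if 0 < mask.sum() < len(mags):
            break
    keep1 = frozenset(m for m, b in zip(mags, mask) if b == 0)
    keep2 = frozenset(m for m, b in zip(mags, mask) if b == 1)
    return RearrangementOp("tdrl", op.start, op.end,
                           keep_first=keep1, keep_second=keep2)


def random_tree(rng: np.random.Generator, n_leaves: int) -> dendropy.Tree:
    """Random binary rooted tree with leaves t1..tn (uniform join order)."""
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_leaves):
        taxon = taxa.new_taxon(f"t{i + 1}")
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    return tree


# ---------------------------------------------------------------------------
# Gene-order evolution along a tree

def simulate_gene_order_evolution(
        tree: dendropy.Tree,
        root_order: Sequence[int],
        rates: Mapping[str, float] | None = None,
        seed: int = 0,
        max_events_per_edge: int | None = None,
        well_separated: bool = False,
        alphabet: Sequence[str] = GENE_ALPHABET,
) -> tuple[list[GeneOrderRecord], dict[str, SignedPerm], SimTruth]:
    """Evolve a signed gene order along a rooted tree.

    Event counts per edge and kind are Poisson at the given per-edge rates
    (defaults: the transposition-dominated regime); operands are drawn
    uniformly over valid blocks, TDRL keep-sets uniformly over non-trivial
    bipartitions.  With ``well_separated`` the operand spans on one edge are
    kept disjoint.  Returns leaf records, the true order of every node
    (internal nodes labelled N1..), and the per-edge event log.
    """
    rates = dict(DEFAULT_REARRANGEMENT_RATES if rates is None else rates)
    rng = np.random.default_rng(seed)
    n = len(root_order)
    counter = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            counter += 1
            node.label = f"N{counter}"

    node_orders: dict[str, SignedPerm] = {}
    events: dict[str, list[dict]] = {}
    root_label = tree.seed_node.label or "N1"
    node_orders[root_label] = tuple(int(x) for x in root_order)
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.is_leaf() else node.label
        if node.parent_node is None:
            node_orders[label] = tuple(int(x) for x in root_order)
            continue
        parent_label = (node.parent_node.taxon.label
                        if node.parent_node.is_leaf()
                        else node.parent_node.label)
        cur = node_orders[parent_label]
        kinds: list[str] = []
        for kind, rate in rates.items():
            kinds.extend([kind] * int(rng.poisson(rate)))
        if kinds:
            kinds = [str(k) for k in rng.permutation(kinds)]
        if max_events_per_edge is not None:
            kinds = kinds[:max_events_per_edge]
        used_spans: list[tuple[int, int]] = []
        log: list[dict] = []
        for kind in kinds:
            op = random_operation(rng, n, kind,
                                  forbidden=used_spans if well_separated else ())
            if kind == "tdrl":
                op = bind_tdrl(rng, cur, op)
            used_spans.append((op.start, op.end))
            cur = apply_operation(cur, op)
            log.append(op.to_dict(alphabet if len(alphabet) == n else None))
        node_orders[label] = cur
        events[f"{parent_label}->{label}"] = log

    leaf_records = []
    for lf in tree.leaf_node_iter():
        perm = node_orders[lf.taxon.label]
        if len(alphabet) == n:
            leaf_records.append(decode(perm, alphabet, taxon=lf.taxon.label))
        else:
            leaf_records.append(GeneOrderRecord(
                taxon=lf.taxon.label,
                genes=tuple(str(v) if v > 0 else f"-{-v}" for v in perm)))
    truth = SimTruth(seed=seed, data={"events": events,
                                      "node_orders": {k: list(v) for k, v
                                                      in node_orders.items()}})
    return leaf_records, node_orders, truth


# ---------------------------------------------------------------------------
# Multi-species locus panels

def _random_seq(rng: np.random.Generator, length: int,
                at_content: float) -> np.ndarray:
    p = np.array([at_content / 2, (1 - at_content) / 2,
                  (1 - at_content) / 2, at_content / 2])
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _mutate(rng: np.random.Generator, base: str) -> str:
    return str(rng.choice([b for b in "ACGT" if b != base]))


def simulate_species_loci(
        n_species: int = 8,
        strains_per_species: int = 4,
        locus_lengths: Sequence[int] = (730, 850, 1650),
        theta_within: float = 0.002,
        fixed_diffs_per_pair: int = 3,
        indel_rate: float = 0.3,
        crossovers: int = 0,
        at_content: float = 0.72,
        seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], SimTruth]:
    """Aligned multi-locus panel with planted population structure.

    Species backbones descend from one ancestral sequence; each species gets
    ``fixed_diffs_per_pair`` private diagnostic substitutions per locus-set
    (so every species pair is separated by at least that many fixed
    differences).  Strains add within-species polymorphism (per-site
    probability ``theta_within``) and Poisson(``indel_rate``) short deletions
    per locus.  ``crossovers`` > 0 appends a reciprocal pair of recombinant
    strains between the first two species per crossover, creating a
    four-gamete signal across the breakpoint.  Defaults mirror an
    eight-species, three-locus barcoding panel.
    """
    rng = np.random.default_rng(seed)
    total_len = int(sum(locus_lengths))
    ancestral = _random_seq(rng, total_len, at_content)
    locus_bounds = []
    off = 0
    for L in locus_lengths:
        locus_bounds.append((off, off + int(L)))
        off += int(L)

    n_fixed_sites = n_species * fixed_diffs_per_pair
    if n_fixed_sites > total_len:
        raise ValueError("loci too short for the requested fixed differences")
    sites = rng.choice(total_len, size=n_fixed_sites, replace=False)
    species_names = [f"sp{i + 1}" for i in range(n_species)]
    backbones: dict[str, np.ndarray] = {}
    planted_fixed: dict[str, list[int]] = {}
    for k, sp in enumerate(species_names):
        bb = ancestral.copy()
        own = sorted(int(s) for s in
                     sites[k * fixed_diffs_per_pair:(k + 1) * fixed_diffs_per_pair])
        for s in own:
            bb[s] = _mutate(rng, str(bb[s]))
        backbones[sp] = bb
        planted_fixed[sp] = own

    alignment: dict[str, str] = {}
    species_map: dict[str, str] = {}
    private_subs: dict[str, list[int]] = {}
    planted_indels: dict[str, list[tuple[int, int]]] = {}
    for sp in species_names:
        for j in range(strains_per_species):
            strain = f"{sp}_s{j + 1}"
            row = backbones[sp].copy()
            hits = np.nonzero(rng.random(total_len) < theta_within)[0]
            for s in hits:
                row[s] = _mutate(rng, str(row[s]))
            private_subs[strain] = [int(s) for s in hits]
            dels: list[tuple[int, int]] = []
            for lo, hi in locus_bounds:
                for _ in range(int(rng.poisson(indel_rate))):
                    length = int(rng.integers(1, 7))
                    start = int(rng.integers(lo, max(lo + 1, hi - length)))
                    row[start:start + length] = "-"
                    dels.append((start, length))
            planted_indels[strain] = dels
            alignment[strain] = "".join(row)
            species_map[strain] = sp

    breakpoints: list[int] = []
    if crossovers > 0:
        sp_a, sp_b = species_names[0], species_names[1]
        for c in range(crossovers):
            bp = int(rng.integers(total_len // 4, 3 * total_len // 4))
            breakpoints.append(bp)
            mosaic_ab = np.concatenate([backbones[sp_a][:bp],
                                        backbones[sp_b][bp:]])
            mosaic_ba = np.concatenate([backbones[sp_b][:bp],
                                        backbones[sp_a][bp:]])
            alignment[f"rec{c + 1}_ab"] = "".join(mosaic_ab)
            alignment[f"rec{c + 1}_ba"] = "".join(mosaic_ba)
            species_map[f"rec{c + 1}_ab"] = sp_a
            species_map[f"rec{c + 1}_ba"] = sp_b

    truth = SimTruth(seed=seed, data={
        "locus_bounds": locus_bounds,
        "fixed_sites": planted_fixed,
        "private_substitutions": private_subs,
        "indels": planted_indels,
        "crossover_breakpoints": breakpoints,
    })
    return alignment, species_map, truth


# ---------------------------------------------------------------------------
# Genome with planted ORFs and a duplication

_SENSE_REPLACEMENT = "TGG"  # never a stop under the mold mitochondrial code


def _plant_orf(rng: np.random.Generator, length_nt: int,
               start_codon: str = "ATG", stop_codon: str = "TAA",
               at_content: float = 0.72) -> str:
    """Stop-free coding sequence of ``length_nt`` (stop included): in-frame
    TAA/TAG in the body are scrubbed to sense codons (TGA is fine: it is
    tryptophan under translation table 4)."""
    if length_nt % 3 or length_nt < 6:
        raise ValueError("ORF length must be a multiple of 3, >= 6")
    body_codons = length_nt // 3 - 2
    codons = [start_codon]
    for _ in range(body_codons):
        codon = "".join(_random_seq(rng, 3, at_content))
        if codon in TT4_STOPS:
            codon = _SENSE_REPLACEMENT
        codons.append(codon)
    codons.append(stop_codon)
    return "".join(codons)


def synthesize_genome(
        length: int = 43742,
        at_content: float = 0.72,
        orf_plan: Sequence[dict] | None = None,
        feature_plan: Sequence[dict] | None = None,
        duplication_plan: dict | None = None,
        circular: bool = True,
        seed: int = 0,
        genome_id: str = "synthetic_mt",
) -> tuple[GenomeRecord, list[Feature], SimTruth]:
    """Background i.i.d. sequence at the requested AT content with planted
    ORFs, class-labelled features and, optionally, an interrupted duplication.

    ``orf_plan`` entries: ``{"start": pos(1-based), "length_nt": int,
    "start_codon": str, "name": str}`` — an in-frame TAA is written just
    upstream so the planted start is also the maximal start.
    ``feature_plan`` entries: ``{"type","start","end","strand","name"}``
    label regions without altering sequence.  ``duplication_plan``:
    ``{"unit_orf_length","up_flank","down_flank","copy_a_start",
    "copy_b_start","insert_len","insert_after","deletion_len",
    "deletion_at"}`` builds one duplication unit (flank + ORF + flank),
    writes copy A verbatim and copy B with the requested insertion and/or
    deletion.
    """
    rng = np.random.default_rng(seed)
    seq = _random_seq(rng, length, at_content)
    features: list[Feature] = []
    truth_data: dict = {"orfs": [], "duplication": None}

    def write(pos0: int, s: str) -> None:
        if pos0 < 0 or pos0 + len(s) > length:
            raise ValueError("planted element does not fit in the genome")
        seq[pos0:pos0 + len(s)] = list(s)

    for plan in orf_plan or ():
        start = int(plan["start"])
        length_nt = int(plan["length_nt"])
        orf = _plant_orf(rng, length_nt,
                         start_codon=plan.get("start_codon", "ATG"),
                         at_content=at_content)
        write(start - 1 - 3, "TAA")  # upstream in-frame stop caps maximality
        write(start - 1, orf)
        features.append(Feature(seq_id=genome_id, type="orf", start=start,
                                end=start + length_nt - 1, strand="+",
                                name=plan.get("name", f"orf_{start}")))
        truth_data["orfs"].append({"start": start, "length_nt": length_nt,
                                   "start_codon": plan.get("start_codon", "ATG"),
                                   "protein_length_aa": length_nt // 3 - 1})

    if duplication_plan:
        dp = dict(duplication_plan)
        up = int(dp.get("up_flank", 124))
        down = int(dp.get("down_flank", 37))
        orf_len = int(dp.get("unit_orf_length", 225))
        unit = ("".join(_random_seq(rng, up, at_content))
                + _plant_orf(rng, orf_len, at_content=at_content)
                + "".join(_random_seq(rng, down, at_content)))
        a0 = int(dp["copy_a_start"]) - 1
        b0 = int(dp["copy_b_start"]) - 1
        copy_b = unit
        ins_len = int(dp.get("insert_len", 0))
        ins_after = int(dp.get("insert_after", up + 14))
        if ins_len:
            insert = "".join(_random_seq(rng, ins_len, at_content))
            copy_b = copy_b[:ins_after] + insert + copy_b[ins_after:]
        del_len = int(dp.get("deletion_len", 0))
        del_at = int(dp.get("deletion_at", up))
        if del_len:
            copy_b = copy_b[:del_at] + copy_b[del_at + del_len:]
        write(a0, unit)
        write(b0, copy_b)
        features.append(Feature(seq_id=genome_id, type="orf",
                                start=a0 + up + 1, end=a0 + up + orf_len,
                                strand="+", name="atp9_copy_a"))
        truth_data["duplication"] = {
            "unit_length": len(unit),
            "copy_a": [a0 + 1, a0 + len(unit)],
            "copy_b": [b0 + 1, b0 + len(copy_b)],
            "insert_len": ins_len, "deletion_len": del_len,
        }

    for plan in feature_plan or ():
        features.append(Feature(seq_id=genome_id, type=plan["type"],
                                start=int(plan["start"]), end=int(plan["end"]),
                                strand=plan.get("strand", "+"),
                                name=plan.get("name", "")))

    genome = GenomeRecord(id=genome_id, sequence="".join(seq),
                          circular=circular)
    return genome, features, SimTruth(seed=seed, data=truth_data)
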