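"""Polymorphism, recombination-signal and species-diagnosability statistics.

Operates on aligned multi-strain sequence panels (rows of equal length over
``ACGT-`` plus ``N``).  Nucleotide diversity pi is the uncorrected average
pairwise per-site difference; segregating and parsimony-informative sites,
a four-gamete compatibility matrix over informative sites, a positional
clustering test for recombination blocks, per-strain outlier substitution
counts and fixed-difference species diagnosability complete the toolkit.

Gap handling is pairwise deletion by default (a column contributes to a pair
only when both sequences carry a nucleotide there), matching the convention
of counting substitutions "not considering indels"; complete deletion is
available as a switch.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DiversityResult",
    "CompatibilityMatrix",
    "RecombinationResult",
    "DiagnosabilityReport",
    "diversity_stats",
    "four_gamete_compatibility",
    "recombination_blocks",
    "focal_substitutions",
    "diagnosability",
]

NUCS = frozenset("ACGT")


def _as_matrix(alignment: Mapping[str, str]) -> tuple[list[str], list[str]]:
    ids = list(alignment)
    rows = [alignment[i].upper() for i in ids]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    return ids, rows


# ---------------------------------------------------------------------------
# Diversity

@dataclass
class DiversityResult:
    pi: float
    S: int
    n_informative: int
    L_effective: int
    windows: list[tuple[int, int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"pi": self.pi, "S": self.S,
                "n_informative": self.n_informative,
                "L_effective": self.L_effective,
                "windows": [list(w) for w in self.windows]}


def _pi_over_columns(rows: Sequence[str], cols: Sequence[int],
                     complete_deletion: bool) -> tuple[float, int]:
    """(pi, L_eff) over the given columns."""
    n = len(rows)
    if complete_deletion:
        cols = [c for c in cols if all(r[c] in NUCS for r in rows)]
    l_eff = 0
    for c in cols:
        states = [r[c] for r in rows if r[c] in NUCS]
        if len(states) >= 2:
            l_eff += 1
    if l_eff == 0:
        return 0.0, 0
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        ri, rj = rows[i], rows[j]
        total += sum(1 for c in cols
                     if ri[c] in NUCS and rj[c] in NUCS and ri[c] != rj[c])
    n_pairs = n * (n - 1) // 2
    return total / (n_pairs * l_eff), l_eff


def segregating_sites(rows: Sequence[str]) -> list[int]:
    out = []
    for c in range(len(rows[0])):
        states = {r[c] for r in rows} & NUCS
        if len(states) >= 2:
            out.append(c)
    return out


def informative_sites(rows: Sequence[str]) -> list[int]:
    """Parsimony-informative: >=2 nucleotide states each carried by >=2
    sequences."""
    out = []
    for c in range(len(rows[0])):
        counts: dict[str, int] = {}
        for r in rows:
            if r[c] in NUCS:
                counts[r[c]] = counts.get(r[c], 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            out.append(c)
    return out


def diversity_stats(alignment: Mapping[str, str], window: int = 100,
                    step: int = 25,
                    complete_deletion: bool = False) -> DiversityResult:
    """Nucleotide diversity, segregating-site counts and a sliding-window
    pi profile on alignment coordinates (1-based window bounds)."""
    _, rows = _as_matrix(alignment)
    if len(rows) < 2:
        raise ValueError("need at least two sequences")
    L = len(rows[0])
    all_cols = list(range(L))
    pi, l_eff = _pi_over_columns(rows, all_cols, complete_deletion)
    seg = segregating_sites(rows)
    info = informative_sites(rows)
    windows = []
    start = 0
    while start < L:
        cols = list(range(start, min(start + window, L)))
        wpi, _ = _pi_over_columns(rows, cols, complete_deletion)
        windows.append((start + 1, min(start + window, L), round(wpi, 6)))
        if start + window >= L:
            break
        start += step
    return DiversityResult(pi=pi, S=len(seg), n_informative=len(info),
                           L_effective=l_eff, windows=windows)


# ---------------------------------------------------------------------------
# Four-gamete compatibility

@dataclass
class CompatibilityMatrix:
    positions: list[int]          # 0-based alignment columns
    compatible: np.ndarray        # boolean, symmetric, diagonal True

    @property
    def incompatible_pairs(self) -> list[tuple[int, int]]:
        out = []
        k = len(self.positions)
        for i in range(k):
            for j in range(i + 1, k):
                if not self.compatible[i, j]:
                    out.append((self.positions[i], self.positions[j]))
        return out


def four_gamete_compatibility(alignment: Mapping[str, str]
                              ) -> CompatibilityMatrix:
    """Pairwise four-gamete test over biallelic parsimony-informative sites.

    Two sites are incompatible iff all four gamete combinations occur among
    the sequences carrying nucleotides at both sites (gap-bearing sequences
    are excluded pairwise) — evidence of recombination or homoplasy.
    """
    _, rows = _as_matrix(alignment)
    if len(rows) < 4:
        raise ValueError("four-gamete screening needs >= 4 sequences")
    sites = []
    for c in informative_sites(rows):
        states = {r[c] for r in rows} & NUCS
        if len(states) == 2:
            sites.append(c)
    k = len(sites)
    compat = np.ones((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            ci, cj = sites[i], sites[j]
            gametes = {(r[ci], r[cj]) for r in rows
                       if r[ci] in NUCS and r[cj] in NUCS}
            if len(gametes) == 4:
                compat[i, j] = compat[j, i] = False
    return CompatibilityMatrix(positions=sites, compatible=compat)


# ---------------------------------------------------------------------------
# Recombination blocks

@dataclass
class RecombinationResult:
    blocks: list[tuple[int, int]]     # 0-based column bounds, inclusive
    verdict: str                      # "no recombination signal" | "blocks"
    p_value: float | None = None      # clustering permutation test

    def to_dict(self) -> dict:
        return {"blocks": [list(b) for b in self.blocks],
                "verdict": self.verdict, "p_value": self.p_value}


def _compatible_runs(incompat: np.ndarray) -> list[tuple[int, int]]:
    """Greedy maximal runs of consecutive sites pairwise compatible within
    the run (index bounds, inclusive)."""
    k = incompat.shape[0]
    runs: list[tuple[int, int]] = []
    start = 0
    while start < k:
        end = start
        while end + 1 < k and not incompat[start:end + 2, start:end + 2].any():
            end += 1
        runs.append((start, end))
        start = end + 1
    return runs


def recombination_blocks(matrix: CompatibilityMatrix, n_perm: int = 999,
                         alpha: float = 0.05,
                         seed: int = 0) -> RecombinationResult:
    """Find recombination blocks, if incompatibilities cluster positionally.

    Crossovers make incompatible site pairs straddle a breakpoint, so the
    informative sites fall into few long runs that are internally
    four-gamete compatible; scattered homoplasy (parallel mutation) cuts
    runs everywhere.  The statistic is the number of greedy maximal
    compatible runs; a permutation test shuffles the site order, and blocks
    are reported only when the observed run count is significantly smaller
    than under shuffling.  Runs without any outside incompatibility carry no
    signal and are not reported as blocks.
    """
    pairs = matrix.incompatible_pairs
    if not pairs:
        return RecombinationResult(blocks=[], verdict="no recombination signal")
    k = len(matrix.positions)
    incompat = ~matrix.compatible
    runs = _compatible_runs(incompat)
    obs = len(runs)
    rng = random.Random(seed)
    at_most = 0
    for _ in range(n_perm):
        perm = list(range(k))
        rng.shuffle(perm)
        shuffled = incompat[np.ix_(perm, perm)]
        if len(_compatible_runs(shuffled)) <= obs:
            at_most += 1
    p = (at_most + 1) / (n_perm + 1)
    if p >= alpha:
        return RecombinationResult(blocks=[], p_value=p,
                                   verdict="no recombination signal")
    blocks = [(matrix.positions[s], matrix.positions[e])
              for s, e in runs if incompat[s:e + 1, :].any()]
    return RecombinationResult(blocks=blocks, p_value=p, verdict="blocks")


# ---------------------------------------------------------------------------
# Outlier strains and diagnosability

def focal_substitutions(alignment: Mapping[str, str],
                        species_map: Mapping[str, str],
                        focal_strain: str) -> int:
    """Columns where the focal strain differs from the base shared by ALL of
    its conspecifics; columns with any gap/ambiguity among the compared
    strains are excluded (indels not considered)."""
    if focal_strain not in alignment:
        raise ValueError(f"focal strain {focal_strain!r} not in alignment")
    species = species_map[focal_strain]
    mates = [s for s, sp in species_map.items()
             if sp == species and s != focal_strain and s in alignment]
    if not mates:
        raise ValueError(f"species {species!r} has no other strains")
    focal = alignment[focal_strain].upper()
    rows = [alignment[m].upper() for m in mates]
    count = 0
    for c in range(len(focal)):
        states = {r[c] for r in rows}
        if focal[c] not in NUCS or (states | {focal[c]}) - NUCS:
            continue
        if len(states) == 1 and focal[c] not in states:
            count += 1
    return count


@dataclass
class DiagnosabilityReport:
    fixed_differences: dict[tuple[str, str], int]
    min_fixed_per_species: dict[str, int]
    locus_diagnostic: bool

    def to_dict(self) -> dict:
        return {
            "fixed_differences": {f"{a}|{b}": v for (a, b), v
                                  in self.fixed_differences.items()},
            "min_fixed_per_species": dict(self.min_fixed_per_species),
            "locus_diagnostic": self.locus_diagnostic,
        }


def diagnosability(alignment: Mapping[str, str],
                   species_map: Mapping[str, str]) -> DiagnosabilityReport:
    """Fixed-difference counts per species pair and a locus verdict.

    A column is a fixed difference for species pair (A, B) when every A
    strain carries nucleotide x, every B strain carries y, and x != y.  The
    locus is diagnostic iff every species pair shows at least one fixed
    difference — deliberately strict: one shared polymorphism (a misplaced
    strain) breaks diagnosability.
    """
    by_species: dict[str, list[str]] = {}
    for strain, sp in species_map.items():
        if strain in alignment:
            by_species.setdefault(sp, []).append(alignment[strain].upper())
    if len(by_species) < 2:
        raise ValueError("need at least two species present in the alignment")
    for sp, rows in by_species.items():
        if not rows:
            raise ValueError(f"species {sp!r} has no strains")
    L = len(next(iter(alignment.values())))
    species = list(by_species)
    fixed: dict[tuple[str, str], int] = {}
    for a, b in itertools.combinations(species, 2):
        n = 0
        for c in range(L):
            sa = {r[c] for r in by_species[a]}
            sb = {r[c] for r in by_species[b]}
            if len(sa) == 1 and len(sb) == 1 and sa <= NUCS and sb <= NUCS \
                    and sa != sb:
                n += 1
        fixed[(a, b)] = n
    min_fixed = {
        sp: min(v for pair, v in fixed.items() if sp in pair)
        for sp in species
    }
    return DiagnosabilityReport(
        fixed_differences=fixed,
        min_fixed_per_species=min_fixed,
        locus_diagnostic=all(v >= 1 for v in fixed.values()),
    )
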