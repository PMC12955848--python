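"""Codon lattice: the compact graph whose paths are the synonymous CDSs.

Position ``i`` (0-based, ``0 <= i < L = 3l``) holds one variant state per
distinct codon *prefix* of length ``i % 3 + 1`` among the synonymous codons
of residue ``i // 3``.  Within a codon, transitions follow the prefix trie,
which is what resolves the intra-codon dependencies of the 6-codon amino
acids (leucine UUR/CUN, arginine CGN/AGR, serine UCN/AGY): e.g. an ``AG``
prefix of serine can only continue with ``U`` or ``C``.  Across a codon
boundary every completed codon connects to every first-position state of the
next residue.  Third-position states carry the completed codon and its
``-ln w`` weight, so a root-to-end path spells a CDS and accumulates exactly
``-sum(ln w)`` — the additive form of ``-l*log(CAI)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .codon_model import AdaptivenessMap, ProteinSequence

__all__ = ["LatticeState", "CodonLattice", "build_lattice", "count_paths"]


@dataclass(frozen=True)
class LatticeState:
    """One variant state: the codon prefix spelled so far."""

    pos: int
    prefix: str  # length pos % 3 + 1
    codon: str | None = None  # set on third-position states
    neg_log_w: float = 0.0  # -ln w(codon), third-position states only

    @property
    def nuc(self) -> str:
        return self.prefix[-1]


class CodonLattice:
    """Layered DAG over ``L = 3l`` positions; paths <-> synonymous CDSs."""

    def __init__(self, protein: ProteinSequence, states: list[list[LatticeState]]):
        self.protein = protein
        self.states = states
        self.length = len(states)

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def transitions(self, i: int) -> list[tuple[int, int]]:
        """Allowed (state-index at i, state-index at i+1) pairs."""
        out = []
        nxt = self.states[i + 1]
        if (i + 1) % 3 == 0:  # codon boundary: complete bipartite
            return [(a, b) for a in range(len(self.states[i])) for b in range(len(nxt))]
        for a, sa in enumerate(self.states[i]):
            for b, sb in enumerate(nxt):
                if sb.prefix[:-1] == sa.prefix:
                    out.append((a, b))
        return out

    def paths(self) -> Iterator[str]:
        """Spell every CDS the lattice encodes (lexicographic order)."""

        def rec(i: int, acc: list[str]) -> Iterator[str]:
            if i == self.n_codons:
                yield "".join(acc)
                return
            for state in self.states[3 * i + 2]:
                acc.append(state.codon)  # type: ignore[arg-type]
                yield from rec(i + 1, acc)
                acc.pop()

        return rec(0, [])

    def dump(self) -> str:
        """Text adjacency listing for inspection."""
        lines = []
        for i, layer in enumerate(self.states):
            tags = []
            for s in layer:
                w = f" w=e^{-s.neg_log_w:.4f}" if s.codon else ""
                tags.append(f"{s.prefix}{w}")
            lines.append(f"pos {i:3d} ({'123'[i % 3]}): " + "  ".join(tags))
        return "\n".join(lines)


def build_lattice(protein: ProteinSequence, w: AdaptivenessMap) -> CodonLattice:
    """Build the prefix-trie lattice of all CDSs of ``protein`` under ``w``.

    State ordering is deterministic: codons of each family sorted
    lexicographically, prefixes likewise.
    """
    states: list[list[LatticeState]] = []
    for idx, aa in enumerate(protein):
        family = w.family(aa)
        if not family:
            raise ValueError(
                f"residue {aa!r} at position {idx + 1} has no codons in the "
                "adaptiveness map"
            )
        base = 3 * idx
        for k in (1, 2):
            prefixes = sorted({c[:k] for c in family})
            states.append(
                [LatticeState(base + k - 1, p) for p in prefixes]
            )
        states.append(
            [
                LatticeState(base + 2, c, codon=c, neg_log_w=-w.log_w[c])
                for c in family
            ]
        )
    return CodonLattice(protein, states)


def count_paths(lattice: CodonLattice) -> int:
    """Exact number of distinct CDSs (product of family sizes)."""
    n = 1
    for i in range(2, lattice.length, 3):
        n *= len(lattice.states[i])
    return n
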