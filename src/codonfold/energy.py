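"""Secondary-structure energy models and loop-decomposition scoring.

Two models are provided behind one interface:

* ``nussinov`` — every closed base pair contributes exactly -1 (arbitrary
  units); all loop terms are zero.  Useful for exact desk-scale testing.
* ``nearest_neighbor`` — a Turner-2004-derived loop model: Watson-Crick and
  wobble stacking energies, hairpin/bulge/internal initiation tables up to
  length 30 with logarithmic extrapolation beyond, an affine multiloop
  penalty ``a + b*branches + c*unpaired`` (the closing pair counts as a
  branch), and a terminal AU/GU helix-end penalty charged for each AU/UA/
  GU/UG pair incident to a non-stack loop.  Dangling ends, terminal
  mismatches, tetraloop bonuses and internal-loop asymmetry are deliberately
  outside this parameter surface.

Free energies are kcal/mol at 37 C for ``nearest_neighbor`` and pair units
for ``nussinov``.  The parameter tables live in a plain-text data file so
they can be swapped without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "PAIR_ORDER",
    "EnergyModel",
    "nussinov_model",
    "nearest_neighbor_model",
    "Loop",
    "loop_decompose",
    "score_structure",
]

PAIR_ORDER: tuple[str, ...] = ("CG", "GC", "GU", "UG", "AU", "UA")
PAIR_INDEX: dict[str, int] = {p: i for i, p in enumerate(PAIR_ORDER)}
_WEAK_PAIRS = frozenset({"AU", "UA", "GU", "UG"})

# log-extrapolation of loop initiation beyond the tabulated length:
# dG(n) = dG(30) + 1.75 * R * T * ln(n / 30)
_RT_EXTRAP = 1.75 * 1.98717e-3 * 310.15
_MAX_TAB = 30


@dataclass(frozen=True)
class EnergyModel:
    """Loop-decomposition scoring terms shared by all folding routines."""

    name: str
    min_hairpin: int = 3
    pair_bonus: float = 0.0  # per closed pair (nussinov: -1)
    stack_table: dict[tuple[str, str], float] = field(default_factory=dict)
    hairpin_tab: dict[int, float] = field(default_factory=dict)
    bulge_tab: dict[int, float] = field(default_factory=dict)
    internal_tab: dict[int, float] = field(default_factory=dict)
    ml_a: float = 0.0
    ml_b: float = 0.0
    ml_c: float = 0.0
    terminal_au: float = 0.0

    def is_pair(self, a: str, b: str) -> bool:
        return a + b in PAIR_INDEX

    def stack(self, outer: str, inner: str) -> float:
        """Stacking energy of ``inner`` pair directly inside ``outer``.

        Both pairs are given 5'->3' on the outer strand (i.e. ``outer`` is
        ``seq[i]+seq[j]`` and ``inner`` is ``seq[i+1]+seq[j-1]``); the
        symmetric table is keyed by (outer, reversed inner).
        """
        key = (outer, inner[::-1])
        if key in self.stack_table:
            return self.stack_table[key]
        return self.stack_table[(key[1], key[0])]

    def _looptab(self, tab: dict[int, float], n: int, kind: str) -> float:
        if n in tab:
            return tab[n]
        if not tab:  # nussinov
            return 0.0
        if n > _MAX_TAB:
            return tab[_MAX_TAB] + _RT_EXTRAP * math.log(n / _MAX_TAB)
        raise ValueError(f"no {kind} initiation for length {n}")

    def hairpin(self, n: int) -> float:
        if n < self.min_hairpin:
            raise ValueError(f"hairpin loop of {n} < minimum {self.min_hairpin}")
        return self._looptab(self.hairpin_tab, n, "hairpin")

    def bulge(self, n: int) -> float:
        return self._looptab(self.bulge_tab, n, "bulge")

    def internal(self, n: int) -> float:
        return self._looptab(self.internal_tab, n, "internal")

    def au_end(self, pair: str) -> float:
        return self.terminal_au if pair in _WEAK_PAIRS else 0.0


def nussinov_model() -> EnergyModel:
    """Base-pair maximization: -1 per pair, no loop terms."""
    return EnergyModel(name="nussinov", pair_bonus=-1.0)


def nearest_neighbor_model(params: str | Path | None = None) -> EnergyModel:
    """Load the nearest-neighbor model (embedded tables by default)."""
    if params is None:
        text = (
            resources.files("codonfold.data").joinpath("nn_params.txt").read_text()
        )
    else:
        text = Path(params).read_text()

    stack: dict[tuple[str, str], float] = {}
    hairpin: dict[int, float] = {}
    bulge: dict[int, float] = {}
    internal: dict[int, float] = {}
    ml = {"a": 0.0, "b": 0.0, "c": 0.0}
    terminal_au = 0.0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            kind = tok[0]
            if kind == "stack":
                stack[(tok[1], tok[2])] = float(tok[3])
            elif kind in ("hairpin", "bulge", "internal"):
                {"hairpin": hairpin, "bulge": bulge, "internal": internal}[kind][
                    int(tok[1])
                ] = float(tok[2])
            elif kind == "multiloop":
                ml[tok[1]] = float(tok[2])
            elif kind == "terminal_au":
                terminal_au = float(tok[1])
            else:
                raise ValueError(f"unknown term {kind!r}")
        except (IndexError, KeyError, ValueError) as exc:
            raise ValueError(f"parameter file line {lineno}: {exc}") from None
    return EnergyModel(
        name="nearest_neighbor",
        stack_table=stack,
        hairpin_tab=hairpin,
        bulge_tab=bulge,
        internal_tab=internal,
        ml_a=ml["a"],
        ml_b=ml["b"],
        ml_c=ml["c"],
        terminal_au=terminal_au,
    )


# ---------------------------------------------------------------------------
# loop decomposition and scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Loop:
    """One loop of the unique decomposition of a secondary structure.

    ``kind`` is one of hairpin/stack/bulge/internal/multiloop/external;
    ``closing`` is the (i, j) pair enclosing the loop (absent for the
    external loop); ``inner`` lists the directly enclosed pairs; ``unpaired``
    counts unpaired positions inside the loop.
    """

    kind: str
    closing: tuple[int, int] | None
    inner: tuple[tuple[int, int], ...]
    unpaired: int


def _parse_pairs(structure: str) -> dict[int, int]:
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i + 1}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at position {i + 1}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return pairs


def loop_decompose(
    seq: str, structure: str, min_hairpin: int = 3
) -> list[Loop]:
    """Decompose a pseudoknot-free structure into its unique loop set."""
    if len(seq) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    pairs = _parse_pairs(structure)

    def children(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        """Directly enclosed pairs and unpaired count in the open interval."""
        inner: list[tuple[int, int]] = []
        unpaired = 0
        k = i + 1
        while k < j:
            if k in pairs:
                inner.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                unpaired += 1
                k += 1
        return inner, unpaired

    loops: list[Loop] = []

    def visit(i: int, j: int) -> None:
        inner, unpaired = children(i, j)
        if not inner:
            if unpaired < min_hairpin:
                raise ValueError(
                    f"hairpin loop of {unpaired} closed by ({i + 1},{j + 1}) "
                    f"is below the minimum of {min_hairpin}"
                )
            loops.append(Loop("hairpin", (i, j), (), unpaired))
        elif len(inner) == 1:
            (p, q) = inner[0]
            l1, l2 = p - i - 1, j - q - 1
            if l1 == 0 and l2 == 0:
                loops.append(Loop("stack", (i, j), ((p, q),), 0))
            elif l1 == 0 or l2 == 0:
                loops.append(Loop("bulge", (i, j), ((p, q),), l1 + l2))
            else:
                loops.append(Loop("internal", (i, j), ((p, q),), l1 + l2))
        else:
            loops.append(Loop("multiloop", (i, j), tuple(inner), unpaired))
        for (p, q) in inner:
            visit(p, q)

    ext_inner, ext_unpaired = children(-1, len(seq))
    loops.append(Loop("external", None, tuple(ext_inner), ext_unpaired))
    for (p, q) in ext_inner:
        visit(p, q)
    return loops


def _pair_str(seq: str, pair: tuple[int, int]) -> str:
    return seq[pair[0]] + seq[pair[1]]


def score_structure(seq: str, structure: str, model: EnergyModel) -> float:
    """Free energy of ``structure`` on ``seq`` under ``model``.

    Sums per-loop terms of the unique decomposition; for the nussinov model
    this reduces to -(number of pairs).  Non-canonical pairs raise.
    """
    seq = seq.upper().replace("T", "U")
    loops = loop_decompose(seq, structure, model.min_hairpin)
    for loop in loops:
        for pair in ((loop.closing,) if loop.closing else ()) + loop.inner:
            ps = _pair_str(seq, pair)
            if ps not in PAIR_INDEX:
                raise ValueError(
                    f"non-canonical pair {ps} at positions "
                    f"({pair[0] + 1},{pair[1] + 1})"
                )

    total = 0.0
    for loop in loops:
        if loop.closing is not None:
            total += model.pair_bonus
        if model.name == "nussinov":
            continue
        if loop.kind == "hairpin":
            cp = _pair_str(seq, loop.closing)
            total += model.hairpin(loop.unpaired) + model.au_end(cp)
        elif loop.kind == "stack":
            total += model.stack(
                _pair_str(seq, loop.closing), _pair_str(seq, loop.inner[0])
            )
        elif loop.kind in ("bulge", "internal"):
            cp = _pair_str(seq, loop.closing)
            ip = _pair_str(seq, loop.inner[0])
            if loop.kind == "bulge":
                total += model.bulge(loop.unpaired)
                if loop.unpaired == 1:
                    # stacking is preserved through a single-nucleotide bulge
                    total += model.stack(cp, ip)
                else:
                    total += model.au_end(cp) + model.au_end(ip)
            else:
                total += model.internal(loop.unpaired)
                total += model.au_end(cp) + model.au_end(ip)
        elif loop.kind == "multiloop":
            cp = _pair_str(seq, loop.closing)
            total += (
                model.ml_a
                + model.ml_b * (1 + len(loop.inner))
                + model.ml_c * loop.unpaired
                + model.au_end(cp)
            )
            for pair in loop.inner:
                total += model.au_end(_pair_str(seq, pair))
        else:  # external
            for pair in loop.inner:
                total += model.au_end(_pair_str(seq, pair))
    return total
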