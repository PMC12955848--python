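"""Weighted-sum enumeration of Pareto-optimal CDS designs.

Repeatedly solves the exact single-objective design at adaptively chosen
``lambda`` values of the normalized scalarization ``lambda*MFE -
(1-lambda)*S`` (``S = l*log(CAI)``) and collects the supported Pareto
points.  The schedule is the standard slope-bisection recursion: solve the
two near-lexicographic endpoints ``lambda = eps`` and ``1 - eps``, then for
each adjacent pair solve at the ``lambda*`` where their objectives tie;
a new point is kept (and both sub-intervals explored) only if it improves
the tied objective by more than a tolerance.  Only supported (convex-hull)
Pareto points are reachable this way; unsupported points are not
enumerated, matching the weighted-sum method's contract.

Bookkeeping follows the n/N convention of the published comparisons: ``N``
counts every solver invocation that returned a solution, ``n`` the distinct
CDSs among them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

from .codon_model import (
    AdaptivenessMap,
    CodonUsageTable,
    ProteinSequence,
    relative_adaptiveness,
)
from .design import DesignResult, Objective, design
from .energy import EnergyModel
from .lattice import build_lattice

__all__ = [
    "ParetoFront",
    "pareto_front",
    "next_lambda",
    "filter_dominated",
    "normalize_percentages",
]


@dataclass(frozen=True)
class ParetoFront:
    """Non-dominated designs ordered by ascending CAI, with n/N accounting."""

    points: tuple[DesignResult, ...]
    raw: tuple[DesignResult, ...]  # every solver output, in solve order
    n: int  # distinct Pareto-optimal CDSs
    N: int  # total solver outputs
    mfe_pct: tuple[float, ...] = ()
    cai_pct: tuple[float, ...] = ()

    def to_tsv(self, dest: str | Path | IO[str]) -> None:
        """One row per distinct CDS; final-front representatives flagged."""
        front_cds = [p.cds for p in self.points]
        seen: set[str] = set()
        lines = [
            "lambda\tcds\tstructure\tmfe\tcai\tS\tmfe_pct\tcai_pct\tdistinct_flag"
        ]
        for r in self.raw:
            if r.cds in seen:
                continue
            seen.add(r.cds)
            flag = int(r.cds in front_cds)
            mp = cp = ""
            if flag:
                idx = front_cds.index(r.cds)
                mp = f"{self.mfe_pct[idx]:.2f}"
                cp = f"{self.cai_pct[idx]:.2f}"
            lines.append(
                f"{r.lambda_used:.9f}\t{r.cds}\t{r.structure}\t{r.mfe:.4f}\t"
                f"{r.cai:.6f}\t{r.S:.6f}\t{mp}\t{cp}\t{flag}"
            )
        text = "\n".join(lines) + "\n"
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            Path(dest).write_text(text)


def next_lambda(
    a: tuple[float, float], b: tuple[float, float]
) -> float | None:
    """The lambda at which the two (MFE, S) points have equal objective.

    ``a`` must be the more stable, lower-CAI point (``Ma < Mb``, ``Sa <
    Sb``).  Returns ``lambda* = (Sa-Sb) / ((Ma-Mb) + (Sa-Sb))``; ``None``
    for the degenerate cases ``Ma == Mb`` or ``Sa == Sb`` (caller closes the
    interval).  Identical points raise.
    """
    (ma, sa), (mb, sb) = a, b
    if a == b:
        raise ValueError("identical points have no separating lambda")
    if ma == mb or sa == sb:
        return None
    if not (ma < mb and sa < sb):
        raise ValueError(f"expected Ma < Mb and Sa < Sb, got {a} vs {b}")
    return (sa - sb) / ((ma - mb) + (sa - sb))


def filter_dominated(points: Sequence[DesignResult]) -> list[DesignResult]:
    """Keep non-dominated, distinct-CDS points, ordered by ascending CAI.

    A point is dominated if another has ``mfe <=`` and ``cai >=`` with at
    least one strict.  Ties in both coordinates collapse to the
    lexicographically smallest CDS.
    """
    by_cds: dict[str, DesignResult] = {}
    for p in points:
        by_cds.setdefault(p.cds, p)
    cands = sorted(by_cds.values(), key=lambda p: (-p.cai, p.mfe, p.cds))
    kept: list[DesignResult] = []
    best_mfe = float("inf")
    for p in cands:  # descending CAI: dominated iff an earlier point has mfe <=
        if p.mfe < best_mfe:
            kept.append(p)
            best_mfe = p.mfe
    kept.reverse()  # ascending CAI
    return kept


def normalize_percentages(front: ParetoFront) -> ParetoFront:
    """Annotate range-normalized MFE%/CAI% (100% = best of the set)."""
    if not front.points:
        raise ValueError("empty front")
    mfes = [p.mfe for p in front.points]
    cais = [p.cai for p in front.points]
    mspan = max(mfes) - min(mfes)
    cspan = max(cais) - min(cais)
    mfe_pct = tuple(
        100.0 if mspan == 0 else 100.0 * (max(mfes) - m) / mspan for m in mfes
    )
    cai_pct = tuple(
        100.0 if cspan == 0 else 100.0 * (c - min(cais)) / cspan for c in cais
    )
    return ParetoFront(
        points=front.points,
        raw=front.raw,
        n=front.n,
        N=front.N,
        mfe_pct=mfe_pct,
        cai_pct=cai_pct,
    )


def pareto_front(
    protein: ProteinSequence | str,
    usage: CodonUsageTable | AdaptivenessMap,
    model: EnergyModel,
    *,
    eps: float = 1e-6,
    tol: float = 1e-9,
    max_depth: int = 64,
    beam: int | None = None,
) -> ParetoFront:
    """Enumerate supported Pareto-optimal CDSs by weighted-sum recursion."""
    if isinstance(protein, str):
        protein = ProteinSequence(protein)
    w = usage if isinstance(usage, AdaptivenessMap) else relative_adaptiveness(usage)
    lattice = build_lattice(protein, w)

    raw: list[DesignResult] = []

    def solve(lam: float) -> DesignResult:
        r = design(lattice, model, Objective("derna", lam), beam)
        raw.append(r)
        return r

    stable = solve(1.0 - eps)  # MFE-lexicographic end
    adapted = solve(eps)  # CAI-lexicographic end

    def recurse(a: DesignResult, b: DesignResult, depth: int) -> None:
        """a = more stable end, b = higher-CAI end of the interval."""
        if depth > max_depth:
            raise RuntimeError(
                f"weighted-sum recursion exceeded depth {max_depth}; "
                "tolerance pathology between "
                f"({a.mfe}, {a.S}) and ({b.mfe}, {b.S})"
            )
        if a.cds == b.cds or (a.mfe, a.S) == (b.mfe, b.S):
            return
        lam = next_lambda((a.mfe, a.S), (b.mfe, b.S))
        if lam is None or not (0.0 < lam < 1.0):
            return
        obj_ab = lam * a.mfe - (1.0 - lam) * a.S
        r = solve(lam)
        obj_r = lam * r.mfe - (1.0 - lam) * r.S
        if obj_r < obj_ab - tol:
            recurse(a, r, depth + 1)
            recurse(r, b, depth + 1)

    recurse(stable, adapted, 0)

    points = filter_dominated(raw)
    front = ParetoFront(
        points=tuple(points),
        raw=tuple(raw),
        n=len(points),
        N=len(raw),
    )
    return normalize_percentages(front)


def plot_front(front: ParetoFront, dest: str | Path, title: str = "") -> None:
    """Scatter of the front: CAI (x) vs MFE (y), percent axes mirrored."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cais = [p.cai for p in front.points]
    mfes = [p.mfe for p in front.points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(cais, mfes, "o-", color="tab:blue")
    ax.set_xlabel("CAI")
    ax.set_ylabel("MFE (kcal/mol)")
    sec_x = ax.secondary_xaxis(
        "top",
        functions=(
            lambda c: _pct(c, min(cais), max(cais)),
            lambda p: _inv_pct(p, min(cais), max(cais)),
        ),
    )
    sec_x.set_xlabel("CAI %")
    sec_y = ax.secondary_yaxis(
        "right",
        functions=(
            lambda m: _pct(-m, -max(mfes), -min(mfes)),
            lambda p: -_inv_pct(p, -max(mfes), -min(mfes)),
        ),
    )
    sec_y.set_ylabel("MFE %")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(dest, dpi=120)
    plt.close(fig)


def _pct(x, lo, hi):
    return 100.0 * (x - lo) / (hi - lo) if hi > lo else 100.0


def _inv_pct(p, lo, hi):
    return lo + (hi - lo) * p / 100.0
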