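"""Brute-force ground truth at desk scale.

Three exhaustive routines used as independent references in the test suite
(and behind the ``--oracle`` CLI flag for tiny inputs):

* :func:`enumerate_cds` — every synonymous CDS of a short protein;
* :func:`exhaustive_fold` — the global MFE by explicit enumeration of every
  pseudoknot-free structure of a short sequence;
* :func:`brute_force_design` — the scalarized-design optimum by scanning
  all CDSs with the fixed-sequence folder as the inner loop.

All three carry hard size guards: they exist to validate the dynamic
programs, not to scale.
"""

from __future__ import annotations

import itertools
import math

from .codon_model import (
    GENETIC_CODE,
    AdaptivenessMap,
    CodonUsageTable,
    ProteinSequence,
    log_adaptiveness_sum,
    relative_adaptiveness,
)
from .design import DesignResult, Objective, fold_energy, fold_fixed
from .energy import EnergyModel, score_structure

__all__ = [
    "enumerate_cds",
    "enumerate_structures",
    "exhaustive_fold",
    "brute_force_design",
    "design_profile",
]

MAX_ENUM_PROTEIN = 8
MAX_FOLD_LEN = 14
MAX_DESIGN_PROTEIN = 6


def enumerate_cds(protein: ProteinSequence | str) -> list[str]:
    """All synonymous CDSs of ``protein``, lexicographic, no duplicates."""
    if isinstance(protein, str):
        protein = ProteinSequence(protein)
    if protein.length > MAX_ENUM_PROTEIN:
        raise ValueError(
            f"protein of {protein.length} aa exceeds the enumeration guard "
            f"of {MAX_ENUM_PROTEIN}"
        )
    families = [GENETIC_CODE[aa] for aa in protein]
    return ["".join(c) for c in itertools.product(*families)]


def enumerate_structures(seq: str, model: EnergyModel) -> list[str]:
    """Every pseudoknot-free dot-bracket structure of ``seq`` under ``model``."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence of {n} nt exceeds the fold guard of {MAX_FOLD_LEN}")
    minhp = model.min_hairpin
    memo: dict[tuple[int, int], list[list[tuple[int, int]]]] = {}

    def region(i: int, j: int) -> list[list[tuple[int, int]]]:
        if j - i + 1 <= 0:
            return [[]]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = [s for s in region(i + 1, j)]
        for k in range(i + minhp + 1, j + 1):
            if not model.is_pair(seq[i], seq[k]):
                continue
            for left in region(i + 1, k - 1):
                for right in region(k + 1, j):
                    out.append([(i, k)] + left + right)
        memo[key] = out
        return out

    structures = []
    for pairs in region(0, n - 1):
        chars = ["."] * n
        for a, b in pairs:
            chars[a], chars[b] = "(", ")"
        structures.append("".join(chars))
    return structures


def exhaustive_fold(seq: str, model: EnergyModel) -> tuple[float, str]:
    """Global MFE over the full structure space (ties: fewer pairs, then
    lexicographically smaller dot-bracket)."""
    seq = seq.upper().replace("T", "U")
    best: tuple[float, int, str] | None = None
    for structure in enumerate_structures(seq, model):
        e = score_structure(seq, structure, model)
        key = (e, structure.count("("), structure)
        if best is None or key < best:
            best = key
    assert best is not None  # all-dots always present
    return best[0], best[2]


def _as_w(usage: CodonUsageTable | AdaptivenessMap) -> AdaptivenessMap:
    if isinstance(usage, AdaptivenessMap):
        return usage
    return relative_adaptiveness(usage)


def design_profile(
    protein: ProteinSequence | str,
    usage: CodonUsageTable | AdaptivenessMap,
    model: EnergyModel,
) -> list[tuple[str, float, float]]:
    """``(cds, mfe, S)`` for every synonymous CDS, lexicographic order.

    ``mfe`` and ``S`` do not depend on the scalarization, so one profile
    serves any number of lambda values.
    """
    if isinstance(protein, str):
        protein = ProteinSequence(protein)
    if protein.length > MAX_DESIGN_PROTEIN:
        raise ValueError(
            f"protein of {protein.length} aa exceeds the design guard "
            f"of {MAX_DESIGN_PROTEIN}"
        )
    w = _as_w(usage)
    out = []
    for cds in enumerate_cds(protein):
        out.append((cds, fold_energy(cds, model), log_adaptiveness_sum(cds, w)))
    return out


def brute_force_design(
    protein: ProteinSequence | str,
    usage: CodonUsageTable | AdaptivenessMap,
    model: EnergyModel,
    objective: Objective,
) -> DesignResult:
    """Argmin of the scalarized objective over all CDSs (exhaustive)."""
    profile = design_profile(protein, usage, model)
    best = None
    for cds, mfe, S in profile:  # lexicographic order; strict < keeps first
        val = objective.value(mfe, S)
        if best is None or val < best[0]:
            best = (val, cds, mfe, S)
    assert best is not None
    val, cds, mfe, S = best
    mfe_chk, structure = fold_fixed(cds, model)
    n_codons = len(cds) // 3
    return DesignResult(
        cds=cds,
        structure=structure,
        mfe=mfe_chk,
        S=S,
        cai=math.exp(S / n_codons),
        objective_value=objective.value(mfe_chk, S),
        lambda_used=objective.lam,
        formulation=objective.formulation,
        exact=True,
    )
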