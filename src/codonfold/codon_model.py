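"""Genetic code, codon-usage tables, relative adaptiveness and CAI.

The codon adaptation index (CAI) of a coding sequence is the geometric mean
of the relative adaptiveness values ``w`` of its codons, where ``w(c)`` is
the usage frequency of codon ``c`` divided by the frequency of the most used
codon of the same synonymous family (Sharp & Li).  Because the geometric
mean turns into a sum of logarithms, ``l * log(CAI)`` equals
``sum(ln w(c))`` over the ``l`` codons — the additive form the joint design
DP charges edge by edge.  Natural logarithms are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping

from Bio.Data import CodonTable

__all__ = [
    "GENETIC_CODE",
    "STOP_CODONS",
    "AMINO_ACIDS",
    "ProteinSequence",
    "CodonUsageTable",
    "AdaptivenessMap",
    "load_codon_usage",
    "embedded_human_usage",
    "relative_adaptiveness",
    "cai",
    "log_adaptiveness_sum",
]

RNA_ALPHABET = frozenset("ACGU")

_table = CodonTable.unambiguous_rna_by_id[1]

#: amino-acid letter (plus '*' for stop) -> sorted tuple of synonymous RNA codons
GENETIC_CODE: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _table.forward_table.items():
    GENETIC_CODE.setdefault(_aa, [])
    GENETIC_CODE[_aa].append(_codon)
GENETIC_CODE["*"] = list(_table.stop_codons)
GENETIC_CODE = {aa: tuple(sorted(cods)) for aa, cods in GENETIC_CODE.items()}

STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)
AMINO_ACIDS: frozenset[str] = frozenset(GENETIC_CODE) - {"*"}

#: RNA codon -> amino-acid letter ('*' for stop)
CODON_TO_AA: dict[str, str] = {c: aa for aa, cods in GENETIC_CODE.items() for c in cods}


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence.

    ``residues`` is a string over the 20 standard amino-acid letters with an
    optional single trailing ``'*'`` (stop).  The stop, if present, counts as
    one codon position, so ``length`` is the number of codons of any encoding
    CDS.
    """

    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("protein sequence must be nonempty")
        for pos, aa in enumerate(self.residues):
            if aa in AMINO_ACIDS:
                continue
            if aa == "*" and pos == len(self.residues) - 1:
                continue
            raise ValueError(
                f"invalid residue {aa!r} at position {pos + 1} "
                "(expected a standard amino-acid letter, or '*' only at the end)"
            )

    @property
    def length(self) -> int:
        """Number of codons ``l`` in any CDS encoding this protein."""
        return len(self.residues)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.residues

    def __iter__(self):
        return iter(self.residues)


def _normalize_codon(tok: str, lineno: int) -> str:
    codon = tok.upper().replace("T", "U")
    if len(codon) != 3 or any(ch not in RNA_ALPHABET for ch in codon):
        raise ValueError(f"line {lineno}: invalid codon {tok!r}")
    return codon


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon usage frequencies (any consistent units; ratios matter)."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        for codon, freq in self.entries.items():
            if codon not in CODON_TO_AA:
                raise ValueError(f"unknown codon {codon!r}")
            if freq < 0:
                raise ValueError(f"negative frequency for {codon}: {freq}")

    def __getitem__(self, codon: str) -> float:
        return self.entries[codon]

    def __contains__(self, codon: str) -> bool:
        return codon in self.entries

    def family(self, aa: str) -> dict[str, float]:
        """Frequencies of the codons of one amino acid that are in the table."""
        return {c: self.entries[c] for c in GENETIC_CODE[aa] if c in self.entries}


def load_codon_usage(source: str | Path | IO[str], dialect: str = "auto") -> CodonUsageTable:
    """Parse a codon-usage table.

    Accepts the whitespace-separated Kazusa "codon frequency" layout (several
    ``codon frequency (count)`` groups per line, counts in parentheses
    ignored) and plain two-column ``codon<TAB>frequency`` files; ``dialect``
    may be ``"kazusa"``, ``"tsv"`` or ``"auto"``.  ``T`` is normalized to
    ``U``.  Malformed lines and duplicate codons raise :class:`ValueError`
    naming the line number.
    """
    if dialect not in ("auto", "kazusa", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()

    entries: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.replace("(", " ").replace(")", " ").split()
        i = 0
        while i < len(tokens):
            codon = _normalize_codon(tokens[i], lineno)
            if i + 1 >= len(tokens):
                raise ValueError(f"line {lineno}: codon {tokens[i]!r} has no frequency")
            try:
                freq = float(tokens[i + 1])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: bad frequency {tokens[i + 1]!r} for codon {tokens[i]!r}"
                ) from None
            if codon in entries:
                raise ValueError(f"line {lineno}: duplicate codon {codon}")
            entries[codon] = freq
            # Kazusa rows carry "codon freq (count)"; the count token, if
            # numeric and followed by another codon, was stripped with the
            # parentheses above.
            i += 2
            if i < len(tokens):
                try:
                    float(tokens[i])
                except ValueError:
                    pass
                else:
                    i += 1  # skip the (count) column
    if not entries:
        raise ValueError("empty codon usage table")
    return CodonUsageTable(entries)


def embedded_human_usage() -> CodonUsageTable:
    """The Homo sapiens per-thousand usage table shipped with the package."""
    with resources.files("codonfold.data").joinpath("human_codon_usage.tsv").open() as fh:
        return load_codon_usage(fh, dialect="tsv")


@dataclass(frozen=True)
class AdaptivenessMap:
    """Relative adaptiveness ``w`` per codon, with the floor that was applied."""

    w: Mapping[str, float]
    floor: float = 1e-3
    log_w: Mapping[str, float] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "log_w", {c: math.log(v) for c, v in self.w.items()}
        )

    def __getitem__(self, codon: str) -> float:
        return self.w[codon]

    def __contains__(self, codon: str) -> bool:
        return codon in self.w

    def family(self, aa: str) -> tuple[str, ...]:
        """Codons of ``aa`` available in this map, lexicographic order."""
        return tuple(c for c in GENETIC_CODE[aa] if c in self.w)


def relative_adaptiveness(table: CodonUsageTable, floor: float = 1e-3) -> AdaptivenessMap:
    """Compute ``w(c) = freq(c) / max-family-freq`` with a floor on zeros.

    Zero- (or near-zero-) frequency codons are kept in the design space with
    ``w`` floored at ``floor`` times the family maximum, so every synonymous
    codon remains available to the structure search.  Within each family the
    maximum ``w`` is exactly 1.
    """
    if not 0 < floor <= 1:
        raise ValueError("floor must be in (0, 1]")
    w: dict[str, float] = {}
    for aa in GENETIC_CODE:
        fam = table.family(aa)
        if not fam:
            continue
        max_freq = max(fam.values())
        if max_freq <= 0:
            raise ValueError(f"all codons of {aa!r} have zero frequency")
        for codon, freq in fam.items():
            w[codon] = max(freq, floor * max_freq) / max_freq
    return AdaptivenessMap(w, floor)


def _codons_of(cds: str) -> list[str]:
    seq = cds.upper().replace("T", "U")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not divisible by 3")
    if not seq:
        raise ValueError("empty CDS")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def log_adaptiveness_sum(cds: str, w: AdaptivenessMap) -> float:
    """``S = sum(ln w(codon))`` over the codons of ``cds`` (equals ``l*ln CAI``)."""
    total = 0.0
    for codon in _codons_of(cds):
        if codon not in w:
            raise ValueError(f"codon {codon} not covered by the adaptiveness map")
        total += w.log_w[codon]
    return total


def cai(cds: str, w: AdaptivenessMap) -> float:
    """Codon adaptation index: geometric mean of per-codon adaptiveness."""
    n_codons = len(_codons_of(cds))
    return math.exp(log_adaptiveness_sum(cds, w) / n_codons)


def translate(cds: str) -> str:
    """Back-translate an RNA CDS to its protein (stop rendered as ``'*'``)."""
    return "".join(CODON_TO_AA[c] for c in _codons_of(cds))
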