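"""FASTA input/output and result serialization."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .codon_model import ProteinSequence
from .design import DesignResult

__all__ = [
    "read_protein_fasta",
    "write_cds_fasta",
    "write_single_result",
]


def read_protein_fasta(path: str | Path) -> list[tuple[str, ProteinSequence]]:
    """Read protein records; invalid residues raise naming record and position."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).strip().upper()
        try:
            records.append((rec.id, ProteinSequence(seq)))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from None
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _maybe_dna(seq: str, dna: bool) -> str:
    return seq.replace("U", "T") if dna else seq


def write_cds_fasta(
    path: str | Path,
    entries: Iterable[tuple[str, DesignResult]],
    dna: bool = False,
    with_structure: bool = True,
) -> None:
    """FASTA of designed CDSs, each with a companion dot-bracket line."""
    lines = []
    for name, r in entries:
        lines.append(f">{name}")
        lines.append(_maybe_dna(r.cds, dna))
        if with_structure:
            lines.append(r.structure)
    Path(path).write_text("\n".join(lines) + "\n")


def write_single_result(path: str | Path, r: DesignResult) -> None:
    """One-row TSV summary of a single design."""
    header = "mfe\tcai\tS\tobjective\tlambda\tformulation\texact"
    row = (
        f"{r.mfe:.4f}\t{r.cai:.6f}\t{r.S:.6f}\t{r.objective_value:.6f}\t"
        f"{r.lambda_used:.9f}\t{r.formulation}\t{int(r.exact)}"
    )
    Path(path).write_text(header + "\n" + row + "\n")
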