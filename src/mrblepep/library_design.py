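"""Peptide scaffolds and systematic substitution libraries.

Short linear motifs (SLiMs) such as the calcineurin-docking PxIxIT element are
studied by synthesizing a scaffold peptide together with systematic single and
double substitutions.  Positions are numbered relative to the motif: the core
spans positions 1-6 (P of PxIxIT is position 1), the flanks are position -1
(immediately upstream) and positions 7-9 (downstream).  There is no position 0.

Phosphorylated residues are written with the single-letter codes ``X``
(phosphoserine) and ``Z`` (phosphothreonine), extending the standard 20-letter
amino-acid alphabet.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO = "XZ"  # X = phosphoserine, Z = phosphothreonine
EXTENDED_ALPHABET = AA20 + PHOSPHO

#: Motif-relative positions addressable on a scaffold (no position 0).
MOTIF_POSITIONS: tuple[int, ...] = (-1, 1, 2, 3, 4, 5, 6, 7, 8, 9)


class PositionError(ValueError):
    """A motif position outside [-1, 9] (or 0) was requested."""


class AlphabetError(ValueError):
    """A residue outside the extended amino-acid alphabet was supplied."""


class LibraryError(ValueError):
    """Invalid library specification (duplicate positions, empty alphabet...)."""


def _check_position(position: int) -> None:
    if position not in MOTIF_POSITIONS:
        raise PositionError(
            f"motif position must be -1 or 1..9 (no position 0), got {position}"
        )


def _check_residue(residue: str) -> None:
    if not (isinstance(residue, str) and len(residue) == 1 and residue in EXTENDED_ALPHABET):
        raise AlphabetError(f"residue {residue!r} not in extended alphabet {EXTENDED_ALPHABET}")


@dataclass(frozen=True)
class Scaffold:
    """A named peptide scaffold with a located 6-residue motif core.

    ``core_offset`` is the 0-based index of motif position 1 within
    ``sequence``.  The sequence must span motif positions -1 through 9, i.e.
    at least one residue upstream of the core and three downstream.
    """

    name: str
    sequence: str
    core_offset: int

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(EXTENDED_ALPHABET)
        if bad:
            raise AlphabetError(f"scaffold {self.name}: illegal residues {sorted(bad)}")
        if self.core_offset < 1:
            raise PositionError(
                f"scaffold {self.name}: core_offset must be >= 1 so position -1 exists"
            )
        if self.core_offset + 9 > len(self.sequence):
            raise PositionError(
                f"scaffold {self.name}: sequence too short to span motif positions -1..9"
            )
        if "_" in self.name:
            raise ValueError("scaffold names may not contain '_' (reserved for variant ids)")

    def index_of(self, position: int) -> int:
        """Sequence index of a motif position (-1 or 1..9)."""
        _check_position(position)
        if position == -1:
            return self.core_offset - 1
        return self.core_offset + position - 1

    def residue_at(self, position: int) -> str:
        return self.sequence[self.index_of(position)]

    @property
    def core(self) -> str:
        """The six core motif residues (positions 1-6)."""
        return self.sequence[self.core_offset : self.core_offset + 6]


#: Reference PxIxIT scaffolds.  PVIVIT is the high-affinity engineered peptide
#: (reference sequence MAGPHPVIVITGPHEE); PKIVIT swaps position 2 to lysine.
PVIVIT = Scaffold("PVIVIT", "MAGPHPVIVITGPHEE", 5)
PKIVIT = Scaffold("PKIVIT", "MAGPHPKIVITGPHEE", 5)


@dataclass(frozen=True)
class PeptideVariant:
    """A scaffold with zero or more point substitutions at motif positions."""

    scaffold_name: str
    substitutions: tuple[tuple[int, str], ...]
    full_sequence: str
    variant_id: str

    @property
    def is_wild_type(self) -> bool:
        return len(self.substitutions) == 0


_SUB_TOKEN = re.compile(r"^(-?\d+)([A-Z])$")


def variant_id_for(scaffold_name: str, substitutions: Sequence[tuple[int, str]]) -> str:
    """Deterministic variant name: scaffold + position/residue tokens.

    ``PVIVIT`` + [(2, 'K'), (9, 'Z')] -> ``PVIVIT_2K_9Z``; no substitutions ->
    ``PVIVIT_WT``.  Tokens are sorted by position, so the id is canonical.
    """
    if not substitutions:
        return f"{scaffold_name}_WT"
    toks = [f"{p}{r}" for p, r in sorted(substitutions)]
    return "_".join([scaffold_name] + toks)


def parse_variant_id(variant_id: str) -> tuple[str, tuple[tuple[int, str], ...]]:
    """Invert :func:`variant_id_for`."""
    parts = variant_id.split("_")
    name, toks = parts[0], parts[1:]
    if toks == ["WT"]:
        return name, ()
    subs = []
    for tok in toks:
        m = _SUB_TOKEN.match(tok)
        if m is None:
            raise ValueError(f"cannot parse variant id token {tok!r} in {variant_id!r}")
        subs.append((int(m.group(1)), m.group(2)))
    return name, tuple(subs)


def _canonical_substitutions(
    substitutions: Iterable[tuple[int, str]],
) -> tuple[tuple[int, str], ...]:
    seen: dict[int, str] = {}
    for position, residue in substitutions:
        _check_position(position)
        _check_residue(residue)
        if position in seen and seen[position] != residue:
            raise LibraryError(
                f"conflicting substitutions at position {position}: "
                f"{seen[position]!r} vs {residue!r}"
            )
        seen[position] = residue
    return tuple(sorted(seen.items()))


def apply_substitutions(
    scaffold: Scaffold, substitutions: Iterable[tuple[int, str]]
) -> PeptideVariant:
    """Build a peptide variant by substituting residues at motif positions.

    Repeated identical substitutions are idempotent; distinct positions commute.
    An empty substitution list returns the wild type.
    """
    subs = _canonical_substitutions(substitutions)
    seq = list(scaffold.sequence)
    for position, residue in subs:
        seq[scaffold.index_of(position)] = residue
    return PeptideVariant(
        scaffold_name=scaffold.name,
        substitutions=subs,
        full_sequence="".join(seq),
        variant_id=variant_id_for(scaffold.name, subs),
    )


def single_substitution_library(
    scaffold: Scaffold,
    positions: Sequence[int],
    alphabet: Sequence[str] = EXTENDED_ALPHABET,
    include_wt: bool = True,
) -> list[PeptideVariant]:
    """All single substitutions of ``scaffold`` at ``positions``.

    One variant per (position, residue) pair, skipping residues identical to
    the wild-type residue at that position; the wild type itself is appended
    once when ``include_wt``.
    """
    if len(set(positions)) != len(positions):
        raise LibraryError("duplicate positions in library specification")
    if len(positions) > 0 and len(alphabet) == 0:
        raise LibraryError("alphabet must be non-empty")
    variants: list[PeptideVariant] = []
    for position in positions:
        _check_position(position)
        wt_res = scaffold.residue_at(position)
        for residue in alphabet:
            _check_residue(residue)
            if residue == wt_res:
                continue
            variants.append(apply_substitutions(scaffold, [(position, residue)]))
    if include_wt:
        variants.append(apply_substitutions(scaffold, []))
    return variants


def double_mutant_set(
    scaffold: Scaffold, sub_a: tuple[int, str], sub_b: tuple[int, str]
) -> list[PeptideVariant]:
    """The four corners of a double-mutant cycle: WT, A, B, AB (stable order)."""
    if sub_a[0] == sub_b[0]:
        raise LibraryError("double-mutant cycle requires substitutions at distinct positions")
    return [
        apply_substitutions(scaffold, []),
        apply_substitutions(scaffold, [sub_a]),
        apply_substitutions(scaffold, [sub_b]),
        apply_substitutions(scaffold, [sub_a, sub_b]),
    ]


# ---------------------------------------------------------------------------
# I/O


def library_to_csv(variants: Sequence[PeptideVariant], path: str | Path) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "scaffold": v.scaffold_name,
            "substitutions": ";".join(f"{p}{r}" for p, r in v.substitutions),
            "full_sequence": v.full_sequence,
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=["variant_id", "scaffold", "substitutions", "full_sequence"]).to_csv(
        path, index=False
    )


def library_from_csv(path: str | Path) -> list[PeptideVariant]:
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        subs = _canonical_substitutions(
            (int(m.group(1)), m.group(2))
            for tok in str(row["substitutions"]).split(";")
            if tok
            for m in [_SUB_TOKEN.match(tok)]
            if m
        )
        out.append(
            PeptideVariant(
                scaffold_name=row["scaffold"],
                substitutions=subs,
                full_sequence=row["full_sequence"],
                variant_id=row["variant_id"],
            )
        )
    return out


def library_to_fasta(variants: Sequence[PeptideVariant], path: str | Path) -> None:
    """Write variants as FASTA (X/Z kept as nonstandard letters)."""
    records = [
        SeqRecord(Seq(v.full_sequence), id=v.variant_id, description="") for v in variants
    ]
    SeqIO.write(records, str(path), "fasta")
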