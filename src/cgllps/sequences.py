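"""Protein sequences, aromatic-sticker variants, and compositions.

The packaged fixture holds seven variants of the hnRNPA1 low-complexity
domain (A1-LCD, wild type carrying a nuclear localization signal) in which
the chemical identity of the aromatic "sticker" residues is changed while
their positions along the sequence are conserved.  The wild type carries
8 tyrosines and 12 phenylalanines; 19 of those 20 aromatics (7Y + 12F; one
NLS-region tyrosine excluded) are the mutable sticker positions.

The packaged sequences are synthetic reconstructions built on an
hnRNPA1-like low-complexity scaffold: the original variant table is
distributed as supplementary material of the measurement papers and is not
reproduced verbatim here.  All printed aromatic compositions are honoured.
"""

from __future__ import annotations

import importlib.resources
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
AROMATIC = set("FWY")


class SequenceError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) == 0:
            raise SequenceError(f"{self.id}: empty sequence")
        for pos, c in enumerate(self.residues):
            if c not in AMINO_ACIDS:
                raise SequenceError(
                    f"{self.id}: non-amino-acid character {c!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class VariantRule:
    """Replacement of aromatic sticker residues at fixed positions.

    ``replacement`` maps the aromatic code found at a mutable position to
    its new identity; ``overrides`` (position -> code) wins over the map,
    which allows sticker-removal variants (aromatic -> spacer).
    """

    name: str
    mutable_positions: tuple[int, ...]  # 0-based indices into the reference
    replacement: dict[str, str] = field(default_factory=dict)
    overrides: dict[int, str] = field(default_factory=dict)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from FASTA; lowercase is uppercased with a warning."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"{rec.id}: lowercase residues uppercased", stacklevel=2)
            seq = seq.upper()
        out.append(ProteinSequence(rec.id, seq))
    return out


def write_fasta(sequences: list[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 60):
                fh.write(s.residues[i : i + 60] + "\n")


def make_variant(reference: ProteinSequence, rule: VariantRule) -> ProteinSequence:
    """Apply a sticker-substitution rule; only mutable positions change."""
    residues = list(reference.residues)
    for pos in rule.mutable_positions:
        if pos < 0 or pos >= len(residues):
            raise SequenceError(f"{rule.name}: position {pos} outside the sequence")
        current = residues[pos]
        if current not in AROMATIC and pos not in rule.overrides:
            raise SequenceError(
                f"{rule.name}: position {pos} holds non-aromatic residue {current!r}"
            )
        if pos in rule.overrides:
            residues[pos] = rule.overrides[pos]
        elif current in rule.replacement:
            residues[pos] = rule.replacement[current]
    return ProteinSequence(f"{rule.name}", "".join(residues))


def composition(sequence: ProteinSequence) -> Counter:
    """Residue-type counts; they always sum to the sequence length."""
    return Counter(sequence.residues)


# ---------------------------------------------------------------------------
# packaged A1-LCD variant fixtures
# ---------------------------------------------------------------------------

VARIANT_NAMES = ("WT+NLS", "allF", "allY", "allW", "YtoW", "FtoW", "W-")


def _fixture_path() -> Path:
    return (
        Path(str(importlib.resources.files("cgllps")))
        / "data"
        / "sequences"
        / "a1_lcd_variants_synthetic.fasta"
    )


def load_a1_lcd_variants() -> dict[str, ProteinSequence]:
    """The seven packaged A1-LCD variant sequences, keyed by variant name."""
    seqs = read_fasta(_fixture_path())
    out = {s.id: s for s in seqs}
    missing = [n for n in VARIANT_NAMES if n not in out]
    if missing:
        raise SequenceError(f"fixture missing variants: {missing}")
    return out


def sticker_positions(reference: ProteinSequence) -> tuple[int, ...]:
    """The 19 mutable aromatic sticker positions of the packaged wild type.

    All aromatics except the last (NLS-region) tyrosine.
    """
    aromatics = [i for i, c in enumerate(reference.residues) if c in AROMATIC]
    if len(aromatics) < 2:
        raise SequenceError("reference carries too few aromatics to define stickers")
    return tuple(aromatics[:-1])


def variant_rule(name: str, reference: ProteinSequence) -> VariantRule:
    """Construction rule for each packaged variant (cross-check for fixtures)."""
    pos = sticker_positions(reference)
    if name == "allF":
        return VariantRule(name, pos, {"Y": "F", "W": "F", "F": "F"})
    if name == "allY":
        return VariantRule(name, pos, {"Y": "Y", "W": "Y", "F": "Y"})
    if name == "allW":
        return VariantRule(name, pos, {"Y": "W", "W": "W", "F": "W"})
    if name == "YtoW":
        return VariantRule(name, pos, {"Y": "W"})
    if name == "FtoW":
        return VariantRule(name, pos, {"F": "W"})
    if name == "W-":
        removed = pos[1::3]  # every third sticker becomes a glycine spacer
        kept = tuple(p for p in pos if p not in removed)
        assert len(kept) == 13
        return VariantRule(
            name,
            pos,
            {"Y": "W", "W": "W", "F": "W"},
            overrides={p: "G" for p in removed},
        )
    if name == "WT+NLS":
        return VariantRule(name, pos)
    raise SequenceError(f"unknown variant {name!r}")
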