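"""Regenerate the packaged A1-LCD variant FASTA (synthetic reconstruction).

The wild-type scaffold is an hnRNPA1-like low-complexity sequence of 137
residues carrying exactly 8 tyrosines and 12 phenylalanines; the last
(NLS-region) tyrosine is not a sticker.  Variants are derived with the
package's own rule machinery so fixture and rules stay consistent.
"""

from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from cgllps.sequences import (  # noqa: E402
    ProteinSequence,
    VARIANT_NAMES,
    make_variant,
    variant_rule,
    write_fasta,
)

WT = (
    "GSMASASSSQRGRSGSGNFGGGRGGGFGGNDNFGRGGNFSGRGGFGGSRGGGGYGGSGDG"
    "YNGFGNDGGYGGGGPGYSGGSRGYGSGGQGYGNQGSGFGGFGGSGSYDSFNNGGGGGFGG"
    "GSGSNFGGGGSFNDYGN"
)


def main():
    wt = ProteinSequence("WT+NLS", WT)
    assert len(wt) == 137, len(wt)
    assert wt.residues.count("Y") == 8 and wt.residues.count("F") == 12
    seqs = [wt]
    for name in VARIANT_NAMES[1:]:
        seqs.append(make_variant(wt, variant_rule(name, wt)))
    out = (
        Path(__file__).resolve().parent.parent
        / "src/cgllps/data/sequences/a1_lcd_variants_synthetic.fasta"
    )
    write_fasta(seqs, out)
    for s in seqs:
        print(s.id, len(s), {c: s.residues.count(c) for c in "FWY"})


if __name__ == "__main__":
    main()
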