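"""RasMol amino-acid color scheme.

The classic RasMol "amino" coloring groups residues by physicochemical
class (acids share one color, the basic pair K/R another, and so on).
Gaps are rendered neutral white so uncovered leaves stay visible but
uncolored in ring annotations; 'X' (unknown residue) is mid grey.
"""

RASMOL_AMINO_HEX: dict[str, str] = {
    "D": "#E60A0A", "E": "#E60A0A",            # acidic, bright red
    "K": "#145AFF", "R": "#145AFF",            # basic, blue
    "C": "#E6E600", "M": "#E6E600",            # sulfur-containing, yellow
    "S": "#FA9600", "T": "#FA9600",            # hydroxyl, orange
    "N": "#00DCDC", "Q": "#00DCDC",            # amide, cyan
    "F": "#3232AA", "Y": "#3232AA",            # mid-size aromatic, mid blue
    "W": "#B45AB4",                            # large aromatic, pink
    "H": "#8282D2",                            # histidine, pale blue
    "G": "#EBEBEB",                            # glycine, light grey
    "A": "#C8C8C8",                            # alanine, dark grey
    "L": "#0F820F", "V": "#0F820F", "I": "#0F820F",  # aliphatic, green
    "P": "#DC9682",                            # proline, flesh
    "X": "#BEBEBE",                            # unknown residue
    "-": "#FFFFFF",                            # gap, neutral
}


def residue_color(residue: str) -> str:
    """Hex color for a one-letter residue code (case-insensitive)."""
    return RASMOL_AMINO_HEX.get(residue.upper(), RASMOL_AMINO_HEX["X"])
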