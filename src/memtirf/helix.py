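"""Amphipathic-helix analysis: helical wheel classes and hydrophobic moment.

Residues are projected onto an ideal α-helical wheel (100° per residue,
3.6 residues per turn).  The hydrophobic moment is the magnitude of the
per-residue hydrophobicity vector sum around the wheel, normalized by
peptide length — a scalar measure of amphipathicity used to rank wild-type
versus mutant membrane-targeting peptides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Peptide",
    "ResidueAssignment",
    "WheelAssignment",
    "HYDROPHOBICITY_SCALES",
    "RESIDUE_CLASSES",
    "classify_residues",
    "hydrophobic_moment",
    "wheel_plot",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEGREES_PER_RESIDUE = 100.0  # ideal α-helix, 3.6 residues/turn

# Eisenberg, Schwarz, Komaromy & Wall (1984) normalized consensus scale.
EISENBERG_CONSENSUS = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Kyte & Doolittle (1982) hydropathy, provided as an alternative.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPHOBICITY_SCALES = {
    "eisenberg": EISENBERG_CONSENSUS,
    "kyte-doolittle": KYTE_DOOLITTLE,
}

# Wheel-display classes.  A partition of the 20 canonical residues:
# bulky and small hydrophobics (alanine included, the standard convention),
# basics, small hydrophilics, and everything else (acidic + C, P).
RESIDUE_CLASSES = {
    "hydrophobic": set("FLIVMWYA"),
    "basic": set("KRH"),
    "small_hydrophilic": set("GSTNQ"),
    "other": set("DECP"),
}
_CLASS_OF = {aa: cls for cls, members in RESIDUE_CLASSES.items() for aa in members}


@dataclass(frozen=True)
class Peptide:
    """One-letter amino-acid sequence with an optional parent-protein offset."""

    sequence: str
    name: str = ""
    offset: int = 1  # residue number of the first position in the parent protein

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in AMINO_ACIDS:
                raise ValueError(
                    f"non-canonical residue {aa!r} at position {i} "
                    f"(residue number {self.offset + i})"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueAssignment:
    index: int  # 0-based position in the peptide
    residue_number: int  # position in the parent protein
    amino_acid: str
    wheel_angle: float  # degrees in [0, 360)
    residue_class: str


@dataclass(frozen=True)
class WheelAssignment:
    peptide: Peptide
    residues: tuple[ResidueAssignment, ...]


def classify_residues(p: Peptide) -> WheelAssignment:
    """Helical-wheel angle and display class for every residue."""
    residues = tuple(
        ResidueAssignment(
            index=i,
            residue_number=p.offset + i,
            amino_acid=aa,
            wheel_angle=(i * DEGREES_PER_RESIDUE) % 360.0,
            residue_class=_CLASS_OF[aa],
        )
        for i, aa in enumerate(p.sequence)
    )
    return WheelAssignment(peptide=p, residues=residues)


def hydrophobic_moment(p: Peptide, scale: str = "eisenberg") -> float:
    """Per-residue hydrophobic moment µH of an ideal helix.

    µH = |Σ_i h_i (cos(i·100°), sin(i·100°))| / n with h_i from the named
    hydrophobicity scale.  Always non-negative; exactly zero (to floating
    point) for an 18-residue homopolymer, whose wheel vectors cancel over
    five full turns.
    """
    try:
        table = HYDROPHOBICITY_SCALES[scale]
    except KeyError:
        raise ValueError(
            f"unknown scale {scale!r}; available: {sorted(HYDROPHOBICITY_SCALES)}"
        ) from None
    n = len(p.sequence)
    h = np.array([table[aa] for aa in p.sequence])
    angles = np.deg2rad(np.arange(n) * DEGREES_PER_RESIDUE)
    mu_cos = float(np.sum(h * np.cos(angles)))
    mu_sin = float(np.sum(h * np.sin(angles)))
    return float(np.hypot(mu_cos, mu_sin)) / n


def wheel_plot(assignment: WheelAssignment, path) -> None:
    """Save a helical-wheel diagram as PNG (display aid, not analysis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "hydrophobic": "#f4d03f",
        "basic": "#5dade2",
        "small_hydrophilic": "#58d68d",
        "other": "#d5d8dc",
    }
    fig, axes = plt.subplots(figsize=(5, 5))
    n = len(assignment.residues)
    for res in assignment.residues:
        # spiral radius so stacked turns stay readable
        r = 1.0 + 0.35 * (res.index * DEGREES_PER_RESIDUE) / 360.0 / max(n / 18.0, 1.0) * 0.5
        a = np.deg2rad(res.wheel_angle)
        x, y = r * np.cos(a), r * np.sin(a)
        axes.scatter([x], [y], s=600, c=colors[res.residue_class], edgecolors="k", zorder=3)
        axes.annotate(
            f"{res.amino_acid}{res.residue_number}",
            (x, y),
            ha="center",
            va="center",
            fontsize=7,
            zorder=4,
        )
    axes.set_xlim(-1.6, 1.6)
    axes.set_ylim(-1.6, 1.6)
    axes.set_aspect("equal")
    axes.axis("off")
    title = assignment.peptide.name or assignment.peptide.sequence
    axes.set_title(title, fontsize=9)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
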