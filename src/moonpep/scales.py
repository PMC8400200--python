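"""Per-residue numeric scales used by the peptide descriptors.

All tables are standard literature scales over the 20 canonical amino
acids (one-letter codes):

* ``hydrophobicity`` — Eisenberg consensus hydrophobicity, the scale the
  hydrophobic-moment formalism was published with.
* ``pka`` — EMBOSS acid-dissociation constants for the ionizable side
  chains (C, D, E, H, K, R, Y) plus the free termini.
* ``logp_octanol`` — Fauchère–Pliška side-chain water/octanol partition
  increments (π values); summing them gives an additive logP estimate.
* ``helix_propensity`` — Chou–Fasman P(alpha) helix propensities;
  residues with P(alpha) >= 1.00 are conventionally "helix formers".

A :class:`ScaleSet` bundles one table of each kind so every descriptor
computation can be re-run under alternative scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS)

# Eisenberg, Schwarz, Komaromy & Wall (1984) consensus scale.
EISENBERG_HYDROPHOBICITY: Dict[str, float] = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

# EMBOSS (iep) side-chain pKa values. Basic groups: H, K, R; acidic
# groups: C, D, E, Y.  Termini are modelled separately because the
# designed peptides here carry an N-terminal fluorophore conjugation.
EMBOSS_PKA: Dict[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
    "K": 10.8, "R": 12.5, "Y": 10.1,
}
EMBOSS_PKA_NTERM = 8.6
EMBOSS_PKA_CTERM = 3.6

BASIC_RESIDUES = frozenset("HKR")
ACIDIC_RESIDUES = frozenset("CDEY")

# Fauchère & Pliška (1983) side-chain pi values (logP relative to Gly).
FAUCHERE_PLISKA_LOGP: Dict[str, float] = {
    "A": 0.31, "C": 1.54, "D": -0.77, "E": -0.64, "F": 1.79,
    "G": 0.00, "H": 0.13, "I": 1.80, "K": -0.99, "L": 1.70,
    "M": 1.23, "N": -0.60, "P": 0.72, "Q": -0.22, "R": -1.01,
    "S": -0.04, "T": 0.26, "V": 1.22, "W": 2.25, "Y": 0.96,
}

# Chou & Fasman (1978) P(alpha) helix conformational parameters.
CHOU_FASMAN_PALPHA: Dict[str, float] = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}


def _complete(table: Dict[str, float], name: str) -> Dict[str, float]:
    missing = ALPHABET - table.keys()
    if missing:
        raise ValueError(f"scale {name!r} missing residues: {sorted(missing)}")
    bad = [r for r, v in table.items() if not (v == v and abs(v) != float("inf"))]
    if bad:
        raise ValueError(f"scale {name!r} has non-finite values for {bad}")
    return dict(table)


@dataclass(frozen=True)
class ScaleSet:
    """Named bundle of the per-residue tables used for featurization.

    The pKa table may be sparse (only ionizable residues appear); every
    other table must cover all 20 residues.
    """

    name: str = "default"
    hydrophobicity: Dict[str, float] = field(
        default_factory=lambda: dict(EISENBERG_HYDROPHOBICITY))
    pka: Dict[str, float] = field(default_factory=lambda: dict(EMBOSS_PKA))
    logp_octanol: Dict[str, float] = field(
        default_factory=lambda: dict(FAUCHERE_PLISKA_LOGP))
    helix_propensity: Dict[str, float] = field(
        default_factory=lambda: dict(CHOU_FASMAN_PALPHA))
    pka_nterm: float = EMBOSS_PKA_NTERM
    pka_cterm: float = EMBOSS_PKA_CTERM

    def __post_init__(self) -> None:
        _complete(self.hydrophobicity, "hydrophobicity")
        _complete(self.logp_octanol, "logp_octanol")
        _complete(self.helix_propensity, "helix_propensity")


DEFAULT_SCALES = ScaleSet()
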