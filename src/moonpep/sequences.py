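"""Published peptide sequences used as worked-example inputs.

These are the moonlighting designs characterized experimentally in the
study this package reimplements: three targeted designs embedding the
S. cerevisiae alpha-pheromone (binds the Ste2p receptor on MATa cells)
and three activation-strategy constructs built on the HIV Tat(47-57)
CPP with the neprilysin recognition site FFGFLA (neprilysin cuts after
the G) and an acidic de-activating tail DDDDEE.
"""

from __future__ import annotations

from .records import PeptideRecord

ALPHA_PHEROMONE = "WHWLQLKPGQPMY"
TAT = "YGRKKRRQRRR"
NEPRILYSIN_SITE = "FFGFLA"
ACIDIC_TAIL = "DDDDEE"

# ID -> (sequence, reported consensus P(CPP), chirality note)
STUDY_PEPTIDES = {
    "alpha-NLS-C": ("RLWHWLQLKPGQPMYWRQPKSKRKVRR", 0.91, None),
    "NLS-alpha-CE": ("FRKWRRKPKKKRKVWWRKVKRRWHWLQLKPGQPMY", 0.97, None),
    "chimera": ("KRRWRFVWMNPKKKRKVPPWPYLLWWHWLQLKPGQPMY", 0.88, None),
    "TatNep": (TAT + "FFG", 0.99, None),
    "TatNepNoCPP": (TAT + NEPRILYSIN_SITE + ACIDIC_TAIL, 0.112, None),
    "D-TatNepNoCPP": (TAT + NEPRILYSIN_SITE + ACIDIC_TAIL, 0.11, "all-D"),
}


def study_records() -> list:
    """The study peptides as validated :class:`PeptideRecord` objects."""
    return [PeptideRecord(id=name, sequence=seq, chirality_note=note)
            for name, (seq, _, note) in STUDY_PEPTIDES.items()]


def reported_pcpp(name: str) -> float:
    return STUDY_PEPTIDES[name][1]
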