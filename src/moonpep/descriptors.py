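"""The 27-attribute peptide featurization.

A peptide sequence is mapped to a fixed-order vector of 27 numbers:

==========  ==============================================================
indices     attribute
==========  ==============================================================
0–19        residue counts, alphabetical one-letter order (A…Y)
20          mean Eisenberg hydrophobicity
21          mean Henderson–Hasselbalch net charge at pH 7 (charge/length)
22          isoelectric point (bisection root of the net charge)
23          sliding-window range (max − min) of window net charge
24          sliding-window range of the Eisenberg hydrophobic moment
25          additive water/octanol partition coefficient (Fauchère–Pliška)
26          helix-former fraction (Chou–Fasman P(alpha) >= 1.00)
==========  ==============================================================

This is the representation a cationic/amphipathic membrane-activity
classifier needs: composition, charge, amphipathic moment, lipophilicity
and helicity.  The window statistics capture local amphipathic segments
that whole-sequence means wash out.

The module exposes both plain functions and a scikit-learn transformer
(:class:`PeptideFeaturizer`) so featurization composes with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .records import PeptideRecord, validate_sequence
from .scales import (ACIDIC_RESIDUES, AMINO_ACIDS, BASIC_RESIDUES,
                     DEFAULT_SCALES, ScaleSet)

FEATURE_NAMES: List[str] = (
    [f"count_{aa}" for aa in AMINO_ACIDS]
    + ["mean_hydrophobicity", "mean_charge", "isoelectric_point",
       "charge_window_range", "moment_window_range",
       "logp_octanol", "helical_content"]
)
N_FEATURES = 27


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window settings for the local charge/moment statistics.

    ``width`` residues per window (step 1); ``delta_angle`` is the
    helical-wheel rotation per residue in degrees (100° for an ideal
    alpha helix).
    """

    width: int = 11
    step: int = 1
    delta_angle: float = 100.0

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValueError("window width must be >= 2")
        if self.step < 1:
            raise ValueError("window step must be >= 1")
        if not 0.0 < self.delta_angle < 360.0:
            raise ValueError("delta_angle must be in (0, 360)")


DEFAULT_WINDOW = WindowParams()

SeqLike = Union[str, PeptideRecord]


def _as_seq(seq: SeqLike) -> str:
    if isinstance(seq, PeptideRecord):
        return seq.sequence
    return validate_sequence(seq).sequence


def residue_counts(seq: SeqLike) -> np.ndarray:
    """Counts of each of the 20 amino acids, alphabetical order."""
    s = _as_seq(seq)
    return np.array([s.count(aa) for aa in AMINO_ACIDS], dtype=float)


def mean_hydrophobicity(seq: SeqLike, scales: ScaleSet = DEFAULT_SCALES) -> float:
    s = _as_seq(seq)
    return sum(scales.hydrophobicity[r] for r in s) / len(s)


def net_charge(seq: SeqLike, pH: float = 7.0,
               scales: ScaleSet = DEFAULT_SCALES,
               include_termini: bool = False) -> float:
    """Henderson–Hasselbalch fractional net charge at a given pH.

    Each basic group (H, K, R and optionally the N-terminus) contributes
    ``+1/(1 + 10^(pH - pKa))``; each acidic group (D, E, C, Y and
    optionally the C-terminus) contributes ``-1/(1 + 10^(pKa - pH))``.
    Termini are excluded by default: the peptides this package was built
    around are N-terminally fluorophore-conjugated, which removes the
    free amine.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    s = _as_seq(seq)
    charge = 0.0
    for r in s:
        if r in BASIC_RESIDUES:
            charge += 1.0 / (1.0 + 10.0 ** (pH - scales.pka[r]))
        elif r in ACIDIC_RESIDUES:
            charge -= 1.0 / (1.0 + 10.0 ** (scales.pka[r] - pH))
    if include_termini:
        charge += 1.0 / (1.0 + 10.0 ** (pH - scales.pka_nterm))
        charge -= 1.0 / (1.0 + 10.0 ** (scales.pka_cterm - pH))
    return charge


def mean_charge(seq: SeqLike, scales: ScaleSet = DEFAULT_SCALES,
                pH: float = 7.0, include_termini: bool = False) -> float:
    """Net charge at pH 7 divided by sequence length."""
    s = _as_seq(seq)
    return net_charge(s, pH=pH, scales=scales,
                      include_termini=include_termini) / len(s)


def isoelectric_point(seq: SeqLike, scales: ScaleSet = DEFAULT_SCALES,
                      tol: float = 1e-4, include_termini: bool = False,
                      return_flag: bool = False):
    """pH at which the net charge is zero, by bisection on [0, 14].

    Net charge is monotone non-increasing in pH, so bisection converges
    whenever the charge changes sign over the bracket.  If it does not
    (e.g. a peptide with only basic groups, or none at all), the bracket
    endpoint with the smaller absolute charge is returned and, with
    ``return_flag=True``, a ``degenerate`` flag is set instead of
    raising — featurization must not fail on valid sequences.
    """
    s = _as_seq(seq)

    def f(pH: float) -> float:
        return net_charge(s, pH=pH, scales=scales,
                          include_termini=include_termini)

    lo, hi = 0.0, 14.0
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return (lo, False) if return_flag else lo
    if f_hi == 0.0:
        return (hi, False) if return_flag else hi
    if f_lo * f_hi > 0.0:
        pi = lo if abs(f_lo) <= abs(f_hi) else hi
        return (pi, True) if return_flag else pi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if f_mid == 0.0:
            lo = hi = mid
            break
        if f_lo * f_mid < 0.0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    pi = 0.5 * (lo + hi)
    return (pi, False) if return_flag else pi


def hydrophobic_moment(window_seq: SeqLike, scales: ScaleSet = DEFAULT_SCALES,
                       delta_angle: float = 100.0) -> float:
    """Per-residue Eisenberg hydrophobic moment of a window.

    mu_H = (1/N) * |sum_k h_k * exp(i * k * delta)|, with residue k at
    helical-wheel angle k*delta (delta in degrees).  Measures how
    segregated hydrophobic and hydrophilic faces are around the helix.
    """
    s = _as_seq(window_seq)
    n = len(s)
    if n < 2:
        raise ValueError("hydrophobic moment needs a window of length >= 2")
    delta = math.radians(delta_angle)
    sin_sum = sum(scales.hydrophobicity[r] * math.sin(k * delta)
                  for k, r in enumerate(s))
    cos_sum = sum(scales.hydrophobicity[r] * math.cos(k * delta)
                  for k, r in enumerate(s))
    return math.hypot(sin_sum, cos_sum) / n


def window_range(seq: SeqLike, statistic: str,
                 params: WindowParams = DEFAULT_WINDOW,
                 scales: ScaleSet = DEFAULT_SCALES) -> float:
    """max − min of a statistic over all width-w windows (step 1).

    ``statistic`` is ``"charge"`` (window net charge at pH 7) or
    ``"hydrophobic_moment"``.  A sequence shorter than the window is its
    own single window, for which the range is 0.
    """
    s = _as_seq(seq)
    if statistic == "charge":
        def stat(w: str) -> float:
            return net_charge(w, pH=7.0, scales=scales)
    elif statistic == "hydrophobic_moment":
        def stat(w: str) -> float:
            if len(w) < 2:
                return 0.0
            return hydrophobic_moment(w, scales=scales,
                                      delta_angle=params.delta_angle)
    else:
        raise ValueError(f"unknown window statistic {statistic!r}")

    width = params.width
    if len(s) <= width:
        return 0.0
    values = [stat(s[i:i + width])
              for i in range(0, len(s) - width + 1, params.step)]
    return max(values) - min(values)


def logp_octanol(seq: SeqLike, scales: ScaleSet = DEFAULT_SCALES) -> float:
    """Additive side-chain water/octanol partition coefficient."""
    s = _as_seq(seq)
    return sum(scales.logp_octanol[r] for r in s)


def helical_content(seq: SeqLike, scales: ScaleSet = DEFAULT_SCALES,
                    threshold: float = 1.00, mode: str = "former_fraction") -> float:
    """Approximate alpha-helical content, in [0, 1].

    Default: fraction of residues that are helix formers under the
    Chou–Fasman propensities (P(alpha) >= ``threshold``).  The
    alternative ``mode="mean_rescaled"`` returns the mean propensity
    clipped into [0, 1] after dividing by the table maximum.
    """
    s = _as_seq(seq)
    if mode == "former_fraction":
        formers = sum(1 for r in s if scales.helix_propensity[r] >= threshold)
        return formers / len(s)
    if mode == "mean_rescaled":
        top = max(scales.helix_propensity.values())
        return min(1.0, max(0.0, (sum(scales.helix_propensity[r] for r in s)
                                  / len(s)) / top))
    raise ValueError(f"unknown helical_content mode {mode!r}")


def featurize(seq: SeqLike, scales: ScaleSet = DEFAULT_SCALES,
              params: WindowParams = DEFAULT_WINDOW,
              include_termini: bool = False,
              normalize_counts: bool = False) -> np.ndarray:
    """Full 27-value descriptor vector in the fixed feature order."""
    s = _as_seq(seq)
    counts = residue_counts(s)
    if normalize_counts:
        counts = counts / len(s)
    vec = np.empty(N_FEATURES, dtype=float)
    vec[:20] = counts
    vec[20] = mean_hydrophobicity(s, scales)
    vec[21] = mean_charge(s, scales, include_termini=include_termini)
    vec[22] = isoelectric_point(s, scales, include_termini=include_termini)
    vec[23] = window_range(s, "charge", params, scales)
    vec[24] = window_range(s, "hydrophobic_moment", params, scales)
    vec[25] = logp_octanol(s, scales)
    vec[26] = helical_content(s, scales)
    return vec


def featurize_many(seqs: Iterable[SeqLike], scales: ScaleSet = DEFAULT_SCALES,
                   params: WindowParams = DEFAULT_WINDOW, **kw) -> np.ndarray:
    return np.vstack([featurize(s, scales, params, **kw) for s in seqs])


class PeptideFeaturizer(TransformerMixin, BaseEstimator):
    """scikit-learn transformer: peptide sequences → (n, 27) array.

    Stateless (``fit`` only records the feature names), so it can sit at
    the head of a :class:`sklearn.pipeline.Pipeline` in front of any
    classifier.

    Parameters
    ----------
    scales : ScaleSet
        Per-residue tables; defaults to Eisenberg / EMBOSS /
        Fauchère–Pliška / Chou–Fasman.
    window : WindowParams
        Sliding-window width and helical-wheel angle.
    include_termini : bool
        Include free-termini ionization in charge features.
    normalize_counts : bool
        Report residue frequencies instead of raw counts.
    """

    def __init__(self, scales: ScaleSet = DEFAULT_SCALES,
                 window: WindowParams = DEFAULT_WINDOW,
                 include_termini: bool = False,
                 normalize_counts: bool = False):
        self.scales = scales
        self.window = window
        self.include_termini = include_termini
        self.normalize_counts = normalize_counts

    def fit(self, X: Sequence[SeqLike], y=None) -> "PeptideFeaturizer":
        self.feature_names_ = list(FEATURE_NAMES)
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[SeqLike]) -> np.ndarray:
        return featurize_many(X, self.scales, self.window,
                              include_termini=self.include_termini,
                              normalize_counts=self.normalize_counts)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
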