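"""Classifier-guided moonlighting-peptide design.

Two strategies are supported, both keeping a functional motif intact
while the classifier's consensus probability P(CPP) drives the search:

* **embed_cpp** (targeted strategy) — add residues at the N- and/or
  C-terminus of a ligand motif (e.g. the yeast alpha-pheromone
  WHWLQLKPGQPMY) until the whole peptide is predicted to penetrate
  (P(CPP) at or above a target, 0.88 by default).
* **embed_noncpp** (activation strategy) — add residues, typically an
  acidic C-terminal tail, to a CPP core carrying a protease cleavage
  site (e.g. Tat + FFGFLA for neprilysin) until the construct is
  predicted *not* to penetrate; proteolysis later releases the active
  CPP.

The optimizer is a genetic algorithm over the flank strings only — the
motif is never touched — with an exhaustive enumerator provided as an
oracle for small search spaces.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .records import validate_sequence
from .scales import AMINO_ACIDS

logger = logging.getLogger(__name__)

Scorer = Callable[[str], float]


def as_scorer(model) -> Scorer:
    """Adapt a model to a ``sequence -> P(CPP)`` callable.

    Accepts a plain callable, anything with ``predict_pcpp(seq)``, or a
    fitted sklearn pipeline/classifier with ``predict_proba``.
    """
    if callable(model) and not hasattr(model, "predict_proba"):
        return model
    if hasattr(model, "predict_pcpp"):
        return model.predict_pcpp
    if hasattr(model, "predict_proba"):
        return lambda seq: float(model.predict_proba([seq])[0, 1])
    raise TypeError(f"cannot build a P(CPP) scorer from {type(model)!r}")


@dataclass(frozen=True)
class DesignTask:
    """What to design: the fixed motif, the mode, and the constraints.

    ``mode="embed_cpp"`` maximizes P(CPP) (success when >= ``target_p``);
    ``mode="embed_noncpp"`` minimizes it (success when <= ``target_p``).
    ``placement`` restricts where residues may be added; ``max_added``
    caps the total number of added residues.
    """

    motif: str
    mode: str = "embed_cpp"
    placement: Optional[str] = None
    max_added: int = 12
    alphabet: str = AMINO_ACIDS
    target_p: Optional[float] = None

    def __post_init__(self) -> None:
        validate_sequence(self.motif)
        if self.mode not in ("embed_cpp", "embed_noncpp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        placement = self.placement
        if placement is None:
            # targeted designs flank both ends; activation appends a tail
            placement = ("both_termini" if self.mode == "embed_cpp"
                         else "c_terminal_tail")
            object.__setattr__(self, "placement", placement)
        if placement not in ("both_termini", "c_terminal_tail",
                             "n_terminal_tail"):
            raise ValueError(f"unknown placement {placement!r}")
        if not 0 <= self.max_added <= 30:
            raise ValueError("max_added must be in 0..30")
        for ch in self.alphabet:
            if ch not in AMINO_ACIDS:
                raise ValueError(f"alphabet residue {ch!r} not canonical")
        if self.target_p is None:
            object.__setattr__(
                self, "target_p", 0.88 if self.mode == "embed_cpp" else 0.20)
        if not 0.0 <= self.target_p <= 1.0:
            raise ValueError("target_p must be in [0, 1]")

    def meets_target(self, p: float) -> bool:
        if self.mode == "embed_cpp":
            return p >= self.target_p
        return p <= self.target_p

    def raw_fitness(self, p: float) -> float:
        return p if self.mode == "embed_cpp" else 1.0 - p


@dataclass(frozen=True)
class SearchParams:
    """Genetic-algorithm settings for the flank search."""

    population: int = 64
    generations: int = 200
    mutation_rate: float = 0.1
    insertion_rate: float = 0.15
    deletion_rate: float = 0.05
    elitism: int = 4
    length_penalty: float = 0.01
    tournament: int = 3
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for r in (self.mutation_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.length_penalty < 0:
            raise ValueError("length_penalty must be >= 0")


@dataclass(frozen=True)
class DesignResult:
    """A designed peptide with its score and added-residue bookkeeping."""

    sequence: str
    p_cpp: float
    added_n_term: str
    added_c_term: str
    motif_span: Tuple[int, int]
    success: bool
    penalized_fitness: float

    @property
    def n_added(self) -> int:
        return len(self.added_n_term) + len(self.added_c_term)

    def to_dict(self) -> dict:
        return {"sequence": self.sequence, "p_cpp": self.p_cpp,
                "added_n_term": self.added_n_term,
                "added_c_term": self.added_c_term,
                "n_added": self.n_added,
                "motif_span": list(self.motif_span),
                "success": self.success,
                "penalized_fitness": self.penalized_fitness}


def verify_motif_integrity(design: str, motif: str) -> Tuple[bool, Optional[Tuple[int, int]]]:
    """True iff the motif occurs contiguously; returns the first span."""
    i = design.find(motif)
    if i < 0:
        return False, None
    return True, (i, i + len(motif))


def evaluate_design(n_flank: str, c_flank: str, task: DesignTask,
                    scorer: Scorer, length_penalty: float = 0.0) -> DesignResult:
    """Score one flank assignment.

    The candidate is ``n_flank + motif + c_flank``; flanks that recreate
    a second copy of the motif are invalid (the added residues must not
    duplicate the functional element) and raise ``ValueError``.
    """
    seq = n_flank + task.motif + c_flank
    if seq.count(task.motif) != 1:
        raise ValueError(f"motif occurs {seq.count(task.motif)} times in "
                         f"candidate {seq!r}")
    ok, span = verify_motif_integrity(seq, task.motif)
    assert ok and span is not None
    p = float(scorer(seq))
    n_added = len(n_flank) + len(c_flank)
    raw = task.raw_fitness(p)
    return DesignResult(sequence=seq, p_cpp=p, added_n_term=n_flank,
                        added_c_term=c_flank, motif_span=span,
                        success=task.meets_target(p),
                        penalized_fitness=raw - length_penalty * n_added)


def _rank_key(r: DesignResult) -> tuple:
    # fewest additions first, then best fitness, then lexicographic
    return (r.n_added, -r.penalized_fitness, r.sequence)


def _flank_ok(task: DesignTask, n_flank: str, c_flank: str) -> bool:
    if len(n_flank) + len(c_flank) > task.max_added:
        return False
    if task.placement == "c_terminal_tail" and n_flank:
        return False
    if task.placement == "n_terminal_tail" and c_flank:
        return False
    return True


class _Evaluator:
    """Caching evaluator; silently drops motif-duplicating candidates."""

    def __init__(self, task: DesignTask, scorer: Scorer, length_penalty: float):
        self.task = task
        self.scorer = scorer
        self.length_penalty = length_penalty
        self.cache: dict = {}
        self.n_discarded = 0

    def __call__(self, flanks: Tuple[str, str]) -> Optional[DesignResult]:
        if flanks in self.cache:
            return self.cache[flanks]
        try:
            res = evaluate_design(flanks[0], flanks[1], self.task, self.scorer,
                                  self.length_penalty)
        except ValueError:
            self.n_discarded += 1
            res = None
        self.cache[flanks] = res
        return res


def _mutate(flanks: Tuple[str, str], task: DesignTask, search: SearchParams,
            rng: np.random.Generator) -> Tuple[str, str]:
    alphabet = task.alphabet
    n_flank, c_flank = flanks
    sides = [0, 1]
    if task.placement == "c_terminal_tail":
        sides = [1]
    elif task.placement == "n_terminal_tail":
        sides = [0]
    pair = [n_flank, c_flank]
    # point mutations within flanks
    for s in sides:
        chars = list(pair[s])
        for i in range(len(chars)):
            if rng.random() < search.mutation_rate:
                chars[i] = alphabet[rng.integers(len(alphabet))]
        pair[s] = "".join(chars)
    # single-residue insertion (budget permitting)
    if rng.random() < search.insertion_rate and \
            len(pair[0]) + len(pair[1]) < task.max_added:
        s = sides[rng.integers(len(sides))]
        pos = int(rng.integers(len(pair[s]) + 1))
        ch = alphabet[rng.integers(len(alphabet))]
        pair[s] = pair[s][:pos] + ch + pair[s][pos:]
    # single-residue deletion
    if rng.random() < search.deletion_rate:
        s = sides[rng.integers(len(sides))]
        if pair[s]:
            pos = int(rng.integers(len(pair[s])))
            pair[s] = pair[s][:pos] + pair[s][pos + 1:]
    return pair[0], pair[1]


def _random_flanks(task: DesignTask, rng: np.random.Generator,
                   max_len: Optional[int] = None) -> Tuple[str, str]:
    # seeding across the whole added-residue budget lets the search reach
    # optima that need many additions without waiting on single insertions
    cap = task.max_added if max_len is None else min(max_len, task.max_added)
    total = int(rng.integers(0, cap + 1))
    if task.placement == "c_terminal_tail":
        n_len = 0
    elif task.placement == "n_terminal_tail":
        n_len = total
    else:
        n_len = int(rng.integers(0, total + 1))
    letters = [task.alphabet[rng.integers(len(task.alphabet))]
               for _ in range(total)]
    return "".join(letters[:n_len]), "".join(letters[n_len:])


def design(task: DesignTask, model, search: SearchParams = SearchParams()
           ) -> List[DesignResult]:
    """Genetic search for flank strings optimizing the task objective.

    The genome is the (N-flank, C-flank) pair; the motif itself is never
    modified.  Selection is tournament on length-penalized fitness with
    elitism.  Returns every distinct evaluated design that meets
    ``target_p``, sorted by (fewest added residues, best fitness,
    sequence); if none succeeds, the single best design is returned with
    ``success=False``.
    """
    scorer = as_scorer(model)
    rng = np.random.default_rng(search.seed)
    evaluate = _Evaluator(task, scorer, search.length_penalty)

    population: List[Tuple[str, str]] = [("", "")]
    while len(population) < search.population:
        population.append(_random_flanks(task, rng))

    def fitness(flanks: Tuple[str, str]) -> float:
        res = evaluate(flanks)
        return -np.inf if res is None else res.penalized_fitness

    for _ in range(search.generations):
        scored = [(fitness(f), f) for f in population]
        # deterministic elite ordering: fitness desc, then rank key
        elite = sorted(
            scored,
            key=lambda t: (-t[0],) + (() if evaluate(t[1]) is None
                                      else _rank_key(evaluate(t[1]))),
        )[:search.elitism]
        next_pop = [f for _, f in elite]
        while len(next_pop) < search.population:
            # tournament selection
            idx = rng.integers(0, len(population), size=search.tournament)
            winner = max((scored[i] for i in idx), key=lambda t: t[0])[1]
            child = _mutate(winner, task, search, rng)
            if _flank_ok(task, *child):
                next_pop.append(child)
            else:
                next_pop.append(winner)
        population = next_pop

    results = [r for r in evaluate.cache.values() if r is not None]
    if evaluate.n_discarded:
        logger.info("discarded %d motif-duplicating candidates",
                    evaluate.n_discarded)
    successes = sorted((r for r in results if r.success), key=_rank_key)
    if successes:
        return successes
    return [min(results, key=_rank_by_fitness)] if results else []


def exhaustive_design(task: DesignTask, model,
                      max_total_flank: Optional[int] = None,
                      length_penalty: float = 0.01,
                      guard: int = 10 ** 6) -> DesignResult:
    """Enumerate every flank assignment up to the cap; the GA's oracle.

    Returns the argmax of penalized fitness under the same tie-breaking
    as :func:`design` (fewest additions, then fitness, then sequence).
    Raises if the candidate count exceeds ``guard``.
    """
    scorer = as_scorer(model)
    cap = task.max_added if max_total_flank is None else max_total_flank
    a = len(task.alphabet)
    n_candidates = sum((t + 1) * a ** t for t in range(cap + 1))
    if n_candidates > guard:
        raise ValueError(
            f"{n_candidates} candidates exceeds the {guard} guard; "
            "shrink the alphabet or the flank cap")
    best: Optional[DesignResult] = None
    for total in range(cap + 1):
        for n_len in range(total + 1):
            c_len = total - n_len
            if task.placement == "c_terminal_tail" and n_len:
                continue
            if task.placement == "n_terminal_tail" and c_len:
                continue
            for n_flank in map("".join, itertools.product(task.alphabet,
                                                          repeat=n_len)):
                for c_flank in map("".join, itertools.product(task.alphabet,
                                                              repeat=c_len)):
                    try:
                        res = evaluate_design(n_flank, c_flank, task, scorer,
                                              length_penalty)
                    except ValueError:
                        continue
                    if best is None or _rank_by_fitness(res) < _rank_by_fitness(best):
                        best = res
    assert best is not None
    return best


def _rank_by_fitness(r: DesignResult) -> tuple:
    # optimum = best penalized fitness; ties to fewer additions, then lex
    return (-r.penalized_fitness, r.n_added, r.sequence)


def cleave(design_seq: str, site: str = "FFGFLA", cut_after: int = 3
           ) -> Tuple[str, str]:
    """Cut a designed peptide at a protease recognition site.

    ``cut_after`` is the 1-based position within the site after which the
    scissile bond lies; neprilysin cuts FFGFLA after the G (position 3),
    so Tat+FFGFLA+tail releases the active fragment ending in ...FFG.
    Returns (N-terminal fragment, C-terminal fragment).
    """
    i = design_seq.find(site)
    if i < 0:
        raise ValueError(f"cleavage site {site!r} not found")
    if not 1 <= cut_after < len(site):
        raise ValueError("cut_after must be inside the site")
    cut = i + cut_after
    return design_seq[:cut], design_seq[cut:]
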