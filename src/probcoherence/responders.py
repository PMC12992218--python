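"""Synthetic responders: generative models of probability judgment.

Three generative regimes produce complete response sets over a battery:

* :func:`coherent_respond` — a normative classical agent.  Latent beliefs are
  a probability measure over the 8 joint outcomes (which candidate wins each
  of the 3 states); every item is answered with the exact classical
  probability of its event.  All coherence scores are zero by construction.

* :func:`bayesian_sampler_respond` — the Bayesian sampler: probability
  reports arise from counting successes in a finite number of memory samples
  and regularizing with a symmetric Beta(beta, beta) prior.  An item with
  true probability ``p`` is answered ``(S + beta) / (N + 2 beta)`` with
  ``S ~ Binomial(N, p)``, where composites receive fewer samples than
  marginals (``n_compound <= n_marginal``).  Small compound samples pull
  judgments toward 1/2, producing conjunction/disjunction fallacies —
  including double fallacies — and complementarity violations.

* :func:`quantum_respond` — a noise-free sequential quantum judge in a
  two-dimensional real Hilbert space: the belief state is a ray at angle
  ``psi`` and each atomic event a projector ray, with the negated event on
  the orthogonal ray (+90 deg).  Marginals are squared projections,
  ``cos^2(psi - theta)``; a conjunction is evaluated sequentially,
  ``P(X then Y) = cos^2(psi - theta_X) * cos^2(theta_X - theta_Y)``, with the
  first event chosen by the *more-likely-first* rule (evaluate the
  subjectively more probable event first).  Disjunctions follow by De Morgan
  on the complements.  Because a sequential product can never exceed its
  first factor, this model permits single conjunction/disjunction fallacies
  but strictly forbids double ones, and it satisfies binary complementarity
  exactly — while systematically inflating the four-term joint conjunction
  sum above 1 (see docs/methods.md).

All responders are deterministic given their seed and return unrounded
probabilities; rounding to 0-100 integers happens at the harness boundary so
the analytic invariants above hold exactly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .battery import (
    TRIPLETS,
    Battery,
    Candidate,
    ConfigurationError,
    EventAtom,
    ItemKind,
)
from .scoring import ResponseSet

__all__ = [
    "LatentWorld",
    "SamplerConfig",
    "QuantumConfig",
    "uniform_world",
    "random_world",
    "make_persona_worlds",
    "coherent_respond",
    "bayesian_sampler_respond",
    "quantum_respond",
    "sample_quantum_configs",
    "coherent_responder",
    "sampler_responder",
    "quantum_responder",
]

Outcome = tuple[str, str, str]  # winner role ("A"/"B") per state, in triplet order

#: Resolution of the dyadic grid used for random worlds.  Probabilities are
#: integer multiples of 2**-30, hence exactly representable in binary floating
#: point; subset sums and complements are then exact, so a coherent responder
#: scores identically zero rather than zero-up-to-rounding.
DYADIC_RESOLUTION = 2**30


@dataclass(frozen=True)
class LatentWorld:
    """Classical belief state: a measure over the 8 joint election outcomes."""

    triplet: str
    outcome_probs: Mapping[Outcome, float]

    def __post_init__(self) -> None:
        if self.triplet not in TRIPLETS:
            raise ConfigurationError(f"unknown triplet {self.triplet!r}")
        expected = set(itertools.product("AB", repeat=3))
        keys = set(self.outcome_probs)
        if keys != expected:
            raise ConfigurationError("outcome_probs must cover all 8 candidate assignments")
        probs = list(self.outcome_probs.values())
        if any(p < 0 for p in probs):
            raise ConfigurationError("outcome probabilities must be nonnegative")
        total = math.fsum(probs)
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(f"outcome probabilities sum to {total}, not 1")

    @property
    def states(self) -> tuple[str, str, str]:
        return TRIPLETS[self.triplet]

    def _atom_holds(self, outcome: Outcome, atom: EventAtom) -> bool:
        return outcome[self.states.index(atom.state)] == atom.candidate.value

    def event_prob(self, atoms: Iterable[EventAtom]) -> float:
        """P(all atoms hold): exact subset sum over joint outcomes."""
        atoms = tuple(atoms)
        return math.fsum(
            p for outcome, p in self.outcome_probs.items()
            if all(self._atom_holds(outcome, a) for a in atoms)
        )

    def union_prob(self, a: EventAtom, b: EventAtom) -> float:
        """P(a or b), summed directly over outcomes for exactness."""
        return math.fsum(
            p for outcome, p in self.outcome_probs.items()
            if self._atom_holds(outcome, a) or self._atom_holds(outcome, b)
        )


def uniform_world(triplet: str) -> LatentWorld:
    probs = {o: 0.125 for o in itertools.product("AB", repeat=3)}
    return LatentWorld(triplet=triplet, outcome_probs=probs)


def world_from_weights(triplet: str, weights: Sequence[float]) -> LatentWorld:
    """Normalize 8 nonnegative weights (triplet-order A/B product keys)."""
    outcomes = list(itertools.product("AB", repeat=3))
    if len(weights) != 8:
        raise ConfigurationError("need exactly 8 outcome weights")
    total = math.fsum(weights)
    if total <= 0:
        raise ConfigurationError("weights must have positive total")
    return LatentWorld(triplet=triplet,
                       outcome_probs={o: w / total for o, w in zip(outcomes, weights)})


def random_world(triplet: str, seed: int | np.random.Generator = 0) -> LatentWorld:
    """Draw a random belief state on the dyadic grid.

    Outcome masses are a multinomial composition of ``DYADIC_RESOLUTION``
    grains over the 8 outcomes, divided by the (power-of-two) resolution, so
    every probability and every event subset sum is exact in floating point.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(DYADIC_RESOLUTION, [0.125] * 8)
    outcomes = list(itertools.product("AB", repeat=3))
    probs = {o: int(c) / DYADIC_RESOLUTION for o, c in zip(outcomes, counts)}
    return LatentWorld(triplet=triplet, outcome_probs=probs)


def make_persona_worlds(personas: Sequence, base_world: LatentWorld,
                        heterogeneity: float, seed: int = 0) -> list[LatentWorld]:
    """One belief state per persona, by jittering the base outcome log-weights.

    Zero-mean Gaussian noise of scale ``heterogeneity`` is added to the log
    of each outcome mass before renormalizing; ``heterogeneity = 0``
    reproduces the base world exactly.  Outcomes with zero base mass stay at
    zero.
    """
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be nonnegative")
    n = len(personas)
    if heterogeneity == 0:
        return [base_world] * n
    rng = np.random.default_rng(seed)
    outcomes = list(itertools.product("AB", repeat=3))
    base = np.array([base_world.outcome_probs[o] for o in outcomes])
    worlds = []
    with np.errstate(divide="ignore"):
        logw = np.log(base)
    for _ in range(n):
        w = np.exp(logw + rng.normal(0.0, heterogeneity, size=8))
        w[base == 0] = 0.0
        worlds.append(world_from_weights(base_world.triplet, w))
    return worlds


def _check_triplet(world: LatentWorld, battery: Battery) -> None:
    if world.triplet != battery.triplet:
        raise ConfigurationError(
            f"world triplet {world.triplet!r} does not match battery triplet {battery.triplet!r}"
        )


def _classical_item_prob(world: LatentWorld, item) -> Optional[float]:
    """True classical probability of an item's event; None if undefined."""
    if item.kind is ItemKind.MARGINAL:
        return world.event_prob([item.first])
    if item.kind is ItemKind.CONJUNCTION:
        return world.event_prob([item.first, item.second])
    if item.kind is ItemKind.DISJUNCTION:
        return world.union_prob(item.first, item.second)
    # conditional: P(first | second), undefined on a zero-probability condition
    p_cond = world.event_prob([item.second])
    if p_cond == 0.0:
        return None
    return world.event_prob([item.first, item.second]) / p_cond


def coherent_respond(world: LatentWorld, battery: Battery,
                     persona_id: str = "coherent") -> ResponseSet:
    """Answer every item with its exact classical probability.

    Conditionals use Bayes' rule; a conditional whose conditioning event has
    zero probability is skipped and flagged.  No rounding is applied, so all
    coherence scores of the output are exactly zero.
    """
    _check_triplet(world, battery)
    values: dict[str, float] = {}
    flagged: set[str] = set()
    for item in battery.items:
        p = _classical_item_prob(world, item)
        if p is None:
            flagged.add(item.item_id)
        else:
            values[item.item_id] = p
    return ResponseSet(persona_id=persona_id, triplet=battery.triplet,
                       values=values, flagged=flagged)


@dataclass(frozen=True)
class SamplerConfig:
    """Bayesian-sampler parameters.

    ``n_marginal`` / ``n_compound`` are the memory sample counts for marginal
    and composite items; the model's central biasing assumption is
    ``n_compound <= n_marginal``.  ``beta`` is the symmetric Beta prior
    parameter.  Defaults (18 marginal samples, 5 compound samples, beta = 1)
    give the pronounced human-like fallacy pattern at small samples.
    """

    n_marginal: int = 18
    n_compound: int = 5
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_marginal <= 0 or self.n_compound <= 0:
            raise ConfigurationError("sample counts must be positive")
        if self.n_compound > self.n_marginal:
            raise ConfigurationError("n_compound must not exceed n_marginal")
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")


def bayesian_sampler_respond(world: LatentWorld, battery: Battery,
                             cfg: SamplerConfig,
                             persona_id: str = "sampler") -> ResponseSet:
    """Finite-sample Beta-regularized probability reports.

    For each item with true classical probability ``p`` the responder draws
    ``S ~ Binomial(N, p)`` (one independent draw per item) and reports
    ``(S + beta) / (N + 2 beta)``, with ``N = n_marginal`` for marginals and
    ``N = n_compound`` for conjunctions, disjunctions, and conditionals.
    """
    _check_triplet(world, battery)
    rng = np.random.default_rng(cfg.seed)
    values: dict[str, float] = {}
    flagged: set[str] = set()
    for item in battery.items:
        p = _classical_item_prob(world, item)
        if p is None:
            flagged.add(item.item_id)
            continue
        n = cfg.n_marginal if item.kind is ItemKind.MARGINAL else cfg.n_compound
        s = int(rng.binomial(n, p))
        values[item.item_id] = (s + cfg.beta) / (n + 2.0 * cfg.beta)
    return ResponseSet(persona_id=persona_id, triplet=battery.triplet,
                       values=values, flagged=flagged)


ORDERINGS = ("more_likely_first", "as_presented")


@dataclass(frozen=True)
class QuantumConfig:
    """Two-dimensional sequential quantum judge.

    ``psi`` is the belief-state ray angle in degrees.  ``theta`` maps each
    state name to the projector-ray angle of the candidate-A event for that
    state; the candidate-B (negated) event lies on the orthogonal ray at
    ``theta + 90``.  Angles are reduced mod 180 (rays, not directions).
    ``ordering`` selects which constituent of a composite is evaluated first:
    ``more_likely_first`` picks the event with the larger marginal (ties go
    to the presented order); ``as_presented`` keeps the presentation order.
    """

    psi: float
    theta: Mapping[str, float]
    ordering: str = "more_likely_first"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ordering not in ORDERINGS:
            raise ConfigurationError(
                f"ordering must be one of {ORDERINGS}, got {self.ordering!r}"
            )

    def angle(self, atom: EventAtom) -> float:
        if atom.state not in self.theta:
            raise ConfigurationError(f"no projector angle configured for state {atom.state!r}")
        base = self.theta[atom.state]
        if atom.candidate is Candidate.B:
            base += 90.0
        return base % 180.0


def _cos2(degrees: float) -> float:
    c = math.cos(math.radians(degrees))
    return c * c


def quantum_respond(cfg: QuantumConfig, battery: Battery,
                    persona_id: str = "quantum") -> ResponseSet:
    """Sequential projective judgments in the two-dimensional model.

    Marginal: ``P(E) = cos^2(psi - theta_E)``.  Conjunction, with first
    event X chosen by the ordering rule:
    ``P(X and Y) = cos^2(psi - theta_X) * cos^2(theta_X - theta_Y)``.
    Disjunction by De Morgan on the complements, with the ordering rule
    applied to the complements.  Conditional:
    ``P(first | second) = cos^2(theta_second - theta_first)``.

    In exact arithmetic a sequential conjunction never exceeds its first
    factor, hence never exceeds the larger constituent marginal, and (by De
    Morgan) a disjunction never falls below the smaller constituent.  Both
    bounds are theorems of the model, so they are enforced numerically
    (clamping away sub-1e-15 roundoff from the trigonometric products) to
    keep the no-double-fallacy invariant exact rather than
    exact-up-to-epsilon.
    """

    def marginal(atom: EventAtom) -> float:
        return _cos2(cfg.psi - cfg.angle(atom))

    def seq_conjunction(x: EventAtom, y: EventAtom) -> float:
        if cfg.ordering == "more_likely_first" and marginal(y) > marginal(x):
            x, y = y, x
        return marginal(x) * _cos2(cfg.angle(x) - cfg.angle(y))

    values: dict[str, float] = {}
    for item in battery.items:
        if item.kind is ItemKind.MARGINAL:
            v = marginal(item.first)
        elif item.kind is ItemKind.CONJUNCTION:
            v = seq_conjunction(item.first, item.second)
            v = min(v, max(marginal(item.first), marginal(item.second)))
        elif item.kind is ItemKind.DISJUNCTION:
            v = 1.0 - seq_conjunction(item.first.negation(), item.second.negation())
            v = max(v, min(marginal(item.first), marginal(item.second)))
        else:
            v = _cos2(cfg.angle(item.second) - cfg.angle(item.first))
        values[item.item_id] = min(max(v, 0.0), 1.0)
    return ResponseSet(persona_id=persona_id, triplet=battery.triplet, values=values)


def sample_quantum_configs(n: int, triplet: str, seed: int = 0,
                           ordering: str = "more_likely_first") -> list[QuantumConfig]:
    """Draw ``n`` quantum configurations with uniformly random ray angles.

    ``psi`` and each state's candidate-A projector angle are independent
    uniform draws on [0, 180); this sweeps the model's full parameter space
    and is used for population-level signature checks (fallacy prevalence,
    CF-DF coupling).
    """
    rng = np.random.default_rng(seed)
    states = TRIPLETS[triplet]
    configs = []
    for _ in range(n):
        psi = float(rng.uniform(0.0, 180.0))
        theta = {s: float(rng.uniform(0.0, 180.0)) for s in states}
        configs.append(QuantumConfig(psi=psi, theta=theta, ordering=ordering))
    return configs


# ---------------------------------------------------------------------------
# Responder contract adapters: (persona, battery, seed) -> ResponseSet.
# External chat backends implement the same contract via the harness.
# ---------------------------------------------------------------------------

Responder = Callable[[object, Battery, int], ResponseSet]


def _resolve(per_persona, persona):
    if callable(per_persona):
        return per_persona(persona)
    if isinstance(per_persona, Mapping):
        return per_persona[persona.persona_id]
    return per_persona


def coherent_responder(world_for) -> Responder:
    """Wrap a world (or persona_id -> world mapping) as a cohort responder."""

    def respond(persona, battery: Battery, seed: int) -> ResponseSet:
        world = _resolve(world_for, persona)
        return coherent_respond(world, battery, persona_id=persona.persona_id)

    return respond


def sampler_responder(world_for, cfg: SamplerConfig = SamplerConfig()) -> Responder:
    """Bayesian-sampler cohort responder; the per-call seed replaces cfg.seed."""

    def respond(persona, battery: Battery, seed: int) -> ResponseSet:
        world = _resolve(world_for, persona)
        return bayesian_sampler_respond(world, battery, replace(cfg, seed=seed),
                                        persona_id=persona.persona_id)

    return respond


def quantum_responder(cfg_for) -> Responder:
    """Wrap a QuantumConfig (or persona_id -> config mapping) as a responder."""

    def respond(persona, battery: Battery, seed: int) -> ResponseSet:
        cfg = _resolve(cfg_for, persona)
        return quantum_respond(cfg, battery, persona_id=persona.persona_id)

    return respond
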