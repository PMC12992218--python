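"""Item battery for the election probability-judgment task.

A participant (human or simulated) judges the likelihood that each of two
candidates wins each of three U.S. states, plus every two-state composite of
those events.  One battery covers a single *state triplet* and comprises 78
items:

* 6 marginals            — candidate c wins state s (2 candidates x 3 states),
* 12 conjunctions        — "X and Y" over two different states,
* 12 disjunctions        — "X or Y",
* 12 conditionals        — "X given Y",
* 36 reversed composites — every composite repeated with its two constituent
  events presented in the opposite order, to counterbalance order effects.

Marginals are always elicited first (to avoid anchoring on composites); the
remaining items are grouped into low-complexity thematic blocks, one block per
(state pair, composite kind).  Block order and within-block item order are
seeded permutations, so a battery is fully reproducible from
``(triplet, candidate_labels, seed)``.
"""

from __future__ import annotations

import enum
import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TRIPLETS",
    "DEFAULT_CANDIDATE_LABELS",
    "Candidate",
    "ItemKind",
    "EventAtom",
    "JudgmentItem",
    "Battery",
    "ConfigurationError",
    "build_battery",
    "render_prompt",
]

#: The two between-subject state triplets of the judgment study.
TRIPLETS: dict[str, tuple[str, str, str]] = {
    "T1": ("Ohio", "Missouri", "Michigan"),
    "T2": ("Georgia", "Montana", "Nevada"),
}

#: Default candidate labels (the 2020 framing).  Overridable, e.g. with
#: ("the Republican candidate", "the Democratic candidate") for a hypothetical
#: future-election framing.
DEFAULT_CANDIDATE_LABELS: tuple[str, str] = ("Trump", "Biden")


class ConfigurationError(ValueError):
    """Raised for an unknown triplet, bad labels, or an incomplete config."""


class Candidate(str, enum.Enum):
    """Role of a candidate in the two-candidate race.

    ``A`` carries the first configured label (default "Trump"), ``B`` the
    second (default "Biden").  With exactly two candidates, negating
    "A wins s" yields "B wins s".
    """

    A = "A"
    B = "B"

    def other(self) -> "Candidate":
        return Candidate.B if self is Candidate.A else Candidate.A


class ItemKind(str, enum.Enum):
    MARGINAL = "marginal"
    CONJUNCTION = "conjunction"
    DISJUNCTION = "disjunction"
    CONDITIONAL = "conditional"


COMPOSITE_KINDS = (ItemKind.CONJUNCTION, ItemKind.DISJUNCTION, ItemKind.CONDITIONAL)


@dataclass(frozen=True)
class EventAtom:
    """Atomic proposition: ``candidate`` wins ``state``."""

    candidate: Candidate
    state: str

    def negation(self) -> "EventAtom":
        """The complementary event: the other candidate wins the same state."""
        return EventAtom(self.candidate.other(), self.state)

    def describe(self, candidate_labels: tuple[str, str] = DEFAULT_CANDIDATE_LABELS) -> str:
        label = candidate_labels[0] if self.candidate is Candidate.A else candidate_labels[1]
        return f"{label} wins {self.state}"


@dataclass(frozen=True)
class JudgmentItem:
    """One elicited question.

    ``second`` is ``None`` exactly for marginals.  For a reversed composite,
    ``first``/``second`` are already swapped relative to its unreversed twin,
    so rendering always mentions ``first`` before ``second``.
    """

    item_id: str
    kind: ItemKind
    first: EventAtom
    second: Optional[EventAtom]
    reversed: bool
    block_id: str
    position: int
    prompt_text: str

    def __post_init__(self) -> None:
        if self.kind is ItemKind.MARGINAL:
            if self.second is not None or self.reversed:
                raise ConfigurationError("marginal items carry a single unreversed event")
        else:
            if self.second is None:
                raise ConfigurationError(f"{self.kind.value} item needs two events")
            if self.first.state == self.second.state:
                raise ConfigurationError("composite events must concern two different states")

    @property
    def atoms(self) -> tuple[EventAtom, ...]:
        return (self.first,) if self.second is None else (self.first, self.second)


def _event_phrase(item_kind: ItemKind, first: EventAtom, second: Optional[EventAtom],
                  labels: tuple[str, str]) -> str:
    if item_kind is ItemKind.MARGINAL:
        return first.describe(labels)
    assert second is not None
    connective = {
        ItemKind.CONJUNCTION: "and",
        ItemKind.DISJUNCTION: "or",
        ItemKind.CONDITIONAL: "given",
    }[item_kind]
    return f"{first.describe(labels)} {connective} {second.describe(labels)}"


def render_prompt(item: JudgmentItem,
                  candidate_labels: tuple[str, str] = DEFAULT_CANDIDATE_LABELS) -> str:
    """Render the natural-language question for one item.

    Conjunctions use "and", disjunctions "or", conditionals "given"; the
    question asks for a likelihood on the 0-100 scale and a single-integer
    reply.  Reversed items mention their (already swapped) first event first.
    """
    return render_prompt_raw(item.kind, item.first, item.second, candidate_labels)


def _item_id(kind: ItemKind, first: EventAtom, second: Optional[EventAtom]) -> str:
    parts = [kind.value, f"{first.candidate.value}:{first.state}"]
    if second is not None:
        parts.append(f"{second.candidate.value}:{second.state}")
    return "|".join(parts)


@dataclass(frozen=True)
class Battery:
    """A complete, ordered 78-item battery for one state triplet."""

    triplet: str
    candidate_labels: tuple[str, str]
    seed: int
    items: tuple[JudgmentItem, ...]
    block_order: tuple[str, ...]

    @property
    def states(self) -> tuple[str, str, str]:
        return TRIPLETS[self.triplet]

    def items_of_kind(self, kind: ItemKind) -> list[JudgmentItem]:
        return [it for it in self.items if it.kind is kind]

    def item_by_id(self, item_id: str) -> JudgmentItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def marginal_ids(self) -> dict[EventAtom, str]:
        """Map each atomic event to the item id of its marginal question."""
        return {it.first: it.item_id for it in self.items_of_kind(ItemKind.MARGINAL)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for it in self.items:
            rows.append(
                {
                    "item_id": it.item_id,
                    "kind": it.kind.value,
                    "candidate1": it.first.candidate.value,
                    "state1": it.first.state,
                    "candidate2": it.second.candidate.value if it.second else "",
                    "state2": it.second.state if it.second else "",
                    "reversed": it.reversed,
                    "block_id": it.block_id,
                    "position": it.position,
                    "prompt_text": it.prompt_text,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "triplet": self.triplet,
            "candidate_labels": list(self.candidate_labels),
            "seed": self.seed,
            "block_order": list(self.block_order),
            "items": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _shuffled(rng: np.random.Generator, seq: list) -> list:
    order = rng.permutation(len(seq))
    return [seq[i] for i in order]


def build_battery(triplet: str,
                  candidate_labels: tuple[str, str] = DEFAULT_CANDIDATE_LABELS,
                  seed: int = 0) -> Battery:
    """Construct the 78-item battery for one triplet, deterministically.

    For each of the three unordered state pairs, all four candidate sign
    combinations are enumerated for conjunctions, disjunctions, and
    conditionals, and every composite is duplicated with the constituent
    order reversed.  Marginals occupy a single leading block; composite
    blocks (one per state pair x kind) follow in seeded random order, with
    item order shuffled within every block.
    """
    if triplet not in TRIPLETS:
        raise ConfigurationError(f"unknown triplet {triplet!r}; expected one of {sorted(TRIPLETS)}")
    a_label, b_label = candidate_labels
    if not a_label or not b_label or a_label == b_label:
        raise ConfigurationError("candidate labels must be distinct and non-empty")

    states = TRIPLETS[triplet]
    rng = np.random.default_rng(seed)

    # Leading marginal block.
    marginal_specs = [
        (ItemKind.MARGINAL, EventAtom(cand, state), None, False)
        for state in states
        for cand in (Candidate.A, Candidate.B)
    ]
    blocks: list[tuple[str, list]] = [("marginals", _shuffled(rng, marginal_specs))]

    composite_blocks: list[tuple[str, list]] = []
    for s1, s2 in itertools.combinations(states, 2):
        for kind in COMPOSITE_KINDS:
            members = []
            for c1 in (Candidate.A, Candidate.B):
                for c2 in (Candidate.A, Candidate.B):
                    fwd_first, fwd_second = EventAtom(c1, s1), EventAtom(c2, s2)
                    members.append((kind, fwd_first, fwd_second, False))
                    members.append((kind, fwd_second, fwd_first, True))
            composite_blocks.append((f"{kind.value}:{s1}-{s2}", _shuffled(rng, members)))
    blocks.extend(_shuffled(rng, composite_blocks))

    items: list[JudgmentItem] = []
    position = 0
    for block_id, members in blocks:
        for kind, first, second, is_rev in members:
            items.append(
                JudgmentItem(
                    item_id=_item_id(kind, first, second),
                    kind=kind,
                    first=first,
                    second=second,
                    reversed=is_rev,
                    block_id=block_id,
                    position=position,
                    prompt_text=render_prompt_raw(kind, first, second, candidate_labels),
                )
            )
            position += 1

    return Battery(
        triplet=triplet,
        candidate_labels=tuple(candidate_labels),
        seed=seed,
        items=tuple(items),
        block_order=tuple(block_id for block_id, _ in blocks),
    )


def render_prompt_raw(kind: ItemKind, first: EventAtom, second: Optional[EventAtom],
                      candidate_labels: tuple[str, str]) -> str:
    phrase = _event_phrase(kind, first, second, candidate_labels)
    return (
        f"On a scale from 0 to 100, how likely is it that {phrase}? "
        "Respond with a single integer between 0 and 100."
    )
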