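"""Persona-matched elicitation sessions with a bounded sliding memory window.

A session initializes a chat backend with a one-sentence demographic persona
prompt plus the task instructions, then issues the 78 battery items one at a
time.  Before each query the visible context is exactly the initialization
exchange (persona prompt and the backend's acknowledgment) plus the most
recent ``window_pairs`` question-answer pairs — all earlier interactions are
dropped, emulating a bounded working memory (7 pairs by default).  Replies
are parsed as single integers 0-100; a failed parse is retried with the same
prompt and recorded as missing after the retry budget is exhausted.

Backends are pluggable: any object with ``reply(messages) -> str`` works.
:class:`ScriptedBackend` supports deterministic mocks, and
:class:`ResponseSetBackend` turns a synthetic responder's response set into a
chat backend (rounding to integers at this boundary), so the whole protocol
is testable without any live model.  A live-API adapter only has to
implement the same one-method contract; sampling settings (e.g. temperature)
are adapter configuration.
"""

from __future__ import annotations

import json
import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .battery import DEFAULT_CANDIDATE_LABELS, Battery, build_battery
from .scoring import ResponseSet

__all__ = [
    "EDUCATION_LEVELS",
    "US_STATES",
    "DEFAULT_INSTRUCTIONS",
    "Persona",
    "TranscriptRecord",
    "SessionTranscript",
    "CohortArchive",
    "ChatBackend",
    "ScriptedBackend",
    "ResponseSetBackend",
    "build_persona_prompt",
    "parse_reply",
    "run_session",
    "run_cohort",
    "synthetic_personas",
    "personas_from_frame",
    "load_personas",
    "save_transcripts_jsonl",
    "load_transcripts_jsonl",
]

#: The four-level education coding used for persona demographics.
EDUCATION_LEVELS = (
    "high school or less",
    "some college",
    "bachelor's degree",
    "postgraduate education",
)

_EDUCATION_PHRASES = {
    "high school or less": "a high school education or less",
    "some college": "some college education",
    "bachelor's degree": "a bachelor's degree",
    "postgraduate education": "postgraduate education",
}

US_STATES = (
    "Alabama", "Alaska", "Arizona", "Arkansas", "California", "Colorado",
    "Connecticut", "Delaware", "Florida", "Georgia", "Hawaii", "Idaho",
    "Illinois", "Indiana", "Iowa", "Kansas", "Kentucky", "Louisiana", "Maine",
    "Maryland", "Massachusetts", "Michigan", "Minnesota", "Mississippi",
    "Missouri", "Montana", "Nebraska", "Nevada", "New Hampshire", "New Jersey",
    "New Mexico", "New York", "North Carolina", "North Dakota", "Ohio",
    "Oklahoma", "Oregon", "Pennsylvania", "Rhode Island", "South Carolina",
    "South Dakota", "Tennessee", "Texas", "Utah", "Vermont", "Virginia",
    "Washington", "West Virginia", "Wisconsin", "Wyoming",
)

# Reconstructed task instructions.  The three directives given to the human
# participants are known — intuitive first-impression estimates, a single
# integer 0-100 per item, and answering as if the election outcome were not
# yet known — the surrounding wording here is this package's own.
DEFAULT_INSTRUCTIONS = (
    "You will be asked a series of questions about the outcome of the U.S. "
    "presidential election. For each question, give your intuitive, "
    "first-impression estimate of how likely the event is. Respond with a "
    "single integer between 0 and 100, where 0 means impossible and 100 "
    "means certain. Answer as if the outcome of the election were not yet "
    "known. Do not explain your answers."
)


@dataclass(frozen=True)
class Persona:
    """Demographic profile conditioning one session.

    Personas differ only in demographics — no psychological or behavioural
    descriptors — so matched cohorts isolate the demographic manipulation.
    """

    persona_id: str
    age: int
    gender: str
    education: str
    state: str

    def __post_init__(self) -> None:
        if not self.persona_id:
            raise ValueError("persona_id must be non-empty")
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not self.gender:
            raise ValueError("gender must be non-empty")
        if self.education not in EDUCATION_LEVELS:
            raise ValueError(
                f"education {self.education!r} not in {EDUCATION_LEVELS}"
            )
        if not self.state:
            raise ValueError("state of residence must be non-empty")


def build_persona_prompt(p: Persona, instructions: str = DEFAULT_INSTRUCTIONS) -> str:
    """One descriptive persona sentence followed by the task instructions.

    Example: ``You are a 54-year-old female with a bachelor's degree living
    in Ohio.`` — the fixed template inserts only the four demographic fields.
    """
    sentence = (
        f"You are a {p.age}-year-old {p.gender} with "
        f"{_EDUCATION_PHRASES[p.education]} living in {p.state}."
    )
    return f"{sentence}\n\n{instructions}"


_REPLY_RE = re.compile(r"^\s*(\d{1,3})\s*%?\s*$")


def parse_reply(raw: str) -> Optional[int]:
    """Parse a reply as a single integer 0-100, or ``None`` on failure.

    Accepts an integer token optionally surrounded by whitespace or followed
    by a percent sign; rejects multiple numbers, out-of-range values, and
    non-numeric text (rejection signals a retry).
    """
    m = _REPLY_RE.match(raw)
    if not m:
        return None
    value = int(m.group(1))
    if value > 100:
        return None
    return value


@dataclass(frozen=True)
class TranscriptRecord:
    item_id: str
    prompt_text: str
    raw_reply: str
    parsed_value: Optional[int]
    context_size_at_query: int


@dataclass
class SessionTranscript:
    """Archived record of one persona's full 78-item session."""

    persona_id: str
    triplet: str
    battery_seed: int
    window_pairs: int
    records: list[TranscriptRecord] = field(default_factory=list)

    @property
    def missing_count(self) -> int:
        return sum(1 for r in self.records if r.parsed_value is None)

    @property
    def flagged(self) -> bool:
        """True when more than 10% of items failed to parse."""
        return bool(self.records) and self.missing_count / len(self.records) > 0.10

    def to_response_set(self) -> ResponseSet:
        raw = {r.item_id: r.parsed_value for r in self.records if r.parsed_value is not None}
        flagged = {r.item_id for r in self.records if r.parsed_value is None}
        return ResponseSet.from_raw(self.persona_id, self.triplet, raw, flagged)


class ChatBackend(Protocol):
    """Minimal chat contract: a full message list in, one reply text out."""

    def reply(self, messages: Sequence[dict]) -> str: ...


class ScriptedBackend:
    """Deterministic mock backend replying from a constant or a sequence."""

    def __init__(self, replies, acknowledgment: str = "Understood."):
        self.acknowledgment = acknowledgment
        self._replies = replies
        self._iter = iter(replies) if not isinstance(replies, str) else None

    def reply(self, messages: Sequence[dict]) -> str:
        if len(messages) == 1:  # initialization exchange
            return self.acknowledgment
        if self._iter is None:
            return self._replies
        return next(self._iter)


class ResponseSetBackend:
    """Serve a synthetic responder's answers through the chat contract.

    Looks up the queried item by its verbatim prompt text and replies with
    the response rounded to an integer 0-100 (the 0-100 integer protocol is
    enforced at this boundary, not inside the responders).  Items the
    responder flagged as unanswerable yield a non-numeric reply, which the
    session records as missing.
    """

    def __init__(self, response_set: ResponseSet, battery: Battery,
                 acknowledgment: str = "Understood."):
        self.response_set = response_set
        self.acknowledgment = acknowledgment
        self._by_prompt = {item.prompt_text: item.item_id for item in battery.items}

    def reply(self, messages: Sequence[dict]) -> str:
        if len(messages) == 1:
            return self.acknowledgment
        prompt = messages[-1]["content"]
        item_id = self._by_prompt.get(prompt)
        if item_id is None or item_id not in self.response_set.values:
            return "I cannot answer that."
        value = self.response_set.values[item_id]
        return str(int(round(min(max(value, 0.0), 1.0) * 100)))


def run_session(persona: Persona, battery: Battery, backend: ChatBackend,
                window_pairs: int = 7, retries: int = 3, seed: int = 0,
                instructions: str = DEFAULT_INSTRUCTIONS) -> SessionTranscript:
    """Run one full elicitation session under the sliding-window protocol.

    Items are issued in battery order.  The context visible at each query is
    the persona-initialization exchange plus the most recent
    ``min(k, window_pairs)`` question-answer pairs (k = items already asked);
    ``window_pairs = 0`` is the memoryless limit.  Each reply is parsed with
    :func:`parse_reply`; a failed parse is retried with the identical prompt
    up to ``retries`` total attempts, then recorded as missing and the
    session continues.  Deterministic for deterministic backends.
    """
    if window_pairs < 0:
        raise ValueError("window_pairs must be nonnegative")
    if retries < 1:
        raise ValueError("retries must be at least 1")

    init_prompt = build_persona_prompt(persona, instructions)
    init_messages = [{"role": "user", "content": init_prompt}]
    acknowledgment = backend.reply(init_messages)
    init_exchange = init_messages + [{"role": "assistant", "content": acknowledgment}]

    window: deque[tuple[str, str]] = deque(maxlen=window_pairs if window_pairs > 0 else None)
    transcript = SessionTranscript(
        persona_id=persona.persona_id,
        triplet=battery.triplet,
        battery_seed=battery.seed,
        window_pairs=window_pairs,
    )

    for item in battery.items:
        context_pairs = list(window) if window_pairs > 0 else []
        messages = list(init_exchange)
        for question, answer in context_pairs:
            messages.append({"role": "user", "content": question})
            messages.append({"role": "assistant", "content": answer})
        messages.append({"role": "user", "content": item.prompt_text})

        raw, parsed = "", None
        for _ in range(retries):
            raw = backend.reply(messages)
            parsed = parse_reply(raw)
            if parsed is not None:
                break

        transcript.records.append(
            TranscriptRecord(
                item_id=item.item_id,
                prompt_text=item.prompt_text,
                raw_reply=raw,
                parsed_value=parsed,
                context_size_at_query=len(context_pairs),
            )
        )
        if window_pairs > 0:
            window.append((item.prompt_text, raw))

    return transcript


@dataclass
class CohortRun:
    persona: Persona
    battery: Battery
    transcript: SessionTranscript


@dataclass
class CohortArchive:
    """All sessions of one cohort, with their personas and batteries."""

    runs: list[CohortRun]

    @property
    def n_records(self) -> int:
        return sum(len(run.transcript.records) for run in self.runs)

    def pairs(self) -> list[tuple[ResponseSet, Battery]]:
        return [(run.transcript.to_response_set(), run.battery) for run in self.runs]

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for run in self.runs:
            for rec in run.transcript.records:
                rows.append(
                    {
                        "persona_id": run.persona.persona_id,
                        "triplet": run.battery.triplet,
                        "item_id": rec.item_id,
                        "parsed_value": rec.parsed_value,
                        "context_size_at_query": rec.context_size_at_query,
                    }
                )
        return pd.DataFrame(rows)


def run_cohort(personas: Sequence[Persona], triplet_assignment: Mapping[str, str],
               responder, *, candidate_labels: tuple[str, str] = DEFAULT_CANDIDATE_LABELS,
               window_pairs: int = 7, retries: int = 3, seed: int = 0,
               instructions: str = DEFAULT_INSTRUCTIONS) -> CohortArchive:
    """One independent session per persona.

    Each persona must be assigned to exactly one triplet condition; item
    order is re-randomized independently per persona (a fresh battery seed),
    and the responder receives a per-persona seed derived from ``seed``.
    Duplicate persona ids raise a validation error.
    """
    ids = [p.persona_id for p in personas]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate persona ids: {dupes}")
    unassigned = [i for i in ids if i not in triplet_assignment]
    if unassigned:
        raise ValueError(f"personas without a triplet assignment: {unassigned}")

    rng = np.random.default_rng(seed)
    runs = []
    for persona in personas:
        battery_seed = int(rng.integers(0, 2**31 - 1))
        responder_seed = int(rng.integers(0, 2**31 - 1))
        battery = build_battery(triplet_assignment[persona.persona_id],
                                candidate_labels, seed=battery_seed)
        response_set = responder(persona, battery, responder_seed)
        backend = ResponseSetBackend(response_set, battery)
        transcript = run_session(persona, battery, backend,
                                 window_pairs=window_pairs, retries=retries,
                                 seed=responder_seed, instructions=instructions)
        runs.append(CohortRun(persona=persona, battery=battery, transcript=transcript))
    return CohortArchive(runs=runs)


# ---------------------------------------------------------------------------
# Persona tables
# ---------------------------------------------------------------------------

def synthetic_personas(n_t1: int = 284, n_t2: int = 269, seed: int = 0) -> pd.DataFrame:
    """Generate a synthetic demographic persona table.

    Defaults mirror the study cohort sizes: 284 personas in the T1 condition
    and 269 in T2 (553 total).  Ages are uniform on 18-80, gender is
    female/male, education uniform over the four levels, and residence
    uniform over the 50 U.S. states.  Columns match the persona CSV
    interface: persona_id, age, gender, education, state, triplet.
    """
    rng = np.random.default_rng(seed)
    n = n_t1 + n_t2
    rows = []
    for i in range(n):
        rows.append(
            {
                "persona_id": f"p{i:04d}",
                "age": int(rng.integers(18, 81)),
                "gender": str(rng.choice(["female", "male"])),
                "education": str(rng.choice(EDUCATION_LEVELS)),
                "state": str(rng.choice(US_STATES)),
                "triplet": "T1" if i < n_t1 else "T2",
            }
        )
    return pd.DataFrame(rows)


def personas_from_frame(df: pd.DataFrame) -> tuple[list[Persona], dict[str, str]]:
    """Split a persona table into Persona objects and a triplet assignment."""
    personas = [
        Persona(
            persona_id=str(row.persona_id),
            age=int(row.age),
            gender=str(row.gender),
            education=str(row.education),
            state=str(row.state),
        )
        for row in df.itertuples(index=False)
    ]
    assignment = {str(row.persona_id): str(row.triplet) for row in df.itertuples(index=False)}
    return personas, assignment


def load_personas(path: str | Path) -> tuple[list[Persona], dict[str, str]]:
    return personas_from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Transcript JSONL IO: one session-header line, then one line per record.
# ---------------------------------------------------------------------------

def save_transcripts_jsonl(transcripts: Iterable[SessionTranscript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            header = {
                "type": "session",
                "persona_id": t.persona_id,
                "triplet": t.triplet,
                "battery_seed": t.battery_seed,
                "window_pairs": t.window_pairs,
            }
            fh.write(json.dumps(header) + "\n")
            for r in t.records:
                fh.write(json.dumps({"type": "record", **r.__dict__}) + "\n")


def load_transcripts_jsonl(path: str | Path) -> list[SessionTranscript]:
    transcripts: list[SessionTranscript] = []
    with open(path) as fh:
        for line in fh:
            obj = json.loads(line)
            kind = obj.pop("type")
            if kind == "session":
                transcripts.append(SessionTranscript(records=[], **obj))
            else:
                transcripts[-1].records.append(TranscriptRecord(**obj))
    return transcripts
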