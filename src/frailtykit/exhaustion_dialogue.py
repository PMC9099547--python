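"""Three-question exhaustion dialogue as a deterministic state machine.

The smart-speaker conversation consists of an availability gate followed by
two sequential questions: a yes/no exhaustion question and a frequency
question answered with one of ``always``/``sometimes``/``rare``.  A
``sometimes`` or ``always`` frequency answer categorizes the respondent as
positive on the exhaustion criterion.  Each question is repeated at most
once after an unrecognized or silent answer; a second failure (or an
availability answer of "no") leaves the dialogue incomplete.

Speech recognition is out of scope: the machine consumes normalized
lowercase text tokens, with an optional synonym table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .errors import DataError

__all__ = [
    "Question",
    "DialogueScript",
    "Prompt",
    "Turn",
    "DialogueOutcome",
    "run_dialogue",
    "scripted_answers",
    "score_exhaustion",
    "percent_recognition_agreement",
    "FRAIL_FREQUENCY_TOKENS",
]

FRAIL_FREQUENCY_TOKENS = frozenset({"always", "sometimes"})

_EXHAUSTION_TEXT = (
    "Do you feel that everything you did was an effort, "
    "or you could not get going in the last week?"
)
_FREQUENCY_TEXT = "How often in the last week did you feel this way?"
_AVAILABILITY_TEXT = "Are you available to answer a few questions right now?"


@dataclass(frozen=True)
class Question:
    question_id: str
    text: str
    options: tuple[str, ...]


@dataclass(frozen=True)
class DialogueScript:
    """The ordered three-question script with a per-question retry budget."""

    questions: tuple[Question, ...] = (
        Question("availability", _AVAILABILITY_TEXT, ("yes", "no")),
        Question("exhaustion", _EXHAUSTION_TEXT, ("yes", "no")),
        Question("frequency", _FREQUENCY_TEXT, ("always", "sometimes", "rare")),
    )
    max_retries_per_question: int = 1

    def __post_init__(self) -> None:
        if len(self.questions) != 3:
            raise DataError("a dialogue script has exactly three questions")
        if self.max_retries_per_question < 0:
            raise DataError("max_retries_per_question must be >= 0")


@dataclass(frozen=True)
class Prompt:
    """What the speaker says before listening: question text plus options."""

    question_id: str
    text: str
    options: tuple[str, ...]
    attempt: int  # 1-based

    def spoken(self) -> str:
        return f"{self.text} Please answer: {' or '.join(self.options)}."


@dataclass(frozen=True)
class Turn:
    role: str  # "prompt" | "answer" | "note"
    question_id: str
    text: str


@dataclass(frozen=True)
class DialogueOutcome:
    completed: bool
    answers: Mapping[str, str]
    exhaustion_positive: Optional[bool]
    transcript: tuple[Turn, ...]


def scripted_answers(tokens: Iterable[Optional[str]]) -> Callable[[Prompt], Optional[str]]:
    """Answer source that plays back ``tokens`` in order; ``None`` is silence.

    Once exhausted it stays silent, so any finite token sequence maps to a
    well-defined outcome.
    """
    queue = list(tokens)

    def source(prompt: Prompt) -> Optional[str]:
        if queue:
            return queue.pop(0)
        return None

    return source


def _normalize(token: Optional[str], synonyms: Optional[Mapping[str, str]]) -> Optional[str]:
    if token is None:
        return None
    tok = token.strip().lower()
    if synonyms and tok in synonyms:
        tok = synonyms[tok]
    return tok


def run_dialogue(
    script: DialogueScript,
    answer_source: Callable[[Prompt], Optional[str]],
    synonyms: Optional[Mapping[str, str]] = None,
) -> DialogueOutcome:
    """Run the dialogue to completion; every user behavior maps to an outcome.

    The machine is deterministic: identical answer sequences produce
    identical outcomes and transcripts, and terminates within
    ``(1 + max_retries) * 3`` prompts.
    """
    answers: dict[str, str] = {}
    transcript: list[Turn] = []
    completed = True
    for question in script.questions:
        recognized: Optional[str] = None
        for attempt in range(1, script.max_retries_per_question + 2):
            prompt = Prompt(question.question_id, question.text, question.options, attempt)
            transcript.append(Turn("prompt", question.question_id, prompt.spoken()))
            token = _normalize(answer_source(prompt), synonyms)
            transcript.append(
                Turn("answer", question.question_id, "<silence>" if token is None else token)
            )
            if token in question.options:
                recognized = token
                break
        if recognized is None:
            completed = False
            break
        answers[question.question_id] = recognized
        if question.question_id == "availability" and recognized == "no":
            completed = False
            break
    exhaustion_positive: Optional[bool] = None
    if completed:
        exhaustion_positive = answers["frequency"] in FRAIL_FREQUENCY_TOKENS
        if answers.get("exhaustion") == "no" and exhaustion_positive:
            transcript.append(
                Turn(
                    "note",
                    "frequency",
                    "inconsistent answers: exhaustion denied but frequency "
                    f"{answers['frequency']!r}; categorized by frequency",
                )
            )
    return DialogueOutcome(
        completed=completed,
        answers=answers,
        exhaustion_positive=exhaustion_positive,
        transcript=tuple(transcript),
    )


def score_exhaustion(outcome: DialogueOutcome) -> str:
    """Map an outcome to the exhaustion criterion flag.

    ``positive`` iff completed with frequency in the frail set,
    ``negative`` iff completed with frequency ``rare``, else ``missing``.
    """
    if not outcome.completed:
        return "missing"
    return "positive" if outcome.exhaustion_positive else "negative"


def percent_recognition_agreement(
    recognized: Sequence[str], reference: Sequence[str]
) -> float:
    """Percentage of positions where recognized and reference tokens match."""
    if len(recognized) != len(reference):
        raise DataError(
            f"length mismatch: {len(recognized)} recognized vs {len(reference)} reference"
        )
    if len(recognized) == 0:
        raise DataError("percent agreement is undefined for empty sequences")
    matches = sum(1 for a, b in zip(recognized, reference) if a == b)
    return 100.0 * matches / len(recognized)
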