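"""Corpus loading, tokenization and token-exclusion rules.

Transcripts are verbatim records of routine-description monologues
("describe a typical day of your life"). Before any linguistic feature can
be computed, each transcript is tokenized and reduced to its analyzable
word stream: filled pauses / hesitations ("eh", "mmm" ...), interrupted
word fragments (marked with a trailing ellipsis, e.g. "hospi…") and
unintelligible spans (marked "[inaudible]") are transcribed but excluded
from every downstream count. Punctuation is split off into its own tokens
and never counts as a word, while stop words (determiners, adpositions,
conjunctions, numbers, ...) remain in the word stream and in the
total-word denominator of the class ratios.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

GROUPS = ("AD", "bvFTD", "HC")

#: token kinds
WORD = "word"
PUNCT = "punctuation"
FILLER = "filler"
FRAGMENT = "fragment"
UNINTELLIGIBLE = "unintelligible"

#: default closed list of filled pauses / hesitations (Spanish)
DEFAULT_FILLERS = frozenset({"eh", "em", "mmm", "mm", "ah", "ehh"})

#: default markup conventions for the transcription
DEFAULT_FRAGMENT_MARKER = "…"  # trailing "…" glued to the fragment
DEFAULT_UNINTELLIGIBLE_MARKER = "[inaudible]"

_PUNCT_CHARS = ".,;:!?¡¿\"'()«»…—–-"
_SENTENCE_FINAL = {".", "!", "?", "…"}


class EmptyTranscriptError(ValueError):
    """Raised when a transcript contains no analyzable material."""


@dataclass(frozen=True)
class Token:
    """A single transcript token.

    ``sentence`` is the 0-based index of the sentence the token belongs
    to, delimited by sentence-final punctuation; it anchors the
    intra/inter-sentential scope of person disambiguation downstream.
    """

    surface: str
    index: int
    kind: str = WORD
    sentence: int = 0

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")


@dataclass
class Transcript:
    participant_id: str
    group: str
    tokens: list[Token] = field(default_factory=list)
    cognitive_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r} for participant "
                f"{self.participant_id!r}; expected one of {GROUPS}"
            )

    @property
    def n_words(self) -> int:
        return sum(1 for t in self.tokens if t.kind == WORD)


@dataclass
class ManifestEntry:
    participant_id: str
    group: str
    path: str
    scores: dict[str, float] | None = None


@dataclass
class CorpusManifest:
    entries: list[ManifestEntry]
    split: str = "main"  # "main" | "holdout"
    root: Path | None = None


def _is_word(chunk: str) -> bool:
    # a word contains at least one alphanumeric character; digit-only
    # chunks (numbers, dates) count as words and stay in the denominator
    return any(ch.isalnum() for ch in chunk)


def tokenize(
    text: str,
    *,
    fillers: Iterable[str] = DEFAULT_FILLERS,
    fragment_marker: str = DEFAULT_FRAGMENT_MARKER,
    unintelligible_marker: str = DEFAULT_UNINTELLIGIBLE_MARKER,
) -> list[Token]:
    """Split a transcript string into :class:`Token` objects.

    Markup conventions: ``unintelligible_marker`` spans become single
    ``unintelligible`` tokens; a word with ``fragment_marker`` glued to
    its end ("hospi…") is an interrupted ``fragment``; surfaces on the
    ``fillers`` closed list become ``filler`` tokens. Everything else is
    a ``word`` or ``punctuation`` token. Sentence indices advance at
    sentence-final punctuation (. ! ? and a free-standing ellipsis).

    Raises :class:`EmptyTranscriptError` on empty/whitespace-only input.
    """
    if not text or not text.strip():
        raise EmptyTranscriptError("empty transcript")
    text = unicodedata.normalize("NFC", text)
    filler_set = {f.lower() for f in fillers}

    tokens: list[Token] = []
    sentence = 0
    index = 0

    def emit(surface: str, kind: str) -> None:
        nonlocal index, sentence
        tokens.append(Token(surface=surface, index=index, kind=kind, sentence=sentence))
        index += 1
        if kind == PUNCT and surface[0] in _SENTENCE_FINAL:
            sentence += 1

    # protect the unintelligible marker (may contain spaces/brackets)
    sentinel = "\x00"
    protected = text.replace(unintelligible_marker, f" {sentinel} ")

    for chunk in protected.split():
        if chunk == sentinel:
            emit(unintelligible_marker, UNINTELLIGIBLE)
            continue
        # fragment: marker glued to the end of a word-like chunk
        if (
            chunk.endswith(fragment_marker)
            and len(chunk) > len(fragment_marker)
            and _is_word(chunk[: -len(fragment_marker)])
        ):
            emit(chunk[: -len(fragment_marker)], FRAGMENT)
            continue
        # strip punctuation off both ends, emitting punctuation tokens
        m = re.match(
            rf"^([{re.escape(_PUNCT_CHARS)}]*)(.*?)([{re.escape(_PUNCT_CHARS)}]*)$",
            chunk,
        )
        lead, core, trail = m.groups()
        for ch in lead:
            emit(ch, PUNCT)
        if core:
            if _is_word(core):
                kind = FILLER if core.lower() in filler_set else WORD
                emit(core, kind)
            else:
                for ch in core:
                    emit(ch, PUNCT)
        for ch in trail:
            emit(ch, PUNCT)

    if not tokens:
        raise EmptyTranscriptError("transcript contains no tokens")
    return tokens


def clean_word_stream(
    source: Transcript | Sequence[Token],
) -> tuple[list[Token], Counter]:
    """Keep only ``word`` tokens; report removals per kind.

    The surviving stream is the single source of truth for the
    total-word denominator used by the class ratios. Raises
    :class:`EmptyTranscriptError` when no word survives.
    """
    tokens = source.tokens if isinstance(source, Transcript) else list(source)
    kept = [t for t in tokens if t.kind == WORD]
    removed = Counter(t.kind for t in tokens if t.kind != WORD)
    if removed:
        logger.debug("excluded tokens: %s", dict(removed))
    if not kept:
        who = source.participant_id if isinstance(source, Transcript) else "<stream>"
        raise EmptyTranscriptError(f"no analyzable words in transcript {who}")
    return kept, removed


def load_manifest(path: str | Path) -> CorpusManifest:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    entries = [
        ManifestEntry(
            participant_id=str(e["participant_id"]),
            group=str(e["group"]),
            path=str(e["path"]),
            scores=e.get("scores"),
        )
        for e in raw["entries"]
    ]
    seen: set[str] = set()
    for e in entries:
        if e.participant_id in seen:
            raise ValueError(f"duplicate participant_id {e.participant_id!r} in manifest {path}")
        seen.add(e.participant_id)
        if e.group not in GROUPS:
            raise ValueError(
                f"unknown group {e.group!r} for participant {e.participant_id!r} in manifest {path}"
            )
    return CorpusManifest(entries=entries, split=raw.get("split", "main"), root=path.parent)


def load_corpus(
    manifest: str | Path | CorpusManifest,
    **tokenize_kwargs,
) -> list[Transcript]:
    """Load and tokenize every transcript referenced by a JSON manifest.

    Relative transcript paths resolve against the manifest's directory.
    """
    if not isinstance(manifest, CorpusManifest):
        manifest = load_manifest(manifest)
    root = manifest.root or Path(".")
    transcripts: list[Transcript] = []
    for entry in manifest.entries:
        fpath = Path(entry.path)
        if not fpath.is_absolute():
            fpath = root / fpath
        try:
            text = fpath.read_text(encoding="utf-8")
        except OSError as exc:
            raise FileNotFoundError(
                f"cannot read transcript for participant {entry.participant_id!r}: {fpath}"
            ) from exc
        transcripts.append(
            Transcript(
                participant_id=entry.participant_id,
                group=entry.group,
                tokens=tokenize(text, **tokenize_kwargs),
                cognitive_scores=entry.scores,
            )
        )
    counts = Counter(t.group for t in transcripts)
    logger.info("loaded %d transcripts (%s): %s", len(transcripts), manifest.split, dict(counts))
    return transcripts


def write_token_tsv(tokens: Sequence[Token], path: str | Path) -> None:
    """Export a token stream as one-token-per-line TSV (surface, index, kind)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("surface\tindex\tkind\n")
        for t in tokens:
            fh.write(f"{t.surface}\t{t.index}\t{t.kind}\n")


def group_counts(transcripts: Iterable[Transcript]) -> Mapping[str, int]:
    return dict(Counter(t.group for t in transcripts))
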