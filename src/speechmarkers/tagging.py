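"""Word-class and grammatical-person tagging.

The pipeline needs, for every analyzable word, a coarse part-of-speech
tag (NOUN, VERB, ADJ, ...) and — for verbs, pronouns and possessive
determiners — a grammatical-person attribute (first/second/third).
Spanish is a pro-drop language: subject pronouns are routinely omitted
because the verb desinence already encodes person ("camino" = I walk,
"caminas" = you walk, "camina" = s/he walks), so person markers must be
read off both pronouns and verb endings, and a pronoun-verb tandem
("yo salgo") contributes two separate markers.

Tagging is a pluggable contract (any callable mapping a cleaned word
stream to :class:`TaggedToken` sequences can stand behind it). The
bundled reference tagger is deterministic: a surface-form lexicon plus
ordered verb-suffix rules. Some endings are genuinely ambiguous — the
imperfect "-aba"/"-ía" serves both first and third person — and are
resolved by agreement context: the nearest preceding subject pronoun in
the sentence, else the nearest person-marked verb in the sentence, else
the previous sentence, else the third-person narrative default.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Token

logger = logging.getLogger(__name__)

POS_TAGS = ("NOUN", "VERB", "ADJ", "ADV", "PRON", "DET", "ADP", "CONJ", "INTJ", "NUM", "OTHER")
CONTENT_POS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})
PERSONS = ("first", "second", "third", "none")
AMBIGUOUS = "ambiguous"  # transient value, removed by resolve_person_ambiguity

#: POS categories allowed to carry person: verbs, pronouns and
#: possessive determiners ("mi"/"su" are read as person markers).
PERSON_BEARING_POS = frozenset({"VERB", "PRON", "DET"})


@dataclass(frozen=True)
class TaggedToken:
    surface: str
    pos: str
    person: str = "none"
    sentence: int = 0
    index: int = 0

    def __post_init__(self) -> None:
        if self.pos not in POS_TAGS:
            raise ValueError(f"unknown pos tag {self.pos!r}")
        if self.person not in PERSONS + (AMBIGUOUS,):
            raise ValueError(f"unknown person value {self.person!r}")
        if self.person not in ("none",) and self.pos not in PERSON_BEARING_POS:
            raise ValueError(
                f"person={self.person!r} not allowed on pos={self.pos!r} ({self.surface!r})"
            )


@dataclass
class TagLexicon:
    """Surface-form lexicon plus ordered verb-suffix rules.

    ``entries`` maps lower-cased surfaces to a (pos, person) analysis,
    with person possibly "ambiguous" for endings like the imperfect.
    ``suffix_rules`` is an ordered list of (verb ending, person) applied
    to out-of-vocabulary surfaces; only distinctively verbal endings are
    enabled for OOV fall-through so that arbitrary unknown strings
    degrade to OTHER.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    suffix_rules: list[tuple[str, str]] = field(default_factory=list)

    def lookup(self, surface: str) -> tuple[str, str] | None:
        return self.entries.get(surface.lower())

    def suffix_person(self, surface: str) -> str | None:
        low = surface.lower()
        for ending, person in self.suffix_rules:
            if low.endswith(ending) and len(low) > len(ending):
                return person
        return None

    def merge(self, other: "TagLexicon") -> "TagLexicon":
        entries = dict(self.entries)
        entries.update(other.entries)
        rules = list(other.suffix_rules) if other.suffix_rules else list(self.suffix_rules)
        return TagLexicon(entries=entries, suffix_rules=rules)


#: OOV fall-through endings: distinctively verbal in Spanish.
DEFAULT_SUFFIX_RULES: list[tuple[str, str]] = [
    ("ábamos", "first"),
    ("íamos", "first"),
    ("aremos", "first"),
    ("eremos", "first"),
    ("aba", AMBIGUOUS),  # imperfect: first or third
    ("ía", AMBIGUOUS),  # imperfect: first or third
    ("aré", "first"),
    ("eré", "first"),
    ("iré", "first"),
    ("ará", "third"),
    ("erá", "third"),
    ("irá", "third"),
    ("amos", "first"),
    ("emos", "first"),
    ("imos", "first"),
    ("é", "first"),  # past simple: caminé
    ("ó", "third"),  # past simple: caminó
]

#: closed-class core of Spanish plus the vocabulary of the worked examples
_CORE = {
    # determiners (articles carry no person; possessives do)
    "el": ("DET", "none"), "la": ("DET", "none"), "los": ("DET", "none"),
    "las": ("DET", "none"), "un": ("DET", "none"), "una": ("DET", "none"),
    "unos": ("DET", "none"), "unas": ("DET", "none"),
    "mi": ("DET", "first"), "mis": ("DET", "first"),
    "tu": ("DET", "second"), "tus": ("DET", "second"),
    "su": ("DET", "third"), "sus": ("DET", "third"),
    # pronouns
    "yo": ("PRON", "first"), "me": ("PRON", "first"), "mí": ("PRON", "first"),
    "conmigo": ("PRON", "first"), "nosotros": ("PRON", "first"), "nos": ("PRON", "first"),
    "tú": ("PRON", "second"), "te": ("PRON", "second"), "usted": ("PRON", "second"),
    "él": ("PRON", "third"), "ella": ("PRON", "third"), "ellos": ("PRON", "third"),
    "ellas": ("PRON", "third"), "se": ("PRON", "third"), "le": ("PRON", "third"),
    "les": ("PRON", "third"), "lo": ("PRON", "third"),
    # adpositions
    "a": ("ADP", "none"), "de": ("ADP", "none"), "en": ("ADP", "none"),
    "con": ("ADP", "none"), "por": ("ADP", "none"), "para": ("ADP", "none"),
    "sin": ("ADP", "none"), "sobre": ("ADP", "none"), "hasta": ("ADP", "none"),
    "desde": ("ADP", "none"),
    "al": ("ADP", "none"), "del": ("ADP", "none"),
    # conjunctions
    "y": ("CONJ", "none"), "o": ("CONJ", "none"), "que": ("CONJ", "none"),
    "pero": ("CONJ", "none"), "si": ("CONJ", "none"), "porque": ("CONJ", "none"),
    "cuando": ("CONJ", "none"), "como": ("CONJ", "none"),
    # adverbs
    "no": ("ADV", "none"), "sí": ("ADV", "none"), "después": ("ADV", "none"),
    "entonces": ("ADV", "none"), "luego": ("ADV", "none"), "siempre": ("ADV", "none"),
    "primero": ("ADV", "none"), "muy": ("ADV", "none"), "también": ("ADV", "none"),
    "ya": ("ADV", "none"), "ahora": ("ADV", "none"), "bien": ("ADV", "none"),
    "temprano": ("ADV", "none"), "tarde": ("ADV", "none"), "allí": ("ADV", "none"),
    # nouns of the worked examples and routine domain
    "señora": ("NOUN", "none"), "hijo": ("NOUN", "none"), "llaves": ("NOUN", "none"),
    "puertas": ("NOUN", "none"), "casa": ("NOUN", "none"), "día": ("NOUN", "none"),
    "hospital": ("NOUN", "none"), "clínica": ("NOUN", "none"),
    "desayuno": ("NOUN", "none"), "café": ("NOUN", "none"), "mañana": ("NOUN", "none"),
    "noche": ("NOUN", "none"), "almuerzo": ("NOUN", "none"),
    # verbs of the worked examples
    "levanta": ("VERB", "third"), "levanto": ("VERB", "first"),
    "voy": ("VERB", "first"), "va": ("VERB", "third"),
    "llega": ("VERB", "third"), "llego": ("VERB", "first"),
    "llegaba": ("VERB", AMBIGUOUS),
    "deja": ("VERB", "third"), "dejo": ("VERB", "first"),
    "dice": ("VERB", "third"), "digo": ("VERB", "first"),
    "quiero": ("VERB", "first"), "quiere": ("VERB", "third"),
    "camino": ("VERB", "first"), "caminas": ("VERB", "second"),
    "camina": ("VERB", "third"), "caminaba": ("VERB", AMBIGUOUS),
    "caminé": ("VERB", "first"), "caminaré": ("VERB", "first"),
    "salgo": ("VERB", "first"), "sale": ("VERB", "third"),
    # adjectives
    "abiertas": ("ADJ", "none"), "típico": ("ADJ", "none"), "bueno": ("ADJ", "none"),
}


def core_lexicon() -> TagLexicon:
    """The bundled Spanish closed-class lexicon with default suffix rules."""
    return TagLexicon(entries=dict(_CORE), suffix_rules=list(DEFAULT_SUFFIX_RULES))


#: subject pronouns usable for agreement-based disambiguation
_SUBJECT_PRONOUNS = {"yo", "tú", "usted", "él", "ella", "nosotros", "ellos", "ellas"}


@dataclass
class TagReport:
    tokens: list[TaggedToken]
    n_total: int
    n_covered: int

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_total if self.n_total else 0.0


def tag_stream(
    tokens: Sequence[Token] | Sequence[str],
    lexicon: TagLexicon,
    *,
    coverage_threshold: float = 0.8,
    resolve: bool = True,
) -> TagReport:
    """Tag a cleaned word stream with the reference lexicon+rule tagger.

    Unknown surfaces degrade to OTHER/none and lower the coverage
    statistic; coverage below ``coverage_threshold`` logs a warning.
    With ``resolve`` (default) ambiguous person values are resolved in
    context so no transient flags remain.
    """
    if len(tokens) == 0:
        raise ValueError("cannot tag an empty stream")
    tagged: list[TaggedToken] = []
    covered = 0
    for i, tok in enumerate(tokens):
        if isinstance(tok, Token):
            surface, sentence, index = tok.surface, tok.sentence, tok.index
        else:
            surface, sentence, index = str(tok), 0, i
        analysis = lexicon.lookup(surface)
        if analysis is not None:
            pos, person = analysis
            covered += 1
            if pos == "VERB" and person == "none":
                person = lexicon.suffix_person(surface) or "none"
        else:
            person = lexicon.suffix_person(surface)
            if person is not None:
                pos = "VERB"
            else:
                pos, person = "OTHER", "none"
        tagged.append(
            TaggedToken(surface=surface, pos=pos, person=person, sentence=sentence, index=index)
        )
    report = TagReport(tokens=tagged, n_total=len(tagged), n_covered=covered)
    if report.coverage < coverage_threshold:
        logger.warning(
            "lexicon coverage %.3f below threshold %.2f (%d/%d tokens)",
            report.coverage, coverage_threshold, covered, len(tagged),
        )
    if resolve:
        report.tokens = resolve_person_ambiguity(report.tokens)
    return report


def _person_cue(tok: TaggedToken, prefer_pronoun: bool) -> str | None:
    if tok.person not in ("first", "second", "third"):
        return None
    if prefer_pronoun:
        return tok.person if tok.pos == "PRON" and tok.surface.lower() in _SUBJECT_PRONOUNS else None
    return tok.person if tok.pos == "VERB" else None


def resolve_person_ambiguity(tagged: Sequence[TaggedToken]) -> list[TaggedToken]:
    """Resolve transient ``ambiguous`` person flags by agreement context.

    Resolution order for each ambiguous verb, scanning left-to-right so
    already-resolved verbs can serve as context: (1) nearest preceding
    subject pronoun in the same sentence; (2) nearest preceding
    person-marked verb in the same sentence; (3) nearest person marker
    (pronoun or verb, nearest first) in the previous sentence;
    (4) third person, the unmarked narrative default.
    Unambiguous tags are never altered.
    """
    out: list[TaggedToken] = []
    for i, tok in enumerate(tagged):
        if tok.person != AMBIGUOUS:
            out.append(tok)
            continue
        resolved: str | None = None
        # (1) nearest preceding subject pronoun, same sentence
        for prev in reversed(out):
            if prev.sentence != tok.sentence:
                break
            resolved = _person_cue(prev, prefer_pronoun=True)
            if resolved:
                break
        # (2) nearest preceding person-marked verb, same sentence
        if not resolved:
            for prev in reversed(out):
                if prev.sentence != tok.sentence:
                    break
                resolved = _person_cue(prev, prefer_pronoun=False)
                if resolved:
                    break
        # (3) nearest marker in the previous sentence
        if not resolved:
            for prev in reversed(out):
                if prev.sentence >= tok.sentence:
                    continue
                if prev.sentence < tok.sentence - 1:
                    break
                if prev.person in ("first", "second", "third") and prev.pos in ("PRON", "VERB"):
                    resolved = prev.person
                    break
        if not resolved:
            resolved = "third"
            logger.debug("unresolvable person for %r; defaulting to third", tok.surface)
        out.append(replace(tok, person=resolved))
    return out


@dataclass
class AgreementReport:
    accuracy: float
    n_total: int
    n_match: int
    confusion: Counter  # (gold (pos, person), predicted (pos, person)) -> count


def tag_agreement(
    predicted: Sequence[TaggedToken], gold: Sequence[TaggedToken]
) -> AgreementReport:
    """Position-aligned agreement between two tag sequences.

    Accuracy counts positions where both pos and person match; the
    confusion counter records mismatching (gold, predicted) pairs.
    """
    if len(predicted) != len(gold):
        raise ValueError(
            f"alignment error: predicted has {len(predicted)} tokens, gold has {len(gold)}"
        )
    confusion: Counter = Counter()
    n_match = 0
    for p, g in zip(predicted, gold):
        if (p.pos, p.person) == (g.pos, g.person):
            n_match += 1
        else:
            confusion[((g.pos, g.person), (p.pos, p.person))] += 1
    return AgreementReport(
        accuracy=n_match / len(gold) if gold else 1.0,
        n_total=len(gold),
        n_match=n_match,
        confusion=confusion,
    )


def load_tag_lexicon(entries_tsv: str | Path, rules_tsv: str | Path | None = None) -> TagLexicon:
    """Read a TagLexicon from TSV (surface, pos, person) plus optional rules TSV."""
    entries: dict[str, tuple[str, str]] = {}
    with open(entries_tsv, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            entries[row["surface"].lower()] = (row["pos"], row["person"])
    rules = list(DEFAULT_SUFFIX_RULES)
    if rules_tsv is not None:
        rules = []
        with open(rules_tsv, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                rules.append((row["suffix"], row["person"]))
    return TagLexicon(entries=entries, suffix_rules=rules)


def save_tag_lexicon(lexicon: TagLexicon, entries_tsv: str | Path, rules_tsv: str | Path) -> None:
    with open(entries_tsv, "w", encoding="utf-8") as fh:
        fh.write("surface\tpos\tperson\n")
        for surface, (pos, person) in sorted(lexicon.entries.items()):
            fh.write(f"{surface}\t{pos}\t{person}\n")
    with open(rules_tsv, "w", encoding="utf-8") as fh:
        fh.write("suffix\tperson\n")
        for suffix, person in lexicon.suffix_rules:
            fh.write(f"{suffix}\t{person}\n")


def write_tagged_tsv(tokens: Iterable[TaggedToken], path: str | Path) -> None:
    """Export tagged tokens as CoNLL-like TSV (surface, pos, person, sentence)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("surface\tpos\tperson\tsentence\n")
        for t in tokens:
            fh.write(f"{t.surface}\t{t.pos}\t{t.person}\t{t.sentence}\n")


def read_tagged_tsv(path: str | Path) -> list[TaggedToken]:
    out: list[TaggedToken] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            out.append(
                TaggedToken(
                    surface=row["surface"],
                    pos=row["pos"],
                    person=row["person"],
                    sentence=int(row.get("sentence", 0)),
                    index=i,
                )
            )
    return out
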