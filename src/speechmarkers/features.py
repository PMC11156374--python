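"""The eight per-participant connected-speech features.

Two word-class ratios (nouns and verbs over all words, stop words
included), two grammatical-person ratios (first and third person markers
over all first+third markers, second person discarded), three lexical
property means over content-word tokens (log10 frequency per million,
phonological neighborhood size, length in phonemes) and one
embedding-based statistic, semantic variability: the variance of the
series of distances between embeddings of successive, deduplicated
content words. A text that drifts inconsistently between semantic
neighborhoods has a high semantic variability.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import Transcript, clean_word_stream
from .tagging import CONTENT_POS, TagLexicon, TaggedToken, tag_stream

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "noun_ratio",
    "verb_ratio",
    "first_person_ratio",
    "third_person_ratio",
    "mean_log_freq",
    "mean_phon_neighbors",
    "mean_length",
    "semantic_variability",
]


@dataclass(frozen=True)
class LexiconEntry:
    """Psycholinguistic properties of one word form.

    log_freq is log10 occurrences per million tokens; phon_neighbors the
    count of words one phoneme substitution/addition/omission away;
    length_phonemes the phoneme count.
    """

    surface: str
    log_freq: float
    phon_neighbors: int
    length_phonemes: int

    def __post_init__(self) -> None:
        if self.phon_neighbors < 0:
            raise ValueError(f"phon_neighbors < 0 for {self.surface!r}")
        if self.length_phonemes < 1:
            raise ValueError(f"length_phonemes < 1 for {self.surface!r}")


class EmbeddingTable:
    """Word -> fixed-dimension vector provider backed by a table.

    All vectors share one dimension; lookups are lower-cased; missing
    words return None.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        self._vectors = {k.lower(): np.asarray(v, dtype=float) for k, v in vectors.items()}
        dims = {v.shape for v in self._vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")
        self.dim = next(iter(dims))[0] if dims else 0

    def get(self, surface: str) -> np.ndarray | None:
        return self._vectors.get(surface.lower())

    def __len__(self) -> int:
        return len(self._vectors)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingTable":
        vectors: dict[str, np.ndarray] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()  # surface\td0\td1...
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        return cls(vectors)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("surface\t" + "\t".join(f"d{i}" for i in range(self.dim)) + "\n")
            for surface, vec in self._vectors.items():
                fh.write(surface + "\t" + "\t".join(f"{x:.6f}" for x in vec) + "\n")


def load_property_lexicon(path: str | Path) -> dict[str, LexiconEntry]:
    """Read the psycholinguistic lexicon TSV (surface, log_freq, phon_neighbors, length_phonemes)."""
    out: dict[str, LexiconEntry] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            e = LexiconEntry(
                surface=row["surface"].lower(),
                log_freq=float(row["log_freq"]),
                phon_neighbors=int(row["phon_neighbors"]),
                length_phonemes=int(row["length_phonemes"]),
            )
            out[e.surface] = e
    return out


def save_property_lexicon(entries: Mapping[str, LexiconEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("surface\tlog_freq\tphon_neighbors\tlength_phonemes\n")
        for surface in sorted(entries):
            e = entries[surface]
            fh.write(f"{e.surface}\t{e.log_freq:.6f}\t{e.phon_neighbors}\t{e.length_phonemes}\n")


@dataclass
class FeatureConfig:
    """Switches for the contractually underdetermined choices."""

    dedup: str = "global"  # "global" | "adjacent": repetition removal mode
    distance: str = "cosine"  # "cosine" | "euclidean"
    variance_ddof: int = 1  # 1 = sample variance, 0 = population
    include_second_person_in_denominator: bool = False


@dataclass
class ParticipantFeatures:
    participant_id: str
    group: str
    noun_ratio: float
    verb_ratio: float
    first_person_ratio: float | None
    third_person_ratio: float | None
    mean_log_freq: float
    mean_phon_neighbors: float
    mean_length: float
    semantic_variability: float | None
    word_count: int
    lexicon_coverage: float
    embedding_coverage: float
    cognitive_scores: dict[str, float] | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        d = {
            "participant_id": self.participant_id,
            "group": self.group,
            **{name: getattr(self, name) for name in FEATURE_NAMES},
            "word_count": self.word_count,
            "lexicon_coverage": self.lexicon_coverage,
            "embedding_coverage": self.embedding_coverage,
        }
        for key, val in (self.cognitive_scores or {}).items():
            d[key] = val
        return d


def word_class_ratios(tagged: Sequence[TaggedToken]) -> tuple[float, float]:
    """Noun and verb counts over the total word count (stop words included)."""
    if len(tagged) == 0:
        raise ValueError("empty tagged stream")
    n = len(tagged)
    nouns = sum(1 for t in tagged if t.pos == "NOUN")
    verbs = sum(1 for t in tagged if t.pos == "VERB")
    return nouns / n, verbs / n


def person_ratios(
    tagged: Sequence[TaggedToken],
    *,
    include_second_in_denominator: bool = False,
) -> tuple[float | None, float | None]:
    """First- and third-person marker ratios over all person occurrences.

    Every marker counts individually: in a pronoun-verb tandem like
    "yo salgo" both the pronoun and the verb desinence contribute.
    Second-person markers are discarded (they are also excluded from the
    denominator unless ``include_second_in_denominator``). When no
    first/third marker exists both ratios are None with a warning.
    """
    first = sum(1 for t in tagged if t.person == "first")
    third = sum(1 for t in tagged if t.person == "third")
    second = sum(1 for t in tagged if t.person == "second")
    denom = first + third + (second if include_second_in_denominator else 0)
    if first + third == 0:
        warnings.warn("no first/third person markers; person ratios undefined", stacklevel=2)
        return None, None
    return first / denom, third / denom


def lexical_property_means(
    tagged: Sequence[TaggedToken],
    lexicon: Mapping[str, LexiconEntry],
    *,
    participant_id: str = "<unknown>",
) -> tuple[float, float, float, float]:
    """Token-level means of the three lexical properties over content words.

    Repeated tokens count repeatedly; lexicon misses are skipped and
    reported through the coverage ratio (hits / content tokens). Zero
    hits is an error naming the participant.
    """
    content = [t for t in tagged if t.pos in CONTENT_POS]
    hits = [lexicon[t.surface.lower()] for t in content if t.surface.lower() in lexicon]
    if not hits:
        raise ValueError(f"no content word of participant {participant_id!r} found in the lexicon")
    coverage = len(hits) / len(content)
    return (
        float(np.mean([e.log_freq for e in hits])),
        float(np.mean([e.phon_neighbors for e in hits])),
        float(np.mean([e.length_phonemes for e in hits])),
        coverage,
    )


def _adjacent_distances(vectors: np.ndarray, metric: str) -> np.ndarray:
    if metric == "cosine":
        a, b = vectors[:-1], vectors[1:]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        return 1.0 - np.sum(a * b, axis=1) / (na * nb)
    if metric == "euclidean":
        return np.linalg.norm(vectors[1:] - vectors[:-1], axis=1)
    raise ValueError(f"unknown distance metric {metric!r}")


def semantic_variability(
    tagged: Sequence[TaggedToken],
    embeddings: EmbeddingTable,
    *,
    dedup: str = "global",
    metric: str = "cosine",
    ddof: int = 1,
) -> tuple[float | None, float]:
    """Variance of distances between embeddings of successive content words.

    The content-word sequence keeps its order; repetitions are removed
    (``global``: keep only the first occurrence of each surface;
    ``adjacent``: collapse immediate repeats only). Words missing from
    the embedding table are skipped and reported via the returned
    coverage. Needs >= 3 embeddable words, else (None, coverage) with a
    warning. Returns (variability, embedding_coverage).
    """
    content = [t.surface.lower() for t in tagged if t.pos in CONTENT_POS]
    if dedup == "global":
        seen: set[str] = set()
        sequence = [s for s in content if not (s in seen or seen.add(s))]
    elif dedup == "adjacent":
        sequence = [s for i, s in enumerate(content) if i == 0 or s != content[i - 1]]
    else:
        raise ValueError(f"unknown dedup mode {dedup!r}")
    vectors = []
    for s in sequence:
        v = embeddings.get(s)
        if v is not None:
            vectors.append(v)
    coverage = len(vectors) / len(sequence) if sequence else 0.0
    if len(vectors) < 3:
        warnings.warn(
            f"semantic variability undefined: only {len(vectors)} embeddable content words",
            stacklevel=2,
        )
        return None, coverage
    mat = np.vstack(vectors)
    dists = _adjacent_distances(mat, metric)
    return float(np.var(dists, ddof=ddof)), coverage


def extract_features(
    transcript: Transcript,
    tag_lexicon: TagLexicon,
    property_lexicon: Mapping[str, LexiconEntry],
    embeddings: EmbeddingTable,
    config: FeatureConfig | None = None,
) -> ParticipantFeatures:
    """Run the whole feature family for one participant: clean, tag, compute."""
    config = config or FeatureConfig()
    words, _removed = clean_word_stream(transcript)
    report = tag_stream(words, tag_lexicon)
    return features_from_tags(
        report.tokens,
        property_lexicon,
        embeddings,
        config=config,
        participant_id=transcript.participant_id,
        group=transcript.group,
        cognitive_scores=transcript.cognitive_scores,
    )


def features_from_tags(
    tagged: Sequence[TaggedToken],
    property_lexicon: Mapping[str, LexiconEntry],
    embeddings: EmbeddingTable,
    *,
    config: FeatureConfig | None = None,
    participant_id: str = "<unknown>",
    group: str = "HC",
    cognitive_scores: dict[str, float] | None = None,
) -> ParticipantFeatures:
    """Feature computation from an already-tagged stream (e.g. gold tags)."""
    config = config or FeatureConfig()
    noun_r, verb_r = word_class_ratios(tagged)
    first_r, third_r = person_ratios(
        tagged, include_second_in_denominator=config.include_second_person_in_denominator
    )
    mfreq, mneigh, mlen, lex_cov = lexical_property_means(
        tagged, property_lexicon, participant_id=participant_id
    )
    semvar, emb_cov = semantic_variability(
        tagged, embeddings, dedup=config.dedup, metric=config.distance, ddof=config.variance_ddof
    )
    return ParticipantFeatures(
        participant_id=participant_id,
        group=group,
        noun_ratio=noun_r,
        verb_ratio=verb_r,
        first_person_ratio=first_r,
        third_person_ratio=third_r,
        mean_log_freq=mfreq,
        mean_phon_neighbors=mneigh,
        mean_length=mlen,
        semantic_variability=semvar,
        word_count=len(tagged),
        lexicon_coverage=lex_cov,
        embedding_coverage=emb_cov,
        cognitive_scores=cognitive_scores,
    )


def features_table(
    rows: Sequence[ParticipantFeatures], split: str | None = None
) -> pd.DataFrame:
    """Assemble per-participant features into a DataFrame (one row each)."""
    df = pd.DataFrame([r.as_dict() for r in rows])
    if split is not None:
        df["split"] = split
    return df
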