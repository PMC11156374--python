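"""Synthetic Spanish-like cohorts with planted, calibrated group effects.

The study's patient recordings are not redistributable, so every
pipeline stage is exercised on simulated routine-description
monologues. The generator emits, for three groups (Alzheimer's disease,
behavioral-variant frontotemporal dementia, healthy controls):

* a synthetic lexicon — Zipf-distributed word frequencies spanning
  several decades, Poisson-like phoneme lengths, neighborhood counts
  decreasing with length, verb lemmas inflected consistently with the
  reference tagger's suffix rules (present -o/-a, ambiguous imperfect
  -aba), and unit-norm embeddings clustered by word class;
* transcripts built clause by clause from Subject-Verb-Object-Adjunct
  templates of a pro-drop language: subjects are realized as a dropped
  pronoun (the verb alone marks person), an explicit pronoun-verb
  tandem (two person markers), or a noun phrase with a third-person
  verb; content words are drawn with a group-specific Zipf temperature;
* parallel gold word-class/person tags, so the tagger can be checked by
  round-trip while features can be computed independently of tagging
  errors; plus optional fillers/fragments/unintelligible spans to
  exercise the exclusion rules.

Group differences are planted as parameter offsets from the healthy
baseline, scaled per subject by a latent severity factor (which also
induces clinically realistic within-group correlation between affected
features), and calibrated by Monte-Carlo bisection so that the realized
between-group Cohen's d of the targeted feature hits the published
effect sizes (noun ratio d = 1.145 and word frequency d = 1.13 for the
AD profile; first/third-person d = 0.91 and frequency d = 0.98 for the
bvFTD profile). Cognitive scores (MoCA, IFS) are drawn independently of
the linguistic features, giving the correlation stage a true null.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .corpus import Transcript, tokenize
from .features import (
    EmbeddingTable,
    FeatureConfig,
    LexiconEntry,
    ParticipantFeatures,
    features_from_tags,
    features_table,
    save_property_lexicon,
)
from .tagging import TagLexicon, TaggedToken, core_lexicon, save_tag_lexicon

logger = logging.getLogger(__name__)

_CONSONANTS = "bcdfgjlmnprstv"
_VOWELS = "aeiou"


# --------------------------------------------------------------------------
# configuration

@dataclass
class BaselineParams:
    """Healthy-control generation parameters (probabilities per clause)."""

    p_third: float = 0.25  # clause narrated in third person
    p_pronoun: float = 0.35  # explicit subject pronoun when not forced
    p_noun_subject: float = 0.50  # third-person subject realized as noun phrase
    p_nounslot: float = 0.55  # object noun phrase present
    p_adj: float = 0.22  # adjective inside object NP
    p_ppslot: float = 0.25  # prepositional adjunct (ADP + DET + NOUN)
    p_adv: float = 0.30  # adverb adjunct
    p_imperfect: float = 0.12  # verb in ambiguous imperfect (-aba), pronoun forced
    p_poss: float = 0.12  # object determiner is a person-marked possessive
    p_deictic: float = 0.90  # clause without object NP takes a deictic
    # ADP+ADV adjunct instead ("por allí", "hasta tarde"), keeping clause
    # length — hence verb share — roughly independent of the noun slot
    freq_alpha: float = 1.0  # Zipf temperature of content-word sampling
    # between-subject heterogeneity
    sd_p_third: float = 0.10
    sd_p_nounslot: float = 0.08
    sd_freq_alpha: float = 0.25
    # transcription noise (excluded tokens)
    p_filler: float = 0.02
    p_fragment: float = 0.004
    p_unintelligible: float = 0.002


@dataclass
class GroupEffect:
    """Offsets from the healthy baseline for one group profile."""

    name: str
    nounslot_offset: float = 0.0
    freq_alpha_offset: float = 0.0
    third_offset: float = 0.0
    length_mean: float = 304.14
    length_sd: float = 80.0
    severity_sd: float = 0.35


# Offsets calibrated by Monte-Carlo bisection (see calibrate_effect and
# docs/methods.md) against the published effect sizes.
TARGET_EFFECTS = {
    "AD": {"noun_ratio": -1.145, "mean_log_freq": 1.13},
    "bvFTD": {"first_person_ratio": -0.91, "mean_log_freq": 0.98},
}

DEFAULT_HC = GroupEffect(name="HC", length_mean=304.14, severity_sd=0.0)
DEFAULT_AD = GroupEffect(
    name="AD",
    nounslot_offset=-0.1547,
    freq_alpha_offset=0.1172,
    length_mean=238.57,
)
DEFAULT_BVFTD = GroupEffect(
    name="bvFTD",
    third_offset=0.1172,
    freq_alpha_offset=0.4336,
    length_mean=253.95,
)

#: cognitive-score distributions (mean, sd) per group, independent of speech
COGNITIVE_NORMS = {
    "AD": {"MoCA": (14.53, 5.46), "IFS": (12.62, 6.29)},
    "bvFTD": {"MoCA": (17.67, 9.55), "IFS": (13.14, 6.33)},
    "HC": {"MoCA": (24.91, 4.11), "IFS": (20.10, 4.37)},
}


@dataclass
class CohortConfig:
    n_main: dict[str, int] = field(default_factory=lambda: {"AD": 21, "bvFTD": 21, "HC": 21})
    n_holdout: dict[str, int] = field(default_factory=lambda: {"AD": 11, "bvFTD": 11, "HC": 11})
    baseline: BaselineParams = field(default_factory=BaselineParams)
    effects: dict[str, GroupEffect] = field(
        default_factory=lambda: {"HC": DEFAULT_HC, "AD": DEFAULT_AD, "bvFTD": DEFAULT_BVFTD}
    )
    lexicon_words: int = 900
    embedding_dim: int = 24
    zipf_exponent: float = 1.0
    min_length: int = 80
    seed: int = 0

    def validate(self) -> None:
        for grp, n in self.n_main.items():
            if n < 2:
                raise ValueError(f"group size must be >= 2 (got {n} for {grp})")
        for grp, n in self.n_holdout.items():
            if n != 0 and n < 2:
                raise ValueError(f"hold-out group size must be 0 or >= 2 (got {n} for {grp})")


def null_config(n_per_group: int = 21, seed: int = 0, **kwargs) -> CohortConfig:
    """A no-effect configuration: all groups generated from the baseline."""
    eff = {g: GroupEffect(name=g, length_mean=270.0, severity_sd=0.0) for g in ("AD", "bvFTD", "HC")}
    return CohortConfig(
        n_main={g: n_per_group for g in ("AD", "bvFTD", "HC")},
        n_holdout={g: 0 for g in ("AD", "bvFTD", "HC")},
        effects=eff,
        seed=seed,
        **kwargs,
    )


# --------------------------------------------------------------------------
# lexicon generation

@dataclass
class SyntheticLexicon:
    entries: dict[str, LexiconEntry]
    tag_lexicon: TagLexicon
    embeddings: EmbeddingTable
    nouns: list[str]
    verbs: list[tuple[str, str, str]]  # (first "-o", third "-a", imperfect "-aba")
    adjectives: list[str]
    adverbs: list[str]
    noun_ranks: np.ndarray
    verb_ranks: np.ndarray
    adj_ranks: np.ndarray
    adv_ranks: np.ndarray
    zipf_exponent: float

    def log_freq(self, surface: str) -> float:
        return self.entries[surface].log_freq


def _make_stem(rng: np.random.Generator, n_syll: int) -> str:
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syll)
    )


def _unique_word(rng: np.random.Generator, used: set[str], suffix: str = "", base_syll: int = 2) -> str:
    for _ in range(1000):
        n_syll = base_syll + int(rng.poisson(0.7))  # Poisson-shifted word length
        w = _make_stem(rng, n_syll) + suffix
        if w not in used:
            used.add(w)
            return w
    raise RuntimeError("could not generate a unique word form")


def make_lexicon(
    n_words: int = 900,
    seed: int = 0,
    *,
    zipf_exponent: float = 1.0,
    dim: int = 24,
) -> SyntheticLexicon:
    """Generate the synthetic lexicon, tag lexicon and embedding table.

    ``n_words`` counts content surfaces (verb lemmas contribute three
    inflected forms each). Frequencies follow log10 f/million =
    4.5 - zipf_exponent * log10(rank), so ~900 ranks span > 2 decades.
    """
    if n_words < 50:
        raise ValueError("n_words must be >= 50 to fill all word classes")
    rng = np.random.default_rng(seed)
    core = core_lexicon()
    used: set[str] = set(core.entries)

    n_lemmas = max(8, int(0.15 * n_words))
    n_nouns = max(10, int(0.45 * n_words))
    n_adj = max(5, int(0.12 * n_words))
    n_adv = max(5, int(0.08 * n_words))

    nouns = [_unique_word(rng, used, rng.choice(["a", "o", "e"])) for _ in range(n_nouns)]
    verbs = []
    for _ in range(n_lemmas):
        stem = _unique_word(rng, used, "")
        first, third, imperf = stem + "o", stem + "a", stem + "aba"
        if first in used or third in used or imperf in used:
            continue
        used.update((first, third, imperf))
        verbs.append((first, third, imperf))
    adjectives = [_unique_word(rng, used, rng.choice(["oso", "ivo", "al"])) for _ in range(n_adj)]
    adverbs = [_unique_word(rng, used, "mente") for _ in range(n_adv)]

    # global frequency ranks: function words first, then shuffled content
    function_words = list(core.entries)
    n_func = len(function_words)
    n_content_ranks = n_nouns + len(verbs) + n_adj + n_adv
    content_ranks = rng.permutation(np.arange(n_func + 1, n_func + n_content_ranks + 1))
    noun_ranks = content_ranks[:n_nouns]
    verb_ranks = content_ranks[n_nouns : n_nouns + len(verbs)]
    adj_ranks = content_ranks[n_nouns + len(verbs) : n_nouns + len(verbs) + n_adj]
    adv_ranks = content_ranks[n_nouns + len(verbs) + n_adj :]

    def logf(rank: float) -> float:
        return 4.5 - zipf_exponent * np.log10(rank)

    entries: dict[str, LexiconEntry] = {}

    def add_entry(surface: str, rank: float) -> None:
        length = len(surface)
        lam = 25.0 * np.exp(-0.3 * max(length - 3, 0))
        entries[surface] = LexiconEntry(
            surface=surface,
            log_freq=float(logf(rank)),
            phon_neighbors=int(rng.poisson(lam)),
            length_phonemes=length,
        )

    for i, w in enumerate(function_words):
        add_entry(w, i + 1)
    for w, r in zip(nouns, noun_ranks):
        add_entry(w, r)
    for (f1, f3, fi), r in zip(verbs, verb_ranks):
        for form in (f1, f3, fi):  # inflected forms share the lemma frequency
            add_entry(form, r)
    for w, r in zip(adjectives, adj_ranks):
        add_entry(w, r)
    for w, r in zip(adverbs, adv_ranks):
        add_entry(w, r)

    tag_entries: dict[str, tuple[str, str]] = {}
    for w in nouns:
        tag_entries[w] = ("NOUN", "none")
    for f1, f3, fi in verbs:
        tag_entries[f1] = ("VERB", "first")
        tag_entries[f3] = ("VERB", "third")
        tag_entries[fi] = ("VERB", "ambiguous")
    for w in adjectives:
        tag_entries[w] = ("ADJ", "none")
    for w in adverbs:
        tag_entries[w] = ("ADV", "none")
    tag_lexicon = core.merge(TagLexicon(entries=tag_entries))

    # embeddings: unit-sphere, clustered by word class
    content_surfaces: list[tuple[str, str]] = (
        [(w, "NOUN") for w in nouns]
        + [(f, "VERB") for trio in verbs for f in trio]
        + [(w, "ADJ") for w in adjectives]
        + [(w, "ADV") for w in adverbs]
    )
    # core content words (connectors, deictic adverbs, example nouns/verbs)
    # can be emitted too and need vectors for full embedding coverage
    content_surfaces += [
        (w, pos) for w, (pos, _) in core.entries.items()
        if pos in ("NOUN", "VERB", "ADJ", "ADV")
    ]
    centers = {pos: rng.normal(size=dim) for pos in ("NOUN", "VERB", "ADJ", "ADV")}
    for pos in centers:
        centers[pos] /= np.linalg.norm(centers[pos])
    vectors: dict[str, np.ndarray] = {}
    for surface, pos in content_surfaces:
        v = 1.5 * centers[pos] + rng.normal(size=dim)
        vectors[surface] = v / np.linalg.norm(v)
    embeddings = EmbeddingTable(vectors)

    return SyntheticLexicon(
        entries=entries,
        tag_lexicon=tag_lexicon,
        embeddings=embeddings,
        nouns=nouns,
        verbs=verbs,
        adjectives=adjectives,
        adverbs=adverbs,
        noun_ranks=np.asarray(noun_ranks, dtype=float),
        verb_ranks=np.asarray(verb_ranks, dtype=float),
        adj_ranks=np.asarray(adj_ranks, dtype=float),
        adv_ranks=np.asarray(adv_ranks, dtype=float),
        zipf_exponent=zipf_exponent,
    )


# --------------------------------------------------------------------------
# transcript generation

@dataclass
class SubjectParams:
    """Concrete per-subject probabilities after jitter and severity scaling."""

    p_third: float
    p_pronoun: float
    p_noun_subject: float
    p_nounslot: float
    p_adj: float
    p_ppslot: float
    p_adv: float
    p_imperfect: float
    p_poss: float
    p_deictic: float
    freq_alpha: float
    length: int
    p_filler: float
    p_fragment: float
    p_unintelligible: float


def draw_subject_params(
    baseline: BaselineParams,
    effect: GroupEffect,
    rng: np.random.Generator,
    min_length: int = 80,
) -> SubjectParams:
    has_offset = any(
        abs(x) > 0 for x in (effect.nounslot_offset, effect.freq_alpha_offset, effect.third_offset)
    )
    severity = max(0.0, rng.normal(1.0, effect.severity_sd)) if has_offset else 1.0
    return SubjectParams(
        p_third=float(np.clip(
            rng.normal(baseline.p_third + severity * effect.third_offset, baseline.sd_p_third),
            0.0, 1.0,
        )),
        p_pronoun=baseline.p_pronoun,
        p_noun_subject=baseline.p_noun_subject,
        p_nounslot=float(np.clip(
            rng.normal(baseline.p_nounslot + severity * effect.nounslot_offset, baseline.sd_p_nounslot),
            0.0, 1.0,
        )),
        p_adj=baseline.p_adj,
        p_ppslot=baseline.p_ppslot,
        p_adv=baseline.p_adv,
        p_imperfect=baseline.p_imperfect,
        p_poss=baseline.p_poss,
        p_deictic=baseline.p_deictic,
        freq_alpha=float(np.clip(
            rng.normal(baseline.freq_alpha + severity * effect.freq_alpha_offset, baseline.sd_freq_alpha),
            0.2, 3.0,
        )),
        length=int(max(min_length, rng.normal(effect.length_mean, effect.length_sd))),
        p_filler=baseline.p_filler,
        p_fragment=baseline.p_fragment,
        p_unintelligible=baseline.p_unintelligible,
    )


class _WordSampler:
    """Per-subject Zipf-tempered sampler over one word-class list."""

    def __init__(self, ranks: np.ndarray, alpha: float):
        w = ranks ** (-alpha)
        self.cdf = np.cumsum(w / w.sum())

    def draw(self, u: float) -> int:
        return int(np.searchsorted(self.cdf, u))


_ARTICLES = ("el", "la", "un", "una")
_PRON_THIRD = ("él", "ella")
_CONNECTORS = ("y", "después", "entonces", "luego")
_DEICTIC_ADVS = ("allí", "tarde", "temprano", "ahora")


def generate_transcript(
    params: SubjectParams,
    lexicon: SyntheticLexicon,
    rng: np.random.Generator,
) -> tuple[str, list[TaggedToken]]:
    """One routine-description monologue with parallel gold tags.

    Clause templates: optional connector; a subject that is dropped, an
    explicit pronoun (pronoun-verb tandem: two person markers) or — in
    the third person — a determiner+noun phrase; the inflected verb; an
    optional object NP (article or person-marked possessive, noun,
    optional adjective); optional prepositional and adverbial adjuncts.
    The imperfect (-aba) tense always carries its subject pronoun so the
    ambiguity stays resolvable. Gold tags cover analyzable words only;
    fillers/fragments/unintelligible marks appear in the text alone.
    """
    nouns = _WordSampler(lexicon.noun_ranks, params.freq_alpha)
    verbs = _WordSampler(lexicon.verb_ranks, params.freq_alpha)
    adjs = _WordSampler(lexicon.adj_ranks, params.freq_alpha)
    advs = _WordSampler(lexicon.adv_ranks, params.freq_alpha)

    gold: list[TaggedToken] = []
    pieces: list[str] = []
    n_words = 0
    sentence = 0
    index = 0

    def emit(surface: str, pos: str, person: str = "none") -> None:
        nonlocal n_words, index
        gold.append(TaggedToken(surface=surface, pos=pos, person=person,
                                sentence=sentence, index=index))
        pieces.append(surface)
        n_words += 1
        index += 1

    while n_words < params.length:
        sent_start = len(pieces)
        n_clauses = 1 + (rng.random() < 0.45)
        for ci in range(n_clauses):
            u = rng.random(16)
            if ci > 0:
                emit("y", "CONJ")
            elif u[0] < 0.25:
                conn = _CONNECTORS[int(u[1] * len(_CONNECTORS))]
                emit(conn, "CONJ" if conn == "y" else "ADV")

            person = "third" if u[2] < params.p_third else "first"
            imperfect = u[3] < params.p_imperfect

            # subject
            if imperfect:
                if person == "first":
                    emit("yo", "PRON", "first")
                else:
                    emit(_PRON_THIRD[int(u[4] * 2)], "PRON", "third")
            elif person == "third" and u[5] < params.p_noun_subject:
                emit(("el", "la")[int(u[4] * 2)], "DET")
                emit(lexicon.nouns[nouns.draw(u[6])], "NOUN")
            elif u[5] < params.p_noun_subject + params.p_pronoun:
                if person == "first":
                    emit("yo", "PRON", "first")
                else:
                    emit(_PRON_THIRD[int(u[4] * 2)], "PRON", "third")
            # else: pro-drop — the verb alone marks person

            # verb
            v1, v3, vi = lexicon.verbs[verbs.draw(u[7])]
            if imperfect:
                emit(vi, "VERB", person)
            else:
                emit(v1 if person == "first" else v3, "VERB", person)

            # object noun phrase, or a deictic adjunct in its place
            if u[8] < params.p_nounslot:
                if u[9] < params.p_poss:
                    emit("mi" if person == "first" else "su", "DET", person)
                else:
                    emit(_ARTICLES[int(u[9] * len(_ARTICLES))], "DET")
                emit(lexicon.nouns[nouns.draw(u[10])], "NOUN")
                if u[11] < params.p_adj:
                    emit(lexicon.adjectives[adjs.draw(u[12])], "ADJ")
            elif u[9] < params.p_deictic:
                emit(("por", "hasta", "desde", "en")[int(u[10] * 4)], "ADP")
                emit(_DEICTIC_ADVS[int(u[11] * len(_DEICTIC_ADVS))], "ADV")
                if u[12] < 0.35:
                    emit("también", "ADV")

            # adjuncts
            if u[13] < params.p_ppslot:
                emit(("a", "en", "de", "con")[int(u[14] * 4)], "ADP")
                emit(("el", "la")[int(u[4] * 2)], "DET")
                emit(lexicon.nouns[nouns.draw(u[15])], "NOUN")
            if u[13] > 1 - params.p_adv:
                emit(lexicon.adverbs[advs.draw(u[14])], "ADV")

            # transcription noise (text only, excluded from gold words)
            v = rng.random(3)
            if v[0] < params.p_filler:
                pieces.append("eh")
                n_words += 1  # fillers were spoken words
            if v[1] < params.p_fragment:
                frag = lexicon.nouns[nouns.draw(v[2])]
                pieces.append(frag[: max(2, len(frag) * 2 // 3)] + "…")
            if v[2] < params.p_unintelligible:
                pieces.append("[inaudible]")

        pieces[sent_start] = pieces[sent_start].capitalize()
        # attach the full stop only to a plain word; fragments ("…") and
        # unintelligible marks keep it separate so markers stay parseable
        if pieces[-1].endswith("…") or pieces[-1].endswith("]"):
            pieces.append(".")
        else:
            pieces[-1] = pieces[-1] + "."
        sentence += 1

    return " ".join(pieces), gold


# --------------------------------------------------------------------------
# cohorts

@dataclass
class SyntheticParticipant:
    participant_id: str
    group: str
    split: str  # "main" | "holdout"
    text: str
    gold: list[TaggedToken]
    scores: dict[str, float]

    def transcript(self) -> Transcript:
        return Transcript(
            participant_id=self.participant_id,
            group=self.group,
            tokens=tokenize(self.text),
            cognitive_scores=self.scores,
        )


@dataclass
class SyntheticCohort:
    config: CohortConfig
    lexicon: SyntheticLexicon
    participants: list[SyntheticParticipant]
    truth: dict

    def split(self, which: str) -> list[SyntheticParticipant]:
        return [p for p in self.participants if p.split == which]

    def gold_features(
        self, which: str = "main", config: FeatureConfig | None = None
    ) -> pd.DataFrame:
        rows: list[ParticipantFeatures] = []
        for p in self.split(which):
            rows.append(
                features_from_tags(
                    p.gold,
                    self.lexicon.entries,
                    self.lexicon.embeddings,
                    config=config,
                    participant_id=p.participant_id,
                    group=p.group,
                    cognitive_scores=p.scores,
                )
            )
        return features_table(rows, split=which)

    def write(self, outdir: str | Path) -> Path:
        from .tagging import write_tagged_tsv

        outdir = Path(outdir)
        (outdir / "transcripts").mkdir(parents=True, exist_ok=True)
        (outdir / "gold").mkdir(exist_ok=True)
        for p in self.participants:
            (outdir / "transcripts" / f"{p.participant_id}.txt").write_text(
                p.text, encoding="utf-8"
            )
            write_tagged_tsv(p.gold, outdir / "gold" / f"{p.participant_id}.tsv")
        for which in ("main", "holdout"):
            entries = [
                {
                    "participant_id": p.participant_id,
                    "group": p.group,
                    "path": f"transcripts/{p.participant_id}.txt",
                    "scores": p.scores,
                }
                for p in self.split(which)
            ]
            if entries:
                (outdir / f"{which}.json").write_text(
                    json.dumps({"split": which, "entries": entries}, indent=1),
                    encoding="utf-8",
                )
        save_property_lexicon(self.lexicon.entries, outdir / "lexicon.tsv")
        save_tag_lexicon(
            self.lexicon.tag_lexicon, outdir / "tag_lexicon.tsv", outdir / "suffix_rules.tsv"
        )
        self.lexicon.embeddings.to_tsv(outdir / "embeddings.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=1, default=float), encoding="utf-8"
        )
        return outdir


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    return float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate the full main + hold-out corpus with gold tags and truth record."""
    config = config or CohortConfig()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    lex_seed, subj_seed, score_seed = ss.spawn(3)
    lexicon = make_lexicon(
        config.lexicon_words,
        seed=int(lex_seed.generate_state(1)[0] % (2**31 - 1)),
        zipf_exponent=config.zipf_exponent,
        dim=config.embedding_dim,
    )
    subj_rng = np.random.default_rng(subj_seed)
    score_rng = np.random.default_rng(score_seed)

    participants: list[SyntheticParticipant] = []
    for split_name, sizes in (("main", config.n_main), ("holdout", config.n_holdout)):
        for group in ("AD", "bvFTD", "HC"):
            effect = config.effects[group]
            for i in range(sizes.get(group, 0)):
                params = draw_subject_params(
                    config.baseline, effect, subj_rng, config.min_length
                )
                text, gold = generate_transcript(params, lexicon, subj_rng)
                scores = {
                    test: float(np.clip(score_rng.normal(mu, sd), 0, 30))
                    for test, (mu, sd) in COGNITIVE_NORMS[group].items()
                }
                participants.append(
                    SyntheticParticipant(
                        participant_id=f"{group}_{split_name}_{i + 1:02d}",
                        group=group,
                        split=split_name,
                        text=text,
                        gold=gold,
                        scores=scores,
                    )
                )

    cohort = SyntheticCohort(config=config, lexicon=lexicon, participants=participants, truth={})
    feats = cohort.gold_features("main")
    realized = {}
    hc = feats[feats.group == "HC"]
    for group in ("AD", "bvFTD"):
        sub = feats[feats.group == group]
        if len(sub) and len(hc):
            realized[group] = {
                feat: _cohens_d(sub[feat].to_numpy(float), hc[feat].to_numpy(float))
                for feat in ("noun_ratio", "first_person_ratio", "third_person_ratio", "mean_log_freq")
            }
    cohort.truth = {
        "seed": config.seed,
        "baseline": asdict(config.baseline),
        "effects": {g: asdict(e) for g, e in config.effects.items()},
        "target_effects": TARGET_EFFECTS,
        "realized_d_main_vs_HC": realized,
        "word_count_means": {
            g: float(v) for g, v in feats.groupby("group")["word_count"].mean().items()
        },
    }
    return cohort


# --------------------------------------------------------------------------
# effect calibration

_PARAM_FEATURE = {
    "p_nounslot": "noun_ratio",
    "freq_alpha": "mean_log_freq",
    "p_third": "first_person_ratio",
}

_PARAM_OFFSET_FIELD = {
    "p_nounslot": "nounslot_offset",
    "freq_alpha": "freq_alpha_offset",
    "p_third": "third_offset",
}

_PARAM_BOUNDS = {
    "p_nounslot": (-0.45, 0.45),
    "freq_alpha": (-1.5, 1.5),
    "p_third": (-0.6, 0.6),
}


def _feature_value(gold: Sequence[TaggedToken], lexicon: SyntheticLexicon, feature: str) -> float:
    if feature == "noun_ratio":
        return sum(1 for t in gold if t.pos == "NOUN") / len(gold)
    if feature == "first_person_ratio":
        first = sum(1 for t in gold if t.person == "first")
        third = sum(1 for t in gold if t.person == "third")
        return first / (first + third) if first + third else np.nan
    if feature == "mean_log_freq":
        vals = [lexicon.entries[t.surface].log_freq for t in gold
                if t.pos in ("NOUN", "VERB", "ADJ", "ADV")]
        return float(np.mean(vals))
    raise ValueError(f"unsupported calibration feature {feature!r}")


def realized_effect(
    param_name: str,
    offset: float,
    base_params: BaselineParams,
    lexicon: SyntheticLexicon,
    *,
    patient_effect: GroupEffect | None = None,
    n_sim: int = 2000,
    seed: int = 0,
    length_mean: float = 270.0,
    length_sd: float = 80.0,
    severity_sd: float = 0.35,
    hc_length_mean: float | None = None,
) -> float:
    """Monte-Carlo Cohen's d (patient - control) for one parameter offset."""
    feature = _PARAM_FEATURE[param_name]
    field_name = _PARAM_OFFSET_FIELD[param_name]
    hc = GroupEffect(
        name="HC",
        length_mean=hc_length_mean if hc_length_mean is not None else length_mean,
        length_sd=length_sd,
        severity_sd=0.0,
    )
    patient = patient_effect or GroupEffect(
        name="patient", length_mean=length_mean, length_sd=length_sd, severity_sd=severity_sd
    )
    patient = replace(patient, **{field_name: offset})
    rng = np.random.default_rng(seed)
    per_group = max(2, n_sim // 2)
    vals = {"hc": np.empty(per_group), "pat": np.empty(per_group)}
    for key, effect in (("hc", hc), ("pat", patient)):
        for i in range(per_group):
            params = draw_subject_params(base_params, effect, rng)
            _, gold = generate_transcript(params, lexicon, rng)
            vals[key][i] = _feature_value(gold, lexicon, feature)
    return _cohens_d(vals["pat"], vals["hc"])


def calibrate_effect(
    param_name: str,
    target_d: float,
    base_params: BaselineParams | None = None,
    *,
    lexicon: SyntheticLexicon | None = None,
    n_sim: int = 2000,
    seed: int = 0,
    tol: float = 0.05,
    max_iter: int = 30,
    **sim_kwargs,
) -> float:
    """Bisection on a generator parameter until the realized Cohen's d of
    its associated feature hits ``target_d`` within ``tol``.

    Uses common random numbers (the same seed for every evaluation) so
    the Monte-Carlo response is monotone and smooth in the offset; a
    non-bracketing response raises with a diagnostic curve.
    """
    base_params = base_params or BaselineParams()
    if lexicon is None:
        lexicon = make_lexicon(seed=seed)
    lo, hi = _PARAM_BOUNDS[param_name]

    def f(offset: float) -> float:
        return realized_effect(
            param_name, offset, base_params, lexicon, n_sim=n_sim, seed=seed, **sim_kwargs
        )

    if abs(target_d) < tol:
        return 0.0
    f_lo, f_hi = f(lo), f(hi)
    if not (min(f_lo, f_hi) <= target_d <= max(f_lo, f_hi)):
        raise ValueError(
            f"target d={target_d} not bracketed for {param_name}: "
            f"d({lo})={f_lo:.3f}, d({hi})={f_hi:.3f} (non-monotone or out of range)"
        )
    sign = 1.0 if f_hi >= f_lo else -1.0
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        d_mid = f(mid)
        if abs(d_mid - target_d) < tol:
            return mid
        if sign * (d_mid - target_d) < 0:
            lo = mid
        else:
            hi = mid
    logger.warning("calibration hit max_iter for %s (last d=%.3f)", param_name, d_mid)
    return mid
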