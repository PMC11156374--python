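import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_lexicon():
    from speechmarkers.simulate import make_lexicon

    return make_lexicon(300, seed=3)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort shared across tests."""
    from speechmarkers.simulate import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return default_cohort.gold_features("main")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


# --- manually gold-tagged versions of the two printed example sentences ---

@pytest.fixture(scope="session")
def example_sentence_1_tags():
    """'La señora se levanta primero, después voy yo.' — 8 words:
    1 noun (señora), 2 verbs (levanta third, voy first); person markers
    first={voy, yo}, third={levanta, se}."""
    from speechmarkers.tagging import TaggedToken

    spec = [
        ("la", "DET", "none"),
        ("señora", "NOUN", "none"),
        ("se", "PRON", "third"),
        ("levanta", "VERB", "third"),
        ("primero", "ADV", "none"),
        ("después", "ADV", "none"),
        ("voy", "VERB", "first"),
        ("yo", "PRON", "first"),
    ]
    return [TaggedToken(s, p, per, sentence=0, index=i) for i, (s, p, per) in enumerate(spec)]


@pytest.fixture(scope="session")
def example_sentence_2_tags():
    """'Mi hijo llega y entonces me deja las llaves y dice que si quiero
    me deja las puertas abiertas.' — person markers first={mi, me,
    quiero, me}, third={llega, deja, dice, deja}."""
    from speechmarkers.tagging import TaggedToken

    spec = [
        ("mi", "DET", "first"),
        ("hijo", "NOUN", "none"),
        ("llega", "VERB", "third"),
        ("y", "CONJ", "none"),
        ("entonces", "ADV", "none"),
        ("me", "PRON", "first"),
        ("deja", "VERB", "third"),
        ("las", "DET", "none"),
        ("llaves", "NOUN", "none"),
        ("y", "CONJ", "none"),
        ("dice", "VERB", "third"),
        ("que", "CONJ", "none"),
        ("si", "CONJ", "none"),
        ("quiero", "VERB", "first"),
        ("me", "PRON", "first"),
        ("deja", "VERB", "third"),
        ("las", "DET", "none"),
        ("puertas", "NOUN", "none"),
        ("abiertas", "ADJ", "none"),
    ]
    return [TaggedToken(s, p, per, sentence=0, index=i) for i, (s, p, per) in enumerate(spec)]
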