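"""Transcript normalization and verb extraction.

The normalization pipeline has a fixed order: (1) lowercase, (2) strip
accents/diacritics, (3) drop tokens containing digits, (4) drop punctuation,
(5) drop stopwords, (6) lemmatize survivors. Part-of-speech tagging runs on
the *raw* token stream (taggers need case, diacritics and context), and verb
lemmas are normalized afterwards so they live in the same string space as
the corpus vocabulary.

Linguistic resources are injected through a :class:`LinguisticBackend`, so
synthetic corpora and tests can use an exact dictionary backend while real
Spanish transcripts use the rule-based backend in this module (or any
user-supplied tagger/lemmatizer wrapped in the same interface).
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Callable, Iterable

logger = logging.getLogger(__name__)

_WORD_RE = re.compile(r"\w+", re.UNICODE)
_DIGIT_RE = re.compile(r"\d")

#: frequent Spanish function words; deliberately small — callers with
#: stronger requirements inject their own list through the backend.
SPANISH_STOPWORDS = frozenset(
    """a al algo ante antes como con contra cual cuando de del desde donde
    durante e el ella ellas ellos en entre era eran es esa esas ese eso esos
    esta estaba estaban estas este esto estos fue fueron ha habia han hasta
    hay la las le les lo los mas me mi mientras muy nada ni no nos o otra
    otras otro otros para pero poco por porque que quien se ser si sin sobre
    son soy su sus tambien te tenia tiene todo todos tras tu un una unas uno
    unos y ya yo""".split()
)


def tokenize(text: str) -> list[str]:
    """Split on Unicode word boundaries (keeps case and diacritics)."""
    return _WORD_RE.findall(text)


def strip_accents(word: str, keep_enye: bool = True) -> str:
    """Remove combining diacritics via NFD decomposition.

    ``ñ`` is a letter of the Spanish alphabet, not an accented ``n``, so it
    is preserved by default.
    """
    out = []
    for ch in word:
        if keep_enye and ch in ("ñ", "Ñ"):
            out.append(ch)
            continue
        decomposed = unicodedata.normalize("NFD", ch)
        out.append("".join(c for c in decomposed if not unicodedata.combining(c)))
    return "".join(out)


@dataclass
class LinguisticBackend:
    """Injectable lemmatizer + POS tagger + stopword list.

    ``pos_tag`` maps a raw token sequence to a same-length tag sequence using
    the coarse universal tags (``VERB`` is the only tag the pipeline acts
    on). Both callables must be deterministic.
    """

    lemmatize: Callable[[str], str]
    pos_tag: Callable[[list[str]], list[str]]
    stopwords: frozenset[str] = frozenset()
    keep_enye: bool = True


def dictionary_backend(
    lemmas: dict[str, str] | None = None,
    tags: dict[str, str] | None = None,
    stopwords: Iterable[str] = (),
    default_tag: str = "NOUN",
    keep_enye: bool = True,
) -> LinguisticBackend:
    """Exact lookup backend: identity lemma / default tag for unlisted words.

    Lookups are case-insensitive and accent-insensitive so the tag map can be
    written in normalized form while tagging runs on raw tokens.
    """
    lemma_map = {k.lower(): v for k, v in (lemmas or {}).items()}
    tag_map = {k.lower(): v for k, v in (tags or {}).items()}

    def _key(word: str) -> str:
        return strip_accents(word.lower(), keep_enye=keep_enye)

    return LinguisticBackend(
        lemmatize=lambda w: lemma_map.get(_key(w), _key(w)),
        pos_tag=lambda toks: [tag_map.get(_key(t), default_tag) for t in toks],
        stopwords=frozenset(strip_accents(s.lower(), keep_enye) for s in stopwords),
        keep_enye=keep_enye,
    )


# Regular Spanish verb inflections, longest-first so e.g. "aríamos" wins
# over "amos". Coverage is heuristic: enough for regular -ar/-er/-ir forms.
_VERB_SUFFIXES: list[tuple[str, str]] = sorted(
    [
        ("aríamos", "ar"), ("eríamos", "er"), ("iríamos", "ir"),
        ("aríais", "ar"), ("ábamos", "ar"), ("áramos", "ar"), ("ásemos", "ar"),
        ("iéramos", "ir"), ("iésemos", "ir"),
        ("aremos", "ar"), ("eremos", "er"), ("iremos", "ir"),
        ("asteis", "ar"), ("isteis", "ir"),
        ("arían", "ar"), ("erían", "er"), ("irían", "ir"),
        ("arías", "ar"), ("aban", "ar"), ("abas", "ar"), ("aba", "ar"),
        ("aran", "ar"), ("asen", "ar"), ("aron", "ar"), ("aste", "ar"),
        ("amos", "ar"), ("emos", "er"), ("imos", "ir"),
        ("ando", "ar"), ("iendo", "er"),
        ("ieron", "ir"), ("ían", "er"), ("ías", "er"), ("ía", "er"),
        ("arán", "ar"), ("erán", "er"), ("irán", "ir"),
        ("ará", "ar"), ("erá", "er"), ("irá", "ir"),
        ("aré", "ar"), ("eré", "er"), ("iré", "ir"),
        ("ado", "ar"), ("ido", "ir"),
        ("áis", "ar"), ("éis", "er"),
        ("an", "ar"), ("as", "ar"), ("en", "er"), ("es", "er"),
        ("ó", "ar"), ("é", "ar"), ("í", "ir"), ("a", "ar"), ("e", "er"), ("o", "ar"),
    ],
    key=lambda p: -len(p[0]),
)


def _rule_lemmatize_es(word: str) -> str:
    w = word.lower()
    if w.endswith(("ar", "er", "ir")) and len(w) > 3:
        return w
    for suffix, infinitive in _VERB_SUFFIXES:
        if w.endswith(suffix) and len(w) - len(suffix) >= 2:
            return w[: -len(suffix)] + infinitive
    return w


_VERBY_END = re.compile(
    r"(?:ar|er|ir|aba|ando|iendo|ado|ido|aron|ieron|aban|ían|amos|emos|imos|ó)$"
)


def _rule_tag_es(tokens: list[str]) -> list[str]:
    tags = []
    for tok in tokens:
        w = strip_accents(tok.lower())
        if w in SPANISH_STOPWORDS:
            tags.append("DET")
        elif _VERBY_END.search(tok.lower()) and len(tok) > 3:
            tags.append("VERB")
        else:
            tags.append("NOUN")
    return tags


def spanish_rule_backend(stopwords: Iterable[str] | None = None) -> LinguisticBackend:
    """Heuristic Spanish backend: suffix-based lemmatizer and verb tagger.

    A coarse, dependency-free approximation for exploratory runs on real
    Spanish transcripts; studies that need accurate tagging should wrap a
    full tagger in a :class:`LinguisticBackend` instead.
    """
    sw = frozenset(stopwords) if stopwords is not None else SPANISH_STOPWORDS
    return LinguisticBackend(
        lemmatize=_rule_lemmatize_es, pos_tag=_rule_tag_es, stopwords=sw
    )


def normalize(raw_text: str, backend: LinguisticBackend) -> list[str]:
    """Run the fixed normalization pipeline; may legally return []."""
    lemmas = []
    for token in tokenize(raw_text.lower()):
        token = strip_accents(token, keep_enye=backend.keep_enye)
        if _DIGIT_RE.search(token):
            continue
        # tokenize() already removed punctuation; a token can still end up
        # empty if it was all combining marks
        if not token or token in backend.stopwords:
            continue
        lemma = backend.lemmatize(token)
        # a lemma can itself be a stopword (e.g. "era" -> "ser"); keep the
        # no-stopword invariant on the output
        if lemma and lemma not in backend.stopwords:
            lemmas.append(lemma)
    if not lemmas:
        logger.info("normalize: no tokens survived preprocessing")
    return lemmas


def extract_verbs(raw_text: str, backend: LinguisticBackend) -> list[str]:
    """Verb lemmas in order of occurrence, duplicates preserved.

    Tagging sees the raw token stream; the returned lemmas are normalized
    (lowercased, accent-stripped, digit/stopword-filtered) so they match the
    vocabulary produced by :func:`normalize`.
    """
    tokens = tokenize(raw_text)
    if not tokens:
        return []
    try:
        tags = backend.pos_tag(tokens)
    except Exception:  # pragma: no cover - defensive per contract
        logger.warning("POS tagger failed; returning no verbs", exc_info=True)
        return []
    verbs = []
    for token, tag in zip(tokens, tags):
        if tag != "VERB":
            continue
        lemma = strip_accents(
            backend.lemmatize(token).lower(), keep_enye=backend.keep_enye
        )
        if not lemma or _DIGIT_RE.search(lemma) or lemma in backend.stopwords:
            continue
        verbs.append(lemma)
    return verbs


@dataclass(frozen=True)
class ProcessedDocument:
    """A transcript after normalization and verb extraction."""

    participant_id: str
    condition: str
    lemmas: tuple[str, ...]
    verbs: tuple[str, ...]


def process_transcript(transcript, backend: LinguisticBackend) -> ProcessedDocument:
    return ProcessedDocument(
        participant_id=transcript.participant_id,
        condition=transcript.condition,
        lemmas=tuple(normalize(transcript.raw_text, backend)),
        verbs=tuple(extract_verbs(transcript.raw_text, backend)),
    )
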