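"""Synthetic retelling studies.

Generates complete studies — two reference stories with disjoint verb
inventories, per-participant retellings, and clinical metadata — so the
whole pipeline (I/O, preprocessing, LSA, P-RSF, ANCOVA, classification) can
be exercised end-to-end without any external data or linguistic tooling.

The generative model mirrors the study design it emulates: an action text
(AT) whose verbs describe bodily movement and a non-action text (nAT) whose
verbs do not, each with a fixed verb inventory. A participant's retelling
retains each reference verb independently with a probability that depends on
(group, condition) — the group-by-text retention profile is the effect the
pipeline must recover. Retained verbs may surface as near-synonym
paraphrases (tokens that share the verb's latent semantic field), and
retellings are padded with off-field distractor words and function words.
Covariates (MoCA, IFS) are drawn from group-specific normal models,
independent of retention within group by default.

Synthetic "words" are letter-only tokens with assigned latent vectors; the
matching dictionary backend (identity lemmas, fixed tag map) removes any
dependence on real taggers, which is what makes downstream checks exact.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import ParticipantRecord, Transcript
from .preprocess import LinguisticBackend, SPANISH_STOPWORDS, dictionary_backend

GROUP_PREFIX = {"HC": "hc", "PD-nMCI": "pn", "PD-MCI": "pm"}
_STOPWORD_POOL = ("el", "la", "de", "que", "y", "en", "un", "se", "no", "con")


def _alpha(i: int) -> str:
    """Letter-only index suffix (a, b, ..., z, ba, bb, ...): normalization
    deletes tokens containing digits, so synthetic tokens must avoid them."""
    letters = string.ascii_lowercase
    out = ""
    while True:
        out = letters[i % 26] + out
        i //= 26
        if i == 0:
            return out


@dataclass
class SimConfig:
    """All knobs of the generative model; generation is a pure function of
    this object (including ``seed``)."""

    n_per_group: dict[str, int]
    retention: dict[tuple[str, str], float]  # (group, condition) -> prob
    n_ref_verbs: int = 32  # verb inventory per reference story
    n_paraphrases: int = 2  # near-synonym variants per reference verb
    paraphrase_rate: float = 0.2  # P(retained verb surfaces as a paraphrase)
    distractor_rate: float = 8.0  # expected off-field fillers per retelling
    n_distractor_pool: int = 30
    latent_dim: int = 12
    paraphrase_cos: float = 0.85  # latent cosine of a paraphrase to its verb
    covariate_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )  # group -> {"moca": (mean, sd), "ifs": (mean, sd)}
    updrs3_model: tuple[float, float] = (31.0, 12.5)  # PD groups only
    confound_covariates: bool = False  # couple MoCA to a participant's retention
    seed: int = 0

    def __post_init__(self) -> None:
        for key, p in self.retention.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"retention{key} = {p} outside [0, 1]")
        if self.n_ref_verbs < 5:
            raise ValueError("n_ref_verbs must be >= 5")
        for group in self.n_per_group:
            for cond in ("AT", "nAT"):
                if (group, cond) not in self.retention:
                    raise ValueError(f"retention missing cell ({group}, {cond})")


@dataclass
class SyntheticStudy:
    """A generated study plus the ground truth that produced it."""

    transcripts: list[Transcript]
    metadata: list[ParticipantRecord]
    story_verbs: dict[str, list[str]]  # condition -> full inventory, story order
    lexicon_tags: dict[str, str]  # token -> POS tag for the dictionary backend
    latent_vectors: dict[str, np.ndarray]
    truth: dict  # config + per-(participant, condition) retained verb indices
    config: SimConfig

    def backend(self) -> LinguisticBackend:
        """Dictionary backend matching this study's lexicon exactly."""
        return dictionary_backend(
            tags=self.lexicon_tags, stopwords=SPANISH_STOPWORDS
        )


def _verb_token(cond: str, j: int) -> str:
    return f"{cond.lower()}verb{_alpha(j)}"


def _paraphrase_token(cond: str, j: int, k: int) -> str:
    return f"{cond.lower()}par{_alpha(j)}{_alpha(k)}"


def _distractor_token(cond: str, i: int) -> str:
    return f"{cond.lower()}fill{_alpha(i)}"


def _latent_vectors(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Unit latent vectors: each verb anchors a field; its paraphrases sit at
    cosine ~``paraphrase_cos`` from it; distractors are random directions."""
    vecs: dict[str, np.ndarray] = {}
    d = config.latent_dim
    for cond in ("AT", "nAT"):
        for j in range(config.n_ref_verbs):
            v = rng.normal(size=d)
            v /= np.linalg.norm(v)
            vecs[_verb_token(cond, j)] = v
            for k in range(config.n_paraphrases):
                noise = rng.normal(size=d)
                noise -= (noise @ v) * v  # orthogonal component
                noise /= np.linalg.norm(noise)
                c = config.paraphrase_cos
                p = c * v + np.sqrt(1 - c**2) * noise
                vecs[_paraphrase_token(cond, j, k)] = p
        for i in range(config.n_distractor_pool):
            u = rng.normal(size=d)
            vecs[_distractor_token(cond, i)] = u / np.linalg.norm(u)
    return vecs


def _render_text(tokens: list[str], rng: np.random.Generator) -> str:
    """Interleave function words and punctuation around the content tokens."""
    if not tokens:
        tokens = ["eh"]  # filled-pause placeholder; never a reference verb
    words: list[str] = []
    for tok in tokens:
        if rng.random() < 0.4:
            words.append(_STOPWORD_POOL[rng.integers(len(_STOPWORD_POOL))])
        words.append(tok)
    sentences = []
    for start in range(0, len(words), 8):
        chunk = words[start : start + 8]
        chunk[0] = chunk[0].capitalize()
        sentences.append(" ".join(chunk) + ".")
    return " ".join(sentences)


def generate_study(config: SimConfig) -> SyntheticStudy:
    """Generate transcripts + metadata per the config; deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    latent = _latent_vectors(config, rng)

    story_verbs = {
        cond: [_verb_token(cond, j) for j in range(config.n_ref_verbs)]
        for cond in ("AT", "nAT")
    }
    lexicon_tags: dict[str, str] = {}
    for cond in ("AT", "nAT"):
        for j in range(config.n_ref_verbs):
            lexicon_tags[_verb_token(cond, j)] = "VERB"
            for k in range(config.n_paraphrases):
                lexicon_tags[_paraphrase_token(cond, j, k)] = "VERB"
        for i in range(config.n_distractor_pool):
            lexicon_tags[_distractor_token(cond, i)] = "NOUN"
    lexicon_tags["eh"] = "INTJ"

    transcripts: list[Transcript] = []
    metadata: list[ParticipantRecord] = []
    retained_truth: dict[tuple[str, str], tuple[int, ...]] = {}

    for group in sorted(config.n_per_group):
        prefix = GROUP_PREFIX.get(group, group.lower()[:2])
        cov = config.covariate_model.get(group, {})
        moca_mean, moca_sd = cov.get("moca", (26.0, 2.0))
        ifs_mean, ifs_sd = cov.get("ifs", (21.0, 3.0))
        for i in range(config.n_per_group[group]):
            pid = f"{prefix}{i + 1:03d}"
            retention_shift = 0.0
            moca = float(np.clip(rng.normal(moca_mean, moca_sd), 0, 30))
            if config.confound_covariates:
                # worse cognition -> lower retention, within-group
                retention_shift = 0.05 * (moca - moca_mean) / max(moca_sd, 1e-9)
            ifs = float(np.clip(rng.normal(ifs_mean, ifs_sd), 0, 30))
            if group == "HC":
                updrs3 = float("nan")
            else:
                updrs3 = float(max(rng.normal(*config.updrs3_model), 0.0))
            metadata.append(
                ParticipantRecord(
                    participant_id=pid, group=group, moca=moca, ifs=ifs, updrs3=updrs3
                )
            )
            for cond in ("AT", "nAT"):
                p_keep = float(
                    np.clip(config.retention[(group, cond)] + retention_shift, 0, 1)
                )
                kept = np.nonzero(rng.random(config.n_ref_verbs) < p_keep)[0]
                retained_truth[(pid, cond)] = tuple(int(j) for j in kept)
                content: list[str] = []
                for j in kept:
                    if rng.random() < config.paraphrase_rate:
                        k = int(rng.integers(config.n_paraphrases))
                        content.append(_paraphrase_token(cond, j, k))
                    else:
                        content.append(_verb_token(cond, j))
                n_fill = int(rng.poisson(config.distractor_rate))
                content.extend(
                    _distractor_token(cond, int(rng.integers(config.n_distractor_pool)))
                    for _ in range(n_fill)
                )
                order = rng.permutation(len(content))
                content = [content[t] for t in order]
                transcripts.append(
                    Transcript(pid, cond, _render_text(content, rng))
                )

    return SyntheticStudy(
        transcripts=transcripts,
        metadata=metadata,
        story_verbs=story_verbs,
        lexicon_tags=lexicon_tags,
        latent_vectors=latent,
        truth={"config": config, "retained": retained_truth},
        config=config,
    )


def default_pd_scenario(seed: int = 0, n_per_group: dict[str, int] | None = None) -> SimConfig:
    """The emulated study conditions: healthy controls retain both stories'
    verbs well; patients without MCI lose action verbs selectively; patients
    with MCI lose verbs of both stories. Cognitive covariates shift
    downward across HC -> PD-nMCI -> PD-MCI."""
    return SimConfig(
        n_per_group=n_per_group or {"HC": 40, "PD-nMCI": 24, "PD-MCI": 16},
        retention={
            ("HC", "AT"): 0.8,
            ("HC", "nAT"): 0.8,
            ("PD-nMCI", "AT"): 0.5,
            ("PD-nMCI", "nAT"): 0.8,
            ("PD-MCI", "AT"): 0.5,
            ("PD-MCI", "nAT"): 0.55,
        },
        covariate_model={
            "HC": {"moca": (26.7, 1.63), "ifs": (22.9, 2.67)},
            "PD-nMCI": {"moca": (26.2, 1.5), "ifs": (20.3, 3.2)},
            "PD-MCI": {"moca": (22.0, 1.8), "ifs": (18.4, 3.4)},
        },
        seed=seed,
    )


def null_scenario(seed: int = 0, n_per_group: dict[str, int] | None = None) -> SimConfig:
    """No group effect: every group retains both texts' verbs equally."""
    groups = n_per_group or {"HC": 40, "PD-nMCI": 24, "PD-MCI": 16}
    base = default_pd_scenario(seed, groups)
    base.retention = {
        (g, cond): 0.65 for g in groups for cond in ("AT", "nAT")
    }
    return base
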