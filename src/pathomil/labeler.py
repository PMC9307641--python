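"""Weak-label extraction from free-text colon pathology reports.

A rule-based re-implementation of unsupervised concept extraction from
diagnostic reports: gazetteer-driven named entity recognition (greedy longest
match over token n-grams), entity linking by exact match, curated ad-hoc
rules, or normalized edit-distance similarity, optional negation detection,
and mapping of the surviving concepts onto the five-class multilabel schema
with a guaranteed ``normal`` fallback.

The recognizer is pluggable: any callable with the signature of
:func:`recognize_mentions` can replace the shipped gazetteer matcher (for
instance a neural biomedical NER model); the rest of the pipeline only sees
:class:`EntityMention` objects.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Callable, Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .schema import (
    AnnotationClass,
    SchemaError,
    labels_to_frame,
    make_label,
)
from .text import Token, normalize_text, term_tokens, tokenize

logger = logging.getLogger(__name__)


class LabelerError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class ReportRecord:
    """One free-text report, optionally linked to image case ids."""

    report_id: str
    text: str
    case_ids: tuple[str, ...] = ()
    source_language: str | None = None

    def __post_init__(self):
        if not self.text or not self.text.strip():
            raise LabelerError(f"report {self.report_id!r} has empty text")


@dataclass(frozen=True)
class GazetteerEntry:
    concept_id: str
    preferred_term: str
    synonyms: tuple[str, ...] = ()
    mapped_class: AnnotationClass | None = None
    grade_sensitive: bool = False

    def __post_init__(self):
        if not self.preferred_term:
            raise LabelerError(f"{self.concept_id}: empty preferred term")

    @property
    def terms(self) -> tuple[str, ...]:
        return (self.preferred_term, *self.synonyms)


@dataclass(frozen=True)
class EntityMention:
    """A surface match in the normalized text.

    ``span`` is a 0-based half-open character interval into the normalized
    text; ``surface`` equals the normalized-text slice at that span.
    """

    span: tuple[int, int]
    surface: str
    candidate_ids: tuple[str, ...]
    sentence: int = 0
    token_range: tuple[int, int] = (0, 0)

    def __post_init__(self):
        if self.span[0] >= self.span[1]:
            raise LabelerError(f"degenerate mention span {self.span}")
        if not self.candidate_ids:
            raise LabelerError("mention without candidate concepts")


@dataclass(frozen=True)
class LinkedConcept:
    """An ontology concept linked to a mention, with provenance."""

    concept_id: str
    method: str  # exact | adhoc_rule | similarity
    score: float
    negated: bool = False
    grade: str | None = None  # low | high
    suppressed: bool = False
    surface: str = ""
    span: tuple[int, int] | None = None


@dataclass
class LabelerConfig:
    """Knobs of the rule-based labeler that the underlying method leaves open."""

    similarity_threshold: float = 0.85
    negation_enabled: bool = True
    negation_window: int = 5
    unspecified_grade_class: AnnotationClass = AnnotationClass.low_grade_dysplasia
    context_rules_enabled: bool = True
    fallback_class: AnnotationClass = AnnotationClass.normal

    def __post_init__(self):
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise LabelerError("similarity_threshold must be in (0, 1]")
        if self.negation_window < 1:
            raise LabelerError("negation_window must be >= 1")
        if isinstance(self.unspecified_grade_class, str):
            self.unspecified_grade_class = AnnotationClass.from_name(
                self.unspecified_grade_class
            )


# ---------------------------------------------------------------------------
# Gazetteer loading and indexing


def load_gazetteer(path=None) -> list[GazetteerEntry]:
    """Read a gazetteer TSV (concept_id, preferred_term, synonyms, mapped_class,
    grade_sensitive).  Without ``path`` the bundled colon gazetteer is used."""
    if path is None:
        with resources.files("pathomil.data").joinpath("gazetteer.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    else:
        table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    entries = []
    for _, row in table.iterrows():
        synonyms = tuple(
            dict.fromkeys(s.strip() for s in row["synonyms"].split("|") if s.strip())
        )
        mapped = row["mapped_class"].strip()
        entries.append(
            GazetteerEntry(
                concept_id=row["concept_id"],
                preferred_term=row["preferred_term"],
                synonyms=synonyms,
                mapped_class=AnnotationClass.from_name(mapped) if mapped else None,
                grade_sensitive=str(row["grade_sensitive"]).strip() in {"1", "true", "True"},
            )
        )
    return entries


class GazetteerIndex:
    """Token n-gram index over normalized terms, shared by matcher and linker."""

    def __init__(self, entries: Sequence[GazetteerEntry]):
        if not entries:
            raise LabelerError("gazetteer is empty")
        self.entries = list(entries)
        self.by_id = {e.concept_id: e for e in self.entries}
        if len(self.by_id) != len(self.entries):
            raise LabelerError("duplicate concept_id in gazetteer")
        self.ngram_index: dict[tuple[str, ...], list[str]] = {}
        self.term_strings: list[tuple[str, str]] = []  # (normalized term, concept_id)
        for entry in self.entries:
            for term in entry.terms:
                toks = term_tokens(term)
                if not toks:
                    continue
                ids = self.ngram_index.setdefault(toks, [])
                if entry.concept_id not in ids:
                    ids.append(entry.concept_id)
                self.term_strings.append((" ".join(toks), entry.concept_id))
        self.max_ngram = max(len(k) for k in self.ngram_index)

    def mapped_class(self, concept_id: str) -> AnnotationClass | None:
        return self.by_id[concept_id].mapped_class

    def grade_sensitive(self, concept_id: str) -> bool:
        return self.by_id[concept_id].grade_sensitive


def _as_index(gazetteer) -> GazetteerIndex:
    if isinstance(gazetteer, GazetteerIndex):
        return gazetteer
    return GazetteerIndex(list(gazetteer))


# ---------------------------------------------------------------------------
# Recognition


def recognize_mentions(normalized: str, gazetteer) -> list[EntityMention]:
    """Greedy longest-match left-to-right over token n-grams.

    Matches never overlap and never cross a sentence boundary; every mention
    carries all concept ids whose term matched that token sequence.
    """
    index = _as_index(gazetteer)
    tokens = tokenize(normalized)
    mentions: list[EntityMention] = []
    i = 0
    while i < len(tokens):
        hit = None
        max_n = min(index.max_ngram, len(tokens) - i)
        for n in range(max_n, 0, -1):
            window = tokens[i : i + n]
            if window[-1].sentence != window[0].sentence:
                continue
            ids = index.ngram_index.get(tuple(t.text for t in window))
            if ids:
                hit = (n, ids)
                break
        if hit is None:
            i += 1
            continue
        n, ids = hit
        start, end = tokens[i].start, tokens[i + n - 1].end
        mentions.append(
            EntityMention(
                span=(start, end),
                surface=normalized[start:end],
                candidate_ids=tuple(sorted(ids)),
                sentence=tokens[i].sentence,
                token_range=(i, i + n),
            )
        )
        i += n
    return mentions


# ---------------------------------------------------------------------------
# Linking


#: Curated ad-hoc surface patterns -> concept id.  A reconstruction of the
#: hand-tuned rules of the original extraction tool (which are unpublished);
#: versioned with the package.
ADHOC_RULES: tuple[tuple[re.Pattern, str], ...] = (
    (re.compile(r"\b(severe|marked)\s+dysplas\w+"), "colon:high-grade-dysplasia"),
    (re.compile(r"\b(mild|moderate|slight)\s+dysplas\w+"), "colon:low-grade-dysplasia"),
    (re.compile(r"\badenocarcinom\w+"), "colon:adenocarcinoma"),
    (re.compile(r"\bcarcinom\w+"), "colon:carcinoma"),
    (re.compile(r"\bhyperplas\w+"), "colon:hyperplastic-polyp"),
    (re.compile(r"\badenom\w+"), "colon:adenoma"),
)


def similarity_ratio(a: str, b: str) -> float:
    """Normalized Levenshtein ratio 1 - d / max(|a|, |b|)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b)["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def link_mention(mention, gazetteer, config: LabelerConfig | None = None) -> LinkedConcept | None:
    """Link a recognized mention or a raw candidate surface to a concept.

    Exact normalized equality to a term wins (score 1.0); otherwise curated
    ad-hoc patterns; otherwise the best similarity over all terms, accepted at
    or above the configured threshold.  Ties break by (higher score, then
    lexicographically smallest concept id).  Returns None when nothing links.
    """
    config = config or LabelerConfig()
    index = _as_index(gazetteer)
    if isinstance(mention, EntityMention):
        # recognize_mentions only emits exact term hits
        concept_id = min(mention.candidate_ids)
        return LinkedConcept(
            concept_id=concept_id,
            method="exact",
            score=1.0,
            surface=mention.surface,
            span=mention.span,
        )
    surface = str(mention)
    toks = term_tokens(surface)
    if not toks:
        return None
    canonical = " ".join(toks)
    ids = index.ngram_index.get(tuple(toks))
    if ids:
        return LinkedConcept(concept_id=min(ids), method="exact", score=1.0, surface=surface)
    for pattern, concept_id in ADHOC_RULES:
        if concept_id in index.by_id and pattern.search(canonical):
            return LinkedConcept(
                concept_id=concept_id, method="adhoc_rule", score=1.0, surface=surface
            )
    best: tuple[float, str] | None = None
    for term, concept_id in index.term_strings:
        score = similarity_ratio(canonical, term)
        if score < config.similarity_threshold:
            continue
        if best is None or score > best[0] + 1e-12 or (
            abs(score - best[0]) <= 1e-12 and concept_id < best[1]
        ):
            best = (score, concept_id)
    if best is None:
        return None
    return LinkedConcept(
        concept_id=best[1], method="similarity", score=best[0], surface=surface
    )


# ---------------------------------------------------------------------------
# Negation and context rules


NEGATION_CUES: tuple[tuple[str, ...], ...] = (
    ("no",),
    ("not",),
    ("without",),
    ("absence", "of"),
    ("free", "of"),
    ("negative", "for"),
)

_MARGIN_CONTEXT = ({"margin", "margins"}, "resection")


def detect_negation(
    normalized: str,
    mention: EntityMention,
    config: LabelerConfig | None = None,
    tokens: list[Token] | None = None,
) -> bool:
    """True iff a negation cue ends within ``negation_window`` tokens before
    the mention, with no intervening sentence boundary."""
    config = config or LabelerConfig()
    tokens = tokens if tokens is not None else tokenize(normalized)
    first = mention.token_range[0]
    preceding = [
        t for t in tokens[:first] if t.sentence == mention.sentence
    ][-config.negation_window :]
    words = [t.text for t in preceding]
    for cue in NEGATION_CUES:
        k = len(cue)
        for j in range(len(words) - k + 1):
            if tuple(words[j : j + k]) == cue:
                return True
    return False


def _margin_context(tokens: list[Token], mention: EntityMention) -> bool:
    """True when the mention sits in a resection-margin clause (same sentence,
    'margin ... resection' appearing before the mention)."""
    words = [
        t.text
        for t in tokens[: mention.token_range[0]]
        if t.sentence == mention.sentence
    ]
    return _MARGIN_CONTEXT[1] in words and bool(_MARGIN_CONTEXT[0] & set(words))


# ---------------------------------------------------------------------------
# Grade resolution

_HIGH_GRADE_CUES = {"severe", "marked", "high"}
_LOW_GRADE_CUES = {"mild", "moderate", "slight", "low"}


def _resolve_grade(tokens: list[Token], mention: EntityMention) -> str | None:
    """Nearest grade adjective in the mention's sentence; ties prefer the
    preceding one.  None when the sentence carries no grade cue."""
    lo, hi = mention.token_range
    best: tuple[int, int, str] | None = None  # (distance, after-flag, grade)
    for idx, tok in enumerate(tokens):
        if tok.sentence != mention.sentence or lo <= idx < hi:
            continue
        if tok.text in _HIGH_GRADE_CUES:
            grade = "high"
        elif tok.text in _LOW_GRADE_CUES:
            grade = "low"
        else:
            continue
        dist = lo - idx if idx < lo else idx - hi + 1
        key = (dist, 0 if idx < lo else 1, grade)
        if best is None or key[:2] < best[:2]:
            best = key
    return best[2] if best else None


_GRADE_TO_CLASS = {
    "high": AnnotationClass.high_grade_dysplasia,
    "low": AnnotationClass.low_grade_dysplasia,
}

_STOPWORDS = frozenset(
    "the a an of with and or in on at for is are was were from to no not without".split()
)


# ---------------------------------------------------------------------------
# Report-level labeling


def label_report(
    report: ReportRecord | str,
    gazetteer,
    config: LabelerConfig | None = None,
) -> tuple[np.ndarray, list[LinkedConcept]]:
    """Label one report: recognize, link, negate, grade-resolve, map, fall back.

    Returns the 5-class label vector (never all-zero: the ``normal`` fallback
    fires when no class survives) and the full linked-concept trace, including
    negated/suppressed concepts.
    """
    config = config or LabelerConfig()
    index = _as_index(gazetteer)
    text = report.text if isinstance(report, ReportRecord) else report
    normalized, _ = normalize_text(text)
    tokens = tokenize(normalized)
    mentions = recognize_mentions(normalized, index)

    covered = np.zeros(len(tokens), dtype=bool)
    for m in mentions:
        covered[m.token_range[0] : m.token_range[1]] = True

    linked: list[tuple[LinkedConcept, EntityMention | None]] = []
    for m in mentions:
        concept = link_mention(m, index, config)
        if concept is not None:
            linked.append((concept, m))

    # Fuzzy pass over uncovered tokens (typos and unseen morphology).
    for idx, tok in enumerate(tokens):
        if covered[idx] or len(tok.text) < 5 or tok.text in _STOPWORDS:
            continue
        if not tok.text.isalpha():
            continue
        concept = link_mention(tok.text, index, config)
        if concept is None or concept.method == "exact":
            continue
        pseudo = EntityMention(
            span=(tok.start, tok.end),
            surface=tok.text,
            candidate_ids=(concept.concept_id,),
            sentence=tok.sentence,
            token_range=(idx, idx + 1),
        )
        linked.append(
            (
                LinkedConcept(
                    concept_id=concept.concept_id,
                    method=concept.method,
                    score=concept.score,
                    surface=tok.text,
                    span=(tok.start, tok.end),
                ),
                pseudo,
            )
        )

    classes: set[AnnotationClass] = set()
    trace: list[LinkedConcept] = []
    for concept, mention in linked:
        entry = index.by_id[concept.concept_id]
        negated = False
        suppressed = False
        grade = None
        if mention is not None:
            if config.negation_enabled:
                negated = detect_negation(normalized, mention, config, tokens)
            if (
                config.context_rules_enabled
                and (
                    entry.mapped_class is AnnotationClass.hyperplastic_polyp
                    or entry.grade_sensitive
                )
                and _margin_context(tokens, mention)
            ):
                suppressed = True
        mapped = entry.mapped_class
        if entry.grade_sensitive:
            grade = _resolve_grade(tokens, mention) if mention is not None else None
            effective = grade or (
                "high"
                if config.unspecified_grade_class is AnnotationClass.high_grade_dysplasia
                else "low"
            )
            mapped = _GRADE_TO_CLASS[effective] if grade else config.unspecified_grade_class
        concept = LinkedConcept(
            concept_id=concept.concept_id,
            method=concept.method,
            score=concept.score,
            negated=negated,
            grade=grade,
            suppressed=suppressed,
            surface=concept.surface,
            span=concept.span,
        )
        trace.append(concept)
        if mapped is not None and not negated and not suppressed:
            classes.add(mapped)

    if not classes:
        classes = {config.fallback_class}
    return make_label(classes), trace


def label_corpus(
    reports: Sequence[ReportRecord],
    gazetteer,
    config: LabelerConfig | None = None,
    gt: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Label a corpus; optionally score agreement against a ground-truth table.

    Returns the label table (case_id + indicator columns, one row per report)
    and an agreement report (empty dict when no ground truth is given).
    """
    ids = [r.report_id for r in reports]
    if len(set(ids)) != len(ids):
        raise LabelerError("duplicate report_id in corpus")
    index = _as_index(gazetteer)
    labels = np.vstack([label_report(r, index, config)[0] for r in reports])
    table = labels_to_frame(ids, labels)
    agreement: dict = {}
    if gt is not None:
        from .metrics import micro_accuracy, weighted_f1
        from .schema import frame_to_labels

        gt_ids, gt_labels = frame_to_labels(gt)
        order = {cid: i for i, cid in enumerate(gt_ids)}
        if set(order) != set(ids):
            raise LabelerError("ground-truth case_ids do not match the corpus")
        gt_aligned = gt_labels[[order[c] for c in ids]]
        f1, per_class = weighted_f1(gt_aligned, labels)
        agreement = {
            "micro_accuracy": micro_accuracy(gt_aligned, labels),
            "weighted_f1": f1,
            "per_class_f1": per_class,
        }
    return table, agreement


def write_trace_jsonl(traces: dict[str, list[LinkedConcept]], path) -> None:
    with open(path, "w") as fh:
        for report_id, concepts in traces.items():
            fh.write(
                json.dumps({"report_id": report_id, "concepts": [asdict(c) for c in concepts]})
                + "\n"
            )


def read_reports_jsonl(path) -> list[ReportRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(
                ReportRecord(
                    report_id=str(obj["report_id"]),
                    text=obj["text"],
                    case_ids=tuple(obj.get("case_ids", ())),
                    source_language=obj.get("source_language"),
                )
            )
    return records


def write_reports_jsonl(reports: Iterable[ReportRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "report_id": r.report_id,
                        "text": r.text,
                        "case_ids": list(r.case_ids),
                        "source_language": r.source_language,
                    }
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Estimator facade


class ReportLabeler(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style facade over the rule-based report labeler.

    ``fit`` compiles the gazetteer index (there are no trainable parameters);
    ``predict`` maps reports to the 5-column multilabel indicator matrix.

    Parameters
    ----------
    gazetteer : path, list of GazetteerEntry, or None
        Concept table; None loads the bundled colon gazetteer.
    similarity_threshold : float
        Minimum normalized Levenshtein ratio for fuzzy linking.
    negation_enabled : bool
        Discard concepts asserted absent.  Disabling reproduces the
        documented failure mode of purely affirmative extraction.
    negation_window : int
        Token lookback for negation cues within a sentence.
    unspecified_grade_class : str
        Class assigned to grade-sensitive concepts with no grade adjective.
    context_rules_enabled : bool
        Suppress hyperplastic-polyp concepts inside resection-margin clauses.
    translator : callable or None
        Optional text -> text hook applied before normalization (for
        non-English reports); none ships with the package.
    """

    def __init__(
        self,
        gazetteer=None,
        similarity_threshold: float = 0.85,
        negation_enabled: bool = True,
        negation_window: int = 5,
        unspecified_grade_class: str = "low_grade_dysplasia",
        context_rules_enabled: bool = True,
        translator: Callable[[str], str] | None = None,
    ):
        self.gazetteer = gazetteer
        self.similarity_threshold = similarity_threshold
        self.negation_enabled = negation_enabled
        self.negation_window = negation_window
        self.unspecified_grade_class = unspecified_grade_class
        self.context_rules_enabled = context_rules_enabled
        self.translator = translator

    def _config(self) -> LabelerConfig:
        return LabelerConfig(
            similarity_threshold=self.similarity_threshold,
            negation_enabled=self.negation_enabled,
            negation_window=self.negation_window,
            unspecified_grade_class=AnnotationClass.from_name(self.unspecified_grade_class)
            if isinstance(self.unspecified_grade_class, str)
            else self.unspecified_grade_class,
            context_rules_enabled=self.context_rules_enabled,
        )

    def fit(self, X=None, y=None):
        gaz = self.gazetteer
        if gaz is None:
            entries = load_gazetteer()
        elif isinstance(gaz, (str,)) or hasattr(gaz, "__fspath__"):
            entries = load_gazetteer(gaz)
        else:
            entries = list(gaz)
        self.index_ = GazetteerIndex(entries)
        self.config_ = self._config()
        return self

    def _text(self, item) -> str:
        text = item.text if isinstance(item, ReportRecord) else str(item)
        return self.translator(text) if self.translator is not None else text

    def annotate(self, item) -> tuple[np.ndarray, list[LinkedConcept]]:
        """Label one report and return (label vector, linked-concept trace)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "index_")
        return label_report(self._text(item), self.index_, self.config_)

    def predict(self, X) -> np.ndarray:
        return np.vstack([self.annotate(item)[0] for item in X])
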