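"""Free-text medication and comorbidity annotation.

Converts the free-text medication history and medical history of a patient
into binary drug-class and condition flags by matching tokens against a
term->code lexicon with a two-level string comparator:

1. exact match of the case-folded token against a lexicon term;
2. otherwise, for tokens and terms of at least four characters, an
   approximate match under the normalized Damerau-Levenshtein (optimal
   string alignment) similarity, accepted at similarity >= 0.85.

A match is discarded when a negation cue ("patient does not take ...",
"kein ...") occurs within a short look-behind window.  Condition
descriptions may span several tokens and are matched with a moving window
of size (description length + 2), scoring the mean of per-token best
similarities.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "Lexicon",
    "LexiconEntry",
    "Token",
    "MatchResult",
    "AnnotationReport",
    "tokenize",
    "dl_distance",
    "similarity",
    "match_token",
    "detect_negation",
    "annotate_medications",
    "annotate_conditions",
    "DEFAULT_NEGATION_TERMS",
    "DEFAULT_NEGATION_WINDOW",
    "DEFAULT_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.85
DEFAULT_NEGATION_WINDOW = 3
# English and German cues; "ohne" = without, "kein/keine" = no/none,
# "nicht" = not, "gestoppt"/"abgesetzt" = stopped/discontinued.
DEFAULT_NEGATION_TERMS = frozenset(
    {
        "no",
        "not",
        "without",
        "stopped",
        "discontinued",
        "never",
        "kein",
        "keine",
        "nicht",
        "ohne",
        "gestoppt",
        "abgesetzt",
    }
)

# Maximal runs of letters/digits, optionally hyphen-joined.
_TOKEN_RE = re.compile(r"[^\W_]+(?:-[^\W_]+)*", re.UNICODE)
_HAS_LETTER_RE = re.compile(r"[^\W\d_]", re.UNICODE)
_HAS_DIGIT_RE = re.compile(r"\d")


@dataclass(frozen=True)
class Token:
    """A case-folded token with its character span in the source text.

    ``clause_start`` marks tokens preceded by clause punctuation
    (comma, semicolon, period, ...); negation scope never crosses a
    clause boundary.
    """

    text: str
    start: int
    end: int
    clause_start: bool = False

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class LexiconEntry:
    term: str
    code: str
    kind: str  # drug-generic | drug-brand | condition
    language: str = "en"


@dataclass(frozen=True)
class MatchResult:
    code: str
    matched_term: str
    source_span: tuple[int, int]  # token index range [start, end)
    match_type: str  # exact | approximate
    similarity: float
    negated: bool = False


@dataclass
class AnnotationReport:
    """Per-patient annotation outcome.

    ``codes`` holds the accepted (non-negated) class identifiers;
    negated matches are kept in ``matches`` for audit but never
    contribute a code.
    """

    codes: set[str] = field(default_factory=set)
    matches: list[MatchResult] = field(default_factory=list)
    n_exact: int = 0
    n_approximate: int = 0
    n_negated: int = 0
    n_rejected: int = 0
    excluded: bool = False


class Lexicon:
    """Term -> code index for drugs (generic + brand) or conditions."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: list[LexiconEntry] = []
        self._by_term: dict[str, LexiconEntry] = {}
        for raw in entries:
            term = _normalize_term(raw.term)
            if not term:
                raise ValueError("empty lexicon term")
            entry = LexiconEntry(term, raw.code, raw.kind, raw.language)
            if term in self._by_term:
                raise ValueError(f"duplicate lexicon term after normalization: {term!r}")
            self._by_term[term] = entry
            self.entries.append(entry)
        if not self.entries:
            raise ValueError("lexicon is empty")
        codes = {e.code for e in self.entries}
        self.codes: list[str] = sorted(codes)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return _normalize_term(term) in self._by_term

    def get(self, term: str) -> Optional[LexiconEntry]:
        return self._by_term.get(_normalize_term(term))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], default_kind: str = "drug-generic") -> "Lexicon":
        entries = []
        for p in pairs:
            if len(p) == 2:
                term, code = p
                entries.append(LexiconEntry(term, code, default_kind))
            elif len(p) == 3:
                term, code, extra = p
                if extra in {"en", "de"}:
                    entries.append(LexiconEntry(term, code, "condition", extra))
                else:
                    entries.append(LexiconEntry(term, code, extra))
            else:
                entries.append(LexiconEntry(*p))
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "Lexicon":
        """Load from a CSV with columns term,code,kind[,language]."""
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"term", "code", "kind"}
            if reader.fieldnames is None or not required.issubset(reader.fieldnames):
                raise ValueError(f"lexicon CSV must have columns {sorted(required)}")
            for row in reader:
                entries.append(
                    LexiconEntry(
                        row["term"], row["code"], row["kind"], row.get("language") or "en"
                    )
                )
        return cls(entries)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["term", "code", "kind", "language"])
            for e in self.entries:
                writer.writerow([e.term, e.code, e.kind, e.language])


def default_drug_lexicon() -> Lexicon:
    from ._lexicon_data import DRUG_ENTRIES

    return Lexicon(LexiconEntry(t, c, k) for t, c, k in DRUG_ENTRIES)


def default_condition_lexicon() -> Lexicon:
    from ._lexicon_data import CONDITION_ENTRIES

    return Lexicon(LexiconEntry(t, c, "condition", lang) for t, c, lang in CONDITION_ENTRIES)


def _normalize_term(term: str) -> str:
    return " ".join(term.casefold().split())


def tokenize(text: Optional[str]) -> list[Token]:
    """Split free text into case-folded tokens, keeping character spans.

    Tokens are maximal runs of letters/digits (hyphen-joined runs stay
    one token); everything else separates.  Empty or missing text yields
    an empty sequence.
    """
    if not text:
        return []
    folded = text.casefold()
    tokens = []
    prev_end = 0
    for m in _TOKEN_RE.finditer(folded):
        sep = folded[prev_end : m.start()]
        boundary = bool(tokens) and any(ch in ",;.!?\n" for ch in sep)
        tokens.append(Token(m.group(0), m.start(), m.end(), boundary))
        prev_end = m.end()
    return tokens


def dl_distance(a: str, b: str) -> int:
    """Damerau-Levenshtein distance, optimal string alignment variant.

    Counts insertions, deletions, substitutions and adjacent
    transpositions; a substring is not edited twice.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[lb]


def similarity(a: str, b: str) -> float:
    """Normalized similarity 1 - DL(a, b) / max(|a|, |b|), in [0, 1].

    Symmetric; 1.0 iff the strings are equal (two empty strings count
    as equal).
    """
    if not a and not b:
        return 1.0
    denom = max(len(a), len(b))
    return 1.0 - dl_distance(a, b) / denom


def _is_candidate(token: str) -> bool:
    # Number-bearing tokens ("40mg") never match lexicon terms.
    return (
        len(token) >= 3
        and _HAS_LETTER_RE.search(token) is not None
        and _HAS_DIGIT_RE.search(token) is None
    )


def match_token(
    token: str,
    lexicon: Lexicon,
    threshold: float = DEFAULT_THRESHOLD,
) -> Optional[MatchResult]:
    """Two-level comparator for a single token.

    Exact lexicon hits win outright.  Otherwise an approximate match is
    sought among terms where both strings have at least four characters,
    accepted at ``similarity >= threshold``; among equal similarities the
    longer term, then the lexicographically smaller code, is retained.
    Returns ``None`` when nothing qualifies.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    tok = token.casefold()
    if not _is_candidate(tok):
        return None
    hit = lexicon.get(tok)
    if hit is not None:
        return MatchResult(hit.code, hit.term, (0, 1), "exact", 1.0)
    best: Optional[tuple[float, LexiconEntry]] = None
    for entry in lexicon.entries:
        if " " in entry.term:
            continue  # multi-token terms are handled by the window matcher
        if min(len(tok), len(entry.term)) < 4:
            continue  # short strings: exact only
        sim = similarity(tok, entry.term)
        if sim < threshold:
            continue
        if best is None or _beats(sim, entry, best):
            best = (sim, entry)
    if best is None:
        return None
    sim, entry = best
    return MatchResult(entry.code, entry.term, (0, 1), "approximate", sim)


def _beats(sim: float, entry: LexiconEntry, best: tuple[float, "LexiconEntry"]) -> bool:
    """Deterministic ordering: higher similarity, then longer term, then smaller code."""
    bsim, bentry = best
    if sim != bsim:
        return sim > bsim
    if len(entry.term) != len(bentry.term):
        return len(entry.term) > len(bentry.term)
    return entry.code < bentry.code


def detect_negation(
    tokens: Sequence[Token | str],
    span: tuple[int, int],
    negation_terms: Iterable[str] = DEFAULT_NEGATION_TERMS,
    window: int = DEFAULT_NEGATION_WINDOW,
) -> bool:
    """True iff a negation cue occurs within `window` tokens before `span`,
    without crossing a clause boundary."""
    cues = {t.casefold() for t in negation_terms}
    start = span[0]
    if start < len(tokens):
        t0 = tokens[start]
        if isinstance(t0, Token) and t0.clause_start:
            return False  # the span opens its clause: nothing precedes it
    lo = max(0, start - window)
    for idx in range(start - 1, lo - 1, -1):
        t = tokens[idx]
        text = t.text if isinstance(t, Token) else str(t).casefold()
        if text in cues:
            return True
        if isinstance(t, Token) and t.clause_start:
            return False  # this token opened the clause; stop looking back
    return False


def annotate_medications(
    text: Optional[str],
    lexicon: Lexicon,
    threshold: float = DEFAULT_THRESHOLD,
    negation_terms: Iterable[str] = DEFAULT_NEGATION_TERMS,
    negation_window: int = DEFAULT_NEGATION_WINDOW,
) -> AnnotationReport:
    """Annotate one patient's medication history.

    A missing or empty history marks the record for exclusion (the study
    flow drops patients with unknown or incomplete medication data).
    """
    report = AnnotationReport()
    if text is None or (isinstance(text, float)) or not str(text).strip():
        report.excluded = True
        return report
    tokens = tokenize(str(text))
    for i, tok in enumerate(tokens):
        m = match_token(tok.text, lexicon, threshold)
        if m is None:
            if _is_candidate(tok.text):
                report.n_rejected += 1
            continue
        negated = detect_negation(tokens, (i, i + 1), negation_terms, negation_window)
        m = MatchResult(m.code, m.matched_term, (i, i + 1), m.match_type, m.similarity, negated)
        report.matches.append(m)
        if negated:
            report.n_negated += 1
            continue
        if m.match_type == "exact":
            report.n_exact += 1
        else:
            report.n_approximate += 1
        report.codes.add(m.code)
    return report


def _token_pair_similarity(a: str, b: str) -> float:
    """Two-level per-token similarity inside a condition window."""
    if not _is_candidate(a) or not _is_candidate(b):
        return 1.0 if a == b and _is_candidate(a) else 0.0
    if a == b:
        return 1.0
    if min(len(a), len(b)) < 4:
        return 0.0  # short strings: exact only
    return similarity(a, b)


def _score_window_aligned(
    description_tokens: Sequence[str], window_tokens: Sequence[str]
) -> tuple[float, int]:
    """Mean of per-token best similarities and the offset of the first
    window token participating in the alignment."""
    if not description_tokens:
        return 0.0, 0
    total = 0.0
    first = 0
    seen_any = False
    for d in description_tokens:
        best, best_at = 0.0, None
        for k, w in enumerate(window_tokens):
            s = _token_pair_similarity(d, w)
            if s > best:
                best, best_at = s, k
        total += best
        if best_at is not None and (not seen_any or best_at < first):
            first, seen_any = best_at, True
    return total / len(description_tokens), first


def score_window(description_tokens: Sequence[str], window_tokens: Sequence[str]) -> float:
    """Mean over description tokens of the best per-token similarity in the window."""
    return _score_window_aligned(description_tokens, window_tokens)[0]


def annotate_conditions(
    text: Optional[str],
    lexicon: Lexicon,
    threshold: float = DEFAULT_THRESHOLD,
    negation_terms: Iterable[str] = DEFAULT_NEGATION_TERMS,
    negation_window: int = DEFAULT_NEGATION_WINDOW,
) -> AnnotationReport:
    """Annotate one patient's free-text medical history.

    For each lexicon description of k tokens a window of k + 2 tokens
    slides across the history (tolerating missing or extra words); the
    window is accepted when the mean of per-token best similarities
    reaches the threshold and no negation cue precedes the window.
    Missing history yields an empty report (conditions are covariates,
    not an exclusion criterion).
    """
    report = AnnotationReport()
    if text is None or isinstance(text, float) or not str(text).strip():
        return report
    tokens = tokenize(str(text))
    token_texts = [t.text for t in tokens]
    n = len(token_texts)
    for entry in lexicon.entries:
        desc = entry.term.split()
        w = len(desc) + 2
        best_score, best_start, best_anchor = 0.0, None, 0
        for start in range(max(1, n - w + 1) if n else 0):
            window = token_texts[start : start + w]
            s, anchor = _score_window_aligned(desc, window)
            if s > best_score:
                best_score, best_start, best_anchor = s, start, start + anchor
        if best_start is None or best_score < threshold:
            if n:
                report.n_rejected += 1
            continue
        # negation scope anchors at the first aligned token, so a cue
        # sitting inside the window ("kein bluthochdruck") still counts
        negated = detect_negation(
            tokens, (best_anchor, best_start + w), negation_terms, negation_window
        )
        mtype = "exact" if best_score == 1.0 else "approximate"
        m = MatchResult(
            entry.code, entry.term, (best_start, best_start + w), mtype, best_score, negated
        )
        report.matches.append(m)
        if negated:
            report.n_negated += 1
            continue
        if mtype == "exact":
            report.n_exact += 1
        else:
            report.n_approximate += 1
        report.codes.add(m.code)
    return report
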