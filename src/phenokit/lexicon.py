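"""Keyword lexicon for ACS symptom matching in clinical free text.

Production EMR query languages often lack regular expressions, so matching is
literal, case-insensitive substring search over an explicit list of term
variants (canonical spelling plus misspellings and abbreviations).  The
lexicon is built by a corpus-frequency admission rule: a candidate term enters
the final list only if its variants appear in at least ``min_count`` documents
of a triage-text corpus (default threshold 20, an arbitrary but conventional
cut-off at corpus sizes around 30,000 forms).

Short abbreviations ("cp", "sob") are pathologically promiscuous as raw
substrings, so variants shorter than ``word_boundary_below`` characters are
matched as whole alphanumeric tokens by default; longer variants use plain
substring semantics.  Both behaviours are configurable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 20
DEFAULT_WORD_BOUNDARY_BELOW = 4


@dataclass(frozen=True)
class LexiconTerm:
    """One search term: a canonical form and its literal variants."""

    canonical: str
    variants: tuple[str, ...]
    source: str = "clinician_seed"  # or "chart_review_extension"

    def __post_init__(self):
        canonical = self.canonical.lower()
        variants = tuple(dict.fromkeys(v.lower() for v in self.variants))
        if canonical not in variants:
            variants = (canonical,) + variants
        if any(not v for v in variants):
            raise ValueError(f"term {canonical!r}: empty variant")
        object.__setattr__(self, "canonical", canonical)
        object.__setattr__(self, "variants", variants)


@dataclass
class Lexicon:
    """An admitted set of search terms plus the matching configuration."""

    terms: list[LexiconTerm]
    min_count: int = DEFAULT_MIN_COUNT
    word_boundary_below: int = DEFAULT_WORD_BOUNDARY_BELOW

    def __post_init__(self):
        if self.min_count < 1:
            raise ValueError(f"min_count must be >= 1, got {self.min_count}")
        canonicals = [t.canonical for t in self.terms]
        if len(set(canonicals)) != len(canonicals):
            dupes = sorted({c for c in canonicals if canonicals.count(c) > 1})
            raise ValueError(f"duplicate canonical terms: {dupes}")

    def all_variants(self) -> list[str]:
        return [v for t in self.terms for v in t.variants]


def _tokens(text: str) -> list[str]:
    """Lower-case alphanumeric tokens (split on every non-alphanumeric char)."""
    out, cur = [], []
    for ch in text.lower():
        if ch.isalnum():
            cur.append(ch)
        elif cur:
            out.append("".join(cur))
            cur = []
    if cur:
        out.append("".join(cur))
    return out


def variant_matches(text: str, variant: str, word_boundary_below: int = DEFAULT_WORD_BOUNDARY_BELOW) -> bool:
    """Case-insensitive literal match of one variant against a text.

    Variants shorter than ``word_boundary_below`` characters must match a
    whole token; longer variants match anywhere as a substring.
    """
    if not text or not variant:
        return False
    variant = variant.lower()
    if len(variant) < word_boundary_below:
        return variant in _tokens(text)
    return variant in text.lower()


def match_text(text: str, lexicon: Lexicon) -> set[str]:
    """Canonical terms whose variants occur in ``text`` (deduplicated)."""
    if not text:
        return set()
    return {
        term.canonical
        for term in lexicon.terms
        if any(variant_matches(text, v, lexicon.word_boundary_below) for v in term.variants)
    }


def count_term_frequency(
    corpus: list[str],
    candidates: list[LexiconTerm],
    word_boundary_below: int = DEFAULT_WORD_BOUNDARY_BELOW,
    occurrence_level: bool = False,
) -> dict[str, int]:
    """Corpus frequency of each candidate term.

    Document-level by default: a document counts once per term no matter how
    many variants (or repeats) it contains.  ``occurrence_level=True`` instead
    counts every non-overlapping occurrence of every variant.
    """
    counts = {t.canonical: 0 for t in candidates}
    for doc in corpus:
        if not doc:
            continue
        low = doc.lower()
        toks = _tokens(doc)
        for term in candidates:
            if occurrence_level:
                for v in term.variants:
                    if len(v) < word_boundary_below:
                        counts[term.canonical] += sum(1 for t in toks if t == v)
                    else:
                        counts[term.canonical] += low.count(v)
            else:
                if any(variant_matches(doc, v, word_boundary_below) for v in term.variants):
                    counts[term.canonical] += 1
    return counts


def build_lexicon(
    seed_terms: list[LexiconTerm],
    corpus: list[str],
    min_count: int = DEFAULT_MIN_COUNT,
    word_boundary_below: int = DEFAULT_WORD_BOUNDARY_BELOW,
    exempt_seed_terms: bool = False,
    occurrence_level: bool = False,
) -> Lexicon:
    """Admit candidates whose corpus frequency is at least ``min_count``.

    The threshold is inclusive ("at least").  With ``exempt_seed_terms``,
    clinician seed terms bypass the frequency check and only chart-review
    extensions are filtered.  Admission decisions are logged per term.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if not seed_terms:
        raise ValueError("seed_terms must be non-empty")
    freq = count_term_frequency(corpus, seed_terms, word_boundary_below, occurrence_level)
    admitted = []
    for term in sorted(seed_terms, key=lambda t: t.canonical):
        exempt = exempt_seed_terms and term.source == "clinician_seed"
        ok = exempt or freq[term.canonical] >= min_count
        logger.info(
            "term %r: frequency %d, threshold %d -> %s%s",
            term.canonical, freq[term.canonical], min_count,
            "admitted" if ok else "excluded", " (seed exempt)" if exempt else "",
        )
        if ok:
            admitted.append(term)
    return Lexicon(terms=admitted, min_count=min_count, word_boundary_below=word_boundary_below)


def default_lexicon() -> Lexicon:
    """Packaged stand-in ACS term list.

    The study's actual term list is not public, so this ships a small set of
    clinician-plausible ACS symptom terms with example misspelling and
    abbreviation variants.  It exercises the matching mechanism and is fully
    overridable via :func:`read_term_file`.
    """
    terms = [
        LexiconTerm("chest pain", ("chest pain", "chest pian", "chets pain", "cp")),
        LexiconTerm("chest tightness", ("chest tightness", "chest tightnes", "tight chest")),
        LexiconTerm("chest heaviness", ("chest heaviness", "heavy chest")),
        LexiconTerm("angina", ("angina", "anginal")),
        LexiconTerm("palpitations", ("palpitations", "palpitation", "palpatations")),
        LexiconTerm("shortness of breath", ("shortness of breath", "short of breath", "sob")),
        LexiconTerm("acs", ("acs",)),
        LexiconTerm("diaphoresis", ("diaphoresis", "diaphoretic", "sweaty")),
    ]
    return Lexicon(terms=terms)


def read_term_file(path: str | Path) -> list[LexiconTerm]:
    """Read a term list from CSV with columns canonical, variant, source."""
    groups: dict[str, dict] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"canonical", "variant", "source"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"term file must have columns {sorted(required)}")
        for row in reader:
            g = groups.setdefault(row["canonical"].lower(),
                                  {"variants": [], "source": row["source"]})
            g["variants"].append(row["variant"])
    return [LexiconTerm(c, tuple(g["variants"]), g["source"]) for c, g in groups.items()]


def write_term_file(terms: list[LexiconTerm] | Lexicon, path: str | Path) -> None:
    if isinstance(terms, Lexicon):
        terms = terms.terms
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["canonical", "variant", "source"])
        for t in terms:
            for v in t.variants:
                writer.writerow([t.canonical, v, t.source])
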