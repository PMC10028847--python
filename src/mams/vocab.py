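"""Controlled vocabularies for MAMS term fields.

Each term-valued field (``processing``, ``analyte``, ``obs_subset``, ...)
has a suggested vocabulary whose terms carry descriptions and an optional
child-of hierarchy (e.g. ``counts`` is a child of ``raw``). All
vocabularies are *open*: any text may be supplied so the fields can adapt
to future scenarios, and a custom term accompanied by its
``<field>_description`` twin is considered conformant. Lookup is therefore
total — it returns a :class:`Term`, :data:`UNKNOWN_TERM`, or
:data:`NO_VOCABULARY` and never raises for ordinary strings.

Vocabularies are shipped as flat TSV tables (token, description, parent,
aliases, provenance) under ``mams/data/vocab`` so they can be extended
without code changes. The provenance column distinguishes terms the
standard enumerates (``builtin``) from parents inferred from description
wording (``inferred``) and suggestion-only term sets (``provisional``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .schema import MamsError

__all__ = [
    "Term",
    "Vocabulary",
    "UNKNOWN_TERM",
    "NO_VOCABULARY",
    "UnknownTermError",
    "builtin_vocabularies",
    "term_lookup",
    "is_descendant",
    "normalize_token",
]


class UnknownTermError(MamsError):
    """A hierarchy query named a token absent from the vocabulary."""


class _Marker:
    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return self._name

    def __bool__(self) -> bool:
        return False


#: The token is not in the (open) vocabulary — not an error.
UNKNOWN_TERM = _Marker("UNKNOWN_TERM")
#: No builtin vocabulary governs the queried field key.
NO_VOCABULARY = _Marker("NO_VOCABULARY")

_NORMALIZE_RE = re.compile(r"[\s_\-]+")


def normalize_token(token: str) -> str:
    """Fold a token to canonical form: lower-case, separators removed.

    "log normalized", "log-normalized" and "lognormalized" all normalize
    identically; the original string as written in a document is preserved
    elsewhere.
    """
    return _NORMALIZE_RE.sub("", str(token).strip().lower())


@dataclass(frozen=True)
class Term:
    """One controlled-vocabulary term."""

    token: str
    description: str
    parent: str | None = None
    aliases: tuple[str, ...] = ()
    provenance: str = "builtin"


@dataclass
class Vocabulary:
    """A named controlled vocabulary governing one MAMS field.

    ``enforced`` marks vocabularies whose terms the validator checks
    (suggestion-only sets like ``obs_unit`` are never flagged); ``open``
    is always True — custom terms are permitted everywhere.
    """

    field_key: str
    terms: dict[str, Term] = field(default_factory=dict)  # by token
    open: bool = True
    enforced: bool = True
    _index: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            for term in self.terms.values():
                self._register(term)

    def _register(self, term: Term) -> None:
        for name in (term.token, *term.aliases):
            folded = normalize_token(name)
            existing = self._index.get(folded)
            if existing is not None and existing != term.token:
                raise MamsError(
                    f"vocabulary {self.field_key!r}: {name!r} collides "
                    f"with token {existing!r} after alias folding"
                )
            self._index[folded] = term.token

    def lookup(self, token: str) -> Term | _Marker:
        """Alias-folded, separator-normalized lookup; UNKNOWN_TERM if the
        token is not in the vocabulary (never an error: it is open)."""
        canonical = self._index.get(normalize_token(token))
        if canonical is None:
            return UNKNOWN_TERM
        return self.terms[canonical]

    def __contains__(self, token: str) -> bool:
        return normalize_token(token) in self._index

    def tokens(self) -> list[str]:
        return sorted(self.terms)

    def ancestors(self, token: str) -> list[str]:
        """Chain of parents from ``token`` (inclusive) up to its root."""
        term = self.lookup(token)
        if term is UNKNOWN_TERM:
            raise UnknownTermError(
                f"unknown term {token!r} in vocabulary {self.field_key!r}"
            )
        chain = [term.token]
        seen = {term.token}
        while term.parent is not None:
            term = self.terms[term.parent]
            if term.token in seen:  # pragma: no cover - guarded by tests
                raise MamsError(
                    f"cycle in vocabulary {self.field_key!r} at "
                    f"{term.token!r}"
                )
            chain.append(term.token)
            seen.add(term.token)
        return chain


# Suggestion-only vocabularies: shipped for lookup and documentation but
# never enforced by validation. ``modality`` deliberately has no builtin
# vocabulary at all — it is a broader integration axis (cross-species,
# cross-technology) where any token is accepted.
_UNENFORCED = {"obs_unit", "data_type", "representation"}


def _load_vocabulary(field_key: str) -> Vocabulary:
    path = resources.files("mams").joinpath(f"data/vocab/{field_key}.tsv")
    terms: dict[str, Term] = {}
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            token = row["token"].strip()
            aliases = tuple(
                a.strip() for a in (row.get("aliases") or "").split("|")
                if a.strip()
            )
            parent = (row.get("parent") or "").strip() or None
            terms[token] = Term(
                token=token,
                description=row["description"].strip(),
                parent=parent,
                aliases=aliases,
                provenance=(row.get("provenance") or "builtin").strip(),
            )
    for term in terms.values():
        if term.parent is not None and term.parent not in terms:
            raise MamsError(
                f"vocabulary {field_key!r}: term {term.token!r} names "
                f"unknown parent {term.parent!r}"
            )
    vocab = Vocabulary(
        field_key=field_key,
        terms=terms,
        enforced=field_key not in _UNENFORCED,
    )
    for token in terms:
        vocab.ancestors(token)  # raises on parent cycles at load time
    return vocab


_VOCAB_FILES = (
    "processing",
    "analyte",
    "obs_subset",
    "feature_subset",
    "parent_relationship",
    "metric_type",
    "obs_unit",
    "data_type",
    "representation",
)


@lru_cache(maxsize=1)
def builtin_vocabularies() -> dict[str, Vocabulary]:
    """All packaged vocabularies, keyed by the MAMS field they govern."""
    return {key: _load_vocabulary(key) for key in _VOCAB_FILES}


def term_lookup(field_key: str, token: str) -> Term | _Marker:
    """Look a token up in the vocabulary governing ``field_key``.

    Returns the :class:`Term`, :data:`UNKNOWN_TERM` for a custom token in
    an existing vocabulary, or :data:`NO_VOCABULARY` when no builtin
    vocabulary governs the field (e.g. ``modality``).
    """
    vocab = builtin_vocabularies().get(field_key)
    if vocab is None:
        return NO_VOCABULARY
    return vocab.lookup(token)


def is_descendant(field_key: str, child: str, ancestor: str) -> bool:
    """True iff following child-of links from ``child`` reaches
    ``ancestor``. Reflexive: every term is its own descendant.

    Raises :class:`UnknownTermError` for tokens outside the vocabulary and
    :class:`MamsError` when no vocabulary governs ``field_key``.
    """
    vocab = builtin_vocabularies().get(field_key)
    if vocab is None:
        raise MamsError(f"no builtin vocabulary for field {field_key!r}")
    ancestor_term = vocab.lookup(ancestor)
    if ancestor_term is UNKNOWN_TERM:
        raise UnknownTermError(
            f"unknown term {ancestor!r} in vocabulary {field_key!r}"
        )
    return ancestor_term.token in vocab.ancestors(child)
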