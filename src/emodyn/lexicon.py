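"""LIWC-style emotion lexicon loading, tokenization and per-post scoring.

A lexicon maps category names ("posemo", "negemo", ...) to sets of entries.
An entry is either a literal token (``sad``, ``:)``) or a wildcard stem with
a single trailing ``*`` (``happ*``) that prefix-matches tokens. Emoticon and
emoji entries are matched verbatim, so tokenization keeps symbol-only tokens
untouched.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

from .ingest import Post, PostSummary

log = logging.getLogger(__name__)

POSITIVE = "posemo"
NEGATIVE = "negemo"

_EDGE_PUNCT = re.compile(r"^\W+|\W+$", flags=re.UNICODE)
_HAS_ALNUM = re.compile(r"\w", flags=re.UNICODE)


@dataclass
class EmotionLexicon:
    """Positive/negative (and possibly other) categories of lexicon entries."""

    categories: dict[str, set[str]]
    _literals: dict[str, frozenset[str]] = field(init=False, repr=False)
    _stems: dict[str, tuple[str, ...]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name, entries in self.categories.items():
            for entry in entries:
                if not entry:
                    raise ValueError(f"empty entry in category {name!r}")
                if entry.count("*") > 1 or ("*" in entry and not entry.endswith("*")):
                    raise ValueError(
                        f"entry {entry!r} in {name!r}: a single trailing '*' is the "
                        "only wildcard supported"
                    )
        self._reindex()

    def _reindex(self) -> None:
        self._literals = {
            name: frozenset(e for e in entries if not e.endswith("*"))
            for name, entries in self.categories.items()
        }
        # longest stems first so diagnostics are deterministic; matching is any()
        self._stems = {
            name: tuple(sorted((e[:-1] for e in entries if e.endswith("*")),
                               key=lambda s: (-len(s), s)))
            for name, entries in self.categories.items()
        }

    def matches(self, token: str, category: str) -> bool:
        """True if ``token`` matches any literal or wildcard entry of ``category``."""
        if token in self._literals[category]:
            return True
        return any(token.startswith(stem) for stem in self._stems[category])

    def add(self, token: str, category: str) -> None:
        self.categories.setdefault(category, set()).add(token)
        self._reindex()


def load_dic(path) -> EmotionLexicon:
    """Parse a LIWC ``.dic`` file.

    The file opens with a ``%``-delimited block mapping numeric category ids
    to names, followed by entry lines ``token<TAB>id [id ...]``. An entry
    listing several ids joins every one of those categories. Unknown ids and
    missing delimiters are fatal; duplicates are deduplicated with a warning.
    """
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    delims = [i for i, line in enumerate(lines) if line.strip() == "%"]
    if len(delims) < 2:
        raise ValueError(f"{path}: missing '%' category-block delimiters")
    id_to_name: dict[str, str] = {}
    for lineno in range(delims[0] + 1, delims[1]):
        line = lines[lineno].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path} line {lineno + 1}: malformed category definition {line!r}")
        cat_id, name = parts
        if name in id_to_name.values():
            raise ValueError(f"{path} line {lineno + 1}: duplicate category name {name!r}")
        id_to_name[cat_id] = name
    categories: dict[str, set[str]] = {name: set() for name in id_to_name.values()}
    for lineno in range(delims[1] + 1, len(lines)):
        line = lines[lineno].rstrip()
        if not line.strip():
            continue
        token, *ids = line.split()
        if not ids:
            raise ValueError(f"{path} line {lineno + 1}: entry {token!r} lists no category")
        for cat_id in ids:
            if cat_id not in id_to_name:
                raise ValueError(
                    f"{path} line {lineno + 1}: entry {token!r} references "
                    f"undefined category id {cat_id}"
                )
            name = id_to_name[cat_id]
            if token in categories[name]:
                log.warning("%s line %d: duplicate entry %r in %s", path, lineno + 1, token, name)
            categories[name].add(token)
    return EmotionLexicon(categories=categories)


def load_supplement(path, lexicon: EmotionLexicon) -> EmotionLexicon:
    """Merge an emoji/slang supplement file: one ``token<TAB>category`` per line."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                token, category = line.split("\t")
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: expected 'token<TAB>category'") from exc
            if category not in lexicon.categories:
                raise ValueError(f"{path} line {lineno}: unknown category {category!r}")
            lexicon.add(token, category)
    return lexicon


def toy_lexicon() -> EmotionLexicon:
    """The small emotion dictionary shipped with the package.

    A stand-in vocabulary (literal words, wildcard stems, emoticons) with the
    same structure as the proprietary LIWC 2007 positive/negative emotion
    dictionaries, which cannot be redistributed.
    """
    ref = resources.files("emodyn") / "_data" / "toy_lexicon.dic"
    with resources.as_file(ref) as path:
        return load_dic(path)


@dataclass(frozen=True)
class TokenizedPost:
    tokens: tuple[str, ...]

    @property
    def n_words(self) -> int:
        return len(self.tokens)


def tokenize(text: str) -> TokenizedPost:
    """Lowercase, split on whitespace, strip edge punctuation from word tokens.

    Tokens containing no letters or digits at all (emoticons like ``:)``,
    emoji) are kept verbatim so they can match lexicon entries. Internal
    punctuation (``don't``) is preserved.
    """
    tokens: list[str] = []
    for chunk in text.lower().split():
        if _HAS_ALNUM.search(chunk):
            tokens.append(_EDGE_PUNCT.sub("", chunk))
        else:
            tokens.append(chunk)
    return TokenizedPost(tokens=tuple(tokens))


def count_matches(tokens, lexicon: EmotionLexicon, category: str) -> int:
    """Number of tokens matching any entry of ``category`` (each token once)."""
    return sum(1 for tok in tokens if lexicon.matches(tok, category))


def score_post(post: Post, lexicon: EmotionLexicon) -> PostSummary:
    """Tokenize a post and count positive/negative emotion words.

    A token matching entries in both categories increments both counts.
    """
    for cat in (POSITIVE, NEGATIVE):
        if cat not in lexicon.categories:
            raise ValueError(f"lexicon lacks required category {cat!r}")
    tokenized = tokenize(post.text)
    return PostSummary(
        participant_id=post.participant_id,
        timestamp=post.timestamp,
        n_words=tokenized.n_words,
        n_pos=count_matches(tokenized.tokens, lexicon, POSITIVE),
        n_neg=count_matches(tokenized.tokens, lexicon, NEGATIVE),
        platform=post.platform,
        is_repost=post.is_repost,
    )


def proportion(summary: PostSummary, category: str) -> float:
    """Per-post emotion-word proportion: count / total words.

    Undefined for zero-word posts; callers must filter those out first.
    """
    if summary.n_words == 0:
        raise ValueError("proportion undefined for a zero-word post")
    if category in ("pos", POSITIVE):
        return summary.n_pos / summary.n_words
    if category in ("neg", NEGATIVE):
        return summary.n_neg / summary.n_words
    raise ValueError(f"unknown category {category!r}")
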