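"""Chemical-aware tokenization.

Chemical names are hostile to whitespace tokenizers: locants carry commas
and hyphens ("2,4-dinitrophenol"), charges live in brackets ("[Ca(2+)]i"),
and possessives and trailing punctuation cling to tokens. The tokenizer
here treats every character that is not a letter or a digit as a word
delimiter, *except* for a configurable set of delimiter exceptions
(full stops, commas, plus signs, hyphens, single quotes and all bracket
types by default), so that a chemical name survives as a small number of
tokens. Tokens are then normalized: trailing full stops and commas are
stripped, brackets with no partner inside the token are dropped, brackets
enclosing the whole token are peeled, an optional suffix list is applied,
and the result is lower-cased.

Spans are 0-based half-open character offsets into the raw document and
are never altered by normalization, so downstream exact-boundary
evaluation always refers to the original text.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = ["Token", "TokenizerConfig", "tokenize", "normalize_token"]

DEFAULT_DELIMITER_EXCEPTIONS = frozenset(".,+-'()[]{}")

_OPENERS = "([{"
_CLOSERS = ")]}"
_BRACKET_OF = {")": "(", "]": "[", "}": "{"}


@dataclass(frozen=True)
class Token:
    """One token: raw surface, character span, and normalized form."""

    surface: str
    start: int
    end: int
    normalized: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid token span [{self.start}, {self.end})")


@dataclass(frozen=True)
class TokenizerConfig:
    """Delimiter exceptions, optional suffix list, and strip toggles.

    ``delimiter_exceptions`` are single characters that do NOT act as word
    delimiters even though they are neither letters nor digits.
    ``suffix_list`` holds common suffixes removed once from token ends
    (empty by default; supplied by the user, one suffix per line in config
    files). ``strip_rules_enabled`` turns off all normalization stripping
    (tokens are then only lower-cased), mainly for diagnostics.
    """

    delimiter_exceptions: frozenset[str] = DEFAULT_DELIMITER_EXCEPTIONS
    suffix_list: tuple[str, ...] = ()
    strip_rules_enabled: bool = True

    def __post_init__(self) -> None:
        for ch in self.delimiter_exceptions:
            if len(ch) != 1:
                raise ValueError(f"delimiter exception {ch!r} is not a single character")
        object.__setattr__(self, "delimiter_exceptions", frozenset(self.delimiter_exceptions))
        object.__setattr__(self, "suffix_list", tuple(self.suffix_list))


def _is_token_char(ch: str, cfg: TokenizerConfig) -> bool:
    return ch.isalnum() or ch in cfg.delimiter_exceptions


def _drop_unmatched_brackets(s: str) -> str:
    """Remove bracket characters with no partner inside the token.

    Matching is local to the token: a stack pairs openers with closers of
    the same type; every unpaired bracket character is deleted.
    """
    stack: list[int] = []
    drop = set()
    for i, ch in enumerate(s):
        if ch in _OPENERS:
            stack.append(i)
        elif ch in _CLOSERS:
            if stack and s[stack[-1]] == _BRACKET_OF[ch]:
                stack.pop()
            else:
                drop.add(i)
    drop.update(stack)
    if not drop:
        return s
    return "".join(ch for i, ch in enumerate(s) if i not in drop)


def _strip_surrounding_brackets(s: str) -> str:
    """Peel brackets that enclose the entire token, e.g. "(aspirin)"."""
    while len(s) >= 2 and s[0] in _OPENERS and s[-1] == _CLOSERS[_OPENERS.index(s[0])]:
        # the outer pair must match each other, not two separate partners:
        # in "(a)(b)" position 0 pairs with 2, not with the final ")".
        depth = 0
        partner_of_first = -1
        for i, ch in enumerate(s):
            if ch == s[0]:
                depth += 1
            elif ch == s[-1]:
                depth -= 1
                if depth == 0:
                    partner_of_first = i
                    break
        if partner_of_first != len(s) - 1:
            break
        s = s[1:-1]
    return s


def _strip_cycle(s: str) -> str:
    """Apply strip steps 1-3 (trailing . and , / unmatched / surrounding
    brackets) until a fixpoint is reached."""
    while True:
        before = s
        s = s.rstrip(".,")
        s = _drop_unmatched_brackets(s)
        s = _strip_surrounding_brackets(s)
        if s == before:
            return s


def normalize_surface(surface: str, cfg: TokenizerConfig | None = None) -> str:
    """Normalized form of a raw token surface (the matcher key unit)."""
    cfg = cfg or TokenizerConfig()
    if not cfg.strip_rules_enabled:
        return surface.lower()
    s = _strip_cycle(surface)
    # one suffix removal pass (longest suffix wins), then re-strip: the
    # suffix may have shielded trailing punctuation or a bracket.
    for suf in sorted(cfg.suffix_list, key=len, reverse=True):
        if suf and s.lower().endswith(suf.lower()) and len(s) > len(suf):
            s = s[: -len(suf)]
            s = _strip_cycle(s)
            break
    return s.lower()


def normalize_token(t: Token, cfg: TokenizerConfig | None = None) -> Token:
    """Return ``t`` with its ``normalized`` field set; offsets unchanged."""
    return replace(t, normalized=normalize_surface(t.surface, cfg))


def tokenize(text: str, cfg: TokenizerConfig | None = None) -> list[Token]:
    """Split ``text`` into normalized tokens with raw-document offsets.

    Maximal runs of letters, digits and delimiter-exception characters form
    token surfaces. Tokens whose normalized form is empty (e.g. a stray
    "()" or "--") are dropped from the output.
    """
    cfg = cfg or TokenizerConfig()
    out: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        if _is_token_char(text[i], cfg):
            j = i
            while j < n and _is_token_char(text[j], cfg):
                j += 1
            tok = normalize_token(Token(text[i:j], i, j), cfg)
            if tok.normalized:
                out.append(tok)
            i = j
        else:
            i += 1
    return out
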