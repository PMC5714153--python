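"""Text normalization for corpus records and user queries.

The cleaning pipeline applies, in order: Greek-letter spelling-out,
lowercasing/tokenization, stopword removal (with an extra search-intent list
for queries), Porter stemming, a non-alphanumeric strip, truncation to 20
characters and substitution of purely numeric tokens by the literal
``_number_``. Both the dataset corpus and the queries run through the same
pipeline so that index terms and query terms live in the same vocabulary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .porter import stem

__all__ = [
    "GREEK_LETTERS",
    "NUMBER_TOKEN",
    "StopwordConfig",
    "TokenList",
    "normalize",
    "skipgrams",
]

NUMBER_TOKEN = "_number_"
MAX_TOKEN_LEN = 20

#: Greek alphabet -> literal name, lower and upper case.
_GREEK_BASE = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta",
    "ε": "epsilon", "ζ": "zeta", "η": "eta", "θ": "theta",
    "ι": "iota", "κ": "kappa", "λ": "lambda", "μ": "mu",
    "ν": "nu", "ξ": "xi", "ο": "omicron", "π": "pi",
    "ρ": "rho", "σ": "sigma", "τ": "tau", "υ": "upsilon",
    "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
    "ς": "sigma",  # final sigma
}
GREEK_LETTERS: dict[str, str] = dict(_GREEK_BASE)
GREEK_LETTERS.update({ch.upper(): name for ch, name in _GREEK_BASE.items()})

_GREEK_RE = re.compile("|".join(map(re.escape, GREEK_LETTERS)))
_TOKEN_RE = re.compile(r"[a-z0-9_]+")
_NON_ALNUM_RE = re.compile(r"[^a-z0-9]")


def _load_list(name: str) -> frozenset[str]:
    text = resources.files("datamed_rank.resources").joinpath(name).read_text("utf-8")
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class StopwordConfig:
    """General stopwords plus search-intent words stripped from queries only.

    Both lists hold lower-case, unstemmed surface forms (matching happens
    before stemming).
    """

    general: frozenset[str] = field(default_factory=lambda: _load_list("stopwords_general.txt"))
    query: frozenset[str] = field(default_factory=lambda: _load_list("stopwords_query.txt"))

    @classmethod
    def from_files(cls, general: str | Path, query: str | Path) -> "StopwordConfig":
        def read(p: str | Path) -> frozenset[str]:
            lines = Path(p).read_text("utf-8").splitlines()
            return frozenset(
                ln.strip().lower() for ln in lines if ln.strip() and not ln.startswith("#")
            )

        return cls(general=read(general), query=read(query))


_DEFAULT_CONFIG: StopwordConfig | None = None


def default_stopwords() -> StopwordConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = StopwordConfig()
    return _DEFAULT_CONFIG


@dataclass(frozen=True)
class TokenList:
    """Ordered normalized tokens with a provenance flag (``corpus``/``query``)."""

    tokens: tuple[str, ...]
    provenance: str = "corpus"

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    def __eq__(self, other) -> bool:
        if isinstance(other, TokenList):
            return self.tokens == other.tokens
        if isinstance(other, (list, tuple)):
            return list(self.tokens) == list(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash((self.tokens, self.provenance))


def normalize(
    text: str,
    config: StopwordConfig | None = None,
    mode: str = "corpus",
) -> TokenList:
    """Normalize free text into the token stream every other module consumes.

    ``mode="query"`` additionally removes the search-intent stopwords
    ("find", "data", "across", ...). The function is total: any unicode input
    yields a (possibly empty) :class:`TokenList`.
    """
    if mode not in ("corpus", "query"):
        raise ValueError(f"mode must be 'corpus' or 'query', got {mode!r}")
    config = config or default_stopwords()
    stop = config.general if mode == "corpus" else config.general | config.query

    text = _GREEK_RE.sub(lambda m: f" {GREEK_LETTERS[m.group(0)]} ", text)
    out: list[str] = []
    for tok in _TOKEN_RE.findall(text.lower()):
        if tok in stop:
            continue
        if tok != NUMBER_TOKEN:
            if "_" not in tok:
                tok = stem(tok)
            tok = _NON_ALNUM_RE.sub("", tok)
            if not tok:
                continue
            tok = tok[:MAX_TOKEN_LEN]
            if tok.isdigit():
                tok = NUMBER_TOKEN
        out.append(tok)
    return TokenList(tuple(out), provenance=mode)


def skipgrams(tokens: Iterable[str], n: int, k: int = 0) -> set[tuple[str, ...]]:
    """All in-order n-tuples whose total positional gap is at most ``k``.

    The gap of a tuple taken at positions i1 < i2 < ... < in is
    sum(i_{j+1} - i_j - 1); ``n=1`` yields the unigram set regardless of k.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    toks = list(tokens)
    if n > len(toks):
        return set()
    if n == 1:
        return {(t,) for t in toks}

    grams: set[tuple[str, ...]] = set()

    def extend(prefix: list[int], budget: int) -> None:
        if len(prefix) == n:
            grams.add(tuple(toks[i] for i in prefix))
            return
        last = prefix[-1]
        for nxt in range(last + 1, min(last + 1 + budget + 1, len(toks))):
            extend(prefix + [nxt], budget - (nxt - last - 1))

    for start in range(len(toks)):
        extend([start], k)
    return grams
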