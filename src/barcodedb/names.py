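"""Open-nomenclature name cleaning.

Taxon names deposited in barcode source databases frequently carry digits
("Bombus sp. 2") or open-nomenclature qualifiers (cf., aff., sp., ...) that
flag uncertain identifications.  Cleaning keeps only the name parts whose
identification was certain: digits are erased, and the first qualifier token
plus everything after it is dropped ("Apis cf. mellifera" -> "Apis", because
the epithet following "cf." is not a reliable identification).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

_ALLOWED = re.compile(r"[^A-Za-z\- ]")
_DIGITS = re.compile(r"[0-9]")


def load_token_list(path=None) -> frozenset[str]:
    """Load open-nomenclature tokens (one per line, '#' comments).

    Tokens are normalized to lowercase without the trailing period, so "cf"
    and "cf." match the same entry.  With no path the packaged default list
    is used.
    """
    if path is None:
        text = (
            resources.files("barcodedb.data")
            .joinpath("open_nomenclature.txt")
            .read_text(encoding="utf-8")
        )
        lines = text.splitlines()
    else:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    tokens = set()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens.add(_norm_token(line))
    return frozenset(tokens)


def _norm_token(tok: str) -> str:
    return tok.lower().rstrip(".")


DEFAULT_TOKENS = load_token_list()


@dataclass(frozen=True)
class CleanedName:
    original: str
    cleaned: str
    removed_tokens: tuple[str, ...]

    @property
    def is_empty(self) -> bool:
        return not self.cleaned


def clean_name(
    name: str, token_list: Optional[Iterable[str]] = None
) -> CleanedName:
    """Strip digits and open-nomenclature qualifiers from a taxon name.

    The first qualifier token and every token after it are dropped; digits
    and characters outside letters/space/hyphen are erased from the kept
    tokens; whitespace is normalized.  An empty result is legal and flagged
    via :attr:`CleanedName.is_empty`.
    """
    tokens = (
        frozenset(_norm_token(t) for t in token_list)
        if token_list is not None
        else DEFAULT_TOKENS
    )
    removed: list[str] = []
    kept: list[str] = []
    parts = name.replace("_", " ").split()
    for i, tok in enumerate(parts):
        norm = _norm_token(tok)
        # "sp.2" style: the qualifier may carry the digits directly
        if norm in tokens or _norm_token(_DIGITS.sub("", norm)) in tokens:
            removed.extend(parts[i:])
            break
        if "×" in tok:  # hybrid marker: strip, keep the rest of the token
            logger.info("stripping hybrid marker from %r", tok)
            tok = tok.replace("×", "")
        stripped = _ALLOWED.sub("", tok)
        if stripped:
            kept.append(stripped)
            if stripped != tok:  # record the erased characters (digits etc.)
                removed.append("".join(_ALLOWED.findall(tok)))
        else:
            removed.append(tok)
    removed = [r for r in removed if r]
    cleaned = " ".join(kept).strip()
    return CleanedName(original=name, cleaned=cleaned, removed_tokens=tuple(removed))


@dataclass(frozen=True)
class Binomial:
    genus: Optional[str]
    epithet: Optional[str]
    remainder: tuple[str, ...] = ()


def parse_binomial(cleaned: str) -> Binomial:
    """Split a cleaned name into genus part and species epithet.

    One token -> genus only; two -> genus + epithet; more than two -> the
    first two are kept and the rest reported in ``remainder`` (subspecies
    epithets are not represented in the seven standard ranks).
    """
    parts = cleaned.split()
    if not parts:
        return Binomial(None, None)
    if len(parts) == 1:
        return Binomial(parts[0], None)
    return Binomial(parts[0], parts[1], tuple(parts[2:]))
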