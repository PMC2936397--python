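"""Tokenization and MIRIAM URN normalization shared across the package."""

from __future__ import annotations

import re
from urllib.parse import quote, unquote

_SPLIT = re.compile(r"[^0-9a-z]+")

#: BioModels.net qualifier names (bare, without the vocabulary prefix).
QUALIFIER_NAMES = frozenset(
    {
        "is",
        "isHomologTo",
        "hasPart",
        "isPartOf",
        "isVersionOf",
        "hasVersion",
        "isEncodedBy",
        "isDerivedFrom",
        "encodes",
        "isDescribedBy",
        "occursIn",
        "hasProperty",
        "isPropertyOf",
    }
)

#: Vocabulary prefixes for qualifiers (biology vs. model qualifiers).
VOCABULARIES = ("bqbiol", "bqmodel")


def tokenize(text: str | None) -> list[str]:
    """Lowercase *text* and split on any character that is neither an ASCII
    letter nor a digit.  Single-character tokens are kept, so chemical
    formulae such as ``c8h10n4o2`` survive as one token while
    ``1,3,7-trimethylxanthine`` splits into ``1 3 7 trimethylxanthine``.
    """
    if not text:
        return []
    return [t for t in _SPLIT.split(text.lower()) if t]


class URNError(ValueError):
    """Raised for strings that are not ``urn:miriam:<namespace>:<id>``."""


def split_urn(uri: str) -> tuple[str, str]:
    """Split a MIRIAM URN into (namespace, decoded identifier).

    The namespace is lowercased; percent-escapes in the identifier are
    decoded (``CHEBI%3A18021`` -> ``CHEBI:18021``) with case preserved.
    """
    parts = uri.strip().split(":", 3)
    if len(parts) != 4 or parts[0].lower() != "urn" or parts[1].lower() != "miriam":
        raise URNError(f"not a MIRIAM URN: {uri!r}")
    namespace = parts[2].strip().lower()
    identifier = unquote(parts[3].strip())
    if not namespace or not identifier:
        raise URNError(f"empty namespace or identifier in URN: {uri!r}")
    return namespace, identifier


def normalize_urn(uri: str) -> str:
    """Canonical text form of a MIRIAM URN.

    Namespace lowercased, identifier percent-encoded so that ``:`` becomes
    ``%3A``.  Idempotent: normalizing a normalized URN is the identity.
    """
    namespace, identifier = split_urn(uri)
    return f"urn:miriam:{namespace}:{quote(identifier, safe='')}"
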