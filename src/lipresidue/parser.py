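"""Shorthand lipid identifier parsing.

A lipid identifier is a textual annotation such as ``PC(16:0/18:1)`` —
a class token followed by one chain token per attached fatty acid.  Two
complications make the format more than a regex:

* **Mass isobars.** When the assay cannot distinguish species of equal
  mass, vendors join the alternatives with a top-level ``/``, as in
  ``PG(P-22:1/18:1)/PG(O-22:2/18:1)``.  Each alternative is equally
  plausible, so the parsed :class:`Lipid` carries an *ambiguity index*
  equal to the number of alternatives, and every residue occurrence is
  weighted ``1/index`` when counting.
* **Sum compositions.** Some annotations give only the total carbons and
  double bonds of all chains combined (``SM 42:2``).  These parse to a
  single total residue flagged as a sum composition.

Two dialects are exposed: ``refmet`` accepts the strict
``CLASS(chain/chain/...)`` shorthand only; ``generic`` additionally
accepts space-separated sum forms, bare chain tokens, and natural-language
fatty-acid and ester names (delegated to :mod:`lipresidue.nomenclature`).
Everything ``refmet`` parses, ``generic`` parses identically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import (
    MalformedIdentifierError,
    UnparseableChainError,
    UnparseableLipidError,
    UnparseableNameError,
)
from .nomenclature import (
    Lexicon,
    Link,
    Residue,
    decode_ester_name,
    decode_fatty_acid_name,
)

__all__ = [
    "AlternativeID",
    "Lipid",
    "WeightedResidue",
    "split_alternatives",
    "parse_chain_token",
    "parse_identifier",
    "weighted_residues",
    "sum_weights_by_label",
]

DIALECTS = ("refmet", "generic")

# optional O-/P- link prefix, optional d/t sphingoid-hydroxylation prefix,
# then carbons:double_bonds
_CHAIN_RE = re.compile(r"(?:(?P<link>[OP])-)?(?P<sph>[dt])?(?P<c>\d+):(?P<d>\d+)")

# CLASS(chains) — class token is anything without parentheses
_CLASS_FORM_RE = re.compile(r"(?P<cls>[^()]+?)\s*\((?P<chains>[^()]*)\)")

# space-separated sum form, e.g. "SM 42:2"
_SUM_FORM_RE = re.compile(
    r"(?P<cls>[A-Za-z][A-Za-z0-9-]*)\s+(?P<chain>(?:[OP]-)?[dt]?\d+:\d+)"
)

_LINK_FROM_PREFIX = {"O": Link.ETHER, "P": Link.PLASMALOGEN}


@dataclass(frozen=True)
class AlternativeID:
    """One alternative identification inside a (possibly isobaric) lipid."""

    class_token: str
    chains: tuple[Residue, ...]
    sum_composition: bool = False

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("an alternative must carry at least one chain")
        if self.sum_composition and len(self.chains) != 1:
            raise ValueError(
                "a sum-composition alternative carries exactly one total residue"
            )


@dataclass(frozen=True)
class Lipid:
    """A parsed identifier: raw text plus its alternative decompositions.

    ``index`` is the ambiguity index — the number of alternative
    identifications joined in the identifier.  Unambiguous lipids have
    index 1; residue amounts are divided by the index downstream.
    """

    raw_name: str
    alternatives: tuple[AlternativeID, ...]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValueError("a lipid must carry at least one alternative")

    @property
    def index(self) -> int:
        return len(self.alternatives)


@dataclass(frozen=True)
class WeightedResidue:
    """A residue occurrence carrying its 1/index allocation weight."""

    residue: Residue
    weight: float

    def __post_init__(self) -> None:
        if not 0.0 < self.weight <= 1.0:
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")


def split_alternatives(name: str) -> list[str]:
    """Split an identifier at ``/`` characters outside any parentheses.

    ``/`` inside ``(...)`` separates chains and never splits; only the
    top-level separator joins mass-isobar alternatives.  Joining the
    fragments back with ``/`` reproduces the input byte-for-byte.
    """
    if not name or not name.strip():
        raise MalformedIdentifierError("empty identifier")
    fragments: list[str] = []
    depth = 0
    start = 0
    for pos, char in enumerate(name):
        if char == "(":
            depth += 1
        elif char == ")":
            depth -= 1
            if depth < 0:
                raise MalformedIdentifierError(
                    f"unbalanced parentheses in identifier: {name!r}"
                )
        elif char == "/" and depth == 0:
            fragments.append(name[start:pos])
            start = pos + 1
    if depth != 0:
        raise MalformedIdentifierError(
            f"unbalanced parentheses in identifier: {name!r}"
        )
    fragments.append(name[start:])
    if any(not frag.strip() for frag in fragments):
        raise MalformedIdentifierError(
            f"empty alternative fragment in identifier: {name!r}"
        )
    return fragments


def parse_chain_token(token: str) -> Residue:
    """Parse one chain token into a residue.

    Accepted forms: ``18:3``, ``O-16:0`` (ether), ``P-22:1``
    (plasmalogen), ``d18:1``/``t18:0`` (sphingoid bases; the
    hydroxylation prefix is stripped to the bare C:D).  The residue label
    never includes the prefix.
    """
    m = _CHAIN_RE.fullmatch(token.strip())
    if m is None:
        raise UnparseableChainError(f"unparseable chain token: {token!r}")
    carbons = int(m.group("c"))
    double_bonds = int(m.group("d"))
    link = _LINK_FROM_PREFIX.get(m.group("link") or "", Link.ACYL)
    try:
        return Residue(carbons, double_bonds, link)
    except ValueError as exc:
        raise UnparseableChainError(f"invalid chain token {token!r}: {exc}") from exc


def _parse_class_form(fragment: str) -> AlternativeID | None:
    """Parse ``CLASS(chain/chain/...)``; None if the shape does not match."""
    m = _CLASS_FORM_RE.fullmatch(fragment)
    if m is None:
        return None
    tokens = [t for t in re.split(r"[/_]", m.group("chains")) if t.strip()]
    # "0:0" marks an empty sn-position in lyso-species; it is not a residue
    chains = tuple(
        parse_chain_token(tok) for tok in tokens if tok.strip() != "0:0"
    )
    if not chains:
        raise UnparseableLipidError(
            f"identifier fragment carries no chains: {fragment!r}"
        )
    return AlternativeID(class_token=m.group("cls").strip(), chains=chains)


def _parse_fragment(
    fragment: str, dialect: str, lexicon: Lexicon | None
) -> AlternativeID:
    fragment = fragment.strip()
    class_form = _parse_class_form(fragment)
    if class_form is not None:
        return class_form
    if dialect == "refmet":
        raise UnparseableLipidError(
            f"not a CLASS(chains) identifier: {fragment!r}"
        )

    m = _SUM_FORM_RE.fullmatch(fragment)
    if m is not None:
        total = parse_chain_token(m.group("chain"))
        return AlternativeID(
            class_token=m.group("cls"), chains=(total,), sum_composition=True
        )
    if _CHAIN_RE.fullmatch(fragment):
        return AlternativeID(class_token="FA", chains=(parse_chain_token(fragment),))
    try:
        return AlternativeID(
            class_token="FA", chains=(decode_fatty_acid_name(fragment, lexicon),)
        )
    except UnparseableNameError:
        pass
    try:
        return AlternativeID(
            class_token="ester",
            chains=tuple(decode_ester_name(fragment, lexicon)),
        )
    except UnparseableNameError:
        pass
    raise UnparseableLipidError(f"unparseable lipid identifier: {fragment!r}")


def parse_identifier(
    name: str, dialect: str = "refmet", lexicon: Lexicon | None = None
) -> Lipid:
    """Parse a lipid identifier into a :class:`Lipid`.

    Parameters
    ----------
    name
        The identifier text, e.g. ``"PG(P-22:1/18:1)/PG(O-22:2/18:1)"``.
    dialect
        ``"refmet"`` (strict shorthand) or ``"generic"`` (additionally
        accepts sum forms like ``"SM 42:2"``, bare chain tokens and
        natural-language names).
    lexicon
        Optional lexicon override for natural-language decoding.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
    fragments = split_alternatives(name)
    alternatives = tuple(
        _parse_fragment(frag, dialect, lexicon) for frag in fragments
    )
    return Lipid(raw_name=name, alternatives=alternatives)


def weighted_residues(
    lipid: Lipid, drop_ambiguous: bool = False
) -> list[WeightedResidue]:
    """Allocate the lipid's residue occurrences with 1/index weights.

    Every chain occurrence across all alternatives yields one entry of
    weight ``1/index``; occurrences of the same label are *not* merged
    here (aggregation merges them downstream).  With ``drop_ambiguous``,
    any lipid with index > 1 yields nothing, so only unambiguous
    identifications contribute.
    """
    if drop_ambiguous and lipid.index > 1:
        return []
    weight = 1.0 / lipid.index
    return [
        WeightedResidue(residue=chain, weight=weight)
        for alternative in lipid.alternatives
        for chain in alternative.chains
    ]


def sum_weights_by_label(entries: list[WeightedResidue]) -> dict[str, float]:
    """Total allocation weight per residue label."""
    totals: dict[str, float] = {}
    for entry in entries:
        totals[entry.residue.label] = (
            totals.get(entry.residue.label, 0.0) + entry.weight
        )
    return totals
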