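"""Natural-language fatty-acid nomenclature.

Fatty acids appear in lipidomic exports under three interchangeable
spellings: RefMet-style shorthand (``FA(18:3)``), systematic names built
from a Greek carbon root and an unsaturation suffix (``octadecatrienoic
acid``), and trivial names (``linolenic acid``).  This module decodes the
latter two into :class:`Residue` objects — the carbons:double-bonds moiety
that is the atomic unit of every downstream table.

The decoding is lexicon-driven: trivial names are data (a tab-separated
file bundled with the package, overridable at run time), while the Greek
multiplying roots (``octadeca`` -> 18) and unsaturation suffixes
(``trienoic`` -> 3) are fixed chemical nomenclature and live here as
constants.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .errors import UnparseableNameError

__all__ = [
    "Link",
    "Residue",
    "Lexicon",
    "decode_fatty_acid_name",
    "decode_ester_name",
    "is_saturated",
]


class Link(str, Enum):
    """How a chain is attached to the lipid backbone.

    ``ETHER`` and ``PLASMALOGEN`` correspond to the ``O-`` and ``P-``
    shorthand prefixes (ether and vinyl-ether bonds); everything else is
    an ordinary ester-linked acyl chain.  Link type is metadata: residues
    aggregate by their carbons:double-bonds label alone.
    """

    ACYL = "acyl"
    ETHER = "ether"
    PLASMALOGEN = "plasmalogen"


@dataclass(frozen=True, order=True)
class Residue:
    """A fatty-acid moiety summarised as carbons:double-bonds.

    Parameters
    ----------
    carbons
        Number of carbon atoms in the chain (>= 1).
    double_bonds
        Number of C=C unsaturations; must be strictly less than
        ``carbons``.
    link
        Attachment chemistry, from the ``O-``/``P-`` shorthand prefixes.
        Not part of residue identity: two residues are the same for
        aggregation purposes iff their labels are equal.
    """

    carbons: int
    double_bonds: int
    link: Link = field(default=Link.ACYL, compare=False)

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"carbons must be >= 1, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(
                f"double_bonds must be >= 0, got {self.double_bonds}"
            )
        if self.double_bonds >= self.carbons:
            raise ValueError(
                f"double_bonds ({self.double_bonds}) must be < carbons "
                f"({self.carbons})"
            )

    @property
    def label(self) -> str:
        """Canonical ``"C:D"`` text, link prefix stripped."""
        return f"{self.carbons}:{self.double_bonds}"

    @classmethod
    def from_label(cls, label: str, link: Link = Link.ACYL) -> "Residue":
        """Parse a canonical ``"C:D"`` label back into a Residue."""
        m = re.fullmatch(r"(\d+):(\d+)", label.strip())
        if m is None:
            raise ValueError(f"not a residue label: {label!r}")
        return cls(int(m.group(1)), int(m.group(2)), link)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


# Greek multiplying roots for chain lengths 2-30.  Spelling variants
# (icosa/eicosa, henicosa/heneicosa) map to the same carbon count.
CARBON_ROOTS: dict[str, int] = {
    "etha": 2,
    "propa": 3,
    "buta": 4,
    "penta": 5,
    "hexa": 6,
    "hepta": 7,
    "octa": 8,
    "nona": 9,
    "deca": 10,
    "undeca": 11,
    "dodeca": 12,
    "trideca": 13,
    "tetradeca": 14,
    "pentadeca": 15,
    "hexadeca": 16,
    "heptadeca": 17,
    "octadeca": 18,
    "nonadeca": 19,
    "eicosa": 20,
    "icosa": 20,
    "heneicosa": 21,
    "henicosa": 21,
    "docosa": 22,
    "tricosa": 23,
    "tetracosa": 24,
    "pentacosa": 25,
    "hexacosa": 26,
    "heptacosa": 27,
    "octacosa": 28,
    "nonacosa": 29,
    "triaconta": 30,
}

# Unsaturation suffixes up to fully polyunsaturated hexaenoic chains.
UNSATURATION_SUFFIXES: dict[str, int] = {
    "anoic": 0,
    "enoic": 1,
    "dienoic": 2,
    "trienoic": 3,
    "tetraenoic": 4,
    "pentaenoic": 5,
    "hexaenoic": 6,
}

# Longest suffixes first, so "docosahexaenoic" is never read as "...enoic".
_SUFFIXES_BY_LENGTH = sorted(UNSATURATION_SUFFIXES, key=len, reverse=True)

# Leading positional/stereochemical locants, e.g. "9Z,12Z-" or "(9Z)-";
# the residue unit carries no double-bond positions, so they are dropped.
_LOCANT_RE = re.compile(r"^\(?\d+[ze]?(?:,\s*\d+[ze]?)*\)?-")


@dataclass(frozen=True)
class Lexicon:
    """Name components used to decode natural-language fatty-acid names.

    ``trivial_names`` maps lowercase trivial stems ("linolenic",
    "palmitic") to (carbons, double_bonds); it is loaded from a bundled
    tab-separated data file so coverage gaps are data patches, not code
    changes.  ``carbon_roots`` and ``unsaturation_suffixes`` hold the
    systematic grammar.
    """

    trivial_names: dict[str, tuple[int, int]]
    carbon_roots: dict[str, int] = field(default_factory=lambda: dict(CARBON_ROOTS))
    unsaturation_suffixes: dict[str, int] = field(
        default_factory=lambda: dict(UNSATURATION_SUFFIXES)
    )

    def __post_init__(self) -> None:
        for stem, (c, d) in self.trivial_names.items():
            # every trivial entry must itself be a valid residue
            Residue(c, d)

    @classmethod
    def from_file(cls, path: str | Path) -> "Lexicon":
        """Load trivial names from a tab-separated file.

        Lines are ``stem<TAB>carbons<TAB>double_bonds``; blank lines and
        ``#`` comments are ignored; stems are lowercased.
        """
        trivial: dict[str, tuple[int, int]] = {}
        text = Path(path).read_text(encoding="utf-8")
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            stem, carbons, double_bonds = parts
            trivial[stem.strip().lower()] = (int(carbons), int(double_bonds))
        return cls(trivial_names=trivial)

    @classmethod
    def default(cls) -> "Lexicon":
        """The lexicon bundled with the package (cached)."""
        return _default_lexicon()


@lru_cache(maxsize=1)
def _default_lexicon() -> Lexicon:
    source = resources.files("lipresidue.data").joinpath("lexicon.tsv")
    with resources.as_file(source) as path:
        return Lexicon.from_file(path)


def _normalize(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().lower())


def decode_fatty_acid_name(name: str, lexicon: Lexicon | None = None) -> Residue:
    """Decode a single fatty-acid name into a residue.

    Trivial names are tried first ("linolenic acid" -> 18:3), then the
    systematic root+suffix grammar ("octadecatrienoic acid" -> 18:3).
    Both routes yield identical labels for the same chemical species.
    The trailing word "acid" is optional; lookup is case-insensitive and
    positional locants ("9Z,12Z-") are ignored.
    """
    lex = lexicon or Lexicon.default()
    stem = _normalize(name)
    stem = re.sub(r" acid$", "", stem)
    stem = _LOCANT_RE.sub("", stem)
    if not stem:
        raise UnparseableNameError(f"empty fatty-acid name: {name!r}")

    hit = lex.trivial_names.get(stem)
    if hit is not None:
        return Residue(*hit)

    for suffix in _SUFFIXES_BY_LENGTH:
        if suffix not in lex.unsaturation_suffixes or not stem.endswith(suffix):
            continue
        root = stem[: -len(suffix)]
        # "octadecanoic" elides the final a of "octadeca": accept both
        for candidate in (root, root + "a"):
            carbons = lex.carbon_roots.get(candidate)
            if carbons is None:
                continue
            double_bonds = lex.unsaturation_suffixes[suffix]
            if double_bonds < carbons:
                return Residue(carbons, double_bonds)
    raise UnparseableNameError(f"unparseable fatty-acid name: {name!r}")


def _decode_acid_component(word: str, lex: Lexicon) -> Residue:
    """Decode an "-ate" ester acid component, e.g. "palmitate" -> 16:0."""
    if not word.endswith("ate"):
        raise UnparseableNameError(
            f"ester acid component must end in -ate: {word!r}"
        )
    candidates = [word[:-3] + "ic"]  # palmitate -> palmitic
    if word.endswith("oate"):
        candidates.append(word[:-4] + "oic")  # octadecanoate -> octadecanoic
    for candidate in candidates:
        try:
            return decode_fatty_acid_name(candidate, lex)
        except UnparseableNameError:
            continue
    raise UnparseableNameError(f"unparseable ester acid component: {word!r}")


def _decode_alcohol_component(word: str, lex: Lexicon) -> Residue:
    """Decode a "-yl" fatty-alcohol component, e.g. "linoleyl" -> 18:2."""
    try:
        # a few alcohol names ("cetyl") are trivial entries in their own right
        return decode_fatty_acid_name(word, lex)
    except UnparseableNameError:
        pass
    if not word.endswith("yl"):
        raise UnparseableNameError(
            f"ester alcohol component must end in -yl: {word!r}"
        )
    stem = word[:-2]
    # oleyl -> oleic; octadecenyl -> octadecenoic; hexadecyl -> hexadecanoic
    for candidate in (stem + "ic", stem + "oic", stem + "anoic"):
        try:
            return decode_fatty_acid_name(candidate, lex)
        except UnparseableNameError:
            continue
    raise UnparseableNameError(f"unparseable ester alcohol component: {word!r}")


def decode_ester_name(name: str, lexicon: Lexicon | None = None) -> list[Residue]:
    """Decode a two-word fatty-acid ester name into its two residues.

    The form is ``"<alcohol>yl <acid>ate"`` ("linoleyl palmitate"); both
    components resolve through the same lexicon as free acids.  The
    result always holds exactly two residues, sorted by label for
    determinism.
    """
    lex = lexicon or Lexicon.default()
    words = _normalize(name).split(" ")
    if len(words) != 2:
        raise UnparseableNameError(
            f"ester name must be two words '<alcohol-yl> <acid-ate>': {name!r}"
        )
    alcohol_word, acid_word = words
    acid = _decode_acid_component(acid_word, lex)
    alcohol = _decode_alcohol_component(alcohol_word, lex)
    return sorted(
        [acid, alcohol], key=lambda r: (r.carbons, r.double_bonds)
    )


def is_saturated(residue: Residue) -> bool:
    """True iff the residue carries no C=C double bond."""
    return residue.double_bonds == 0
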