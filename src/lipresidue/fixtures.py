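"""Deterministic synthetic lipidomes with known ground truth.

The generator emits abundance tables whose identifiers are drawn from a
small grammar covering the shapes real vendor exports contain: plain
``CLASS(chain/chain)`` species, ether/plasmalogen prefixes, sphingoid
``d``/``t`` bases, top-level mass-isobar alternatives, space-separated
sum compositions (``SM 42:2``) and natural-language fatty-acid names.

Crucially, the ground-truth residue table is written *during generation*
by a brute-force allocator that walks the generated chain structures and
adds ``abundance / n_alternatives`` per occurrence.  It shares no code
with the identifier parser or the table converter, so it can serve as an
independent oracle for both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneratorConfig", "GeneratedLipidome", "generate_lipidome"]

# (rendered name, residues as (carbons, double_bonds) tuples) for the
# natural-language fraction.  Values are standard fatty-acid chemistry,
# embedded here verbatim so the generator never consults the lexicon it
# is meant to test.
_COMMON_NAMES: tuple[tuple[str, tuple[tuple[int, int], ...]], ...] = (
    ("palmitic acid", ((16, 0),)),
    ("stearic acid", ((18, 0),)),
    ("oleic acid", ((18, 1),)),
    ("linoleic acid", ((18, 2),)),
    ("linolenic acid", ((18, 3),)),
    ("arachidonic acid", ((20, 4),)),
    ("lignoceric acid", ((24, 0),)),
    ("nervonic acid", ((24, 1),)),
    ("octadecatrienoic acid", ((18, 3),)),
    ("hexadecanoic acid", ((16, 0),)),
    ("docosahexaenoic acid", ((22, 6),)),
    ("eicosapentaenoic acid", ((20, 5),)),
    ("tetracosaenoic acid", ((24, 1),)),
    ("oleyl oleate", ((18, 1), (18, 1))),
    ("linoleyl palmitate", ((16, 0), (18, 2))),
    ("stearyl stearate", ((18, 0), (18, 0))),
)

# class token -> number of chains
_PLAIN_CLASSES: tuple[tuple[str, int], ...] = (
    ("PC", 2),
    ("PE", 2),
    ("PG", 2),
    ("PI", 2),
    ("PS", 2),
    ("DG", 2),
    ("TG", 3),
    ("CE", 1),
    ("FA", 1),
)
_SPHINGO_CLASSES: tuple[str, ...] = ("SM", "Cer")
_SUM_CLASSES: tuple[str, ...] = ("SM", "PC", "TG")
_ETHER_CLASSES: frozenset[str] = frozenset({"PC", "PE", "PG"})


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic lipidome.

    Defaults emulate a modest plasma-style panel: a few dozen analytes,
    a handful of samples, log-normal abundances whose spread straddles
    the conventional 0.5-unit abundant/less-abundant threshold, roughly
    one identifier in five being an unresolved mass isobar and a smaller
    share being sum compositions or natural-language names.
    """

    n_lipids: int = 50
    n_samples: int = 6
    fraction_ambiguous: float = 0.2
    fraction_sum_composition: float = 0.15
    fraction_common_names: float = 0.1
    carbon_range: tuple[int, int] = (12, 26)
    double_bond_range: tuple[int, int] = (0, 6)
    abundance_location: float = -1.0
    abundance_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids < 1 or self.n_samples < 1:
            raise ValueError("n_lipids and n_samples must be >= 1")
        fractions = (
            self.fraction_ambiguous,
            self.fraction_sum_composition,
            self.fraction_common_names,
        )
        if any(not 0.0 <= f <= 1.0 for f in fractions) or sum(fractions) > 1.0:
            raise ValueError("fractions must lie in [0, 1] and sum to <= 1")
        lo, hi = self.carbon_range
        if not 2 <= lo <= hi:
            raise ValueError(f"infeasible carbon range {self.carbon_range}")
        dlo, dhi = self.double_bond_range
        if not 0 <= dlo <= dhi:
            raise ValueError(f"infeasible double-bond range {self.double_bond_range}")


@dataclass
class GeneratedLipidome:
    """A synthetic table plus its independently computed ground truth."""

    lipid_table: pd.DataFrame
    residue_table: pd.DataFrame
    # per input row: {"name", "kind", "refmet_compatible"}
    manifest: list[dict] = field(default_factory=list)


def _random_chain(
    rng: np.random.Generator, config: GeneratorConfig
) -> tuple[int, int]:
    lo, hi = config.carbon_range
    carbons = int(rng.integers(lo, hi + 1))
    dlo, dhi = config.double_bond_range
    double_bonds = int(rng.integers(dlo, min(dhi, carbons - 1) + 1))
    return carbons, double_bonds


def _render_plain(
    rng: np.random.Generator, config: GeneratorConfig
) -> tuple[str, list[tuple[int, int]]]:
    """One unambiguous identifier and its chains."""
    if rng.random() < 0.2:
        cls = _SPHINGO_CLASSES[int(rng.integers(len(_SPHINGO_CLASSES)))]
        base = _random_chain(rng, config)
        acyl = _random_chain(rng, config)
        name = f"{cls}(d{base[0]}:{base[1]}/{acyl[0]}:{acyl[1]})"
        return name, [base, acyl]
    cls, n_chains = _PLAIN_CLASSES[int(rng.integers(len(_PLAIN_CLASSES)))]
    chains = [_random_chain(rng, config) for _ in range(n_chains)]
    tokens = [f"{c}:{d}" for c, d in chains]
    if cls in _ETHER_CLASSES and rng.random() < 0.3:
        prefix = "O-" if rng.random() < 0.5 else "P-"
        tokens[0] = prefix + tokens[0]
    return f"{cls}({'/'.join(tokens)})", chains


def _render_ambiguous(
    rng: np.random.Generator, config: GeneratorConfig
) -> tuple[str, list[list[tuple[int, int]]]]:
    """A two-alternative mass isobar: P-C:D vs the isobaric O-C:D+1.

    A plasmalogen (vinyl ether) chain of D double bonds has the same mass
    as an ether chain with D+1, which is exactly the kind of pair assays
    cannot resolve.
    """
    cls = ("PC", "PE", "PG")[int(rng.integers(3))]
    for _ in range(1000):
        first = _random_chain(rng, config)
        if first[1] + 1 < first[0]:  # room for the O- alternative's extra bond
            break
    else:
        raise ValueError(
            "infeasible config: no chain admits an isobaric O- alternative"
        )
    second = _random_chain(rng, config)
    alt_a = [first, second]
    alt_b = [(first[0], first[1] + 1), second]
    name = (
        f"{cls}(P-{first[0]}:{first[1]}/{second[0]}:{second[1]})"
        f"/{cls}(O-{first[0]}:{first[1] + 1}/{second[0]}:{second[1]})"
    )
    return name, [alt_a, alt_b]


def _render_sum(
    rng: np.random.Generator, config: GeneratorConfig
) -> tuple[str, list[tuple[int, int]]]:
    cls = _SUM_CLASSES[int(rng.integers(len(_SUM_CLASSES)))]
    total_c = int(rng.integers(30, 45))
    total_d = int(rng.integers(0, 7))
    return f"{cls} {total_c}:{total_d}", [(total_c, total_d)]


def generate_lipidome(config: GeneratorConfig) -> GeneratedLipidome:
    """Generate a lipid table and its exact ground-truth residue table.

    The ground truth accumulates ``abundance / n_alternatives`` per chain
    occurrence directly from the generated structures (brute force over
    alternatives), so it is exact by construction and independent of the
    parsing code under test.  The same seed reproduces the output
    byte-for-byte.
    """
    rng = np.random.default_rng(config.seed)
    samples = [f"S{i + 1}" for i in range(config.n_samples)]

    names: list[str] = []
    # per row: list of alternatives, each a list of (carbons, double_bonds)
    structures: list[list[list[tuple[int, int]]]] = []
    manifest: list[dict] = []

    cut_ambiguous = config.fraction_ambiguous
    cut_sum = cut_ambiguous + config.fraction_sum_composition
    cut_common = cut_sum + config.fraction_common_names

    for _ in range(config.n_lipids):
        draw = rng.random()
        if draw < cut_ambiguous:
            name, alternatives = _render_ambiguous(rng, config)
            kind, refmet_ok = "ambiguous", True
        elif draw < cut_sum:
            name, chains = _render_sum(rng, config)
            alternatives = [chains]
            kind, refmet_ok = "sum_composition", False
        elif draw < cut_common:
            name, residues = _COMMON_NAMES[int(rng.integers(len(_COMMON_NAMES)))]
            alternatives = [list(residues)]
            kind, refmet_ok = "common_name", False
        else:
            name, chains = _render_plain(rng, config)
            alternatives = [chains]
            kind, refmet_ok = "plain", True
        names.append(name)
        structures.append(alternatives)
        manifest.append(
            {"name": name, "kind": kind, "refmet_compatible": refmet_ok}
        )

    abundances = rng.lognormal(
        mean=config.abundance_location,
        sigma=config.abundance_scale,
        size=(config.n_lipids, config.n_samples),
    )
    lipid_table = pd.DataFrame(abundances, index=names, columns=samples)
    lipid_table.index.name = "lipid"

    # brute-force ground truth: enumerate alternatives, 1/index per occurrence
    truth: dict[tuple[int, int], np.ndarray] = {}
    for row_values, alternatives in zip(abundances, structures):
        weight = 1.0 / len(alternatives)
        for chains in alternatives:
            for key in chains:
                if key not in truth:
                    truth[key] = np.zeros(config.n_samples)
                truth[key] += weight * row_values
    keys = sorted(truth)
    residue_table = pd.DataFrame(
        np.array([truth[k] for k in keys], dtype=float).reshape(
            len(keys), config.n_samples
        ),
        index=[f"{c}:{d}" for c, d in keys],
        columns=samples,
    )
    residue_table.index.name = "residue"

    return GeneratedLipidome(
        lipid_table=lipid_table, residue_table=residue_table, manifest=manifest
    )
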