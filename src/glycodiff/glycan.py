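"""N-glycan compositions and derivatization metrics.

An N-glycan is represented here purely by its monosaccharide composition —
counts of fucose (F), hexose (H: mannose/galactose), N-acetylhexosamine
(N: GlcNAc/GalNAc) and sialic acid (S) — written in the compact ``F#H#N#S#``
nomenclature used on glycopeptide labels (e.g. ``F1H5N4S1``). No topology is
inferred beyond what composition alone supports: the ubiquitous N-glycan core
(two GlcNAc + three mannose) is assumed, every HexNAc beyond the core two is
counted as antenna-initiating, and every hexose beyond the three core mannoses
is counted as a potential antennal galactose.

From a composition the module derives

* a glycan class (high-mannose, paucimannose, hybrid, complex, unclassified)
  under a configurable composition-only ruleset,
* an antenna count,
* per-glycopeptide derivatization metrics: sialylation and galactosylation as
  proportions of antennae, fucosylation as a binary indicator,
* abundance-weighted overall metrics across a set of glycopeptides.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import yaml

__all__ = [
    "MAX_MONOSACCHARIDES",
    "GlycanComposition",
    "GlycanClass",
    "GlycanMetrics",
    "OverallMetrics",
    "ClassificationRules",
    "GlycanParseError",
    "parse_composition",
    "classify_glycan",
    "antenna_count",
    "glycan_metrics",
    "weighted_overall_metrics",
    "enumerate_compositions",
]

#: Search-space bound on total monosaccharides per glycan.
MAX_MONOSACCHARIDES = 26

_TOKEN_RE = re.compile(r"([A-Za-z])(\d*)")
_LETTER_TO_FIELD = {"F": "fucose", "H": "hexose", "N": "hexnac", "S": "sialic"}


class GlycanParseError(ValueError):
    """Raised when a composition string cannot be parsed."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan, without topology."""

    fucose: int = 0
    hexose: int = 0
    hexnac: int = 0
    sialic: int = 0

    def __post_init__(self) -> None:
        for name in ("fucose", "hexose", "hexnac", "sialic"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} count must be a non-negative integer, got {v!r}")
        if self.total > MAX_MONOSACCHARIDES:
            raise ValueError(
                f"composition has {self.total} monosaccharides, "
                f"exceeding the search-space bound of {MAX_MONOSACCHARIDES}"
            )

    @property
    def total(self) -> int:
        return self.fucose + self.hexose + self.hexnac + self.sialic

    def format(self) -> str:
        """Canonical rendering: F,H,N,S order, zero counts omitted."""
        parts = []
        for letter, field in _LETTER_TO_FIELD.items():
            count = getattr(self, field)
            if count > 0:
                parts.append(f"{letter}{count}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


def parse_composition(s: str) -> GlycanComposition:
    """Parse an ``F#H#N#S#`` composition string.

    Letters may appear in any order but at most once each; absent letters mean
    a count of zero. Raises :class:`GlycanParseError` naming the offending
    token on malformed input.
    """
    if not isinstance(s, str) or not s.strip():
        raise GlycanParseError("empty composition string")
    s = s.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None or m.start() != pos:
            raise GlycanParseError(f"malformed token at {s[pos:]!r} in {s!r}")
        letter, digits = m.group(1).upper(), m.group(2)
        if letter not in _LETTER_TO_FIELD:
            raise GlycanParseError(f"unknown residue letter {letter!r} in {s!r}")
        if letter in counts:
            raise GlycanParseError(f"repeated residue letter {letter!r} in {s!r}")
        if not digits:
            raise GlycanParseError(f"missing count after {letter!r} in {s!r}")
        counts[letter] = int(digits)
        pos = m.end()
    kwargs = {_LETTER_TO_FIELD[letter]: n for letter, n in counts.items()}
    try:
        return GlycanComposition(**kwargs)
    except ValueError as exc:
        raise GlycanParseError(str(exc)) from exc


class GlycanClass(str, Enum):
    HIGH_MANNOSE = "high_mannose"
    PAUCIMANNOSE = "paucimannose"
    HYBRID = "hybrid"
    COMPLEX = "complex"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassificationRules:
    """Composition-only classification thresholds.

    Defaults implement the standard heuristics: HexNAc 2 with >= 5 hexoses is
    high-mannose (chitobiose core, mannose-only), HexNAc 2 with fewer is
    paucimannose, HexNAc 3 with enough hexoses for an untrimmed mannose arm is
    hybrid, any other HexNAc >= 3 is complex, HexNAc < 2 cannot carry the core
    and is unclassified.
    """

    high_mannose_min_hexose: int = 5
    hybrid_hexnac: int = 3
    hybrid_min_hexose: int = 5

    @classmethod
    def from_yaml(cls, path) -> "ClassificationRules":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown classification rule keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_RULES = ClassificationRules()


def classify_glycan(
    c: GlycanComposition, rules: ClassificationRules = DEFAULT_RULES
) -> GlycanClass:
    """Assign exactly one glycan class to a composition."""
    if c.hexnac < 2:
        return GlycanClass.UNCLASSIFIED
    if c.hexnac == 2:
        if c.hexose >= rules.high_mannose_min_hexose:
            return GlycanClass.HIGH_MANNOSE
        return GlycanClass.PAUCIMANNOSE
    if c.hexnac == rules.hybrid_hexnac and c.hexose >= rules.hybrid_min_hexose:
        return GlycanClass.HYBRID
    return GlycanClass.COMPLEX


def antenna_count(c: GlycanComposition, cls: GlycanClass) -> int:
    """Number of antennae: non-core HexNAc for complex/hybrid glycans, else 0.

    The two chitobiose-core GlcNAcs are subtracted; high-mannose and
    paucimannose glycans have no antennal GlcNAc by definition.
    """
    if cls in (GlycanClass.COMPLEX, GlycanClass.HYBRID):
        return max(c.hexnac - 2, 0)
    return 0


@dataclass(frozen=True)
class GlycanMetrics:
    """Per-glycopeptide derivatization metrics.

    ``sialylation`` and ``galactosylation`` are proportions of antennae and
    are ``None`` (undefined) when the glycan has no antennae; ``fucosylated``
    is the presence of any fucose, core or antennal.
    """

    antennae: int
    sialylation: float | None
    galactosylation: float | None
    fucosylated: bool


def glycan_metrics(
    c: GlycanComposition, rules: ClassificationRules = DEFAULT_RULES
) -> GlycanMetrics:
    cls = classify_glycan(c, rules)
    a = antenna_count(c, cls)
    if a > 0:
        sial = min(c.sialic, a) / a
        # antennal galactoses = hexoses beyond the 3 core mannoses, capped at a
        gal = min(max(c.hexose - 3, 0), a) / a
    else:
        sial = None
        gal = None
    return GlycanMetrics(
        antennae=a,
        sialylation=sial,
        galactosylation=gal,
        fucosylated=c.fucose >= 1,
    )


@dataclass(frozen=True)
class OverallMetrics:
    """Abundance-weighted overall metrics over a set of glycopeptides."""

    sialylation: float | None
    galactosylation: float | None
    fucosylation: float | None


def weighted_overall_metrics(
    rows: Sequence[tuple[GlycanMetrics, float]],
    weighting: str = "proportion",
) -> OverallMetrics:
    """Abundance-weighted average of per-glycopeptide metrics.

    Each overall metric is sum(abundance_i * metric_i) / sum(abundance_i) over
    the rows where the metric is defined; fucosylation averages the 0/1
    indicator over all rows. A metric whose defined set is empty is ``None``.

    ``weighting="proportion"`` (default) weights each glycopeptide by its
    abundance alone; ``weighting="antenna"`` additionally weights sialylation
    and galactosylation by the antenna count, averaging over antennae rather
    than over glycopeptides.
    """
    if weighting not in ("proportion", "antenna"):
        raise ValueError(f"unknown weighting {weighting!r}")
    rows = list(rows)
    if not rows:
        raise ValueError("no glycopeptide rows supplied")
    for _, ab in rows:
        if ab < 0 or not math.isfinite(ab):
            raise ValueError(f"abundance must be finite and non-negative, got {ab}")
    if all(ab == 0 for _, ab in rows):
        raise ValueError("all abundances are zero; overall metrics undefined")

    def weighted(pairs: Iterable[tuple[float, float]]) -> float | None:
        num = den = 0.0
        for value, weight in pairs:
            num += value * weight
            den += weight
        return num / den if den > 0 else None

    extra = (lambda m: m.antennae) if weighting == "antenna" else (lambda m: 1.0)
    sial = weighted(
        (m.sialylation, ab * extra(m))
        for m, ab in rows
        if m.sialylation is not None
    )
    gal = weighted(
        (m.galactosylation, ab * extra(m))
        for m, ab in rows
        if m.galactosylation is not None
    )
    fuc = weighted((1.0 if m.fucosylated else 0.0, ab) for m, ab in rows)
    return OverallMetrics(sialylation=sial, galactosylation=gal, fucosylation=fuc)


def enumerate_compositions(max_total: int = MAX_MONOSACCHARIDES):
    """Yield every composition with total monosaccharides <= ``max_total``.

    Intended for exhaustive property checks; the default bound matches the
    search-space limit.
    """
    for f, h, n, s in itertools.product(range(max_total + 1), repeat=4):
        if f + h + n + s <= max_total:
            yield GlycanComposition(fucose=f, hexose=h, hexnac=n, sialic=s)
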