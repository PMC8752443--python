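"""Driver-event catalogue and growth-advantage models for ccRCC simulations.

The simulation considers a fixed panel of 26 recurrent clear-cell renal cell
carcinoma (ccRCC) driver events: 12 driver gene mutations and 14 arm-level
somatic copy-number alterations (SCNAs).  Every tumour voxel carries a
genotype over this panel; its instantaneous growth probability is derived
from the genotype under one of two selection models:

* **saturated** — growth probability takes one of three tiered levels,
  ``p_init``, ``(1+s)·p_init`` and ``(1+s)²·p_init`` (capped at 1), according
  to the strongest tier among harboured drivers.  The four SCNAs most
  strongly associated with proliferation (7q gain, 20q gain, 4q loss,
  8p loss) sit in the maximal tier.
* **additive** — each non-truncal driver adds an increment
  ``s_k(rank)·p_init`` with a linear rank schedule
  ``s_k(r) = min_sk + (r-1)·delta_sk``; the sum is capped at 1.

The truncal events (VHL mutation and 3p loss) define the parental clone and
carry no growth advantage in either model, so the founder voxel always grows
at the baseline ``p_init``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

GENE_MUTATION = "gene_mutation"
SCNA = "scna"

TIER_INITIAL = "initial"
TIER_MODERATE = "moderate"
TIER_MAXIMAL = "maximal"

_TIER_LEVEL = {TIER_INITIAL: 0, TIER_MODERATE: 1, TIER_MAXIMAL: 2}

#: The four SCNAs treated as the strongest drivers (maximal tier).
STRONGEST_SCNAS = ("7q gain", "20q gain", "4q loss", "8p loss")

#: Truncal events present in every founder voxel.
TRUNCAL_EVENTS = ("VHL", "3p loss")

#: Gene mutations that elevate the SCNA acquisition rate to p_driver.
SCNA_RATE_ENHANCERS = ("PBRM1", "BAP1")

#: SCNAs acquire at this multiple of p_driver unless an enhancer is present.
SCNA_RATE_FACTOR = 1e-3


class PanelValidationError(ValueError):
    """A panel definition violates a structural invariant."""


@dataclass(frozen=True)
class DriverEvent:
    """One driver event in the panel.

    ``rank`` orders events by strength of proliferation association
    (1 = weakest); it feeds the additive model.  ``tier`` feeds the
    saturated model.
    """

    id: int
    name: str
    event_class: str
    tier: str
    rank: int
    is_truncal: bool = False
    enhances_scna_rate: bool = False
    is_strongest: bool = False

    def __post_init__(self) -> None:
        if self.event_class not in (GENE_MUTATION, SCNA):
            raise PanelValidationError(
                f"bad event_class {self.event_class!r} for {self.name!r}"
            )
        if self.tier not in _TIER_LEVEL:
            raise PanelValidationError(f"bad tier {self.tier!r} for {self.name!r}")


class DriverPanel:
    """Ordered catalogue of driver events with cached index structures."""

    def __init__(self, events: Sequence[DriverEvent]):
        self.events: tuple[DriverEvent, ...] = tuple(events)
        self._validate()
        n = len(self.events)
        self.n_events = n
        self.gene_mask = np.array(
            [e.event_class == GENE_MUTATION for e in self.events], dtype=bool
        )
        self.scna_mask = ~self.gene_mask
        self.tier_level = np.array(
            [_TIER_LEVEL[e.tier] for e in self.events], dtype=np.int8
        )
        self.rank = np.array([e.rank for e in self.events], dtype=np.int32)
        self.truncal_mask = np.array([e.is_truncal for e in self.events], dtype=bool)
        self.enhancer_mask = np.array(
            [e.enhances_scna_rate for e in self.events], dtype=bool
        )
        self.enhancer_bits = int(np.sum(1 << np.flatnonzero(self.enhancer_mask)))
        self.truncal_bits = int(np.sum(1 << np.flatnonzero(self.truncal_mask)))
        self._by_name = {e.name: e for e in self.events}

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        names = [e.name for e in self.events]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise PanelValidationError(f"duplicate event names: {dupes}")
        ids = [e.id for e in self.events]
        if ids != list(range(len(self.events))):
            raise PanelValidationError("event ids must be 0..n-1 in order")
        ranks = sorted(e.rank for e in self.events)
        if ranks != list(range(1, len(self.events) + 1)):
            raise PanelValidationError(
                f"ranks must be a permutation of 1..{len(self.events)}"
            )

    # -- queries -------------------------------------------------------

    def __len__(self) -> int:
        return self.n_events

    def __getitem__(self, name: str) -> DriverEvent:
        return self._by_name[name]

    def event_id(self, name: str) -> int:
        return self._by_name[name].id

    @property
    def n_gene_mutations(self) -> int:
        return int(self.gene_mask.sum())

    @property
    def n_scnas(self) -> int:
        return int(self.scna_mask.sum())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DriverPanel) and self.events == other.events

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "events": [
                {
                    "name": e.name,
                    "class": e.event_class,
                    "tier": e.tier,
                    "rank": e.rank,
                    "flags": {
                        "is_truncal": e.is_truncal,
                        "enhances_scna_rate": e.enhances_scna_rate,
                        "is_strongest": e.is_strongest,
                    },
                }
                for e in self.events
            ]
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class Genotype:
    """The set of panel events harboured by one voxel (or clone).

    ``bits`` is a bitmask over panel event ids.  ``allele_ids`` maps each
    harboured gene-mutation event to the unique allele identity of its
    acquisition; a gene is mutated at most once per voxel, but distinct
    voxel lineages may carry distinct alleles of the same gene (parallel
    evolution).
    """

    panel: DriverPanel
    bits: int = 0
    allele_ids: dict[int, int] = field(default_factory=dict)

    def has(self, name: str) -> bool:
        return bool(self.bits >> self.panel.event_id(name) & 1)

    @property
    def presence(self) -> np.ndarray:
        ids = np.arange(self.panel.n_events)
        return (self.bits >> ids & 1).astype(bool)

    @property
    def n_events(self) -> int:
        return int(self.bits.bit_count())

    def with_events(self, names: Iterable[str]) -> "Genotype":
        bits = self.bits
        for nm in names:
            bits |= 1 << self.panel.event_id(nm)
        return Genotype(self.panel, bits, dict(self.allele_ids))


def founder_genotype(panel: DriverPanel) -> Genotype:
    """The parental-clone genotype: VHL mutation + 3p loss, allele 0 for VHL."""
    g = Genotype(panel, panel.truncal_bits)
    g.allele_ids[panel.event_id("VHL")] = 0
    return g


@dataclass
class AdvantageModel:
    """Parameters of the selection model mapping genotypes to p_growth."""

    model: str = "saturated"  # "saturated" | "additive"
    s: float = 1.0
    min_sk: float = 0.01
    delta_sk: float = 0.01
    p_growth_initial: float = 0.25
    # hooks for general tier multipliers g(s), h(s); None = (1+s), (1+s)^2
    g: object = None
    h: object = None

    def __post_init__(self) -> None:
        if self.model not in ("saturated", "additive"):
            raise ValueError(f"unknown advantage model {self.model!r}")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("s must lie in [0, 1]")
        if not 0.0 < self.p_growth_initial <= 1.0:
            raise ValueError("p_growth_initial must lie in (0, 1]")

    def tier_probabilities(self) -> np.ndarray:
        """p_growth at tiers (initial, moderate, maximal), capped at 1."""
        g = self.g if self.g is not None else (lambda s: 1.0 + s)
        h = self.h if self.h is not None else (lambda s: (1.0 + s) ** 2)
        p = self.p_growth_initial
        return np.minimum([p, g(self.s) * p, h(self.s) * p], 1.0)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "s": self.s,
            "min_sk": self.min_sk,
            "delta_sk": self.delta_sk,
            "p_growth_initial": self.p_growth_initial,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdvantageModel":
        return cls(**d)


#: Additive-model presets spanning weak to strong average driver increments.
ADDITIVE_SCENARIOS = {
    "weak": {"min_sk": 0.002, "delta_sk": 0.002},
    "intermediate": {"min_sk": 0.01, "delta_sk": 0.01},
    "strong": {"min_sk": 0.02, "delta_sk": 0.02},
}


# ----------------------------------------------------------------------
# default panel
# ----------------------------------------------------------------------

# 12 recurrently mutated ccRCC driver genes and 14 arm-level SCNAs.  VHL and
# 3p loss are truncal; PBRM1/BAP1 mutations raise the SCNA rate; the four
# strongest SCNAs occupy the maximal tier.  The rank order (1 = weakest) is a
# documented default, configurable through panel files.
_DEFAULT_GENES = (
    "VHL", "PBRM1", "SETD2", "BAP1", "MTOR", "KDM5C",
    "PIK3CA", "PTEN", "TP53", "TSC1", "TSC2", "CSMD3",
)
_DEFAULT_SCNAS = (
    "3p loss", "9p loss", "14q loss", "8q gain", "12p gain", "5q gain",
    "1p loss", "6q loss", "10q loss", "18p loss",
    "7q gain", "20q gain", "4q loss", "8p loss",
)


def default_panel() -> DriverPanel:
    """The built-in 26-event ccRCC driver panel.

    Truncal events sit at the bottom of the rank order, the four maximal-tier
    SCNAs at the top; intermediate ranks follow catalogue order.
    """
    names = list(_DEFAULT_GENES) + list(_DEFAULT_SCNAS)
    # rank: truncal first (weakest), strongest SCNAs last
    ordered = (
        [n for n in names if n in TRUNCAL_EVENTS]
        + [n for n in names if n not in TRUNCAL_EVENTS and n not in STRONGEST_SCNAS]
        + list(STRONGEST_SCNAS)
    )
    rank_of = {n: i + 1 for i, n in enumerate(ordered)}
    events = []
    for i, name in enumerate(names):
        is_gene = name in _DEFAULT_GENES
        strongest = name in STRONGEST_SCNAS
        truncal = name in TRUNCAL_EVENTS
        if truncal:
            tier = TIER_INITIAL
        elif strongest:
            tier = TIER_MAXIMAL
        elif is_gene:
            tier = TIER_INITIAL
        else:
            tier = TIER_MODERATE
        events.append(
            DriverEvent(
                id=i,
                name=name,
                event_class=GENE_MUTATION if is_gene else SCNA,
                tier=tier,
                rank=rank_of[name],
                is_truncal=truncal,
                enhances_scna_rate=name in SCNA_RATE_ENHANCERS,
                is_strongest=strongest,
            )
        )
    return DriverPanel(events)


def load_panel(path: str | Path) -> DriverPanel:
    """Load and validate a panel definition from a JSON file."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise PanelValidationError(f"cannot parse panel file {path}: {exc}") from exc
    try:
        entries = raw["events"]
    except (TypeError, KeyError) as exc:
        raise PanelValidationError("panel file must contain an 'events' list") from exc
    events = []
    for i, ent in enumerate(entries):
        flags = ent.get("flags", {})
        events.append(
            DriverEvent(
                id=i,
                name=ent["name"],
                event_class=ent["class"],
                tier=ent["tier"],
                rank=int(ent["rank"]),
                is_truncal=bool(flags.get("is_truncal", False)),
                enhances_scna_rate=bool(flags.get("enhances_scna_rate", False)),
                is_strongest=bool(flags.get("is_strongest", False)),
            )
        )
    return DriverPanel(events)


# ----------------------------------------------------------------------
# fitness models
# ----------------------------------------------------------------------

def growth_probability_from_bits(
    bits: int, model: AdvantageModel, panel: DriverPanel
) -> float:
    """Growth probability of a genotype given as a bitmask (engine fast path)."""
    ids = np.flatnonzero((bits >> np.arange(panel.n_events)) & 1)
    p_init = model.p_growth_initial
    if model.model == "saturated":
        tiers = panel.tier_level[ids]
        level = int(tiers.max()) if len(tiers) else 0
        return float(model.tier_probabilities()[level])
    # additive: truncal events carry no increment (baseline definition)
    adv = ids[~panel.truncal_mask[ids]]
    s_k = model.min_sk + (panel.rank[adv] - 1) * model.delta_sk
    return float(min(1.0, p_init + np.sum(s_k) * p_init))


def growth_probability(genotype: Genotype, model: AdvantageModel) -> float:
    """Growth probability per simulation step for a voxel genotype.

    Saturated: the highest tier among harboured drivers selects one of the
    three tier probabilities.  Additive: baseline plus per-driver increments
    ``s_k(rank)·p_init``, capped at 1.
    """
    return growth_probability_from_bits(genotype.bits, model, genotype.panel)


def scna_acquisition_probability(
    genotype: Genotype | int, p_driver: float, panel: DriverPanel | None = None
) -> float:
    """Per-event SCNA acquisition probability for a genotype.

    SCNAs arise at ``0.001·p_driver`` unless the genotype harbours a PBRM1 or
    BAP1 mutation, which elevates chromosomal instability and restores the
    full ``p_driver`` rate.
    """
    if not 0.0 < p_driver <= 1.0:
        raise ValueError("p_driver must lie in (0, 1]")
    if isinstance(genotype, Genotype):
        bits = genotype.bits
        panel = genotype.panel
    else:
        bits = genotype
        if panel is None:
            raise ValueError("panel required when genotype given as bitmask")
    if bits & panel.enhancer_bits:
        return p_driver
    return SCNA_RATE_FACTOR * p_driver
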