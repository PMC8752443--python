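"""Clone bookkeeping: cancer cell fractions, Shannon diversity, fitness,
driver burden and parallel-event catalogues.

A voxel belongs to exactly one clone — its most-derived clone label — so
clone frequencies partition the scope and cancer cell fractions (CCF) sum to
one.  The parental clone counts as a clone throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .driver_panel import AdvantageModel, DriverPanel
from .engine import CloneRegistry, LatticeState

WHOLE = "whole"
SLICE = "slice"
BIOPSY = "biopsy"


@dataclass
class ClonalComposition:
    """Clone frequencies within one scope (whole tumour, slice or biopsy)."""

    scope: str
    clone_ids: np.ndarray  # clones with count > 0, ascending id
    counts: np.ndarray
    ccf: np.ndarray  # counts / total, sums to 1

    @property
    def n_voxels(self) -> int:
        return int(self.counts.sum())

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"clone_id": self.clone_ids, "n_voxels": self.counts, "ccf": self.ccf}
        )


def _labels_of(source) -> np.ndarray:
    if isinstance(source, LatticeState):
        return source.clone[source.occupied_indices()]
    labels = np.asarray(source)
    return labels[labels >= 0]


def composition(source, scope: str = WHOLE) -> ClonalComposition:
    """Partition voxels by most-derived clone label and return CCFs.

    ``source`` is a LatticeState or any array of clone labels (negative
    labels, i.e. empty sites, are ignored)."""
    labels = _labels_of(source)
    if len(labels) == 0:
        raise ValueError(f"empty scope {scope!r}: no voxels to account")
    ids, counts = np.unique(labels, return_counts=True)
    return ClonalComposition(
        scope=scope,
        clone_ids=ids.astype(np.int64),
        counts=counts.astype(np.int64),
        ccf=counts / counts.sum(),
    )


def detectable_clones(
    comp: ClonalComposition, threshold: float = 0.01, inclusive: bool = False
) -> np.ndarray:
    """Clones whose CCF exceeds ``threshold``.

    The detectability convention is strict (CCF > 0.01 by default); clone
    counting against a coarser floor (e.g. CCF >= 0.05) uses
    ``inclusive=True``."""
    keep = comp.ccf >= threshold if inclusive else comp.ccf > threshold
    return comp.clone_ids[keep]


def shannon_index(comp: ClonalComposition) -> float:
    """Shannon diversity S = -Σ f_i ln f_i over all clones present."""
    f = comp.ccf[comp.ccf > 0]
    return float(-np.sum(f * np.log(f)))


def tumour_fitness(
    source, registry: CloneRegistry, model: AdvantageModel | None = None
) -> float:
    """Mean growth probability of the voxels in scope.

    ``model=None`` uses the registry's configured advantage model (cached
    per-clone probabilities); passing a model re-evaluates genotypes."""
    labels = _labels_of(source)
    if len(labels) == 0:
        raise ValueError("empty scope")
    if model is None:
        return float(registry.growth_prob[labels].mean())
    from .driver_panel import growth_probability_from_bits

    probs = np.array(
        [
            growth_probability_from_bits(registry.genotype_bits[c], model, registry.panel)
            for c in np.unique(labels)
        ]
    )
    lookup = dict(zip(np.unique(labels), probs))
    return float(np.mean([lookup[c] for c in labels]))


def mean_drivers(source, registry: CloneRegistry) -> float:
    """Mean number of harboured drivers (mutations + SCNAs) per voxel."""
    labels = _labels_of(source)
    if len(labels) == 0:
        raise ValueError("empty scope")
    return float(registry.n_drivers[labels].mean())


def parallel_event_catalog(
    region_labels: dict[object, np.ndarray],
    registry: CloneRegistry,
    panel: DriverPanel,
    region_margin_distance: dict[object, float] | None = None,
) -> pd.DataFrame:
    """Per-gene allele table across regions (biopsies or cohort regions).

    For each gene-mutation allele observed in any region: the set of regions
    it spans, the span count, and — for alleles confined to a single region —
    that region's distance to the tumour margin (if provided).  Two alleles
    of the same gene in different regions constitute a parallel event."""
    rows = []
    allele_regions: dict[tuple[int, int], set] = {}
    for region_id, labels in region_labels.items():
        labels = _labels_of(labels)
        for clone in np.unique(labels):
            for gene_ev, allele in registry.allele_set(int(clone)):
                allele_regions.setdefault((gene_ev, allele), set()).add(region_id)
    for (gene_ev, allele), regions in sorted(
        allele_regions.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        span = len(regions)
        dist = np.nan
        if span == 1 and region_margin_distance is not None:
            dist = float(region_margin_distance.get(next(iter(regions)), np.nan))
        rows.append(
            {
                "gene": panel.events[gene_ev].name,
                "event_id": gene_ev,
                "allele_id": allele,
                "regions": tuple(sorted(regions, key=str)),
                "span": span,
                "single_region_margin_distance_mm": dist,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "event_id",
            "allele_id",
            "regions",
            "span",
            "single_region_margin_distance_mm",
        ],
    )
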