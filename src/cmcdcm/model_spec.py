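"""Network specifications for the two CMC effective-connectivity variants.

The Common Model of Cognition (CMC) is mapped onto five regions of interest:

======  =====  ==========================================
index   label  CMC component
======  =====  ==========================================
0       MC     motor cortex (action)
1       PFC    prefrontal cortex (working memory)
2       BG     basal ganglia (procedural memory)
3       MTL    medial temporal lobe (long-term memory)
4       SENS   sensory cortices (perception)
======  =====  ==========================================

Two variants differ only in how the basal ganglia reach the prefrontal
cortex:

* ``direct`` — a fixed (first-order) BG→PFC connection in matrix A.
* ``modulatory`` — no BG→PFC entry in A; instead the BG gate the two
  incoming cortical pathways to PFC via second-order (bilinear) terms:
  BG modulating MTL→PFC and BG modulating SENS→PFC.

All connectivity matrices use "row = target, column = source": entry
``[r, c]`` is the directed connection from region ``c`` to region ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REGION_LABELS",
    "RegionSet",
    "CmcModelSpec",
    "build_cmc_spec",
    "count_free_parameters",
    "SHARED_EDGES",
    "DIRECT_ONLY_EDGE",
    "MODULATORY_TRIPLES",
]

REGION_LABELS = ("MC", "PFC", "BG", "MTL", "SENS")

#: Directed off-diagonal fixed connections present in *both* variants,
#: as (target, source) label pairs: the three bidirectional cortical
#: pairs SENS↔MC, MTL↔PFC, SENS↔PFC plus PFC→MC and PFC→BG.
SHARED_EDGES = (
    ("MC", "SENS"),
    ("SENS", "MC"),
    ("PFC", "MTL"),
    ("MTL", "PFC"),
    ("PFC", "SENS"),
    ("SENS", "PFC"),
    ("MC", "PFC"),
    ("BG", "PFC"),
)

#: The direct variant's extra fixed edge: BG→PFC as (target, source).
DIRECT_ONLY_EDGE = ("PFC", "BG")

#: The modulatory variant's second-order connections as
#: (modulator, source, target) label triples.
MODULATORY_TRIPLES = (
    ("BG", "MTL", "PFC"),
    ("BG", "SENS", "PFC"),
)

VARIANTS = ("direct", "modulatory")


@dataclass(frozen=True)
class RegionSet:
    """The ordered five-region system; index order is fixed."""

    labels: tuple[str, ...] = REGION_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != 5:
            raise ValueError(f"exactly 5 regions required, got {len(self.labels)}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown region label {label!r}; known: {self.labels}") from None

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class CmcModelSpec:
    """Sparsity masks of one CMC variant over the five-region system.

    Attributes
    ----------
    variant:
        ``"direct"`` or ``"modulatory"``.
    a_mask:
        5×5 binary matrix; ``a_mask[r, c] == 1`` iff the fixed connection
        source ``c`` → target ``r`` is estimated.  The diagonal
        (self-connections) is always 1.
    c_mask:
        5×K binary matrix over the K driving regressors (all ones: every
        low-frequency driver enters every node).
    d_masks:
        Tuple of (modulator, source, target) label triples naming the
        estimated second-order connections.
    """

    variant: str
    a_mask: np.ndarray
    c_mask: np.ndarray
    d_masks: tuple[tuple[str, str, str], ...]
    regions: RegionSet = field(default_factory=RegionSet)

    def __post_init__(self) -> None:
        object.__setattr__(self, "a_mask", np.asarray(self.a_mask, dtype=int))
        object.__setattr__(self, "c_mask", np.asarray(self.c_mask, dtype=int))
        if self.a_mask.shape != (5, 5):
            raise ValueError("a_mask must be 5x5")
        if not np.all(np.diag(self.a_mask) == 1):
            raise ValueError("self-connections (a_mask diagonal) must all be present")

    @property
    def n_regressors(self) -> int:
        return int(self.c_mask.shape[1])

    def edges(self) -> list[tuple[str, str]]:
        """Off-diagonal fixed connections as (target, source) label pairs."""
        lab = self.regions.labels
        return [
            (lab[r], lab[c])
            for r in range(5)
            for c in range(5)
            if r != c and self.a_mask[r, c]
        ]

    def d_index_triples(self) -> list[tuple[int, int, int]]:
        """d_masks as (modulator, source, target) integer index triples."""
        ix = self.regions.index
        return [(ix(m), ix(s), ix(t)) for m, s, t in self.d_masks]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "regions": list(self.regions.labels),
            "n_regressors": self.n_regressors,
            "edges": [list(e) for e in self.edges()],
            "d_masks": [list(t) for t in self.d_masks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CmcModelSpec":
        regions = RegionSet(tuple(d["regions"]))
        a = np.eye(5, dtype=int)
        for tgt, src in d["edges"]:
            a[regions.index(tgt), regions.index(src)] = 1
        c = np.ones((5, int(d["n_regressors"])), dtype=int)
        return cls(
            variant=d["variant"],
            a_mask=a,
            c_mask=c,
            d_masks=tuple(tuple(t) for t in d["d_masks"]),
            regions=regions,
        )


def build_cmc_spec(variant: str, n_regressors: int = 8) -> CmcModelSpec:
    """Construct the mask set of one CMC variant.

    Parameters
    ----------
    variant:
        ``"direct"`` (first-order BG→PFC connection, no second-order terms)
        or ``"modulatory"`` (BG gates MTL→PFC and SENS→PFC bilinearly).
    n_regressors:
        Number of driving regressors K (default 8, the four-frequency
        sine/cosine boxcar set).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown CMC variant {variant!r}; expected one of {VARIANTS}")
    if n_regressors < 1:
        raise ValueError("n_regressors must be >= 1")
    regions = RegionSet()
    a = np.eye(5, dtype=int)
    for tgt, src in SHARED_EDGES:
        a[regions.index(tgt), regions.index(src)] = 1
    if variant == "direct":
        tgt, src = DIRECT_ONLY_EDGE
        a[regions.index(tgt), regions.index(src)] = 1
        d_masks: tuple = ()
    else:
        d_masks = MODULATORY_TRIPLES
    c = np.ones((5, n_regressors), dtype=int)
    return CmcModelSpec(variant=variant, a_mask=a, c_mask=c, d_masks=d_masks, regions=regions)


def count_free_parameters(spec: CmcModelSpec) -> dict[str, int]:
    """Parameter-count bookkeeping for one variant.

    Returns a dict with ``fixed`` (ones in the A mask, self-connections
    included), ``input`` (ones in the C mask), ``modulatory`` (number of
    second-order triples) and ``total``.  The two CMC variants differ by
    exactly one parameter: the modulatory variant trades the BG→PFC fixed
    entry for two second-order gains.
    """
    fixed = int(spec.a_mask.sum())
    inp = int(spec.c_mask.sum())
    mod = len(spec.d_masks)
    return {"fixed": fixed, "input": inp, "modulatory": mod, "total": fixed + inp + mod}
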