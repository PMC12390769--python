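"""Default excitatory/inhibitory receptor-subunit gene sets.

Excitatory = AMPA-type glutamate receptor subunits (GRIA1-4) plus NMDA
subunits (GRIN1, GRIN2A, GRIN2B, GRIN2C); inhibitory = GABA-A receptor
subunits (alpha 1-5, beta 1-3, gamma 1-3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

EXCITATORY_GENES: tuple[str, ...] = (
    "GRIA1", "GRIA2", "GRIA3", "GRIA4",
    "GRIN1", "GRIN2A", "GRIN2B", "GRIN2C",
)

INHIBITORY_GENES: tuple[str, ...] = (
    "GABRA1", "GABRA2", "GABRA3", "GABRA4", "GABRA5",
    "GABRB1", "GABRB2", "GABRB3",
    "GABRG1", "GABRG2", "GABRG3",
)


@dataclass(frozen=True)
class EIGeneSets:
    """Ordered excitatory and inhibitory gene symbol lists.

    The two sets must be disjoint and non-empty.
    """

    excitatory: tuple[str, ...] = EXCITATORY_GENES
    inhibitory: tuple[str, ...] = INHIBITORY_GENES

    def __post_init__(self) -> None:
        if not self.excitatory or not self.inhibitory:
            raise ValueError("gene sets must be non-empty")
        overlap = set(self.excitatory) & set(self.inhibitory)
        if overlap:
            raise ValueError(f"gene sets must be disjoint; shared: {sorted(overlap)}")
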