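"""Sample-aligned multi-omics data container.

An :class:`OmicsDataset` holds one matrix of samples x nodes together with a
layer label for every node.  Genotype nodes are exogenous (they are never
regressed on anything); methylation, expression, phenotype and disease nodes
are endogenous.  All estimators in this package consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Recognised layers, ordered from most upstream to most downstream.
LAYER_ORDER = ("genotype", "methylation", "expression", "phenotype", "disease")


@dataclass
class OmicsDataset:
    """Sample-aligned matrix of omics measurements with per-node layer labels.

    Parameters
    ----------
    data
        DataFrame of shape (samples, nodes); column names are node ids.
    layers
        Mapping node id -> layer, with layers drawn from :data:`LAYER_ORDER`.
    """

    data: pd.DataFrame
    layers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.layers]
        if missing:
            raise ValueError(f"nodes without a layer label: {missing[:5]}")
        bad = {v for v in self.layers.values()} - set(LAYER_ORDER)
        if bad:
            raise ValueError(f"unknown layers: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def nodes(self) -> list[str]:
        return list(self.data.columns)

    def layer_nodes(self, layer: str) -> list[str]:
        return [c for c in self.data.columns if self.layers[c] == layer]

    @property
    def genotype_nodes(self) -> list[str]:
        return self.layer_nodes("genotype")

    @property
    def endogenous_nodes(self) -> list[str]:
        return [c for c in self.data.columns if self.layers[c] != "genotype"]

    def values(self, columns) -> "pd.DataFrame":
        return self.data[list(columns)]
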