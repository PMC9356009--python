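"""In-memory containers shared across pipeline stages.

``ResponseTensor`` holds child x cytokine x stimulus concentrations in pg/mL
(NaN marks missing wells) plus per-child batch and viability metadata.  The
media-normalized representation is a pandas DataFrame indexed by child with a
(cytokine, stimulus) MultiIndex on columns, holding log2 fold inductions —
referred to throughout as the *fold matrix*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panels import CytokinePanel, StimulusPanel


@dataclass
class ResponseTensor:
    """Child x cytokine x stimulus concentration tensor with metadata.

    ``values[c, k, s]`` is a concentration in pg/mL or NaN when the well is
    missing.  All present concentrations are positive (censored wells hold
    half the batch LOD).
    """

    values: np.ndarray  # (n_children, n_cytokines, n_stimuli)
    children: list[str]
    batch: np.ndarray  # per child, in {1, 2}
    viability: np.ndarray  # per child, percentage in [0, 100]
    stimulus_panel: StimulusPanel
    cytokine_panel: CytokinePanel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_c = len(self.children)
        n_k = len(self.cytokine_panel.names)
        n_s = len(self.stimulus_panel.names)
        if self.values.shape != (n_c, n_k, n_s):
            raise ValueError(
                f"values shape {self.values.shape} != ({n_c}, {n_k}, {n_s})"
            )
        if len(self.batch) != n_c or len(self.viability) != n_c:
            raise ValueError("batch and viability must be defined for every child")
        present = self.values[~np.isnan(self.values)]
        if present.size and present.min() <= 0:
            raise ValueError("all present concentrations must be > 0")

    @property
    def cytokines(self) -> list[str]:
        return self.cytokine_panel.names

    @property
    def stimuli(self) -> list[str]:
        # stimulus axis follows Table-rank order
        return [e.name for e in self.stimulus_panel.by_rank()]

    @property
    def n_children(self) -> int:
        return len(self.children)

    def stimulus_index(self, name: str) -> int:
        return self.stimuli.index(name)

    def cytokine_index(self, name: str) -> int:
        return self.cytokines.index(name)

    def get(self, child: str, cytokine: str, stimulus: str) -> float:
        return float(
            self.values[
                self.children.index(child),
                self.cytokine_index(cytokine),
                self.stimulus_index(stimulus),
            ]
        )

    def log2_values(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.log2(self.values)

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def subset_children(self, keep: list[str]) -> "ResponseTensor":
        idx = [self.children.index(c) for c in keep]
        return replace(
            self,
            values=self.values[idx].copy(),
            children=list(keep),
            batch=self.batch[idx].copy(),
            viability=self.viability[idx].copy(),
        )

    def copy(self) -> "ResponseTensor":
        return replace(
            self,
            values=self.values.copy(),
            children=list(self.children),
            batch=self.batch.copy(),
            viability=self.viability.copy(),
            meta=dict(self.meta),
        )


def fold_columns(
    cytokines: list[str], stimuli: list[str], media: str
) -> pd.MultiIndex:
    """(cytokine, stimulus) column index of a fold matrix; media excluded."""
    pairs = [(k, s) for k in cytokines for s in stimuli if s != media]
    return pd.MultiIndex.from_tuples(pairs, names=["cytokine", "stimulus"])
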