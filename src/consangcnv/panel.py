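"""Sample-by-marker genotype panel bound to a genetic map."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd

MISSING = -1
HOM_REF = 0
HET = 1
HOM_ALT = 2


@dataclass
class GenotypePanel:
    """Genotype calls for samples x markers.

    ``markers`` has columns chrom, marker_id, cm, bp (sorted by chromosome
    then bp). ``genotypes`` is an int8 matrix (n_samples, n_markers) coded
    0 = hom ref, 1 = het, 2 = hom alt, -1 = missing.
    """

    samples: List[str]
    markers: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        required = {"chrom", "marker_id", "cm", "bp"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"marker table needs columns {sorted(required)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError as exc:
            raise KeyError(f"sample {sample} not in panel") from exc

    def sample_genotypes(self, sample: str) -> np.ndarray:
        return self.genotypes[self.sample_index(sample)]

    def marker_mask(self, chromosomes: Sequence[str]) -> np.ndarray:
        return self.markers["chrom"].isin(list(chromosomes)).to_numpy()

    def subset_samples(self, samples: Sequence[str]) -> "GenotypePanel":
        idx = [self.sample_index(s) for s in samples]
        return GenotypePanel(list(samples), self.markers, self.genotypes[idx])
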